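"""miRNA filtering, cis/trans annotation, methylation aggregation, assembly."""

import numpy as np
import pandas as pd
import pytest

from cnmir.errors import ValidationError
from cnmir.diffexp import DEResult
from cnmir.io_formats import ExpressionMatrix, Feature
from cnmir.regions import AberrationRegion
from cnmir import regulator as reg


def _rpm(rows, samples=None):
    df = pd.DataFrame(rows)
    df.columns = samples or [f"S{i}" for i in range(df.shape[1])]
    df.index = [f"miR-{i}" for i in range(df.shape[0])]
    return ExpressionMatrix(df, "rpm")


# ---------------------------------------------------------------------------
# miRNA expression filter

def test_filter_keeps_mirna_above_thresholds():
    # 0.02 RPM in 40% of 10 samples
    m = _rpm([[0.02] * 4 + [0.0] * 6])
    assert reg.filter_mirnas(m).row_ids == ["miR-0"]


def test_filter_drops_mirna_below_fraction():
    # 0.02 RPM in 29 of 100 samples
    m = _rpm([[0.02] * 29 + [0.0] * 71])
    assert reg.filter_mirnas(m).row_ids == []


def test_filter_drops_all_zero_mirna():
    m = _rpm([[0.0] * 10])
    assert reg.filter_mirnas(m).row_ids == []


def test_filter_boundary_is_inclusive():
    # exactly 0.01 RPM in exactly 30% of samples: kept (>= on both)
    m = _rpm([[0.01] * 3 + [0.0] * 7])
    assert reg.filter_mirnas(m).row_ids == ["miR-0"]


def test_filter_requires_rpm_matrix():
    df = pd.DataFrame([[1, 2]], index=["m"], columns=["a", "b"])
    with pytest.raises(ValidationError):
        reg.filter_mirnas(ExpressionMatrix(df, "raw_count"))


# ---------------------------------------------------------------------------
# cis/trans annotation

REGION = AberrationRegion("r1", "chr1", 1000, 2000, "amp")
FEATURES = [
    Feature("inside", "gene", "chr1", 1200, 1300),
    Feature("straddle", "gene", "chr1", 900, 1100),
    Feature("outside", "gene", "chr1", 5000, 6000),
    Feature("other_chrom", "gene", "chr2", 1200, 1300),
    Feature("miR-in", "mirna", "chr1", 1500, 1550),
    Feature("miR-out", "mirna", "chr3", 100, 150),
]


def _de(gene, is_de=True):
    return DEResult("r1", gene, 2.0 if is_de else 0.1, 1e-4, 1e-3 if is_de else 0.9,
                    is_de)


def test_cis_trans_partition():
    de = [_de("inside"), _de("straddle"), _de("outside"), _de("other_chrom")]
    ann = reg.annotate_cis_trans(REGION, de, FEATURES)
    assert ann.cis_genes == {"inside", "straddle"}  # any-overlap rule
    assert ann.trans_genes == {"outside", "other_chrom"}
    assert ann.cis_genes & ann.trans_genes == set()


def test_non_de_genes_excluded_but_mirnas_need_no_de():
    de = [_de("inside", is_de=False)]
    ann = reg.annotate_cis_trans(REGION, de, FEATURES)
    assert ann.cis_genes == set() and ann.trans_genes == set()
    assert ann.cis_mirnas == {"miR-in"}  # no DE requirement for miRNAs


def test_mirna_filter_restricts_cis_mirnas():
    ann = reg.annotate_cis_trans(REGION, [], FEATURES, filtered_mirna_ids=set())
    assert ann.cis_mirnas == set()


def test_unannotated_de_gene_warned_and_excluded(caplog):
    ann = reg.annotate_cis_trans(REGION, [_de("ghost")], FEATURES)
    assert "ghost" not in ann.cis_genes | ann.trans_genes


# ---------------------------------------------------------------------------
# methylation aggregation

def _beta_probes(vals, probes, samples=("A", "B")):
    df = pd.DataFrame(vals, index=probes, columns=list(samples))
    return ExpressionMatrix(df, "beta")


GENE_PLUS = Feature("gP", "gene", "chr1", 10_000, 20_000, "+")
GENE_MINUS = Feature("gM", "gene", "chr1", 50_000, 60_000, "-")


def test_450k_promoter_mean():
    # two probes inside the promoter window (TSS=10000, -2000..+500)
    beta = _beta_probes([[0.2, 0.2], [0.4, 0.4]], ["p1", "p2"])
    manifest = pd.DataFrame({"probe_id": ["p1", "p2"],
                             "gene_id": ["gP", "gP"],
                             "position": [9_000, 10_400]})
    out = reg.gene_level_methylation(beta, manifest, [GENE_PLUS], "p450k")
    assert out.df.loc["gP", "A"] == pytest.approx(0.3)


def test_450k_distant_probe_gives_missing():
    beta = _beta_probes([[0.5, 0.5]], ["p1"])
    manifest = pd.DataFrame({"probe_id": ["p1"], "gene_id": ["gP"],
                             "position": [30_000]})  # 10 kb downstream of TSS
    out = reg.gene_level_methylation(beta, manifest, [GENE_PLUS], "p450k")
    assert np.isnan(out.df.loc["gP", "A"])


def test_450k_minus_strand_window_is_strand_aware():
    """For a minus-strand gene the promoter extends beyond the interval end."""
    beta = _beta_probes([[0.6, 0.6]], ["p1"])
    # TSS of gM is at 59_999; upstream (greater coordinates) 2 kb
    manifest = pd.DataFrame({"probe_id": ["p1"], "gene_id": ["gM"],
                             "position": [61_000]})
    out = reg.gene_level_methylation(beta, manifest, [GENE_MINUS], "p450k")
    assert out.df.loc["gM", "A"] == pytest.approx(0.6)
    # the same probe is not a promoter probe for a plus-strand reading
    manifest2 = pd.DataFrame({"probe_id": ["p1"], "gene_id": ["gP"],
                              "position": [61_000]})
    out2 = reg.gene_level_methylation(beta, manifest2, [GENE_PLUS], "p450k")
    assert np.isnan(out2.df.loc["gP", "A"])


def test_27k_uses_all_probes():
    beta = _beta_probes([[0.1, 0.1], [0.2, 0.2], [0.9, 0.9]], ["p1", "p2", "p3"])
    manifest = pd.DataFrame({"probe_id": ["p1", "p2", "p3"],
                             "gene_id": ["gP"] * 3,
                             "position": [10_100, 15_000, 19_999]})
    out = reg.gene_level_methylation(beta, manifest, [GENE_PLUS], "p27k")
    assert out.df.loc["gP", "A"] == pytest.approx(0.4)


def test_manifest_must_cover_all_probes():
    beta = _beta_probes([[0.1, 0.1]], ["p1"])
    manifest = pd.DataFrame({"probe_id": ["other"], "gene_id": ["gP"],
                             "position": [10_000]})
    with pytest.raises(ValidationError, match="cover"):
        reg.gene_level_methylation(beta, manifest, [GENE_PLUS], "p450k")


# ---------------------------------------------------------------------------
# predictor assembly

def _assembly_inputs(n=30):
    samples = [f"S{i}" for i in range(n)]
    rng = np.random.default_rng(0)
    genes = ["cisA", "transX", "TF1", "TF2"]
    counts = ExpressionMatrix(
        pd.DataFrame(rng.integers(10, 1000, size=(len(genes), n)),
                     index=genes, columns=samples), "raw_count")
    mirna = ExpressionMatrix(
        pd.DataFrame(rng.uniform(1, 50, size=(2, n)),
                     index=["miR-1", "miR-2"], columns=samples), "rpm")
    cn = pd.DataFrame(rng.normal(0, 0.1, size=(len(genes), n)),
                      index=genes, columns=samples)
    meth = ExpressionMatrix(
        pd.DataFrame(rng.uniform(0.1, 0.9, size=(len(genes), n)),
                     index=genes, columns=samples), "beta")
    tf = pd.DataFrame({"tf_id": ["TF1", "TF2"], "target_id": ["transX", "transX"],
                       "confidence": ["A", "C"]})
    return samples, counts, mirna, cn, meth, tf


def test_assembly_structure_and_classes():
    samples, counts, mirna, cn, meth, tf = _assembly_inputs()
    ann = reg.RegionAnnotation("r1", cis_genes={"cisA"}, trans_genes={"transX"},
                               cis_mirnas={"miR-1", "miR-2"})
    (ps,) = reg.assemble_predictors(ann, counts, mirna, cn, meth, tf)
    assert ps.trans_gene == "transX"
    assert set(ps.columns_of_class("cis_mirna")) == {"miR-1", "miR-2"}
    assert ps.columns_of_class("cn") == ["transX__cn"]
    assert ps.columns_of_class("methylation") == ["transX__meth"]
    assert set(ps.columns_of_class("tf")) == {"TF1", "TF2"}
    assert list(ps.response.index) == list(ps.predictors.index)


def test_assembly_zero_cis_mirnas_emits_nothing():
    samples, counts, mirna, cn, meth, tf = _assembly_inputs()
    ann = reg.RegionAnnotation("r1", cis_genes={"cisA"}, trans_genes={"transX"},
                               cis_mirnas=set())
    assert reg.assemble_predictors(ann, counts, mirna, cn, meth, tf) == []


def test_assembly_tf_confidence_filter():
    samples, counts, mirna, cn, meth, tf = _assembly_inputs()
    ann = reg.RegionAnnotation("r1", cis_genes=set(), trans_genes={"transX"},
                               cis_mirnas={"miR-1"})
    (ps,) = reg.assemble_predictors(ann, counts, mirna, cn, meth, tf,
                                    tf_confidence_keep={"A", "B"})
    assert ps.columns_of_class("tf") == ["TF1"]  # grade C dropped


def test_assembly_dedups_cis_gene_that_is_also_tf():
    samples, counts, mirna, cn, meth, tf = _assembly_inputs()
    ann = reg.RegionAnnotation("r1", cis_genes={"TF1"}, trans_genes={"transX"},
                               cis_mirnas={"miR-1"})
    (ps,) = reg.assemble_predictors(ann, counts, mirna, cn, meth, tf)
    assert ps.column_class["TF1"] == "cis_gene"
    assert list(ps.predictors.columns).count("TF1") == 1


def test_assembly_missing_methylation_column_omitted():
    samples, counts, mirna, cn, meth, tf = _assembly_inputs()
    df = meth.df.copy()
    df.loc["transX"] = np.nan
    meth_missing = ExpressionMatrix(df, "beta")
    ann = reg.RegionAnnotation("r1", cis_genes=set(), trans_genes={"transX"},
                               cis_mirnas={"miR-1"})
    (ps,) = reg.assemble_predictors(ann, counts, mirna, cn, meth_missing, tf)
    assert ps.columns_of_class("methylation") == []


def test_predictor_set_drops_constant_columns():
    samples = [f"S{i}" for i in range(10)]
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"miR-1": rng.normal(size=10), "flat": np.ones(10)},
                      index=samples)
    ps = reg.PredictorSet("r1", "g", pd.Series(rng.normal(size=10), index=samples),
                          df, {"miR-1": "cis_mirna", "flat": "cn"})
    assert list(ps.predictors.columns) == ["miR-1"]


def test_predictor_set_requires_cis_mirna():
    samples = [f"S{i}" for i in range(10)]
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"cnX": rng.normal(size=10)}, index=samples)
    with pytest.raises(ValidationError, match="miRNA"):
        reg.PredictorSet("r1", "g", pd.Series(rng.normal(size=10), index=samples),
                         df, {"cnX": "cn"})


def test_predictor_set_round_trip(tmp_path):
    samples, counts, mirna, cn, meth, tf = _assembly_inputs()
    ann = reg.RegionAnnotation("r1", cis_genes={"cisA"}, trans_genes={"transX"},
                               cis_mirnas={"miR-1"})
    (ps,) = reg.assemble_predictors(ann, counts, mirna, cn, meth, tf)
    p = tmp_path / "ps.tsv"
    reg.write_predictor_set(p, ps)
    back = reg.read_predictor_set(p)
    assert back.region_id == "r1" and back.trans_gene == "transX"
    assert back.column_class == ps.column_class
    assert back.predictors.to_numpy() == pytest.approx(ps.predictors.to_numpy(),
                                                       rel=1e-9)


def test_cis_rule_robust_for_planted_edges(mini_cohort, mini_segs):
    """Any-overlap vs full-containment does not change planted eligibility."""
    from cnmir.regions import RegionCallerConfig, call_regions, assign_status
    regs = call_regions(mini_segs, RegionCallerConfig(seed=3))
    feats = {f.feature_id: f for f in mini_cohort.features}
    for m, g, _ in mini_cohort.truth.true_edges:
        fm, fg = feats[m], feats[g]
        for r in regs:
            any_overlap_m = fm.chrom == r.chrom and fm.start < r.end and r.start < fm.end
            contained_m = fm.chrom == r.chrom and fm.start >= r.start and fm.end <= r.end
            assert any_overlap_m == contained_m  # planted features are unambiguous
            any_overlap_g = fg.chrom == r.chrom and fg.start < r.end and r.start < fg.end
            contained_g = fg.chrom == r.chrom and fg.start >= r.start and fg.end <= r.end
            assert any_overlap_g == contained_g
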