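"""Synthetic multi-omics cohort with planted regulatory structure.

The generator emulates a tumor cohort as seen by the pipeline: segmented
copy-number profiles with planted recurrent amplifications/deletions, a
negative-binomial gene count matrix with copy-number dosage effects, a
log-normal miRNA RPM matrix, gene-level methylation beta values, a
TF-target table, and the ground truth needed to score recovery.

Planted causal structure
------------------------
* Each planted region is carried (segment mean exactly ``amp_log2`` or
  ``del_log2``) by exactly ``round(region_recurrence * n_samples)`` samples;
  all other segments have log2 ratio ~ N(0, 0.03).
* cis features (genes and miRNAs inside a region) gain
  ``dosage_effect * log2_ratio`` on their log2 expression scale.
* Each true edge (miRNA m -> trans gene g) adds
  ``-edge_effect * standardize(log2 RPM of m)`` to g's log2 mean
  (negative sign: canonical miRNA-mediated repression).
* Decoy trans genes respond to region carrier status directly (a
  confounder, not a miRNA effect) and to their own promoter methylation;
  they exist so that specificity — not just sensitivity — of the LASSO
  step is measurable.
* TF targets gain ``tf_effect * standardize(TF log2 expression)``.

The default configuration is the desk fixture used throughout the test
suite: 150 samples, 300 genes, 30 miRNAs, 3 regions (2 amp / 1 del),
recurrence 0.6, 5 true edges with standardized effect 0.9, NB dispersion
0.1.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from . import io_formats
from .io_formats import ExpressionMatrix, Feature, Segment
from .regions import feature_centric_cn_matrix

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "GroundTruth", "Cohort", "generate_cohort", "write_cohort",
           "read_cohort", "config_hash"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    The first block mirrors the quantities a study design would state
    (cohort size, number of planted lesions, effect sizes); the second
    block are generator internals with realistic defaults (genome layout,
    per-role feature counts, residual noise scales).
    """

    n_samples: int = 150
    n_genes: int = 300
    n_mirnas: int = 30
    n_regions: int = 3
    region_recurrence: float = 0.6
    amp_log2: float = 0.8
    del_log2: float = -0.8
    n_true_edges: int = 5
    edge_effect: float = 0.9
    dosage_effect: float = 0.5
    methyl_effect: float = -5.0
    nb_dispersion: float = 0.1
    mean_library_size: float = 5e6
    seed: int = 0

    # genome / layout internals
    n_chroms: int = 3
    chrom_length: int = 30_000_000
    region_length: int = 2_000_000
    cis_genes_per_region: int = 4
    cis_mirnas_per_region: int = 3
    decoys_per_region: int = 4
    n_tfs: int = 5
    tf_targets_per_tf: int = 6
    tf_effect: float = 0.5
    decoy_beta_shift: float = 0.25  # carrier-associated promoter (de)methylation
    cis_gene_dosage_slope: float = 1.8  # dosage-sensitive driver genes
    mirna_noise_sd: float = 0.2
    baseline_noise_sd: float = 0.03
    n_low_expression_mirnas: int = 2

    def __post_init__(self) -> None:
        if self.n_true_edges > self.n_mirnas * self.n_genes:
            raise ConfigError("n_true_edges exceeds n_mirnas * n_genes")
        if round(self.region_recurrence * self.n_samples) < 2:
            raise ConfigError("region_recurrence * n_samples must be >= 2")
        if not (self.amp_log2 > 0.1 and self.del_log2 < -0.1):
            raise ConfigError("need amp_log2 > 0.1 and del_log2 < -0.1 so carriers "
                              "pass the aberration status rule")
        if not 0 < self.region_recurrence <= 1:
            raise ConfigError("region_recurrence must be in (0, 1]")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if self.n_true_edges > self.n_regions * self.cis_mirnas_per_region:
            raise ConfigError("not enough cis miRNAs to host all true edges")
        slots = self.n_chroms * max(
            0, (self.chrom_length - 10_000_000) // (3 * self.region_length)
        )
        if self.n_regions > slots:
            raise ConfigError("infeasible placement: regions do not fit the genome")
        min_genes = self.n_regions * (self.cis_genes_per_region + self.decoys_per_region) \
            + self.n_true_edges + self.n_tfs
        if self.n_genes < min_genes + 10:
            raise ConfigError(f"n_genes must be >= {min_genes + 10} for this layout")
        if self.n_mirnas < self.n_regions * self.cis_mirnas_per_region \
                + self.n_low_expression_mirnas:
            raise ConfigError("n_mirnas too small for layout")


@dataclass
class PlantedRegion:
    region_id: str
    chrom: str
    start: int
    end: int
    direction: str
    carriers: frozenset[str]


@dataclass
class GroundTruth:
    """What was planted: edges, regions, carriers, expected DE genes."""

    true_edges: set[tuple[str, str, str]]  # (mirna_id, gene_id, sign)
    true_regions: list[PlantedRegion]
    carrier_samples: dict[str, frozenset[str]]
    true_de_genes: dict[str, frozenset[str]]

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(m, g) for m, g, _ in self.true_edges}


@dataclass
class Cohort:
    config: SimConfig
    segments: list[Segment]
    features: list[Feature]
    gene_counts: ExpressionMatrix
    mirna_rpm: ExpressionMatrix
    methylation: ExpressionMatrix
    tf_table: pd.DataFrame
    truth: GroundTruth


def config_hash(cfg: SimConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _place_regions(cfg: SimConfig) -> list[tuple[str, int, int, str]]:
    """Deterministic region slots: round-robin over chromosomes, spaced by
    3x region length starting 10 Mb in; every third region is a deletion."""
    out = []
    for r in range(cfg.n_regions):
        chrom = f"chr{(r % cfg.n_chroms) + 1}"
        start = 10_000_000 + (r // cfg.n_chroms) * 3 * cfg.region_length
        end = start + cfg.region_length
        if end > cfg.chrom_length:
            raise ConfigError("infeasible placement: region exceeds chromosome")
        direction = "del" if (r + 1) % 3 == 0 else "amp"
        out.append((chrom, start, end, direction))
    return out


def _scatter_intervals(rng, n, length, cfg, forbidden):
    """Place n features of given length uniformly, avoiding forbidden spans."""
    out = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > 100 * n + 1000:
            raise ConfigError("infeasible placement: could not scatter features")
        chrom = f"chr{rng.integers(1, cfg.n_chroms + 1)}"
        start = int(rng.integers(0, cfg.chrom_length - length))
        end = start + length
        if any(c == chrom and start < fe and fs < end for c, fs, fe in forbidden):
            continue
        out.append((chrom, start, end))
    return out


def generate_cohort(cfg: SimConfig = SimConfig()) -> Cohort:
    """Generate the full synthetic cohort; deterministic given cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    samples = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]

    region_spans = _place_regions(cfg)
    n_carriers = round(cfg.region_recurrence * cfg.n_samples)
    planted: list[PlantedRegion] = []
    for i, (chrom, start, end, direction) in enumerate(region_spans):
        carriers = frozenset(
            str(s) for s in rng.choice(samples, size=n_carriers, replace=False)
        )
        planted.append(PlantedRegion(f"r{i + 1}", chrom, start, end, direction, carriers))

    segments = _make_segments(cfg, rng, samples, planted)
    features, roles = _make_features(cfg, rng, planted)
    cn = feature_centric_cn_matrix(features, segments)  # features x samples
    cn = cn.loc[:, samples]

    mirna_ids = [f.feature_id for f in features if f.kind == "mirna"]
    gene_ids = [f.feature_id for f in features if f.kind == "gene"]

    # miRNA expression: log-normal RPM with cis dosage effect
    mirna_base = rng.uniform(2.0, 8.0, size=len(mirna_ids))
    for i, m in enumerate(mirna_ids):
        if m in roles["low_mirnas"]:
            mirna_base[i] = np.log2(1e-3)
    mirna_log2 = (
        mirna_base[:, None]
        + cfg.dosage_effect * cn.loc[mirna_ids].to_numpy()
        + rng.normal(0, cfg.mirna_noise_sd, size=(len(mirna_ids), cfg.n_samples))
    )
    mirna_rpm = ExpressionMatrix(
        pd.DataFrame(2.0 ** mirna_log2, index=mirna_ids, columns=samples), "rpm"
    )

    # methylation betas (gene level); decoy rows are rewritten below so that
    # region status acts on decoy expression through measured methylation
    a = rng.uniform(1.0, 4.0, size=len(gene_ids))
    b = rng.uniform(1.0, 4.0, size=len(gene_ids))
    beta = rng.beta(a[:, None], b[:, None], size=(len(gene_ids), cfg.n_samples))

    # gene log2 means
    gene_base = rng.uniform(5.0, 11.0, size=len(gene_ids))
    mu = gene_base[:, None] + cfg.dosage_effect * cn.loc[gene_ids].to_numpy()
    gidx = {g: i for i, g in enumerate(gene_ids)}
    for pr in planted:
        for g in roles["cis_genes"][pr.region_id]:
            mu[gidx[g]] += (cfg.cis_gene_dosage_slope - cfg.dosage_effect) \
                * cn.loc[g].to_numpy()

    # TF latent expression drives its targets
    tf_latent = {}
    for tf in roles["tfs"]:
        tf_latent[tf] = mu[gidx[tf]] + rng.normal(0, 0.3, size=cfg.n_samples)
        mu[gidx[tf]] = tf_latent[tf]
    tf_rows = []
    grades = np.array(["A", "B", "C"])
    for tf, targets in roles["tf_targets"].items():
        z = _standardize(tf_latent[tf])
        for t in targets:
            mu[gidx[t]] += cfg.tf_effect * z
            tf_rows.append((tf, t, grades[rng.integers(0, 3)]))
    tf_table = pd.DataFrame(tf_rows, columns=["tf_id", "target_id", "confidence"])

    # decoys: region status shifts the decoy's own promoter methylation
    # (hyper- in carriers for even indices, hypo- for odd), and expression
    # responds to that methylation — a measured confounder, not a miRNA
    carrier_ind = {
        pr.region_id: np.array([1.0 if s in pr.carriers else 0.0 for s in samples])
        for pr in planted
    }
    for pr in planted:
        z = carrier_ind[pr.region_id]
        for j, g in enumerate(roles["decoys"][pr.region_id]):
            hyper = j % 2 == 0
            b0 = 0.25 if hyper else 0.25 + cfg.decoy_beta_shift
            shift = cfg.decoy_beta_shift if hyper else -cfg.decoy_beta_shift
            noise = (rng.beta(5.0, 5.0, size=cfg.n_samples) - 0.5) * 1.2
            bvec = np.clip(b0 + shift * z + noise, 0.02, 0.98)
            beta[gidx[g]] = bvec
            mu[gidx[g]] += cfg.methyl_effect * (bvec - bvec.mean())
    methylation = ExpressionMatrix(
        pd.DataFrame(beta, index=gene_ids, columns=samples), "beta"
    )

    # true edges: trans gene repressed by its cis miRNA
    true_edges: set[tuple[str, str, str]] = set()
    edge_region: dict[tuple[str, str], str] = {}
    for m, g, region_id in roles["edges"]:
        z = _standardize(np.log2(mirna_rpm.df.loc[m].to_numpy()))
        mu[gidx[g]] -= cfg.edge_effect * z
        true_edges.add((m, g, "negative"))
        edge_region[(m, g)] = region_id

    # counts: NB around library-scaled means
    lib = np.exp(rng.normal(0, 0.15, size=cfg.n_samples))
    mean = (2.0 ** mu) * lib[None, :]
    mean *= cfg.mean_library_size / mean.sum(axis=0).mean()
    if cfg.nb_dispersion > 0:
        r = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mean))
    else:
        counts = rng.poisson(mean)
    gene_counts = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=samples), "raw_count"
    )

    true_de = {}
    for pr in planted:
        targets = {g for (m, g), rid in edge_region.items() if rid == pr.region_id}
        true_de[pr.region_id] = frozenset(
            set(roles["cis_genes"][pr.region_id])
            | set(roles["decoys"][pr.region_id])
            | targets
        )
    truth = GroundTruth(
        true_edges=true_edges,
        true_regions=planted,
        carrier_samples={pr.region_id: pr.carriers for pr in planted},
        true_de_genes=true_de,
    )
    return Cohort(cfg, segments, features, gene_counts, mirna_rpm, methylation,
                  tf_table, truth)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _make_segments(cfg, rng, samples, planted) -> list[Segment]:
    by_chrom: dict[str, list[PlantedRegion]] = {}
    for pr in planted:
        by_chrom.setdefault(pr.chrom, []).append(pr)
    segments: list[Segment] = []
    for sample in samples:
        for c in range(1, cfg.n_chroms + 1):
            chrom = f"chr{c}"
            cuts = [0, cfg.chrom_length]
            spans = sorted(by_chrom.get(chrom, []), key=lambda p: p.start)
            for pr in spans:
                cuts.extend([pr.start, pr.end])
            cuts = sorted(set(cuts))
            region_at = {(pr.start, pr.end): pr for pr in spans}
            for lo, hi in zip(cuts, cuts[1:]):
                pr = region_at.get((lo, hi))
                if pr is not None and sample in pr.carriers:
                    log2 = cfg.amp_log2 if pr.direction == "amp" else cfg.del_log2
                else:
                    log2 = rng.normal(0, cfg.baseline_noise_sd)
                segments.append(Segment(sample, chrom, lo, hi, float(log2)))
    return segments


def _make_features(cfg, rng, planted):
    """Lay out genes and miRNAs; returns (features, role bookkeeping)."""
    features: list[Feature] = []
    forbidden = [(pr.chrom, pr.start, pr.end) for pr in planted]
    roles = {
        "cis_genes": {}, "decoys": {}, "tfs": [], "tf_targets": {},
        "cis_mirnas": {}, "edges": [], "low_mirnas": set(),
    }
    strand_cycle = ["+", "-"]
    gene_len, mirna_len = 10_000, 200
    g_counter = m_counter = 0

    def add_gene(chrom, start, end, strand="+"):
        nonlocal g_counter
        g_counter += 1
        gid = f"G{g_counter:04d}"
        features.append(Feature(gid, "gene", chrom, start, end, strand))
        return gid

    def add_mirna(chrom, start, end):
        nonlocal m_counter
        m_counter += 1
        mid = f"miR-{m_counter:03d}"
        features.append(Feature(mid, "mirna", chrom, start, end, "+"))
        return mid

    # cis genes and cis miRNAs inside each region, evenly spaced
    for pr in planted:
        n_inside = cfg.cis_genes_per_region + cfg.cis_mirnas_per_region
        step = (pr.end - pr.start) // (n_inside + 1)
        pos = pr.start + step
        cis_g, cis_m = [], []
        for i in range(cfg.cis_genes_per_region):
            cis_g.append(add_gene(pr.chrom, pos, pos + gene_len, strand_cycle[i % 2]))
            pos += step
        for _ in range(cfg.cis_mirnas_per_region):
            cis_m.append(add_mirna(pr.chrom, pos, pos + mirna_len))
            pos += step
        roles["cis_genes"][pr.region_id] = cis_g
        roles["cis_mirnas"][pr.region_id] = cis_m

    # true-edge target genes (outside all regions), round-robin over regions
    target_spots = _scatter_intervals(rng, cfg.n_true_edges, gene_len, cfg, forbidden)
    used_mirnas: dict[str, int] = {}
    for e, (chrom, start, end) in enumerate(target_spots):
        pr = planted[e % len(planted)]
        k = used_mirnas.get(pr.region_id, 0) % cfg.cis_mirnas_per_region
        used_mirnas[pr.region_id] = k + 1
        mirna = roles["cis_mirnas"][pr.region_id][k]
        gid = add_gene(chrom, start, end)
        roles["edges"].append((mirna, gid, pr.region_id))

    # decoy trans genes per region
    n_decoys = cfg.n_regions * cfg.decoys_per_region
    for i, (chrom, start, end) in enumerate(
        _scatter_intervals(rng, n_decoys, gene_len, cfg, forbidden)
    ):
        pr = planted[i // cfg.decoys_per_region]
        roles["decoys"].setdefault(pr.region_id, []).append(
            add_gene(chrom, start, end, strand_cycle[i % 2])
        )

    # TFs
    for chrom, start, end in _scatter_intervals(rng, cfg.n_tfs, gene_len, cfg, forbidden):
        roles["tfs"].append(add_gene(chrom, start, end))

    # null genes fill the remainder
    n_null = cfg.n_genes - g_counter
    null_ids = [
        add_gene(chrom, start, end, strand_cycle[i % 2])
        for i, (chrom, start, end) in enumerate(
            _scatter_intervals(rng, n_null, gene_len, cfg, forbidden)
        )
    ]

    # TF targets drawn from null genes (keeps roles disjoint)
    pool = list(null_ids)
    for tf in roles["tfs"]:
        take = min(cfg.tf_targets_per_tf, len(pool))
        picked = [pool[j] for j in rng.choice(len(pool), size=take, replace=False)]
        roles["tf_targets"][tf] = picked

    # remaining miRNAs outside regions; the last few nearly silent
    n_extra = cfg.n_mirnas - m_counter
    for i, (chrom, start, end) in enumerate(
        _scatter_intervals(rng, n_extra, mirna_len, cfg, forbidden)
    ):
        mid = add_mirna(chrom, start, end)
        if i >= n_extra - cfg.n_low_expression_mirnas:
            roles["low_mirnas"].add(mid)
    return features, roles


# ---------------------------------------------------------------------------
# persistence

_FILES = {
    "segments": "segments.seg",
    "features": "features.bed",
    "gene_counts": "gene_counts.tsv",
    "mirna_rpm": "mirna_rpm.tsv",
    "methylation": "methylation.tsv",
    "tf_table": "tf_table.tsv",
    "true_edges": "truth_edges.tsv",
    "true_regions": "truth_regions.tsv",
    "carriers": "truth_carriers.tsv",
    "true_de_genes": "truth_de_genes.tsv",
}


def write_cohort(outdir, cohort: Cohort, force: bool = False) -> Path:
    """Write every table via the io_formats writers; returns manifest path.

    Refuses to overwrite an existing cohort (manifest present) unless
    ``force`` is set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not force:
        raise ValidationError(f"{manifest_path} exists; pass force=True to overwrite")
    ctx = f"config={config_hash(cohort.config)}"
    io_formats.write_seg(outdir / _FILES["segments"], cohort.segments, context=ctx)
    io_formats.write_features(outdir / _FILES["features"], cohort.features, context=ctx)
    io_formats.write_matrix(outdir / _FILES["gene_counts"], cohort.gene_counts, context=ctx)
    io_formats.write_matrix(outdir / _FILES["mirna_rpm"], cohort.mirna_rpm, context=ctx)
    io_formats.write_matrix(outdir / _FILES["methylation"], cohort.methylation, context=ctx)
    io_formats.write_tf_table(outdir / _FILES["tf_table"], cohort.tf_table, context=ctx)

    truth = cohort.truth
    with open(outdir / _FILES["true_edges"], "w") as fh:
        fh.write("mirna_id\tgene_id\tsign\n")
        for m, g, sign in sorted(truth.true_edges):
            fh.write(f"{m}\t{g}\t{sign}\n")
    with open(outdir / _FILES["true_regions"], "w") as fh:
        fh.write("region_id\tchrom\tstart\tend\tdirection\n")
        for pr in truth.true_regions:
            fh.write(f"{pr.region_id}\t{pr.chrom}\t{pr.start}\t{pr.end}\t{pr.direction}\n")
    with open(outdir / _FILES["carriers"], "w") as fh:
        fh.write("region_id\tsample_id\n")
        for rid in sorted(truth.carrier_samples):
            for s in sorted(truth.carrier_samples[rid]):
                fh.write(f"{rid}\t{s}\n")
    with open(outdir / _FILES["true_de_genes"], "w") as fh:
        fh.write("region_id\tgene_id\n")
        for rid in sorted(truth.true_de_genes):
            for g in sorted(truth.true_de_genes[rid]):
                fh.write(f"{rid}\t{g}\n")

    manifest = {
        "files": sorted(_FILES.values()),
        "seed": cohort.config.seed,
        "config_hash": config_hash(cohort.config),
        "config": dataclasses.asdict(cohort.config),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


def read_cohort(outdir) -> Cohort:
    """Round-trip loader for a written cohort directory."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    cfg = SimConfig(**manifest["config"])
    segments = io_formats.read_seg(outdir / _FILES["segments"],
                                   io_formats.Dialect.one_based_inclusive)
    features = io_formats.read_features(outdir / _FILES["features"], format="bed")
    gene_counts = io_formats.read_matrix(outdir / _FILES["gene_counts"], "raw_count")
    mirna_rpm = io_formats.read_matrix(outdir / _FILES["mirna_rpm"], "rpm")
    methylation = io_formats.read_matrix(outdir / _FILES["methylation"], "beta")
    tf_table = io_formats.read_tf_table(outdir / _FILES["tf_table"])

    edges_df = pd.read_csv(outdir / _FILES["true_edges"], sep="\t")
    regions_df = pd.read_csv(outdir / _FILES["true_regions"], sep="\t")
    carriers_df = pd.read_csv(outdir / _FILES["carriers"], sep="\t")
    de_df = pd.read_csv(outdir / _FILES["true_de_genes"], sep="\t")
    carrier_samples = {
        rid: frozenset(sub["sample_id"]) for rid, sub in carriers_df.groupby("region_id")
    }
    planted = [
        PlantedRegion(r.region_id, r.chrom, int(r.start), int(r.end), r.direction,
                      carrier_samples.get(r.region_id, frozenset()))
        for r in regions_df.itertuples()
    ]
    truth = GroundTruth(
        true_edges={(r.mirna_id, r.gene_id, r.sign) for r in edges_df.itertuples()},
        true_regions=planted,
        carrier_samples=carrier_samples,
        true_de_genes={
            rid: frozenset(sub["gene_id"]) for rid, sub in de_df.groupby("region_id")
        },
    )
    return Cohort(cfg, segments, features, gene_counts, mirna_rpm, methylation,
                  tf_table, truth)
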