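"""Predictor assembly: cis/trans annotation and per-trans-gene design matrices.

For each aberration region, DE genes overlapping the region interval (by
any overlap, >= 1 bp) are cis; the rest are trans. cis miRNAs are *all*
expression-filtered miRNAs overlapping the region — no DE requirement,
because miRNA counts per region are low and a DE filter would cost
sensitivity. Each eligible trans gene (>= 1 cis miRNA available) gets a
design matrix whose columns are the region's cis gene expressions, the cis
miRNA expressions, the trans gene's own gene-centric copy number, its own
promoter methylation (when available), and the expression of TFs known to
target it. Expression predictors and the response use log2(x+1) of
normalized values; copy number and methylation stay on their native
scales. Standardization happens downstream in the LASSO step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .diffexp import DEResult
from .io_formats import ExpressionMatrix, Feature
from .regions import AberrationRegion

logger = logging.getLogger(__name__)

__all__ = ["RegionAnnotation", "PredictorSet", "filter_mirnas", "annotate_cis_trans",
           "gene_level_methylation", "assemble_predictors", "normalized_log2",
           "write_predictor_set", "read_predictor_set"]

MIN_RPM = 0.01
MIN_FRACTION = 0.30


@dataclass
class RegionAnnotation:
    region_id: str
    cis_genes: set[str] = field(default_factory=set)
    trans_genes: set[str] = field(default_factory=set)
    cis_mirnas: set[str] = field(default_factory=set)


@dataclass
class PredictorSet:
    """One trans gene's response vector and class-labeled design matrix.

    ``predictors`` rows are samples (aligned with ``response``); columns are
    named predictors with classes in {cis_gene, cis_mirna, cn, methylation,
    tf}. Constant columns are dropped at construction (logged) — they carry
    no information and break standardization.
    """

    region_id: str
    trans_gene: str
    response: pd.Series
    predictors: pd.DataFrame
    column_class: dict[str, str]

    def __post_init__(self) -> None:
        if list(self.response.index) != list(self.predictors.index):
            raise ValidationError(
                f"{self.trans_gene}: response and predictor sample order differ"
            )
        const = [c for c in self.predictors.columns
                 if np.ptp(self.predictors[c].to_numpy()) == 0]
        if const:
            logger.info("%s/%s: dropping constant predictor columns %s",
                        self.region_id, self.trans_gene, const)
            self.predictors = self.predictors.drop(columns=const)
            for c in const:
                self.column_class.pop(c, None)
        classes = set(self.column_class.values())
        if "cis_mirna" not in classes:
            raise ValidationError(
                f"{self.trans_gene}: a predictor set needs >= 1 cis miRNA column"
            )

    def columns_of_class(self, cls: str) -> list[str]:
        return [c for c, k in self.column_class.items() if k == cls]


def filter_mirnas(
    mirna_rpm: ExpressionMatrix,
    min_rpm: float = MIN_RPM,
    min_fraction: float = MIN_FRACTION,
) -> ExpressionMatrix:
    """Keep miRNAs with RPM >= min_rpm in >= min_fraction of samples."""
    if mirna_rpm.value_kind != "rpm":
        raise ValidationError("filter_mirnas expects an RPM matrix")
    frac = (mirna_rpm.df >= min_rpm).mean(axis=1)
    kept = mirna_rpm.df.loc[frac >= min_fraction]
    if kept.empty:
        logger.warning("miRNA expression filter removed every miRNA")
    return ExpressionMatrix(kept, "rpm")


def _overlaps(f: Feature, region: AberrationRegion) -> bool:
    return f.chrom == region.chrom and f.start < region.end and region.start < f.end


def annotate_cis_trans(
    region: AberrationRegion,
    de_results: list[DEResult],
    features: list[Feature],
    filtered_mirna_ids: set[str] | None = None,
) -> RegionAnnotation:
    """Partition a region's DE genes into cis/trans; collect cis miRNAs.

    ``filtered_mirna_ids`` restricts cis miRNAs to the expression-filtered
    set (None = all annotated miRNAs). DE genes absent from the annotation
    are excluded with a warning.
    """
    by_id = {f.feature_id: f for f in features if f.kind == "gene"}
    ann = RegionAnnotation(region_id=region.region_id)
    for r in de_results:
        if r.region_id != region.region_id or not r.is_de:
            continue
        f = by_id.get(r.gene_id)
        if f is None:
            logger.warning("DE gene %s missing from feature annotation; excluded",
                           r.gene_id)
            continue
        (ann.cis_genes if _overlaps(f, region) else ann.trans_genes).add(r.gene_id)
    for f in features:
        if f.kind != "mirna" or not _overlaps(f, region):
            continue
        if filtered_mirna_ids is not None and f.feature_id not in filtered_mirna_ids:
            continue
        ann.cis_mirnas.add(f.feature_id)
    return ann


def gene_level_methylation(
    beta: ExpressionMatrix,
    manifest: pd.DataFrame,
    features: list[Feature],
    platform: str,
    promoter_upstream: int = 2000,
    promoter_downstream: int = 500,
) -> ExpressionMatrix:
    """Aggregate probe-level beta values to one beta per gene.

    450K: mean over probes inside the strand-aware promoter window
    (TSS - upstream .. TSS + downstream); genes without a qualifying probe
    are missing (NaN row). 27K: mean over all of the gene's probes. The
    manifest maps probe_id -> (gene_id, position).
    """
    if platform not in ("p450k", "p27k"):
        raise ValidationError("platform must be 'p450k' or 'p27k'")
    needed = {"probe_id", "gene_id", "position"}
    if not needed <= set(manifest.columns):
        raise ValidationError(f"manifest needs columns {sorted(needed)}")
    probe_rows = set(beta.row_ids)
    unknown = probe_rows - set(manifest["probe_id"].astype(str))
    if unknown:
        raise ValidationError(f"manifest does not cover probes {sorted(unknown)[:5]}")
    genes = {f.feature_id: f for f in features if f.kind == "gene"}

    rows = {}
    for gene_id, sub in manifest.groupby("gene_id"):
        f = genes.get(str(gene_id))
        if f is None:
            logger.warning("methylation manifest maps probes to unknown gene %s; skipped",
                           gene_id)
            continue
        probes = [str(p) for p in sub["probe_id"] if str(p) in probe_rows]
        if platform == "p450k":
            if f.strand == "-":
                win_lo, win_hi = f.tss - promoter_downstream, f.tss + promoter_upstream
            else:
                win_lo, win_hi = f.tss - promoter_upstream, f.tss + promoter_downstream
            pos = dict(zip(sub["probe_id"].astype(str), sub["position"].astype(int)))
            probes = [p for p in probes if win_lo <= pos[p] <= win_hi]
        if probes:
            rows[f.feature_id] = beta.df.loc[probes].mean(axis=0)
        else:
            rows[f.feature_id] = pd.Series(np.nan, index=beta.df.columns)
    out = pd.DataFrame(rows).T
    out.index.name = "gene_id"
    return ExpressionMatrix(out, "beta")


def normalized_log2(matrix: ExpressionMatrix) -> pd.DataFrame:
    """log2(x+1) of library-normalized values (CPM for counts, raw for RPM)."""
    df = matrix.df.astype(float)
    if matrix.value_kind == "raw_count":
        lib = df.sum(axis=0)
        df = df / lib * lib.mean()
    return np.log2(df + 1.0)


def assemble_predictors(
    region_ann: RegionAnnotation,
    gene_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    gene_cn: pd.DataFrame,
    gene_meth: ExpressionMatrix | None,
    tf_table: pd.DataFrame,
    tf_confidence_keep: set[str] | None = None,
) -> list[PredictorSet]:
    """One PredictorSet per eligible trans gene of a region.

    Eligibility requires >= 1 cis miRNA (regions without any emit nothing).
    The sample set is the intersection of all provided matrices (logged when
    smaller than any single table). A predictor appearing under two classes
    (a cis gene that is also a TF of the target) is kept once with class
    cis_gene. Missing methylation for the trans gene drops that column with
    a log entry rather than imputing.
    """
    if not region_ann.cis_mirnas:
        logger.info("region %s has no cis miRNAs; no predictor sets",
                    region_ann.region_id)
        return []
    samples = [s for s in gene_expr.col_ids if s in set(mirna_expr.col_ids)
               and s in set(gene_cn.columns)]
    if gene_meth is not None:
        samples = [s for s in samples if s in set(gene_meth.col_ids)]
    if len(samples) < len(gene_expr.col_ids):
        logger.info("region %s: sample intersection %d of %d",
                    region_ann.region_id, len(samples), len(gene_expr.col_ids))

    log_gene = normalized_log2(gene_expr)[samples]
    log_mirna = normalized_log2(mirna_expr)[samples]
    if tf_confidence_keep is not None and "confidence" in tf_table.columns:
        tf_table = tf_table[
            tf_table["confidence"].isna() | tf_table["confidence"].isin(tf_confidence_keep)
        ]
    tf_of: dict[str, list[str]] = {}
    for row in tf_table.itertuples():
        tf_of.setdefault(str(row.target_id), []).append(str(row.tf_id))

    cis_genes = sorted(g for g in region_ann.cis_genes if g in log_gene.index)
    cis_mirnas = sorted(m for m in region_ann.cis_mirnas if m in log_mirna.index)
    if not cis_mirnas:
        logger.warning("region %s: cis miRNAs absent from expression matrix",
                       region_ann.region_id)
        return []

    out: list[PredictorSet] = []
    for gene in sorted(region_ann.trans_genes):
        if gene not in log_gene.index:
            logger.warning("trans gene %s absent from expression matrix; excluded", gene)
            continue
        cols: dict[str, pd.Series] = {}
        classes: dict[str, str] = {}
        for g in cis_genes:
            if g == gene:
                continue
            cols[g] = log_gene.loc[g]
            classes[g] = "cis_gene"
        for m in cis_mirnas:
            cols[m] = log_mirna.loc[m]
            classes[m] = "cis_mirna"
        cn_col = f"{gene}__cn"
        if gene in gene_cn.index:
            cols[cn_col] = gene_cn.loc[gene, samples]
            classes[cn_col] = "cn"
        meth_col = f"{gene}__meth"
        if gene_meth is not None and gene in gene_meth.df.index:
            mvals = gene_meth.df.loc[gene, samples]
            if mvals.isna().any():
                logger.info("%s: methylation missing for some samples; column omitted",
                            gene)
            else:
                cols[meth_col] = mvals
                classes[meth_col] = "methylation"
        for tf in sorted(set(tf_of.get(gene, []))):
            if tf in classes or tf == gene or tf not in log_gene.index:
                if tf in classes:
                    logger.info("%s: predictor %s already present as %s; "
                                "tf column deduplicated", gene, tf, classes[tf])
                continue
            cols[tf] = log_gene.loc[tf]
            classes[tf] = "tf"
        predictors = pd.DataFrame(cols, index=samples)
        try:
            out.append(
                PredictorSet(
                    region_id=region_ann.region_id,
                    trans_gene=gene,
                    response=log_gene.loc[gene],
                    predictors=predictors,
                    column_class=classes,
                )
            )
        except ValidationError as exc:
            logger.warning("trans gene %s skipped: %s", gene, exc)
    return out


def write_predictor_set(path, ps: PredictorSet, context: str = "") -> None:
    """One TSV per trans gene: samples x columns, header tagged name|class;
    the response is the column trans_gene|response."""
    from .io_formats import provenance_line

    header = [f"{ps.trans_gene}|response"] + [
        f"{c}|{ps.column_class[c]}" for c in ps.predictors.columns
    ]
    with open(path, "w") as fh:
        fh.write(provenance_line(context) + "\n")
        fh.write(f"# region_id={ps.region_id}\n")
        fh.write("sample_id\t" + "\t".join(header) + "\n")
        for s in ps.predictors.index:
            vals = [f"{ps.response.loc[s]:.10g}"] + [
                f"{v:.10g}" for v in ps.predictors.loc[s]
            ]
            fh.write(f"{s}\t" + "\t".join(vals) + "\n")


def read_predictor_set(path) -> PredictorSet:
    region_id = "unknown"
    with open(path) as fh:
        for line in fh:
            if line.startswith("# region_id="):
                region_id = line.strip().split("=", 1)[1]
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    resp_col = [c for c in df.columns if c.endswith("|response")]
    if len(resp_col) != 1:
        raise ValidationError(f"{path}: predictor file needs exactly one response column")
    trans_gene = resp_col[0].rsplit("|", 1)[0]
    response = df[resp_col[0]]
    response.name = trans_gene
    predictors = df.drop(columns=resp_col)
    classes = {}
    renames = {}
    for c in predictors.columns:
        name, cls = c.rsplit("|", 1)
        renames[c] = name
        classes[name] = cls
    predictors = predictors.rename(columns=renames)
    return PredictorSet(region_id=region_id, trans_gene=trans_gene,
                        response=response, predictors=predictors,
                        column_class=classes)
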