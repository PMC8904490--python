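"""Enrichment-based evaluation of computed miRNA-gene interaction networks.

Statistics implemented here mirror how such networks are scored against
curated knowledge: expansion of validated miRNA-target pairs with the
targets of TFs that are themselves validated targets (indirect
regulation), a one-sided hypergeometric over-representation test of each
miRNA's computed targets in the expanded truth, a two-sided Fisher exact
test for enrichment of known oncogenic miRNAs among the computed miRNAs,
win/loss/draw bookkeeping between two methods restricted to their shared
eligible miRNAs, a generic over-representation analysis for user-supplied
gene sets, Spearman correlation between miRNA copy number and expression,
and precision/recall/sign accuracy against a planted synthetic truth.

A miRNA is *eligible* when at least one of its computed targets is a known
target in the ground truth, and *significant* when, additionally, its
target-enrichment p-value is below alpha (default 0.05). Universes are
always explicit arguments — the correct background differs per test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .errors import ValidationError
from .stability_lasso import InteractionEdge
from .synthetic_data import GroundTruth

logger = logging.getLogger(__name__)

__all__ = ["GroundTruthInteractions", "EnrichmentResult", "expand_ground_truth",
           "hypergeom_upper", "fisher_two_sided", "mirna_target_enrichment",
           "fisher_oncomirna_enrichment", "compare_methods", "ora",
           "cn_expression_correlation", "recovery_metrics", "targets_by_mirna"]

FISHER_TIE_SLACK = 1 + 1e-7


@dataclass
class GroundTruthInteractions:
    pairs: set[tuple[str, str]]
    provenance: dict[tuple[str, str], str]  # "direct" | "tf_expanded"

    def targets_of(self, mirna: str) -> set[str]:
        return {g for m, g in self.pairs if m == mirna}


@dataclass
class EnrichmentResult:
    subject_id: str
    k: int  # overlap
    n: int  # draws (computed targets in universe)
    K: int  # successes in universe (truth targets in universe)
    N: int  # universe size
    p_value: float
    eligible: bool
    significant: bool
    adj_p: float = float("nan")

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.K):
            raise ValidationError(f"{self.subject_id}: overlap exceeds margins")


def expand_ground_truth(direct_pairs: set[tuple[str, str]],
                        tf_table: pd.DataFrame) -> GroundTruthInteractions:
    """Add (miRNA, t) for every target t of a TF the miRNA validly targets.

    Expanded pairs are tagged ``tf_expanded``; a pair that is also directly
    validated keeps the ``direct`` tag.
    """
    targets_of_tf: dict[str, set[str]] = {}
    for row in tf_table.itertuples():
        targets_of_tf.setdefault(str(row.tf_id), set()).add(str(row.target_id))
    prov = {pair: "direct" for pair in direct_pairs}
    for m, g in list(direct_pairs):
        for t in targets_of_tf.get(g, ()):
            prov.setdefault((m, t), "tf_expanded")
    return GroundTruthInteractions(pairs=set(prov), provenance=prov)


def hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), computed via the stable
    survival function; k=0 returns exactly 1."""
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValidationError(f"invalid hypergeometric parameters k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums, over all tables with the observed margins, the probabilities not
    exceeding the observed table's (1 + 1e-7 slack for float ties).
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValidationError("Fisher table cells must be non-negative integers")
    row1, col1, total = a + b, a + c, a + b + c + d
    if total == 0:
        return 1.0
    lo, hi = max(0, row1 + col1 - total), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, total, col1, row1)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * FISHER_TIE_SLACK].sum()))


def targets_by_mirna(edges: list[InteractionEdge]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for e in edges:
        out.setdefault(e.mirna_id, set()).add(e.gene_id)
    return out


def mirna_target_enrichment(
    edges: list[InteractionEdge] | dict[str, set[str]],
    truth: GroundTruthInteractions,
    universe: set[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-miRNA hypergeometric enrichment of computed targets in the truth.

    For each miRNA with computed targets: draws n = computed targets in the
    universe, successes K = the miRNA's truth targets in the universe,
    overlap k, universe size N. Eligibility requires a known target *among
    the computed targets* (k >= 1); significance requires eligibility and
    p < alpha. miRNAs with no computed target inside the universe are
    skipped with a log entry.
    """
    if not universe:
        raise ValidationError("empty universe")
    computed = edges if isinstance(edges, dict) else targets_by_mirna(edges)
    N = len(universe)
    results = []
    for mirna in sorted(computed):
        targets = computed[mirna] & universe
        if not targets:
            logger.info("miRNA %s has no computed target in the universe; skipped", mirna)
            continue
        truth_targets = truth.targets_of(mirna) & universe
        k = len(targets & truth_targets)
        p = hypergeom_upper(k, len(targets), len(truth_targets), N)
        eligible = k >= 1
        results.append(
            EnrichmentResult(
                subject_id=mirna, k=k, n=len(targets), K=len(truth_targets), N=N,
                p_value=p, eligible=eligible,
                significant=bool(eligible and p < alpha),
            )
        )
    return results


def percent_significant(results: list[EnrichmentResult]) -> float:
    """Percentage of eligible miRNAs that are significant (NaN if none)."""
    eligible = [r for r in results if r.eligible]
    if not eligible:
        return float("nan")
    return 100.0 * sum(r.significant for r in eligible) / len(eligible)


def fisher_oncomirna_enrichment(
    computed_mirnas: set[str],
    onco_list: set[str],
    background_mirnas: set[str],
) -> tuple[tuple[int, int, int, int], float]:
    """Two-sided Fisher test: computed miRNAs vs known oncogenic miRNAs.

    Background is the full miRNA set that entered the LASSO step; the
    oncogenic list is intersected with it first.
    """
    if not computed_mirnas <= background_mirnas:
        raise ValidationError("computed miRNAs must be a subset of the background")
    onco = onco_list & background_mirnas
    if not onco:
        logger.warning("oncogenic miRNA list is disjoint from the background")
        return (0, len(computed_mirnas), 0, len(background_mirnas - computed_mirnas)), 1.0
    a = len(computed_mirnas & onco)
    b = len(computed_mirnas - onco)
    c = len(onco - computed_mirnas)
    d = len(background_mirnas - computed_mirnas - onco)
    return (a, b, c, d), fisher_two_sided(a, b, c, d)


def compare_methods(
    edges_a: list[InteractionEdge] | dict[str, set[str]],
    edges_b: list[InteractionEdge] | dict[str, set[str]],
    truth: GroundTruthInteractions,
    universe: set[str],
    alpha: float = 0.05,
) -> dict:
    """Win/loss/draw between two methods on their shared eligible miRNAs.

    Both methods' target sets are scored with the same hypergeometric test;
    the comparison restricts to miRNAs eligible under *both* methods and
    counts significant miRNAs per method within that overlap. No overlap
    means the methods are not comparable on this cohort.
    """
    res_a = {r.subject_id: r for r in mirna_target_enrichment(edges_a, truth, universe, alpha)}
    res_b = {r.subject_id: r for r in mirna_target_enrichment(edges_b, truth, universe, alpha)}
    overlap = sorted(
        m for m in set(res_a) & set(res_b)
        if res_a[m].eligible and res_b[m].eligible
    )
    if not overlap:
        return {"verdict": "not_comparable", "overlap": [], "significant_a": 0,
                "significant_b": 0}
    sig_a = sum(res_a[m].significant for m in overlap)
    sig_b = sum(res_b[m].significant for m in overlap)
    verdict = "a_wins" if sig_a > sig_b else "b_wins" if sig_b > sig_a else "draw"
    return {"verdict": verdict, "overlap": overlap, "significant_a": sig_a,
            "significant_b": sig_b}


def ora(
    gene_set: set[str],
    annotation: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Over-representation of a gene set in user-supplied term gene sets.

    One-sided hypergeometric per term, BH-adjusted across terms; terms with
    empty universe intersection are skipped.
    """
    if not gene_set <= universe:
        raise ValidationError("gene_set must be a subset of the universe")
    N, n = len(universe), len(gene_set)
    rows = []
    for term in sorted(annotation):
        members = annotation[term] & universe
        if not members:
            continue
        k = len(gene_set & members)
        rows.append((term, k, len(members), hypergeom_upper(k, n, len(members), N)))
    if not rows:
        return []
    adj = bh_adjust([r[3] for r in rows])
    return [
        EnrichmentResult(
            subject_id=term, k=k, n=n, K=K, N=N, p_value=p,
            eligible=True, significant=bool(q < alpha), adj_p=float(q),
        )
        for (term, k, K, p), q in zip(rows, adj)
    ]


def cn_expression_correlation(
    mirna_ids: list[str],
    mirna_cn: pd.DataFrame,
    mirna_expr: pd.DataFrame,
) -> tuple[pd.Series, float]:
    """Spearman rho between copy number and expression per miRNA.

    Both tables are miRNAs x samples; only shared samples with finite
    values in both enter. Fewer than 3 pairs or a constant vector gives a
    missing rho. Returns (per-miRNA rho, median over defined values).
    """
    rhos = {}
    samples = [s for s in mirna_cn.columns if s in set(mirna_expr.columns)]
    for m in mirna_ids:
        if m not in mirna_cn.index or m not in mirna_expr.index:
            rhos[m] = float("nan")
            continue
        cn = mirna_cn.loc[m, samples].to_numpy(dtype=float)
        ex = mirna_expr.loc[m, samples].to_numpy(dtype=float)
        ok = np.isfinite(cn) & np.isfinite(ex)
        if ok.sum() < 3 or np.ptp(cn[ok]) == 0 or np.ptp(ex[ok]) == 0:
            rhos[m] = float("nan")
            continue
        rhos[m] = float(stats.spearmanr(cn[ok], ex[ok]).statistic)
    series = pd.Series(rhos, name="spearman_rho")
    defined = series.dropna()
    median = float(defined.median()) if len(defined) else float("nan")
    return series, median


def recovery_metrics(edges: list[InteractionEdge], truth: GroundTruth) -> dict:
    """Precision/recall/sign accuracy of computed edges vs planted truth."""
    true_pairs = truth.edge_pairs()
    true_sign = {(m, g): s for m, g, s in truth.true_edges}
    found = {(e.mirna_id, e.gene_id): e for e in edges}
    hits = set(found) & true_pairs
    precision = len(hits) / len(found) if found else float("nan")
    recall = len(hits) / len(true_pairs) if true_pairs else float("nan")
    if hits:
        sign_acc = sum(found[p].sign == true_sign[p] for p in hits) / len(hits)
    else:
        sign_acc = float("nan")
    return {
        "n_edges": len(found),
        "n_true_edges": len(true_pairs),
        "n_recovered": len(hits),
        "n_false": len(found) - len(hits),
        "precision": precision,
        "recall": recall,
        "sign_accuracy": sign_acc,
    }
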