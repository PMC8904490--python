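"""Per-region differential expression from raw counts.

Classic count-based DE between a region's aberrated and non-aberrated
sample groups: trimmed-mean-of-M (TMM) normalization, common negative-
binomial dispersion by conditional maximum likelihood on library-size-
equalized pseudo-counts, and a two-sided NB exact test on group sums
(binomial when dispersion is zero, a beta-distribution tail approximation
when both group sums are large). Benjamini-Hochberg adjustment is applied
within each region — the unit at which DE gene lists are formed — and a
gene is DE when |log2 fold change| >= 1 and adjusted p < 0.05 (defaults).

Numerical equality with any particular DE package is not a goal; the
contract is calibrated p-values (type-I error near nominal on null NB
data), correct fold-change signs, and exact label-swap antisymmetry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from ._stats import bh_adjust
from .errors import ValidationError
from .io_formats import ExpressionMatrix
from .regions import AberrationRegion

logger = logging.getLogger(__name__)

__all__ = ["DEConfig", "DEResult", "tmm_factors", "estimate_common_dispersion",
           "exact_test", "run_region_de", "write_de_table"]

BIG_COUNT = 900          # both group sums above this: use beta approximation
MAX_ENUM_TOTAL = 20_000  # total above this: always approximate
TIE_SLACK = 1 + 1e-7


@dataclass(frozen=True)
class DEConfig:
    method: str = "nb_exact"  # "nb_exact" | "wilcoxon"
    de_lfc_min: float = 1.0
    de_alpha: float = 0.05
    min_group_size: int = 3
    prior_count: float = 0.5

    def __post_init__(self) -> None:
        if self.method not in ("nb_exact", "wilcoxon"):
            raise ValidationError(f"unknown DE method {self.method!r}")
        if not 0 < self.de_alpha < 1:
            raise ValidationError("de_alpha must be in (0, 1)")
        if self.min_group_size < 2:
            raise ValidationError("min_group_size must be >= 2")


@dataclass(frozen=True)
class DEResult:
    region_id: str
    gene_id: str
    logFC: float
    p_value: float
    adj_p: float
    is_de: bool


def tmm_factors(counts: ExpressionMatrix | pd.DataFrame) -> pd.Series:
    """Trimmed-mean-of-M normalization factors, geometric mean rescaled to 1.

    The reference sample is the one whose upper-quartile of library-size-
    scaled counts is closest to the cohort mean upper-quartile. For each
    sample, M (log2 ratio vs reference, library-scaled) and A (average log2
    abundance) are computed over genes positive in both; the 30% tails of M
    and 5% tails of A are trimmed (each side) and the factor is 2 to the
    precision-weighted mean of the surviving M values.
    """
    df = counts.df if isinstance(counts, ExpressionMatrix) else counts
    y = df.to_numpy(dtype=float)
    if y.shape[1] < 2:
        raise ValidationError("TMM needs >= 2 samples")
    lib = y.sum(axis=0)
    if np.any(lib <= 0):
        raise ValidationError("every sample needs a positive library size")
    scaled = y / lib
    f75 = np.array([np.percentile(scaled[:, j][y[:, j] > 0], 75) if (y[:, j] > 0).any()
                    else 0.0 for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            continue
        factors[j] = _tmm_pair(y[:, j], y[:, ref], lib[j], lib[ref])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=df.columns, name="tmm_factor")


def _tmm_pair(obs, ref, n_obs, n_ref, logratio_trim=0.3, sum_trim=0.05):
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise ValidationError("sample shares no positive gene with the reference")
    obs, ref = obs[pos], ref[pos]
    m = np.log2((obs / n_obs) / (ref / n_ref))
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    # asymptotic (delta-method) variance of M; weight = 1/variance
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    n = len(m)
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - (np.floor(n * logratio_trim) + 1)
    lo_a, hi_a = np.floor(n * sum_trim) + 1, n + 1 - (np.floor(n * sum_trim) + 1)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def _equalize_library_sizes(y: np.ndarray, eff_lib: np.ndarray, phi: float
                            ) -> tuple[np.ndarray, float]:
    """Quantile-map counts from each sample's effective library size to the
    common (geometric mean) size, via a gamma approximation of the NB cdf.

    Returns (pseudo-count matrix, common library size). The mapping goes
    through the upper tail when the observed count is above its median so
    both tails stay numerically stable.
    """
    common = float(np.exp(np.mean(np.log(eff_lib))))
    abundance = y.sum(axis=1) / eff_lib.sum()
    pseudo = np.zeros_like(y, dtype=float)
    rows = abundance > 0
    if not rows.any():
        return pseudo, common
    mu_in = abundance[rows][:, None] * eff_lib[None, :]
    mu_out = np.broadcast_to(abundance[rows][:, None] * common, mu_in.shape)
    theta_in = 1.0 + phi * mu_in
    theta_out = 1.0 + phi * mu_out
    k_in = mu_in / theta_in
    k_out = mu_out / theta_out
    yy = y[rows] + 0.5
    lower = stats.gamma.cdf(yy, a=k_in, scale=theta_in)
    use_sf = lower > 0.5
    out = np.empty_like(yy, dtype=float)
    out[~use_sf] = stats.gamma.ppf(lower[~use_sf], a=k_out[~use_sf],
                                   scale=theta_out[~use_sf])
    upper = stats.gamma.sf(yy[use_sf], a=k_in[use_sf], scale=theta_in[use_sf])
    out[use_sf] = stats.gamma.isf(upper, a=k_out[use_sf], scale=theta_out[use_sf])
    # counts so extreme the tail probability underflows: fall back to
    # straight library-size scaling
    bad = ~np.isfinite(out)
    if bad.any():
        out[bad] = yy[bad] * (mu_out[bad] / mu_in[bad])
    pseudo[rows] = np.clip(out - 0.5, 0.0, None)
    return pseudo, common


def _conditional_loglik(pseudo: np.ndarray, group_cols: list[np.ndarray],
                        phi: float) -> float:
    """Common-dispersion conditional log-likelihood given per-group totals,
    assuming equalized library sizes (qCML)."""
    r = 1.0 / max(phi, 1e-10)
    total = 0.0
    for cols in group_cols:
        yg = pseudo[:, cols]
        n = yg.shape[1]
        n_genes = yg.shape[0]
        z = yg.sum(axis=1)
        total += float(
            np.sum(gammaln(yg + r))
            + n_genes * gammaln(n * r)
            - np.sum(gammaln(z + n * r))
            - n_genes * n * gammaln(r)
        )
    return total


def estimate_common_dispersion(
    counts: ExpressionMatrix | pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    factors: pd.Series | None = None,
    min_group_size: int = 2,
) -> float:
    """Common NB dispersion by conditional (quantile-adjusted) ML.

    Grid search over log-spaced dispersions with golden-section refinement;
    returns 0.0 when the likelihood is maximized at the lower boundary
    (no evidence of overdispersion beyond Poisson).
    """
    df = counts.df if isinstance(counts, ExpressionMatrix) else counts
    if len(group_a) < min_group_size or len(group_b) < min_group_size:
        raise ValidationError("both groups must have at least min_group_size samples")
    cols = list(group_a) + list(group_b)
    y = df.loc[:, cols].to_numpy(dtype=float)
    if y.sum() == 0:
        raise ValidationError("all-zero count matrix")
    if factors is None:
        factors = tmm_factors(df.loc[:, cols])
    eff_lib = y.sum(axis=0) * factors.loc[cols].to_numpy()
    group_cols = [np.arange(len(group_a)), np.arange(len(group_a), len(cols))]

    keep = y.sum(axis=1) > 0
    grid = np.concatenate([[1e-6], np.geomspace(1e-4, 5.0, 25)])

    def ll_at(phi):
        pseudo, _ = _equalize_library_sizes(y[keep], eff_lib, phi)
        return _conditional_loglik(pseudo, group_cols, phi)

    lls = np.array([ll_at(p) for p in grid])
    best = int(np.argmax(lls))
    if best == 0:
        return 0.0
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    phi = _golden_max(ll_at, np.log(lo), np.log(hi))
    if phi <= grid[1] * 1.01 and ll_at(1e-6) >= ll_at(phi):
        return 0.0
    return float(phi)


def _golden_max(f, log_lo, log_hi, tol=1e-3, max_iter=40):
    gr = (np.sqrt(5) - 1) / 2
    a, b = log_lo, log_hi
    c, d = b - gr * (b - a), a + gr * (b - a)
    fc, fd = f(np.exp(c)), f(np.exp(d))
    for _ in range(max_iter):
        if b - a < tol:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = f(np.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = f(np.exp(d))
    return np.exp((a + b) / 2)


def exact_test(
    counts: ExpressionMatrix | pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    dispersion: float,
    factors: pd.Series | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Two-sided NB exact test on library-equalized group sums.

    Per gene, the probability of every split of the (pseudo-)total between
    the two groups is computed under NB with the common dispersion
    (binomial at dispersion 0); the p-value sums the probabilities not
    exceeding the observed split's probability (with a 1+1e-7 float-tie
    slack). logFC is log2 of the ratio of prior-damped per-sample
    normalized group means, group A over group B.
    """
    df = counts.df if isinstance(counts, ExpressionMatrix) else counts
    cols = list(group_a) + list(group_b)
    y = df.loc[:, cols].to_numpy(dtype=float)
    n1, n2 = len(group_a), len(group_b)
    if factors is None:
        factors = tmm_factors(df.loc[:, cols])
    eff_lib = y.sum(axis=0) * factors.loc[cols].to_numpy()
    pseudo, _ = _equalize_library_sizes(y, eff_lib, dispersion)
    s1f = pseudo[:, :n1].sum(axis=1)
    s2f = pseudo[:, n1:].sum(axis=1)
    m1, m2 = s1f / n1, s2f / n2
    logfc = np.log2(m1 + prior_count) - np.log2(m2 + prior_count)

    s1 = np.round(s1f).astype(np.int64)
    s2 = np.round(s2f).astype(np.int64)
    pvals = np.ones(len(df))
    for i in range(len(df)):
        pvals[i] = _exact_p(s1[i], s2[i], n1, n2, dispersion)
    return pd.DataFrame(
        {"gene_id": df.index.astype(str), "logFC": logfc, "p_value": pvals}
    ).set_index("gene_id")


def _exact_p(s1: int, s2: int, n1: int, n2: int, phi: float) -> float:
    total = s1 + s2
    if total == 0:
        return 1.0
    if (s1 > BIG_COUNT and s2 > BIG_COUNT) or total > MAX_ENUM_TOTAL:
        return _beta_approx_p(s1, s2, n1, n2, phi)
    mu = total / (n1 + n2)
    a = np.arange(total + 1)
    if phi <= 0:
        logp = stats.binom.logpmf(a, total, n1 / (n1 + n2))
    else:
        r1, r2 = n1 / phi, n2 / phi
        p1 = r1 / (r1 + n1 * mu)
        p2 = r2 / (r2 + n2 * mu)
        logp = stats.nbinom.logpmf(a, r1, p1) + stats.nbinom.logpmf(total - a, r2, p2)
        logp -= logsumexp(logp)
    obs = logp[s1]
    keep = logp <= obs + np.log(TIE_SLACK)
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def _beta_approx_p(s1, s2, n1, n2, phi) -> float:
    """Beta-distribution approximation to the double-tail exact p-value for
    large group sums (the proportion s1/(s1+s2) is approximately Beta)."""
    total = s1 + s2
    mu = total / (n1 + n2)
    alpha1 = n1 * mu / (1.0 + phi * mu)
    alpha2 = (n2 / n1) * alpha1
    med = stats.beta.ppf(0.5, alpha1, alpha2)
    if (s1 + 0.5) / total < med:
        p = 2 * stats.beta.cdf((s1 + 0.5) / total, alpha1, alpha2)
    elif (s1 - 0.5) / total > med:
        p = 2 * stats.beta.sf((s1 - 0.5) / total, alpha1, alpha2)
    else:
        p = 1.0
    return float(min(1.0, p))


def _wilcoxon_test(df, group_a, group_b, factors, prior_count):
    cols = list(group_a) + list(group_b)
    y = df.loc[:, cols].to_numpy(dtype=float)
    eff_lib = y.sum(axis=0) * factors.loc[cols].to_numpy()
    cpm = y / eff_lib * 1e6
    n1 = len(group_a)
    m1 = cpm[:, :n1].mean(axis=1) * eff_lib.mean() / 1e6
    m2 = cpm[:, n1:].mean(axis=1) * eff_lib.mean() / 1e6
    logfc = np.log2(m1 + prior_count) - np.log2(m2 + prior_count)
    pvals = np.ones(len(df))
    method = "exact" if len(cols) <= 20 else "asymptotic"
    for i in range(len(df)):
        a, b = cpm[i, :n1], cpm[i, n1:]
        if np.all(a == a[0]) and np.all(b == a[0]):
            continue
        try:
            pvals[i] = stats.mannwhitneyu(a, b, alternative="two-sided",
                                          method=method).pvalue
        except ValueError:
            pvals[i] = stats.mannwhitneyu(a, b, alternative="two-sided",
                                          method="asymptotic").pvalue
    return pd.DataFrame({"gene_id": df.index.astype(str), "logFC": logfc,
                         "p_value": pvals}).set_index("gene_id")


def run_region_de(
    region: AberrationRegion,
    counts: ExpressionMatrix,
    cfg: DEConfig = DEConfig(),
) -> list[DEResult]:
    """DE of all genes between a region's aberrated and non-aberrated groups.

    Returns an empty list (with a log entry) when either group is smaller
    than ``cfg.min_group_size`` — an untestable region is skipped, not an
    error. BH adjustment is across genes within this region; results are
    sorted by adjusted p.
    """
    in_matrix = set(counts.col_ids)
    group_a = [s for s in region.aberrated_samples() if s in in_matrix]
    group_b = [s for s in region.non_aberrated_samples() if s in in_matrix]
    if len(group_a) < cfg.min_group_size or len(group_b) < cfg.min_group_size:
        logger.warning(
            "region %s skipped: group sizes %d vs %d below min_group_size %d",
            region.region_id, len(group_a), len(group_b), cfg.min_group_size,
        )
        return []
    factors = tmm_factors(counts.df.loc[:, group_a + group_b])
    if cfg.method == "nb_exact":
        phi = estimate_common_dispersion(counts, group_a, group_b, factors=factors,
                                         min_group_size=cfg.min_group_size)
        table = exact_test(counts, group_a, group_b, phi, factors=factors,
                           prior_count=cfg.prior_count)
    else:
        table = _wilcoxon_test(counts.df, group_a, group_b, factors, cfg.prior_count)
    adj = bh_adjust(table["p_value"].to_numpy())
    results = [
        DEResult(
            region_id=region.region_id,
            gene_id=str(g),
            logFC=float(row.logFC),
            p_value=float(row.p_value),
            adj_p=float(q),
            is_de=bool(abs(row.logFC) >= cfg.de_lfc_min and q < cfg.de_alpha),
        )
        for (g, row), q in zip(table.iterrows(), adj)
    ]
    results.sort(key=lambda r: (r.adj_p, r.p_value, r.gene_id))
    return results


def write_de_table(path, results: list[DEResult], context: str = "") -> None:
    from .io_formats import provenance_line

    with open(path, "w") as fh:
        fh.write(provenance_line(context) + "\n")
        fh.write("region_id\tgene_id\tlogFC\tp\tadj_p\tis_de\n")
        for r in results:
            fh.write(f"{r.region_id}\t{r.gene_id}\t{r.logFC:.6g}\t{r.p_value:.6g}\t"
                     f"{r.adj_p:.6g}\t{int(r.is_de)}\n")
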