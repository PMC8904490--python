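"""Stability-selection LASSO over each trans gene's predictor set.

For every trans gene the L1-penalized regression of its expression on the
assembled predictors is repeated ``n_runs`` times (default 100). Each run
draws fresh cross-validation folds (the only source of randomness), picks
the penalty weight lambda by ``n_folds``-fold CV — the *largest* lambda
attaining the minimal CV error, i.e. the simplest model at that error —
and refits at that lambda on the full data. A predictor counts as selected
in a run when its refit coefficient is nonzero; cis miRNA predictors
selected in at least ``keep_threshold`` runs (default 70) become signed
miRNA-gene interaction edges. Both signs are kept: repression gives
negative coefficients, but indirect regulation can legitimately be
positive.

The solver is plain cyclic coordinate descent with warm starts along a
descending log-spaced lambda grid, minimizing
``(1/2n)||y - X b||^2 + lambda * ||b||_1`` on standardized predictors,
compiled with numba. At ``lambda >= lambda_max = max_j |x_j' y| / n`` all
coefficients are exactly zero (KKT).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .errors import ValidationError
from .regulator import PredictorSet

logger = logging.getLogger(__name__)

__all__ = ["StabilityConfig", "SelectionRecord", "InteractionEdge", "lambda_grid",
           "lasso_path", "cv_select_lambda", "stability_select", "two_phase_select",
           "extract_edges", "kkt_max_violation", "write_edge_table",
           "read_edge_table", "write_selection_records"]


@dataclass(frozen=True)
class StabilityConfig:
    n_runs: int = 100
    keep_threshold: int = 70
    n_folds: int = 10
    lambda_grid_size: int = 100
    lambda_min_ratio: float = 1e-3
    lambda_rule: str = "one_se"  # "one_se" | "min"
    standardize: bool = True
    zero_tol: float = 1e-9
    base_seed: int = 0
    two_phase: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.keep_threshold <= self.n_runs:
            raise ValidationError("need 0 < keep_threshold <= n_runs")
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValidationError("lambda_min_ratio must be in (0, 1)")
        if self.lambda_rule not in ("min", "one_se"):
            raise ValidationError("lambda_rule must be 'min' or 'one_se'")


@dataclass
class SelectionRecord:
    region_id: str
    trans_gene: str
    predictor: str
    predictor_class: str
    selection_count: int
    mean_coef: float
    sign: str
    phase: int = 1

    def __post_init__(self) -> None:
        expect = "negative" if self.mean_coef < 0 else "positive"
        if self.sign != expect:
            raise ValidationError(f"{self.predictor}: sign inconsistent with mean_coef")


@dataclass
class InteractionEdge:
    mirna_id: str
    gene_id: str
    region_ids: tuple[str, ...]
    selection_count: int
    mean_coef: float
    sign: str


@njit(cache=True)
def _cd_path_gram(G, c, lambdas, tol, max_iter):  # pragma: no cover - numba kernel
    # cyclic coordinate descent with covariance updates and warm starts:
    # G = X'X/n, c = X'y/n; grad_j = c_j - sum_k G_jk beta_k
    p = c.size
    out = np.zeros((lambdas.size, p))
    beta = np.zeros(p)
    q = np.zeros(p)  # q_j = (G beta)_j, maintained incrementally
    for k in range(lambdas.size):
        lam = lambdas[k]
        for _ in range(max_iter):
            maxd = 0.0
            for j in range(p):
                gjj = G[j, j]
                if gjj <= 0.0:
                    continue
                bj = beta[j]
                rho = c[j] - q[j] + gjj * bj
                if rho > lam:
                    bnew = (rho - lam) / gjj
                elif rho < -lam:
                    bnew = (rho + lam) / gjj
                else:
                    bnew = 0.0
                d = bnew - bj
                if d != 0.0:
                    for m in range(p):
                        q[m] += d * G[m, j]
                    beta[j] = bnew
                    if abs(d) > maxd:
                        maxd = abs(d)
            if maxd < tol:
                break
        out[k] = beta
    return out


def _cd_path(X, y, lambdas, tol, max_iter):
    n = X.shape[0]
    G = np.ascontiguousarray(X.T @ X / n)
    c = X.T @ y / n
    return _cd_path_gram(G, c, lambdas, tol, max_iter)


def lambda_grid(X: np.ndarray, y: np.ndarray, size: int = 100,
                min_ratio: float = 1e-3) -> np.ndarray:
    """Descending log-spaced grid from lambda_max = max|X'y|/n down to
    lambda_max * min_ratio."""
    n = X.shape[0]
    lam_max = float(np.max(np.abs(X.T @ y)) / n)
    if lam_max <= 0:
        lam_max = 1e-12
    return np.geomspace(lam_max, lam_max * min_ratio, size)


def lasso_path(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
               tol: float = 1e-7, max_iter: int = 10_000) -> np.ndarray:
    """Coefficients (grid x predictors) along a descending lambda grid.

    Expects standardized (or at least finite, non-constant) predictor
    columns and a centered response; convergence is max coefficient change
    below ``tol`` within a sweep.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    lambdas = np.asarray(lambdas, dtype=np.float64)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in X or y")
    if np.any(np.diff(lambdas) > 0):
        raise ValidationError("lambda grid must be descending")
    if np.any(X.std(axis=0) == 0):
        raise ValidationError("constant predictor column (drop it upstream)")
    return _cd_path(X, y, lambdas, tol, max_iter)


def kkt_max_violation(X: np.ndarray, y: np.ndarray, beta: np.ndarray,
                      lam: float) -> float:
    """Max KKT residual of a lasso solution: for active j,
    |x_j'(y-Xb)/n - lam*sign(b_j)|; for inactive j, excess of |x_j'r/n|
    over lam."""
    n = X.shape[0]
    grad = X.T @ (y - X @ beta) / n
    active = beta != 0
    viol = 0.0
    if active.any():
        viol = float(np.max(np.abs(grad[active] - lam * np.sign(beta[active]))))
    if (~active).any():
        viol = max(viol, float(np.max(np.abs(grad[~active])) - lam))
    return viol


def _fold_assignment(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=np.int64)
    for f, chunk in enumerate(np.array_split(perm, n_folds)):
        folds[chunk] = f
    return folds


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    n_folds: int = 10,
    rule: str = "min",
    run_seed: int = 0,
) -> float:
    """Pick lambda by seeded K-fold CV mean squared error.

    ``rule='min'``: the largest lambda attaining the minimal CV error (ties
    break toward the sparser model). ``rule='one_se'``: the largest lambda
    whose CV error is within one standard error of the minimum.
    """
    n = X.shape[0]
    if n < n_folds:
        raise ValidationError("need at least n_folds samples")
    eff_folds = n_folds
    if n // n_folds < 2:
        eff_folds = max(2, n // 2)
        logger.warning("reducing n_folds from %d to %d (small sample)", n_folds, eff_folds)
    rng = np.random.default_rng(run_seed)
    folds = _fold_assignment(n, eff_folds, rng)
    sq_err = np.zeros((eff_folds, lambdas.size))
    for f in range(eff_folds):
        test = folds == f
        train = ~test
        coefs = _cd_path(np.ascontiguousarray(X[train]), y[train],
                         lambdas, 1e-7, 10_000)
        pred = X[test] @ coefs.T
        sq_err[f] = np.mean((y[test][:, None] - pred) ** 2, axis=0)
    cv_mean = sq_err.mean(axis=0)
    i_min = int(np.argmax(cv_mean == cv_mean.min()))  # first (= largest lambda)
    if rule == "one_se":
        se = sq_err[:, i_min].std(ddof=1) / np.sqrt(eff_folds)
        ok = cv_mean <= cv_mean[i_min] + se
        i_min = int(np.argmax(ok))
    return float(lambdas[i_min])


def _standardize_design(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = df.to_numpy(dtype=np.float64)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mean) / sd, mean, sd


def _stability_core(
    predictors: pd.DataFrame,
    response: np.ndarray,
    classes: dict[str, str],
    cfg: StabilityConfig,
    region_id: str,
    trans_gene: str,
    phase: int,
) -> list[SelectionRecord]:
    if predictors.shape[1] == 0:
        return []
    if cfg.standardize:
        X, _, _ = _standardize_design(predictors)
    else:
        X = predictors.to_numpy(dtype=np.float64)
    y = response - response.mean()
    n = X.shape[0]
    if n <= cfg.n_folds:
        raise ValidationError("need more samples than folds")
    grid = lambda_grid(X, y, cfg.lambda_grid_size, cfg.lambda_min_ratio)
    full_path = lasso_path(X, y, grid)

    counts = np.zeros(X.shape[1], dtype=np.int64)
    coef_sums = np.zeros(X.shape[1])
    grid_index = {float(l): i for i, l in enumerate(grid)}
    for r in range(1, cfg.n_runs + 1):
        lam = cv_select_lambda(X, y, grid, cfg.n_folds, cfg.lambda_rule,
                               run_seed=cfg.base_seed + r)
        beta = full_path[grid_index[lam]]
        sel = np.abs(beta) > cfg.zero_tol
        counts += sel
        coef_sums[sel] += beta[sel]

    records = []
    names = list(predictors.columns)
    for j, name in enumerate(names):
        if counts[j] == 0:
            continue
        mean_coef = coef_sums[j] / counts[j]
        records.append(
            SelectionRecord(
                region_id=region_id,
                trans_gene=trans_gene,
                predictor=name,
                predictor_class=classes[name],
                selection_count=int(counts[j]),
                mean_coef=float(mean_coef),
                sign="negative" if mean_coef < 0 else "positive",
                phase=phase,
            )
        )
    return records


def stability_select(ps: PredictorSet, cfg: StabilityConfig = StabilityConfig()
                     ) -> list[SelectionRecord]:
    """Repeated CV-LASSO of one trans gene; per-predictor selection counts.

    Deterministic given ``cfg.base_seed``: run ``r`` uses seed
    ``base_seed + r`` for its fold shuffle, which is the only randomness.
    The full-data coefficient path is computed once; each run's refit reads
    the coefficients at its CV-chosen lambda off that path.
    """
    y = ps.response.to_numpy(dtype=np.float64)
    return _stability_core(ps.predictors, y, ps.column_class, cfg,
                           ps.region_id, ps.trans_gene, phase=1)


def two_phase_select(ps: PredictorSet, cfg: StabilityConfig) -> list[SelectionRecord]:
    """Residual-mode selection: transcriptional predictors first, then miRNAs.

    Phase 1 runs stability LASSO of the response on the cn/methylation/tf/
    cis_gene columns; consensus predictors (count >= keep_threshold) are
    refit by least squares and their fit removed. Phase 2 runs stability
    LASSO of the residual on the cis miRNA columns alone. Records carry a
    phase tag; edge extraction uses phase-2 miRNA records.
    """
    if not cfg.two_phase:
        raise ValidationError("two_phase_select requires cfg.two_phase=True")
    y = ps.response.to_numpy(dtype=np.float64)
    covar_cols = [c for c in ps.predictors.columns
                  if ps.column_class[c] != "cis_mirna"]
    mirna_cols = [c for c in ps.predictors.columns
                  if ps.column_class[c] == "cis_mirna"]
    phase1 = _stability_core(ps.predictors[covar_cols], y, ps.column_class, cfg,
                             ps.region_id, ps.trans_gene, phase=1)
    consensus = [r.predictor for r in phase1
                 if r.selection_count >= cfg.keep_threshold]
    if consensus:
        Z = ps.predictors[consensus].to_numpy(dtype=np.float64)
        Z = np.column_stack([np.ones(len(Z)), Z])
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        residual = y - Z @ coef
    else:
        logger.info("%s/%s: empty phase-1 consensus; using centered response",
                    ps.region_id, ps.trans_gene)
        residual = y - y.mean()
    phase2 = _stability_core(ps.predictors[mirna_cols], residual, ps.column_class,
                             cfg, ps.region_id, ps.trans_gene, phase=2)
    return phase1 + phase2


def extract_edges(records: list[SelectionRecord],
                  cfg: StabilityConfig = StabilityConfig()) -> list[InteractionEdge]:
    """miRNA records with selection_count >= keep_threshold become edges.

    The same (miRNA, gene) pair reached from several regions collapses to
    one edge: union of region ids, the maximal selection count, and the
    coefficient of the max-count record.
    """
    best: dict[tuple[str, str], SelectionRecord] = {}
    region_sets: dict[tuple[str, str], set[str]] = {}
    for r in records:
        if r.predictor_class != "cis_mirna" or r.selection_count < cfg.keep_threshold:
            continue
        key = (r.predictor, r.trans_gene)
        region_sets.setdefault(key, set()).add(r.region_id)
        if key not in best or r.selection_count > best[key].selection_count:
            best[key] = r
    edges = [
        InteractionEdge(
            mirna_id=m,
            gene_id=g,
            region_ids=tuple(sorted(region_sets[(m, g)])),
            selection_count=best[(m, g)].selection_count,
            mean_coef=best[(m, g)].mean_coef,
            sign=best[(m, g)].sign,
        )
        for (m, g) in sorted(best)
    ]
    return edges


def write_edge_table(path, edges: list[InteractionEdge], context: str = "") -> None:
    from .io_formats import provenance_line

    with open(path, "w") as fh:
        fh.write(provenance_line(context) + "\n")
        fh.write("mirna_id\tgene_id\tregion_ids\tselection_count\tmean_coef\tsign\n")
        for e in edges:
            fh.write(f"{e.mirna_id}\t{e.gene_id}\t{','.join(e.region_ids)}\t"
                     f"{e.selection_count}\t{e.mean_coef:.6g}\t{e.sign}\n")


def read_edge_table(path) -> list[InteractionEdge]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        InteractionEdge(
            mirna_id=str(r.mirna_id), gene_id=str(r.gene_id),
            region_ids=tuple(str(r.region_ids).split(",")) if pd.notna(r.region_ids) else (),
            selection_count=int(r.selection_count),
            mean_coef=float(r.mean_coef), sign=str(r.sign),
        )
        for r in df.itertuples()
    ]


def write_selection_records(path, records: list[SelectionRecord],
                            context: str = "") -> None:
    from .io_formats import provenance_line

    with open(path, "w") as fh:
        fh.write(provenance_line(context) + "\n")
        fh.write("region_id\ttrans_gene\tpredictor\tpredictor_class\t"
                 "selection_count\tmean_coef\tsign\tphase\n")
        for r in records:
            fh.write(f"{r.region_id}\t{r.trans_gene}\t{r.predictor}\t"
                     f"{r.predictor_class}\t{r.selection_count}\t{r.mean_coef:.6g}\t"
                     f"{r.sign}\t{r.phase}\n")
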