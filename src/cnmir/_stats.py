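"""Small shared statistical utilities (single source for BH adjustment)."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR).

    Adjusted values are monotone in the rank of the raw p-value and never
    smaller than the raw p-value. Used by both the differential-expression
    and the enrichment modules so the procedure has one implementation.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
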