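"""Benjamini-Hochberg step-up FDR adjustment."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust"]


def bh_adjust(p_values) -> np.ndarray:
    """BH step-up adjusted p-values, returned in input order.

    Equivalent to sorting ascending, taking ``q_i = min_{j>=i} (p_j * n / j)``
    clipped at 1, and undoing the sort.  Input must lie in [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
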