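"""Shared low-level statistics (multiple-testing adjustment)."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, returned in input order.

    NaN entries (e.g., scores without an analytic p-value) are passed
    through as NaN and do not count toward the number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    finite = np.isfinite(p)
    if not finite.any():
        return out
    vals = p[finite]
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    out[finite] = multipletests(vals, method="fdr_bh")[1]
    return out
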