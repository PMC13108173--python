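"""Shared statistical helpers: BH adjustment with missing values, rounding."""

from __future__ import annotations

import math

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjustment, propagating NaN.

    Features whose fit failed (NaN p) are excluded from the adjustment and
    from the effective number of tests; their adjusted value stays NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.sum() > 0:
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (54.5 → 55, −0.5 → −1)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))
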