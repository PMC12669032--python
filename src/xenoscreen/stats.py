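"""Shared statistical helpers used across the screen modules."""

from __future__ import annotations

import numpy as np

__all__ = ["bh_adjust"]


def bh_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Parameters
    ----------
    pvalues
        Raw p-values in [0, 1].
    m
        Denominator of the correction (number of tests corrected for).
        Defaults to ``len(pvalues)``; may be larger, e.g. when a strain was
        assayed against fewer compounds than the full library but the
        correction is over the library size.

    Returns
    -------
    Adjusted p-values in the original order, elementwise >= the input and
    capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be in [0, 1]")
    n = p.size
    if m is None:
        m = n
    if m < n:
        raise ValueError(f"m ({m}) must be >= number of p-values ({n})")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    # enforce monotonicity from the largest rank down (step-up)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out
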