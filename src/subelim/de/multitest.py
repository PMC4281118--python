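"""Benjamini–Hochberg step-up false-discovery-rate adjustment."""

from __future__ import annotations

import numpy as np

__all__ = ["adjust_bh"]


def adjust_bh(pvalues) -> np.ndarray:
    """BH-adjusted p-values: p_(i)·m/i with a running minimum from the top rank.

    Input order is preserved; values are capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("pvalues must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out
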