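"""Normalization, subpopulation gating, and subgroup co-expression statistics.

Gating follows the flow-cytometry convention for bimodal markers: a Gaussian
kernel density estimate on log intensities, with the threshold placed at the
deepest interior local minimum between the two largest modes.  A fixed
threshold (on scaled data) is supported for routine counting once the
distribution shape is known.  Percent-positive values carry 95% Wilson
binomial confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = ["normalize_scale", "gate", "GateResult", "NoValleyError", "subgroup_stats"]


class NoValleyError(RuntimeError):
    """Raised when the KDE has no interior valley; advises a fixed threshold."""


def normalize_scale(
    table: pd.DataFrame,
    reference_condition: str,
    channels: Sequence[str],
    scale_constant: float = 1.0,
    in_prefix: str = "comp_",
    out_prefix: str = "scaled_",
    condition_col: str = "condition",
) -> pd.DataFrame:
    """Scale each channel so the reference-condition mean equals the constant.

    The reference is the unstimulated/control condition; scaling adjusts for
    day-to-day staining variability.  ``scale_constant`` is conventionally 1
    or 1000.
    """
    if scale_constant not in (1, 1000):
        raise ValueError("scale_constant: use 1 or 1000")
    ref = table[table[condition_col] == reference_condition]
    if len(ref) == 0:
        raise ValueError(f"reference condition {reference_condition!r} has no objects")
    out = table.copy()
    for ch in channels:
        col = f"{in_prefix}{ch}"
        if col not in table.columns:
            raise ValueError(f"table lacks column {col!r}")
        mean = ref[col].mean()
        if mean == 0:
            raise ValueError(f"reference mean of {col!r} is zero")
        out[f"{out_prefix}{ch}"] = table[col] / mean * scale_constant
    return out


@dataclass
class GateResult:
    """Threshold, per-object labels and the positive-fraction summary."""

    threshold: float
    method: str
    labels: np.ndarray
    n: int
    n_positive: int
    percent_positive: float
    ci_low: float
    ci_high: float
    channel: Optional[str] = None

    def summary(self) -> str:
        return (
            f"gate[{self.method}] threshold={self.threshold:.4g} "
            f"positive {self.n_positive}/{self.n} = {self.percent_positive:.1f}% "
            f"(95% CI {self.ci_low:.1f}–{self.ci_high:.1f}%)"
        )


_MIN_MODE_PROMINENCE = 0.002  # of the density maximum; rejects tail wiggles


def _kde_valley(log_values: np.ndarray, bandwidth, n_grid: int = 512) -> float:
    from scipy.signal import find_peaks

    kde = stats.gaussian_kde(log_values, bw_method=bandwidth or "silverman")
    pad = 0.05 * (log_values.max() - log_values.min() + 1e-12)
    grid = np.linspace(log_values.min() - pad, log_values.max() + pad, n_grid)
    dens = kde(grid)
    maxima, _ = find_peaks(dens, prominence=_MIN_MODE_PROMINENCE * dens.max())
    if len(maxima) < 2:
        raise NoValleyError(
            "density is unimodal — no interior valley to gate on; use a fixed threshold"
        )
    top_two = np.sort(maxima[np.argsort(dens[maxima])[-2:]])
    lo, hi = top_two
    segment = dens[lo : hi + 1]
    valley = lo + int(np.argmin(segment))  # deepest interior minimum between the modes
    return float(grid[valley])


def gate(
    values,
    method: str = "density_minimum",
    fixed_threshold: Optional[float] = None,
    bandwidth: Optional[float] = None,
    channel: Optional[str] = None,
) -> GateResult:
    """Gate a vector of (scaled) intensities into negative/positive.

    ``density_minimum`` places the threshold at the deepest interior minimum
    of the log-intensity KDE between the two largest modes (requires ≥ 100
    values); ``fixed`` uses the given threshold, which must lie inside the
    observed data range.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise ValueError("values must be a non-empty 1-D array")
    if method == "density_minimum":
        if len(values) < 100:
            raise ValueError("density_minimum gating needs at least 100 values")
        positive = values[values > 0]
        if len(positive) < len(values):
            values = np.clip(values, positive.min() / 2 if len(positive) else 1e-12, None)
        threshold = float(np.exp(_kde_valley(np.log(values), bandwidth)))
    elif method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed gating needs fixed_threshold")
        threshold = float(fixed_threshold)
        if not values.min() <= threshold <= values.max():
            raise ValueError(
                f"fixed threshold {threshold} outside the observed range "
                f"[{values.min():.4g}, {values.max():.4g}]"
            )
    else:
        raise ValueError(f"unknown gating method {method!r}")
    labels = values > threshold
    n, k = len(values), int(labels.sum())
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return GateResult(
        threshold=threshold,
        method=method,
        labels=labels,
        n=n,
        n_positive=k,
        percent_positive=100.0 * k / n,
        ci_low=100.0 * lo,
        ci_high=100.0 * hi,
        channel=channel,
    )


def subgroup_stats(
    table: pd.DataFrame,
    channel_a: str,
    channel_b: str,
    gate_a: GateResult,
    gate_b: GateResult,
    value_prefix: str = "scaled_",
    experiment_col: str = "experiment",
) -> dict:
    """Co-expression summary of marker B within the A(+) subgroup.

    Returns percent positive per channel, the percent of A(+) objects that
    are B(+), and the ratio of mean B intensity in A(+) vs A(−) objects with
    a paired two-tailed t-test across experiment labels (when ≥ 2 replicate
    experiments are present).
    """
    if len(gate_a.labels) != len(table) or len(gate_b.labels) != len(table):
        raise ValueError("gate labels must match the table length")
    a = np.asarray(gate_a.labels, dtype=bool)
    b = np.asarray(gate_b.labels, dtype=bool)
    vb = table[f"{value_prefix}{channel_b}"].to_numpy(dtype=float)
    pct_b_given_a = 100.0 * (a & b).sum() / a.sum() if a.sum() else np.nan
    mean_pos = vb[a].mean() if a.any() else np.nan
    mean_neg = vb[~a].mean() if (~a).any() else np.nan
    ratio = mean_pos / mean_neg if mean_neg else np.nan

    p_paired = None
    if experiment_col in table.columns:
        groups = table.assign(_a=a, _b_int=vb).groupby(experiment_col, observed=True)
        pos_means, neg_means = [], []
        for _, g in groups:
            if g["_a"].any() and (~g["_a"]).any():
                pos_means.append(g.loc[g["_a"], "_b_int"].mean())
                neg_means.append(g.loc[~g["_a"], "_b_int"].mean())
        if len(pos_means) >= 2:
            p_paired = float(stats.ttest_rel(pos_means, neg_means).pvalue)
    return {
        "channel_a": channel_a,
        "channel_b": channel_b,
        "percent_positive_a": gate_a.percent_positive,
        "percent_positive_b": gate_b.percent_positive,
        "percent_b_given_a": pct_b_given_a,
        "intensity_ratio_b_in_a": float(ratio),
        "paired_t_p": p_paired,
    }
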