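"""Sequencing branch: RPKM, size factors, count normalization, NB exact test.

The exact test conditions on the total count S = K_A + K_B of a gene: under
the null of equal per-gene abundance, the probability of the observed split
is f_A(a)·f_B(S−a) with f the negative-binomial sampling laws of the two
condition sums, and the two-sided p-value sums the probabilities of all
splits at most as likely as the observed one, normalized over all splits.
All summation runs in log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.nonparametric.smoothers_lowess import lowess

from ..containers import CountMatrix
from .array import quantile_normalize
from .multitest import adjust_bh

__all__ = [
    "estimate_size_factors",
    "compute_rpkm",
    "filter_expressed_rpkm",
    "normalize_counts",
    "nbinom_exact_test",
]

_DISPERSION_FLOOR = 1e-8
_MAX_EXACT_TOTAL = 200_000  # beyond this the conditional law is effectively Gaussian


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1."""
    arr = counts.to_numpy(dtype=float)
    all_positive = (arr > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("size factors need at least one gene with all-positive counts")
    log_counts = np.log(arr[all_positive])
    log_gm = log_counts.mean(axis=1, keepdims=True)
    log_sf = np.median(log_counts - log_gm, axis=0)
    log_sf -= log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def compute_rpkm(
    counts: pd.DataFrame, lengths: pd.Series, totals: Optional[pd.Series] = None
) -> pd.DataFrame:
    """RPKM_gj = 10⁹ · count_gj / (total_j · length_g)."""
    if totals is None:
        totals = counts.sum(axis=0)
    lengths = lengths.loc[counts.index].to_numpy(dtype=float)
    totals = totals.loc[counts.columns].to_numpy(dtype=float)
    return pd.DataFrame(
        1e9 * counts.to_numpy(dtype=float) / (totals[None, :] * lengths[:, None]),
        index=counts.index,
        columns=counts.columns,
    )


def filter_expressed_rpkm(rpkm: pd.DataFrame, min_rpkm: float = 0.1) -> pd.Index:
    """Genes whose mean RPKM strictly exceeds the threshold."""
    return rpkm.index[rpkm.mean(axis=1) > min_rpkm]


def normalize_counts(
    cm: CountMatrix, loess_frac: float = 0.3, min_genes_for_loess: int = 200
) -> CountMatrix:
    """Within-lane GC-loess correction, then between-lane full-quantile normalization.

    Within each lane, log counts are regressed on GC content with a loess
    smoother; the fitted trend is subtracted and the lane re-centred so its
    total count is preserved.  Between lanes, counts are full-quantile
    normalized.  Outputs are rounded to integers with round-half-to-even
    (numpy ``rint``).
    """
    counts = cm.counts.to_numpy(dtype=float)
    gc = cm.gc.to_numpy(dtype=float)
    n_genes, n_samples = counts.shape
    adjusted = counts.copy()
    if n_genes < min_genes_for_loess:
        warnings.warn(
            f"only {n_genes} genes (< {min_genes_for_loess}); skipping GC loess",
            stacklevel=2,
        )
    else:
        for j in range(n_samples):
            log_c = np.log(counts[:, j] + 0.5)
            fit = lowess(log_c, gc, frac=loess_frac, return_sorted=False)
            resid = log_c - fit
            lane = np.exp(resid + fit.mean()) - 0.5
            lane = np.clip(lane, 0.0, None)
            total = counts[:, j].sum()
            if lane.sum() > 0:
                lane *= total / lane.sum()  # preserve the lane total
            adjusted[:, j] = lane
    adjusted_df = pd.DataFrame(adjusted, index=cm.counts.index, columns=cm.counts.columns)
    fq = quantile_normalize(adjusted_df)
    rounded = pd.DataFrame(
        np.rint(fq.to_numpy()).astype(int), index=fq.index, columns=fq.columns
    )
    return CountMatrix(
        counts=rounded,
        lengths=cm.lengths,
        gc=cm.gc,
        conditions=cm.conditions,
        totals=None,  # recomputed from the normalized counts
        size_factors=None,
    )


def _nb_logpmf(k: np.ndarray, mean: float, var: float) -> np.ndarray:
    """Log pmf of a count with matched mean/variance (NB, or Poisson when var <= mean)."""
    if var <= mean * (1 + 1e-12):
        return stats.poisson.logpmf(k, mean)
    r = mean**2 / (var - mean)
    p = r / (r + mean)
    return stats.nbinom.logpmf(k, r, p)


def _exact_split_pvalue(
    k_a: int, k_b: int, mean_a: float, var_a: float, mean_b: float, var_b: float
) -> float:
    """Two-sided conditional p-value of the split (k_a, k_b) given S = k_a + k_b."""
    total = k_a + k_b
    if total == 0:
        return 1.0
    if total > _MAX_EXACT_TOTAL:
        # Gaussian limit of the conditional law of K_A | S
        w = var_a / (var_a + var_b)
        mu = mean_a + (total - mean_a - mean_b) * w
        sd = np.sqrt(var_a * var_b / (var_a + var_b))
        z = abs(k_a - mu) / max(sd, 1e-12)
        return float(min(1.0, 2.0 * stats.norm.sf(z)))
    a = np.arange(total + 1)
    log_p = _nb_logpmf(a, mean_a, var_a) + _nb_logpmf(total - a, mean_b, var_b)
    log_obs = log_p[k_a]
    keep = log_p <= log_obs + 1e-10
    return float(np.exp(logsumexp(log_p[keep]) - logsumexp(log_p)))


@dataclass
class NbTestResult:
    table: pd.DataFrame
    size_factors: pd.Series

    def summary(self) -> str:
        n_sig = int((self.table["adj_p"] < 0.05).sum())
        return f"NB exact test: {len(self.table)} genes, {n_sig} at adj p < 0.05"


def nbinom_exact_test(
    cm: CountMatrix,
    groups: Tuple[str, str] = ("control", "depleted"),
    size_factors: Optional[pd.Series] = None,
    dispersions: Optional[pd.Series] = None,
) -> NbTestResult:
    """Negative-binomial exact test between the two condition count sums.

    Per gene: size-factor-normalized counts give a pooled mean and a
    method-of-moments dispersion (floored at 1e-8); the condition sums K_A
    and K_B are modelled as NB with means q̄·Σ_j sf_j and variances
    Σ_j (q̄·sf_j + α·(q̄·sf_j)²); the p-value sums all splits of S = K_A+K_B
    whose point probability does not exceed the observed one.  Fold-change is
    the ratio of base means in ``groups[0]/groups[1]`` orientation.  All-zero
    genes get p = 1 and are flagged.
    """
    cond = cm.conditions
    idx_a = [s for s in cm.samples if cond[s] == groups[0]]
    idx_b = [s for s in cm.samples if cond[s] == groups[1]]
    if not idx_a or not idx_b:
        raise ValueError(f"need samples in both conditions {groups}")
    if size_factors is None:
        size_factors = cm.size_factors
    if size_factors is None:
        size_factors = estimate_size_factors(cm.counts)
    sf = size_factors.loc[list(cm.samples)]
    counts = cm.counts.to_numpy(dtype=float)
    q = counts / sf.to_numpy()[None, :]

    sf_a = sf.loc[idx_a].to_numpy()
    sf_b = sf.loc[idx_b].to_numpy()
    pos_a = [list(cm.samples).index(s) for s in idx_a]
    pos_b = [list(cm.samples).index(s) for s in idx_b]

    q_bar = q.mean(axis=1)
    if dispersions is not None:
        alpha = np.clip(dispersions.loc[cm.genes].to_numpy(dtype=float), _DISPERSION_FLOOR, None)
    else:
        q_var = q.var(axis=1, ddof=1)
        xi = float(np.mean(1.0 / sf.to_numpy()))
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = (q_var - q_bar * xi) / q_bar**2
        alpha = np.where(np.isfinite(alpha), alpha, 0.0)
        alpha = np.clip(alpha, _DISPERSION_FLOOR, None)

    k_a = counts[:, pos_a].sum(axis=1)
    k_b = counts[:, pos_b].sum(axis=1)
    mean_a = q_bar * sf_a.sum()
    mean_b = q_bar * sf_b.sum()
    var_a = (q_bar[:, None] * sf_a[None, :] + alpha[:, None] * (q_bar[:, None] * sf_a[None, :]) ** 2).sum(axis=1)
    var_b = (q_bar[:, None] * sf_b[None, :] + alpha[:, None] * (q_bar[:, None] * sf_b[None, :]) ** 2).sum(axis=1)

    base_mean_a = q[:, pos_a].mean(axis=1)
    base_mean_b = q[:, pos_b].mean(axis=1)

    pvals = np.ones(len(q_bar))
    flagged = q_bar == 0
    for g in np.flatnonzero(~flagged):
        pvals[g] = _exact_split_pvalue(
            int(k_a[g]), int(k_b[g]), mean_a[g], var_a[g], mean_b[g], var_b[g]
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = base_mean_a / base_mean_b
    table = pd.DataFrame(
        {
            "gene": cm.genes,
            "base_mean": q_bar,
            "base_mean_a": base_mean_a,
            "base_mean_b": base_mean_b,
            "fold_change": fc,
            "dispersion": alpha,
            "p_value": pvals,
            "all_zero": flagged,
        }
    ).set_index("gene")
    table["adj_p"] = adjust_bh(table["p_value"].to_numpy())
    return NbTestResult(table=table, size_factors=pd.Series(sf))
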