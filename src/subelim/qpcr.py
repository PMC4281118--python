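"""Relative qPCR quantification normalized to a reference gene.

The quantity of a target in a sample relative to the control sample is

    Q = E_t^(ΔCt_t) / E_r^(ΔCt_r),   ΔCt = Ct̄(control) − Ct̄(sample),

with E the amplification efficiency (fold per cycle, 2.0 for perfect
doubling) and Ct̄ the mean over replicate wells.  Standard errors propagate
first-order from the replicate Ct standard deviations.  Reported fold-
changes use the signed display convention: Q ≥ 1 prints as +Q, Q < 1 as
−1/Q (so a residual of 12% prints as −8.3-fold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["QpcrMeasurement", "relative_quantity", "fold_report"]


@dataclass
class QpcrMeasurement:
    """Replicate Ct values for one gene in one sample."""

    sample: str
    gene: str
    cts: Sequence[float]
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        cts = np.asarray(self.cts, dtype=float)
        if not np.isfinite(cts).all():
            raise ValueError(f"{self.sample}/{self.gene}: Ct values must be finite")
        if not 1.0 < self.efficiency <= 2.2:
            raise ValueError(f"{self.sample}/{self.gene}: efficiency must lie in (1, 2.2]")
        self.cts = cts

    @property
    def mean_ct(self) -> float:
        return float(self.cts.mean())

    @property
    def se_ct(self) -> float:
        n = len(self.cts)
        return float(self.cts.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0


def fold_report(q: float) -> float:
    """Signed display fold: Q ≥ 1 → +Q, Q < 1 → −1/Q, one decimal."""
    if q <= 0:
        raise ValueError("quantity must be positive")
    return round(q, 1) if q >= 1 else -round(1.0 / q, 1)


def _by_sample(measurements: Iterable[QpcrMeasurement]) -> Dict[str, QpcrMeasurement]:
    out: Dict[str, QpcrMeasurement] = {}
    for m in measurements:
        if m.sample in out:
            raise ValueError(f"duplicate measurement for sample {m.sample!r}")
        out[m.sample] = m
    return out


def relative_quantity(
    target: Iterable[QpcrMeasurement],
    reference: Iterable[QpcrMeasurement],
    control_sample: str,
) -> pd.DataFrame:
    """Reference-normalized relative quantities with control sample = 1.

    ``target`` and ``reference`` (e.g. beta-actin) must cover the same
    samples.  Multi-reference normalization is supported by passing the
    geometric-mean-combined reference as a single measurement series; the
    default design matches a single housekeeping gene.  Returns a DataFrame
    with columns ``sample, gene, quantity, se, signed_fold``.
    """
    tgt = _by_sample(target)
    ref = _by_sample(reference)
    missing = set(tgt) - set(ref)
    if missing:
        raise ValueError(f"missing reference measurements for samples {sorted(missing)}")
    if control_sample not in tgt:
        raise ValueError(f"control sample {control_sample!r} not measured")
    t_ctrl, r_ctrl = tgt[control_sample], ref[control_sample]
    rows = []
    for sample, t in tgt.items():
        r = ref[sample]
        log_et, log_er = np.log(t.efficiency), np.log(r.efficiency)
        d_ct_t = t_ctrl.mean_ct - t.mean_ct
        d_ct_r = r_ctrl.mean_ct - r.mean_ct
        q = t.efficiency**d_ct_t / r.efficiency**d_ct_r
        if sample == control_sample:
            var_log_q = 0.0  # ΔCt ≡ 0 by construction
        else:
            var_log_q = log_et**2 * (t.se_ct**2 + t_ctrl.se_ct**2) + log_er**2 * (
                r.se_ct**2 + r_ctrl.se_ct**2
            )
        rows.append(
            {
                "sample": sample,
                "gene": t.gene,
                "quantity": float(q),
                "se": float(q * np.sqrt(var_log_q)),
                "signed_fold": fold_report(float(q)),
            }
        )
    return pd.DataFrame(rows)
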