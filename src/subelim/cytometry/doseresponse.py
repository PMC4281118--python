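"""Four-parameter logistic dose–response fitting.

The model is f(x) = bottom + (top − bottom) / (1 + (EC50/x)^hill), fitted by
least squares with the EC50 parametrized on the log10 scale (it is a
concentration and must stay positive).  Initialization is multi-start over a
grid of candidate log-EC50 values spanning the dosed range; the best
converged start by residual sum of squares wins.  Non-convergence is
reported through the ``converged`` flag, never as an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np
from scipy.optimize import curve_fit

from ..simulate.doseresponse import four_pl

__all__ = ["DoseResponseFit", "fit_4pl"]


@dataclass
class DoseResponseFit:
    """4PL parameter estimates with standard errors and a convergence flag."""

    bottom: float
    top: float
    ec50: float
    hill: float
    bse: Dict[str, float] = field(default_factory=dict)
    converged: bool = True
    ssr: float = np.nan
    n: int = 0

    def predict(self, x):
        return four_pl(x, self.bottom, self.top, self.ec50, self.hill)

    def params(self) -> Dict[str, float]:
        return {"bottom": self.bottom, "top": self.top, "ec50": self.ec50, "hill": self.hill}

    def summary(self) -> str:
        lines = [
            "Four-parameter logistic fit",
            f"  n = {self.n}, SSR = {self.ssr:.4g}, converged = {self.converged}",
            f"  {'param':<8}{'estimate':>12}{'std err':>12}",
        ]
        for name, value in self.params().items():
            se = self.bse.get(name, np.nan)
            lines.append(f"  {name:<8}{value:>12.4g}{se:>12.4g}")
        return "\n".join(lines)


def _model(x, bottom, top, log10_ec50, hill):
    return four_pl(x, bottom, top, 10.0**log10_ec50, hill)


def fit_4pl(doses, responses) -> DoseResponseFit:
    """Fit the 4PL to (dose, response) observations.

    Requires at least 4 distinct positive doses and finite responses.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValueError("doses and responses must have the same length")
    if (x <= 0).any():
        raise ValueError("doses must be positive")
    if not np.isfinite(y).all():
        raise ValueError("responses must be finite")
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct doses")

    lo, hi = np.log10(x.min()), np.log10(x.max())
    y_lo, y_hi = float(y.min()), float(y.max())
    spread = max(y_hi - y_lo, 1e-12)
    bounds = (
        [y_lo - 2 * spread, y_lo - 2 * spread, lo - 3, 0.05],
        [y_hi + 2 * spread, y_hi + 2 * spread, hi + 3, 10.0],
    )
    best = None
    for log_ec50_0 in np.linspace(lo, hi, 5):
        for hill0 in (0.7, 1.0, 2.0):
            p0 = [y_lo, y_hi, log_ec50_0, hill0]
            try:
                popt, pcov = curve_fit(
                    _model, x, y, p0=p0, bounds=bounds, maxfev=20_000, method="trf"
                )
            except (RuntimeError, ValueError):
                continue
            ssr = float(np.sum((y - _model(x, *popt)) ** 2))
            if best is None or ssr < best[2]:
                best = (popt, pcov, ssr)
    if best is None:
        return DoseResponseFit(
            bottom=float(np.median(y)),
            top=float(np.median(y)),
            ec50=float(np.sqrt(x.min() * x.max())),
            hill=1.0,
            converged=False,
            n=len(x),
        )
    popt, pcov, ssr = best
    bottom, top, log_ec50, hill = popt
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    ec50 = 10.0**log_ec50
    bse = {
        "bottom": float(perr[0]),
        "top": float(perr[1]),
        # delta method: d(ec50)/d(log10 ec50) = ln(10)·ec50
        "ec50": float(np.log(10.0) * ec50 * perr[2]),
        "hill": float(perr[3]),
    }
    if bottom > top:  # canonical orientation: bottom <= top
        bottom, top = top, bottom
        bse["bottom"], bse["top"] = bse["top"], bse["bottom"]
        hill = -hill
    return DoseResponseFit(
        bottom=float(bottom),
        top=float(top),
        ec50=float(ec50),
        hill=float(hill),
        bse=bse,
        converged=True,
        ssr=ssr,
        n=len(x),
    )
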