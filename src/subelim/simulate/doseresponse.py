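"""Four-parameter-logistic dose–response simulator (pRII-style readouts)."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .._rng import spawn

__all__ = ["four_pl", "simulate_dose_response"]


def four_pl(x, bottom: float, top: float, ec50: float, hill: float):
    """f(x) = bottom + (top − bottom) / (1 + (ec50/x)^hill)."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / x) ** hill)


def simulate_dose_response(
    doses: Sequence[float],
    n_per_dose: int,
    cv: float,
    seed: int,
    bottom: float = 1.0,
    top: float = 3.0,
    ec50: float = 377.0,
    hill: float = 1.5,
) -> pd.DataFrame:
    """Replicated responses = 4PL(dose) × mean-one log-normal noise(cv).

    Doses must be positive and strictly increasing (concentrations, nM by
    convention); at cv = 0 the responses are exactly on the curve.
    """
    doses = np.asarray(doses, dtype=float)
    if (doses <= 0).any():
        raise ValueError("doses: all doses must be positive")
    if (np.diff(doses) <= 0).any():
        raise ValueError("doses: must be strictly increasing")
    if cv < 0:
        raise ValueError("cv: must be >= 0")
    if bottom > top:
        raise ValueError("bottom must not exceed top")
    rng = spawn(seed, "dose_response")
    mu = four_pl(doses, bottom, top, ec50, hill)
    rows = []
    sigma = np.sqrt(np.log1p(cv**2))
    for d, m in zip(doses, mu):
        if cv == 0:
            y = np.full(n_per_dose, m)
        else:
            y = m * np.exp(rng.normal(-(sigma**2) / 2, sigma, n_per_dose))
        for i, v in enumerate(y):
            rows.append({"dose": d, "replicate": i + 1, "response": v})
    return pd.DataFrame(rows)
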