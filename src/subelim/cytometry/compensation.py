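"""Fluorescence spill-over estimation and compensation.

Spill-over slopes are estimated from single-stain controls: for the control
stained only in channel j, the intensity of every other channel i is
regressed on channel j by ordinary least squares through an estimated
intercept; the slope is s[i][j] and the intercept is treated as background.
Compensation is full-matrix unmixing — observed = S · true per object, so
true = S⁻¹ · observed — which coincides with sequential subtraction when the
spill is one-way.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ..simulate.cells import SpilloverMatrix

__all__ = ["SpilloverEstimationError", "estimate_spillover", "compensate"]


class SpilloverEstimationError(RuntimeError):
    pass


def _ols_slope(x: np.ndarray, y: np.ndarray, control_name: str) -> float:
    vx = np.var(x)
    if vx <= 0:
        raise SpilloverEstimationError(
            f"control {control_name!r}: zero variance in the stained channel — degenerate regression"
        )
    return float(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1))


def estimate_spillover(
    control_tables: Mapping[str, pd.DataFrame],
    channels: Optional[Sequence[str]] = None,
    value_prefix: str = "raw_",
    min_objects: int = 50,
) -> SpilloverMatrix:
    """Estimate the spill-over matrix from one single-stain control per channel.

    ``control_tables`` maps each stained channel name to its control table
    (columns ``<value_prefix><channel>``).  Channels without a control keep
    zero spill into the others.  Diagonal is fixed at 1.
    """
    if channels is None:
        channels = list(control_tables)
    channels = list(channels)
    mat = pd.DataFrame(np.eye(len(channels)), index=channels, columns=channels)
    for stained, table in control_tables.items():
        if stained not in channels:
            raise ValueError(f"control for unknown channel {stained!r}")
        if len(table) < min_objects:
            raise SpilloverEstimationError(
                f"control {stained!r}: only {len(table)} objects (< {min_objects})"
            )
        x = table[f"{value_prefix}{stained}"].to_numpy(dtype=float)
        for other in channels:
            if other == stained:
                continue
            y = table[f"{value_prefix}{other}"].to_numpy(dtype=float)
            slope = _ols_slope(x, y, stained)
            mat.loc[other, stained] = np.clip(slope, 0.0, 1.0 - 1e-9)
    return SpilloverMatrix(mat)


def compensate(
    table: pd.DataFrame,
    spill: SpilloverMatrix,
    in_prefix: str = "raw_",
    out_prefix: str = "comp_",
) -> pd.DataFrame:
    """Unmix observed intensities: compensated = S⁻¹ · observed per object.

    Raw columns are preserved; compensated columns are added with
    ``out_prefix``.
    """
    channels = spill.channels
    cols = [f"{in_prefix}{ch}" for ch in channels]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks intensity columns {missing}")
    observed = table[cols].to_numpy(dtype=float)
    true = observed @ spill.inverse().T
    out = table.copy()
    for k, ch in enumerate(channels):
        out[f"{out_prefix}{ch}"] = true[:, k]
    return out
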