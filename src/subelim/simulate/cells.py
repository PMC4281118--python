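"""Single-cell immunofluorescence simulator with spill-over.

Each marker follows a two-component log-normal intensity model: cells
positive for the marker draw around a high median, negative cells around a
low one.  Marker positivity is assigned from the ground-truth cell classes —
either directly (TRPV1, UCHL1, PTGDS) or as a stated fraction of neurons
with a stated share of positives falling inside the TRPV1(+) subgroup
(CART, Nos1, CaMKIIα).  Observed intensities are the true intensities mixed
through a known spill-over matrix, and the three single-stain control tables
the compensation stage needs are emitted alongside the full stain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .._rng import spawn
from ..population import NEURON_CLASSES, TRPV1_POS, CellPopulation

__all__ = [
    "MarkerModel",
    "SpilloverMatrix",
    "DEFAULT_MARKERS",
    "default_panel",
    "default_spillover",
    "simulate_single_cell_table",
]


@dataclass(frozen=True)
class MarkerModel:
    """Two-component log-normal intensity model for one marker."""

    name: str
    positive_classes: Optional[tuple] = None  # positivity = membership of these classes
    fraction_of_neurons: Optional[float] = None  # or: a stated fraction of neurons
    trpv1_share: Optional[float] = None  # share of positives that are TRPV1(+)
    restrict_class: Optional[str] = None  # positives drawn only from this class
    neg_median: float = 100.0
    pos_median: float = 1500.0
    sigma_log: float = 0.45

    def __post_init__(self) -> None:
        if (self.positive_classes is None) == (self.fraction_of_neurons is None):
            raise ValueError(f"{self.name}: set exactly one of positive_classes / fraction_of_neurons")
        if self.fraction_of_neurons is not None and not 0 <= self.fraction_of_neurons <= 1:
            raise ValueError(f"{self.name}: fraction_of_neurons must lie in [0, 1]")
        if self.sigma_log <= 0:
            raise ValueError(f"{self.name}: sigma_log must be positive")


DEFAULT_MARKERS: Dict[str, MarkerModel] = {
    "UCHL1": MarkerModel("UCHL1", positive_classes=NEURON_CLASSES, neg_median=30.0, pos_median=1500.0),
    "TRPV1": MarkerModel("TRPV1", positive_classes=(TRPV1_POS,), neg_median=100.0, pos_median=1500.0),
    "CART": MarkerModel("CART", fraction_of_neurons=0.029, trpv1_share=0.79,
                        neg_median=100.0, pos_median=3000.0),
    "NOS1": MarkerModel("NOS1", fraction_of_neurons=0.020, trpv1_share=0.86,
                        neg_median=100.0, pos_median=3000.0),
    "CAMK2A": MarkerModel("CAMK2A", fraction_of_neurons=0.45, trpv1_share=0.56,
                          neg_median=100.0, pos_median=1500.0),
    "PTGDS": MarkerModel("PTGDS", fraction_of_neurons=0.19, restrict_class="nf200_large_neuron",
                         trpv1_share=0.0, neg_median=100.0, pos_median=1500.0),
}


class SpilloverMatrix:
    """Square matrix of spill slopes; s[i][j] = leak of channel j into channel i."""

    def __init__(self, matrix: pd.DataFrame):
        if not matrix.index.equals(matrix.columns):
            raise ValueError("spill-over matrix must be square with matching labels")
        m = matrix.to_numpy(dtype=float)
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("spill-over diagonal must be exactly 1")
        off = m[~np.eye(len(m), dtype=bool)]
        if ((off < 0) | (off >= 1)).any():
            raise ValueError("off-diagonal spill slopes must lie in [0, 1)")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("spill-over matrix is singular")
        self.matrix = matrix.astype(float)

    @property
    def channels(self) -> list:
        return list(self.matrix.index)

    def to_numpy(self) -> np.ndarray:
        return self.matrix.to_numpy()

    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.to_numpy())

    @classmethod
    def identity(cls, channels) -> "SpilloverMatrix":
        return cls(pd.DataFrame(np.eye(len(channels)), index=channels, columns=channels))

    @classmethod
    def from_pairs(cls, channels, pairs: Mapping[tuple, float]) -> "SpilloverMatrix":
        """Build from {(receiving_channel, source_channel): slope} pairs."""
        m = pd.DataFrame(np.eye(len(channels)), index=channels, columns=channels)
        for (i, j), s in pairs.items():
            m.loc[i, j] = s
        return cls(m)


def default_panel() -> Dict[str, str]:
    """Channel → marker map for the default triple stain."""
    return {"ch1": "UCHL1", "ch2": "TRPV1", "ch3": "CART"}


def default_spillover() -> SpilloverMatrix:
    return SpilloverMatrix.from_pairs(
        ["ch1", "ch2", "ch3"],
        {("ch2", "ch1"): 0.04, ("ch3", "ch2"): 0.06, ("ch1", "ch2"): 0.02},
    )


def _assign_marker(cells: pd.DataFrame, model: MarkerModel, rng: np.random.Generator) -> np.ndarray:
    """Boolean positivity per cell (non-neuronal cells are never positive)."""
    cls = cells["cell_class"].astype(str).to_numpy()
    is_neuron = np.isin(cls, NEURON_CLASSES)
    if model.positive_classes is not None:
        return np.isin(cls, list(model.positive_classes))
    n_neurons = int(is_neuron.sum())
    n_target = int(round(model.fraction_of_neurons * n_neurons))
    pos = np.zeros(len(cells), dtype=bool)
    if n_target == 0:
        return pos
    pool = is_neuron.copy()
    if model.restrict_class is not None:
        pool &= cls == model.restrict_class
    if pool.sum() < n_target:
        raise ValueError(
            f"{model.name}: restrict_class {model.restrict_class!r} has too few cells "
            f"for fraction {model.fraction_of_neurons}"
        )
    if model.trpv1_share is None:
        chosen = rng.choice(np.flatnonzero(pool), size=n_target, replace=False)
    else:
        # stratified draw: a stated share of positives falls in the TRPV1(+) class
        in_pos = np.flatnonzero(pool & (cls == TRPV1_POS))
        in_neg = np.flatnonzero(pool & (cls != TRPV1_POS))
        n_in = int(round(model.trpv1_share * n_target))
        n_in = min(n_in, len(in_pos))
        n_out = min(n_target - n_in, len(in_neg))
        chosen = np.concatenate(
            [
                rng.choice(in_pos, size=n_in, replace=False),
                rng.choice(in_neg, size=n_out, replace=False),
            ]
        )
    pos[chosen] = True
    return pos


def _draw_intensity(
    pos: np.ndarray, model: MarkerModel, rng: np.random.Generator, sigma_log: Optional[float]
) -> np.ndarray:
    sigma = model.sigma_log if sigma_log is None else sigma_log
    median = np.where(pos, model.pos_median, model.neg_median)
    return np.exp(rng.normal(np.log(median), sigma))


_AUTOFLUOR_MEDIAN = 10.0
_AUTOFLUOR_SIGMA = 0.3


def simulate_single_cell_table(
    pop: CellPopulation,
    panel: Optional[Mapping[str, str]] = None,
    spill: Optional[SpilloverMatrix] = None,
    seed: int = 0,
    sigma_log: Optional[float] = None,
    condition: str = "control",
    experiment: str = "exp1",
    markers: Optional[Mapping[str, MarkerModel]] = None,
    neurons_only: bool = True,
    reference_channel: Optional[str] = None,
    autofluor_sigma: float = _AUTOFLUOR_SIGMA,
) -> tuple[pd.DataFrame, Dict[str, pd.DataFrame]]:
    """Simulate the full-stain single-cell table plus single-stain controls.

    Returns ``(table, controls)``.  ``controls`` maps each stained channel to
    a control table in which only that channel (plus the neuron-marker
    reference channel) is stained; unstained channels carry autofluorescence.
    All tables share the same spill-over matrix and column layout:
    ``cell_id, condition, experiment, cell_class, diameter_um,
    <marker>_pos, raw_<channel>``.
    """
    panel = dict(panel or default_panel())
    spill = spill or default_spillover()
    markers = dict(markers or DEFAULT_MARKERS)
    channels = spill.channels
    unknown = set(panel) - set(channels)
    if unknown:
        raise ValueError(f"panel channels {sorted(unknown)} not in spill-over matrix")
    if reference_channel is None:
        # the neuron-marker channel: UCHL1 if present, else the first channel
        by_marker = {m: c for c, m in panel.items()}
        reference_channel = by_marker.get("UCHL1", channels[0])

    cells = pop.cells
    if neurons_only:
        cells = cells[cells["cell_class"].isin(NEURON_CLASSES)].reset_index(drop=True)
    rng_assign = spawn(seed, "markers", condition)
    positivity = {}
    for ch in channels:
        name = panel.get(ch)
        if name is None:
            continue
        if name not in markers:
            raise ValueError(f"unknown marker {name!r} for channel {ch}")
        positivity[ch] = _assign_marker(cells, markers[name], rng_assign)

    smat = spill.to_numpy()

    def _one_table(stained: set, tag: str) -> pd.DataFrame:
        rng = spawn(seed, "intensity", condition, tag)
        true = np.empty((len(cells), len(channels)))
        for k, ch in enumerate(channels):
            if ch in stained and ch in positivity:
                true[:, k] = _draw_intensity(positivity[ch], markers[panel[ch]], rng, sigma_log)
            else:
                true[:, k] = np.exp(
                    rng.normal(np.log(_AUTOFLUOR_MEDIAN), autofluor_sigma, len(cells))
                    if autofluor_sigma > 0
                    else np.full(len(cells), np.log(_AUTOFLUOR_MEDIAN))
                )
        observed = true @ smat.T
        out = cells[["cell_id", "cell_class", "diameter_um"]].copy()
        out.insert(1, "condition", condition)
        out.insert(2, "experiment", experiment)
        for ch in channels:
            if ch in positivity:
                out[f"{panel[ch]}_pos"] = positivity[ch]
        for k, ch in enumerate(channels):
            out[f"raw_{ch}"] = observed[:, k]
            out[f"true_{ch}"] = true[:, k]
        return out

    stained_all = set(positivity)
    table = _one_table(stained_all, "full")
    controls: Dict[str, pd.DataFrame] = {}
    for ch in positivity:
        if ch == reference_channel:
            controls[ch] = _one_table({ch}, f"control_{ch}")
        else:
            controls[ch] = _one_table({ch, reference_channel}, f"control_{ch}")
    return table, controls
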