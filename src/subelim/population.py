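"""Simulated sensory-ganglion cell populations and agonist depletion.

A dissociated dorsal-root-ganglion culture is modelled as a finite mixture of
four cell classes: TRPV1(+) nociceptive neurons, TRPV1(−) small neurons,
NF200(+) large myelinated neurons, and non-neuronal cells (glia, fibroblasts),
which outnumber the neurons.  TRPV1 agonists (capsaicin, resiniferatoxin)
compromise TRPV1(+) neurons via calcium cytotoxicity; the subsequent density
separation is abstracted to a single per-cell removal probability ε, so that a
culture with positive fraction ``f0`` among neurons retains an expected
positive fraction ``f0·(1−ε) / (1−f0·ε)`` after treatment.

Ground-truth class labels are kept on every cell, which makes the population
the reference for every downstream stage (bulk profiling, cytometry, qPCR).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from ._rng import spawn

__all__ = [
    "CLASSES",
    "NEURON_CLASSES",
    "TRPV1_POS",
    "PopulationConfig",
    "CellPopulation",
    "DepletionSpec",
    "make_population",
    "apply_depletion",
    "surviving_positive_fraction",
    "removal_probability_for_residual",
    "default_gene_profiles",
]

TRPV1_POS = "trpv1_pos_neuron"
CLASSES = (
    TRPV1_POS,
    "trpv1_neg_small_neuron",
    "nf200_large_neuron",
    "non_neuronal",
)
NEURON_CLASSES = CLASSES[:3]

# Median soma diameters (µm) per class; NF200(+) neurons are the large ones.
_DIAMETER_MEDIAN_UM = {
    TRPV1_POS: 22.0,
    "trpv1_neg_small_neuron": 20.0,
    "nf200_large_neuron": 35.0,
    "non_neuronal": 12.0,
}
_DIAMETER_SIGMA_LOG = 0.15


@dataclass
class PopulationConfig:
    """Mixture weights and size of a simulated culture.

    ``fractions`` are over all four classes and must sum to 1.  The neuron
    classes together should be a minority — non-neuronal cells are in excess
    in dissociated ganglia — but that is a convention, not a hard validation.
    """

    n_cells: int
    fractions: Dict[str, float] = field(
        default_factory=lambda: {
            TRPV1_POS: 0.44 * 0.35,
            "trpv1_neg_small_neuron": 0.36 * 0.35,
            "nf200_large_neuron": 0.20 * 0.35,
            "non_neuronal": 0.65,
        }
    )

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells: must be positive")
        unknown = set(self.fractions) - set(CLASSES)
        if unknown:
            raise ValueError(f"fractions: unknown cell classes {sorted(unknown)}")
        for cls, f in self.fractions.items():
            if f < 0:
                raise ValueError(f"fractions[{cls}]: negative fraction {f}")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions: must sum to 1 (got {total!r})")

    @classmethod
    def from_neurons(
        cls,
        n_neurons: int,
        f_trpv1_pos: float = 0.44,
        f_nf200: float = 0.20,
        neuron_share: float = 0.35,
    ) -> "PopulationConfig":
        """Build a config from the neuron count and within-neuron fractions.

        ``f_trpv1_pos`` and ``f_nf200`` are fractions *among neurons*;
        ``neuron_share`` is the fraction of all cells that are neurons.
        """
        if not 0 < neuron_share < 1:
            raise ValueError("neuron_share: must be in (0, 1)")
        if not 0 <= f_trpv1_pos <= 1 or not 0 <= f_nf200 <= 1:
            raise ValueError("f_trpv1_pos/f_nf200: must lie in [0, 1]")
        if f_trpv1_pos + f_nf200 > 1 + 1e-12:
            raise ValueError("f_trpv1_pos + f_nf200 exceeds 1")
        n_cells = int(round(n_neurons / neuron_share))
        f_small = 1.0 - f_trpv1_pos - f_nf200
        fr = {
            TRPV1_POS: f_trpv1_pos * neuron_share,
            "trpv1_neg_small_neuron": f_small * neuron_share,
            "nf200_large_neuron": f_nf200 * neuron_share,
            "non_neuronal": 1.0 - neuron_share,
        }
        return cls(n_cells=n_cells, fractions=fr)


def default_gene_profiles() -> pd.DataFrame:
    """Per-class mean expression (arbitrary abundance units) for marker genes.

    Trpv1 is exclusive to the positive subgroup; Ptgds is exclusive to
    NF200(+) large neurons; Uchl1 marks all neurons; Actb is ubiquitous.
    """
    data = {
        #                 trpv1+   trpv1-   nf200   non-neuronal
        "Trpv1": [100.0, 0.0, 0.0, 0.0],
        "Cartpt": [40.0, 2.0, 2.0, 0.0],
        "Nos1": [20.0, 1.0, 1.0, 0.0],
        "Camk2a": [30.0, 10.0, 10.0, 0.0],
        "Ptgds": [0.0, 0.0, 80.0, 0.0],
        "Uchl1": [200.0, 200.0, 200.0, 2.0],
        "Actb": [500.0, 500.0, 500.0, 500.0],
    }
    return pd.DataFrame(data, index=list(CLASSES)).T


@dataclass
class CellPopulation:
    """Roster of simulated cells plus the per-class expression profiles."""

    cells: pd.DataFrame  # columns: cell_id, cell_class, diameter_um
    gene_profiles: pd.DataFrame  # genes × classes, mean expression per cell
    marker_map: Optional[pd.DataFrame] = None  # gene → enrichment, exclusive

    def __post_init__(self) -> None:
        if (self.gene_profiles.to_numpy() < 0).any():
            bad = self.gene_profiles.index[(self.gene_profiles < 0).any(axis=1)]
            raise ValueError(f"gene_profiles[{bad[0]}]: negative expression mean")
        if not np.isfinite(self.gene_profiles.to_numpy()).all():
            raise ValueError("gene_profiles: expression means must be finite")
        if (self.cells["diameter_um"] <= 0).any():
            raise ValueError("cells.diameter_um: must be positive")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_neurons(self) -> int:
        return int(self.cells["cell_class"].isin(NEURON_CLASSES).sum())

    def class_counts(self) -> pd.Series:
        counts = self.cells["cell_class"].value_counts()
        return counts.reindex(CLASSES, fill_value=0)

    def positive_fraction_neurons(self) -> float:
        n_neu = self.n_neurons
        if n_neu == 0:
            return float("nan")
        n_pos = int((self.cells["cell_class"] == TRPV1_POS).sum())
        return n_pos / n_neu

    def bulk_signal(self) -> pd.Series:
        """Expected total expression per gene: Σ_class n_class · mean_class."""
        counts = self.class_counts().astype(float)
        return self.gene_profiles.reindex(columns=CLASSES, fill_value=0.0) @ counts

    def positive_mass_share(self) -> float:
        """Share of the total transcriptome mass carried by TRPV1(+) neurons."""
        counts = self.class_counts().astype(float)
        profiles = self.gene_profiles.reindex(columns=CLASSES, fill_value=0.0)
        per_class_mass = profiles.sum(axis=0) * counts
        total = per_class_mass.sum()
        return float(per_class_mass[TRPV1_POS] / total) if total > 0 else 0.0


def make_population(
    config: PopulationConfig,
    seed: int,
    gene_profiles: Optional[pd.DataFrame] = None,
    marker_map: Optional[pd.DataFrame] = None,
) -> CellPopulation:
    """Draw a cell roster multinomially from the configured class fractions."""
    rng = spawn(seed, "population")
    classes = list(CLASSES)
    probs = np.array([config.fractions.get(c, 0.0) for c in classes])
    counts = rng.multinomial(config.n_cells, probs)
    labels = np.repeat(classes, counts)
    diam = np.concatenate(
        [
            rng.lognormal(np.log(_DIAMETER_MEDIAN_UM[c]), _DIAMETER_SIGMA_LOG, n)
            for c, n in zip(classes, counts)
        ]
    )
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(config.n_cells),
            "cell_class": pd.Categorical(labels, categories=classes),
            "diameter_um": diam,
        }
    )
    if gene_profiles is None:
        gene_profiles = default_gene_profiles()
    return CellPopulation(cells=cells, gene_profiles=gene_profiles, marker_map=marker_map)


@dataclass
class DepletionSpec:
    """Agonist treatment turning into a per-cell removal probability ε.

    ε(dose, t) = ε_max · dose^h / (dose^h + ec50^h) · g(t) with g a saturating
    time factor normalized to 1 at the 30-minute reference duration.  Control
    treatments have ε = 0; ``epsilon_override`` pins ε directly (used when a
    residual fraction, not a dose, defines the operating point).
    """

    agonist: str = "rtx"
    dose_nm: float = 100.0
    duration_min: float = 30.0
    epsilon_max: float = 0.97
    ec50_nm: float = 0.05
    hill: float = 1.0
    epsilon_override: Optional[float] = None
    tau_min: float = 10.0
    ref_duration_min: float = 30.0

    def __post_init__(self) -> None:
        if self.agonist not in ("capsaicin", "rtx", "control"):
            raise ValueError(f"agonist: unknown agonist {self.agonist!r}")
        if not 0 <= self.epsilon_max <= 1:
            raise ValueError("epsilon_max: must lie in [0, 1]")
        if self.ec50_nm <= 0 or self.hill <= 0:
            raise ValueError("ec50_nm and hill must be positive")
        if self.dose_nm < 0 or self.duration_min < 0:
            raise ValueError("dose_nm and duration_min must be non-negative")
        if self.epsilon_override is not None and not 0 <= self.epsilon_override <= 1:
            raise ValueError("epsilon_override: must lie in [0, 1]")

    @classmethod
    def capsaicin(cls, dose_nm: float = 10_000.0, duration_min: float = 30.0) -> "DepletionSpec":
        # ε_max chosen so ε(10 µM, 30 min) = 0.83 with half-maximal removal at 1 µM.
        return cls(
            agonist="capsaicin",
            dose_nm=dose_nm,
            duration_min=duration_min,
            epsilon_max=0.913,
            ec50_nm=1000.0,
            hill=1.0,
        )

    @classmethod
    def rtx(cls, dose_nm: float = 100.0, duration_min: float = 30.0) -> "DepletionSpec":
        return cls(
            agonist="rtx",
            dose_nm=dose_nm,
            duration_min=duration_min,
            epsilon_max=0.97,
            ec50_nm=0.05,
            hill=1.0,
        )

    @classmethod
    def control(cls) -> "DepletionSpec":
        return cls(agonist="control", dose_nm=0.0)

    @classmethod
    def from_epsilon(cls, epsilon: float, agonist: str = "rtx") -> "DepletionSpec":
        return cls(agonist=agonist, epsilon_override=float(epsilon))

    def epsilon(self) -> float:
        if self.agonist == "control":
            return 0.0
        if self.epsilon_override is not None:
            return self.epsilon_override
        d = self.dose_nm**self.hill
        hill = self.epsilon_max * d / (d + self.ec50_nm**self.hill)
        tf = (1.0 - np.exp(-self.duration_min / self.tau_min)) / (
            1.0 - np.exp(-self.ref_duration_min / self.tau_min)
        )
        return float(np.clip(hill * min(tf, 1.0 / (1.0 - np.exp(-3.0))), 0.0, 1.0))


def apply_depletion(pop: CellPopulation, spec: DepletionSpec, seed: int) -> CellPopulation:
    """Remove each TRPV1(+) neuron independently with probability ε."""
    if pop.n_cells == 0:
        raise ValueError("population is empty")
    eps = spec.epsilon()
    if eps == 0.0:
        return CellPopulation(pop.cells.copy(), pop.gene_profiles, pop.marker_map)
    rng = spawn(seed, "depletion")
    is_pos = (pop.cells["cell_class"] == TRPV1_POS).to_numpy()
    removed = is_pos & (rng.random(pop.n_cells) < eps)
    cells = pop.cells.loc[~removed].reset_index(drop=True)
    return CellPopulation(cells=cells, gene_profiles=pop.gene_profiles, marker_map=pop.marker_map)


def surviving_positive_fraction(f0: float, epsilon: float) -> float:
    """Expected positive fraction among neurons after Bernoulli(ε) removal."""
    return f0 * (1.0 - epsilon) / (1.0 - f0 * epsilon)


def removal_probability_for_residual(f0: float, f1: float) -> float:
    """Invert the mixture identity: ε such that f0 drops to residual f1."""
    if not 0 < f0 < 1 or not 0 <= f1 <= f0:
        raise ValueError("need 0 < f0 < 1 and 0 <= f1 <= f0")
    return (f0 - f1) / (f0 * (1.0 - f1))
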