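"""Canonical in-silico experiments at the study's operating points.

Each function wires the generators to the analysis operations exactly the
way the corresponding bench experiment was run: simulate a culture at a
stated mixture, deplete at a stated removal probability, push the cells
through the full cytometry path (intensity simulation, spill-over
estimation and compensation, scaling, gating), or push bulk samples through
the array DE branch, and return the measured quantity.  These are the
entry points used for end-to-end validation of the whole pipeline against
closed-form expectations.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from ._rng import spawn
from .cytometry import compensate, estimate_spillover, fit_4pl, gate, normalize_scale
from .de import moderated_t, preprocess_array
from .population import (
    CellPopulation,
    DepletionSpec,
    PopulationConfig,
    apply_depletion,
    make_population,
    surviving_positive_fraction,
)
from .simulate import (
    default_panel,
    default_spillover,
    marker_profile_for_bulk_ratio,
    simulate_array_experiment,
    simulate_dose_response,
    simulate_single_cell_table,
)

__all__ = [
    "cytometry_positive_fraction",
    "depletion_positive_fraction",
    "naive_positive_fraction",
    "rare_marker_fraction",
    "ec50_recovery",
    "array_marker_fold_change",
]

_GATE_CHANNEL = "ch2"  # TRPV1 in the default panel


def _full_cytometry(
    pop_control: CellPopulation,
    pop_treated: Optional[CellPopulation],
    seed: int,
    channel: str = _GATE_CHANNEL,
) -> pd.DataFrame:
    """Simulate, compensate and scale the control(+treated) stain tables."""
    panel, spill = default_panel(), default_spillover()
    table_c, controls = simulate_single_cell_table(
        pop_control, panel, spill, seed=seed, condition="control"
    )
    tables = [table_c]
    if pop_treated is not None:
        table_t, _ = simulate_single_cell_table(
            pop_treated, panel, spill, seed=spawn(seed, "treated").integers(2**31),
            condition="treated"
        )
        tables.append(table_t)
    table = pd.concat(tables, ignore_index=True)
    est = estimate_spillover(controls, channels=spill.channels)
    table = compensate(table, est)
    return normalize_scale(table, "control", channels=spill.channels)


def cytometry_positive_fraction(
    f0: float,
    epsilon: float,
    n_neurons_measured: int,
    seed: int,
    gate_method: str = "density_minimum",
) -> float:
    """Percent marker-positive neurons measured after depletion.

    A culture with pre-treatment positive fraction ``f0`` is sized so the
    expected surviving neuron count equals ``n_neurons_measured``, depleted
    at removal probability ε, and measured by the full cytometry path.  With
    ``gate_method='fixed'`` the threshold is taken from a density gate on
    the control condition (the treated sample alone may have no valley).
    """
    survive = 1.0 - f0 * epsilon  # expected surviving share of neurons
    n_pre = int(round(n_neurons_measured / survive))
    pop = make_population(PopulationConfig.from_neurons(n_pre, f_trpv1_pos=f0), seed=seed)
    depleted = apply_depletion(pop, DepletionSpec.from_epsilon(epsilon), seed=spawn(seed, "dep").integers(2**31))
    table = _full_cytometry(pop, depleted, seed)
    treated = table[table["condition"] == "treated"]
    values_treated = treated[f"scaled_{_GATE_CHANNEL}"]
    if gate_method == "fixed":
        control = table[table["condition"] == "control"]
        g_control = gate(control[f"scaled_{_GATE_CHANNEL}"], method="density_minimum")
        g = gate(values_treated, method="fixed", fixed_threshold=g_control.threshold)
    else:
        g = gate(values_treated, method=gate_method)
    return g.percent_positive


def depletion_positive_fraction(f0: float, epsilon: float) -> float:
    """Closed-form expected surviving positive fraction (percent)."""
    return 100.0 * surviving_positive_fraction(f0, epsilon)


def naive_positive_fraction(
    n_neurons: int,
    seed: int,
    positive_weight: float = 0.44,
    fixed_threshold: float = 0.49,
) -> float:
    """Percent positive in a naive culture by fixed-threshold gating.

    The threshold is the shipped default on data scaled to a control mean
    of 1 (the geometric midpoint of the two intensity modes).
    """
    pop = make_population(
        PopulationConfig.from_neurons(n_neurons, f_trpv1_pos=positive_weight), seed=seed
    )
    table = _full_cytometry(pop, None, seed)
    g = gate(
        table[f"scaled_{_GATE_CHANNEL}"], method="fixed", fixed_threshold=fixed_threshold
    )
    return g.percent_positive


def rare_marker_fraction(
    n_neurons: int, seed: int, weight: float = 0.029, channel: str = "ch3"
) -> float:
    """Percent high-expressors of a rare marker (CART-like) by density gating."""
    pop = make_population(PopulationConfig.from_neurons(n_neurons), seed=seed)
    from .simulate.cells import DEFAULT_MARKERS, MarkerModel

    markers = dict(DEFAULT_MARKERS)
    base = markers["CART"]
    markers["CART"] = MarkerModel(
        "CART",
        fraction_of_neurons=weight,
        trpv1_share=base.trpv1_share,
        neg_median=base.neg_median,
        pos_median=base.pos_median,
        sigma_log=base.sigma_log,
    )
    panel, spill = default_panel(), default_spillover()
    table, controls = simulate_single_cell_table(
        pop, panel, spill, seed=seed, markers=markers
    )
    est = estimate_spillover(controls, channels=spill.channels)
    table = compensate(table, est)
    table = normalize_scale(table, "control", channels=spill.channels)
    g = gate(table[f"scaled_{channel}"], method="density_minimum")
    return g.percent_positive


def ec50_recovery(
    seed: int,
    ec50: float = 377.0,
    doses=None,
    n_per_dose: int = 3,
    cv: float = 0.1,
    bottom: float = 1.0,
    top: float = 3.0,
    hill: float = 1.5,
) -> float:
    """Refit EC50 (nM) from one simulated dose–response experiment."""
    if doses is None:
        doses = np.geomspace(1.0, 1e5, 8)  # 1 nM – 100 µM
    data = simulate_dose_response(
        doses, n_per_dose, cv, seed, bottom=bottom, top=top, ec50=ec50, hill=hill
    )
    fit = fit_4pl(data["dose"], data["response"])
    return fit.ec50


def array_marker_fold_change(
    seed: int,
    bulk_ratio: float = 4.6,
    epsilon: float = 0.9718,
    n_control: int = 4,
    n_depleted: int = 4,
    noise_sd_log2: float = 0.15,
    n_genes: int = 5000,
    n_neurons: int = 4000,
    marker_other_mean: float = 10.0,
) -> float:
    """Marker fold-change recovered by the array DE branch.

    The marker gene's per-class means are solved so its expected
    control/depleted bulk ratio equals ``bulk_ratio`` at removal
    probability ε; the 4+4 experiment is simulated, quantile-normalized,
    filtered, and tested with the moderated t; the marker's fold-change
    estimate is returned.
    """
    from .simulate.bulk import make_gene_profiles

    pop_cfg = PopulationConfig.from_neurons(n_neurons)
    profiles, _ = make_gene_profiles(n_genes, n_enriched=0, seed=spawn(seed, "prof").integers(2**31))
    pop0 = make_population(pop_cfg, seed=seed, gene_profiles=profiles)
    marker = marker_profile_for_bulk_ratio(
        pop0.class_counts(),
        bulk_ratio,
        epsilon,
        other_mean=marker_other_mean,
        background_positive_share=pop0.positive_mass_share(),
    )
    profiles = pd.concat([profiles, marker.to_frame("Trpv1").T])
    pop = CellPopulation(pop0.cells, profiles)
    expr = simulate_array_experiment(
        pop,
        DepletionSpec.from_epsilon(epsilon),
        n_control,
        n_depleted,
        noise_sd_log2,
        seed=spawn(seed, "array").integers(2**31),
    )
    filtered, _ = preprocess_array(expr)
    result = moderated_t(filtered)
    return float(result.table.loc["Trpv1", "fold_change"])
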