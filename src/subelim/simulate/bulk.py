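"""Bulk-platform simulators: array-like log intensities and NB read counts.

The bulk signal of a gene is the population total of its per-class means
(cells of a class contribute their class mean; biological replicate-to-
replicate variation enters through independent depletion draws and through
measurement noise).  The array branch adds log-normal measurement noise and
an additive optical background that also defines the detection p-value; the
sequencing branch draws negative-binomial counts whose expectations are
proportional to abundance × gene length × sequencing depth.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .._rng import spawn
from ..containers import CountMatrix, ExpressionMatrix
from ..population import (
    CLASSES,
    TRPV1_POS,
    CellPopulation,
    DepletionSpec,
    apply_depletion,
)

__all__ = [
    "make_gene_profiles",
    "make_gene_annotation",
    "marker_profile_for_bulk_ratio",
    "simulate_bulk_array",
    "simulate_array_experiment",
    "simulate_bulk_counts",
    "simulate_counts_experiment",
]


def make_gene_profiles(
    n_genes: int,
    n_enriched: int,
    seed: int,
    enrichment_range: tuple[float, float] = (1.5, 12.0),
    frac_exclusive: float = 0.2,
    base_log_mean: float = 2.0,
    base_log_sd: float = 1.0,
    subgroup: str = TRPV1_POS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random per-class expression profiles with a known enriched subset.

    Returns ``(profiles, truth)``: profiles are genes × classes mean
    expression; truth records per gene whether it is subgroup-enriched, its
    enrichment factor, and whether it is subgroup-exclusive.
    """
    if n_enriched > n_genes:
        raise ValueError("n_enriched cannot exceed n_genes")
    rng = spawn(seed, "gene_profiles")
    genes = [f"g{i:05d}" for i in range(n_genes)]
    base = rng.lognormal(base_log_mean, base_log_sd, n_genes)
    profiles = pd.DataFrame(
        np.tile(base[:, None], (1, len(CLASSES))), index=genes, columns=list(CLASSES)
    )
    # non-neuronal cells express a reduced share of the neuronal programme
    profiles["non_neuronal"] *= 0.3
    enriched_idx = rng.choice(n_genes, size=n_enriched, replace=False)
    factors = rng.uniform(*enrichment_range, size=n_enriched)
    exclusive = rng.random(n_enriched) < frac_exclusive
    for i, (gi, f, ex) in enumerate(zip(enriched_idx, factors, exclusive)):
        gene = genes[gi]
        if ex:
            profiles.loc[gene, :] = 0.0
            profiles.loc[gene, subgroup] = base[gi] * f
        else:
            profiles.loc[gene, subgroup] = base[gi] * f
    truth = pd.DataFrame(
        {"enriched": False, "enrichment": 1.0, "exclusive": False}, index=genes
    )
    truth.loc[[genes[i] for i in enriched_idx], "enriched"] = True
    truth.loc[[genes[i] for i in enriched_idx], "enrichment"] = factors
    truth.loc[[genes[i] for i in enriched_idx], "exclusive"] = exclusive
    return profiles, truth


def marker_profile_for_bulk_ratio(
    class_counts: pd.Series,
    ratio: float,
    epsilon: float,
    subgroup: str = TRPV1_POS,
    other_mean: float = 1.0,
    background_positive_share: float = 0.0,
) -> pd.Series:
    """Per-class means giving an expected control/depleted measured ratio.

    The array measures concentrations in a fixed mass of RNA, so depleting
    the subgroup rescales every gene by the surviving share of total mass.
    With a fraction ρ of the marker's mass in the removable subgroup and a
    fraction φ (``background_positive_share``) of the *total* transcriptome
    mass there, the expected measured ratio is R = (1 − ε·φ) / (1 − ε·ρ),
    hence ρ = (1 − (1 − ε·φ)/R) / ε.  The non-subgroup classes share a
    common mean; the subgroup mean is solved from ρ and the class counts.
    """
    if ratio <= 1 or not 0 < epsilon <= 1:
        raise ValueError("need ratio > 1 and epsilon in (0, 1]")
    if not 0 <= background_positive_share < 1:
        raise ValueError("background_positive_share must lie in [0, 1)")
    rho = (1.0 - (1.0 - epsilon * background_positive_share) / ratio) / epsilon
    if rho >= 1 or rho <= 0:
        raise ValueError(
            f"ratio {ratio} is unreachable at epsilon {epsilon} with "
            f"background share {background_positive_share}"
        )
    counts = class_counts.reindex(CLASSES, fill_value=0).astype(float)
    n_pos = counts[subgroup]
    if n_pos == 0:
        raise ValueError("subgroup has no cells")
    mass_other = other_mean * (counts.sum() - n_pos)
    m_pos = rho / (1.0 - rho) * mass_other / n_pos
    prof = pd.Series(other_mean, index=list(CLASSES))
    prof[subgroup] = m_pos
    return prof


def simulate_bulk_array(
    pop: CellPopulation,
    n_replicates: int,
    noise_sd_log2: float,
    seed: int,
    condition: str = "control",
    background_mean: float = 100.0,
    background_sd: float = 30.0,
    total_intensity: float = 1e6,
) -> ExpressionMatrix:
    """Array-like log2 intensities with detection p-values for one condition.

    A fixed mass of RNA is hybridized, so the linear signal of a gene is its
    *share* of the population's bulk expression scaled to ``total_intensity``
    (set ``total_intensity=None`` to report absolute bulk totals instead),
    times log-normal measurement noise (2^N(0, noise_sd_log2)); the reported
    value is log2(signal + 1).  The detection p-value is the upper-tail
    probability of a Gaussian optical background at the observed signal, so
    unexpressed genes get p ≈ 1 and robustly expressed genes p ≈ 0.
    """
    if pop.n_cells == 0:
        raise ValueError("population is empty")
    if n_replicates < 2:
        raise ValueError("n_replicates: need at least 2 replicates")
    if noise_sd_log2 < 0:
        raise ValueError("noise_sd_log2: must be >= 0")
    rng = spawn(seed, "bulk_array", condition)
    signal = pop.bulk_signal().to_numpy()[:, None]
    if total_intensity is not None:
        total = signal.sum()
        if total == 0:
            raise ValueError("population expresses no gene")
        signal = signal / total * total_intensity
    noise = rng.normal(0.0, noise_sd_log2, size=(signal.shape[0], n_replicates))
    linear = signal * np.exp2(noise)
    values = np.log2(linear + 1.0)
    detection = stats.norm.sf(linear, loc=background_mean, scale=background_sd)
    samples = [f"{condition}_{i + 1}" for i in range(n_replicates)]
    genes = pop.gene_profiles.index
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        detection_p=pd.DataFrame(detection, index=genes, columns=samples),
        conditions=pd.Series(condition, index=samples),
    )


def _concat_expression(mats: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    return ExpressionMatrix(
        values=pd.concat([m.values for m in mats], axis=1),
        detection_p=pd.concat([m.detection_p for m in mats], axis=1),
        conditions=pd.concat([m.conditions for m in mats]),
        probe_to_gene=mats[0].probe_to_gene,
    )


def simulate_array_experiment(
    pop: CellPopulation,
    spec: DepletionSpec,
    n_control: int,
    n_depleted: int,
    noise_sd_log2: float,
    seed: int,
    **kwargs,
) -> ExpressionMatrix:
    """Control vs depleted array experiment with fresh depletion per replicate."""
    control = simulate_bulk_array(
        pop, n_control, noise_sd_log2, seed, condition="control", **kwargs
    )
    cols = []
    for i in range(n_depleted):
        dep_pop = apply_depletion(pop, spec, spawn(seed, "rep", i).integers(2**31))
        m = simulate_bulk_array(
            dep_pop, 2, noise_sd_log2, spawn(seed, "dep", i).integers(2**31),
            condition="depleted", **kwargs
        )
        col = m.values.iloc[:, [0]].rename(columns={m.values.columns[0]: f"depleted_{i + 1}"})
        dp = m.detection_p.iloc[:, [0]].rename(
            columns={m.detection_p.columns[0]: f"depleted_{i + 1}"}
        )
        cols.append(
            ExpressionMatrix(col, dp, pd.Series("depleted", index=col.columns))
        )
    return _concat_expression([control] + cols)


def make_gene_annotation(
    genes: Sequence[str],
    seed: int,
    length_range_bp: tuple[float, float] = (500.0, 10_000.0),
) -> pd.DataFrame:
    """Gene lengths (log-uniform) and GC fractions (Beta-shaped around 0.5)."""
    rng = spawn(seed, "annotation")
    n = len(genes)
    lengths = np.exp(rng.uniform(np.log(length_range_bp[0]), np.log(length_range_bp[1]), n))
    gc = 0.3 + 0.4 * rng.beta(5, 5, n)
    return pd.DataFrame(
        {"length_bp": np.round(lengths).astype(int), "gc_fraction": gc},
        index=pd.Index(genes, name="gene_id"),
    )


def simulate_bulk_counts(
    pop: CellPopulation,
    depth: int,
    dispersion: float,
    gene_annotation: pd.DataFrame,
    seed: int,
    n_replicates: int = 1,
    condition: str = "control",
    gc_bias: Optional[Sequence[float]] = None,
) -> CountMatrix:
    """Negative-binomial gene counts for one condition.

    μ_gj ∝ abundance_g × length_g, scaled so each sample's expected total is
    ``depth``; counts have variance μ + dispersion·μ².  ``gc_bias`` injects a
    per-sample log-linear lane effect in GC content (used to exercise the
    GC-loess normalization); expectations are re-normalized so the injected
    trend does not change the expected lane total.
    """
    if pop.n_cells == 0:
        raise ValueError("population is empty")
    if depth <= 0:
        raise ValueError("depth: must be positive")
    if dispersion < 0:
        raise ValueError("dispersion: must be >= 0")
    genes = pop.gene_profiles.index
    missing = genes.difference(gene_annotation.index)
    if len(missing):
        raise ValueError(f"gene_annotation: missing rows for genes {list(missing)}")
    ann = gene_annotation.loc[genes]
    lengths = ann["length_bp"].astype(float).to_numpy()
    if (lengths < 1).any():
        raise ValueError("gene_annotation.length_bp: every gene needs length >= 1 bp")
    gc = ann["gc_fraction"].astype(float).to_numpy()
    abundance = pop.bulk_signal().to_numpy()
    weight = abundance * lengths
    if weight.sum() == 0:
        raise ValueError("population expresses no annotated gene")
    rng = spawn(seed, "bulk_counts", condition)
    if gc_bias is None:
        gc_bias = [0.0] * n_replicates
    if len(gc_bias) != n_replicates:
        raise ValueError("gc_bias: need one slope per replicate")
    cols = {}
    for j in range(n_replicates):
        w = weight * np.exp(gc_bias[j] * (gc - gc.mean()))
        mu = depth * w / w.sum()
        if dispersion == 0:
            k = rng.poisson(mu)
        else:
            r = 1.0 / dispersion
            k = rng.negative_binomial(r, r / (r + np.where(mu > 0, mu, 1e-12)))
            k = np.where(mu > 0, k, 0)
        cols[f"{condition}_{j + 1}"] = k
    counts = pd.DataFrame(cols, index=genes)
    return CountMatrix(
        counts=counts,
        lengths=ann["length_bp"],
        gc=ann["gc_fraction"],
        conditions=pd.Series(condition, index=counts.columns),
    )


def simulate_counts_experiment(
    pop: CellPopulation,
    spec: DepletionSpec,
    n_control: int,
    n_depleted: int,
    depth: int,
    dispersion: float,
    gene_annotation: pd.DataFrame,
    seed: int,
    **kwargs,
) -> CountMatrix:
    """Control vs depleted count experiment with fresh depletion per replicate."""
    control = simulate_bulk_counts(
        pop, depth, dispersion, gene_annotation, seed,
        n_replicates=n_control, condition="control", **kwargs
    )
    dep_cols = []
    for i in range(n_depleted):
        dep_pop = apply_depletion(pop, spec, spawn(seed, "seqrep", i).integers(2**31))
        m = simulate_bulk_counts(
            dep_pop, depth, dispersion, gene_annotation,
            spawn(seed, "seqdep", i).integers(2**31),
            n_replicates=1, condition="depleted", **kwargs
        )
        dep_cols.append(m.counts.rename(columns={m.counts.columns[0]: f"depleted_{i + 1}"}))
    counts = pd.concat([control.counts] + dep_cols, axis=1)
    conditions = pd.Series(
        ["control"] * n_control + ["depleted"] * n_depleted, index=counts.columns
    )
    return CountMatrix(
        counts=counts,
        lengths=control.lengths,
        gc=control.gc,
        conditions=conditions,
    )
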