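"""Bulk-platform data containers shared by the simulator and the DE code.

Two containers mirror the two profiling platforms:

``ExpressionMatrix``
    genes/probes × samples log2 intensities with per-probe detection
    p-values, as produced by a bead-array scan after background correction.
``CountMatrix``
    genes × samples non-negative integer read counts with the gene lengths
    and GC fractions needed for RPKM and GC-loess normalization.

Both carry a per-sample condition label Series aligned to the columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "CountMatrix"]


@dataclass
class ExpressionMatrix:
    """Log2 expression values plus detection p-values for an array-like platform."""

    values: pd.DataFrame
    detection_p: pd.DataFrame
    conditions: pd.Series
    probe_to_gene: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.detection_p.index):
            raise ValueError("values and detection_p must share the probe index")
        if not self.values.columns.equals(self.detection_p.columns):
            raise ValueError("values and detection_p must share the sample columns")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("values: all log2 intensities must be finite")
        dp = self.detection_p.to_numpy()
        if ((dp < 0) | (dp > 1)).any():
            raise ValueError("detection_p: detection p-values must lie in [0, 1]")
        self.conditions = pd.Series(self.conditions)
        if list(self.conditions.index) != list(self.values.columns):
            self.conditions.index = self.values.columns

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    def subset_probes(self, probes) -> "ExpressionMatrix":
        return replace(
            self,
            values=self.values.loc[probes],
            detection_p=self.detection_p.loc[probes],
            probe_to_gene=None if self.probe_to_gene is None else self.probe_to_gene.loc[probes],
        )

    def genes(self) -> pd.Series:
        """Gene symbol per probe (identity map when no probe annotation is set)."""
        if self.probe_to_gene is None:
            return pd.Series(self.values.index, index=self.values.index)
        return self.probe_to_gene


@dataclass
class CountMatrix:
    """Integer read counts with the annotation needed for normalization."""

    counts: pd.DataFrame
    lengths: pd.Series
    gc: pd.Series
    conditions: pd.Series
    totals: Optional[pd.Series] = None
    size_factors: Optional[pd.Series] = field(default=None)

    def __post_init__(self) -> None:
        k = self.counts.to_numpy()
        if (k < 0).any():
            raise ValueError("counts: read counts must be >= 0")
        if not np.allclose(k, np.round(k)):
            raise ValueError("counts: read counts must be integers")
        missing = self.counts.index.difference(self.lengths.index)
        if len(missing):
            raise ValueError(f"lengths: missing annotation for genes {list(missing)[:5]}")
        missing = self.counts.index.difference(self.gc.index)
        if len(missing):
            raise ValueError(f"gc: missing annotation for genes {list(missing)[:5]}")
        self.lengths = self.lengths.loc[self.counts.index].astype(float)
        self.gc = self.gc.loc[self.counts.index].astype(float)
        if (self.lengths < 1).any():
            raise ValueError("lengths: every gene needs length >= 1 bp")
        self.conditions = pd.Series(self.conditions)
        if list(self.conditions.index) != list(self.counts.columns):
            self.conditions.index = self.counts.columns
        if self.totals is None:
            self.totals = self.counts.sum(axis=0).astype(float)

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts.loc[genes],
            lengths=self.lengths.loc[genes],
            gc=self.gc.loc[genes],
            conditions=self.conditions,
            totals=self.totals,
            size_factors=self.size_factors,
        )
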