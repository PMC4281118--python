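"""Cross-platform merging, concordance, ranking, and overlap enrichment.

Candidates are genes with adjusted p < 0.05 and fold-change > 1.5 (in either
direction, strict inequalities) on at least one platform, fold-changes being
oriented control/depleted so FC > 1 means enriched in the eliminated
subgroup.  Concordance between the platforms' fold-changes is Spearman rank
correlation with a seeded permutation p-value.  Candidate overlap against an
external gene list is the one-sided (upper-tail) hypergeometric test over a
coding-genome universe of 22 777 genes by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from ._rng import spawn

__all__ = [
    "MergedPlatforms",
    "merge_platforms",
    "concordance",
    "EnrichmentResult",
    "overlap_enrichment",
    "rank_table",
]

DEFAULT_UNIVERSE = 22_777


def _qualifies(fc: pd.Series, adj_p: pd.Series, p_cut: float, fc_cut: float) -> pd.Series:
    strong = (fc > fc_cut) | (fc < 1.0 / fc_cut)
    return (adj_p < p_cut) & strong & fc.notna() & adj_p.notna()


@dataclass
class MergedPlatforms:
    """Union of per-gene statistics with the candidate rule applied."""

    table: pd.DataFrame
    n_up: int
    n_down: int
    n_discordant: int

    def candidates(self, direction: Optional[str] = None) -> pd.DataFrame:
        t = self.table[self.table["candidate"].astype(bool)]
        if direction is not None:
            t = t[t["direction"] == direction]
        return t

    def summary(self) -> str:
        return (
            f"merged platforms: {len(self.table)} genes, "
            f"{self.n_up} up / {self.n_down} down in the subgroup, "
            f"{self.n_discordant} discordant (excluded)"
        )


def merge_platforms(
    array_stats: pd.DataFrame,
    seq_stats: pd.DataFrame,
    p_cut: float = 0.05,
    fc_cut: float = 1.5,
) -> MergedPlatforms:
    """Merge per-gene statistics of the two platforms with the candidate rule.

    Both inputs need columns ``gene``, ``fold_change`` and ``adj_p`` (FCs in
    control/depleted orientation); ``seq_stats`` may carry ``rpkm``.  Arrays
    with several probes per gene are collapsed to the probe with minimum
    adjusted p.  Genes qualifying on both platforms in opposite directions
    are flagged discordant and excluded from the candidate counts.
    """
    arr = array_stats.reset_index()
    if "gene" not in arr.columns:
        raise ValueError("array_stats needs a 'gene' column")
    arr = arr.sort_values("adj_p").drop_duplicates("gene").set_index("gene")
    seq = seq_stats.reset_index()
    if "gene" not in seq.columns:
        raise ValueError("seq_stats needs a 'gene' column")
    seq = seq.sort_values("adj_p").drop_duplicates("gene").set_index("gene")

    genes = arr.index.union(seq.index)
    out = pd.DataFrame(index=genes)
    out["fc_array"] = arr["fold_change"].reindex(genes)
    out["adjp_array"] = arr["adj_p"].reindex(genes)
    out["fc_seq"] = seq["fold_change"].reindex(genes)
    out["adjp_seq"] = seq["adj_p"].reindex(genes)
    out["rpkm"] = seq["rpkm"].reindex(genes) if "rpkm" in seq.columns else np.nan

    qual_a = _qualifies(out["fc_array"], out["adjp_array"], p_cut, fc_cut)
    qual_s = _qualifies(out["fc_seq"], out["adjp_seq"], p_cut, fc_cut)
    dir_a = np.where(out["fc_array"] > 1, "up_in_subgroup", "down_in_subgroup")
    dir_s = np.where(out["fc_seq"] > 1, "up_in_subgroup", "down_in_subgroup")

    direction = np.where(qual_a, dir_a, np.where(qual_s, dir_s, None))
    discordant = qual_a & qual_s & (dir_a != dir_s)
    candidate = (qual_a | qual_s) & ~discordant

    out["candidate"] = candidate
    out["discordant"] = discordant
    out["direction"] = pd.Series(direction, index=genes).where(candidate)
    n_up = int((out["direction"] == "up_in_subgroup").sum())
    n_down = int((out["direction"] == "down_in_subgroup").sum())
    return MergedPlatforms(
        table=out, n_up=n_up, n_down=n_down, n_discordant=int(discordant.sum())
    )


def concordance(
    fc_a, fc_b, n_permutations: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Spearman ρ of paired fold-changes with a seeded permutation p-value.

    Implemented as Pearson correlation on mid-ranks (average tie handling);
    the p-value is the two-sided permutation tail over ``n_permutations``
    shuffles of one vector.
    """
    a = np.asarray(fc_a, dtype=float)
    b = np.asarray(fc_b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need >= 3 paired fold-changes")
    ra = stats.rankdata(a, method="average")
    rb = stats.rankdata(b, method="average")
    rho = float(np.corrcoef(ra, rb)[0, 1])
    rng = spawn(seed, "concordance")
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(rb)
        if abs(np.corrcoef(ra, perm)[0, 1]) >= abs(rho) - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return rho, float(p)


@dataclass
class EnrichmentResult:
    """Upper-tail hypergeometric overlap of a candidate set with a reference set."""

    overlap: int
    candidate_size: int
    reference_size: int
    universe: int
    p_value: float

    @property
    def expected_overlap(self) -> float:
        return self.candidate_size * self.reference_size / self.universe

    def summary(self) -> str:
        return (
            f"overlap {self.overlap} of {self.candidate_size}×{self.reference_size} "
            f"in universe {self.universe}: expected {self.expected_overlap:.2f}, "
            f"one-sided p = {self.p_value:.3g}"
        )


def overlap_enrichment(
    candidates: Iterable[str],
    reference: Iterable[str],
    universe_size: int = DEFAULT_UNIVERSE,
) -> EnrichmentResult:
    """One-sided overrepresentation test: P(X ≥ k) under the hypergeometric law.

    X counts reference genes in a random candidate-sized draw from the
    universe; the tail is accumulated in log space.
    """
    cand = set(candidates)
    ref = set(reference)
    n, big_k = len(cand), len(ref)
    if big_k > universe_size or n > universe_size:
        raise ValueError("reference or candidate set larger than the universe")
    k = len(cand & ref)
    if k == 0:
        p = 1.0
    else:
        upper = min(n, big_k)
        support = np.arange(k, upper + 1)
        log_pmf = stats.hypergeom.logpmf(support, universe_size, big_k, n)
        p = float(np.exp(logsumexp(log_pmf)))
    return EnrichmentResult(
        overlap=k,
        candidate_size=n,
        reference_size=big_k,
        universe=universe_size,
        p_value=min(p, 1.0),
    )


def rank_table(
    merged: MergedPlatforms, min_rpkm: float = 0.5, top_n: int = 50
) -> pd.DataFrame:
    """Top-N subgroup-enriched genes: RPKM > threshold, sorted by best-platform FC.

    Sort key: maximum fold-change over the platforms, descending; ties by
    the smaller adjusted p, ascending.
    """
    t = merged.candidates("up_in_subgroup").copy()
    t = t[t["rpkm"] > min_rpkm]
    if t.empty:
        return t
    t["max_fc"] = t[["fc_array", "fc_seq"]].max(axis=1)
    t["min_adjp"] = t[["adjp_array", "adjp_seq"]].min(axis=1)
    t = t.sort_values(["max_fc", "min_adjp"], ascending=[False, True])
    return t.head(top_n).drop(columns=["candidate", "discordant"])
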