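"""Chromatin-state transition analysis between two genome segmentations.

Given ChromHMM-style segmentations of a normal and a tumor sample, the
genome is cut into fixed-width bins (200 bp by default), each bin is
assigned the state covering most of it, and the joint occupancy of
(normal state i, tumor state j) is compared with the expectation under
independence:

    RES[i][j] = observed[i][j] / expected[i][j]
    NES[i][j] = RES[i][j] / RES[j][i]

RES > 1 marks state pairs jointly occupied more often than chance; NES > 1
marks a directional preference for the i -> j transition over its reverse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GeneModel, GenomicInterval, promoter_of

logger = logging.getLogger(__name__)

__all__ = [
    "StateSegmentation",
    "BinnedTrack",
    "TransitionEnrichment",
    "STATE_PRESET_19",
    "STATE_GROUPS_19",
    "bin_segmentation",
    "joint_occupancy",
    "raw_enrichment",
    "normalized_enrichment",
    "chisq_independence",
    "transition_genes",
]

# 19-state vocabulary with functional group annotations.
STATE_PRESET_19: tuple[str, ...] = tuple(f"E{i}" for i in range(1, 20))
STATE_GROUPS_19: dict[str, str] = {
    **{f"E{i}": "promoter" for i in range(1, 5)},
    **{f"E{i}": "transcribed" for i in range(5, 9)},
    **{f"E{i}": "enhancer" for i in range(9, 15)},
    "E15": "znf",
    "E16": "bivalent_tss",
    "E17": "bivalent_weak_enhancer",
    "E18": "polycomb",
    "E19": "quiescent",
}


@dataclass
class StateSegmentation:
    """A genome partition into labeled state intervals for one condition."""

    condition: str
    intervals: list[GenomicInterval]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping segments in {self.condition}: "
                        f"{chrom}:{a.start}-{a.end} and {chrom}:{b.start}-{b.end}"
                    )

    @property
    def states(self) -> list[str]:
        return sorted({str(iv.payload) for iv in self.intervals})


@dataclass
class BinnedTrack:
    """Fixed-width binning of a segmentation: (chrom, bin_index) -> state."""

    bin_size: int
    bins: dict[tuple[str, int], str]


@dataclass
class TransitionEnrichment:
    """Joint bin-occupancy counts and enrichment matrices for a state pair grid.

    All matrices are DataFrames indexed by normal state (rows) and tumor
    state (columns). Undefined RES/NES entries are NaN, never infinite.
    """

    states: list[str]
    observed: pd.DataFrame
    total_bins: int
    n_excluded: int = 0
    expected: pd.DataFrame | None = None
    res: pd.DataFrame | None = None
    nes: pd.DataFrame | None = None

    def normal_marginal(self) -> pd.Series:
        return self.observed.sum(axis=1)

    def tumor_marginal(self) -> pd.Series:
        return self.observed.sum(axis=0)


def bin_segmentation(seg: StateSegmentation, bin_size: int = 200) -> BinnedTrack:
    """Assign each covered bin the state occupying most of its bases.

    A bin straddling a state boundary goes to the majority state; exact
    ties go to the leftmost (first-encountered) state. Uncovered bins are
    absent from the track.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    cover: dict[tuple[str, int], dict[str, int]] = {}
    order: dict[tuple[str, int], dict[str, int]] = {}
    ivs = sorted(seg.intervals, key=lambda iv: (iv.chrom, iv.start))
    for rank, iv in enumerate(ivs):
        state = str(iv.payload)
        first = iv.start // bin_size
        last = (iv.end - 1) // bin_size
        for b in range(first, last + 1):
            lo = max(iv.start, b * bin_size)
            hi = min(iv.end, (b + 1) * bin_size)
            key = (iv.chrom, b)
            cover.setdefault(key, {})
            order.setdefault(key, {})
            cover[key][state] = cover[key].get(state, 0) + (hi - lo)
            order[key].setdefault(state, rank)
    bins: dict[tuple[str, int], str] = {}
    for key, counts in cover.items():
        # majority bp; ties resolved by leftmost interval order
        best = min(counts, key=lambda s: (-counts[s], order[key][s]))
        bins[key] = best
    return BinnedTrack(bin_size=bin_size, bins=bins)


def joint_occupancy(
    normal: BinnedTrack,
    tumor: BinnedTrack,
    states: Sequence[str] | None = None,
) -> TransitionEnrichment:
    """Count bins assigned state i in normal and state j in tumor.

    Bins present in only one track are excluded (their count is logged and
    carried on the result).
    """
    if normal.bin_size != tumor.bin_size:
        raise ValueError(
            f"bin_size mismatch: normal {normal.bin_size} vs tumor {tumor.bin_size}"
        )
    shared = normal.bins.keys() & tumor.bins.keys()
    n_excluded = (
        len(normal.bins.keys() | tumor.bins.keys()) - len(shared)
    )
    if n_excluded:
        logger.info("joint_occupancy: excluded %d bins present in one track only", n_excluded)
    if states is None:
        states = sorted(
            {normal.bins[k] for k in shared} | {tumor.bins[k] for k in shared}
        )
    states = list(states)
    idx = {s: i for i, s in enumerate(states)}
    obs = np.zeros((len(states), len(states)), dtype=np.int64)
    for key in shared:
        obs[idx[normal.bins[key]], idx[tumor.bins[key]]] += 1
    observed = pd.DataFrame(obs, index=states, columns=states)
    return TransitionEnrichment(
        states=states,
        observed=observed,
        total_bins=len(shared),
        n_excluded=n_excluded,
    )


def raw_enrichment(te: TransitionEnrichment) -> TransitionEnrichment:
    """Fill expected counts and RES under the independence null."""
    if te.total_bins == 0:
        raise ValueError("no co-covered bins: total_bins is 0")
    rows = te.normal_marginal().to_numpy(dtype=float)
    cols = te.tumor_marginal().to_numpy(dtype=float)
    expected = np.outer(rows, cols) / te.total_bins
    with np.errstate(divide="ignore", invalid="ignore"):
        res = np.where(expected > 0, te.observed.to_numpy() / expected, np.nan)
    te.expected = pd.DataFrame(expected, index=te.states, columns=te.states)
    te.res = pd.DataFrame(res, index=te.states, columns=te.states)
    return te


def normalized_enrichment(te: TransitionEnrichment) -> TransitionEnrichment:
    """Fill NES: RES of i->j divided by RES of the reverse transition j->i.

    Entries are NaN (flagged undefined, never infinite) when the reverse
    RES is zero or either side is undefined.
    """
    if te.res is None:
        raise ValueError("raw_enrichment must run before normalized_enrichment")
    r = te.res.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        nes = np.where((r.T > 0) & np.isfinite(r.T) & np.isfinite(r), r / r.T, np.nan)
    # a state mapping onto itself is, by construction, not a transition
    np.fill_diagonal(nes, np.where(np.diag(r) > 0, 1.0, np.nan))
    te.nes = pd.DataFrame(nes, index=te.states, columns=te.states)
    return te


def chisq_independence(te: TransitionEnrichment) -> dict:
    """Pearson chi-square of the observed grid against independence."""
    obs = te.observed.to_numpy(dtype=float)
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("degenerate table: fewer than 2 non-zero rows or columns")
    result = stats.chi2_contingency(obs, correction=False)
    return {"statistic": float(result[0]), "df": int(result[2]), "p": float(result[1])}


def transition_genes(
    normal: BinnedTrack,
    tumor: BinnedTrack,
    from_state: str,
    to_state: str,
    genes: Sequence[GeneModel],
    flank: int = 2000,
) -> list[str]:
    """Genes whose promoter holds >=1 bin transitioning from_state -> to_state."""
    if normal.bin_size != tumor.bin_size:
        raise ValueError("tracks must share the bin grid")
    known = {s for s in normal.bins.values()} | {s for s in tumor.bins.values()}
    for s in (from_state, to_state):
        if s not in known:
            raise ValueError(f"unknown state {s!r}; known states: {sorted(known)}")
    bs = normal.bin_size
    hits: set[str] = set()
    for g in genes:
        prom = promoter_of(g, flank=flank)
        first = prom.start // bs
        last = (prom.end - 1) // bs
        for b in range(first, last + 1):
            key = (g.chrom, b)
            if normal.bins.get(key) == from_state and tumor.bins.get(key) == to_state:
                hits.add(g.gene_id)
                break
    return sorted(hits)
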