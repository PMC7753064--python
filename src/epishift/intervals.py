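"""Genomic-interval engine.

Overlap arithmetic, co-localization significance, promoter construction and
priority-based feature annotation for differential epigenetically modified
regions (DEMRs). All coordinates follow the BED convention: 0-based,
half-open [start, end).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "FeatureAnnotation",
    "FEATURE_PRIORITY",
    "intersect",
    "fisher_colocalization",
    "promoter_of",
    "annotate_feature",
    "mark_combination_counts",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with an opaque payload.

    The payload carries whatever label the caller attaches: a chromatin
    state, a mark name, an alteration direction.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    payload: object = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval with empty chromosome name")
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} (end <= start)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS/TES and ordered exon structure."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...] = ()
    utr5: tuple[int, int] | None = None
    utr3: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.tx_end <= self.tx_start:
            raise ValueError(f"gene {self.gene_id}: tx_end <= tx_start")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"gene {self.gene_id}: malformed exon {s}-{e}")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start site: tx_start on +, tx_end on -."""
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tes(self) -> int:
        return self.tx_end if self.strand == "+" else self.tx_start

    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return tuple(out)

    def cds_intervals(self) -> tuple[tuple[int, int], ...]:
        """Union of exons minus UTRs — the coding-sequence scope."""
        cut = [u for u in (self.utr5, self.utr3) if u is not None]
        out = []
        for s, e in self.exons:
            pieces = [(s, e)]
            for cs, ce in cut:
                nxt = []
                for ps, pe in pieces:
                    if ce <= ps or cs >= pe:
                        nxt.append((ps, pe))
                        continue
                    if ps < cs:
                        nxt.append((ps, cs))
                    if ce < pe:
                        nxt.append((ce, pe))
                pieces = nxt
            out.extend(pieces)
        return tuple(out)


# Annotation categories ordered by assignment priority (highest first).
FEATURE_PRIORITY: tuple[str, ...] = (
    "Promoter(<1kb)",
    "Promoter(1-2kb)",
    "UTR5",
    "UTR3",
    "FirstExon",
    "OtherExon",
    "FirstIntron",
    "OtherIntron",
    "Downstream",
    "DistalIntergenic",
)

_PRIORITY_RANK = {name: i for i, name in enumerate(FEATURE_PRIORITY)}

DOWNSTREAM_MAX = 3000  # bp past the strand-aware gene end still called Downstream


@dataclass(frozen=True)
class FeatureAnnotation:
    feature: str
    gene_id: str | None

    def __post_init__(self) -> None:
        if self.feature not in _PRIORITY_RANK:
            raise ValueError(f"unknown feature category {self.feature!r}")


# ---------------------------------------------------------------------------
# interval arithmetic


def _to_pyranges(ivs: Sequence[GenomicInterval], label: str) -> pr.PyRanges:
    for i, iv in enumerate(ivs):
        if not isinstance(iv, GenomicInterval):
            raise TypeError(f"{label}[{i}] is not a GenomicInterval")
    return pr.PyRanges(
        chromosomes=[iv.chrom for iv in ivs],
        starts=[iv.start for iv in ivs],
        ends=[iv.end for iv in ivs],
    )


def merge(ivs: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Sorted union of intervals, overlapping/adjacent runs merged."""
    if not ivs:
        return []
    df = _to_pyranges(ivs, "intervals").merge().df
    return [
        GenomicInterval(str(r.Chromosome), int(r.Start), int(r.End))
        for r in df.itertuples()
    ]


def intersect(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Maximal intervals covered by both a and b (as base sets).

    Output is sorted and non-overlapping within each chromosome; the total
    returned length equals the overlap in bp.
    """
    if not a or not b:
        return []
    ra = _to_pyranges(a, "a").merge()
    rb = _to_pyranges(b, "b").merge()
    df = ra.intersect(rb).df
    if df.empty:
        return []
    df = df.sort_values(["Chromosome", "Start"], kind="mergesort")
    return [
        GenomicInterval(str(r.Chromosome), int(r.Start), int(r.End))
        for r in df.itertuples()
    ]


def _overlap_counts(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> tuple[int, int]:
    """(number of a-intervals overlapping any b-interval, a-only count)."""
    rb = _to_pyranges(b, "b").merge()
    ra = _to_pyranges(a, "a")
    hit = ra.count_overlaps(rb).df
    n_hit = int((hit["NumberOverlaps"] > 0).sum())
    return n_hit, len(a) - n_hit


def fisher_exact_two_tail(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table."""
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p)


def fisher_colocalization(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    genome_size: int,
) -> dict:
    """Two-tailed Fisher exact test of co-localization of two region sets.

    The contingency table mirrors the model used by ``bedtools fisher``:
    the genome is treated as a population of slots of size
    mean_len(a) + mean_len(b); n22 estimates the slots hit by neither set.
    """
    if not a or not b:
        raise ValueError("degenerate contingency table: empty interval list")
    n11, n12 = _overlap_counts(a, b)
    n21 = _overlap_counts(b, a)[1]
    mean_a = sum(len(iv) for iv in a) / len(a)
    mean_b = sum(len(iv) for iv in b) / len(b)
    slots = int(genome_size // (mean_a + mean_b))
    n22 = max(0, slots - n11 - n12 - n21)
    table = [[n11, n12], [n21, n22]]
    return {"table": table, "p_two_tail": fisher_exact_two_tail(table)}


def promoter_of(g: GeneModel, flank: int = 2000) -> GenomicInterval:
    """Symmetric promoter window around the strand-aware TSS, clipped at 0."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    start = max(0, g.tss - flank)
    return GenomicInterval(g.chrom, start, g.tss + flank, strand=g.strand, payload=g.gene_id)


# ---------------------------------------------------------------------------
# feature annotation


def _gene_feature(mid: int, g: GeneModel) -> str | None:
    """Category of a midpoint with respect to one gene, or None if unrelated."""
    d_tss = abs(mid - g.tss)
    if d_tss < 1000:
        return "Promoter(<1kb)"
    if d_tss < 2000:
        return "Promoter(1-2kb)"
    if g.utr5 is not None and g.utr5[0] <= mid < g.utr5[1]:
        return "UTR5"
    if g.utr3 is not None and g.utr3[0] <= mid < g.utr3[1]:
        return "UTR3"
    exons = g.exons if g.strand == "+" else tuple(reversed(g.exons))
    for k, (s, e) in enumerate(exons):
        if s <= mid < e:
            return "FirstExon" if k == 0 else "OtherExon"
    introns = g.introns() if g.strand == "+" else tuple(reversed(g.introns()))
    for k, (s, e) in enumerate(introns):
        if s <= mid < e:
            return "FirstIntron" if k == 0 else "OtherIntron"
    if g.strand == "+" and g.tes <= mid < g.tes + DOWNSTREAM_MAX:
        return "Downstream"
    if g.strand == "-" and g.tes - DOWNSTREAM_MAX < mid <= g.tes:
        return "Downstream"
    return None


def annotate_feature(
    iv: GenomicInterval, genes: Sequence[GeneModel]
) -> FeatureAnnotation:
    """Assign exactly one genomic-feature category to an interval.

    Judged at the interval midpoint with a fixed promoter-first priority;
    gene ties are broken by nearest TSS then lexicographic gene id.
    """
    if not genes:
        logger.warning("annotate_feature called with empty gene list")
        return FeatureAnnotation("DistalIntergenic", None)
    mid = iv.midpoint
    best: tuple[int, int, str, str] | None = None  # (rank, d_tss, gene_id, feature)
    for g in genes:
        if g.chrom != iv.chrom:
            continue
        feat = _gene_feature(mid, g)
        if feat is None:
            continue
        key = (_PRIORITY_RANK[feat], abs(mid - g.tss), g.gene_id, feat)
        if best is None or key[:3] < best[:3]:
            best = key
    if best is None:
        return FeatureAnnotation("DistalIntergenic", None)
    return FeatureAnnotation(best[3], best[2])


def annotate_features(
    ivs: Sequence[GenomicInterval], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Vector form of :func:`annotate_feature` plus per-region/per-bp tallies."""
    rows = []
    for iv in ivs:
        ann = annotate_feature(iv, genes)
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "feature": ann.feature,
                "gene_id": ann.gene_id,
                "bp": len(iv),
            }
        )
    return pd.DataFrame(rows)


def feature_fractions(annotated: pd.DataFrame, per: str = "region") -> pd.Series:
    """Fraction of annotated intervals (or bp) in each feature category."""
    if annotated.empty:
        return pd.Series(dtype=float)
    if per == "region":
        counts = annotated["feature"].value_counts()
    elif per == "bp":
        counts = annotated.groupby("feature")["bp"].sum()
    else:
        raise ValueError("per must be 'region' or 'bp'")
    frac = counts / counts.sum()
    return frac.reindex(FEATURE_PRIORITY).dropna()


# ---------------------------------------------------------------------------
# combination partitioning


def mark_combination_counts(
    marked_regions: Mapping[str, Sequence[GenomicInterval]],
) -> dict[tuple[str, ...], int]:
    """Partition the union of marked bases by the exact subset of marks.

    Returns bp per combination (keys are sorted mark-name tuples); values
    sum to the bp of the union of all marks.
    """
    if not marked_regions:
        raise ValueError("at least one mark required")
    merged = {m: merge(ivs) for m, ivs in marked_regions.items()}
    chroms = sorted({iv.chrom for ivs in merged.values() for iv in ivs})
    out: dict[tuple[str, ...], int] = {}
    for chrom in chroms:
        per_mark = {
            m: [(iv.start, iv.end) for iv in ivs if iv.chrom == chrom]
            for m, ivs in merged.items()
        }
        points = sorted(
            {p for spans in per_mark.values() for s, e in spans for p in (s, e)}
        )
        starts = {m: np.array([s for s, _ in spans]) for m, spans in per_mark.items()}
        ends = {m: np.array([e for _, e in spans]) for m, spans in per_mark.items()}
        for lo, hi in zip(points, points[1:]):
            combo = tuple(
                sorted(
                    m
                    for m in per_mark
                    if starts[m].size
                    and (idx := np.searchsorted(starts[m], lo, side="right") - 1) >= 0
                    and ends[m][idx] > lo
                )
            )
            if combo:
                out[combo] = out.get(combo, 0) + (hi - lo)
    return out
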