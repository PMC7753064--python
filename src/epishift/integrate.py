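"""Integration of differential epigenetic marks and methylation with expression.

Genes are profiled by which marks are altered in their promoter (TSS ±2 kb)
and in which direction, classified into active / poised / repressive
subgroups by a voting rule — H3K4me1, H3K4me3, H3K27ac and H3K36me3 act as
activating signals, H3K27me3 and DNA methylation (mC) as repressive — and
the additive effect of carrying 1, 2, 3 or 4+ altered marks on log2 FPKM
fold change is quantified with paired t-tests across patients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GeneModel, GenomicInterval, promoter_of

logger = logging.getLogger(__name__)

ACTIVE_MARKS = frozenset({"H3K4me1", "H3K4me3", "H3K27ac", "H3K36me3"})
REPRESSIVE_MARKS = frozenset({"H3K27me3", "mC"})
ALL_MARKS = tuple(sorted(ACTIVE_MARKS | REPRESSIVE_MARKS))

PSEUDOCOUNT = 0.01  # added to FPKM before log2

__all__ = [
    "MarkAlteration",
    "MethylPosition",
    "GeneEpiProfile",
    "ExpressionTable",
    "ACTIVE_MARKS",
    "REPRESSIVE_MARKS",
    "ALL_MARKS",
    "summarize_methylation",
    "build_gene_profiles",
    "classify_subgroup",
    "additive_effect",
    "select_candidates",
    "methylation_expression_correlation",
    "stratified_spearman",
    "pairwise_mark_correlation",
]


@dataclass(frozen=True)
class MarkAlteration:
    """One differentially modified region for one mark."""

    mark: str
    region: GenomicInterval
    direction: str  # "up" | "down"
    stat: float = 0.0  # signed effect size (log2 FC of signal)
    q: float = np.nan

    def __post_init__(self) -> None:
        if self.mark not in ALL_MARKS:
            raise ValueError(f"unknown mark {self.mark!r}; expected one of {ALL_MARKS}")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up/down, got {self.direction!r}")


@dataclass(frozen=True)
class MethylPosition:
    """One differentially methylated CpG position."""

    cpg_id: str
    chrom: str
    pos: int
    delta_beta: float  # tumor - normal methylation
    q: float = np.nan
    in_cgi: bool = False

    def __post_init__(self) -> None:
        if not -1.0 <= self.delta_beta <= 1.0:
            raise ValueError(f"{self.cpg_id}: delta_beta outside [-1, 1]")


@dataclass
class GeneEpiProfile:
    """Which marks are altered in a gene's promoter, with directions and stats."""

    gene_id: str
    marks: dict[str, str] = field(default_factory=dict)  # mark -> up/down
    stats: dict[str, float] = field(default_factory=dict)  # mark -> signed stat

    @property
    def n_marks(self) -> int:
        return len(self.marks)

    @property
    def group(self) -> str:
        """Mark-count group label: 1, 2, 3 or 4+."""
        return str(self.n_marks) if self.n_marks < 4 else "4+"

    @property
    def subgroup(self) -> str | None:
        return classify_subgroup(self) if self.n_marks else None


@dataclass
class ExpressionTable:
    """Genes x samples FPKM matrix with a tumor/normal sample pairing."""

    fpkm: pd.DataFrame
    pairs: list[tuple[str, str]]  # (tumor sample, normal sample) per patient

    def __post_init__(self) -> None:
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        flat = [s for pair in self.pairs for s in pair]
        if len(set(flat)) != len(flat):
            raise ValueError("sample pairing is not a bijection on patients")
        missing = set(flat) - set(self.fpkm.columns)
        if missing:
            raise ValueError(f"paired samples missing from matrix: {sorted(missing)}")

    @property
    def tumor_samples(self) -> list[str]:
        return [t for t, _ in self.pairs]

    @property
    def normal_samples(self) -> list[str]:
        return [n for _, n in self.pairs]

    def log2fc(self, genes: Iterable[str] | None = None) -> pd.Series:
        """Per-gene log2((mean tumor FPKM + eps) / (mean normal FPKM + eps))."""
        df = self.fpkm if genes is None else self.fpkm.loc[list(genes)]
        t = df[self.tumor_samples].mean(axis=1)
        n = df[self.normal_samples].mean(axis=1)
        return np.log2((t + PSEUDOCOUNT) / (n + PSEUDOCOUNT))

    def log2_matrix(self) -> pd.DataFrame:
        return np.log2(self.fpkm + PSEUDOCOUNT)


# ---------------------------------------------------------------------------
# methylation summary


def summarize_methylation(dmps: Sequence[MethylPosition]) -> dict:
    """Global hypo/hyper split and its association with CpG islands.

    Returns counts, the 2x2 table (rows hypo/hyper x columns non-CGI/CGI)
    and the Yates-corrected chi-square on it. Zero delta-beta positions are
    counted separately and excluded from the table.
    """
    n_hypo = sum(1 for d in dmps if d.delta_beta < 0)
    n_hyper = sum(1 for d in dmps if d.delta_beta > 0)
    n_zero = len(dmps) - n_hypo - n_hyper
    table = np.array(
        [
            [
                sum(1 for d in dmps if d.delta_beta < 0 and not d.in_cgi),
                sum(1 for d in dmps if d.delta_beta < 0 and d.in_cgi),
            ],
            [
                sum(1 for d in dmps if d.delta_beta > 0 and not d.in_cgi),
                sum(1 for d in dmps if d.delta_beta > 0 and d.in_cgi),
            ],
        ]
    )
    out = {
        "n_total": len(dmps),
        "n_hypo": n_hypo,
        "n_hyper": n_hyper,
        "n_zero": n_zero,
        "cgi_table": table,
        "chisq_yates": None,
    }
    if (table.sum(axis=1) > 0).all() and (table.sum(axis=0) > 0).all():
        stat, p, _, _ = stats.chi2_contingency(table, correction=True)
        out["chisq_yates"] = {"statistic": float(stat), "p": float(p)}
    elif len(dmps):
        logger.warning("summarize_methylation: degenerate hypo/hyper x CGI table, test skipped")
    return out


# ---------------------------------------------------------------------------
# profiles and subgroups


def _overlap_bp(region: GenomicInterval, prom: GenomicInterval) -> int:
    if region.chrom != prom.chrom:
        return 0
    return max(0, min(region.end, prom.end) - max(region.start, prom.start))


def build_gene_profiles(
    alterations: Sequence[MarkAlteration],
    dmps: Sequence[MethylPosition],
    genes: Sequence[GeneModel],
    flank: int = 2000,
) -> list[GeneEpiProfile]:
    """Profile each gene by the marks altered within its promoter.

    A histone mark's direction is the sign of the bp-weighted vote of its
    promoter-overlapping regions; mC's direction is the majority sign of
    promoter DMPs. An exact tie drops the mark with a warning. The per-mark
    stat recorded is the overlap-weighted mean signed stat (mean delta-beta
    for mC), used by the correlation analyses.
    """
    # index alterations and DMPs per chromosome for windowed lookup
    alt_index: dict[str, list[MarkAlteration]] = {}
    for alt in alterations:
        alt_index.setdefault(alt.region.chrom, []).append(alt)
    alt_starts: dict[str, np.ndarray] = {}
    max_width: dict[str, int] = {}
    for chrom, alts in alt_index.items():
        alts.sort(key=lambda a: a.region.start)
        alt_starts[chrom] = np.array([a.region.start for a in alts])
        max_width[chrom] = max(len(a.region) for a in alts)
    dmp_index: dict[str, list[MethylPosition]] = {}
    for d in dmps:
        dmp_index.setdefault(d.chrom, []).append(d)
    dmp_pos: dict[str, np.ndarray] = {}
    for chrom, ds in dmp_index.items():
        ds.sort(key=lambda d: d.pos)
        dmp_pos[chrom] = np.array([d.pos for d in ds])

    profiles = []
    for g in genes:
        prom = promoter_of(g, flank=flank)
        marks: dict[str, str] = {}
        mstats: dict[str, float] = {}
        by_mark: dict[str, list[tuple[int, MarkAlteration]]] = {}
        if g.chrom in alt_index:
            starts = alt_starts[g.chrom]
            lo = int(np.searchsorted(starts, prom.start - max_width[g.chrom], "left"))
            hi = int(np.searchsorted(starts, prom.end, "left"))
            for alt in alt_index[g.chrom][lo:hi]:
                bp = _overlap_bp(alt.region, prom)
                if bp > 0:
                    by_mark.setdefault(alt.mark, []).append((bp, alt))
        for mark, hits in by_mark.items():
            vote = sum(bp * (1 if a.direction == "up" else -1) for bp, a in hits)
            if vote == 0:
                warnings.warn(
                    f"gene {g.gene_id}: tied up/down bp for {mark}, mark dropped"
                )
                continue
            marks[mark] = "up" if vote > 0 else "down"
            total_bp = sum(bp for bp, _ in hits)
            mstats[mark] = sum(bp * a.stat for bp, a in hits) / total_bp
        prom_dmps = []
        if g.chrom in dmp_index:
            pos = dmp_pos[g.chrom]
            lo = int(np.searchsorted(pos, prom.start, "left"))
            hi = int(np.searchsorted(pos, prom.end, "left"))
            prom_dmps = [d for d in dmp_index[g.chrom][lo:hi] if d.delta_beta != 0]
        if prom_dmps:
            sign_vote = sum(np.sign(d.delta_beta) for d in prom_dmps)
            if sign_vote == 0:
                warnings.warn(f"gene {g.gene_id}: tied DMP signs, mC dropped")
            else:
                marks["mC"] = "up" if sign_vote > 0 else "down"
                mstats["mC"] = float(np.mean([d.delta_beta for d in prom_dmps]))
        if marks:
            profiles.append(GeneEpiProfile(gene_id=g.gene_id, marks=marks, stats=mstats))
    return profiles


def classify_subgroup(profile: GeneEpiProfile) -> str:
    """Active / poised / repressive by unanimous vs conflicting mark votes.

    Each (mark, direction) votes activating (active mark up, or repressive
    mark down) or silencing (active mark down, or repressive mark up).
    Unanimous activating -> active; unanimous silencing -> repressive;
    mixed -> poised.
    """
    if not profile.marks:
        raise ValueError(f"gene {profile.gene_id}: empty profile has no subgroup")
    votes = set()
    for mark, direction in profile.marks.items():
        activating = (mark in ACTIVE_MARKS) == (direction == "up")
        votes.add("activating" if activating else "silencing")
    if votes == {"activating"}:
        return "active"
    if votes == {"silencing"}:
        return "repressive"
    return "poised"


# ---------------------------------------------------------------------------
# additive effect and candidate selection


def _paired_t(tumor: np.ndarray, normal: np.ndarray) -> tuple[float, float]:
    diffs = tumor - normal
    if len(diffs) < 2 or np.allclose(diffs, diffs[0]):
        return np.nan, np.nan
    t, p = stats.ttest_rel(tumor, normal)
    return float(t), float(p)


def additive_effect(
    profiles: Sequence[GeneEpiProfile], expr: ExpressionTable
) -> pd.DataFrame:
    """Mean log2 FPKM fold change per (mark-count group x subgroup).

    The paired t-test compares, patient by patient, the mean log2
    expression of the cell's genes between tumor and normal. Cells with
    fewer than 2 genes keep their count but have statistics suppressed.
    """
    log2 = expr.log2_matrix()
    fc = expr.log2fc()
    rows = []
    for group in ("1", "2", "3", "4+"):
        for subgroup in ("active", "poised", "repressive"):
            members = [
                p.gene_id
                for p in profiles
                if p.group == group and p.subgroup == subgroup and p.gene_id in fc.index
            ]
            row = {
                "group": group,
                "subgroup": subgroup,
                "n_genes": len(members),
                "mean_log2fc": float(fc.loc[members].mean()) if members else np.nan,
                "se_log2fc": (
                    float(fc.loc[members].std(ddof=1) / np.sqrt(len(members)))
                    if len(members) > 1
                    else np.nan
                ),
                "paired_t": np.nan,
                "p": np.nan,
            }
            if len(members) >= 2:
                t_means = log2.loc[members, expr.tumor_samples].mean(axis=0).to_numpy()
                n_means = log2.loc[members, expr.normal_samples].mean(axis=0).to_numpy()
                row["paired_t"], row["p"] = _paired_t(t_means, n_means)
            rows.append(row)
    return pd.DataFrame(rows)


def per_gene_paired_tests(
    genes: Sequence[str], expr: ExpressionTable
) -> pd.DataFrame:
    """Per-gene paired t-test across patients on log2(FPKM + eps)."""
    if len(expr.pairs) < 3:
        raise ValueError("insufficient pairing for t-test: need >=3 patient pairs")
    log2 = expr.log2_matrix()
    fc = expr.log2fc()
    rows = []
    for gene in genes:
        t_vals = log2.loc[gene, expr.tumor_samples].to_numpy(dtype=float)
        n_vals = log2.loc[gene, expr.normal_samples].to_numpy(dtype=float)
        t, p = _paired_t(t_vals, n_vals)
        rows.append({"gene_id": gene, "log2fc": float(fc.loc[gene]), "t": t, "p": p})
    df = pd.DataFrame(rows).set_index("gene_id")
    df["q"] = _bh_adjust(df["p"].to_numpy())
    return df


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        ps = p[ok]
        order = np.argsort(ps)
        ranked = ps[order] * len(ps) / (np.arange(len(ps)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(ranked)
        out[order] = np.clip(ranked, 0, 1)
        q[ok] = out
    return q


def select_candidates(
    profiles: Sequence[GeneEpiProfile],
    expr: ExpressionTable,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> dict[str, list[str]]:
    """Retain screened candidates from the active and repressive subgroups.

    Overexpressed: active subgroup, log2 FC > fc_threshold, paired-t
    p < p_threshold. Underexpressed: repressive subgroup, log2 FC below
    -fc_threshold at the same significance. Raw p gates retention; BH q is
    reported alongside by :func:`per_gene_paired_tests`.
    """
    by_sub = {"active": [], "repressive": []}
    for p in profiles:
        if p.subgroup in by_sub and p.gene_id in expr.fpkm.index:
            by_sub[p.subgroup].append(p.gene_id)
    over, under = [], []
    for sub, genes in by_sub.items():
        if not genes:
            continue
        tests = per_gene_paired_tests(genes, expr)
        sig = tests[tests["p"] < p_threshold]
        if sub == "active":
            over = sorted(sig[sig["log2fc"] > fc_threshold].index)
        else:
            under = sorted(sig[sig["log2fc"] < -fc_threshold].index)
    return {"overexpressed": over, "underexpressed": under}


# ---------------------------------------------------------------------------
# correlation analyses


def methylation_expression_correlation(
    gene_delta_beta: Mapping[str, float], expr: ExpressionTable
) -> dict:
    """Across genes: promoter mean delta-beta vs expression log2 fold change."""
    genes = [g for g in gene_delta_beta if g in expr.fpkm.index]
    if len(genes) < 3:
        raise ValueError("need >=3 genes with both methylation and expression")
    fc = expr.log2fc(genes)
    db = np.array([gene_delta_beta[g] for g in genes])
    table = pd.DataFrame({"gene_id": genes, "delta_beta": db, "log2fc": fc.to_numpy()})
    if np.std(db) == 0 or np.std(fc) == 0:
        return {"per_gene": table, "fraction_negative": np.nan, "r_overall": np.nan,
                "p": np.nan, "flag": "zero-variance input"}
    r, p = stats.pearsonr(db, fc.to_numpy())
    frac_neg = float(np.mean(db * fc.to_numpy() < 0))
    return {
        "per_gene": table,
        "fraction_negative": frac_neg,
        "r_overall": float(r),
        "p": float(p),
        "flag": None,
    }


def stratified_spearman(
    profiles: Sequence[GeneEpiProfile],
    expr: ExpressionTable,
    min_genes: int = 5,
) -> pd.DataFrame:
    """Spearman rho of mark alteration stat vs expression fold change,
    separately for genes carrying only that mark vs >=2 marks."""
    fc = expr.log2fc()
    n_profiled = sum(1 for p in profiles if p.gene_id in fc.index)
    rows = []
    for mark in ALL_MARKS:
        for stratum, cond in (
            ("1 mark", lambda p: p.n_marks == 1),
            (">1 mark", lambda p: p.n_marks >= 2),
        ):
            sel = [
                p for p in profiles
                if mark in p.marks and cond(p) and p.gene_id in fc.index
            ]
            x = np.array([p.stats.get(mark, np.nan) for p in sel])
            y = fc.loc[[p.gene_id for p in sel]].to_numpy() if sel else np.array([])
            ok = np.isfinite(x)
            row = {
                "mark": mark,
                "stratum": stratum,
                "n": int(ok.sum()),
                "rho": np.nan,
                "p": np.nan,
                "coverage": (ok.sum() / n_profiled) if n_profiled else np.nan,
            }
            if ok.sum() >= min_genes and np.std(x[ok]) > 0 and np.std(y[ok]) > 0:
                rho, p = stats.spearmanr(x[ok], y[ok])
                row["rho"], row["p"] = float(rho), float(p)
            rows.append(row)
    return pd.DataFrame(rows)


def _scope_regions(g: GeneModel, scope: str, flank: int = 2000) -> list[GenomicInterval]:
    if scope == "promoter":
        return [promoter_of(g, flank=flank)]
    if scope == "cds":
        return [GenomicInterval(g.chrom, s, e) for s, e in g.cds_intervals()]
    raise ValueError("region_scope must be 'promoter' or 'cds'")


def pairwise_mark_correlation(
    alterations: Sequence[MarkAlteration],
    region_scope: str,
    genes: Sequence[GeneModel],
    dmps: Sequence[MethylPosition] = (),
    min_shared: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson r between signed per-gene stats of each mark pair.

    Computed over genes where both marks are altered within the scoped
    region (promoter or CDS); entries with p >= alpha are masked as NaN.
    """
    per_gene: dict[str, dict[str, float]] = {}
    for g in genes:
        regions = _scope_regions(g, region_scope)
        stats_g: dict[str, list[tuple[int, float]]] = {}
        for alt in alterations:
            bp = sum(_overlap_bp(alt.region, r) for r in regions)
            if bp > 0:
                stats_g.setdefault(alt.mark, []).append((bp, alt.stat))
        vals = {
            m: sum(bp * s for bp, s in hits) / sum(bp for bp, _ in hits)
            for m, hits in stats_g.items()
        }
        in_scope = [
            d.delta_beta
            for d in dmps
            if any(r.chrom == d.chrom and r.start <= d.pos < r.end for r in regions)
        ]
        if in_scope:
            vals["mC"] = float(np.mean(in_scope))
        if vals:
            per_gene[g.gene_id] = vals
    marks = sorted({m for v in per_gene.values() for m in v})
    mat = pd.DataFrame(np.nan, index=marks, columns=marks)
    for i, a in enumerate(marks):
        mat.loc[a, a] = 1.0
        for b in marks[i + 1:]:
            shared = [
                (v[a], v[b]) for v in per_gene.values() if a in v and b in v
            ]
            if len(shared) < min_shared:
                continue
            x, y = np.array(shared).T
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r, p = stats.pearsonr(x, y)
            if p < alpha:
                mat.loc[a, b] = mat.loc[b, a] = float(r)
    return mat
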