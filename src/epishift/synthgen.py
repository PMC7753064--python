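"""Synthetic paired tumor/normal epigenome data with planted ground truth.

Every pipeline input is generated with known structure so each stage can be
tested against what was planted: chromatin segmentations whose tumor track
rewrites a configured fraction of state-i bins to state j; promoter mark
alterations whose directions realize a chosen active/poised/repressive
subgroup; DMPs with a hypomethylation excess and CGI-biased hypermethylation;
paired FPKM values whose tumor shift adds one signed per-mark effect per
altered mark; methylation coupled to expression at a target correlation; a
preferential-attachment PPI graph with planted hubs; and exponential
survival with planted per-gene, per-subtype log hazard ratios.

All randomness flows from a single seed through per-stage child streams, so
regeneration is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .chromstate import STATE_PRESET_19, BinnedTrack, StateSegmentation
from .integrate import (
    ACTIVE_MARKS,
    ALL_MARKS,
    ExpressionTable,
    MarkAlteration,
    MethylPosition,
)
from .intervals import GeneModel, GenomicInterval
from .survival import SurvivalRecord

__all__ = [
    "SimConfig",
    "make_genome_and_genes",
    "make_segmentations",
    "make_marks_and_methylation",
    "make_expression",
    "make_ppi_and_survival",
    "make_null_bin_tracks",
    "simulate_methylation_expression_pairs",
    "simulate_all",
]

# preference order used to inflate mark co-occurrence
_COLOC_ORDER = ("H3K4me3", "H3K27ac", "mC", "H3K4me1", "H3K36me3", "H3K27me3")


@dataclass
class SimConfig:
    """Parameters of the planted study conditions.

    Defaults mirror the emulated study: 19 tumor/normal pairs, 200-bp
    segmentation bins over a 19-state vocabulary, a weak-TSS to active-TSS
    transition planted on 30% of source bins, a 0.5 log2 expression effect
    per altered promoter mark, a methylation-expression correlation target
    of -0.436, an 87% hypomethylation excess with CGI-biased
    hypermethylation, and a survival cohort of 300 patients with planted
    log hazard ratio 1.0 under 30% censoring.
    """

    seed: int = 0
    genome: tuple[tuple[str, int], ...] = (("chr1", 3_600_000),)
    n_genes: int = 300
    n_patients: int = 19
    state_labels: tuple[str, ...] = STATE_PRESET_19
    transition_plants: tuple[tuple[str, str, float], ...] = (("E4", "E1", 0.3),)
    mark_effects: Mapping[str, float] = field(
        default_factory=lambda: {m: 0.5 for m in ALL_MARKS}
    )
    colocalization_rate: float = 0.5
    meth_expr_r: float = -0.436
    hypo_fraction: float = 0.87
    cgi_bias_hyper: float = 0.8
    cgi_bias_hypo: float = 0.15
    hub_plants: tuple[str, ...] = ()  # empty -> first 5 PPI candidates
    hazard_plants: Mapping[tuple[str, str], float] | None = None  # None -> auto
    n_survival_patients: int = 300
    censor_rate: float = 0.3
    bin_size: int = 200
    promoter_flank: int = 2000
    stay_prob: float = 0.92  # spatial persistence of chromatin states
    segmentation_noise: float = 0.10  # background tumor/normal state discordance
    p_marked: float = 0.75  # probability a gene carries >=1 altered mark
    p_mc_only: float = 0.35  # marked genes whose sole alteration is mC
    gene_noise_sd: float | None = None  # fixed gene-level shift noise; None -> solved
    base_log2_mean: float = 3.0
    gene_sd: float = 1.2  # between-gene spread of baseline log2 FPKM
    patient_sd: float = 0.3  # within-gene between-patient noise (log2)
    n_background_dmps: int = 3000  # distal DMPs dominate the genome-wide pool
    n_background_regions: int = 40  # per mark, outside promoters
    hub_extra_edges: int = 60  # forced neighbors per planted hub

    def __post_init__(self) -> None:
        for _, _, f in self.transition_plants:
            if not 0 <= f <= 1:
                raise ValueError("transition fractions must be in [0, 1]")
        for rate in (self.colocalization_rate, self.censor_rate, self.hypo_fraction):
            if not 0 <= rate <= 1:
                raise ValueError("rates must be in [0, 1]")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stage,))
        )


# ---------------------------------------------------------------------------
# genome and genes


def make_genome_and_genes(cfg: SimConfig) -> list[GeneModel]:
    """Non-overlapping genes with strand, TSS and 2-5 exons, one per slot."""
    if cfg.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = cfg.rng(1)
    total = sum(length for _, length in cfg.genome)
    slot = total // cfg.n_genes
    if slot < 12_000:
        raise ValueError(
            f"genome too small for {cfg.n_genes} genes: need >=12 kb per gene, have {slot}"
        )
    genes = []
    offsets = np.cumsum([0] + [length for _, length in cfg.genome])
    for i in range(cfg.n_genes):
        pos = i * slot
        ci = int(np.searchsorted(offsets, pos, side="right") - 1)
        chrom = cfg.genome[ci][0]
        local = pos - int(offsets[ci])
        # keep the TSS +/-2 kb window inside the slot and clear of the
        # slot-boundary zone where background alterations are placed
        start = local + 2500 + int(rng.integers(0, 1000))
        length = int(rng.integers(3000, min(6000, slot - 6000)))
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(2, 6))
        cuts = np.sort(rng.choice(np.arange(start + 200, end - 200, 100),
                                  size=2 * (n_ex - 1), replace=False))
        bounds = [start, *cuts.tolist(), end]
        exons = tuple((bounds[k], bounds[k + 1]) for k in range(0, len(bounds) - 1, 2))
        first = exons[0] if strand == "+" else exons[-1]
        last = exons[-1] if strand == "+" else exons[0]
        u5_len = min(150, (first[1] - first[0]) // 2)
        u3_len = min(150, (last[1] - last[0]) // 2)
        utr5 = (first[0], first[0] + u5_len) if strand == "+" else (first[1] - u5_len, first[1])
        utr3 = (last[1] - u3_len, last[1]) if strand == "+" else (last[0], last[0] + u3_len)
        genes.append(
            GeneModel(
                gene_id=f"G{i + 1:04d}",
                chrom=chrom,
                strand=strand,
                tx_start=start,
                tx_end=end,
                exons=exons,
                utr5=utr5,
                utr3=utr3,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# segmentations


def _chain_states(n_bins: int, labels: Sequence[str], stay: float,
                  rng: np.random.Generator) -> np.ndarray:
    """First-order spatial chain: geometric runs of a single state."""
    states = np.empty(n_bins, dtype=object)
    i = 0
    current = labels[int(rng.integers(len(labels)))]
    while i < n_bins:
        run = int(rng.geometric(1 - stay))
        states[i : i + run] = current
        i += run
        nxt = int(rng.integers(len(labels) - 1))
        others = [s for s in labels if s != current]
        current = others[nxt]
    return states


def _states_to_intervals(chrom: str, states: np.ndarray, bin_size: int) -> list[GenomicInterval]:
    out = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            out.append(
                GenomicInterval(chrom, start * bin_size, i * bin_size, payload=str(states[start]))
            )
            start = i
    return out


def make_segmentations(cfg: SimConfig) -> tuple[StateSegmentation, StateSegmentation, dict]:
    """Normal chain plus a tumor copy with planted state rewrites.

    For each planted (i, j, f), a fraction f of normal state-i bins is
    rewritten to state j in the tumor track; the converted bins are logged
    in the ground-truth record.
    """
    if len(cfg.state_labels) < 2:
        raise ValueError("need at least 2 state labels")
    rng = cfg.rng(2)
    normal_ivs, tumor_ivs = [], []
    truth: dict = {"plants": [], "bin_size": cfg.bin_size}
    for chrom, length in cfg.genome:
        n_bins = length // cfg.bin_size
        normal = _chain_states(n_bins, cfg.state_labels, cfg.stay_prob, rng)
        tumor = normal.copy()
        # background discordance: tumor states differ broadly, not only at
        # the planted pairs, so every transition cell is populated
        flip = np.flatnonzero(rng.random(n_bins) < cfg.segmentation_noise)
        for b in flip:
            others = [s for s in cfg.state_labels if s != normal[b]]
            tumor[b] = others[int(rng.integers(len(others)))]
        for from_s, to_s, frac in cfg.transition_plants:
            idx = np.flatnonzero(normal == from_s)
            k = int(np.floor(frac * len(idx)))
            chosen = rng.choice(idx, size=k, replace=False) if k else np.array([], int)
            tumor[chosen] = to_s
            truth["plants"].append(
                {
                    "chrom": chrom,
                    "from": from_s,
                    "to": to_s,
                    "fraction": frac,
                    "converted_bins": sorted(int(b) for b in chosen),
                }
            )
        normal_ivs.extend(_states_to_intervals(chrom, normal, cfg.bin_size))
        tumor_ivs.extend(_states_to_intervals(chrom, tumor, cfg.bin_size))
    return (
        StateSegmentation("normal", normal_ivs),
        StateSegmentation("tumor", tumor_ivs),
        truth,
    )


def make_null_bin_tracks(
    n_bins: int,
    labels: Sequence[str],
    rng: np.random.Generator,
    probs: Sequence[float] | None = None,
) -> tuple[BinnedTrack, BinnedTrack, ]:
    """Two tracks with states drawn i.i.d. from the same distribution —
    the independence null for transition-enrichment calibration."""
    labels = list(labels)
    a = rng.choice(labels, size=n_bins, p=probs)
    b = rng.choice(labels, size=n_bins, p=probs)
    mk = lambda arr: BinnedTrack(
        bin_size=200, bins={("chr1", i): str(s) for i, s in enumerate(arr)}
    )
    return mk(a), mk(b)


# ---------------------------------------------------------------------------
# marks and methylation


def _choose_marks(n: int, rng: np.random.Generator, coloc: float) -> list[str]:
    if rng.random() < coloc:
        return [str(m) for m in _COLOC_ORDER[:n]]
    return [str(m) for m in rng.choice(ALL_MARKS, size=n, replace=False)]


def make_marks_and_methylation(
    cfg: SimConfig, genes: Sequence[GeneModel]
) -> tuple[list[MarkAlteration], list[MethylPosition], dict]:
    """Promoter mark alterations realizing planted subgroups, plus DMPs.

    Each marked gene draws a subgroup (active/repressive/poised) and a mark
    count whose subset is inflated toward a fixed co-occurrence module at
    ``colocalization_rate``. Directions follow the subgroup's votes. mC is
    emitted as promoter DMPs whose shared sign encodes the direction;
    background DMPs (hypomethylated with probability ``hypo_fraction``,
    hypermethylation biased into CGIs) sit outside every promoter.
    """
    rng = cfg.rng(3)
    alterations: list[MarkAlteration] = []
    dmps: list[MethylPosition] = []
    truth_genes: dict[str, dict] = {}
    n_marks_probs = {1: 0.35, 2: 0.30, 3: 0.20, 4: 0.10, 5: 0.04, 6: 0.01}
    counts, probs = zip(*n_marks_probs.items())
    cpg_serial = 0
    for g in genes:
        if rng.random() > cfg.p_marked:
            continue
        # DNA methylation predominantly acts alone; histone marks co-occur
        if rng.random() < cfg.p_mc_only:
            marks = ["mC"]
            subgroup = str(rng.choice(["active", "repressive"], p=[0.5, 0.5]))
        else:
            subgroup = str(rng.choice(["active", "repressive", "poised"], p=[0.4, 0.3, 0.3]))
            n = int(rng.choice(counts, p=probs))
            if subgroup == "poised" and n < 2:
                n = 2
            marks = _choose_marks(n, rng, cfg.colocalization_rate)
        if subgroup == "active":
            votes = {m: "activating" for m in marks}
        elif subgroup == "repressive":
            votes = {m: "silencing" for m in marks}
        else:
            flips = rng.random(len(marks)) < 0.5
            flips[0], flips[1] = True, False  # guarantee a conflict
            votes = {
                m: ("activating" if f else "silencing") for m, f in zip(marks, flips)
            }
        directions = {
            m: (
                "up"
                if (votes[m] == "activating") == (m in ACTIVE_MARKS)
                else "down"
            )
            for m in marks
        }
        prom_lo = max(0, g.tss - cfg.promoter_flank)
        prom_hi = g.tss + cfg.promoter_flank
        mc_mag = float(np.clip(abs(rng.normal(0.25, 0.08)), 0.05, 0.6))
        for mark in marks:
            if mark == "mC":
                sign = 1.0 if directions[mark] == "up" else -1.0
                for _ in range(int(rng.integers(3, 9))):
                    cpg_serial += 1
                    db = sign * float(np.clip(mc_mag + rng.normal(0, 0.04), 0.01, 0.99))
                    hyper = db > 0
                    cgi_p = cfg.cgi_bias_hyper if hyper else cfg.cgi_bias_hypo
                    dmps.append(
                        MethylPosition(
                            cpg_id=f"cg{cpg_serial:07d}",
                            chrom=g.chrom,
                            pos=int(rng.integers(prom_lo, prom_hi)),
                            delta_beta=db,
                            q=float(rng.uniform(0, 0.049)),
                            in_cgi=bool(rng.random() < cgi_p),
                        )
                    )
            else:
                for _ in range(int(rng.integers(1, 3))):
                    width = int(rng.integers(200, 800))
                    start = int(rng.integers(prom_lo, max(prom_lo + 1, prom_hi - width)))
                    sign = 1.0 if directions[mark] == "up" else -1.0
                    alterations.append(
                        MarkAlteration(
                            mark=mark,
                            region=GenomicInterval(g.chrom, start, start + width),
                            direction=directions[mark],
                            stat=sign * float(abs(rng.normal(1.2, 0.4))),
                            q=float(rng.uniform(0, 0.049)),
                        )
                    )
        truth_genes[g.gene_id] = {
            "marks": {m: directions[m] for m in marks},
            "votes": votes,
            "subgroup": str(subgroup),
            "n_marks": len(marks),
            "mc_magnitude": mc_mag if "mC" in marks else None,
        }
    # background alterations outside promoters (slot boundaries are gene-free)
    total = sum(length for _, length in cfg.genome)
    slot = total // cfg.n_genes
    up_bias = {"H3K4me1": 0.59, "H3K4me3": 0.48, "H3K27ac": 0.64,
               "H3K27me3": 0.70, "H3K36me3": 0.60}
    for mark, bias in up_bias.items():
        for _ in range(cfg.n_background_regions):
            # confined to the first 500 bp of a slot, which no promoter reaches
            i = int(rng.integers(cfg.n_genes))
            start = i * slot + int(rng.integers(0, 300))
            chrom = cfg.genome[0][0]
            width = int(rng.integers(100, 200))
            direction = "up" if rng.random() < bias else "down"
            sign = 1.0 if direction == "up" else -1.0
            alterations.append(
                MarkAlteration(
                    mark=mark,
                    region=GenomicInterval(chrom, start, start + width),
                    direction=direction,
                    stat=sign * float(abs(rng.normal(1.0, 0.4))),
                    q=float(rng.uniform(0, 0.049)),
                )
            )
    for _ in range(cfg.n_background_dmps):
        cpg_serial += 1
        i = int(rng.integers(cfg.n_genes))
        pos = i * slot + int(rng.integers(0, 400))
        hypo = rng.random() < cfg.hypo_fraction
        mag = float(np.clip(abs(rng.normal(0.22, 0.1)), 0.01, 0.99))
        db = -mag if hypo else mag
        cgi_p = cfg.cgi_bias_hypo if hypo else cfg.cgi_bias_hyper
        dmps.append(
            MethylPosition(
                cpg_id=f"cg{cpg_serial:07d}",
                chrom=cfg.genome[0][0],
                pos=pos,
                delta_beta=db,
                q=float(rng.uniform(0, 0.049)),
                in_cgi=bool(rng.random() < cgi_p),
            )
        )
    truth = {"genes": truth_genes}
    return alterations, dmps, truth


# ---------------------------------------------------------------------------
# expression


def make_expression(
    cfg: SimConfig, genes: Sequence[GeneModel], truth: dict
) -> tuple[ExpressionTable, dict]:
    """Paired FPKM with additive per-mark tumor shifts.

    The tumor shift of gene g is the sum of signed per-mark effects
    (positive for activating votes) plus gene-level noise whose scale is
    solved so that the correlation between gene-level delta-beta and the
    tumor shift matches ``meth_expr_r`` over mC-marked genes.
    """
    rng = cfg.rng(4)
    gene_truth = truth["genes"]
    gene_ids = [g.gene_id for g in genes]
    y0 = np.zeros(len(gene_ids))
    x_mc, y0_mc = [], []
    for k, gid in enumerate(gene_ids):
        info = gene_truth.get(gid)
        if info is None:
            continue
        shift = 0.0
        for mark, vote in info["votes"].items():
            eff = cfg.mark_effects.get(mark, 0.0)
            shift += eff if vote == "activating" else -eff
        y0[k] = shift
        if "mC" in info["marks"]:
            sign = 1.0 if info["marks"]["mC"] == "up" else -1.0
            x_mc.append(sign * info["mc_magnitude"])
            y0_mc.append(shift)
    sigma = 0.6
    if cfg.gene_noise_sd is not None:
        sigma = cfg.gene_noise_sd
    elif len(x_mc) >= 3 and cfg.meth_expr_r != 0:
        x_arr, y_arr = np.asarray(x_mc), np.asarray(y0_mc)
        cov = float(np.mean((x_arr - x_arr.mean()) * (y_arr - y_arr.mean())))
        sd_x = float(np.std(x_arr))
        if sd_x > 0 and cov * cfg.meth_expr_r > 0:
            need = (cov / (sd_x * cfg.meth_expr_r)) ** 2 - float(np.var(y_arr))
            sigma = float(np.sqrt(max(need, 0.04)))
    shifts = y0 + rng.normal(0, sigma, size=len(gene_ids))
    mu = cfg.base_log2_mean + rng.normal(0, cfg.gene_sd, size=len(gene_ids))
    samples, cols, pairs = [], [], []
    for p in range(cfg.n_patients):
        t_name, n_name = f"P{p + 1:02d}_T", f"P{p + 1:02d}_N"
        pairs.append((t_name, n_name))
        n_log2 = mu + rng.normal(0, cfg.patient_sd, size=len(gene_ids))
        t_log2 = mu + shifts + rng.normal(0, cfg.patient_sd, size=len(gene_ids))
        samples.extend([np.power(2.0, t_log2), np.power(2.0, n_log2)])
        cols.extend([t_name, n_name])
    fpkm = pd.DataFrame(np.column_stack(samples), index=gene_ids, columns=cols)
    expr = ExpressionTable(fpkm=fpkm, pairs=pairs)
    expr_truth = {
        "sigma_gene_noise": sigma,
        "shifts": {gid: float(s) for gid, s in zip(gene_ids, shifts)},
        "target_meth_expr_r": cfg.meth_expr_r,
    }
    return expr, expr_truth


def simulate_methylation_expression_pairs(
    n: int, r: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate-normal (delta-beta, log2 fold change) pairs at correlation r."""
    z = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=n)
    delta_beta = np.clip(0.25 * z[:, 0], -1, 1)
    log2fc = 1.0 * z[:, 1]
    return delta_beta, log2fc


# ---------------------------------------------------------------------------
# PPI and survival


def make_ppi_and_survival(
    cfg: SimConfig,
    genes: Sequence[GeneModel],
    truth: dict,
    expr_shifts: Mapping[str, float] | None = None,
) -> tuple[list[tuple[str, str]], list[SurvivalRecord], dict]:
    """Preferential-attachment PPI with planted hubs, plus survival records.

    Survival times are exponential with per-subject log hazard equal to the
    sum of planted beta x expression terms that apply to the subject's
    subtype ('ALL' plants apply to everyone); censoring is independent at
    ``censor_rate``.
    """
    rng = cfg.rng(5)
    gene_truth = truth["genes"]
    candidates = [g.gene_id for g in genes if gene_truth.get(g.gene_id, {}).get("n_marks", 0) >= 1]
    if len(candidates) < 10:
        candidates = [g.gene_id for g in genes][: max(10, len(genes) // 2)]
    if cfg.hub_plants:
        hubs = list(cfg.hub_plants)
    else:
        # plant hubs on genes the expression screen will retain: strongly
        # shifted active (overexpressed) and repressive (underexpressed) genes
        active = [c for c in candidates
                  if gene_truth.get(c, {}).get("subgroup") == "active"
                  and gene_truth[c]["n_marks"] >= 3]
        repressive = [c for c in candidates
                      if gene_truth.get(c, {}).get("subgroup") == "repressive"
                      and gene_truth[c]["n_marks"] >= 3]
        if expr_shifts is not None:
            # rank by realized tumor shift so the plants actually sit on
            # dys-expressed genes, as the emulated screen expects
            active = sorted(
                (c for c in candidates
                 if gene_truth.get(c, {}).get("subgroup") == "active"
                 and expr_shifts.get(c, 0.0) > 1.2),
                key=lambda c: -expr_shifts[c],
            ) or active
            repressive = sorted(
                (c for c in candidates
                 if gene_truth.get(c, {}).get("subgroup") == "repressive"
                 and expr_shifts.get(c, 0.0) < -1.2),
                key=lambda c: expr_shifts[c],
            ) or repressive
        hubs = (active[:3] + repressive[:2]) or candidates[:5]
    ba = nx.barabasi_albert_graph(len(candidates), m=2, seed=int(cfg.seed % (2**31)))
    idx = {i: gid for i, gid in enumerate(candidates)}
    edges = {tuple(sorted((idx[a], idx[b]))) for a, b in ba.edges}
    for hub in hubs:
        others = [c for c in candidates if c != hub]
        extra = rng.choice(others, size=min(cfg.hub_extra_edges, len(others)), replace=False)
        edges.update(tuple(sorted((hub, str(o)))) for o in extra)
    if cfg.hazard_plants is not None:
        plants = dict(cfg.hazard_plants)
    else:
        # default plants go on the repressive (underexpressed) hubs: the hub
        # screen retains every underexpressed candidate, so the planted
        # prognostic genes always reach the signature stage
        rep_hubs = [h for h in hubs
                    if gene_truth.get(h, {}).get("subgroup") == "repressive"]
        first = rep_hubs[0] if rep_hubs else hubs[0]
        second = rep_hubs[1] if len(rep_hubs) > 1 else hubs[1]
        plants = {(first, "ALL"): 1.0, (second, "CIN"): 1.0}
    for (gid, _), _beta in plants.items():
        if gid not in {g.gene_id for g in genes}:
            raise ValueError(f"hazard plant {gid!r} is not a simulated gene")
    subtype_probs = {"CIN": 0.50, "GS": 0.20, "EBV": 0.09, "MSI": 0.21}
    subtype_names = list(subtype_probs)
    subtypes = rng.choice(subtype_names, size=cfg.n_survival_patients,
                          p=list(subtype_probs.values()))
    plant_genes = sorted({gid for gid, _ in plants})
    expr_genes = sorted(set(candidates) | set(plant_genes))
    x = rng.standard_normal((cfg.n_survival_patients, len(expr_genes)))
    col = {gid: j for j, gid in enumerate(expr_genes)}
    records = []
    for i in range(cfg.n_survival_patients):
        loghaz = 0.0
        for (gid, st), beta in plants.items():
            if st == "ALL" or st == subtypes[i]:
                loghaz += beta * x[i, col[gid]]
        rate = np.exp(loghaz) / 1000.0
        t = float(rng.exponential(1.0 / rate))
        censored = rng.random() < cfg.censor_rate
        if censored:
            t *= float(rng.uniform(0.1, 1.0))
        records.append(
            SurvivalRecord(
                sample_id=f"S{i + 1:04d}",
                time=max(t, 1e-3),
                event=0 if censored else 1,
                subtype=str(subtypes[i]),
                expression={gid: float(x[i, col[gid]]) for gid in expr_genes},
            )
        )
    surv_truth = {
        "hubs": hubs,
        "hazard_plants": {f"{gid}|{st}": b for (gid, st), b in plants.items()},
        "candidates": candidates,
    }
    return sorted(edges), records, surv_truth


# ---------------------------------------------------------------------------
# file emission


def _write_genes(genes: Sequence[GeneModel], path: Path) -> None:
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "tx_start": g.tx_start,
                "tx_end": g.tx_end,
                "exon_starts": ",".join(str(s) for s, _ in g.exons),
                "exon_ends": ",".join(str(e) for _, e in g.exons),
                "utr5_start": g.utr5[0] if g.utr5 else "",
                "utr5_end": g.utr5[1] if g.utr5 else "",
                "utr3_start": g.utr3[0] if g.utr3 else "",
                "utr3_end": g.utr3[1] if g.utr3 else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def simulate_all(cfg: SimConfig, outdir: str | Path) -> dict:
    """Generate and write every pipeline input plus the truth sidecar."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genes = make_genome_and_genes(cfg)
    normal, tumor, seg_truth = make_segmentations(cfg)
    alterations, dmps, mark_truth = make_marks_and_methylation(cfg, genes)
    expr, expr_truth = make_expression(cfg, genes, mark_truth)
    edges, records, surv_truth = make_ppi_and_survival(
        cfg, genes, mark_truth, expr_shifts=expr_truth["shifts"]
    )

    _write_genes(genes, out / "genes.tsv")
    pd.DataFrame(cfg.genome, columns=["chrom", "length"]).to_csv(
        out / "genome.tsv", sep="\t", index=False
    )
    for seg, name in ((normal, "seg_normal.bed"), (tumor, "seg_tumor.bed")):
        with open(out / name, "w") as fh:
            for iv in seg.intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.payload}\n")
    for mark in ALL_MARKS:
        rows = [
            {
                "chrom": a.region.chrom,
                "start": a.region.start,
                "end": a.region.end,
                "direction": a.direction,
                "log2FC": round(a.stat, 6),
                "padj": round(a.q, 6),
            }
            for a in alterations
            if a.mark == mark
        ]
        pd.DataFrame(rows, columns=["chrom", "start", "end", "direction", "log2FC", "padj"]
                     ).to_csv(out / f"marks_{mark}.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "cpg_id": d.cpg_id,
                "chrom": d.chrom,
                "pos": d.pos,
                "delta_beta": round(d.delta_beta, 6),
                "q": round(d.q, 6),
                "in_cgi": int(d.in_cgi),
            }
            for d in dmps
        ]
    ).to_csv(out / "dmps.tsv", sep="\t", index=False)
    expr.fpkm.round(6).to_csv(out / "expression.tsv", sep="\t", index_label="gene_id")
    pd.DataFrame(expr.pairs, columns=["tumor", "normal"]).to_csv(
        out / "pairing.tsv", sep="\t", index=False
    )
    pd.DataFrame(edges, columns=["geneA", "geneB"]).to_csv(
        out / "ppi_edges.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {"sample_id": r.sample_id, "time": round(r.time, 4), "event": r.event,
             "subtype": r.subtype}
            for r in records
        ]
    ).to_csv(out / "survival.tsv", sep="\t", index=False)
    surv_expr = pd.DataFrame(
        {r.sample_id: r.expression for r in records}
    ).T.round(6)
    surv_expr.to_csv(out / "survival_expression.tsv", sep="\t", index_label="sample_id")
    truth = {
        "config": {
            **{k: v for k, v in asdict(cfg).items() if k not in ("mark_effects", "hazard_plants")},
            "mark_effects": dict(cfg.mark_effects),
        },
        "segmentation": seg_truth,
        "genes": mark_truth["genes"],
        "expression": expr_truth,
        "survival": surv_truth,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
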