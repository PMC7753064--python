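"""End-to-end orchestration: intervals -> chromstate -> integrate -> network
-> survival, with plain-text stage artifacts and a deterministic manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, chromstate, integrate, intervals, io, network, survival

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Input paths and analysis thresholds for a full pipeline run."""

    indir: str
    outdir: str
    seed: int = 0
    bin_size: int = 200
    promoter_flank: int = 2000
    fc_threshold: float = 1.0
    p_threshold: float = 0.05
    closeness_min: float = 130.0
    top_frac: float = 0.30
    kappa_threshold: float = 0.4
    transition_query: tuple[str, str] = ("E4", "E1")

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if not 0 < self.top_frac <= 1:
            raise ValueError("top_frac must lie in (0, 1]")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage on the inputs under ``cfg.indir``.

    Writes stage artifacts (TSV/BED/JSON) and a manifest with the config
    echo and a content hash of every output; rerunning on identical inputs
    reproduces the manifest byte for byte.
    """
    indir, outdir = Path(cfg.indir), Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # the config echo drops paths so reports/manifests are location-independent
    cfg_echo = {k: v for k, v in asdict(cfg).items() if k not in ("indir", "outdir")}
    report: dict = {"config": cfg_echo, "version": __version__, "stages": {}}

    def need(name: str) -> Path:
        p = indir / name
        if not p.exists():
            raise FileNotFoundError(f"pipeline input missing: {p}")
        return p

    genes = io.read_gene_models(need("genes.tsv"))
    genome = pd.read_csv(need("genome.tsv"), sep="\t")
    genome_size = int(genome["length"].sum())

    # --- stage: intervals ---------------------------------------------------
    marks = {
        m: io.read_mark_table(need(f"marks_{m}.tsv"), m)
        for m in integrate.ALL_MARKS
        if (indir / f"marks_{m}.tsv").exists()
    }
    dmps = io.read_dmp_table(need("dmps.tsv"))
    regions_by_mark = {
        m: [a.region for a in alts] for m, alts in marks.items() if alts
    }
    regions_by_mark["mC"] = [
        intervals.GenomicInterval(d.chrom, d.pos, d.pos + 2) for d in dmps
    ]
    combo = intervals.mark_combination_counts(regions_by_mark)
    pd.DataFrame(
        [{"combination": "+".join(k), "n_marks": len(k), "bp": v} for k, v in sorted(combo.items())]
    ).to_csv(outdir / "mark_combinations.tsv", sep="\t", index=False)
    fisher_rows = []
    mark_names = sorted(regions_by_mark)
    for i, a in enumerate(mark_names):
        for b in mark_names[i + 1:]:
            res = intervals.fisher_colocalization(
                regions_by_mark[a], regions_by_mark[b], genome_size
            )
            fisher_rows.append(
                {"markA": a, "markB": b, "n11": res["table"][0][0], "p": res["p_two_tail"]}
            )
    pd.DataFrame(fisher_rows).to_csv(outdir / "colocalization_fisher.tsv", sep="\t", index=False)
    feature_tables = {}
    for m, regs in regions_by_mark.items():
        ann = intervals.annotate_features(regs, genes)
        feature_tables[m] = intervals.feature_fractions(ann, per="region")
    pd.DataFrame(feature_tables).round(6).to_csv(
        outdir / "feature_fractions.tsv", sep="\t", index_label="feature"
    )
    report["stages"]["intervals"] = {
        "n_combinations": len(combo),
        "union_bp": int(sum(combo.values())),
    }

    # --- stage: chromstate --------------------------------------------------
    seg_n = chromstate.StateSegmentation("normal", io.read_bed(need("seg_normal.bed")))
    seg_t = chromstate.StateSegmentation("tumor", io.read_bed(need("seg_tumor.bed")))
    track_n = chromstate.bin_segmentation(seg_n, cfg.bin_size)
    track_t = chromstate.bin_segmentation(seg_t, cfg.bin_size)
    te = chromstate.joint_occupancy(track_n, track_t)
    te = chromstate.raw_enrichment(te)
    te = chromstate.normalized_enrichment(te)
    for name, mat in (("observed", te.observed), ("expected", te.expected),
                      ("res", te.res), ("nes", te.nes)):
        mat.round(6).to_csv(outdir / f"transition_{name}.tsv", sep="\t", index_label="normal_state")
    chisq = chromstate.chisq_independence(te)
    tg = chromstate.transition_genes(
        track_n, track_t, cfg.transition_query[0], cfg.transition_query[1],
        genes, flank=cfg.promoter_flank,
    )
    pd.Series(tg, name="gene_id").to_csv(outdir / "transition_genes.tsv", sep="\t", index=False)
    report["stages"]["chromstate"] = {
        "total_bins": te.total_bins,
        "chisq": chisq,
        "transition_query": list(cfg.transition_query),
        "n_transition_genes": len(tg),
    }

    # --- stage: integrate ---------------------------------------------------
    meth = integrate.summarize_methylation(dmps)
    all_alts = [a for alts in marks.values() for a in alts]
    profiles = integrate.build_gene_profiles(all_alts, dmps, genes, flank=cfg.promoter_flank)
    expr = io.read_expression(need("expression.tsv"), need("pairing.tsv"))
    pd.DataFrame(
        [
            {"gene_id": p.gene_id, "n_marks": p.n_marks, "group": p.group,
             "subgroup": p.subgroup,
             "marks": ";".join(f"{m}:{d}" for m, d in sorted(p.marks.items()))}
            for p in profiles
        ]
    ).to_csv(outdir / "gene_profiles.tsv", sep="\t", index=False)
    additive = integrate.additive_effect(profiles, expr)
    additive.round(6).to_csv(outdir / "additive_effect.tsv", sep="\t", index=False)
    candidates = integrate.select_candidates(
        profiles, expr, fc_threshold=cfg.fc_threshold, p_threshold=cfg.p_threshold
    )
    gene_db = {
        p.gene_id: p.stats["mC"] for p in profiles if "mC" in p.stats
    }
    meth_corr = integrate.methylation_expression_correlation(gene_db, expr)
    meth_corr["per_gene"].round(6).to_csv(
        outdir / "methylation_expression.tsv", sep="\t", index=False
    )
    spearman = integrate.stratified_spearman(profiles, expr)
    spearman.round(6).to_csv(outdir / "stratified_spearman.tsv", sep="\t", index=False)
    for scope in ("promoter", "cds"):
        mat = integrate.pairwise_mark_correlation(all_alts, scope, genes, dmps=dmps)
        mat.round(6).to_csv(outdir / f"mark_correlation_{scope}.tsv", sep="\t",
                            index_label="mark")
    report["stages"]["integrate"] = {
        "n_profiles": len(profiles),
        "n_dmps": meth["n_total"],
        "frac_hypo": meth["n_hypo"] / meth["n_total"] if meth["n_total"] else None,
        "cgi_chisq_yates": meth["chisq_yates"],
        "meth_expr_r": meth_corr["r_overall"],
        "fraction_negative": meth_corr["fraction_negative"],
        "n_overexpressed": len(candidates["overexpressed"]),
        "n_underexpressed": len(candidates["underexpressed"]),
    }

    # --- stage: network -----------------------------------------------------
    edges = io.read_edge_list(need("ppi_edges.tsv"))
    graph = network.build_graph(edges)
    cent = network.centralities(graph)
    cent.round(6).to_csv(outdir / "centralities.tsv", sep="\t", index_label="gene")
    over = [g for g in candidates["overexpressed"] if g in graph]
    under = [g for g in candidates["underexpressed"] if g in graph]
    hubs = network.hub_filter(
        cent, over, under, closeness_min=cfg.closeness_min, top_frac=cfg.top_frac
    )
    pd.Series(hubs, name="gene").to_csv(outdir / "hub_genes.tsv", sep="\t", index=False)
    report["stages"]["network"] = {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "n_hubs": len(hubs),
    }

    # --- stage: survival ----------------------------------------------------
    records = io.read_survival(need("survival.tsv"), need("survival_expression.tsv"))
    usable = [g for g in hubs if g in records[0].expression] or [
        g for g in candidates["overexpressed"] + candidates["underexpressed"]
        if g in records[0].expression
    ]
    model = survival.build_signature(records, usable, p_threshold=cfg.p_threshold)
    pd.DataFrame({"gene": model.genes, "beta": model.beta}).round(6).to_csv(
        outdir / "signature.tsv", sep="\t", index=False
    )
    surv_section: dict = {"signature_size": model.n}
    if model.n:
        split = dichot = survival.dichotomize(records, model)
        by_id = {r.sample_id: r for r in records}
        high = [by_id[s] for s in split["high_risk"]]
        low = [by_id[s] for s in split["low_risk"]]
        lr = survival.logrank(high, low)
        km_high = survival.km_estimate(high).assign(arm="high")
        km_low = survival.km_estimate(low).assign(arm="low")
        pd.concat([km_high, km_low]).round(6).to_csv(
            outdir / "km_curves.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            sorted(split["scores"].items()), columns=["sample_id", "risk_score"]
        ).round(6).to_csv(outdir / "risk_scores.tsv", sep="\t", index=False)
        surv_section.update({"logrank": lr, "cutoff": split["cutoff"]})
    markers = survival.subtype_markers(records, usable, p_threshold=cfg.p_threshold)
    markers.round(6).to_csv(outdir / "subtype_markers.tsv", sep="\t", index=False)
    surv_section["n_marker_rows"] = len(markers)
    report["stages"]["survival"] = surv_section

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_jsonable)
    artifacts = sorted(p for p in outdir.iterdir() if p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "config": cfg_echo,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_echo, sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {p.name: _sha256(p) for p in artifacts},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
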