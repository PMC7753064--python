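#!/usr/bin/env python
"""Integrate mark and methylation alterations with paired expression.

Summarizes the DMP landscape (hypo/hyper x CGI), profiles genes by promoter
alterations, quantifies the additive effect of stacked marks on log2 FPKM
fold change, screens over/underexpressed candidates, and reports the
methylation-expression correlation. Tables land in results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from epishift import integrate, io


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    genes = io.read_gene_models(args.sim / "genes.tsv")
    alts = [a for m in integrate.ALL_MARKS
            if (args.sim / f"marks_{m}.tsv").exists()
            for a in io.read_mark_table(args.sim / f"marks_{m}.tsv", m)]
    dmps = io.read_dmp_table(args.sim / "dmps.tsv")
    expr = io.read_expression(args.sim / "expression.tsv", args.sim / "pairing.tsv")

    meth = integrate.summarize_methylation(dmps)
    print(f"{meth['n_total']} DMPs: {100 * meth['n_hypo'] / meth['n_total']:.1f}% "
          f"hypomethylated; CGI association Yates chi-square "
          f"{meth['chisq_yates']['statistic']:.1f} (p {meth['chisq_yates']['p']:.3g})")

    profiles = integrate.build_gene_profiles(alts, dmps, genes)
    pd.DataFrame(
        [{"gene_id": p.gene_id, "group": p.group, "subgroup": p.subgroup,
          "marks": ";".join(f"{m}:{d}" for m, d in sorted(p.marks.items()))}
         for p in profiles]
    ).to_csv(args.out / "gene_profiles.tsv", sep="\t", index=False)

    table = integrate.additive_effect(profiles, expr)
    table.round(4).to_csv(args.out / "additive_effect.tsv", sep="\t", index=False)
    active = table[table.subgroup == "active"].dropna(subset=["mean_log2fc"])
    print("active-subgroup mean log2 fold change by mark count:",
          ", ".join(f"{r.group}: {r.mean_log2fc:+.2f}" for r in active.itertuples()))

    cand = integrate.select_candidates(profiles, expr)
    print(f"retained {len(cand['overexpressed'])} overexpressed / "
          f"{len(cand['underexpressed'])} underexpressed candidates")
    pd.Series(cand["overexpressed"], name="gene_id").to_csv(
        args.out / "overexpressed.tsv", sep="\t", index=False)
    pd.Series(cand["underexpressed"], name="gene_id").to_csv(
        args.out / "underexpressed.tsv", sep="\t", index=False)

    mc = {p.gene_id: p.stats["mC"] for p in profiles if "mC" in p.stats}
    corr = integrate.methylation_expression_correlation(mc, expr)
    print(f"methylation vs expression across {len(mc)} genes: "
          f"r = {corr['r_overall']:.3f} (p {corr['p']:.3g}); "
          f"{100 * corr['fraction_negative']:.1f}% anticorrelated")


if __name__ == "__main__":
    main()
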