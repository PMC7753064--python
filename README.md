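# epishift

Analysis pipeline for paired tumor/normal epigenomes in gastric
adenocarcinoma-style cohorts: how do chromatin states shift between normal
and tumor tissue, how do stacked histone-mark and DNA-methylation
alterations add up on gene expression, and which epigenetically
dysregulated hub genes carry prognostic signal?

The package re-implements, as tested and reusable code, four bespoke
computations that sit downstream of standard callers (ChromHMM-style
segmentation, diffReps-like differential regions, 450k DMP tables,
FPKM matrices):

1. **Chromatin-state transition enrichment.** Both segmentations are cut
   into 200-bp bins; for normal state *i* and tumor state *j*,

   `RES[i][j] = N_observed[i][j] / N_expected[i][j]`, with
   `N_expected[i][j] = n_i· × n·j / N` under independence, and

   `NES[i][j] = RES[i][j] / RES[j][i]`,

   so NES > 1 flags a directional preference for the *i* → *j* transition.
   A Pearson chi-square tests the full grid against independence, and
   genes whose ±2 kb promoters carry a queried transition are extracted.
2. **Combinatorial mark-expression integration.** Each gene is profiled by
   the marks altered in its promoter; H3K4me1/H3K4me3/H3K27ac/H3K36me3
   vote activating when up, H3K27me3 and mC when down. Unanimous votes
   give active/repressive subgroups, conflicts give poised; mean log2
   FPKM fold change is tracked across 1/2/3/4+ mark-count groups with
   paired t-tests, and candidates are retained at |log2 FC| > 1, p < 0.05.
3. **PPI hub screening.** Harmonic closeness (Σ 1/d) and degree on an
   edge-list graph; genes with closeness > 130 are kept, then all
   underexpressed candidates plus the top 30% of overexpressed candidates
   by degree. Cohen's-kappa grouping of gene-set terms and a
   hypergeometric over-representation test are included.
4. **Survival signature.** Univariate Cox fits (Breslow ties) screen
   candidates at Wald p < 0.05; each patient gets
   `risk_score = Σ β_i × Exp_i`; the cohort is split at the median score
   and compared with Kaplan-Meier curves and the log-rank test, overall
   and within the CIN/GS/EBV/MSI molecular subtypes, where significant
   genes are classed Risky (β > 0) or Protective (β < 0).

A synthetic-data generator (`epishift.synthgen`) produces every input with
planted ground truth — transition rewrites, mark subsets realizing chosen
subgroups, additive expression effects, a methylation-expression
correlation target, forced PPI hubs and per-subtype hazards — so each
stage is testable against what was planted.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data (about a minute end to end):

```sh
python analysis/01_simulate.py --seed 0
python analysis/02_chromatin_transitions.py
python analysis/03_epigenome_expression.py
python analysis/04_ppi_hubs.py
python analysis/05_survival_signature.py
```

With seed 0 this prints (abridged):

```
planted chromatin transition E4->E1 on 297 bins (fraction 0.3)
hazard plants: {"G0149|ALL": 1.0, "G0298|CIN": 1.0}
18000 co-covered bins; independence chi-square 250971.1 (df 324, p 0)
strongest directional transition: E4 -> E1 (NES 32.79)
37 genes carry that transition in their promoter
3737 DMPs: 79.0% hypomethylated; CGI association Yates chi-square 1300.8 (p 7.5e-285)
active-subgroup mean log2 fold change by mark count: 1: +0.93, 2: +0.71, 3: +1.24, 4+: +1.95
retained 49 overexpressed / 37 underexpressed candidates
methylation vs expression across 134 genes: r = -0.498 (p 9.27e-10); 72.4% anticorrelated
PPI network: 227 nodes, 745 edges; 5 nodes pass closeness > 130
hub screen kept 3 genes: G0125, G0149, G0298
signature: 2 of 3 candidate genes
median risk cutoff -0.009; log-rank high vs low: chi-square 72.03, p 2.12e-17
marker G0149 [ALL]: beta +0.79 -> Risky
marker G0298 [CIN]: beta +0.63 -> Risky
```

Reading it: the planted weak-TSS → active-TSS rewrite is recovered as the
top directional transition; hypomethylation dominates the DMP pool with
hypermethylation concentrated in CpG islands; expression shifts grow with
the number of altered marks; the candidate screen plus the PPI filter
narrow 86 genes to 3 hubs; both planted prognostic genes enter the
signature, the high-risk arm dies faster, the cohort-wide plant (G0149)
is Risky in every subtype while the CIN-specific plant (G0298) shows its
effect concentrated in CIN. Tables are written under `results/`.

The same stages are available as a CLI (`epishift simulate | transitions |
integrate | network | survival | run-all`), with `run-all` writing a
deterministic manifest of every artifact.

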