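#!/usr/bin/env python
"""Screen hub genes on the PPI network.

Computes degree and harmonic closeness, keeps candidates above the
closeness threshold, retains every underexpressed candidate plus the top
30% of overexpressed candidates by degree, and writes the hub list.
"""

import argparse
from pathlib import Path

import pandas as pd

from epishift import io, network


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--closeness-min", type=float, default=130.0)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    graph = network.build_graph(io.read_edge_list(args.sim / "ppi_edges.tsv"))
    cent = network.centralities(graph)
    cent.round(4).to_csv(args.out / "centralities.tsv", sep="\t", index_label="gene")
    print(f"PPI network: {graph.number_of_nodes()} nodes, "
          f"{graph.number_of_edges()} edges; "
          f"{(cent['closeness'] > args.closeness_min).sum()} nodes pass "
          f"closeness > {args.closeness_min:g}")

    over = pd.read_csv(args.out / "overexpressed.tsv", sep="\t")["gene_id"].tolist()
    under = pd.read_csv(args.out / "underexpressed.tsv", sep="\t")["gene_id"].tolist()
    over = [g for g in over if g in graph]
    under = [g for g in under if g in graph]
    hubs = network.hub_filter(cent, over, under, closeness_min=args.closeness_min)
    pd.Series(hubs, name="gene").to_csv(args.out / "hub_genes.tsv", sep="\t", index=False)
    print(f"hub screen kept {len(hubs)} genes: {', '.join(hubs) or '(none)'}")


if __name__ == "__main__":
    main()
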