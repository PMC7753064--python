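"""PPI hub-gene screening, kappa-based term grouping and over-representation.

Hub screening follows a two-step rule: keep genes whose harmonic closeness
exceeds a threshold (default 130), then keep every underexpressed candidate
plus the top 30% of overexpressed candidates ranked by degree. Pathway
terms are grouped by Cohen's kappa over shared genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetTerm",
    "build_graph",
    "centralities",
    "hub_filter",
    "kappa_score",
    "kappa_grouping",
    "ora_hypergeometric",
]


@dataclass(frozen=True)
class GeneSetTerm:
    term_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.term_id}: empty gene set")


def build_graph(edges: Iterable[tuple[str, str]]) -> nx.Graph:
    """Undirected PPI graph; self-loops dropped, duplicate edges collapsed."""
    g = nx.Graph()
    for a, b in edges:
        if a != b:
            g.add_edge(a, b)
    return g


def centralities(g: nx.Graph) -> pd.DataFrame:
    """Degree and harmonic closeness (sum of 1/d to every reachable node).

    Harmonic closeness is unbounded — it scales with network size — which
    matches threshold-style screening on networks of a few hundred nodes.
    Unreachable pairs contribute 0; isolated nodes score 0.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    closeness = nx.harmonic_centrality(g)
    return pd.DataFrame(
        {
            "gene": list(g.nodes),
            "degree": [g.degree(n) for n in g.nodes],
            "closeness": [closeness[n] for n in g.nodes],
        }
    ).set_index("gene")


def hub_filter(
    cent: pd.DataFrame,
    overexpressed: Sequence[str],
    underexpressed: Sequence[str],
    closeness_min: float = 130.0,
    top_frac: float = 0.30,
) -> list[str]:
    """Screen hub genes from candidate lists by closeness then degree.

    Genes must exceed ``closeness_min`` (strict). All passing
    underexpressed candidates are kept; of the passing overexpressed
    candidates the top ceil(top_frac * n) by degree are kept, ties broken
    by closeness then gene id.
    """
    if set(overexpressed) & set(underexpressed):
        raise ValueError("candidate lists must be disjoint")
    if not overexpressed and not underexpressed:
        logger.warning("hub_filter: both candidate lists empty")
        return []
    passing = cent[cent["closeness"] > closeness_min]
    under = [g for g in underexpressed if g in passing.index]
    over = [g for g in overexpressed if g in passing.index]
    kept_over: list[str] = []
    if over:
        k = math.ceil(top_frac * len(over))
        ranked = sorted(
            over,
            key=lambda g: (-passing.loc[g, "degree"], -passing.loc[g, "closeness"], g),
        )
        kept_over = ranked[:k]
    return sorted(set(under) | set(kept_over))


def kappa_score(a: GeneSetTerm, b: GeneSetTerm, universe: Iterable[str]) -> float:
    """Cohen's kappa between two terms' binary membership vectors."""
    uni = set(universe)
    if len(uni) < 2:
        raise ValueError("universe must contain at least 2 genes")
    if not a.genes <= uni or not b.genes <= uni:
        raise ValueError("term genes must be a subset of the universe")
    n = len(uni)
    n11 = len(a.genes & b.genes)
    n10 = len(a.genes - b.genes)
    n01 = len(b.genes - a.genes)
    n00 = n - n11 - n10 - n01
    po = (n11 + n00) / n
    pe = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / n**2
    if pe == 1.0:
        return float("nan")  # flagged undefined: no disagreement possible
    return (po - pe) / (1 - pe)


def kappa_grouping(
    terms: Sequence[GeneSetTerm],
    universe: Iterable[str],
    threshold: float = 0.4,
) -> list[list[str]]:
    """Group terms by connected components of the kappa >= threshold graph.

    Groups (and terms within them) are ordered by smallest term_id.
    """
    if not terms:
        raise ValueError("at least one term required")
    uni = set(universe)
    g = nx.Graph()
    g.add_nodes_from(t.term_id for t in terms)
    for i, a in enumerate(terms):
        for b in terms[i + 1:]:
            k = kappa_score(a, b, uni)
            if np.isfinite(k) and k >= threshold:
                g.add_edge(a.term_id, b.term_id)
    groups = [sorted(c) for c in nx.connected_components(g)]
    return sorted(groups, key=lambda c: c[0])


def ora_hypergeometric(
    query: Iterable[str], term: GeneSetTerm, universe: Iterable[str]
) -> dict:
    """Upper-tail hypergeometric over-representation of a query in a term."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query) & uni
    t = term.genes & uni
    k = len(q & t)
    p = float(stats.hypergeom.sf(k - 1, len(uni), len(t), len(q)))
    expected = len(q) * len(t) / len(uni)
    fold = k / expected if expected > 0 else float("nan")
    return {"p": min(p, 1.0), "fold_enrichment": fold, "overlap": k}
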