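"""Scored PPI-network statistics and GO hypergeometric enrichment.

Networks are simple undirected graphs whose edges carry a combined
confidence score in (0, 1]; threshold views retain edges at or above a
score cutoff. Enrichment uses the hypergeometric upper tail with BH
adjustment and a conservative doubling of the FDR (parallel testing of
two datasets), capped at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "LCCStats",
    "threshold_view",
    "lcc_stats",
    "clustering_coefficient",
    "ppi_enrichment",
    "go_enrichment",
]

from .group_stats import bh_fdr


@dataclass(frozen=True)
class LCCStats:
    lcc_nodes: frozenset[str]
    degrees: dict[str, int]
    mean_degree_lcc: float
    isolated_count: int

    @property
    def lcc_size(self) -> int:
        return len(self.lcc_nodes)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # sample genes with the term
    K: int  # universe genes with the term
    n: int  # sample size
    N_universe: int
    p: float
    fdr: float
    fdr_adjusted: float  # min(1, 2 * fdr)
    enriched: bool


def threshold_view(net: nx.Graph, threshold: float) -> nx.Graph:
    """Same nodes, only edges with score >= threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    view = nx.Graph()
    view.add_nodes_from(net.nodes)
    view.add_edges_from(
        (u, v, d) for u, v, d in net.edges(data=True)
        if d["score"] >= threshold)
    return view


def lcc_stats(net: nx.Graph, degrees_within_lcc: bool = False) -> LCCStats:
    """Largest connected component, per-node degrees, mean degree over
    LCC members, and the count of isolated nodes.

    Ties for the largest component break to the one containing the
    lexicographically smallest member. Degrees are counted in the full
    graph by default; ``degrees_within_lcc`` restricts them to the LCC
    subgraph.
    """
    degrees = {n: d for n, d in net.degree()}
    isolated = sum(1 for d in degrees.values() if d == 0)
    components = list(nx.connected_components(net))
    if not components:
        return LCCStats(frozenset(), degrees, math.nan, isolated)
    lcc = sorted(components, key=lambda c: (-len(c), min(c)))[0]
    if degrees_within_lcc:
        sub = net.subgraph(lcc)
        lcc_degrees = {n: d for n, d in sub.degree()}
    else:
        lcc_degrees = {n: degrees[n] for n in lcc}
    mean_degree = float(np.mean(list(lcc_degrees.values())))
    return LCCStats(frozenset(lcc), degrees, mean_degree, isolated)


def clustering_coefficient(net: nx.Graph) -> float:
    """Mean local (Watts-Strogatz) clustering coefficient over all nodes;
    nodes with degree < 2 contribute 0."""
    if net.number_of_nodes() == 0:
        return math.nan
    return float(nx.average_clustering(net))


def ppi_enrichment(net: nx.Graph,
                   background_edge_prob: float) -> tuple[float, float]:
    """Upper-tail binomial test of the observed edge count against a
    uniform background edge probability.

    Returns (p_value, expected_edge_count). This is a simplification of
    degree-corrected nulls: the background probability is user-supplied.
    """
    if not 0.0 < background_edge_prob < 1.0:
        raise ValueError("background_edge_prob must lie in (0, 1)")
    n = net.number_of_nodes()
    pairs = n * (n - 1) // 2
    observed = net.number_of_edges()
    expected = pairs * background_edge_prob
    if observed == 0:
        return 1.0, expected
    p = float(stats.binom.sf(observed - 1, pairs, background_edge_prob))
    return p, expected


def go_enrichment(
    sample: set[str],
    annotations: Mapping[str, set[str]],
    universe: set[str],
    go_alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """Hypergeometric term enrichment of ``sample`` against ``universe``.

    For each term annotating at least one universe gene: p is the
    upper-tail probability of drawing >= k term genes in n draws from a
    universe of N with K term genes. BH runs across all tested terms;
    the adjusted value is doubled (capped at 1) and compared to
    ``go_alpha``.
    """
    offenders = sorted(sample - universe)
    if offenders:
        raise ValueError(f"sample genes missing from universe: {offenders}")
    term_universe: dict[str, set[str]] = {}
    for gene in universe:
        for term in annotations.get(gene, ()):
            term_universe.setdefault(term, set()).add(gene)
    N = len(universe)
    n = len(sample)
    terms = sorted(term_universe)
    pvals = []
    counts = []
    for term in terms:
        members = term_universe[term]
        K = len(members)
        k = len(members & sample)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        pvals.append(p)
        counts.append((k, K))
    fdrs = bh_fdr(pvals)
    out = []
    for term, p, fdr, (k, K) in zip(terms, pvals, fdrs, counts):
        adj = min(1.0, 2.0 * float(fdr))
        out.append(EnrichmentResult(
            term=term, k=k, K=K, n=n, N_universe=N, p=p, fdr=float(fdr),
            fdr_adjusted=adj, enriched=adj < go_alpha))
    out.sort(key=lambda r: (r.p, r.term))
    return out
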