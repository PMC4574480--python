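"""Multi-source interaction-network assembly and over-representation analysis.

A composite network is built from heterogeneous evidence: unscored
protein-protein interactions (``ppi_a``), scored interactions
(``ppi_scored``, kept only at or above a confidence cutoff, 0.9 by
default), directed transcription-factor edges (``tf``), and pathway
co-membership (``pathway``). The subnetwork induced by the mapped genes and
their first neighbors is then tested for over-representation with the exact
one-sided hypergeometric tail; regulator enrichment replays the same test
against each regulator's target set with Benjamini-Hochberg q-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import InteractionEdge


@dataclass
class AssembledNetwork:
    """Undirected interaction graph plus the directed regulator layer.

    ``graph`` holds every kept edge (tf edges included, so adjacency counts
    both directions); each edge carries a ``sources`` provenance set and the
    maximum ``score`` seen. ``regulators`` holds only the directed tf edges.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    regulators: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)


def assemble_network(edges: Iterable[InteractionEdge], score_cutoff: float = 0.9) -> AssembledNetwork:
    """Merge sourced edges into one network, thresholding scored PPIs.

    ``ppi_scored`` edges survive iff score >= score_cutoff (inclusive);
    other sources are kept unconditionally. Self-loops are dropped;
    duplicate pairs merge with provenance union and maximum score.
    """
    if not (0.0 <= score_cutoff <= 1.0):
        raise ValueError("score_cutoff must lie in [0, 1]")
    net = AssembledNetwork()
    for e in edges:
        if e.gene_a == e.gene_b:
            continue
        if e.source == "ppi_scored":
            if e.score is None:
                raise ValueError(f"ppi_scored edge {e.gene_a}-{e.gene_b} lacks a score")
            if e.score < score_cutoff:
                continue
        if net.graph.has_edge(e.gene_a, e.gene_b):
            data = net.graph.edges[e.gene_a, e.gene_b]
            data["sources"].add(e.source)
            if e.score is not None:
                data["score"] = max(e.score, data["score"] or 0.0)
        else:
            net.graph.add_edge(e.gene_a, e.gene_b, sources={e.source}, score=e.score)
        if e.source == "tf" or e.directed:
            net.regulators.add_edge(e.gene_a, e.gene_b)
    return net


def first_neighbors(
    network: AssembledNetwork, seeds: Sequence[str]
) -> tuple[nx.Graph, list[str]]:
    """Subnetwork of the seed genes and everything adjacent to them.

    Seeds absent from the network are ignored with a warning; present seeds
    are kept even when isolated. The edge set is the full induced subgraph
    on seeds plus neighbors, and the returned gene list is its (sorted)
    node set.
    """
    present = [s for s in dict.fromkeys(seeds) if s in network.graph]
    missing = set(seeds) - set(present)
    if missing:
        warnings.warn(f"{len(missing)} seed gene(s) absent from network", stacklevel=2)
    nodes = set(present)
    for s in present:
        nodes.update(network.graph.neighbors(s))
    sub = network.graph.subgraph(nodes).copy()
    return sub, sorted(nodes)


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    universe_size: int  # N
    set_size: int  # K
    query_size: int  # n
    overlap: int  # k
    p: float


def hypergeom_enrich(
    query: Sequence[str], gene_set: Sequence[str], universe: Sequence[str], set_id: str = ""
) -> EnrichmentResult:
    """Exact one-sided hypergeometric over-representation test.

    p = P(overlap >= k) for a draw of |query| genes from a universe of N
    containing |gene_set| marked genes. Query and set must be subsets of
    the universe.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    qset = set(query)
    sset = set(gene_set)
    if not qset <= uni:
        raise ValueError(f"{len(qset - uni)} query gene(s) outside the universe")
    if not sset <= uni:
        raise ValueError(f"{len(sset - uni)} gene-set member(s) outside the universe")
    n_uni, n_set, n_query = len(uni), len(sset), len(qset)
    k = len(qset & sset)
    p = float(stats.hypergeom.sf(k - 1, n_uni, n_set, n_query))
    return EnrichmentResult(set_id, n_uni, n_set, n_query, k, min(p, 1.0))


def regulator_enrich(
    network: AssembledNetwork, query: Sequence[str], universe: Sequence[str] | None = None
) -> pd.DataFrame:
    """Hypergeometric enrichment of the query against each regulator's targets.

    The universe defaults to the assembled network's node set. Regulators
    with no targets inside the universe are skipped. Results are sorted by
    p with Benjamini-Hochberg q-values alongside.
    """
    if universe is None:
        universe = sorted(network.nodes)
    if network.regulators.number_of_edges() == 0:
        warnings.warn("no transcription-factor edges in network", stacklevel=2)
        return pd.DataFrame(columns=["regulator", "N", "K", "n", "k", "p", "q"])
    uni = set(universe)
    rows = []
    for reg in sorted(network.regulators.nodes):
        targets = set(network.regulators.successors(reg)) & uni
        if not targets:
            continue
        res = hypergeom_enrich(query, sorted(targets), sorted(uni), set_id=reg)
        rows.append(
            {
                "regulator": reg,
                "N": res.universe_size,
                "K": res.set_size,
                "n": res.query_size,
                "k": res.overlap,
                "p": res.p,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df = df.sort_values(["p", "regulator"], kind="mergesort").reset_index(drop=True)
    else:
        df["q"] = []
    return df
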