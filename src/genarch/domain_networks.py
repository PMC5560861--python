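"""Domain co-occurrence networks, Louvain communities and rewiring nulls.

A genome (extant proteome or ancestral reconstruction called at >= 90%
posterior) is modelled as an undirected simple graph whose vertices are
domains and whose edges link domains co-occurring as a pair within a gene
family; edge provenance records the orthoclusters supporting it.  Community
structure comes from seeded Louvain clustering; modularity Q is Newman's
fraction of intra-community edges minus its degree-matched expectation.
The null model preserves every vertex degree exactly via double-edge swaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from .synthetic_data import substream

logger = logging.getLogger("genarch")

REWIRE_SWAPS_PER_EDGE = 10


def build_network(pairs, genome: str = "",
                  weighted: bool = False) -> nx.Graph:
    """Undirected domain co-occurrence graph from (a, b, orthocluster) rows.

    Pair direction is discarded; parallel pairs merge into one edge whose
    ``orthoclusters`` attribute accumulates provenance (and ``weight``
    counts distinct orthoclusters when ``weighted``).  Self-pairs (A, A)
    become a vertex attribute instead of a self-loop edge.
    """
    G = nx.Graph(genome=genome)
    for a, b, og in pairs:
        if a == b:
            if not G.has_node(a):
                G.add_node(a)
            G.nodes[a]["self_pair"] = True
            continue
        if G.has_edge(a, b):
            G.edges[a, b]["orthoclusters"].add(og)
        else:
            G.add_edge(a, b, orthoclusters={og})
    if weighted:
        for u, v, data in G.edges(data=True):
            data["weight"] = len(data["orthoclusters"])
    return G


def pairs_from_calls(calls: pd.DataFrame, node: str) -> list[tuple[str, str, str]]:
    """(domain_a, domain_b, orthocluster) rows present in one genome/node.

    ``calls`` is indexed by (domain_a, domain_b, orthocluster) with 0/1
    entries per node, e.g. the >= 90%-posterior ancestral calls.
    """
    sel = calls[node]
    return [tuple(ix[:3]) for ix in sel.index[sel > 0]]


@dataclass
class NetworkStats:
    """Community partition and modularity of one genome's domain network."""

    genome: str
    modularity: float
    communities: list[set]
    mean_domains_per_community: float
    null_q: np.ndarray | None = None

    @property
    def n_communities(self) -> int:
        return len(self.communities)


LOUVAIN_RESTARTS = 10


def community_modularity(net: nx.Graph, seed: int = 0,
                         resolution: float = 1.0,
                         n_restarts: int = LOUVAIN_RESTARTS) -> NetworkStats:
    """Best-of-restarts Louvain communities and Newman Q.

    Louvain is greedy and order-dependent; ``n_restarts`` seeded runs are
    performed (seeds derived deterministically from ``seed``) and the
    partition with the highest modularity is returned, so results are
    reproducible for a fixed seed.
    """
    if net.number_of_edges() == 0:
        raise ValueError("edgeless graph: modularity undefined")
    q, communities = -np.inf, None
    for r in range(n_restarts):
        cand = nx.community.louvain_communities(
            net, seed=int(seed) + 7919 * r, resolution=resolution)
        qc = nx.community.modularity(net, cand, resolution=resolution)
        if qc > q:
            q, communities = qc, cand
    mean_size = float(np.mean([len(c) for c in communities]))
    return NetworkStats(genome=net.graph.get("genome", ""), modularity=float(q),
                        communities=[set(c) for c in communities],
                        mean_domains_per_community=mean_size)


def rewire(net: nx.Graph, seed: int,
           swaps_per_edge: int = REWIRE_SWAPS_PER_EDGE) -> nx.Graph:
    """One degree-preserving rewired replicate via double-edge swaps.

    Applies ``swaps_per_edge * |E|`` accepted swaps, rejecting self-loops
    and parallel edges; a graph admitting no valid swap is returned
    unchanged with a warning.
    """
    m = net.number_of_edges()
    H = nx.Graph()
    H.add_nodes_from(net.nodes)
    H.add_edges_from(net.edges)
    try:
        nx.double_edge_swap(H, nswap=swaps_per_edge * m,
                            max_tries=100 * swaps_per_edge * m,
                            seed=int(seed))
    except nx.NetworkXError:
        logger.warning("no valid double-edge swap: replicate keeps the "
                       "original topology")
        return net
    return H


def rewire_null(net: nx.Graph, n_reps: int = 100, seed: int = 0,
                swaps_per_edge: int = REWIRE_SWAPS_PER_EDGE) -> np.ndarray:
    """Modularity distribution over degree-preserving rewired replicates."""
    if net.number_of_edges() < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = substream(seed, f"rewire:{net.graph.get('genome', '')}")
    qs = np.empty(n_reps)
    for r in range(n_reps):
        H = rewire(net, seed=int(rng.integers(2**31 - 1)),
                   swaps_per_edge=swaps_per_edge)
        qs[r] = community_modularity(H, seed=int(rng.integers(2**31 - 1))).modularity
    return qs


def modularity_vs_community_size(stats: list[NetworkStats]
                                 ) -> tuple[float, float]:
    """Spearman rank correlation of Q against mean domains per community."""
    if len(stats) < 4:
        raise ValueError("need at least 4 genomes")
    q = np.array([s.modularity for s in stats])
    size = np.array([s.mean_domains_per_community for s in stats])
    if np.all(q == q[0]) or np.all(size == size[0]):
        logger.warning("constant input: Spearman correlation undefined")
        return float("nan"), float("nan")
    res = scipy.stats.spearmanr(q, size)
    return float(res.statistic), float(res.pvalue)


def subnetwork(net: nx.Graph, domain_list: list[str],
               mode: str = "orthocluster") -> nx.Graph:
    """Function-oriented subnetwork.

    mode="orthocluster" (default): keep edges whose provenance includes an
    orthocluster that itself contains a listed domain anywhere in the
    network, matching retrieval of whole orthologous groups.
    mode="vertex": plain vertex-induced subgraph on the listed domains.
    """
    if not domain_list:
        raise ValueError("empty domain list")
    wanted = set(domain_list)
    if mode == "vertex":
        return net.subgraph(wanted & set(net.nodes)).copy()
    if mode != "orthocluster":
        raise ValueError(f"unknown subnetwork mode {mode!r}")
    hit_ogs = set()
    for u, v, data in net.edges(data=True):
        if u in wanted or v in wanted:
            hit_ogs |= data["orthoclusters"]
    H = nx.Graph(genome=net.graph.get("genome", ""))
    for u, v, data in net.edges(data=True):
        keep = data["orthoclusters"] & hit_ogs
        if keep:
            H.add_edge(u, v, orthoclusters=set(keep))
    if H.number_of_edges() == 0:
        logger.warning("no orthocluster matches the domain list: empty "
                       "subnetwork")
    return H
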