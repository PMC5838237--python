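"""Disease-network extraction, community detection, and term enrichment.

The disease network is the subgraph of the FRN spanned by a set of
highly ranked genes and every gene connected to one of them at posterior
≥ 0.98.  Communities are found with the divisive Girvan–Newman
algorithm: repeatedly remove the edge of highest betweenness (unweighted
shortest paths; ties broken by lexicographic edge label), record the
connected-component partition whenever the graph splits, and keep the
recorded partition of maximal Newman–Girvan modularity evaluated on the
original edge set.  Each community is then tested for gene-set
over-representation with a one-sided hypergeometric test and
Benjamini–Hochberg FDR correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .bayes import FunctionalNetwork
from .io import GeneSetCollection
from .pairs import canonical_pair

log = logging.getLogger(__name__)


@dataclass
class Partition:
    """Node→community assignment with the modularity of the chosen split."""

    community_of: dict[str, int]
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.community_of.values()))

    def members(self, cid: int) -> set[str]:
        return {n for n, c in self.community_of.items() if c == cid}


def extract_disease_network(
    network: FunctionalNetwork,
    top_genes: list[str],
    threshold: float = 0.98,
) -> nx.Graph:
    """Subnetwork of top genes plus their direct high-confidence neighbors.

    Nodes: the top genes (role "top-decile", kept even if isolated) and
    every gene with posterior >= threshold to a top gene (role
    "neighbor").  Edges: all pairs within that node set with posterior
    >= threshold, including neighbor–neighbor pairs.
    """
    index = {g: i for i, g in enumerate(network.genes)}
    missing = [g for g in top_genes if g not in index]
    if missing:
        raise ValueError(f"top genes absent from network: {missing[:5]}")
    top_idx = np.array([index[g] for g in top_genes], dtype=np.intp)
    post = network.posterior
    hit = (post[top_idx] >= threshold).any(axis=0)
    node_idx = sorted(set(np.where(hit)[0]) | set(top_idx.tolist()))
    G = nx.Graph()
    top_set = set(top_genes)
    for i in node_idx:
        g = network.genes[i]
        G.add_node(g, role="top-decile" if g in top_set else "neighbor")
    sub = post[np.ix_(node_idx, node_idx)]
    ii, jj = np.where(np.triu(sub >= threshold, k=1))
    for i, j in zip(ii, jj):
        a, b = network.genes[node_idx[i]], network.genes[node_idx[j]]
        G.add_edge(a, b, weight=float(sub[i, j]))
    if G.number_of_edges() == 0:
        log.warning("disease network has no edge at threshold %.3g", threshold)
    return G


def _components(G: nx.Graph) -> list[set[str]]:
    return [set(c) for c in nx.connected_components(G)]


def girvan_newman_partition(network: nx.Graph, seed: int | None = None) -> Partition:
    """Divisive edge-betweenness community detection, modularity-selected.

    Deterministic: betweenness on the unweighted graph, ties broken by
    lexicographic (canonical) edge label; the partition of maximal
    modularity on the original edge set is returned, preferring the
    earliest (coarsest) partition on ties.  *seed* is accepted for
    interface symmetry; the algorithm involves no randomness.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty graph")
    original = network.copy()
    work = network.copy()
    recorded = [_components(work)]
    n_comp = len(recorded[0])
    while work.number_of_edges() > 0:
        bet = nx.edge_betweenness_centrality(work, normalized=False)
        top = max(bet.values())
        # among tied edges the lexicographically smallest canonical label wins
        ties = [e for e, v in bet.items() if v == top]
        edge = min(canonical_pair(*e) for e in ties)
        work.remove_edge(*edge)
        comps = _components(work)
        if len(comps) > n_comp:
            recorded.append(comps)
            n_comp = len(comps)

    m = original.number_of_edges()
    if m == 0:
        comms = sorted(_components(original), key=lambda c: sorted(c)[0])
        return Partition({n: i + 1 for i, c in enumerate(comms) for n in c}, 0.0)
    best_part, best_q = None, -np.inf
    for part in recorded:
        q = nx.community.modularity(original, part)
        if q > best_q + 1e-12:
            best_q, best_part = q, part
    comms = sorted(best_part, key=lambda c: (-len(c), sorted(c)[0]))
    community_of = {n: i + 1 for i, c in enumerate(comms) for n in c}
    return Partition(community_of, float(best_q))


def hypergeometric_enrichment(
    cluster: set[str],
    sets: GeneSetCollection,
    universe: set[str],
) -> pd.DataFrame:
    """Over-representation of each gene set in the cluster, BH-corrected.

    p = P(X >= overlap) for X ~ Hypergeometric(|universe|, |set ∩
    universe|, |cluster|); Q-values by Benjamini–Hochberg over all sets
    tested for this cluster; significant iff Q <= 0.01.
    """
    if not cluster:
        raise ValueError("empty cluster")
    if not cluster <= universe:
        raise ValueError("cluster must be a subset of the universe")
    M, n_cluster = len(universe), len(cluster)
    rows = []
    for name, gs in sets.sets.items():
        members = set(gs.genes) & universe
        overlap = len(cluster & members)
        p = float(hypergeom.sf(overlap - 1, M, len(members), n_cluster))
        rows.append((name, len(members), overlap, p))
    df = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p_value"])
    if len(df):
        _, q, _, _ = multipletests(df["p_value"], method="fdr_bh")
        df["q_value"] = q
        df["significant"] = df["q_value"] <= 0.01
    return df.sort_values(["p_value", "set"]).reset_index(drop=True)
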