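"""Topological analysis of the chosen residue network.

Degree and coreness are computed on the unweighted skeleton; betweenness and
closeness use the traversal cost 1/weight (strong coupling = short), and
eigenvector centrality uses the raw edge weight.  Community structure is
assessed by consensus over many independently seeded Louvain runs, because a
single Louvain run is a heuristic whose output varies with its seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .residues import ResidueKey


@dataclass
class NodeMetricsTable:
    table: pd.DataFrame  # index: node key string; degree, betweenness, closeness, eigenvector, coreness

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def node_metrics(g: nx.Graph, eigen_max_iter: int = 2000, eigen_tol: float = 1e-8,
                 harmonic_closeness: bool = False) -> NodeMetricsTable:
    """Standard centrality panel for the residue network.

    degree: unweighted edge count.  betweenness/closeness: shortest-path
    based with edge cost 1/weight; closeness uses the component-scaled
    (Wasserman-Faust) convention on disconnected graphs, or the harmonic
    variant when requested.  eigenvector: weighted, normalized to unit
    maximum.  coreness: k-core index of the unweighted skeleton.
    """
    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g, weight="cost", normalized=True)
    if harmonic_closeness:
        n = g.number_of_nodes()
        closeness = {
            k: v / (n - 1) if n > 1 else 0.0
            for k, v in nx.harmonic_centrality(g, distance="cost").items()
        }
    else:
        closeness = nx.closeness_centrality(g, distance="cost", wf_improved=True)
    if g.number_of_edges() == 0:
        eigenvector = {v: 0.0 for v in g}
    else:
        try:
            eigenvector = nx.eigenvector_centrality(
                g, weight="weight", max_iter=eigen_max_iter, tol=eigen_tol
            )
        except nx.PowerIterationFailedConvergence as exc:
            raise RuntimeError(
                f"eigenvector centrality failed to converge within "
                f"{eigen_max_iter} iterations at tol={eigen_tol}"
            ) from exc
        peak = max(eigenvector.values())
        if peak > 0:
            eigenvector = {k: v / peak for k, v in eigenvector.items()}
    # self-loops would break core_number; the network type forbids them
    coreness = nx.core_number(g)
    nodes = sorted(g.nodes)
    table = pd.DataFrame(
        {
            "label": [g.nodes[n].get("label", str(n)) for n in nodes],
            "degree": [degree[n] for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
            "closeness": [closeness[n] for n in nodes],
            "eigenvector": [eigenvector[n] for n in nodes],
            "coreness": [coreness[n] for n in nodes],
        },
        index=pd.Index([str(n) for n in nodes], name="node"),
    )
    return NodeMetricsTable(table=table)


@dataclass
class PathsFromSource:
    source: ResidueKey
    distances: dict[ResidueKey, float]  # cumulative traversal cost; inf if unreachable
    traversed_edges: set[tuple[ResidueKey, ResidueKey]]  # canonical (sorted) pairs
    unreachable: set[ResidueKey]

    def to_frame(self, labels=None) -> pd.DataFrame:
        labels = labels or {}
        nodes = sorted(self.distances)
        return pd.DataFrame(
            {
                "node": [str(n) for n in nodes],
                "label": [labels.get(n, str(n)) for n in nodes],
                "distance": [self.distances[n] for n in nodes],
                "reachable": [n not in self.unreachable for n in nodes],
            }
        )


def paths_from(g: nx.Graph, source: ResidueKey) -> PathsFromSource:
    """Dijkstra tree from a focal residue (cost 1/weight): per-node weighted
    distance plus the set of edges traversed by any shortest path, for
    mapping the coupling flow onto the structure."""
    if source not in g:
        raise ValueError(f"source residue {source} not in network")
    dist, paths = nx.single_source_dijkstra(g, source, weight="cost")
    distances = {n: dist.get(n, float("inf")) for n in g.nodes}
    unreachable = {n for n in g.nodes if n not in dist}
    traversed = set()
    for node, path in paths.items():
        for a, b in zip(path, path[1:]):
            traversed.add((a, b) if a <= b else (b, a))
    return PathsFromSource(
        source=source, distances=distances, traversed_edges=traversed, unreachable=unreachable
    )


def _canonical_partition(communities) -> frozenset[frozenset]:
    return frozenset(frozenset(c) for c in communities)


@dataclass
class CommunityConsensus:
    iterations: int
    most_frequent_partition: list[set[ResidueKey]]
    most_frequent_share: float  # fraction of iterations yielding that partition
    co_occurrence: dict[ResidueKey, float]  # with focal residue
    focal: ResidueKey

    def co_occurrence_frame(self, labels=None) -> pd.DataFrame:
        labels = labels or {}
        nodes = sorted(self.co_occurrence)
        return pd.DataFrame(
            {
                "node": [str(n) for n in nodes],
                "label": [labels.get(n, str(n)) for n in nodes],
                "co_occurrence": [self.co_occurrence[n] for n in nodes],
            }
        )


def louvain_consensus(
    g: nx.Graph,
    focal: ResidueKey,
    iterations: int = 10_000,
    seed: int | None = None,
    resolution: float = 1.0,
) -> CommunityConsensus:
    """Consensus Louvain community detection.

    Runs weighted-modularity Louvain once per iteration with an independent
    pseudo-random seed, canonicalizes each partition to a set of node sets
    (so community labels never matter), counts partition recurrences, and
    records how often every node shares a community with the focal residue.
    """
    if focal not in g:
        raise ValueError(f"focal residue {focal} not in network")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    counter: Counter = Counter()
    co_counts = {n: 0 for n in g.nodes}
    for _ in range(iterations):
        run_seed = int(rng.integers(0, 2**31 - 1))
        communities = nx.community.louvain_communities(
            g, weight="weight", resolution=resolution, seed=run_seed
        )
        counter[_canonical_partition(communities)] += 1
        focal_comm = next(c for c in communities if focal in c)
        for n in focal_comm:
            co_counts[n] += 1
    best, best_count = counter.most_common(1)[0]
    return CommunityConsensus(
        iterations=iterations,
        most_frequent_partition=[set(c) for c in best],
        most_frequent_share=best_count / iterations,
        co_occurrence={n: c / iterations for n, c in co_counts.items()},
        focal=focal,
    )
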