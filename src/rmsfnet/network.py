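"""Dynamic correlation network construction and shortest-path validation.

Nodes are interface residues with Cα coordinates; an edge (u, v) exists iff
the coupling is significant (p_adj < alpha and |rho_s| >= rho_min) and the
through-space Cα distance is below a threshold t, with weight

    E[u, v, n, t] = |rho_s[u, v]| / r_Ca[u, v]**n,

where the exponent n and threshold t are the two construction parameters
scanned during validation.  Strong coupling should mean short graph
distance, so Dijkstra traverses edges at cost 1/weight.

Validation asks whether shortest paths behave like physical signal
propagation: F1 is the fraction of shortest paths containing an edge that
spans a larger through-space distance than the endpoints' own separation;
F2 the fraction with any step that lengthens relative to the previous step;
F3 the fraction with an intermediate node farther from the target than the
start is.  Good networks keep F1 low while holding >90% of nodes in one
connected component.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .corrstats import CorrelationResult
from .io_formats import CaCoordinates
from .residues import ResidueKey


@dataclass
class EdgeWeightParams:
    """Construction parameters for the edge-weight metric."""

    exponent: float = 0.0  # n: inverse power of distance in the weight
    threshold: float = 10.0  # t: Cα distance cutoff, Å
    alpha: float = 0.05
    rho_min: float = 0.5

    def __post_init__(self) -> None:
        if self.exponent < 0:
            raise ValueError("exponent n must be >= 0")
        if self.threshold <= 0:
            raise ValueError("distance threshold t must be > 0 Å")


def build_network(
    corr: CorrelationResult,
    coords: CaCoordinates,
    params: EdgeWeightParams,
    labels: Mapping[ResidueKey, str] | None = None,
) -> nx.Graph:
    """Build the residue network for one (n, t) parameter choice.

    Every residue becomes a node (with its Cα position); edges follow the
    existence predicate above.  Edge attributes: rho, abs_rho, r_ca (Å),
    weight, and traversal cost = 1/weight.
    """
    missing = coords.missing(corr.residues)
    if missing:
        raise ValueError(
            f"residues without Cα coordinates: {[str(m) for m in missing]}"
        )
    labels = labels or {}
    g = nx.Graph()
    for key in corr.residues:
        g.add_node(key, pos=coords.positions[key], label=labels.get(key, str(key)))
    residues = corr.residues
    dist = coords.distance_matrix(residues)
    k = len(residues)
    for i in range(k):
        for j in range(i + 1, k):
            if not corr.mask[i, j]:
                continue
            r_ca = dist[i, j]
            if not (r_ca < params.threshold):
                continue
            abs_rho = abs(corr.rho[i, j])
            weight = abs_rho / r_ca**params.exponent
            g.add_edge(
                residues[i],
                residues[j],
                rho=float(corr.rho[i, j]),
                abs_rho=float(abs_rho),
                r_ca=float(r_ca),
                weight=float(weight),
                cost=float(1.0 / weight),
            )
    g.graph.update(
        exponent=params.exponent,
        threshold=params.threshold,
        alpha=params.alpha,
        rho_min=params.rho_min,
    )
    return g


def _lexicographic_dijkstra(
    g: nx.Graph, source: ResidueKey, order: Mapping[ResidueKey, int]
) -> dict[ResidueKey, tuple[float, tuple[ResidueKey, ...]]]:
    """Single-source Dijkstra returning, per reachable node, the minimum cost
    and the lexicographically smallest minimum-cost path (by node order).

    Heap entries are (cost, path-as-order-indices); tuple comparison makes
    the first settled entry per node both cheapest and lexicographically
    minimal among cheapest.
    """
    settled: dict[ResidueKey, tuple[float, tuple[ResidueKey, ...]]] = {}
    heap: list[tuple[float, tuple[int, ...], tuple[ResidueKey, ...]]] = [
        (0.0, (order[source],), (source,))
    ]
    while heap:
        cost, _idx_path, path = heapq.heappop(heap)
        node = path[-1]
        if node in settled:
            continue
        settled[node] = (cost, path)
        for nbr in g.neighbors(node):
            if nbr in settled:
                continue
            edge_cost = g.edges[node, nbr]["cost"]
            heapq.heappush(
                heap,
                (cost + edge_cost, _idx_path + (order[nbr],), path + (nbr,)),
            )
    return settled


@dataclass
class ShortestPathSet:
    """One minimum-cost path per ordered reachable node pair."""

    paths: dict[tuple[ResidueKey, ResidueKey], tuple[ResidueKey, ...]]
    costs: dict[tuple[ResidueKey, ResidueKey], float]
    n_unreachable_pairs: int

    def __len__(self) -> int:
        return len(self.paths)


def all_shortest_paths(g: nx.Graph) -> ShortestPathSet:
    """Dijkstra shortest paths between every ordered reachable node pair
    (traversal cost 1/weight), ties broken lexicographically by node order
    for determinism.  Unreachable pairs are skipped and counted."""
    nodes = sorted(g.nodes)
    order = {n: i for i, n in enumerate(nodes)}
    paths: dict[tuple[ResidueKey, ResidueKey], tuple[ResidueKey, ...]] = {}
    costs: dict[tuple[ResidueKey, ResidueKey], float] = {}
    unreachable = 0
    for source in nodes:
        settled = _lexicographic_dijkstra(g, source, order)
        for target in nodes:
            if target == source:
                continue
            if target in settled:
                cost, path = settled[target]
                paths[(source, target)] = path
                costs[(source, target)] = cost
            else:
                unreachable += 1
    return ShortestPathSet(paths=paths, costs=costs, n_unreachable_pairs=unreachable)


def path_flags(path: Sequence[ResidueKey], coords: CaCoordinates) -> tuple[int, int, int]:
    """(f1, f2, f3) indicator flags for one shortest path.

    f1: some edge spans a larger Cα distance than the start-end separation.
    f2: some interior node's step to its successor is longer than the step
        from its predecessor.
    f3: some interior node lies farther from the end node than the start
        does.
    Single-edge paths have no interior node and contribute 0 to all three.
    """
    start, end = path[0], path[-1]
    span = coords.distance(start, end)
    f1 = int(
        any(
            coords.distance(path[i], path[i + 1]) > span
            for i in range(len(path) - 1)
        )
    )
    f2 = int(
        any(
            coords.distance(path[i], path[i - 1]) < coords.distance(path[i], path[i + 1])
            for i in range(1, len(path) - 1)
        )
    )
    f3 = int(
        any(
            coords.distance(path[i], end) > span
            for i in range(1, len(path) - 1)
        )
    )
    return f1, f2, f3


def validation_metrics(
    paths: ShortestPathSet | Iterable[Sequence[ResidueKey]],
    coords: CaCoordinates,
) -> tuple[float, float, float]:
    """Mean of the (f1, f2, f3) flags over all shortest paths.

    Paths are counted over ordered pairs (f2 is direction-asymmetric).
    Returns NaN triple when there are no paths.
    """
    if isinstance(paths, ShortestPathSet):
        iterable = paths.paths.values()
    else:
        iterable = list(paths)
    flags = np.array([path_flags(p, coords) for p in iterable], dtype=float)
    if flags.size == 0:
        return (float("nan"),) * 3
    f1, f2, f3 = flags.mean(axis=0)
    return float(f1), float(f2), float(f3)


def lcc_fraction(g: nx.Graph) -> float:
    """Fraction of nodes in the largest connected component."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    return max(len(c) for c in nx.connected_components(g)) / g.number_of_nodes()


@dataclass
class PathValidationReport:
    """Per-(n, t) validation table from the 2D parameter scan."""

    table: pd.DataFrame  # columns: exponent, threshold, F1, F2, F3, lcc_fraction, edges, paths

    def row(self, exponent: float, threshold: float) -> pd.Series:
        t = self.table
        match = t[(t.exponent == exponent) & (t.threshold == threshold)]
        if match.empty:
            raise KeyError(f"no scan row for (n={exponent}, t={threshold})")
        return match.iloc[0]


def scan_parameters(
    corr: CorrelationResult,
    coords: CaCoordinates,
    n_grid: Sequence[float] = (0.0, 0.5, 1.0, 2.0),
    t_grid: Sequence[float] = tuple(range(6, 54, 2)),
    alpha: float = 0.05,
    rho_min: float = 0.5,
) -> PathValidationReport:
    """Build one network per (n, t) grid cell and record its validation
    metrics.  Default grids span both canonical configurations: the
    biophysically relevant network (n=0, t=10 Å) and the plain significant
    correlation network (n=0, t above the largest pairwise distance)."""
    if not len(n_grid) or not len(t_grid):
        raise ValueError("parameter grids must be non-empty")
    rows = []
    for n in n_grid:
        for t in t_grid:
            g = build_network(
                corr, coords, EdgeWeightParams(exponent=n, threshold=t, alpha=alpha, rho_min=rho_min)
            )
            paths = all_shortest_paths(g)
            f1, f2, f3 = validation_metrics(paths, coords)
            rows.append(
                {
                    "exponent": n,
                    "threshold": t,
                    "F1": f1,
                    "F2": f2,
                    "F3": f3,
                    "lcc_fraction": lcc_fraction(g),
                    "edges": g.number_of_edges(),
                    "paths": len(paths),
                }
            )
    return PathValidationReport(table=pd.DataFrame(rows))


@dataclass
class NetworkSelection:
    exponent: float
    threshold: float
    constraint_met: bool
    ranking: pd.DataFrame


def select_network(
    report: PathValidationReport,
    lcc_min: float = 0.9,
) -> NetworkSelection:
    """Choose (n, t) by the compromise rule: among rows whose largest
    connected component holds more than ``lcc_min`` of the nodes, minimize
    F1; ties prefer smaller exponent (lower edge-weight complexity), then
    smaller threshold.  If no row satisfies the constraint the best-effort
    row (max LCC, then min F1) is returned flagged."""
    t = report.table
    if t.empty:
        raise ValueError("empty scan report")
    eligible = t[t.lcc_fraction > lcc_min]
    constraint_met = not eligible.empty
    pool = eligible if constraint_met else t
    ranked = pool.sort_values(
        by=(["F1", "exponent", "threshold"] if constraint_met
            else ["lcc_fraction", "F1", "exponent", "threshold"]),
        ascending=([True, True, True] if constraint_met else [False, True, True, True]),
        kind="mergesort",
    )
    best = ranked.iloc[0]
    return NetworkSelection(
        exponent=float(best.exponent),
        threshold=float(best.threshold),
        constraint_met=constraint_met,
        ranking=ranked.reset_index(drop=True),
    )
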