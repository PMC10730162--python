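"""Degree-weighted metabolite graphs and cross-dataset shortest-path linkage.

A stoichiometric model is projected to a graph with metabolites as nodes and
an edge for every (substrate, product) pair of each internal reaction.  To
keep high-degree currency cofactors (ATP-like hubs) from acting as shortcuts,
each edge is weighted by the sum of the degrees of its endpoints, computed on
the merged simple graph.  Linkage between an in vitro screen compound and a
metabolome compound is scored by the mean weighted length of the five
shortest loopless paths, and a pair is reported only when that mean falls in
the shortest 5% of the source's full pathway set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import islice
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from ._util import ValidationError
from .fba import MetabolicModel

#: sentinel length for unreachable pairs; sorts after every finite length
UNREACHABLE = math.inf


@dataclass(frozen=True)
class PathParams:
    k_paths: int = 5
    quantile: float = 0.05
    use_weights: bool = True  # False switches to hop-count lengths

    def __post_init__(self) -> None:
        if self.k_paths < 1:
            raise ValidationError("k_paths must be >= 1")
        if not 0 < self.quantile <= 1:
            raise ValidationError("quantile must be in (0, 1]")


@dataclass
class PathResult:
    source: str
    target: str
    mean_length: float  # mean of up to k_paths shortest path weights
    n_paths_found: int
    degenerate: bool = False  # source == target


def model_to_graph(model: MetabolicModel, directed: bool = False) -> nx.Graph:
    """Project a validated model onto a (by default undirected) metabolite graph.

    Exchange and biomass reactions contribute no edges.  Every substrate x
    product pair of an internal reaction becomes an edge; parallel reactions
    merge into one edge carrying the full reaction provenance list.  Edge
    weights (degree(u) + degree(v) on the unweighted merged graph) are
    computed after full construction and must be recomputed after any edit.
    """
    model.validate()
    graph: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    graph.add_nodes_from(model.metabolites)
    boundary = set(model.exchanges.values()) | {model.biomass}
    n_internal = 0
    for rxn in model.reactions:
        if rxn.id in boundary or len(rxn.stoich) < 2:
            continue
        n_internal += 1
        substrates = [m for m, c in rxn.stoich.items() if c < 0]
        products = [m for m, c in rxn.stoich.items() if c > 0]
        pairs = [(s, p) for s in substrates for p in products if s != p]
        if directed and rxn.reversible:
            pairs += [(p, s) for s, p in pairs]
        for u, v in pairs:
            if graph.has_edge(u, v):
                graph[u][v]["reactions"].append(rxn.id)
            else:
                graph.add_edge(u, v, reactions=[rxn.id])
    if n_internal == 0:
        import warnings

        warnings.warn("model has no internal reactions: empty graph")
    recompute_weights(graph)
    return graph


def recompute_weights(graph: nx.Graph) -> None:
    """Set every edge weight to degree(u) + degree(v) on the current graph."""
    degree = graph.degree()
    for u, v in graph.edges():
        graph[u][v]["weight"] = degree[u] + degree[v]


def path_length(graph: nx.Graph, path: Sequence[str], use_weights: bool = True) -> float:
    if use_weights:
        return float(sum(graph[u][v]["weight"] for u, v in zip(path, path[1:])))
    return float(len(path) - 1)


def k_shortest_mean(
    graph: nx.Graph, source: str, target: str, params: PathParams = PathParams()
) -> PathResult:
    """Mean length of up to ``k_paths`` shortest loopless paths (Yen/Dijkstra).

    No path yields ``n_paths_found = 0`` with an infinite sentinel; a
    degenerate query (source == target) reports length 0, flagged.
    """
    for node in (source, target):
        if node not in graph:
            raise ValidationError(f"node {node!r} not in graph")
    if source == target:
        return PathResult(source, target, 0.0, 0, degenerate=True)
    weight = "weight" if params.use_weights else None
    try:
        paths = list(islice(nx.shortest_simple_paths(graph, source, target, weight=weight), params.k_paths))
    except nx.NetworkXNoPath:
        return PathResult(source, target, UNREACHABLE, 0)
    lengths = [path_length(graph, p, params.use_weights) for p in paths]
    return PathResult(source, target, float(sum(lengths) / len(lengths)), len(lengths))


def pathway_set(
    graph: nx.Graph, source: str, params: PathParams = PathParams()
) -> dict[str, PathResult]:
    """Shortest-path results from ``source`` to every other node (sentinel for
    unreachable nodes)."""
    if source not in graph:
        raise ValidationError(f"source {source!r} not in graph")
    return {
        node: k_shortest_mean(graph, source, node, params)
        for node in graph.nodes
        if node != source
    }


def nearest_rank_threshold(lengths: Sequence[float], quantile: float) -> float:
    """ceil(q*n)-th order statistic of the finite lengths (nearest rank)."""
    finite = sorted(x for x in lengths if math.isfinite(x))
    if not finite:
        return -math.inf
    rank = max(1, math.ceil(quantile * len(finite)))
    return finite[rank - 1]


def select_cross_pairs(
    pathway_sets: Mapping[str, Mapping[str, PathResult]],
    screen_compounds: Iterable[str],
    metabolome_compounds: Iterable[str],
    params: PathParams = PathParams(),
) -> tuple[pd.DataFrame, list[str]]:
    """Rank (screen compound, metabolome compound) pairs by mean path length.

    For each source the cutoff is the nearest-rank ``quantile`` of the finite
    mean lengths in its full pathway set; only metabolome targets at or below
    the cutoff are kept (ties at the threshold admitted, unreachable targets
    never pass).  Compounds with no pathway set are skipped and reported.
    """
    metabolome = set(metabolome_compounds)
    skipped: list[str] = []
    rows = []
    for source in screen_compounds:
        pset = pathway_sets.get(source)
        if pset is None:
            skipped.append(source)
            continue
        threshold = nearest_rank_threshold(
            [r.mean_length for r in pset.values()], params.quantile
        )
        for target, result in pset.items():
            if target not in metabolome:
                continue
            if math.isfinite(result.mean_length) and result.mean_length <= threshold:
                rows.append((source, target, result.mean_length, result.n_paths_found))
    pairs = pd.DataFrame(
        rows, columns=["source", "target", "mean_length", "n_paths_found"]
    ).sort_values(["mean_length", "source", "target"], kind="mergesort").reset_index(drop=True)
    return pairs, skipped
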