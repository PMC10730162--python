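"""Independent oracles used by the test suite.

Kept deliberately separate from the implementation paths they check:
exhaustive simple-path enumeration (vs Yen/Dijkstra k-shortest means) and a
cobrapy/GLPK formulation of the producibility LP (vs the scipy/HiGHS one).
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np


def enumerate_k_shortest_mean(graph: nx.Graph, source, target, k: int) -> tuple[int, float]:
    """Mean of the k smallest simple-path weights by brute-force enumeration."""
    lengths = sorted(
        sum(graph[u][v]["weight"] for u, v in zip(path, path[1:]))
        for path in nx.all_simple_paths(graph, source, target)
    )
    if not lengths:
        return 0, math.inf
    chosen = lengths[:k]
    return len(chosen), sum(chosen) / len(chosen)


def random_connected_graph(seed: int, max_nodes: int = 8) -> nx.Graph:
    """Seeded random connected graph with positive integer edge weights."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_nodes + 1))
    while True:
        graph = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 31)))
        if graph.number_of_edges() > 0 and nx.is_connected(graph):
            break
    for u, v in graph.edges():
        graph[u][v]["weight"] = float(rng.integers(1, 10))
    return graph


def cobra_max_growth(model, cfg=None, scenario=None, source=None) -> float:
    """Maximal biomass flux via an independently assembled cobrapy model."""
    cm = _to_cobra(model, cfg, scenario, source)
    value = cm.slim_optimize(error_value=float("nan"))
    return value


def cobra_producible(model, cfg, source: str, scenario: str, targets) -> dict[str, bool]:
    """Producibility calls per target via cobrapy/GLPK (independent LP route)."""
    cm = _to_cobra(model, cfg, scenario, source)
    mu = cm.slim_optimize(error_value=float("nan"))
    calls = {}
    for target in targets:
        with cm as probe:
            if not math.isnan(mu) and mu > 1e-9:
                probe.reactions.get_by_id(model.biomass).lower_bound = (
                    cfg.growth_fraction * mu
                )
            if target in model.exchanges:
                rxn_id = model.exchanges[target]
            else:
                from cobra import Reaction as CobraReaction

                demand = CobraReaction(f"DM_{target}_oracle")
                demand.lower_bound, demand.upper_bound = 0.0, 1e6
                demand.add_metabolites({probe.metabolites.get_by_id(target): -1})
                probe.add_reactions([demand])
                rxn_id = demand.id
            probe.objective = rxn_id
            flux = probe.slim_optimize(error_value=0.0)
            if math.isnan(mu):
                flux = 0.0
            calls[target] = flux > cfg.producibility_epsilon
    return calls


def _to_cobra(model, cfg=None, scenario=None, source=None):
    from cobra import Metabolite, Model, Reaction as CobraReaction

    cm = Model("oracle")
    mets = {m: Metabolite(m) for m in model.metabolites}
    for r in model.reactions:
        rxn = CobraReaction(r.id)
        rxn.lower_bound, rxn.upper_bound = r.lb, r.ub
        rxn.add_metabolites({mets[m]: c for m, c in r.stoich.items()})
        cm.add_reactions([rxn])
    if cfg is not None:
        for rxn_id in model.exchanges.values():
            cm.reactions.get_by_id(rxn_id).lower_bound = 0.0
        medium = dict(cfg.medium)
        if cfg.remove_glucose:
            medium.pop(cfg.glucose_id, None)
        for met, rate in medium.items():
            if met in model.exchanges:
                cm.reactions.get_by_id(model.exchanges[met]).lower_bound = -rate
        if cfg.oxygen_id in model.exchanges:
            cm.reactions.get_by_id(
                model.exchanges[cfg.oxygen_id]
            ).lower_bound = -cfg.oxygen_levels[scenario]
        if source is not None:
            if source in model.exchanges:
                cm.reactions.get_by_id(model.exchanges[source]).lower_bound = (
                    -cfg.source_uptake
                )
            else:
                ex = CobraReaction(f"EX_{source}_oracle")
                ex.lower_bound, ex.upper_bound = -cfg.source_uptake, 1e6
                ex.add_metabolites({mets[source]: -1})
                cm.add_reactions([ex])
    cm.objective = model.biomass
    return cm
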