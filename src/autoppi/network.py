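"""Interaction network construction, hub ranking, and dense modules.

Module extraction follows the molecular-complex-detection (MCODE)
scheme: every vertex is weighted by the densest core of its closed
neighborhood (weight = k of the highest k-core times that core's
density), modules grow breadth-first from the highest-weight unassigned
seed over vertices whose weight stays within ``1 - node_score_cutoff``
of the seed's, and a "haircut" strips loosely attached degree-1 chains.

One deliberate refinement: before scoring, cut (bridge) edges are
removed from a candidate module and each remaining component's 2-core
becomes a module of its own.  A cut edge lies on no cycle, so it cannot
be part of a densely interconnected complex; without this step two
dense complexes touching through a single spurious edge would be fused
into one diluted module.  Modules are scored density x size and ranked
descending (ties: larger first, then lexicographic seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .pairs import Pair, canonical_pair

log = logging.getLogger("autoppi")

NODE_SCORE_CUTOFF = 0.2
K_CORE = 2


def build_graph(pairs) -> nx.Graph:
    """Simple undirected graph over canonical pairs (nodes only from edges)."""
    g = nx.Graph()
    n_in = 0
    for a, b in pairs:
        g.add_edge(*canonical_pair(a, b))
        n_in += 1
    if g.number_of_edges() == 0:
        raise ValueError("cannot build a network from an empty pair set")
    log.info("build_graph: %d input pairs -> %d nodes, %d edges",
             n_in, g.number_of_nodes(), g.number_of_edges())
    return g


def degree_ranking(graph: nx.Graph) -> list[tuple[str, int]]:
    """(protein, degree) in descending degree order; ties lexicographic."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    return sorted(graph.degree(), key=lambda kv: (-kv[1], kv[0]))


def k_core(graph: nx.Graph, k: int) -> nx.Graph:
    """Maximal subgraph with all degrees >= k (may be empty)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return nx.k_core(graph, k)


def density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def vertex_weights(graph: nx.Graph) -> dict[str, float]:
    """MCODE vertex weight: k_max of the closed neighborhood's densest core
    times that core's density."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    weights: dict[str, float] = {}
    for v in graph.nodes():
        closed = graph.subgraph([v, *graph.neighbors(v)])
        core_num = nx.core_number(closed)
        k_max = max(core_num.values())
        if k_max == 0:
            weights[v] = 0.0
            continue
        top = closed.subgraph([u for u, c in core_num.items() if c >= k_max])
        weights[v] = k_max * density(top)
    return weights


@dataclass
class Module:
    nodes: frozenset[str]
    seed: str
    score: float
    rank: int = 0

    @property
    def size(self) -> int:
        return len(self.nodes)


def _haircut(graph: nx.Graph) -> nx.Graph:
    """Iteratively remove degree-1 (and isolated) vertices: the 2-core."""
    return nx.k_core(graph, 2)


def find_modules(graph: nx.Graph, node_score_cutoff: float = NODE_SCORE_CUTOFF,
                 k_core_k: int = K_CORE) -> list[Module]:
    """Extract ranked dense modules (see module docstring for the scheme)."""
    if not (0.0 <= node_score_cutoff <= 1.0):
        raise ValueError(f"node_score_cutoff must be in [0, 1], got {node_score_cutoff}")
    weights = vertex_weights(graph)
    unassigned = set(graph.nodes())
    modules: list[Module] = []
    # deterministic seed order: weight desc, then lexicographic
    for seed in sorted(graph.nodes(), key=lambda v: (-weights[v], v)):
        if seed not in unassigned:
            continue
        floor = (1.0 - node_score_cutoff) * weights[seed]
        members = {seed}
        frontier = [seed]
        while frontier:
            nxt = []
            for v in frontier:
                for u in graph.neighbors(v):
                    if u in unassigned and u not in members and weights[u] >= floor:
                        members.add(u)
                        nxt.append(u)
            frontier = nxt
        unassigned -= members
        candidate = _haircut(graph.subgraph(members))
        if candidate.number_of_nodes() == 0:
            continue
        # split at cut edges: a bridge cannot belong to a dense complex
        pruned = nx.Graph(candidate)
        pruned.remove_edges_from(list(nx.bridges(pruned)))
        for comp in nx.connected_components(pruned):
            final = nx.k_core(pruned.subgraph(comp), k_core_k)
            if final.number_of_nodes() == 0:
                continue
            comp_seed = max(final.nodes(), key=lambda v: (weights[v], v))
            modules.append(Module(nodes=frozenset(final.nodes()),
                                  seed=comp_seed,
                                  score=density(final) * final.number_of_nodes()))
    modules.sort(key=lambda m: (-m.score, -m.size, m.seed))
    for rank, m in enumerate(modules, start=1):
        m.rank = rank
    log.info("find_modules: %d modules (cutoff=%.2f, k=%d)",
             len(modules), node_score_cutoff, k_core_k)
    return modules


def module_table(modules: list[Module]) -> list[dict]:
    return [{"rank": m.rank, "size": m.size, "score": round(m.score, 6),
             "seed": m.seed, "nodes": sorted(m.nodes)} for m in modules]
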