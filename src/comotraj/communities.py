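"""Overlapping community detection by local fitness maximization (LFM).

A community G has fitness  f_G = k_in / (k_in + k_out)^a  where k_in is
the total internal weighted degree of its members (each internal edge
counts for both endpoints) and k_out the total weight of edges leaving the
community; a is the resolution parameter, a = 1 by default.

Growth of a *natural community* from a seed: repeatedly add the neighbor
with the largest positive fitness gain, then sweep the members removing
any whose removal raises the fitness (repeating the sweep until stable);
the community is closed when no addition or removal improves f_G.  Seeding
from every node and deleting duplicate member sets yields the overlapping
cover; ties are broken lexicographically by node id, so the outcome is
deterministic regardless of any RNG seed.

The two link types of the multilayer network are merged into one weighted
undirected graph for detection (the fitness function does not distinguish
them); directed weights are symmetrized by summation by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx

__all__ = [
    "DetectionConfig", "CommunityState", "build_adjacency",
    "node_fitness_gain", "grow_natural_community", "detect_all",
    "communities_to_jsonl",
]

_EPS = 1e-12


@dataclass(frozen=True)
class DetectionConfig:
    a: float = 1.0
    seed_order: str = "lexicographic"  # or "random"
    rng_seed: int = 0
    merge_duplicates: bool = True
    treat_as_undirected: bool = True
    combine: str = "sum"  # directed-weight symmetrization: sum | max | mean

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("resolution parameter a must be positive")
        if self.combine not in ("sum", "max", "mean"):
            raise ValueError(f"unknown combine rule {self.combine!r}")


class CommunityState:
    """A community with cached internal/external weighted degrees."""

    __slots__ = ("members", "k_in", "k_out", "a")

    def __init__(self, members, k_in, k_out, a=1.0):
        self.members = frozenset(members)
        self.k_in = k_in
        self.k_out = k_out
        self.a = a

    @property
    def fitness(self) -> float:
        return fitness(self.k_in, self.k_out, self.a)

    @classmethod
    def from_members(cls, members, adj, a=1.0):
        """Exact recomputation from scratch (the audit path)."""
        members = frozenset(members)
        k_in = k_out = 0.0
        for u in members:
            for v, w in adj.get(u, {}).items():
                if v in members:
                    k_in += w  # counts each internal edge from both ends
                else:
                    k_out += w
        return cls(members, k_in, k_out, a)

    def __repr__(self):
        return (f"CommunityState(n={len(self.members)}, k_in={self.k_in:.3g}, "
                f"k_out={self.k_out:.3g}, fitness={self.fitness:.4f})")


def fitness(k_in: float, k_out: float, a: float = 1.0) -> float:
    """f = k_in / (k_in + k_out)^a; a singleton with k_in = 0 has f = 0."""
    if k_in <= 0:
        return 0.0
    return k_in / (k_in + k_out) ** a


def build_adjacency(net, combine="sum"):
    """Weighted undirected adjacency dict from a multilayer network, a
    networkx graph, or an existing adjacency dict.

    Directed edge pairs are symmetrized with the given rule; normalized
    weights are used when present.
    """
    if isinstance(net, dict):
        return net
    inner = getattr(net, "graph", None)
    graph = inner if isinstance(inner, nx.Graph) else net
    directed = graph.is_directed()
    adj: dict = {n: {} for n in graph.nodes}
    seen_both: dict = {}
    for u, v, d in graph.edges(data=True):
        if u == v:
            continue
        w = d.get("norm_weight")
        if w is None:
            w = d.get("weight", d.get("raw_weight", 1.0))
        w = float(w)
        key = (u, v) if u <= v else (v, u)
        if directed and combine != "sum":
            seen_both.setdefault(key, []).append(w)
            continue
        adj[u][v] = adj[u].get(v, 0.0) + w
        adj[v][u] = adj[v].get(u, 0.0) + w
    for (u, v), ws in seen_both.items():
        w = max(ws) if combine == "max" else sum(ws) / len(ws)
        adj[u][v] = w
        adj[v][u] = w
    return adj


def _degree(adj, node):
    return sum(adj.get(node, {}).values())


def _w_to_set(adj, node, members):
    return sum(w for v, w in adj.get(node, {}).items() if v in members)


def node_fitness_gain(state: CommunityState, node, adj) -> float:
    """Signed fitness gain: f(G ∪ {v}) − f(G) for an outsider,
    f(G) − f(G \\ {v}) for a member (positive = the node helps)."""
    a = state.a
    if node in state.members:
        w_in = _w_to_set(adj, node, state.members - {node})
        deg = _degree(adj, node)
        k_in = state.k_in - 2 * w_in
        k_out = state.k_out - (deg - w_in) + w_in
        return state.fitness - fitness(k_in, k_out, a)
    w_in = _w_to_set(adj, node, state.members)
    deg = _degree(adj, node)
    k_in = state.k_in + 2 * w_in
    k_out = state.k_out - w_in + (deg - w_in)
    return fitness(k_in, k_out, a) - state.fitness


def _add(state, node, adj):
    w_in = _w_to_set(adj, node, state.members)
    deg = _degree(adj, node)
    return CommunityState(
        state.members | {node},
        state.k_in + 2 * w_in,
        state.k_out - w_in + (deg - w_in),
        state.a,
    )


def _remove(state, node, adj):
    w_in = _w_to_set(adj, node, state.members - {node})
    deg = _degree(adj, node)
    return CommunityState(
        state.members - {node},
        state.k_in - 2 * w_in,
        state.k_out - (deg - w_in) + w_in,
        state.a,
    )


def grow_natural_community(seed, net, cfg: DetectionConfig = DetectionConfig(),
                           protect_seed=False) -> CommunityState:
    """Grow the natural community of ``seed`` until fitness is locally
    maximal under single additions and removals.

    The seed itself may be swept out unless ``protect_seed`` is set; the
    closed community is returned regardless.
    """
    adj = build_adjacency(net, cfg.combine)
    if seed not in adj:
        raise KeyError(f"seed {seed!r} not in network")
    state = CommunityState({seed}, 0.0, _degree(adj, seed), cfg.a)
    max_steps = 4 * len(adj) + 8
    for _ in range(max_steps):
        # best single addition among the frontier
        frontier = sorted(
            {v for u in state.members for v in adj.get(u, {})} - state.members
        )
        best, best_gain = None, _EPS
        for v in frontier:
            gain = node_fitness_gain(state, v, adj)
            if gain > best_gain:
                best, best_gain = v, gain
        if best is None:
            break
        state = _add(state, best, adj)
        # removal sweep to a fixed point
        changed = True
        while changed and len(state.members) > 1:
            changed = False
            for v in sorted(state.members):
                if protect_seed and v == seed:
                    continue
                if node_fitness_gain(state, v, adj) < -_EPS:
                    state = _remove(state, v, adj)
                    changed = True
    return state


def detect_all(net, cfg: DetectionConfig = DetectionConfig()):
    """Natural community of every node, deduplicated.

    Every node ends up in at least one returned community: nodes whose
    own growth swept them out and that no other community covers get a
    second, seed-protected pass.
    """
    adj = build_adjacency(net, cfg.combine)
    seeds = sorted(adj)
    if cfg.seed_order == "random":
        import random

        random.Random(cfg.rng_seed).shuffle(seeds)
    found: list[CommunityState] = []
    seen: set = set()
    for seed in seeds:
        com = grow_natural_community(seed, adj, cfg)
        if not com.members:
            com = CommunityState({seed}, 0.0, _degree(adj, seed), cfg.a)
        if not cfg.merge_duplicates or com.members not in seen:
            seen.add(com.members)
            found.append(com)
    covered = set().union(*(c.members for c in found)) if found else set()
    for seed in seeds:
        if seed in covered:
            continue
        com = grow_natural_community(seed, adj, cfg, protect_seed=True)
        covered |= com.members
        if not cfg.merge_duplicates or com.members not in seen:
            seen.add(com.members)
            found.append(com)
    return found


def communities_to_jsonl(communities, path):
    with open(path, "w") as fh:
        for k, com in enumerate(communities):
            fh.write(json.dumps({
                "community_id": k,
                "members": sorted(
                    [list(m) if isinstance(m, tuple) else m
                     for m in com.members]
                ),
                "k_in": com.k_in,
                "k_out": com.k_out,
                "fitness": com.fitness,
            }) + "\n")
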