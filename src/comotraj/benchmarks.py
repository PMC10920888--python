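"""Small planted-partition benchmarks for the community detector.

These generators build weighted graphs with known community structure —
disjoint cliques, and overlapping planted communities with a tunable
mixing parameter (the fraction of a node's degree pointing outside its
community, in the spirit of LFR benchmarks but small enough to run in a
test-suite) — plus the matching recovery score.
"""

from __future__ import annotations

import numpy as np
import networkx as nx


def disjoint_cliques(sizes=(4, 5, 6)):
    """Disjoint unit-weight cliques; returns (graph, planted_sets)."""
    g = nx.Graph()
    planted, start = [], 0
    for s in sizes:
        nodes = [f"n{start + k:03d}" for k in range(s)]
        g.add_nodes_from(nodes)
        for i in range(s):
            for j in range(i + 1, s):
                g.add_edge(nodes[i], nodes[j], weight=1.0)
        planted.append(frozenset(nodes))
        start += s
    return g, planted


def overlapping_benchmark(n_communities=4, size=10, n_overlap=1, mixing=0.2,
                          p_in=0.95, seed=0):
    """Planted overlapping communities with approximate mixing ``mixing``.

    Consecutive communities share ``n_overlap`` nodes.  Internal edges
    are drawn with probability ``p_in``; external edges are added at
    random until the expected mixing (external / total degree) is
    reached.
    """
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    planted = []
    next_id = 0
    prev_tail: list = []
    for c in range(n_communities):
        fresh = [f"n{next_id + k:03d}" for k in range(size - len(prev_tail))]
        next_id += len(fresh)
        members = list(prev_tail) + fresh
        planted.append(frozenset(members))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < p_in:
                    g.add_edge(members[i], members[j], weight=1.0)
        prev_tail = members[-n_overlap:] if n_overlap else []
    nodes = sorted(g.nodes)
    internal = g.number_of_edges()
    n_external = int(round(internal * mixing / max(1e-9, 1 - mixing)))
    community_of = {}
    for k, com in enumerate(planted):
        for n in com:
            community_of.setdefault(n, set()).add(k)
    added = 0
    for _ in range(50 * n_external + 100):
        if added >= n_external:
            break
        u, v = rng.choice(len(nodes), 2, replace=False)
        u, v = nodes[u], nodes[v]
        if community_of[u] & community_of[v] or g.has_edge(u, v):
            continue
        g.add_edge(u, v, weight=1.0)
        added += 1
    return g, planted


def best_match_jaccard(detected, planted):
    """Mean over planted communities of the best Jaccard match among the
    detected ones (the standard planted-recovery score)."""
    scores = []
    for truth in planted:
        best = 0.0
        for com in detected:
            members = frozenset(getattr(com, "members", com))
            j = len(truth & members) / len(truth | members)
            best = max(best, j)
        scores.append(best)
    return float(np.mean(scores)) if scores else 0.0
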