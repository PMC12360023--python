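"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results from first principles (exhaustive
bijection search, subset enumeration) and never call the code paths
they check.
"""

from __future__ import annotations

from itertools import combinations, permutations

import networkx as nx
import numpy as np

from ccinfer.chemgraph import ChemicalGraph


def rooted_isomorphic_bruteforce(t1: ChemicalGraph, r1, t2: ChemicalGraph, r2) -> bool:
    """Exhaustive bijection search for rooted isomorphism (n <= 8)."""
    v1, v2 = t1.atoms(), t2.atoms()
    if len(v1) != len(v2):
        return False
    others1 = [v for v in v1 if v != r1]
    others2 = [v for v in v2 if v != r2]
    e1 = {frozenset(e): t1.order(*e) for e in t1.bonds()}
    for perm in permutations(others2):
        phi = dict(zip(others1, perm))
        phi[r1] = r2
        if any(t1.element(v) != t2.element(phi[v]) for v in v1):
            continue
        ok = True
        for edge, m in e1.items():
            a, b = tuple(edge)
            if not t2.graph.has_edge(phi[a], phi[b]) or t2.order(phi[a], phi[b]) != m:
                ok = False
                break
        if ok:
            return True
    return False


def chordless_cycles_bruteforce(graph: ChemicalGraph, c_min: int, c_max: int) -> set:
    """All induced-cycle vertex sets of size c_min..c_max, by subset scan."""
    g = graph.graph
    out = set()
    nodes = list(g.nodes)
    for size in range(c_min, c_max + 1):
        for subset in combinations(nodes, size):
            sub = g.subgraph(subset)
            if sub.number_of_edges() == size and all(d == 2 for _, d in sub.degree):
                if nx.is_connected(sub):
                    out.add(frozenset(subset))
    return out


def canonical_cc_bruteforce(masses) -> tuple:
    """Lexicographic minimum over the 2*l dihedral orderings, from scratch."""
    l = len(masses)
    distinct = sorted(set(masses))
    rank = {v: i + 1 for i, v in enumerate(distinct)}
    candidates = []
    seq = [rank[m] for m in masses]
    for base in (seq, seq[::-1]):
        for s in range(l):
            candidates.append(tuple(base[s:] + base[:s]))
    return min(candidates)


def random_rooted_tree(rng: np.random.Generator, n: int,
                       elements=("C", "O", "N")) -> tuple[ChemicalGraph, int]:
    """Random labelled rooted tree with random bond orders in {1, 2}."""
    t = ChemicalGraph()
    for i in range(n):
        t.add_atom(i, str(rng.choice(elements)))
    for i in range(1, n):
        t.add_bond(i, int(rng.integers(0, i)), int(rng.integers(1, 3)))
    return t, 0


def random_graph(rng: np.random.Generator, n: int, extra_edges: int) -> ChemicalGraph:
    """Random connected labelled graph (tree plus random extra edges)."""
    g = ChemicalGraph()
    for i in range(n):
        g.add_atom(i, "C")
    for i in range(1, n):
        g.add_bond(i, int(rng.integers(0, i)), 1)
    tries = 0
    added = 0
    while added < extra_edges and tries < 20 * extra_edges + 20:
        tries += 1
        u, v = rng.integers(0, n, size=2)
        u, v = int(u), int(v)
        if u != v and not g.graph.has_edge(u, v):
            g.add_bond(u, v, 1)
            added += 1
    return g


def select_threshold_bruteforce(scores, labels) -> float:
    """Best tilde-BACC over candidate thresholds, recomputed directly."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    c1 = (labels == 1).sum()
    c0 = (labels == 0).sum()
    best = -1.0
    for r in scores:
        tp = ((labels == 1) & (scores >= r)).sum()
        tn = ((labels == 0) & (scores <= r)).sum()
        best = max(best, 0.5 * (tp / c1 + tn / c0))
    return float(best)
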