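"""Chordless-cycle enumeration and cycle-configuration (CC) descriptors.

The cycle-configuration of a chordless cycle records, up to rotation and
reflection, the order in which fringe-tree masses appear around the
cycle.  Masses are reduced to 1-based ranks among the distinct values on
the cycle, and the rank sequence is canonicalised to the lexicographic
minimum over all 2*l rotations/reflected rotations.  This is exactly the
information the plain 2L descriptor family discards, and it is what
separates meta from para substitution patterns on an aromatic ring.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .chemgraph import ChemGraphError, ChemicalGraph, Vertex
from .elements import ElementTable, default_element_table
from .twolayer import TwoLayerDecomposition


@dataclass(frozen=True)
class CCParams:
    """Allowed chordless-cycle lengths for CC descriptors (defaults 4..6)."""

    c_min: int = 4
    c_max: int = 6

    def __post_init__(self) -> None:
        if self.c_min < 3:
            raise ValueError("c_min must be >= 3")
        if self.c_max < self.c_min:
            raise ValueError("c_max must be >= c_min")


def rank_in_set(values: Sequence[float]) -> list[int]:
    """1-based rank of each entry among the distinct values, ascending.

    Equal values share a rank: rank(a) = i iff a is the i-th smallest of
    the distinct values.  E.g. (14, 14, 28, 29) -> (1, 1, 2, 3).
    """
    if len(values) == 0:
        raise ValueError("values must be non-empty")
    distinct = sorted(set(values))
    pos = {v: i + 1 for i, v in enumerate(distinct)}
    return [pos[v] for v in values]


def canonical_cycle_config(masses: Sequence[float]) -> tuple[int, ...]:
    """Canonical CC of a cyclically ordered mass sequence.

    The rank sequence is minimised lexicographically over all l rotations
    and the l rotations of the reversed sequence (an explicit scan of the
    2*l candidates, matching the definition verbatim; cycles are short).
    """
    l = len(masses)
    if l < 3:
        raise ValueError("a cycle has at least 3 vertices")
    ranks = rank_in_set(masses)
    best: tuple[int, ...] | None = None
    for seq in (ranks, ranks[::-1]):
        for s in range(l):
            cand = tuple(seq[s:] + seq[:s])
            if best is None or cand < best:
                best = cand
    assert best is not None
    return best


def cc_key(xi: Sequence[int]) -> tuple[int, tuple[int, ...]]:
    """Deterministic sort key for CC vocabularies: (length, sequence)."""
    return (len(xi), tuple(xi))


def is_canonical_cc(xi: Sequence[int]) -> bool:
    """Check the two CC invariants: ranks cover {1..k}; sequence is minimal."""
    xi = tuple(xi)
    vals = set(xi)
    if vals != set(range(1, len(vals) + 1)):
        return False
    return canonical_cycle_config(xi) == xi


def enumerate_chordless_cycles(graph: ChemicalGraph,
                               params: CCParams = CCParams()) -> list[tuple]:
    """All chordless cycles with length in [c_min, c_max], each once.

    Cycles are returned as vertex tuples starting at their smallest
    vertex (by sort order of the ids' repr), with the rotation/reflection
    ambiguity fixed by requiring the second vertex to sort below the
    last.  Enumeration is a bounded-depth DFS over induced paths from
    each start vertex, with chordality enforced by construction.
    """
    g = graph.graph
    order = {v: i for i, v in enumerate(sorted(g.nodes, key=repr))}
    adj = {v: set(g.neighbors(v)) for v in g.nodes}
    cycles: list[tuple] = []

    def dfs(path: list, on_path: set) -> None:
        # `path` is an induced path from s = path[0]; every vertex sorts
        # above s, and no non-consecutive pair is adjacent (in particular
        # only path[1] touches s).
        last = path[-1]
        s = path[0]
        for w in sorted(adj[last], key=lambda x: order[x]):
            if order[w] <= order[s] or w in on_path:
                continue
            if any(p in adj[w] for p in path[1:-1]):
                continue  # chord
            if s in adj[w]:
                # w can only ever be a closing vertex: record, never extend
                if params.c_min <= len(path) + 1 <= params.c_max \
                        and order[path[1]] < order[w]:
                    cycles.append(tuple(path) + (w,))
                continue
            if len(path) + 1 < params.c_max:  # room for w plus a closer
                path.append(w)
                on_path.add(w)
                dfs(path, on_path)
                path.pop()
                on_path.remove(w)

    for s in sorted(g.nodes, key=lambda x: order[x]):
        for a in sorted(adj[s], key=lambda x: order[x]):
            if order[a] > order[s]:
                dfs([s, a], {s, a})
    return cycles


def cycle_config_of(cycle: Sequence[Vertex], decomp: TwoLayerDecomposition,
                    table: ElementTable | None = None) -> tuple[int, ...]:
    """Canonical CC of an enumerated chordless cycle via fringe-tree masses.

    Every cycle vertex must be interior (its fringe-tree mass mu_i is
    undefined otherwise).
    """
    table = table or default_element_table()
    masses = []
    for u in cycle:
        if u not in decomp.interior_vertices:
            raise ChemGraphError(
                f"cycle vertex {u!r} is not interior; its fringe mass is undefined"
            )
        masses.append(decomp.fringe[u].mass(table))
    return canonical_cycle_config(masses)


def f_cc(graph: ChemicalGraph, decomp: TwoLayerDecomposition,
         vocabulary: Sequence[Sequence[int]],
         params: CCParams = CCParams(),
         table: ElementTable | None = None) -> list[int]:
    """CC feature vector of one molecule over an ordered CC vocabulary.

    Entry i counts the chordless cycles whose canonical CC equals the
    i-th vocabulary entry; cycles whose CC is outside the vocabulary are
    ignored (they are surfaced by the featurize module).
    """
    table = table or default_element_table()
    sup = decomp.suppressed
    index = {tuple(xi): i for i, xi in enumerate(vocabulary)}
    vec = [0] * len(vocabulary)
    for cycle in enumerate_chordless_cycles(sup, params):
        xi = cycle_config_of(cycle, decomp, table)
        if xi in index:
            vec[index[xi]] += 1
    return vec


def detect_unsupported(graph: ChemicalGraph) -> dict[str, bool]:
    """Flags for ring systems that ring-node expansion cannot produce.

    (i)  two chordless cycles sharing exactly one vertex (spiro);
    (ii) more than two chordless cycles sharing a common vertex or edge.
    All chordless cycles of the graph are considered, regardless of the
    descriptor length window.
    """
    sup = graph
    n = sup.n_atoms()
    if n < 3:
        return {"spiro_pair": False, "multi_shared": False}
    all_cycles = enumerate_chordless_cycles(sup, CCParams(c_min=3, c_max=n))
    spiro = False
    for c1, c2 in combinations(all_cycles, 2):
        shared = set(c1) & set(c2)
        if len(shared) == 1:
            spiro = True
            break
    multi = False
    vertex_count: Counter = Counter()
    edge_count: Counter = Counter()
    for c in all_cycles:
        vertex_count.update(set(c))
        l = len(c)
        edge_count.update(frozenset((c[i], c[(i + 1) % l])) for i in range(l))
    if any(k > 2 for k in vertex_count.values()) or any(k > 2 for k in edge_count.values()):
        multi = True
    return {"spiro_pair": spiro, "multi_shared": multi}
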