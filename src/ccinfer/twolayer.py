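"""Interior/exterior decomposition and the two-layered descriptor family.

The hydrogen-suppressed graph of a molecule is split by a branch
parameter ``rho`` (standard value 2) into an *interior* (vertices that
survive ``rho`` rounds of leaf deletion, plus the 2-core) and an
*exterior* (everything else).  Exterior edges form trees hanging off
interior vertices; restoring the original hydrogens to such a tree gives
the *fringe tree* of its interior root.

2L descriptors are counts of local patterns: fringe-configurations
(rooted-isomorphism classes of fringe trees, per interior vertex),
adjacency-configurations ``(a, b, m)`` and edge-configurations
``(a d, b d', m)`` per interior edge, plus a small catalogue of static
descriptors (atom counts, degree counts, bond-multiplicity counts, ...).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .chemgraph import (
    ChemGraphError,
    ChemicalGraph,
    FringeTree,
    Vertex,
    hydrogen_suppress,
    mass_of,
)
from .elements import ElementTable, default_element_table

Edge = frozenset


def heights_by_leaf_deletion(graph: ChemicalGraph) -> dict[Vertex, int]:
    """Heights ht(v) under iterated leaf deletion.

    ``ht(v) = i`` iff v has degree 1 in the graph obtained after deleting
    the leaf set i times.  Vertices that never become leaves (the 2-core,
    or a final isolated vertex) receive no height.
    """
    g = graph.graph.copy()
    heights: dict[Vertex, int] = {}
    i = 0
    while True:
        leaves = [v for v in g.nodes if g.degree[v] == 1]
        if not leaves:
            break
        for v in leaves:
            heights[v] = i
        g.remove_nodes_from(leaves)
        i += 1
    return heights


def orient_ac(a: str, b: str, m: int, table: ElementTable) -> tuple[str, str, int]:
    """Canonically oriented adjacency-configuration (a, b, m)."""
    if table.rank(b) < table.rank(a):
        a, b = b, a
    return (a, b, m)


def orient_ec(a: str, d: int, b: str, d2: int, m: int,
              table: ElementTable) -> tuple[tuple[str, int], tuple[str, int], int]:
    """Canonically oriented edge-configuration ((a, d), (b, d')), m).

    Endpoint descriptors are ordered lexicographically by
    (element rank, degree) so that e.g. (C3, C2, m) collapses onto
    (C2, C3, m).
    """
    if (table.rank(b), d2) < (table.rank(a), d):
        a, d, b, d2 = b, d2, a, d
    return ((a, d), (b, d2), m)


@dataclass
class TwoLayerDecomposition:
    """Partition of a hydrogen-suppressed graph into interior and exterior."""

    rho: int
    suppressed: ChemicalGraph
    interior_vertices: set
    exterior_vertices: set
    interior_edges: set  # frozensets {u, v}
    exterior_edges: set
    heights: dict
    fringe: dict = field(default_factory=dict)  # interior vertex -> FringeTree

    def fringe_of(self, u: Vertex) -> FringeTree:
        return self.fringe[u]


def decompose(graph: ChemicalGraph, rho: int = 2,
              table: ElementTable | None = None) -> TwoLayerDecomposition:
    """Two-layered decomposition of a chemical graph.

    Returns the interior/exterior partition of the hydrogen-suppressed
    graph and, for every interior vertex u, the fringe tree C[u]
    (its exterior subtree with the original hydrogens put back).
    """
    if rho < 1:
        raise ValueError("branch parameter rho must be >= 1")
    table = table or default_element_table()
    sup = hydrogen_suppress(graph)
    heights = heights_by_leaf_deletion(sup)
    exterior = {v for v in sup.atoms() if heights.get(v, rho) < rho}
    interior = set(sup.atoms()) - exterior
    if not interior:
        raise ChemGraphError("2L-infeasible: interior is empty")
    ext_edges = {Edge(e) for e in sup.bonds() if e[0] in exterior or e[1] in exterior}
    int_edges = {Edge(e) for e in sup.bonds()} - ext_edges

    # grow the exterior tree of each interior vertex
    fringe: dict[Vertex, FringeTree] = {}
    claimed: dict[Vertex, Vertex] = {}
    hydrogen = set(graph.hydrogens())
    for u in sorted(interior, key=repr):
        tree_vertices = {u}
        frontier = [u]
        while frontier:
            v = frontier.pop()
            for w in sup.neighbors(v):
                if w in exterior and w not in tree_vertices:
                    if w in claimed:
                        raise ChemGraphError(
                            f"exterior vertex {w!r} reachable from two interior roots"
                        )
                    claimed[w] = u
                    tree_vertices.add(w)
                    frontier.append(w)
        with_h = set(tree_vertices)
        for v in tree_vertices:
            with_h.update(w for w in graph.neighbors(v) if w in hydrogen)
        fringe[u] = FringeTree(graph.subgraph(with_h), u)
    unclaimed = exterior - set(claimed)
    if unclaimed:
        raise ChemGraphError(f"exterior vertices not attached to the interior: {unclaimed!r}")
    return TwoLayerDecomposition(
        rho=rho,
        suppressed=sup,
        interior_vertices=interior,
        exterior_vertices=exterior,
        interior_edges=int_edges,
        exterior_edges=ext_edges,
        heights=heights,
        fringe=fringe,
    )


def edge_configuration(e, graph: ChemicalGraph, decomp: TwoLayerDecomposition,
                       table: ElementTable | None = None):
    """Edge-configuration (a d, b d', m) of an interior edge.

    Degrees are taken in the hydrogen-suppressed graph; the tuple is
    returned in canonical orientation.
    """
    table = table or default_element_table()
    u, v = tuple(e)
    if Edge((u, v)) not in decomp.interior_edges:
        raise ChemGraphError(f"edge {e!r} is not an interior edge")
    sup = decomp.suppressed
    return orient_ec(sup.element(u), sup.degree(u), sup.element(v), sup.degree(v),
                     sup.order(u, v), table)


def adjacency_configuration(e, graph: ChemicalGraph, decomp: TwoLayerDecomposition,
                            table: ElementTable | None = None):
    """Adjacency-configuration (a, b, m) of an interior edge."""
    table = table or default_element_table()
    u, v = tuple(e)
    if Edge((u, v)) not in decomp.interior_edges:
        raise ChemGraphError(f"edge {e!r} is not an interior edge")
    sup = decomp.suppressed
    return orient_ac(sup.element(u), sup.element(v), sup.order(u, v), table)


def count_configs(graph: ChemicalGraph, decomp: TwoLayerDecomposition,
                  table: ElementTable | None = None) -> dict[str, Counter]:
    """All enumerative 2L pattern counts of one molecule.

    Returns counters keyed ``fringe`` (canonical fringe codes over
    interior vertices), ``ac`` / ``ec`` (tuples over interior edges) and
    ``leaf_ac`` (adjacency-configurations on heavy leaf-edges of fringe
    trees, hydrogens excluded).
    """
    table = table or default_element_table()
    fringe = Counter(ft.canonical_code for ft in decomp.fringe.values())
    ac: Counter = Counter()
    ec: Counter = Counter()
    for e in decomp.interior_edges:
        ac[adjacency_configuration(e, graph, decomp, table)] += 1
        ec[edge_configuration(e, graph, decomp, table)] += 1
    leaf_ac: Counter = Counter()
    for ft in decomp.fringe.values():
        leaf_ac.update(ft.leaf_ac_counts(table))
    return {"fringe": fringe, "ac": ac, "ec": ec, "leaf_ac": leaf_ac}


# ---------------------------------------------------------------------------
# Static descriptors
# ---------------------------------------------------------------------------

def _descriptor_value(name: str, graph: ChemicalGraph,
                      decomp: TwoLayerDecomposition, table: ElementTable) -> float:
    sup = decomp.suppressed
    if name == "n_heavy":
        return float(sup.n_atoms())
    if name == "n_interior":
        return float(len(decomp.interior_vertices))
    if name == "avg_mass":
        return mass_of(graph, table) / sup.n_atoms()
    if name.startswith("deg_int_"):
        k = int(name.rsplit("_", 1)[1])
        return float(sum(1 for v in decomp.interior_vertices if sup.degree(v) == k))
    if name.startswith("bond_int_"):
        m = int(name.rsplit("_", 1)[1])
        return float(sum(1 for e in decomp.interior_edges
                         if sup.order(*tuple(e)) == m))
    if name.startswith("na_int_"):
        code = name[len("na_int_"):]
        return float(sum(1 for v in decomp.interior_vertices if sup.element(v) == code))
    if name.startswith("na_ex_"):
        code = name[len("na_ex_"):]
        return float(sum(1 for v in decomp.exterior_vertices if sup.element(v) == code))
    raise KeyError(f"unknown static descriptor {name!r}")


def default_static_names(element_codes) -> list[str]:
    """Default static-descriptor catalogue for a given heavy-element set."""
    names = ["n_heavy", "n_interior", "avg_mass",
             "deg_int_1", "deg_int_2", "deg_int_3", "deg_int_4",
             "bond_int_2", "bond_int_3"]
    for code in element_codes:
        if code != "H":
            names.append(f"na_int_{code}")
            names.append(f"na_ex_{code}")
    return names


def static_descriptors(graph: ChemicalGraph, decomp: TwoLayerDecomposition,
                       names: list[str], table: ElementTable | None = None) -> list[float]:
    """Deterministic vector of the requested static descriptors (in order)."""
    table = table or default_element_table()
    return [_descriptor_value(n, graph, decomp, table) for n in names]
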