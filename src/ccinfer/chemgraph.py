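"""Chemical graphs, fringe trees, and rooted-tree canonical codes.

A chemical graph is a simple connected graph whose vertices carry element
codes (``alpha``) and whose edges carry bond multiplicities in [1, 3]
(``beta``).  Hydrogens are explicit vertices; the hydrogen-suppressed
graph removes them.  A fringe tree is a rooted chemical tree (the
exterior subtree hanging off an interior vertex, hydrogens restored);
its rooted-isomorphism class is identified by a canonical string code.
"""

from __future__ import annotations

from typing import Hashable, Iterable, Iterator

import networkx as nx

from .elements import ElementTable, UnknownElementError, default_element_table

BOND_CHARS = {1: "-", 2: "=", 3: "#"}
CHAR_BONDS = {c: m for m, c in BOND_CHARS.items()}

Vertex = Hashable


class ChemGraphError(ValueError):
    """Raised on structurally invalid chemical-graph operations."""


class ChemicalGraph:
    """Simple labeled graph with element codes on vertices and bond orders on edges."""

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -------------------------------------------------
    def add_atom(self, vid: Vertex, element: str) -> Vertex:
        if vid in self._g:
            raise ChemGraphError(f"duplicate vertex id {vid!r}")
        self._g.add_node(vid, element=element)
        return vid

    def add_bond(self, u: Vertex, v: Vertex, order: int = 1) -> None:
        if u == v:
            raise ChemGraphError("loops are not allowed")
        if not (u in self._g and v in self._g):
            raise ChemGraphError(f"bond endpoints must be existing atoms: {u!r}, {v!r}")
        if self._g.has_edge(u, v):
            raise ChemGraphError(f"parallel bond {u!r}-{v!r}")
        if order not in (1, 2, 3):
            raise ChemGraphError(f"bond multiplicity must be 1, 2 or 3: {order}")
        self._g.add_edge(u, v, order=int(order))

    # -- accessors ----------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        """The underlying networkx graph (element/order attributes)."""
        return self._g

    def atoms(self) -> list[Vertex]:
        return list(self._g.nodes)

    def bonds(self) -> list[tuple[Vertex, Vertex]]:
        return list(self._g.edges)

    def element(self, v: Vertex) -> str:
        return self._g.nodes[v]["element"]

    def order(self, u: Vertex, v: Vertex) -> int:
        return self._g.edges[u, v]["order"]

    def neighbors(self, v: Vertex) -> list[Vertex]:
        return list(self._g.neighbors(v))

    def degree(self, v: Vertex) -> int:
        return self._g.degree[v]

    def bond_sum(self, v: Vertex) -> int:
        """Sum of bond multiplicities incident to ``v`` (beta_C(v))."""
        return sum(self._g.edges[v, w]["order"] for w in self._g.neighbors(v))

    def n_atoms(self) -> int:
        return self._g.number_of_nodes()

    def hydrogens(self) -> list[Vertex]:
        return [v for v in self._g.nodes if self.element(v) == "H"]

    def heavy_atoms(self) -> list[Vertex]:
        return [v for v in self._g.nodes if self.element(v) != "H"]

    def is_connected(self) -> bool:
        return self._g.number_of_nodes() > 0 and nx.is_connected(self._g)

    # -- transforms ---------------------------------------------------
    def copy(self) -> "ChemicalGraph":
        out = ChemicalGraph()
        out._g = self._g.copy()
        return out

    def relabel(self, mapping: dict) -> "ChemicalGraph":
        out = ChemicalGraph()
        out._g = nx.relabel_nodes(self._g, mapping, copy=True)
        return out

    def subgraph(self, vertices: Iterable[Vertex]) -> "ChemicalGraph":
        out = ChemicalGraph()
        out._g = self._g.subgraph(vertices).copy()
        return out

    def is_isomorphic_to(self, other: "ChemicalGraph") -> bool:
        return nx.is_isomorphic(
            self._g,
            other._g,
            node_match=lambda a, b: a["element"] == b["element"],
            edge_match=lambda a, b: a["order"] == b["order"],
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<ChemicalGraph {self._g.number_of_nodes()} atoms, {self._g.number_of_edges()} bonds>"


def mass_of(graph: "ChemicalGraph | FringeTree", table: ElementTable | None = None) -> int:
    """Total nominal mass: sum of vertex masses (hydrogens included).

    Rejects unknown element codes, naming the offending code.
    """
    if isinstance(graph, FringeTree):
        graph = graph.tree
    table = table or default_element_table()
    total = 0
    for v in graph.atoms():
        code = graph.element(v)
        if code not in table:
            raise UnknownElementError(code)
        total += table.mass(code)
    return total


def hydrogen_suppress(graph: ChemicalGraph) -> ChemicalGraph:
    """Remove all hydrogen vertices (and incident bonds).

    The result must stay connected and non-empty; otherwise the molecule
    cannot be handled by the two-layered model and is rejected.
    """
    heavy = graph.heavy_atoms()
    if not heavy:
        raise ChemGraphError("no non-hydrogen atoms after suppression")
    out = graph.subgraph(heavy)
    if not out.is_connected():
        raise ChemGraphError("hydrogen suppression disconnects the graph")
    return out


# ---------------------------------------------------------------------------
# Rooted-tree canonical codes
# ---------------------------------------------------------------------------

def _subtree_code(tree: ChemicalGraph, v: Vertex, parent: Vertex | None) -> str:
    children = [w for w in tree.neighbors(v) if w != parent]
    if not children:
        return tree.element(v)
    parts = sorted(
        (BOND_CHARS[tree.order(v, w)], _subtree_code(tree, w, v)) for w in children
    )
    return tree.element(v) + "[" + "".join(b + c for b, c in parts) + "]"


def canonical_rooted_code(tree: ChemicalGraph, root: Vertex) -> str:
    """Canonical string code of a rooted chemical tree.

    Two rooted chemical trees receive equal codes iff they are
    rooted-isomorphic (respecting element labels and bond multiplicities).
    The encoding is a label-aware minimum-multiset recursion: each vertex
    is serialised as its element followed by the sorted codes of its
    child subtrees, each prefixed with the bond character (-, =, #).
    """
    n = tree.n_atoms()
    if root not in tree.graph:
        raise ChemGraphError(f"root {root!r} not in tree")
    if tree.graph.number_of_edges() != n - 1 or not tree.is_connected():
        raise ChemGraphError("input is not a tree")
    return _subtree_code(tree, root, None)


def _parse_element(code: str, i: int) -> tuple[str, int]:
    j = i
    if j < len(code) and code[j].isupper():
        j += 1
        while j < len(code) and code[j].islower():
            j += 1
        if j < len(code) and code[j] == "(":
            k = code.index(")", j)
            j = k + 1
        return code[i:j], j
    raise ChemGraphError(f"cannot parse element at position {i} of {code!r}")


def _parse_node(code: str, i: int, tree: ChemicalGraph, counter: list[int],
                parent: Vertex | None, bond: int) -> tuple[Vertex, int]:
    elem, i = _parse_element(code, i)
    vid = counter[0]
    counter[0] += 1
    tree.add_atom(vid, elem)
    if parent is not None:
        tree.add_bond(parent, vid, bond)
    if i < len(code) and code[i] == "[":
        i += 1
        while i < len(code) and code[i] != "]":
            if code[i] not in CHAR_BONDS:
                raise ChemGraphError(f"expected bond character at {i} in {code!r}")
            b = CHAR_BONDS[code[i]]
            _, i = _parse_node(code, i + 1, tree, counter, vid, b)
        if i >= len(code):
            raise ChemGraphError(f"unbalanced brackets in {code!r}")
        i += 1
    return vid, i


class FringeTree:
    """A rooted chemical tree: carrier of fringe-configurations and CC masses.

    The tree includes hydrogens; with branch parameter rho = 2 every
    non-hydrogen non-root vertex lies at depth <= 2 from the root.
    """

    def __init__(self, tree: ChemicalGraph, root: Vertex):
        n = tree.n_atoms()
        if tree.graph.number_of_edges() != n - 1 or not tree.is_connected():
            raise ChemGraphError("fringe tree must be a tree")
        if root not in tree.graph:
            raise ChemGraphError("root must belong to the tree")
        self.tree = tree
        self.root = root
        self._code: str | None = None

    @property
    def canonical_code(self) -> str:
        if self._code is None:
            self._code = canonical_rooted_code(self.tree, self.root)
        return self._code

    @classmethod
    def from_code(cls, code: str) -> "FringeTree":
        tree = ChemicalGraph()
        counter = [0]
        root, i = _parse_node(code, 0, tree, counter, None, 1)
        if i != len(code):
            raise ChemGraphError(f"trailing characters in fringe code {code!r}")
        return cls(tree, root)

    # -- summary quantities (used by descriptors and the MILP) --------
    def mass(self, table: ElementTable | None = None) -> int:
        return mass_of(self.tree, table)

    @property
    def root_element(self) -> str:
        return self.tree.element(self.root)

    def heavy_size(self) -> int:
        return len(self.tree.heavy_atoms())

    def root_bond_sum(self) -> int:
        """Bond multiplicity consumed at the root inside the tree (H included)."""
        return self.tree.bond_sum(self.root)

    def root_heavy_degree(self) -> int:
        return sum(1 for w in self.tree.neighbors(self.root)
                   if self.tree.element(w) != "H")

    def height(self) -> int:
        """Maximum depth of a non-hydrogen vertex below the root."""
        depths = nx.single_source_shortest_path_length(self.tree.graph, self.root)
        heavy = [d for v, d in depths.items() if self.tree.element(v) != "H"]
        return max(heavy)

    def element_counts(self, heavy_only: bool = True,
                       exclude_root: bool = False) -> dict[str, int]:
        counts: dict[str, int] = {}
        for v in self.tree.atoms():
            if exclude_root and v == self.root:
                continue
            e = self.tree.element(v)
            if heavy_only and e == "H":
                continue
            counts[e] = counts.get(e, 0) + 1
        return counts

    def leaf_ac_counts(self, table: ElementTable | None = None) -> dict[tuple, int]:
        """Adjacency-configurations on heavy leaf-edges of the tree.

        A leaf is a non-root heavy vertex all of whose heavy neighbours
        number one; hydrogen leaves are excluded.  Tuples are canonically
        oriented with :func:`ccinfer.twolayer.orient_ac`.
        """
        from .twolayer import orient_ac  # local import avoids a cycle

        table = table or default_element_table()
        heavy = set(self.tree.heavy_atoms())
        counts: dict[tuple, int] = {}
        for v in heavy:
            if v == self.root:
                continue
            heavy_nb = [w for w in self.tree.neighbors(v) if w in heavy]
            if len(heavy_nb) != 1:
                continue
            w = heavy_nb[0]
            ac = orient_ac(self.tree.element(w), self.tree.element(v),
                           self.tree.order(v, w), table)
            counts[ac] = counts.get(ac, 0) + 1
        return counts

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FringeTree):
            return NotImplemented
        return self.canonical_code == other.canonical_code

    def __hash__(self) -> int:
        return hash(self.canonical_code)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"FringeTree({self.canonical_code!r})"


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate(graph: ChemicalGraph, table: ElementTable | None = None,
             min_carbons: int = 4) -> list[str]:
    """Diagnostic report of violated chemical-graph / 2L-feasibility invariants.

    Returns a list of human-readable violations; an empty list means the
    graph is a valid, 2L-feasible chemical graph (connected, valences
    satisfied, hydrogens terminal, at least ``min_carbons`` carbon atoms,
    non-empty interior under rho = 2).
    """
    table = table or default_element_table()
    report: list[str] = []
    if graph.n_atoms() == 0:
        return ["graph is empty"]
    if not graph.is_connected():
        report.append("graph is not connected")
    for v in graph.atoms():
        code = graph.element(v)
        if code not in table:
            report.append(f"unknown element code {code!r} at vertex {v!r}")
            continue
        if graph.bond_sum(v) != table.valence(code):
            report.append(
                f"valence violation at {v!r}: {code} needs {table.valence(code)}, "
                f"has bond sum {graph.bond_sum(v)}"
            )
        if code == "H":
            if graph.degree(v) != 1:
                report.append(f"hydrogen {v!r} has degree {graph.degree(v)} != 1")
            elif graph.order(v, graph.neighbors(v)[0]) != 1:
                report.append(f"hydrogen {v!r} carries a multiple bond")
    n_carbon = sum(1 for v in graph.atoms()
                   if ElementTable.symbol(graph.element(v)) == "C"
                   if graph.element(v) in table)
    if n_carbon < min_carbons:
        report.append(f"2L-infeasible: {n_carbon} carbon atoms (< {min_carbons})")
    if not report:
        # interior emptiness check (2L decomposition must have a root set)
        from .twolayer import heights_by_leaf_deletion

        try:
            sup = hydrogen_suppress(graph)
        except ChemGraphError as exc:
            report.append(f"2L-infeasible: {exc}")
        else:
            heights = heights_by_leaf_deletion(sup)
            interior = [v for v in sup.atoms() if heights.get(v, 2) >= 2]
            if not interior:
                report.append("2L-infeasible: interior is empty under rho = 2")
    return report
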