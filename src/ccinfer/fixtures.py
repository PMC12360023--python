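"""Reference molecules and a random generator of valence-feasible graphs.

The named fixtures include the three dihydroxybenzene isomers (catechol,
resorcinol, hydroquinone) with fixed Kekule structures — double bonds at
ring positions 1-2, 3-4, 5-6 and hydroxyls at (1,2), (1,3), (1,4)
respectively — plus benzene and small pathological ring systems (spiro,
fused, triple-shared-edge) used to exercise the descriptor and MILP
machinery.  Everything is constructed programmatically; no external
files are needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemgraph import ChemicalGraph, FringeTree, validate
from .elements import ElementTable, default_element_table


def complete_hydrogens(graph: ChemicalGraph,
                       table: ElementTable | None = None) -> ChemicalGraph:
    """Attach hydrogens to every heavy atom until its valence is saturated."""
    table = table or default_element_table()
    out = graph.copy()
    h = 0
    for v in graph.atoms():
        need = table.valence(out.element(v)) - out.bond_sum(v)
        if need < 0:
            raise ValueError(f"vertex {v!r} exceeds its valence")
        for _ in range(need):
            hid = f"H{h}"
            h += 1
            out.add_atom(hid, "H")
            out.add_bond(v, hid, 1)
    return out


def _benzene_ring(hydroxyl_positions: tuple[int, ...]) -> ChemicalGraph:
    g = ChemicalGraph()
    for i in range(6):
        g.add_atom(f"C{i}", "C")
    for i in range(6):
        order = 2 if i % 2 == 0 else 1  # Kekule: double bonds at 1-2, 3-4, 5-6
        g.add_bond(f"C{i}", f"C{(i + 1) % 6}", order)
    for k, i in enumerate(hydroxyl_positions):
        g.add_atom(f"O{k}", "O")
        g.add_bond(f"C{i}", f"O{k}", 1)
    return complete_hydrogens(g)


def _ring_of_carbons(n: int, prefix: str, g: ChemicalGraph) -> list[str]:
    ids = [f"{prefix}{i}" for i in range(n)]
    for vid in ids:
        g.add_atom(vid, "C")
    for i in range(n):
        g.add_bond(ids[i], ids[(i + 1) % n], 1)
    return ids


def _spiro() -> ChemicalGraph:
    # two cyclopentane rings sharing one carbon (spiro[4.4]nonane)
    g = ChemicalGraph()
    g.add_atom("S", "C")
    for p in ("a", "b"):
        ids = [f"{p}{i}" for i in range(4)]
        for vid in ids:
            g.add_atom(vid, "C")
        g.add_bond("S", ids[0], 1)
        for i in range(3):
            g.add_bond(ids[i], ids[i + 1], 1)
        g.add_bond(ids[3], "S", 1)
    return complete_hydrogens(g)


def _fused_bicyclic() -> ChemicalGraph:
    # decalin: two cyclohexane rings sharing one edge
    g = ChemicalGraph()
    ids = _ring_of_carbons(6, "r", g)
    extra = [f"s{i}" for i in range(4)]
    for vid in extra:
        g.add_atom(vid, "C")
    g.add_bond(ids[0], extra[0], 1)
    for i in range(3):
        g.add_bond(extra[i], extra[i + 1], 1)
    g.add_bond(extra[3], ids[1], 1)
    return complete_hydrogens(g)


def _triple_shared_edge() -> ChemicalGraph:
    # three 4-cycles through one shared C-C edge
    g = ChemicalGraph()
    g.add_atom("a", "C")
    g.add_atom("b", "C")
    g.add_bond("a", "b", 1)
    for p in range(3):
        g.add_atom(f"x{p}", "C")
        g.add_atom(f"y{p}", "C")
        g.add_bond("a", f"x{p}", 1)
        g.add_bond(f"x{p}", f"y{p}", 1)
        g.add_bond(f"y{p}", "b", 1)
    return complete_hydrogens(g)


def _propane() -> ChemicalGraph:
    g = ChemicalGraph()
    for i in range(3):
        g.add_atom(f"C{i}", "C")
    g.add_bond("C0", "C1", 1)
    g.add_bond("C1", "C2", 1)
    return complete_hydrogens(g)


_FIXTURES = {
    "catechol": lambda: _benzene_ring((0, 1)),
    "resorcinol": lambda: _benzene_ring((0, 2)),
    "hydroquinone": lambda: _benzene_ring((0, 3)),
    "benzene": lambda: _benzene_ring(()),
    "spiro": _spiro,
    "fused_bicyclic": _fused_bicyclic,
    "triple_shared_edge": _triple_shared_edge,
    "propane": _propane,
}


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def reference_molecule(name: str) -> ChemicalGraph:
    """A named reference molecule (fresh copy)."""
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {fixture_names()}") from None


#: canonical small fringe trees used throughout the worked examples:
#: psi1 = CH (ring CH), psi2 = C-OH (phenolic carbon), plus the four
#: fringe formulas N, CH2, CO, CH3N of the fused-ring worked example.
_FRINGES = {
    "psi1": "C[-H]",
    "psi2": "C[-O[-H]]",
    "n": "N",
    "ch2": "C[-H-H]",
    "co": "C[=O]",
    "ch3n": "N[-C[-H-H-H]]",
}


def reference_fringe(name: str) -> FringeTree:
    """A named reference fringe tree (psi1, psi2, n, ch2, co, ch3n)."""
    try:
        return FringeTree.from_code(_FRINGES[name])
    except KeyError:
        raise KeyError(f"unknown fringe {name!r}; known: {sorted(_FRINGES)}") from None


# ---------------------------------------------------------------------------
# Random valence-feasible chemical graphs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomGraphParams:
    """Knobs of the random molecule generator.

    ``n_heavy`` is an inclusive range for the number of non-hydrogen
    atoms; ``elements`` is the heavy-element pool (must contain C);
    ``n_rings`` an inclusive range for the number of extra ring-closing
    bonds.  Defaults give small drug-like graphs: 8-16 heavy atoms over
    {C, O, N} with up to two rings.
    """

    n_heavy: tuple[int, int] = (8, 16)
    elements: tuple[str, ...] = ("C", "O", "N")
    n_rings: tuple[int, int] = (0, 2)
    seed: int = 0
    max_retries: int = 200


def generate_random(params: RandomGraphParams,
                    table: ElementTable | None = None) -> ChemicalGraph:
    """One random connected, valence-feasible, 2L-feasible chemical graph.

    Reproducible from ``params.seed``.  Construction: random labelled
    tree grown under valence budgets, optional ring-closing bonds between
    vertices at distance 3-5, occasional bond-order upgrades, hydrogen
    completion; rejected and retried until :func:`validate` passes.
    """
    table = table or default_element_table()
    if "C" not in params.elements:
        raise ValueError("element pool must contain C")
    rng = np.random.default_rng(params.seed)
    for _ in range(params.max_retries):
        g = _try_generate(rng, params, table)
        if g is not None and not validate(g, table):
            return g
    raise RuntimeError(f"could not generate a feasible graph from {params}")


def _try_generate(rng: np.random.Generator, params: RandomGraphParams,
                  table: ElementTable) -> ChemicalGraph | None:
    import networkx as nx

    lo, hi = params.n_heavy
    n = int(rng.integers(lo, hi + 1))
    if n < 4:
        return None
    elems = ["C"] * 4 + [str(rng.choice(params.elements)) for _ in range(n - 4)]
    order = rng.permutation(n)
    elems = [elems[i] for i in order]
    g = ChemicalGraph()
    for i, e in enumerate(elems):
        g.add_atom(i, e)
    spare = {i: table.valence(e) for i, e in enumerate(elems)}
    for i in range(1, n):
        candidates = [j for j in range(i) if spare[j] >= 1]
        if not candidates:
            return None
        j = int(rng.choice(candidates))
        g.add_bond(i, j, 1)
        spare[i] -= 1
        spare[j] -= 1
    # ring-closing bonds between distance-3..5 vertices with spare valence
    want_rings = int(rng.integers(params.n_rings[0], params.n_rings[1] + 1))
    for _ in range(want_rings):
        dist = dict(nx.all_pairs_shortest_path_length(g.graph))
        pairs = [(u, v) for u in range(n) for v in range(u + 1, n)
                 if spare[u] >= 1 and spare[v] >= 1 and 3 <= dist[u][v] <= 5]
        if not pairs:
            break
        u, v = pairs[int(rng.integers(len(pairs)))]
        g.add_bond(u, v, 1)
        spare[u] -= 1
        spare[v] -= 1
    # occasional double bonds
    for u, v in list(g.bonds()):
        if spare[u] >= 1 and spare[v] >= 1 and rng.random() < 0.2:
            g.graph.edges[u, v]["order"] = 2
            spare[u] -= 1
            spare[v] -= 1
    try:
        return complete_hydrogens(g, table)
    except ValueError:
        return None
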