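"""MILP inversion of a linear prediction function over a seed tree.

The program expands a seed tree into a concrete chemical graph: every
ring node picks one cycle-configuration from its availability set and
becomes a chordless cycle of that length; ring-edge-joined cycles share
exactly one edge; non-ring nodes/edges map to single interior
vertices/edges.  Every interior vertex picks a fringe tree, every
interior edge a bond multiplicity.  Linear constraints tie the feature
coordinates (static counts, fringe/adjacency/edge/leaf-adjacency/
cycle-configuration counts) to these selections, enforce all
specification bounds, and pin the hyperplane score into the requested
property window.  Feasible solutions are decoded back into a chemical
graph and re-featurized; the round trip must agree coordinate-wise.

Cycle-configuration consistency is linearised by enumeration: for each
ring node and each available CC, all mass sequences over the masses
occurring in the relevant fringe sets whose canonical rank sequence
equals that CC are precomputed (all 2*l orientations times all
order-preserving injections of ranks into mass values); one selector
per admissible sequence forces the fringe masses around the cycle.
Equal-mass fringe trees are interchangeable within a rank, as the rank
classes are mass classes, not tree classes.

The solver backend is HiGHS through :func:`scipy.optimize.milp`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds as OptBounds
from scipy.optimize import LinearConstraint, milp

from .chemgraph import ChemicalGraph, FringeTree
from .cycleconf import canonical_cycle_config
from .elements import ElementTable, default_element_table
from .featurize import DescriptorVocabulary, cc_name, feature_vector
from .featurize import _ac_name, _ec_name  # stable column namers
from .seedtree import InferenceTask, SeedTree, SeedTreeError, Specification

_MAX_CC_SELECTORS = 20000
_DEG_RANGE = range(0, 7)  # degrees in the hydrogen-suppressed graph


class Expr:
    """Sparse linear expression: sum of coef * var plus a constant."""

    __slots__ = ("terms", "const")

    def __init__(self, terms: dict | None = None, const: float = 0.0):
        self.terms = dict(terms or {})
        self.const = float(const)

    @classmethod
    def of(cls, var: int, coef: float = 1.0) -> "Expr":
        return cls({var: coef})

    def add(self, other: "Expr | int", scale: float = 1.0) -> "Expr":
        if isinstance(other, int):
            self.terms[other] = self.terms.get(other, 0.0) + scale
            return self
        for v, c in other.terms.items():
            self.terms[v] = self.terms.get(v, 0.0) + scale * c
        self.const += scale * other.const
        return self

    def value(self, x: np.ndarray) -> float:
        return self.const + sum(c * x[v] for v, c in self.terms.items())

    def is_zero(self) -> bool:
        return not self.terms and self.const == 0.0


class _LP:
    """Plain variable/constraint container consumable by any MILP solver."""

    def __init__(self) -> None:
        self.lb: list[float] = []
        self.ub: list[float] = []
        self.integer: list[bool] = []
        self.rows: list[tuple[dict, float, float]] = []

    def n_vars(self) -> int:
        return len(self.lb)

    def var(self, lo: float, hi: float, integer: bool) -> int:
        self.lb.append(lo)
        self.ub.append(hi)
        self.integer.append(integer)
        return len(self.lb) - 1

    def binary(self) -> int:
        return self.var(0.0, 1.0, True)

    def cont(self, lo: float = 0.0, hi: float = 1.0) -> int:
        return self.var(lo, hi, False)

    def constrain(self, expr: Expr, lo: float, hi: float) -> None:
        self.rows.append((dict(expr.terms), lo - expr.const, hi - expr.const))

    def eq(self, expr: Expr, value: float) -> None:
        self.constrain(expr, value, value)

    def le(self, expr: Expr, hi: float) -> None:
        self.constrain(expr, -np.inf, hi)

    def ge(self, expr: Expr, lo: float) -> None:
        self.constrain(expr, lo, np.inf)

    def matrices(self):
        n = self.n_vars()
        data, ri, ci, lo, hi = [], [], [], [], []
        for r, (terms, l, h) in enumerate(self.rows):
            for v, c in terms.items():
                ri.append(r)
                ci.append(v)
                data.append(c)
            lo.append(l)
            hi.append(h)
        A = sp.csr_matrix((data, (ri, ci)), shape=(len(self.rows), n))
        return A, np.array(lo), np.array(hi)


@dataclass
class _Psi:
    """Precomputed summary of one admissible fringe tree."""

    code: str
    tree: FringeTree
    mass: int
    heavy: int
    root_elem: str
    cap: int              # bond multiplicity left at the root for interior edges
    root_heavy_deg: int   # heavy children inside the tree
    ext_counts: dict      # heavy element counts excluding the root
    leaf_acs: dict        # AC tuple -> count on heavy leaf edges


@dataclass
class InferenceResult:
    status: str                       # optimal | infeasible | timeout | error
    graph: ChemicalGraph | None = None
    milp_feature_values: dict = field(default_factory=dict)
    recomputed_feature_values: dict = field(default_factory=dict)
    predicted_value: float | None = None
    message: str = ""


def expand_ring_node(xi: Sequence[int], fringe_assignment: Sequence[FringeTree],
                     table: ElementTable | None = None) -> bool:
    """Check that a cyclic fringe assignment realises the CC ``xi``.

    True iff the canonical cycle-configuration of the masses of the
    assigned fringe trees, in cyclic order, equals ``xi``.
    """
    if len(fringe_assignment) != len(xi):
        raise ValueError("assignment length must equal the CC length")
    table = table or default_element_table()
    masses = [ft.mass(table) for ft in fringe_assignment]
    return canonical_cycle_config(masses) == tuple(xi)


def _cc_orientations(xi: tuple) -> set[tuple]:
    l = len(xi)
    out = set()
    for seq in (list(xi), list(xi)[::-1]):
        for s in range(l):
            out.add(tuple(seq[s:] + seq[:s]))
    return out


class MilpInstance:
    """A built (not yet solved) seed-tree expansion MILP."""

    def __init__(self, seed: SeedTree, spec: Specification, task: InferenceTask,
                 vocabulary: DescriptorVocabulary, table: ElementTable | None = None,
                 rho: int = 2):
        self.seed = seed
        self.spec = spec
        self.task = task
        self.vocab = vocabulary
        self.table = table or default_element_table()
        self.rho = rho
        self.lp = _LP()
        self._build()

    # -- construction -------------------------------------------------
    def _psi_records(self) -> None:
        t = self.table
        self.F: dict[str, list[_Psi]] = {}
        for u in self.seed.nodes:
            records: dict[str, _Psi] = {}
            is_leaf_nonring = (u not in self.seed.ring_nodes
                               and self.seed.degree(u) <= 1)
            for ft in self.spec.fringe_sets[u]:
                if ft.height() > self.rho:
                    continue
                if is_leaf_nonring and ft.height() != self.rho:
                    # a shallower fringe would drag this node into the exterior
                    continue
                cap = t.valence(ft.root_element) - ft.root_bond_sum()
                if cap < 0:
                    continue
                records[ft.canonical_code] = _Psi(
                    code=ft.canonical_code, tree=ft, mass=ft.mass(t),
                    heavy=ft.heavy_size(), root_elem=ft.root_element, cap=cap,
                    root_heavy_deg=ft.root_heavy_degree(),
                    ext_counts=ft.element_counts(heavy_only=True, exclude_root=True),
                    leaf_acs=ft.leaf_ac_counts(t),
                )
            if not records:
                raise SeedTreeError(
                    f"node {u!r} has no admissible fringe tree "
                    f"(height/valence filters emptied its set)")
            self.F[u] = sorted(records.values(), key=lambda r: r.code)

    def _ring_skeleton(self) -> None:
        seed = self.seed
        incident_ring = {u: [e for e in seed.ring_edges if u in e] for u in seed.nodes}
        for u, es in incident_ring.items():
            if len(es) > 1:
                raise SeedTreeError(
                    f"ring node {u!r} is incident to {len(es)} ring edges; "
                    "ring edges must form a matching")
        order = {u: i for i, u in enumerate(seed.nodes)}
        self.shared_parent: dict[str, str] = {}
        for e in seed.ring_edges:
            a, b = sorted(e, key=order.get)
            self.shared_parent[b] = a

        lp = self.lp
        self.x: dict[tuple, int] = {}
        self.ring_lengths: dict[str, list[int]] = {}
        self.act: dict[tuple, Expr] = {}
        self.len_sel: dict[tuple, Expr] = {}
        for u in seed.nodes:
            if u not in seed.ring_nodes:
                continue
            xis = sorted({tuple(x) for x in self.spec.cc_sets[u]},
                         key=lambda x: (len(x), x))
            pick = Expr()
            for xi in xis:
                self.x[(u, xi)] = lp.binary()
                pick.add(self.x[(u, xi)])
            lp.eq(pick, 1.0)
            lengths = sorted({len(xi) for xi in xis})
            self.ring_lengths[u] = lengths
            for l in lengths:
                e = Expr()
                for xi in xis:
                    if len(xi) == l:
                        e.add(self.x[(u, xi)])
                self.len_sel[(u, l)] = e
            lmax = lengths[-1]
            for p in range(lmax):
                if p < lengths[0]:
                    self.act[(u, p)] = Expr(const=1.0)
                else:
                    e = Expr()
                    for xi in xis:
                        if len(xi) > p:
                            e.add(self.x[(u, xi)])
                    self.act[(u, p)] = e

    def _vtx(self, u: str, p: int):
        """Concrete vertex of cycle position p of ring node u (alias-aware)."""
        if p < 2 and u in self.shared_parent:
            return ("c", self.shared_parent[u], p)
        return ("c", u, p)

    def _vertices(self) -> None:
        self.vertex_owner: dict[tuple, str] = {}
        self.vertex_active: dict[tuple, Expr] = {}
        for u in self.seed.nodes:
            if u not in self.seed.ring_nodes:
                self.vertex_owner[("n", u)] = u
                self.vertex_active[("n", u)] = Expr(const=1.0)
            else:
                lmax = self.ring_lengths[u][-1]
                for p in range(lmax):
                    if p < 2 and u in self.shared_parent:
                        continue  # alias of the parent's shared edge
                    self.vertex_owner[("c", u, p)] = u
                    self.vertex_active[("c", u, p)] = self.act[(u, p)]
        lp = self.lp
        self.y: dict[tuple, int] = {}
        for vid, u in self.vertex_owner.items():
            tot = Expr()
            for psi in self.F[u]:
                self.y[(vid, psi.code)] = lp.binary()
                tot.add(self.y[(vid, psi.code)])
            lp.constrain(tot.add(self.vertex_active[vid], -1.0), 0.0, 0.0)

    def _elem_ind(self, vid, code: str) -> Expr:
        e = Expr()
        for psi in self.F[self.vertex_owner[vid]]:
            if psi.root_elem == code:
                e.add(self.y[(vid, psi.code)])
        return e

    def _edges(self) -> None:
        lp = self.lp
        self.edges: list[dict] = []
        self.att: dict[tuple, dict[int, int]] = {}

        def new_edge(ends, exist: Expr, label) -> dict:
            b = {m: lp.binary() for m in (1, 2, 3)}
            tot = Expr()
            beta = Expr()
            for m, v in b.items():
                tot.add(v)
                beta.add(v, m)
            lp.constrain(Expr(tot.terms).add(exist, -1.0), 0.0, 0.0)
            rec = {"id": len(self.edges), "ends": ends, "exist": exist,
                   "b": b, "beta": beta, "label": label}
            self.edges.append(rec)
            return rec

        for u in self.seed.nodes:
            if u not in self.seed.ring_nodes:
                continue
            lengths = self.ring_lengths[u]
            lmax = lengths[-1]
            start = 1 if u in self.shared_parent else 0  # (0,1) owned by parent
            for p in range(start, lmax - 1):
                new_edge((("fixed", self._vtx(u, p)), ("fixed", self._vtx(u, p + 1))),
                         self.act[(u, p + 1)], ("cycle", u, p, p + 1))
            for l in lengths:
                new_edge((("fixed", self._vtx(u, l - 1)), ("fixed", self._vtx(u, 0))),
                         Expr(self.len_sel[(u, l)].terms, self.len_sel[(u, l)].const),
                         ("closing", u, l))
        for (a, b_node) in self.seed.non_ring_edges():
            ends = []
            for w in (a, b_node):
                if w in self.seed.ring_nodes:
                    item = ("att", len(self.att), w)
                    lmax = self.ring_lengths[w][-1]
                    att = {p: lp.binary() for p in range(lmax)}
                    self.att[item[1]] = att
                    tot = Expr()
                    for p, v in att.items():
                        tot.add(v)
                        gate = Expr.of(v).add(self.act[(w, p)], -1.0)
                        lp.le(gate, 0.0)  # only active positions
                    lp.eq(tot, 1.0)
                    ends.append(item)
                else:
                    ends.append(("fixed", ("n", w)))
            new_edge(tuple(ends), Expr(const=1.0), ("seed", a, b_node))

    def _incidence(self) -> None:
        """Interior degree and valence bookkeeping per vertex."""
        lp = self.lp
        self.int_deg: dict[tuple, Expr] = {vid: Expr() for vid in self.vertex_owner}
        val_use: dict[tuple, Expr] = {vid: Expr() for vid in self.vertex_owner}
        for e in self.edges:
            for end in e["ends"]:
                if end[0] == "fixed":
                    vid = end[1]
                    self.int_deg[vid].add(e["exist"])
                    val_use[vid].add(e["beta"])
                else:
                    _, item_id, w = end
                    att = self.att[item_id]
                    for p, av in att.items():
                        vid = self._vtx(w, p)
                        self.int_deg[vid].add(av)
                        # c_p = beta * att_p, linearised
                        c = lp.cont(0.0, 3.0)
                        lp.le(Expr.of(c).add(Expr.of(av), -3.0), 0.0)
                        lp.le(Expr.of(c).add(e["beta"], -1.0), 0.0)
                        lp.ge(Expr.of(c).add(e["beta"], -1.0).add(Expr.of(av), -3.0),
                              -3.0)
                        val_use[vid].add(Expr.of(c))
        for vid, u in self.vertex_owner.items():
            cap = Expr()
            for psi in self.F[u]:
                cap.add(self.y[(vid, psi.code)], psi.cap)
            lp.eq(Expr(val_use[vid].terms, val_use[vid].const).add(cap, -1.0), 0.0)

    def _degree_states(self) -> None:
        lp = self.lp
        self.d: dict[tuple, dict[int, int]] = {}
        self.s: dict[tuple, dict[tuple, int]] = {}
        for vid, u in self.vertex_owner.items():
            deg = Expr(self.int_deg[vid].terms, self.int_deg[vid].const)
            for psi in self.F[u]:
                deg.add(self.y[(vid, psi.code)], psi.root_heavy_deg)
            dv = {k: lp.binary() for k in _DEG_RANGE}
            self.d[vid] = dv
            tot, wsum = Expr(), Expr()
            for k, v in dv.items():
                tot.add(v)
                wsum.add(v, k)
            lp.constrain(tot.add(self.vertex_active[vid], -1.0), 0.0, 0.0)
            lp.eq(wsum.add(deg, -1.0), 0.0)
            elems = sorted({psi.root_elem for psi in self.F[u]}, key=self.table.rank)
            sv: dict[tuple, int] = {}
            tot_s = Expr()
            for a in elems:
                aind = self._elem_ind(vid, a)
                for k in _DEG_RANGE:
                    s = lp.cont()
                    sv[(a, k)] = s
                    tot_s.add(s)
                    lp.ge(Expr.of(s).add(aind, -1.0).add(Expr.of(dv[k]), -1.0), -1.0)
            lp.constrain(tot_s.add(self.vertex_active[vid], -1.0), 0.0, 0.0)
            self.s[vid] = sv

    def _cc_consistency(self) -> None:
        lp = self.lp
        total_z = 0
        self.z: dict[tuple, int] = {}
        for u in self.seed.nodes:
            if u not in self.seed.ring_nodes:
                continue
            xis = sorted({tuple(x) for x in self.spec.cc_sets[u]},
                         key=lambda x: (len(x), x))
            for xi in xis:
                l = len(xi)
                alphabets = []
                for p in range(l):
                    vid = self._vtx(u, p)
                    alphabets.append(sorted({psi.mass for psi in
                                             self.F[self.vertex_owner[vid]]}))
                union = sorted(set().union(*map(set, alphabets)))
                r = max(xi)
                seqs: set[tuple] = set()
                for vals in combinations(union, r):
                    for pat in _cc_orientations(xi):
                        seq = tuple(vals[k - 1] for k in pat)
                        if all(seq[p] in alphabets[p] for p in range(l)):
                            seqs.add(seq)
                total_z += len(seqs)
                if total_z > _MAX_CC_SELECTORS:
                    raise SeedTreeError(
                        "cycle-configuration linearisation too large; "
                        "shrink the CC or fringe availability sets")
                if not seqs:
                    lp.eq(Expr.of(self.x[(u, xi)]), 0.0)
                    continue
                sel = Expr()
                for seq in sorted(seqs):
                    zv = lp.binary()
                    self.z[(u, xi, seq)] = zv
                    sel.add(zv)
                    for p in range(l):
                        vid = self._vtx(u, p)
                        match = Expr()
                        for psi in self.F[self.vertex_owner[vid]]:
                            if psi.mass == seq[p]:
                                match.add(self.y[(vid, psi.code)])
                        lp.ge(match.add(Expr.of(zv), -1.0), 0.0)
                lp.eq(sel.add(Expr.of(self.x[(u, xi)]), -1.0), 0.0)

    # -- endpoint state helpers for AC/EC indicators -------------------
    def _end_state(self, end, a: str, k: int) -> Expr | None:
        """Expression for 'this endpoint has element a and degree k' (or None = 0)."""
        if end[0] == "fixed":
            sv = self.s[end[1]]
            if (a, k) not in sv:
                return None
            return Expr.of(sv[(a, k)])
        _, item_id, w = end
        Sv = self._att_states[item_id]
        if (a, k) not in Sv:
            return None
        return Expr.of(Sv[(a, k)])

    def _end_elem(self, end, a: str) -> Expr | None:
        if end[0] == "fixed":
            e = self._elem_ind(end[1], a)
            return None if not e.terms else e
        _, item_id, w = end
        Sv = self._att_states[item_id]
        terms = [v for (aa, k), v in Sv.items() if aa == a]
        if not terms:
            return None
        e = Expr()
        for v in terms:
            e.add(v)
        return e

    def _attachment_states(self) -> None:
        """Selected-position (element, degree) state of each attachment item."""
        lp = self.lp
        self._att_states: dict[int, dict[tuple, int]] = {}
        for item_id, att in self.att.items():
            # recover which ring node this item attaches to
            w = next(end[2] for e in self.edges for end in e["ends"]
                     if end[0] == "att" and end[1] == item_id)
            states = sorted({key for p in att for key in self.s[self._vtx(w, p)]})
            Sv: dict[tuple, int] = {}
            tot = Expr()
            for key in states:
                s = lp.cont()
                Sv[key] = s
                tot.add(s)
                for p, av in att.items():
                    base = self.s[self._vtx(w, p)].get(key)
                    if base is not None:
                        lp.ge(Expr.of(s).add(Expr.of(av), -1.0)
                              .add(Expr.of(base), -1.0), -1.0)
            lp.eq(tot, 1.0)
            self._att_states[item_id] = Sv

    def _product(self, parts: list[Expr]) -> Expr:
        """Exact 0/1 product of expressions each known to lie in [0, 1]."""
        lp = self.lp
        t = lp.cont()
        lower = Expr.of(t)
        for p in parts:
            lp.le(Expr.of(t).add(p, -1.0), 0.0)
            lower.add(p, -1.0)
        lp.ge(lower, -(len(parts) - 1))
        return Expr.of(t)

    def _config_counts(self) -> None:
        """Indicator sums for every needed AC/EC pattern on interior edges."""
        needed_ec = sorted(set(self.vocab.ecs) | set(self.spec.bounds.ec_int),
                           key=lambda e: (self.table.rank(e[0][0]), e[0][1],
                                          self.table.rank(e[1][0]), e[1][1], e[2]))
        needed_ac = sorted(set(self.vocab.acs) | set(self.spec.bounds.ac_int),
                           key=lambda a: (self.table.rank(a[0]),
                                          self.table.rank(a[1]), a[2]))
        self.ec_expr: dict[tuple, Expr] = {g: Expr() for g in needed_ec}
        self.ac_expr: dict[tuple, Expr] = {g: Expr() for g in needed_ac}
        for e in self.edges:
            endA, endB = e["ends"]
            for g in needed_ec:
                (a, d), (b, d2), m = g
                bm = Expr.of(e["b"][m])
                orientations = [((a, d), (b, d2))]
                if (a, d) != (b, d2):
                    orientations.append(((b, d2), (a, d)))
                for (pa, pb) in orientations:
                    sA = self._end_state(endA, *pa)
                    sB = self._end_state(endB, *pb)
                    if sA is None or sB is None:
                        continue
                    self.ec_expr[g].add(self._product([sA, sB, bm]))
            for g in needed_ac:
                a, b, m = g
                bm = Expr.of(e["b"][m])
                orientations = [(a, b)]
                if a != b:
                    orientations.append((b, a))
                for (pa, pb) in orientations:
                    eA = self._end_elem(endA, pa)
                    eB = self._end_elem(endB, pb)
                    if eA is None or eB is None:
                        continue
                    self.ac_expr[g].add(self._product([eA, eB, bm]))

    # -- feature linking ----------------------------------------------
    def _psi_weighted(self, weight) -> Expr:
        e = Expr()
        for vid, u in self.vertex_owner.items():
            for psi in self.F[u]:
                w = weight(psi)
                if w:
                    e.add(self.y[(vid, psi.code)], w)
        return e

    def _feature_exprs(self) -> None:
        v = self.vocab
        t = self.table
        self.features: dict[str, Expr] = {}
        unlinked: list[str] = []
        for name in v.static_names:
            if name == "n_heavy":
                self.features[name] = self._psi_weighted(lambda p: p.heavy)
            elif name == "n_interior":
                e = Expr()
                for vid in self.vertex_owner:
                    e.add(self.vertex_active[vid])
                self.features[name] = e
            elif name.startswith("deg_int_"):
                k = int(name.rsplit("_", 1)[1])
                e = Expr()
                for vid in self.vertex_owner:
                    if k in self.d[vid]:
                        e.add(self.d[vid][k])
                self.features[name] = e
            elif name.startswith("bond_int_"):
                m = int(name.rsplit("_", 1)[1])
                e = Expr()
                for edge in self.edges:
                    e.add(edge["b"][m])
                self.features[name] = e
            elif name.startswith("na_int_"):
                code = name[len("na_int_"):]
                e = Expr()
                for vid in self.vertex_owner:
                    e.add(self._elem_ind(vid, code))
                self.features[name] = e
            elif name.startswith("na_ex_"):
                code = name[len("na_ex_"):]
                self.features[name] = self._psi_weighted(
                    lambda p, c=code: p.ext_counts.get(c, 0))
            else:
                unlinked.append(name)  # e.g. avg_mass: a ratio, not linear
        self.fc_expr: dict[str, Expr] = {}
        for code in sorted({c for u in self.seed.nodes for c in
                            (psi.code for psi in self.F[u])} | set(v.fringe_configs)
                           | set(self.spec.bounds.fc)):
            e = Expr()
            for vid, u in self.vertex_owner.items():
                if (vid, code) in self.y:
                    e.add(self.y[(vid, code)])
            self.fc_expr[code] = e
        for code in v.fringe_configs:
            self.features[f"fc:{code}"] = self.fc_expr[code]
        for g in v.acs:
            self.features[f"ac:{_ac_name(g)}"] = self.ac_expr[g]
        for g in v.ecs:
            self.features[f"ec:{_ec_name(g)}"] = self.ec_expr[g]
        self.lac_expr: dict[tuple, Expr] = {}
        for g in sorted(set(v.leaf_acs) | set(self.spec.bounds.ac_lf),
                        key=lambda a: (t.rank(a[0]), t.rank(a[1]), a[2])):
            self.lac_expr[g] = self._psi_weighted(lambda p, gg=g: p.leaf_acs.get(gg, 0))
        for g in v.leaf_acs:
            self.features[f"lac:{_ac_name(g)}"] = self.lac_expr[g]
        for xi in v.ccs:
            e = Expr()
            for u in self.seed.ring_nodes:
                if (u, tuple(xi)) in self.x:
                    e.add(self.x[(u, tuple(xi))])
            self.features[f"cc:{cc_name(xi)}"] = e
        self.unlinked = unlinked

    def _apply_bounds(self) -> None:
        lp = self.lp
        b = self.spec.bounds

        def rng(expr: Expr, pair) -> None:
            lo = -np.inf if pair[0] is None else float(pair[0])
            hi = np.inf if pair[1] is None else float(pair[1])
            lp.constrain(expr, lo, hi)

        if b.n is not None:
            rng(self.features["n_heavy"] if "n_heavy" in self.features
                else self._psi_weighted(lambda p: p.heavy), b.n)
        elems = sorted(set(b.na_int) | set(b.na_ex) | set(b.na))
        for code in elems:
            na_int = Expr()
            for vid in self.vertex_owner:
                na_int.add(self._elem_ind(vid, code))
            na_ex = self._psi_weighted(lambda p, c=code: p.ext_counts.get(c, 0))
            if code in b.na_int:
                rng(na_int, b.na_int[code])
            if code in b.na_ex:
                rng(na_ex, b.na_ex[code])
            if code in b.na:
                rng(Expr(na_int.terms, na_int.const).add(na_ex), b.na[code])
        for code, pair in b.fc.items():
            rng(self.fc_expr.get(code, Expr()), pair)
        for g, pair in b.ac_int.items():
            rng(self.ac_expr[g], pair)
        for g, pair in b.ac_lf.items():
            rng(self.lac_expr[g], pair)
        for g, pair in b.ec_int.items():
            rng(self.ec_expr[g], pair)

    def _property_constraint(self) -> None:
        model = self.task.model
        cols = self.vocab.columns("2L+CC")
        if list(model.columns) != cols:
            raise SeedTreeError("model columns do not match the vocabulary")
        score = Expr(const=model.b)
        for w, name in zip(model.w, model.columns):
            if w == 0.0:
                continue
            if name not in self.features:
                raise SeedTreeError(
                    f"model puts weight on descriptor {name!r} which has no "
                    "linear encoding (e.g. avg_mass); refit without it")
            score.add(self.features[name], float(w))
        if self.task.mode == "regression":
            self.lp.constrain(score, self.task.y_lb, self.task.y_ub)
        elif self.task.target_class == 1:
            self.lp.ge(score, model.theta)
        else:
            self.lp.le(score, model.theta)

    def _build(self) -> None:
        self.spec.validate_against(self.seed)
        self._psi_records()
        self._ring_skeleton()
        self._vertices()
        self._edges()
        self._incidence()
        self._degree_states()
        self._attachment_states()
        self._cc_consistency()
        self._config_counts()
        self._feature_exprs()
        self._apply_bounds()
        self._property_constraint()

    # -- solving and decoding -----------------------------------------
    def solve(self, time_limit: float = 600.0) -> InferenceResult:
        """Solve for feasibility, decode, and verify the feature round trip."""
        lp = self.lp
        A, lo, hi = lp.matrices()
        res = milp(
            c=np.zeros(lp.n_vars()),
            constraints=[LinearConstraint(A, lo, hi)],
            integrality=np.array([1 if i else 0 for i in lp.integer]),
            bounds=OptBounds(np.array(lp.lb), np.array(lp.ub)),
            options={"time_limit": time_limit},
        )
        if res.status == 2:
            return InferenceResult(status="infeasible", message=res.message)
        if res.status == 1:
            return InferenceResult(status="timeout", message=res.message)
        if res.x is None:
            return InferenceResult(status="error", message=res.message)
        return self._decode(res.x)

    def _decode(self, xv: np.ndarray) -> InferenceResult:
        graph = ChemicalGraph()
        chosen_fringe: dict[tuple, str] = {}
        for vid, u in self.vertex_owner.items():
            if self.vertex_active[vid].value(xv) < 0.5:
                continue
            code = next(psi.code for psi in self.F[u]
                        if xv[self.y[(vid, psi.code)]] > 0.5)
            chosen_fringe[vid] = code
            ft = FringeTree.from_code(code)
            mapping = {w: (vid if w == ft.root else (vid, i))
                       for i, w in enumerate(ft.tree.atoms())}
            sub = ft.tree.relabel(mapping)
            for w in sub.atoms():
                graph.add_atom(w, sub.element(w))
            for (p, q) in sub.bonds():
                graph.add_bond(p, q, sub.order(p, q))
        for e in self.edges:
            if e["exist"].value(xv) < 0.5:
                continue
            m = next(mm for mm, v in e["b"].items() if xv[v] > 0.5)
            ends = []
            for end in e["ends"]:
                if end[0] == "fixed":
                    ends.append(end[1])
                else:
                    _, item_id, w = end
                    p = next(pp for pp, v in self.att[item_id].items()
                             if xv[v] > 0.5)
                    ends.append(self._vtx(w, p))
            graph.add_bond(ends[0], ends[1], m)
        # restore hydrogens are already inside the fringe trees; nothing to add
        milp_vals = {name: round(expr.value(xv), 6)
                     for name, expr in self.features.items()}
        vec = feature_vector(graph, self.vocab, "2L+CC",
                             params=self.spec.cc_params, rho=self.rho,
                             table=self.table, warn_oov=False)
        cols = self.vocab.columns("2L+CC")
        recomputed = dict(zip(cols, vec))
        for name, mv in milp_vals.items():
            rv = recomputed[name]
            tol = 1e-6 if abs(rv - round(rv)) > 1e-9 else 1e-6
            if abs(mv - rv) > tol:
                raise RuntimeError(
                    f"feature round-trip mismatch on {name!r}: MILP {mv} vs "
                    f"recomputed {rv} (formulation bug)")
        predicted = float(np.dot(self.task.model.w,
                                 np.array([recomputed[c] for c in cols]))
                          + self.task.model.b)
        return InferenceResult(status="optimal", graph=graph,
                               milp_feature_values=milp_vals,
                               recomputed_feature_values=recomputed,
                               predicted_value=predicted)

    # -- diagnostics ---------------------------------------------------
    def write_lp(self, path) -> None:
        """Dump the instance in a simple LP-like text format."""
        lines = ["\\ seed-tree expansion MILP", "Minimize", " obj: 0", "Subject To"]
        for r, (terms, lo, hi) in enumerate(self.lp.rows):
            body = " + ".join(f"{c:g} x{v}" for v, c in sorted(terms.items()))
            if lo == hi:
                lines.append(f" c{r}: {body} = {lo:g}")
            else:
                if np.isfinite(lo):
                    lines.append(f" c{r}l: {body} >= {lo:g}")
                if np.isfinite(hi):
                    lines.append(f" c{r}u: {body} <= {hi:g}")
        lines.append("Bounds")
        for i, (lo, hi) in enumerate(zip(self.lp.lb, self.lp.ub)):
            lines.append(f" {lo:g} <= x{i} <= {hi:g}")
        lines.append("General")
        lines.append(" " + " ".join(f"x{i}" for i, ii in enumerate(self.lp.integer) if ii))
        lines.append("End")
        from pathlib import Path

        Path(path).write_text("\n".join(lines) + "\n")


def build_milp(seed: SeedTree, spec: Specification, task: InferenceTask,
               vocabulary: DescriptorVocabulary,
               table: ElementTable | None = None, rho: int = 2) -> MilpInstance:
    """Build the seed-tree expansion MILP (see module docstring).

    Contradictory bounds and structurally unusable specifications are
    rejected here, before any solver runs.
    """
    return MilpInstance(seed, spec, task, vocabulary, table, rho)


def solve_and_decode(instance: MilpInstance,
                     time_limit: float = 600.0) -> InferenceResult:
    """Solve a built instance and decode/verify the solution."""
    return instance.solve(time_limit)
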