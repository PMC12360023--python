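"""Seed trees, specifications and inference tasks for inverse design.

A *seed tree* is the abstract form of the target molecule: an unrooted
tree whose *ring nodes* expand to chordless cycles (a *ring edge* forces
its two cycles to share exactly one edge), while non-ring nodes/edges
map to single interior vertices/edges.  The *specification* lists, per
node, the available cycle-configurations and fringe trees, the element
alphabet, and lower/upper bounds on atom counts and configuration
counts.  The *inference task* carries the trained hyperplane and the
requested property window (regression) or class side (classification).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

from .chemgraph import FringeTree
from .cycleconf import CCParams, is_canonical_cc
from .learn import Hyperplane

_EC_PART = re.compile(r"^([A-Z][a-z]?(?:\(\d\))?)(\d+)$")


def parse_ac_name(name: str) -> tuple[str, str, int]:
    a, b, m = name.split("-")
    return (a, b, int(m))


def parse_ec_name(name: str) -> tuple[tuple[str, int], tuple[str, int], int]:
    p, q, m = name.split("-")
    mp, mq = _EC_PART.match(p), _EC_PART.match(q)
    if mp is None or mq is None:
        raise ValueError(f"malformed edge-configuration name {name!r}")
    return ((mp.group(1), int(mp.group(2))), (mq.group(1), int(mq.group(2))), int(m))


class SeedTreeError(ValueError):
    """Raised for structurally invalid seed trees or specifications."""


@dataclass
class SeedTree:
    """Tree skeleton (T; V°, E°) with ring nodes V° and ring edges E°."""

    nodes: list[str]
    edges: list[tuple[str, str]]
    ring_nodes: set[str] = field(default_factory=set)
    ring_edges: set[frozenset] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.ring_nodes = set(self.ring_nodes)
        self.ring_edges = {frozenset(e) for e in self.ring_edges}
        nodes = set(self.nodes)
        if len(self.nodes) != len(nodes):
            raise SeedTreeError("duplicate node names")
        edge_sets = [frozenset(e) for e in self.edges]
        if len(set(edge_sets)) != len(edge_sets):
            raise SeedTreeError("duplicate edges")
        for e in self.edges:
            if not set(e) <= nodes or len(set(e)) != 2:
                raise SeedTreeError(f"bad edge {e!r}")
        if len(self.edges) != len(self.nodes) - 1:
            raise SeedTreeError("seed tree must have |V| - 1 edges")
        import networkx as nx

        g = nx.Graph(self.edges)
        g.add_nodes_from(self.nodes)
        if not nx.is_connected(g):
            raise SeedTreeError("seed tree must be connected")
        if not self.ring_nodes <= nodes:
            raise SeedTreeError("ring nodes must be tree nodes")
        for e in self.ring_edges:
            if e not in set(edge_sets) or not e <= self.ring_nodes:
                raise SeedTreeError(f"ring edge {set(e)!r} must join two ring nodes")

    def degree(self, u: str) -> int:
        return sum(1 for e in self.edges if u in e)

    def non_ring_edges(self) -> list[tuple[str, str]]:
        return [e for e in self.edges if frozenset(e) not in self.ring_edges]


#: a (lower, upper) bound pair; either side may be None for "unbounded".
BoundPair = tuple


@dataclass
class Bounds:
    """Table of lower/upper bounds on counts in the expanded graph."""

    n: BoundPair | None = None
    na_int: dict = field(default_factory=dict)   # element -> (lb, ub)
    na_ex: dict = field(default_factory=dict)
    na: dict = field(default_factory=dict)
    fc: dict = field(default_factory=dict)       # fringe code -> (lb, ub)
    ac_int: dict = field(default_factory=dict)   # AC tuple -> (lb, ub)
    ac_lf: dict = field(default_factory=dict)
    ec_int: dict = field(default_factory=dict)   # EC tuple -> (lb, ub)

    def validate(self) -> None:
        def check(label, pair):
            lb, ub = pair
            if lb is not None and ub is not None and lb > ub:
                raise SeedTreeError(f"contradictory bounds for {label}: LB {lb} > UB {ub}")

        if self.n is not None:
            check("n", self.n)
        for attr in ("na_int", "na_ex", "na", "fc", "ac_int", "ac_lf", "ec_int"):
            for key, pair in getattr(self, attr).items():
                check(f"{attr}({key})", pair)


@dataclass
class Specification:
    """Availability sets and bounds constraining the expanded graph."""

    element_set: list[str]
    cc_sets: dict = field(default_factory=dict)      # ring node -> [CC tuple]
    fringe_sets: dict = field(default_factory=dict)  # node -> [FringeTree]
    bounds: Bounds = field(default_factory=Bounds)
    cc_params: CCParams = field(default_factory=CCParams)

    def validate_against(self, seed: SeedTree) -> None:
        self.bounds.validate()
        for u in seed.ring_nodes:
            xis = self.cc_sets.get(u, [])
            if not xis:
                raise SeedTreeError(f"ring node {u!r} has an empty CC set")
            for xi in xis:
                if not self.cc_params.c_min <= len(xi) <= self.cc_params.c_max:
                    raise SeedTreeError(
                        f"CC {tuple(xi)} at {u!r} has length outside "
                        f"[{self.cc_params.c_min}, {self.cc_params.c_max}]")
                if not is_canonical_cc(xi):
                    raise SeedTreeError(f"CC {tuple(xi)} at {u!r} is not canonical")
        for u in seed.nodes:
            if not self.fringe_sets.get(u):
                raise SeedTreeError(f"node {u!r} has an empty fringe-tree set")
        allowed = set(self.element_set)
        for u, fts in self.fringe_sets.items():
            for ft in fts:
                heavy = set(ft.element_counts(heavy_only=True))
                if not heavy <= allowed:
                    raise SeedTreeError(
                        f"fringe {ft.canonical_code!r} at {u!r} uses elements "
                        f"outside the alphabet: {sorted(heavy - allowed)}")


@dataclass
class InferenceTask:
    """Property constraint C1 over a trained hyperplane."""

    model: Hyperplane
    mode: str = "regression"          # or "classification"
    y_lb: float | None = None
    y_ub: float | None = None
    target_class: int | None = None   # 1 (>= theta) or 0 (<= theta)

    def __post_init__(self) -> None:
        if self.mode == "regression":
            if self.y_lb is None or self.y_ub is None:
                raise SeedTreeError("regression task needs y_lb and y_ub")
            if self.y_lb > self.y_ub:
                raise SeedTreeError(f"contradictory target interval: "
                                    f"[{self.y_lb}, {self.y_ub}]")
        elif self.mode == "classification":
            if self.target_class not in (0, 1):
                raise SeedTreeError("classification task needs target_class 0 or 1")
            if self.model.theta is None:
                raise SeedTreeError("classification task needs a model with theta")
        else:
            raise SeedTreeError(f"unknown task mode {self.mode!r}")


# ---------------------------------------------------------------------------
# JSON round trip
# ---------------------------------------------------------------------------

def load_seed_spec(path: str | Path) -> tuple[SeedTree, Specification]:
    """Read a seed tree + specification document (JSON)."""
    raw = json.loads(Path(path).read_text())
    seed = SeedTree(
        nodes=list(raw["nodes"]),
        edges=[tuple(e) for e in raw["edges"]],
        ring_nodes=set(raw.get("ring_nodes", [])),
        ring_edges={frozenset(e) for e in raw.get("ring_edges", [])},
    )
    b = raw.get("bounds", {})

    def pair(v):
        return (v[0], v[1])

    bounds = Bounds(
        n=pair(b["n"]) if "n" in b else None,
        na_int={k: pair(v) for k, v in b.get("na_int", {}).items()},
        na_ex={k: pair(v) for k, v in b.get("na_ex", {}).items()},
        na={k: pair(v) for k, v in b.get("na", {}).items()},
        fc={k: pair(v) for k, v in b.get("fc", {}).items()},
        ac_int={parse_ac_name(k): pair(v) for k, v in b.get("ac_int", {}).items()},
        ac_lf={parse_ac_name(k): pair(v) for k, v in b.get("ac_lf", {}).items()},
        ec_int={parse_ec_name(k): pair(v) for k, v in b.get("ec_int", {}).items()},
    )
    cc_params = CCParams(**raw.get("cc_params", {}))
    spec = Specification(
        element_set=list(raw["lambda"]),
        cc_sets={u: [tuple(x) for x in xs] for u, xs in raw.get("cc_sets", {}).items()},
        fringe_sets={u: [FringeTree.from_code(c) for c in codes]
                     for u, codes in raw.get("fringe_sets", {}).items()},
        bounds=bounds,
        cc_params=cc_params,
    )
    spec.validate_against(seed)
    return seed, spec
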