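"""Seed-tree expansion MILP: build, solve, decode, verify."""

import numpy as np
import pytest

from ccinfer.chemgraph import FringeTree, hydrogen_suppress, validate
from ccinfer.cycleconf import enumerate_chordless_cycles
from ccinfer.featurize import build_vocabulary
from ccinfer.fixtures import reference_molecule, reference_fringe
from ccinfer.learn import Hyperplane
from ccinfer.milp import build_milp, expand_ring_node, solve_and_decode
from ccinfer.seedtree import (
    Bounds,
    InferenceTask,
    SeedTree,
    SeedTreeError,
    Specification,
)

XI_BENZENE = (1, 1, 1, 1, 1, 1)
XI_META = (1, 1, 1, 2, 1, 2)


@pytest.fixture(scope="module")
def vocab():
    mols = [reference_molecule(n) for n in
            ("benzene", "catechol", "resorcinol", "hydroquinone")]
    return build_vocabulary(mols)


def _model(vocab, weights=None, b=0.0, theta=None):
    cols = vocab.columns("2L+CC")
    w = np.zeros(len(cols))
    for name, val in (weights or {}).items():
        w[cols.index(name)] = val
    return Hyperplane(cols, w, b, theta)


def _benzene_setup(vocab):
    seed = SeedTree(nodes=["u1"], edges=[], ring_nodes={"u1"}, ring_edges=set())
    spec = Specification(element_set=["C"], cc_sets={"u1": [XI_BENZENE]},
                         fringe_sets={"u1": [reference_fringe("psi1")]})
    return seed, spec


class TestExpandRingNode:
    def test_printed_mass_order_is_consistent_with_its_cc(self):
        fringes = [reference_fringe(n) for n in ("n", "ch2", "n", "n", "co", "ch3n")]
        # masses (14, 14, 14, 14, 28, 29) -> ranks (1,1,1,1,2,3)
        assert expand_ring_node((1, 1, 1, 1, 2, 3), fringes)

    def test_all_equal_masses(self):
        fringes = [reference_fringe("psi1")] * 6
        assert expand_ring_node(XI_BENZENE, fringes)

    def test_meta_ordering_is_not_the_para_cc(self):
        # heavy fringes at cyclic distance 2 -> meta pattern, never para
        f13, f29 = reference_fringe("psi1"), reference_fringe("psi2")
        fringes = [f13, f29, f13, f29, f13, f13]
        assert not expand_ring_node((1, 1, 2, 1, 1, 2), fringes)
        assert expand_ring_node(XI_META, fringes)

    def test_para_ordering_under_rotation_still_matches_para(self):
        # heavy fringes at cyclic distance 3 in any rotation -> para pattern
        f13, f29 = reference_fringe("psi1"), reference_fringe("psi2")
        fringes = [f13, f29, f13, f13, f29, f13]
        assert expand_ring_node((1, 1, 2, 1, 1, 2), fringes)
        assert not expand_ring_node(XI_META, fringes)


class TestBenzeneInstance:
    def test_solves_to_benzene_with_exact_roundtrip(self, vocab):
        seed, spec = _benzene_setup(vocab)
        task = InferenceTask(model=_model(vocab, {"n_heavy": 1.0}), mode="regression",
                             y_lb=0.0, y_ub=10.0)
        inst = build_milp(seed, spec, task, vocab)
        res = solve_and_decode(inst, time_limit=120)
        assert res.status == "optimal"
        assert validate(res.graph) == []
        assert res.graph.is_isomorphic_to(reference_molecule("benzene"))
        for name, mv in res.milp_feature_values.items():
            assert mv == pytest.approx(res.recomputed_feature_values[name], abs=1e-6)
        assert task.y_lb <= res.predicted_value <= task.y_ub

    def test_unattainable_interval_is_infeasible(self, vocab):
        seed, spec = _benzene_setup(vocab)
        task = InferenceTask(model=_model(vocab), mode="regression",
                             y_lb=5.0, y_ub=6.0)  # all-zero w, b = 0
        res = build_milp(seed, spec, task, vocab).solve(60)
        assert res.status == "infeasible"

    def test_contradictory_bounds_rejected_at_build_time(self, vocab):
        seed, spec = _benzene_setup(vocab)
        spec.bounds = Bounds(n=(10, 5))
        task = InferenceTask(model=_model(vocab), mode="regression", y_lb=0, y_ub=99)
        with pytest.raises(SeedTreeError, match="n"):
            build_milp(seed, spec, task, vocab)

    def test_contradictory_target_interval_rejected(self, vocab):
        with pytest.raises(SeedTreeError):
            InferenceTask(model=_model(vocab), mode="regression", y_lb=2.0, y_ub=1.0)


class TestStructuralLaws:
    def test_ring_edge_pair_shares_exactly_one_edge(self, vocab):
        seed = SeedTree(nodes=["u1", "u2"], edges=[("u1", "u2")],
                        ring_nodes={"u1", "u2"},
                        ring_edges={frozenset(("u1", "u2"))})
        F = [reference_fringe("psi1"), reference_fringe("psi2")]
        spec = Specification(element_set=["C", "O"],
                             cc_sets={u: [XI_BENZENE, XI_META] for u in seed.nodes},
                             fringe_sets={u: list(F) for u in seed.nodes})
        task = InferenceTask(model=_model(vocab, {"n_heavy": 1.0}), mode="regression",
                             y_lb=0, y_ub=99)
        res = build_milp(seed, spec, task, vocab).solve(120)
        assert res.status == "optimal"
        sup = hydrogen_suppress(res.graph)
        cycles = enumerate_chordless_cycles(sup)
        assert len(cycles) == 2

        def edges(c):
            return {frozenset((c[i], c[(i + 1) % len(c)])) for i in range(len(c))}

        assert len(edges(cycles[0]) & edges(cycles[1])) == 1

    def test_cycle_count_equals_ring_nodes_without_ring_edges(self, vocab):
        seed = SeedTree(nodes=["u1", "u2"], edges=[("u1", "u2")],
                        ring_nodes={"u1", "u2"}, ring_edges=set())
        F = [reference_fringe("psi1"), reference_fringe("psi2"), FringeTree.from_code("C")]
        spec = Specification(element_set=["C", "O"],
                             cc_sets={u: [XI_BENZENE, XI_META] for u in seed.nodes},
                             fringe_sets={u: list(F) for u in seed.nodes})
        task = InferenceTask(model=_model(vocab, {"n_heavy": 1.0}), mode="regression",
                             y_lb=0, y_ub=99)
        res = build_milp(seed, spec, task, vocab).solve(120)
        assert res.status == "optimal"
        sup = hydrogen_suppress(res.graph)
        assert len(enumerate_chordless_cycles(sup)) == 2

    def test_two_ring_edges_at_one_node_rejected(self, vocab):
        seed = SeedTree(nodes=["u1", "u2", "u3"], edges=[("u1", "u2"), ("u2", "u3")],
                        ring_nodes={"u1", "u2", "u3"},
                        ring_edges={frozenset(("u1", "u2")), frozenset(("u2", "u3"))})
        spec = Specification(element_set=["C"],
                             cc_sets={u: [XI_BENZENE] for u in seed.nodes},
                             fringe_sets={u: [reference_fringe("psi1")] for u in seed.nodes})
        task = InferenceTask(model=_model(vocab), mode="regression", y_lb=-9, y_ub=9)
        with pytest.raises(SeedTreeError, match="matching"):
            build_milp(seed, spec, task, vocab)


class TestBoundsAndCCSelection:
    def test_decoded_graph_satisfies_every_specification_bound(self, vocab):
        seed = SeedTree(nodes=["u1"], edges=[], ring_nodes={"u1"}, ring_edges=set())
        psi1, psi2 = reference_fringe("psi1"), reference_fringe("psi2")
        spec = Specification(
            element_set=["C", "O"],
            cc_sets={"u1": [XI_BENZENE, XI_META]},
            fringe_sets={"u1": [psi1, psi2]},
            bounds=Bounds(n=(7, 9),
                          na_ex={"O": (1, 3)},
                          fc={psi2.canonical_code: (1, 2)}),
        )
        task = InferenceTask(model=_model(vocab, {"n_heavy": 1.0}), mode="regression",
                             y_lb=0, y_ub=99)
        res = build_milp(seed, spec, task, vocab).solve(120)
        assert res.status == "optimal"
        sup = hydrogen_suppress(res.graph)
        assert 7 <= sup.n_atoms() <= 9
        n_oxygen = sum(1 for v in sup.atoms() if sup.element(v) == "O")
        assert 1 <= n_oxygen <= 3
        from ccinfer.twolayer import count_configs, decompose

        counts = count_configs(res.graph, decompose(res.graph))
        assert 1 <= counts["fringe"][psi2.canonical_code] <= 2

    def test_forced_meta_cc_is_realised(self, vocab):
        seed = SeedTree(nodes=["u1"], edges=[], ring_nodes={"u1"}, ring_edges=set())
        spec = Specification(element_set=["C", "O"], cc_sets={"u1": [XI_META]},
                             fringe_sets={"u1": [reference_fringe("psi1"),
                                                 reference_fringe("psi2")]})
        task = InferenceTask(model=_model(vocab, {"n_heavy": 1.0}), mode="regression",
                             y_lb=0, y_ub=99)
        res = build_milp(seed, spec, task, vocab).solve(120)
        assert res.status == "optimal"
        assert res.recomputed_feature_values["cc:1.1.1.2.1.2"] == 1
        assert res.graph.is_isomorphic_to(reference_molecule("resorcinol"))

    def test_tightened_bounds_solution_feasible_under_looser_spec(self, vocab):
        """Adding a bound can only shrink the feasible set."""
        seed = SeedTree(nodes=["u1"], edges=[], ring_nodes={"u1"}, ring_edges=set())
        base = dict(element_set=["C", "O"],
                    cc_sets={"u1": [XI_BENZENE, XI_META]},
                    fringe_sets={"u1": [reference_fringe("psi1"), reference_fringe("psi2")]})
        task = InferenceTask(model=_model(vocab, {"n_heavy": 1.0}), mode="regression",
                             y_lb=0, y_ub=99)
        tight = Specification(**base, bounds=Bounds(n=(8, 8)))
        res = build_milp(seed, tight, task, vocab).solve(120)
        assert res.status == "optimal"
        # the decoded graph satisfies the original (bound-free) specification:
        # same alphabet, its CC is available, its fringe trees are available
        assert validate(res.graph) == []
        sup = hydrogen_suppress(res.graph)
        assert {sup.element(v) for v in sup.atoms()} <= {"C", "O"}


class TestClassificationConstraint:
    def test_positive_class_forces_score_above_theta(self, vocab):
        seed, spec = _benzene_setup(vocab)
        model = _model(vocab, {"n_heavy": 1.0}, b=-5.0, theta=0.5)
        task = InferenceTask(model=model, mode="classification", target_class=1)
        res = build_milp(seed, spec, task, vocab).solve(60)
        assert res.status == "optimal"
        assert res.predicted_value >= 0.5

    def test_negative_class_infeasible_when_score_is_forced_high(self, vocab):
        seed, spec = _benzene_setup(vocab)
        # benzene instance always scores 6 - 5 = 1 > theta
        model = _model(vocab, {"n_heavy": 1.0}, b=-5.0, theta=0.5)
        task = InferenceTask(model=model, mode="classification", target_class=0)
        res = build_milp(seed, spec, task, vocab).solve(60)
        assert res.status == "infeasible"


class TestWholePipelineSmoke:
    def test_featurize_train_invert_roundtrip(self):
        """Trained hyperplane inverted over a one-ring seed tree stays in bounds."""
        from ccinfer.featurize import featurize_dataset
        from ccinfer.fixtures import RandomGraphParams, generate_random
        from ccinfer.learn import train
        from ccinfer.twolayer import default_static_names

        mols = [reference_molecule(n) for n in
                ("benzene", "catechol", "resorcinol", "hydroquinone")]
        mols += [generate_random(RandomGraphParams(seed=s, elements=("C", "O")))
                 for s in range(8)]
        statics = [n for n in default_static_names(["C", "O"]) if n != "avg_mass"]
        vocab = build_vocabulary(mols, static_names=statics)
        X = featurize_dataset(mols, vocab, "2L+CC")
        y = 2.0 * X["n_heavy"].to_numpy() + 3.0
        plane = train(X, y, "llr", "regression",
                      hyperparams={"alphas": [1e-8]}).hyperplane

        seed = SeedTree(nodes=["u1"], edges=[], ring_nodes={"u1"}, ring_edges=set())
        spec = Specification(element_set=["C", "O"],
                             cc_sets={"u1": [(1, 1, 1, 1, 1, 1), XI_META]},
                             fringe_sets={"u1": [reference_fringe("psi1"),
                                                 reference_fringe("psi2")]})
        target = float(plane.score(X.loc[[2]])[0])  # resorcinol's own score
        task = InferenceTask(model=plane, mode="regression",
                             y_lb=target - 0.5, y_ub=target + 0.5)
        res = build_milp(seed, spec, task, vocab).solve(time_limit=300)
        assert res.status == "optimal"
        assert validate(res.graph) == []
        assert task.y_lb <= res.predicted_value <= task.y_ub
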