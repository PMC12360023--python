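"""Interior/exterior decomposition and 2L configuration counts."""

from collections import Counter

import pytest

from ccinfer.chemgraph import ChemGraphError, ChemicalGraph
from ccinfer.fixtures import complete_hydrogens, reference_molecule
from ccinfer.twolayer import (
    count_configs,
    decompose,
    edge_configuration,
    heights_by_leaf_deletion,
    static_descriptors,
)


def _carbon_path(n):
    g = ChemicalGraph()
    for i in range(n):
        g.add_atom(i, "C")
    for i in range(n - 1):
        g.add_bond(i, i + 1, 1)
    return g


class TestHeights:
    def test_path_of_five(self):
        ht = heights_by_leaf_deletion(_carbon_path(5))
        assert ht == {0: 0, 4: 0, 1: 1, 3: 1}  # centre never becomes a leaf

    def test_catechol_ring_survives(self, isomers):
        from ccinfer.chemgraph import hydrogen_suppress

        sup = hydrogen_suppress(isomers["catechol"])
        ht = heights_by_leaf_deletion(sup)
        oxygens = [v for v in sup.atoms() if sup.element(v) == "O"]
        assert all(ht[o] == 0 for o in oxygens)
        carbons = [v for v in sup.atoms() if sup.element(v) == "C"]
        assert all(c not in ht for c in carbons)

    def test_bare_cycle_has_no_heights(self, benzene):
        from ccinfer.chemgraph import hydrogen_suppress

        assert heights_by_leaf_deletion(hydrogen_suppress(benzene)) == {}


class TestDecompose:
    def test_resorcinol_partition_and_fringe_counts(self, isomers, psi1, psi2):
        d = decompose(isomers["resorcinol"])
        assert len(d.interior_vertices) == 6
        assert len(d.exterior_vertices) == 2
        codes = Counter(ft.canonical_code for ft in d.fringe.values())
        assert codes == {psi1.canonical_code: 4, psi2.canonical_code: 2}

    def test_benzene_all_fringe_trees_are_ch(self, benzene, psi1):
        d = decompose(benzene)
        assert len(d.interior_vertices) == 6
        assert all(ft.canonical_code == psi1.canonical_code
                   for ft in d.fringe.values())

    def test_rho_one_keeps_oxygens_exterior(self, isomers):
        d = decompose(isomers["resorcinol"], rho=1)
        sup = d.suppressed
        assert all(sup.element(v) == "O" for v in d.exterior_vertices)

    def test_fringe_heavy_sizes_partition_suppressed_graph(self, isomers):
        for mol in isomers.values():
            d = decompose(mol)
            assert sum(ft.heavy_size() for ft in d.fringe.values()) == d.suppressed.n_atoms()

    def test_relabeling_invariance(self, isomers):
        mol = isomers["hydroquinone"]
        mapping = {v: f"q{i}" for i, v in enumerate(mol.atoms())}
        d1 = decompose(mol)
        d2 = decompose(mol.relabel(mapping))
        assert {mapping[v] for v in d1.interior_vertices} == d2.interior_vertices
        c1 = Counter(ft.canonical_code for ft in d1.fringe.values())
        c2 = Counter(ft.canonical_code for ft in d2.fringe.values())
        assert c1 == c2


class TestEdgeConfigs:
    def test_resorcinol_double_bond_edge_is_c2_c3_2(self, isomers):
        mol = isomers["resorcinol"]
        d = decompose(mol)
        ecs = Counter(edge_configuration(e, mol, d) for e in d.interior_edges)
        assert ecs[(("C", 2), ("C", 3), 2)] == 2

    def test_catechol_ec_multiset(self, isomers):
        mol = isomers["catechol"]
        counts = count_configs(mol, decompose(mol))
        assert counts["ec"] == {
            (("C", 2), ("C", 2), 1): 1,
            (("C", 2), ("C", 2), 2): 2,
            (("C", 2), ("C", 3), 1): 2,
            (("C", 3), ("C", 3), 2): 1,
        }

    def test_resorcinol_ec_multiset(self, isomers):
        mol = isomers["resorcinol"]
        counts = count_configs(mol, decompose(mol))
        assert counts["ec"] == {
            (("C", 2), ("C", 2), 1): 1,
            (("C", 2), ("C", 2), 2): 1,
            (("C", 2), ("C", 3), 1): 2,
            (("C", 2), ("C", 3), 2): 2,
        }

    def test_non_interior_edge_rejected(self, isomers):
        mol = isomers["resorcinol"]
        d = decompose(mol)
        ext_edge = next(iter(d.exterior_edges))
        with pytest.raises(ChemGraphError):
            edge_configuration(tuple(ext_edge), mol, d)

    def test_counts_conserve_interior_sizes(self, isomers):
        for mol in isomers.values():
            d = decompose(mol)
            counts = count_configs(mol, d)
            assert sum(counts["fringe"].values()) == len(d.interior_vertices)
            assert sum(counts["ec"].values()) == len(d.interior_edges)
            assert sum(counts["ac"].values()) == len(d.interior_edges)


class TestStaticDescriptors:
    def test_resorcinol_values(self, isomers):
        mol = isomers["resorcinol"]
        d = decompose(mol)
        vec = static_descriptors(mol, d, ["n_heavy", "n_interior", "deg_int_2",
                                          "deg_int_3", "bond_int_2", "na_ex_O"])
        assert vec == [8.0, 6.0, 4.0, 2.0, 3.0, 2.0]

    def test_empty_request_gives_empty_vector(self, benzene):
        assert static_descriptors(benzene, decompose(benzene), []) == []

    def test_unknown_name_rejected(self, benzene):
        with pytest.raises(KeyError):
            static_descriptors(benzene, decompose(benzene), ["nope"])

    def test_acyclic_single_interior_vertex_has_no_interior_edges(self):
        # pentane: only the centre carbon survives two rounds of leaf deletion
        mol = complete_hydrogens(_carbon_path(5))
        d = decompose(mol)
        assert d.interior_vertices == {2}
        assert d.interior_edges == set()
        counts = count_configs(mol, d)
        assert counts["ec"] == {}
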