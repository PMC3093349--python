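"""Structural CRNT computations checked against hand-derived oracles."""

import numpy as np
import pytest

from grnswitch import crn as C
from grnswitch import grammar as G

RUDIMENTARY = """
# basal production and degradation only
X1 -> X1 + P1
X2 -> X2 + P2
P1 -> 0
P2 -> 0
"""


@pytest.fixture
def rudimentary():
    return C.read_network(RUDIMENTARY)


def net_from(text):
    return C.read_network(text)


class TestComplexesAndLinkage:
    def test_rudimentary_complexes(self, rudimentary):
        got = {C.format_complex(c) for c in C.complexes(rudimentary)}
        assert got == {"X1", "P1 + X1", "X2", "P2 + X2", "P1", "P2", "0"}

    def test_single_reaction(self):
        assert len(C.complexes(net_from("A -> B"))) == 2

    def test_kqw_complexes(self):
        net = G.circuit_to_crn(G.circuit("kqw"))
        assert len(C.complexes(net)) == 12

    def test_rudimentary_linkage_classes(self, rudimentary):
        classes = [{C.format_complex(c) for c in cls}
                   for cls in C.linkage_classes(rudimentary)]
        # the zero complex joins both degradations into one class
        expected = [{"X1", "P1 + X1"}, {"X2", "P2 + X2"}, {"P1", "0", "P2"}]
        assert len(classes) == 3
        for cls in expected:
            assert cls in classes

    def test_chain_is_one_class(self):
        assert len(C.linkage_classes(net_from("A -> B\nB -> C"))) == 1

    def test_kqw_linkage_classes(self):
        net = G.circuit_to_crn(G.circuit("kqw"))
        assert len(C.linkage_classes(net)) == 5


class TestRankAndDeficiency:
    def test_rudimentary_rank(self, rudimentary):
        assert C.network_rank(rudimentary) == 2

    def test_reversible_pair_rank_one(self):
        assert C.network_rank(net_from("A <-> B")) == 1

    def test_kqw_rank(self):
        # 6 species minus two conservation laws (X1; X2 + X2P2P2)
        assert C.network_rank(G.circuit_to_crn(G.circuit("kqw"))) == 4

    @pytest.mark.parametrize("text, expected", [
        (RUDIMENTARY, (7, 3, 2, 2)),
        ("A <-> B", (2, 1, 1, 0)),
    ])
    def test_summary(self, text, expected):
        s = C.deficiency(net_from(text))
        assert (s.n_complexes, s.n_linkage_classes, s.rank,
                s.deficiency) == expected

    def test_kqw_summary(self):
        s = C.deficiency(G.circuit_to_crn(G.circuit("kqw")))
        assert (s.n_complexes, s.n_linkage_classes, s.rank,
                s.deficiency) == (12, 5, 4, 3)

    def test_exact_rank_matches_svd_oracle(self):
        """Exact integer rank equals floating-point SVD rank on random
        small stoichiometries."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_sp = rng.integers(2, 7)
            n_rx = rng.integers(1, 9)
            mat = rng.integers(-3, 4, size=(n_rx, n_sp))
            got = C._int_rank([tuple(r) for r in mat.tolist()])
            assert got == np.linalg.matrix_rank(mat.astype(float))


class TestSubspace:
    def test_reversible_pair_basis(self):
        basis = C.stoich_subspace(net_from("A <-> B"))
        assert basis.dimension == 1
        assert [float(v) for v in basis.basis[0]] == [1.0, -1.0]

    def test_rudimentary_spans_monomers(self, rudimentary):
        basis = C.stoich_subspace(rudimentary)
        rows = {tuple(float(v) for v in row) for row in basis.basis}
        i_p1 = rudimentary.species_names.index("P1")
        i_p2 = rudimentary.species_names.index("P2")
        e1 = [0.0] * 4; e1[i_p1] = 1.0
        e2 = [0.0] * 4; e2[i_p2] = 1.0
        assert rows == {tuple(e1), tuple(e2)}

    def test_bound_production_leaves_basis_identical(self):
        base = net_from("X1 + P1 <-> X1P1\nP1 -> 0")
        extended = net_from("X1 + P1 <-> X1P1\nP1 -> 0\nX1P1 -> X1P1 + P1")
        order = tuple(sorted(set(base.species_names)
                             | set(extended.species_names)))
        assert (C.stoich_subspace(base, order).basis
                == C.stoich_subspace(extended, order).basis)

    def test_same_subspace_reflexive(self):
        net = G.circuit_to_crn(G.circuit("ckn"))
        assert C.same_subspace(net, net)

    def test_production_addition_preserves(self):
        # the vector of g is +e_P2, already in the span via P2 -> 0
        a = G.circuit_to_crn(G.circuit("ckn"))
        b = G.circuit_to_crn(G.circuit("ckng"))
        assert C.same_subspace(a, b)

    def test_new_species_direction_breaks(self):
        a = G.circuit_to_crn(G.circuit("ckn"))
        b = G.circuit_to_crn(G.circuit("cknq"))
        assert not C.same_subspace(a, b)

    def test_equivalence_relation_on_random_circuits(self, family):
        """same_subspace is reflexive, symmetric and transitive."""
        rng = np.random.default_rng(7)
        picks = rng.choice(len(family), size=30)
        nets = [G.circuit_to_crn(family[i]) for i in picks]
        for i in range(0, 30, 3):
            a, b, c = nets[i], nets[i + 1], nets[i + 2]
            assert C.same_subspace(a, a)
            assert C.same_subspace(a, b) == C.same_subspace(b, a)
            if C.same_subspace(a, b) and C.same_subspace(b, c):
                assert C.same_subspace(a, c)


class TestConservationLaws:
    def test_reversible_pair(self):
        laws = C.conservation_laws(net_from("A <-> B"))
        assert [[float(v) for v in row] for row in laws.laws] == [[1.0, 1.0]]

    def test_rudimentary_gene_totals(self, rudimentary):
        laws = C.conservation_laws(rudimentary)
        rows = {tuple(float(v) for v in r) for r in laws.laws}
        names = rudimentary.species_names
        def law(*species):
            v = [0.0] * len(names)
            for s in species:
                v[names.index(s)] = 1.0
            return tuple(v)
        assert rows == {law("X1"), law("X2")}

    def test_bcdh_laws(self):
        net = G.circuit_to_crn(G.circuit("bcdh"))
        laws = C.conservation_laws(net)
        names = net.species_names
        def law(*species):
            v = [0.0] * len(names)
            for s in species:
                v[names.index(s)] = 1.0
            return tuple(v)
        rows = {tuple(float(v) for v in r) for r in laws.laws}
        assert rows == {law("X1", "X1P2"), law("X2", "X2P1", "X2P2")}

    def test_rows_annihilate_stoichiometry(self, family):
        rng = np.random.default_rng(11)
        for i in rng.choice(len(family), size=25):
            net = G.circuit_to_crn(family[i])
            laws = C.conservation_laws(net)
            smat = net.stoichiometry_matrix()
            assert len(laws.laws) == len(net.species) - C.network_rank(net)
            for row in laws.laws:
                for col in smat.T:
                    assert sum(f * int(v) for f, v in zip(row, col)) == 0


class TestMassAction:
    def test_linear_chain_derivative(self):
        net = net_from("A -> B")
        f, _ = C.mass_action_system(net, {"k1": 2.5})
        np.testing.assert_allclose(f(np.array([2.0, 0.0])), [-5.0, 5.0])

    def test_rudimentary_equilibrium_closed_form(self, rudimentary):
        f, _ = C.mass_action_system(
            rudimentary, {f"k{i}": 1.0 for i in range(1, 5)})
        x = np.array([1.0, 1.0, 1.0, 1.0])  # X1, X2 totals 1 -> P* = 1
        np.testing.assert_allclose(f(x), 0.0, atol=1e-14)

    def test_missing_rate_raises(self, rudimentary):
        with pytest.raises(ValueError, match="missing rate"):
            C.mass_action_system(rudimentary, {"k1": 1.0})

    def test_nonpositive_rate_raises(self, rudimentary):
        rates = {f"k{i}": 1.0 for i in range(1, 5)}
        rates["k2"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            C.mass_action_system(rudimentary, rates)

    def test_jacobian_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        for name in ["bcdh", "kqw", "jmpsv", ""]:
            circ = G.circuit(name)
            net = G.circuit_to_crn(circ)
            rates = {r.rate_symbol: 10.0 ** rng.uniform(-1, 1)
                     for r in net.reactions}
            f, jac = C.mass_action_system(net, rates)
            for _ in range(3):
                x = rng.uniform(0.05, 2.0, len(net.species))
                jnum = np.empty((len(x), len(x)))
                h = 1e-6
                for j in range(len(x)):
                    e = np.zeros_like(x); e[j] = h
                    jnum[:, j] = (f(x + e) - f(x - e)) / (2 * h)
                scale = max(1.0, np.max(np.abs(jnum)))
                assert np.max(np.abs(jac(x) - jnum)) / scale < 1e-6

    def test_derivative_respects_conservation(self):
        """Conservation-law rows annihilate the time derivative for any
        state and rates (bcdh)."""
        circ = G.circuit("bcdh")
        net = G.circuit_to_crn(circ)
        laws = C.conservation_laws(net)
        rng = np.random.default_rng(5)
        rates = {r.rate_symbol: 10.0 ** rng.uniform(-2, 2)
                 for r in net.reactions}
        f, _ = C.mass_action_system(net, rates)
        for _ in range(5):
            x = rng.uniform(0.0, 3.0, len(net.species))
            np.testing.assert_allclose(laws.matrix() @ f(x), 0.0, atol=1e-10)


class TestStructuralScreen:
    def test_deficiency_zero_weakly_reversible(self):
        assert (C.structural_screen(net_from("A <-> B"))
                is C.ScreenVerdict.NO_MULTISTATIONARITY)

    def test_deficiency_zero_irreversible(self):
        # no positive steady state at all, hence no multistationarity
        assert (C.structural_screen(net_from("A -> B"))
                is C.ScreenVerdict.NO_MULTISTATIONARITY)

    def test_rudimentary_inconclusive(self, rudimentary):
        assert (C.structural_screen(rudimentary)
                is C.ScreenVerdict.INCONCLUSIVE)

    def test_family_sample_inconclusive(self, family):
        """Every two-gene circuit has deficiency >= 2, so the deficiency
        theorems never apply."""
        rng = np.random.default_rng(13)
        for i in rng.choice(len(family), size=20):
            net = G.circuit_to_crn(family[i])
            assert C.structural_screen(net) is C.ScreenVerdict.INCONCLUSIVE


class TestValidationAndFormat:
    def test_duplicate_species_rejected(self):
        with pytest.raises(ValueError, match="duplicate species"):
            C.ReactionNetwork([C.Species("A"), C.Species("A")], [])

    def test_undeclared_species_rejected(self):
        rxn = C.Reaction(C.Complex({"A": 1}), C.Complex({"B": 1}), "k")
        with pytest.raises(ValueError, match="undeclared"):
            C.ReactionNetwork([C.Species("A")], [rxn])

    def test_self_reaction_rejected(self):
        with pytest.raises(ValueError, match="must differ"):
            C.Reaction(C.Complex({"A": 1}), C.Complex({"A": 1}), "k")

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            C.Complex({"A": -1})

    def test_duplicate_reaction_rejected(self):
        rxn = C.Reaction(C.Complex({"A": 1}), C.Complex({"B": 1}), "k")
        rxn2 = C.Reaction(C.Complex({"A": 1}), C.Complex({"B": 1}), "k2")
        with pytest.raises(ValueError, match="duplicate reaction"):
            C.ReactionNetwork([C.Species("A"), C.Species("B")], [rxn, rxn2])

    @pytest.mark.parametrize("text", [
        "A -> B\nB -> 0\n",
        "X1 + P1 <-> X1P1\nP1 -> 0\n",
        "2A <-> A2\n0 -> A\n",
    ])
    def test_round_trip(self, text):
        net = C.read_network(text)
        again = C.read_network(C.write_network(net))
        assert C.write_network(again) == C.write_network(net)
        assert set(again.species_names) == set(net.species_names)
        assert len(again.reactions) == len(net.reactions)
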