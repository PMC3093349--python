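"""Numerical bistability oracle: sampling, equilibria, certificates."""

import numpy as np
import pytest

from grnswitch import crn as C
from grnswitch import grammar as G
from grnswitch import oracle as O


class TestSampleRates:
    def test_deterministic(self):
        circ = G.circuit("bcdh")
        assert O.sample_rates(circ, 5) == O.sample_rates(circ, 5)

    def test_within_range(self):
        circ = G.circuit("jmpsv")
        for seed in range(20):
            for scheme in ("log-uniform", "guided"):
                rates = O.sample_rates(circ, seed, scheme=scheme)
                assert all(1e-3 <= v <= 1e3 for v in rates.values())

    def test_distinct_seeds_distinct_draws(self):
        circ = G.circuit("kqw")
        draws = {tuple(sorted(O.sample_rates(circ, s).items()))
                 for s in range(100)}
        assert len(draws) == 100

    def test_covers_all_symbols(self):
        circ = G.circuit("ckn")
        rates = O.sample_rates(circ, 0)
        needed = {r.rate_symbol for r in G.circuit_to_crn(circ).reactions}
        assert set(rates) == needed

    def test_unknown_scheme(self):
        with pytest.raises(ValueError):
            O.sample_rates(G.circuit(""), 0, scheme="bogus")


class TestEquilibria:
    def test_rudimentary_closed_form(self):
        """The linear rudimentary circuit has the unique stable
        equilibrium P_i* = basal_i / degradation_i (gene totals one)."""
        circ = G.circuit("")
        rates = {"k_B1": 2.0, "k_B2": 0.5, "k_D1": 4.0, "k_D2": 0.25}
        eqs = O.circuit_equilibria(circ, rates)
        assert len(eqs) == 1
        eq = eqs[0]
        assert eq.stability is O.Stability.STABLE
        names = G.circuit_to_crn(circ).species_names
        state = dict(zip(names, eq.state))
        assert state["P1"] == pytest.approx(0.5, rel=1e-8)
        assert state["P2"] == pytest.approx(2.0, rel=1e-8)
        assert state["X1"] == pytest.approx(1.0)

    def test_residual_postcondition(self):
        circ = G.circuit("bcdh")
        for seed in range(5):
            rates = O.sample_rates(circ, seed, scheme="guided")
            for eq in O.circuit_equilibria(circ, rates):
                assert eq.residual < O.RESIDUAL_TOL

    def test_general_solver_matches_reduced(self):
        """The generic multistart solver finds the same equilibrium as
        the reduced-manifold solver on the rudimentary network."""
        circ = G.circuit("")
        net = G.circuit_to_crn(circ)
        rates = {"k_B1": 2.0, "k_B2": 0.5, "k_D1": 4.0, "k_D2": 0.25}
        totals = O.default_totals(circ)
        eqs = O.find_equilibria(net, rates, totals, n_starts=8, rng_seed=0)
        assert len(eqs) == 1
        ref = O.circuit_equilibria(circ, rates)[0]
        np.testing.assert_allclose(eqs[0].state, ref.state, atol=1e-7)

    def test_find_equilibria_totals_mismatch(self):
        net = G.circuit_to_crn(G.circuit(""))
        with pytest.raises(ValueError, match="totals"):
            O.find_equilibria(net, {"k_B1": 1, "k_B2": 1, "k_D1": 1,
                                    "k_D2": 1}, [1.0], n_starts=2)


class TestIsBistable:
    def test_rudimentary_never_certifies(self):
        assert O.is_bistable(G.circuit(""), budget=25, rng_seed=0) is None

    def test_deterministic(self):
        cert1 = O.is_bistable(G.circuit("bcdh"), budget=400, rng_seed=1)
        cert2 = O.is_bistable(G.circuit("bcdh"), budget=400, rng_seed=1)
        assert cert1 is not None and cert2 is not None
        assert cert1.rates == cert2.rates
        np.testing.assert_array_equal(cert1.stable[0].state,
                                      cert2.stable[0].state)

    def test_certificate_structure(self, certificates):
        cert = certificates("ckn")
        assert cert is not None
        assert len(cert.stable) == 2
        lo, hi = cert.stable
        scale = max(np.max(np.abs(lo.state)), np.max(np.abs(hi.state)))
        assert np.max(np.abs(lo.state - hi.state)) > O.DEDUP_TOL * scale
        for eq in cert.stable:
            assert np.min(eq.state) > O.POSITIVITY_TOL
            assert eq.leading_real < -O.STABILITY_TOL
        totals = np.asarray(cert.totals)
        net = G.circuit_to_crn(G.circuit("ckn"))
        laws = C.conservation_laws(net)
        for eq in cert.equilibria:
            np.testing.assert_allclose(laws.totals(eq.state), totals,
                                       atol=1e-8)

    def test_certificate_validates_by_integration(self, certificates):
        for name in ("bcdh", "kqw"):
            cert = certificates(name)
            assert cert is not None
            assert O.validate_certificate(cert, rng_seed=0)

    def test_certificate_round_trips_json(self, certificates):
        cert = certificates("bcdh")
        again = O.BistabilityCertificate.from_json(cert.to_json())
        assert again.rates == cert.rates
        np.testing.assert_array_equal(again.stable[1].state,
                                      cert.stable[1].state)

    def test_invalid_budget(self):
        with pytest.raises(ValueError):
            O.is_bistable(G.circuit(""), budget=0)


class TestGrowth:
    def test_noop_returns_parent(self, certificates):
        cert = certificates("ckn")
        assert O.grow_certificate(cert, G.circuit("ckn")) is cert

    def test_ckn_grows_by_g(self, certificates):
        grown = O.grow_certificate(certificates("ckn"), G.circuit("ckng"))
        assert grown is not None
        assert grown.circuit == G.circuit("ckng").name
        assert len(grown.stable) == 2
        assert O.validate_certificate(grown, rng_seed=0)

    def test_warm_start_shortcut(self, certificates):
        cert = O.is_bistable(G.circuit("ckng"), budget=1, rng_seed=10**6,
                             warm_start=certificates("ckn"))
        assert cert is not None and cert.circuit == G.circuit("ckng").name

    def test_mismatched_child_raises(self, certificates):
        with pytest.raises(ValueError):
            O.grow_certificate(certificates("ckn"), G.circuit("kqw"))

    def test_warm_started_growth_along_preserving_edges(self, certificates):
        """After a subspace-preserving addition with a small new rate the
        parent's two stable states persist (continuity)."""
        from grnswitch import ancestry as A
        n_checked = 0
        for name in ("ckn", "bcdh", "abejp"):
            parent_cert = certificates(name)
            parent = G.circuit(name)
            for label, child in A.one_reaction_extensions(parent):
                if not A.subspace_preserving(parent, label):
                    continue
                grown = O.grow_certificate(parent_cert, child, label)
                assert grown is not None, (name, label)
                n_checked += 1
        assert n_checked >= 5


class TestBifurcation:
    def test_rudimentary_single_branch(self):
        circ = G.circuit("")
        rates = {"k_B1": 1.0, "k_B2": 1.0, "k_D1": 1.0, "k_D2": 1.0}
        grid = np.geomspace(0.1, 10.0, 9)
        branch = O.bifurcation_scan(circ, rates, "k_D1", grid)
        assert branch.folds == []
        names = G.circuit_to_crn(circ).species_names
        i_p1 = names.index("P1")
        for value, eqs in zip(branch.grid, branch.points):
            assert len(eqs) == 1
            assert eqs[0].stability is O.Stability.STABLE
            assert eqs[0].state[i_p1] == pytest.approx(1.0 / value, rel=1e-6)

    def test_bcdh_fold_bounded_bistable_window(self, certificates):
        """Sweeping the P2 degradation rate around a certificate shows a
        bistable interval (two stable + one unstable branch) bounded by
        two folds."""
        cert = certificates("bcdh")
        base = cert.rates["k_D2"]
        grid = np.geomspace(base / 30, base * 30, 31)
        branch = O.bifurcation_scan(G.circuit("bcdh"), cert.rates,
                                    "k_D2", grid)
        counts = branch.stable_counts()
        assert max(counts) == 2
        assert len(branch.folds) == 2
        window = [i for i, c in enumerate(counts) if c == 2]
        assert window == list(range(window[0], window[-1] + 1))
        for i in window:
            stabs = [e.stability for e in branch.points[i]]
            assert stabs.count(O.Stability.UNSTABLE) == 1
        for eqs in branch.points:
            for eq in eqs:
                assert eq.residual < O.RESIDUAL_TOL

    def test_unknown_parameter(self):
        with pytest.raises(KeyError):
            O.bifurcation_scan(G.circuit(""), {"k_B1": 1.0}, "k_zz", [1.0])
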