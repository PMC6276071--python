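"""Network data model, steady-state solvers, cycles, tracer expansion."""

import numpy as np
import pytest

from portersim import (
    CarrierParams,
    ConfigurationError,
    NetworkModel,
    StructuralError,
    build_asymmetric_carrier,
    build_multisite_chain,
    build_symmetric_carrier,
    check_detailed_balance,
    enumerate_cycles,
    expand_tracer,
    integrate_time_course,
    random_balanced_carrier,
    solve_steady_state,
    unidirectional_flux,
)
from portersim.models import build_branched_multisite
from portersim.network import FINITE

from conftest import oracle_carrier_occupancies


def random_conformational_network(rng, n_states=6, extra_edges=3):
    """A random connected single-group network of first-order steps."""
    m = NetworkModel()
    m.add_species("glucose")
    m.add_compartment("out", conc={"glucose": 1.0})
    m.add_compartment("in", conc={"glucose": 1.0})
    ids = [f"s{i}" for i in range(n_states)]
    for i in ids:
        m.add_state(i, group="carrier")
    edges = set()
    for i in range(1, n_states):  # spanning tree
        j = rng.integers(0, i)
        edges.add((int(j), i))
    while len(edges) < n_states - 1 + extra_edges:
        i, j = sorted(rng.choice(n_states, size=2, replace=False))
        edges.add((int(i), int(j)))
    for k, (i, j) in enumerate(sorted(edges)):
        m.add_conformational(ids[i], ids[j],
                             float(10 ** rng.uniform(-1, 2)),
                             float(10 ** rng.uniform(-1, 2)), name=f"e{k}")
    return m


class TestSteadyState:
    def test_symmetric_mirror(self, sym_model):
        """Equal baths on a symmetric carrier give mirror occupancies."""
        ss = solve_steady_state(sym_model, {"out": 3.0, "in": 3.0})
        assert ss.occupancy["C_out"] == pytest.approx(ss.occupancy["C_in"], rel=1e-10)
        assert ss.occupancy["GC_out"] == pytest.approx(ss.occupancy["GC_in"], rel=1e-10)

    def test_asymmetric_vacant_site_distribution(self, asym_model):
        """A tenfold affinity asymmetry forces C_in/C_out = 10 at equal
        baths (the vacant-site distribution of the closed cycle)."""
        ss = solve_steady_state(asym_model, {"out": 3.0, "in": 3.0})
        assert ss.occupancy["C_in"] / ss.occupancy["C_out"] == pytest.approx(10.0, rel=1e-8)

    def test_conservation(self, asym_model):
        ss = solve_steady_state(asym_model, {"out": 7.0, "in": 1.0})
        assert sum(ss.occupancy.values()) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_network_matches_long_ode(self, seed):
        """Direct linear solve agrees with brute-force ODE integration
        to long times on random 6-state networks."""
        rng = np.random.default_rng(seed)
        m = random_conformational_network(rng)
        ss = solve_steady_state(m)
        tc = integrate_time_course(m, np.linspace(0.0, 2000.0, 5),
                                   rtol=1e-11, atol=1e-13)
        for s in m.states:
            assert tc.occupancy[s][-1] == pytest.approx(ss.occupancy[s],
                                                        rel=1e-8, abs=1e-10)

    def test_linear_vs_ode_cross_check(self, asym_model):
        solve_steady_state(asym_model, {"out": 10.0, "in": 2.0}, cross_check=True)

    def test_matches_independent_oracle(self):
        """Package steady state equals a hand-assembled rate-matrix
        solve for the 4-state carrier."""
        p = CarrierParams(kd_out=2.0, kd_in=17.0, b_out_in=0.7, b_in_out=None,
                          f_out_in=4.0, f_in_out=9.0, k_on=500.0, auto_close=True)
        model = build_asymmetric_carrier(p)
        ss = solve_steady_state(model, {"out": 5.0, "in": 1.0})
        expected = oracle_carrier_occupancies(p, 5.0, 1.0)
        got = [ss.occupancy[s] for s in ("C_out", "GC_out", "GC_in", "C_in")]
        assert got == pytest.approx(list(expected), rel=1e-10)

    def test_detailed_balanced_equal_baths_has_zero_net_fluxes(self):
        """Every elementary step of a detailed-balanced model carries
        zero net flux at equal baths."""
        for model in (build_symmetric_carrier(), build_asymmetric_carrier(),
                      build_multisite_chain()):
            ss = solve_steady_state(model, {"out": 5.0, "in": 5.0})
            for fwd, rev in ss.model.reversible_pairs():
                one_way = max(ss.flux[fwd.name], ss.flux[rev.name])
                if one_way > 0:
                    assert abs(ss.net_flux(fwd.name)) <= 1e-9 * one_way

    def test_disconnected_graph_rejected(self):
        m = NetworkModel()
        m.add_species("glucose")
        m.add_state("a", group="carrier")
        m.add_state("b", group="carrier")
        with pytest.raises(StructuralError, match="not connected"):
            m.validate()


class TestCycles:
    def test_single_cycle_carrier(self, asym_model):
        cycles = enumerate_cycles(asym_model)
        assert len(cycles) == 1
        assert len(cycles[0]) == 4

    def test_acyclic_network_has_empty_basis(self):
        rng = np.random.default_rng(0)
        m = random_conformational_network(rng, n_states=5, extra_edges=0)
        assert enumerate_cycles(m) == []

    def test_basis_size_follows_euler_formula(self):
        for model in (build_multisite_chain(), build_branched_multisite(),
                      build_branched_multisite(True)):
            pairs = model.reversible_pairs()
            nodes = set()
            for fwd, _ in pairs:
                if fwd.kind == "void_diffusion":
                    nodes.update({"c:" + fwd.compartment, "c:" + fwd.compartment2})
                else:
                    nodes.update({"s:" + fwd.source, "s:" + fwd.target})
            import networkx as nx
            g = nx.Graph()
            g.add_nodes_from(nodes)
            for fwd, _ in pairs:
                if fwd.kind == "void_diffusion":
                    g.add_edge("c:" + fwd.compartment, "c:" + fwd.compartment2)
                else:
                    g.add_edge("s:" + fwd.source, "s:" + fwd.target)
            n_components = nx.number_connected_components(g)
            expected = len(pairs) - len(nodes) + n_components
            assert len(enumerate_cycles(model)) == expected

    def test_blocking_a_branch_removes_one_cycle(self):
        open_cycles = enumerate_cycles(build_branched_multisite(False))
        blocked_cycles = enumerate_cycles(build_branched_multisite(True))
        assert len(open_cycles) == len(blocked_cycles) + 1


class TestDetailedBalance:
    def test_symmetric_carrier_ratios_exactly_one(self, sym_model):
        report = check_detailed_balance(sym_model)
        assert report.passed
        for cycle in report.cycles:
            assert cycle.ratio == pytest.approx(1.0, abs=1e-14)

    def test_auto_closed_asymmetric_ratio_one(self, asym_model):
        report = check_detailed_balance(asym_model, tolerance=1e-12)
        assert report.passed
        assert report.cycles[0].ratio == pytest.approx(1.0, abs=1e-12)

    def test_tampered_rate_detected(self, asym_model):
        tampered = asym_model.copy()
        tampered.transitions["empty"].rate *= 2.0
        report = check_detailed_balance(tampered)
        assert not report.passed
        ratios = [c.ratio for c in report.cycles]
        assert any(r == pytest.approx(2.0, rel=1e-9) or
                   r == pytest.approx(0.5, rel=1e-9) for r in ratios)

    def test_composite_cycles_balance_when_basis_does(self):
        """If every basis-cycle ratio is 1, every simple closed walk of
        the reversible-pair multigraph balances (exhaustive DFS on the
        small fixed-site chain)."""
        from portersim.network import _edge_endpoints, _effective_rate
        model = build_multisite_chain()
        assert check_detailed_balance(model).passed
        pairs = model.reversible_pairs()
        adjacency: dict[str, list[tuple[str, int]]] = {}
        for k, (fwd, _) in enumerate(pairs):
            a, b = _edge_endpoints(fwd)
            adjacency.setdefault(a, []).append((b, k))
            adjacency.setdefault(b, []).append((a, k))

        def ratio_of(walk):  # walk: list of (edge index, from, to)
            fwd_prod = rev_prod = 1.0
            for k, frm, to in walk:
                fwd, rev = pairs[k]
                a, b = _edge_endpoints(fwd)
                t_fwd, t_rev = (fwd, rev) if (frm, to) == (a, b) else (rev, fwd)
                fwd_prod *= _effective_rate(t_fwd, 1.0)
                rev_prod *= _effective_rate(t_rev, 1.0)
            return fwd_prod / rev_prod

        found = []

        def dfs(start, node, walk, used):
            if len(walk) > 6:
                return
            for nxt, k in adjacency[node]:
                if k in used:
                    continue
                if nxt == start and len(walk) >= 1:
                    found.append(walk + [(k, node, nxt)])
                    continue
                if any(frm == nxt or to == nxt for _, frm, to in walk):
                    continue
                dfs(start, nxt, walk + [(k, node, nxt)], used | {k})

        for start in adjacency:
            dfs(start, start, [], set())
        assert found, "expected closed walks in the chain"
        for walk in found:
            assert ratio_of(walk) == pytest.approx(1.0, rel=1e-9)

    def test_random_balanced_carriers_all_pass(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            _, model = random_balanced_carrier(rng)
            assert check_detailed_balance(model, tolerance=1e-10).passed


class TestTracer:
    def test_expansion_duplicates_bound_states(self, asym_model):
        expanded = expand_tracer(asym_model, 0.5, "out")
        assert len(expanded.states) == 6  # two liganded states duplicated
        assert len(expanded.species) == 2

    def test_twin_edges_share_rates(self, asym_model):
        expanded = expand_tracer(asym_model, 0.5, "out")
        for t in expanded.transitions.values():
            twin = t.name[:-2] if t.name.endswith("~L") else t.name + "~L"
            if twin in expanded.transitions:
                assert expanded.transitions[twin].rate == t.rate

    def test_totals_preserved(self, asym_model):
        m = asym_model.copy()
        m.compartments["out"].conc = {"glucose": 8.0}
        expanded = expand_tracer(m, 0.25, "out")
        conc = expanded.compartments["out"].conc
        assert sum(conc.values()) == pytest.approx(8.0)
        assert conc["glucose*"] == pytest.approx(2.0)
        assert expanded.groups == m.groups

    def test_tracer_linearity(self, asym_model):
        """Unidirectional flux is independent of the labelled fraction
        in the linear-tracer regime."""
        m = asym_model.copy()
        m.compartments["out"].conc = {"glucose": 10.0}
        m.compartments["in"].conc = {"glucose": 10.0}
        fluxes = []
        for lf in (1e-6, 1e-3):
            ss = solve_steady_state(expand_tracer(m, lf, "out"))
            fluxes.append(unidirectional_flux(ss, "in"))
        assert fluxes[0] == pytest.approx(fluxes[1], rel=1e-8)

    def test_zero_trans_unidirectional_equals_net(self, asym_model):
        m = asym_model.copy()
        m.compartments["out"].conc = {"glucose": 10.0}
        ss_net = solve_steady_state(m)
        ss_tr = solve_steady_state(expand_tracer(m, 1e-6, "out"))
        assert unidirectional_flux(ss_tr, "in") == pytest.approx(
            ss_net.net_delivery("in"), rel=1e-8)

    def test_equilibrium_exchange_symmetry(self, asym_model):
        """At equal baths the unidirectional influx equals the
        unidirectional efflux on a detailed-balanced model."""
        m = asym_model.copy()
        m.compartments["out"].conc = {"glucose": 5.0}
        m.compartments["in"].conc = {"glucose": 5.0}
        ss_in = solve_steady_state(expand_tracer(m, 1e-6, "out"))
        ss_out = solve_steady_state(expand_tracer(m, 1e-6, "in"))
        assert unidirectional_flux(ss_in, "in") == pytest.approx(
            unidirectional_flux(ss_out, "out"), rel=1e-8)

    def test_bad_fraction_rejected(self, asym_model):
        with pytest.raises(ValueError):
            expand_tracer(asym_model, 0.0, "out")
        with pytest.raises(ValueError):
            expand_tracer(asym_model, 1.5, "out")

    def test_unidirectional_needs_tracer_model(self, asym_model):
        ss = solve_steady_state(asym_model, {"out": 1.0, "in": 0.0})
        with pytest.raises(ConfigurationError):
            unidirectional_flux(ss, "in")


class TestTimeCourse:
    def test_relaxation_to_equilibrium(self, asym_model):
        """From a skewed initial distribution at equal baths, all net
        fluxes decay to zero."""
        m = asym_model.copy()
        m.compartments["out"].conc = {"glucose": 5.0}
        m.compartments["in"].conc = {"glucose": 5.0}
        tc = integrate_time_course(
            m, np.linspace(0.0, 50.0, 20),
            initial_occupancy={"C_out": 1.0, "GC_out": 0.0, "GC_in": 0.0, "C_in": 0.0})
        ss = solve_steady_state(m)
        for s in m.states:
            assert tc.occupancy[s][-1] == pytest.approx(ss.occupancy[s], abs=1e-8)

    def test_carrier_conservation_along_trajectory(self, asym_model):
        m = asym_model.copy()
        m.compartments["out"].conc = {"glucose": 20.0}
        tc = integrate_time_course(
            m, np.linspace(0.0, 10.0, 50),
            initial_occupancy={"C_out": 0.4, "GC_out": 0.3, "GC_in": 0.2, "C_in": 0.1})
        total = sum(tc.occupancy[s] for s in m.states)
        assert np.max(np.abs(total - 1.0)) < 1e-9

    def test_total_ligand_conserved_with_finite_baths(self, asym_model):
        """With both baths finite the ligand amount (baths + bound) is
        an exact invariant of the dynamics."""
        m = asym_model.with_compartment("out", FINITE, 2.0) \
                      .with_compartment("in", FINITE, 3.0)
        m.compartments["out"].conc = {"glucose": 10.0}
        m.compartments["in"].conc = {"glucose": 1.0}
        tc = integrate_time_course(m, np.linspace(0.0, 30.0, 30))
        bound = tc.occupancy["GC_out"] + tc.occupancy["GC_in"]
        amount = (tc.conc["out"]["glucose"] * 2.0 +
                  tc.conc["in"]["glucose"] * 3.0 + bound)
        assert np.max(np.abs(amount - amount[0])) < 1e-7 * amount[0]

    def test_bad_grid_rejected(self, asym_model):
        with pytest.raises(ValueError):
            integrate_time_course(asym_model, [0.0, 0.0, 1.0])


class TestSolverEquivalence:
    @pytest.mark.parametrize("seed", range(4))
    def test_linear_and_ode_agree_on_random_carriers(self, seed):
        rng = np.random.default_rng(100 + seed)
        _, model = random_balanced_carrier(rng)
        clamps = {"out": float(10 ** rng.uniform(-1, 2)),
                  "in": float(10 ** rng.uniform(-1, 2))}
        solve_steady_state(model, clamps, cross_check=True)
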