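"""Rate laws, steady-state solvers and ensemble simulation."""

import numpy as np
import pytest

from ggmetab.kinetics import (
    KineticsError,
    MMParams,
    Reaction,
    ReactionNetwork,
    SolverError,
    linear_steady_state,
    mass_action_rate,
    mixed_inhibition_rate,
    nominal_draw,
    numerical_steady_state,
    pathway_distances,
    read_network,
    reversible_mm_rate,
    sample_parameters,
    simulate_ensemble,
    verify_monostability,
    write_network,
)
from ggmetab.networks import available_networks, make_network


def _net(reactions, mets):
    return ReactionNetwork(mets, reactions)


class TestMassActionRate:
    def test_bimolecular_product_of_educts(self):
        # x1 + x2 -> x3 gives c = x1 * x2
        net = _net([Reaction("r", {"x1": 1, "x2": 1}, {"x3": 1}, k=1.0)], ["x1", "x2", "x3"])
        assert mass_action_rate(np.array([2.0, 3.0, 9.9]), 1.0, net, 0) == pytest.approx(6.0)

    def test_stoichiometric_exponents(self):
        # 2x1 + 3x2 -> 2x3 gives c = x1^2 * x2^3
        net = _net([Reaction("r", {"x1": 2, "x2": 3}, {"x3": 2}, k=1.0)], ["x1", "x2", "x3"])
        assert mass_action_rate(np.array([2.0, 1.0, 0.3]), 1.0, net, 0) == pytest.approx(4.0)

    def test_zeroth_order_input_returns_k(self):
        net = _net([Reaction("in", {}, {"x1": 1}, k=5.0)], ["x1"])
        assert mass_action_rate(np.array([123.4]), 5.0, net, 0) == pytest.approx(5.0)

    def test_negative_concentration_rejected(self):
        net = _net([Reaction("r", {"x1": 1}, {}, k=1.0)], ["x1"])
        with pytest.raises(KineticsError):
            mass_action_rate(np.array([-0.1]), 1.0, net, 0)


class TestMichaelisMenten:
    params = MMParams(vmax_fwd=2.0, vmax_bwd=1.0, km_s=1.5, km_p=0.5)

    def test_zero_concentrations_zero_rate(self):
        assert reversible_mm_rate(0.0, 0.0, self.params) == 0.0

    def test_chemical_balance_zero_rate(self):
        # Vmax+ * S / KMs == Vmax- * P / KMp  ->  numerator cancels
        s = 1.0
        p = (self.params.vmax_fwd / self.params.km_s) * s * self.params.km_p / self.params.vmax_bwd
        assert reversible_mm_rate(s, p, self.params) == pytest.approx(0.0, abs=1e-14)

    def test_saturation_limit_is_vmax(self):
        assert reversible_mm_rate(1e9, 0.0, self.params) == pytest.approx(2.0, rel=1e-6)

    def test_inhibition_vanishes_without_inhibitor(self):
        p = MMParams(2.0, 1.0, 1.5, 0.5, inhibitor_id="I", ki=2.0, kii=2.0)
        assert mixed_inhibition_rate(0.7, 0.2, 0.0, p) == pytest.approx(
            reversible_mm_rate(0.7, 0.2, self.params)
        )

    def test_inhibitor_at_ki_halves_rate(self):
        # non-competitive case Ki == Kii: I = Ki doubles the denominator
        p = MMParams(2.0, 1.0, 1.5, 0.5, inhibitor_id="I", ki=2.0, kii=2.0)
        assert mixed_inhibition_rate(0.7, 0.2, 2.0, p) == pytest.approx(
            reversible_mm_rate(0.7, 0.2, self.params) / 2.0
        )

    def test_strong_inhibition_kills_rate(self):
        p = MMParams(2.0, 1.0, 1.5, 0.5, inhibitor_id="I", ki=2.0, kii=2.0)
        assert abs(mixed_inhibition_rate(0.7, 0.2, 1e12, p)) < 1e-10

    def test_missing_inhibitor_constants_rejected(self):
        with pytest.raises(KineticsError):
            MMParams(2.0, 1.0, 1.0, 1.0, inhibitor_id="I")  # no ki/kii


class TestParameterSampling:
    net = make_network("chain_reversible")

    def test_sigma_zero_reproduces_nominal(self):
        draw = sample_parameters(self.net, sigma=0.0, seed=1)
        np.testing.assert_array_equal(draw.values, self.net.nominal_constants())

    def test_same_seed_identical(self):
        d1 = sample_parameters(self.net, sigma=0.2, seed=42)
        d2 = sample_parameters(self.net, sigma=0.2, seed=42)
        np.testing.assert_array_equal(d1.values, d2.values)

    def test_log_sd_matches_sigma(self):
        # moment check: sd of log(k/nominal) over many draws equals sigma
        rng = np.random.default_rng(3)
        sigma = 0.2
        n = 100_000
        logs = np.concatenate(
            [
                np.log(sample_parameters(self.net, sigma, seed=rng).values
                       / self.net.nominal_constants())
                for _ in range(n // self.net.r // 10)
            ]
        )
        se = sigma / np.sqrt(2 * logs.size)
        assert abs(logs.std(ddof=1) - sigma) < 3 * se

    def test_mean_mode_shifts_location(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate(
            [sample_parameters(self.net, 0.5, seed=rng, lognormal_mode="mean").values
             for _ in range(4000)]
        )
        # with mu = -sigma^2/2 the arithmetic mean equals the nominal value
        assert abs(vals.mean() / self.net.nominal_constants().mean() - 1.0) < 0.05

    def test_negative_sigma_rejected(self):
        with pytest.raises(KineticsError):
            sample_parameters(self.net, sigma=-0.1, seed=0)

    def test_per_reaction_sigma_map(self):
        draw = sample_parameters(self.net, sigma={"in_A": 0.5}, seed=5)
        nominal = self.net.nominal_constants()
        changed = np.flatnonzero(draw.values != nominal)
        assert changed.size == 1 and draw.names[changed[0]] == "in_A.k"


class TestLinearSteadyState:
    def test_single_pool(self):
        net = _net(
            [Reaction("in", {}, {"A": 1}, k=2.0), Reaction("out", {"A": 1}, {}, k=1.0)], ["A"]
        )
        x = linear_steady_state(net, nominal_draw(net))
        assert x == pytest.approx([2.0])

    def test_flux_balance_chain(self):
        net = _net(
            [
                Reaction("in", {}, {"A": 1}, k=2.0),
                Reaction("ab", {"A": 1}, {"B": 1}, k=1.0),
                Reaction("out", {"B": 1}, {}, k=4.0),
            ],
            ["A", "B"],
        )
        x = linear_steady_state(net, nominal_draw(net))
        assert x == pytest.approx([2.0, 0.5])

    def test_singular_closed_system(self):
        net = _net(
            [Reaction("f", {"A": 1}, {"B": 1}, k=1.0), Reaction("b", {"B": 1}, {"A": 1}, k=2.0)],
            ["A", "B"],
        )
        with pytest.raises(SolverError, match="singular"):
            linear_steady_state(net, nominal_draw(net))

    @pytest.mark.parametrize(
        "name", ["chain_reversible", "chain_irreversible", "chain_irreversible_exchange", "branched"]
    )
    def test_agrees_with_numerical_solver(self, name):
        net = make_network(name)
        rng = np.random.default_rng(9)
        for _ in range(25):
            draw = sample_parameters(net, sigma=0.3, seed=rng)
            xa = linear_steady_state(net, draw)
            xn = numerical_steady_state(net, draw, tol=1e-10)
            np.testing.assert_allclose(xn, xa, rtol=1e-6)

    def test_flux_balance_residual_invariant(self):
        from ggmetab.kinetics import reaction_rates

        for name in available_networks():
            net = make_network(name)
            draw = sample_parameters(net, sigma=0.2, seed=13)
            if net.is_linear():
                x = linear_steady_state(net, draw)
            else:
                x = numerical_steady_state(net, draw)
            v = reaction_rates(net, x, draw)
            resid = np.linalg.norm(net.S @ v)
            assert resid <= 1e-6 * (1 + np.linalg.norm(v))


class TestNumericalSteadyState:
    def test_closed_isomerization_conserves_mass(self):
        net = _net(
            [Reaction("f", {"A": 1}, {"B": 1}, k=1.0), Reaction("b", {"B": 1}, {"A": 1}, k=2.0)],
            ["A", "B"],
        )
        x0 = np.array([3.0, 1.0])
        x = numerical_steady_state(net, nominal_draw(net), x0=x0, polish=False)
        assert x.sum() == pytest.approx(x0.sum(), rel=1e-6)

    def test_bimolecular_split_unique_steady_state(self):
        net = make_network("bimolecular_split")
        draw = sample_parameters(net, sigma=0.2, seed=21)
        x1 = numerical_steady_state(net, draw, x0=np.array([0.2, 0.2, 0.2]))
        x2 = numerical_steady_state(net, draw, x0=np.array([5.0, 1.0, 3.0]))
        np.testing.assert_allclose(x1, x2, rtol=1e-5)

    def test_nonpositive_initial_state_rejected(self):
        net = make_network("bimolecular_split")
        with pytest.raises(KineticsError):
            numerical_steady_state(net, nominal_draw(net), x0=np.zeros(3))


class TestMonostability:
    def test_linear_reversible_chain_passes(self):
        report = verify_monostability(make_network("chain_reversible"), 5, 3, seed=1)
        assert report.passed

    def test_negative_feedback_module_passes(self):
        report = verify_monostability(
            make_network("end_product_inhibition_closed"), 4, 3, seed=2, tol=1e-5
        )
        assert report.passed and report.worst_divergence < 1e-5

    def test_degenerate_network_reports_failure(self):
        # no output reactions: flux balance is rank deficient
        net = _net([Reaction("in", {}, {"A": 1}, k=1.0)], ["A"])
        report = verify_monostability(net, 2, 2, seed=3)
        assert not report.passed and report.failures


class TestSimulateEnsemble:
    def test_shape_and_completeness(self, chain_reversible_ensemble):
        ens = chain_reversible_ensemble
        assert ens.data.shape == (1000, 3)
        assert not ens.data.isna().any().any()

    def test_sigma_zero_flags_constant_columns(self):
        ens = simulate_ensemble(make_network("chain_reversible"), sigma=0.0, n_samples=5, seed=0)
        assert ens.zero_variance_columns() == ["A", "B", "C"]

    def test_reproducible_given_seed(self):
        net = make_network("chain_irreversible")
        e1 = simulate_ensemble(net, 0.2, 50, seed=8)
        e2 = simulate_ensemble(net, 0.2, 50, seed=8)
        assert e1.data.equals(e2.data)

    def test_rate_constant_rescaling_preserves_correlations(self):
        # multiplying every rate constant by a common factor leaves first-order
        # steady states unchanged, hence identical correlation structure
        net = make_network("chain_reversible")
        scaled = ReactionNetwork(
            net.metabolite_ids,
            [
                Reaction(rx.name, rx.educts, rx.products, law=rx.law, k=rx.k * 10.0)
                for rx in net.reactions
            ],
        )
        e1 = simulate_ensemble(net, 0.2, 200, seed=4)
        e2 = simulate_ensemble(scaled, 0.2, 200, seed=4)
        c1 = np.corrcoef(e1.data.to_numpy(), rowvar=False)
        c2 = np.corrcoef(e2.data.to_numpy(), rowvar=False)
        np.testing.assert_allclose(c1, c2, atol=1e-10)


class TestNetworkLibrary:
    def test_unknown_name_raises(self):
        with pytest.raises(KeyError):
            make_network("nope")

    def test_chain_reversible_topology(self):
        net = make_network("chain_reversible")
        assert net.metabolite_ids == ["A", "B", "C"]
        names = [r.name for r in net.reactions]
        assert "in_A" in names and "out_C" in names and "AB_b" in names

    def test_cofactor_network_has_cofactor_exchange(self):
        net = make_network("cofactor_glycolysis")
        names = [r.name for r in net.reactions]
        for n in ("in_ATP", "out_ATP", "in_ADP", "out_ADP"):
            assert n in names

    def test_mm_chain_forward_backward_ratio(self):
        net = make_network("mm_chain")
        mm = [r.mm for r in net.reactions if r.mm is not None]
        assert mm and all(p.vmax_fwd == pytest.approx(2 * p.vmax_bwd) for p in mm)

    def test_network_file_round_trip(self, tmp_path):
        for name in ("chain_reversible", "mm_chain", "end_product_inhibition_closed"):
            net = make_network(name)
            path = tmp_path / f"{name}.yaml"
            write_network(net, path)
            back = read_network(path)
            assert back.metabolite_ids == net.metabolite_ids
            np.testing.assert_array_equal(back.S, net.S)
            np.testing.assert_array_equal(back.S_e, net.S_e)
            np.testing.assert_array_equal(back.nominal_constants(), net.nominal_constants())

    def test_pathway_distances_on_chain(self):
        D = pathway_distances(make_network("chain_irreversible"))
        assert D.loc["A", "B"] == 1 and D.loc["A", "C"] == 2 and D.loc["A", "A"] == 0
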