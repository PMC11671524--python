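"""One-way DSA, parameter paths, PSA sampling and the acceptability curve."""

import numpy as np
import pytest

from markovcea import (
    DSASpec,
    ModelConfig,
    StateSpec,
    StrategyParams,
    TransitionMatrix,
    build_psa_distributions,
    ceac,
    default_psa_ranges,
    evaluate,
    get_parameter,
    one_way_dsa,
    run_psa,
    set_parameter,
)
from markovcea.sensitivity import PSASpec, ParameterDistribution


class TestParameterPaths:
    @pytest.mark.parametrize(
        "path, expected",
        [
            ("annual_discount", 0.05),
            ("states.PFS.utility", 0.77),
            ("strategies.mGEMOX.cycle_costs.PD", 2017.94),
            ("strategies.mGEMOX.ae_cost_per_cycle", 1.26),
            ("strategies.mGEMOX.transition.PFS.PD", 0.08),
            ("strategies.FUFA.transition.PD.DEATH", 0.47),
        ],
    )
    def test_get(self, gbc_config, path, expected):
        assert get_parameter(gbc_config.resolved(), path) == pytest.approx(expected)

    def test_set_returns_modified_copy(self, gbc_config):
        cfg = gbc_config.resolved()
        cfg2 = set_parameter(cfg, "states.PFS.utility", 0.9)
        assert get_parameter(cfg2, "states.PFS.utility") == 0.9
        assert get_parameter(cfg, "states.PFS.utility") == 0.77  # original intact

    def test_transition_set_renormalises_self_loop(self, gbc_config):
        cfg = set_parameter(gbc_config.resolved(), "strategies.mGEMOX.transition.PFS.PD", 0.10)
        tm = cfg.get_strategy("mGEMOX").transition
        assert tm.entry("PFS", "PFS") == pytest.approx(0.83)
        assert np.allclose(tm.as_array().sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize(
        "path",
        ["nonsense", "states.NOPE.utility", "strategies.mGEMOX.cycle_costs.NOPE",
         "strategies.NOPE.ae_cost_per_cycle"],
    )
    def test_unresolvable_paths_error(self, gbc_config, path):
        with pytest.raises(KeyError, match="parameter path"):
            get_parameter(gbc_config.resolved(), path)

    def test_invalid_values_error_naming_the_parameter(self, gbc_config):
        cfg = gbc_config.resolved()
        with pytest.raises(ValueError, match="states.PFS.utility"):
            set_parameter(cfg, "states.PFS.utility", 1.4)
        with pytest.raises(ValueError, match="transition.PFS.PD"):
            set_parameter(cfg, "strategies.mGEMOX.transition.PFS.PD", 0.99)


def config_with_unreachable_state():
    """Three live states but one (SPARE) that no transition ever enters,
    so a cost attached to it cannot move the ICER."""
    labels = ("PFS", "SPARE", "DEATH")
    def tm(p_exit):
        return TransitionMatrix(
            labels=labels,
            probs=((1 - p_exit, 0.0, p_exit), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)),
        )
    return ModelConfig(
        states=[
            StateSpec(name="PFS", utility=0.8),
            StateSpec(name="SPARE", utility=0.5),
            StateSpec(name="DEATH", utility=0.0, absorbing=True),
        ],
        strategies=[
            StrategyParams(name="new", cycle_costs={"PFS": 500.0, "SPARE": 100.0}, transition=tm(0.05)),
            StrategyParams(name="old", cycle_costs={"PFS": 100.0, "SPARE": 100.0}, transition=tm(0.15)),
        ],
        horizon=60,
        wtp=50000.0,
        intervention="new",
        comparator="old",
    )


class TestOneWayDSA:
    def test_unreachable_state_cost_has_zero_spread(self):
        cfg = config_with_unreachable_state()
        entries = one_way_dsa(cfg, [DSASpec("strategies.new.cycle_costs.SPARE", 50.0, 150.0)])
        e = entries[0]
        assert e.icer_at_low == pytest.approx(e.baseline_icer, rel=1e-12)
        assert e.spread == pytest.approx(0.0, abs=1e-9)

    def test_icer_affine_in_a_per_cycle_cost(self, gbc_config):
        """Incremental QALYs are fixed and incremental cost is linear in a
        state's per-cycle cost, so the ICER is affine in it: a five-point
        brute-force grid must be collinear and the midpoint ICER must be
        the mean of the endpoint ICERs."""
        cfg = gbc_config.resolved()
        path = "strategies.mGEMOX.cycle_costs.PFS"
        base = get_parameter(cfg, path)
        grid = np.linspace(0.8 * base, 1.2 * base, 5)
        icers = np.array([evaluate(set_parameter(cfg, path, c)).icer for c in grid])
        slopes = np.diff(icers) / np.diff(grid)
        assert np.allclose(slopes, slopes[0], rtol=1e-9)
        assert icers[2] == pytest.approx((icers[0] + icers[-1]) / 2, rel=1e-9)
        spread = abs(icers[-1] - icers[0])
        assert spread == pytest.approx(abs(slopes[0]) * (grid[-1] - grid[0]), rel=1e-6)

    def test_icer_decreases_as_pfs_utility_rises(self, gbc_config):
        """Published direction: raising the progression-free utility from
        0.62 to 1.00 lowers the ICER monotonically."""
        cfg = gbc_config.resolved()
        icers = [
            evaluate(set_parameter(cfg, "states.PFS.utility", u)).icer
            for u in np.linspace(0.62, 1.00, 8)
        ]
        assert all(a > b for a, b in zip(icers, icers[1:]))

    def test_entries_sorted_by_descending_spread(self, bundle):
        from markovcea import default_dsa_specs

        cfg = bundle.config
        entries = one_way_dsa(
            cfg, default_dsa_specs(cfg, transition_limits=bundle.transition_limits())
        )
        spreads = [e.spread for e in entries]
        assert spreads == sorted(spreads, reverse=True)

    def test_top_drivers_are_pfs_cost_and_pfs_utility(self, bundle):
        """The published tornado ranks the intervention's progression-free
        state cost and the progression-free utility as the widest bars."""
        from markovcea import default_dsa_specs

        cfg = bundle.config
        entries = one_way_dsa(
            cfg, default_dsa_specs(cfg, transition_limits=bundle.transition_limits())
        )
        top2 = {e.parameter_path for e in entries[:2]}
        assert top2 == {"strategies.mGEMOX.cycle_costs.PFS", "states.PFS.utility"}

    def test_empty_spec_list_rejected(self, gbc_config):
        with pytest.raises(ValueError):
            one_way_dsa(gbc_config, [])

    def test_bounds_must_be_ordered(self):
        with pytest.raises(ValueError):
            DSASpec("states.PFS.utility", 0.9, 0.6)


class TestBuildPSADistributions:
    def test_cost_range_maps_to_gamma_moments(self, gbc_config):
        spec = build_psa_distributions(
            gbc_config, {"strategies.mGEMOX.cycle_costs.PD": (2017.94 * 0.8, 2017.94 * 1.2)}
        )
        d = spec.distributions[0]
        assert d.family == "gamma"
        mean, sd = d.a * d.b, np.sqrt(d.a) * d.b
        assert mean == pytest.approx(2017.94, rel=1e-12)
        assert sd == pytest.approx(2017.94 * 0.4 / 3.92, rel=1e-12)

    def test_probability_range_maps_to_beta_with_baseline_mean(self, gbc_config):
        spec = build_psa_distributions(
            gbc_config, {"strategies.mGEMOX.transition.PFS.PD": (0.06, 0.09)}
        )
        d = spec.distributions[0]
        assert d.family == "beta"
        assert d.a / (d.a + d.b) == pytest.approx(0.08, rel=1e-12)

    def test_zero_width_ranges_become_point_masses(self, gbc_config):
        ranges = {p: (v, v) for p, v in [
            ("strategies.mGEMOX.cycle_costs.PD", 2017.94),
            ("states.PFS.utility", 0.77),
        ]}
        spec = build_psa_distributions(gbc_config, ranges)
        assert all(d.family == "point" for d in spec.distributions)

    def test_baseline_outside_range_rejected(self, gbc_config):
        with pytest.raises(ValueError, match="outside"):
            build_psa_distributions(gbc_config, {"states.PFS.utility": (0.9, 1.0)})


class TestRunPSA:
    def test_point_mass_spec_reproduces_the_base_case(self, bundle):
        cfg = bundle.config
        base = evaluate(cfg)
        ranges = {
            p: (v, v)
            for p, v in [
                ("states.PFS.utility", 0.77),
                ("strategies.mGEMOX.cycle_costs.PFS", cfg.get_strategy("mGEMOX").cycle_costs["PFS"]),
            ]
        }
        spec = build_psa_distributions(cfg, ranges, n_iterations=25, seed=7)
        psa = run_psa(cfg, spec)
        assert np.allclose(psa.delta_cost, base.incremental_cost, atol=1e-9)
        assert np.allclose(psa.delta_qaly, base.incremental_qaly, atol=1e-12)
        assert psa.prob_at_wtp == 0.0  # base ICER sits above the threshold

    def test_identical_seed_gives_bit_identical_results(self, bundle):
        cfg = bundle.config
        ranges = default_psa_ranges(cfg, transition_limits=bundle.transition_limits())
        spec = build_psa_distributions(cfg, ranges, n_iterations=50, seed=11)
        a, b = run_psa(cfg, spec), run_psa(cfg, spec)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert np.array_equal(a.delta_qaly, b.delta_qaly)

    def test_sampled_rows_stay_stochastic_and_parameters_in_support(self, bundle):
        # indirectly: every iteration must produce a valid evaluation,
        # and the recorded increments must all be finite
        cfg = bundle.config
        ranges = default_psa_ranges(cfg, transition_limits=bundle.transition_limits())
        spec = build_psa_distributions(cfg, ranges, n_iterations=100, seed=3)
        psa = run_psa(cfg, spec)
        assert np.all(np.isfinite(psa.delta_cost)) and np.all(np.isfinite(psa.delta_qaly))

    def test_iteration_count_validated(self):
        with pytest.raises(ValueError):
            PSASpec(distributions=(), n_iterations=0)


@pytest.fixture(scope="module")
def psa(bundle):
    cfg = bundle.config
    ranges = default_psa_ranges(cfg, transition_limits=bundle.transition_limits())
    return run_psa(cfg, build_psa_distributions(cfg, ranges, n_iterations=200, seed=5))


class TestCEAC:

    def test_values_are_probabilities(self, psa):
        curve = ceac(psa, np.arange(0, 100001, 5000))
        assert all(0.0 <= p <= 1.0 for p in curve.values())

    def test_zero_wtp_with_all_extra_cost_gives_zero(self, psa):
        assert np.all(psa.delta_cost > 0)
        assert ceac(psa, [0.0])[0.0] == 0.0

    def test_huge_wtp_with_all_qaly_gains_gives_one(self, psa):
        assert np.all(psa.delta_qaly > 0)
        assert ceac(psa, [1e9])[1e9] == 1.0

    def test_monotone_when_all_iterations_gain_qalys(self, psa):
        grid = np.arange(0, 100001, 1000.0)
        probs = list(ceac(psa, grid).values())
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_curve_agrees_with_prob_at_wtp(self, psa):
        assert ceac(psa, [psa.wtp])[psa.wtp] == psa.prob_at_wtp

    def test_well_above_the_icer_acceptance_exceeds_half(self, psa):
        assert ceac(psa, [100000.0])[100000.0] > 0.5

    def test_empty_grid_rejected(self, psa):
        with pytest.raises(ValueError):
            ceac(psa, [])
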