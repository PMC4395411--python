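"""Steady-state enzyme-set model: solver contracts, the stochastic oracle,
beta fitting and the variation scans."""

import numpy as np
import pytest

import sbecld as sb
from sbecld.biosynthesis import growth_rate_identity_gap
from sbecld.errors import ConvergenceError, ParameterError


class TestSteadyStateContract:
    def test_normalization_and_residual(self, reference_solution):
        dp, v = reference_solution.cld.as_arrays()
        assert v.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.all(v >= 0)
        assert reference_solution.residual < 1e-8
        assert reference_solution.growth_rate > 0

    def test_no_mass_below_fragment_minimum(self, reference_solution):
        assert reference_solution.cld.support_min() == 6

    def test_growth_rate_self_consistency(self, reference_solution):
        # each branching event adds one chain, so g must equal the
        # population-averaged cleavage propensity at the converged shape
        assert growth_rate_identity_gap(reference_solution) < 1e-8

    def test_high_beta_limit_confines_support(self):
        sol = sb.steady_state_cld(
            sb.EnzymeSetParams(beta=50.0, x_min=6, x_0=6), x_max=60
        )
        dp, v = sol.cld.as_arrays()
        assert v[dp >= 2 * 12].sum() < 1e-4

    def test_xmax_too_small_rejected(self):
        with pytest.raises(ParameterError):
            sb.steady_state_cld(sb.EnzymeSetParams(beta=1.4), x_max=30)

    def test_truncation_guard_triggers(self):
        # a very weak brancher pushes mass far beyond a tight x_max
        with pytest.raises((ConvergenceError, ParameterError)):
            sb.steady_state_cld(
                sb.EnzymeSetParams(beta=0.05, x_min=6, x_0=7), x_max=40
            )

    def test_beta_monotonicity(self):
        # weaker branching -> longer chains: mean dp and the DP>13 tail
        # both increase as beta decreases
        sols = [
            sb.steady_state_cld(sb.EnzymeSetParams(beta=b, x_min=6, x_0=7), x_max=200)
            for b in (2.8, 1.4, 0.7)
        ]
        means = [sb.mean_dp(s.cld) for s in sols]
        tails = [s.tail_mass(13) for s in sols]
        assert means[0] < means[1] < means[2]
        assert tails[0] < tails[1] < tails[2]


class TestGillespieOracle:
    def test_constraint_compliance(self):
        cld = sb.gillespie_cld(
            sb.EnzymeSetParams(beta=1.4, x_min=6, x_0=6), 50_000, seed=2
        )
        assert min(cld.values) >= 6

    def test_agrees_with_solver(self, reference_params, reference_solution):
        cld = sb.gillespie_cld(reference_params, 200_000, seed=7)
        assert sb.total_variation(cld, reference_solution.cld) < 0.05

    def test_seed_repeatability_band(self, reference_params):
        a = sb.gillespie_cld(reference_params, 100_000, seed=1)
        b = sb.gillespie_cld(reference_params, 100_000, seed=2)
        assert sb.total_variation(a, b) < 0.02
        c = sb.gillespie_cld(reference_params, 100_000, seed=1)
        assert sb.total_variation(a, c) == 0.0

    def test_too_few_chains_rejected(self, reference_params):
        with pytest.raises(ParameterError):
            sb.gillespie_cld(reference_params, 100, seed=0)


class TestCombineSets:
    def test_single_set_identity(self, reference_solution):
        out = sb.combine_sets([reference_solution], [1.0])
        for dp in reference_solution.cld.values:
            assert out[dp] == pytest.approx(reference_solution.cld[dp])

    def test_equal_weights_of_identical_clds(self, reference_solution):
        out = sb.combine_sets([reference_solution, reference_solution], [0.5, 0.5])
        for dp in reference_solution.cld.values:
            assert out[dp] == pytest.approx(reference_solution.cld[dp])

    def test_zero_weight_drops_component(self, reference_solution):
        other = sb.steady_state_cld(sb.EnzymeSetParams(beta=0.7, x_min=6, x_0=7), x_max=200)
        out = sb.combine_sets([reference_solution, other], [1.0, 0.0])
        for dp in reference_solution.cld.values:
            assert out[dp] == pytest.approx(reference_solution.cld[dp])

    def test_all_zero_weights_rejected(self, reference_solution):
        with pytest.raises(ParameterError):
            sb.combine_sets([reference_solution], [0.0])


class TestFitBeta:
    def test_recovers_own_output(self, reference_solution):
        fitted, sse = sb.fit_beta(reference_solution.cld, 6, 7)
        assert abs(fitted.beta - 1.4) < 1e-3
        assert sse < 1e-10

    def test_recovers_under_sampling_noise(self, reference_params):
        pop = sb.make_amylopectin_substrate(reference_params, 100_000, seed=13)
        noisy = sb.to_number_cld(pop, "chains100")
        fitted, _ = sb.fit_beta(noisy, 6, 7)
        assert abs(fitted.beta - 1.4) < 0.1

    def test_flat_target_reports_large_sse(self):
        flat = sb.NumberCLD({dp: 1.0 for dp in range(6, 40)}).renormalized(
            "chains100"
        )
        _, sse = sb.fit_beta(flat, 6, 7)
        assert sse > 1.0  # diagnostic, not a silent success


class TestVariationScans:
    def test_scan_covers_range_with_complementary_minima(self, reference_params):
        scan = sb.variation_scan(reference_params, sb.VariationSpec.variation_a())
        assert sorted(scan) == list(range(2, 12))
        for x_min, sol in scan.items():
            assert sol.params.x_min == x_min
            assert sol.params.x_0 == 13 - x_min
            assert sol.params.beta == 1.4

    def test_variation_b_halves_beta(self, reference_params):
        scan = sb.variation_scan(reference_params, sb.VariationSpec.variation_b())
        assert all(s.params.beta == pytest.approx(0.7) for s in scan.values())

    def test_halved_beta_elevates_long_chains_everywhere(self, reference_params):
        a = sb.variation_scan(reference_params, sb.VariationSpec.variation_a())
        b = sb.variation_scan(reference_params, sb.VariationSpec.variation_b())
        for x_min in a:
            assert b[x_min].tail_mass(13) > a[x_min].tail_mass(13)

    def test_extreme_split_grows_a_short_chain_local_maximum(self, reference_params):
        # at the most asymmetric split a bump between the two minima
        # becomes a local maximum
        scan = sb.variation_scan(reference_params, sb.VariationSpec.variation_a())
        dp, v = scan[2].cld.as_arrays()
        dense = np.zeros(int(dp.max()) + 2)
        dense[dp] = v
        local_max = [
            x for x in range(3, 12)
            if dense[x] > dense[x - 1] and dense[x] >= dense[x + 1]
        ]
        assert local_max, "expected a local maximum between the two minima"

    def test_long_chain_ratio_trivia(self, reference_solution):
        assert sb.long_chain_ratio(reference_solution, reference_solution) == pytest.approx(100.0)
        empty_tail = sb.NumberCLD({6: 50.0, 7: 50.0}, "chains100")
        assert sb.long_chain_ratio(empty_tail, reference_solution.cld) == 0.0

    def test_long_chain_ratio_zero_reference_rejected(self):
        no_tail = sb.NumberCLD({6: 100.0}, "chains100")
        with pytest.raises(ParameterError):
            sb.long_chain_ratio(no_tail, no_tail)

    def test_invalid_range_rejected(self):
        with pytest.raises(ParameterError):
            sb.VariationSpec(mode="A", sum_s=13, x_min_range=(1, 11))
        with pytest.raises(ParameterError):
            sb.VariationSpec(mode="A", sum_s=13, x_min_range=(5, 3))


class TestPropensityConventions:
    """The branching-propensity discretization is an explicit model choice;
    all three conventions must satisfy the structural invariants."""

    @pytest.mark.parametrize("propensity", ["random_bond", "per_chain", "per_site"])
    def test_solver_oracle_agreement(self, propensity):
        params = sb.EnzymeSetParams(beta=1.4, x_min=6, x_0=7)
        sol = sb.steady_state_cld(params, propensity=propensity)
        cld = sb.gillespie_cld(params, 100_000, seed=21, propensity=propensity)
        assert sb.total_variation(cld, sol.cld) < 0.05

    def test_per_chain_growth_rate_is_beta_times_eligible_fraction(self):
        params = sb.EnzymeSetParams(beta=1.4, x_min=6, x_0=7)
        sol = sb.steady_state_cld(params, propensity="per_chain")
        dp, v = sol.cld.as_arrays()
        eligible = v[dp >= 13].sum() / v.sum()
        assert sol.growth_rate == pytest.approx(1.4 * eligible, rel=1e-6)
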