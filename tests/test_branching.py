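"""In-vitro branching simulator: constraint semantics, cut kernels,
conservation bookkeeping, and structural cross-checks."""

import numpy as np
import pytest
from scipy import stats

import sbecld as sb
from sbecld.errors import ParameterError


class TestEligibleSiteCount:
    @pytest.mark.parametrize(
        "dp, expected",
        [(12, 1), (11, 0), (20, 9), (1, 0), (13, 2)],
    )
    def test_wild_type(self, dp, expected):
        spec = sb.SBESpecificity(x_min=6, x_0=6)
        assert sb.eligible_site_count(dp, spec) == expected

    def test_donor_floor_overrides_sum(self):
        # R456K: minima 2/2 but the subsite count (donor floor) stays 12
        spec = sb.SBESpecificity(2, 2, min_donor_dp=12)
        assert sb.eligible_site_count(11, spec) == 0
        assert sb.eligible_site_count(12, spec) == 9

    def test_floor_below_sum_rejected(self):
        with pytest.raises(ParameterError):
            sb.SBESpecificity(6, 6, min_donor_dp=10)


class TestDrawCut:
    def test_single_eligible_cut_is_forced(self, rng):
        spec = sb.SBESpecificity(6, 6)
        for _ in range(20):
            assert sb.draw_cut(12, spec, rng) == (6, 6)

    def test_uniform_kernel_is_uniform(self, rng):
        spec = sb.SBESpecificity(6, 6)
        draws = [sb.draw_cut(14, spec, rng)[0] for _ in range(100_000)]
        values, counts = np.unique(draws, return_counts=True)
        assert list(values) == [6, 7, 8]
        # chi-square goodness of fit against uniform, alpha = 0.01
        assert stats.chisquare(counts).pvalue > 0.01

    def test_relaxed_specificity_support(self, rng):
        # R456K-style relaxation: fragment minima 2, sum constraint 12
        spec = sb.SBESpecificity(2, 2, min_donor_dp=12)
        transferred = {sb.draw_cut(12, spec, rng)[0] for _ in range(5000)}
        assert transferred == set(range(2, 11))

    def test_complementarity(self, rng):
        spec = sb.SBESpecificity(6, 7)
        for _ in range(200):
            t, r = sb.draw_cut(25, spec, rng)
            assert t + r == 25 and t >= 6 and r >= 7

    def test_ineligible_donor_rejected(self, rng):
        spec = sb.SBESpecificity(6, 6)
        with pytest.raises(ParameterError):
            sb.draw_cut(11, spec, rng)

    def test_geometric_kernel_prefers_shortest(self, rng):
        spec = sb.SBESpecificity(6, 6, sb.geometric_kernel(0.45))
        draws = np.array([sb.draw_cut(30, spec, rng)[0] for _ in range(20_000)])
        values, counts = np.unique(draws, return_counts=True)
        order = values[np.argsort(counts)[::-1]]
        assert order[0] == 6 and order[1] == 7


class TestExpectedEvents:
    def test_direct_product(self):
        act = sb.SBEActivity(10.0, enzyme_mass=0.2, reaction_time=5.0)
        assert sb.expected_events(act) == pytest.approx(10.0)

    def test_zero_activity(self):
        act = sb.SBEActivity(0.0, 1.0, 60.0)
        assert sb.expected_events(act) == 0.0

    def test_wild_type_hour(self):
        act = sb.SBEActivity(34.3, 1.0, 60.0)
        assert sb.expected_events(act) == pytest.approx(2058.0)

    def test_bad_scale(self):
        act = sb.SBEActivity(1.0)
        with pytest.raises(ParameterError):
            sb.expected_events(act, population_scale=0.0)


class TestSimulateInVitro:
    def test_zero_activity_is_the_control(self):
        pop = sb.ChainPopulation({500: 100})
        spec = sb.SBESpecificity(6, 6)
        trace = sb.simulate_in_vitro(
            pop, spec, sb.SBEActivity(0.0), sample_times_h=(0, 3, 6, 9, 24), seed=1
        )
        for _, p, events in trace.timepoints:
            assert p == pop and events == 0

    def test_dp12_substrate_saturates_to_dp6(self):
        # every DP-12 donor has exactly one cut, yielding 6 + 6; products
        # are ineligible so the reaction saturates at {6: 200}
        pop = sb.ChainPopulation({12: 100})
        spec = sb.SBESpecificity(6, 6)
        act = sb.SBEActivity(1000.0, 1.0, 60.0)
        trace = sb.simulate_in_vitro(pop, spec, act, (0, 1), seed=2)
        assert trace.saturated
        assert trace.final_population().counts == {6: 200}

    def test_conservation_and_bookkeeping(self, wt_spec):
        pop = sb.ChainPopulation({500: 200, 300: 100})
        act = sb.SBEActivity(30.0, 1.0, 60.0)
        trace = sb.simulate_in_vitro(pop, wt_spec, act, (0, 1, 2), seed=3)
        for _, p, events in trace.timepoints:
            assert p.total_glucose == pop.total_glucose
            assert p.total_chains - pop.total_chains == events
        events = [e for _, _, e in trace.timepoints]
        assert events == sorted(events)

    def test_constraint_minima_on_long_chains(self, wt_spec):
        pop = sb.ChainPopulation({500: 200})
        act = sb.SBEActivity(40.0, 1.0, 60.0)
        trace = sb.simulate_in_vitro(pop, wt_spec, act, (0, 1), seed=4)
        final = trace.final_population()
        assert min(final.counts) == 6
        # nothing between the product minimum and twice it minus one except
        # lengths >= 6; no product below 6 ever
        assert all(dp >= 6 for dp in final.counts)

    def test_mean_dp_nonincreasing(self, wt_spec):
        pop = sb.ChainPopulation({500: 300})
        act = sb.SBEActivity(20.0, 1.0, 24 * 60.0)
        trace = sb.simulate_in_vitro(pop, wt_spec, act, (0, 3, 6, 9, 24), seed=5)
        means = [p.mean_dp() for _, p, _ in trace.timepoints]
        assert all(b <= a for a, b in zip(means, means[1:]))

    def test_deterministic_given_seed(self, wt_spec):
        pop = sb.ChainPopulation({400: 100})
        act = sb.SBEActivity(10.0, 1.0, 60.0)
        a = sb.simulate_in_vitro(pop, wt_spec, act, (0, 1), seed=6)
        b = sb.simulate_in_vitro(pop, wt_spec, act, (0, 1), seed=6)
        assert a.final_population() == b.final_population()
        assert a.total_events() == b.total_events()

    def test_expected_count_variant_is_exact(self, wt_spec):
        pop = sb.ChainPopulation({500: 100})
        act = sb.SBEActivity(5.0, 2.0, 60.0)  # 600 nmol over an hour
        trace = sb.simulate_in_vitro(
            pop, wt_spec, act, (0, 1), seed=7, poisson=False
        )
        assert trace.total_events() == 600

    def test_bad_sample_times(self, wt_spec):
        pop = sb.ChainPopulation({500: 10})
        act = sb.SBEActivity(1.0)
        with pytest.raises(ParameterError):
            sb.simulate_in_vitro(pop, wt_spec, act, (1, 2), seed=0)
        with pytest.raises(ParameterError):
            sb.simulate_in_vitro(pop, wt_spec, act, (0, 2, 1), seed=0)


class TestStructureTracking:
    @pytest.mark.parametrize("transfer", ["inter", "intra"])
    def test_structure_debranches_to_population_ledger(self, transfer):
        pop = sb.ChainPopulation({60: 40})
        spec = sb.SBESpecificity(6, 6)
        act = sb.SBEActivity(2.0, 1.0, 60.0)
        trace = sb.simulate_in_vitro(
            pop, spec, act, (0, 1), seed=9,
            track_structure=True, transfer=transfer,
        )
        assert trace.total_events() > 0
        assert sb.debranch(trace.molecules) == trace.final_population()

    def test_debranched_cld_invariant_to_transfer_mode(self):
        pop = sb.ChainPopulation({60: 40})
        spec = sb.SBESpecificity(6, 6)
        act = sb.SBEActivity(2.0, 1.0, 60.0)
        runs = {
            mode: sb.simulate_in_vitro(
                pop, spec, act, (0, 1), seed=9,
                track_structure=True, transfer=mode,
            )
            for mode in ("inter", "intra")
        }
        assert (
            runs["inter"].final_population() == runs["intra"].final_population()
        )

    def test_no_giant_molecules_from_inter_transfer(self):
        # branching moves segments between molecules but each event splits
        # one chain, so the molecule count is conserved
        pop = sb.ChainPopulation({60: 40})
        spec = sb.SBESpecificity(6, 6)
        act = sb.SBEActivity(2.0, 1.0, 60.0)
        trace = sb.simulate_in_vitro(
            pop, spec, act, (0, 1), seed=10, track_structure=True
        )
        assert trace.molecules.n_molecules() == 40
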