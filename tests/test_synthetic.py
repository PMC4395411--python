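"""Synthetic substrates and the emulated FACE / SEC measurement channels."""

import numpy as np
import pytest
from scipy import stats

import sbecld as sb
from sbecld.errors import DegenerateInputError, ParameterError


class TestLinearSubstrate:
    def test_empty(self):
        pop = sb.make_linear_substrate(
            sb.SubstrateSpec(n_chains=0, mean_dp=500, seed=0)
        )
        assert pop.total_chains == 0

    def test_mean_within_three_standard_errors(self):
        # lognormal with cv 0.5: sd = 250, se = 2.5 at n = 1e4; allow 3 se
        spec = sb.SubstrateSpec(n_chains=10_000, mean_dp=500.0, seed=42)
        pop = sb.make_linear_substrate(spec)
        assert abs(pop.mean_dp() - 500.0) < 3 * 250.0 / np.sqrt(10_000)
        assert min(pop.counts) >= 1

    def test_degenerate_limit(self):
        spec = sb.SubstrateSpec(n_chains=100, mean_dp=1.0, dispersion=0.0, seed=0)
        pop = sb.make_linear_substrate(spec)
        assert pop.counts == {1: 100}

    def test_bit_reproducible(self):
        spec = sb.SubstrateSpec(n_chains=5000, mean_dp=500.0, seed=7)
        assert sb.make_linear_substrate(spec) == sb.make_linear_substrate(spec)

    def test_invalid_mean_rejected(self):
        with pytest.raises(ParameterError):
            sb.SubstrateSpec(n_chains=10, mean_dp=0.5)


class TestAmylopectinSubstrate:
    def test_empty(self, reference_params):
        assert not sb.make_amylopectin_substrate(reference_params, 0, seed=0)

    def test_mode_matches_model(self, reference_params, reference_solution):
        pop = sb.make_amylopectin_substrate(reference_params, 100_000, seed=3)
        dp, n = pop.as_arrays()
        assert dp[np.argmax(n)] == reference_solution.mode_dp()

    def test_converges_in_total_variation(self, reference_params, reference_solution):
        pop = sb.make_amylopectin_substrate(reference_params, 200_000, seed=5)
        emp = sb.to_number_cld(pop, "chains100")
        assert sb.total_variation(emp, reference_solution.cld) < 0.01

    def test_high_beta_confines_support(self):
        # immediate cleavage of any eligible chain keeps everything short
        params = sb.EnzymeSetParams(beta=50.0, x_min=6, x_0=6)
        pop = sb.make_amylopectin_substrate(params, 50_000, seed=1, x_max=60)
        assert max(pop.counts) < 2 * params.s

    def test_deterministic(self, reference_params):
        a = sb.make_amylopectin_substrate(reference_params, 10_000, seed=9)
        b = sb.make_amylopectin_substrate(reference_params, 10_000, seed=9)
        assert a == b


class TestFaceMeasure:
    def test_single_dp(self):
        cld = sb.face_measure(
            sb.ChainPopulation({6: 100}), sb.InstrumentSpec(seed=0)
        )
        assert cld.values == pytest.approx({6: 100.0})

    def test_truncation_forced(self):
        pop = sb.ChainPopulation({100: 50, 200: 50})
        cld = sb.face_measure(pop, sb.InstrumentSpec(face_max_dp=160, seed=0))
        assert cld.values == pytest.approx({100: 100.0})

    def test_all_above_truncation_errors(self):
        pop = sb.ChainPopulation({500: 10})
        with pytest.raises(DegenerateInputError):
            sb.face_measure(pop, sb.InstrumentSpec(face_max_dp=160, seed=0))

    def test_multinomial_sampling_is_unbiased(self):
        # chi-square goodness of fit of sampled counts vs the true CLD
        pop = sb.ChainPopulation({6: 500, 7: 300, 8: 150, 9: 50})
        inst = sb.InstrumentSpec(face_sampling_n=100_000, seed=11)
        cld = sb.face_measure(pop, inst)
        observed = np.array([cld[d] for d in (6, 7, 8, 9)]) * 1000.0  # back to counts
        expected = np.array([500, 300, 150, 50]) / 1000.0 * 100_000
        assert stats.chisquare(observed, expected).pvalue > 0.01

    def test_measurement_is_pure(self):
        pop = sb.ChainPopulation({6: 5, 200: 5})
        before = pop.counts
        sb.face_measure(pop, sb.InstrumentSpec(face_max_dp=160, seed=0))
        assert pop.counts == before


class TestSecMeasure:
    def test_zero_sigma_equals_exact_transform(self):
        pop = sb.ChainPopulation({6: 3, 40: 1})
        inst = sb.InstrumentSpec(sec_band_sigma=0.0, noise_scale=0.0, seed=0)
        measured = sb.sec_measure(pop, inst)
        exact = sb.number_to_weight_log(sb.to_number_cld(pop))
        np.testing.assert_allclose(measured.x, exact.x)
        np.testing.assert_allclose(measured.w, exact.w)

    def test_point_mass_broadens_to_gaussian_at_log_dp(self):
        pop = sb.ChainPopulation({50: 10})
        inst = sb.InstrumentSpec(sec_band_sigma=0.05, noise_scale=0.0, seed=0)
        w = sb.sec_measure(pop, inst)
        peak_x = w.x[np.argmax(w.w)]
        # grid resolution is sigma/8, so the peak node is within half a step
        assert np.log10(peak_x) == pytest.approx(np.log10(50), abs=0.05 / 16)
        # closed-form peak height: mass * gaussian normalization (the grid
        # node nearest the center is within sigma/8, a <1% height offset)
        assert w.w.max() == pytest.approx(
            10 * 50**2 / (0.05 * np.sqrt(2 * np.pi)), rel=0.01
        )

    def test_broadening_preserves_area(self):
        pop = sb.ChainPopulation({6: 100, 18: 40, 140: 5})
        inst = sb.InstrumentSpec(sec_band_sigma=0.08, noise_scale=0.0, seed=0)
        w = sb.sec_measure(pop, inst)
        point_mass_area = sum(dp**2 * c for dp, c in pop.counts.items())
        assert w.area() == pytest.approx(point_mass_area, rel=1e-6)

    def test_sigma_to_zero_converges_to_exact(self):
        pop = sb.ChainPopulation({20: 10})
        exact = sb.number_to_weight_log(sb.to_number_cld(pop))
        # compare the broadened curve's mass concentration near log10(20)
        for sigma in (0.02, 0.005):
            inst = sb.InstrumentSpec(sec_band_sigma=sigma, noise_scale=0.0, seed=0)
            w = sb.sec_measure(pop, inst)
            within = np.abs(np.log10(w.x) - np.log10(20)) < 3 * sigma
            u = np.log10(w.x)
            mass_near = np.trapezoid(np.where(within, w.w, 0.0), u)
            assert mass_near == pytest.approx(exact.w.sum(), rel=5e-3)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ParameterError):
            sb.InstrumentSpec(sec_band_sigma=-0.1)

    def test_noise_is_seeded(self):
        pop = sb.ChainPopulation({30: 10})
        inst = sb.InstrumentSpec(sec_band_sigma=0.05, noise_scale=0.01, seed=3)
        a = sb.sec_measure(pop, inst)
        b = sb.sec_measure(pop, inst)
        np.testing.assert_array_equal(a.w, b.w)
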