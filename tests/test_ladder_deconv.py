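import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haptenfit import (
    ConjugateLadder,
    FitConfig,
    MassSpectrum,
    SimulationConfig,
    adjusted_r2,
    fit_ladder,
    predict_ladder,
    select_load_range,
)
from haptenfit.errors import FitError
from haptenfit.pipeline import estimate_hapten_density
from haptenfit.simulate import simulate_spectrum
from tests.conftest import make_sim


def exact_ladder_spectrum(amps, M0=58408.0, delta=1835.0, z=2, sigma=90.0):
    """Noise-free sum of shared-width Gaussians on the exact ladder."""
    centers = np.array([c for _, c in predict_ladder(M0, delta, z, (0, len(amps) - 1))])
    x = np.linspace(centers[0] - 6 * sigma, centers[-1] + 6 * sigma, 6000)
    y = np.zeros_like(x)
    for a, c in zip(amps, centers):
        y += a * np.exp(-0.5 * ((x - c) / sigma) ** 2)
    ladder = ConjugateLadder(M0=M0, delta=delta, z=z, n_min=0, n_max=len(amps) - 1)
    return MassSpectrum(x, y), centers, ladder


class TestPredictLadder:
    def test_doubly_charged_arithmetic(self):
        out = predict_ladder(60_000.0, 2_000.0, 2, (0, 2))
        loads, centers = zip(*out)
        assert loads == (0, 1, 2)
        np.testing.assert_allclose(
            centers, [30_001.007276, 31_001.007276, 32_001.007276], atol=1e-3
        )

    def test_singly_charged_spacing_is_delta(self):
        out = predict_ladder(50_000.0, 1_700.0, 1, (0, 5))
        centers = np.array([c for _, c in out])
        np.testing.assert_allclose(np.diff(centers), 1_700.0, rtol=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(M0=st.floats(10_000.0, 100_000.0), delta=st.floats(500.0, 5_000.0))
    def test_spacing_half_delta_at_z2(self, M0, delta):
        centers = np.array([c for _, c in predict_ladder(M0, delta, 2, (0, 6))])
        np.testing.assert_allclose(np.diff(centers), delta / 2.0, rtol=1e-9)

    def test_invalid_ladder(self):
        with pytest.raises(FitError):
            ConjugateLadder(M0=1000.0, delta=-5.0)


class TestAdjustedR2:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 5.0, 3.0, 4.0])
        assert adjusted_r2(y, y, n_params=2) == pytest.approx(1.0)

    def test_mean_model_zero(self):
        y = np.array([1.0, 2.0, 5.0, 3.0, 4.0])
        fitted = np.full_like(y, y.mean())
        assert adjusted_r2(y, fitted, n_params=0) == pytest.approx(0.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), n_params=st.integers(0, 5))
    def test_matches_brute_force_formula(self, seed, n_params):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=40)
        f = y + rng.normal(scale=0.3, size=40)
        ss_res = sum((a - b) ** 2 for a, b in zip(y, f))
        ss_tot = sum((a - np.mean(y)) ** 2 for a in y)
        r2 = 1 - ss_res / ss_tot
        expected = 1 - (1 - r2) * (len(y) - 1) / (len(y) - n_params - 1)
        assert adjusted_r2(y, f, n_params) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance(self):
        y = np.ones(10)
        with pytest.raises(FitError):
            adjusted_r2(y, y, 0)

    def test_too_few_points(self):
        with pytest.raises(FitError):
            adjusted_r2([1.0, 2.0], [1.0, 2.0], n_params=3)


class TestFitLadder:
    def test_exact_model_recovery(self):
        amps = [0.3, 1.0, 0.7, 0.2]
        spectrum, _, ladder = exact_ladder_spectrum(amps)
        res = fit_ladder(spectrum, ladder)
        assert res.adj_r2 >= 0.9999
        true_areas = np.array(amps) * 90.0 * np.sqrt(2 * np.pi)
        np.testing.assert_allclose(res.areas(), true_areas, rtol=1e-3)
        for peak, a in zip(res.peaks, amps):
            assert abs(peak.amplitude - a) / a <= 1e-3

    def test_noisy_recovery_within_5_percent(self):
        amps = np.array([0.3, 1.0, 0.7, 0.2])
        spectrum, _, ladder = exact_ladder_spectrum(list(amps))
        rng = np.random.default_rng(42)
        noisy = MassSpectrum(
            spectrum.mz,
            np.clip(spectrum.intensity + rng.normal(0, 0.01, len(spectrum)), 0, None),
        )
        res = fit_ladder(noisy, ladder)
        true_areas = amps * 90.0 * np.sqrt(2 * np.pi)
        np.testing.assert_allclose(res.areas(), true_areas, rtol=0.05)

    def test_single_species_pruned_to_one_peak(self):
        amps = [1.0, 0.0, 0.0, 0.0, 0.0]
        spectrum, _, ladder = exact_ladder_spectrum(amps)
        res = fit_ladder(spectrum, ladder)
        assert res.loads() == [0]

    def test_shift_recovered(self):
        amps = [0.5, 1.0, 0.5]
        spectrum, true_centers, ladder = exact_ladder_spectrum(amps)
        shifted = ConjugateLadder(
            M0=ladder.M0 - 60.0, delta=ladder.delta, z=2, n_min=0, n_max=2
        )
        res = fit_ladder(spectrum, shifted)
        # the 60 Da (30 Th) M0 error is absorbed by shift + jitter: fitted
        # centers land on the true peak positions
        for peak, c in zip(res.peaks, true_centers):
            assert peak.center == pytest.approx(c, abs=0.5)
        assert res.adj_r2 >= 0.999

    def test_deterministic(self):
        spectrum, _, ladder = make_sim(seed=3, p=0.2)
        r1 = fit_ladder(spectrum, ladder)
        r2 = fit_ladder(spectrum, ladder)
        np.testing.assert_array_equal(r1.areas(), r2.areas())
        assert r1.adj_r2 == r2.adj_r2

    def test_no_runaway_amplitudes(self):
        spectrum, _, ladder = make_sim(seed=8, p=0.3)
        res = fit_ladder(spectrum, ladder)
        model_max = max(p.amplitude for p in res.peaks)
        assert model_max <= 1.1 * spectrum.intensity.max()

    def test_all_zero_spectrum(self):
        x = np.linspace(28_000.0, 42_000.0, 2000)
        s = MassSpectrum(x, np.zeros_like(x))
        ladder = ConjugateLadder(M0=58_408.0, delta=1_835.0, z=2, n_min=0, n_max=5)
        with pytest.raises(FitError):
            fit_ladder(s, ladder)

    def test_empty_fit_window(self):
        x = np.linspace(100.0, 200.0, 500)
        s = MassSpectrum(x, np.ones_like(x))
        ladder = ConjugateLadder(M0=58_408.0, delta=1_835.0, z=2, n_min=0, n_max=5)
        with pytest.raises(FitError):
            fit_ladder(s, ladder)

    @pytest.mark.parametrize("seed", range(10))
    def test_area_recovery_across_simulations(self, seed):
        # random HD in [1, 8] at SNR >= 50: major species' areas within 5%.
        # Baseline-free input (the fit contract assumes preprocessed data);
        # TOF peak widths grow with m/z, so use the linear width model.
        rng = np.random.default_rng(1000 + seed)
        p = rng.uniform(0.05, 0.4)
        spectrum, truth, ladder = make_sim(
            seed=seed, p=p, noise_sd=0.01, baseline_amplitude=0.0, n_max=20
        )
        res = fit_ladder(spectrum, ladder, FitConfig(width_model="linear"))
        areas = res.areas()
        fractions = dict(zip(res.loads(), areas / areas.sum()))
        for load, frac in truth.species:
            if frac >= 0.05:
                assert load in fractions
                assert abs(fractions[load] - frac) / frac <= 0.05


class TestSelectLoadRange:
    def test_three_species_from_wide_candidate(self):
        cfg = SimulationConfig(
            load_model="explicit",
            explicit_species=[(2, 0.3), (3, 0.5), (4, 0.2)],
            noise_sd=0.002,
            baseline_amplitude=0.0,
            seed=5,
        )
        spectrum, _ = simulate_spectrum(cfg)
        ladder = ConjugateLadder(
            M0=cfg.carrier_mass, delta=cfg.delta, z=2, n_min=0, n_max=10
        )
        assert select_load_range(spectrum, ladder, criterion="bic") == (2, 4)

    def test_single_species(self):
        cfg = SimulationConfig(
            load_model="explicit",
            explicit_species=[(3, 1.0)],
            noise_sd=0.002,
            baseline_amplitude=0.0,
            seed=6,
        )
        spectrum, _ = simulate_spectrum(cfg)
        ladder = ConjugateLadder(
            M0=cfg.carrier_mass, delta=cfg.delta, z=2, n_min=2, n_max=4
        )
        assert select_load_range(spectrum, ladder, criterion="bic") == (3, 3)

    def test_all_zero_errors(self):
        x = np.linspace(28_000.0, 42_000.0, 2000)
        s = MassSpectrum(x, np.zeros_like(x))
        ladder = ConjugateLadder(M0=58_408.0, delta=1_835.0, z=2, n_min=0, n_max=5)
        with pytest.raises(FitError):
            select_load_range(s, ladder)
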