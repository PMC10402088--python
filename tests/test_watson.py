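"""Watson difference-of-exponentials model: closed forms, fitting, bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

from flickerfit.watson import (
    PEAK_GRID_HZ,
    WatsonParams,
    WatsonTSFModel,
    fit_tsf,
    is_unimodal,
    params_for_peak,
    peak_of_fit,
    watson_amplitude,
)

STIM_FREQS = np.array([2.0, 4.0, 8.0, 16.0, 32.0, 64.0])


class TestClosedForms:
    def test_dc_response_is_gain_times_one_minus_surround(self):
        p = WatsonParams(gain=2.5, tau_center_s=0.02, tau_ratio=3.0, surround_gain=0.7)
        assert watson_amplitude(0.0, p) == pytest.approx(2.5 * 0.3, abs=1e-12)

    def test_center_only_amplitude_at_unit_angular_frequency(self):
        # with G_s = 0 and 2*pi*w*tau = 1: |1 + i|^(-9) = 2^(-9/2)
        tau = 0.01
        w = 1.0 / (2.0 * np.pi * tau)
        p = WatsonParams(gain=1.0, tau_center_s=tau, tau_ratio=2.0, surround_gain=0.0)
        assert watson_amplitude(w, p) == pytest.approx(2.0 ** (-4.5), abs=1e-12)

    def test_amplitude_vanishes_at_high_frequency(self):
        p = WatsonParams(gain=1.0, tau_center_s=0.02, tau_ratio=2.0, surround_gain=0.8)
        assert watson_amplitude(1e6, p) < 1e-12


class TestPeakExtraction:
    def test_dense_grid_peak_matches_brute_force_oracle(self):
        p = WatsonParams(gain=1.0, tau_center_s=0.01, tau_ratio=2.0, surround_gain=0.8)
        oracle_grid = np.logspace(np.log10(0.5), 2.0, 100_000)
        oracle_amp = watson_amplitude(oracle_grid, p)
        i = np.argmax(oracle_amp)
        pf, pa = peak_of_fit(p)
        assert abs(np.log10(pf / oracle_grid[i])) <= 0.011
        assert watson_amplitude(oracle_grid[i], p) == pytest.approx(oracle_amp[i], abs=1e-9)

    def test_grid_peak_within_one_step_of_golden_section_refinement(self):
        p = WatsonParams(gain=2.0, tau_center_s=0.008, tau_ratio=1.8, surround_gain=0.9)
        pf, _ = peak_of_fit(p)
        res = minimize_scalar(
            lambda lf: -watson_amplitude(10.0**lf, p),
            bounds=(np.log10(0.5), 2.0),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert abs(np.log10(pf) - res.x) <= 0.011

    def test_lowpass_params_peak_at_grid_edge(self):
        p = WatsonParams(gain=1.0, tau_center_s=0.02, tau_ratio=2.0, surround_gain=0.0)
        pf, _ = peak_of_fit(p)
        assert pf == pytest.approx(PEAK_GRID_HZ[0])

    def test_peak_dominates_stimulus_frequencies(self):
        p = params_for_peak(12.0, 2.0)
        _, pa = peak_of_fit(p)
        assert np.all(pa >= watson_amplitude(STIM_FREQS, p))


class TestFit:
    def test_noiseless_parameter_recovery(self):
        rng = np.random.default_rng(7)
        for _ in range(8):
            true = params_for_peak(
                10 ** rng.uniform(np.log10(2.5), np.log10(40.0)),
                10 ** rng.uniform(-0.5, 0.8),
                tau_ratio=rng.uniform(1.1, 4.0),
                surround_gain=rng.uniform(0.3, 0.95),
            )
            fit = fit_tsf(STIM_FREQS, watson_amplitude(STIM_FREQS, true))
            pf_t, pa_t = peak_of_fit(true)
            pf_e, pa_e = peak_of_fit(fit)
            assert abs(np.log10(pf_e / pf_t)) < 0.05
            assert abs(pa_e / pa_t - 1.0) < 0.02

    def test_filter_orders_held_fixed(self):
        fit = fit_tsf(STIM_FREQS, watson_amplitude(STIM_FREQS, params_for_peak(10, 1)))
        assert fit.n_center == 9 and fit.n_surround == 10

    def test_all_zero_amplitudes_give_zero_gain(self):
        fit = fit_tsf(STIM_FREQS, np.zeros(6))
        assert fit.gain < 1e-6
        assert peak_of_fit(fit)[1] < 1e-6

    def test_fit_is_unimodal(self):
        rng = np.random.default_rng(3)
        amps = watson_amplitude(STIM_FREQS, params_for_peak(16, 2.0))
        fit = fit_tsf(STIM_FREQS, amps + 0.3 * rng.standard_normal(6))
        assert is_unimodal(fit)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(c=st.floats(0.1, 10.0))
    def test_scale_equivariance(self, c):
        amps = watson_amplitude(STIM_FREQS, params_for_peak(10.0, 2.0))
        f1 = fit_tsf(STIM_FREQS, amps)
        f2 = fit_tsf(STIM_FREQS, c * amps)
        pf1, pa1 = peak_of_fit(f1)
        pf2, pa2 = peak_of_fit(f2)
        assert abs(np.log10(pf2 / pf1)) < 0.02
        assert pa2 == pytest.approx(c * pa1, rel=0.02)

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            fit_tsf([2.0, 4.0, 8.0], [1.0, 2.0, 1.0])


class TestBootstrap:
    def test_default_replicate_count_is_1000(self):
        import inspect

        from flickerfit.watson import WatsonTSFResults

        sig = inspect.signature(WatsonTSFResults.bootstrap)
        assert sig.parameters["n_boot"].default == 1000

    def test_identical_acquisitions_have_zero_iqr(self):
        amps = watson_amplitude(STIM_FREQS, params_for_peak(12.0, 2.0))
        model = WatsonTSFModel(STIM_FREQS, np.tile(amps, (6, 1)))
        summ = model.fit().bootstrap(n_boot=50, seed=0)
        assert np.allclose(summ.amplitude_iqr_high - summ.amplitude_iqr_low, 0.0)
        assert np.allclose(summ.amplitude_median, amps)
        assert summ.peak_freq_hz_iqr[0] == summ.peak_freq_hz_iqr[1]

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(0)
        data = watson_amplitude(STIM_FREQS, params_for_peak(10, 2.0)) + 0.2 * rng.standard_normal((8, 6))
        res = WatsonTSFModel(STIM_FREQS, data).fit()
        s1 = res.bootstrap(n_boot=100, seed=5)
        s2 = res.bootstrap(n_boot=100, seed=5)
        assert s1.peak_freq_hz_median == s2.peak_freq_hz_median

    def test_summary_mentions_peak(self):
        res = WatsonTSFModel(STIM_FREQS, np.tile(watson_amplitude(STIM_FREQS, params_for_peak(10, 2.0)), (2, 1))).fit()
        text = res.summary()
        assert "peak frequency" in text and "nc=9, ns=10" in text
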