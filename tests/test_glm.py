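"""Joint HRF + amplitude time-series fit: recovery, averaging, selection."""

import numpy as np
import pandas as pd
import pytest

from flickerfit import FlickerGLM, GroundTruth, simulate_bold
from flickerfit.design import dct_highpass_basis
from flickerfit.glm import AmplitudeTable, relative_amplitudes
from flickerfit.simulate import true_amplitude_table


def _merge(est: AmplitudeTable, true: AmplitudeTable) -> pd.DataFrame:
    keys = ["vertex", "acquisition", "direction", "sequence_label", "frequency_hz"]
    return est.table.merge(true.table, on=keys, suffixes=("_est", "_true"))


class TestNoiselessRecovery:
    def test_amplitudes_recovered_exactly(
        self, noiseless_fit, schedules, noiseless_truth, geometry
    ):
        true = true_amplitude_table(schedules, noiseless_truth, geometry)
        m = _merge(noiseless_fit.amplitudes, true)
        assert np.max(np.abs(m["amplitude_est"] - m["amplitude_true"])) < 1e-6

    def test_full_study_time_and_covariate_counts(self, noiseless_fit):
        model = noiseless_fit.model
        assert model.n_acq * model.n_samp == 12096
        assert model.n_acq * 8 == 288

    def test_r2_is_one(self, noiseless_fit):
        assert np.all(np.abs(noiseless_fit.r2 - 1.0) < 1e-9)

    def test_attention_amplitude_recovered(self, noiseless_fit, noiseless_truth):
        att = noiseless_fit.attention_amplitudes
        # acquisitions with at least one attention event recover the amplitude
        scheds = noiseless_fit.model.data.schedules
        has_event = att["acquisition"].map(lambda a: len(scheds[a].attention_onsets) > 0)
        est = att.loc[has_event, "amplitude"]
        assert np.max(np.abs(est - noiseless_truth.attention_amplitude)) < 1e-6


class TestNoisyRecovery:
    def test_crossing_mean_relative_amplitudes_correlate_with_truth(
        self, noisy_fit, schedules, noisy_truth, geometry
    ):
        from flickerfit.simulate import _pattern_templates

        templates = _pattern_templates(noisy_truth, len(geometry), np.random.default_rng(3))
        true = true_amplitude_table(schedules, noisy_truth, geometry, templates=templates)
        m = _merge(noisy_fit.amplitudes.relative(), true.relative())
        m = m[m["frequency_hz"] > 0]
        g = m.groupby(["vertex", "direction", "frequency_hz"])[
            ["amplitude_est", "amplitude_true"]
        ].mean()
        r = np.corrcoef(g["amplitude_est"], g["amplitude_true"])[0, 1]
        assert r > 0.95

    def test_hrf_weights_close_to_generating_kernel(self, noisy_fit, basis):
        w_true = basis.canonical_weights()
        w_true = w_true / float(np.sum(basis.kernels @ w_true))
        err = np.linalg.norm(noisy_fit.hrf_weights - w_true, axis=1)
        assert np.median(err) < 0.1 * np.linalg.norm(w_true)


class TestDriftInvariance:
    def test_amplitudes_invariant_to_subcutoff_drift(
        self, schedules, basis, geometry
    ):
        truth = GroundTruth.noiseless()
        ds = simulate_bold(schedules[:6], truth, basis, geometry, seed=5)
        res0 = FlickerGLM(ds, basis).fit()
        # add drift lying in the slow DCT subspace (frequencies < cutoff)
        dct = dct_highpass_basis(336)
        drift = 2.0 * (dct[:, 3] + 0.5 * dct[:, 10])
        ds_d = simulate_bold(schedules[:6], truth, basis, geometry, seed=5)
        ds_d.data = ds_d.data + np.tile(drift, 6)[None, :]
        res1 = FlickerGLM(ds_d, basis).fit()
        assert np.max(np.abs(res1.betas - res0.betas)) < 1e-3


class TestCleanAndAverage:
    def test_pure_noise_r2_is_low(self, schedules, basis):
        from flickerfit.simulate import make_vertex_geometry

        geom = make_vertex_geometry(40, seed=8)
        truth = GroundTruth.noiseless(
            peak_amps={"LMS": 0.0, "L-M": 0.0, "S": 0.0},
            noise_sd=0.5,
            attention_amplitude=0.0,
        )
        ds = simulate_bold(schedules, truth, basis, geom, seed=21)
        res = FlickerGLM(ds, basis).fit(optimize_hrf=False)
        assert np.mean(res.r2) < 0.1

    def test_averaging_six_identical_acquisitions_is_identity(
        self, noiseless_fit, noiseless_dataset
    ):
        avg = noiseless_fit.clean_and_average()
        combos = avg["combos"]
        # noiseless data: averaged filtered data equals the filtered model
        assert len(combos) == 6
        assert np.max(np.abs(avg["data"] - avg["model"])) < 1e-8


class TestSelection:
    def test_strict_threshold(self, noiseless_fit):
        res = noiseless_fit
        r2 = np.array([0.05, 0.10, 0.35])
        keep = r2 > 0.1
        assert list(keep) == [False, False, True]
        # and on the fitted object: all noiseless vertices pass
        assert len(res.select_vertices(0.1)) == len(res.model.vertex_indices)

    def test_empty_selection_is_explicit_not_error(self, noiseless_fit):
        sel = noiseless_fit.select_vertices(threshold=2.0)
        assert sel.size == 0

    def test_signal_and_null_vertices_separated(self, schedules, basis):
        from flickerfit.simulate import make_vertex_geometry

        geom = make_vertex_geometry(30, seed=9)
        signal = GroundTruth.default(noise_sd=0.3, pattern_scale=0.0)
        null = GroundTruth.noiseless(
            peak_amps={"LMS": 0.0, "L-M": 0.0, "S": 0.0},
            noise_sd=0.3,
            attention_amplitude=0.0,
        )
        ds_s = simulate_bold(schedules, signal, basis, geom, seed=31)
        ds_n = simulate_bold(schedules, null, basis, geom, seed=32)
        r2_s = FlickerGLM(ds_s, basis).fit(optimize_hrf=False).r2
        r2_n = FlickerGLM(ds_n, basis).fit(optimize_hrf=False).r2
        sensitivity = np.mean(r2_s > 0.1)
        specificity = np.mean(r2_n <= 0.1)
        assert sensitivity > 0.9 and specificity > 0.9


class TestRelativeAmplitudes:
    def test_zero_hz_reference_subtraction(self):
        df = pd.DataFrame(
            {
                "vertex": [0, 0],
                "acquisition": [0, 0],
                "direction": ["LMS", "LMS"],
                "sequence_label": ["A", "A"],
                "frequency_hz": [0.0, 16.0],
                "amplitude": [0.2, 1.0],
            }
        )
        rel = relative_amplitudes(AmplitudeTable(df)).table
        assert rel.loc[rel.frequency_hz == 16.0, "amplitude"].item() == pytest.approx(0.8)
        assert rel.loc[rel.frequency_hz == 0.0, "amplitude"].item() == pytest.approx(0.0)

    def test_shift_invariance_per_acquisition(self, noiseless_fit):
        table = noiseless_fit.amplitudes
        shifted = AmplitudeTable(table.table.assign(amplitude=table.table.amplitude + 1.7))
        a = table.relative().table["amplitude"].to_numpy()
        b = shifted.relative().table["amplitude"].to_numpy()
        assert np.allclose(a, b, atol=1e-12)

    def test_n_measures_is_12_for_full_study(self, noiseless_fit):
        counts = noiseless_fit.amplitudes.n_measures()
        assert (counts == 12).all()


class TestEdgeCases:
    def test_zero_variance_vertex_gives_zero_amplitudes(self, schedules, basis, geometry):
        truth = GroundTruth.noiseless()
        ds = simulate_bold(schedules[:2], truth, basis, geometry, seed=0)
        ds.data[2] = 0.0
        res = FlickerGLM(ds, basis).fit()
        assert np.allclose(res.betas[2], 0.0)
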