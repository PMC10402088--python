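"""Stimulus sequence construction, schedules, design matrices, high-pass."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flickerfit import design as dsn
from flickerfit.design import (
    build_design_matrix,
    build_study_schedule,
    dct_highpass_basis,
    highpass_project,
    make_counterbalanced_sequence,
    split_and_pad,
)
from flickerfit.hrf import build_orthonormal_basis, kernel_from_params


class TestCounterbalancedSequence:
    def test_seven_conditions_has_fifty_elements(self):
        seq = make_counterbalanced_sequence(7, seed=0)
        assert len(seq.elements) == 50
        seq.validate()

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(k=st.integers(1, 6), seed=st.integers(0, 10_000))
    def test_every_ordered_pair_occurs_exactly_once(self, k, seed):
        seq = make_counterbalanced_sequence(k, seed=seed)
        assert len(seq.elements) == k * k + 1
        assert np.array_equal(seq.pair_counts(), np.ones((k, k), dtype=int))

    def test_single_condition_gives_repeat_pair(self):
        seq = make_counterbalanced_sequence(1, seed=5)
        assert seq.elements == (1, 1)

    def test_two_conditions_matches_exhaustive_enumeration(self):
        # brute force over all 2^5 candidate sequences: the valid set is the
        # set of length-5 sequences whose 4 consecutive pairs are exactly
        # {(1,1),(1,2),(2,1),(2,2)}
        valid = set()
        for cand in itertools.product((1, 2), repeat=5):
            pairs = sorted(zip(cand[:-1], cand[1:]))
            if pairs == [(1, 1), (1, 2), (2, 1), (2, 2)]:
                valid.add(cand)
        assert valid  # existence by enumeration
        for seed in range(10):
            seq = make_counterbalanced_sequence(2, seed=seed)
            assert seq.elements in valid

    def test_seeded_reproducibility(self):
        a = make_counterbalanced_sequence(7, seed=42)
        b = make_counterbalanced_sequence(7, seed=42)
        assert a.elements == b.elements

    def test_invalid_condition_count_raises(self):
        with pytest.raises(ValueError):
            make_counterbalanced_sequence(0, seed=0)


class TestSplitAndPad:
    def test_halves_are_28_trials_with_zero_padding(self):
        seq = make_counterbalanced_sequence(7, seed=0)
        a, b = split_and_pad(seq)
        assert len(a) == len(b) == 28
        assert a[-3:] == [0.0, 0.0, 0.0]
        assert b[-3:] == [0.0, 0.0, 0.0]

    def test_concatenation_recovers_master_sequence(self):
        seq = make_counterbalanced_sequence(7, seed=3)
        a, b = split_and_pad(seq)
        master = [dsn.frequency_of_condition(c) for c in seq.elements]
        assert a[:25] + b[:25] == master

    def test_wrong_length_raises(self):
        seq = make_counterbalanced_sequence(2, seed=0)
        with pytest.raises(ValueError):
            split_and_pad(seq)


class TestStudySchedule:
    def test_full_study_structure(self, schedules):
        assert len(schedules) == 36
        assert sum(s.acquisition_duration_s for s in schedules) == 36 * 336
        for s in schedules:
            s.validate()

    def test_blocks_contain_two_acquisitions_per_direction(self, schedules):
        for b in range(6):
            block = schedules[b * 6 : (b + 1) * 6]
            dirs = [s.direction for s in block]
            assert dirs == ["LMS", "L-M", "S", "S", "L-M", "LMS"]
            assert [s.sequence_label for s in block] == list("AAABBB")

    def test_attention_rate_matches_design_probability(self):
        # Monte-Carlo over many seeded schedules
        counts = []
        for seed in range(40):
            for s in build_study_schedule(seed)[:2]:
                counts.append(len(s.attention_onsets))
        rate = np.mean(counts) / 28
        assert abs(rate - 0.33) < 0.02

    def test_attention_events_respect_trial_guard(self, schedules):
        for s in schedules:
            for a in s.attention_onsets:
                within = a % 12.0
                assert 2.0 <= within <= 10.0 - 0.25


class TestDesignMatrix:
    def test_full_study_has_288_covariates(self, schedules):
        dm = build_design_matrix(schedules)
        assert dm.n_covariates == 288
        assert dm.matrix.shape[0] == 12096

    def test_single_acquisition_has_8_columns(self, schedules):
        dm = build_design_matrix(schedules[:1])
        assert dm.n_covariates == 8

    def test_unconvolved_column_sums_count_trial_support(self, schedules):
        dm = build_design_matrix(schedules[:3])
        for col, (acq, tag) in enumerate(dm.labels):
            if tag.endswith("Hz"):
                f = float(tag[:-2])
                n_trials = sum(
                    1 for t in schedules[acq].trials if t.frequency_hz == f
                )
                assert dm.matrix[:, col].sum() == 12 * n_trials

    def test_convolution_stays_within_acquisition(self, schedules, basis):
        kernel = kernel_from_params(basis, basis.canonical_weights())
        dm = build_design_matrix(schedules[:2], hrf_kernel=kernel)
        first_cols = [c for c, (a, _) in enumerate(dm.labels) if a == 0]
        assert np.all(dm.matrix[336:, first_cols] == 0.0)

    def test_unknown_frequency_raises(self, schedules):
        import copy

        bad = copy.deepcopy(schedules[0])
        bad.trials[0] = dsn.Trial(0.0, 12.0, 5.0)
        with pytest.raises(ValueError, match="unknown"):
            build_design_matrix([bad])


class TestHighpass:
    def test_constant_signal_is_removed(self):
        out = highpass_project(np.full(336, 3.7))
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_fast_sinusoid_passes_through(self):
        t = np.arange(336.0)
        x = np.sin(2 * np.pi * 0.1 * t)
        out = highpass_project(x)
        # oracle: independent least-squares projection onto explicitly
        # constructed slow regressors (constant + cosines below cutoff)
        regs = [np.ones(336)]
        k = 1
        while k / (2 * 336) < 0.0387:
            regs.append(np.cos(np.pi * k * (t + 0.5) / 336))
            k += 1
        X = np.column_stack(regs)
        beta, *_ = np.linalg.lstsq(X, x, rcond=None)
        oracle = x - X @ beta
        assert np.max(np.abs(out - oracle)) < 1e-10
        # the fast signal is nearly orthogonal to the slow set: almost all of
        # its power survives, and mid-signal samples are barely perturbed
        assert np.sum(out**2) > 0.99 * np.sum(x**2)
        mid = slice(112, 224)
        assert np.max(np.abs(out[mid] - x[mid])) < 0.02

    def test_slow_sinusoid_is_suppressed(self):
        t = np.arange(336.0)
        x = np.sin(2 * np.pi * 0.01 * t + 0.4)
        out = highpass_project(x)
        assert np.sum(out**2) < 0.05 * np.sum(x**2)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(672)
        once = highpass_project(x, segment_length=336)
        twice = highpass_project(once, segment_length=336)
        assert np.max(np.abs(twice - once)) < 1e-10

    def test_empty_signal_raises(self):
        with pytest.raises(ValueError):
            highpass_project(np.array([]))

    def test_basis_is_orthonormal(self):
        b = dct_highpass_basis(336)
        assert np.allclose(b.T @ b, np.eye(b.shape[1]), atol=1e-10)
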