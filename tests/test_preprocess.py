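"""Preprocessing oracles: averaging, filtering, differentiation, segmentation,
normalization, and the exclusion bookkeeping."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liftsig.preprocess import (CHANNELS, FilterSpec, SegmentationError,
                                barbell_centre, differentiate, lowpass,
                                normalize_and_trim, process_dataset,
                                process_trial, segment_trial, total_grf)


class TestElementwiseOps:
    def test_centre_identity_and_midpoint(self):
        x = np.arange(12.0).reshape(4, 3)
        np.testing.assert_array_equal(barbell_centre(x, x), x)
        left = np.array([[0.0, 0.0, 0.0]])
        right = np.array([[2.0, 0.0, 1.0]])
        np.testing.assert_array_equal(barbell_centre(left, right),
                                      [[1.0, 0.0, 0.5]])

    def test_centre_matches_loop_oracle(self, rng):
        left = rng.normal(size=(50, 3))
        right = rng.normal(size=(50, 3))
        oracle = np.array([[(left[i, j] + right[i, j]) / 2 for j in range(3)]
                           for i in range(50)])
        np.testing.assert_allclose(barbell_centre(left, right), oracle, rtol=1e-15)

    def test_total_grf_additive_identity_and_oracle(self, rng):
        p1 = rng.normal(size=(40, 3))
        np.testing.assert_array_equal(total_grf(p1, np.zeros_like(p1)), p1)
        p2 = rng.normal(size=(40, 3))
        oracle = np.array([[p1[i, j] + p2[i, j] for j in range(3)]
                           for i in range(40)])
        np.testing.assert_allclose(total_grf(p1, p2), oracle, rtol=1e-15)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            barbell_centre(np.zeros((5, 3)), np.zeros((6, 3)))
        with pytest.raises(ValueError):
            total_grf(np.zeros((5, 3)), np.zeros((5, 2)))


class TestLowpass:
    def test_dc_gain_unity(self):
        x = np.full(500, 3.7)
        np.testing.assert_allclose(lowpass(x, 250, 4), x, rtol=1e-9)

    def test_cutoff_attenuation_is_half(self):
        # two passes of a 4th-order Butterworth: |H|^2 = 1/2 at the cutoff
        fs, f = 250.0, 4.0
        t = np.arange(0, 60, 1 / fs)
        y = lowpass(np.sin(2 * np.pi * f * t), fs, f)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        ratio = np.abs(y[mid]).max()
        assert ratio == pytest.approx(0.5, abs=0.02)

    def test_passband_flat(self):
        fs, f = 250.0, 0.4
        t = np.arange(0, 60, 1 / fs)
        y = lowpass(np.sin(2 * np.pi * f * t), fs, 4.0)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        assert np.abs(y[mid]).max() > 0.99

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass(np.zeros(100), 250, 125)


class TestDifferentiate:
    def test_exact_on_ramp_including_ends(self):
        fs, a = 250.0, 1.37
        t = np.arange(200) / fs
        v = differentiate(a * t, fs)
        np.testing.assert_allclose(v, a, rtol=1e-9)

    def test_zero_on_constant(self):
        np.testing.assert_allclose(differentiate(np.full(100, 2.0), 250), 0.0,
                                   atol=1e-12)

    def test_sine_error_within_taylor_bound(self):
        # central differences: |error| <= (2 pi f)^3 / (6 fs^2) for unit sine
        fs, f = 250.0, 3.0
        t = np.arange(1000) / fs
        v = differentiate(np.sin(2 * np.pi * f * t), fs)
        exact = 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        bound = (2 * np.pi * f) ** 3 / (6 * fs**2)
        assert np.abs(v[1:-1] - exact[1:-1]).max() < bound

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            differentiate(np.array([1.0, 2.0]), 250)


class TestSegmentation:
    def test_start_index_at_threshold_crossing(self):
        v = np.array([0.000, 0.004, 0.011, 0.5, 1.0, -0.2, 0.1])
        z = np.array([0.0, 0.0, 0.1, 0.4, 0.9, 0.7, 0.6])
        start, _ = segment_trial(v, z, 250)
        assert start == 2

    def test_catch_index_hand_traced(self):
        # position max at sample 60; velocity negative on 61-70, >= 0 at 71
        n = 100
        v = np.full(n, 0.02)
        z = np.linspace(0, 1, n)
        z[60] = 2.0
        z[61:] = 1.5
        v[61:71] = -0.3
        v[71:] = 0.0
        start, catch = segment_trial(v, z, 250)
        assert start == 0
        assert catch == 71

    def test_no_negative_phase_raises(self):
        v = np.full(50, 0.5)
        z = np.linspace(0, 1, 50)
        with pytest.raises(SegmentationError):
            segment_trial(v, z, 250)

    def test_never_reaching_threshold_raises(self):
        v = np.full(50, 0.005)
        with pytest.raises(SegmentationError):
            segment_trial(v, np.linspace(0, 1, 50), 250)

    def test_no_return_to_zero_raises(self):
        v = np.r_[np.full(30, 0.5), np.full(30, -0.2)]
        z = np.r_[np.linspace(0, 1, 30), np.linspace(1, 0.5, 30)]
        with pytest.raises(SegmentationError):
            segment_trial(v, z, 250)


class TestNormalizeAndTrim:
    def test_channel_lengths_and_baseline(self, processed):
        for trial in processed[:20]:
            assert set(trial.channels) == set(CHANNELS)
            for ch in CHANNELS:
                assert trial.channels[ch].shape == (101,)
            assert trial.channels["position.AP"][0] == 0.0
            assert trial.channels["position.V"][0] == 0.0

    def test_constant_grf_scales_to_g(self):
        n, m = 200, 800
        mass = 80.0
        pos = np.zeros((n, 3))
        pos[:, 2] = np.linspace(0, 1, n)
        vel = np.ones((n, 3))
        grf = np.zeros((m, 3))
        grf[:, 2] = mass * 9.81
        out = normalize_and_trim(pos, vel, grf, 10, 190, 250, 1000, 1.8, mass)
        np.testing.assert_allclose(out["GRF.V"], 9.81, rtol=1e-12)

    def test_resampling_passes_through_knots(self):
        # trim window spanning the whole series with 101 samples: identity
        n = 101
        pos = np.zeros((n, 3))
        pos[:, 2] = np.sin(np.linspace(0, 3, n))
        vel = np.zeros((n, 3))
        grf = np.zeros((4 * n, 3))
        out = normalize_and_trim(pos, vel, grf, 0, n - 1, 250, 1000, 1.0, 70.0)
        np.testing.assert_allclose(out["position.V"], pos[:, 2] - pos[0, 2],
                                   rtol=1e-12)

    def test_bad_body_metrics_rejected(self):
        z = np.zeros((50, 3))
        with pytest.raises(ValueError):
            normalize_and_trim(z, z, np.zeros((200, 3)), 0, 40, 250, 1000, 0.0, 70)

    @settings(max_examples=10, deadline=None)
    @given(st.floats(min_value=0.5, max_value=2.0))
    def test_body_size_scale_invariance(self, k):
        """Scaling positions and body height by k (and GRF and body mass by k)
        leaves the normalized channels unchanged, events held fixed.  The
        event detection itself is intentionally dimensional (the 0.01 m/s
        onset threshold is a protocol constant), so invariance is a property
        of the normalization."""
        rng = np.random.default_rng(21)
        n, m = 400, 1600
        pos = rng.normal(size=(n, 3)).cumsum(axis=0) * 0.01
        vel = rng.normal(size=(n, 3))
        grf = rng.normal(size=(m, 3)) * 100
        base = normalize_and_trim(pos, vel, grf, 20, 380, 250, 1000, 1.8, 80.0)
        out = normalize_and_trim(pos * k, vel * k, grf * k, 20, 380, 250, 1000,
                                 1.8 * k, 80.0 * k)
        for ch in CHANNELS:
            np.testing.assert_allclose(out[ch], base[ch], rtol=1e-9, atol=1e-12)


class TestPipelineBookkeeping:
    def test_labels_pass_through(self, dataset, processed):
        raw_keys = sorted(r.key for r in dataset)
        proc_keys = sorted(p.key for p in processed)
        assert raw_keys == proc_keys

    def test_event_ordering(self, processed):
        for trial in processed:
            assert trial.start_time_s < trial.peak_time_s < trial.catch_time_s

    def test_exclusions_are_counted_and_logged(self, dataset):
        # corrupt one trial so that it cannot be segmented
        bad = dataclasses.replace(
            dataset[0],
            marker_left=dataset[0].marker_left.copy(),
            marker_right=dataset[0].marker_right.copy())
        ramp = np.linspace(0, 1.5, bad.marker_left.shape[0])
        bad.marker_left[:, 2] = ramp
        bad.marker_right[:, 2] = ramp
        processed, exclusions = process_dataset([bad] + list(dataset[1:5]))
        assert len(processed) + len(exclusions) == 5
        assert len(exclusions) == 1
        assert exclusions[0][0] == bad.key
        assert "negative-velocity" in exclusions[0][1]
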