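"""OD conversion, filtering, GSR, GVTD, censoring, DPF and the MBLL."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from infantfc.preprocess import (GvtdTrace, ODSeries, bandpass, compute_gvtd, dpf,
                                 extinction_coefficients, global_signal_regression,
                                 hb_to_od, intensity_to_od, mask_and_segment, od_to_hb)

FS = 10.0
WL = (780.0, 850.0)


class TestIntensityToOD:
    def test_constant_channel_gives_zero(self):
        I = np.ones((1, 2, 100)) * 3.7
        od = intensity_to_od(I, FS, WL)
        assert np.allclose(od.data, 0.0)

    def test_exponential_inverse(self, rng):
        x = 0.01 * rng.standard_normal((2, 2, 500))
        x -= x.mean(axis=2, keepdims=True)
        I = np.exp(-x)
        od = intensity_to_od(I, FS, WL)
        # −ln(I/mean I) recovers x up to the constant ln(mean(exp(−x)))
        rec = od.data - od.data.mean(axis=2, keepdims=True)
        assert np.allclose(rec, x - x.mean(axis=2, keepdims=True), atol=1e-12)

    def test_scale_invariance(self, rng):
        I = np.exp(rng.standard_normal((1, 2, 100)) * 0.01)
        a = intensity_to_od(I, FS, WL).data
        b = intensity_to_od(10 * I, FS, WL).data
        assert np.allclose(a, b, atol=1e-12)

    def test_nonpositive_channel_invalidated(self):
        I = np.ones((2, 2, 50))
        I[1, 0, 10] = 0.0
        od = intensity_to_od(I, FS, WL)
        assert od.channel_valid.tolist() == [True, False]


class TestBandpass:
    def test_dc_removed(self):
        out = bandpass(np.full(6000, 5.0), FS, 0.009, 0.08)
        assert np.abs(out).max() < 1e-6

    def test_passband_amplitude_preserved(self):
        t = np.arange(60000) / FS
        x = np.sin(2 * np.pi * 0.04 * t)
        out = bandpass(x, FS, 0.009, 0.08)
        mid = slice(20000, 40000)
        ratio = out[mid].std() / x[mid].std()
        assert 0.95 <= ratio <= 1.05

    def test_stopband_attenuated_20db(self):
        t = np.arange(6000) / FS
        x = np.sin(2 * np.pi * 1.0 * t)
        out = bandpass(x, FS, 0.009, 0.08)
        mid = slice(2000, 4000)
        assert out[mid].std() / x[mid].std() < 0.1

    def test_invalid_band_raises(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), FS, 0.08, 0.009)
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), FS, 0.009, 6.0)


def _od_series(data):
    data = np.asarray(data, float)
    return ODSeries(data, FS, WL, np.ones(data.shape[0], bool))


class TestGSR:
    def test_identical_channels_give_zero_residuals(self, rng):
        x = rng.standard_normal(200)
        od = _od_series(np.tile(x, (5, 2, 1)))
        out = global_signal_regression(od)
        assert np.abs(out.data).max() < 1e-10

    def test_matches_normal_equations_oracle(self, rng):
        od = _od_series(rng.standard_normal((6, 2, 300)))
        out = global_signal_regression(od)
        for w in range(2):
            g = od.data[:, w, :].mean(axis=0)
            X = np.column_stack([np.ones_like(g), g])
            H = X @ np.linalg.inv(X.T @ X) @ X.T
            expected = od.data[:, w, :] - od.data[:, w, :] @ H.T
            assert np.allclose(out.data[:, w, :], expected, atol=1e-10)

    def test_residuals_orthogonal_to_mean(self, rng):
        od = _od_series(rng.standard_normal((8, 2, 400)))
        out = global_signal_regression(od)
        for w in range(2):
            g = od.data[:, w, :].mean(axis=0)
            assert np.abs(out.data[:, w, :] @ g).max() < 1e-8

    def test_idempotent(self, rng):
        od = _od_series(rng.standard_normal((6, 2, 300)))
        once = global_signal_regression(od)
        twice = global_signal_regression(once)
        assert np.allclose(once.data, twice.data, atol=1e-10)

    def test_requires_two_channels(self, rng):
        od = _od_series(rng.standard_normal((1, 2, 100)))
        with pytest.raises(ValueError):
            global_signal_regression(od)


class TestGvtd:
    def test_constant_signals_give_zero(self):
        tr = compute_gvtd(np.ones((4, 100)))
        assert np.allclose(tr.gvtd, 0.0)

    def test_step_spike_height(self):
        """A step of height h in 1 of N flat channels spikes at h/sqrt(N)."""
        N, h = 16, 0.8
        y = np.zeros((N, 100))
        y[0, 50:] = h
        tr = compute_gvtd(y)
        assert tr.gvtd[50] == pytest.approx(h / np.sqrt(N), rel=1e-12)
        assert np.count_nonzero(tr.gvtd) == 1

    def test_iid_noise_level(self, rng):
        """For N iid channels with sd σ, GVTD ≈ σ·sqrt(2) on average."""
        sigma = 0.3
        y = sigma * rng.standard_normal((200, 5000))
        tr = compute_gvtd(y)
        assert np.mean(tr.gvtd[1:]) == pytest.approx(sigma * np.sqrt(2), rel=0.02)

    def test_offset_invariance(self, rng):
        y = rng.standard_normal((6, 500))
        shifted = y + rng.standard_normal((6, 1)) * 100
        a, b = compute_gvtd(y), compute_gvtd(shifted)
        assert np.allclose(a.gvtd, b.gvtd, atol=1e-9)

    def test_single_sample_raises(self):
        with pytest.raises(ValueError):
            compute_gvtd(np.ones((3, 1)))


def _trace_with_artifacts(n, artifact_idx):
    g = np.zeros(n)
    art = np.zeros(n, bool)
    art[list(artifact_idx)] = True
    g[list(artifact_idx)] = 10.0
    return GvtdTrace(g, 1.0, art)


class TestMaskAndSegment:
    def test_no_artifacts_single_chunk(self):
        mask, chunks = mask_and_segment(_trace_with_artifacts(3000, []), FS)
        assert mask.all()
        assert chunks == [(0, 3000)]

    def test_single_artifact_splits_recording(self):
        """Artifact at t=100 s in 300 s leaves [0, 95 s) and (105 s, 300 s]."""
        mask, chunks = mask_and_segment(_trace_with_artifacts(3000, [1000]), FS)
        assert chunks == [(0, 950), (1051, 3000)]
        assert not mask[950:1051].any()

    def test_short_middle_segment_dropped(self):
        """Artifacts at 30 s and 55 s leave a 15 s middle run, below 20 s."""
        mask, chunks = mask_and_segment(_trace_with_artifacts(3000, [300, 550]), FS)
        assert chunks == [(0, 250), (601, 3000)]
        assert not mask[351:501].any()

    def test_all_censored_gives_empty_chunks(self):
        mask, chunks = mask_and_segment(_trace_with_artifacts(300, range(0, 300, 40)), FS)
        assert chunks == []
        assert not mask.any()

    def test_matches_brute_force_oracle(self, rng):
        """Random artifact sets against a sample-by-sample enumeration."""
        for trial in range(5):
            r = np.random.default_rng(trial)
            idx = sorted(r.choice(4000, size=r.integers(1, 6), replace=False))
            trace = _trace_with_artifacts(4000, idx)
            mask, chunks = mask_and_segment(trace, FS, pad_s=5, min_chunk_s=20)
            # oracle: flag ±50 samples around each artifact, then drop runs < 200
            ok = np.ones(4000, bool)
            for t in idx:
                ok[max(0, t - 50): t + 51] = False
            expected_chunks = []
            start = None
            for i in range(4001):
                valid = i < 4000 and ok[i]
                if valid and start is None:
                    start = i
                elif not valid and start is not None:
                    if i - start >= 200:
                        expected_chunks.append((start, i))
                    else:
                        ok[start:i] = False
                    start = None
            assert chunks == expected_chunks
            assert np.array_equal(mask, ok)


class TestDpf:
    @pytest.mark.parametrize("wl,age_months,expected", [
        (780, 5, 5.24), (850, 5, 4.25), (780, 8, 5.26), (850, 8, 4.26),
        (780, 12, 5.27), (850, 12, 4.28), (780, 18, 5.30), (850, 18, 4.30),
        (780, 24, 5.32), (850, 24, 4.32),
    ])
    def test_reference_values_to_two_decimals(self, wl, age_months, expected):
        assert abs(dpf(wl, age_months / 12.0) - expected) <= 0.01

    def test_monotone_in_age(self):
        ages = np.linspace(0.1, 10, 50)
        for wl in (780, 850):
            vals = [dpf(wl, a) for a in ages]
            assert np.all(np.diff(vals) > 0)

    def test_out_of_range_wavelength(self):
        with pytest.raises(ValueError):
            dpf(500, 1.0)
        with pytest.raises(ValueError):
            dpf(950, 1.0)

    @given(st.floats(690, 900), st.floats(0, 18))
    @settings(max_examples=50, deadline=None)
    def test_always_positive(self, wl, age):
        assert dpf(wl, age) > 0


class TestMbll:
    def test_zero_od_gives_zero_concentration(self, probe_smap):
        probe, _ = probe_smap
        od = ODSeries(np.zeros((34, 2, 100)), FS, WL, np.ones(34, bool))
        hb = od_to_hb(od, probe, 1.0)
        assert np.allclose(hb.hbo2, 0) and np.allclose(hb.hhb, 0)

    def test_forward_inverse_round_trip(self, probe_smap, rng):
        probe, _ = probe_smap
        hbo2 = rng.standard_normal((34, 200))
        hhb = rng.standard_normal((34, 200))
        od = hb_to_od(hbo2, hhb, probe, 2.0, FS)
        back = od_to_hb(od, probe, 2.0)
        assert np.allclose(back.hbo2, hbo2, rtol=1e-9, atol=1e-12)
        assert np.allclose(back.hhb, hhb, rtol=1e-9, atol=1e-12)

    def test_age_enters_through_dpf(self, probe_smap, rng):
        probe, _ = probe_smap
        hbo2 = rng.standard_normal((34, 50))
        hhb = rng.standard_normal((34, 50))
        od = hb_to_od(hbo2, hhb, probe, 5 / 12, FS)
        wrong_age = od_to_hb(od, probe, 2.0)
        assert not np.allclose(wrong_age.hbo2, hbo2, rtol=1e-3)

    def test_extinction_matrix_well_conditioned(self):
        E = extinction_coefficients(WL)
        assert E.shape == (2, 2)
        assert (E > 0).all()
        assert abs(np.linalg.det(E)) > 1e3

    def test_single_wavelength_rejected(self, probe_smap):
        probe, _ = probe_smap
        od = ODSeries(np.zeros((34, 1, 10)), FS, (780.0,), np.ones(34, bool))
        with pytest.raises(ValueError):
            od_to_hb(od, probe, 1.0)
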