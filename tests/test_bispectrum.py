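"""Bispectrum estimator against a brute-force DFT oracle; normalization contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from b2bsync.bispectrum import (
    EPS,
    band_average,
    bispectrum_pair,
    calibration_baseline,
    normalize,
    spectral_frame,
    window_matrix,
)
from b2bsync.core import BandTable, band_bin_map, enumerate_combinations, make_axis
from b2bsync.errors import (
    AlignmentError,
    MissingChannelError,
    NoCalibrationError,
    ShapeError,
    TooShortError,
)
from b2bsync.preprocess import SampleWindow


from conftest import brute_force_bispectrum


def frame_of(samples_by_channel, axis, subject="s", index=1):
    w = SampleWindow(subject, index, samples_by_channel, 0.0)
    return spectral_frame(w, axis)


class TestSpectralFrame:
    def test_zero_window_gives_zero_spectrum(self, axis):
        f = frame_of({"C3": np.zeros(1000)}, axis)
        assert np.allclose(f.one_sided("C3"), 0.0)

    def test_on_bin_cosine_peaks_at_half_n(self, axis):
        t = np.arange(1000) / 250.0
        f = frame_of({"C3": np.cos(2 * np.pi * 10 * t)}, axis)
        mag = np.abs(f.one_sided("C3"))
        assert np.argmax(mag) == 40
        assert mag[40] == pytest.approx(500.0, rel=1e-9)

    def test_real_signal_conjugate_symmetry(self, axis, rng):
        f = frame_of({"C3": rng.standard_normal(1000)}, axis)
        x = f.full("C3")
        k = np.arange(1, 1000)
        assert np.allclose(x[1000 - k], np.conj(x[k]), atol=1e-9 * np.abs(x).max())

    def test_wrong_length_rejected(self, axis):
        with pytest.raises(TooShortError):
            frame_of({"C3": np.zeros(999)}, axis)

    def test_missing_channel_rejected(self, axis):
        f = frame_of({"C3": np.zeros(1000)}, axis)
        with pytest.raises(MissingChannelError):
            f.one_sided("C4")


class TestBispectrumPair:
    def test_all_zero_channels_hit_clamp_floor(self):
        axis = make_axis(16, 4)
        fa = frame_of({"c": np.zeros(64)}, axis, "a")
        fb = frame_of({"c": np.zeros(64)}, axis, "b")
        b = bispectrum_pair(fa, "c", fb, "c", axis)
        assert np.allclose(b, np.log(EPS))

    def test_two_tone_window_matches_brute_force_at_peak(self):
        axis = make_axis(16, 4)  # 64 samples, 32 bins
        t = np.arange(64) / 16.0
        xa = np.cos(2 * np.pi * 2 * t)
        xb = np.cos(2 * np.pi * 2 * t) + np.cos(2 * np.pi * 4 * t)
        fa = frame_of({"c": xa}, axis, "a")
        fb = frame_of({"c": xb}, axis, "b")
        got = bispectrum_pair(fa, "c", fb, "c", axis)
        want = brute_force_bispectrum(xa, xb)
        k2 = 8  # 2 Hz bin: both factors and the 4 Hz sum-frequency are populated
        assert got[k2] == pytest.approx(want[k2], rel=1e-6)
        assert want[k2] > np.log(EPS)

    @pytest.mark.parametrize("sum_factor", ["a", "b"])
    def test_matches_brute_force_on_random_windows(self, sum_factor, rng):
        axis = make_axis(16, 4)
        for _ in range(25):
            xa = rng.standard_normal(64)
            xb = rng.standard_normal(64)
            fa = frame_of({"c": xa}, axis, "a")
            fb = frame_of({"c": xb}, axis, "b")
            got = bispectrum_pair(fa, "c", fb, "c", axis, sum_factor)
            want = brute_force_bispectrum(xa, xb, sum_factor)
            np.testing.assert_allclose(got, want, rtol=1e-6, atol=1e-6)

    def test_scaling_one_subject_shifts_by_log_c(self, rng):
        axis = make_axis(16, 4)
        xa = rng.standard_normal(64)
        xb = rng.standard_normal(64)
        fa = frame_of({"c": xa}, axis, "a")
        fa3 = frame_of({"c": 3.0 * xa}, axis, "a")
        fb = frame_of({"c": xb}, axis, "b")
        base = bispectrum_pair(fa, "c", fb, "c", axis)
        scaled = bispectrum_pair(fa3, "c", fb, "c", axis)
        unclamped = base > np.log(EPS) + 1e-9
        assert unclamped.sum() > 20
        np.testing.assert_allclose(
            scaled[unclamped] - base[unclamped], np.log(3.0), rtol=1e-9
        )

    def test_window_index_mismatch_rejected(self, axis):
        fa = frame_of({"c": np.zeros(1000)}, axis, "a", index=1)
        fb = frame_of({"c": np.zeros(1000)}, axis, "b", index=2)
        with pytest.raises(AlignmentError):
            bispectrum_pair(fa, "c", fb, "c", axis)


class TestWindowMatrix:
    def test_full_montage_matrix_is_16_by_500(self, axis, rng):
        chans = ("A1", "A2", "C3", "C4")
        fa = frame_of({c: rng.standard_normal(1000) for c in chans}, axis, "a")
        fb = frame_of({c: rng.standard_normal(1000) for c in chans}, axis, "b")
        combos = enumerate_combinations(chans, chans)
        m = window_matrix(fa, fb, combos, axis)
        assert m.values.shape == (16, 500)
        assert m.kind == "raw"

    def test_referenced_matrix_is_4_by_500(self, axis, rng):
        chans = ("C3'", "C4'")
        fa = frame_of({c: rng.standard_normal(1000) for c in chans}, axis, "a")
        fb = frame_of({c: rng.standard_normal(1000) for c in chans}, axis, "b")
        m = window_matrix(fa, fb, enumerate_combinations(chans, chans), axis)
        assert m.values.shape == (4, 500)

    def test_single_combination(self, axis, rng):
        fa = frame_of({"x": rng.standard_normal(1000)}, axis, "a")
        fb = frame_of({"y": rng.standard_normal(1000)}, axis, "b")
        m = window_matrix(fa, fb, enumerate_combinations(["x"], ["y"]), axis)
        assert m.values.shape == (1, 500)

    def test_permuting_combinations_permutes_rows(self, axis, rng):
        chans = ("C3'", "C4'")
        fa = frame_of({c: rng.standard_normal(1000) for c in chans}, axis, "a")
        fb = frame_of({c: rng.standard_normal(1000) for c in chans}, axis, "b")
        combos = enumerate_combinations(chans, chans)
        m = window_matrix(fa, fb, combos, axis)
        perm = [combos[i] for i in (2, 0, 3, 1)]
        mp = window_matrix(fa, fb, perm, axis)
        np.testing.assert_array_equal(mp.values, m.values[[2, 0, 3, 1]])

    def test_missing_channel_rejected(self, axis, rng):
        fa = frame_of({"x": rng.standard_normal(1000)}, axis, "a")
        fb = frame_of({"y": rng.standard_normal(1000)}, axis, "b")
        with pytest.raises(MissingChannelError):
            window_matrix(fa, fb, enumerate_combinations(["x"], ["z"]), axis)


def _matrix(values, axis, kind="raw"):
    from b2bsync.bispectrum import BispectrumMatrix

    combos = enumerate_combinations(
        [f"c{i}" for i in range(values.shape[0])], ["d"]
    )
    return BispectrumMatrix(1, values, combos, kind)


class TestCalibrationAndNormalize:
    def test_identical_matrices_average_to_themselves(self, axis, rng):
        v = rng.standard_normal((4, 500))
        ms = [_matrix(v.copy(), axis) for _ in range(5)]
        base = calibration_baseline(ms)
        np.testing.assert_allclose(base.values, v)
        assert base.n_windows == 5

    def test_mean_of_zeros_and_twos_is_ones(self, axis):
        ms = [_matrix(np.zeros((2, 500)), axis), _matrix(np.full((2, 500), 2.0), axis)]
        np.testing.assert_allclose(calibration_baseline(ms).values, 1.0)

    def test_empty_calibration_rejected(self):
        with pytest.raises(NoCalibrationError):
            calibration_baseline([])

    def test_baseline_input_gives_all_zeros(self, axis, rng):
        v = rng.standard_normal((4, 500))
        base = calibration_baseline([_matrix(v.copy(), axis)])
        out = normalize(_matrix(v.copy(), axis), base)
        np.testing.assert_allclose(out.values, 0.0)
        assert out.kind == "normalized"

    def test_formula_arithmetic(self, axis):
        base = calibration_baseline([_matrix(np.ones((1, 500)), axis)])
        out = normalize(_matrix(np.full((1, 500), 3.0), axis), base)
        assert out.values[0, 0] == pytest.approx(0.5, abs=1e-9)

    def test_shape_mismatch_rejected(self, axis, rng):
        base = calibration_baseline([_matrix(np.zeros((2, 500)), axis)])
        with pytest.raises(ShapeError):
            normalize(_matrix(np.zeros((3, 500)), axis), base)

    @given(seed=st.integers(0, 2**31 - 1), scale=st.floats(1e-6, 1e6))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_normalized_values_bounded_zero_at_baseline_sign_correct(
        self, seed, scale
    ):
        r = np.random.default_rng(seed)
        axis = make_axis(250, 4)
        b = scale * r.standard_normal((3, 500))
        c = scale * r.standard_normal((3, 500))
        b[0, :10] = c[0, :10]  # force exact-baseline cells
        base = calibration_baseline([_matrix(c, axis)])
        out = normalize(_matrix(b, axis), base).values
        # the exact bound is open, but floats can round onto the endpoints
        assert np.all(out >= -1.0) and np.all(out <= 1.0)
        assert np.allclose(out[0, :10], 0.0)
        assert np.array_equal(np.sign(out), np.sign(b - c))


class TestBandAverage:
    def test_constant_matrix_gives_constant_bands(self, axis, bands):
        m = _matrix(np.full((2, 500), 0.3), axis, kind="normalized")
        s = band_average(m, bands, axis)
        assert s.values.shape == (5, 2)
        np.testing.assert_allclose(s.values, 0.3)

    def test_indicator_on_gamma_bins(self, axis, bands):
        v = np.zeros((1, 500))
        gamma_bins = band_bin_map(bands, axis)["Gamma"]
        v[0, gamma_bins] = 1.0
        s = band_average(_matrix(v, axis, kind="normalized"), bands, axis)
        row = dict(zip(s.band_names, s.values[:, 0]))
        assert row["Gamma"] == 1.0
        for name in ("Delta", "Theta", "Alpha", "Beta"):
            assert row[name] == 0.0

    def test_matches_independent_recomputation(self, axis, bands, rng):
        v = rng.uniform(-1, 1, (4, 500))
        s = band_average(_matrix(v, axis, kind="normalized"), bands, axis)
        bin_map = band_bin_map(bands, axis)
        for bi, name in enumerate(s.band_names):
            np.testing.assert_allclose(
                s.values[bi], v[:, bin_map[name]].mean(axis=1)
            )
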