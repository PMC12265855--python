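import math

import numpy as np
import pytest

import perfectavg as pa
from perfectavg import (
    DegenerateSpectrumError,
    PowerSpectrum,
    detect_stability,
    power_spectrum,
    smooth,
    spectral_entropy,
)


def brute_force_plateau(seq, threshold):
    """Independent oracle: scan every candidate start index with plain loops."""
    x = [float(v) for v in seq]
    n = len(x)
    lo, hi = min(x), max(x)
    if hi == lo:
        return 0, True
    s = [(v - lo) / (hi - lo) for v in x]
    for i in range(1, n - 1):
        sustained = True
        for j in range(i, n - 1):
            if abs(s[j + 1] - s[j]) >= threshold:
                sustained = False
        if sustained:
            return i, True
    return n - 1, False


class TestPowerSpectrum:
    def test_constant_image_concentrates_at_centered_dc(self):
        v, h, w = 3.0, 4, 6
        ps = power_spectrum(np.full((h, w), v))
        dc = ps.power[h // 2, w // 2]
        assert dc == pytest.approx((v * h * w) ** 2)
        assert ps.power.sum() == pytest.approx(dc)
        assert ps.probabilities[h // 2, w // 2] == pytest.approx(1.0)

    def test_parseval_identity(self):
        rng = np.random.default_rng(3)
        for shape in [(8, 8), (7, 9), (16, 5)]:
            img = rng.uniform(0, 10, shape)
            ps = power_spectrum(img)
            assert ps.power.sum() == pytest.approx(img.size * np.sum(img**2), rel=1e-10)

    def test_cosine_concentrates_at_symmetric_bins(self):
        h, w, f = 16, 32, 5
        x = np.arange(w)
        img = np.tile(np.cos(2 * np.pi * f * x / w), (h, 1))
        ps = power_spectrum(img)
        top = ps.probabilities[h // 2, [w // 2 - f, w // 2 + f]].sum()
        assert top == pytest.approx(1.0, abs=1e-10)

    def test_probabilities_sum_to_one(self, phantom):
        assert power_spectrum(phantom).probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_image_is_degenerate(self):
        with pytest.raises(DegenerateSpectrumError):
            power_spectrum(np.zeros((4, 4)))


class TestSpectralEntropy:
    def test_single_bin_spectrum_has_zero_entropy(self):
        H, H_norm = spectral_entropy(power_spectrum(np.full((8, 8), 5.0)))
        assert H == pytest.approx(0.0, abs=1e-12)
        assert H_norm == pytest.approx(0.0, abs=1e-12)

    def test_delta_image_has_flat_spectrum_and_maximum_entropy(self):
        img = np.zeros((8, 8))
        img[2, 5] = 7.0  # |FFT| of a delta is flat
        H, H_norm = spectral_entropy(power_spectrum(img))
        assert H == pytest.approx(math.log(64), rel=1e-12)
        assert H_norm == pytest.approx(1.0, rel=1e-12)

    def test_two_point_distribution(self):
        p = np.array([[0.5, 0.5, 0.0, 0.0]])
        H, _ = spectral_entropy(PowerSpectrum(power=p, probabilities=p))
        assert H == pytest.approx(math.log(2))

    def test_invariant_to_intensity_scaling(self, phantom):
        H1, n1 = spectral_entropy(power_spectrum(phantom))
        H2, n2 = spectral_entropy(power_spectrum(7.3 * phantom))
        assert H1 == pytest.approx(H2, rel=1e-12)
        assert n1 == pytest.approx(n2, rel=1e-12)

    def test_bounds_on_random_images(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            img = rng.uniform(0, 255, (12, 12))
            H, H_norm = spectral_entropy(power_spectrum(img))
            assert 0 <= H <= math.log(144) + 1e-12
            assert 0 <= H_norm <= 1 + 1e-12

    def test_exclude_dc_drops_one_bin(self, phantom):
        full = spectral_entropy(power_spectrum(phantom), exclude_dc=False)
        nodc = spectral_entropy(power_spectrum(phantom), exclude_dc=True)
        assert nodc != full  # DC dominates a structured image
        assert 0 <= nodc[1] <= 1


class TestEntropySeries:
    def test_identical_levels_give_identical_entropy(self, phantom):
        frames = np.stack([phantom] * 8)
        series = pa.geometric_average(pa.ImageStack(frames=frames))
        ent = pa.entropy_series(series)
        np.testing.assert_allclose(ent.H, ent.H[0])
        np.testing.assert_allclose(ent.smoothed, ent.H_norm)

    def test_noise_averaging_monotonically_reduces_entropy(self, const_noise_stack):
        series = pa.geometric_average(const_noise_stack)
        ent = pa.entropy_series(series)
        assert np.all(np.diff(ent.H_norm) < 0)

    def test_single_level_smoothing_is_identity(self, phantom):
        series = pa.geometric_average(pa.ImageStack(frames=phantom[None]))
        ent = pa.entropy_series(series)
        np.testing.assert_array_equal(ent.smoothed, ent.H_norm)


class TestSmooth:
    def test_constant_sequence_unchanged(self):
        np.testing.assert_array_equal(smooth([4.0] * 7, 5), np.full(7, 4.0))

    def test_hand_computed_shrinking_window(self):
        out = smooth([0.0, 0.0, 5.0, 0.0, 0.0], 5)
        np.testing.assert_allclose(out, [0.0, 5 / 3, 1.0, 5 / 3, 0.0])

    def test_window_one_is_identity(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0]
        np.testing.assert_array_equal(smooth(x, 1), x)

    def test_output_length_preserved(self):
        assert smooth(np.arange(9.0), 5).size == 9

    @pytest.mark.parametrize("window", [0, 2, 4, -3])
    def test_even_or_nonpositive_window_rejected(self, window):
        with pytest.raises(ValueError):
            smooth([1.0, 2.0], window)


class TestDetectStability:
    def test_sustained_plateau_start(self):
        # already on [0, 1]; successive diffs 0.8, 0.15, 0.05, 0.02, 0.01
        s = [1.0, 0.2, 0.05, 0.0, 0.02, 0.03]
        assert detect_stability(s, 0.1) == (2, True)

    def test_constant_sequence_returns_zero(self):
        assert detect_stability([5.0] * 6, 0.1) == (0, True)

    def test_generous_threshold_returns_earliest_index(self):
        assert detect_stability([0.0, 1.0, 2.0, 3.0], threshold=10.0).index == 1

    def test_no_plateau_flags_last_index(self):
        idx, found = detect_stability([0.0, 1.0, 0.0, 1.0, 0.0], threshold=0.05)
        assert idx == 4 and not found

    def test_matches_brute_force_oracle_on_random_sequences(self):
        rng = np.random.default_rng(1234)
        for _ in range(1000):
            n = int(rng.integers(2, 13))
            seq = rng.uniform(0, 1, n)
            th = float(rng.uniform(0.01, 1.2))
            assert tuple(detect_stability(seq, th)) == brute_force_plateau(seq, th)

    def test_index_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(99)
        thresholds = [0.01, 0.05, 0.1, 0.2, 0.5, 1.0]
        for _ in range(100):
            seq = rng.uniform(0, 1, int(rng.integers(3, 12)))
            indices = [detect_stability(seq, th).index for th in thresholds]
            assert all(a >= b for a, b in zip(indices, indices[1:]))

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            detect_stability([1.0], 0.1)
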