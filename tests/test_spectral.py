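import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgfusion.spectral import (SpectralFeatureSet, SubwavePartition,
                                band_prefix, beat_features, default_partition,
                                dft_magnitude, subband_features)


class TestDftMagnitude:
    def test_constant_beat_is_dc_only(self):
        mags = dft_magnitude(np.full(250, 3.0))
        assert mags[0] == pytest.approx(250 * 3.0)
        np.testing.assert_allclose(mags[1:], 0.0, atol=1e-9)

    def test_single_tone_peaks_at_its_bin(self):
        t = np.arange(250)
        mags = dft_magnitude(np.cos(2 * np.pi * 10 * t / 250))
        assert int(np.argmax(mags)) == 10

    def test_parseval_and_conjugate_symmetry(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(250)
        full = np.fft.fft(x)
        half = dft_magnitude(x)
        # bins 126..249 recovered from bins 1..124 by conjugate symmetry
        np.testing.assert_allclose(np.abs(full[126:]), half[1:125][::-1],
                                   rtol=1e-10)
        recovered_power = (half[0] ** 2 + np.abs(full[125]) ** 2
                           + 2 * np.sum(half[1:125] ** 2))
        assert np.sum(x ** 2) == pytest.approx(recovered_power / 250)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            dft_magnitude(np.zeros(100))


class TestPartition:
    def test_default_partition_geometry(self):
        p = default_partition()
        assert p.p_window == (0, 90)
        assert p.qrs_window == (90, 126)
        assert p.t_window == (126, 250)
        # QRS width = 36 samples = 100 ms at 360 Hz, containing the anchor
        assert p.qrs_window[1] - p.qrs_window[0] == 36
        assert p.p_window[0] == 0 and p.t_window[1] == 250
        assert p.qrs_window[0] <= 108 < p.qrs_window[1]

    def test_invalid_partition_rejected(self):
        with pytest.raises(ValueError):
            SubwavePartition((0, 80), (90, 126), (126, 250))


class TestSubbandFeatures:
    def test_default_lengths_concatenate_to_125(self):
        fset = subband_features(np.zeros(250))
        # ceil(90/2) + ceil(36/2) + ceil(124/2) = 45 + 18 + 62
        assert fset.n_components == 45 + 18 + 62 == 125
        windows = [w for w, _ in fset.band_index]
        assert windows[:45] == ["P"] * 45
        assert windows[45:63] == ["QRS"] * 18
        assert windows[63:] == ["T"] * 62

    def test_energy_confined_to_qrs_window(self):
        beat = np.zeros(250)
        beat[95:120] = 1.0  # inside the QRS window only
        fset = subband_features(beat)
        vals = fset.features[0]
        p_block = vals[:45]
        t_block = vals[63:]
        np.testing.assert_allclose(p_block, 0.0, atol=1e-12)
        np.testing.assert_allclose(t_block, 0.0, atol=1e-12)
        assert vals[45:63].max() > 0

    def test_per_window_parseval(self):
        rng = np.random.default_rng(3)
        beat = rng.standard_normal(250)
        part = default_partition()
        for name, (lo, hi) in part.windows.items():
            seg = beat[lo:hi]
            full = np.abs(np.fft.fft(seg))
            assert np.sum(seg ** 2) == pytest.approx(np.sum(full ** 2) / seg.size)

    def test_degenerate_window_rejected(self):
        part = SubwavePartition((0, 2), (2, 126), (126, 250))
        with pytest.raises(ValueError):
            subband_features(np.zeros(250), part)

    def test_slice_mode_covers_half_spectrum(self):
        fset = subband_features(np.random.default_rng(0).standard_normal(250),
                                mode="slice")
        assert fset.n_components == 125
        assert [k for _w, k in fset.band_index] == list(range(125))

    def test_zero_beat_gives_zero_features_both_ways(self):
        assert np.all(beat_features(np.zeros((2, 250)), segmented=True).features == 0)
        assert np.all(beat_features(np.zeros((2, 250)), segmented=False).features == 0)


class TestBandPrefix:
    @pytest.fixture()
    def full(self):
        rng = np.random.default_rng(1)
        return beat_features(rng.standard_normal((5, 250)), segmented=False)

    def test_full_prefix_is_identity(self, full):
        np.testing.assert_array_equal(band_prefix(full, 125).features,
                                      full.features)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(min_value=1, max_value=124))
    def test_prefix_nesting(self, k):
        rng = np.random.default_rng(2)
        full = beat_features(rng.standard_normal((3, 250)), segmented=False)
        small = band_prefix(full, k)
        big = band_prefix(full, min(125, k + 17))
        np.testing.assert_array_equal(big.features[:, :k], small.features)

    def test_out_of_range_rejected(self, full):
        for k in (0, 126):
            with pytest.raises(ValueError):
                band_prefix(full, k)

    def test_segmented_input_rejected(self):
        seg = beat_features(np.zeros((1, 250)), segmented=True)
        with pytest.raises(ValueError):
            band_prefix(seg, 5)


def test_feature_set_invariants():
    with pytest.raises(ValueError):
        SpectralFeatureSet(features=-np.ones((1, 125)),
                           band_index=[("full", k) for k in range(125)],
                           segmented=False)
    with pytest.raises(ValueError):
        SpectralFeatureSet(features=np.ones((1, 3)),
                           band_index=[("full", 0)], segmented=False)


def test_unit_energy_normalization():
    rng = np.random.default_rng(4)
    fset = beat_features(rng.standard_normal((6, 250)), segmented=False,
                         normalize=True)
    np.testing.assert_allclose(np.linalg.norm(fset.features, axis=1), 1.0,
                               rtol=1e-12)
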