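"""Anchored-STFT framing arithmetic, spectrograms and feature assembly.

The transform itself is checked against an independent brute-force
O(n^2) discrete Fourier sum.
"""

import numpy as np
import pytest

import anchoreeg as ae
from anchoreeg.errors import (
    EmptyBandError,
    InvalidLengthError,
    InvalidStrideError,
    TooFewRowsError,
    UnknownAnchorError,
)


def brute_force_stft(signal, anchor_len, stride, nfft, taper):
    """Textbook fixed-window STFT via an explicit O(n^2) DFT sum.

    Independent of the package's FFT path: frames the zero-padded signal,
    applies the taper, and evaluates sum_n x[n] exp(-2i pi k n / nfft)
    term by term for the one-sided bins.
    """
    n_pos = len(signal) // stride
    pad = max(0, stride * (n_pos - 1) - len(signal) + anchor_len)
    padded = np.concatenate([signal, np.zeros(pad)])
    n_bins = nfft // 2 + 1
    out = np.zeros((n_bins, n_pos))
    for f in range(n_pos):
        seg = padded[f * stride : f * stride + anchor_len] * taper
        for k in range(n_bins):
            acc = 0.0 + 0.0j
            for n, v in enumerate(seg):
                acc += v * np.exp(-2j * np.pi * k * n / nfft)
            out[k, f] = abs(acc)
    return out


class TestFramingArithmetic:
    @pytest.mark.parametrize("sL,expected", [(1024, 10), (625, 9), (2, 1)])
    def test_max_num_anchors(self, sL, expected):
        assert ae.max_num_anchors(sL) == expected

    def test_max_num_anchors_rejects_tiny_signals(self):
        with pytest.raises(InvalidLengthError):
            ae.max_num_anchors(1)

    @pytest.mark.parametrize(
        "anchor,stride,expected", [(16, 8, 8), (8, 8, 0), (256, 8, 248)]
    )
    def test_overlap(self, anchor, stride, expected):
        assert ae.anchor_overlap(anchor, stride) == expected

    def test_overlap_rejects_stride_beyond_anchor(self):
        with pytest.raises(InvalidStrideError):
            ae.anchor_overlap(8, 16)

    @pytest.mark.parametrize(
        "sL,stride,expected", [(625, 8, 78), (16, 16, 1), (100, 10, 10)]
    )
    def test_num_positions(self, sL, stride, expected):
        assert ae.num_anchor_positions(sL, stride) == expected

    def test_num_positions_matches_enumeration(self):
        # independent oracle: count starts 0, s, 2s, ... for which a whole
        # stride of signal remains (the last partial stride is dropped)
        for sL, stride in [(100, 10), (625, 8), (97, 13)]:
            starts = [s for s in range(0, sL, stride) if s + stride <= sL]
            assert ae.num_anchor_positions(sL, stride) == len(starts)

    @pytest.mark.parametrize(
        "stride,n_pos,sL,anchor,expected",
        [(8, 78, 625, 16, 7), (8, 78, 625, 256, 247), (4, 1, 4, 4, 0)],
    )
    def test_zero_padding(self, stride, n_pos, sL, anchor, expected):
        assert ae.zero_padding_length(stride, n_pos, sL, anchor) == expected

    def test_anchor_set_requires_odd_count(self):
        with pytest.raises(InvalidLengthError):
            ae.AnchorSet(lengths=(16, 32))

    def test_anchor_set_requires_powers_of_two(self):
        with pytest.raises(InvalidLengthError):
            ae.AnchorSet(lengths=(16, 48, 64))

    def test_center_focal_lengths_are_pow2_plus_one(self):
        aset = ae.AnchorSet(lengths=(17, 33, 65), focal="center")
        assert aset.stride == 8
        with pytest.raises(InvalidLengthError):
            ae.AnchorSet(lengths=(16, 32, 64), focal="center")


class TestSpectrogram:
    def test_reference_configuration_shape(self, reference_anchor_set):
        sig = np.random.default_rng(0).standard_normal(625)
        for L in reference_anchor_set.lengths:
            spec = ae.compute_spectrogram(sig, 250.0, L, reference_anchor_set)
            assert spec.values.shape == (257, 78)

    def test_zero_signal_gives_zero_spectrogram(self, reference_anchor_set):
        spec = ae.compute_spectrogram(np.zeros(625), 250.0, 16, reference_anchor_set)
        assert np.all(spec.values == 0)

    def test_exact_bin_tone_peaks_at_its_row(self):
        # 31.25 Hz = bin 64 of a 512-point transform at 250 Hz
        aset = ae.AnchorSet(lengths=(256,), stride=8, window_shape="rectangular")
        t = np.arange(625) / 250.0
        sig = np.cos(2 * np.pi * 31.25 * t)
        spec = ae.compute_spectrogram(sig, 250.0, 256, aset)
        peak_rows = np.argmax(spec.values, axis=0)
        target = int(np.argmin(np.abs(spec.bin_freqs - 31.25)))
        assert spec.bin_freqs[target] == pytest.approx(31.25)
        # all frames fully inside the signal peak at that bin
        full = spec.frame_times * 250.0 + 256 <= 625
        assert np.all(peak_rows[full] == target)

    def test_unknown_anchor_rejected(self, reference_anchor_set):
        with pytest.raises(UnknownAnchorError):
            ae.compute_spectrogram(np.zeros(625), 250.0, 512, reference_anchor_set)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("anchor_len,n", [(16, 128), (32, 200), (64, 300)])
    def test_matches_brute_force_dft(self, seed, anchor_len, n):
        """Single anchor equals a textbook STFT computed by the O(n^2) sum."""
        rng = np.random.default_rng(seed)
        sig = rng.standard_normal(n)
        aset = ae.AnchorSet(
            lengths=(anchor_len,),
            stride=anchor_len // 2,
            n_unique_fft=129,
        )
        spec = ae.compute_spectrogram(sig, 100.0, anchor_len, aset)
        oracle = brute_force_stft(
            sig, anchor_len, anchor_len // 2, 256, aset.taper(anchor_len)
        )
        np.testing.assert_allclose(spec.values, oracle, rtol=1e-9, atol=1e-9)

    def test_all_anchors_share_frame_count(self, reference_anchor_set):
        sig = np.random.default_rng(1).standard_normal(625)
        counts = {
            ae.compute_spectrogram(sig, 250.0, L, reference_anchor_set).n_frames
            for L in reference_anchor_set.lengths
        }
        assert counts == {78}

    def test_parseval_single_rectangular_frame(self):
        # one full-length frame, no zero padding: one-sided power with the
        # conjugate-symmetry doubling equals nfft * time-domain energy
        L = 256
        aset = ae.AnchorSet(
            lengths=(L,), stride=L, window_shape="rectangular", n_unique_fft=L // 2 + 1
        )
        sig = np.random.default_rng(2).standard_normal(L)
        spec = ae.compute_spectrogram(sig, 250.0, L, aset)
        assert spec.n_frames == 1
        mag = spec.values[:, 0]
        one_sided = mag[0] ** 2 + mag[-1] ** 2 + 2 * np.sum(mag[1:-1] ** 2)
        np.testing.assert_allclose(one_sided, L * np.sum(sig**2), rtol=1e-6)

    def test_peak_width_shrinks_with_anchor_length(self, reference_anchor_set):
        """Longer anchors sharpen the spectral peak of a pure tone."""
        t = np.arange(625) / 250.0
        sig = np.sin(2 * np.pi * 11.0 * t)
        widths = []
        for L in reference_anchor_set.lengths:
            spec = ae.compute_spectrogram(sig, 250.0, L, reference_anchor_set)
            profile = spec.values.mean(axis=1)
            width = np.sum(profile >= profile.max() / 2)
            widths.append(width)
        assert all(a >= b for a, b in zip(widths, widths[1:]))


@pytest.fixture(scope="module")
def spec625(reference_anchor_set):
    sig = np.random.default_rng(0).standard_normal(625)
    return ae.compute_spectrogram(sig, 250.0, 16, reference_anchor_set)


class TestBandsAndResize:
    @pytest.mark.parametrize(
        "band,rows",
        [(ae.MU_BAND, 22), (ae.BETA_BAND, 23), (ae.BandSpec("all", 0, 125), 257)],
    )
    def test_row_counts(self, spec625, band, rows):
        assert ae.band_slice(spec625, band).shape == (rows, 78)

    def test_empty_band_rejected(self, spec625):
        with pytest.raises(EmptyBandError):
            ae.band_slice(spec625, ae.BandSpec("null", 125.2, 125.4))

    def test_resize_preserves_constants(self):
        block = np.full((23, 78), 3.7)
        out = ae.resize_band(block, 22)
        np.testing.assert_allclose(out, 3.7)

    def test_resize_exact_on_linear_ramps(self):
        rows = np.arange(23, dtype=float)
        block = np.tile(rows[:, None], (1, 10))
        out = ae.resize_band(block, 22)
        expected = np.tile(np.linspace(0, 22, 22)[:, None], (1, 10))
        np.testing.assert_allclose(out, expected, atol=1e-10)
        assert out[0, 0] == pytest.approx(0.0) and out[-1, 0] == pytest.approx(22.0)

    def test_resize_identity(self):
        block = np.random.default_rng(0).standard_normal((22, 5))
        np.testing.assert_array_equal(ae.resize_band(block, 22), block)

    def test_resize_needs_two_rows(self):
        with pytest.raises(TooFewRowsError):
            ae.resize_band(np.ones((1, 5)), 3)


class TestFeaturize:
    def _soi(self, n_channels=3, seed=0):
        rng = np.random.default_rng(seed)
        return ae.Trial(
            rng.standard_normal((n_channels, 625)),
            250.0,
            ["C3", "Cz", "C4"][:n_channels],
            0,
            "soi",
        )

    def test_reference_shape_five_images_132x78(self, reference_anchor_set):
        fs = ae.featurize_soi(self._soi(), reference_anchor_set)
        assert fs.n_anchors == 5
        for im in fs.images:
            assert im.shape == (132, 78)

    def test_single_channel_gives_44_rows(self, reference_anchor_set):
        fs = ae.featurize_soi(self._soi(n_channels=1), reference_anchor_set)
        assert fs.images[0].shape == (44, 78)

    def test_single_anchor_single_band(self):
        aset = ae.AnchorSet(lengths=(16,), stride=8)
        fs = ae.featurize_soi(self._soi(n_channels=1), aset, bands=[ae.MU_BAND])
        assert fs.n_anchors == 1
        assert fs.images[0].shape == (22, 78)

    @pytest.mark.parametrize("n_channels", [1, 2, 3])
    @pytest.mark.parametrize("n_bands", [1, 2])
    @pytest.mark.parametrize("common_rows", [5, 22])
    def test_row_count_formula(self, n_channels, n_bands, common_rows):
        """N_h = common_rows * n_bands * n_channels, always."""
        aset = ae.AnchorSet(lengths=(16, 32, 64), stride=8)
        bands = [ae.MU_BAND, ae.BETA_BAND][:n_bands]
        fs = ae.featurize_soi(
            self._soi(n_channels=n_channels), aset, bands=bands, common_rows=common_rows
        )
        assert fs.images[0].shape == (common_rows * n_bands * n_channels, 78)

    def test_row_layout_records_blocks(self, reference_anchor_set):
        fs = ae.featurize_soi(self._soi(), reference_anchor_set)
        layout = fs.images[0].row_layout
        assert [(c, b) for c, b, _, _ in layout] == [
            ("C3", "mu"),
            ("C3", "beta"),
            ("Cz", "mu"),
            ("Cz", "beta"),
            ("C4", "mu"),
            ("C4", "beta"),
        ]
        assert layout[-1][3] == 132

    def test_minmax_normalization_bounds(self, reference_anchor_set):
        fs = ae.featurize_soi(self._soi(), reference_anchor_set, normalize="minmax")
        for im in fs.images:
            assert im.values.min() == pytest.approx(0.0)
            assert im.values.max() == pytest.approx(1.0)

    def test_feature_archive_round_trip(self, tmp_path, reference_anchor_set):
        sets = [
            ae.featurize_soi(self._soi(seed=s), reference_anchor_set) for s in range(3)
        ]
        path = tmp_path / "features.h5"
        ae.write_feature_archive(sets, path, {"note": "fixture"})
        back, config = ae.read_feature_archive(path)
        assert config == {"note": "fixture"}
        assert len(back) == 3
        for a, b in zip(sets, back):
            assert a.label == b.label and a.trial_id == b.trial_id
            for ia, ib in zip(a.images, b.images):
                np.testing.assert_array_equal(ia.values, ib.values)
                assert ia.anchor_length == ib.anchor_length
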