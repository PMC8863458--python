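"""Transform correctness: DFT, STFT, DWT and the hybrid-input assembly."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st

from eegfusion import (
    EEGSegment,
    InvalidInputError,
    ConfigurationError,
    TransformConfig,
    compute_dft,
    compute_dwt,
    compute_stft,
    make_hybrid,
)
from eegfusion.transforms import _dwt_blocks, standardize


def _segment(samples, **kw):
    return EEGSegment(samples=np.asarray(samples, dtype=float), **kw)


def naive_dft_magnitudes(x):
    """Brute-force O(N^2) evaluation of |sum_n x(n) e^{-2i pi k n / N}|."""
    n = len(x)
    k = np.arange(n // 2 + 1)
    ang = -2j * np.pi * np.outer(k, np.arange(n)) / n
    return np.abs(np.exp(ang) @ x)


class TestDFT:
    def test_constant_segment_is_dc_only(self):
        spec = compute_dft(_segment(np.full(32, 2.5)))
        assert spec.magnitudes[0] == pytest.approx(32 * 2.5)
        assert np.all(np.abs(spec.magnitudes[1:]) < 1e-9)

    @pytest.mark.parametrize("k0", [1, 3, 7])
    def test_single_tone_magnitude(self, k0):
        n = 64
        x = np.cos(2 * np.pi * k0 * np.arange(n) / n)
        spec = compute_dft(_segment(x))
        assert spec.magnitudes[k0] == pytest.approx(n / 2, abs=1e-9)
        others = np.delete(spec.magnitudes, k0)
        assert np.all(others < 1e-9)

    def test_matches_naive_summation(self, rng):
        x = rng.standard_normal(16)
        spec = compute_dft(_segment(x))
        np.testing.assert_allclose(spec.magnitudes, naive_dft_magnitudes(x), atol=1e-9)

    def test_one_sided_bin_count(self, rng):
        for n in (16, 17, 101):
            spec = compute_dft(_segment(rng.standard_normal(n)))
            assert len(spec) == n // 2 + 1

    def test_rejects_degenerate_input(self):
        with pytest.raises(InvalidInputError):
            compute_dft(_segment([1.0]))
        with pytest.raises(InvalidInputError):
            _segment([1.0, np.nan])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(n=st.integers(8, 1024), seed=st.integers(0, 2**16))
    def test_parseval(self, n, seed):
        """Two-sided spectral energy equals N times the signal energy."""
        x = np.random.default_rng(seed).standard_normal(n)
        mags = compute_dft(_segment(x)).magnitudes
        # reconstruct the two-sided energy from the one-sided magnitudes
        doubled = slice(1, (n + 1) // 2) if n % 2 else slice(1, n // 2)
        e2 = mags[0] ** 2 + 2 * np.sum(mags[doubled] ** 2)
        if n % 2 == 0:
            e2 += mags[n // 2] ** 2
        assert e2 == pytest.approx(n * np.sum(x**2), rel=1e-6)


class TestSTFT:
    def test_canonical_shape(self, rng):
        spec = compute_stft(_segment(rng.standard_normal(4097)), 128, 120)
        assert spec.magnitudes.shape == (65, 497)
        assert spec.hop == 8

    def test_zero_segment_gives_zero_spectrogram(self):
        spec = compute_stft(_segment(np.zeros(300)), 64, 32)
        assert np.all(spec.magnitudes == 0)

    def test_first_frame_is_windowed_dft(self, rng):
        x = rng.standard_normal(600)
        spec = compute_stft(_segment(x), 128, 120)
        windowed = _segment(x[:128] * np.hamming(128))
        np.testing.assert_allclose(
            spec.magnitudes[:, 0], compute_dft(windowed).magnitudes, atol=1e-9
        )

    def test_window_longer_than_segment_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_stft(_segment(np.ones(64)), 128, 120)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n=st.integers(64, 2000),
        window=st.integers(8, 64),
        overlap=st.integers(0, 63),
    )
    def test_frame_count_contract(self, n, window, overlap):
        if overlap >= window:
            overlap = window - 1
        hop = window - overlap
        spec = compute_stft(_segment(np.random.default_rng(0).standard_normal(n)), window, overlap)
        assert spec.n_frames == (n - window) // hop + 1
        assert spec.n_bins == window // 2 + 1


class TestDWT:
    def test_haar_on_constant_signal(self):
        vec = compute_dwt(_segment([1.0, 1.0, 1.0, 1.0]), "db1", 1, ("cA1", "cD1"))
        np.testing.assert_allclose(vec.block("cA1"), [np.sqrt(2), np.sqrt(2)])
        np.testing.assert_allclose(vec.block("cD1"), [0.0, 0.0])

    @pytest.mark.parametrize("n", [64, 257, 4097])
    def test_perfect_reconstruction(self, n, rng):
        x = rng.standard_normal(n)
        blocks = _dwt_blocks(x, "db1", 2, "symmetric")
        a1 = pywt.idwt(blocks["cA2"], blocks["cD2"], "db1", mode="symmetric")
        a1 = a1[: blocks["cA1"].size]
        rec = pywt.idwt(a1, blocks["cD1"], "db1", mode="symmetric")[:n]
        np.testing.assert_allclose(rec, x, atol=1e-9)

    def test_canonical_layout_length(self, rng):
        vec = compute_dwt(_segment(rng.standard_normal(4097)))
        assert len(vec) == 1025 + 1025 + 2049 == 4099
        assert [name for name, _ in vec.layout] == ["cA2", "cD2", "cA1"]
        assert [n for _, n in vec.layout] == [1025, 1025, 2049]

    def test_energy_conservation_complete_set(self, rng):
        # db1 is orthogonal: on lengths divisible by 2^J the complete level-J
        # coefficient set carries exactly the input energy
        x = rng.standard_normal(1024)
        blocks = _dwt_blocks(x, "db1", 2, "symmetric")
        e = sum(np.sum(blocks[k] ** 2) for k in ("cA2", "cD2", "cD1"))
        assert e == pytest.approx(np.sum(x**2), rel=1e-6)

    def test_unknown_wavelet_and_missing_block(self):
        seg = _segment(np.arange(16.0))
        with pytest.raises(ConfigurationError):
            compute_dwt(seg, "nosuchwavelet")
        with pytest.raises(ConfigurationError):
            compute_dwt(seg, "db1", 1, ("cA2",))


class TestHybrid:
    def test_shape_composition(self, rng):
        h = make_hybrid(_segment(rng.standard_normal(4097)))
        assert h.model_raw.shape == (4097,)
        assert h.model_dft.shape == (2049,)
        assert h.model_stft.shape == (65, 497)
        assert h.model_dwt.shape == (4099,)

    def test_standardization(self, rng):
        h = make_hybrid(_segment(rng.standard_normal(700)))
        for arr in h.model_arrays().values():
            assert abs(float(arr.mean())) < 1e-4
            assert float(arr.std()) == pytest.approx(1.0, abs=1e-4)

    def test_zero_variance_falls_back_to_centering(self):
        out = standardize(np.full(10, 3.0))
        assert np.all(out == 0.0)
        h = make_hybrid(_segment(np.full(256, 5.0)))
        assert np.all(np.isfinite(h.model_raw))

    def test_determinism_and_purity(self, rng):
        x = rng.standard_normal(512)
        a = make_hybrid(_segment(x, label="normal", source_id="a"))
        b = make_hybrid(_segment(x, label="epileptic", source_id="b"))
        for k in ("raw", "dft", "stft", "dwt"):
            np.testing.assert_array_equal(a.model_arrays()[k], b.model_arrays()[k])
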