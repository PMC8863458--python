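"""The four per-segment input representations.

Every segment is expanded into a *hybrid input*: the raw time series, its
one-sided DFT magnitude spectrum, a Hamming-windowed STFT magnitude
spectrogram, and a concatenated multilevel DWT coefficient vector.  The four
representations feed the four CNN branches of the classifier.

Conventions
-----------
* DFT: one-sided magnitude, bins ``k = 0 .. floor(N/2)`` (real input makes the
  upper half redundant).  Magnitude, not power, and no log scaling by default.
* STFT: frame ``t`` covers samples ``[t*hop, t*hop + window)``; trailing
  samples that do not fill a window are dropped (no zero padding).  A
  symmetric Hamming window is applied before each frame's DFT.
* DWT: multilevel decomposition with per-level downsampling by 2; symmetric
  (half-sample) boundary extension, so db1's length-2 filters give subband
  length ``floor((n+1)/2)``.  The returned vector concatenates the requested
  subband blocks in layout order (default ``[cA2, cD2, cA1]``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from ._errors import ConfigurationError, InvalidInputError
from .segment import EEGSegment

__all__ = [
    "SpectrumVector",
    "Spectrogram",
    "WaveletVector",
    "HybridInput",
    "TransformConfig",
    "compute_dft",
    "compute_stft",
    "compute_dwt",
    "make_hybrid",
    "standardize",
]


# ---------------------------------------------------------------------------
# representation containers
# ---------------------------------------------------------------------------

@dataclass
class SpectrumVector:
    """One-sided DFT magnitude spectrum |X(k)|, k = 0 .. floor(N/2)."""

    magnitudes: np.ndarray
    bin_hz: float

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=np.float64).ravel()

    def __len__(self) -> int:
        return int(self.magnitudes.size)


@dataclass
class Spectrogram:
    """STFT magnitude matrix, frequency bins x time frames."""

    magnitudes: np.ndarray  # (bins, frames)
    window_length: int
    overlap: int

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=np.float64)
        if self.magnitudes.ndim != 2:
            raise InvalidInputError("spectrogram must be a 2-D matrix")
        if not 0 <= self.overlap < self.window_length:
            raise InvalidInputError("overlap must satisfy 0 <= overlap < window")

    @property
    def hop(self) -> int:
        return self.window_length - self.overlap

    @property
    def n_bins(self) -> int:
        return self.magnitudes.shape[0]

    @property
    def n_frames(self) -> int:
        return self.magnitudes.shape[1]


@dataclass
class WaveletVector:
    """Concatenation of selected DWT subband blocks in a declared order."""

    coefficients: np.ndarray
    layout: tuple[tuple[str, int], ...]  # (block name, block length) pairs
    wavelet_name: str = "db1"
    level: int = 2

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64).ravel()
        total = sum(n for _, n in self.layout)
        if total != self.coefficients.size:
            raise InvalidInputError(
                f"layout lengths sum to {total} but vector has "
                f"{self.coefficients.size} coefficients"
            )

    def __len__(self) -> int:
        return int(self.coefficients.size)

    def block(self, name: str) -> np.ndarray:
        """Return one named subband block as a view into the vector."""
        start = 0
        for bname, blen in self.layout:
            if bname == name:
                return self.coefficients[start : start + blen]
            start += blen
        raise KeyError(name)


@dataclass
class HybridInput:
    """The four representations of one segment, plus model-ready arrays.

    ``raw``/``dft``/``stft``/``dwt`` hold the untouched representations.  The
    ``model_*`` arrays are the standardized (zero mean, unit variance) float32
    versions actually ingested by the network; a zero-variance representation
    is only centered, never divided.
    """

    raw: EEGSegment
    dft: SpectrumVector
    stft: Spectrogram
    dwt: WaveletVector
    model_raw: np.ndarray = field(repr=False, default=None)
    model_dft: np.ndarray = field(repr=False, default=None)
    model_stft: np.ndarray = field(repr=False, default=None)
    model_dwt: np.ndarray = field(repr=False, default=None)

    @property
    def label(self) -> str | None:
        return self.raw.label

    def model_arrays(self) -> dict[str, np.ndarray]:
        return {
            "raw": self.model_raw,
            "dft": self.model_dft,
            "stft": self.model_stft,
            "dwt": self.model_dwt,
        }


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransformConfig:
    """Parameters of the hybrid-input computation.

    Defaults follow the study configuration: Hamming window of 128 samples
    with 120-sample overlap for the STFT, and a two-level db1 (Haar) DWT
    whose output is laid out as ``[cA2, cD2, cA1]``.
    """

    window_length: int = 128
    overlap: int = 120
    wavelet_name: str = "db1"
    level: int = 2
    dwt_layout: tuple[str, ...] = ("cA2", "cD2", "cA1")
    dwt_mode: str = "symmetric"
    log_spectra: bool = False
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.window_length < 2:
            raise ConfigurationError("window_length must be >= 2")
        if not 0 <= self.overlap < self.window_length:
            raise ConfigurationError("overlap must satisfy 0 <= overlap < window")
        if self.level < 1:
            raise ConfigurationError("level must be >= 1")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def _validate_segment(segment: EEGSegment, min_length: int = 2) -> np.ndarray:
    x = segment.samples
    if x.size < min_length:
        raise InvalidInputError(
            f"segment must have at least {min_length} samples, got {x.size}"
        )
    return x


def compute_dft(segment: EEGSegment) -> SpectrumVector:
    """One-sided DFT magnitude spectrum of a segment.

    Returns |X(k)| for ``k = 0 .. floor(N/2)`` where
    ``X(k) = sum_n x(n) exp(-2j pi k n / N)``.
    """
    x = _validate_segment(segment)
    mags = np.abs(np.fft.rfft(x))
    return SpectrumVector(magnitudes=mags, bin_hz=segment.sampling_rate_hz / x.size)


def compute_stft(
    segment: EEGSegment,
    window_length: int = 128,
    overlap: int = 120,
) -> Spectrogram:
    """Hamming-windowed one-sided magnitude spectrogram.

    Frame ``t`` covers samples ``[t*hop, t*hop + window_length)``; the tail
    that does not fill a whole window is dropped.  Frame count is therefore
    ``floor((N - window) / hop) + 1`` and bin count ``floor(window/2) + 1``.
    """
    x = _validate_segment(segment)
    if window_length > x.size:
        raise InvalidInputError(
            f"window ({window_length}) longer than segment ({x.size})"
        )
    if not 0 <= overlap < window_length:
        raise InvalidInputError("overlap must satisfy 0 <= overlap < window")
    hop = window_length - overlap
    frames = np.lib.stride_tricks.sliding_window_view(x, window_length)[::hop]
    window = np.hamming(window_length)
    spec = np.abs(np.fft.rfft(frames * window, axis=1))
    return Spectrogram(
        magnitudes=spec.T.copy(),
        window_length=window_length,
        overlap=overlap,
    )


def _dwt_blocks(
    x: np.ndarray, wavelet_name: str, level: int, mode: str
) -> dict[str, np.ndarray]:
    """All approximation/detail blocks cA1..cA{level}, cD1..cD{level}."""
    try:
        wavelet = pywt.Wavelet(wavelet_name)
    except ValueError as exc:
        raise ConfigurationError(f"unknown wavelet {wavelet_name!r}") from exc
    blocks: dict[str, np.ndarray] = {}
    approx = x
    for j in range(1, level + 1):
        approx, detail = pywt.dwt(approx, wavelet, mode=mode)
        blocks[f"cA{j}"] = approx
        blocks[f"cD{j}"] = detail
    return blocks


def compute_dwt(
    segment: EEGSegment,
    wavelet_name: str = "db1",
    level: int = 2,
    layout: tuple[str, ...] = ("cA2", "cD2", "cA1"),
    mode: str = "symmetric",
) -> WaveletVector:
    """Multilevel DWT, returning the requested subband blocks concatenated.

    Each level convolves the running approximation with the wavelet's low- and
    high-pass decomposition filters and downsamples by 2; ``cAj``/``cDj`` are
    the level-``j`` approximation/detail coefficients.
    """
    x = _validate_segment(segment)
    if level < 1:
        raise ConfigurationError("level must be >= 1")
    if 2**level > x.size:
        raise InvalidInputError(
            f"segment of length {x.size} too short for a level-{level} DWT"
        )
    blocks = _dwt_blocks(x, wavelet_name, level, mode)
    missing = [name for name in layout if name not in blocks]
    if missing:
        raise ConfigurationError(
            f"blocks {missing} not available at level {level} "
            f"(have {sorted(blocks)})"
        )
    parts = [blocks[name] for name in layout]
    return WaveletVector(
        coefficients=np.concatenate(parts),
        layout=tuple((name, blocks[name].size) for name in layout),
        wavelet_name=wavelet_name,
        level=level,
    )


def standardize(values: np.ndarray) -> np.ndarray:
    """Zero-mean / unit-variance scaling over all entries.

    A zero-variance input is only centered (no division), so constant inputs
    map to all-zero arrays instead of NaNs.
    """
    values = np.asarray(values, dtype=np.float64)
    centered = values - values.mean()
    sd = values.std()
    if sd > 0.0:
        centered = centered / sd
    return centered


def make_hybrid(segment: EEGSegment, config: TransformConfig | None = None) -> HybridInput:
    """Compute all four representations of one segment.

    The representations are pure functions of the samples and the config; the
    segment's label and source id only travel along as metadata.  The
    ``model_*`` arrays are standardized per representation (when
    ``config.standardize``) and cast to float32 for the network.
    """
    config = config or TransformConfig()
    dft = compute_dft(segment)
    stft = compute_stft(segment, config.window_length, config.overlap)
    dwt = compute_dwt(
        segment, config.wavelet_name, config.level, config.dwt_layout, config.dwt_mode
    )

    def prep(values: np.ndarray, log: bool = False) -> np.ndarray:
        values = np.log1p(values) if log else values
        if config.standardize:
            values = standardize(values)
        return np.asarray(values, dtype=np.float32)

    return HybridInput(
        raw=segment,
        dft=dft,
        stft=stft,
        dwt=dwt,
        model_raw=prep(segment.samples),
        model_dft=prep(dft.magnitudes, config.log_spectra),
        model_stft=prep(stft.magnitudes, config.log_spectra),
        model_dwt=prep(dwt.coefficients),
    )
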