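"""Synthetic single-channel EEG with class-specific spectral structure.

The generator emulates the qualitative contrast between healthy and ictal
surface EEG: normal segments carry a theta-dominant (4-8 Hz) oscillation of
moderate amplitude, while ictal segments carry a much larger delta-dominant
(0.5-4 Hz) oscillation plus elevated alpha- and beta-band power, all on top
of 1/f-shaped background noise.  It is an emulation target for testing the
pipeline, not a claim about real EEG morphology (no spike-wave complexes, no
artifacts, no nonstationarity beyond the random component frequencies).

Every segment is fully determined by ``(seed, class, index)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import ConfigurationError
from .segment import (
    DEFAULT_LENGTH,
    DEFAULT_SAMPLING_RATE_HZ,
    LABEL_EPILEPTIC,
    LABEL_NORMAL,
    LABELS,
    EEGSegment,
)

__all__ = ["SynthConfig", "generate_segment", "generate_dataset"]

#: Conventional rhythm bands (Hz) used for the ictal broadband components.
ALPHA_BAND = (8.0, 13.0)
BETA_BAND = (13.0, 30.0)


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters.

    ``ictal_amplitude_gain`` multiplies the whole deterministic (oscillatory)
    part of ictal segments; ``broadband_gain_ictal`` scales the extra alpha
    and beta components (base amplitude 0.2 each) that give ictal segments
    their elevated broadband power.  ``noise_sd`` is the standard deviation
    of the 1/f background shared by both classes.
    """

    n_per_class: int = 100
    length: int = DEFAULT_LENGTH
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    normal_band_hz: tuple[float, float] = (4.0, 8.0)
    ictal_band_hz: tuple[float, float] = (0.5, 4.0)
    ictal_amplitude_gain: float = 4.0
    broadband_gain_ictal: float = 1.5
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        nyquist = self.sampling_rate_hz / 2.0
        for band in (self.normal_band_hz, self.ictal_band_hz):
            if not (0.0 < band[0] < band[1] < nyquist):
                raise ConfigurationError(
                    f"band {band} must lie within (0, {nyquist}) with low < high"
                )
        if self.ictal_amplitude_gain <= 0 or self.broadband_gain_ictal < 0:
            raise ConfigurationError("gains must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.n_per_class < 1 or self.length < 4:
            raise ConfigurationError("n_per_class >= 1 and length >= 4 required")


def _pink_noise(
    rng: np.random.Generator, n: int, sampling_rate_hz: float, cutoff_hz: float = 0.5
) -> np.ndarray:
    """Unit-variance 1/f background noise via spectral shaping of white noise.

    White Gaussian noise is filtered so its power spectrum falls off as 1/f
    (amplitude exponent 1/2).  Content below ``cutoff_hz`` is removed,
    mirroring the high-pass of clinical EEG acquisition; without it the
    lowest bins of a true 1/f process dwarf everything else.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate_hz)
    shape = np.zeros_like(freqs)
    passband = freqs >= cutoff_hz
    shape[passband] = (freqs[passband] / sampling_rate_hz) ** -0.5
    pink = np.fft.irfft(spec * shape, n=n)
    sd = pink.std()
    return pink / sd if sd > 0 else pink


def generate_segment(
    class_label: str, config: SynthConfig | None = None, index: int = 0
) -> EEGSegment:
    """One synthetic segment, deterministic in (config.seed, class, index).

    The segment is the sum of a dominant oscillation at a random frequency
    drawn from the class's band (random phase, amplitude 1), for ictal
    segments additional alpha- and beta-band oscillations scaled by
    ``broadband_gain_ictal``, and 1/f background noise of scale ``noise_sd``.
    The deterministic part of ictal segments is multiplied by
    ``ictal_amplitude_gain``.
    """
    config = config or SynthConfig()
    if class_label not in LABELS:
        raise ConfigurationError(f"class_label must be one of {LABELS}")
    cls = LABELS.index(class_label)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(cls, int(index)))
    )
    t = np.arange(config.length) / config.sampling_rate_hz
    band = config.normal_band_hz if cls == 0 else config.ictal_band_hz

    def tone(lo: float, hi: float, amplitude: float) -> np.ndarray:
        f = rng.uniform(lo, hi)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        return amplitude * np.sin(2.0 * np.pi * f * t + phase)

    signal = tone(*band, 1.0)
    if cls == 1:
        signal = signal + tone(*ALPHA_BAND, 0.2 * config.broadband_gain_ictal)
        signal = signal + tone(*BETA_BAND, 0.2 * config.broadband_gain_ictal)
        signal = signal * config.ictal_amplitude_gain
    samples = signal + config.noise_sd * _pink_noise(
        rng, config.length, config.sampling_rate_hz
    )
    return EEGSegment(
        samples=samples,
        sampling_rate_hz=config.sampling_rate_hz,
        label=class_label,
        source_id=f"synth-{class_label}-{config.seed}-{index:04d}",
    )


def generate_dataset(config: SynthConfig | None = None) -> list[EEGSegment]:
    """``n_per_class`` segments per class, normal first then epileptic."""
    config = config or SynthConfig()
    segments = [
        generate_segment(LABEL_NORMAL, config, i) for i in range(config.n_per_class)
    ]
    segments += [
        generate_segment(LABEL_EPILEPTIC, config, i) for i in range(config.n_per_class)
    ]
    return segments
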