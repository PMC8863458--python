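"""Single-channel EEG segments.

A segment is a fixed-length, uniformly sampled voltage trace with an optional
class label.  The canonical layout (one 4097-sample trace per file, five sets
A-E of 100 traces each, nominally sampled at 173.61 Hz) matches the widely
used Andrzejak surface/intracranial EEG collection, but nothing in the package
depends on those particular numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import InvalidInputError

#: Recognised class labels.  ``None`` marks an unlabeled segment.
LABEL_NORMAL = "normal"
LABEL_EPILEPTIC = "epileptic"
LABELS = (LABEL_NORMAL, LABEL_EPILEPTIC)

DEFAULT_LENGTH = 4097
DEFAULT_SAMPLING_RATE_HZ = 173.61


@dataclass
class EEGSegment:
    """A sampled single-channel EEG trace.

    Parameters
    ----------
    samples
        Real-valued voltage samples (microvolt scale; unitless after any
        normalization).  Stored as a float64 1-D array.
    sampling_rate_hz
        Sampling frequency in Hz.  Used only for axis labeling and band
        definitions, never inside the transforms themselves.
    label
        ``"normal"``, ``"epileptic"`` or ``None``.
    source_id
        Free-text provenance identifier (e.g. file name or generator key).
    """

    samples: np.ndarray
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    label: str | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.samples.size == 0:
            raise InvalidInputError("EEGSegment requires at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidInputError(
                f"EEGSegment {self.source_id!r} contains non-finite samples"
            )
        if not self.sampling_rate_hz > 0:
            raise InvalidInputError("sampling_rate_hz must be positive")
        if self.label is not None and self.label not in LABELS:
            raise InvalidInputError(
                f"label must be one of {LABELS} or None, got {self.label!r}"
            )

    @property
    def length(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.length / self.sampling_rate_hz

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.length


def labels_to_indices(segments: list[EEGSegment]) -> np.ndarray:
    """Map segment labels to class indices (0 = normal, 1 = epileptic)."""
    out = np.empty(len(segments), dtype=np.int64)
    for i, seg in enumerate(segments):
        if seg.label not in LABELS:
            raise InvalidInputError(
                f"segment {seg.source_id!r} is unlabeled; cannot form class indices"
            )
        out[i] = LABELS.index(seg.label)
    return out
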