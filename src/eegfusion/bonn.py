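"""Readers and writers for the plain-text five-set EEG layout.

Layout: a root directory with one subdirectory per set (A-E; the mirror
aliases Z, O, N, F, S are accepted), each holding one text file per segment
with one sample value per line (canonically 4097 lines).  Sets A/B are
healthy recordings, C/D interictal and E ictal, so binary tasks map A/B to
"normal" and C/D/E to "epileptic".
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import InvalidInputError
from .evaluation import FoldReport
from .segment import DEFAULT_SAMPLING_RATE_HZ, LABEL_EPILEPTIC, LABEL_NORMAL, EEGSegment
from .transforms import HybridInput

__all__ = [
    "SET_ALIASES",
    "TASKS",
    "read_bonn_directory",
    "write_bonn_directory",
    "write_report",
    "read_report",
    "save_hybrid_container",
    "RunManifest",
]

#: Canonical set name -> accepted directory aliases.
SET_ALIASES = {
    "A": ("A", "Z"),
    "B": ("B", "O"),
    "C": ("C", "N"),
    "D": ("D", "F"),
    "E": ("E", "S"),
}

_SET_LABEL = {"A": LABEL_NORMAL, "B": LABEL_NORMAL,
              "C": LABEL_EPILEPTIC, "D": LABEL_EPILEPTIC, "E": LABEL_EPILEPTIC}

#: Binary task name -> sets involved.
TASKS = {"A_vs_E": ("A", "E"), "AB_vs_CD": ("A", "B", "C", "D")}


def _find_set_dir(root: Path, set_name: str) -> Path | None:
    for alias in SET_ALIASES[set_name]:
        for candidate in (root / alias, root / alias.lower()):
            if candidate.is_dir():
                return candidate
    return None


def _read_segment_file(
    path: Path,
    label: str,
    sampling_rate_hz: float,
    expected_length: int | None,
    on_length_mismatch: str,
) -> EEGSegment | None:
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError as exc:
                raise InvalidInputError(
                    f"{path}:{lineno}: cannot parse {line!r} as a number"
                ) from exc
    if expected_length is not None and len(values) != expected_length:
        warnings.warn(
            f"{path}: expected {expected_length} samples, found {len(values)}",
            stacklevel=3,
        )
        if on_length_mismatch == "reject":
            return None
        if on_length_mismatch == "truncate":
            values = values[:expected_length]
    return EEGSegment(
        samples=np.array(values),
        sampling_rate_hz=sampling_rate_hz,
        label=label,
        source_id=path.name,
    )


def read_bonn_directory(
    path: str | Path,
    sets: tuple[str, ...] = ("A", "E"),
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    expected_length: int | None = None,
    on_length_mismatch: str = "truncate",
) -> list[EEGSegment]:
    """Read the requested sets, one labeled segment per file.

    Files within each set are read in sorted order, preserved in
    ``source_id``.  A/B map to normal, C/D/E to epileptic.  With
    ``expected_length`` set, off-length files trigger a warning and are
    truncated or rejected per ``on_length_mismatch``.
    """
    root = Path(path)
    if not root.is_dir():
        raise InvalidInputError(f"{root} is not a directory")
    if on_length_mismatch not in ("truncate", "reject"):
        raise InvalidInputError("on_length_mismatch must be 'truncate' or 'reject'")
    segments: list[EEGSegment] = []
    for set_name in sets:
        if set_name not in SET_ALIASES:
            raise InvalidInputError(f"unknown set {set_name!r}")
        set_dir = _find_set_dir(root, set_name)
        if set_dir is None:
            warnings.warn(f"set {set_name} not found under {root}", stacklevel=2)
            continue
        files = sorted(p for p in set_dir.iterdir() if p.is_file())
        if not files:
            warnings.warn(f"set directory {set_dir} is empty", stacklevel=2)
        for f in files:
            seg = _read_segment_file(
                f, _SET_LABEL[set_name], sampling_rate_hz,
                expected_length, on_length_mismatch,
            )
            if seg is not None:
                seg.source_id = f"{set_name}/{f.name}"
                segments.append(seg)
    if not segments:
        warnings.warn(f"no segments read from {root}", stacklevel=2)
    return segments


def write_bonn_directory(
    segments: list[EEGSegment],
    path: str | Path,
    set_names: dict[str, str] | None = None,
) -> None:
    """Export segments to the plain-text layout (one subdirectory per class).

    ``set_names`` maps class label to directory name; defaults write normal
    segments to ``A`` and epileptic ones to ``E``.
    """
    set_names = set_names or {LABEL_NORMAL: "A", LABEL_EPILEPTIC: "E"}
    root = Path(path)
    counters: dict[str, int] = {}
    for seg in segments:
        if seg.label not in set_names:
            raise InvalidInputError(f"no set name for label {seg.label!r}")
        sdir = root / set_names[seg.label]
        sdir.mkdir(parents=True, exist_ok=True)
        counters[seg.label] = counters.get(seg.label, 0) + 1
        fname = sdir / f"{set_names[seg.label]}{counters[seg.label]:03d}.txt"
        np.savetxt(fname, seg.samples, fmt="%.6f")


def write_report(report: FoldReport, path: str | Path) -> None:
    """Write a fold report as CSV with K1..KN, Mean, Variance columns."""
    df = report.summary()
    df.to_csv(path, index_label="Methods", float_format="%.4f")


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="Methods")


def save_hybrid_container(
    hybrids: list[HybridInput], path: str | Path, config_dict: dict | None = None
) -> None:
    """Save transformed representations plus a JSON sidecar of shapes/config.

    One compressed container holds the stacked model-ready blocks (raw, dft,
    stft, dwt) and labels; ``<path>.json`` records the config and shapes.
    """
    path = Path(path)
    blocks = {
        name: np.stack([h.model_arrays()[name] for h in hybrids])
        for name in ("raw", "dft", "stft", "dwt")
    }
    labels = np.array([h.label or "" for h in hybrids])
    sources = np.array([h.raw.source_id for h in hybrids])
    np.savez_compressed(path, labels=labels, sources=sources, **blocks)
    sidecar = {
        "n_segments": len(hybrids),
        "shapes": {k: list(v.shape[1:]) for k, v in blocks.items()},
        "config": config_dict or {},
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit."""

    master_seed: int
    fold_seeds: list[int] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    tool_version: str = ""

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
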