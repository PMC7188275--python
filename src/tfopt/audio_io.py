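"""Audio and annotation I/O plus the shared coordinate conventions.

All downstream modules receive times in seconds.  Sample index ``i`` covers
the half-open interval ``[i/fs, (i+1)/fs)``; a time ``t`` maps to sample
``floor(t * fs)``.  Annotation intervals are half-open ``[onset, offset)``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "AudioRecording",
    "SegmentAnnotation",
    "SEGMENT_TYPES",
    "read_audio",
    "write_audio",
    "read_annotations",
    "write_annotations",
    "validate_annotations",
]

SEGMENT_TYPES = ("syllable", "call", "noise", "click", "excluded")

ANNOTATION_COLUMNS = ("onset", "offset", "label", "segment_type")


class AudioFormatError(ValueError):
    """Raised for unsupported or malformed audio input."""


class AnnotationError(ValueError):
    """Raised for invalid annotation content."""


@dataclass
class AudioRecording:
    """Mono audio samples with their sampling rate.

    Parameters
    ----------
    samples : ndarray of float
        Mono waveform, arbitrary amplitude units.  Per-slice spectral
        normalization downstream makes the absolute scale irrelevant.
    sample_rate : int
        Sampling rate in Hz (both 44100 and 44150 Hz occur in practice).
    identifier : str
        Free-form recording id (typically the file stem).
    """

    samples: np.ndarray
    sample_rate: int
    identifier: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise AudioFormatError("AudioRecording requires mono (1-D) samples")
        if self.samples.size < 1:
            raise AudioFormatError("AudioRecording requires at least one sample")
        if int(self.sample_rate) <= 0:
            raise AudioFormatError("sample_rate must be positive")
        self.sample_rate = int(self.sample_rate)

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class SegmentAnnotation:
    """One annotated segment: half-open interval [onset, offset) in seconds."""

    onset: float
    offset: float
    label: str
    segment_type: str = "syllable"

    def __post_init__(self) -> None:
        if not (0.0 <= self.onset < self.offset):
            raise AnnotationError(
                f"invalid segment: require 0 <= onset < offset, got "
                f"({self.onset}, {self.offset})"
            )
        if self.segment_type not in SEGMENT_TYPES:
            raise AnnotationError(
                f"unknown segment_type {self.segment_type!r}; "
                f"expected one of {SEGMENT_TYPES}"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def time_to_sample(t: float, sample_rate: int) -> int:
    """Convert a time in seconds to the sample index covering it."""
    return int(np.floor(t * sample_rate))


def read_audio(path, downmix: bool = False) -> AudioRecording:
    """Read a PCM WAV file as a mono :class:`AudioRecording`.

    Integer PCM is rescaled to [-1, 1); float WAVs are taken as-is.
    Multi-channel input raises :class:`AudioFormatError` unless ``downmix``
    is set, in which case channels are averaged.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"audio file not found: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise AudioFormatError(f"unsupported WAV encoding in {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        if not downmix:
            raise AudioFormatError(
                f"{path} has {data.shape[1]} channels; pass downmix=True to average"
            )
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    return AudioRecording(samples=data, sample_rate=int(rate), identifier=path.stem)


def write_audio(recording: AudioRecording, path, subtype: str = "float32") -> None:
    """Write a mono recording as WAV (``float32`` or 16-bit ``pcm16``)."""
    path = Path(path)
    if subtype == "float32":
        data = recording.samples.astype(np.float32)
    elif subtype == "pcm16":
        clipped = np.clip(recording.samples, -1.0, 1.0 - 1.0 / 32768)
        data = np.round(clipped * 32768.0).astype(np.int16)
    else:
        raise AudioFormatError(f"unsupported subtype {subtype!r}")
    try:
        wavfile.write(str(path), recording.sample_rate, data)
    except OSError as exc:
        raise IOError(f"cannot write audio to {path}: {exc}") from exc


def validate_annotations(
    annotations: Iterable[SegmentAnnotation],
) -> list[SegmentAnnotation]:
    """Sort by onset and reject overlapping segments."""
    out = sorted(annotations, key=lambda a: a.onset)
    for prev, cur in zip(out, out[1:]):
        if cur.onset < prev.offset:
            raise AnnotationError(
                f"overlapping segments: [{prev.onset}, {prev.offset}) and "
                f"[{cur.onset}, {cur.offset})"
            )
    return out


def read_annotations(path) -> list[SegmentAnnotation]:
    """Read a CSV of segments (columns onset, offset, label, segment_type)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"annotation file not found: {path}")
    df = pd.read_csv(
        path,
        dtype={"label": str, "segment_type": str},
        float_precision="round_trip",
    )
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(f"{path}: missing columns {sorted(missing)}")
    anns = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            anns.append(
                SegmentAnnotation(
                    onset=float(row.onset),
                    offset=float(row.offset),
                    label=str(row.label),
                    segment_type=str(row.segment_type),
                )
            )
        except AnnotationError as exc:
            raise AnnotationError(f"{path} row {i + 2}: {exc}") from exc
    return validate_annotations(anns)


def write_annotations(annotations: Sequence[SegmentAnnotation], path) -> None:
    """Write segments as CSV; round-trips exactly through read_annotations."""
    anns = validate_annotations(annotations)
    df = pd.DataFrame(
        {
            "onset": [a.onset for a in anns],
            "offset": [a.offset for a in anns],
            "label": [a.label for a in anns],
            "segment_type": [a.segment_type for a in anns],
        },
        columns=list(ANNOTATION_COLUMNS),
    )
    try:
        # pandas' default float formatting is shortest-round-trip: exact
        df.to_csv(path, index=False)
    except OSError as exc:
        raise IOError(f"cannot write annotations to {path}: {exc}") from exc
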