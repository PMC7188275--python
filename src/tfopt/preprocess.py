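"""Spectral slicing, normalization, slice labeling and the amplitude threshold.

The raw audio stream is cut into non-overlapping 256-sample frames
(~6 msec at 44.1 kHz).  Each frame is mean-subtracted, Hamming-windowed and
Fourier transformed; the one-sided magnitude spectrum (129 bins) is the raw
slice.  Song amplitude is the sum of squared magnitudes of the raw spectrum.
Bins whose center frequency lies below 1 kHz are zeroed, and the remaining
bins are min-max scaled into [0, 1]; this normalized vector is the "slice"
that all template matching operates on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .audio_io import AudioRecording, SegmentAnnotation

__all__ = [
    "SLICE_SAMPLES",
    "N_BINS",
    "RawSlice",
    "Slice",
    "AmplitudeThreshold",
    "frame_audio",
    "compute_raw_slice",
    "normalize_spectrum",
    "normalize_slice",
    "slice_recording",
    "label_slices",
    "fit_amplitude_threshold",
    "low_freq_mask",
]

SLICE_SAMPLES = 256
N_BINS = SLICE_SAMPLES // 2 + 1  # one-sided spectrum of a 256-point transform
LOW_FREQ_CUTOFF_HZ = 1000.0


@dataclass
class RawSlice:
    """Pre-normalization magnitude spectrum of one frame."""

    spectrum_raw: np.ndarray
    amplitude: float
    start_sample: int

    def __post_init__(self) -> None:
        self.spectrum_raw = np.asarray(self.spectrum_raw, dtype=np.float64)
        if np.any(self.spectrum_raw < 0):
            raise ValueError("magnitude spectrum must be non-negative")
        expected = float(np.sum(self.spectrum_raw**2))
        if not np.isclose(self.amplitude, expected, rtol=1e-9, atol=1e-12):
            raise ValueError("amplitude must equal sum of squared spectrum values")


@dataclass
class Slice:
    """Normalized spectral slice: values in [0, 1], sub-1 kHz bins zero."""

    spectrum: np.ndarray
    start_sample: int
    center_time: float
    amplitude: float
    label: str = "gap"
    degenerate: bool = False
    segment_type: str = "gap"
    segment_index: int = -1  # index into the annotation list; -1 for gaps

    def __post_init__(self) -> None:
        self.spectrum = np.asarray(self.spectrum, dtype=np.float64)


@dataclass(frozen=True)
class AmplitudeThreshold:
    """Amplitude separating syllable slices from gap slices."""

    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("amplitude threshold must be >= 0")


def bin_frequencies(sample_rate: int) -> np.ndarray:
    """Center frequency of each one-sided bin, k * fs / 256."""
    return np.arange(N_BINS) * sample_rate / SLICE_SAMPLES


def low_freq_mask(sample_rate: int) -> np.ndarray:
    """Boolean mask of bins with center frequency below 1 kHz."""
    return bin_frequencies(sample_rate) < LOW_FREQ_CUTOFF_HZ


def frame_audio(recording: AudioRecording) -> np.ndarray:
    """Cut the recording into consecutive non-overlapping 256-sample frames.

    Returns an array of shape (n_frames, 256).  A trailing partial frame is
    discarded; a recording shorter than one frame yields an empty result
    with a warning.
    """
    n = recording.samples.size
    n_frames = n // SLICE_SAMPLES
    if n_frames == 0:
        warnings.warn(
            f"recording {recording.identifier!r} shorter than one "
            f"{SLICE_SAMPLES}-sample frame; no slices produced"
        )
        return np.empty((0, SLICE_SAMPLES))
    return recording.samples[: n_frames * SLICE_SAMPLES].reshape(
        n_frames, SLICE_SAMPLES
    )


_HAMMING = np.hamming(SLICE_SAMPLES)


def compute_raw_slice(frame: np.ndarray, start_sample: int = 0) -> RawSlice:
    """Magnitude spectrum of one mean-subtracted, Hamming-windowed frame."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != (SLICE_SAMPLES,):
        raise ValueError(f"frame must have exactly {SLICE_SAMPLES} samples")
    windowed = (frame - frame.mean()) * _HAMMING
    spectrum = np.abs(np.fft.rfft(windowed))
    return RawSlice(
        spectrum_raw=spectrum,
        amplitude=float(np.sum(spectrum**2)),
        start_sample=int(start_sample),
    )


def normalize_spectrum(
    spectrum: np.ndarray, sample_rate: int
) -> tuple[np.ndarray, bool]:
    """Zero sub-1 kHz bins; min-max scale the remaining bins into [0, 1].

    Returns ``(normalized, degenerate)``.  If the spectrum is constant over
    the >= 1 kHz bins the map is undefined and the slice is all-zero and
    flagged degenerate.
    """
    spectrum = np.asarray(spectrum, dtype=np.float64)
    mask = low_freq_mask(sample_rate)
    out = np.zeros_like(spectrum)
    hi = spectrum[~mask]
    lo_val, hi_val = hi.min(), hi.max()
    if hi_val == lo_val:
        return out, True
    out[~mask] = (hi - lo_val) / (hi_val - lo_val)
    return out, False


def normalize_slice(raw: RawSlice, sample_rate: int) -> Slice:
    """Build the normalized :class:`Slice` for one raw spectrum."""
    spectrum, degenerate = normalize_spectrum(raw.spectrum_raw, sample_rate)
    center_sample = raw.start_sample + SLICE_SAMPLES // 2
    return Slice(
        spectrum=spectrum,
        start_sample=raw.start_sample,
        center_time=center_sample / sample_rate,
        amplitude=raw.amplitude,
        degenerate=degenerate,
    )


def slice_recording(recording: AudioRecording) -> list[Slice]:
    """Frame, transform and normalize an entire recording (vectorized)."""
    frames = frame_audio(recording)
    if frames.shape[0] == 0:
        return []
    windowed = (frames - frames.mean(axis=1, keepdims=True)) * _HAMMING
    spectra = np.abs(np.fft.rfft(windowed, axis=1))
    amplitudes = np.sum(spectra**2, axis=1)
    mask = low_freq_mask(recording.sample_rate)
    hi = spectra[:, ~mask]
    lo_val = hi.min(axis=1, keepdims=True)
    hi_val = hi.max(axis=1, keepdims=True)
    span = hi_val - lo_val
    degenerate = span[:, 0] == 0
    span[span == 0] = 1.0
    norm = np.zeros_like(spectra)
    norm[:, ~mask] = (hi - lo_val) / span
    norm[degenerate] = 0.0
    out = []
    for i in range(frames.shape[0]):
        start = i * SLICE_SAMPLES
        out.append(
            Slice(
                spectrum=norm[i],
                start_sample=start,
                center_time=(start + SLICE_SAMPLES // 2) / recording.sample_rate,
                amplitude=float(amplitudes[i]),
                degenerate=bool(degenerate[i]),
            )
        )
    return out


def label_slices(
    slices: Sequence[Slice], annotations: Sequence[SegmentAnnotation]
) -> list[Slice]:
    """Assign each slice the label of the segment containing its center.

    Segments are half-open [onset, offset); a slice whose center time falls
    between segments is labeled 'gap'.  Labels are set in place and the list
    is returned for convenience.
    """
    anns = sorted(annotations, key=lambda a: a.onset)
    onsets = np.array([a.onset for a in anns])
    offsets = np.array([a.offset for a in anns])
    for s in slices:
        idx = np.searchsorted(onsets, s.center_time, side="right") - 1
        if idx >= 0 and s.center_time < offsets[idx]:
            s.label = anns[idx].label
            s.segment_type = anns[idx].segment_type
            s.segment_index = int(idx)
        else:
            s.label = "gap"
            s.segment_type = "gap"
            s.segment_index = -1
    return list(slices)


def fit_amplitude_threshold(
    syllable_amplitudes: Iterable[float],
    gap_amplitudes: Iterable[float],
) -> AmplitudeThreshold:
    """Threshold best separating syllable from gap slice amplitudes.

    Minimizes the balanced misclassification
    ``(frac syllables below + frac gaps at/above) / 2`` over candidate
    thresholds: midpoints between consecutive distinct pooled amplitudes
    plus one candidate below the minimum and one above the maximum.  Ties
    are broken toward the candidate with the largest margin to its
    neighboring amplitudes.
    """
    syl = np.asarray(list(syllable_amplitudes), dtype=np.float64)
    gap = np.asarray(list(gap_amplitudes), dtype=np.float64)
    if syl.size == 0 or gap.size == 0:
        raise ValueError("both amplitude collections must be non-empty")
    pooled = np.unique(np.concatenate([syl, gap]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0 if pooled.size > 1 else np.empty(0)
    lo = pooled[0] - 1.0 if pooled[0] <= 1.0 else pooled[0] / 2.0
    lo = max(lo, 0.0)
    hi = pooled[-1] + max(1.0, pooled[-1])
    candidates = np.concatenate([[lo], mids, [hi]])
    # balanced error at each candidate threshold t:
    #   (frac syllable amps < t  +  frac gap amps >= t) / 2
    fn = np.searchsorted(np.sort(syl), candidates, side="left") / syl.size
    fp = 1.0 - np.searchsorted(np.sort(gap), candidates, side="left") / gap.size
    err = (fn + fp) / 2.0
    best = err.min()
    tied = np.flatnonzero(np.isclose(err, best, rtol=0, atol=1e-15))
    if tied.size > 1:
        # prefer the tied candidate farthest from any observed amplitude
        margins = np.min(np.abs(candidates[tied, None] - pooled[None, :]), axis=1)
        choice = tied[int(np.argmax(margins))]
    else:
        choice = int(tied[0])
    if best >= 0.5 - 1e-12:
        warnings.warn(
            "syllable and gap amplitude distributions are not separable "
            f"(best balanced misclassification {best:.3f})"
        )
    return AmplitudeThreshold(value=float(candidates[choice]))
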