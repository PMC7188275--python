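"""Offline simulation of real-time triggered-feedback detection.

A slice matches when its distance to the template is at or below a scaled
slice-optimal threshold AND its amplitude exceeds the amplitude threshold.
A run of `criterion` consecutive matching slices triggers a detection,
attributed to the song element (syllable, call/noise/click segment, or
inter-segment gap) containing the run's final slice.  Consecutive-match
runs are counted on the raw slice stream, as real-time hardware would,
without knowledge of element boundaries; elements matter only for scoring.

Because there are vastly more distractor elements than targets, the false
positive rate is normalized by the number of *target* syllables, and the
balanced error is the mean of the false-negative ratio and this redefined
false-positive ratio, in percent.  Detection parameters are tuned by brute
force over 21 threshold scalings (0–200% in 10% steps) x 5 criteria (1–5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import discriminant as disc
from .audio_io import SegmentAnnotation
from .preprocess import AmplitudeThreshold, Slice
from .template import Template

__all__ = [
    "DetectionConfig",
    "DetectionEvent",
    "Element",
    "BalancedErrorReport",
    "enumerate_elements",
    "stream_detect",
    "balanced_error",
    "grid_search",
    "best_template_per_syllable",
    "THRESHOLD_GRID",
    "CRITERION_GRID",
]

THRESHOLD_GRID = tuple(range(0, 201, 10))  # percent of slice-optimal theta
CRITERION_GRID = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class DetectionConfig:
    """Syllable-level targeting parameters."""

    threshold_fraction: float = 100.0  # percent of slice-optimal theta
    criterion: int = 1  # consecutive matches required
    amplitude_threshold: AmplitudeThreshold = field(
        default_factory=lambda: AmplitudeThreshold(0.0)
    )

    def __post_init__(self) -> None:
        if self.threshold_fraction < 0:
            raise ValueError("threshold_fraction must be >= 0")
        if int(self.criterion) < 1:
            raise ValueError("criterion must be a positive integer")


@dataclass(frozen=True)
class Element:
    """One scoreable song element: a segment or an inter-segment gap."""

    song_id: str
    onset: float
    offset: float
    label: str
    segment_type: str  # 'gap' for inter-segment elements
    slice_indices: tuple[int, ...]
    max_amplitude: float


@dataclass(frozen=True)
class DetectionEvent:
    """One detection: the element containing the triggering slice."""

    song_id: str
    element_index: int
    trigger_slice_start: int
    trigger_time: float
    element_label: str
    is_target: bool


def enumerate_elements(
    slices: Sequence[Slice],
    annotations: Sequence[SegmentAnnotation],
    song_id: str = "",
) -> list[Element]:
    """List scoreable elements of one song: segments plus gaps.

    Gap elements are maximal runs of gap-labeled slices; their amplitude
    statistics decide later whether they can count as false positives.
    """
    elements: list[Element] = []
    anns = sorted(annotations, key=lambda a: a.onset)
    by_segment: dict[int, list[int]] = {}
    gap_runs: list[list[int]] = []
    prev_gap = False
    for i, s in enumerate(slices):
        if s.segment_index >= 0:
            by_segment.setdefault(s.segment_index, []).append(i)
            prev_gap = False
        else:
            if not prev_gap:
                gap_runs.append([])
            gap_runs[-1].append(i)
            prev_gap = True
    for idx, ann in enumerate(anns):
        elements.append(
            Element(
                song_id=song_id,
                onset=ann.onset,
                offset=ann.offset,
                label=ann.label,
                segment_type=ann.segment_type,
                slice_indices=tuple(by_segment.get(idx, ())),
                max_amplitude=max(
                    (slices[i].amplitude for i in by_segment.get(idx, ())),
                    default=0.0,
                ),
            )
        )
    for run in gap_runs:
        elements.append(
            Element(
                song_id=song_id,
                onset=slices[run[0]].center_time,
                offset=slices[run[-1]].center_time,
                label="gap",
                segment_type="gap",
                slice_indices=tuple(run),
                max_amplitude=max(slices[i].amplitude for i in run),
            )
        )
    elements.sort(key=lambda e: e.onset)
    return elements


def _match_mask(
    slices: Sequence[Slice],
    template: Template,
    config: DetectionConfig,
    precomputed_distances: np.ndarray | None = None,
) -> np.ndarray:
    if precomputed_distances is None:
        spectra = np.stack([s.spectrum for s in slices])
        precomputed_distances = disc.distances(template.vector, spectra)
    thr = (config.threshold_fraction / 100.0) * template.theta
    amps = np.array([s.amplitude for s in slices])
    return (precomputed_distances <= thr) & (
        amps > config.amplitude_threshold.value
    )


def stream_detect(
    slices: Sequence[Slice],
    template: Template,
    config: DetectionConfig,
    elements: Sequence[Element] | None = None,
    annotations: Sequence[SegmentAnnotation] | None = None,
    song_id: str = "",
    precomputed_distances: np.ndarray | None = None,
) -> list[DetectionEvent]:
    """Run the consecutive-match detector over one song's slice stream.

    Returns at most one event per element (the first); the run counter
    resets after each trigger so a long matching run yields one detection.
    """
    if elements is None:
        if annotations is None:
            raise ValueError("provide either elements or annotations")
        elements = enumerate_elements(slices, annotations, song_id)
    matches = _match_mask(slices, template, config, precomputed_distances)
    # element index per slice
    slice_to_element = np.full(len(slices), -1, dtype=int)
    for ei, el in enumerate(elements):
        for si in el.slice_indices:
            slice_to_element[si] = ei
    events: list[DetectionEvent] = []
    detected: set[int] = set()
    run = 0
    for i, m in enumerate(matches):
        if not m:
            run = 0
            continue
        run += 1
        if run >= config.criterion:
            run = 0  # one detection per distinct run
            ei = int(slice_to_element[i])
            if ei < 0 or ei in detected:
                continue
            detected.add(ei)
            el = elements[ei]
            events.append(
                DetectionEvent(
                    song_id=song_id or el.song_id,
                    element_index=ei,
                    trigger_slice_start=slices[i].start_sample,
                    trigger_time=slices[i].center_time,
                    element_label=el.label,
                    is_target=False,  # filled by scoring against a target
                )
            )
    return events


@dataclass
class BalancedErrorReport:
    """Syllable-level error summary for one template and configuration."""

    n_targets: int
    false_negatives: int
    false_positives: int
    fn_ratio: float
    fp_ratio: float
    balanced_error: float  # percent


def balanced_error(
    events: Sequence[DetectionEvent],
    elements: Sequence[Element],
    target_label: str,
    amplitude_threshold: AmplitudeThreshold | None = None,
) -> BalancedErrorReport:
    """Score detections against elements of one (or several pooled) songs.

    False negatives: target elements with no detection.  False positives:
    detections on non-target elements, divided by the number of *targets*
    (the ratio may exceed 1).  Gap elements count as potential false
    positives only when they contain at least one slice above the
    amplitude threshold.  Segments marked 'excluded' are ignored entirely.
    """
    targets = [
        e
        for e in elements
        if e.label == target_label and e.segment_type == "syllable"
    ]
    if not targets:
        raise ValueError(f"no target elements labeled {target_label!r}")
    amp = amplitude_threshold.value if amplitude_threshold else 0.0

    def scoreable(e: Element) -> bool:
        if e.segment_type == "excluded":
            return False
        if e.segment_type == "gap":
            return e.max_amplitude > amp
        return True

    target_keys = {(e.song_id, e.onset) for e in targets}
    detected_keys: set[tuple[str, float]] = set()
    fp = 0
    for ev in events:
        el = elements[ev.element_index]
        if not scoreable(el):
            continue
        if el.label == target_label and el.segment_type == "syllable":
            detected_keys.add((el.song_id, el.onset))
        else:
            fp += 1
    fn = sum(1 for k in target_keys if k not in detected_keys)
    n = len(targets)
    fn_ratio = fn / n
    fp_ratio = fp / n
    return BalancedErrorReport(
        n_targets=n,
        false_negatives=fn,
        false_positives=fp,
        fn_ratio=fn_ratio,
        fp_ratio=fp_ratio,
        balanced_error=100.0 * (fn_ratio + fp_ratio) / 2.0,
    )


@dataclass
class SongData:
    """Slices + ground-truth annotations of one song, with cached elements."""

    song_id: str
    slices: list
    annotations: list
    _elements: list[Element] | None = None

    @property
    def elements(self) -> list[Element]:
        if self._elements is None:
            self._elements = enumerate_elements(
                self.slices, self.annotations, self.song_id
            )
        return self._elements


def _trigger_indices(matches: np.ndarray, criterion: int) -> list[int]:
    """Slice indices that complete a run of `criterion` consecutive matches.

    The run counter resets after each trigger, so a maximal run of length L
    produces floor(L / criterion) triggers.
    """
    matches = np.asarray(matches, dtype=bool)
    if not matches.any():
        return []
    padded = np.concatenate([[False], matches, [False]]).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    out: list[int] = []
    for a, b in zip(starts, stops):
        length = b - a
        for k in range(1, length // criterion + 1):
            out.append(int(a + k * criterion - 1))
    return out


def detect_songs(
    songs: Sequence[SongData],
    template: Template,
    config: DetectionConfig,
) -> tuple[list[DetectionEvent], list[Element]]:
    """Run stream detection over many songs, pooling elements globally.

    Returned events index into the pooled element list.
    """
    all_events: list[DetectionEvent] = []
    all_elements: list[Element] = []
    for song in songs:
        offset = len(all_elements)
        elements = song.elements
        events = stream_detect(
            song.slices, template, config, elements=elements,
            song_id=song.song_id,
        )
        for ev in events:
            all_events.append(
                DetectionEvent(
                    song_id=ev.song_id,
                    element_index=ev.element_index + offset,
                    trigger_slice_start=ev.trigger_slice_start,
                    trigger_time=ev.trigger_time,
                    element_label=ev.element_label,
                    is_target=ev.is_target,
                )
            )
        all_elements.extend(elements)
    return all_events, all_elements


def grid_search(
    template: Template,
    songs: Sequence[SongData],
    target_label: str,
    amplitude_threshold: AmplitudeThreshold,
) -> tuple[DetectionConfig, float, pd.DataFrame]:
    """Brute-force search over the 21 x 5 targeting-parameter grid.

    Evaluates the balanced error for every combination of threshold scaling
    (0-200% of the slice-optimal threshold, step 10%) and detection
    criterion (1-5 consecutive matches).  Ties are broken toward stringency:
    lower threshold fraction, then higher criterion.  Returns the winning
    configuration, its balanced error (percent) and the full table.
    """
    # distances and element maps are independent of the grid cell
    per_song: list[tuple[np.ndarray, np.ndarray, np.ndarray, list[Element]]] = []
    all_elements: list[Element] = []
    offsets: list[int] = []
    for song in songs:
        spectra = np.stack([s.spectrum for s in song.slices])
        dists = disc.distances(template.vector, spectra)
        amps = np.array([s.amplitude for s in song.slices])
        elements = song.elements
        slice_to_element = np.full(len(song.slices), -1, dtype=int)
        for ei, el in enumerate(elements):
            for si in el.slice_indices:
                slice_to_element[si] = ei
        offsets.append(len(all_elements))
        per_song.append((dists, amps, slice_to_element, elements))
        all_elements.extend(elements)

    rows = []
    best: tuple[float, float, int] | None = None  # (error, frac, -criterion)
    best_cfg = None
    for frac in THRESHOLD_GRID:
        thr = (frac / 100.0) * template.theta
        for crit in CRITERION_GRID:
            events: list[DetectionEvent] = []
            for (dists, amps, s2e, elements), off in zip(per_song, offsets):
                matches = (dists <= thr) & (
                    amps > amplitude_threshold.value
                )
                detected: set[int] = set()
                for i in _trigger_indices(matches, crit):
                    ei = int(s2e[i])
                    if ei < 0 or ei in detected:
                        continue
                    detected.add(ei)
                    events.append(
                        DetectionEvent(
                            song_id=elements[ei].song_id,
                            element_index=ei + off,
                            trigger_slice_start=i,
                            trigger_time=0.0,
                            element_label=elements[ei].label,
                            is_target=False,
                        )
                    )
            report = balanced_error(
                events, all_elements, target_label, amplitude_threshold
            )
            rows.append(
                {
                    "threshold_fraction": frac,
                    "criterion": crit,
                    "fn_ratio": report.fn_ratio,
                    "fp_ratio": report.fp_ratio,
                    "balanced_error": report.balanced_error,
                }
            )
            key = (report.balanced_error, float(frac), -crit)
            if best is None or key < best:
                best = key
                best_cfg = DetectionConfig(
                    threshold_fraction=float(frac),
                    criterion=crit,
                    amplitude_threshold=amplitude_threshold,
                )
    table = pd.DataFrame(rows)
    assert best is not None and best_cfg is not None
    return best_cfg, best[0], table


def best_template_per_syllable(
    templates: Sequence[Template],
    songs: Sequence[SongData],
    target_label: str,
    amplitude_threshold: AmplitudeThreshold,
) -> tuple[Template, DetectionConfig, float]:
    """Pick the slice position whose tuned template has lowest balanced error.

    Ties break toward stringency (as in :func:`grid_search`) and then the
    earlier slice position.
    """
    if not templates:
        raise ValueError("no templates to evaluate")
    best_key = None
    best_out = None
    for tmpl in templates:
        cfg, err, _ = grid_search(tmpl, songs, target_label, amplitude_threshold)
        key = (err, cfg.threshold_fraction, -cfg.criterion, tmpl.position)
        if best_key is None or key < best_key:
            best_key = key
            best_out = (tmpl, cfg, err)
    assert best_out is not None
    return best_out


def process_song(recording, annotations) -> SongData:
    """Slice, normalize and label one recording into a :class:`SongData`."""
    from .preprocess import label_slices, slice_recording

    slices = slice_recording(recording)
    label_slices(slices, annotations)
    return SongData(
        song_id=recording.identifier,
        slices=slices,
        annotations=sorted(annotations, key=lambda a: a.onset),
    )
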