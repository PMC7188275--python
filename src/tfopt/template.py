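"""Syllable instances, time alignment, averaged templates and slice sets.

To build a template at a fixed position within a syllable, slices at the
same position must be collected across syllable instances that naturally
vary in duration.  Instances more than two standard deviations from the
category's mean duration are discarded; the survivors are linearly stretched
in slice-index space to the modal slice count, and the element-wise mean at
the chosen position — re-scaled into [0, 1] — is the averaged template.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .audio_io import SegmentAnnotation
from .preprocess import AmplitudeThreshold, Slice, normalize_spectrum

__all__ = [
    "SyllableInstance",
    "Template",
    "SliceSets",
    "collect_instances",
    "filter_duration_outliers",
    "modal_slice_length",
    "align_instance",
    "averaged_template",
    "assemble_slice_sets",
    "save_template",
    "load_template",
]


@dataclass
class SyllableInstance:
    """One occurrence of a syllable: its ordered slices plus bookkeeping."""

    label: str
    slices: list[Slice]
    duration_ms: float
    song_id: str = ""
    excluded: bool = False

    @property
    def n_slices(self) -> int:
        return len(self.slices)


@dataclass
class Template:
    """A spectral template: 129-bin vector, possibly outside [0, 1].

    ``sigma`` is the Gaussian smoothing width and ``theta`` the
    slice-optimal distance threshold; both are attached once the smoothed
    error model has been fitted.  ``position`` is 0-based internally
    (user-facing reports are 1-based).
    """

    vector: np.ndarray
    syllable: str
    position: int
    sigma: float = float("nan")
    theta: float = float("nan")
    kind: str = "averaged"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if self.kind not in ("averaged", "optimized"):
            raise ValueError(f"unknown template kind {self.kind!r}")


@dataclass
class SliceSets:
    """Target and distractor slice collections for one (syllable, position)."""

    targets: np.ndarray  # (M, n_bins)
    distractors: np.ndarray  # (N, n_bins)

    def __post_init__(self) -> None:
        self.targets = np.atleast_2d(np.asarray(self.targets, dtype=np.float64))
        self.distractors = np.atleast_2d(
            np.asarray(self.distractors, dtype=np.float64)
        )
        if self.targets.shape[0] < 2:
            raise ValueError("need at least M >= 2 target slices")
        if self.distractors.shape[0] < 1 or self.distractors.size == 0:
            raise ValueError("need at least N >= 1 distractor slices")

    @property
    def M(self) -> int:
        return self.targets.shape[0]

    @property
    def N(self) -> int:
        return self.distractors.shape[0]


def collect_instances(
    labeled_slices: Sequence[Slice],
    annotations: Sequence[SegmentAnnotation],
    song_id: str = "",
) -> list[SyllableInstance]:
    """Group labeled slices of one recording into syllable instances.

    Every syllable-type (or excluded) annotation becomes one instance whose
    slices are those attributed to that segment by :func:`label_slices`.
    Instances with no covering slice are dropped with a warning.
    """
    anns = sorted(annotations, key=lambda a: a.onset)
    by_segment: dict[int, list[Slice]] = {}
    for s in labeled_slices:
        if s.segment_index >= 0:
            by_segment.setdefault(s.segment_index, []).append(s)
    out = []
    for idx, ann in enumerate(anns):
        if ann.segment_type not in ("syllable", "excluded"):
            continue
        slices = sorted(by_segment.get(idx, []), key=lambda s: s.start_sample)
        if not slices:
            warnings.warn(
                f"segment {ann.label!r} at {ann.onset:.3f}s contains no "
                "slice centers; skipped"
            )
            continue
        out.append(
            SyllableInstance(
                label=ann.label,
                slices=slices,
                duration_ms=(ann.offset - ann.onset) * 1e3,
                song_id=song_id,
                excluded=ann.segment_type == "excluded",
            )
        )
    return out


def filter_duration_outliers(
    instances: Sequence[SyllableInstance],
) -> list[SyllableInstance]:
    """Drop instances more than 2 sd from the category's mean duration.

    Statistics are computed once over all input instances (single pass);
    with fewer than 3 instances the input is passed through with a warning.
    """
    if len(instances) < 3:
        warnings.warn(
            f"only {len(instances)} instances; duration filter skipped"
        )
        return list(instances)
    durations = np.array([inst.duration_ms for inst in instances])
    mean, sd = durations.mean(), durations.std(ddof=1)
    keep = np.abs(durations - mean) <= 2.0 * sd
    return [inst for inst, k in zip(instances, keep) if k]


def modal_slice_length(instances: Sequence[SyllableInstance]) -> int:
    """Most frequent slice count among instances; ties go to the smaller."""
    if not instances:
        raise ValueError("no instances")
    counts: dict[int, int] = {}
    for inst in instances:
        counts[inst.n_slices] = counts.get(inst.n_slices, 0) + 1
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]


def align_instance(
    spectra: np.ndarray, m: int, sample_rate: int, renormalize: bool = True
) -> np.ndarray:
    """Linearly stretch an (n, bins) slice sequence to m slices.

    Output position j maps to input coordinate ``x = j*(n-1)/(m-1)``;
    spectra at non-integer x are linear blends of the two bracketing
    slices.  Endpoints are preserved exactly.  Interpolated slices are
    re-normalized into [0, 1] over the >= 1 kHz bins so aligned training
    slices obey the same contract as streamed detection slices.
    """
    spectra = np.asarray(spectra, dtype=np.float64)
    n = spectra.shape[0]
    if n < 2 or m < 2:
        raise ValueError("alignment requires n >= 2 and m >= 2")
    x = np.arange(m) * (n - 1) / (m - 1)
    lo = np.floor(x).astype(int)
    lo = np.minimum(lo, n - 2)
    frac = x - lo
    out = (1.0 - frac[:, None]) * spectra[lo] + frac[:, None] * spectra[lo + 1]
    if renormalize:
        for j in range(m):
            out[j], _ = normalize_spectrum(out[j], sample_rate)
    return out


def align_instances(
    instances: Sequence[SyllableInstance],
    m: int,
    sample_rate: int,
    renormalize: bool = True,
) -> np.ndarray:
    """Stack aligned spectra for many instances: (n_instances, m, bins)."""
    usable = [inst for inst in instances if inst.n_slices >= 2]
    if len(usable) < len(instances):
        warnings.warn(
            f"{len(instances) - len(usable)} single-slice instances dropped "
            "from alignment"
        )
    return np.stack(
        [
            align_instance(
                np.stack([s.spectrum for s in inst.slices]),
                m,
                sample_rate,
                renormalize,
            )
            for inst in usable
        ]
    )


def averaged_template(
    aligned: np.ndarray, position: int, syllable: str, sample_rate: int
) -> Template:
    """Element-wise mean at ``position``, re-scaled into [0, 1].

    ``aligned`` has shape (n_instances, m, bins).  A constant mean over the
    >= 1 kHz bins cannot be normalized and raises.
    """
    aligned = np.asarray(aligned, dtype=np.float64)
    if aligned.ndim != 3 or aligned.shape[0] < 2:
        raise ValueError("need >= 2 aligned instances")
    mean = aligned[:, position, :].mean(axis=0)
    vec, degenerate = normalize_spectrum(mean, sample_rate)
    if degenerate:
        raise ValueError(
            f"mean spectrum at position {position} is constant over the "
            ">= 1 kHz bins; no averaged template"
        )
    return Template(vector=vec, syllable=syllable, position=position)


def assemble_slice_sets(
    labeled_slices: Sequence[Slice],
    instances: Sequence[SyllableInstance],
    syllable: str,
    position: int,
    amplitude_threshold: AmplitudeThreshold,
    sample_rate: int,
) -> tuple[SliceSets, np.ndarray]:
    """Build target and distractor sets for one (syllable, position).

    Targets: aligned slices at ``position`` from duration-filtered instances
    of ``syllable``.  Distractors: every slice from other syllables and
    non-song categories, plus gap slices whose amplitude strictly exceeds
    the threshold.  Non-target positions within the target syllable do not
    participate; slices from segments marked ``excluded`` are omitted, as
    are degenerate (constant-spectrum) slices.

    Returns ``(sets, aligned)`` where ``aligned`` is the full
    (n_instances, m, bins) stack so other positions can reuse it.
    """
    own = [
        inst
        for inst in instances
        if inst.label == syllable and not inst.excluded and inst.n_slices >= 2
    ]
    retained = filter_duration_outliers(own)
    if len(retained) < 2:
        raise ValueError(
            f"need >= 2 retained instances of {syllable!r}, got {len(retained)}"
        )
    m = modal_slice_length(retained)
    if not 0 <= position < m:
        raise ValueError(f"position {position} outside modal length {m}")
    aligned = align_instances(retained, m, sample_rate)
    targets = aligned[:, position, :]

    distractors = []
    for s in labeled_slices:
        if s.degenerate or s.segment_type == "excluded":
            continue
        if s.label == "gap":
            if s.amplitude > amplitude_threshold.value:
                distractors.append(s.spectrum)
        elif s.label != syllable:
            distractors.append(s.spectrum)
    if not distractors:
        raise ValueError(
            f"no distractor slices found for {syllable!r} (need N >= 1)"
        )
    sets = SliceSets(targets=targets, distractors=np.stack(distractors))
    return sets, aligned


def save_template(template: Template, path) -> None:
    """Serialize a template to JSON; round trip is bit-exact.

    ``position`` is stored 1-based for human readers.
    """
    record = {
        "syllable": template.syllable,
        "position": template.position + 1,
        "kind": template.kind,
        "sigma": template.sigma,
        "theta": template.theta,
        "vector": [v.hex() for v in template.vector.astype(np.float64)],
        "metadata": template.metadata,
    }
    Path(path).write_text(json.dumps(record, indent=1))


def load_template(path) -> Template:
    record = json.loads(Path(path).read_text())
    return Template(
        vector=np.array([float.fromhex(v) for v in record["vector"]]),
        syllable=record["syllable"],
        position=record["position"] - 1,
        sigma=record["sigma"],
        theta=record["theta"],
        kind=record["kind"],
        metadata=record.get("metadata", {}),
    )
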