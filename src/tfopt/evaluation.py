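"""Performance summaries: slice errors, syllable errors, jitter, learning curve.

Everything here respects strict train/test separation: templates, sigma,
theta, the amplitude threshold and the detection configuration are fitted on
training songs only and then evaluated, frozen, on the test songs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import discriminant as disc
from .detection import (
    DetectionConfig,
    DetectionEvent,
    Element,
    SongData,
    best_template_per_syllable,
    detect_songs,
    grid_search,
)
from .optimizer import OptimizationTrace, OptimizerConfig, optimize_all_positions
from .preprocess import AmplitudeThreshold, fit_amplitude_threshold
from .template import SliceSets, Template, collect_instances

__all__ = [
    "JitterReport",
    "LearningCurvePoint",
    "SyllableFit",
    "fit_syllable",
    "slice_error_summary",
    "timing_jitter",
    "learning_curve",
]

logger = logging.getLogger(__name__)


@dataclass
class JitterReport:
    """Temporal precision of detection for one syllable."""

    syllable: str
    n_used: int
    n_excluded_outliers: int
    latencies_ms: np.ndarray
    jitter_ms: float  # sample sd of latencies; NaN if < 2 usable


@dataclass
class LearningCurvePoint:
    """Mean balanced error for one training-set size."""

    n_songs: int
    mean_balanced_error: float
    replicate_errors: list[float]
    n_failed: int = 0


@dataclass
class SyllableFit:
    """Everything fitted on the training songs for one syllable."""

    syllable: str
    amplitude_threshold: AmplitudeThreshold
    positions: list[int]
    averaged: list[Template]
    optimized: list[Template]
    traces: list[OptimizationTrace]
    failures: dict[int, str]
    sample_rate: int


def fit_syllable(
    train_songs: Sequence[SongData],
    syllable: str,
    sample_rate: int,
    config: OptimizerConfig | None = None,
    positions: Sequence[int] | None = None,
) -> SyllableFit:
    """Fit amplitude threshold, averaged and optimized templates from training songs."""
    all_slices = [s for song in train_songs for s in song.slices]
    syl_amps = [s.amplitude for s in all_slices if s.segment_type == "syllable"]
    gap_amps = [s.amplitude for s in all_slices if s.label == "gap"]
    amp_thr = fit_amplitude_threshold(syl_amps, gap_amps)

    instances = []
    for song in train_songs:
        instances.extend(
            collect_instances(song.slices, song.annotations, song.song_id)
        )
    results, failures = optimize_all_positions(
        all_slices,
        instances,
        syllable,
        amp_thr,
        sample_rate,
        config,
        positions=positions,
    )
    return SyllableFit(
        syllable=syllable,
        amplitude_threshold=amp_thr,
        positions=[avg.position for avg, _, _ in results],
        averaged=[avg for avg, _, _ in results],
        optimized=[opt for _, opt, _ in results],
        traces=[tr for _, _, tr in results],
        failures=failures,
        sample_rate=sample_rate,
    )


def slice_error_summary(
    averaged: Sequence[Template],
    optimized: Sequence[Template],
    slice_sets: Sequence[SliceSets],
) -> tuple[pd.DataFrame, float, float]:
    """Per-position discrete slice errors and the aggregate fractional reduction.

    Each template is scored at its own slice-optimal threshold on the
    training slice sets.  Fractional reduction is (before - after) / before,
    in percent; positions with zero pre-optimization error are recorded as
    missing and excluded from the aggregate.  Returns
    ``(table, mean_reduction, sd_reduction)``.
    """
    rows = []
    for avg, opt, sets in zip(averaged, optimized, slice_sets):
        d_avg = disc.distance_set(avg.vector, sets)
        d_opt = disc.distance_set(opt.vector, sets)
        _, _, err_avg = disc.discrete_error_rates(d_avg, avg.theta)
        _, _, err_opt = disc.discrete_error_rates(d_opt, opt.theta)
        reduction = (
            100.0 * (err_avg - err_opt) / err_avg if err_avg > 0 else np.nan
        )
        rows.append(
            {
                "syllable": avg.syllable,
                "position": avg.position + 1,
                "slice_error_averaged": err_avg,
                "slice_error_optimized": err_opt,
                "fractional_reduction": reduction,
            }
        )
    table = pd.DataFrame(rows)
    valid = table["fractional_reduction"].dropna()
    mean = float(valid.mean()) if len(valid) else float("nan")
    sd = float(valid.std(ddof=1)) if len(valid) > 1 else float("nan")
    return table, mean, sd


def timing_jitter(
    events: Sequence[DetectionEvent],
    elements: Sequence[Element],
    target_label: str,
    sample_rate: int,
) -> JitterReport:
    """Standard deviation of onset-to-trigger latency for detected targets.

    Target instances whose duration exceeds Q3 + 1.5 IQR of that syllable's
    duration distribution (linear-interpolation quantiles) are excluded
    before latencies are collected.  Latency runs from the element onset to
    the *onset* of the triggering slice.
    """
    targets = [
        e
        for e in elements
        if e.label == target_label and e.segment_type == "syllable"
    ]
    if not targets:
        raise ValueError(f"no target elements labeled {target_label!r}")
    durations = np.array([e.offset - e.onset for e in targets])
    q1, q3 = np.quantile(durations, [0.25, 0.75])
    cutoff = q3 + 1.5 * (q3 - q1)
    excluded_keys = {
        (e.song_id, e.onset)
        for e, d in zip(targets, durations)
        if d > cutoff
    }
    latencies = []
    for ev in events:
        el = elements[ev.element_index]
        if el.label != target_label or el.segment_type != "syllable":
            continue
        if (el.song_id, el.onset) in excluded_keys:
            continue
        trigger_onset = ev.trigger_slice_start / sample_rate
        latencies.append(1e3 * (trigger_onset - el.onset))
    lat = np.array(latencies)
    jitter = float(lat.std(ddof=1)) if lat.size >= 2 else float("nan")
    return JitterReport(
        syllable=target_label,
        n_used=lat.size,
        n_excluded_outliers=len(excluded_keys),
        latencies_ms=lat,
        jitter_ms=jitter,
    )


def _evaluate_replicate(
    train_songs: list[SongData],
    test_songs: Sequence[SongData],
    syllable: str,
    sample_rate: int,
    config: OptimizerConfig | None,
    positions: Sequence[int] | None,
) -> float:
    fit = fit_syllable(train_songs, syllable, sample_rate, config, positions)
    if not fit.optimized:
        raise ValueError("no position could be fitted in this replicate")
    _, _, err = best_template_per_syllable(
        fit.optimized, test_songs, syllable, fit.amplitude_threshold
    )
    return err


def learning_curve(
    train_songs: Sequence[SongData],
    test_songs: Sequence[SongData],
    syllable: str,
    sample_rate: int,
    seed: int = 0,
    sizes: Sequence[int] = (1, 5, 10, 15, 20, 25),
    config: OptimizerConfig | None = None,
    positions: Sequence[int] | None = None,
    shuffle_groups: bool = False,
) -> list[LearningCurvePoint]:
    """Balanced error as a function of training-set size.

    The training songs (25 by convention) are split into 5 groups of 5 —
    round-robin over songs sorted by id, or a seeded shuffle.  Sizes 5-20
    use replicate r = groups {r, r+1, ..., r+k-1} (mod 5), cycling
    circularly, 5 replicates each.  Size 1 uses 5 seeded random single
    songs; the full size uses one replicate and reproduces the main-pipeline
    result exactly.  Evaluation is always on the same test set.
    """
    songs = sorted(train_songs, key=lambda s: s.song_id)
    n_groups = 5
    rng = np.random.default_rng(seed)
    order = list(range(len(songs)))
    if shuffle_groups:
        rng.shuffle(order)
    groups: list[list[SongData]] = [[] for _ in range(n_groups)]
    for i, idx in enumerate(order):
        groups[i % n_groups].append(songs[idx])

    points = []
    for size in sizes:
        replicate_errors: list[float] = []
        n_failed = 0
        if size == len(songs):
            replicates: list[list[SongData]] = [list(songs)]
        elif size == 1:
            picks = rng.choice(len(songs), size=n_groups, replace=False)
            replicates = [[songs[int(p)]] for p in picks]
        elif (
            size % (len(songs) // n_groups) == 0
            and size // (len(songs) // n_groups) <= n_groups
        ):
            k = size // (len(songs) // n_groups)
            replicates = [
                [
                    song
                    for g in range(r, r + k)
                    for song in groups[g % n_groups]
                ]
                for r in range(n_groups)
            ]
        else:
            raise ValueError(f"unsupported training size {size}")
        for rep in replicates:
            try:
                replicate_errors.append(
                    _evaluate_replicate(
                        rep, test_songs, syllable, sample_rate, config, positions
                    )
                )
            except (ValueError, disc.SeparabilityError) as exc:
                n_failed += 1
                logger.warning(
                    "learning-curve replicate (size %d) failed: %s", size, exc
                )
        mean = float(np.mean(replicate_errors)) if replicate_errors else float("nan")
        points.append(
            LearningCurvePoint(
                n_songs=size,
                mean_balanced_error=mean,
                replicate_errors=replicate_errors,
                n_failed=n_failed,
            )
        )
    return points
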