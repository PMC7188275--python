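"""Seeded synthetic-song generator.

Generates Bengalese-finch-like songs as sequences of harmonic-stack
syllables with per-instance duration and timbre jitter, separated by
silent gaps, on a Gaussian noise floor, with occasional calls, cage
noises and clicks.  Ground-truth annotations are exact by construction,
so every pipeline stage can be exercised without recorded data.

The benchmark corpus contains a deliberate "hard pair": a target syllable
and a spectrally near-identical confuser that differs only in the strength
of one harmonic.  Separating the pair rewards templates that caricature
the target spectrum (values pushed outside [0, 1] in the distinguishing
band), which is exactly the behavior the optimizer is meant to exhibit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .audio_io import AudioRecording, SegmentAnnotation

__all__ = [
    "SyllableSpec",
    "SongSpec",
    "Benchmark",
    "render_syllable",
    "draw_duration",
    "generate_song",
    "default_repertoire",
    "make_benchmark",
]


@dataclass(frozen=True)
class SyllableSpec:
    """Acoustic recipe for one syllable category.

    The fundamental runs linearly from ``f0_start`` to ``f0_end`` over the
    syllable (equal values give a flat harmonic stack).  Per-instance
    jitter perturbs the fundamental and each harmonic's amplitude so that
    instances of one category form a cloud, not a point.
    """

    label: str
    f0_start: float
    f0_end: float
    harmonic_amps: tuple[float, ...]
    mean_duration_ms: float = 93.0
    duration_sd_ms: float = 3.0
    attack_ms: float = 3.0
    release_ms: float = 3.0
    amplitude: float = 0.3
    f0_jitter: float = 0.005  # relative sd of per-instance f0 scaling
    amp_jitter: float = 0.12  # relative sd of per-instance harmonic gains

    def __post_init__(self) -> None:
        if self.duration_sd_ms < 0:
            raise ValueError("duration_sd_ms must be >= 0")
        if min(self.f0_start, self.f0_end) <= 0:
            raise ValueError("fundamental must be positive")


@dataclass(frozen=True)
class SongSpec:
    """Structure of one synthetic song bout."""

    phrase_pool: tuple[tuple[str, ...], ...]
    n_phrases: tuple[int, int] = (2, 3)  # inclusive draw range
    gap_mean_ms: float = 45.0
    gap_sd_ms: float = 10.0
    gap_min_ms: float = 20.0
    noise_floor: float = 0.002
    call_rate: float = 0.8  # expected calls in the padding regions
    click_rate: float = 1.0
    cage_noise_rate: float = 1.5
    pad_s: float = 0.5
    sample_rate: int = 44100


def draw_duration(spec: SyllableSpec, rng: np.random.Generator) -> float:
    """Duration draw in msec: Normal(mean, sd) truncated at +/- 3 sd."""
    if spec.duration_sd_ms == 0:
        return spec.mean_duration_ms
    while True:
        d = rng.normal(spec.mean_duration_ms, spec.duration_sd_ms)
        if abs(d - spec.mean_duration_ms) <= 3.0 * spec.duration_sd_ms:
            return float(d)


def render_syllable(
    spec: SyllableSpec,
    duration_ms: float,
    sample_rate: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one syllable instance as a float waveform.

    Harmonics above Nyquist are silently omitted (with a logged warning).
    With an rng, per-instance jitter is applied to the fundamental and the
    harmonic amplitude profile.
    """
    n = int(round(duration_ms * 1e-3 * sample_rate))
    t = np.arange(n) / sample_rate
    dur = n / sample_rate
    f0_scale = 1.0
    amps = np.asarray(spec.harmonic_amps, dtype=np.float64)
    if rng is not None:
        f0_scale = 1.0 + spec.f0_jitter * rng.standard_normal()
        amps = amps * np.exp(spec.amp_jitter * rng.standard_normal(amps.size))
    f0 = (
        spec.f0_start + (spec.f0_end - spec.f0_start) * (t / max(dur, 1e-12))
    ) * f0_scale
    phase0 = 2.0 * np.pi * np.cumsum(f0) / sample_rate
    wave = np.zeros(n)
    nyq = sample_rate / 2.0
    for k, a in enumerate(amps, start=1):
        if k * max(spec.f0_start, spec.f0_end) * f0_scale >= nyq:
            warnings.warn(
                f"harmonic {k} of {spec.label!r} exceeds Nyquist; omitted"
            )
            continue
        wave += a * np.sin(k * phase0)
    # attack / sustain / release envelope
    env = np.ones(n)
    na = min(n, int(round(spec.attack_ms * 1e-3 * sample_rate)))
    nr = min(n, int(round(spec.release_ms * 1e-3 * sample_rate)))
    if na > 0:
        env[:na] = np.linspace(0.0, 1.0, na, endpoint=False)
    if nr > 0:
        env[n - nr:] = np.linspace(1.0, 0.0, nr)
    peak = np.max(np.abs(wave)) or 1.0
    return spec.amplitude * env * wave / peak


def _render_call(sample_rate: int, rng: np.random.Generator) -> np.ndarray:
    spec = SyllableSpec(
        label="call",
        f0_start=1600.0,
        f0_end=1500.0,
        harmonic_amps=(1.0, 0.4),
        mean_duration_ms=45.0,
        duration_sd_ms=8.0,
        amplitude=0.25,
    )
    return render_syllable(spec, draw_duration(spec, rng), sample_rate, rng)


def _render_click(sample_rate: int, rng: np.random.Generator) -> np.ndarray:
    n = int(round(rng.uniform(2.0, 5.0) * 1e-3 * sample_rate))
    return 0.2 * rng.standard_normal(n) * np.hanning(n)


def _render_cage_noise(sample_rate: int, rng: np.random.Generator) -> np.ndarray:
    """Band-limited noise burst with a random center band and bandwidth.

    Varying the band fills the far range of template distances with a
    continuum, as heterogeneous cage sounds do in real recordings.
    """
    from scipy import signal as sps

    n = int(round(rng.uniform(30.0, 80.0) * 1e-3 * sample_rate))
    center = rng.uniform(1500.0, 7000.0)
    width = rng.uniform(500.0, 6000.0)
    lo = max(200.0, center - width / 2.0)
    hi = min(sample_rate / 2.0 - 200.0, center + width / 2.0)
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=sample_rate,
                     output="sos")
    burst = sps.sosfilt(sos, rng.standard_normal(n + 256))[256:]
    return 0.12 * burst * np.hanning(n)


def generate_song(
    song_spec: SongSpec,
    repertoire: dict[str, SyllableSpec],
    rng: np.random.Generator,
    song_id: str = "song",
) -> tuple[AudioRecording, list[SegmentAnnotation]]:
    """Render one song bout plus its exact ground-truth annotations.

    Syllables are concatenated with drawn gaps over a Gaussian noise
    floor; calls, cage noises and clicks are injected into the silent
    padding before and after the song.
    """
    fs = song_spec.sample_rate
    if not repertoire:
        n = int(round(2 * song_spec.pad_s * fs))
        noise = song_spec.noise_floor * rng.standard_normal(n)
        return AudioRecording(noise, fs, song_id), []

    sequence: list[str] = []
    n_phrases = int(rng.integers(song_spec.n_phrases[0], song_spec.n_phrases[1] + 1))
    for _ in range(n_phrases):
        phrase = song_spec.phrase_pool[int(rng.integers(len(song_spec.phrase_pool)))]
        sequence.extend(phrase)

    pieces: list[np.ndarray] = []
    annotations: list[SegmentAnnotation] = []
    cursor = int(round(song_spec.pad_s * fs))
    pieces.append(np.zeros(cursor))
    for i, label in enumerate(sequence):
        spec = repertoire[label]
        dur = draw_duration(spec, rng)
        wave = render_syllable(spec, dur, fs, rng)
        annotations.append(
            SegmentAnnotation(
                onset=cursor / fs,
                offset=(cursor + wave.size) / fs,
                label=label,
                segment_type="syllable",
            )
        )
        pieces.append(wave)
        cursor += wave.size
        if i < len(sequence) - 1:
            gap_ms = max(
                song_spec.gap_min_ms,
                rng.normal(song_spec.gap_mean_ms, song_spec.gap_sd_ms),
            )
            n_gap = int(round(gap_ms * 1e-3 * fs))
            pieces.append(np.zeros(n_gap))
            cursor += n_gap
    pieces.append(np.zeros(int(round(song_spec.pad_s * fs))))
    cursor += pieces[-1].size

    samples = np.concatenate(pieces)

    # inject non-song sounds into the padding regions
    def inject(wave: np.ndarray, seg_label: str, seg_type: str) -> None:
        pad = int(round(song_spec.pad_s * fs))
        if wave.size >= pad - 2:
            return
        region_starts = [0, samples.size - pad]
        start = int(
            region_starts[int(rng.integers(2))]
            + rng.integers(0, pad - wave.size)
        )
        # keep injections clear of existing segments
        t0, t1 = start / fs, (start + wave.size) / fs
        for ann in annotations:
            if t0 < ann.offset and ann.onset < t1:
                return
        samples[start : start + wave.size] += wave
        annotations.append(
            SegmentAnnotation(
                onset=t0, offset=t1, label=seg_label, segment_type=seg_type
            )
        )

    for _ in range(rng.poisson(song_spec.call_rate)):
        inject(_render_call(fs, rng), "call", "call")
    for _ in range(rng.poisson(song_spec.cage_noise_rate)):
        inject(_render_cage_noise(fs, rng), "cage", "noise")
    for _ in range(rng.poisson(song_spec.click_rate)):
        inject(_render_click(fs, rng), "click", "click")

    samples = samples + song_spec.noise_floor * rng.standard_normal(samples.size)
    annotations.sort(key=lambda a: a.onset)
    return AudioRecording(samples, fs, song_id), annotations


TARGET_LABEL = "A"
CONFUSER_LABEL = "B"


def default_repertoire(confuser_attenuation: float = 0.1) -> dict[str, SyllableSpec]:
    """Six-syllable repertoire with a target/confuser hard pair.

    The confuser copies the target's harmonic stack but attenuates the
    third harmonic (the distinguishing band) by ``confuser_attenuation``.
    The remaining categories share the target's harmonic bands at graded
    degrees of similarity, so distractor distances to a target template
    form a continuum rather than one far-away cluster — as slices of real
    song do.
    """
    # the hard pair shares one harmonic stack; the target's copy of the
    # 5th harmonic (~10 kHz, a band no other category occupies) is
    # attenuated to near silence while the confuser keeps it.  An averaged
    # template sees almost no distance contrast from that weak band; a
    # caricatured template (value pushed below 0 there) amplifies it —
    # squared distances grow linearly in the template's excursion.
    base_amps = (1.0, 0.7, 0.85, 0.5, 0.3)
    target_amps = list(base_amps)
    target_amps[4] *= confuser_attenuation
    target = SyllableSpec(
        label=TARGET_LABEL,
        f0_start=2000.0,
        f0_end=2060.0,
        harmonic_amps=tuple(target_amps),
    )
    confuser = replace(target, label=CONFUSER_LABEL, harmonic_amps=base_amps)
    return {
        TARGET_LABEL: target,
        CONFUSER_LABEL: confuser,
        # same fundamental, reshuffled harmonic profile: moderately close
        "C": SyllableSpec(
            label="C", f0_start=2000.0, f0_end=2060.0,
            harmonic_amps=(0.75, 1.0, 0.45, 0.8),
            mean_duration_ms=78.0,
        ),
        # slightly detuned stack: partial band overlap
        "D": SyllableSpec(
            label="D", f0_start=1840.0, f0_end=1890.0,
            harmonic_amps=(1.0, 0.8, 0.6, 0.4), mean_duration_ms=105.0,
            duration_sd_ms=5.0,
        ),
        # downsweep crossing the target's bands
        "E": SyllableSpec(
            label="E", f0_start=2350.0, f0_end=1950.0,
            harmonic_amps=(1.0, 0.55, 0.35), mean_duration_ms=64.0,
        ),
        # distant stack
        "F": SyllableSpec(
            label="F", f0_start=2700.0, f0_end=2700.0,
            harmonic_amps=(0.8, 1.0, 0.5), mean_duration_ms=85.0,
        ),
        # wide upsweep bridging the mid-distance range
        "G": SyllableSpec(
            label="G", f0_start=2050.0, f0_end=2550.0,
            harmonic_amps=(1.0, 0.65, 0.45), mean_duration_ms=90.0,
        ),
    }


PHRASE_POOL = (
    ("C", CONFUSER_LABEL, TARGET_LABEL, CONFUSER_LABEL, CONFUSER_LABEL, "E"),
    ("D", TARGET_LABEL, CONFUSER_LABEL, CONFUSER_LABEL, "F", "G"),
    ("F", CONFUSER_LABEL, CONFUSER_LABEL, TARGET_LABEL, CONFUSER_LABEL, "E"),
    ("C", TARGET_LABEL, CONFUSER_LABEL, "G", CONFUSER_LABEL, "E"),
)


@dataclass
class Benchmark:
    """A reproducible 50-song corpus split into train and test halves."""

    train: list[tuple[AudioRecording, list[SegmentAnnotation]]]
    test: list[tuple[AudioRecording, list[SegmentAnnotation]]]
    repertoire: dict[str, SyllableSpec]
    song_spec: SongSpec
    target_label: str = TARGET_LABEL
    confuser_label: str = CONFUSER_LABEL


def make_benchmark(
    rng: np.random.Generator | int,
    n_songs: int = 50,
    sample_rate: int = 44100,
    confuser_attenuation: float = 0.1,
) -> Benchmark:
    """Generate the seeded hard-pair benchmark corpus.

    Half the songs are the training set, half the test set (disjoint by
    construction).  Every song's phrase structure contains at least one
    target and one confuser instance, so 25 training songs guarantee at
    least 25 target instances.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    repertoire = default_repertoire(confuser_attenuation)
    song_spec = SongSpec(phrase_pool=PHRASE_POOL, sample_rate=sample_rate)
    songs = []
    for i in range(n_songs):
        rec, anns = generate_song(
            song_spec, repertoire, rng, song_id=f"song{i:03d}"
        )
        songs.append((rec, anns))
    half = n_songs // 2
    return Benchmark(
        train=songs[:half],
        test=songs[half:],
        repertoire=repertoire,
        song_spec=song_spec,
    )
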