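# Methods

## The detection model

All processing acts on non-overlapping 256-sample frames of mono audio
(≈ 5.8 ms at 44.1 kHz; both 44100 and 44150 Hz are accepted and the slice
length is defined in samples, not milliseconds). Each frame is
mean-subtracted, multiplied by a Hamming window, and Fourier transformed;
the one-sided magnitude spectrum (129 bins, bin k centered at k·fs/256) is
the raw slice. Song amplitude is the sum of squared magnitudes of the raw
spectrum, computed *before* normalization. Bins whose center frequency lies
below 1 kHz are zeroed; the remaining bins are mapped linearly so their
minimum is 0 and maximum is 1. A slice whose spectrum is constant above
1 kHz cannot be normalized; it is set to all-zero, flagged degenerate, and
excluded from optimization sets. Magnitude (not power, not log-magnitude)
spectra are normalized; this is configurable in principle but fixed here as
the most literal reading of the procedure.

A slice is attributed to the annotated segment containing its center
(start + 128 samples); intervals are half-open `[onset, offset)`, times are
seconds, and a time t maps to sample `floor(t·fs)`. Slices between
segments are "gap" slices. The per-bird amplitude threshold is the value
minimizing the balanced misclassification between syllable-slice and
gap-slice amplitude distributions, searched over midpoints of consecutive
distinct pooled amplitudes plus one candidate beyond each extreme; ties go
to the candidate with the largest margin to the data. Only gap slices
*strictly above* this threshold act as distractors.

## Template construction

For one syllable category, instances more than two sample standard
deviations from the category's mean duration are discarded (one pass; the
statistics are not recomputed). Survivors are linearly stretched in
slice-index space to the modal slice count (ties toward the smaller
count): output position j of m maps to input coordinate j·(n−1)/(m−1) and
non-integer coordinates blend the two bracketing slices. Interpolated
slices are re-normalized to [0, 1] over the ≥ 1 kHz bins so that aligned
training slices satisfy the same contract as streamed detection slices
(the blend of two normalized spectra need not span [0, 1] exactly). The
averaged template at a position is the element-wise mean over aligned
instances, re-normalized the same way.

Targets for one (syllable, position) pair are the aligned slices at that
position; distractors are every slice of other categories (syllables,
calls, noises, clicks — regardless of amplitude) plus supra-threshold gap
slices. Slices at non-target positions inside the target syllable
participate on neither side, and segments annotated `excluded` are omitted
entirely.

## The smoothed error model

Distances are Euclidean. With target distances d_i (i = 1..M) and
distractor distances d_j (j = 1..N), the smoothed densities are averages
of normal densities, T(x) = (1/M)Σ G_σ(x−d_i) and D(x) = (1/N)Σ G_σ(x−d_j),
and the total error at threshold θ is the mean of the smoothed miss rate
and false-positive rate; the Gaussian tail integrals are evaluated in
closed form through the standard normal CDF. The negative gradient pulls
the template toward targets and pushes it from distractors, each slice
weighted by G_σ(θ − d); a slice at distance exactly 0 has no defined
direction and contributes zero.

σ starts at 0.2 and moves on a 0.05 grid to the smallest value at which
both densities are unimodal; when 0.2 already qualifies the search
continues downward to a floor of 0.05 (a strict mode that never goes below
0.2 is available, since the published procedure starts at 0.2 but asks for
the smallest qualifying value). Unimodality is tested on a 2048-point grid
over [0, max distance + 4σ]: the sign of the discrete difference may change
at most once, and only from rise to fall; differences below 10⁻¹⁰ of the
maximum count as flat. For more than 256 distances the grid density is
computed by binning the distances to the grid (spacing ≪ σ) and convolving
with the Gaussian kernel via FFT; the approximation error is orders of
magnitude below the unimodality tolerance, and the final threshold is
always refined on the exact mixture.

θ is the unique crossing T(x) = D(x). It is bracketed by a sign change on
the grid searched from the target-density peak to the end of the grid —
not merely between the two peaks, because when a large near-target
distractor mode sits close to the target cloud the crossing falls beyond
the distractor peak — and refined by Brent root finding to 10⁻⁹. If D
already dominates at the target peak, or the target peak does not precede
the distractor peak, the configuration is reported as non-separable.

## Gradient descent

Each outer step recomputes distances, checks unimodality at the current σ
(on failure σ is raised in 0.05 steps until both densities are unimodal and
the whole descent restarts from the initial template with the trace
cleared), recomputes θ as the crossing, evaluates the gradient, and takes
one Armijo backtracking step (c = 10⁻⁴, contraction ½, α₀ = 1, floor
10⁻¹²) with θ and σ held fixed during the line search. Because θ is the
interior stationary point of TE in the threshold, re-optimizing it between
steps cannot increase TE, so the TE trace is non-increasing at fixed σ.

Termination watches (A) the gradient norm, (B) its change over the last 10
steps, and (C) the change in TE over the last 10 steps; descent stops when
C and B, or C and A, fall below thresholds (defaults 10⁻³, 10⁻⁴, 10⁻⁶ —
engineering choices on the natural scales of those quantities, exposed in
the config), or at 1000 steps, in which case the step-1000 state is used.
The optimizer never clips the template: components outside [0, 1] are the
caricature mechanism, not an error.

## Syllable-level detection and tuning

Detection mimics the real-time loop: a slice matches when its distance is
≤ (f/100)·θ *and* its amplitude exceeds the amplitude threshold; a run of
`c` consecutive matches triggers, the counter resets after each trigger,
and runs are counted on the raw slice stream (hardware knows nothing of
element boundaries). For scoring, a detection is attributed to the song
element — segment or inter-segment gap — containing the trigger slice, an
element counts at most once, and gap elements can be false positives only
if they contain at least one supra-threshold slice. The balanced error
divides the false-positive count by the number of *targets* (so the ratio
may exceed 1) and averages it with the miss rate, in percent. All 21 × 5
combinations of f ∈ {0, 10, …, 200} and c ∈ {1..5} are evaluated; ties
break toward stringency (lower f, then higher c), then the earlier slice
position when comparing positions. Note that the detected-element set is
*not* guaranteed to shrink as c grows (a run spanning an element boundary
can move the trigger into the next element); the count of triggers per
maximal run, ⌊L/c⌋, is monotone and is the invariant the tests pin.

Evaluation is strictly split: the amplitude threshold, σ, θ, templates and
detection configuration are fitted on the 25 training songs and frozen
before the 25 test songs are touched. Timing jitter is the sample (n−1)
standard deviation of the latency from element onset to the *onset* of the
trigger slice, after excluding target instances whose duration exceeds
Q3 + 1.5·IQR (linear-interpolation quantiles) of that syllable's test-set
durations. The learning curve partitions the training songs into 5 groups
(round-robin over songs sorted by id; a seeded shuffle is available),
builds sizes 5–20 by circular cycling through consecutive groups (5
replicates each), uses 5 seeded random single songs for size 1, and re-runs
the full pipeline per replicate against the fixed test set; the full-size
point is bit-identical to the main pipeline.

## The synthetic corpus

The generator emulates the statistical structure the pipeline assumes
rather than syrinx acoustics. Syllables are harmonic stacks: a fundamental
running linearly between two frequencies, a per-harmonic amplitude
profile, a 3 ms attack/release envelope, duration drawn from a normal
distribution truncated at ±3 sd (target: mean 93 ms, sd 3 ms). Rendition
variability is deliberately *instance-level*: each rendition draws one
fundamental scaling (sd 0.5 %) and one log-normal gain per harmonic
(sd 12 %), so the slices of a rendition move together, as motor variability
moves real renditions — per-slice independent noise would let the
consecutive-match criterion filter distractors for free and understate the
value of template optimization. Songs are 2–3 phrases drawn from a pool,
with gaps of 45 ± 10 ms (min 20), a Gaussian noise floor (2·10⁻³ of full
scale against syllable amplitudes of 0.3), and calls, clicks, and
band-limited cage-noise bursts injected into 0.5 s padding regions.
Annotations are exact by construction.

The benchmark repertoire holds seven syllable types plus the non-song
categories. The hard pair shares one harmonic stack on a 2000→2060 Hz
fundamental; the target's fifth harmonic (~10 kHz) is attenuated to 10 %
of the confuser's. That band is the pair's only reliable difference, it is
occupied by no other category, and its amplitude is small — so an averaged
template (whose value there equals the target's near-zero energy) gains
almost no distance contrast from it, while a template pushed *below zero*
in that band amplifies the difference linearly in the excursion. This is
the caricature mechanism, and the benchmark is constructed so that
exploiting it is the only way to separate the pair. The remaining
categories are placed at graded spectral similarity (same-fundamental
profile shuffle, detuned stack, sweeps crossing the target's bands, a
distant stack) and the confuser is sung 2–3 times per phrase: real
repertoires (10–23 categories, repeated syllables) give the distractor
distance distribution a dense continuum, and without that continuum the
unimodality rule drives σ so high that the gradient is too blurred to act.
Corpora are reproducible from a single seed; 50 songs split 25/25.

What passing the synthetic benchmark does *not* show: robustness to
recording artifacts (reverberation, microphone coloration, amplitude
drift), to segmentation errors in the annotations (ground truth is exact
here), or to within-rendition spectral trajectories richer than linear
sweeps. Numbers from this corpus characterize the implementation, not any
bird.

## Default problem sizes

The shipped benchmark (50 songs of ~8–16 syllables, ≈ 300 slices per song,
one target syllable with ~16 slice positions) keeps a full end-to-end run —
corpus, all-position optimization, 21×5 tuning for both template kinds,
jitter, and a 3-point learning curve — at about half a minute on one CPU.
The learning curve in the acceptance script evaluates the best slice
position only; evaluating every position per replicate multiplies cost
~16-fold without changing the comparison being made.

## Known limitations

- The balanced error on ~60 test targets is granular (one missed target ≈
  0.8 percentage points), so seed-to-seed variation of a few points is
  expected.
- Timing jitter here (~13 ms) is larger than for real harmonic syllables
  with strong temporal structure: the synthetic target is nearly
  stationary in time, so neighboring slice positions match almost equally
  well and the trigger position wanders.
- `fit_envelope_threshold` is a convenience for choosing the (per-dataset,
  manually tuned in practice) segmentation threshold against reference
  intervals; it is not part of the published procedure.
- Optimization failures on a position (non-separable configurations) are
  recorded and skipped, never silently repaired.
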