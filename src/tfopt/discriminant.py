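"""The smoothed discrimination-error model.

Slices are matched to a template by Euclidean distance.  For M target
distances d_i and N distractor distances d_j, smoothing each point mass with
a Gaussian density G_sigma gives continuous distance densities

    T(x) = (1/M) sum_i G_sigma(x - d_i),   D(x) = (1/N) sum_j G_sigma(x - d_j)

and, for a threshold theta, a differentiable total error

    TE = (1/2M) sum_i Phi((d_i - theta)/sigma)
       + (1/2N) sum_j Phi((theta - d_j)/sigma)

(the smoothed false-negative and false-positive rates; Phi is the standard
normal CDF).  sigma is chosen as the smallest value on a 0.05 grid that
makes both smoothed densities unimodal, which guarantees a unique crossing
T(x) = D(x) between the two peaks — the "slice optimal" threshold.  The
negative gradient of TE with respect to the template pulls the template
toward targets and pushes it away from distractors, weighted by how close
each slice's distance is to the threshold:

    -grad TE = (1/2M) sum_i G_sigma(theta - d_i) (s_i - t)/d_i
             - (1/2N) sum_j G_sigma(theta - d_j) (s_j - t)/d_j
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr

from .template import SliceSets

__all__ = [
    "DistanceSet",
    "SmoothedDistributions",
    "distances",
    "gaussian_tail_above",
    "total_error",
    "smoothed_distributions",
    "is_unimodal",
    "select_sigma",
    "slice_optimal_threshold",
    "gradient",
    "discrete_error_rates",
    "SeparabilityError",
    "SIGMA_DEFAULT",
    "SIGMA_STEP",
    "SIGMA_FLOOR",
    "SIGMA_CAP",
]

SIGMA_DEFAULT = 0.2
SIGMA_STEP = 0.05
SIGMA_FLOOR = 0.05
SIGMA_CAP = 5.0
GRID_POINTS = 2048


class SeparabilityError(RuntimeError):
    """Target and distractor distance distributions cannot be separated."""


@dataclass
class DistanceSet:
    """Distances from one template to its target and distractor slices."""

    target_distances: np.ndarray
    distractor_distances: np.ndarray

    def __post_init__(self) -> None:
        self.target_distances = np.asarray(
            self.target_distances, dtype=np.float64
        ).ravel()
        self.distractor_distances = np.asarray(
            self.distractor_distances, dtype=np.float64
        ).ravel()
        if self.target_distances.size == 0 or self.distractor_distances.size == 0:
            raise ValueError("both distance collections must be non-empty")
        if (self.target_distances < 0).any() or (
            self.distractor_distances < 0
        ).any():
            raise ValueError("distances must be >= 0")

    @property
    def M(self) -> int:
        return self.target_distances.size

    @property
    def N(self) -> int:
        return self.distractor_distances.size


@dataclass
class SmoothedDistributions:
    """Smoothed target/distractor densities evaluated on a shared grid."""

    sigma: float
    grid: np.ndarray
    T: np.ndarray
    D: np.ndarray


def distances(template_vector: np.ndarray, slices: np.ndarray) -> np.ndarray:
    """Euclidean distance from the template to each row of ``slices``."""
    template_vector = np.asarray(template_vector, dtype=np.float64)
    slices = np.atleast_2d(np.asarray(slices, dtype=np.float64))
    if slices.shape[1] != template_vector.size:
        raise ValueError(
            f"slice length {slices.shape[1]} != template length "
            f"{template_vector.size}"
        )
    return np.linalg.norm(slices - template_vector, axis=1)


def distance_set(template_vector: np.ndarray, sets: SliceSets) -> DistanceSet:
    """Distances of a template to both collections of a :class:`SliceSets`."""
    return DistanceSet(
        target_distances=distances(template_vector, sets.targets),
        distractor_distances=distances(template_vector, sets.distractors),
    )


def gaussian_tail_above(d, theta: float, sigma: float):
    """P[x > theta] for x ~ Normal(d, sigma^2): the Gaussian tail integral.

    Closed form Phi((d - theta)/sigma).  Accepts scalar or array ``d``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return ndtr((np.asarray(d, dtype=np.float64) - theta) / sigma)


def total_error(dset: DistanceSet, theta: float, sigma: float) -> float:
    """Smoothed total error TE(theta, sigma) in [0, 1]."""
    fn = gaussian_tail_above(dset.target_distances, theta, sigma).mean()
    fp = (1.0 - gaussian_tail_above(dset.distractor_distances, theta, sigma)).mean()
    return float((fn + fp) / 2.0)


def _density(dists: np.ndarray, grid: np.ndarray, sigma: float) -> np.ndarray:
    """Exact Gaussian-mixture density (1/n) sum_k G_sigma(x - d_k)."""
    z = (grid[:, None] - dists[None, :]) / sigma
    g = np.exp(-0.5 * z**2) / (sigma * np.sqrt(2.0 * np.pi))
    return g.mean(axis=1)


def _density_grid(dists: np.ndarray, grid: np.ndarray, sigma: float) -> np.ndarray:
    """Mixture density on a uniform grid.

    For large collections the point masses are binned to the grid (spacing
    << sigma) and convolved with the Gaussian kernel via FFT; the binning
    error is far below the unimodality tolerance.  Small collections use
    the exact mixture.
    """
    if dists.size <= 256:
        return _density(dists, grid, sigma)
    from scipy.signal import fftconvolve

    dx = grid[1] - grid[0]
    edges = np.concatenate([grid - dx / 2.0, [grid[-1] + dx / 2.0]])
    counts, _ = np.histogram(dists, bins=edges)
    half = int(np.ceil(6.0 * sigma / dx))
    x = np.arange(-half, half + 1) * dx
    kernel = np.exp(-0.5 * (x / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))
    dens = fftconvolve(counts.astype(np.float64), kernel, mode="same")
    return np.maximum(dens, 0.0) / dists.size


def smoothed_distributions(
    dset: DistanceSet, sigma: float, n_points: int = GRID_POINTS
) -> SmoothedDistributions:
    """Evaluate T(x) and D(x) on the standard grid [0, max distance + 4 sigma]."""
    hi = float(
        max(dset.target_distances.max(), dset.distractor_distances.max())
        + 4.0 * sigma
    )
    grid = np.linspace(0.0, hi, n_points)
    return SmoothedDistributions(
        sigma=sigma,
        grid=grid,
        T=_density_grid(dset.target_distances, grid, sigma),
        D=_density_grid(dset.distractor_distances, grid, sigma),
    )


def is_unimodal(values: np.ndarray, rel_tol: float = 1e-10) -> bool:
    """True if the sampled curve rises to a single peak then falls.

    Implemented as: the sign of the discrete difference changes at most
    once, and only from positive to negative.  Differences smaller than
    ``rel_tol * max`` are treated as flat.
    """
    values = np.asarray(values, dtype=np.float64)
    diffs = np.diff(values)
    tol = rel_tol * max(values.max(), 1e-300)
    signs = np.sign(np.where(np.abs(diffs) <= tol, 0.0, diffs))
    signs = signs[signs != 0]
    if signs.size == 0:
        return True
    changes = np.flatnonzero(np.diff(signs) != 0)
    if changes.size == 0:
        return True  # monotone
    if changes.size > 1:
        return False
    # exactly one change: must be rise -> fall
    return signs[0] > 0 and signs[-1] < 0


def _both_unimodal(dset: DistanceSet, sigma: float) -> bool:
    sd = smoothed_distributions(dset, sigma)
    return is_unimodal(sd.T) and is_unimodal(sd.D)


def select_sigma(
    dset: DistanceSet,
    sigma_init: float = SIGMA_DEFAULT,
    step: float = SIGMA_STEP,
    floor: float = SIGMA_FLOOR,
    cap: float = SIGMA_CAP,
    strict_floor_at_init: bool = False,
) -> float:
    """Smallest sigma on the 0.05 grid making both densities unimodal.

    Starts at ``sigma_init`` (default 0.2) and moves in ``step`` increments:
    upward until the unimodality condition holds, or — if it already holds —
    downward to ``floor`` to find the smallest passing value.  With
    ``strict_floor_at_init`` the search never goes below ``sigma_init``.
    """
    sigma = float(sigma_init)
    if _both_unimodal(dset, sigma):
        low_floor = sigma_init if strict_floor_at_init else floor
        best = sigma
        while best - step >= low_floor - 1e-12:
            candidate = round(best - step, 10)
            if _both_unimodal(dset, candidate):
                best = candidate
            else:
                break
        return best
    while sigma < cap:
        sigma = round(sigma + step, 10)
        if _both_unimodal(dset, sigma):
            return sigma
    raise SeparabilityError(
        f"no sigma <= {cap} makes both smoothed densities unimodal"
    )


def slice_optimal_threshold(
    dset: DistanceSet,
    sigma: float,
    xtol: float = 1e-9,
    sd: SmoothedDistributions | None = None,
) -> float:
    """The unique crossing T(x) = D(x) between the two density peaks.

    Requires sigma already selected so both densities are unimodal and the
    target peak lies below the distractor peak.  The crossing is bracketed
    by a sign change on the evaluation grid and refined by root finding on
    the exact mixture densities.
    """
    if sd is None:
        sd = smoothed_distributions(dset, sigma)
    i_t = int(np.argmax(sd.T))
    i_d = int(np.argmax(sd.D))
    if i_t >= i_d:
        raise SeparabilityError(
            "target density peak does not precede distractor peak "
            f"(target peak at x={sd.grid[i_t]:.4g}, distractor at "
            f"x={sd.grid[i_d]:.4g}); targets are not closer to the template "
            "than distractors"
        )
    # the crossing lies at/after the target peak: T starts above D there and
    # D dominates in the far tail (its mass sits at larger distances)
    diff = sd.T - sd.D
    if diff[i_t] <= 0:
        raise SeparabilityError(
            "distractor density dominates at the target peak; "
            "targets are not separable from distractors"
        )
    seg = diff[i_t:]
    sign_changes = np.flatnonzero(np.sign(seg[:-1]) * np.sign(seg[1:]) < 0)
    if sign_changes.size == 0:
        zero_hits = np.flatnonzero(seg == 0)
        if zero_hits.size:
            return float(sd.grid[i_t + zero_hits[0]])
        raise SeparabilityError(
            "no crossing of T and D beyond the target peak; re-select sigma"
        )
    k = i_t + int(sign_changes[0])
    td = dset.target_distances
    dd = dset.distractor_distances

    def f(x: float) -> float:
        return float(
            _density(td, np.array([x]), sigma)[0]
            - _density(dd, np.array([x]), sigma)[0]
        )

    # the grid densities may be binned approximations; re-bracket with the
    # exact mixture in a window widening around the grid-detected crossing
    for halfwidth in (1, 4, 16, 64):
        lo = max(i_t, k - halfwidth)
        hi = min(sd.grid.size - 1, k + halfwidth)
        xs = sd.grid[lo : hi + 1]
        vals = np.array([f(x) for x in xs])
        flips = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
        if flips.size:
            j = int(flips[0])
            return float(brentq(f, xs[j], xs[j + 1], xtol=xtol))
        zeros = np.flatnonzero(vals == 0)
        if zeros.size:
            return float(xs[zeros[0]])
    raise SeparabilityError(
        "grid crossing could not be confirmed on the exact densities; "
        "re-select sigma"
    )


def gradient(
    template_vector: np.ndarray,
    sets: SliceSets,
    theta: float,
    sigma: float,
) -> np.ndarray:
    """Negative gradient of TE with respect to the template vector.

    Each target slice contributes a pull toward itself and each distractor
    a push away, weighted by the Gaussian density of (theta - distance).
    Slices exactly at the template (distance 0) have no defined direction
    and contribute zero.
    """
    t = np.asarray(template_vector, dtype=np.float64)
    out = np.zeros_like(t)
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    for slices_arr, sign, count in (
        (sets.targets, +1.0, sets.M),
        (sets.distractors, -1.0, sets.N),
    ):
        d = np.linalg.norm(slices_arr - t, axis=1)
        ok = d > 0
        w = np.zeros_like(d)
        w[ok] = (
            norm
            * np.exp(-0.5 * ((theta - d[ok]) / sigma) ** 2)
            / d[ok]
        )
        contrib = (w[ok, None] * (slices_arr[ok] - t)).sum(axis=0)
        out += sign * contrib / (2.0 * count)
    return out


def discrete_error_rates(
    dset: DistanceSet, theta: float
) -> tuple[float, float, float]:
    """Hard-classification error rates at threshold theta.

    A slice matches when its distance is <= theta.  Returns
    ``(false_negative_rate, false_positive_rate, slice_error_percent)``
    where the rates are fractions and the slice error is their mean as a
    percentage.
    """
    fn = float((dset.target_distances > theta).mean())
    fp = float((dset.distractor_distances <= theta).mean())
    return fn, fp, 100.0 * (fn + fp) / 2.0
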