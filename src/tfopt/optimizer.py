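"""Gradient descent on the smoothed total error with backtracking line search.

Each outer step recomputes the distances to the current template, verifies
that the smoothed densities are still unimodal at the current sigma (if not,
sigma is raised in 0.05 increments and the whole optimization restarts from
the initial template), recomputes the slice-optimal threshold, and takes one
Armijo backtracking step along the negative gradient.  Termination watches
(A) the gradient magnitude, (B) its change over the last 10 steps, and (C)
the change in total error over the last 10 steps: descent stops when C and B,
or C and A, fall below their thresholds, or after 1000 steps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import discriminant as disc
from .discriminant import DistanceSet, SeparabilityError
from .preprocess import AmplitudeThreshold, Slice
from .template import (
    SliceSets,
    SyllableInstance,
    Template,
    assemble_slice_sets,
    averaged_template,
)

__all__ = [
    "OptimizerConfig",
    "OptimizationTrace",
    "backtracking_step",
    "optimize_template",
    "optimize_all_positions",
]

logger = logging.getLogger(__name__)


@dataclass
class OptimizerConfig:
    """Descent, line-search and termination settings.

    The termination thresholds act on the natural scales of the gradient
    norm and the total error; B and C compare the current value with the
    value ``history_window`` steps earlier.
    """

    max_steps: int = 1000
    history_window: int = 10
    thr_A: float = 1e-3  # |grad|
    thr_B: float = 1e-4  # change in |grad| over the window
    thr_C: float = 1e-6  # change in TE over the window
    armijo_c: float = 1e-4
    contraction: float = 0.5
    alpha0: float = 1.0
    alpha_floor: float = 1e-12
    sigma_cap: float = disc.SIGMA_CAP
    strict_sigma_floor: bool = False

    def __post_init__(self) -> None:
        for name in ("thr_A", "thr_B", "thr_C", "armijo_c", "alpha0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.contraction < 1:
            raise ValueError("contraction must be in (0, 1)")
        if self.max_steps < self.history_window:
            raise ValueError("max_steps must be >= history_window")


@dataclass
class OptimizationTrace:
    """Per-step log of one gradient descent run."""

    te: list[float] = field(default_factory=list)
    grad_norm: list[float] = field(default_factory=list)
    theta: list[float] = field(default_factory=list)
    sigma: list[float] = field(default_factory=list)
    step_size: list[float] = field(default_factory=list)
    termination: str = ""
    restarts: int = 0
    n_steps: int = 0

    def record(
        self, te: float, gnorm: float, theta: float, sigma: float, alpha: float
    ) -> None:
        self.te.append(te)
        self.grad_norm.append(gnorm)
        self.theta.append(theta)
        self.sigma.append(sigma)
        self.step_size.append(alpha)
        self.n_steps += 1

    def clear(self) -> None:
        self.te.clear()
        self.grad_norm.clear()
        self.theta.clear()
        self.sigma.clear()
        self.step_size.clear()
        self.n_steps = 0


class _Stall(Exception):
    """Line search could not decrease TE above the step-size floor."""


def backtracking_step(
    template_vector: np.ndarray,
    sets: SliceSets,
    theta: float,
    sigma: float,
    config: OptimizerConfig,
    grad: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """One Armijo backtracking step along the negative TE gradient.

    theta and sigma are held fixed during the search.  Returns the new
    template and the accepted step size; raises :class:`_Stall` when no
    sufficient decrease is found above the step-size floor.
    """
    if grad is None:
        grad = disc.gradient(template_vector, sets, theta, sigma)
    gnorm2 = float(grad @ grad)
    if gnorm2 == 0.0:
        raise ValueError("gradient is zero; no descent direction")
    te0 = disc.total_error(disc.distance_set(template_vector, sets), theta, sigma)
    alpha = config.alpha0
    while alpha >= config.alpha_floor:
        candidate = template_vector + alpha * grad  # grad is already -grad TE
        te = disc.total_error(disc.distance_set(candidate, sets), theta, sigma)
        if te <= te0 - config.armijo_c * alpha * gnorm2:
            return candidate, alpha
        alpha *= config.contraction
    raise _Stall(f"no sufficient decrease above alpha floor (TE={te0:.6g})")


def optimize_template(
    initial: Template,
    sets: SliceSets,
    config: OptimizerConfig | None = None,
) -> tuple[Template, OptimizationTrace]:
    """Run the full gradient descent from an averaged template.

    Per step: distances -> unimodality check (failure raises sigma and
    restarts the whole descent from the initial template) -> slice-optimal
    threshold -> gradient -> backtracking step.  The result carries the
    final sigma and threshold and is marked ``kind='optimized'``.
    """
    config = config or OptimizerConfig()
    trace = OptimizationTrace()
    t0 = initial.vector.copy()

    dset0 = disc.distance_set(t0, sets)
    sigma = disc.select_sigma(
        dset0,
        cap=config.sigma_cap,
        strict_floor_at_init=config.strict_sigma_floor,
    )

    t = t0.copy()
    theta = float("nan")
    step = 0
    while step < config.max_steps:
        dset = disc.distance_set(t, sets)
        sd = disc.smoothed_distributions(dset, sigma)
        if not (disc.is_unimodal(sd.T) and disc.is_unimodal(sd.D)):
            # raise sigma until smooth again and restart from the beginning
            new_sigma = sigma
            while new_sigma < config.sigma_cap:
                new_sigma = round(new_sigma + disc.SIGMA_STEP, 10)
                sd = disc.smoothed_distributions(dset, new_sigma)
                if disc.is_unimodal(sd.T) and disc.is_unimodal(sd.D):
                    break
            else:
                raise SeparabilityError(
                    f"sigma cap {config.sigma_cap} reached during restart"
                )
            logger.info(
                "densities lost unimodality at step %d; restarting with "
                "sigma %.2f -> %.2f",
                step,
                sigma,
                new_sigma,
            )
            sigma = new_sigma
            t = t0.copy()
            trace.clear()
            trace.restarts += 1
            step = 0
            continue

        theta = disc.slice_optimal_threshold(dset, sigma, sd=sd)
        grad = disc.gradient(t, sets, theta, sigma)
        gnorm = float(np.linalg.norm(grad))
        te = disc.total_error(dset, theta, sigma)

        if gnorm == 0.0:
            trace.record(te, gnorm, theta, sigma, 0.0)
            trace.termination = "zero_gradient"
            break
        try:
            t, alpha = backtracking_step(t, sets, theta, sigma, config, grad)
        except _Stall:
            trace.record(te, gnorm, theta, sigma, 0.0)
            trace.termination = "stall"
            break
        trace.record(te, gnorm, theta, sigma, alpha)
        step += 1

        w = config.history_window
        if trace.n_steps > w:
            c_change = abs(trace.te[-1] - trace.te[-1 - w])
            b_change = abs(trace.grad_norm[-1] - trace.grad_norm[-1 - w])
            a_val = trace.grad_norm[-1]
            if c_change < config.thr_C and b_change < config.thr_B:
                trace.termination = "CB"
                break
            if c_change < config.thr_C and a_val < config.thr_A:
                trace.termination = "CA"
                break
    else:
        trace.termination = "max_steps"

    if not trace.termination:
        trace.termination = "max_steps"

    # final threshold for the returned template
    dset = disc.distance_set(t, sets)
    theta = disc.slice_optimal_threshold(dset, sigma)
    optimized = Template(
        vector=t,
        syllable=initial.syllable,
        position=initial.position,
        sigma=sigma,
        theta=theta,
        kind="optimized",
        metadata=dict(initial.metadata),
    )
    return optimized, trace


def attach_threshold(template: Template, sets: SliceSets,
                     config: OptimizerConfig | None = None) -> Template:
    """Fit sigma and the slice-optimal threshold for an averaged template."""
    config = config or OptimizerConfig()
    dset = disc.distance_set(template.vector, sets)
    sigma = disc.select_sigma(
        dset, cap=config.sigma_cap,
        strict_floor_at_init=config.strict_sigma_floor,
    )
    template.sigma = sigma
    template.theta = disc.slice_optimal_threshold(dset, sigma)
    return template


def optimize_all_positions(
    labeled_slices: Sequence[Slice],
    instances: Sequence[SyllableInstance],
    syllable: str,
    amplitude_threshold: AmplitudeThreshold,
    sample_rate: int,
    config: OptimizerConfig | None = None,
    positions: Sequence[int] | None = None,
) -> tuple[list[tuple[Template, Template, OptimizationTrace]], dict[int, str]]:
    """Average + optimize templates for every slice position of a syllable.

    Returns ``(results, failures)``: per successful position a triple
    (averaged template with fitted theta, optimized template, trace);
    failures maps position -> error message without aborting the batch.
    """
    config = config or OptimizerConfig()
    sets0, aligned = assemble_slice_sets(
        labeled_slices, instances, syllable, 0, amplitude_threshold, sample_rate
    )
    m = aligned.shape[1]
    results = []
    failures: dict[int, str] = {}
    wanted = range(m) if positions is None else positions
    for pos in wanted:
        try:
            sets = (
                sets0
                if pos == 0
                else SliceSets(
                    targets=aligned[:, pos, :], distractors=sets0.distractors
                )
            )
            avg = averaged_template(aligned, pos, syllable, sample_rate)
            avg = attach_threshold(avg, sets, config)
            opt, trace = optimize_template(avg, sets, config)
            results.append((avg, opt, trace))
        except (ValueError, SeparabilityError) as exc:
            failures[pos] = str(exc)
            logger.warning("position %d failed: %s", pos + 1, exc)
    return results, failures
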