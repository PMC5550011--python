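"""Cursor-position densities and optimal aim points for the end-point task.

In the second experiment the cursor lands at ``hand + shift`` where the hand
scatters as a Gaussian (SD ``sigma_mv``) around the aim and the shift is
drawn from a three-point skewed distribution.  The cursor density is thus a
Gaussian mixture.  Two asymptotic aiming policies are dissociated:

* ``aim_min_sq_error`` — minimize expected squared cursor error about the
  target; equals minus the shift-distribution mean and is invariant to
  movement variability.
* ``aim_max_hits_mode`` — place the *mode* of the cursor density on the
  target (the 0-1 loss optimum); depends on movement variability.
* ``aim_max_hits_width`` — maximize the probability that the cursor lands
  within a finite-width target; converges to the mode solution as the
  width shrinks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .bayes import AimSolution, Grid, PosteriorOnGrid
from .distributions import ShiftDistribution

__all__ = [
    "MotorNoise",
    "DEFAULT_GRID",
    "cursor_density",
    "mixture_mode",
    "aim_min_sq_error",
    "aim_max_hits_mode",
    "aim_max_hits_width",
    "hit_probability",
]

#: Default evaluation grid: covers every built-in shift +-5 SD of the
#: largest plausible movement noise at 0.02 mm resolution.
DEFAULT_GRID = Grid(-80.0, 80.0, 0.02)


@dataclass(frozen=True)
class MotorNoise:
    """Movement (execution) variability: SD of final hand position, mm."""

    sigma_mv: float

    def __post_init__(self) -> None:
        if self.sigma_mv < 0:
            raise ValueError("sigma_mv must be nonnegative")


def cursor_density(
    x_aim: float,
    noise: MotorNoise,
    d: ShiftDistribution,
    grid: Grid = DEFAULT_GRID,
) -> PosteriorOnGrid:
    """Density of cursor position given an aim: hand noise convolved with
    the shift distribution.

    For a discrete shift distribution the convolution is the mixture
    ``sum_i p_i Normal(x; x_aim + shift_i, sigma_mv)`` sampled on the grid
    and renormalized.  Raises if the grid clips >= 1e-3 of the mass.
    """
    if noise.sigma_mv <= 0:
        raise ValueError("cursor_density requires sigma_mv > 0")
    pts = grid.points
    dens = np.zeros_like(pts)
    for s, p in zip(d.support, d.probs):
        dens += p * stats.norm.pdf(pts, loc=x_aim + s, scale=noise.sigma_mv)
    mass = dens * grid.step
    clipped = 1.0 - mass.sum()
    if clipped >= 1e-3:
        raise ValueError(
            f"grid too narrow: {clipped:.2e} of the cursor mass clipped"
        )
    return PosteriorOnGrid(pts, mass / mass.sum())


def _refine_argmax(pts: np.ndarray, dens: np.ndarray) -> float:
    """Argmax with parabolic refinement of the top three grid points."""
    i = int(np.argmax(dens))
    if i == 0 or i == len(pts) - 1:
        return float(pts[i])
    y0, y1, y2 = dens[i - 1], dens[i], dens[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return float(pts[i])
    step = pts[i] - pts[i - 1]
    return float(pts[i] + 0.5 * (y0 - y2) / denom * step)


def _mixture_peaks(
    d: ShiftDistribution, noise: MotorNoise, grid: Grid = DEFAULT_GRID
) -> tuple[np.ndarray, bool]:
    """Refined locations of the near-global maxima of the zero-aim cursor
    mixture, plus a flag set when more than one peak ties the global height
    within 1e-6 relative tolerance."""
    pts = grid.points
    dens = np.zeros_like(pts)
    for s, p in zip(d.support, d.probs):
        dens += p * stats.norm.pdf(pts, loc=s, scale=noise.sigma_mv)
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(interior) + 1
    if peaks.size == 0:
        return np.array([pts[int(np.argmax(dens))]]), False
    heights = dens[peaks]
    contenders = peaks[heights >= heights.max() * (1.0 - 1e-6)]
    # collapse plateau runs of adjacent grid indices to one peak each
    groups = np.split(contenders, np.flatnonzero(np.diff(contenders) > 1) + 1)
    locs = []
    for g in groups:
        i = int(g[len(g) // 2])  # center of a flat run
        lo = max(i - 1, 0)
        locs.append(_refine_argmax(pts[lo : i + 2], dens[lo : i + 2]))
    return np.asarray(locs), len(groups) > 1


def mixture_mode(
    d: ShiftDistribution, noise: MotorNoise, grid: Grid = DEFAULT_GRID
) -> tuple[float, bool]:
    """Mode of the zero-aim cursor mixture, with an ambiguity flag.

    Aiming merely translates the density, so the mode for any aim is
    ``aim + mixture_mode(...)``.  Equal-height peaks are flagged and broken
    toward the leftmost peak.
    """
    locs, ambiguous = _mixture_peaks(d, noise, grid)
    return float(locs[0]), ambiguous


def aim_min_sq_error(
    d: ShiftDistribution,
    noise: MotorNoise,
    target: float = 0.0,
    method: str = "analytic",
    grid: Grid = DEFAULT_GRID,
) -> AimSolution:
    """Aim that minimizes expected squared cursor error about the target.

    The expected squared error is minimized when the cursor-density mean
    sits on the target, so the analytic solution is
    ``-(mean(d) - target)`` — independent of movement variability.  The
    ``numeric`` method instead minimizes the sampled expected loss and is
    provided to confirm the closed form.
    """
    analytic = -(d.mean - target)
    if method == "analytic":
        aim = analytic
    elif method == "numeric":
        if noise.sigma_mv <= 0:
            raise ValueError("numeric method requires sigma_mv > 0")

        def el(a: float) -> float:
            dens = cursor_density(a, noise, d, grid)
            return float(dens.mass @ (dens.points - target) ** 2)

        res = optimize.minimize_scalar(
            el, bounds=(analytic - 10.0, analytic + 10.0), method="bounded",
            options={"xatol": 1e-6},
        )
        aim = float(res.x)
    else:
        raise ValueError("method must be 'analytic' or 'numeric'")
    # objective: expected squared error at the chosen aim
    obj = noise.sigma_mv**2 + d.variance + (aim + d.mean - target) ** 2
    return AimSolution(
        aim_mm=float(aim), criterion="min_power_error", alpha=2.0,
        objective=float(obj),
    )


def aim_max_hits_mode(
    d: ShiftDistribution,
    noise: MotorNoise,
    target: float = 0.0,
    grid: Grid = DEFAULT_GRID,
) -> AimSolution:
    """Aim that places the mode of the cursor density on the target.

    Equivalent to minimizing the 0-1 loss in the vanishing-target limit.
    Because aiming translates the density, the solution is
    ``target - mode`` of the zero-aim mixture.  In the zero-noise limit the
    mode is the modal shift, so the aim tends to ``target - mode(d)``.
    """
    if noise.sigma_mv == 0:
        aim = target - d.mode
        return AimSolution(aim_mm=float(aim), criterion="max_hits_mode",
                           objective=0.0)
    locs, ambiguous = _mixture_peaks(d, noise, grid)
    aims = target - locs
    aim = aims[int(np.argmin(np.abs(aims)))]  # smallest |aim| among ties
    return AimSolution(
        aim_mm=float(aim), criterion="max_hits_mode", objective=0.0,
        ambiguous=ambiguous,
    )


def hit_probability(
    x_aim: float,
    d: ShiftDistribution,
    noise: MotorNoise,
    target: float = 0.0,
    target_width: float = 14.0,
) -> float:
    """Probability the cursor lands within the target (closed form).

    ``sum_i p_i [Phi((w/2 - m_i)/sigma) - Phi((-w/2 - m_i)/sigma)]`` with
    ``m_i = x_aim + shift_i - target``.
    """
    if noise.sigma_mv == 0:
        m = x_aim + d.support - target
        return float(d.probs @ (np.abs(m) <= target_width / 2.0))
    m = x_aim + d.support - target
    upper = stats.norm.cdf((target_width / 2.0 - m) / noise.sigma_mv)
    lower = stats.norm.cdf((-target_width / 2.0 - m) / noise.sigma_mv)
    return float(d.probs @ (upper - lower))


def aim_max_hits_width(
    d: ShiftDistribution,
    noise: MotorNoise,
    target: float = 0.0,
    target_width: float = 14.0,
) -> AimSolution:
    """Aim that maximizes the probability of hitting a finite-width target.

    Coarse scan plus bounded refinement of the closed-form hit probability;
    as ``target_width -> 0`` this recovers the mode-alignment solution.
    """
    if target_width <= 0:
        raise ValueError("target_width must be positive")
    span = float(d.support.max() - d.support.min()) + 5 * noise.sigma_mv + 10
    lo, hi = target - span, target + span
    xs = np.arange(lo, hi + 0.05, 0.1)
    probs = np.array(
        [hit_probability(x, d, noise, target, target_width) for x in xs]
    )
    x0 = xs[int(np.argmax(probs))]
    res = optimize.minimize_scalar(
        lambda a: -hit_probability(a, d, noise, target, target_width),
        bounds=(x0 - 0.2, x0 + 0.2), method="bounded",
        options={"xatol": 1e-7},
    )
    return AimSolution(
        aim_mm=float(res.x), criterion="max_hits_width",
        target_width=float(target_width), objective=float(-res.fun),
    )
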