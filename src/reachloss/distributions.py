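"""Discrete lateral-shift distributions and trial schedules.

Lateral shifts are horizontal offsets (mm, positive = rightward, relative to
the displayed target center) applied between the true hand position and the
displayed cursor.  The two reaching experiments use skewed discrete
distributions whose mean and mode are separated, so that mean-seeking
(error-based) and mode-seeking (reinforcement-based) aiming policies make
different predictions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "ShiftDistribution",
    "TrialSchedule",
    "DistributionStats",
    "make_exp1_prior",
    "make_exp2_prior",
    "distribution_stats",
    "sample_schedule_exp1",
    "sample_schedule_exp2",
    "flip_values",
    "EXP1_CUES",
    "EXP1_CUE_RATIO",
]

#: Visual-uncertainty cue conditions in experiment 1: a single dot, a 15 mm
#: dot cloud, a 30 mm dot cloud, or feedback withheld.  Presented in a
#: 3:1:1:1 ratio.
EXP1_CUES = ("dot", "cloud15", "cloud30", "none")
EXP1_CUE_RATIO = (3, 1, 1, 1)

_BUILTIN_LABELS = {"exp1_SR", "exp1_SL", "exp2_SR", "exp2_SL"}

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class ShiftDistribution:
    """A discrete probability distribution over lateral shifts.

    Parameters
    ----------
    support
        Ordered lateral-shift values in mm (strictly increasing).
    probs
        Relative frequencies; nonnegative, summing to 1 within 1e-12.
    label
        Text tag, e.g. ``"exp1_SR"`` for the built-in distributions.
    skew
        One of ``{"right", "left", "none"}``.
    """

    support: np.ndarray
    probs: np.ndarray
    label: str = ""
    skew: str = "none"

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=float)
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "probs", probs)
        if support.ndim != 1 or probs.shape != support.shape:
            raise ValueError("support and probs must be 1-D and equal length")
        if support.size == 0:
            raise ValueError("empty support")
        if np.any(np.diff(support) <= 0):
            raise ValueError("support must be strictly increasing")
        if np.any(probs < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(probs.sum() - 1.0) > _PROB_TOL:
            raise ValueError(
                f"probabilities must sum to 1 (got {probs.sum()!r})"
            )
        if self.skew not in {"right", "left", "none"}:
            raise ValueError(f"invalid skew {self.skew!r}")

    # -- moments ---------------------------------------------------------
    @property
    def mean(self) -> float:
        return float(self.probs @ self.support)

    @property
    def median(self) -> float:
        """Smallest support value whose cumulative probability reaches 0.5."""
        cum = np.cumsum(self.probs)
        idx = int(np.searchsorted(cum, 0.5 - _PROB_TOL))
        return float(self.support[idx])

    @property
    def mode(self) -> float:
        return float(self.support[int(np.argmax(self.probs))])

    @property
    def variance(self) -> float:
        return float(self.probs @ (self.support - self.mean) ** 2)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "support_mm": self.support.tolist(),
            "probs": self.probs.tolist(),
            "skew": self.skew,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "ShiftDistribution":
        return cls(
            support=np.asarray(d["support_mm"], dtype=float),
            probs=np.asarray(d["probs"], dtype=float),
            label=d.get("label", ""),
            skew=d.get("skew", "none"),
        )

    @classmethod
    def from_json(cls, path) -> "ShiftDistribution":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class TrialSchedule:
    """A per-trial sequence of lateral shifts and cue conditions."""

    shifts: np.ndarray
    cues: tuple
    seed: int | None = None

    def __post_init__(self) -> None:
        shifts = np.asarray(self.shifts, dtype=float)
        object.__setattr__(self, "shifts", shifts)
        object.__setattr__(self, "cues", tuple(self.cues))
        if len(self.cues) != shifts.size:
            raise ValueError("shifts and cues must have equal length")

    def __len__(self) -> int:
        return int(self.shifts.size)


@dataclass(frozen=True)
class DistributionStats:
    mean: float
    median: float
    mode: float
    mode_tied: bool = False


def make_exp1_prior(skew: str) -> ShiftDistribution:
    """Build an experiment-1 skewed lateral-shift prior.

    Seven equally spaced (5 mm) shifts; the modal shift carries 9/21 of the
    mass and each of the other six carries 2/21.  The right-skewed variant
    spans 0..30 mm with mode 0 (mean 10, median 5); the left-skewed variant
    spans -10..20 mm with mode 20 (mean 10, median 15).
    """
    if skew not in {"right", "left"}:
        raise ValueError("skew must be 'right' or 'left'")
    probs = np.full(7, float(Fraction(2, 21)))
    if skew == "right":
        support = np.arange(0.0, 31.0, 5.0)
        probs[0] = float(Fraction(9, 21))
        label = "exp1_SR"
    else:
        support = np.arange(-10.0, 21.0, 5.0)
        probs[6] = float(Fraction(9, 21))
        label = "exp1_SL"
    probs /= probs.sum()  # remove last-bit float residue
    return ShiftDistribution(support, probs, label=label, skew=skew)


def make_exp2_prior(skew: str) -> ShiftDistribution:
    """Build an experiment-2 three-point lateral-shift distribution.

    Support {-14, 0, 14} mm; the modal shift (-14 for right skew, +14 for
    left skew) has probability 0.6, the other two 0.2 each.
    """
    if skew not in {"right", "left"}:
        raise ValueError("skew must be 'right' or 'left'")
    support = np.array([-14.0, 0.0, 14.0])
    if skew == "right":
        probs = np.array([0.6, 0.2, 0.2])
        label = "exp2_SR"
    else:
        probs = np.array([0.2, 0.2, 0.6])
        label = "exp2_SL"
    return ShiftDistribution(support, probs, label=label, skew=skew)


def builtin_distribution(label: str) -> ShiftDistribution:
    """Look up a built-in distribution by label (e.g. ``exp1_SR``)."""
    makers = {
        "exp1_SR": lambda: make_exp1_prior("right"),
        "exp1_SL": lambda: make_exp1_prior("left"),
        "exp2_SR": lambda: make_exp2_prior("right"),
        "exp2_SL": lambda: make_exp2_prior("left"),
    }
    if label not in makers:
        raise KeyError(f"unknown distribution label {label!r}")
    return makers[label]()


def distribution_stats(d: ShiftDistribution) -> DistributionStats:
    """Mean, weighted median and mode of a shift distribution (mm).

    The weighted median is the smallest support value with cumulative
    probability >= 0.5.  A tie in the maximal probability is an error for the
    built-in experiment distributions (they are unimodal by construction);
    for user distributions the smallest tied value is returned with
    ``mode_tied=True`` and a warning.
    """
    pmax = d.probs.max()
    tied = np.flatnonzero(np.isclose(d.probs, pmax, rtol=0, atol=_PROB_TOL))
    mode_tied = tied.size > 1
    if mode_tied:
        if d.label in _BUILTIN_LABELS:
            raise ValueError(
                f"built-in distribution {d.label!r} must be unimodal"
            )
        warnings.warn(
            "tied modal probabilities; returning the smallest modal value",
            stacklevel=2,
        )
    mode = float(d.support[tied[0]])
    return DistributionStats(
        mean=d.mean, median=d.median, mode=mode, mode_tied=mode_tied
    )


def sample_schedule_exp1(
    d: ShiftDistribution,
    n_trials: int,
    seed: int | None = None,
    cue_ratio: Sequence[float] = EXP1_CUE_RATIO,
) -> TrialSchedule:
    """Sample an experiment-1 trial schedule.

    Shifts are drawn i.i.d. (with replacement) from ``d``; cue conditions
    are independent categorical draws with expected proportions
    dot:cloud15:cloud30:none = 3:1:1:1.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    rng = np.random.default_rng(seed)
    shifts = rng.choice(d.support, size=n_trials, p=d.probs)
    ratio = np.asarray(cue_ratio, dtype=float)
    cues = rng.choice(EXP1_CUES, size=n_trials, p=ratio / ratio.sum())
    return TrialSchedule(shifts=shifts, cues=tuple(cues), seed=seed)


def sample_schedule_exp2(
    d: ShiftDistribution, seed: int | None = None, n_trials: int = 500
) -> TrialSchedule:
    """Sample an experiment-2 schedule: a fixed multiset, shuffled.

    The 500 shifts are drawn "until depletion": exactly ``round(p_i * 500)``
    trials per support value (300 modal / 100 / 100 for the built-ins), in a
    seeded uniform random order.  Every seed yields the same multiset.
    """
    counts = np.rint(d.probs * n_trials).astype(int)
    if counts.sum() != n_trials:
        raise ValueError(
            "distribution probabilities do not tile the trial count "
            f"(counts {counts.tolist()} for {n_trials} trials)"
        )
    pool = np.repeat(d.support, counts)
    rng = np.random.default_rng(seed)
    shifts = rng.permutation(pool)
    return TrialSchedule(
        shifts=shifts, cues=("target_only",) * n_trials, seed=seed
    )


def flip_values(values, pivot: float):
    """Reflect values about a pivot: ``v -> 2*pivot - v``.

    Used to mirror left-skew data onto the right-skew frame (the two skewed
    distributions in each experiment are reflections of one another), so
    both skews can be pooled.  Involution: flipping twice is the identity.
    """
    arr = 2.0 * pivot - np.asarray(values, dtype=float)
    if np.isscalar(values) or np.ndim(values) == 0:
        return float(arr)
    return arr
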