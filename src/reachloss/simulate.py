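"""Synthetic participants: trial-log generators for both experiments.

Each simulated participant is an ideal Bayesian observer-actor plus Gaussian
execution noise.  In the cue-uncertainty experiment (2000 reaches) the
per-trial compensation is the power-loss optimal compensation given the cue's
sensory uncertainty; in the end-point experiment (500 reaches) the
participant settles on one asymptotic aim (mean-seeking or mode-seeking),
optionally approached through a single-exponential learning transient so
trial-binning code sees realistic early data.

Trial logs are tidy :class:`pandas.DataFrame` objects with the schema in
:data:`TRIAL_COLUMNS`; ``cursor_x_mm = hand_x_mm + shift_mm`` holds exactly
on every row.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayes
from .aims import MotorNoise, aim_max_hits_mode, aim_max_hits_width, aim_min_sq_error
from .distributions import (
    EXP1_CUES,
    ShiftDistribution,
    builtin_distribution,
    sample_schedule_exp1,
    sample_schedule_exp2,
)

__all__ = [
    "TRIAL_COLUMNS",
    "SimParticipant",
    "simulate_exp1_participant",
    "simulate_exp2_participant",
    "generate_cloud_dots",
    "simulate_cohort",
    "DEFAULT_HIT_RADIUS_MM",
]

TRIAL_COLUMNS = [
    "participant_id",
    "group",
    "trial",
    "cue",
    "shift_mm",
    "sensed_mm",
    "hand_x_mm",
    "cursor_x_mm",
    "hit",
    "reward",
]

#: Half the 14 mm target diameter: a reach scores a hit when the displaced
#: cursor lands within the target.
DEFAULT_HIT_RADIUS_MM = 7.0

EXP1_GROUPS = {"Error_SR", "Error_SL", "ReinfError_SR"}
EXP2_GROUPS = {"Reinforcement", "Error", "ReinfError"}
_REINFORCED = {"ReinfError_SR", "Reinforcement", "ReinfError"}


@dataclass(frozen=True)
class SimParticipant:
    """Generating parameters of one synthetic participant.

    ``sigma_sensed`` maps cue names to sensed-centroid SDs (mm) for the
    cue-uncertainty experiment; the withheld cue is always infinite.
    ``policy`` selects the asymptotic aim of an end-point participant:
    ``"min_power_error"`` (mean-seeking), ``"max_hits"`` (mode-seeking,
    per ``max_hits_variant``) or a fixed aim in mm.
    """

    id: str
    group: str
    alpha: float = 2.0
    sigma_sensed: dict = field(
        default_factory=lambda: {"dot": 1.0, "cloud15": 15.0, "cloud30": 30.0}
    )
    motor_sd: float = 2.0
    policy: str | float = "min_power_error"
    max_hits_variant: str = "mode"
    sensing_sd: float = 0.0
    learning_tau: float | None = 25.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.motor_sd < 0 or self.sensing_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if any(v < 0 for v in self.sigma_sensed.values()):
            raise ValueError("sigma_sensed values must be nonnegative")


def _is_reinforced(group: str) -> bool:
    return group in _REINFORCED


def _finish_records(
    p: SimParticipant,
    cues,
    shifts: np.ndarray,
    sensed: np.ndarray,
    hand: np.ndarray,
    hit_radius: float,
    reward_cues: set | None,
) -> pd.DataFrame:
    cursor = hand + shifts
    hit = np.abs(cursor) <= hit_radius
    if _is_reinforced(p.group):
        if reward_cues is None:
            reward = hit.copy()
        else:
            reward = hit & np.isin(np.asarray(cues), sorted(reward_cues))
    else:
        reward = np.zeros_like(hit)
    n = len(shifts)
    return pd.DataFrame(
        {
            "participant_id": [p.id] * n,
            "group": [p.group] * n,
            "trial": np.arange(1, n + 1),
            "cue": list(cues),
            "shift_mm": shifts,
            "sensed_mm": sensed,
            "hand_x_mm": hand,
            "cursor_x_mm": cursor,
            "hit": hit,
            "reward": reward,
        }
    )


def simulate_exp1_participant(
    p: SimParticipant,
    prior: ShiftDistribution,
    n_trials: int = 2000,
    hit_radius: float = DEFAULT_HIT_RADIUS_MM,
) -> pd.DataFrame:
    """Simulate one cue-uncertainty participant (default 2000 reaches).

    Per trial the shift and cue come from the 3:1:1:1 schedule, the sensed
    centroid equals the true shift (plus optional sensing noise), and the
    hand lands at the Bayes-optimal compensation for the trial's posterior
    plus Gaussian execution noise.  Reinforced groups are rewarded only on
    single-dot trials, mirroring the protocol.
    """
    if p.group not in EXP1_GROUPS:
        raise ValueError(f"{p.group!r} is not a cue-uncertainty group")
    missing = set(EXP1_CUES) - {"none"} - set(p.sigma_sensed)
    if missing:
        raise ValueError(f"missing sigma_sensed for cues: {sorted(missing)}")
    schedule = sample_schedule_exp1(prior, n_trials, seed=p.seed)
    rng = np.random.default_rng(
        None if p.seed is None else np.random.SeedSequence([p.seed, 1])
    )
    shifts = schedule.shifts
    cues = schedule.cues
    if p.sensing_sd > 0:
        sensed = shifts + rng.normal(0.0, p.sensing_sd, size=n_trials)
        comp = np.array(
            [
                bayes.optimal_compensation(
                    bayes.posterior(
                        prior, float(x), _cue_sigma(p, c)
                    ),
                    p.alpha,
                ).aim_mm
                for x, c in zip(sensed, cues)
            ]
        )
    else:
        sensed = shifts.copy()
        # sensed == true shift, so the policy is a lookup over the 7 x 4
        # (shift, cue) cells
        lookup: dict[tuple[float, str], float] = {}
        for c in EXP1_CUES:
            sig = _cue_sigma(p, c)
            for s in prior.support:
                post = bayes.posterior(prior, float(s), sig)
                lookup[(float(s), c)] = bayes.optimal_compensation(
                    post, p.alpha
                ).aim_mm
        comp = np.array(
            [lookup[(float(s), c)] for s, c in zip(shifts, cues)]
        )
    hand = comp
    if p.motor_sd > 0:
        hand = hand + rng.normal(0.0, p.motor_sd, size=n_trials)
    return _finish_records(
        p, cues, shifts, sensed, hand, hit_radius, reward_cues={"dot"}
    )


def _cue_sigma(p: SimParticipant, cue: str) -> float:
    return math.inf if cue == "none" else float(p.sigma_sensed[cue])


def asymptotic_aim(
    p: SimParticipant,
    d: ShiftDistribution,
    target: float = 0.0,
    target_width: float = 14.0,
) -> float:
    """Asymptotic aim of an end-point participant under its policy."""
    if isinstance(p.policy, (int, float)):
        return float(p.policy)
    noise = MotorNoise(p.motor_sd)
    if p.policy == "min_power_error":
        return aim_min_sq_error(d, noise, target).aim_mm
    if p.policy == "max_hits":
        if p.max_hits_variant == "width":
            return aim_max_hits_width(d, noise, target, target_width).aim_mm
        return aim_max_hits_mode(d, noise, target).aim_mm
    raise ValueError(f"unknown policy {p.policy!r}")


def simulate_exp2_participant(
    p: SimParticipant,
    d: ShiftDistribution,
    hit_radius: float = DEFAULT_HIT_RADIUS_MM,
    target: float = 0.0,
) -> pd.DataFrame:
    """Simulate one end-point participant (500 reaches, depletion schedule).

    The aim approaches the policy's asymptote from 0 along a single
    exponential with time constant ``learning_tau`` trials (``None``
    disables the transient), so the asymptote is effectively reached before
    trial 100; the hand lands at the current aim plus execution noise.
    """
    if p.group not in EXP2_GROUPS:
        raise ValueError(f"{p.group!r} is not an end-point group")
    schedule = sample_schedule_exp2(d, seed=p.seed)
    n = len(schedule)
    rng = np.random.default_rng(
        None if p.seed is None else np.random.SeedSequence([p.seed, 1])
    )
    aim_inf = asymptotic_aim(p, d, target)
    t = np.arange(1, n + 1, dtype=float)
    if p.learning_tau:
        aim_t = aim_inf * (1.0 - np.exp(-(t - 1.0) / p.learning_tau))
    else:
        aim_t = np.full(n, aim_inf)
    hand = aim_t
    if p.motor_sd > 0:
        hand = hand + rng.normal(0.0, p.motor_sd, size=n)
    shifts = schedule.shifts
    sensed = shifts.copy()
    return _finish_records(
        p, schedule.cues, shifts, sensed, hand, hit_radius, reward_cues=None
    )


def generate_cloud_dots(
    centroid: tuple[float, float],
    sigma: float,
    n: int = 25,
    seed: int | None = None,
) -> np.ndarray:
    """Generate a feedback cloud of ``n`` bivariate-normal dots.

    Dots have independent x/y coordinates with SD ``sigma`` per axis around
    the centroid, produced by the Box-Muller transform from seeded uniform
    deviates (the same construction used to draw the stimulus clouds).
    Returns an ``(n, 2)`` array of mm coordinates.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    m = (2 * n + 1) // 2
    u1 = rng.random(m)
    u2 = rng.random(m)
    r = np.sqrt(-2.0 * np.log1p(-u1))  # log1p avoids log(0)
    z = np.empty(2 * m)
    z[0::2] = r * np.cos(2.0 * np.pi * u2)
    z[1::2] = r * np.sin(2.0 * np.pi * u2)
    dots = z[: 2 * n].reshape(n, 2) * sigma
    return dots + np.asarray(centroid, dtype=float)


def _participant_seed(master_seed: int, index: int) -> int:
    """Derive a stable 31-bit per-participant seed from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(config: dict, out_dir) -> dict:
    """Simulate a cohort of participants and write per-participant CSVs.

    ``config`` keys::

        experiment   1 or 2
        master_seed  int
        groups       list of {name, n, skew, and per-participant parameter
                     overrides (alpha, sigma_sensed, motor_sd, policy,
                     max_hits_variant, learning_tau, n_trials)}

    Writes one trial-log CSV per participant plus ``manifest.json``
    recording every derived seed and parameter; re-running with the same
    config is byte-identical.  Returns the manifest dict.
    """
    from .io import write_trial_log

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    experiment = int(config["experiment"])
    if experiment not in (1, 2):
        raise ValueError("experiment must be 1 or 2")
    master_seed = int(config["master_seed"])
    valid_groups = EXP1_GROUPS if experiment == 1 else EXP2_GROUPS
    manifest = {
        "experiment": experiment,
        "master_seed": master_seed,
        "participants": [],
    }
    index = 0
    for spec in config["groups"]:
        name = spec["name"]
        if name not in valid_groups:
            raise ValueError(f"invalid group {name!r} for experiment "
                             f"{experiment}")
        n = int(spec.get("n", 1))
        if n <= 0:
            raise ValueError("group size must be positive")
        skew = spec.get("skew", "right")
        dist = builtin_distribution(
            f"exp{experiment}_{'SR' if skew == 'right' else 'SL'}"
        )
        for k in range(n):
            seed = _participant_seed(master_seed, index)
            pid = f"{name}_{skew[0].upper()}{k + 1:02d}"
            p = SimParticipant(
                id=pid,
                group=name,
                alpha=float(spec.get("alpha", 2.0)),
                sigma_sensed=dict(
                    spec.get(
                        "sigma_sensed",
                        {"dot": 1.0, "cloud15": 15.0, "cloud30": 30.0},
                    )
                ),
                motor_sd=float(spec.get("motor_sd", 2.0)),
                policy=spec.get("policy", "min_power_error"),
                max_hits_variant=spec.get("max_hits_variant", "mode"),
                learning_tau=spec.get("learning_tau", 25.0),
                seed=seed,
            )
            if experiment == 1:
                records = simulate_exp1_participant(
                    p, dist, n_trials=int(spec.get("n_trials", 2000))
                )
            else:
                records = simulate_exp2_participant(p, dist)
            path = out / f"{pid}.csv"
            write_trial_log(records, path)
            manifest["participants"].append(
                {
                    "id": pid,
                    "group": name,
                    "skew": skew,
                    "seed": seed,
                    "alpha": p.alpha,
                    "sigma_sensed": p.sigma_sensed,
                    "motor_sd": p.motor_sd,
                    "policy": p.policy,
                    "file": path.name,
                }
            )
            index += 1
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
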