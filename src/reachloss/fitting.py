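"""Condition averaging and the four-parameter Bayesian model fit.

The fit recovers a participant's loss exponent alpha and the three sensed
SDs (single dot, 15 mm cloud, 30 mm cloud) from their 7-shift x 4-cue table
of mean compensations.  The withheld-feedback cue is modeled with infinite
sensory uncertainty, so its (shift-independent) prediction depends only on
alpha and anchors the loss exponent.  The objective is the weighted least
absolute error between the data table and the optimal-compensation surface,
minimized by multi-start Nelder-Mead on log-transformed parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .bayes import _argmin_expected_loss_rows, posterior
from .distributions import EXP1_CUES, ShiftDistribution

__all__ = [
    "FitOptions",
    "FitResult",
    "condition_averages",
    "fit_weights",
    "fit_bayes_model",
    "predict_from_fit",
    "linear_condition_fit",
]

FIT_CUES = ("dot", "cloud15", "cloud30")  # the three finite-sigma cues


@dataclass(frozen=True)
class FitOptions:
    n_restarts: int = 8
    maxfev: int = 5000
    fatol: float = 1e-6
    xatol: float = 1e-5
    alpha_starts: tuple = (1.0, 1.5, 2.0, 2.5)
    sigma_start: tuple = (5.0, 15.0, 30.0)
    sigma_scalings: tuple = (0.7, 1.3)


@dataclass(frozen=True)
class FitResult:
    """Best-fit loss exponent and sensed SDs with fit diagnostics."""

    alpha_opt: float
    sigma_opt: dict
    objective: float
    n_restarts: int
    converged: bool
    n_fev: int = 0

    def __post_init__(self) -> None:
        if self.alpha_opt <= 0:
            raise ValueError("alpha_opt must be positive")
        if any(v < 0 for v in self.sigma_opt.values()):
            raise ValueError("sigma_opt values must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "alpha_opt": self.alpha_opt,
            "sigma_opt": dict(self.sigma_opt),
            "objective": self.objective,
            "n_restarts": self.n_restarts,
            "converged": self.converged,
            "n_fev": self.n_fev,
        }


def condition_averages(
    records: pd.DataFrame, last_n: int = 1000
) -> pd.DataFrame:
    """Mean compensation per (shift, cue) cell over the last ``last_n``
    trials of one participant's log.

    The trailing window excludes early learning; for the built-in design
    this yields the full 7 x 4 = 28-cell table.  Raises (naming the cells)
    if any (shift, cue) combination has no trials in the window.
    """
    if last_n > len(records):
        raise ValueError("last_n exceeds the record count")
    tail = records.sort_values("trial").iloc[-last_n:]
    table = (
        tail.groupby(["shift_mm", "cue"], as_index=False)
        .agg(comp_mean=("hand_x_mm", "mean"), n_trials=("hand_x_mm", "size"))
    )
    shifts = np.sort(records["shift_mm"].unique())
    cues = [c for c in EXP1_CUES if c in set(records["cue"])] or sorted(
        set(records["cue"])
    )
    have = set(zip(table["shift_mm"], table["cue"]))
    empty = [
        (float(s), c) for s in shifts for c in cues if (s, c) not in have
    ]
    if empty:
        raise ValueError(f"empty condition cells in window: {empty}")
    order = {c: i for i, c in enumerate(cues)}
    table = table.sort_values(
        ["cue", "shift_mm"], key=lambda col: col.map(order) if col.name == "cue" else col
    ).reset_index(drop=True)
    return table


def fit_weights(prior: ShiftDistribution) -> pd.DataFrame:
    """Fitting weights w_{i,j}: within each cue, each shift is weighted by
    its prior probability, so every cue condition contributes equally to
    the objective while shifts weigh in proportion to how often they occur.
    """
    rows = [
        {"shift_mm": float(s), "cue": c, "weight": float(p)}
        for c in EXP1_CUES
        for s, p in zip(prior.support, prior.probs)
    ]
    return pd.DataFrame(rows)


def _comp_surface(
    prior: ShiftDistribution, alpha: float, sigmas: np.ndarray
) -> np.ndarray:
    """Optimal compensation matrix, shape (7 shifts, 4 cues).

    Columns follow :data:`EXP1_CUES`; the last column (withheld feedback)
    uses the prior itself.
    """
    support = prior.support
    n = support.size
    out = np.empty((n, 4))
    for j, sigma in enumerate(sigmas):
        Q = np.empty((n, n))
        for i, xs in enumerate(support):
            Q[i] = posterior(prior, float(xs), float(sigma)).mass
        out[:, j] = -_argmin_expected_loss_rows(support, Q, alpha)
    prior_argmin = -_argmin_expected_loss_rows(
        support, prior.probs[None, :], alpha
    )[0]
    out[:, 3] = prior_argmin
    return out


def fit_bayes_model(
    table: pd.DataFrame,
    prior: ShiftDistribution,
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Fit (alpha, sigma_dot, sigma_cloud15, sigma_cloud30) to a 28-cell
    condition table by weighted least absolute error.

    Multi-start Nelder-Mead over log-transformed parameters; the best of
    all starts is returned.  Raises if every start fails.
    """
    shifts = np.sort(table["shift_mm"].unique())
    if shifts.size != prior.support.size or not np.allclose(
        shifts, prior.support
    ):
        raise ValueError("table shifts do not match the prior support")
    data = np.full((shifts.size, 4), np.nan)
    for _, row in table.iterrows():
        j = EXP1_CUES.index(row["cue"])
        i = int(np.argmin(np.abs(shifts - row["shift_mm"])))
        data[i, j] = row["comp_mean"]
    if np.isnan(data).any():
        raise ValueError("incomplete condition table")
    weights = np.tile(prior.probs[:, None], (1, 4))

    def objective(theta: np.ndarray) -> float:
        alpha = math.exp(theta[0])
        sigmas = np.exp(theta[1:])
        pred = _comp_surface(prior, alpha, sigmas)
        return float(np.sum(weights * np.abs(data - pred)))

    starts = []
    for a0 in options.alpha_starts:
        for scale in options.sigma_scalings:
            starts.append(
                np.log(np.r_[a0, scale * np.asarray(options.sigma_start)])
            )
    starts = starts[: options.n_restarts]

    best = None
    n_fev = 0
    any_ok = False
    for x0 in starts:
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={
                "maxfev": options.maxfev,
                "fatol": options.fatol,
                "xatol": options.xatol,
            },
        )
        n_fev += res.nfev
        any_ok = any_ok or res.success
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all optimizer starts failed")
    alpha_opt = float(math.exp(best.x[0]))
    sig = np.exp(best.x[1:])
    return FitResult(
        alpha_opt=alpha_opt,
        sigma_opt={c: float(s) for c, s in zip(FIT_CUES, sig)},
        objective=float(best.fun),
        n_restarts=len(starts),
        converged=bool(any_ok),
        n_fev=n_fev,
    )


def predict_from_fit(
    fit: FitResult, prior: ShiftDistribution
) -> pd.DataFrame:
    """Model-predicted condition table at the fitted parameters."""
    sigmas = np.array([fit.sigma_opt[c] for c in FIT_CUES])
    pred = _comp_surface(prior, fit.alpha_opt, sigmas)
    rows = [
        {
            "shift_mm": float(s),
            "cue": c,
            "comp_pred": float(pred[i, j]),
        }
        for j, c in enumerate(EXP1_CUES)
        for i, s in enumerate(prior.support)
    ]
    return pd.DataFrame(rows)


def variance_explained(
    table: pd.DataFrame, predictions: pd.DataFrame
) -> float:
    """Fraction of condition-table variance explained by the model (R^2)."""
    merged = table.merge(predictions, on=["shift_mm", "cue"])
    resid = merged["comp_mean"] - merged["comp_pred"]
    total = merged["comp_mean"] - merged["comp_mean"].mean()
    ss_tot = float(total @ total)
    if ss_tot == 0:
        raise ValueError("zero variance in the data table")
    return 1.0 - float(resid @ resid) / ss_tot


def linear_condition_fit(
    records: pd.DataFrame, last_n: int = 1000
) -> pd.DataFrame:
    """Per-cue OLS of mean compensation against shift over the 7 cell means.

    A descriptive complement to the Bayesian fit: the slope tracks how
    strongly compensation follows the trial's shift (0 = prior only, -1 =
    full compensation) and the intercept the shift-independent bias.
    """
    table = condition_averages(records, last_n=last_n)
    rows = []
    for cue, sub in table.groupby("cue", sort=False):
        if sub["shift_mm"].nunique() < 2:
            raise ValueError(f"cue {cue!r} has fewer than 2 distinct shifts")
        slope, intercept = np.polyfit(sub["shift_mm"], sub["comp_mean"], 1)
        rows.append(
            {"cue": cue, "slope": float(slope),
             "intercept": float(intercept)}
        )
    return pd.DataFrame(rows)
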