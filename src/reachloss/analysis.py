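"""Descriptive trial-log analyses: binning, asymptote, variability, R^2."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "bin_trials",
    "asymptote_mean",
    "movement_variability",
    "variability_compensation_r2",
]


def _hand_series(records: pd.DataFrame) -> np.ndarray:
    return records.sort_values("trial")["hand_x_mm"].to_numpy()


def bin_trials(
    records: pd.DataFrame, bin_size: int = 10, head: int = 3
) -> pd.DataFrame:
    """Bin compensation into a head bin plus fixed-size trial bins.

    Bin 0 aggregates the first ``head`` trials (behavior right after
    perturbation onset); bins 1..K aggregate consecutive ``bin_size``-trial
    chunks starting at trial 1.  Note bin 0 therefore *overlaps* bin 1 —
    its trials are counted again in the first full bin, mirroring the usual
    presentation of these learning curves.  A trailing partial bin is
    dropped with a warning.  Returns columns ``bin, mean_mm, sd_mm, n``.
    """
    x = _hand_series(records)
    if len(x) < head:
        raise ValueError(f"need at least {head} trials")
    rows = [
        {
            "bin": 0,
            "mean_mm": float(x[:head].mean()),
            "sd_mm": float(x[:head].std(ddof=1)) if head > 1 else 0.0,
            "n": head,
        }
    ]
    n_full = len(x) // bin_size
    if len(x) % bin_size:
        warnings.warn(
            f"dropping trailing partial bin of {len(x) % bin_size} trials",
            stacklevel=2,
        )
    for k in range(n_full):
        chunk = x[k * bin_size : (k + 1) * bin_size]
        rows.append(
            {
                "bin": k + 1,
                "mean_mm": float(chunk.mean()),
                "sd_mm": float(chunk.std(ddof=1)),
                "n": bin_size,
            }
        )
    return pd.DataFrame(rows)


def asymptote_mean(records: pd.DataFrame, last_n: int = 400) -> float:
    """Mean compensation (hand x, mm) over the final ``last_n`` trials."""
    x = _hand_series(records)
    if last_n > len(x):
        raise ValueError("last_n exceeds the record count")
    return float(x[-last_n:].mean())


def movement_variability(records: pd.DataFrame, last_n: int = 400) -> float:
    """Sample SD (n-1 denominator) of final hand position over the
    asymptotic window."""
    if last_n < 2:
        raise ValueError("need at least 2 trials")
    x = _hand_series(records)
    if last_n > len(x):
        raise ValueError("last_n exceeds the record count")
    return float(x[-last_n:].std(ddof=1))


def variability_compensation_r2(pairs) -> float:
    """Coefficient of determination between per-participant movement
    variability and asymptotic compensation.

    ``pairs`` is a sequence of (variability, asymptote) tuples, one per
    participant (at least 3).  Returns the squared Pearson correlation.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (variability, asymptote) pairs")
    v, c = arr[:, 0], arr[:, 1]
    if np.std(v) == 0 or np.std(c) == 0:
        raise ValueError("zero variance in one of the variables")
    r = np.corrcoef(v, c)[0, 1]
    return float(r * r)
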