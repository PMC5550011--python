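"""Resampling statistics: bootstrap tests, Holm correction, effect sizes.

Group comparisons use nonparametric bootstrap hypothesis tests (default
one million resamples): the samples are shifted to satisfy the null (one
sample: recentered on the null value; two samples: both recentered on the
pooled mean), resampled with replacement, and the p-value is the fraction
of null mean differences at least as extreme as the observed one.  A
label-permutation variant of the two-sample test is also provided, since
the recentering construction is one of several standard readings.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BootstrapResult",
    "bootstrap_test",
    "holm_bonferroni",
    "common_language_effect",
    "percentile_ci",
]

_CHUNK_DRAWS = 20_000_000  # cap on resample draws held in memory at once


@dataclass(frozen=True)
class BootstrapResult:
    p_value: float
    n_resamples: int
    tails: str
    observed: float
    ci_95: tuple
    seed: int | None
    kind: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value out of [0, 1]")
        if self.ci_95[0] > self.ci_95[1]:
            raise ValueError("CI lower bound exceeds upper bound")


def _resample_means(rng, x: np.ndarray, n_resamples: int) -> np.ndarray:
    """Means of bootstrap resamples of x, computed in memory-bounded
    chunks."""
    n = x.size
    out = np.empty(n_resamples)
    chunk = max(1, _CHUNK_DRAWS // n)
    done = 0
    while done < n_resamples:
        m = min(chunk, n_resamples - done)
        idx = rng.integers(0, n, size=(m, n))
        out[done : done + m] = x[idx].mean(axis=1)
        done += m
    return out


def _resample_mean_se(rng, x: np.ndarray, n_resamples: int):
    """Bootstrap resample means and standard errors of the mean, chunked."""
    n = x.size
    means = np.empty(n_resamples)
    ses = np.empty(n_resamples)
    chunk = max(1, _CHUNK_DRAWS // n)
    done = 0
    while done < n_resamples:
        m = min(chunk, n_resamples - done)
        idx = rng.integers(0, n, size=(m, n))
        draws = x[idx]
        means[done : done + m] = draws.mean(axis=1)
        ses[done : done + m] = draws.std(axis=1, ddof=1) / np.sqrt(n)
        done += m
    return means, ses


def _se(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / np.sqrt(x.size))


def _tail_p(null_stats: np.ndarray, observed: float, tails: str) -> float:
    if tails == "two":
        return float(np.mean(np.abs(null_stats) >= abs(observed)))
    if tails in ("one", "greater"):
        return float(np.mean(null_stats >= observed))
    if tails == "less":
        return float(np.mean(null_stats <= observed))
    raise ValueError(f"invalid tails {tails!r}")


def bootstrap_test(
    a,
    b=None,
    kind: str = "one_sample",
    null_value: float = 0.0,
    tails: str = "two",
    n_resamples: int = 1_000_000,
    seed: int | None = None,
    method: str = "recenter",
    statistic: str = "studentized",
) -> BootstrapResult:
    """Nonparametric bootstrap hypothesis test on means.

    ``kind``:

    * ``one_sample`` — H0: mean(a) == ``null_value``; ``a`` is recentered
      on the null before resampling.
    * ``two_sample`` — H0: mean(a) == mean(b); both groups recentered on
      the pooled mean (``method="recenter"``) or labels permuted
      (``method="permutation"``).
    * ``paired`` — one-sample test on the element-wise differences.

    ``statistic="studentized"`` (default) compares mean differences on the
    scale of their resampled standard errors — the bootstrap-t recipe,
    which keeps the type-I error close to nominal at small n.
    ``statistic="mean"`` compares raw mean differences instead.

    ``tails`` is ``two``, ``greater``/``one`` (observed statistic in the
    positive direction) or ``less``.  The 95% CI is the percentile interval
    of the bootstrap distribution of the observed mean difference (no null
    shift).  ``observed`` is always the raw mean difference in data units.
    Deterministic for a fixed seed.
    """
    if statistic not in ("studentized", "mean"):
        raise ValueError(f"invalid statistic {statistic!r}")
    a = np.asarray(a, dtype=float)
    if a.size == 0:
        raise ValueError("empty sample")
    if n_resamples < 1000:
        warnings.warn("fewer than 1000 resamples: p-value is unstable",
                      stacklevel=2)
    rng = np.random.default_rng(seed)

    if kind == "paired":
        b = np.asarray(b, dtype=float)
        if b.shape != a.shape:
            raise ValueError("paired samples must have equal length")
        res = bootstrap_test(
            a - b, kind="one_sample", null_value=null_value, tails=tails,
            n_resamples=n_resamples, seed=seed, statistic=statistic,
        )
        return dataclasses.replace(res, kind="paired")

    if kind == "one_sample":
        observed = float(a.mean() - null_value)
        if np.ptp(a) == 0:  # zero variance: degenerate exact answer
            p = 1.0 if observed == 0 else 0.0
            c = float(a.mean())
            return BootstrapResult(p, n_resamples, tails, observed,
                                   (c, c), seed, kind)
        shifted = a - a.mean() + null_value
        if statistic == "studentized":
            means, ses = _resample_mean_se(rng, shifted, n_resamples)
            with np.errstate(divide="ignore", invalid="ignore"):
                null_stats = (means - null_value) / ses
            null_stats[~np.isfinite(null_stats)] = np.inf
            obs_stat = observed / _se(a)
        else:
            null_stats = _resample_means(rng, shifted, n_resamples) - null_value
            obs_stat = observed
        p = _tail_p(null_stats, obs_stat, tails)
        ci_means = _resample_means(rng, a, min(n_resamples, 100_000))
        ci = tuple(np.percentile(ci_means, [2.5, 97.5]))
        return BootstrapResult(p, n_resamples, tails, observed, ci, seed,
                               kind)

    if kind != "two_sample":
        raise ValueError(f"invalid kind {kind!r}")
    b = np.asarray(b, dtype=float)
    if b.size == 0:
        raise ValueError("empty sample")
    observed = float(a.mean() - b.mean())
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        p = 1.0 if observed == 0 else 0.0
        return BootstrapResult(p, n_resamples, tails, observed,
                               (observed, observed), seed, kind)
    obs_stat = observed
    if method == "recenter":
        pooled = np.concatenate([a, b]).mean()
        a0 = a - a.mean() + pooled
        b0 = b - b.mean() + pooled
        if statistic == "studentized":
            ma, sa = _resample_mean_se(rng, a0, n_resamples)
            mb, sb = _resample_mean_se(rng, b0, n_resamples)
            with np.errstate(divide="ignore", invalid="ignore"):
                null_stats = (ma - mb) / np.sqrt(sa**2 + sb**2)
            null_stats[~np.isfinite(null_stats)] = np.inf
            obs_stat = observed / math.sqrt(_se(a) ** 2 + _se(b) ** 2)
        else:
            null_stats = _resample_means(rng, a0, n_resamples) - (
                _resample_means(rng, b0, n_resamples)
            )
    elif method == "permutation":
        # label permutation is exact under exchangeability; the raw mean
        # difference is used regardless of `statistic`
        pool = np.concatenate([a, b])
        n = a.size
        null_stats = np.empty(n_resamples)
        chunk = max(1, _CHUNK_DRAWS // pool.size)
        done = 0
        while done < n_resamples:
            m = min(chunk, n_resamples - done)
            perm = rng.permuted(
                np.broadcast_to(pool, (m, pool.size)).copy(), axis=1
            )
            null_stats[done : done + m] = (
                perm[:, :n].mean(axis=1) - perm[:, n:].mean(axis=1)
            )
            done += m
    else:
        raise ValueError(f"invalid method {method!r}")
    p = _tail_p(null_stats, obs_stat, tails)
    n_ci = min(n_resamples, 100_000)
    ci_stats = _resample_means(rng, a, n_ci) - _resample_means(rng, b, n_ci)
    ci = tuple(np.percentile(ci_stats, [2.5, 97.5]))
    return BootstrapResult(p, n_resamples, tails, observed, ci, seed, kind)


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    _, adjusted, _, _ = multipletests(p, method="holm")
    return adjusted


def common_language_effect(
    a, b, seed: int | None = None, max_exact: int = 10_000_000
) -> float:
    """Common-language effect size: percentage of (x in a, y in b) pairs
    with x > y, counting ties as half.

    Exact pairwise enumeration when ``len(a) * len(b) <= max_exact``,
    otherwise a seeded Monte Carlo estimate over ``max_exact`` pairs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    if a.size * b.size <= max_exact:
        wins = (a[:, None] > b[None, :]).sum()
        ties = (a[:, None] == b[None, :]).sum()
        theta = (wins + 0.5 * ties) / (a.size * b.size)
    else:
        rng = np.random.default_rng(seed)
        ia = rng.integers(0, a.size, size=max_exact)
        ib = rng.integers(0, b.size, size=max_exact)
        x, y = a[ia], b[ib]
        theta = float(np.mean((x > y) + 0.5 * (x == y)))
    return float(100.0 * theta)


def percentile_ci(
    sample,
    level: float = 95.0,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> tuple:
    """Percentile bootstrap confidence interval for the mean."""
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    rng = np.random.default_rng(seed)
    means = _resample_means(rng, x, n_boot)
    half = (100.0 - level) / 2.0
    lo, hi = np.percentile(means, [half, 100.0 - half])
    return (float(lo), float(hi))
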