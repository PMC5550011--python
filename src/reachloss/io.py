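"""Trial-log I/O, run configuration, and the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis
from .aims import MotorNoise, aim_max_hits_mode, aim_max_hits_width, aim_min_sq_error
from .distributions import builtin_distribution, flip_values
from .fitting import condition_averages, fit_bayes_model
from .simulate import TRIAL_COLUMNS, simulate_cohort
from .stats import bootstrap_test, common_language_effect, holm_bonferroni

__all__ = [
    "ValidationError",
    "read_trial_log",
    "write_trial_log",
    "run_pipeline",
]

log = logging.getLogger("reachloss")

_CONSISTENCY_TOL = 1e-6


class ValidationError(ValueError):
    """A trial log violated the schema or its internal consistency."""


def write_trial_log(records: pd.DataFrame, path) -> None:
    """Write a trial log as CSV (full float precision, schema order)."""
    missing = [c for c in TRIAL_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    records[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trial_log(path) -> pd.DataFrame:
    """Read and validate a trial-log CSV.

    Columns may appear in any order (parsed by header).  Validates a
    monotone 1-based trial index and the exact-bookkeeping identity
    ``cursor_x_mm == hand_x_mm + shift_mm`` (tolerance 1e-6), naming the
    first offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df = df[TRIAL_COLUMNS]
    trials = df["trial"].to_numpy()
    if np.any(np.diff(trials) <= 0):
        row = int(np.flatnonzero(np.diff(trials) <= 0)[0]) + 2
        raise ValidationError(f"{path}: non-monotone trial index at row {row}")
    resid = np.abs(
        df["cursor_x_mm"] - (df["hand_x_mm"] + df["shift_mm"])
    ).to_numpy()
    bad = np.flatnonzero(resid > _CONSISTENCY_TOL)
    if bad.size:
        raise ValidationError(
            f"{path}: cursor_x_mm != hand_x_mm + shift_mm at row "
            f"{int(bad[0]) + 2}"
        )
    df["hit"] = df["hit"].astype(bool)
    df["reward"] = df["reward"].astype(bool)
    return df


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _analyze_participant(records: pd.DataFrame, last_n: int) -> dict:
    return {
        "asymptote_mm": analysis.asymptote_mean(records, last_n=last_n),
        "variability_mm": analysis.movement_variability(records,
                                                        last_n=last_n),
    }


def run_pipeline(config: dict, out_dir) -> Path:
    """Run simulate -> analyze -> fit (experiment 1) or
    simulate -> analyze -> aims + stats (experiment 2).

    Writes all artifacts plus a manifest (software version, config hash,
    every derived seed) under ``out_dir`` and returns that path.
    Re-running with an identical config reproduces identical outputs.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    experiment = int(config["experiment"])

    cohort_dir = out / "trial_logs"
    manifest = simulate_cohort(config, cohort_dir)
    log.info("simulate: %d participants (%.1fs)",
             len(manifest["participants"]), time.perf_counter() - t0)

    last_n = int(config.get("last_n", 1000 if experiment == 1 else 400))
    summaries = []
    fits = []
    for entry in manifest["participants"]:
        records = read_trial_log(cohort_dir / entry["file"])
        summary = {"participant_id": entry["id"], "group": entry["group"],
                   "skew": entry["skew"]}
        summary.update(_analyze_participant(records, last_n))
        if experiment == 2 and entry["skew"] == "left":
            # mirror left-skew data onto the right-skew frame
            summary["asymptote_mm"] = flip_values(
                summary["asymptote_mm"], 0.0
            )
        summaries.append(summary)
        if experiment == 1:
            prior = builtin_distribution(
                f"exp1_{'SR' if entry['skew'] == 'right' else 'SL'}"
            )
            table = condition_averages(records, last_n=last_n)
            fit = fit_bayes_model(table, prior)
            fits.append(
                {"participant_id": entry["id"], "group": entry["group"],
                 "alpha_opt": fit.alpha_opt, **{
                     f"sigma_{c}": v for c, v in fit.sigma_opt.items()
                 },
                 "objective": fit.objective}
            )
    summary_df = pd.DataFrame(summaries)
    summary_df.to_csv(out / "participant_summary.csv", index=False)
    log.info("analyze: %d summaries (%.1fs)", len(summaries),
             time.perf_counter() - t0)

    if experiment == 1:
        pd.DataFrame(fits).to_csv(out / "fit_summary.csv", index=False)
    else:
        _exp2_reports(config, summary_df, out)

    run_manifest = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "config": config,
        "seeds": [p["seed"] for p in manifest["participants"]],
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=1, sort_keys=True)
    log.info("pipeline done (%.1fs)", time.perf_counter() - t0)
    return out


def _exp2_reports(config: dict, summary: pd.DataFrame, out: Path) -> None:
    """Aims report plus group-comparison bootstrap statistics."""
    d = builtin_distribution("exp2_SR")
    aims_report = {}
    for spec in config["groups"]:
        noise = MotorNoise(float(spec.get("motor_sd", 2.0)))
        aims_report[spec["name"]] = {
            "sigma_mv": noise.sigma_mv,
            "aim_min_sq_error_mm": aim_min_sq_error(d, noise).aim_mm,
            "aim_max_hits_mode_mm": aim_max_hits_mode(d, noise).aim_mm,
            "aim_max_hits_width_mm": aim_max_hits_width(d, noise).aim_mm,
        }
    with open(out / "aims_report.json", "w") as fh:
        json.dump(aims_report, fh, indent=1, sort_keys=True)

    groups = {g: sub["asymptote_mm"].to_numpy()
              for g, sub in summary.groupby("group")}
    names = sorted(groups)
    seed = int(config.get("master_seed", 0)) % (2**31)
    n_res = int(config.get("n_resamples", 100_000))
    comparisons = []
    for i, ga in enumerate(names):
        for gb in names[i + 1:]:
            res = bootstrap_test(groups[ga], groups[gb], kind="two_sample",
                                 tails="two", n_resamples=n_res, seed=seed)
            comparisons.append(
                {"a": ga, "b": gb, "p_raw": res.p_value,
                 "observed_diff_mm": res.observed,
                 "ci_95": list(res.ci_95),
                 "theta_hat_pct": common_language_effect(groups[ga],
                                                         groups[gb])}
            )
    adjusted = holm_bonferroni([c["p_raw"] for c in comparisons])
    for c, p in zip(comparisons, adjusted):
        c["p_holm"] = float(p)
    with open(out / "stats_report.json", "w") as fh:
        json.dump({"comparisons": comparisons}, fh, indent=1, sort_keys=True)
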