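"""Condition averaging and four-parameter observer-model recovery."""

import numpy as np
import pandas as pd
import pytest

import reachloss as rl
from reachloss.distributions import EXP1_CUES
from reachloss.fitting import FIT_CUES, FitOptions, _comp_surface


def table_from_surface(prior, alpha, sigmas):
    """Noiseless condition table straight from the policy surface."""
    pred = _comp_surface(prior, alpha, np.asarray(sigmas, dtype=float))
    rows = [
        {"shift_mm": float(s), "cue": c, "comp_mean": float(pred[i, j]),
         "n_trials": 50}
        for j, c in enumerate(EXP1_CUES)
        for i, s in enumerate(prior.support)
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def noisy_log(exp1_sr):
    p = rl.SimParticipant(id="f1", group="Error_SR", alpha=2.0,
                          motor_sd=2.0, seed=21)
    return rl.simulate_exp1_participant(p, exp1_sr, n_trials=2000)


class TestConditionAverages:
    def test_full_design_yields_28_cells(self, noisy_log):
        table = rl.condition_averages(noisy_log, last_n=1000)
        assert len(table) == 28
        assert set(table["cue"]) == set(EXP1_CUES)

    def test_constant_series_gives_constant_cells(self, exp1_sr):
        p = rl.SimParticipant(
            id="c", group="Error_SR",
            sigma_sensed={c: np.inf for c in FIT_CUES}, motor_sd=0.0, seed=2,
        )
        rec = rl.simulate_exp1_participant(p, exp1_sr, n_trials=600)
        table = rl.condition_averages(rec, last_n=600)
        assert np.allclose(table["comp_mean"], -10.0, atol=1e-6)

    def test_matches_independent_groupby_oracle(self, noisy_log):
        table = rl.condition_averages(noisy_log, last_n=1000)
        tail = noisy_log.sort_values("trial").iloc[-1000:]
        for _, row in table.iterrows():
            sel = tail[(tail["shift_mm"] == row["shift_mm"])
                       & (tail["cue"] == row["cue"])]
            assert row["comp_mean"] == pytest.approx(
                sel["hand_x_mm"].mean(), rel=1e-12
            )
            assert row["n_trials"] == len(sel)

    def test_empty_cell_raises_and_names_cells(self, noisy_log):
        few = noisy_log.iloc[:40]
        with pytest.raises(ValueError, match="empty condition cells"):
            rl.condition_averages(few, last_n=40)

    def test_last_n_larger_than_log_rejected(self, noisy_log):
        with pytest.raises(ValueError):
            rl.condition_averages(noisy_log, last_n=5000)


class TestFitWeights:
    def test_modal_weight_and_column_sums(self, exp1_sr):
        w = rl.fit_weights(exp1_sr)
        for cue in EXP1_CUES:
            col = w[w["cue"] == cue]
            assert col["weight"].sum() == pytest.approx(1.0)
            modal = col[col["shift_mm"] == 0.0]["weight"].iloc[0]
            assert modal == pytest.approx(9 / 21)

    def test_uniform_prior_gives_uniform_weights(self):
        d = rl.ShiftDistribution(np.arange(7.0), np.full(7, 1 / 7))
        w = rl.fit_weights(d)
        assert np.allclose(w["weight"], 1 / 7)


class TestBayesModelFit:
    def test_noiseless_round_trip_alpha2(self, exp1_sr):
        truth = (2.0, (1.0, 15.0, 30.0))
        table = table_from_surface(exp1_sr, *truth)
        fit = rl.fit_bayes_model(table, exp1_sr)
        assert fit.converged
        assert fit.alpha_opt == pytest.approx(2.0, rel=0.01)
        for c, t in zip(FIT_CUES, truth[1]):
            assert fit.sigma_opt[c] == pytest.approx(t, rel=0.01)

    def test_noiseless_round_trip_alpha1(self, exp1_sr):
        table = table_from_surface(exp1_sr, 1.0, (5.0, 15.0, 30.0))
        fit = rl.fit_bayes_model(table, exp1_sr)
        assert abs(fit.alpha_opt - 1.0) < 0.05

    def test_objective_at_optimum_beats_truth(self, exp1_sr, noisy_log):
        table = rl.condition_averages(noisy_log, last_n=1000)
        fit = rl.fit_bayes_model(table, exp1_sr)

        def objective(alpha, sigmas):
            pred = _comp_surface(exp1_sr, alpha, np.asarray(sigmas))
            data = table.pivot(index="shift_mm", columns="cue",
                               values="comp_mean")[list(EXP1_CUES)]
            w = np.tile(exp1_sr.probs[:, None], (1, 4))
            return float(np.sum(w * np.abs(data.to_numpy() - pred)))

        at_truth = objective(2.0, (1.0, 15.0, 30.0))
        assert fit.objective <= at_truth + 1e-6

    def test_recovery_with_motor_noise(self, exp1_sr):
        # generating alpha recovered to ~0.1 despite 2 mm execution noise
        errs = []
        for seed in (31, 32, 33):
            p = rl.SimParticipant(id=f"r{seed}", group="Error_SR",
                                  alpha=2.0, motor_sd=2.0, seed=seed)
            rec = rl.simulate_exp1_participant(p, exp1_sr, 2000)
            fit = rl.fit_bayes_model(rl.condition_averages(rec, 1000),
                                     exp1_sr)
            errs.append(fit.alpha_opt - 2.0)
        assert abs(np.median(errs)) < 0.1

    def test_flip_invariance_of_alpha(self, exp1_sr, exp1_sl):
        # fitting mirrored left-skew data against the right-skew prior
        # must recover the same loss exponent
        truth = (1.6, (4.0, 15.0, 30.0))
        sl_table = table_from_surface(exp1_sl, *truth)
        flipped = sl_table.assign(
            shift_mm=rl.flip_values(sl_table["shift_mm"].to_numpy(), 10.0),
            comp_mean=-20.0 - sl_table["comp_mean"].to_numpy(),
        )
        fit_sr = rl.fit_bayes_model(
            table_from_surface(exp1_sr, *truth), exp1_sr
        )
        fit_flip = rl.fit_bayes_model(flipped, exp1_sr)
        assert abs(fit_sr.alpha_opt - fit_flip.alpha_opt) < 0.02

    def test_incomplete_table_rejected(self, exp1_sr):
        table = table_from_surface(exp1_sr, 2.0, (1.0, 15.0, 30.0))
        with pytest.raises(ValueError):
            rl.fit_bayes_model(table.iloc[:-1], exp1_sr)


class TestPredictions:
    def test_withheld_column_constant_and_round_trip(self, exp1_sr):
        table = table_from_surface(exp1_sr, 2.0, (1.0, 15.0, 30.0))
        fit = rl.fit_bayes_model(table, exp1_sr)
        pred = rl.predict_from_fit(fit, exp1_sr)
        none_col = pred[pred["cue"] == "none"]["comp_pred"]
        assert np.allclose(none_col, none_col.iloc[0])
        merged = table.merge(pred, on=["shift_mm", "cue"])
        assert np.max(np.abs(merged["comp_mean"] - merged["comp_pred"])) < 0.05

    def test_variance_explained_is_one_on_noiseless_data(self, exp1_sr):
        table = table_from_surface(exp1_sr, 2.0, (1.0, 15.0, 30.0))
        fit = rl.fit_bayes_model(table, exp1_sr)
        r2 = rl.variance_explained(table, rl.predict_from_fit(fit, exp1_sr))
        assert r2 == pytest.approx(1.0, abs=1e-6)


class TestLinearFit:
    def test_full_compensation_line(self, exp1_sr):
        p = rl.SimParticipant(
            id="l", group="Error_SR",
            sigma_sensed={c: 0.0 for c in FIT_CUES}, motor_sd=0.0, seed=5,
        )
        rec = rl.simulate_exp1_participant(p, exp1_sr, 800)
        lines = rl.linear_condition_fit(rec, last_n=800)
        dot = lines[lines["cue"] == "dot"].iloc[0]
        assert dot["slope"] == pytest.approx(-1.0, abs=1e-6)
        assert dot["intercept"] == pytest.approx(0.0, abs=1e-6)

    def test_withheld_feedback_line_is_flat_at_prior_mean(self, exp1_sr):
        p = rl.SimParticipant(
            id="l2", group="Error_SR",
            sigma_sensed={c: np.inf for c in FIT_CUES}, motor_sd=0.0, seed=6,
        )
        rec = rl.simulate_exp1_participant(p, exp1_sr, 800)
        lines = rl.linear_condition_fit(rec, last_n=800)
        for _, row in lines.iterrows():
            assert row["slope"] == pytest.approx(0.0, abs=1e-6)
            assert row["intercept"] == pytest.approx(-10.0, abs=1e-6)

    def test_matches_closed_form_normal_equations(self, exp1_sr):
        p = rl.SimParticipant(id="l3", group="Error_SR", motor_sd=2.0,
                              seed=8)
        rec = rl.simulate_exp1_participant(p, exp1_sr, 1200)
        lines = rl.linear_condition_fit(rec, last_n=1000)
        table = rl.condition_averages(rec, last_n=1000)
        for _, row in lines.iterrows():
            sub = table[table["cue"] == row["cue"]]
            x = sub["shift_mm"].to_numpy()
            y = sub["comp_mean"].to_numpy()
            sxx = ((x - x.mean()) ** 2).sum()
            slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
            intercept = y.mean() - slope * x.mean()
            assert row["slope"] == pytest.approx(slope, rel=1e-9)
            assert row["intercept"] == pytest.approx(intercept, rel=1e-9)
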