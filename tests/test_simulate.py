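"""Tests for the game engine and the synthetic signal generator."""

import numpy as np
import pandas as pd
import pytest

import foxrabbit as fr
from foxrabbit.model import ChoiceParams

from conftest import EXP1_PARAMS, uniform_cohort


def binomial_band(p, n, k=4.0):
    return k * np.sqrt(p * (1 - p) / n)


class TestSimulatedOpponent:
    def test_degenerate_rates(self):
        rng = np.random.default_rng(0)
        constant = fr.simulate_opponent(0.0, 50, rng)
        assert np.all(constant == constant[0])
        alternating = fr.simulate_opponent(1.0, 50, rng)
        assert np.all(np.abs(np.diff(alternating)) == 1)

    def test_empirical_switch_rate(self):
        """8,000 trials at p=0.8: empirical rate within 4 binomial SEs."""
        seq = fr.simulate_opponent(0.8, 8000, np.random.default_rng(42))
        rate = np.mean(np.diff(seq) != 0)
        assert abs(rate - 0.8) < binomial_band(0.8, 7999)

    def test_bad_arguments(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="n_trials"):
            fr.simulate_opponent(0.5, 0, rng)
        with pytest.raises(ValueError, match="p_os"):
            fr.simulate_opponent(1.2, 10, rng)


class TestSession:
    def test_zero_params_switch_rate_is_half(self):
        cfg = fr.SessionConfig(
            player_params=ChoiceParams(0, 0, 0, 0), error_rate=0.0, rt_model=None
        )
        s = fr.simulate_session(cfg, 9)
        sw = s["player_switch"].dropna()
        assert abs(sw.mean() - 0.5) < binomial_band(0.5, len(sw))

    def test_probability_matching_conditional_rates(self):
        """ms=1 vs a p=0.8 opponent: post-win switch rate ~0.8, post-loss ~0.2
        (reversed-label symmetry of the model)."""
        cfg = fr.SessionConfig(
            n_blocks=40, opponent_rates=[0.8], player_params=ChoiceParams(1, 0, 0, 0),
            error_rate=0.0, rt_model=None,
        )
        s = fr.simulate_session(cfg, 13)
        t = fr.behavior.add_previous_feedback(s)
        t = t[t["wl"].notna()]
        for wl, expected in ((1.0, 0.8), (-1.0, 0.2)):
            sub = t[t["wl"] == wl]["player_switch"]
            assert abs(sub.mean() - expected) < binomial_band(expected, len(sub))

    def test_zero_sum_bookkeeping(self):
        """Non-error trials: fox wins exactly when rules match; errors lose;
        wins + losses = trial count; first-trial switches missing."""
        s = fr.simulate_session(fr.SessionConfig(error_rate=0.15), 21)
        assert s["outcome"].isin(["win", "loss"]).all()
        clean = s[s["action_error"] == 0]
        match = clean["player_rule"] == clean["opponent_rule"]
        should_win = np.where(clean["role"] == "fox", match, ~match)
        assert np.array_equal(should_win, clean["outcome"] == "win")
        assert (s.loc[s["action_error"] == 1, "outcome"] == "loss").all()
        assert s.loc[s["trial_in_block"] == 1, "player_switch"].isna().all()
        assert s["player_switch"].notna().sum() == len(s) - s["block"].nunique()

    def test_switch_indicators_follow_rules(self):
        s = fr.simulate_session(fr.SessionConfig(), 2)
        for col, rules in (("player_switch", "player_rule"), ("opponent_switch", "opponent_rule")):
            got = s[col].to_numpy(dtype=float)
            for b, sub in s.groupby("block"):
                r = sub[rules].to_numpy()
                expected = (r[1:] != r[:-1]).astype(float)
                np.testing.assert_array_equal(got[sub.index[1:]], expected)

    def test_seed_determinism(self):
        a, pa = fr.simulate_cohort(3, rng=123)
        b, pb = fr.simulate_cohort(3, rng=123)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(pa, pb)

    def test_opponent_choices_independent_of_player(self):
        """Permutation test at alpha=0.01: the opponent's switch at t carries
        no information about the player's switch at t-1."""
        cfg = fr.SessionConfig(n_blocks=40, opponent_rates=[0.5],
                               error_rate=0.0, rt_model=None)
        s = fr.simulate_session(cfg, 17)
        rng = np.random.default_rng(18)
        stats = []
        obs = None
        for b, sub in s.groupby("block"):
            o = sub["opponent_switch"].to_numpy(dtype=float)[2:]
            p = sub["player_switch"].to_numpy(dtype=float)[1:-1]
            stats.append((o, p))
        o = np.concatenate([x for x, _ in stats])
        p = np.concatenate([x for _, x in stats])
        obs = abs(np.corrcoef(o, p)[0, 1])
        null = np.array([
            abs(np.corrcoef(o, rng.permutation(p))[0, 1]) for _ in range(500)
        ])
        assert (null >= obs).mean() > 0.01

    def test_simple_mode_has_no_errors_and_updown_labels(self):
        cfg = fr.SessionConfig(mode="simple", error_rate=0.5)
        s = fr.simulate_session(cfg, 4)
        assert set(s["player_rule"]) <= {"up", "down"}
        assert (s["action_error"] == 0).all()

    def test_random_feedback_decouples_outcome_from_match(self):
        cfg = fr.SessionConfig(random_feedback=True, error_rate=0.0,
                               n_blocks=20, rt_model=None)
        s = fr.simulate_session(cfg, 31)
        match = (s["player_rule"] == s["opponent_rule"]).to_numpy()
        win = (s["outcome"] == "win").to_numpy()
        # win rate ~0.5 and independent of the rule match
        assert abs(win.mean() - 0.5) < binomial_band(0.5, len(s))
        assert abs(win[match].mean() - win[~match].mean()) < 4 * np.sqrt(
            0.25 / match.sum() + 0.25 / (~match).sum()
        )

    def test_config_validation(self):
        with pytest.raises(ValueError, match="trials_per_block"):
            fr.SessionConfig(trials_per_block=1)
        with pytest.raises(ValueError, match="opponent_rates"):
            fr.SessionConfig(opponent_rates=[0.0, 0.5])


class TestCohort:
    def test_degenerate_distribution(self):
        trials, subjects = uniform_cohort(3, EXP1_PARAMS, 1, n_blocks=2)
        assert np.allclose(subjects[["ms", "sm", "pe", "ss"]].to_numpy(),
                           EXP1_PARAMS.as_array())

    def test_invalid_size(self):
        with pytest.raises(ValueError, match="n_subjects"):
            fr.simulate_cohort(0)

    def test_generator_estimator_closure(self, cohort12):
        """Cohort-mean trialwise estimates sit near the cohort-mean truths."""
        trials, subjects = cohort12
        rows = []
        for sid, sub in trials.groupby("subject_id"):
            res = fr.fit_trialwise(sub)
            rows.append([res.params.ms, res.params.sm])
        est = np.mean(rows, axis=0)
        truth = subjects[["ms", "sm"]].mean().to_numpy()
        se = np.std(rows, axis=0, ddof=1) / np.sqrt(len(rows))
        assert np.all(np.abs(est - truth) < 3.5 * se + 0.02)


class TestDyad:
    def test_zero_sum_mirror(self):
        d = fr.simulate_dyad(EXP1_PARAMS, EXP1_PARAMS, n_blocks=3, rng=6)
        fox = d[d["role"] == "fox"].reset_index(drop=True)
        rab = d[d["role"] == "rabbit"].reset_index(drop=True)
        assert np.array_equal(fox["outcome"] == "win", rab["outcome"] == "loss")
        assert np.array_equal(fox["player_rule"], rab["opponent_rule"])

    def test_random_players_split_evenly(self):
        """Memory-free play on both sides: switch rates and the fox win rate
        all sit at the analytic 0.5 (a coin flipper is unexploitable)."""
        zero = ChoiceParams(0, 0, 0, 0)
        d = fr.simulate_dyad(zero, zero, n_blocks=12, rng=8)
        fox = d[d["role"] == "fox"]
        n = len(fox)
        assert abs((fox["outcome"] == "win").mean() - 0.5) < binomial_band(0.5, n)
        for role in ("fox", "rabbit"):
            sw = d[d["role"] == role]["player_switch"].dropna()
            assert abs(sw.mean() - 0.5) < binomial_band(0.5, len(sw))

    def test_model_player_exploits_perseverator(self):
        """A model-based fox beats a rabbit with a strong perseveration bias."""
        fox = ChoiceParams(1, 0, 0, 0)
        rabbit = ChoiceParams(0, 0, 1.5, 0)  # repeats ~82% of trials
        d = fr.simulate_dyad(fox, rabbit, n_blocks=12, rng=9)
        wins = (d[d["role"] == "fox"]["outcome"] == "win").mean()
        assert wins - 0.5 > binomial_band(0.5, 12 * 80) / 2


class TestSignalSpec:
    def test_grid_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            fr.SignalSpec(times_ms=np.array([0.0, 10.0, 5.0]))
        with pytest.raises(ValueError, match="fixed step"):
            fr.SignalSpec(times_ms=np.array([0.0, 10.0, 30.0]))
        with pytest.raises(ValueError, match="noise_sd"):
            fr.SignalSpec(noise_sd=0.0)

    def test_loss_curve_attenuates_to_zero(self):
        spec = fr.SignalSpec()
        loss = spec.beta_curve("A", -1)
        win = spec.beta_curve("A", 1)
        late = spec.times_ms >= spec.loss_attenuation_ms + spec.loss_ramp_ms
        assert np.allclose(loss[late], 0.0)
        early = (spec.times_ms > 0) & (spec.times_ms <= spec.loss_attenuation_ms)
        assert np.allclose(loss[early], win[early])

    def test_epoch_matrix_shape_validation(self):
        with pytest.raises(ValueError, match="shape"):
            fr.EpochMatrix(
                times_ms=np.arange(0, 100, 10.0),
                values=np.zeros((3, 5)),
                design=pd.DataFrame({"wl": [1, 1, -1]}),
            )


class TestNeuralEpochs:
    def test_rows_match_retained_trials(self, neural_cohort):
        sessions, epochs, spec = neural_cohort
        for sid, em in epochs.items():
            retained = fr.build_context_design(sessions[sid]).dropna(
                subset=["B", "C", "wl"]
            )
            assert em.n_trials == len(retained)
            assert em.values.shape[1] == spec.times_ms.size

    def test_linearity_of_embedded_betas(self):
        """Doubling the embedded amplitudes doubles the recovered coefficients."""
        cfg = fr.SessionConfig(opponent_rates=(0.25, 0.5, 0.75), n_blocks=6)
        session = fr.simulate_session(cfg, 55)
        session["subject_id"] = "s000"
        recovered = {}
        for scale in (1.0, 2.0):
            spec = fr.SignalSpec(
                amplitudes={"A": 0.5 * scale, "B": 0.4 * scale,
                            "C": 0.2 * scale, "AB": -0.4 * scale},
                noise_sd=0.05, subject_coefficient_sd=0.0,
            )
            em = fr.simulate_neural_epochs(session, spec, np.random.default_rng(5))
            des = em.design
            a = des["A_raw"].to_numpy(float)
            X = np.column_stack([
                np.ones(len(des)),
                (a - a.mean()) / a.std(),
                des["B"], des["C"],
                ((a - a.mean()) / a.std()) * des["B"],
            ])
            peak = np.argmin(np.abs(spec.times_ms - spec.peak_ms))
            win = des["wl"].to_numpy() == 1
            beta, *_ = np.linalg.lstsq(X[win], em.values[win, peak], rcond=None)
            recovered[scale] = beta[1]
        assert recovered[2.0] / recovered[1.0] == pytest.approx(2.0, abs=0.1)

    def test_grid_mismatch_rejected(self, neural_cohort):
        sessions, epochs, spec = neural_cohort
        em = next(iter(epochs.values()))
        with pytest.raises(ValueError, match="shape"):
            fr.EpochMatrix(times_ms=em.times_ms[:-5], values=em.values, design=em.design)
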