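"""Unit and property tests for the four-parameter choice model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import foxrabbit as fr
from foxrabbit.model import ChoiceParams, DEFAULT_INIT

from conftest import EXP1_PARAMS, RATES5


finite_param = st.floats(-1.5, 1.5)
rate = st.floats(0.02, 0.98)
wl_values = st.sampled_from([1, -1])


class TestSwitchLogit:
    @pytest.mark.parametrize(
        "params, p_os, wl, expected",
        [
            # all-zero parameters: flat coin regardless of context
            ((0, 0, 0, 0), 0.3, 1, 0.0),
            ((0, 0, 0, 0), 0.8, -1, 0.0),
            # probability matching: post-win logit equals the opponent log-odds
            ((1, 0, 0, 0), 0.8, 1, np.log(4.0)),
            # ms + sm = 0 makes the post-loss logit flat
            ((0.5, -0.5, 0, 0), 0.2, -1, 0.0),
            # hand-evaluated: ln(0.25)*0.48 - 0.21 - 0.20
            ((0.48, -0.38, 0.21, 0.20), 0.2, 1, np.log(0.25) * 0.48 - 0.41),
        ],
    )
    def test_anchor_values(self, params, p_os, wl, expected):
        got = fr.switch_logit(ChoiceParams(*params), p_os, wl)
        assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.2])
    def test_boundary_rate_rejected(self, bad):
        with pytest.raises(ValueError, match=str(bad)):
            fr.switch_logit(EXP1_PARAMS, bad, 1)

    def test_invalid_feedback_code_rejected(self):
        with pytest.raises(ValueError, match="wl"):
            fr.switch_logit(EXP1_PARAMS, 0.5, 0)

    def test_nonfinite_parameter_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            ChoiceParams(np.nan, 0, 0, 0)

    def test_derived_slopes(self):
        p = EXP1_PARAMS
        assert p.post_win_slope == p.ms
        assert p.post_loss_slope == pytest.approx(p.ms + p.sm)


class TestSwitchProbability:
    @pytest.mark.parametrize("p_os", [0.8, 0.35])
    def test_probability_matching_identity(self, p_os):
        """ms=1 reproduces the opponent's switch rate after wins."""
        assert fr.switch_probability(ChoiceParams(1, 0, 0, 0), p_os, 1) == pytest.approx(p_os)

    def test_all_zero_is_fair_coin(self):
        probs = fr.switch_probability(ChoiceParams(0, 0, 0, 0), np.array(RATES5), -1)
        assert np.allclose(probs, 0.5)

    @given(ms=finite_param, sm=finite_param, p=rate)
    @settings(max_examples=50, deadline=None)
    def test_log_odds_antisymmetry(self, ms, sm, p):
        """Without pe/ss biases, P(p) + P(1-p) = 1 after wins."""
        params = ChoiceParams(ms, sm, 0, 0)
        total = fr.switch_probability(params, p, 1) + fr.switch_probability(params, 1 - p, 1)
        assert total == pytest.approx(1.0, abs=1e-12)

    @given(ms=finite_param, sm=finite_param, pe=finite_param, ss=finite_param,
           p=rate, wl=wl_values)
    @settings(max_examples=200, deadline=None)
    def test_logistic_identity(self, ms, sm, pe, ss, p, wl):
        params = ChoiceParams(ms, sm, pe, ss)
        logit = fr.switch_logit(params, p, wl)
        assert fr.switch_probability(params, p, wl) == pytest.approx(
            1.0 / (1.0 + np.exp(-logit)), abs=1e-14
        )

    @given(ms=st.floats(0.05, 1.5), pe=finite_param, ss=finite_param)
    @settings(max_examples=50, deadline=None)
    def test_monotonicity(self, ms, pe, ss):
        """Positive model strength: post-win switch probability rises in p_os;
        positive ms+sm: post-loss probability falls in p_os."""
        grid = np.linspace(0.05, 0.95, 19)
        params = ChoiceParams(ms, 0.0, pe, ss)  # ms + sm = ms > 0
        up = fr.switch_probability(params, grid, 1)
        down = fr.switch_probability(params, grid, -1)
        assert np.all(np.diff(up) > 0)
        assert np.all(np.diff(down) < 0)

    def test_suppression_limit(self):
        """sm = -ms: post-loss probability is flat at logistic(-pe + ss)."""
        params = ChoiceParams(0.7, -0.7, 0.3, 0.1)
        probs = fr.switch_probability(params, np.array(RATES5), -1)
        expected = 1.0 / (1.0 + np.exp(-(-0.3 + 0.1)))
        assert np.allclose(probs, expected)


class TestPredictConditionGrid:
    def test_all_zero_grid(self):
        grid = fr.predict_condition_grid(ChoiceParams(0, 0, 0, 0), RATES5)
        assert len(grid) == 10
        assert np.allclose(grid["switch_rate"], 0.5)

    def test_probability_matching_cells(self):
        grid = fr.predict_condition_grid(ChoiceParams(1, 0, 0, 0), [0.2, 0.5, 0.8])
        win = grid[grid["wl"] == 1].sort_values("p_os")
        assert np.allclose(win["switch_rate"], [0.2, 0.5, 0.8])

    def test_matches_per_cell_evaluation(self):
        """Each grid cell equals the direct per-cell probability (oracle)."""
        grid = fr.predict_condition_grid(EXP1_PARAMS, RATES5)
        for row in grid.itertuples():
            assert row.switch_rate == pytest.approx(
                fr.switch_probability(EXP1_PARAMS, row.p_os, row.wl)
            )

    def test_empty_rate_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            fr.predict_condition_grid(EXP1_PARAMS, [])


class TestRunningAverage:
    def test_first_trial_is_half(self):
        out = fr.running_opponent_switch_rate([np.nan, 1, 1], [1, 1, 1])
        assert out[0] == 0.5

    def test_hand_trace_prior_as_pseudo_observation(self):
        """Events {1, 0, 1} with the prior as one pseudo-observation and no
        smoothing: estimates {0.5, 0.75, 0.5} (frozen hand trace)."""
        out = fr.running_opponent_switch_rate(
            [np.nan, 1, 0, 1], [1, 1, 1, 1], smoothing=0.0
        )
        assert np.allclose(out, [0.5, 0.5, 0.75, 0.5])

    def test_all_switch_stream_stays_clipped(self):
        ev = np.ones(200)
        out = fr.running_opponent_switch_rate(ev)
        assert np.all(out < 1.0) and np.all(out > 0.0)

    def test_block_carryover(self):
        """Block n starts from block n-1's final running average."""
        ev = np.array([np.nan, 1, 1, 1, np.nan, 0])
        blocks = np.array([1, 1, 1, 1, 2, 2])
        out = fr.running_opponent_switch_rate(ev, blocks)
        # block 1's final running average includes all three switches:
        # (0.5 + 1*0.5 + 3) / (1 + 1 + 3) = 0.8 (default Laplace smoothing)
        assert out[4] == pytest.approx((0.5 + 1.0 * 0.8 + 0) / (1 + 1 + 0))

    def test_empty_input(self):
        assert fr.running_opponent_switch_rate([]).size == 0


class TestConditionAverageFit:
    def test_noise_free_inversion(self):
        """Fitting the model's own predictions recovers the parameters."""
        grid = fr.predict_condition_grid(EXP1_PARAMS, RATES5)
        res = fr.fit_condition_averages(grid, n_boot=0)
        assert np.abs(res.params.as_array() - EXP1_PARAMS.as_array()).max() < 1e-4
        assert res.r2 >= 0.9999
        assert res.converged

    def test_flat_grid_identifies_zero_model(self):
        grid = pd.DataFrame(
            [{"p_os": p, "wl": wl, "switch_rate": 0.5} for p in RATES5 for wl in (1, -1)]
        )
        res = fr.fit_condition_averages(grid, n_boot=0)
        assert np.abs(res.params.as_array()).max() < 1e-6

    def test_too_few_cells_rejected(self):
        grid = fr.predict_condition_grid(EXP1_PARAMS, [0.3])  # 2 cells < 4 params
        with pytest.raises(ValueError, match="4 distinct"):
            fr.fit_condition_averages(grid)

    def test_duplicate_cells_rejected(self):
        grid = fr.predict_condition_grid(EXP1_PARAMS, RATES5)
        dup = pd.concat([grid, grid.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="at most once"):
            fr.fit_condition_averages(dup)

    def test_bootstrap_interval_brackets_estimate(self):
        rng = np.random.default_rng(3)
        grid = fr.predict_condition_grid(EXP1_PARAMS, RATES5)
        grid["switch_rate"] = np.clip(
            grid["switch_rate"] + rng.normal(0, 0.02, len(grid)), 0, 1
        )
        res = fr.fit_condition_averages(grid, n_boot=99)
        ci = res.conf_int()
        est = res.params.as_array()
        assert np.all(ci["lo95"].to_numpy() <= est + 1e-9)
        assert np.all(ci["hi95"].to_numpy() >= est - 1e-9)
        assert np.all(np.isfinite(ci.to_numpy()))

    def test_weighted_fit_requires_counts(self):
        grid = fr.predict_condition_grid(EXP1_PARAMS, RATES5)
        with pytest.raises(ValueError, match="'n'"):
            fr.fit_condition_averages(grid, weight_by_n=True)

    def test_serializable_summary(self):
        grid = fr.predict_condition_grid(EXP1_PARAMS, RATES5)
        res = fr.fit_condition_averages(grid, n_boot=9)
        text = res.summary()
        assert "condition_LS" in text and "R^2" in text


class TestTrialwiseFit:
    def test_monte_carlo_recovery_within_3_se(self):
        """4,000 simulated trials with known programmed rates recover the
        generating parameters within 3 Wald SEs."""
        cfg = fr.SessionConfig(
            n_blocks=50, trials_per_block=80, error_rate=0.0, rt_model=None
        )
        trials = fr.simulate_session(cfg, 3)
        res = fr.fit_trialwise(trials)
        z = (res.params.as_array() - np.array([0.48, -0.38, 0.21, 0.20])) / res.bse
        assert np.abs(z).max() < 3.0
        assert res.converged

    def test_constant_context_flags_rank_deficiency(self):
        """A single block has constant p_os; post-win rows alone leave ms and
        sm confounded with the intercept structure -> flagged, not crashed."""
        cfg = fr.SessionConfig(
            n_blocks=1, trials_per_block=200, opponent_rates=[0.5],
            error_rate=0.0, rt_model=None,
        )
        trials = fr.simulate_session(cfg, 5)
        # os = logit(0.5) = 0 kills both model columns
        with pytest.warns(RuntimeWarning, match="rank"):
            res = fr.fit_trialwise(trials)
        assert res.rank_deficient
        assert not res.converged

    def test_degenerate_all_repeat_sequence_warns(self):
        trials = fr.simulate_session(
            fr.SessionConfig(n_blocks=2, opponent_rates=[0.3, 0.7],
                             error_rate=0.0, rt_model=None),
            11,
        )
        trials["player_switch"] = np.where(
            trials["trial_in_block"] == 1, np.nan, 0.0
        )
        with pytest.warns(RuntimeWarning):
            res = fr.fit_trialwise(trials)
        assert not res.converged

    def test_running_rate_input(self):
        """Dyad-style fits use the running opponent estimate without error."""
        d = fr.simulate_dyad(EXP1_PARAMS, EXP1_PARAMS, n_blocks=4, rng=2)
        fox = d[d["role"] == "fox"]
        res = fr.fit_trialwise(fox, p_os="running")
        assert res.converged
        assert np.all(np.isfinite(res.params.as_array()))

    def test_init_matches_default_protocol(self):
        assert DEFAULT_INIT == (0.5, -0.3, 0.1, 0.2)
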