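"""Behavioral pipeline for feedback-contingent choice in the fox/rabbit game.

Covers the descriptive and inferential analyses run on trial logs:

* condition-mean switch rates over the (opponent rate x post-win/post-loss)
  grid, the target of the condition-average choice-model fit;
* reversed-label slope contrasts — after recoding the opponent rate on
  post-loss trials (p becomes 1 - p), the post-win and post-loss switch-rate
  slopes are directly comparable and their difference indexes loss-contingent
  suppression of model-based choice;
* lag-history multilevel logistic regressions (choice at trial n on the
  player's and opponent's switch history at lags 1-3 plus the opponent's
  overall rate, split by and interacted with previous feedback);
* a stochasticity-vs-noise control (does the post-win/post-loss slope
  contrast survive controlling for response times and action-error rates?);
* regression of competitive success on the fitted model parameters.

Group-level logistic inference uses a two-stage summary-statistics estimator
(per-subject maximum likelihood, then random-effects inference across
subjects); linear mixed models use statsmodels MixedLM with a stepwise
fallback from random slopes to random intercepts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import ChoiceModelResults, fit_condition_averages, opponent_log_odds

__all__ = [
    "add_previous_feedback",
    "condition_switch_rates",
    "fit_subject_conditions",
    "subject_win_rates",
    "reversed_label_slopes",
    "history_regression",
    "stochasticity_vs_noise",
    "success_regression",
    "SlopeResult",
    "HistoryCoefficients",
    "RegressionSummary",
    "SuccessRegressionResult",
    "plot_condition_grid",
]


def add_previous_feedback(trials: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a ``wl`` column (+1/-1 from the previous trial's
    outcome within the same block and subject; NaN on first trials of blocks).

    Action errors were fed back as losses, so ``wl`` follows ``outcome``
    directly.
    """
    t = trials.copy()
    grp = t.groupby(["subject_id", "block"], sort=False)
    prev = grp["outcome"].shift(1)
    t["wl"] = np.where(prev.isna(), np.nan, np.where(prev.eq("win"), 1.0, -1.0))
    return t


def _usable(trials: pd.DataFrame) -> pd.DataFrame:
    t = trials if "wl" in trials.columns else add_previous_feedback(trials)
    return t[t["wl"].notna() & t["player_switch"].notna()]


def condition_switch_rates(trials: pd.DataFrame, per_subject: bool = False) -> pd.DataFrame:
    """Mean player switch rate per (programmed opponent rate, previous feedback) cell.

    First trials of blocks (no previous feedback) are excluded.  With several
    subjects and ``per_subject=False`` the grid averages the per-subject cell
    means (n = pooled trial count); empty cells are omitted with a warning.
    """
    t = _usable(trials)
    if t["opponent_rate"].isna().all():
        raise ValueError(
            "trials carry no programmed opponent rate (dyad data?); "
            "condition grids require simulated-opponent sessions"
        )
    cells = (
        t.groupby(["subject_id", "opponent_rate", "wl"], sort=True)["player_switch"]
        .agg(["mean", "size"])
        .reset_index()
    )
    if per_subject:
        out = cells.rename(
            columns={"opponent_rate": "p_os", "mean": "switch_rate", "size": "n"}
        )
        return out[["subject_id", "p_os", "wl", "switch_rate", "n"]]
    grid = (
        cells.groupby(["opponent_rate", "wl"], sort=True)
        .agg(switch_rate=("mean", "mean"), n=("size", "sum"))
        .reset_index()
        .rename(columns={"opponent_rate": "p_os"})
    )
    expected = t[["opponent_rate"]].drop_duplicates().shape[0] * 2
    if len(grid) < expected:
        warnings.warn(
            f"{expected - len(grid)} empty (p_os, wl) cells omitted from the grid",
            RuntimeWarning,
            stacklevel=2,
        )
    grid["wl"] = grid["wl"].astype(int)
    return grid


def fit_subject_conditions(trials: pd.DataFrame, n_boot: int = 0, **fit_kwargs) -> pd.DataFrame:
    """Condition-average choice-model fit per subject.

    Returns one row per subject with the four parameter estimates, R^2 and
    the convergence flag.  Bootstrap intervals are off by default (set
    ``n_boot`` for per-subject CIs).
    """
    rows = []
    for sid, sub in trials.groupby("subject_id", sort=True):
        grid = condition_switch_rates(sub)
        res = fit_condition_averages(grid, n_boot=n_boot, **fit_kwargs)
        rows.append(
            {"subject_id": sid, "ms": res.params.ms, "sm": res.params.sm,
             "pe": res.params.pe, "ss": res.params.ss, "r2": res.r2,
             "converged": res.converged}
        )
    return pd.DataFrame(rows)


def subject_win_rates(trials: pd.DataFrame) -> pd.Series:
    """Proportion of win trials per subject (errors count as losses)."""
    return trials.groupby("subject_id", sort=True)["outcome"].agg(
        lambda s: float(np.mean(s == "win"))
    )


# ---------------------------------------------------------------------------
# Mixed-model helpers


def _fit_mixedlm(endog, exog, groups, exog_re=None):
    """MixedLM with stepwise fallback: random slopes -> random intercept.

    Returns (results, structure_label).  The final random-effects structure is
    always reported so filter accounting stays auditable.
    """
    import statsmodels.api as sm

    structures = []
    if exog_re is not None:
        structures.append((exog_re, "random intercept + slope"))
    structures.append((np.ones((len(endog), 1)), "random intercept"))

    last_exc = None
    for re_mat, label in structures:
        for reml in (True, False):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = sm.MixedLM(endog, exog, groups=groups, exog_re=re_mat)
                    res = model.fit(reml=reml, maxiter=200)
                ok = np.all(np.isfinite(res.fe_params)) and np.all(
                    np.isfinite(res.bse_fe)
                )
                if ok and (res.converged or (label, reml) == ("random intercept", False)):
                    return res, label + ("" if reml else " (ML)")
            except Exception as exc:  # singular fits etc.
                last_exc = exc
                continue
    raise RuntimeError(f"mixed model failed under all structures: {last_exc}")


def _within_ols(y, X, groups):
    """Subject-fixed-effects OLS: demean within groups, then least squares.

    Returns (coef, se, residual df).  Absorbs per-subject intercepts exactly,
    which is the conditional analogue of a random-intercept model.
    """
    df = pd.DataFrame(X)
    g = pd.Series(groups)
    Xw = (df - df.groupby(g).transform("mean")).to_numpy()
    yw = (pd.Series(y) - pd.Series(y).groupby(g).transform("mean")).to_numpy()
    coef, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ coef
    dfree = len(yw) - g.nunique() - X.shape[1]
    if dfree < 1:
        raise ValueError("not enough rows for the within-subject estimator")
    s2 = float(resid @ resid) / dfree
    cov = s2 * np.linalg.pinv(Xw.T @ Xw)
    return coef, np.sqrt(np.diag(cov)), dfree


def _group_stats(coef_wide: pd.DataFrame) -> pd.DataFrame:
    """Random-effects group inference from per-subject coefficients.

    One-sample inference per column: mean, SE across subjects, z = mean/SE and
    a p-value from the t distribution with (n_subjects - 1) df.
    """
    n = len(coef_wide)
    mean = coef_wide.mean(axis=0)
    se = coef_wide.std(axis=0, ddof=1) / np.sqrt(n)
    z = mean / se
    p = 2.0 * stats.t.sf(np.abs(z), df=n - 1)
    return pd.DataFrame(
        {"coef": mean, "se": se, "z": z, "p": p, "n_subjects": n}
    ).rename_axis("term")


# ---------------------------------------------------------------------------
# Reversed-label slopes


@dataclass
class SlopeResult:
    """Per-subject and group-level reversed-label switch-rate slopes."""

    per_subject: pd.DataFrame  # subject_id, post_win_slope, post_loss_slope
    group: pd.DataFrame  # term, coef, se, stat, p
    interaction_t: float
    interaction_p: float
    df: int
    structure: str

    def summary(self) -> str:
        g = self.group.set_index("term")
        return (
            "Reversed-label slope analysis (switch rate ~ opponent rate x feedback)\n"
            f"  subjects: {len(self.per_subject)}   random effects: {self.structure}\n"
            f"  post-win slope  : {self.per_subject['post_win_slope'].mean():.3f}\n"
            f"  post-loss slope : {self.per_subject['post_loss_slope'].mean():.3f}\n"
            f"  rate x win/loss interaction: t = {self.interaction_t:.2f} "
            f"(df={self.df}, p = {self.interaction_p:.2g})\n"
            + g.to_string(float_format=lambda v: f"{v: .4f}")
        )


def invert_post_loss_labels(p_os, wl):
    """Reversed-label recoding: post-loss opponent rates map p -> 1 - p.

    An involution: applying it twice restores the original rates.
    """
    return np.where(np.asarray(wl) == 1, p_os, 1.0 - np.asarray(p_os, dtype=float))


def _reversed_cells(trials: pd.DataFrame) -> pd.DataFrame:
    cells = condition_switch_rates(trials, per_subject=True)
    if cells["p_os"].nunique() < 2:
        raise ValueError(
            "slope undefined: need at least 2 distinct opponent switch rates"
        )
    cells = cells.copy()
    cells["p_rev"] = invert_post_loss_labels(cells["p_os"], cells["wl"])
    return cells


def reversed_label_slopes(trials: pd.DataFrame, logistic_scale: bool = False) -> SlopeResult:
    """Slope contrast after inverting post-loss opponent-rate labels.

    Per subject, the mean switch rate is regressed on the (reversed) opponent
    rate separately for post-win and post-loss trials (least squares over
    condition means, proportion scale by default; ``logistic_scale`` uses the
    empirical log-odds instead).  The group-level test is a linear mixed
    model of the cell means on centered rate, the win/loss contrast and their
    interaction, with by-subject random intercepts and rate slopes (stepwise
    fallback on non-convergence).  A positive interaction means steeper
    slopes after wins, i.e. loss-contingent suppression of the model.
    """
    cells = _reversed_cells(trials)
    y = cells["switch_rate"].to_numpy(dtype=float)
    if logistic_scale:
        eps = 1.0 / (2.0 * cells["n"].to_numpy())
        y = np.log(np.clip(y, eps, 1 - eps) / (1 - np.clip(y, eps, 1 - eps)))
    cells = cells.assign(y=y)

    per_rows = []
    for sid, sub in cells.groupby("subject_id", sort=True):
        slopes = {}
        for wl, lbl in ((1, "post_win_slope"), (-1, "post_loss_slope")):
            s = sub[sub["wl"] == wl]
            if s["p_rev"].nunique() < 2:
                slopes[lbl] = np.nan
                continue
            slopes[lbl] = float(np.polyfit(s["p_rev"], s["y"], 1)[0])
        per_rows.append({"subject_id": sid, **slopes})
    per_subject = pd.DataFrame(per_rows)

    rate_c = cells["p_rev"].to_numpy() - 0.5
    wlc = cells["wl"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(rate_c), rate_c, wlc, rate_c * wlc])
    exog_re = np.column_stack([np.ones_like(rate_c), rate_c])
    res, structure = _fit_mixedlm(
        cells["y"].to_numpy(), X, cells["subject_id"].to_numpy(), exog_re
    )
    terms = ["intercept", "rate", "win_loss", "rate_x_win_loss"]
    group = pd.DataFrame(
        {"term": terms, "coef": res.fe_params, "se": res.bse_fe[: len(terms)]}
    )
    group["stat"] = group["coef"] / group["se"]
    n_sub = cells["subject_id"].nunique()
    group["p"] = 2.0 * stats.t.sf(np.abs(group["stat"]), df=n_sub - 1)

    it = group.loc[group["term"] == "rate_x_win_loss"].iloc[0]
    return SlopeResult(
        per_subject=per_subject,
        group=group,
        interaction_t=float(it["stat"]),
        interaction_p=float(it["p"]),
        df=n_sub - 1,
        structure=structure,
    )


# ---------------------------------------------------------------------------
# History regressions


@dataclass
class HistoryCoefficients:
    """Group-level standardized coefficients from the history regressions.

    ``split`` holds the per-feedback models (post-win / post-loss); ``joint``
    the single model with the win/loss contrast and its interactions with
    every history/context predictor.  ``flipped_player_lags`` lists the
    player-history predictors whose post-loss labels were reversed because
    their split-model coefficients flipped sign.
    """

    split: pd.DataFrame
    joint: pd.DataFrame
    flipped_player_lags: list = field(default_factory=list)
    reverse_labels: bool = True
    n_obs: int = 0
    n_obs_total: int = 0
    n_subjects_dropped: int = 0

    def summary(self) -> str:
        lines = [
            "History regression (switch ~ opponent rate + lag-1..%d history)"
            % (self.split["predictor"].str.extract(r"lag(\d)").astype(float).max().iloc[0]
               if len(self.split) else 0),
            f"  rows used: {self.n_obs} of {self.n_obs_total} "
            f"(first-of-block and short-history trials excluded)",
            f"  post-loss labels reversed: {self.reverse_labels}; "
            f"player-lag flips: {self.flipped_player_lags or 'none'}",
            self.joint.to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)


def _history_design(trials: pd.DataFrame, lags: int) -> pd.DataFrame:
    """Per-trial design rows with y, wl and lagged (effect-coded) history."""
    t = add_previous_feedback(trials)
    rate = t["opponent_rate"].to_numpy(dtype=float)
    if np.isnan(rate).all():
        raise ValueError("history design requires the programmed opponent rate")
    parts = []
    for (sid, blk), sub in t.groupby(["subject_id", "block"], sort=False):
        ps = sub["player_switch"].to_numpy(dtype=float)
        osw = sub["opponent_switch"].to_numpy(dtype=float)
        d = {
            "subject_id": sid,
            "block": blk,
            "y": ps,
            "wl": sub["wl"].to_numpy(dtype=float),
            "os": opponent_log_odds(sub["opponent_rate"].to_numpy(dtype=float)),
        }
        for k in range(1, lags + 1):
            d[f"opp_lag{k}"] = np.concatenate([[np.nan] * k, osw[:-k]])
            d[f"ply_lag{k}"] = np.concatenate([[np.nan] * k, ps[:-k]])
        parts.append(pd.DataFrame(d))
    des = pd.concat(parts, ignore_index=True)
    return des


def _fit_subject_logit(y, X):
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100)
    if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 50:
        raise RuntimeError("unstable subject-level logistic fit")
    return res.params


def history_regression(
    trials: pd.DataFrame, lags: int = 3, reverse_labels: bool = True
) -> HistoryCoefficients:
    """Multilevel logistic regression of choices on switch history.

    Predicts the trial-n switch/repeat choice from the opponent's overall
    switch rate (log-odds scale, z-scored) and the opponent's and player's
    lag-1..``lags`` switch decisions (effect-coded +1/-1), estimated per
    subject and aggregated with random-effects group inference.  The joint
    model adds the previous-feedback contrast and its interaction with every
    predictor (15 terms at the default three lags).

    With ``reverse_labels`` the opponent predictors are sign-flipped on
    post-loss rows so post-win and post-loss coefficient magnitudes are
    directly comparable; player-history predictors are flipped only where
    the split models show an empirical sign flip between feedback conditions.
    """
    des = _history_design(trials, lags)
    n_total = len(des)
    lag_cols = [f"{w}_lag{k}" for w in ("opp", "ply") for k in range(1, lags + 1)]
    des = des.dropna(subset=["y", "wl"] + lag_cols).reset_index(drop=True)
    n_used = len(des)

    # effect-code history, standardize the continuous rate within fitted subset
    for c in lag_cols:
        des[c] = 2.0 * des[c] - 1.0
    os_ = des["os"].to_numpy()
    des["rate"] = (os_ - os_.mean()) / os_.std() if os_.std() > 0 else 0.0

    predictors = ["rate"] + lag_cols

    def split_fit(frame, flips=()):
        rows = {1: [], -1: []}
        dropped = 0
        for sid, sub in frame.groupby("subject_id", sort=True):
            for wl in (1, -1):
                s = sub[sub["wl"] == wl]
                X = s[predictors].to_numpy().copy()
                if wl == -1:
                    for j, name in enumerate(predictors):
                        if name in flips:
                            X[:, j] = -X[:, j]
                X = np.column_stack([np.ones(len(s)), X])
                try:
                    beta = _fit_subject_logit(s["y"].to_numpy(), X)
                    rows[wl].append(
                        pd.Series(beta[1:], index=predictors, name=sid)
                    )
                except Exception:
                    dropped += 1
        out = {}
        for wl in (1, -1):
            if len(rows[wl]) < 2:
                raise ValueError("need at least 2 subjects with stable fits per condition")
            out[wl] = _group_stats(pd.DataFrame(rows[wl]))
        return out, dropped

    raw_split, raw_dropped = split_fit(des)
    flips: list = []
    if reverse_labels:
        flips = ["rate"] + [f"opp_lag{k}" for k in range(1, lags + 1)]
        for k in range(1, lags + 1):
            name = f"ply_lag{k}"
            if np.sign(raw_split[1].loc[name, "coef"]) != np.sign(
                raw_split[-1].loc[name, "coef"]
            ):
                flips.append(name)
        split_stats, dropped = split_fit(des, flips)
    else:
        split_stats, dropped = raw_split, raw_dropped
    split_frames = []
    for wl in (1, -1):
        f = split_stats[wl].reset_index().rename(columns={"term": "predictor"})
        f.insert(0, "wl", wl)
        split_frames.append(f)
    split = pd.concat(split_frames, ignore_index=True)

    # joint model: predictors + wl contrast + interactions (15 terms at lags=3)
    joint_rows = []
    for sid, sub in des.groupby("subject_id", sort=True):
        X = sub[predictors].to_numpy().copy()
        wl = sub["wl"].to_numpy()
        for j, name in enumerate(predictors):
            if name in flips:
                X[:, j] = np.where(wl == -1, -X[:, j], X[:, j])
        terms = np.column_stack(
            [np.ones(len(sub)), X, wl] + [X[:, j] * wl for j in range(X.shape[1])]
        )
        names = (
            ["intercept"] + predictors + ["win_loss"]
            + [f"win_loss_x_{p}" for p in predictors]
        )
        try:
            beta = _fit_subject_logit(sub["y"].to_numpy(), terms)
            joint_rows.append(pd.Series(beta[1:], index=names[1:], name=sid))
        except Exception:
            dropped += 1
    if len(joint_rows) < 2:
        raise ValueError("need at least 2 subjects with stable joint fits")
    joint = _group_stats(pd.DataFrame(joint_rows)).reset_index()

    flipped_players = [f for f in flips if f.startswith("ply")]
    return HistoryCoefficients(
        split=split,
        joint=joint,
        flipped_player_lags=flipped_players,
        reverse_labels=reverse_labels,
        n_obs=n_used,
        n_obs_total=n_total,
        n_subjects_dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Stochasticity vs. information-processing noise


@dataclass
class RegressionSummary:
    """Tidy fixed-effect table plus the statistic of primary interest."""

    table: pd.DataFrame
    contrast_t: float
    contrast_p: float
    structure: str

    def summary(self) -> str:
        return (
            f"Mixed model ({self.structure}); win/loss contrast "
            f"t = {self.contrast_t:.2f}, p = {self.contrast_p:.2g}\n"
            + self.table.to_string(float_format=lambda v: f"{v: .4f}")
        )


def stochasticity_vs_noise(trials: pd.DataFrame) -> RegressionSummary:
    """Does the slope contrast survive controlling for RTs and error rates?

    The absolute per-subject switch-rate slopes (post-win and post-loss,
    reversed-label) are regressed on the win/loss contrast with the
    subject-centered mean RT and action-error rate of the corresponding
    trials as within-subject fixed effects, with by-subject random
    intercepts.  Reports the contrast's t statistic: if loss-induced
    stochasticity were mere processing noise, the contrast should vanish
    once RT/error covariates absorb it.
    """
    for col in ("rt_ms", "action_error"):
        if col not in trials.columns or trials[col].isna().all():
            raise ValueError(f"stochasticity_vs_noise requires a populated {col!r} column")

    slopes = reversed_label_slopes(trials).per_subject.set_index("subject_id")
    t = add_previous_feedback(trials)
    t = t[t["wl"].notna()]
    cond = (
        t.groupby(["subject_id", "wl"])
        .agg(rt=("rt_ms", "mean"), err=("action_error", "mean"))
        .reset_index()
    )
    cond["abs_slope"] = [
        abs(slopes.loc[r.subject_id, "post_win_slope" if r.wl == 1 else "post_loss_slope"])
        for r in cond.itertuples()
    ]
    # within-subject centering isolates the win/loss-linked RT & error variation
    for c in ("rt", "err"):
        cond[c] = cond[c] - cond.groupby("subject_id")[c].transform("mean")

    y = cond["abs_slope"].to_numpy(dtype=float)
    groups = cond["subject_id"].to_numpy()
    terms = ["intercept", "win_loss", "rt", "error_rate"]
    X = np.column_stack([np.ones(len(cond)), cond["wl"], cond["rt"], cond["err"]])
    dfree = cond["subject_id"].nunique() - 1
    try:
        res, structure = _fit_mixedlm(y, X, groups)
        table = pd.DataFrame(
            {"term": terms, "coef": res.fe_params, "se": res.bse_fe[: len(terms)]}
        )
    except RuntimeError:
        # paired two-rows-per-subject design: the within-subject (subject
        # fixed-effects) estimator gives the same conditional inference and
        # is numerically robust where the mixed model is singular
        coef, se, dfree = _within_ols(y, X[:, 1:], groups)
        table = pd.DataFrame(
            {"term": terms,
             "coef": np.concatenate([[y.mean()], coef]),
             "se": np.concatenate([[np.nan], se])}
        )
        structure = "within-subject fixed effects (OLS)"
    table["t"] = table["coef"] / table["se"]
    table["p"] = 2.0 * stats.t.sf(np.abs(table["t"]), df=dfree)
    row = table.loc[table["term"] == "win_loss"].iloc[0]
    return RegressionSummary(
        table=table, contrast_t=float(row["t"]), contrast_p=float(row["p"]),
        structure=structure,
    )


# ---------------------------------------------------------------------------
# Parameters -> competitive success


@dataclass
class SuccessRegressionResult:
    """Fixed effects of the model parameters on the win proportion."""

    table: pd.DataFrame
    grouping: str
    n_subjects: int

    def summary(self) -> str:
        return (
            f"Success regression ({self.n_subjects} subjects, grouped by {self.grouping})\n"
            + self.table.to_string(float_format=lambda v: f"{v: .4f}")
        )


def success_regression(
    subject_params: pd.DataFrame, win_rates, groups, grouping: str = "experiment"
) -> SuccessRegressionResult:
    """Regress win proportion on ms, sm, |pe| and |ss|.

    ``subject_params`` has one row per subject with columns ms, sm, pe, ss
    (the perseveration and win-stay/lose-shift parameters enter in absolute
    value: either bias direction is a deviation from optimal play);
    ``win_rates`` and ``groups`` align with its rows.  A two-level model with
    a random intercept per group.
    """
    y = np.asarray(win_rates, dtype=float)
    g = np.asarray(groups)
    if pd.unique(g).size < 2:
        raise ValueError("need at least 2 groups for the random grouping factor")
    X = np.column_stack(
        [
            np.ones(len(subject_params)),
            subject_params["ms"].to_numpy(dtype=float),
            subject_params["sm"].to_numpy(dtype=float),
            np.abs(subject_params["pe"].to_numpy(dtype=float)),
            np.abs(subject_params["ss"].to_numpy(dtype=float)),
        ]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design: parameter columns are collinear")
    res, structure = _fit_mixedlm(y, X, g)
    terms = ["intercept", "ms", "sm", "abs_pe", "abs_ss"]
    table = pd.DataFrame(
        {"term": terms, "coef": res.fe_params, "se": res.bse_fe[: len(terms)]}
    )
    table["t"] = table["coef"] / table["se"]
    dfree = len(subject_params) - X.shape[1]
    table["p"] = 2.0 * stats.t.sf(np.abs(table["t"]), df=max(dfree, 1))
    return SuccessRegressionResult(
        table=table, grouping=f"{grouping} ({structure})", n_subjects=len(subject_params)
    )


def plot_condition_grid(grid: pd.DataFrame, results: ChoiceModelResults = None, ax=None):
    """Minimal plot of observed (and optionally model-predicted) switch rates."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for wl, color, label in ((1, "tab:green", "post-win"), (-1, "tab:red", "post-loss")):
        sub = grid[grid["wl"] == wl].sort_values("p_os")
        ax.plot(sub["p_os"], sub["switch_rate"], "o-", color=color, label=label)
        if results is not None:
            fine = np.linspace(0.05, 0.95, 61)
            ax.plot(fine, results.predict(fine, wl), "--", color=color, alpha=0.6)
    ax.set_xlabel("opponent switch rate")
    ax.set_ylabel("player switch rate")
    ax.set_ylim(0, 1)
    ax.axhline(0.5, color="grey", lw=0.5)
    ax.legend()
    return ax
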