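"""Four-parameter feedback-contingent choice model for competitive rule selection.

The model describes the probability that a player in a matching-pennies-style
game (fox/rabbit rule selection) switches away from the previously executed
rule, as a function of the opponent's switch rate and the previous trial's
win/loss feedback.  Writing ``os = ln(p_os / (1 - p_os))`` for the log-odds of
the opponent's switch rate ``p_os`` and ``wl`` = +1 after a win, -1 after a
loss, the switch log-odds are

    logit P(switch) = wl * os * (ms + sm * (1 - wl) / 2) - pe - wl * ss

with four parameters:

``ms``
    model strength — the post-win slope of the switch log-odds on ``os``;
    ``ms = 1`` is exact probability matching of the opponent's switch rate.
``sm``
    strategy mix — the change of the model-based slope on post-loss trials,
    measured on the reversed-label axis (post-loss slope = ``ms + sm``);
    a negative ``sm`` means the internal model is suppressed after losses.
``pe``
    perseveration — an unconditional log-odds bias against switching
    (positive values favour repeating the previous rule).
``ss``
    win-stay/lose-shift — a feedback-contingent bias: after a win it lowers,
    after a loss it raises, the switch log-odds.

Two estimators are provided, both statsmodels-style Model classes whose
``fit()`` returns a :class:`ChoiceModelResults`:

* :class:`ConditionAverageModel` — least squares on mean switch rates over the
  (opponent rate x post-win/post-loss) condition grid, with residual-bootstrap
  confidence intervals.
* :class:`TrialwiseModel` — Bernoulli maximum likelihood on a single player's
  trial sequence.  Because the switch log-odds are linear in the parameters
  given the transformed regressors [wl*os, wl*os*(1-wl)/2, -1, -wl], this is
  an ordinary logistic regression with Wald standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

__all__ = [
    "ChoiceParams",
    "opponent_log_odds",
    "switch_logit",
    "switch_probability",
    "predict_condition_grid",
    "running_opponent_switch_rate",
    "ConditionAverageModel",
    "TrialwiseModel",
    "ChoiceModelResults",
    "fit_condition_averages",
    "fit_trialwise",
    "DEFAULT_INIT",
]

#: Default optimizer start per the fitting protocol (jittered restarts around it).
DEFAULT_INIT = (0.5, -0.3, 0.1, 0.2)

PARAM_NAMES = ("ms", "sm", "pe", "ss")


@dataclass(frozen=True)
class ChoiceParams:
    """The four choice-model parameters (all on the log-odds scale)."""

    ms: float
    sm: float
    pe: float
    ss: float

    def __post_init__(self):
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {name!r} must be finite, got {v!r}")

    @property
    def post_win_slope(self) -> float:
        """Slope of the switch log-odds on ``os`` after wins."""
        return self.ms

    @property
    def post_loss_slope(self) -> float:
        """Slope after losses, on the reversed-label axis (ms + sm)."""
        return self.ms + self.sm

    def as_array(self) -> np.ndarray:
        return np.array([self.ms, self.sm, self.pe, self.ss], dtype=float)

    @classmethod
    def from_array(cls, theta) -> "ChoiceParams":
        ms, sm, pe, ss = np.asarray(theta, dtype=float)
        return cls(ms, sm, pe, ss)


def _as_params(params) -> ChoiceParams:
    if isinstance(params, ChoiceParams):
        return params
    if isinstance(params, dict):
        return ChoiceParams(**params)
    return ChoiceParams.from_array(params)


def opponent_log_odds(p_os):
    """Log-odds ``os = ln(p_os / (1 - p_os))`` of the opponent switch rate.

    ``p_os`` must lie strictly inside (0, 1); boundary values would map to
    infinite log-odds and are rejected.
    """
    p = np.asarray(p_os, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        bad = np.atleast_1d(p)[(np.atleast_1d(p) <= 0) | (np.atleast_1d(p) >= 1)]
        raise ValueError(
            f"opponent switch rate must be strictly inside (0, 1); got {bad[0]!r}"
        )
    return np.log(p / (1.0 - p))


def _check_wl(wl):
    w = np.asarray(wl, dtype=float)
    if not np.all(np.isin(w, (-1.0, 1.0))):
        raise ValueError("wl must be +1 (post-win) or -1 (post-loss)")
    return w


def switch_logit(params, p_os, wl):
    """Switch log-odds ``wl*os*(ms + sm*(1-wl)/2) - pe - wl*ss``.

    Broadcasts over array-valued ``p_os`` and ``wl``.
    """
    p = _as_params(params)
    os_ = opponent_log_odds(p_os)
    w = _check_wl(wl)
    out = w * os_ * (p.ms + p.sm * (1.0 - w) / 2.0) - p.pe - w * p.ss
    return out if np.ndim(out) else float(out)


def switch_probability(params, p_os, wl):
    """Probability of switching: the logistic transform of :func:`switch_logit`."""
    out = expit(switch_logit(params, p_os, wl))
    return out if np.ndim(out) else float(out)


def predict_condition_grid(params, p_os_list) -> pd.DataFrame:
    """Model-predicted mean switch rate for every (p_os, wl) cell.

    Returns a tidy frame with columns ``p_os``, ``wl`` (+1/-1) and
    ``switch_rate``, one row per combination of the given opponent rates with
    post-win and post-loss feedback.
    """
    rates = np.atleast_1d(np.asarray(p_os_list, dtype=float))
    if rates.size == 0:
        raise ValueError("p_os_list must contain at least one opponent rate")
    rows = []
    for wl in (1, -1):
        probs = switch_probability(params, rates, wl)
        for p_os, pr in zip(rates, np.atleast_1d(probs)):
            rows.append({"p_os": float(p_os), "wl": wl, "switch_rate": float(pr)})
    return pd.DataFrame(rows)


def running_opponent_switch_rate(
    events,
    blocks=None,
    *,
    first_prior: float = 0.5,
    prior_weight: float = 1.0,
    smoothing: float = 0.5,
    clip: float = 0.01,
):
    """Per-trial running estimate of the opponent's switch rate within blocks.

    ``events`` is the opponent's per-trial switch indicator (0/1; NaN where
    undefined, e.g. the first trial of a block), ordered in play order;
    ``blocks`` gives the block index per trial (one block if omitted).  The
    estimate returned for trial ``t`` uses only events strictly before ``t``.

    The estimate is a Beta-style posterior mean: within a block with ``s``
    observed switches out of ``n`` events so far,

        est = (smoothing + prior_weight * prior + s)
              / (2 * smoothing + prior_weight + n)

    where ``prior`` is 0.5 in the first block and the final estimate of the
    previous block afterwards (carried over as ``prior_weight``
    pseudo-observations), and ``smoothing`` adds a symmetric Laplace-style
    0.5-success/0.5-failure cushion by default so the estimate never reaches
    0 or 1.  The output is additionally clipped to [clip, 1 - clip] so its
    log-odds stay finite.
    """
    ev = np.asarray(events, dtype=float)
    if ev.size == 0:
        return np.array([], dtype=float)
    if blocks is None:
        blk = np.zeros(ev.shape, dtype=int)
    else:
        blk = np.asarray(blocks)
        if blk.shape != ev.shape:
            raise ValueError("blocks must align with events")

    def estimate(prior, s, n):
        est = (smoothing + prior_weight * prior + s) / (
            2.0 * smoothing + prior_weight + n
        )
        return min(max(est, clip), 1.0 - clip)

    out = np.empty(ev.shape, dtype=float)
    prior = float(first_prior)
    current_block = None
    s = n = 0.0
    for i in range(ev.size):
        if blk[i] != current_block:
            if current_block is not None:
                # carry the latest running average (all of the previous
                # block's events) into the new block as the prior
                prior = estimate(prior, s, n)
            current_block = blk[i]
            s = n = 0.0
        out[i] = estimate(prior, s, n)
        if np.isfinite(ev[i]):
            s += ev[i]
            n += 1.0
    return out


class ChoiceModelResults:
    """Estimation results for the four-parameter choice model.

    Attributes
    ----------
    params : ChoiceParams
        Point estimates.
    bse : pandas.Series or None
        Wald standard errors (trialwise ML fits only).
    r2 : float or None
        Variance explained over the condition grid (condition fits only).
    objective : float
        Sum of squared residuals (condition fits) or negative log-likelihood.
    llf : float or None
        Log-likelihood at the optimum (trialwise fits).
    converged : bool
        Honest convergence flag; ``False`` triggers a warning at access time
        in downstream consumers via :meth:`warn_if_unconverged`.
    method : str
        ``"condition_LS"`` or ``"trialwise_ML"``.
    """

    def __init__(
        self,
        params: ChoiceParams,
        *,
        method: str,
        converged: bool,
        objective: float,
        nobs: int,
        bse=None,
        conf_int=None,
        r2=None,
        llf=None,
        rank_deficient: bool = False,
        message: str = "",
        fittedvalues=None,
    ):
        self.params = params
        self.method = method
        self.converged = bool(converged)
        self.objective = float(objective)
        self.nobs = int(nobs)
        self.bse = bse
        self._conf_int = conf_int
        self.r2 = r2
        self.llf = llf
        self.rank_deficient = bool(rank_deficient)
        self.message = message
        self.fittedvalues = fittedvalues
        if not self.converged:
            warnings.warn(
                f"choice-model fit ({method}) did not converge: {message}",
                RuntimeWarning,
                stacklevel=2,
            )

    def conf_int(self) -> pd.DataFrame:
        """95% intervals per parameter (bootstrap for LS, Wald for ML)."""
        if self._conf_int is not None:
            return self._conf_int.copy()
        if self.bse is not None:
            est = pd.Series(dict(zip(PARAM_NAMES, self.params.as_array())))
            lo = est - 1.959963984540054 * self.bse
            hi = est + 1.959963984540054 * self.bse
            return pd.DataFrame({"lo95": lo, "hi95": hi})
        raise ValueError("no uncertainty information available for this fit")

    def warn_if_unconverged(self):
        if not self.converged:
            warnings.warn(
                f"using results from a non-converged fit ({self.message})",
                RuntimeWarning,
                stacklevel=2,
            )

    def predict(self, p_os, wl):
        """Predicted switch probability at the fitted parameters."""
        return switch_probability(self.params, p_os, wl)

    def params_frame(self) -> pd.DataFrame:
        est = self.params.as_array()
        try:
            ci = self.conf_int()
            lo, hi = ci["lo95"].to_numpy(), ci["hi95"].to_numpy()
        except ValueError:
            lo = hi = [np.nan] * 4
        return pd.DataFrame(
            {"parameter": PARAM_NAMES, "estimate": est, "lo95": lo, "hi95": hi}
        )

    def summary(self) -> str:
        """Plain-text summary table."""
        lines = [
            "Feedback-contingent choice model",
            f"  method:    {self.method}",
            f"  nobs:      {self.nobs}",
            f"  converged: {self.converged}",
            f"  objective: {self.objective:.6g}",
        ]
        if self.r2 is not None:
            lines.append(f"  R^2:       {self.r2:.4f}")
        if self.llf is not None:
            lines.append(f"  loglike:   {self.llf:.4f}")
        if self.rank_deficient:
            lines.append("  WARNING: design is rank deficient; estimates not unique")
        lines.append(f"{'param':>6} {'estimate':>10} {'lo95':>10} {'hi95':>10}")
        pf = self.params_frame()
        for _, row in pf.iterrows():
            lines.append(
                f"{row['parameter']:>6} {row['estimate']:>10.4f} "
                f"{row['lo95']:>10.4f} {row['hi95']:>10.4f}"
            )
        return "\n".join(lines)

    def __repr__(self):
        p = self.params
        return (
            f"<ChoiceModelResults {self.method} ms={p.ms:.3f} sm={p.sm:.3f} "
            f"pe={p.pe:.3f} ss={p.ss:.3f} converged={self.converged}>"
        )


def _validate_grid(grid: pd.DataFrame) -> pd.DataFrame:
    required = {"p_os", "wl", "switch_rate"}
    missing = required - set(grid.columns)
    if missing:
        raise ValueError(f"condition grid is missing columns {sorted(missing)}")
    g = grid.copy()
    _check_wl(g["wl"].to_numpy())
    opponent_log_odds(g["p_os"].to_numpy())
    rates = g["switch_rate"].to_numpy(dtype=float)
    if np.any((rates < 0) | (rates > 1)):
        raise ValueError("switch_rate must lie in [0, 1]")
    cells = list(zip(g["p_os"], g["wl"]))
    if len(set(cells)) != len(cells):
        raise ValueError("each (p_os, wl) cell may appear at most once")
    if len(cells) < 4:
        raise ValueError(
            f"need at least 4 distinct (p_os, wl) cells to identify 4 parameters, "
            f"got {len(cells)}"
        )
    return g


class ConditionAverageModel:
    """Least-squares fit of the choice model to condition-mean switch rates.

    Parameters
    ----------
    grid : pandas.DataFrame
        Columns ``p_os`` (opponent switch rate, in (0,1)), ``wl`` (+1/-1) and
        ``switch_rate`` (observed mean in [0,1]); optionally ``n`` with the
        per-cell trial count for weighted fitting.
    """

    def __init__(self, grid: pd.DataFrame):
        self.grid = _validate_grid(grid)

    def predict(self, params) -> np.ndarray:
        return switch_probability(
            params, self.grid["p_os"].to_numpy(), self.grid["wl"].to_numpy()
        )

    def _residuals(self, theta, y, w):
        pred = switch_probability(
            ChoiceParams.from_array(theta),
            self.grid["p_os"].to_numpy(),
            self.grid["wl"].to_numpy(),
        )
        return np.sqrt(w) * (pred - y)

    def fit(
        self,
        init=None,
        *,
        weight_by_n: bool = False,
        n_restarts: int = 5,
        restart_seed: int = 0,
        n_boot: int = 199,
        bootstrap_seed: int = 0,
    ) -> ChoiceModelResults:
        """Minimise the (optionally n-weighted) sum of squared cell deviations.

        Derivative-free simplex search from the default start plus
        ``n_restarts`` jittered restarts (fixed ``restart_seed``), followed by a
        Levenberg-Marquardt polish of the best candidate.  Uncertainty comes
        from a residual bootstrap (``n_boot`` resamples) unless ``n_boot=0``.
        """
        y = self.grid["switch_rate"].to_numpy(dtype=float)
        if weight_by_n:
            if "n" not in self.grid.columns:
                raise ValueError("weight_by_n requires an 'n' column")
            w = self.grid["n"].to_numpy(dtype=float)
            w = w / w.mean()
        else:
            w = np.ones_like(y)

        x0 = np.asarray(init if init is not None else DEFAULT_INIT, dtype=float)
        rng = np.random.default_rng(restart_seed)
        starts = [x0] + [x0 + rng.normal(0.0, 0.3, size=4) for _ in range(n_restarts)]

        def sse(theta):
            r = self._residuals(theta, y, w)
            return float(r @ r)

        best = None
        for s in starts:
            res = optimize.minimize(
                sse, s, method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-9, "maxiter": 800},
            )
            if best is None or res.fun < best.fun:
                best = res

        polish = optimize.least_squares(
            self._residuals, best.x, args=(y, w), method="lm", xtol=1e-14, ftol=1e-14
        )
        theta = polish.x if polish.cost * 2 <= best.fun + 1e-12 else best.x
        converged = bool(best.success or polish.success)
        message = "" if converged else f"{best.message}; {polish.message}"

        fitted = switch_probability(
            ChoiceParams.from_array(theta),
            self.grid["p_os"].to_numpy(),
            self.grid["wl"].to_numpy(),
        )
        resid = y - fitted
        ss_res = float(np.sum(w * resid**2))
        ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

        jac = optimize.approx_fprime(
            theta,
            lambda th: self._residuals(th, y, w),
            1e-6,
        )
        rank_deficient = np.linalg.matrix_rank(np.atleast_2d(jac)) < 4

        ci = None
        if n_boot:
            ci = self._bootstrap_ci(theta, fitted, resid, w, n_boot, bootstrap_seed)

        return ChoiceModelResults(
            ChoiceParams.from_array(theta),
            method="condition_LS",
            converged=converged,
            objective=ss_res,
            nobs=len(y),
            conf_int=ci,
            r2=r2,
            rank_deficient=rank_deficient,
            message=message,
            fittedvalues=fitted,
        )

    def _bootstrap_ci(self, theta, fitted, resid, w, n_boot, seed):
        """Residual-bootstrap 95% percentile intervals (fixed seed)."""
        rng = np.random.default_rng(seed)
        draws = np.empty((n_boot, 4))
        for b in range(n_boot):
            r_star = rng.choice(resid, size=resid.size, replace=True)
            y_star = np.clip(fitted + r_star, 0.0, 1.0)
            try:
                sol = optimize.least_squares(
                    self._residuals, theta, args=(y_star, w), method="lm",
                    xtol=1e-10, ftol=1e-10,
                )
                draws[b] = sol.x
            except Exception:  # pragma: no cover - defensive
                draws[b] = np.nan
        lo = np.nanpercentile(draws, 2.5, axis=0)
        hi = np.nanpercentile(draws, 97.5, axis=0)
        return pd.DataFrame({"lo95": lo, "hi95": hi}, index=list(PARAM_NAMES))


def _trialwise_design(trials: pd.DataFrame, p_os, running_kwargs):
    """Build (y, X, kept_index) for the trialwise logistic fit.

    ``trials`` must be a single player's log ordered in play order with
    columns ``block``, ``trial_in_block``, ``player_switch``, ``outcome`` and
    (for ``p_os="programmed"``) ``opponent_rate`` or (for ``p_os="running"``)
    ``opponent_switch``.  First trials of blocks have no previous feedback and
    are excluded.
    """
    t = trials.reset_index(drop=True)
    if p_os == "programmed":
        rate = t["opponent_rate"].to_numpy(dtype=float)
    elif p_os == "running":
        rate = running_opponent_switch_rate(
            t["opponent_switch"].to_numpy(dtype=float),
            t["block"].to_numpy(),
            **(running_kwargs or {}),
        )
    else:
        rate = np.asarray(p_os, dtype=float)
        if rate.shape[0] != len(t):
            raise ValueError("per-trial p_os must align with trials")

    prev_outcome = t["outcome"].shift(1)
    same_block = t["block"].eq(t["block"].shift(1))
    wl = np.where(prev_outcome.eq("win"), 1.0, -1.0)
    y = t["player_switch"].to_numpy(dtype=float)
    keep = same_block.to_numpy() & np.isfinite(y) & prev_outcome.notna().to_numpy()
    keep &= np.isfinite(rate)

    wl, rate, y = wl[keep], rate[keep], y[keep]
    os_ = opponent_log_odds(rate)
    X = np.column_stack([wl * os_, wl * os_ * (1.0 - wl) / 2.0, -np.ones_like(wl), -wl])
    return y, X, np.flatnonzero(keep)


class TrialwiseModel:
    """Bernoulli maximum-likelihood fit of the choice model to one player's trials.

    ``p_os`` selects the per-trial opponent-rate input: ``"programmed"`` (the
    known simulated-opponent rate, column ``opponent_rate``), ``"running"``
    (running average of the partner's observed switches, for dyad play), or an
    explicit per-trial array.
    """

    def __init__(self, trials: pd.DataFrame, p_os="programmed", running_kwargs=None):
        self.trials = trials
        self.endog, self.exog, self.kept_index = _trialwise_design(
            trials, p_os, running_kwargs
        )

    def fit(self, init=None) -> ChoiceModelResults:
        import statsmodels.api as sm

        y, X = self.endog, self.exog
        n = len(y)
        if n < 8:
            raise ValueError(f"too few usable trials ({n}) for a trialwise fit")

        rank = np.linalg.matrix_rank(X)
        rank_deficient = rank < X.shape[1]
        boundary = y.min() == y.max()
        message = ""
        if boundary:
            message = "degenerate all-switch or all-repeat sequence (boundary)"
            warnings.warn(message, RuntimeWarning, stacklevel=2)
        if rank_deficient:
            message = (
                f"design rank {rank} < 4: ms/sm (or pe/ss) jointly unidentified"
            )
            warnings.warn(message, RuntimeWarning, stacklevel=2)

        start = np.asarray(init if init is not None else DEFAULT_INIT, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, X).fit(
                    start_params=start, method="newton", disp=0, maxiter=200
                )
                converged = bool(res.mle_retvals.get("converged", False))
                params = res.params
                bse = pd.Series(res.bse, index=list(PARAM_NAMES))
                llf = float(res.llf)
            except Exception as exc:
                # perfect separation / singular Hessian: report, never crash
                message = message or f"logistic fit failed: {exc}"
                params = start * np.nan
                bse = pd.Series(np.nan, index=list(PARAM_NAMES))
                llf = np.nan
                converged = False
        if boundary or rank_deficient:
            converged = False
        if np.any(~np.isfinite(params)):
            params = np.zeros(4)

        return ChoiceModelResults(
            ChoiceParams.from_array(params),
            method="trialwise_ML",
            converged=converged,
            objective=-llf if np.isfinite(llf) else np.nan,
            nobs=n,
            bse=bse,
            llf=llf,
            rank_deficient=rank_deficient,
            message=message,
        )


def fit_condition_averages(grid: pd.DataFrame, init=None, **kwargs) -> ChoiceModelResults:
    """Convenience wrapper: ``ConditionAverageModel(grid).fit(init, **kwargs)``."""
    return ConditionAverageModel(grid).fit(init, **kwargs)


def fit_trialwise(
    trials: pd.DataFrame, init=None, p_os="programmed", running_kwargs=None
) -> ChoiceModelResults:
    """Convenience wrapper: ``TrialwiseModel(trials, p_os).fit(init)``."""
    return TrialwiseModel(trials, p_os=p_os, running_kwargs=running_kwargs).fit(init)
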