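"""Regression-based information analysis of feedback-locked signals.

Quantifies how much information about the choice context is carried by a
single-channel, feedback-locked signal (e.g. mid-frontal EEG averaged over
Fz/Cz), and whether that information is behaviourally relevant:

* per-time-point context regressions, split by previous win/loss — the
  signal is regressed on A) the opponent's overall switch rate, B) the
  opponent's lag-1 switch, C) the player's lag-1 switch and D) the A x B
  interaction;
* window averaging over an a-priori 300-700 ms post-feedback interval;
* a psychophysiological-interaction (PPI) analysis: the trial n-1 residual
  signal (after removing the context variables) and its interactions with
  them predict the trial n switch choice;
* individual-difference correlations between subjects' window-averaged
  coefficients and their behavioural slopes / win rates, with post-win vs
  post-loss contrasts via Steiger's z for dependent correlations.

Group inference uses the two-stage summary-statistics scheme (per-subject
fits, then random-effects statistics across subjects).  Post-loss label
reversal (A and B sign-flipped; C optionally) mirrors the behavioural
reversed-label strategy so coefficient magnitudes are comparable across
feedback conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "build_context_design",
    "timepoint_context_regression",
    "subject_window_coefficients",
    "window_average",
    "detrend_epochs",
    "ppi_analysis",
    "individual_difference_correlations",
    "steiger_z",
    "PPIResult",
    "PREDICTORS",
]

#: Context predictors, in reporting order.
PREDICTORS = ("A", "B", "C", "AB")

_PPI_TERMS = ("A", "B", "C", "AB", "D", "DxA", "DxB", "DxC", "DxAB")


def build_context_design(session: pd.DataFrame) -> pd.DataFrame:
    """Per-trial context variables at feedback time.

    For every trial ``m`` with a defined lag-1 context (``trial_in_block >=
    2``) the row holds what is known when trial ``m``'s feedback appears:
    the block's opponent rate (``A_raw``), the opponent's and player's
    switch at ``m`` (``B``, ``C``, effect-coded +1 switch / -1 repeat), the
    feedback itself (``wl``) and the upcoming choice (``next_switch``,
    NaN on the last trial of a block).
    """
    required = {"block", "trial_in_block", "player_switch", "opponent_switch",
                "outcome", "opponent_rate"}
    missing = required - set(session.columns)
    if missing:
        raise ValueError(f"session is missing columns {sorted(missing)}")
    t = session.copy()
    if "subject_id" not in t.columns:
        t["subject_id"] = "s000"
    parts = []
    for (sid, blk), sub in t.groupby(["subject_id", "block"], sort=False):
        ps = sub["player_switch"].to_numpy(dtype=float)
        nxt = np.concatenate([ps[1:], [np.nan]])
        parts.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "block": blk,
                    "trial_in_block": sub["trial_in_block"].to_numpy(),
                    "A_raw": sub["opponent_rate"].to_numpy(dtype=float),
                    "B": 2.0 * sub["opponent_switch"].to_numpy(dtype=float) - 1.0,
                    "C": 2.0 * ps - 1.0,
                    "wl": np.where(sub["outcome"].eq("win"), 1.0, -1.0),
                    "next_switch": nxt,
                }
            )
        )
    des = pd.concat(parts, ignore_index=True)
    return des[des["trial_in_block"] >= 2].reset_index(drop=True)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _baseline(em) -> np.ndarray:
    """Subtract each trial's mean over the pre-feedback interval (t < 0)."""
    pre = em.times_ms < 0
    if not pre.any():
        return em.values.copy()
    return em.values - em.values[:, pre].mean(axis=1, keepdims=True)


def detrend_epochs(values: np.ndarray) -> np.ndarray:
    """Remove linear and quadratic across-trial trends per time point.

    Optional pre-whitening stage for user-supplied recordings; synthetic
    epochs do not need it.
    """
    n = values.shape[0]
    x = np.arange(n, dtype=float)
    X = np.column_stack([np.ones(n), _zscore(x), _zscore(x**2)])
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X[:, 1:] @ beta[1:]


def _design_matrix(des: pd.DataFrame, wl: int, reverse_labels: bool,
                   reverse_player: bool) -> np.ndarray:
    """Standardized [A, B, C, AB] for one feedback subset (label-reversed)."""
    A = _zscore(des["A_raw"].to_numpy(dtype=float))
    B = des["B"].to_numpy(dtype=float)
    C = des["C"].to_numpy(dtype=float)
    if wl == -1 and reverse_labels:
        A, B = -A, -B
        if reverse_player:
            C = -C
    return np.column_stack([A, B, C, A * B])


def _iter_subject_epochs(epochs):
    if isinstance(epochs, dict):
        yield from epochs.items()
    else:
        for i, em in enumerate(epochs):
            sid = em.design["subject_id"].iloc[0] if "subject_id" in em.design else i
            yield sid, em


def _subject_timecourses(epochs, reverse_labels, reverse_player, standardize,
                         prewhiten=False):
    """Yield (sid, wl, coef 4 x T) per subject and feedback condition."""
    for sid, em in _iter_subject_epochs(epochs):
        Y_full = _baseline(em)
        if prewhiten:
            Y_full = detrend_epochs(Y_full)
        wl_col = em.design["wl"].to_numpy(dtype=float)
        for wl in (1, -1):
            mask = wl_col == wl
            if mask.sum() < 8:
                continue
            des = em.design[mask]
            X = _design_matrix(des, wl, reverse_labels, reverse_player)
            Y = Y_full[mask]
            if standardize:
                X = np.column_stack([_zscore(X[:, j]) for j in range(X.shape[1])])
                sd = Y.std(axis=0)
                sd[sd == 0] = 1.0
                Y = (Y - Y.mean(axis=0)) / sd
            Xc = np.column_stack([np.ones(mask.sum()), X])
            beta, *_ = np.linalg.lstsq(Xc, Y, rcond=None)
            yield sid, wl, beta[1:]


def timepoint_context_regression(
    epochs,
    *,
    reverse_labels: bool = True,
    reverse_player: bool = False,
    standardize: bool = True,
    prewhiten: bool = False,
) -> pd.DataFrame:
    """Two-level context regression of the signal, per time point.

    ``epochs`` is a dict (or list) of per-subject :class:`EpochMatrix`
    objects whose ``design`` carries the context variables.  Per subject and
    feedback condition the baselined signal at each time point is regressed
    on the standardized {A, B, C, AxB}; group-level coefficients are the
    across-subject means with random-effects SEs.

    Returns a tidy frame with columns ``time_ms, predictor, wl, beta, se,
    t, p, n_subjects``.
    """
    store: dict = {}
    times = None
    for sid, wl, coef in _subject_timecourses(
        epochs, reverse_labels, reverse_player, standardize, prewhiten
    ):
        store.setdefault(wl, []).append(coef)
    for _, em in _iter_subject_epochs(epochs):
        times = em.times_ms
        break
    if not store or min(len(v) for v in store.values()) < 2:
        raise ValueError("need at least 2 subjects per feedback condition")

    frames = []
    for wl, coefs in store.items():
        arr = np.stack(coefs)  # subjects x 4 x T
        n = arr.shape[0]
        mean = arr.mean(axis=0)
        se = arr.std(axis=0, ddof=1) / np.sqrt(n)
        tval = np.divide(mean, se, out=np.zeros_like(mean), where=se > 0)
        p = 2.0 * stats.t.sf(np.abs(tval), df=n - 1)
        for j, name in enumerate(PREDICTORS):
            frames.append(
                pd.DataFrame(
                    {
                        "time_ms": times,
                        "predictor": name,
                        "wl": wl,
                        "beta": mean[j],
                        "se": se[j],
                        "t": tval[j],
                        "p": p[j],
                        "n_subjects": n,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def window_average(epochs, lo: float = 300.0, hi: float = 700.0) -> np.ndarray:
    """Mean signal per trial over time points in [lo, hi) ms.

    ``epochs`` is an :class:`EpochMatrix` (or any object with ``times_ms``
    and ``values``).  The window must contain at least one grid point.
    """
    if hi <= lo:
        raise ValueError(f"window must satisfy lo < hi, got [{lo}, {hi})")
    mask = (epochs.times_ms >= lo) & (epochs.times_ms < hi)
    if not mask.any():
        raise ValueError(f"window [{lo}, {hi}) ms contains no grid points")
    return epochs.values[:, mask].mean(axis=1)


def subject_window_coefficients(
    epochs,
    lo: float = 300.0,
    hi: float = 700.0,
    *,
    reverse_labels: bool = True,
    reverse_player: bool = False,
    standardize: bool = True,
) -> pd.DataFrame:
    """Per-subject standardized coefficients averaged over a time window.

    Averages each subject's per-time-point coefficient curves over
    [lo, hi) ms; rows: subject_id, wl, predictor, coef.  Feeds the
    individual-difference correlation analysis.
    """
    if hi <= lo:
        raise ValueError(f"window must satisfy lo < hi, got [{lo}, {hi})")
    rows = []
    for sid, em in _iter_subject_epochs(epochs):
        mask = (em.times_ms >= lo) & (em.times_ms < hi)
        if not mask.any():
            raise ValueError(f"window [{lo}, {hi}) ms contains no grid points")
        for s, wl, coef in _subject_timecourses(
            {sid: em}, reverse_labels, reverse_player, standardize
        ):
            for j, name in enumerate(PREDICTORS):
                rows.append(
                    {"subject_id": s, "wl": wl, "predictor": name,
                     "coef": float(coef[j, mask].mean())}
                )
    return pd.DataFrame(rows)


@dataclass
class PPIResult:
    """Group-level PPI coefficients, split by previous feedback.

    ``table`` rows follow the context-then-residual order (A, B, C, AxB,
    residual D, and the D interactions); ``orthogonality`` is the largest
    absolute correlation between step-1 residuals and the step-1 predictors
    (should be ~0 by construction).
    """

    table: pd.DataFrame
    orthogonality: float
    notes: list = field(default_factory=list)

    def summary(self) -> str:
        head = (
            "PPI analysis: switch(n) ~ context(n-1) + residual signal(n-1) "
            f"+ interactions\n  max |corr(residual, predictor)| = "
            f"{self.orthogonality:.2e}"
        )
        if self.notes:
            head += "\n  notes: " + "; ".join(self.notes)
        return head + "\n" + self.table.to_string(float_format=lambda v: f"{v: .4f}")


def ppi_analysis(
    data: pd.DataFrame,
    *,
    reverse_labels: bool = False,
    min_residual_sd: float = 1e-10,
) -> PPIResult:
    """Residual-signal psychophysiological interaction on upcoming choices.

    ``data`` has one row per trial n-1 with columns ``subject_id``, ``wl``,
    the context variables ``A`` (continuous), ``B``, ``C`` (effect-coded),
    the window-averaged ``signal`` and the upcoming ``next_switch`` (0/1).

    Step 1 regresses the signal on {A, B, C, AxB} per subject and feedback
    condition and keeps the residual D (z-scored).  Step 2 fits a logistic
    model of the next switch on {A, B, C, AxB, D, DxA, DxB, DxC, DxAxB};
    coefficients are aggregated across subjects (random-effects z).
    """
    required = {"subject_id", "wl", "A", "B", "C", "signal", "next_switch"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"PPI data is missing columns {sorted(missing)}")
    d = data.dropna(subset=["next_switch"]).copy()

    notes: list = []
    rows: dict = {1: [], -1: []}
    max_corr = 0.0
    for (sid, wl), sub in d.groupby(["subject_id", "wl"], sort=True):
        if len(sub) < 20:
            continue
        A = _zscore(sub["A"].to_numpy(dtype=float))
        B = sub["B"].to_numpy(dtype=float)
        C = sub["C"].to_numpy(dtype=float)
        if wl == -1 and reverse_labels:
            A, B = -A, -B
        X1 = np.column_stack([np.ones(len(sub)), A, B, C, A * B])
        sig = sub["signal"].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X1, sig, rcond=None)
        resid = sig - X1 @ beta
        for j in range(1, X1.shape[1]):
            sd = X1[:, j].std()
            if sd > 0 and resid.std() > 0:
                max_corr = max(max_corr, abs(np.corrcoef(X1[:, j], resid)[0, 1]))
        if resid.std() < min_residual_sd:
            notes.append(
                f"subject {sid} wl={int(wl)}: residual variance ~ 0, "
                "interaction terms dropped"
            )
            D = np.zeros(len(sub))
        else:
            D = _zscore(resid)
        X2 = np.column_stack(
            [np.ones(len(sub)), A, B, C, A * B, D, D * A, D * B, D * C, D * A * B]
        )
        y = sub["next_switch"].to_numpy(dtype=float)
        try:
            import statsmodels.api as sm

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X2).fit(disp=0, method="newton", maxiter=100)
            if np.abs(fit.params).max() > 50 or not np.all(np.isfinite(fit.params)):
                raise RuntimeError("unstable fit")
            rows[int(wl)].append(pd.Series(fit.params[1:], index=_PPI_TERMS, name=sid))
        except Exception:
            notes.append(f"subject {sid} wl={int(wl)}: logistic fit dropped")

    frames = []
    for wl in (1, -1):
        if len(rows[wl]) < 2:
            raise ValueError(
                f"need at least 2 subjects with stable fits for wl={wl}"
            )
        g = pd.DataFrame(rows[wl])
        n = len(g)
        mean, se = g.mean(axis=0), g.std(axis=0, ddof=1) / np.sqrt(len(g))
        z = mean / se
        p = 2.0 * stats.t.sf(np.abs(z), df=n - 1)
        frames.append(
            pd.DataFrame(
                {"wl": wl, "term": _PPI_TERMS, "coef": mean.to_numpy(),
                 "se": se.to_numpy(), "z": z.to_numpy(), "p": p, "n_subjects": n}
            )
        )
    return PPIResult(
        table=pd.concat(frames, ignore_index=True),
        orthogonality=max_corr,
        notes=notes,
    )


def steiger_z(r_jk: float, r_jh: float, r_kh: float, n: int) -> tuple[float, float]:
    """Steiger's z for two dependent correlations sharing one variable.

    Compares ``r_jk`` with ``r_jh`` (both involve variable j) given the
    correlation ``r_kh`` between the non-shared variables, for sample size
    ``n``.  Uses Steiger's (1980) modification of the Dunn-Clark statistic
    with the averaged correlation.  Returns (z, two-sided p).
    """
    if n < 4:
        raise ValueError("need n >= 4 for Steiger's z")
    rjk, rjh, rkh = (float(np.clip(r, -0.9999, 0.9999)) for r in (r_jk, r_jh, r_kh))
    zjk, zjh = np.arctanh(rjk), np.arctanh(rjh)
    rm2 = (rjk**2 + rjh**2) / 2.0
    f = min((1.0 - rkh) / (2.0 * (1.0 - rm2)), 1.0)
    h = (1.0 - f * rm2) / (1.0 - rm2)
    z = (zjk - zjh) * np.sqrt((n - 3) / (2.0 * (1.0 - rkh) * h))
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def individual_difference_correlations(
    subject_coefs: pd.DataFrame, measures: dict, min_subjects: int = 10
) -> pd.DataFrame:
    """Correlate subjects' signal coefficients with behavioural measures.

    ``subject_coefs`` comes from :func:`subject_window_coefficients`
    (columns subject_id, wl, predictor, coef); ``measures`` maps a measure
    name (e.g. ``"slope"``, ``"win_rate"``) to a Series indexed by
    subject_id.  For every predictor x measure the post-win and post-loss
    Pearson correlations are reported along with the dependent-correlation
    contrast (Steiger's z, sharing the behavioural measure).  Zero-variance
    inputs yield NaN correlations, flagged in the ``note`` column.
    """
    wide = subject_coefs.pivot_table(
        index="subject_id", columns=["wl", "predictor"], values="coef"
    )
    n = len(wide)
    if n < min_subjects:
        warnings.warn(
            f"only {n} subjects; individual-difference correlations are unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    rows = []
    for measure_name, series in measures.items():
        m = pd.Series(series).reindex(wide.index).to_numpy(dtype=float)
        for pred in subject_coefs["predictor"].unique():
            note = ""
            r = {}
            for wl in (1, -1):
                x = wide[(wl, pred)].to_numpy(dtype=float)
                if np.std(x) == 0 or np.std(m) == 0:
                    r[wl] = (np.nan, np.nan)
                    note = "zero-variance input; correlation undefined"
                else:
                    r[wl] = stats.pearsonr(x, m)
            if note or np.isnan(r[1][0]) or np.isnan(r[-1][0]):
                zc, pc = np.nan, np.nan
            else:
                r_wl = float(np.corrcoef(
                    wide[(1, pred)].to_numpy(float), wide[(-1, pred)].to_numpy(float)
                )[0, 1])
                zc, pc = steiger_z(r[1][0], r[-1][0], r_wl, n)
            rows.append(
                {
                    "measure": measure_name,
                    "predictor": pred,
                    "r_win": r[1][0], "p_win": r[1][1],
                    "r_loss": r[-1][0], "p_loss": r[-1][1],
                    "z_contrast": zc, "p_contrast": pc,
                    "n": n, "note": note,
                }
            )
    return pd.DataFrame(rows)
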