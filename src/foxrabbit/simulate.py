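"""Closed-loop fox/rabbit game engine and feedback-locked signal generator.

Generates trial logs with the statistical structure the analyses assume:
simulated opponents that switch rules with a fixed per-block probability,
players whose switch probability follows the four-parameter choice model
given last-trial feedback, 80-trial blocks with fox/rabbit role assignment,
an independent action-error process (errors count as losses), and optional
response times.  Human-vs-human play is emulated by :func:`simulate_dyad`,
where both players are model-governed and each tracks the partner's switch
rate with a running average.  :func:`simulate_neural_epochs` adds synthetic
feedback-locked signal epochs that carry linear context information which is
attenuated after losses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import ChoiceParams, switch_probability

__all__ = [
    "SessionConfig",
    "SignalSpec",
    "EpochMatrix",
    "DEFAULT_PLAYER_PARAMS",
    "DEFAULT_PARAM_SDS",
    "RATES_FIVE",
    "RATES_THREE",
    "simulate_opponent",
    "simulate_session",
    "simulate_cohort",
    "simulate_dyad",
    "simulate_neural_epochs",
    "simulate_ppi_dataset",
    "default_parameter_distribution",
]

#: Group-level parameter means for the standard rule-selection design
#: (model strength, strategy mix, perseveration, win-stay/lose-shift).
DEFAULT_PLAYER_PARAMS = ChoiceParams(ms=0.48, sm=-0.38, pe=0.21, ss=0.20)

#: Between-subject SDs used by the default cohort parameter distribution.
DEFAULT_PARAM_SDS = (0.25, 0.20, 0.15, 0.15)

#: Programmed opponent switch rates in the five-opponent design.
RATES_FIVE = (0.20, 0.35, 0.50, 0.65, 0.80)
#: Programmed rates in the three-opponent (EEG) design.
RATES_THREE = (0.25, 0.50, 0.75)

_RULE_LABELS = {"rule": ("run", "freeze"), "simple": ("up", "down")}


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass
class SessionConfig:
    """Design of one player's session.

    ``opponent_rates``/``role_schedule`` give the per-block programmed
    opponent switch rate and the player's role; when omitted, blocks cover
    the crossing of :data:`RATES_FIVE` with the two roles in random order
    (the standard ten-block design).  ``error_rate`` is the probability of
    an action error per trial, independent of the choice process;
    ``error_rate_post_loss`` optionally overrides it on trials following a
    loss (used to construct error-rate confounds).  ``rt_model`` gives
    (mu, sigma) of a lognormal response-time distribution in ms, or None.
    ``mode="simple"`` is the plain key-choice variant (labels up/down,
    error process disabled); ``random_feedback=True`` replaces outcomes
    with a fair coin (non-competition control).

    By default error trials keep the intended rule on record and switch
    indicators derive from intended rules; ``errors_corrupt_rule=True``
    instead records a random rule on error trials (the executed response
    does not identify the intended rule), injecting error-driven noise
    into the observed switch sequence.
    """

    n_blocks: int = 10
    trials_per_block: int = 80
    opponent_rates: Optional[Sequence[float]] = None
    role_schedule: Optional[Sequence[str]] = None
    player_params: ChoiceParams = DEFAULT_PLAYER_PARAMS
    error_rate: float = 0.05
    error_rate_post_loss: Optional[float] = None
    rt_model: Optional[tuple] = (6.35, 0.25)
    mode: str = "rule"
    random_feedback: bool = False
    errors_corrupt_rule: bool = False

    def __post_init__(self):
        if self.trials_per_block < 2:
            raise ValueError("trials_per_block must be at least 2")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be at least 1")
        if self.mode not in _RULE_LABELS:
            raise ValueError(f"mode must be one of {sorted(_RULE_LABELS)}")
        if self.opponent_rates is not None:
            r = np.asarray(self.opponent_rates, dtype=float)
            if np.any((r <= 0) | (r >= 1)):
                raise ValueError("opponent_rates must lie strictly inside (0, 1)")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")

    def resolve_schedule(self, rng) -> tuple[np.ndarray, np.ndarray]:
        """Per-block (rates, roles) arrays, randomising the default design."""
        rng = _rng(rng)
        if self.opponent_rates is None:
            combos = [(r, role) for role in ("fox", "rabbit") for r in RATES_FIVE]
            order = rng.permutation(len(combos))
            picked = [combos[i] for i in order]
            while len(picked) < self.n_blocks:
                picked += [combos[i] for i in rng.permutation(len(combos))]
            rates = np.array([picked[b][0] for b in range(self.n_blocks)])
            roles = np.array([picked[b][1] for b in range(self.n_blocks)])
        else:
            rates = np.resize(np.asarray(self.opponent_rates, float), self.n_blocks)
            if self.role_schedule is None:
                roles = np.array(
                    ["fox" if b % 2 == 0 else "rabbit" for b in range(self.n_blocks)]
                )
            else:
                roles = np.resize(np.asarray(self.role_schedule), self.n_blocks)
        return rates, roles


def simulate_opponent(p_os: float, n_trials: int, rng) -> np.ndarray:
    """Simulated opponent's rule sequence (0/1 codes).

    The first rule is uniform; each subsequent rule switches with probability
    ``p_os``, independently of everything else.  ``p_os`` may be 0 or 1
    (degenerate constant/alternating opponents).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    if not 0.0 <= p_os <= 1.0:
        raise ValueError(f"p_os must lie in [0, 1], got {p_os!r}")
    rng = _rng(rng)
    switches = rng.random(n_trials) < p_os
    switches[0] = rng.random() < 0.5  # first rule uniform
    # cumulative XOR: rule_t = switches_0 ^ switches_1 ^ ... ^ switches_t
    return np.bitwise_xor.accumulate(switches.astype(np.int8))


def _session_blocks(config: SessionConfig, rng, rates, roles):
    """Yield per-block column dictionaries for one session."""
    params = config.player_params
    labels = _RULE_LABELS[config.mode]
    err_base = 0.0 if config.mode == "simple" else config.error_rate
    err_loss = (
        err_base
        if config.error_rate_post_loss is None or config.mode == "simple"
        else config.error_rate_post_loss
    )
    T = config.trials_per_block

    for b in range(config.n_blocks):
        p_os, role = float(rates[b]), roles[b]
        opp = simulate_opponent(p_os, T, rng)
        p_win = switch_probability(params, p_os, +1)
        p_loss = switch_probability(params, p_os, -1)
        u_choice = rng.random(T)
        u_err = rng.random(T)
        u_fb = rng.random(T) if config.random_feedback else None
        u_corrupt = rng.random(T) if config.errors_corrupt_rule else None

        player = np.empty(T, dtype=np.int8)
        outcome = np.empty(T, dtype=object)
        error = np.zeros(T, dtype=np.int8)
        is_fox = role == "fox"
        prev_win = None
        for t in range(T):
            if t == 0:
                player[t] = 1 if u_choice[t] < 0.5 else 0
            else:
                psw = p_win if prev_win else p_loss
                if u_choice[t] < psw:
                    player[t] = 1 - player[t - 1]
                else:
                    player[t] = player[t - 1]
            e_rate = err_base if (prev_win is None or prev_win) else err_loss
            err = u_err[t] < e_rate
            error[t] = err
            if config.random_feedback:
                win = bool(u_fb[t] < 0.5) and not err
            elif err:
                win = False
            else:
                match = player[t] == opp[t]
                win = match if is_fox else not match
            outcome[t] = "win" if win else "loss"
            prev_win = win

        recorded = player
        if config.errors_corrupt_rule:
            recorded = player.copy()
            for t in np.flatnonzero(error):
                recorded[t] = 1 if u_corrupt[t] < 0.5 else 0

        cols = {
            "block": np.full(T, b + 1),
            "trial_in_block": np.arange(1, T + 1),
            "role": np.full(T, role, dtype=object),
            "opponent_rate": np.full(T, p_os),
            "player_rule": np.array([labels[i] for i in recorded], dtype=object),
            "opponent_rule": np.array([labels[i] for i in opp], dtype=object),
            "player_switch": np.concatenate(
                [[np.nan], (recorded[1:] != recorded[:-1]).astype(float)]
            ),
            "opponent_switch": np.concatenate(
                [[np.nan], (opp[1:] != opp[:-1]).astype(float)]
            ),
            "outcome": outcome,
            "action_error": error,
        }
        if config.rt_model is not None:
            mu, sigma = config.rt_model
            cols["rt_ms"] = rng.lognormal(mu, sigma, size=T)
        else:
            cols["rt_ms"] = np.full(T, np.nan)
        yield cols


def simulate_session(config: SessionConfig, rng) -> pd.DataFrame:
    """Simulate one player's full session against programmed opponents.

    The loop is closed: at each trial the player's switch probability is the
    choice model evaluated at the block's programmed opponent rate and the
    previous trial's feedback (the first trial of each block is a uniform
    draw).  Fully reproducible from the seed.
    """
    rng = _rng(rng)
    rates, roles = config.resolve_schedule(rng)
    frames = [pd.DataFrame(cols) for cols in _session_blocks(config, rng, rates, roles)]
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "subject_id", "s000")
    out.insert(1, "dyad_id", "")
    return out


def default_parameter_distribution(
    means: ChoiceParams = DEFAULT_PLAYER_PARAMS, sds=DEFAULT_PARAM_SDS
) -> Callable[[np.random.Generator], ChoiceParams]:
    """Gaussian subject-parameter distribution around the group means."""

    m = means.as_array()
    s = np.asarray(sds, dtype=float)

    def draw(rng: np.random.Generator) -> ChoiceParams:
        return ChoiceParams.from_array(m + s * rng.standard_normal(4))

    return draw


def simulate_cohort(
    n_subjects: int,
    config: Optional[SessionConfig] = None,
    parameter_distribution=None,
    rng=0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort of independent players.

    Per-subject generators are spawned from the master seed, so cohorts are
    reproducible and subjects are independent.  Returns ``(trials, subjects)``
    where ``subjects`` records each subject's generating parameters (for
    recovery experiments).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    config = config if config is not None else SessionConfig()
    if parameter_distribution is None:
        parameter_distribution = default_parameter_distribution()

    if isinstance(rng, np.random.Generator):
        seeds = rng.integers(0, 2**31 - 1, size=n_subjects + 1)
        children = [np.random.default_rng(int(s)) for s in seeds]
    else:
        ss = np.random.SeedSequence(rng)
        children = [np.random.default_rng(c) for c in ss.spawn(n_subjects + 1)]
    param_rng, subject_rngs = children[0], children[1:]

    trial_frames, subject_rows = [], []
    for i, sub_rng in enumerate(subject_rngs):
        sid = f"s{i:03d}"
        params = parameter_distribution(param_rng)
        cfg = dataclasses.replace(config, player_params=params)
        trials = simulate_session(cfg, sub_rng)
        trials["subject_id"] = sid
        trial_frames.append(trials)
        subject_rows.append(
            {"subject_id": sid, "ms": params.ms, "sm": params.sm,
             "pe": params.pe, "ss": params.ss}
        )
    return (
        pd.concat(trial_frames, ignore_index=True),
        pd.DataFrame(subject_rows),
    )


class _RunningEstimate:
    """Incremental partner-switch-rate tracker (mirrors running_opponent_switch_rate)."""

    def __init__(self, prior=0.5, prior_weight=1.0, smoothing=0.5, clip=0.01):
        self.prior, self.w = prior, prior_weight
        self.a, self.clip = smoothing, clip
        self.s = self.n = 0.0

    def new_block(self):
        self.prior = self.value()
        self.s = self.n = 0.0

    def value(self) -> float:
        est = (self.a + self.w * self.prior + self.s) / (2 * self.a + self.w + self.n)
        return min(max(est, self.clip), 1.0 - self.clip)

    def observe(self, switched: bool):
        self.s += float(switched)
        self.n += 1.0


def simulate_dyad(
    params_fox: ChoiceParams,
    params_rabbit: ChoiceParams,
    n_blocks: int = 7,
    trials_per_block: int = 80,
    rng=0,
    running_kwargs: Optional[dict] = None,
    dyad_id: str = "d000",
) -> pd.DataFrame:
    """Two model-governed players competing in real time (zero-sum).

    Each player's opponent-rate input is a running average of the partner's
    actual switch behaviour (carried over between blocks), since no rate is
    programmed.  Returns a long trial log with one row per trial per player
    (subject ids ``<dyad_id>-fox`` and ``<dyad_id>-rabbit``); the
    ``opponent_rate`` column is empty.
    """
    rng = _rng(rng)
    kw = running_kwargs or {}
    est_of_rabbit = _RunningEstimate(**kw)  # fox's model of the rabbit
    est_of_fox = _RunningEstimate(**kw)

    T, B = trials_per_block, n_blocks
    rows = {name: [] for name in ("fox", "rabbit")}
    params = {"fox": params_fox, "rabbit": params_rabbit}
    for b in range(B):
        if b > 0:
            est_of_rabbit.new_block()
            est_of_fox.new_block()
        rule = {"fox": None, "rabbit": None}
        prev_rule = {"fox": None, "rabbit": None}
        prev_win = {"fox": None, "rabbit": None}
        for t in range(T):
            for name, est in (("fox", est_of_rabbit), ("rabbit", est_of_fox)):
                if t == 0:
                    rule[name] = int(rng.random() < 0.5)
                else:
                    wl = 1 if prev_win[name] else -1
                    psw = switch_probability(params[name], est.value(), wl)
                    if rng.random() < psw:
                        rule[name] = 1 - prev_rule[name]
                    else:
                        rule[name] = prev_rule[name]
            match = rule["fox"] == rule["rabbit"]
            win = {"fox": match, "rabbit": not match}
            for name, other in (("fox", "rabbit"), ("rabbit", "fox")):
                sw = np.nan if t == 0 else float(rule[name] != prev_rule[name])
                osw = np.nan if t == 0 else float(rule[other] != prev_rule[other])
                rows[name].append(
                    (b + 1, t + 1, name, rule[name], rule[other], sw, osw,
                     "win" if win[name] else "loss")
                )
            if t > 0:
                est_of_rabbit.observe(rule["rabbit"] != prev_rule["rabbit"])
                est_of_fox.observe(rule["fox"] != prev_rule["fox"])
            prev_rule = dict(rule)
            prev_win = dict(win)

    labels = _RULE_LABELS["rule"]
    frames = []
    for name in ("fox", "rabbit"):
        df = pd.DataFrame(
            rows[name],
            columns=["block", "trial_in_block", "role", "player_rule",
                     "opponent_rule", "player_switch", "opponent_switch", "outcome"],
        )
        df["player_rule"] = df["player_rule"].map(lambda i: labels[i])
        df["opponent_rule"] = df["opponent_rule"].map(lambda i: labels[i])
        df["action_error"] = 0
        df["rt_ms"] = np.nan
        df["opponent_rate"] = np.nan
        df.insert(0, "subject_id", f"{dyad_id}-{name}")
        df.insert(1, "dyad_id", dyad_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@dataclass
class SignalSpec:
    """Shape of the synthetic feedback-locked signal.

    The signal at time ``t`` (ms from feedback onset) on a retained trial is

        baseline_wl(t) + gain * sum_k beta_k(wl, t) * x_k + offset + noise

    where the ``x_k`` are the standardized context variables (opponent
    overall switch rate A, opponent lag-1 switch B, player lag-1 switch C,
    and A x B), ``beta_k(win, t)`` is a Gaussian bump of amplitude
    ``amplitudes[k]`` peaking at ``peak_ms``, and ``beta_k(loss, t)`` is the
    same curve linearly attenuated to zero between ``loss_attenuation_ms``
    and ``loss_attenuation_ms + loss_ramp_ms`` (context information present
    early after losses, then suppressed).  ``gain`` is a per-subject
    multiplicative factor with SD ``subject_coefficient_sd`` around 1.
    """

    times_ms: np.ndarray = field(
        default_factory=lambda: np.arange(-200.0, 1050.0 + 1e-9, 10.0)
    )
    amplitudes: dict = field(
        default_factory=lambda: {"A": 0.5, "B": 0.4, "C": 0.2, "AB": -0.4}
    )
    peak_ms: float = 450.0
    width_ms: float = 150.0
    loss_attenuation_ms: float = 400.0
    loss_ramp_ms: float = 300.0
    erp_scale: float = 2.0
    frn_scale: float = 1.5
    noise_sd: float = 2.0
    subject_coefficient_sd: float = 0.1
    subject_offset_sd: float = 0.5

    def __post_init__(self):
        t = np.asarray(self.times_ms, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times_ms must be a strictly increasing 1-D grid")
        steps = np.diff(t)
        if not np.allclose(steps, steps[0]):
            raise ValueError("times_ms must use a fixed step")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        self.times_ms = t

    def _bump(self) -> np.ndarray:
        t = self.times_ms
        return np.exp(-0.5 * ((t - self.peak_ms) / self.width_ms) ** 2) * (t > 0)

    def beta_curve(self, predictor: str, wl: int) -> np.ndarray:
        """Embedded coefficient time course for one predictor and feedback sign."""
        curve = self.amplitudes[predictor] * self._bump()
        if wl == -1:
            t = self.times_ms
            lo = self.loss_attenuation_ms
            ramp = np.clip(1.0 - (t - lo) / self.loss_ramp_ms, 0.0, 1.0)
            curve = curve * ramp
        return curve

    def erp_baseline(self, wl: int) -> np.ndarray:
        t = self.times_ms
        wave = self.erp_scale * np.exp(-0.5 * ((t - 300.0) / 200.0) ** 2) * (t > 0)
        if wl == -1:
            wave = wave - self.frn_scale * np.exp(-0.5 * ((t - 250.0) / 60.0) ** 2)
        return wave


@dataclass
class EpochMatrix:
    """Per-trial signal time courses aligned to feedback onset (t = 0 ms).

    ``values`` is (n_trials x n_times); ``design`` carries the aligned
    per-trial context variables (one row per retained trial).
    """

    times_ms: np.ndarray
    values: np.ndarray
    design: pd.DataFrame

    def __post_init__(self):
        t = np.asarray(self.times_ms, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.design), t.size):
            raise ValueError(
                f"values shape {v.shape} does not match "
                f"({len(self.design)} trials, {t.size} time points)"
            )
        self.times_ms, self.values = t, v

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]


def simulate_neural_epochs(
    session: pd.DataFrame, spec: SignalSpec, rng, subject_gain: Optional[float] = None
) -> EpochMatrix:
    """Synthetic feedback-locked epochs for one session.

    One epoch per trial with defined lag-1 context (trial_in_block >= 2); the
    context variables are standardized over the retained trials before being
    injected, matching how the recovery analyses standardize them.
    """
    from .neural import build_context_design

    rng = _rng(rng)
    design = build_context_design(session)
    design = design.dropna(subset=["B", "C", "wl"]).reset_index(drop=True)
    if design.empty:
        raise ValueError("session has no trials with defined lag-1 context")

    a = design["A_raw"].to_numpy(dtype=float)
    a_sd = a.std()
    A = (a - a.mean()) / a_sd if a_sd > 0 else np.zeros_like(a)
    B = design["B"].to_numpy(dtype=float)
    C = design["C"].to_numpy(dtype=float)
    X = {"A": A, "B": B, "C": C, "AB": A * B}
    wl = design["wl"].to_numpy(dtype=int)

    gain = (
        subject_gain
        if subject_gain is not None
        else 1.0 + spec.subject_coefficient_sd * rng.standard_normal()
    )
    offset = spec.subject_offset_sd * rng.standard_normal()

    T = spec.times_ms.size
    values = np.empty((len(design), T))
    for w in (1, -1):
        mask = wl == w
        if not mask.any():
            continue
        contrib = np.tile(spec.erp_baseline(w), (mask.sum(), 1))
        for k, x in X.items():
            contrib += gain * np.outer(x[mask], spec.beta_curve(k, w))
        values[mask] = contrib
    values += offset + spec.noise_sd * rng.standard_normal(values.shape)
    return EpochMatrix(times_ms=spec.times_ms.copy(), values=values, design=design)


def simulate_ppi_dataset(
    n_subjects: int = 20,
    *,
    gamma: float = 0.5,
    coupling: str = "B",
    choice_coefs: Optional[dict] = None,
    signal_coefs: Optional[dict] = None,
    residual_sd: float = 1.0,
    config: Optional[SessionConfig] = None,
    rng=0,
) -> pd.DataFrame:
    """Constructed cohort in which residual signal modulates a choice pathway.

    For every retained trial the window-averaged signal is a linear function
    of the context variables plus an idiosyncratic residual ``d``; the next
    trial's switch is drawn from a logistic model whose ``coupling`` pathway
    (default the opponent lag-1 switch, B) is modulated by ``gamma * d``.
    With ``gamma=0`` and all coefficients zero this is the pure-noise null.
    Returns one row per trial with columns subject_id, wl, A, B, C, signal
    and next_switch, ready for :func:`foxrabbit.neural.ppi_analysis`.
    """
    from scipy.special import expit

    from .neural import build_context_design

    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    cc = {"A": 1.0, "B": 0.6, "C": 0.15, "AB": -0.15}
    if choice_coefs is not None:
        cc.update(choice_coefs)
    sc = {"A": 0.3, "B": 0.2, "C": 0.1, "AB": 0.0}
    if signal_coefs is not None:
        sc.update(signal_coefs)
    config = config if config is not None else SessionConfig()
    rng = _rng(rng)

    frames = []
    for i in range(n_subjects):
        session = simulate_session(config, rng)
        des = build_context_design(session).dropna(
            subset=["B", "C", "wl", "next_switch"]
        )
        a = des["A_raw"].to_numpy(float)
        A = (a - a.mean()) / a.std() if a.std() > 0 else np.zeros_like(a)
        B = des["B"].to_numpy(float)
        C = des["C"].to_numpy(float)
        AB = A * B
        X = {"A": A, "B": B, "C": C, "AB": AB}
        d = residual_sd * rng.standard_normal(len(des))
        signal = sum(sc[k] * X[k] for k in X) + d
        logit = sum(cc[k] * X[k] for k in X) + gamma * d * X[coupling]
        next_switch = (rng.random(len(des)) < expit(logit)).astype(float)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": f"s{i:03d}",
                    "wl": des["wl"].to_numpy(int),
                    "A": A, "B": B, "C": C,
                    "signal": signal,
                    "next_switch": next_switch,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
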