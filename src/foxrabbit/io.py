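"""Readers and writers for trial logs, epochs, parameters and fit results.

All formats are plain text: comma-separated, UTF-8, '.' decimal, empty
fields for missing values, header mandatory.  Every writer's output is
re-parseable by the corresponding reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ChoiceModelResults, ChoiceParams

__all__ = [
    "TRIAL_COLUMNS",
    "read_trial_log",
    "write_trial_log",
    "validate_trials",
    "write_epochs",
    "read_epochs",
    "read_params",
    "write_fit_results",
    "read_fit_results",
]

#: Canonical trial-log column order.
TRIAL_COLUMNS = [
    "subject_id", "dyad_id", "block", "trial_in_block", "role",
    "player_rule", "opponent_rule", "player_switch", "opponent_switch",
    "outcome", "action_error", "rt_ms", "opponent_rate",
]

_MANDATORY = [
    "subject_id", "block", "trial_in_block", "role", "player_rule",
    "opponent_rule", "outcome", "action_error",
]


def write_trial_log(trials: pd.DataFrame, path) -> Path:
    """Write a trial log as CSV (missing values as empty fields)."""
    path = Path(path)
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns]
    extra = [c for c in trials.columns if c not in cols]
    trials[cols + extra].to_csv(path, index=False, na_rep="")
    return path


def validate_trials(trials: pd.DataFrame, mode: str = "strict") -> list:
    """Check TrialRecord invariants; returns [(row_number, message), ...].

    ``mode="strict"`` additionally enforces the zero-sum outcome rule
    (fox wins exactly when rules match on non-error trials); use
    ``mode="basic"`` for random-feedback control logs, where outcomes are
    decoupled from rule matches by design.
    """
    problems = []
    err = trials["action_error"].to_numpy()
    outcome = trials["outcome"].to_numpy()
    bad_outcome = ~np.isin(outcome, ("win", "loss"))
    for i in np.flatnonzero(bad_outcome):
        problems.append((i, f"invalid outcome {outcome[i]!r}"))
    for i in np.flatnonzero((err == 1) & (outcome == "win")):
        problems.append((i, "action_error=1 must imply outcome=loss"))
    first = trials["trial_in_block"].to_numpy() == 1
    ps = trials["player_switch"].to_numpy(dtype=float)
    for i in np.flatnonzero(first & ~np.isnan(ps)):
        problems.append((i, "player_switch must be missing on first trial of block"))
    if mode == "strict":
        match = trials["player_rule"].to_numpy() == trials["opponent_rule"].to_numpy()
        is_fox = trials["role"].to_numpy() == "fox"
        should_win = np.where(is_fox, match, ~match)
        clean = err == 0
        wrong = clean & (should_win != (outcome == "win")) & ~bad_outcome
        for i in np.flatnonzero(wrong):
            problems.append(
                (i, f"outcome {outcome[i]!r} inconsistent with role/rule match "
                    "on a non-error trial")
            )
    return problems


def read_trial_log(path, column_map: dict | None = None, validate="strict") -> pd.DataFrame:
    """Read and validate a trial-log CSV.

    ``column_map`` maps file column names to the canonical names (for data
    deposited under other dialects).  ``validate`` is ``"strict"``,
    ``"basic"`` or ``False``; invariant violations raise a ValueError
    naming the offending rows (2-based file line numbers, after the header).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"trial log {path} is missing mandatory columns {missing}")
    for c in TRIAL_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    for c in ("player_switch", "opponent_switch", "rt_ms", "opponent_rate"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df["dyad_id"] = df["dyad_id"].fillna("").astype(str).replace("nan", "")
    df["action_error"] = pd.to_numeric(df["action_error"]).astype(int)
    if validate:
        problems = validate_trials(df, mode="strict" if validate is True or validate == "strict" else "basic")
        if problems:
            lines = "; ".join(f"row {i + 2}: {msg}" for i, msg in problems[:10])
            raise ValueError(
                f"trial log {path} violates invariants ({len(problems)} rows): {lines}"
            )
    return df


def write_epochs(em, path) -> tuple[Path, Path]:
    """Write one subject's epochs: wide CSV (trial_id + one column per time
    point) plus a sidecar ``*.times.csv`` time-grid file."""
    path = Path(path)
    times_path = path.with_suffix(".times.csv")
    wide = pd.DataFrame(em.values, columns=[f"t{int(t)}" for t in em.times_ms])
    wide.insert(0, "trial_id", np.arange(len(wide)))
    wide.to_csv(path, index=False)
    pd.DataFrame({"time_ms": em.times_ms}).to_csv(times_path, index=False)
    return path, times_path


def read_epochs(path, session: pd.DataFrame | None = None):
    """Read epochs written by :func:`write_epochs`.

    Returns an :class:`~foxrabbit.simulate.EpochMatrix` when ``session``
    (the matching trial log) is supplied — the context design is rebuilt
    from it and aligned by row order — else ``(times_ms, values)``.
    """
    path = Path(path)
    wide = pd.read_csv(path)
    times = pd.read_csv(path.with_suffix(".times.csv"))["time_ms"].to_numpy(float)
    values = wide.drop(columns=["trial_id"]).to_numpy(dtype=float)
    if values.shape[1] != times.size:
        raise ValueError("epoch file and time-grid sidecar disagree on grid size")
    if session is None:
        return times, values
    from .neural import build_context_design
    from .simulate import EpochMatrix

    design = build_context_design(session).reset_index(drop=True)
    if len(design) != values.shape[0]:
        raise ValueError(
            f"epoch rows ({values.shape[0]}) do not match retained trials "
            f"({len(design)}) of the session"
        )
    return EpochMatrix(times_ms=times, values=values, design=design)


def read_params(path) -> ChoiceParams:
    """Read model parameters from a JSON object or ``key=value`` lines."""
    text = Path(path).read_text().strip()
    if text.startswith("{"):
        d = json.loads(text)
    else:
        d = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            d[key.strip()] = float(val)
    unknown = set(d) - {"ms", "sm", "pe", "ss"}
    if unknown:
        raise ValueError(f"unknown parameter keys {sorted(unknown)}")
    return ChoiceParams(**{k: float(v) for k, v in d.items()})


def write_fit_results(results: ChoiceModelResults, path) -> Path:
    """Serialize a fit: ``# key: value`` header lines, then a parameter table."""
    path = Path(path)
    lines = [
        f"# method: {results.method}",
        f"# objective: {results.objective!r}",
        f"# r2: {results.r2!r}",
        f"# converged: {results.converged}",
        f"# nobs: {results.nobs}",
        "parameter,estimate,lo95,hi95",
    ]
    for _, row in results.params_frame().iterrows():
        lines.append(
            f"{row['parameter']},{row['estimate']!r},{row['lo95']!r},{row['hi95']!r}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_fit_results(path) -> dict:
    """Parse a file written by :func:`write_fit_results` into a dict with
    keys ``method, objective, r2, converged, nobs, table``."""
    header, rows = {}, []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            header[key.strip()] = val.strip()
        elif line and not line.startswith("parameter,"):
            name, est, lo, hi = line.split(",")
            rows.append(
                {"parameter": name, "estimate": float(est),
                 "lo95": float(lo), "hi95": float(hi)}
            )
    return {
        "method": header.get("method"),
        "objective": float(header.get("objective", "nan")),
        "r2": None if header.get("r2") == "None" else float(header["r2"]),
        "converged": header.get("converged") == "True",
        "nobs": int(header.get("nobs", 0)),
        "table": pd.DataFrame(rows),
    }
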