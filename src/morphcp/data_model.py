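"""Trial-level data structures for two-alternative forced-choice morph experiments.

A *trial* is one presentation of a morphed face drawn from a continuum between
two identities ("A" and "B"), followed by a forced choice between the two
original identities.  Trials are carried as a tidy :class:`pandas.DataFrame`
with one row per trial and the columns in :data:`TRIAL_COLUMNS`; the functions
here validate that frame, read and write it as CSV, and apply the standard
filtering rules used before reaction-time analysis.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: The nine design morph levels: percent of Identity B in the morph.
MORPH_LEVELS: tuple[int, ...] = tuple(range(10, 100, 10))

EXP1_CONDITIONS = ("unfamiliar_familiar", "unfamiliar_unfamiliar")
EXP2_CONDITIONS = (
    "stranger_friend",
    "stranger_self",
    "friend_self",
    "stranger_stranger",
    "friend_friend",
)
KNOWN_CONDITIONS = frozenset(EXP1_CONDITIONS) | frozenset(EXP2_CONDITIONS)

#: Conditions in which the Identity-B designation is arbitrary (both endpoints
#: equally familiar), so response curves must be label-symmetrized.
ARBITRARY_LABEL_CONDITIONS = frozenset(
    {"unfamiliar_unfamiliar", "stranger_stranger", "friend_friend"}
)

#: Reaction-time window retained for RT analysis, inclusive at both ends.
RT_MIN_MS = 150.0
RT_MAX_MS = 5000.0

TRIAL_COLUMNS = (
    "participant_id",
    "continuum_id",
    "condition",
    "morph_pct",
    "response",
    "rt_ms",
    "block",
)

CONTINUUM_COLUMNS = (
    "continuum_id",
    "identity_A",
    "identity_B",
    "condition",
    "b_is_more_familiar",
)


class SchemaError(ValueError):
    """A required column is missing from a trial or continuum table."""


class TrialValidationError(ValueError):
    """One or more rows violate the Trial invariants."""

    def __init__(self, message: str, rows: list[int]):
        super().__init__(message)
        self.rows = rows


@dataclasses.dataclass(frozen=True)
class MorphContinuum:
    """A morph continuum between two identities.

    ``b_is_more_familiar`` is meaningful only where familiarity differs
    between the endpoints; for the two-unfamiliar / two-friend control
    conditions the designation is arbitrary.
    """

    continuum_id: str
    identity_A: str
    identity_B: str
    condition: str
    b_is_more_familiar: bool

    def __post_init__(self):
        if self.identity_A == self.identity_B:
            raise ValueError(
                f"continuum {self.continuum_id!r}: endpoint identities must differ"
            )
        if self.condition not in KNOWN_CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclasses.dataclass(frozen=True)
class FilterReport:
    """Accounting of the reaction-time filter chain.

    Every input trial is attributed to exactly one bucket: retained, removed
    as too fast, removed as too slow, removed as a 50% (no-correct-answer)
    trial, or removed as incorrect.
    """

    n_input: int
    n_rt_fast: int
    n_rt_slow: int
    n_midpoint: int
    n_incorrect: int
    n_retained: int

    def __post_init__(self):
        counts = dataclasses.astuple(self)
        if any(c < 0 for c in counts):
            raise ValueError("filter counts must be nonnegative")
        removed = self.n_rt_fast + self.n_rt_slow + self.n_midpoint + self.n_incorrect
        if self.n_input != self.n_retained + removed:
            raise ValueError("filter report does not partition the input")

    def to_dict(self) -> dict[str, int]:
        return dataclasses.asdict(self)


def _check_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table against the Trial invariants.

    Returns the frame with canonical dtypes.  Raises
    :class:`TrialValidationError` listing the offending row indices (0-based
    data rows) on any violation, and :class:`SchemaError` on missing columns.
    """
    _check_columns(trials, TRIAL_COLUMNS, "trial")
    df = trials.copy()
    problems: list[str] = []
    bad_rows: set[int] = set()

    morph = pd.to_numeric(df["morph_pct"], errors="coerce")
    bad = ~morph.isin(MORPH_LEVELS)
    if bad.any():
        rows = list(np.flatnonzero(bad.to_numpy()))
        bad_rows.update(rows)
        problems.append(f"morph_pct outside design levels {MORPH_LEVELS} at rows {rows}")

    bad = ~df["condition"].isin(KNOWN_CONDITIONS)
    if bad.any():
        rows = list(np.flatnonzero(bad.to_numpy()))
        bad_rows.update(rows)
        problems.append(f"unknown condition label at rows {rows}")

    bad = ~df["response"].isin(["A", "B"])
    if bad.any():
        rows = list(np.flatnonzero(bad.to_numpy()))
        bad_rows.update(rows)
        problems.append(f"response must be 'A' or 'B' at rows {rows}")

    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    bad = ~(rt > 0)
    if bad.any():
        rows = list(np.flatnonzero(bad.to_numpy()))
        bad_rows.update(rows)
        problems.append(f"rt_ms must be positive at rows {rows}")

    if problems:
        raise TrialValidationError("; ".join(problems), sorted(bad_rows))

    df["morph_pct"] = morph.astype(int)
    df["rt_ms"] = rt.astype(float)
    df["block"] = pd.to_numeric(df["block"]).astype(int)
    for col in ("participant_id", "continuum_id", "condition", "response"):
        df[col] = df[col].astype(str)
    return df


def infer_continua(trials: pd.DataFrame) -> pd.DataFrame:
    """Infer the continuum table from the distinct (continuum, condition) pairs.

    Endpoint identity labels are not recoverable from trials alone, so they are
    filled with placeholders derived from the continuum id;
    ``b_is_more_familiar`` is set by condition.
    """
    pairs = (
        trials[["continuum_id", "condition"]]
        .drop_duplicates()
        .sort_values(["condition", "continuum_id"])
        .reset_index(drop=True)
    )
    pairs["identity_A"] = pairs["continuum_id"] + "_A"
    pairs["identity_B"] = pairs["continuum_id"] + "_B"
    pairs["b_is_more_familiar"] = ~pairs["condition"].isin(ARBITRARY_LABEL_CONDITIONS)
    return pairs[list(CONTINUUM_COLUMNS)]


def read_trials(
    path: str | Path, continua_path: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a trial CSV (and optional continuum sidecar).

    Returns ``(trials, continua)``.  If no sidecar is given, continua are
    inferred from the trial table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty:
        raise TrialValidationError(f"trial table {path} contains no rows", [])
    trials = validate_trials(df)
    if continua_path is not None:
        continua = read_continua(continua_path)
    else:
        continua = infer_continua(trials)
    return trials, continua


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a validated trial table as CSV (stable column order, no index)."""
    validate_trials(trials)[list(TRIAL_COLUMNS)].to_csv(path, index=False)


def read_continua(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, CONTINUUM_COLUMNS, "continuum")
    # instantiating checks the per-continuum invariants
    for row in df.itertuples(index=False):
        MorphContinuum(
            str(row.continuum_id),
            str(row.identity_A),
            str(row.identity_B),
            str(row.condition),
            bool(row.b_is_more_familiar),
        )
    return df[list(CONTINUUM_COLUMNS)]


def write_continua(continua: pd.DataFrame, path: str | Path) -> None:
    continua[list(CONTINUUM_COLUMNS)].to_csv(path, index=False)


def is_correct(morph_pct: int, response: str) -> bool | None:
    """Whether a response matches the majority identity of the morph.

    Above 50% Identity B the correct response is ``"B"``; below, ``"A"``.
    At the 50% morph no correct answer exists and ``None`` is returned.
    """
    if morph_pct == 50:
        return None
    return response == ("B" if morph_pct > 50 else "A")


def correctness(trials: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`is_correct`: float Series with NaN at the 50% morph."""
    morph = trials["morph_pct"].to_numpy()
    resp_b = (trials["response"] == "B").to_numpy()
    out = np.where(morph > 50, resp_b, ~resp_b).astype(float)
    out[morph == 50] = np.nan
    return pd.Series(out, index=trials.index, name="correct")


def filter_for_rt(trials: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the reaction-time filter chain and account for every removal.

    Rules, applied in order (a trial is attributed to the first rule that
    removes it): the RT window [150 ms, 5000 ms] (inclusive bounds retained),
    removal of 50% morphs (no correct answer exists there), and removal of
    incorrect responses.  An empty retained set is allowed.
    """
    df = validate_trials(trials)
    n_input = len(df)
    rt = df["rt_ms"].to_numpy()
    fast = rt < RT_MIN_MS
    slow = rt > RT_MAX_MS
    in_window = ~(fast | slow)
    midpoint = in_window & (df["morph_pct"] == 50).to_numpy()
    corr = correctness(df).to_numpy()
    incorrect = in_window & ~midpoint & (corr == 0.0)
    keep = in_window & ~midpoint & ~incorrect
    report = FilterReport(
        n_input=n_input,
        n_rt_fast=int(fast.sum()),
        n_rt_slow=int(slow.sum()),
        n_midpoint=int(midpoint.sum()),
        n_incorrect=int(incorrect.sum()),
        n_retained=int(keep.sum()),
    )
    return df.loc[keep].copy(), report
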