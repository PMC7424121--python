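"""Response curves: percent-"Identity B" aggregation, symmetrization, bootstrap CIs.

The central summary is the response curve ``f(m)``: the mean percentage of
"Identity B" choices at each of the nine morph levels in one condition.  For
control conditions whose Identity-B designation is arbitrary, curves are
*symmetrized* by averaging each level with the label-flipped mirror level::

    f'(x) = (f(x) + 100 - f(100 - x)) / 2,      f'(50) = 50 exactly

Confidence intervals are percentile bootstrap intervals obtained by resampling
participants (the independent sampling units) with replacement; for
arbitrary-label conditions each replicate additionally re-randomizes the A/B
designation of every control continuum before symmetrizing, so the interval
reflects the arbitrariness of the labeling as well as sampling noise.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import ARBITRARY_LABEL_CONDITIONS, MORPH_LEVELS, validate_trials

DEFAULT_N_BOOT = 10_000


@dataclasses.dataclass
class ResponseCurve:
    """Mean percent Identity-B response per morph level, with optional CIs.

    ``f``, ``ci_low``, ``ci_high`` and ``n_trials`` map morph level -> value;
    a design level with no trials is present with ``NaN`` and listed in
    ``missing_levels`` rather than silently reported as 0.
    """

    condition: str
    f: dict[int, float]
    n_trials: dict[int, int]
    ci_low: dict[int, float] | None = None
    ci_high: dict[int, float] | None = None
    symmetrized: bool = False
    levels: tuple[int, ...] = MORPH_LEVELS

    @property
    def missing_levels(self) -> tuple[int, ...]:
        return tuple(l for l in self.levels if np.isnan(self.f.get(l, np.nan)))

    def values(self) -> np.ndarray:
        return np.array([self.f[l] for l in self.levels])

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for l in self.levels:
            rows.append(
                dict(
                    condition=self.condition,
                    morph_pct=l,
                    mean_pct=self.f[l],
                    ci_low=None if self.ci_low is None else self.ci_low[l],
                    ci_high=None if self.ci_high is None else self.ci_high[l],
                    n=self.n_trials.get(l, 0),
                )
            )
        return pd.DataFrame(rows)


def _check_curve(curve: ResponseCurve) -> None:
    missing = [l for l in MORPH_LEVELS if l not in curve.f]
    if missing:
        raise ValueError(f"curve for {curve.condition!r} lacks level(s) {missing}")


def percent_b(
    trials: pd.DataFrame,
    condition: str,
    grouping: str = "per_participant",
) -> ResponseCurve:
    """Aggregate trials of one condition into a response curve.

    ``grouping="pooled"`` uses the grand trial proportion at each level;
    ``"per_participant"`` averages participant-level percentages with equal
    weight (the two coincide when trial counts are balanced).
    """
    if grouping not in ("pooled", "per_participant"):
        raise ValueError(f"unknown grouping {grouping!r}")
    df = validate_trials(trials)
    df = df[df["condition"] == condition]
    if df.empty:
        raise ValueError(f"no trials for condition {condition!r}")
    is_b = (df["response"] == "B").astype(float)
    f: dict[int, float] = {}
    n: dict[int, int] = {}
    for level in MORPH_LEVELS:
        sel = df["morph_pct"] == level
        n[level] = int(sel.sum())
        if n[level] == 0:
            f[level] = np.nan
        elif grouping == "pooled":
            f[level] = 100.0 * float(is_b[sel].mean())
        else:
            per = is_b[sel].groupby(df.loc[sel, "participant_id"]).mean()
            f[level] = 100.0 * float(per.mean())
    return ResponseCurve(condition=condition, f=f, n_trials=n)


def symmetrize(curve: ResponseCurve) -> ResponseCurve:
    """Average each level with its label-flipped mirror level.

    ``f'(x) = (f(x) + 100 - f(100-x))/2`` for x != 50 and ``f'(50) = 50``
    exactly.  Idempotent: symmetrizing a symmetrized curve changes nothing.
    Intended for conditions where the Identity-B designation is arbitrary.
    """
    _check_curve(curve)
    f = {
        l: 50.0 if l == 50 else (curve.f[l] + 100.0 - curve.f[100 - l]) / 2.0
        for l in curve.levels
    }
    n = {l: curve.n_trials.get(l, 0) + curve.n_trials.get(100 - l, 0) for l in curve.levels}
    if curve.symmetrized:
        n = dict(curve.n_trials)
    return ResponseCurve(
        condition=curve.condition, f=f, n_trials=n, symmetrized=True, levels=curve.levels
    )


# ---------------------------------------------------------------------------
# bootstrap machinery


def bootstrap_ci(
    trials: pd.DataFrame,
    statistic: Callable[[pd.DataFrame], np.ndarray],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    level: float = 0.95,
    unit: str = "participant_id",
) -> tuple[np.ndarray, np.ndarray]:
    """Generic percentile bootstrap over resampled sampling units.

    ``statistic`` maps a trial table to a float array; units (participants by
    default) are resampled with replacement and the percentile bounds of the
    replicate statistics are returned as ``(low, high)`` arrays.  This is the
    general-purpose route; the curve- and effect-specific helpers use an
    equivalent vectorized path.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    groups = [g for _, g in trials.groupby(unit, sort=True)]
    if len(groups) < 2:
        raise ValueError("bootstrap requires at least 2 sampling units")
    reps = []
    for _ in range(n_boot):
        pick = rng.integers(0, len(groups), size=len(groups))
        reps.append(np.atleast_1d(np.asarray(statistic(pd.concat([groups[i] for i in pick])), float)))
    reps_arr = np.vstack(reps)
    alpha = (1.0 - level) / 2.0
    return (
        np.quantile(reps_arr, alpha, axis=0),
        np.quantile(reps_arr, 1.0 - alpha, axis=0),
    )


def _cell_arrays(
    trials: pd.DataFrame, condition: str
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Per (participant, continuum, level) B-counts and trial counts."""
    df = trials[trials["condition"] == condition]
    if df.empty:
        raise ValueError(f"no trials for condition {condition!r}")
    participants = sorted(df["participant_id"].unique())
    continua = sorted(df["continuum_id"].unique())
    p_idx = pd.Categorical(df["participant_id"], categories=participants).codes
    c_idx = pd.Categorical(df["continuum_id"], categories=continua).codes
    l_idx = pd.Categorical(df["morph_pct"], categories=list(MORPH_LEVELS)).codes
    shape = (len(participants), len(continua), len(MORPH_LEVELS))
    k = np.zeros(shape)
    n = np.zeros(shape)
    np.add.at(k, (p_idx, c_idx, l_idx), (df["response"] == "B").to_numpy(float))
    np.add.at(n, (p_idx, c_idx, l_idx), 1.0)
    return k, n, participants, continua


def _curves_from_cells(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Equal-weight participant averaging of per-participant pooled percents.

    ``k``, ``n`` have shape (..., P, C, L); returns (..., L).
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        per_part = 100.0 * k.sum(axis=-2) / n.sum(axis=-2)
    with warnings.catch_warnings():
        # levels with no trials anywhere produce all-NaN slices by design
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(per_part, axis=-2)


def _symmetrize_values(vals: np.ndarray) -> np.ndarray:
    out = (vals + 100.0 - vals[..., ::-1]) / 2.0
    out[..., len(MORPH_LEVELS) // 2] = 50.0
    return out


def response_curve(
    trials: pd.DataFrame,
    condition: str,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    level: float = 0.95,
    symmetrize_labels: bool | None = None,
    chunk: int = 1000,
) -> ResponseCurve:
    """Response curve with participant-bootstrap percentile CIs.

    ``symmetrize_labels=None`` symmetrizes exactly the arbitrary-label control
    conditions.  When symmetrizing, every bootstrap replicate re-randomizes
    each continuum's A/B designation before symmetrizing, mirroring how the
    arbitrary designation would vary across label assignments.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    df = validate_trials(trials)
    if symmetrize_labels is None:
        symmetrize_labels = condition in ARBITRARY_LABEL_CONDITIONS
    point = percent_b(df, condition, grouping="per_participant")
    if symmetrize_labels:
        point = symmetrize(point)

    k, n, participants, continua = _cell_arrays(df, condition)
    P, C, _ = k.shape
    if P < 2:
        raise ValueError("bootstrap requires at least 2 participants")
    k_flip, n_flip = n[..., ::-1] - k[..., ::-1], n[..., ::-1]
    rng = np.random.default_rng(seed)
    alpha = (1.0 - level) / 2.0
    reps = np.empty((n_boot, len(MORPH_LEVELS)))
    for start in range(0, n_boot, chunk):
        b = min(chunk, n_boot - start)
        pick = rng.integers(0, P, size=(b, P))
        kk, nn = k[pick], n[pick]  # (b, P, C, L)
        if symmetrize_labels:
            flip = rng.integers(0, 2, size=(b, 1, C, 1)).astype(bool)
            kk = np.where(flip, k_flip[pick], kk)
            nn = np.where(flip, n_flip[pick], nn)
        vals = _curves_from_cells(kk, nn)
        if symmetrize_labels:
            vals = _symmetrize_values(vals)
        reps[start : start + b] = vals
    low = np.quantile(reps, alpha, axis=0)
    high = np.quantile(reps, 1.0 - alpha, axis=0)
    point.ci_low = dict(zip(MORPH_LEVELS, low))
    point.ci_high = dict(zip(MORPH_LEVELS, high))
    return point


def curves_to_frame(curves: Sequence[ResponseCurve]) -> pd.DataFrame:
    """Tidy table ``condition,morph_pct,mean_pct,ci_low,ci_high,n``."""
    return pd.concat([c.as_frame() for c in curves], ignore_index=True)
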