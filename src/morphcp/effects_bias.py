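"""Per-morph-level condition contrasts and the asymmetry-bias statistic.

Effect sizes are raw percentage-point differences between two response curves
at each morph level.  The sign convention is an explicit parameter because
both directions are in common use: comparing a familiar condition against its
control can be reported as control minus condition (a positive value at the
50% morph then means fewer "familiar" responses) or condition minus control.

The asymmetry bias quantifies, within a single condition, how conservatively
the "more familiar" label is used across mirror-image morph pairs::

    bias(x) = f(x) - (100 - f(100 - x))   for x in {10, 20, 30, 40}
    bias(50) = f(50) - 50

Negative values indicate a preference for the less familiar identity: a
perfectly label-symmetric curve has bias identically zero.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data_model import ARBITRARY_LABEL_CONDITIONS, MORPH_LEVELS, validate_trials
from .aggregation import (
    DEFAULT_N_BOOT,
    ResponseCurve,
    _cell_arrays,
    _check_curve,
    _curves_from_cells,
    _symmetrize_values,
    percent_b,
    symmetrize,
)

SIGN_CONVENTIONS = ("reference_minus_condition", "condition_minus_reference")

BIAS_LEVELS: tuple[int, ...] = (10, 20, 30, 40, 50)


@dataclasses.dataclass
class EffectTable:
    """Signed per-level difference between a condition curve and a reference."""

    comparison: tuple[str, str]  # (condition, reference)
    sign_convention: str
    effect: dict[int, float]
    ci_low: dict[int, float] | None = None
    ci_high: dict[int, float] | None = None

    def as_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                comparison=f"{self.comparison[0]}_vs_{self.comparison[1]}",
                morph_pct=l,
                effect=self.effect[l],
                ci_low=None if self.ci_low is None else self.ci_low[l],
                ci_high=None if self.ci_high is None else self.ci_high[l],
            )
            for l in MORPH_LEVELS
        ]
        return pd.DataFrame(rows)


@dataclasses.dataclass
class BiasTable:
    """Asymmetry bias per lower-half morph level for one condition."""

    condition: str
    bias: dict[int, float]
    ci_low: dict[int, float] | None = None
    ci_high: dict[int, float] | None = None

    def as_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                condition=self.condition,
                x=x,
                bias=self.bias[x],
                ci_low=None if self.ci_low is None else self.ci_low[x],
                ci_high=None if self.ci_high is None else self.ci_high[x],
            )
            for x in BIAS_LEVELS
        ]
        return pd.DataFrame(rows)


def effect_size(
    condition_curve: ResponseCurve,
    reference_curve: ResponseCurve,
    sign_convention: str = "reference_minus_condition",
) -> EffectTable:
    """Per-level signed difference between two response curves.

    Both curves must cover all nine levels; flipping the sign convention
    negates every effect exactly.
    """
    if sign_convention not in SIGN_CONVENTIONS:
        raise ValueError(f"unknown sign convention {sign_convention!r}")
    _check_curve(condition_curve)
    _check_curve(reference_curve)
    sign = 1.0 if sign_convention == "condition_minus_reference" else -1.0
    effect = {
        l: sign * (condition_curve.f[l] - reference_curve.f[l]) for l in MORPH_LEVELS
    }
    return EffectTable(
        comparison=(condition_curve.condition, reference_curve.condition),
        sign_convention=sign_convention,
        effect=effect,
    )


def effect_size_with_ci(
    trials: pd.DataFrame,
    condition: str,
    reference: str,
    sign_convention: str = "reference_minus_condition",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    level: float = 0.95,
    chunk: int = 1000,
) -> EffectTable:
    """Effect sizes with paired participant-bootstrap percentile CIs.

    Each replicate resamples one set of participants that feeds both curves
    (the pairing of conditions within participant is preserved), re-randomizes
    arbitrary continuum labels for whichever curve needs symmetrizing, and
    takes the per-level difference.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    df = validate_trials(trials)
    point = effect_size(
        _point_curve(df, condition), _point_curve(df, reference), sign_convention
    )
    sign = 1.0 if sign_convention == "condition_minus_reference" else -1.0

    rng = np.random.default_rng(seed)
    sides = {}
    for name in (condition, reference):
        k, n, participants, continua = _cell_arrays(df, name)
        sides[name] = dict(
            k=k,
            n=n,
            k_flip=n[..., ::-1] - k[..., ::-1],
            n_flip=n[..., ::-1],
            participants=participants,
            sym=name in ARBITRARY_LABEL_CONDITIONS,
        )
    parts = sides[condition]["participants"]
    if sides[reference]["participants"] != parts:
        raise ValueError(
            "paired effect bootstrap requires the same participants in both conditions"
        )
    P = len(parts)
    if P < 2:
        raise ValueError("bootstrap requires at least 2 participants")

    reps = np.empty((n_boot, len(MORPH_LEVELS)))
    for start in range(0, n_boot, chunk):
        b = min(chunk, n_boot - start)
        pick = rng.integers(0, P, size=(b, P))
        vals = {}
        for name, side in sides.items():
            kk, nn = side["k"][pick], side["n"][pick]
            if side["sym"]:
                C = side["k"].shape[1]
                flip = rng.integers(0, 2, size=(b, 1, C, 1)).astype(bool)
                kk = np.where(flip, side["k_flip"][pick], kk)
                nn = np.where(flip, side["n_flip"][pick], nn)
            v = _curves_from_cells(kk, nn)
            if side["sym"]:
                v = _symmetrize_values(v)
            vals[name] = v
        reps[start : start + b] = sign * (vals[condition] - vals[reference])
    alpha = (1.0 - level) / 2.0
    point.ci_low = dict(zip(MORPH_LEVELS, np.quantile(reps, alpha, axis=0)))
    point.ci_high = dict(zip(MORPH_LEVELS, np.quantile(reps, 1.0 - alpha, axis=0)))
    return point


def _point_curve(df: pd.DataFrame, condition: str) -> ResponseCurve:
    curve = percent_b(df, condition, grouping="per_participant")
    if condition in ARBITRARY_LABEL_CONDITIONS:
        curve = symmetrize(curve)
    return curve


def asymmetry_bias(curve: ResponseCurve) -> BiasTable:
    """Asymmetry bias of a response curve with a meaningful Identity-B label."""
    _check_curve(curve)
    bias = {
        x: curve.f[x] - (100.0 - curve.f[100 - x]) if x != 50 else curve.f[50] - 50.0
        for x in BIAS_LEVELS
    }
    return BiasTable(condition=curve.condition, bias=bias)


def asymmetry_bias_with_ci(
    trials: pd.DataFrame,
    condition: str,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    level: float = 0.95,
    chunk: int = 1000,
) -> BiasTable:
    """Asymmetry bias with participant-bootstrap percentile CIs."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    df = validate_trials(trials)
    point = asymmetry_bias(_point_curve(df, condition))
    k, n, participants, _ = _cell_arrays(df, condition)
    P = len(participants)
    if P < 2:
        raise ValueError("bootstrap requires at least 2 participants")
    rng = np.random.default_rng(seed)
    idx50 = len(MORPH_LEVELS) // 2
    reps = np.empty((n_boot, len(BIAS_LEVELS)))
    for start in range(0, n_boot, chunk):
        b = min(chunk, n_boot - start)
        pick = rng.integers(0, P, size=(b, P))
        vals = _curves_from_cells(k[pick], n[pick])  # (b, L)
        bias = vals[:, : idx50 + 1] - (100.0 - vals[:, ::-1][:, : idx50 + 1])
        bias[:, idx50] = vals[:, idx50] - 50.0
        reps[start : start + b] = bias
    alpha = (1.0 - level) / 2.0
    point.ci_low = dict(zip(BIAS_LEVELS, np.quantile(reps, alpha, axis=0)))
    point.ci_high = dict(zip(BIAS_LEVELS, np.quantile(reps, 1.0 - alpha, axis=0)))
    return point
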