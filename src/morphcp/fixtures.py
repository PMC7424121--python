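"""Packaged reference tables and fixture builders.

These transcribe the published summary tables of the two morphed-face
experiments: mean percent "Identity B" response per morph level with 95%
bootstrap CIs (the familiar and control continua of the blocked experiment,
and the five conditions of the intermixed experiment), plus the mean correct
reaction times.  They serve as worked-example inputs: the effects stage run
on these curves reproduces the published per-level effect sizes.

`exp1_trial_fixture` additionally builds a trial-level table of the blocked
design (15 participants x 6 continua x 9 levels x 12 repetitions = 9,720
rows) whose aggregated curve is as close to the familiar-condition reference
table as integer response counts allow: with 540 trials per level the
percentage grid has steps of ~0.185, so each level matches the printed value
to within half a grid step (< 0.1 percentage points).

Note one internal inconsistency of the source tables, preserved verbatim:
the stranger-with-stranger rows at levels 70/80/90 duplicate the
stranger-with-self rows and do not reproduce the published tail effect sizes,
so tail-level contrasts for the intermixed experiment are not used as
reference values anywhere in this package.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .aggregation import ResponseCurve
from .data_model import MORPH_LEVELS, TRIAL_COLUMNS, infer_continua, write_continua, write_trials

# level: (mean_pct, ci_low, ci_high)
EXP1_FAMILIAR = {  # unfamiliar -> familiar continua; Identity B = the familiar face
    10: (5.4, 2.8, 8.1),
    20: (6.3, 3.1, 10.0),
    30: (7.5, 4.8, 10.3),
    40: (16.3, 11.7, 21.5),
    50: (41.3, 34.6, 47.4),
    60: (79.1, 73.1, 83.7),
    70: (91.4, 87.6, 94.6),
    80: (95.4, 92.4, 98.0),
    90: (97.0, 94.1, 98.9),
}

EXP1_CONTROL = {  # unfamiliar-unfamiliar continua, symmetrized around 50
    10: (4.8, 1.7, 9.4),
    20: (5.9, 2.4, 10.2),
    30: (9.2, 5.2, 13.9),
    40: (20.2, 15.6, 25.1),
    50: (50.0, 44.6, 55.2),
    60: (79.8, 74.9, 84.4),
    70: (90.8, 86.1, 94.8),
    80: (94.1, 89.8, 97.6),
    90: (95.2, 90.6, 98.3),
}

EXP2_CURVES = {
    "stranger_friend": {
        10: (3.2, 1.8, 4.5),
        20: (4.5, 3.0, 6.2),
        30: (4.7, 3.2, 6.4),
        40: (12.8, 10.3, 15.3),
        50: (36.4, 32.7, 39.3),
        60: (77.9, 74.8, 81.0),
        70: (94.3, 92.5, 96.2),
        80: (97.5, 96.2, 98.7),
        90: (98.0, 96.8, 99.0),
    },
    "stranger_self": {
        10: (2.4, 0.7, 4.4),
        20: (2.7, 1.0, 4.8),
        30: (4.7, 2.7, 7.1),
        40: (11.4, 8.4, 14.4),
        50: (30.2, 26.2, 34.6),
        60: (59.3, 54.6, 64.0),
        70: (86.0, 82.3, 89.3),
        80: (85.3, 81.7, 89.0),
        90: (88.9, 85.9, 91.9),
    },
    "friend_self": {
        10: (2.7, 1.0, 4.3),
        20: (2.0, 0.7, 3.7),
        30: (5.4, 3.0, 8.0),
        40: (17.4, 13.7, 21.4),
        50: (37.4, 32.6, 42.4),
        60: (68.1, 63.1, 72.8),
        70: (91.9, 88.9, 94.9),
        80: (97.3, 95.3, 98.9),
        90: (98.3, 96.9, 99.7),
    },
    "stranger_stranger": {
        10: (11.1, 8.1, 14.1),
        20: (14.7, 11.0, 18.3),
        30: (14.0, 10.7, 17.7),
        40: (27.4, 22.7, 32.1),
        50: (50.0, 50.0, 50.0),
        60: (72.6, 67.9, 77.3),
        70: (86.0, 82.3, 89.3),
        80: (85.3, 81.7, 89.0),
        90: (88.9, 85.9, 91.9),
    },
    "friend_friend": {
        10: (3.0, 1.3, 5.0),
        20: (2.4, 1.0, 4.1),
        30: (5.0, 2.7, 7.4),
        40: (17.9, 13.8, 22.0),
        50: (50.0, 50.0, 50.0),
        60: (82.2, 78.1, 86.2),
        70: (95.0, 92.6, 97.3),
        80: (97.6, 95.9, 99.0),
        90: (97.0, 95.0, 98.6),
    },
}

# mean correct RT in seconds per level (no 50% level: no correct answer there)
EXP1_RT = {
    "unfamiliar_familiar": {10: 0.76, 20: 0.80, 30: 0.83, 40: 0.88, 60: 0.85, 70: 0.78, 80: 0.75, 90: 0.74},
    "unfamiliar_unfamiliar": {10: 0.67, 20: 0.71, 30: 0.75, 40: 0.83, 60: 0.83, 70: 0.75, 80: 0.71, 90: 0.67},
}

EXP2_RT = {
    "stranger_friend": {10: 0.70, 20: 0.72, 30: 0.74, 40: 0.80, 60: 0.75, 70: 0.71, 80: 0.71, 90: 0.66},
    "stranger_self": {10: 0.69, 20: 0.73, 30: 0.75, 40: 0.75, 60: 0.79, 70: 0.74, 80: 0.64, 90: 0.67},
    "friend_self": {10: 0.74, 20: 0.71, 30: 0.70, 40: 0.83, 60: 0.78, 70: 0.71, 80: 0.70, 90: 0.68},
    "stranger_stranger": {10: 0.78, 20: 0.77, 30: 0.88, 40: 0.96, 60: 0.91, 70: 0.83, 80: 0.80, 90: 0.76},
    "friend_friend": {10: 0.67, 20: 0.69, 30: 0.72, 40: 0.80, 60: 0.79, 70: 0.71, 80: 0.67, 90: 0.70},
}

#: Trials per level per condition in the blocked design: 15 participants x
#: 3 continua x 12 repetitions.
EXP1_TRIALS_PER_LEVEL = 540


def _curve(condition: str, table: dict, symmetrized: bool, n_per_level: int) -> ResponseCurve:
    return ResponseCurve(
        condition=condition,
        f={l: table[l][0] for l in MORPH_LEVELS},
        ci_low={l: table[l][1] for l in MORPH_LEVELS},
        ci_high={l: table[l][2] for l in MORPH_LEVELS},
        n_trials={l: n_per_level for l in MORPH_LEVELS},
        symmetrized=symmetrized,
    )


def exp1_familiar_curve() -> ResponseCurve:
    return _curve("unfamiliar_familiar", EXP1_FAMILIAR, False, EXP1_TRIALS_PER_LEVEL)


def exp1_control_curve() -> ResponseCurve:
    return _curve("unfamiliar_unfamiliar", EXP1_CONTROL, True, EXP1_TRIALS_PER_LEVEL)


def exp2_curve(condition: str) -> ResponseCurve:
    if condition not in EXP2_CURVES:
        raise KeyError(condition)
    sym = condition in ("stranger_stranger", "friend_friend")
    # per level per condition: 15 participants x (continua x reps) varies; use
    # stranger_friend's 600 (4 continua x 10 reps x 15) as the densest case
    n = {"stranger_friend": 600, "stranger_self": 300, "friend_self": 300,
         "stranger_stranger": 150, "friend_friend": 150}[condition]
    return _curve(condition, EXP2_CURVES[condition], sym, n)


def _allocate_counts(total_b: int, cells: int, per_cell: int) -> np.ndarray:
    """Spread ``total_b`` B-responses over ``cells`` cells of ``per_cell``
    trials each, as evenly as integers allow."""
    base = total_b // cells
    extra = total_b - base * cells
    counts = np.full(cells, base)
    counts[:extra] += 1
    if counts.max() > per_cell:
        raise ValueError("cannot allocate counts")
    return counts


def exp1_trial_fixture() -> pd.DataFrame:
    """Blocked-design trial table whose aggregated curves are the closest
    integer-count realization of the packaged reference curves.

    The familiar condition targets its printed percentages directly; the
    control condition's raw counts are built point-symmetric (count at level
    x plus count at 100-x equals the level total), so its symmetrized curve
    equals its raw curve and matches the printed symmetric values.  RTs are
    filled with a neutral 700 ms; they carry no information here.
    """
    participants = [f"P{i + 1:02d}" for i in range(15)]
    rows: list[dict] = []
    for cond, prefix, table in (
        ("unfamiliar_familiar", "uf", {l: EXP1_FAMILIAR[l][0] for l in MORPH_LEVELS}),
        ("unfamiliar_unfamiliar", "uu", {l: EXP1_CONTROL[l][0] for l in MORPH_LEVELS}),
    ):
        continua = [f"{prefix}{j + 1}" for j in range(3)]
        cells = len(participants) * len(continua)  # 45 cells x 12 trials
        targets = {}
        for l in MORPH_LEVELS:
            if cond == "unfamiliar_unfamiliar" and l > 50:
                targets[l] = EXP1_TRIALS_PER_LEVEL - targets[100 - l]
            elif cond == "unfamiliar_unfamiliar" and l == 50:
                targets[l] = EXP1_TRIALS_PER_LEVEL // 2
            else:
                targets[l] = int(round(table[l] / 100.0 * EXP1_TRIALS_PER_LEVEL))
        for l in MORPH_LEVELS:
            counts = _allocate_counts(targets[l], cells, 12)
            for idx, (pid, cid) in enumerate(
                (p, c) for p in participants for c in continua
            ):
                n_b = int(counts[idx])
                for r in range(12):
                    rows.append(
                        dict(
                            participant_id=pid,
                            continuum_id=cid,
                            condition=cond,
                            morph_pct=l,
                            response="B" if r < n_b else "A",
                            rt_ms=700.0,
                            block=r // 4,
                        )
                    )
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))


def reference_tables() -> dict[str, pd.DataFrame]:
    """All packaged tables in tidy form, keyed by a short name."""
    out: dict[str, pd.DataFrame] = {}
    exp1 = pd.concat(
        [exp1_familiar_curve().as_frame(), exp1_control_curve().as_frame()],
        ignore_index=True,
    )
    out["exp1_curves"] = exp1
    out["exp2_curves"] = pd.concat(
        [exp2_curve(c).as_frame() for c in EXP2_CURVES], ignore_index=True
    )
    rt_rows = []
    for exp, tables in (("exp1", EXP1_RT), ("exp2", EXP2_RT)):
        for cond, table in tables.items():
            rt_rows.extend(
                dict(experiment=exp, condition=cond, morph_pct=l, mean_rt_s=v)
                for l, v in table.items()
            )
    out["rt_means"] = pd.DataFrame(rt_rows)
    return out


def make_fixtures(out_dir: str | Path) -> list[Path]:
    """Write every packaged table plus the blocked-design trial fixture."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in reference_tables().items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.6g")
        written.append(path)
    trials = exp1_trial_fixture()
    tpath = out_dir / "exp1_trials_synthetic.csv"
    write_trials(trials, tpath)
    written.append(tpath)
    cpath = out_dir / "exp1_continua_synthetic.csv"
    write_continua(infer_continua(trials), cpath)
    written.append(cpath)
    return written
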