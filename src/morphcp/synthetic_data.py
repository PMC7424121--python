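"""Synthetic trial generator for the two morphed-face 2AFC designs.

The generator emulates the statistical structure the analysis pipeline
assumes, not the images: a lapse-adjusted logistic choice rule whose
categorical boundary (PSE) shifts by condition, crossed Gaussian random
intercepts for participants and morph continua on the logit scale, and
lognormal reaction times whose location peaks at the ambiguous 50% morph.

Choice model, for morph percent ``m`` in condition ``k``, participant ``i``,
continuum ``c``::

    P(response = B) = lapse/2 + (1 - lapse) * expit(slope*(m - pse_k) + u_i + v_c)

with ``u_i ~ N(0, sd_participant^2)`` and ``v_c ~ N(0, sd_continuum^2)``.
Setting ``lapse = 0`` gives the plain random-intercept logistic model that the
inference module fits.

Reaction times are lognormal in milliseconds with location::

    rt_base_log + rt_condition_offsets[k] + rt_ambiguity_gain * (1 - |m - 50| / 40)

scale ``rt_sd_log``, truncated to at most 10 s.

Two designs are built in.  ``exp1``: every participant sees the same six
continua (three with a familiar Identity B, three all-unfamiliar controls),
nine morph levels, 12 presentations per morph image, blocked by condition
(six blocks of 108 trials).  ``exp2``: each participant has ten unique
continua over five familiarity conditions (4 stranger-friend,
2 stranger-self, 2 friend-self, 1 stranger-stranger, 1 friend-friend), ten
presentations per stimulus, intermixed in ten blocks of 90 trials.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    ARBITRARY_LABEL_CONDITIONS,
    CONTINUUM_COLUMNS,
    EXP1_CONDITIONS,
    EXP2_CONDITIONS,
    MORPH_LEVELS,
    TRIAL_COLUMNS,
)

#: Upper truncation of generated reaction times, ms.
RT_CAP_MS = 10_000.0

_DEFAULT_PSE = {
    "exp1": {"unfamiliar_familiar": 55.0, "unfamiliar_unfamiliar": 50.0},
    "exp2": {
        "stranger_friend": 55.0,
        "stranger_self": 57.0,
        "friend_self": 55.0,
        "stranger_stranger": 50.0,
        "friend_friend": 50.0,
    },
}

_DEFAULT_RT_OFFSETS = {
    "exp1": {"unfamiliar_familiar": 0.08, "unfamiliar_unfamiliar": 0.0},
    "exp2": {
        "stranger_friend": 0.0,
        "stranger_self": 0.0,
        "friend_self": 0.0,
        "stranger_stranger": 0.12,
        "friend_friend": 0.0,
    },
}

#: Continuum multiplicities per participant in the exp2 design.
EXP2_CONTINUA_PER_PARTICIPANT = {
    "stranger_friend": 4,
    "stranger_self": 2,
    "friend_self": 2,
    "stranger_stranger": 1,
    "friend_friend": 1,
}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclasses.dataclass
class SimulationConfig:
    """Full generative specification of one simulated experiment.

    Parameters
    ----------
    design:
        ``"exp1"`` or ``"exp2"`` (see module docstring for the layouts).
    n_participants:
        Number of simulated participants (both designs used 15).
    pse_by_condition:
        Boundary location per condition in morph-percent units; ``None``
        selects the design default (50 for controls, a 5-7 point shift toward
        Identity B for the more-familiar-B conditions).
    slope:
        Logistic steepness per morph-percent unit.
    lapse:
        Probability of a stimulus-independent guess trial; the guess is
        symmetric (B with probability 1/2).  0 disables lapsing.
    sd_participant, sd_continuum:
        Standard deviations of the crossed random intercepts (logit scale).
    rt_base_log:
        Mean log-RT (log ms) at unambiguous morphs for a zero-offset condition.
    rt_ambiguity_gain:
        Added mean log-RT at the 50% morph, interpolated linearly by
        ``1 - |m - 50|/40``.
    rt_condition_offsets:
        Additive log-RT shift per condition; ``None`` selects design defaults.
    rt_sd_log:
        Lognormal scale of RTs.
    seed:
        Seed for the whole simulation; identical configs produce identical
        output.
    """

    design: str = "exp1"
    n_participants: int = 15
    pse_by_condition: Mapping[str, float] | None = None
    slope: float = 0.12
    lapse: float = 0.02
    sd_participant: float = 0.5
    sd_continuum: float = 0.3
    rt_base_log: float = 6.48
    rt_ambiguity_gain: float = 0.2
    rt_condition_offsets: Mapping[str, float] | None = None
    rt_sd_log: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if self.design not in ("exp1", "exp2"):
            raise ConfigError(f"unknown design {self.design!r}")
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if not 0.0 <= self.lapse <= 1.0:
            raise ConfigError("lapse must be in [0, 1]")
        if self.sd_participant < 0 or self.sd_continuum < 0:
            raise ConfigError("random-intercept standard deviations must be >= 0")
        if self.rt_ambiguity_gain < 0:
            raise ConfigError("rt_ambiguity_gain must be >= 0")
        if self.rt_sd_log <= 0:
            raise ConfigError("rt_sd_log must be > 0")
        conditions = self.conditions()
        for field in ("pse_by_condition", "rt_condition_offsets"):
            mapping = getattr(self, field)
            if mapping is not None:
                unknown = set(mapping) - set(conditions)
                if unknown:
                    raise ConfigError(f"{field} names unknown condition(s): {unknown}")
                missing = set(conditions) - set(mapping)
                if missing:
                    raise ConfigError(f"{field} is missing condition(s): {missing}")

    def conditions(self) -> tuple[str, ...]:
        return EXP1_CONDITIONS if self.design == "exp1" else EXP2_CONDITIONS

    def resolved_pse(self) -> dict[str, float]:
        src = self.pse_by_condition or _DEFAULT_PSE[self.design]
        return {k: float(v) for k, v in src.items()}

    def resolved_rt_offsets(self) -> dict[str, float]:
        src = self.rt_condition_offsets or _DEFAULT_RT_OFFSETS[self.design]
        return {k: float(v) for k, v in src.items()}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pse_by_condition"] = self.resolved_pse()
        d["rt_condition_offsets"] = self.resolved_rt_offsets()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load a config from a YAML (or JSON, a YAML subset) file."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)


def _exp1_layout(n_participants: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One row per trial (without responses) plus the continuum table."""
    continua = []
    for j, cond in enumerate(["unfamiliar_familiar"] * 3 + ["unfamiliar_unfamiliar"] * 3):
        cid = f"{'uf' if cond == 'unfamiliar_familiar' else 'uu'}{j % 3 + 1}"
        continua.append(
            dict(
                continuum_id=cid,
                identity_A=f"{cid}_A",
                identity_B=f"{cid}_B",
                condition=cond,
                b_is_more_familiar=cond not in ARBITRARY_LABEL_CONDITIONS,
            )
        )
    cont_df = pd.DataFrame(continua, columns=list(CONTINUUM_COLUMNS))

    rows = []
    participants = [f"P{i + 1:02d}" for i in range(n_participants)]
    for pid in participants:
        block = 0
        for cond in EXP1_CONDITIONS:
            cids = cont_df.loc[cont_df["condition"] == cond, "continuum_id"]
            # 3 blocks per condition; each block holds every morph image 4x
            for _ in range(3):
                for cid in cids:
                    for m in MORPH_LEVELS:
                        rows.extend(
                            dict(
                                participant_id=pid,
                                continuum_id=cid,
                                condition=cond,
                                morph_pct=m,
                                block=block,
                            )
                            for _ in range(4)
                        )
                block += 1
    return pd.DataFrame(rows), cont_df


def _exp2_layout(n_participants: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    continua = []
    participants = [f"P{i + 1:02d}" for i in range(n_participants)]
    for pid in participants:
        for cond, count in EXP2_CONTINUA_PER_PARTICIPANT.items():
            short = "".join(w[0] for w in cond.split("_"))
            for j in range(count):
                cid = f"{pid}_{short}{j + 1}"
                continua.append(
                    dict(
                        continuum_id=cid,
                        identity_A=f"{cid}_A",
                        identity_B=f"{cid}_B",
                        condition=cond,
                        b_is_more_familiar=cond not in ARBITRARY_LABEL_CONDITIONS,
                        participant_id=pid,
                    )
                )
    cont_df = pd.DataFrame(continua)

    rows = []
    for pid in participants:
        own = cont_df[cont_df["participant_id"] == pid]
        # 10 blocks; each block presents every unique stimulus exactly once
        for block in range(10):
            for row in own.itertuples(index=False):
                for m in MORPH_LEVELS:
                    rows.append(
                        dict(
                            participant_id=pid,
                            continuum_id=row.continuum_id,
                            condition=row.condition,
                            morph_pct=m,
                            block=block,
                        )
                    )
    return pd.DataFrame(rows), cont_df[list(CONTINUUM_COLUMNS)]


def _shuffle_no_repeat(
    frame: pd.DataFrame, rng: np.random.Generator, max_retries: int = 50
) -> pd.DataFrame:
    """Shuffle trials within each (participant, block) so that the same
    continuum never appears on consecutive trials.

    Sequential sampling: each next trial is drawn proportional to the
    remaining per-continuum counts, excluding the previous continuum; a
    continuum holding a strict majority of the remaining trials is forced
    (otherwise no valid completion exists).  The rare dead ends restart the
    block, with a retry cap.  Trial order is cosmetic for every analysis in
    this package; it is randomized only so simulated tables look like real
    session logs.
    """

    def reorder(idx_by_cont: list[np.ndarray]) -> np.ndarray:
        n_cont = len(idx_by_cont)
        total = sum(len(a) for a in idx_by_cont)
        for _ in range(max_retries):
            counts = np.array([len(a) for a in idx_by_cont], float)
            pos = np.zeros(n_cont, int)
            shuffled = [rng.permutation(a) for a in idx_by_cont]
            order = np.empty(total, dtype=np.int64)
            prev = -1
            dead_end = False
            for t in range(total):
                remaining = counts.sum()
                forced = np.flatnonzero(counts > remaining / 2.0)
                if forced.size and forced[0] != prev:
                    c = int(forced[0])
                else:
                    w = counts.copy()
                    if prev >= 0:
                        w[prev] = 0.0
                    if w.sum() <= 0:
                        dead_end = True  # only the previous continuum remains
                        break
                    c = int(rng.choice(n_cont, p=w / w.sum()))
                order[t] = shuffled[c][pos[c]]
                pos[c] += 1
                counts[c] -= 1
                prev = c
            if not dead_end:
                return order
        raise RuntimeError("could not order block without consecutive repeats")

    pieces = []
    for _, grp in frame.groupby(["participant_id", "block"], sort=True):
        by_cont = [
            sub.index.to_numpy() for _, sub in grp.groupby("continuum_id", sort=True)
        ]
        pieces.append(reorder(by_cont))
    return frame.loc[np.concatenate(pieces)].reset_index(drop=True)


def simulate(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate one simulated experiment.

    Returns ``(trials, continua, truth)`` where ``trials`` is a validated
    trial table, ``continua`` the matching continuum table, and ``truth``
    records every latent draw: participant and continuum intercepts, per-trial
    lapse indicators and choice probabilities, and the resolved config.
    """
    rng = np.random.default_rng(config.seed)
    layout, continua = (
        _exp1_layout(config.n_participants)
        if config.design == "exp1"
        else _exp2_layout(config.n_participants)
    )
    layout = _shuffle_no_repeat(layout, rng)

    participants = sorted(layout["participant_id"].unique())
    cont_ids = list(continua["continuum_id"])
    u = dict(zip(participants, config.sd_participant * rng.standard_normal(len(participants))))
    v = dict(zip(cont_ids, config.sd_continuum * rng.standard_normal(len(cont_ids))))

    pse = config.resolved_pse()
    m = layout["morph_pct"].to_numpy(float)
    eta = (
        config.slope * (m - layout["condition"].map(pse).to_numpy(float))
        + layout["participant_id"].map(u).to_numpy(float)
        + layout["continuum_id"].map(v).to_numpy(float)
    )
    p_psycho = 1.0 / (1.0 + np.exp(-eta))
    p_b = config.lapse / 2.0 + (1.0 - config.lapse) * p_psycho

    lapsed = rng.random(len(layout)) < config.lapse
    choice_b = np.where(lapsed, rng.random(len(layout)) < 0.5, rng.random(len(layout)) < p_psycho)

    offsets = config.resolved_rt_offsets()
    loc = (
        config.rt_base_log
        + layout["condition"].map(offsets).to_numpy(float)
        + config.rt_ambiguity_gain * (1.0 - np.abs(m - 50.0) / 40.0)
    )
    rt = np.exp(loc + config.rt_sd_log * rng.standard_normal(len(layout)))
    for _ in range(50):  # truncate to (0, 10 s] by redrawing the tail
        over = rt > RT_CAP_MS
        if not over.any():
            break
        rt[over] = np.exp(loc[over] + config.rt_sd_log * rng.standard_normal(int(over.sum())))
    np.minimum(rt, RT_CAP_MS, out=rt)

    trials = layout.copy()
    trials["response"] = np.where(choice_b, "B", "A")
    trials["rt_ms"] = rt
    trials = trials[list(TRIAL_COLUMNS)]

    truth = {
        "config": config.to_dict(),
        "participant_intercepts": {k: float(x) for k, x in u.items()},
        "continuum_intercepts": {k: float(x) for k, x in v.items()},
        "lapsed": lapsed,
        "p_b": p_b,
        "rt_location_log": loc,
    }
    return trials, continua, truth


def truth_to_json(truth: dict, path: str | Path) -> None:
    """Write the scalar part of a ground-truth record as JSON (per-trial
    arrays are summarized by counts)."""
    out = {
        "config": truth["config"],
        "participant_intercepts": truth["participant_intercepts"],
        "continuum_intercepts": truth["continuum_intercepts"],
        "n_lapsed": int(np.asarray(truth["lapsed"]).sum()),
        "n_trials": int(len(truth["p_b"])),
    }
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")
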