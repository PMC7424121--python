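import numpy as np
import pandas as pd
import pytest
from scipy import special

from morphcp import SimulationConfig, simulate, validate_trials
from morphcp.data_model import MORPH_LEVELS
from morphcp.synthetic_data import EXP2_CONTINUA_PER_PARTICIPANT, ConfigError


def percent_b_at(trials, condition, morph):
    sub = trials[(trials["condition"] == condition) & (trials["morph_pct"] == morph)]
    return 100.0 * (sub["response"] == "B").mean()


class TestConfig:
    def test_unknown_condition_in_pse_map_rejected(self):
        with pytest.raises(ConfigError, match="unknown condition"):
            SimulationConfig(design="exp1", pse_by_condition={"nope": 50.0})

    def test_incomplete_pse_map_rejected(self):
        with pytest.raises(ConfigError, match="missing"):
            SimulationConfig(design="exp1", pse_by_condition={"unfamiliar_familiar": 55.0})

    @pytest.mark.parametrize(
        "field,value",
        [("lapse", 1.5), ("sd_participant", -0.1), ("rt_sd_log", 0.0), ("design", "exp3")],
    )
    def test_invalid_scalars_rejected(self, field, value):
        with pytest.raises(ConfigError):
            SimulationConfig(**{field: value})

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = SimulationConfig(design="exp2", seed=3, slope=0.1)
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert SimulationConfig.from_file(path) == SimulationConfig.from_dict(cfg.to_dict())


class TestDesigns:
    def test_exp1_shape_and_validity(self, exp1_sim):
        trials, continua, _ = exp1_sim
        validate_trials(trials)
        assert len(trials) == 9720
        assert trials["participant_id"].nunique() == 15
        assert set(trials["condition"]) == {"unfamiliar_familiar", "unfamiliar_unfamiliar"}
        # every participant: 6 blocks of 108 trials
        sizes = trials.groupby(["participant_id", "block"]).size()
        assert (sizes == 108).all()

    def test_exp2_continuum_multiplicities(self, exp2_sim):
        trials, continua, _ = exp2_sim
        assert len(trials) == 15 * 10 * 90 == 13500
        per_cond = continua["condition"].value_counts() / 15
        for cond, count in EXP2_CONTINUA_PER_PARTICIPANT.items():
            assert per_cond[cond] == count
        sizes = trials.groupby(["participant_id", "block"]).size()
        assert (sizes == 90).all()

    def test_no_consecutive_same_continuum(self, exp1_sim, exp2_sim):
        for trials, _, _ in (exp1_sim, exp2_sim):
            for _, grp in trials.groupby(["participant_id", "block"]):
                cont = grp["continuum_id"].to_numpy()
                assert not (cont[1:] == cont[:-1]).any()

    def test_seed_determinism(self):
        cfg = SimulationConfig(design="exp2", seed=123)
        a, _, _ = simulate(cfg)
        b, _, _ = simulate(SimulationConfig(design="exp2", seed=123))
        c, _, _ = simulate(SimulationConfig(design="exp2", seed=124))
        pd.testing.assert_frame_equal(a, b)
        assert not a["response"].equals(c["response"])


class TestChoiceModel:
    def test_full_lapse_means_pure_guessing(self):
        trials, _, _ = simulate(SimulationConfig(design="exp1", lapse=1.0, seed=2))
        for cond in trials["condition"].unique():
            for m in (10, 50, 90):
                # binomial MC error on 540 trials: 3 SE ~ 6.5 points
                assert abs(percent_b_at(trials, cond, m) - 50.0) < 6.5

    def test_steep_slope_approaches_step_function(self):
        cfg = SimulationConfig(
            design="exp1", slope=10.0, lapse=0.0, sd_participant=0.0, sd_continuum=0.0,
            pse_by_condition={"unfamiliar_familiar": 50.0, "unfamiliar_unfamiliar": 50.0},
            seed=3,
        )
        trials, _, _ = simulate(cfg)
        for m in MORPH_LEVELS:
            pct = percent_b_at(trials, "unfamiliar_familiar", m)
            assert pct == (0.0 if m < 50 else 100.0 if m > 50 else pct)

    def test_midpoint_gap_matches_closed_form(self):
        """Empirical percent-B at the 50% morph vs numerical integration
        of lapse/2 + (1-lapse) E_u[expit(slope*(50-pse) + u)]."""
        cfg = SimulationConfig(
            design="exp1", slope=0.15, lapse=0.02, sd_participant=0.5, sd_continuum=0.0,
            pse_by_condition={"unfamiliar_familiar": 55.0, "unfamiliar_unfamiliar": 50.0},
            seed=42,
        )
        trials, _, _ = simulate(cfg)
        nodes, wts = np.polynomial.hermite.hermgauss(81)
        u = np.sqrt(2.0) * cfg.sd_participant * nodes
        expected = 100.0 * (
            cfg.lapse / 2.0
            + (1 - cfg.lapse) * np.sum(wts * special.expit(0.15 * (50 - 55) + u)) / np.sqrt(np.pi)
        )
        sub = trials[(trials["condition"] == "unfamiliar_familiar") & (trials["morph_pct"] == 50)]
        per_part = 100.0 * (sub["response"] == "B").groupby(sub["participant_id"]).mean()
        se = per_part.std(ddof=1) / np.sqrt(per_part.size)
        assert abs(per_part.mean() - expected) <= 3.0 * se
        # control condition sits at 50% by symmetry
        ctl = trials[(trials["condition"] == "unfamiliar_unfamiliar") & (trials["morph_pct"] == 50)]
        ctl_pp = 100.0 * (ctl["response"] == "B").groupby(ctl["participant_id"]).mean()
        assert abs(ctl_pp.mean() - 50.0) <= 3.0 * ctl_pp.std(ddof=1) / np.sqrt(ctl_pp.size)
        assert per_part.mean() < ctl_pp.mean()

    def test_marginal_curve_converges_to_analytic_psychometric(self):
        """At 10x the design repetition count the empirical curve tracks the
        analytic lapse-adjusted logistic within Monte-Carlo error."""
        cfg = SimulationConfig(
            design="exp1", n_participants=150, slope=0.12, lapse=0.04,
            sd_participant=0.0, sd_continuum=0.0, seed=8,
        )
        trials, _, _ = simulate(cfg)
        pse = cfg.resolved_pse()["unfamiliar_familiar"]
        for m in MORPH_LEVELS:
            p = cfg.lapse / 2 + (1 - cfg.lapse) * special.expit(cfg.slope * (m - pse))
            n = 150 * 3 * 12
            se = 100.0 * np.sqrt(p * (1 - p) / n)
            assert abs(percent_b_at(trials, "unfamiliar_familiar", m) - 100 * p) <= 4 * se


class TestReactionTimes:
    def test_ambiguity_gain_in_log_rt(self, exp1_sim):
        trials, _, truth = exp1_sim
        gain = truth["config"]["rt_ambiguity_gain"]
        for cond in trials["condition"].unique():
            mid = np.log(trials.loc[(trials["condition"] == cond) & (trials["morph_pct"] == 50), "rt_ms"])
            end = np.log(trials.loc[(trials["condition"] == cond) & (trials["morph_pct"] == 10), "rt_ms"])
            se = np.sqrt(mid.var(ddof=1) / len(mid) + end.var(ddof=1) / len(end))
            assert abs((mid.mean() - end.mean()) - gain) <= 3 * se

    def test_rt_truncated_to_ten_seconds(self):
        trials, _, _ = simulate(SimulationConfig(design="exp1", rt_base_log=9.0, seed=4))
        assert trials["rt_ms"].between(0, 10_000, inclusive="right").all()

    def test_condition_offset_shifts_log_rt(self, exp1_sim):
        trials, _, truth = exp1_sim
        off = truth["config"]["rt_condition_offsets"]["unfamiliar_familiar"]
        fam = np.log(trials.loc[trials["condition"] == "unfamiliar_familiar", "rt_ms"])
        ctl = np.log(trials.loc[trials["condition"] == "unfamiliar_unfamiliar", "rt_ms"])
        se = np.sqrt(fam.var(ddof=1) / len(fam) + ctl.var(ddof=1) / len(ctl))
        assert abs((fam.mean() - ctl.mean()) - off) <= 3 * se


def test_truth_records_all_latent_draws(exp1_sim):
    trials, continua, truth = exp1_sim
    assert set(truth["participant_intercepts"]) == set(trials["participant_id"])
    assert set(truth["continuum_intercepts"]) == set(continua["continuum_id"])
    assert len(truth["lapsed"]) == len(truth["p_b"]) == len(trials)
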