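"""Synthetic cohort generator: determinism, planted structure, task logic."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import socdisc as sd
from socdisc.errors import ConfigError, DataError


def _make_records(brackets):
    recs = []
    for i, b in enumerate(brackets):
        recs.append(
            sd.ParticipantRecord(
                id=f"P{i}", group="control", tripm_total=50, tripm_boldness=17,
                tripm_meanness=17, tripm_disinhibition=16, stab_total=60, age=30,
                gender="female", income_bracket=b, fluid_intelligence=5,
                attention_failures=0, committed_crime=0,
            )
        )
    return recs


class TestConfig:
    @pytest.mark.parametrize(
        "field, value",
        [
            ("n_control", 0),
            ("n_high", -3),
            ("logk_sd", 0.0),
            ("choice_temperature", -1.0),
            ("tripm_sd_by_group", (5.0, -1.0)),
            ("income_probs", (0.5, 0.5)),
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        cfg = dataclasses.replace(sd.CohortConfig(), **{field: value})
        with pytest.raises(ConfigError, match=field.split("_")[0]):
            sd.generate_cohort(cfg)


class TestGeneration:
    def test_determinism_and_group_sizes(self, small_cohort):
        cfg, records = small_cohort
        again = sd.generate_cohort(cfg)
        assert sd.synthetic.participants_frame(records).equals(sd.synthetic.participants_frame(again))
        assert sd.synthetic.choices_frame(records).equals(sd.synthetic.choices_frame(again))
        groups = pd.Series([r.group for r in records]).value_counts()
        assert groups["control"] == cfg.n_control and groups["high"] == cfg.n_high

    def test_moment_recovery_at_large_n(self):
        cfg = sd.CohortConfig(
            n_control=500, n_high=500, logk_mean_by_group=(-3.0, -1.5), logk_sd=1.0, seed=5
        )
        records = sd.generate_cohort(cfg)
        logk = np.array([r.latent_logk for r in records])
        high = np.array([r.group == "high" for r in records])
        tripm = np.array([r.tripm_total for r in records])
        for gi, mask in ((0, ~high), (1, high)):
            se = cfg.tripm_sd_by_group[gi] / math.sqrt(500)
            assert abs(tripm[mask].mean() - cfg.tripm_mean_by_group[gi]) < 3 * se
            assert abs(logk[mask].mean() - cfg.logk_mean_by_group[gi]) < 3 / math.sqrt(500)
        pooled_sd = math.sqrt((logk[high].var(ddof=1) + logk[~high].var(ddof=1)) / 2)
        std_diff = (logk[high].mean() - logk[~high].mean()) / pooled_sd
        assert abs(std_diff - 1.5) < 0.15

    def test_subscales_sum_to_total(self, small_cohort):
        _, records = small_cohort
        for r in records[:20]:
            assert r.tripm_boldness + r.tripm_meanness + r.tripm_disinhibition == pytest.approx(
                r.tripm_total
            )

    def test_blocks_cover_all_distances(self, small_cohort):
        _, records = small_cohort
        for r in records[:10]:
            assert tuple(b.social_distance for b in r.choice_blocks) == sd.task.SOCIAL_DISTANCES


class TestSimulateChoices:
    def test_threshold_rule_at_temperature_zero(self):
        # k = 1 gives v = 40 at N = 1: generous exactly when forgoing <= $40,
        # so the downstream indifference point is $115.
        blocks = sd.simulate_choices(0.0, temperature=0.0, seed=0)
        ip, violation = sd.extract_indifference(blocks[0])
        assert ip == 115.0 and not violation

    def test_extreme_discounter_forgoes_nothing(self):
        # v_N -> 0 for k -> inf: nothing with a positive price is shared, so
        # every block resolves to the $75 censoring point (v = 0). The final
        # $0-sacrifice trial may still be generous (costless sharing).
        blocks = sd.simulate_choices(12.0, temperature=0.0, seed=0)
        prof = sd.build_profile(blocks)
        assert prof.forgone_v == (0.0,) * 7
        for b in blocks:
            assert set(b.choices[:-1]) == {"selfish"}

    def test_huge_temperature_approaches_coin_flip(self):
        rates = []
        for seed in range(40):
            blocks = sd.simulate_choices(-2.0, temperature=1e9, seed=seed)
            rates.extend(c == "generous" for b in blocks for c in b.choices)
        assert abs(np.mean(rates) - 0.5) < 0.05

    def test_negative_temperature_rejected(self):
        with pytest.raises(ConfigError):
            sd.simulate_choices(-2.0, temperature=-0.1, seed=0)


class TestGroupAssignment:
    @pytest.mark.parametrize(
        "score, gender, expected",
        [
            (105, "male", "high"),
            (104, "male", "control"),
            (91, "female", "high"),
            (90, "other", "control"),
            (400, "female", "high"),
        ],
    )
    def test_cutoff_boundary(self, score, gender, expected):
        assert sd.assign_group(score, gender) == expected

    def test_missing_gender_cutoff(self):
        with pytest.raises(ConfigError):
            sd.assign_group(100, "nonbinary", cutoffs={"male": 105.0})


class TestExclusionsAndRecoding:
    def test_attention_check_threshold(self):
        recs = _make_records([2, 2, 4])
        recs[0].attention_failures = 2
        recs[1].attention_failures = 1
        recs[2].attention_failures = 4
        retained, excluded = sd.apply_exclusions(recs)
        assert [r.id for r in retained] == ["P1"]
        assert sorted(r.id for r, _ in excluded) == ["P0", "P2"]
        assert all("attention" in reason for _, reason in excluded)

    def test_attention_out_of_range(self):
        recs = _make_records([2])
        recs[0].attention_failures = 5
        with pytest.raises(DataError):
            sd.apply_exclusions(recs)

    def test_income_recode_round_half_up(self):
        recs = _make_records([2, 2, 4, None])
        out = sd.recode_income(recs)
        assert out[-1].income_bracket == 3  # mean 8/3 rounds half-up to 3
        assert [r.income_bracket for r in out[:3]] == [2, 2, 4]

    def test_income_recode_identity_and_constant(self):
        recs = _make_records([5, 5, 5])
        assert [r.income_bracket for r in sd.recode_income(recs)] == [5, 5, 5]
        recs = _make_records([5, 5, None])
        assert sd.recode_income(recs)[-1].income_bracket == 5

    def test_all_unknown_income_rejected(self):
        with pytest.raises(DataError):
            sd.recode_income(_make_records([None, None]))


class TestPlantedMediation:
    def test_zero_logk_effect_yields_null_acme(self):
        """With the logk→STAB path switched off, the ACME interval behaves
        like a null 95% CI: it covers zero in ≥ 90% of generated cohorts."""
        covered = 0
        for rep in range(20):
            cfg = sd.CohortConfig(
                n_control=200, n_high=200, stab_coefs=(60.0, 35.0, 0.0, 18.0), seed=300 + rep
            )
            records = sd.generate_cohort(cfg)
            df = pd.DataFrame(
                {
                    "group_high": [r.group == "high" for r in records],
                    "logk": [r.latent_logk for r in records],
                    "stab_total": [r.stab_total for r in records],
                }
            ).astype(float)
            res = sd.mediate(df, "stab_total", "group_high", "logk", sims=300, seed=9)
            covered += res.acme.ci_low <= 0 <= res.acme.ci_high
        assert covered >= 18

    def test_configured_indirect_effect_recovered(self):
        cfg = sd.CohortConfig(n_control=500, n_high=500, seed=4)
        records = sd.generate_cohort(cfg)
        df = pd.DataFrame(
            {
                "group_high": [r.group == "high" for r in records],
                "logk": [r.latent_logk for r in records],
                "stab_total": [r.stab_total for r in records],
            }
        ).astype(float)
        res = sd.mediate(df, "stab_total", "group_high", "logk", sims=1000, seed=9)
        planted = (cfg.logk_mean_by_group[1] - cfg.logk_mean_by_group[0]) * cfg.stab_coefs[2]
        assert res.acme.ci_low < planted < res.acme.ci_high
        assert res.acme.point == pytest.approx(planted, abs=0.5)
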