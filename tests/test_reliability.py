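"""Cronbach's alpha, ICC(1,1), k-fold CV, propensity matching."""

import numpy as np
import pandas as pd
import pytest

import socdisc as sd
from socdisc.errors import ModelError, StatisticError, UsageError

TOY_ITEMS = np.array(
    [[2.0, 3.0, 3.0], [4.0, 4.0, 5.0], [3.0, 4.0, 4.0], [5.0, 5.0, 6.0], [1.0, 2.0, 1.0]]
)

TOY_RATINGS = np.array([[9.0, 10.0], [6.0, 5.0], [8.0, 7.0], [2.0, 3.0]])


def alpha_oracle(X):
    """Spreadsheet-style evaluation from item variances and the total variance."""
    m = X.shape[1]
    item_vars = [np.var(X[:, j], ddof=1) for j in range(m)]
    total_var = np.var(X.sum(axis=1), ddof=1)
    return (m / (m - 1)) * (1 - sum(item_vars) / total_var)


def icc_oracle(X):
    """Hand one-way ANOVA mean squares."""
    n, k = X.shape
    grand = X.mean()
    msb = k * sum((X[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msw = sum((X[i, j] - X[i].mean()) ** 2 for i in range(n) for j in range(k)) / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


class TestAlpha:
    def test_identical_items_give_one(self):
        x = np.tile(np.array([[1.0], [4.0], [2.0], [5.0]]), (1, 3))
        assert sd.cronbach_alpha(x).value == pytest.approx(1.0)

    def test_uncorrelated_equal_variance_items_give_zero(self):
        # Orthogonal contrast columns: exactly zero pairwise covariance.
        x = np.array([[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]])
        assert sd.cronbach_alpha(x).value == pytest.approx(0.0, abs=1e-12)

    def test_toy_table_matches_formula_oracle(self):
        assert sd.cronbach_alpha(TOY_ITEMS).value == pytest.approx(alpha_oracle(TOY_ITEMS))

    def test_shift_invariance(self):
        shifted = TOY_ITEMS.copy()
        shifted[:, 1] += 100
        assert sd.cronbach_alpha(shifted).value == pytest.approx(
            sd.cronbach_alpha(TOY_ITEMS).value
        )

    def test_degenerate_rejected(self):
        with pytest.raises(StatisticError):
            sd.cronbach_alpha(np.ones((5, 3)))


class TestIcc:
    def test_perfect_agreement(self):
        x = np.array([[1.0, 1.0], [5.0, 5.0], [3.0, 3.0]])
        assert sd.icc_oneway(x).value == pytest.approx(1.0)

    def test_pure_noise_nonpositive_in_expectation(self):
        rng = np.random.default_rng(20)
        vals = [sd.icc_oneway(rng.normal(0, 1, (20, 2)) + 5.0).value for _ in range(200)]
        assert np.mean(vals) < 0.05

    def test_toy_table_matches_anova_oracle(self):
        res = sd.icc_oneway(TOY_RATINGS)
        assert res.value == pytest.approx(icc_oracle(TOY_RATINGS))
        assert res.ci_low < res.value < res.ci_high

    def test_matches_pingouin_icc1(self):
        pingouin = pytest.importorskip("pingouin")
        n, k = TOY_RATINGS.shape
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "score": TOY_RATINGS.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(long, targets="targets", raters="raters", ratings="score")
        row = ref[ref["Type"].str.startswith("ICC(1,1)") | (ref["Type"] == "ICC1")].iloc[0]
        res = sd.icc_oneway(TOY_RATINGS)
        assert res.value == pytest.approx(row["ICC"], abs=1e-6)
        ci_col = "CI95" if "CI95" in ref.columns else "CI95%"
        assert res.ci_low == pytest.approx(row[ci_col][0], abs=0.01)
        assert res.ci_high == pytest.approx(row[ci_col][1], abs=0.01)

    def test_shift_invariance(self):
        assert sd.icc_oneway(TOY_RATINGS + 7.5).value == pytest.approx(
            sd.icc_oneway(TOY_RATINGS).value
        )

    def test_degenerate_rejected(self):
        with pytest.raises(StatisticError):
            sd.icc_oneway(np.full((4, 2), 3.0))


class TestKfold:
    @staticmethod
    def _df(n, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        df["y"] = 1.0 + 0.5 * df["x1"] - 0.3 * df["x2"] + rng.normal(size=n)
        return df

    def test_fold_sizes_and_determinism(self):
        df = self._df(100, 21)
        res = sd.kfold_cv(df, "y", ["x1", "x2"], k=10, seed=0)
        assert len(res.fold_coefs) == 10
        res2 = sd.kfold_cv(df, "y", ["x1", "x2"], k=10, seed=0)
        assert res.fold_coefs.equals(res2.fold_coefs) and res.oof_r2 == res2.oof_r2

    def test_well_specified_oof_r2_tracks_in_sample(self):
        df = self._df(2000, 22)
        res = sd.kfold_cv(df, "y", ["x1", "x2"], k=10, seed=1)
        assert res.oof_r2 == pytest.approx(res.in_sample_adj_r2, abs=0.05)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(UsageError):
            sd.kfold_cv(self._df(5, 23), "y", ["x1"], k=10, seed=0)


class TestMatching:
    @staticmethod
    def _balanced(n, seed):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(n)],
                "treat": rng.integers(0, 2, n),
                "age": rng.normal(35, 10, n),
                "iq": rng.normal(5, 2, n),
            }
        )

    def test_exchangeable_covariates_balance(self):
        df = self._balanced(600, 30)
        res = sd.propensity_match(df, "treat", ["age", "iq"])
        assert len(res.matched_pairs) > 100
        for cov in ("age", "iq"):
            assert abs(res.smd_after[cov]) < 0.1

    def test_zero_caliper_matches_nothing(self):
        df = self._balanced(100, 31)
        res = sd.propensity_match(df, "treat", ["age", "iq"], caliper=0.0)
        assert res.matched_pairs == []

    def test_controls_never_reused_and_within_caliper(self):
        df = self._balanced(300, 32)
        res = sd.propensity_match(df, "treat", ["age", "iq"])
        controls = [c for _, c in res.matched_pairs]
        assert len(controls) == len(set(controls))
        logit = dict(zip(df["participant_id"], _logit_ps(df, "treat", ["age", "iq"])))
        for t, c in res.matched_pairs:
            assert abs(logit[t] - logit[c]) <= res.caliper_logit + 1e-12

    def test_toy_matches_greedy_oracle(self):
        df = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(8)],
                "treat": [1, 1, 1, 0, 0, 0, 0, 0],
                "x": [2.0, 1.0, 0.5, 1.9, 1.2, 0.4, -0.5, 2.5],
            }
        )
        res = sd.propensity_match(df, "treat", ["x"], caliper=5.0)
        logit = _logit_ps(df, "treat", ["x"])
        # Greedy oracle: treated in descending logit-PS order, nearest unused control.
        treated = sorted(range(3), key=lambda i: -logit[i])
        available = set(range(3, 8))
        expected = []
        for ti in treated:
            ci = min(available, key=lambda c: (abs(logit[ti] - logit[c]), df["participant_id"][c]))
            available.remove(ci)
            expected.append((f"P{ti}", f"P{ci}"))
        assert sorted(res.matched_pairs) == sorted(expected)

    def test_single_class_rejected(self):
        df = self._balanced(50, 33)
        df["treat"] = 1
        with pytest.raises(ModelError):
            sd.propensity_match(df, "treat", ["age"])

    @pytest.mark.parametrize("seed", [40, 41, 42])
    def test_matched_subsample_retains_group_effect(self, seed):
        cfg = sd.CohortConfig(n_control=150, n_high=100, seed=seed)
        records = sd.generate_cohort(cfg)
        df = pd.DataFrame(
            {
                "participant_id": [r.id for r in records],
                "group_high": [int(r.group == "high") for r in records],
                "logk": [r.latent_logk for r in records],
                "age": [r.age for r in records],
                "fluid": [r.fluid_intelligence for r in records],
            }
        )
        res = sd.propensity_match(df, "group_high", ["age", "fluid"])
        ids = {i for pair in res.matched_pairs for i in pair}
        matched = df[df["participant_id"].isin(ids)]
        fit = sd.fit_ols(matched, "logk", ["group_high"], ["age", "fluid"])
        assert fit.term("group_high").b > 0


def _logit_ps(df, treatment, covariates):
    import statsmodels.api as sm

    X = sm.add_constant(df[covariates].astype(float).to_numpy())
    ps = sm.Logit(df[treatment].astype(int).to_numpy(), X).fit(disp=0).predict(X)
    ps = np.clip(ps, 1e-12, 1 - 1e-12)
    return np.log(ps / (1 - ps))
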