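"""Statistical pipeline: oracle equivalences, identities, and calibration."""

import numpy as np
import pandas as pd
import pytest

from coopsignal import stats
from coopsignal.stats import (
    PowerSpec,
    anova_two_way,
    cooperation_rate,
    effect_size_r,
    fixed_effects_power,
    mixed_anova,
    multiple_mediation,
    partial_eta_sq,
    planned_contrast,
    power_sample_size,
    ttest_ind,
)


def _trials(rows):
    return pd.DataFrame(rows, columns=["participant_id", "strategy", "emotion", "round", "participant_move"])


class TestCooperationRate:
    def test_rates(self):
        rows = [("p1", "generosity", "cooperative", r, "C") for r in range(1, 21)]
        rows += [("p2", "extortion", "competitive", r, "C" if r <= 10 else "D") for r in range(1, 21)]
        out = cooperation_rate(_trials(rows))
        rates = out.set_index("participant_id")["coop_rate"]
        assert rates["p1"] == 1.0
        assert rates["p2"] == 0.5

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            cooperation_rate(_trials([]))


class TestFactorialAnova:
    def balanced_oracle(self, df):
        """Textbook balanced two-way SS decomposition."""
        grand = df["y"].mean()
        n = df.groupby(["A", "B"]).size().iloc[0]
        a_means = df.groupby("A")["y"].mean()
        b_means = df.groupby("B")["y"].mean()
        cell = df.groupby(["A", "B"])["y"].mean()
        ss_a = n * len(b_means) * ((a_means - grand) ** 2).sum()
        ss_b = n * len(a_means) * ((b_means - grand) ** 2).sum()
        ss_cells = n * ((cell - grand) ** 2).sum()
        ss_ab = ss_cells - ss_a - ss_b
        ss_err = ((df["y"] - df.set_index(["A", "B"]).index.map(cell).to_numpy()) ** 2).sum()
        return ss_a, ss_b, ss_ab, ss_err

    def test_balanced_design_matches_textbook_decomposition(self, rng):
        rows = []
        for a in ("a1", "a2"):
            for b in ("b1", "b2"):
                for v in rng.normal(hash((a, b)) % 5, 1.0, 4):
                    rows.append((a, b, v))
        df = pd.DataFrame(rows, columns=["A", "B", "y"])
        res = anova_two_way(df, "y", "A", "B")
        ss_a, ss_b, ss_ab, ss_err = self.balanced_oracle(df)
        tab = res.table.set_index("effect")
        assert tab.loc["A", "SS"] == pytest.approx(ss_a, abs=1e-10)
        assert tab.loc["B", "SS"] == pytest.approx(ss_b, abs=1e-10)
        assert tab.loc["A:B", "SS"] == pytest.approx(ss_ab, abs=1e-10)
        assert res.residual_ss == pytest.approx(ss_err, abs=1e-10)

    def test_unbalanced_type_iii_matches_statsmodels(self, rng):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rows = []
        for (a, b, n, mu) in [("a1", "b1", 14, 0.2), ("a1", "b2", 11, 0.5),
                              ("a2", "b1", 9, 0.9), ("a2", "b2", 17, 0.1)]:
            for v in rng.normal(mu, 1.0, n):
                rows.append((a, b, v))
        df = pd.DataFrame(rows, columns=["A", "B", "y"])
        mine = anova_two_way(df, "y", "A", "B").table.set_index("effect")
        sm_fit = smf.ols("y ~ C(A, Sum)*C(B, Sum)", data=df).fit()
        ref = anova_lm(sm_fit, typ=3)
        assert mine.loc["A", "SS"] == pytest.approx(ref.loc["C(A, Sum)", "sum_sq"], rel=1e-10)
        assert mine.loc["B", "SS"] == pytest.approx(ref.loc["C(B, Sum)", "sum_sq"], rel=1e-10)
        assert mine.loc["A:B", "F"] == pytest.approx(
            ref.loc["C(A, Sum):C(B, Sum)", "F"], rel=1e-10
        )

    def test_eta_squared_identity_on_every_row(self, rng):
        rows = [(a, b, v) for a in "xy" for b in "uv"
                for v in rng.normal(0, 1, 6)]
        df = pd.DataFrame(rows, columns=["A", "B", "y"])
        tab = anova_two_way(df, "y", "A", "B").table
        for _, row in tab.iterrows():
            assert row["partial_eta_sq"] == pytest.approx(
                row["F"] * row["df1"] / (row["F"] * row["df1"] + row["df2"]), abs=1e-12
            )

    def test_null_type_one_error_near_alpha(self):
        """Balanced 2x2 with equal cell means: main-effect rejection rate
        at alpha=0.05 stays within Monte-Carlo error of 0.05."""
        rng = np.random.default_rng(2024)
        n_sim, rejections = 1000, 0
        for _ in range(n_sim):
            df = pd.DataFrame(
                {
                    "A": np.repeat(["a1", "a2"], 20),
                    "B": np.tile(np.repeat(["b1", "b2"], 10), 2),
                    "y": rng.normal(1.0, 1.0, 40),
                }
            )
            p = anova_two_way(df, "y", "A", "B").table.set_index("effect").loc["A", "p"]
            rejections += p < 0.05
        rate = rejections / n_sim
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) <= 3 * se

    def test_zero_variance_errors(self):
        df = pd.DataFrame(
            {"A": ["a1"] * 4 + ["a2"] * 4, "B": ["b1", "b2"] * 4, "y": [1.0] * 8}
        )
        with pytest.raises(ValueError):
            anova_two_way(df, "y", "A", "B")


class TestEffectSizes:
    @pytest.mark.parametrize(
        "F,df1,df2,expected",
        [(92.06, 1, 317, 0.225), (7.70, 1, 317, 0.024), (0.0, 1, 100, 0.0)],
    )
    def test_partial_eta_sq_printed_values(self, F, df1, df2, expected):
        assert partial_eta_sq(F, df1, df2) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize("t,df,expected", [(2.99, 163, 0.228), (0.76, 152, 0.0615)])
    def test_r_from_t(self, t, df, expected):
        assert effect_size_r(t, df) == pytest.approx(expected, abs=5e-4)


class TestPlannedContrast:
    def _data(self, means, n=10, sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for (s, e), mu in means.items():
            for v in mu + sd * rng.normal(size=n):
                rows.append((s, e, v))
        return pd.DataFrame(rows, columns=["strategy", "emotion", "y"])

    def test_equal_means_give_zero(self):
        df = self._data({k: 0.5 for k in stats.SYNERGISTIC_WEIGHTS}, sd=0.1, seed=1)
        df["y"] = df.groupby(["strategy", "emotion"])["y"].transform(lambda s: s - s.mean() + 0.5)
        res = planned_contrast(df, "y")
        assert res.t == pytest.approx(0.0, abs=1e-9)

    def test_weight_scale_invariance(self):
        means = {("generosity", "cooperative"): 0.8, ("generosity", "competitive"): 0.5,
                 ("extortion", "cooperative"): 0.5, ("extortion", "competitive"): 0.5}
        df = self._data(means, sd=0.2, seed=2)
        w1 = {("generosity", "cooperative"): 1, ("generosity", "competitive"): 1,
              ("extortion", "cooperative"): -1, ("extortion", "competitive"): -1}
        w2 = {k: 2 * v for k, v in w1.items()}
        assert planned_contrast(df, "y", weights=w1).t == pytest.approx(
            planned_contrast(df, "y", weights=w2).t, abs=1e-12
        )

    def test_hand_formula(self):
        means = {("generosity", "cooperative"): 0.8, ("generosity", "competitive"): 0.5,
                 ("extortion", "cooperative"): 0.5, ("extortion", "competitive"): 0.5}
        df = self._data(means, n=6, sd=0.3, seed=3)
        res = planned_contrast(df, "y")
        g = df.groupby(["strategy", "emotion"])["y"]
        m, ns = g.mean(), g.size()
        mse = float(((df["y"] - g.transform("mean")) ** 2).sum()) / (len(df) - 4)
        est = sum(w * m[c] for c, w in stats.SYNERGISTIC_WEIGHTS.items())
        t = est / np.sqrt(mse * sum(w**2 / ns[c] for c, w in stats.SYNERGISTIC_WEIGHTS.items()))
        assert res.t == pytest.approx(t, abs=1e-12)
        assert res.df == len(df) - 4

    def test_df_policy_override(self):
        means = {k: v for k, v in zip(stats.SYNERGISTIC_WEIGHTS, (0.8, 0.5, 0.5, 0.5))}
        df = self._data(means, sd=0.2, seed=4)
        res = planned_contrast(df, "y", df_policy=119)
        assert res.df == 119

    def test_nonzero_weight_sum_rejected(self):
        df = self._data({k: 0.5 for k in stats.SYNERGISTIC_WEIGHTS}, sd=0.1, seed=5)
        bad = dict(stats.SYNERGISTIC_WEIGHTS)
        bad[("generosity", "cooperative")] = 5
        with pytest.raises(ValueError):
            planned_contrast(df, "y", weights=bad)


class TestTTest:
    def test_matches_scipy(self, rng):
        from scipy import stats as sps

        a, b = rng.normal(0, 1, 25), rng.normal(0.4, 1.2, 30)
        mine = ttest_ind(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert mine.t == pytest.approx(ref.statistic, rel=1e-12)
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_identical_groups_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = ttest_ind(x, x)
        assert res.t == 0.0 and res.r == 0.0

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            ttest_ind([1.0, 1.0], [1.0, 1.0])


class TestMixedAnova:
    def _long(self, Y, groups=None):
        n, k = Y.shape
        rows = []
        for i in range(n):
            for t in range(k):
                rows.append((f"s{i:03d}", (groups[i] if groups is not None else "g"), t + 1, Y[i, t]))
        return pd.DataFrame(rows, columns=["subj", "grp", "time", "y"])

    def test_two_within_levels_force_epsilon_one(self, rng):
        Y = rng.normal(size=(16, 2))
        df = self._long(Y, groups=["g1"] * 8 + ["g2"] * 8)
        res = mixed_anova(df, "y", within="time", subject="subj", between=["grp"])
        assert res.eps_gg == 1.0 and res.eps_hf == 1.0

    def test_corrected_df_is_epsilon_times_uncorrected(self, rng):
        Y = rng.normal(size=(20, 5)).cumsum(axis=1)
        df = self._long(Y, groups=["g1"] * 10 + ["g2"] * 10)
        res = mixed_anova(df, "y", within="time", subject="subj", between=["grp"])
        for _, row in res.within.iterrows():
            assert row["df1_hf"] == pytest.approx(res.eps_hf * row["df1"], abs=1e-12)
            assert row["df2_hf"] == pytest.approx(res.eps_hf * row["df2"], abs=1e-12)

    def test_compound_symmetry_gives_epsilon_near_one(self):
        """Exchangeable (compound-symmetric) responses satisfy sphericity,
        so the HF epsilon should be ~1 (mean over 20 seeds)."""
        eps = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, k = 40, 5
            subj_eff = rng.normal(0, 1.0, n)[:, None]
            Y = subj_eff + rng.normal(0, 1.0, (n, k))
            df = self._long(Y)
            res = mixed_anova(df, "y", within="time", subject="subj", between=[])
            eps.append(res.eps_hf)
        assert abs(float(np.mean(eps)) - 1.0) <= 0.05

    def test_single_group_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(11)
        n, k = 18, 5
        cov = np.array([[0.7 ** abs(i - j) for j in range(k)] for i in range(k)])
        L = np.linalg.cholesky(cov)
        Y = np.arange(k) * 0.15 + (L @ rng.normal(size=(k, n))).T
        df = self._long(Y)
        res = mixed_anova(df, "y", within="time", subject="subj", between=[])
        wide = df.pivot(index="subj", columns="time", values="y")
        assert res.eps_gg == pytest.approx(pg.epsilon(wide, correction="gg"), abs=1e-9)
        assert res.eps_hf == pytest.approx(pg.epsilon(wide, correction="hf"), abs=1e-9)
        rm = pg.rm_anova(data=df, dv="y", within="time", subject="subj")
        assert res.within.iloc[0]["F"] == pytest.approx(rm["F"].iloc[0], rel=1e-9)

    def test_between_factor_f_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(3)
        n, k = 24, 6
        cov = np.array([[0.8 ** abs(i - j) for j in range(k)] for i in range(k)])
        L = np.linalg.cholesky(cov)
        groups = ["g1"] * 12 + ["g2"] * 12
        Y = np.array(
            [
                (0.3 if g == "g1" else 0.0) + np.arange(k) * 0.1 + L @ rng.normal(size=k)
                for g in groups
            ]
        )
        df = self._long(Y, groups=groups)
        res = mixed_anova(df, "y", within="time", subject="subj", between=["grp"])
        ref = pg.mixed_anova(data=df, dv="y", within="time", subject="subj", between="grp")
        ref = ref.set_index("Source")
        assert res.between.iloc[0]["F"] == pytest.approx(ref.loc["grp", "F"], rel=1e-9)
        within = res.within.set_index("effect")
        assert within.loc["time", "F"] == pytest.approx(ref.loc["time", "F"], rel=1e-9)
        assert within.loc["time:grp", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9
        )

    def test_missing_rounds_error(self, rng):
        Y = rng.normal(size=(10, 4))
        df = self._long(Y).iloc[:-1]  # drop one observation
        with pytest.raises(ValueError, match="missing"):
            mixed_anova(df, "y", within="time", subject="subj", between=[])


class TestMediation:
    def _dataset(self, rng, n=80):
        iv = np.repeat([0.0, 1.0], n // 2)
        M = pd.DataFrame(
            {
                "m1": 0.9 * iv + rng.normal(size=n),
                "m2": rng.normal(size=n),
            }
        )
        y = 0.6 * M["m1"].to_numpy() + 0.3 * iv + rng.normal(size=n)
        return iv, M, y

    def test_ols_decomposition_identity(self, rng):
        iv, M, y = self._dataset(rng)
        res = multiple_mediation(iv, M, y, n_boot=200, seed=0)
        assert res.total - (res.direct + res.indirect_sum) == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_chain_has_zero_direct(self, rng):
        n = 60
        iv = np.repeat([0.0, 1.0], n // 2)
        M = pd.DataFrame({"m": 1.5 * iv + rng.normal(size=n)})
        y = 3.0 * M["m"].to_numpy()  # outcome fully determined by the mediator
        res = multiple_mediation(iv, M, y, n_boot=200, seed=1)
        assert res.direct == pytest.approx(0.0, abs=1e-10)
        assert res.total == pytest.approx(res.indirect_sum, abs=1e-10)

    def test_bootstrap_deterministic_under_seed(self, rng):
        iv, M, y = self._dataset(rng)
        r1 = multiple_mediation(iv, M, y, n_boot=500, seed=7)
        r2 = multiple_mediation(iv, M, y, n_boot=500, seed=7)
        assert r1.paths.equals(r2.paths)
        assert r1.total_ci == r2.total_ci and r1.direct_ci == r2.direct_ci

    def test_collinear_mediators_named(self, rng):
        n = 40
        iv = np.repeat([0.0, 1.0], n // 2)
        m1 = rng.normal(size=n)
        M = pd.DataFrame({"m1": m1, "m2": 2 * m1})
        with pytest.raises(ValueError, match="m2|m1"):
            multiple_mediation(iv, M, rng.normal(size=n), n_boot=50, seed=0)

    def test_iv_coding_validated(self, rng):
        iv = np.repeat([1.0, 2.0], 20)
        M = pd.DataFrame({"m": rng.normal(size=40)})
        with pytest.raises(ValueError, match="0, 1"):
            multiple_mediation(iv, M, rng.normal(size=40), n_boot=50, seed=0)

    def test_ci_ordering(self, rng):
        iv, M, y = self._dataset(rng)
        res = multiple_mediation(iv, M, y, n_boot=500, seed=3)
        for _, row in res.paths.iterrows():
            assert row["ci_low"] <= row["ci_high"]


class TestParameterRecovery:
    def test_calibrated_strategy_effect_detected_with_high_power(self):
        """At the calibrated effect size (~0.2 partial eta-squared) and the
        study's cell size, the strategy main effect is detected in >= 90%
        of 50 generated cohorts."""
        from coopsignal.cohort import CohortConfig, generate_cohort

        detected = 0
        for seed in range(50):
            trials, _ = generate_cohort(CohortConfig(seed=seed))
            rates = cooperation_rate(trials)
            tab = anova_two_way(rates, "coop_rate", "strategy", "emotion").table
            detected += tab.set_index("effect").loc["strategy", "p"] < 0.05
        assert detected >= 45


class TestPower:
    def test_study_sample_size(self):
        assert power_sample_size(PowerSpec(f=0.20, alpha=0.05, power=0.95, n_groups=4, df1=1)) == 327

    def test_monotone_in_effect_size(self):
        n_small = power_sample_size(PowerSpec(f=0.30, alpha=0.05, power=0.95, n_groups=4, df1=1))
        assert n_small < 327

    def test_boundary_is_tight(self):
        spec = PowerSpec(f=0.20, alpha=0.05, power=0.95, n_groups=4, df1=1)
        assert fixed_effects_power(spec, 326) < 0.95 <= fixed_effects_power(spec, 327)

    def test_cross_check_against_statsmodels(self):
        """Independent noncentral-F power oracle for a two-group design
        (where numerator df = k - 1 matches both parameterizations)."""
        from statsmodels.stats.power import FTestAnovaPower

        spec = PowerSpec(f=0.25, alpha=0.05, power=0.80, n_groups=2, df1=1)
        mine = power_sample_size(spec)
        ref = FTestAnovaPower().solve_power(
            effect_size=0.25, alpha=0.05, power=0.80, k_groups=2
        )
        assert mine == int(np.ceil(ref))

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            PowerSpec(f=-0.1)
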