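"""Regression battery, rank tests vs enumeration oracles, report assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from wmcvol.cohort import CohortSpec, LinearModel, generate_cohort
from wmcvol.scores import score_cohort
from wmcvol.stats import (
    ModelSpec,
    build_report,
    compare_groups,
    fit_outcome_model,
    log2_volumes,
    paired_change_tests,
    paired_t,
    spearman_corr,
    wilcoxon_signed,
)


def mannwhitney_enumeration(x, y):
    """Independent oracle: U and two-sided p by enumerating every assignment
    of the pooled values to the two groups (distinct values assumed)."""
    x, y = list(x), list(y)
    pooled = x + y
    m = len(x)

    def u_stat(a, b):
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in a for yi in b)

    u_obs = u_stat(x, y)
    us = [
        u_stat(list(c), [p for i, p in enumerate(pooled) if i not in idxset])
        for c, idxset in (
            (c, set(idx)) for idx, c in (
                (idx, [pooled[i] for i in idx])
                for idx in itertools.combinations(range(len(pooled)), m)
            )
        )
    ]
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return u_obs, min(p, 1.0)


def wilcoxon_enumeration(diffs):
    """Oracle: exact two-sided signed-rank p over all 2^n sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d < 0].sum()
    n = len(d)
    ws = [
        ranks[np.array(signs, dtype=bool)].sum()
        for signs in itertools.product([0, 1], repeat=n)
    ]
    ws = np.array(ws)
    w_plus = ranks[d > 0].sum()
    stat = min(w_obs, w_plus)
    p = 2 * min((ws <= stat).mean(), (ws >= max(w_obs, w_plus)).mean())
    return stat, min(p, 1.0)


class TestLog2Volumes:
    def test_examples_and_nonpositive_flagging(self, caplog):
        df = pd.DataFrame({"pvh_ml": [8.0, 1.0, 0.0]})
        out = log2_volumes(df, columns=("pvh_ml",))
        assert out["log2_pvh_ml"].tolist()[:2] == [3.0, 0.0]
        assert np.isnan(out["log2_pvh_ml"].iloc[2])
        assert "pvh_ml" in df  # originals retained


class TestMannWhitney:
    def test_separated_groups_exact(self):
        df = pd.DataFrame(
            {"v": [1, 2, 3, 4, 5, 6], "g": [1, 1, 1, 0, 0, 0]}
        )
        res = compare_groups(df, "v", "g")
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_large_groups_p_one(self):
        v = np.tile(np.arange(15, dtype=float), 2)
        df = pd.DataFrame({"v": v, "g": [1] * 15 + [0] * 15})
        res = compare_groups(df, "v", "g")
        assert res.method == "asymptotic"
        assert res.p_value == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"v": [1.0, 2.0], "g": [1, 1]})
        with pytest.raises(ValueError, match="empty group"):
            compare_groups(df, "v", "g")

    @given(st.integers(0, 10_000), st.integers(2, 8))
    def test_matches_enumeration_oracle(self, seed, m):
        """Exact path agrees with brute-force enumeration, combined n <= 10."""
        rng = np.random.default_rng(seed)
        n_total = rng.integers(m + 1, 11)
        vals = rng.choice(np.arange(100), size=n_total, replace=False).astype(float)
        x, y = vals[:m], vals[m:]
        df = pd.DataFrame(
            {"v": np.concatenate([x, y]), "g": [1] * len(x) + [0] * len(y)}
        )
        res = compare_groups(df, "v", "g")
        u_ref, p_ref = mannwhitney_enumeration(x, y)
        assert res.u_statistic == pytest.approx(u_ref)
        assert res.p_value == pytest.approx(p_ref, abs=1e-9)


class TestWilcoxon:
    def test_three_positive_differences(self):
        w, p, n = wilcoxon_signed([0, 0, 0], [1, 2, 3])
        assert w == 0
        assert p == pytest.approx(0.25)
        assert n == 3

    def test_zero_differences_dropped(self):
        w, p, n = wilcoxon_signed([5, 5, 5, 5], [5, 6, 7, 8])
        assert n == 3
        assert p == pytest.approx(0.25)

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError, match="all differences zero"):
            wilcoxon_signed([1.0, 2.0], [1.0, 2.0])

    @given(st.integers(0, 10_000))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        mags = rng.choice(np.arange(1, 50), size=n, replace=False).astype(float)
        d = mags * rng.choice([-1.0, 1.0], size=n)
        w, p, _ = wilcoxon_signed(np.zeros(n), d)
        w_ref, p_ref = wilcoxon_enumeration(d)
        assert p == pytest.approx(p_ref, abs=1e-9)


class TestSpearman:
    def test_monotone_is_one(self):
        x = np.array([1.0, 4.0, 9.0, 20.0])
        r, _ = spearman_corr(x, np.exp(x / 10))
        assert r == pytest.approx(1.0)

    def test_formula_oracle_example(self):
        r, _ = spearman_corr([1, 2, 3], [3, 1, 2])
        assert r == pytest.approx(-0.5)

    def test_reversal_is_minus_one(self):
        r, _ = spearman_corr([1, 2, 3, 4], [8, 7, 6, 5])
        assert r == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.integers(0, 10_000))
    def test_matches_rank_formula(self, seed):
        """r_s = 1 - 6 sum(d^2) / (n (n^2-1)) for distinct values, n <= 8."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        x = rng.permutation(n).astype(float)
        y = rng.permutation(n).astype(float)
        r, _ = spearman_corr(x, y)
        d = pd.Series(x).rank() - pd.Series(y).rank()
        r_ref = 1 - 6 * float((d**2).sum()) / (n * (n**2 - 1))
        assert r == pytest.approx(r_ref, abs=1e-12)


class TestPairedTests:
    def test_zero_variance_differences_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t([1.0, 2.0, 3.0], [3.0, 4.0, 5.0])

    def test_dispatcher_uses_t_for_total_and_wilcoxon_for_mmse(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "pre_total": rng.normal(50, 10, 40),
                "mmse_pre": rng.integers(15, 30, 40).astype(float),
            }
        )
        df["post_total"] = df["pre_total"] + rng.normal(5, 8, 40)
        df["mmse_post"] = df["mmse_pre"] + rng.integers(-2, 3, 40)
        total = paired_change_tests(df, "total")
        mmse = paired_change_tests(df, "mmse")
        assert total["test"] == "paired-t"
        assert mmse["test"] == "wilcoxon-signed-rank"
        assert 0 <= total["p_value"] <= 1


class TestOutcomeModels:
    def _noise_free_cohort(self, n=120, beta=-1.5):
        spec = CohortSpec(
            n=n,
            seed=9,
            delta_score_model=LinearModel(40.0, {"log2_pvh_ml": beta}, 0.0),
            baseline_score_model=LinearModel(50.0, {}, 0.0),
            domain_deviation_sd=0.0,
            domain_missing={d: 0.0 for d in ("gait", "balance", "continence", "cognition")},
        )
        return log2_volumes(score_cohort(generate_cohort(spec)))

    def test_noise_free_fit_recovers_generating_coefficient(self):
        # baseline covariate set: the noise-free baseline total is constant,
        # so it cannot itself sit in the design
        df = self._noise_free_cohort()
        res = fit_outcome_model(df, ModelSpec("delta_total", "pvh_ml", "baseline"))
        assert res.B == pytest.approx(-1.5, abs=1e-6)
        assert res.n == len(df)

    def test_residuals_orthogonal_to_design(self):
        import statsmodels.api as sm

        df = log2_volumes(score_cohort(generate_cohort(CohortSpec(n=200, seed=2))))
        d = df[["delta_total", "log2_pvh_ml", "age", "sex_male", "evans_index"]].dropna()
        X = sm.add_constant(d.drop(columns="delta_total"))
        fit = sm.OLS(d["delta_total"], X).fit()
        assert np.allclose(X.to_numpy().T @ fit.resid.to_numpy(), 0.0, atol=1e-6)

    def test_adjustment_corrects_builtin_confounding(self):
        """Age both raises volume exposure and lowers outcome: the unadjusted
        coefficient is biased downward, adjustment recovers the null."""
        rng = np.random.default_rng(11)
        n = 4000
        age = rng.normal(75, 6, n)
        log2_pvh = 0.12 * (age - 75) + rng.normal(3.9, 1.0, n)
        delta = 10.0 - 0.5 * age + rng.normal(0, 5, n)
        df = pd.DataFrame(
            {
                "delta_total": delta,
                "pvh_ml": np.power(2.0, log2_pvh),
                "age": age,
                "sex_male": rng.integers(0, 2, n).astype(float),
                "evans_index": rng.normal(0.38, 0.03, n),
                "desh": rng.integers(0, 2, n).astype(float),
            }
        )
        df = log2_volumes(df)
        unadj = fit_outcome_model(
            df, ModelSpec("delta_total", "pvh_ml", "none", adjusted=False)
        )
        adj = fit_outcome_model(df, ModelSpec("delta_total", "pvh_ml", "baseline"))
        assert unadj.B < adj.B - 0.1  # confounding pulls the crude estimate down
        assert adj.B == pytest.approx(0.0, abs=0.15)

    def test_rank_deficient_design_names_columns(self):
        df = self._noise_free_cohort(n=60)
        df["evans_index"] = 0.4  # constant column duplicates the intercept
        with pytest.raises(ValueError, match="collinear.*evans_index"):
            fit_outcome_model(df, ModelSpec("delta_total", "pvh_ml", "delta"))

    def test_too_few_complete_cases(self):
        df = self._noise_free_cohort(n=120).head(5)
        with pytest.raises(ValueError, match="complete cases"):
            fit_outcome_model(df, ModelSpec("delta_total", "pvh_ml", "delta"))


@pytest.fixture(scope="module")
def scored():
    return score_cohort(generate_cohort(CohortSpec(n=220, seed=4)))


class TestReport:

    def test_delta_table_has_full_row_structure(self, scored):
        report = build_report(scored)
        t3 = report["delta_models"]
        assert len(t3) == 18  # 6 delta outcomes x 3 volumes
        assert set(t3["volume"]) == {"pvh_ml", "dwmh_ml", "ventricles_ml"}
        assert ((t3["p_adjusted"] >= 0) & (t3["p_adjusted"] <= 1)).all()

    def test_significance_stars_follow_thresholds(self, scored):
        report = build_report(scored)
        for _, row in report["delta_models"].iterrows():
            p = row["p_adjusted"]
            expected = "**" if p < 0.01 else "*" if p < 0.05 else ""
            assert row["sig_adjusted"] == expected

    def test_no_biomarkers_yields_empty_table_with_notice(self, scored):
        df = scored.drop(columns=["t_tau", "p_tau", "abeta42", "nfl"])
        report = build_report(df)
        assert report["biomarker_models"].empty
        assert "biomarker table empty" in report["note"]

    def test_report_is_deterministic(self, scored):
        r1 = build_report(scored)
        r2 = build_report(scored)
        for key in ("volumes_by_response", "delta_models", "baseline_models"):
            pd.testing.assert_frame_equal(r1[key], r2[key])
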