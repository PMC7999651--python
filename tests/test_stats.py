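"""Univariate screen, Bonferroni thresholds, multivariate models, ADR tests."""

import numpy as np
import pandas as pd
import pytest

from statinpgx import stats


def _dataset(n=200, seed=3):
    rng = np.random.default_rng(seed)
    weight = np.where(np.arange(n) % 2 == 0, 61.5, 75.3)
    sex = np.where(np.arange(n) % 2 == 0, "F", "M")
    cl_w = 7000.0 * np.exp(rng.normal(0, 0.3, n))    # per-kg clearance, sex-free
    auc = 80e6 / (cl_w * weight)
    return pd.DataFrame({
        "sex": sex, "weight_kg": weight, "dose_mg": 80.0,
        "auc_inf": auc, "cmax": auc * 0.2, "tmax": 1.4, "t_half": 9.1,
        "vd_f_w": 90000.0, "cl_f_w": cl_w,
    })


class TestNormalization:
    def test_unit_dose_weight_ratio_is_identity(self):
        df = _dataset(10)
        df["dose_mg"] = df["weight_kg"]
        out = stats.normalize_exposure(df)
        np.testing.assert_allclose(out["auc_dw"], out["auc_inf"])

    def test_printed_cohort_example(self):
        df = _dataset(2)
        df.loc[0, ["auc_inf", "dose_mg", "weight_kg"]] = [166.6, 80.0, 67.7]
        out = stats.normalize_exposure(df)
        assert out.loc[0, "auc_dw"] == pytest.approx(140.985, abs=0.001)

    def test_halving_dose_doubles_dw_corrected_exposure(self):
        df = _dataset(4)
        half = df.copy()
        half["dose_mg"] = df["dose_mg"] / 2
        a = stats.normalize_exposure(df)["auc_dw"]
        b = stats.normalize_exposure(half)["auc_dw"]
        np.testing.assert_allclose(b, 2 * a)

    def test_nonpositive_dose_rejected(self):
        df = _dataset(4)
        df.loc[0, "dose_mg"] = 0.0
        with pytest.raises(ValueError):
            stats.normalize_exposure(df)


class TestUnivariate:
    def test_identical_groups_give_t_zero_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        df = pd.DataFrame({"y": vals * 2, "g": ["a"] * 4 + ["b"] * 4})
        (res,) = stats.univariate_screen(df, ["y"], ["g"])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_constant_outcome_flagged_undefined(self):
        df = pd.DataFrame({"y": [2.0] * 8, "g": ["a"] * 4 + ["b"] * 4})
        (res,) = stats.univariate_screen(df, ["y"], ["g"])
        assert "zero_variance" in res.flags and np.isnan(res.p_value)

    def test_shifted_group_found_by_anova_and_posthoc(self, rng):
        y = np.concatenate([rng.lognormal(0, 0.05, 30),
                            rng.lognormal(0, 0.05, 30),
                            rng.lognormal(2.0, 0.05, 30)])
        df = pd.DataFrame({"y": y, "g": ["a"] * 30 + ["b"] * 30 + ["c"] * 30})
        (res,) = stats.univariate_screen(df, ["y"], ["g"])
        assert res.test_name == "anova" and res.p_value < 0.05
        assert res.posthoc[("a", "c")] < 0.05
        assert res.posthoc[("b", "c")] < 0.05
        assert res.posthoc[("a", "b")] > 0.05

    def test_small_groups_reported_descriptively_only(self):
        df = pd.DataFrame({"y": [1.0, 2, 3, 4, 5, 6, 7],
                           "g": ["a", "a", "a", "b", "b", "b", "c"]})
        (res,) = stats.univariate_screen(df, ["y"], ["g"])
        small = [g for g in res.groups if g.level == "c"][0]
        assert not small.tested and small.n == 1
        assert res.test_name == "t-test"

    def test_dw_correction_removes_body_size_artifact(self):
        # same per-kg clearance in both sexes: fixed-dose AUC differs by
        # weight only, so sex separates raw exposure but not AUC/DW
        df = stats.normalize_exposure(_dataset(400))
        raw = stats.univariate_screen(
            df.assign(raw_auc=df["auc_inf"]), ["raw_auc"], ["sex"])[0]
        corrected = stats.univariate_screen(df, ["auc_dw"], ["sex"])[0]
        assert raw.p_value < 0.001
        assert corrected.p_value > 0.05

    def test_group_ns_sum_to_analyzed_n(self):
        df = _dataset(50)
        (res,) = stats.univariate_screen(df, ["auc_inf"], ["sex"])
        assert sum(g.n for g in res.groups) == 50


class TestBonferroni:
    @pytest.mark.parametrize("k,alpha", [(8, 0.00625), (1, 0.05), (5, 0.01)])
    def test_threshold(self, k, alpha):
        assert stats.bonferroni_alpha(k) == pytest.approx(alpha)

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            stats.bonferroni_alpha(0)


class TestMultivariate:
    def test_exact_binary_predictor_recovered(self):
        df = pd.DataFrame({"y": np.exp([1.0, 1, 1, 2, 2, 2]),
                           "g": ["a", "a", "a", "b", "b", "b"]})
        stats.REFERENCE_LEVELS.setdefault("g", "a")
        res = stats.multivariate_model(df, "y", ["g"])
        assert res.r_squared == pytest.approx(1.0)
        assert res.coefficients["g[b]"] == pytest.approx(1.0)

    def test_duplicated_predictor_reports_rank_deficiency(self):
        df = pd.DataFrame({"y": np.exp(np.arange(1.0, 7)),
                           "x1": [0, 0, 0, 1, 1, 1.0]})
        df["x2"] = df["x1"]
        with pytest.raises(ValueError, match="rank-deficient"):
            stats.multivariate_model(df, "y", ["x1", "x2"])

    def test_agrees_with_normal_equations_oracle(self, rng):
        n = 40
        x1 = rng.random(n)
        g = rng.choice(["a", "b"], n)
        y = np.exp(0.5 + 0.3 * x1 + 0.8 * (g == "b") + rng.normal(0, 0.1, n))
        df = pd.DataFrame({"y": y, "x1": x1, "g": g})
        stats.REFERENCE_LEVELS.setdefault("g", "a")
        res = stats.multivariate_model(df, "y", ["x1", "g"])
        X = np.column_stack([np.ones(n), x1, (g == "b").astype(float)])
        beta = np.linalg.solve(X.T @ X, X.T @ np.log(y))
        assert res.coefficients["x1"] == pytest.approx(beta[1], rel=1e-10)
        assert res.coefficients["g[b]"] == pytest.approx(beta[2], rel=1e-10)

    def test_alpha_star_uses_screened_count(self):
        df = pd.DataFrame({"y": np.exp(np.arange(1.0, 9)),
                           "x1": [0, 1, 0, 1, 0, 1, 0, 1.0]})
        res = stats.multivariate_model(df, "y", ["x1"], k=8)
        assert res.alpha_star == pytest.approx(0.00625)


class TestAdr:
    def test_identical_incidence_gives_zero_statistic(self):
        df = pd.DataFrame({"adr": [True, False] * 20,
                           "g": ["a"] * 20 + ["b"] * 20})
        stat, p, _ = stats.adr_incidence_test(df, "adr", "g")
        assert stat == pytest.approx(0.0)

    def test_concentrated_events_highly_significant(self):
        df = pd.DataFrame({"adr": [True] * 30 + [False] * 90,
                           "g": ["a"] * 30 + ["b"] * 30 + ["c"] * 60})
        _, p, _ = stats.adr_incidence_test(df, "adr", "g")
        assert p < 0.001

    def test_trial_concentrated_gi_proportions(self):
        # 10/2/1 cases concentrated in three of five arms: case shares
        # 76.9% / 15.4% / 7.7%
        cases = {"A": 0, "B": 1, "C": 0, "D": 2, "E": 10}
        sizes = {"A": 14, "B": 30, "C": 39, "D": 37, "E": 36}
        rows = []
        for arm, n in sizes.items():
            rows += [{"g": arm, "adr": i < cases[arm]} for i in range(n)]
        df = pd.DataFrame(rows)
        total = df["adr"].sum()
        shares = df[df.adr].groupby("g").size() / total * 100
        assert shares["E"] == pytest.approx(76.9, abs=0.05)
        assert shares["D"] == pytest.approx(15.4, abs=0.05)
        assert shares["B"] == pytest.approx(7.7, abs=0.05)
        _, p, _ = stats.adr_incidence_test(df, "adr", "g")
        assert p < 0.001

    def test_separation_detected_and_penalized_fallback_used(self):
        # headache occurring only in one sex is a quasi-separated design
        df = pd.DataFrame({
            "adr": [True] * 10 + [False] * 40 + [False] * 50,
            "sex": ["F"] * 50 + ["M"] * 50,
        })
        res = stats.logistic_adr_model(df, "adr", ["sex"])
        assert "quasi_separation" in res.flags
        assert "penalized_estimates" in res.flags
        assert np.isfinite(res.coefficients).all()

    def test_well_conditioned_logistic_reports_mle(self, rng):
        n = 400
        x = rng.random(n)
        p = 1 / (1 + np.exp(-(x - 0.5)))
        df = pd.DataFrame({"adr": rng.random(n) < p, "x": x})
        res = stats.logistic_adr_model(df, "adr", ["x"])
        assert not res.flags and res.p_values is not None


class TestSmallLevelMerge:
    def test_two_small_levels_merge_into_combined_label(self):
        s = pd.Series(["Caucasian"] * 81 + ["Latin-American"] * 70
                      + ["Black"] * 4 + ["Arabic"])
        merged = stats.merge_small_levels(s, min_n=6)
        counts = merged.value_counts()
        assert counts["Black or Arabic"] == 5
        assert "Black" not in counts.index

    def test_single_small_level_left_alone(self):
        s = pd.Series(["a"] * 10 + ["b"])
        assert stats.merge_small_levels(s, min_n=6).equals(s)
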