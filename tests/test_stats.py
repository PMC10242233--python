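"""Statistical pipeline: annualization through IDI."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from choroidkit.stats import (MODEL1_PREDICTORS, MODEL2_PREDICTORS,
                              annualize_elongation, auc_rank, compare_groups,
                              compute_idi, delong_compare,
                              dichotomize_by_median, fit_linear_model,
                              fit_logistic_and_roc, roc_from_scores,
                              screen_univariable)
from choroidkit.synthetic import CohortGenParams, generate_cohort


def brute_force_auc(scores, positive):
    """Exhaustive concordant-pair counting; ties count 1/2."""
    scores = np.asarray(scores, float)
    positive = np.asarray(positive, bool)
    pairs = concordant = 0.0
    for i, j in itertools.product(np.nonzero(positive)[0],
                                  np.nonzero(~positive)[0]):
        pairs += 1
        if scores[i] > scores[j]:
            concordant += 1
        elif scores[i] == scores[j]:
            concordant += 0.5
    return concordant / pairs


class TestAnnualize:
    def test_values(self):
        assert annualize_elongation(0.19, 365) == pytest.approx(0.19)
        assert annualize_elongation(0.10, 182.5) == pytest.approx(0.20)
        assert annualize_elongation(0.0, 123) == 0.0

    def test_nonpositive_days_raise(self):
        with pytest.raises(ValueError):
            annualize_elongation(0.1, 0)


class TestMedianSplit:
    def test_three_values(self):
        med, labels = dichotomize_by_median([0.1, 0.16, 0.3])
        assert med == 0.16
        assert list(labels) == ["slow", "slow", "fast"]

    def test_all_equal_all_slow(self):
        _, labels = dichotomize_by_median([0.2] * 5)
        assert (labels == "slow").all()

    def test_even_n_mean_of_middle_two(self):
        med, _ = dichotomize_by_median([1.0, 2.0, 3.0, 4.0])
        assert med == 2.5

    def test_against_exhaustive_comparison(self, rng):
        vals = rng.normal(size=50)
        med, labels = dichotomize_by_median(vals)
        for v, lab in zip(vals, labels):
            assert lab == ("slow" if v <= med else "fast")

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            dichotomize_by_median([])


class TestScreening:
    def test_identical_variable_fully_correlated(self, rng):
        y = rng.normal(size=40)
        table = pd.DataFrame({"x": y, "y": y})
        res = screen_univariable(table, outcome="y", variables=("x",))[0]
        assert res.r == pytest.approx(1.0)
        assert res.selected

    def test_independent_noise_not_selected(self, rng):
        """Null calibration spot check (single seeded draw; the 5% false-
        positive rate of the screen makes this flaky by construction)."""
        table = pd.DataFrame({"x": rng.normal(size=1000),
                              "y": rng.normal(size=1000)})
        res = screen_univariable(table, outcome="y", variables=("x",))[0]
        assert abs(res.r) < 0.1
        assert not res.selected

    def test_generator_effects_recovered_with_negative_sign(self, cohort5000):
        table, _ = cohort5000
        res = {r.variable: r for r in screen_univariable(table)}
        for var in ("cvi0_pct", "d_sfct_um"):
            assert res[var].selected
            assert res[var].r < 0

    def test_constant_variable_warns(self, rng):
        table = pd.DataFrame({"x": np.ones(30), "y": rng.normal(size=30)})
        with pytest.warns(UserWarning, match="constant"):
            res = screen_univariable(table, outcome="y", variables=("x",))[0]
        assert np.isnan(res.r) and not res.selected


class TestGroupComparison:
    def test_identical_groups_t_p_is_one(self, rng):
        x = rng.normal(10, 2, size=25)
        table = pd.DataFrame({"v": np.r_[x, x]})
        labels = np.array(["slow"] * 25 + ["fast"] * 25)
        res = compare_groups(table, labels, variables=("v",))[0]
        assert res.test == "t"
        assert res.p == pytest.approx(1.0)

    def test_power_for_two_sd_shift(self):
        """n=25 per group at a 2-SD mean shift: essentially always detected."""
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            table = pd.DataFrame({"v": np.r_[r.normal(0, 1, 25),
                                             r.normal(2, 1, 25)]})
            labels = np.array(["slow"] * 25 + ["fast"] * 25)
            if compare_groups(table, labels, variables=("v",))[0].p < 0.05:
                hits += 1
        assert hits / n_seeds >= 0.95

    def test_sex_routed_to_chi_squared(self, cohort50):
        table, _ = cohort50
        _, labels = dichotomize_by_median(table.d_al_annualized_mm_yr)
        res = {r.variable: r for r in compare_groups(table, labels)}
        assert res["sex"].test == "chi2"
        assert res["age_years"].test in ("t", "mannwhitney")

    def test_small_group_raises(self, rng):
        table = pd.DataFrame({"v": rng.normal(size=5)})
        labels = np.array(["slow"] * 4 + ["fast"])
        with pytest.raises(ValueError):
            compare_groups(table, labels, variables=("v",))


class TestLinearModel:
    def test_noiseless_recovery_to_machine_precision(self, rng):
        n = 60
        table = pd.DataFrame({
            "cvi0_pct": rng.normal(60, 3, n),
            "la0_mm2": rng.normal(0.84, 0.18, n),
            "d_sfct_um": rng.normal(10, 20, n),
            "age_years": rng.normal(10, 1.5, n),
            "sex": rng.choice(["male", "female"], n),
        })
        y = (0.5 - 0.02 * table.cvi0_pct
             - 0.001 * table.la0_mm2 / 0.01
             - 0.03 * table.d_sfct_um / 10
             + 0.004 * table.age_years
             + 0.01 * (table.sex == "male"))
        table["d_al_annualized_mm_yr"] = y
        fit = fit_linear_model(table, MODEL2_PREDICTORS)
        assert fit.term("const")["beta"] == pytest.approx(0.5, abs=1e-10)
        assert fit.term("cvi0_pct")["beta"] == pytest.approx(-0.02, abs=1e-12)
        assert fit.term("la0_mm2")["beta"] == pytest.approx(-0.001, abs=1e-12)
        assert fit.term("d_sfct_um")["beta"] == pytest.approx(-0.03,
                                                              abs=1e-12)
        assert fit.term("sex_male")["beta"] == pytest.approx(0.01, abs=1e-10)

    def test_duplicated_predictor_raises(self, cohort50):
        table, _ = cohort50
        table = table.copy()
        table["cvi0_copy_pct"] = table["cvi0_pct"]
        with pytest.raises(ValueError, match="collinear"):
            fit_linear_model(table, ("cvi0_pct", "cvi0_copy_pct"))

    def test_ci_brackets_beta(self, cohort50):
        table, _ = cohort50
        fit = fit_linear_model(table, MODEL2_PREDICTORS)
        for t in fit.terms:
            assert t["ci_low"] <= t["beta"] <= t["ci_high"]

    def test_replicate_recovery_and_ci_coverage(self):
        """Over 100 small-cohort replicates the mean fitted coefficients for
        baseline CVI and the SFCT change are within 15% of the generating
        values and the 95% CIs cover the truth 90-98% of the time."""
        b_cvi, b_dsfct = [], []
        cover_cvi = cover_dsfct = 0
        n_rep = 100
        for rep in range(n_rep):
            table, truth = generate_cohort(CohortGenParams(n=50, seed=100 + rep))
            fit = fit_linear_model(table, MODEL2_PREDICTORS)
            tc = fit.term("cvi0_pct")
            td = fit.term("d_sfct_um")
            b_cvi.append(tc["beta"])
            b_dsfct.append(td["beta"])
            cover_cvi += tc["ci_low"] <= truth["beta_cvi0"] <= tc["ci_high"]
            cover_dsfct += (td["ci_low"] <= truth["beta_dsfct_per10um"]
                            <= td["ci_high"])
        assert np.mean(b_cvi) == pytest.approx(-0.023, rel=0.15)
        assert np.mean(b_dsfct) == pytest.approx(-0.035, rel=0.15)
        assert 0.90 <= cover_cvi / n_rep <= 0.98
        assert 0.90 <= cover_dsfct / n_rep <= 0.98


class TestRocAuc:
    def test_perfect_separation_auc_one(self):
        scores = np.r_[np.ones(5), np.zeros(5)]
        labels = np.array(["slow"] * 5 + ["fast"] * 5)
        assert roc_from_scores(scores, labels).auc == 1.0

    def test_null_scores_auc_half(self, rng):
        scores = rng.normal(size=2000)
        labels = np.where(rng.random(2000) < 0.5, "slow", "fast")
        assert auc_rank(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_six_subject_worked_example(self):
        scores = np.array([0.9, 0.8, 0.8, 0.4, 0.3, 0.8])
        positive = np.array([True, True, False, False, False, True])
        assert auc_rank(scores, positive) == pytest.approx(
            brute_force_auc(scores, positive))

    @settings(max_examples=60, derandomize=True)
    @given(st.data())
    def test_rank_auc_equals_pair_counting(self, data):
        """Rank formulation == exhaustive pair counting for n <= 30,
        including ties."""
        n = data.draw(st.integers(6, 30))
        scores = np.array(data.draw(st.lists(
            st.integers(0, 8), min_size=n, max_size=n)), dtype=float)
        n_pos = data.draw(st.integers(2, n - 2))
        positive = np.zeros(n, bool)
        positive[:n_pos] = True
        assert auc_rank(scores, positive) == pytest.approx(
            brute_force_auc(scores, positive), abs=1e-12)

    def test_curve_monotone(self, cohort50):
        table, _ = cohort50
        _, labels = dichotomize_by_median(table.d_al_annualized_mm_yr)
        roc = fit_logistic_and_roc(table, ("cvi0_pct",), labels)
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)
        assert 0.0 <= roc.auc <= 1.0
        assert roc.ci_low <= roc.auc <= roc.ci_high

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_from_scores([1.0, 2.0, 3.0], ["slow", "slow", "slow"])


class TestDeLong:
    def _two_models(self, n=50, seed=17):
        r = np.random.default_rng(seed)
        positive = r.random(n) < 0.5
        positive[:2] = [True, False]
        base = positive.astype(float)
        s_a = base + r.normal(0, 1.2, n)
        s_b = base + r.normal(0, 1.4, n)
        labels = np.where(positive, "slow", "fast")
        return s_a, s_b, labels, positive

    def test_self_comparison(self):
        s_a, _, labels, _ = self._two_models()
        roc = roc_from_scores(s_a, labels)
        d, p = delong_compare(roc, roc)
        assert d == 0.0
        assert p == 1.0

    def test_antisymmetry(self):
        s_a, s_b, labels, _ = self._two_models()
        ra = roc_from_scores(s_a, labels)
        rb = roc_from_scores(s_b, labels)
        d1, p1 = delong_compare(ra, rb)
        d2, p2 = delong_compare(rb, ra)
        assert d1 == pytest.approx(-d2)
        assert p1 == pytest.approx(p2)

    def test_against_permutation_oracle(self):
        """DeLong P agrees with a paired model-swap permutation test."""
        s_a, s_b, labels, positive = self._two_models()
        ra = roc_from_scores(s_a, labels)
        rb = roc_from_scores(s_b, labels)
        _, p_delong = delong_compare(ra, rb)
        obs = abs(auc_rank(s_a, positive) - auc_rank(s_b, positive))
        r = np.random.default_rng(0)
        n_perm, hits = 10000, 0
        for _ in range(n_perm):
            swap = r.random(s_a.size) < 0.5
            pa = np.where(swap, s_b, s_a)
            pb = np.where(swap, s_a, s_b)
            d = abs(auc_rank(pa, positive) - auc_rank(pb, positive))
            hits += d >= obs - 1e-12
        p_perm = hits / n_perm
        assert p_delong == pytest.approx(p_perm, abs=0.05)

    def test_mismatched_subjects_raise(self):
        s_a, s_b, labels, _ = self._two_models()
        ra = roc_from_scores(s_a, labels)
        rb = roc_from_scores(s_b[:-2], labels[:-2])
        with pytest.raises(ValueError):
            delong_compare(ra, rb)


class TestIdi:
    def test_identical_models_zero(self, rng):
        p = rng.random(30)
        labels = np.where(rng.random(30) < 0.5, "slow", "fast")
        with pytest.warns(UserWarning, match="degenerate"):
            res = compute_idi(p, p, labels)
        assert res.idi == 0.0

    def test_hand_example(self):
        p_new = np.array([0.9, 0.8, 0.2, 0.3])
        p_old = np.array([0.6, 0.6, 0.4, 0.4])
        labels = np.array(["slow", "slow", "fast", "fast"])
        res = compute_idi(p_new, p_old, labels)
        assert res.idi == pytest.approx(0.6 - 0.2)

    def test_noise_predictor_near_zero(self, cohort5000):
        table, _ = cohort5000
        table = table.head(2000).copy()
        table["noise"] = np.random.default_rng(3).normal(size=len(table))
        _, labels = dichotomize_by_median(table.d_al_annualized_mm_yr)
        r_old = fit_logistic_and_roc(table, ("cvi0_pct",), labels)
        r_new = fit_logistic_and_roc(table, ("cvi0_pct", "noise"), labels)
        res = compute_idi(r_new.scores, r_old.scores, labels)
        assert abs(res.idi) < 0.01

    def test_true_added_predictor_positive_idi(self):
        """IDI of nested models is positive in nearly all replicates when
        the added predictor has a real effect."""
        wins = 0
        n_rep = 25
        for rep in range(n_rep):
            table, _ = generate_cohort(CohortGenParams(n=400, seed=500 + rep))
            _, labels = dichotomize_by_median(table.d_al_annualized_mm_yr)
            r_old = fit_logistic_and_roc(table, ("cvi0_pct",), labels)
            r_new = fit_logistic_and_roc(table, ("cvi0_pct", "d_sfct_um"),
                                         labels)
            wins += compute_idi(r_new.scores, r_old.scores, labels).idi > 0
        assert wins / n_rep >= 0.95

    def test_degenerate_probabilities_warn(self):
        p = np.full(10, 0.5)
        labels = np.array(["slow"] * 5 + ["fast"] * 5)
        with pytest.warns(UserWarning, match="degenerate"):
            res = compute_idi(p, np.full(10, 0.4), labels)
        assert np.isnan(res.p)

    def test_probability_bounds_checked(self):
        with pytest.raises(ValueError):
            compute_idi([1.2, 0.5], [0.5, 0.5], ["slow", "fast"])
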