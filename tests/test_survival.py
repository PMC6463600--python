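"""Unit tests for the survival-statistics core, with lifelines and direct
enumeration as independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bbocox.simulate import GeneratorConfig, generate_cohort
from bbocox.survival import (
    ConcordanceUndefinedError,
    CoxData,
    DegenerateDesignError,
    chisq_test,
    concordance,
    fit_cox,
    km_curve,
    logrank_test,
    null_log_partial_likelihood,
)
from conftest import brute_force_concordance, random_survival_fixture

BETA_CLOSED_FORM = np.log((1 + np.sqrt(17)) / 2)


class TestCox:
    def test_worked_example_closed_form(self, worked_cox_cohort):
        fit = fit_cox(worked_cox_cohort, ("x",))
        assert fit.converged and not fit.diverged
        assert abs(fit.beta[0] - BETA_CLOSED_FORM) < 1e-8

    def test_score_at_solution_below_tolerance(self, default_cohort):
        fit = fit_cox(default_cohort, ("tumor_gt2cm", "node_pos", "no_ht"))
        assert fit.converged
        from bbocox.survival import _breslow_ll_grad_hess

        data = CoxData.from_cohort(default_cohort,
                                   ["tumor_gt2cm", "node_pos", "no_ht"])
        _, grad, _ = _breslow_ll_grad_hess(data, data.X, fit.beta)
        assert np.max(np.abs(grad)) < 1e-8

    def test_monotone_likelihood_flags_divergence(self):
        df = pd.DataFrame({"time": [1.0, 2, 3, 4], "event": [1, 1, 1, 1],
                           "x": [1, 1, 0, 0]})
        fit = fit_cox(df, ("x",))
        assert fit.diverged and not fit.converged

    def test_hr_and_ci_are_transformed_beta(self, default_cohort):
        fit = fit_cox(default_cohort, ("tumor_gt2cm", "no_ht"))
        np.testing.assert_allclose(fit.hr, np.exp(fit.beta), rtol=1e-12)
        np.testing.assert_allclose(
            fit.ci95[:, 0], np.exp(fit.beta - 1.959964 * fit.se), rtol=1e-12)

    def test_constant_covariate_raises(self, default_cohort):
        df = default_cohort.copy()
        df["flat"] = 1
        with pytest.raises(DegenerateDesignError):
            fit_cox(df, ("flat", "no_ht"))

    def test_empty_subset_rejected(self, default_cohort):
        with pytest.raises(ValueError):
            fit_cox(default_cohort, ())

    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_agreement_with_lifelines(self, ties):
        """Reference-implementation agreement: beta within 1e-4 and C within
        1e-6 on random synthetic cohorts."""
        lifelines = pytest.importorskip("lifelines")
        from lifelines.utils import concordance_index

        subset = ("tumor_gt2cm", "node_pos", "no_ht", "grade3", "er_pos")
        n_checks = 25 if ties == "breslow" else 10
        for seed in range(n_checks):
            cohort = generate_cohort(GeneratorConfig(
                n_patients=250, target_event_fraction=0.35, seed=seed,
                tie_rounding=2.0 if seed % 3 == 0 else None))
            mine = fit_cox(cohort, subset, ties=ties)
            cph = lifelines.CoxPHFitter()
            with np.errstate(all="ignore"):
                cph.fit(cohort[["time", "event", *subset]], "time", "event",
                        fit_options={"precision": 5e-13})
            if ties == "efron":
                assert np.abs(mine.beta - cph.params_.values).max() < 1e-4
            else:
                # lifelines fits Efron; on tie-free cohorts both coincide
                if cohort["time"].duplicated().sum() == 0:
                    assert np.abs(mine.beta - cph.params_.values).max() < 1e-4
            if cohort["time"].duplicated().sum() == 0:
                # with tied times lifelines credits pairs our usable-pair
                # rule excludes, so the C cross-check is tie-free only
                c_mine = concordance(cohort["time"].to_numpy(),
                                     cohort["event"].to_numpy(),
                                     mine.linear_predictor).c
                c_ll = concordance_index(cohort["time"], -mine.linear_predictor,
                                         cohort["event"])
                assert abs(c_mine - c_ll) < 1e-6

    def test_breslow_efron_coincide_without_ties(self, default_cohort):
        sub = ("tumor_gt2cm", "no_ht")
        b = fit_cox(default_cohort, sub, ties="breslow")
        e = fit_cox(default_cohort, sub, ties="efron")
        assert np.abs(b.beta - e.beta).max() < 1e-10

    def test_null_loglik_matches_zero_beta_limit(self, default_cohort):
        data = CoxData.from_cohort(default_cohort)
        from bbocox.survival import _breslow_ll_grad_hess

        ll0, _, _ = _breslow_ll_grad_hess(data, data.X[:, :2], np.zeros(2))
        assert abs(null_log_partial_likelihood(data) - ll0) < 1e-9


class TestConcordance:
    def test_three_patient_example(self):
        res = concordance(np.array([2.0, 4, 6]), np.array([1, 1, 0]),
                          np.array([3.0, 1, 2]))
        assert (res.usable_pairs, res.concordant) == (3, 2)
        assert res.c == pytest.approx(2 / 3)

    def test_perfect_anti_monotone_risk(self):
        t = np.arange(1.0, 8)
        res = concordance(t, np.ones(7, int), -t)
        assert res.c == 1.0

    def test_all_tied_risks_harrell_half(self):
        t = np.arange(1.0, 8)
        res = concordance(t, np.ones(7, int), np.zeros(7))
        assert res.c == 0.5
        strict = concordance(t, np.ones(7, int), np.zeros(7), mode="strict")
        assert strict.c == 0.0

    def test_counts_partition_usable_pairs(self):
        rng = np.random.default_rng(3)
        t, e, r = random_survival_fixture(rng, 40)
        res = concordance(t, e, r)
        assert (res.concordant + res.discordant + res.tied_predictions
                == res.usable_pairs)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(2, 30))
            t, e, r = random_survival_fixture(rng, n)
            for mode in ("harrell", "strict"):
                expected = brute_force_concordance(t, e, r, mode)
                try:
                    res = concordance(t, e, r, mode=mode)
                except ConcordanceUndefinedError as err:
                    assert expected[4] == 0
                    assert err.result.usable_pairs == 0
                    continue
                assert (res.concordant, res.discordant, res.tied_predictions,
                        res.usable_pairs) == expected[1:]
                assert res.c == pytest.approx(expected[0])

    def test_strict_complement_identity(self):
        """With distinct times, distinct risks and full follow-up,
        C(risk) + C(-risk) = 1 in strict mode."""
        rng = np.random.default_rng(5)
        t = rng.permutation(20) + 1.0
        r = rng.permutation(20).astype(float)
        e = np.ones(20, int)
        c1 = concordance(t, e, r, mode="strict").c
        c2 = concordance(t, e, -r, mode="strict").c
        assert c1 + c2 == pytest.approx(1.0)

    def test_equals_auroc_for_binary_outcome_ranking(self):
        """With all-event data and a two-valued time (late = good outcome),
        Harrell's C is the AUROC of risk for the early-event class."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 50)  # 1 = early event
        time = np.where(y == 1, 1.0, 2.0)
        risk = rng.normal(size=50) + y
        c = concordance(time, np.ones(50, int), risk).c
        auroc = roc_auc_score(y, risk)
        assert c == pytest.approx(auroc)

    def test_zero_events_raises_with_counts(self):
        with pytest.raises(ConcordanceUndefinedError) as exc:
            concordance(np.array([1.0, 2]), np.array([0, 0]), np.array([1.0, 2]))
        assert exc.value.result.usable_pairs == 0


class TestKaplanMeier:
    def test_uncensored_closed_form(self):
        n = 6
        curve = km_curve(np.arange(1.0, n + 1), np.ones(n, int))
        np.testing.assert_allclose(curve.survival, (n - np.arange(1, n + 1)) / n)

    def test_all_censored_survival_one(self):
        curve = km_curve(np.arange(1.0, 5), np.zeros(4, int))
        assert curve.times.size == 0

    def test_hand_enumerated_six_patient_fixture(self):
        # events at 1 (6 at risk), 3 (4 at risk), 5 (2 at risk);
        # censoring at 2 and 4 only shrinks later risk sets
        time = np.array([1.0, 2, 3, 4, 5, 6])
        event = np.array([1, 0, 1, 0, 1, 0])
        curve = km_curve(time, event)
        np.testing.assert_allclose(curve.times, [1, 3, 5])
        np.testing.assert_allclose(curve.at_risk, [6, 4, 2])
        np.testing.assert_allclose(curve.survival,
                                   [5 / 6, 5 / 6 * 3 / 4, 5 / 6 * 3 / 4 * 1 / 2])

    def test_monotone_and_in_range(self, default_cohort):
        curve = km_curve(default_cohort["time"].to_numpy(),
                         default_cohort["event"].to_numpy())
        assert np.all(np.diff(curve.survival) <= 0)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))
        assert np.all(curve.at_risk > 0)

    def test_matches_lifelines(self, default_cohort):
        lifelines = pytest.importorskip("lifelines")
        kmf = lifelines.KaplanMeierFitter()
        kmf.fit(default_cohort["time"], default_cohort["event"])
        curve = km_curve(default_cohort["time"].to_numpy(),
                         default_cohort["event"].to_numpy())
        ref = kmf.survival_function_.loc[curve.times, "KM_estimate"].to_numpy()
        np.testing.assert_allclose(curve.survival, ref, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_curve(np.array([]), np.array([]))


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_label_permutation_invariance(self, default_cohort):
        t = default_cohort["time"].to_numpy()
        e = default_cohort["event"].to_numpy()
        g = default_cohort["no_ht"].to_numpy()
        a = logrank_test(t, e, g)
        b = logrank_test(t, e, 1 - g)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_matches_lifelines_two_and_three_groups(self, default_cohort):
        pytest.importorskip("lifelines")
        from lifelines.statistics import multivariate_logrank_test

        t = default_cohort["time"].to_numpy()
        e = default_cohort["event"].to_numpy()
        g2 = default_cohort["no_ht"].to_numpy()
        g3 = (default_cohort["tumor_gt2cm"] + default_cohort["node_pos"]).to_numpy()
        for g in (g2, g3):
            mine = logrank_test(t, e, g)
            ref = multivariate_logrank_test(t, g, e)
            assert mine.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
            assert mine.p == pytest.approx(ref.p_value, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(np.array([1.0, 2]), np.array([1, 1]), np.array([0, 0]))


class TestChiSquared:
    def test_proportional_rows_independent(self):
        res = chisq_test([[10, 20], [30, 60]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_transposition_invariance(self):
        a = chisq_test([[1195, 635], [35, 31]])
        b = chisq_test([[1195, 35], [635, 31]])
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_matches_scipy(self):
        from scipy.stats import chi2_contingency

        table = [[688, 1142], [31, 35]]
        mine = chisq_test(table)
        stat, p, dof, _ = chi2_contingency(table, correction=False)
        assert mine.statistic == pytest.approx(stat, rel=1e-12)
        assert mine.p == pytest.approx(p, rel=1e-12)
        assert mine.df == dof

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_test([[0, 0], [3, 5]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            chisq_test([[1.5, 2], [3, 4]])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(
    st.tuples(st.integers(1, 8), st.booleans(), st.integers(-3, 3)),
    min_size=2, max_size=20))
def test_concordance_property_matches_enumeration(rows):
    """Property check: the pair-counting implementation agrees with direct
    enumeration on arbitrary small tied/censored inputs."""
    t = np.array([r[0] for r in rows], dtype=float)
    e = np.array([int(r[1]) for r in rows])
    r = np.array([r[2] for r in rows], dtype=float)
    expected = brute_force_concordance(t, e, r)
    try:
        res = concordance(t, e, r)
    except ConcordanceUndefinedError:
        assert expected[4] == 0
        return
    assert (res.concordant, res.discordant, res.tied_predictions,
            res.usable_pairs) == expected[1:]
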