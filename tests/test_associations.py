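"""Association suite: logistic status model, ROC increment, censored
Cox onset model, Kaplan-Meier tertile analysis, biomarker models,
single-variant tests, stratified reruns and demographics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pdprs import (
    aao_survival,
    biomarker_association,
    km_tertile_analysis,
    mann_whitney_auc,
    roc_increment,
    single_variant_tests,
    status_association,
    stratified_rerun,
    summarize_cohort,
    assign_tertiles,
)
from pdprs.associations import kaplan_meier_curve, split_by_family_history
from pdprs.scoring import ScoreSet
from conftest import make_cohort


def score_set(values, index):
    return ScoreSet(
        pd.DataFrame(
            {"score": values, "n_variants_used": [16] * len(values)}, index=index
        )
    )


class TestStatusAssociation:
    def test_binary_predictor_recovers_2x2_log_odds_ratio(self, rng):
        # exposed: 30 cases, 10 controls; unexposed: 10 cases, 30 controls
        # cross-product OR = 30*30 / (10*10) = 9
        cohort = make_cohort(40, 40, rng)
        exposure = [1.0] * 30 + [0.0] * 10 + [1.0] * 10 + [0.0] * 30
        scores = score_set(exposure, cohort.index)
        res = status_association(scores, cohort, covariates=[])
        assert res.beta == pytest.approx(np.log(9.0), abs=1e-6)

    def test_constant_predictor_rejected(self, rng):
        cohort = make_cohort(20, 20, rng)
        with pytest.raises(ValueError, match="constant"):
            status_association(score_set([1.0] * 40, cohort.index), cohort)

    def test_one_outcome_class_rejected(self, rng):
        cohort = make_cohort(20, 20, rng)
        cases = cohort[cohort.status == "case"]
        with pytest.raises(ValueError, match="outcome"):
            status_association(score_set(range(20), cases.index), cases)

    def test_separation_flagged_not_crashed(self, rng):
        cohort = make_cohort(30, 30, rng)
        # score perfectly separates cases from controls
        sep = [1.0 + i / 100 for i in range(30)] + [-1.0 - i / 100 for i in range(30)]
        res = status_association(score_set(sep, cohort.index), cohort, covariates=[])
        assert not res.converged

    def test_effect_recovery_with_covariates(self, rng):
        n = 1500
        score = rng.normal(0.5, 0.4, n)
        logit = -0.5 + 1.2 * score
        status = rng.random(n) < 1 / (1 + np.exp(-logit))
        cohort = make_cohort(int(status.sum()), int(n - status.sum()), rng)
        order = np.concatenate([np.where(status)[0], np.where(~status)[0]])
        scores = score_set(score[order], cohort.index)
        res = status_association(scores, cohort)
        assert res.beta == pytest.approx(1.2, abs=0.35)
        assert res.ci_low <= res.beta <= res.ci_high


class TestROC:
    def test_auc_matches_pairwise_brute_force(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 1])
        s = np.array([3.2, 1.1, 2.0, 0.5, 1.1, 0.2, 2.5, 2.5])
        concordant = sum(
            1.0 if si > sj else (0.5 if si == sj else 0.0)
            for si, sj in itertools.product(s[y == 1], s[y == 0])
        )
        assert mann_whitney_auc(y, s) == pytest.approx(
            concordant / (y.sum() * (len(y) - y.sum()))
        )

    def test_perfect_separation_gives_unit_auc(self, rng):
        cohort = make_cohort(25, 25, rng)
        sep = [2.0 + i / 50 for i in range(25)] + [-2.0 - i / 50 for i in range(25)]
        _, auc = roc_increment(score_set(sep, cohort.index), cohort)
        assert auc == pytest.approx(1.0, abs=0.01)

    def test_uninformative_score_gives_half_auc(self, rng):
        y = rng.random(2000) < 0.5
        s = rng.normal(size=2000)
        assert mann_whitney_auc(y, s) == pytest.approx(0.5, abs=0.03)

    def test_prs_auc_not_below_base(self, sim_data):
        _, cohort, scores, _ = sim_data
        auc_base, auc_prs = roc_increment(scores, cohort)
        assert 0.5 <= auc_base <= 1.0
        assert auc_prs >= auc_base - 0.01


def grid_partial_likelihood(durations, events, x, grid):
    """Brute-force 1-D profile of the Cox partial likelihood."""
    best_beta, best_ll = None, -np.inf
    order = np.argsort(durations)
    d, e, xv = durations[order], events[order], x[order]
    for beta in grid:
        ll = 0.0
        for i in range(len(d)):
            if e[i] == 1:
                risk = xv[d >= d[i]]
                ll += beta * xv[i] - np.log(np.exp(beta * risk).sum())
        if ll > best_ll:
            best_beta, best_ll = beta, ll
    return best_beta


class TestCoxOnset:
    def test_three_subject_fit_matches_grid_search(self, rng):
        cohort = make_cohort(3, 1, rng)
        cohort.loc[cohort.status == "case", "age_at_onset"] = [50.0, 60.0, 70.0]
        cohort.loc[cohort.status == "case", "age_at_last_assessment"] = [55.0, 65.0, 75.0]
        cohort["sex"] = "male"  # constant covariates must drop out
        cohort["pc1"] = 0.0
        cohort["pc2"] = 0.0
        x = np.array([1.0, 0.0, 1.0, 0.0])
        res = aao_survival(score_set(x, cohort.index), cohort, cases_only=True)
        grid = np.arange(-4, 4, 1e-3)
        expected = grid_partial_likelihood(
            np.array([50.0, 60.0, 70.0]), np.ones(3), x[:3], grid
        )
        assert res.hazard_beta == pytest.approx(expected, abs=1e-3)

    def test_recovers_known_hazard_ratio(self, rng):
        n = 400
        group = rng.random(n) < 0.5
        rate = np.where(group, 1.0 / 4.0, 1.0 / 8.0)  # rate ratio 2
        onset = 30.0 + np.minimum(rng.exponential(1.0 / rate), 85.0)
        cohort = make_cohort(n, 2, rng)
        cases = cohort.index[cohort.status == "case"]
        cohort.loc[cases, "age_at_onset"] = onset
        cohort.loc[cases, "age_at_last_assessment"] = onset + 1.0
        res = aao_survival(
            score_set(
                np.concatenate([group.astype(float), [0.0, 1.0]]), cohort.index
            ),
            cohort,
            cases_only=True,
        )
        assert res.hazard_beta == pytest.approx(np.log(2.0), abs=0.15)

    def test_zero_events_rejected(self, rng):
        cohort = make_cohort(2, 20, rng)
        controls = cohort[cohort.status == "control"]
        with pytest.raises(ValueError, match="events"):
            aao_survival(score_set(range(20), controls.index), controls)

    def test_censoring_direction_on_synthetic_cohort(self, sim_data):
        _, cohort, scores, _ = sim_data
        res = aao_survival(scores, cohort)
        assert res.hazard_beta > 0  # higher PRS -> earlier onset
        assert res.p_value < 0.05
        cases_only = aao_survival(scores, cohort, cases_only=True)
        assert cases_only.n_events == cases_only.n_used


class TestKaplanMeierTertiles:
    def test_curve_matches_hand_product_limit(self):
        durations = pd.Series([50.0, 55.0, 58.0, 60.0, 65.0])
        events = pd.Series([1, 1, 0, 1, 0])
        curve = kaplan_meier_curve(durations, events)
        surv = dict(zip(curve["age"], curve["survival"]))
        assert surv[50.0] == pytest.approx(4 / 5)
        assert surv[55.0] == pytest.approx(4 / 5 * 3 / 4)
        assert surv[60.0] == pytest.approx(4 / 5 * 3 / 4 * 1 / 2)

    def test_curves_are_valid_survival_functions(self, sim_data):
        _, cohort, scores, _ = sim_data
        res = km_tertile_analysis(assign_tertiles(scores), cohort)
        for t, curve in res.km_curves.items():
            vals = curve["survival"].to_numpy()
            assert vals[0] <= 1.0 and (np.diff(vals) <= 1e-12).all()
            assert ((0.0 <= vals) & (vals <= 1.0)).all()

    def test_high_tertile_has_higher_hazard(self, sim_data):
        _, cohort, scores, _ = sim_data
        res = km_tertile_analysis(assign_tertiles(scores), cohort)
        assert res.tertile_effect > 1.0
        assert res.logrank_df == 1
        assert res.logrank_p < 0.05

    def test_all_censored_rejected(self, rng):
        cohort = make_cohort(3, 30, rng)
        sub = cohort[cohort.status == "control"]
        scores = assign_tertiles(score_set(range(30), sub.index))
        with pytest.raises(ValueError):
            km_tertile_analysis(scores, sub)


class TestBiomarkerAssociation:
    def _harmonized(self, cohort, values, analyte="t_tau"):
        return pd.DataFrame(
            {
                "sample_id": cohort.index,
                "analyte": analyte,
                "raw_level": 100.0,
                "platform": cohort["platform"],
                "age_at_lp": cohort["age_at_lp"],
                "harmonized_level": values,
            }
        )

    def test_recovers_negative_generative_slope(self, rng):
        cohort = make_cohort(250, 250, rng)
        score = rng.normal(0.6, 0.3, 500)
        level = -0.4 * score + rng.normal(0, 0.15, 500)
        res = biomarker_association(
            score_set(score, cohort.index),
            self._harmonized(cohort, level),
            cohort,
            "t_tau",
        )
        assert -0.5 <= res.beta <= -0.3
        assert res.p_value < 1e-6

    def test_exact_linear_relation_recovered_exactly(self, rng):
        cohort = make_cohort(6, 6, rng)
        cohort["sex"] = "male"
        cohort["pc1"] = 0.0
        cohort["pc2"] = 0.0
        cohort["age_at_lp"] = 60.0
        score = np.arange(12, dtype=float)
        level = 2.0 - 0.3 * score
        res = biomarker_association(
            score_set(score, cohort.index),
            self._harmonized(cohort, level),
            cohort,
            "t_tau",
        )
        assert res.beta == pytest.approx(-0.3, abs=1e-10)

    def test_null_coverage(self, rng):
        covered = 0
        reps = 100
        for _ in range(reps):
            cohort = make_cohort(30, 30, rng)
            score = rng.normal(size=60)
            level = rng.normal(0, 0.15, 60)
            res = biomarker_association(
                score_set(score, cohort.index),
                self._harmonized(cohort, level),
                cohort,
                "t_tau",
            )
            covered += res.ci_low <= 0.0 <= res.ci_high
        # ~95% nominal coverage within Monte-Carlo slack
        assert 0.85 <= covered / reps <= 1.0

    def test_unknown_analyte_rejected(self, rng):
        cohort = make_cohort(10, 10, rng)
        bio = self._harmonized(cohort, np.zeros(20))
        with pytest.raises(ValueError, match="absent"):
            biomarker_association(
                score_set(range(20), cohort.index), bio, cohort, "abeta_1_42"
            )


class TestSingleVariantAndStrata:
    def test_one_result_per_panel_variant(self, panel, sim_data):
        matrix, cohort, _, _ = sim_data
        results = single_variant_tests(matrix, panel, cohort, "status")
        assert [r.predictor for r in results] == panel.variant_ids

    def test_monomorphic_variant_flagged(self, panel, sim_data, caplog):
        matrix, cohort, _, _ = sim_data
        matrix = matrix.subset()  # copy
        matrix.dosages["rs35749011"] = 0.0
        with caplog.at_level("WARNING"):
            results = single_variant_tests(matrix, panel, cohort, "status")
        flagged = {r.predictor: r for r in results}["rs35749011"]
        assert not flagged.converged and np.isnan(flagged.beta)

    def test_risk_direction_recovered_for_strong_variant(self, sim_data, panel):
        matrix, cohort, _, _ = sim_data
        results = single_variant_tests(matrix, panel, cohort, "status")
        gba = {r.predictor: r for r in results}["rs35749011"]  # OR 2.307
        assert gba.beta > 0

    def test_stratum_of_everyone_matches_unstratified(self, rng):
        cohort = make_cohort(60, 60, rng)
        cohort["family_history"] = np.where(cohort.status == "case", "yes", "no")
        scores = score_set(rng.normal(size=120), cohort.index)
        full = status_association(scores, cohort)
        strat = stratified_rerun(status_association, cohort, "yes", scores)
        assert strat.beta == pytest.approx(full.beta)
        assert strat.stratum == "family_history=yes"

    def test_cases_only_stratum_fails_status_model(self, rng):
        cohort = make_cohort(40, 10, rng)
        cohort["family_history"] = "yes"
        scores = score_set(rng.normal(size=50), cohort.index)
        with pytest.raises(ValueError, match="outcome"):
            stratified_rerun(
                status_association, cohort, "yes", scores, keep_controls=False
            )

    def test_empty_stratum_rejected(self, rng):
        cohort = make_cohort(10, 10, rng)
        cohort["family_history"] = "no"
        with pytest.raises(ValueError, match="empty"):
            split_by_family_history(cohort, "yes")

    def test_equal_effects_in_both_strata(self, rng):
        # same generative PRS effect in both family-history strata:
        # stratum estimates should agree within sampling error
        agree = 0
        reps = 20
        for _ in range(reps):
            n = 600
            score = rng.normal(0, 0.5, n)
            status = rng.random(n) < 1 / (1 + np.exp(-(0.2 + 1.0 * score)))
            cohort = make_cohort(int(status.sum()), int(n - status.sum()), rng)
            order = np.concatenate([np.where(status)[0], np.where(~status)[0]])
            scores = score_set(score[order], cohort.index)
            betas, ses = [], []
            for stratum in ("yes", "no"):
                r = stratified_rerun(status_association, cohort, stratum, scores)
                betas.append(r.beta)
                ses.append((r.ci_high - r.ci_low) / (2 * 1.96))
            pooled_se = np.hypot(*ses)
            agree += abs(betas[0] - betas[1]) < 2 * pooled_se
        assert agree / reps >= 0.9


class TestDemographics:
    def test_female_percentages_from_counts(self, rng):
        cohort = make_cohort(
            829, 432, rng, n_female_cases=278, n_female_controls=197
        )
        table = summarize_cohort(cohort)
        assert table.loc[("combined", "control"), "n"] == 432
        assert table.loc[("combined", "case"), "n"] == 829
        assert table.loc[("combined", "control"), "pct_female"] == 45.60
        assert table.loc[("combined", "case"), "pct_female"] == 33.53

    def test_per_platform_rows_present(self, sim_data):
        _, cohort, _, _ = sim_data
        table = summarize_cohort(cohort)
        assert {"combined", "PPMI", "WUSTL"} <= set(table.index.get_level_values(0))

    def test_empty_cohort_gives_empty_table(self):
        assert summarize_cohort(pd.DataFrame()).empty
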