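"""Evaluation metrics: IQ-OR, extreme-quartile OR, AUC, decile calibration,
residual adjustment and the interaction scan."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

import prsforge as pf
from prsforge.evaluate import bonferroni_alpha, oe_slope
from prsforge.synthdata import SimulationConfig, SNPSpec


class TestIqOr:
    def test_null_scores_ci_contains_one(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=10000)
        status = (rng.random(10000) < 0.5).astype(float)
        orr, (lo, hi) = pf.iq_or(scores, status)
        assert lo <= 1.0 <= hi

    def test_scale_invariance(self, scored_cohort):
        scores, status = scored_cohort
        a, _ = pf.iq_or(scores, status)
        b, _ = pf.iq_or(scores * 7.3, status)
        assert a == pytest.approx(b, rel=1e-9)

    def test_matches_independent_logistic_fit(self):
        controls = np.array([0.0, 1.0, 2.0, 3.0])
        cases = np.array([2.0, 3.0, 4.0, 5.0])
        scores = np.concatenate([controls, cases])
        status = np.array([0.0] * 4 + [1.0] * 4)
        iqr = np.percentile(controls, 75) - np.percentile(controls, 25)
        # independent route: sklearn's near-unpenalized logistic on raw scores
        lr = LogisticRegression(C=1e8, max_iter=10000, tol=1e-12)
        lr.fit(scores[:, None], status)
        expected = np.exp(lr.coef_[0, 0] * iqr)
        got, _ = pf.iq_or(scores, status)
        assert got == pytest.approx(expected, rel=1e-3)

    def test_zero_iqr_rejected(self):
        with pytest.raises(ValueError):
            pf.iq_or(np.array([1.0, 1.0, 1.0, 2.0]), np.array([0.0, 0.0, 0.0, 1.0]))


class TestQuartileOr:
    def test_uniform_cases_give_unit_or(self):
        controls = np.arange(100, dtype=float)
        cases = np.arange(100, dtype=float) + 0.5
        scores = np.concatenate([controls, cases])
        status = np.array([0.0] * 100 + [1.0] * 100)
        orr, _ = pf.quartile_or(scores, status)
        assert orr == pytest.approx(1.0, rel=0.1)

    def test_hand_computed_cross_product(self):
        controls = np.arange(1, 101, dtype=float)  # 25 per quartile
        cases = np.concatenate([np.full(10, 2.0), np.full(30, 99.0)])
        scores = np.concatenate([controls, cases])
        status = np.array([0.0] * 100 + [1.0] * 40)
        orr, (lo, hi) = pf.quartile_or(scores, status)
        assert orr == pytest.approx((30 * 25) / (10 * 25))
        assert lo < orr < hi

    def test_cut_points_from_controls_only(self):
        controls = np.arange(1, 101, dtype=float)
        cases = np.concatenate([np.full(10, 2.0), np.full(30, 99.0)])
        extreme_cases = np.concatenate([cases, np.full(50, 1e6)])
        s1 = np.concatenate([controls, cases])
        y1 = np.array([0.0] * 100 + [1.0] * 40)
        s2 = np.concatenate([controls, extreme_cases])
        y2 = np.array([0.0] * 100 + [1.0] * 90)
        # adding extreme-valued cases must not move the control cut points:
        # Q1 cell counts are unchanged
        or1, _ = pf.quartile_or(s1, y1)
        or2, _ = pf.quartile_or(s2, y2)
        assert or2 == pytest.approx(or1 * (30 + 50) / 30)


class TestAucCi:
    def test_perfect_separation(self):
        scores = np.array([1.0, 2.0, 10.0, 11.0])
        status = np.array([0.0, 0.0, 1.0, 1.0])
        auc, (lo, hi) = pf.auc_ci(scores, status)
        assert auc == 1.0 and hi == 1.0

    def test_exhaustive_pair_enumeration_toy(self):
        scores = np.array([2.0, 3.0, 1.0, 2.5])
        status = np.array([1.0, 1.0, 0.0, 0.0])
        auc, _ = pf.auc_ci(scores, status)
        assert auc == pytest.approx(3 / 4)

    def test_antisymmetry(self, scored_cohort):
        scores, status = scored_cohort
        a, _ = pf.auc_ci(scores, status)
        b, _ = pf.auc_ci(-scores, status)
        assert a == pytest.approx(1 - b, abs=1e-12)

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(1)
        scores = np.round(rng.normal(size=160), 1)  # ties likely
        status = (rng.random(160) < 0.45).astype(float)
        cases = scores[status == 1]
        controls = scores[status == 0]
        wins = 0.0
        for c in cases:
            wins += np.sum(c > controls) + 0.5 * np.sum(c == controls)
        expected = wins / (len(cases) * len(controls))
        got, _ = pf.auc_ci(scores, status)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            pf.auc_ci(np.array([1.0, 2.0]), np.array([1.0, 1.0]))


class TestCalibration:
    def test_through_origin_slope_closed_form(self):
        expected = np.array([-0.2, 0.1, 0.3])
        observed = np.array([-0.1, 0.2, 0.25])
        slope, ci = oe_slope(expected, observed)
        # sum(xy)/sum(x^2) = 0.115 / 0.14
        assert slope == pytest.approx(0.115 / 0.14, abs=1e-12)
        assert ci[0] < slope < ci[1]

    def test_well_specified_scores_slope_near_one(self, scored_cohort):
        scores, status = scored_cohort
        cal = pf.calibration(scores, status)
        assert cal.ci[0] <= 1.0 <= cal.ci[1]
        assert abs(cal.slope - 1.0) < 0.25

    def test_doubled_scores_halve_slope(self, scored_cohort):
        scores, status = scored_cohort
        s1 = pf.calibration(scores, status).slope
        s2 = pf.calibration(2.0 * scores, status).slope
        assert s2 == pytest.approx(0.5 * s1, rel=1e-6)

    def test_table_shape_and_reference(self, scored_cohort):
        scores, status = scored_cohort
        cal = pf.calibration(scores, status)
        assert len(cal.table) == 10
        assert cal.reference_bins == (5, 6)
        assert cal.table["is_reference"].sum() == 2

    def test_first_bin_reference_mode(self, scored_cohort):
        scores, status = scored_cohort
        cal = pf.calibration(scores, status, reference="first")
        assert cal.reference_bins == (1,)
        assert (cal.table.loc[~cal.table.is_reference, "expected_log_or"] > 0).all()


class TestResidualAdjust:
    def _table(self, n, rng):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "age": rng.uniform(35, 70, n),
                "age_menarche": rng.normal(14, 1.5, n),
                "live_births": rng.poisson(1.2, n).astype(float),
                "family_history": rng.random(n) < 0.05,
                "bmi": rng.normal(23, 3, n),
                "menopausal": rng.random(n) < 0.4,
                "external_5yr_risk": rng.uniform(0.002, 0.02, n),
            }
        )

    def test_orthogonal_covariates_return_centered_scores(self):
        rng = np.random.default_rng(2)
        t = self._table(2000, rng)
        scores = rng.normal(size=2000)  # independent of covariates
        resid = pf.residual_adjust(scores, t, mode="classical")
        # residuals are centered and barely differ from centered scores
        assert abs(resid.mean()) < 1e-10
        assert np.corrcoef(resid, scores - scores.mean())[0, 1] > 0.99

    def test_exact_linear_score_gives_zero_residuals(self):
        rng = np.random.default_rng(3)
        t = self._table(500, rng)
        scores = 2.0 * t["age"].to_numpy() - 0.5
        resid = pf.residual_adjust(scores, t, mode="classical")
        assert np.abs(resid).max() < 1e-8

    def test_residuals_uncorrelated_with_covariate(self):
        rng = np.random.default_rng(4)
        t = self._table(1000, rng)
        scores = 2.0 * t["age"].to_numpy() + rng.normal(size=1000)
        resid = pf.residual_adjust(scores, t, mode="classical")
        assert abs(np.corrcoef(resid, t["age"])[0, 1]) < 1e-8

    def test_gail_mode_uses_risk_column_only(self):
        rng = np.random.default_rng(5)
        t = self._table(1000, rng)
        scores = 10.0 * t["external_5yr_risk"].to_numpy() + rng.normal(size=1000)
        resid = pf.residual_adjust(scores, t, mode="gail")
        assert abs(np.corrcoef(resid, t["external_5yr_risk"])[0, 1]) < 1e-8

    def test_missing_covariates_rejected_with_sample_list(self):
        rng = np.random.default_rng(6)
        t = self._table(10, rng)
        t.loc[3, "bmi"] = np.nan
        with pytest.raises(ValueError, match="s3"):
            pf.residual_adjust(rng.normal(size=10), t, mode="classical")


class TestInteractionScan:
    def test_bonferroni_threshold_24_snps(self):
        assert bonferroni_alpha(24) == pytest.approx(0.05 / 276)
        assert bonferroni_alpha(24) == pytest.approx(1.8e-4, rel=0.01)

    def test_two_snps_single_pair(self, small_cohort):
        g, t = small_cohort
        res = pf.interaction_scan(g.subset(snp_idx=[0, 1]), t)
        assert len(res.pairs) == 1
        assert res.bonferroni_alpha == pytest.approx(0.05)

    def test_planted_interaction_detected(self):
        specs = [SNPSpec("a", 0.3, 0.0), SNPSpec("b", 0.3, 0.0),
                 SNPSpec("c", 0.3, 0.0)]
        cfg = SimulationConfig(5000, 5000, specs,
                               interaction_terms=[("a", "b", 0.5)], seed=41)
        g, t = pf.simulate_cohort(cfg)
        res = pf.interaction_scan(g, t)
        top = res.pairs.sort_values("p").iloc[0]
        assert {top.snp_i, top.snp_j} == {"a", "b"}
        assert top.p < res.bonferroni_alpha
        assert res.n_significant >= 1

    def test_pair_count_is_choose_two(self, small_cohort):
        g, t = small_cohort
        res = pf.interaction_scan(g.subset(snp_idx=range(6)), t)
        assert len(res.pairs) == 15


class TestEvaluatePrs:
    def test_deterministic_and_complete(self, scored_cohort):
        scores, status = scored_cohort
        n = len(scores)
        rng = np.random.default_rng(7)
        table = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "age": rng.uniform(35, 70, n),
                "age_menarche": rng.normal(14, 1.5, n),
                "live_births": rng.poisson(1.2, n).astype(float),
                "family_history": rng.random(n) < 0.05,
                "bmi": rng.normal(23, 3, n),
                "menopausal": rng.random(n) < 0.4,
                "external_5yr_risk": rng.uniform(0.002, 0.02, n),
            }
        )
        r1 = pf.evaluate_prs(scores, status, table,
                             adjustments=("none", "gail", "classical"))
        r2 = pf.evaluate_prs(scores, status, table,
                             adjustments=("none", "gail", "classical"))
        assert [r.as_row() for r in r1] == [r.as_row() for r in r2]
        for r in r1:
            row = r.as_row()
            for key in ("iq_or", "q4_vs_q1_or", "oe_or", "auc"):
                assert np.isfinite(row[key])
            assert row["iq_or_lo"] <= row["iq_or"] <= row["iq_or_hi"]
            assert row["auc_lo"] <= row["auc"] <= row["auc_hi"]

    def test_independent_covariates_barely_change_metrics(self, scored_cohort):
        scores, status = scored_cohort
        n = len(scores)
        rng = np.random.default_rng(8)
        table = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "age": rng.uniform(35, 70, n),
                "age_menarche": rng.normal(14, 1.5, n),
                "live_births": rng.poisson(1.2, n).astype(float),
                "family_history": rng.random(n) < 0.05,
                "bmi": rng.normal(23, 3, n),
                "menopausal": rng.random(n) < 0.4,
            }
        )
        r_none, r_cls = pf.evaluate_prs(scores, status, table,
                                        adjustments=("none", "classical"))
        assert r_cls.auc == pytest.approx(r_none.auc, abs=0.02)
        assert r_cls.iq_or == pytest.approx(r_none.iq_or, rel=0.1)
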