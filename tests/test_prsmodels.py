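"""PRS weighting models: PCs, RLR, LRR, the bottleneck network, scoring
and cross-validation."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import prsforge as pf
from prsforge.containers import GenotypeMatrix
from prsforge.prsmodels import (
    ANNConfig,
    PRSWeights,
    cross_validate,
    hidden_width,
    training_mask,
)
from prsforge.synthdata import SimulationConfig, SNPSpec


@pytest.fixture(scope="module")
def fitted_cohort(effect_panel):
    cfg = SimulationConfig(2000, 2000, effect_panel, seed=31)
    g, t = pf.simulate_cohort(cfg)
    t = pf.attach_pcs(g, t)
    return g, t


class TestComputePCs:
    def test_scores_orthogonal(self, fitted_cohort):
        g, _ = fitted_cohort
        pcs = pf.compute_pcs(g, 3)
        norm = pcs / np.linalg.norm(pcs, axis=0)
        off = norm.T @ norm - np.eye(3)
        assert np.abs(off).max() < 1e-8

    def test_duplicating_samples_preserves_directions(self, fitted_cohort):
        g, _ = fitted_cohort
        small = g.subset(sample_idx=range(200))
        doubled = GenotypeMatrix(
            small.sample_ids + [s + "b" for s in small.sample_ids],
            list(small.snp_ids),
            np.vstack([small.dosages, small.dosages]),
            list(small.effect_alleles),
            list(small.other_alleles),
        )
        p1 = pf.compute_pcs(small, 2)
        p2 = pf.compute_pcs(doubled, 2)[:200]
        for j in range(2):
            c = np.corrcoef(p1[:, j], p2[:, j])[0, 1]
            assert abs(c) > 1 - 1e-9

    def test_too_few_polymorphic_snps(self):
        g = GenotypeMatrix(["a", "b"], ["rs1"], np.array([[1.0], [1.0]]), ["A"], ["G"])
        with pytest.raises(ValueError):
            pf.compute_pcs(g, 2)


class TestTrainingMask:
    def test_subtype_mask_is_subtype_cases_plus_all_controls(self):
        t = pd.DataFrame(
            {
                "sample_id": list("abcdef"),
                "status": ["case", "case", "case", "control", "control", "control"],
                "er_status": ["positive", "negative", "positive",
                              "unknown", "unknown", "unknown"],
            }
        )
        mask = training_mask(t, "er_neg")
        assert mask.tolist() == [False, True, False, True, True, True]
        assert training_mask(t, "overall").all()

    def test_unknown_case_set_rejected(self):
        t = pd.DataFrame({"sample_id": ["a"], "status": ["case"],
                          "er_status": ["positive"]})
        with pytest.raises(ValueError):
            training_mask(t, "er_unknown")


class TestFitRLR:
    def test_null_snp_beta_near_zero(self):
        specs = [SNPSpec("rs1", 0.3, 0.0)]
        g, t = pf.simulate_cohort(SimulationConfig(10000, 10000, specs, seed=32))
        w = pf.fit_rlr(g, t)
        assert abs(w.betas[0]) < 0.05

    def test_effect_recovery(self):
        specs = [SNPSpec("rs1", 0.3, 0.3), SNPSpec("rs2", 0.3, 0.0)]
        g, t = pf.simulate_cohort(SimulationConfig(10000, 10000, specs, seed=33))
        w = pf.fit_rlr(g, t)
        assert 0.25 <= w.betas[0] <= 0.35

    def test_panel_coverage(self, fitted_cohort):
        g, t = fitted_cohort
        w = pf.fit_rlr(g, t)
        assert len(w.betas) == g.n_snps == 24


class TestFitLRR:
    def test_zero_penalty_matches_joint_mle(self, fitted_cohort):
        g, t = fitted_cohort
        w, _ = pf.fit_lrr(g, t, lambda_grid=[1e-8])
        X = np.hstack([g.dosages, t[["age", "pc1", "pc2"]].to_numpy(float)])
        fit = sm.Logit(pf.status_to_binary(t), sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(w.betas, fit.params[1:25], atol=1e-3)

    def test_huge_penalty_kills_snp_betas_only(self, fitted_cohort):
        g, t = fitted_cohort
        w, _ = pf.fit_lrr(g, t, lambda_grid=[1e6])
        assert np.abs(w.betas).max() < 1e-3
        assert abs(w.covariate_betas["pc1"]) > 1e-3 or abs(w.covariate_betas["age"]) > 1e-4

    def test_snp_beta_norm_shrinks_with_lambda(self, fitted_cohort):
        g, t = fitted_cohort
        norms = []
        for lam in (0.01, 1.0, 100.0, 10000.0):
            w, _ = pf.fit_lrr(g, t, lambda_grid=[lam])
            norms.append(np.linalg.norm(w.betas))
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_cv_ties_prefer_larger_lambda(self, fitted_cohort):
        g, t = fitted_cohort
        _, cv = pf.fit_lrr(g, t, lambda_grid=[0.5, 0.5, 0.5])
        assert cv.chosen == 0.5 and cv.chosen_index == 0


class TestScorePRS:
    def _g(self, dosages, ids=None, alleles=None):
        dosages = np.atleast_2d(np.asarray(dosages, dtype=float))
        m = dosages.shape[1]
        ids = ids or [f"rs{k}" for k in range(m)]
        alleles = alleles or ["A"] * m
        return GenotypeMatrix(
            [f"s{i}" for i in range(len(dosages))], ids, dosages, alleles, ["G"] * m
        )

    def test_zero_betas_zero_scores(self):
        g = self._g([[0, 1, 2], [2, 1, 0]])
        w = PRSWeights("rlr", g.snp_ids, g.effect_alleles, np.zeros(3))
        np.testing.assert_array_equal(pf.score_prs(w, g), [0.0, 0.0])

    def test_single_snp_arithmetic(self):
        g = self._g([[2.0]])
        w = PRSWeights("rlr", g.snp_ids, g.effect_alleles, np.array([np.log(2)]))
        assert pf.score_prs(w, g)[0] == pytest.approx(2 * np.log(2))

    def test_three_snp_hand_computation(self):
        g = self._g([[1, 2, 0]])
        w = PRSWeights("rlr", g.snp_ids, g.effect_alleles, np.array([0.1, -0.2, 0.3]))
        assert pf.score_prs(w, g)[0] == pytest.approx(-0.3)

    def test_linear_in_betas(self):
        rng = np.random.default_rng(5)
        g = self._g(rng.integers(0, 3, (20, 4)))
        b1, b2 = rng.normal(size=4), rng.normal(size=4)
        w = lambda b: PRSWeights("rlr", g.snp_ids, g.effect_alleles, b)
        np.testing.assert_allclose(
            pf.score_prs(w(b1 + b2), g),
            pf.score_prs(w(b1), g) + pf.score_prs(w(b2), g),
        )
        np.testing.assert_allclose(
            pf.score_prs(w(3.0 * b1), g), 3.0 * pf.score_prs(w(b1), g)
        )

    def test_panel_mismatch_raises(self):
        g = self._g([[1, 0]])
        w = PRSWeights("rlr", ["rs0", "zz"], ["A", "A"], np.array([0.1, 0.2]))
        with pytest.raises(ValueError, match="panel mismatch"):
            pf.score_prs(w, g)

    def test_effect_allele_mismatch_raises(self):
        g = self._g([[1, 0]])
        w = PRSWeights("rlr", g.snp_ids, ["A", "T"], np.array([0.1, 0.2]))
        with pytest.raises(ValueError, match="allele"):
            pf.score_prs(w, g)


class TestANN:
    def test_hidden_width_rule(self):
        assert hidden_width(24) == 7

    def test_default_hyperparameters(self):
        cfg = ANNConfig()
        assert (cfg.n_iterations, cfg.n_hidden_layers, cfg.dropout_rate) == (60, 3, 0.4)
        assert cfg.bottleneck_dim == 6 and cfg.learning_rate == 0.01

    def test_bit_reproducible(self, fitted_cohort):
        g, t = fitted_cohort
        m1, _ = pf.fit_ann(g, t, config=ANNConfig(seed=3))
        m2, _ = pf.fit_ann(g, t, config=ANNConfig(seed=3))
        np.testing.assert_array_equal(pf.score_ann(m1, g), pf.score_ann(m2, g))

    def test_identical_genotypes_identical_scores(self, fitted_cohort):
        g, t = fitted_cohort
        model, _ = pf.fit_ann(g, t, config=ANNConfig(seed=4))
        dup = GenotypeMatrix(
            ["x", "y"], list(g.snp_ids), np.vstack([g.dosages[0], g.dosages[0]]),
            list(g.effect_alleles), list(g.other_alleles),
        )
        s = pf.score_ann(model, dup)
        assert s[0] == s[1]  # covariates never enter the score

    def test_zero_output_weights_constant_score(self, fitted_cohort):
        g, t = fitted_cohort
        model, _ = pf.fit_ann(g, t, config=ANNConfig(seed=5, n_iterations=1))
        model.net.v[: model.net.bottleneck_dim] = 0.0
        s = pf.score_ann(model, g)
        assert np.allclose(s, model.net.c)

    def test_permuted_labels_no_signal(self, fitted_cohort):
        g, t = fitted_cohort
        rng = np.random.default_rng(6)
        t_perm = t.copy()
        t_perm["status"] = rng.permutation(t["status"].to_numpy())
        half = g.n_samples // 2
        model, _ = pf.fit_ann(
            g.subset(sample_idx=range(half)), t_perm.iloc[:half],
            config=ANNConfig(seed=7),
        )
        s = pf.score_ann(model, g.subset(sample_idx=range(half, g.n_samples)))
        y = pf.status_to_binary(t_perm.iloc[half:])
        auc, _ = pf.auc_ci(s, y)
        assert 0.45 <= auc <= 0.55

    def test_signal_learned_from_additive_data(self, fitted_cohort, effect_panel):
        g, t = fitted_cohort
        model, _ = pf.fit_ann(g, t, config=ANNConfig(seed=8))
        g_new, t_new = pf.simulate_cohort(
            SimulationConfig(1000, 1000, effect_panel, seed=77)
        )
        s = pf.score_ann(model, g_new)
        assert s.std() > 0
        assert pf.auc_ci(s, pf.status_to_binary(t_new))[0] > 0.55


def test_interaction_pseudo_snp_scores_like_a_25th_snp(fitted_cohort):
    """A planted product term enters the ridge PRS as one more weighted
    column: scoring the augmented panel equals the base score plus
    beta_25 * (x_i * x_j)."""
    g, t = fitted_cohort
    g25 = pf.add_interaction_pseudo_snp(g, g.snp_ids[0], g.snp_ids[1])
    assert g25.n_snps == g.n_snps + 1
    np.testing.assert_array_equal(
        g25.dosages[:, -1], g.dosages[:, 0] * g.dosages[:, 1]
    )
    w, _ = pf.fit_lrr(g25, t, lambda_grid=[10.0])
    base = PRSWeights("lrr", list(g.snp_ids), list(g.effect_alleles), w.betas[:-1])
    s25 = pf.score_prs(w, g25)
    s_base = pf.score_prs(base, g)
    np.testing.assert_allclose(
        s25, s_base + w.betas[-1] * g25.dosages[:, -1], rtol=1e-10
    )


class TestCrossValidate:
    def test_constant_half_probability_gives_ln2(self):
        y = np.array([0, 1] * 30, dtype=float)
        cv = cross_validate(lambda tr, va, p: np.full(len(va), 0.5), y, ["only"],
                            folds=10, seed=0)
        assert cv.mean_losses[0] == pytest.approx(np.log(2), abs=1e-12)

    def test_every_sample_in_exactly_one_validation_fold(self):
        y = np.array([0, 1] * 55, dtype=float)
        seen = []
        cross_validate(
            lambda tr, va, p: (seen.append(va), np.full(len(va), 0.5))[1],
            y, ["only"], folds=10, seed=1,
        )
        all_idx = np.concatenate(seen)
        assert sorted(all_idx) == list(range(110))

    def test_cv_choice_beats_worst_grid_point_on_holdout(self, fitted_cohort):
        g, t = fitted_cohort
        half = g.n_samples // 2
        gtr, gva = g.subset(sample_idx=range(half)), g.subset(
            sample_idx=range(half, g.n_samples))
        ttr, tva = t.iloc[:half].reset_index(drop=True), t.iloc[half:].reset_index(drop=True)
        grid = [0.1, 1e5]
        w_cv, cv = pf.fit_lrr(gtr, ttr, lambda_grid=grid)
        w_big, _ = pf.fit_lrr(gtr, ttr, lambda_grid=[1e5])
        y = pf.status_to_binary(tva)

        def logloss(w):
            eta = (gva.dosages @ w.betas
                   + tva[["age", "pc1", "pc2"]].to_numpy(float)
                   @ np.array([w.covariate_betas[c] for c in ("age", "pc1", "pc2")])
                   + w.intercept)
            p = np.clip(1 / (1 + np.exp(-eta)), 1e-12, 1 - 1e-12)
            return -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))

        assert logloss(w_cv) <= logloss(w_big) + 1e-9

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(lambda tr, va, p: np.full(len(va), 0.5),
                           np.array([0.0, 1.0] * 10), [], folds=2)
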