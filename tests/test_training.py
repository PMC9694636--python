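import itertools

import numpy as np
import pytest
from scipy.special import expit

from pgspipe import (
    ResampleScheme,
    balance_controls,
    collinearity_screen,
    cross_validated_auc,
    fit_logistic,
    mann_whitney_auc,
    stepwise_aic,
    train_pgs,
)
from pgspipe.training import SeparationError

from conftest import make_cohort, make_genotypes


class TestBalanceControls:
    def test_default_scheme_sizes(self):
        cohort = make_cohort(["case"] * 100 + ["control"] * 4000)
        subsets = balance_controls(cohort, ResampleScheme(seed=1))
        assert len(subsets) == 10
        for idx in subsets:
            status = cohort.status[idx]
            assert (status == "case").sum() == 100
            assert (status == "control").sum() == 400

    def test_exact_pool_single_subset(self):
        cohort = make_cohort(["case"] * 50 + ["control"] * 200)
        (idx,) = balance_controls(cohort, ResampleScheme(n_subsets=1, seed=0))
        assert len(idx) == 250
        assert len(np.unique(idx)) == 250  # the full pool, no replacement

    def test_determinism(self):
        cohort = make_cohort(["case"] * 30 + ["control"] * 300)
        a = balance_controls(cohort, ResampleScheme(seed=42))
        b = balance_controls(cohort, ResampleScheme(seed=42))
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_insufficient_controls_reported(self):
        cohort = make_cohort(["case"] * 100 + ["control"] * 100)
        with pytest.raises(ValueError, match="need 400"):
            balance_controls(cohort, ResampleScheme(seed=0))


class TestCollinearityScreen:
    def test_independent_snps_all_retained(self):
        rng = np.random.default_rng(3)
        g = make_genotypes(rng.integers(0, 3, size=(500, 5)).astype(float))
        retained, report = collinearity_screen(g)
        assert len(retained) == 5
        assert all(v < 1.1 for v in report.values())

    def test_duplicated_column_drops_one(self):
        rng = np.random.default_rng(4)
        col = rng.integers(0, 3, size=400).astype(float)
        other = rng.integers(0, 3, size=400).astype(float)
        g = make_genotypes(np.column_stack([col, col, other]))
        retained, _ = collinearity_screen(g)
        assert len(retained) == 2
        assert "rs2" in retained
        assert ("rs0" in retained) != ("rs1" in retained)

    def test_exact_linear_combination_dropped(self):
        rng = np.random.default_rng(5)
        g1 = rng.integers(0, 2, size=600).astype(float)
        g2 = rng.integers(0, 2, size=600).astype(float)
        g = make_genotypes(np.column_stack([g1, g2, g1 + g2]))
        retained, _ = collinearity_screen(g, vif_threshold=10.0)
        assert len(retained) == 2
        # remaining pair no longer collinear
        sub = make_genotypes(np.column_stack([g.column(s) for s in retained]))
        _, report = collinearity_screen(sub, vif_threshold=10.0)
        assert all(v < 10.0 for v in report.values())

    def test_zero_variance_fails(self):
        g = make_genotypes(np.column_stack([[0, 1, 2, 1], [1, 1, 1, 1.0]]))
        with pytest.raises(ValueError, match="rs1"):
            collinearity_screen(g)


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        # 20% cases, no informative predictor: intercept -> ln(0.25)
        y = np.array([1] * 200 + [0] * 800)
        x = np.zeros((1000, 1))
        x[::2, 0] = 1.0  # balanced, label-independent covariate
        fit = fit_logistic(x, y)
        assert fit.intercept + fit.weights[0] * 0.5 == pytest.approx(np.log(0.25), abs=1e-6)

    def test_consistency_with_generative_weight(self):
        rng = np.random.default_rng(8)
        n = 50_000
        g = rng.binomial(2, 0.4, size=n).astype(float)
        y = (rng.random(n) < expit(-1.0 + 0.3 * g)).astype(int)
        fit = fit_logistic(g, y)
        assert abs(fit.weights[0] - 0.3) < 2 * fit.se[0]

    def test_null_z_scores_are_standard_normal(self):
        rng = np.random.default_rng(12)
        n_extreme = 0
        for _ in range(100):
            g = rng.binomial(2, 0.3, size=2000).astype(float)
            y = (rng.random(2000) < 0.25).astype(int)
            fit = fit_logistic(g, y)
            n_extreme += abs(fit.z[0]) > 3
        assert n_extreme <= 3  # P(|z|>3) ~ 0.0027 per rep

    def test_perfect_separation_raises(self):
        x = np.concatenate([np.zeros(20), np.ones(20) * 2])
        y = np.concatenate([np.zeros(20), np.ones(20)]).astype(int)
        with pytest.raises(SeparationError):
            fit_logistic(x, y)

    def test_missing_dosages_rejected(self):
        x = np.array([[0.0], [np.nan], [1.0], [2.0]])
        with pytest.raises(ValueError, match="imput"):
            fit_logistic(x, np.array([0, 1, 0, 1]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.zeros((10, 1)), np.ones(10))


def enumeration_auc(case_scores, control_scores):
    """Pair-enumeration oracle for the AUC kernel."""
    wins = 0.0
    for c, k in itertools.product(case_scores, control_scores):
        wins += 1.0 if c > k else (0.5 if c == k else 0.0)
    return wins / (len(case_scores) * len(control_scores))


class TestAuc:
    def test_kernel_matches_pair_enumeration_example(self):
        scores = np.array([2.0, 3.0, 1.0, 2.5])
        labels = np.array([True, True, False, False])
        assert mann_whitney_auc(scores, labels) == pytest.approx(0.75)
        assert enumeration_auc([2, 3], [1, 2.5]) == pytest.approx(0.75)

    def test_kernel_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n1, n0 = rng.integers(2, 15, size=2)
            cases = rng.integers(0, 6, size=n1).astype(float)  # forces ties
            controls = rng.integers(0, 6, size=n0).astype(float)
            scores = np.concatenate([cases, controls])
            labels = np.array([True] * n1 + [False] * n0)
            assert mann_whitney_auc(scores, labels) == pytest.approx(
                enumeration_auc(cases, controls)
            )

    def test_perfectly_separable_cv_auc_is_one(self):
        x = np.concatenate([np.full(100, 5.0), np.zeros(100)])[:, None]
        y = np.array([1] * 100 + [0] * 100)
        mean_auc, per_repeat = cross_validated_auc(x, y, n_folds=5, n_repeats=2, seed=0)
        assert mean_auc == 1.0
        assert all(a == 1.0 for a in per_repeat)

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(2000, 3))
        y = rng.permutation([1] * 500 + [0] * 1500)
        mean_auc, _ = cross_validated_auc(x, y, n_folds=5, n_repeats=2, seed=1)
        assert abs(mean_auc - 0.5) < 0.05

    def test_small_class_fails_with_minimum(self):
        x = np.zeros((12, 1))
        y = np.array([1] * 3 + [0] * 9)
        with pytest.raises(ValueError, match="at least 10"):
            cross_validated_auc(x, y, n_folds=10)


class TestTrainPgs:
    def test_single_subset_equals_direct_fit(self, small_sim):
        _, genotypes, cohort, _ = small_sim
        scheme = ResampleScheme(n_subsets=1, control_ratio=4, seed=3)
        model = train_pgs(cohort, genotypes, scheme, n_folds=5, n_repeats=2)
        (idx,) = balance_controls(cohort, scheme)
        retained, _ = collinearity_screen(
            make_genotypes(
                genotypes.dosages[idx],
                snp_ids=list(genotypes.snp_ids),
            )
        )
        cols = [list(genotypes.snp_ids).index(s) for s in retained]
        fit = fit_logistic(genotypes.imputed()[idx][:, cols], cohort.is_case[idx].astype(int))
        assert list(model.snp_ids) == retained
        np.testing.assert_allclose(model.weights, fit.weights, atol=1e-8)

    def test_same_seed_identical_model(self, small_sim):
        _, genotypes, cohort, _ = small_sim
        scheme = ResampleScheme(n_subsets=2, seed=7)
        a = train_pgs(cohort, genotypes, scheme, n_folds=5, n_repeats=2)
        b = train_pgs(cohort, genotypes, scheme, n_folds=5, n_repeats=2)
        assert np.array_equal(a.snp_ids, b.snp_ids)
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.training_auc == b.training_auc

    def test_selected_model_has_best_auc(self, small_sim):
        _, genotypes, cohort, _ = small_sim
        scheme = ResampleScheme(n_subsets=3, seed=1)
        model = train_pgs(cohort, genotypes, scheme, n_folds=5, n_repeats=2)
        aucs = model.provenance["subset_mean_aucs"]
        assert model.training_auc == max(aucs)
        assert aucs[model.provenance["selected_subset"]] == max(aucs)


class TestStepwiseAic:
    def test_causal_snp_selected_first(self):
        rng = np.random.default_rng(30)
        n = 10_000
        x = rng.binomial(2, 0.3, size=(n, 6)).astype(float)
        y = (rng.random(n) < expit(-1.2 + 0.8 * x[:, 2])).astype(int)
        model = stepwise_aic(x, y, [f"c{j}" for j in range(6)])
        assert model.snp_ids[0] == "c2"

    def test_all_noise_admits_almost_nothing(self):
        rng = np.random.default_rng(31)
        admitted = []
        for _ in range(20):
            x = rng.binomial(2, 0.3, size=(10_000, 5)).astype(float)
            y = (rng.random(10_000) < 0.2).astype(int)
            model = stepwise_aic(x, y, [f"c{j}" for j in range(5)])
            admitted.append(model.n_snps)
        # AIC admits a null candidate when its LR stat exceeds 2
        # (P ~ 0.16 each), so a small tail is expected; the bulk stays empty
        assert np.median(admitted) == 0
        assert np.mean(admitted) < 1.5
        assert max(admitted) <= 4

    def test_single_improving_candidate_selected(self):
        rng = np.random.default_rng(32)
        x = rng.binomial(2, 0.4, size=(5000, 1)).astype(float)
        y = (rng.random(5000) < expit(-1.0 + 0.6 * x[:, 0])).astype(int)
        model = stepwise_aic(x, y, ["only"])
        assert list(model.snp_ids) == ["only"]

    def test_aic_path_non_increasing(self):
        rng = np.random.default_rng(33)
        x = rng.binomial(2, 0.3, size=(4000, 8)).astype(float)
        eta = -1.0 + 0.4 * x[:, 0] - 0.3 * x[:, 5]
        y = (rng.random(4000) < expit(eta)).astype(int)
        model = stepwise_aic(x, y, [f"c{j}" for j in range(8)])
        path = model.provenance["aic_path"]
        assert all(b < a for a, b in zip(path, path[1:]))

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            stepwise_aic(np.zeros((10, 0)), np.array([0, 1] * 5), [])
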