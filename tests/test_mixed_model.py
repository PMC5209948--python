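import itertools

import numpy as np
import pytest

from epiblup import (
    GenotypeSimConfig,
    MarkerMatrix,
    Phenotypes,
    RelationshipMatrix,
    VarianceComponents,
    backsolve_interaction_effects,
    build_egblup,
    build_gblup,
    estimate_variance_components,
    predict_genetic_values,
    ridge_effect_solution,
    scale_coding,
    simulate_genotypes,
    translate_coding,
)

from conftest import make_binary_markers, make_markers, random_phenotypes


def ridge_predictions(M, y_train_ids, y, lam):
    """Oracle: fit penalized marker effects on the training rows only."""
    idx = [M.individual_ids.index(i) for i in y_train_ids]
    Mtr = MarkerMatrix(M.values[idx], tuple(y_train_ids), M.marker_ids, M.levels)
    mu, beta = ridge_effect_solution(Mtr, y, lam)
    return mu + M.values @ beta, mu, beta


class TestREML:
    def test_constant_phenotypes_are_degenerate(self, rng):
        M = make_markers(rng, n=12, p=6)
        K = build_gblup(M)
        vc = estimate_variance_components(K, Phenotypes(M.individual_ids, np.ones(12)))
        assert vc.degenerate and vc.sigma2_g == 0.0 and vc.sigma2_e == 0.0

    def test_pure_noise_gives_near_zero_heritability(self):
        rng = np.random.default_rng(11)
        M = make_markers(rng, n=200, p=60)
        K = build_gblup(M)
        vc = estimate_variance_components(K, random_phenotypes(rng, M))
        assert vc.heritability < 0.2

    def test_too_few_individuals_rejected(self, rng):
        M = make_markers(rng, n=5, p=3)
        with pytest.raises(ValueError, match="at least 10"):
            estimate_variance_components(build_gblup(M), random_phenotypes(rng, M))

    def test_recovers_heritability_from_model_draws(self):
        # g ~ N(0, 4 K), e ~ N(0, 1) with K scaled to unit mean diagonal:
        # true h2 = 0.8; the median estimate over replicates must sit close
        rng = np.random.default_rng(5)
        M = simulate_genotypes(GenotypeSimConfig.scaled(500, 400, seed=9))
        K = build_gblup(M).values
        K = K / np.mean(np.diag(K))
        w, V = np.linalg.eigh(K)
        w = np.clip(w, 0, None)
        Khalf = V * np.sqrt(w)
        Kr = RelationshipMatrix(K, M.individual_ids, "G")
        h2s = []
        for _ in range(30):
            g = Khalf @ rng.standard_normal(500) * 2.0  # var 4 on the kernel scale
            y = Phenotypes(M.individual_ids, g + rng.standard_normal(500))
            h2s.append(estimate_variance_components(Kr, y).heritability)
        assert abs(np.median(h2s) - 0.8) < 0.05


class TestKernelPredictor:
    def test_constant_training_phenotypes_predict_zero_genetic_values(self, rng):
        M = make_markers(rng, n=10, p=12)
        y = Phenotypes(M.individual_ids, np.concatenate([np.full(7, 2.5), rng.normal(size=3)]))
        pred = predict_genetic_values(build_gblup(M), y, M.individual_ids[:7], VarianceComponents(1.0, 1.0))
        assert np.allclose(pred.g_hat, 0.0, atol=1e-12)
        assert pred.mu_hat == pytest.approx(2.5)

    def test_matches_ridge_oracle(self):
        # the relationship-matrix solve and penalized marker regression are
        # the same model; predictions must agree to numerical precision
        rng = np.random.default_rng(3)
        for trial in range(25):
            n = int(rng.integers(8, 15))
            p = int(rng.integers(4, 20))
            M = make_markers(rng, n=n, p=p)
            y = random_phenotypes(rng, M)
            lam = float(rng.uniform(0.2, 5.0))
            train = M.individual_ids[: n - 3]
            pred = predict_genetic_values(build_gblup(M), y, train, VarianceComponents(lam, 1.0))
            oracle, mu, _ = ridge_predictions(M, train, y, lam)
            scale = max(np.abs(oracle).max(), 1.0)
            assert np.abs(pred.y_hat - oracle).max() < 1e-8 * scale
            assert pred.mu_hat == pytest.approx(mu, rel=1e-8)

    def test_vanishing_noise_interpolates_training_data(self, rng):
        M = make_markers(rng, n=8, p=30)
        y = random_phenotypes(rng, M)
        train = M.individual_ids[:6]
        pred = predict_genetic_values(build_gblup(M), y, train, VarianceComponents(1e-10, 1.0))
        y_tr = y.reindex(train).y
        assert np.abs(pred.y_hat[:6] - y_tr).max() < 1e-4

    def test_zero_genetic_variance_predicts_the_mean(self, rng):
        M = make_markers(rng, n=10, p=5)
        y = random_phenotypes(rng, M)
        pred = predict_genetic_values(build_gblup(M), y, M.individual_ids[:8], VarianceComponents(1.0, 0.0))
        assert np.allclose(pred.g_hat, 0.0)

    def test_train_test_partition(self, rng):
        M = make_markers(rng, n=10, p=5)
        y = random_phenotypes(rng, M)
        train = M.individual_ids[2:9]
        pred = predict_genetic_values(build_gblup(M), y, train, VarianceComponents(1.0, 1.0))
        assert set(pred.train_ids) | set(pred.test_ids) == set(M.individual_ids)
        assert not set(pred.train_ids) & set(pred.test_ids)


class TestCodingInvarianceOfPredictions:
    """Executable versions of the translation/scaling behavior of the models."""

    def test_gblup_translation_invariance_at_fixed_ratio(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            M = make_markers(rng, n=9, p=6)
            y = random_phenotypes(rng, M)
            P = rng.integers(-2, 3, size=6).astype(float)
            vc = VarianceComponents(1.5, 1.0)
            train = M.individual_ids[:7]
            a = predict_genetic_values(build_gblup(M), y, train, vc)
            b = predict_genetic_values(build_gblup(translate_coding(M, P)), y, train, vc)
            assert np.abs(a.y_hat - b.y_hat).max() < 1e-8

    def test_egblup_translation_changes_predictions(self, rng):
        M = make_markers(rng, n=9, p=6)
        y = random_phenotypes(rng, M)
        vc = VarianceComponents(1.5, 1.0)
        train = M.individual_ids[:7]
        a = predict_genetic_values(build_egblup(M), y, train, vc)
        b = predict_genetic_values(build_egblup(translate_coding(M, np.ones(6))), y, train, vc)
        assert np.abs(a.y_hat - b.y_hat).max() > 1e-4

    def test_ridge_translation_shifts_only_the_intercept(self, rng):
        M = make_markers(rng, n=8, p=5)
        y = random_phenotypes(rng, M)
        P = rng.integers(-2, 3, size=5).astype(float)
        mu, beta = ridge_effect_solution(M, y, 2.0)
        mu_t, beta_t = ridge_effect_solution(translate_coding(M, P), y, 2.0)
        assert np.allclose(beta_t, beta, atol=1e-10)
        assert mu_t == pytest.approx(mu + P @ beta, rel=1e-10)

    def test_ridge_scaling_rescales_effects(self, rng):
        M = make_markers(rng, n=8, p=5)
        y = random_phenotypes(rng, M)
        c = 2.5
        mu, beta = ridge_effect_solution(M, y, 2.0)
        mu_c, beta_c = ridge_effect_solution(scale_coding(M, c), y, 2.0 * c**2)
        assert mu_c == pytest.approx(mu, rel=1e-10)
        assert np.allclose(beta_c, beta / c, atol=1e-10)

    def test_ridge_infinite_penalty_shrinks_to_the_mean(self, rng):
        M = make_markers(rng, n=8, p=5)
        y = random_phenotypes(rng, M)
        mu, beta = ridge_effect_solution(M, y, 1e12)
        assert np.allclose(beta, 0.0, atol=1e-9)
        assert mu == pytest.approx(y.y.mean(), abs=1e-9)


class TestInteractionBacksolve:
    def test_flat_phenotypes_give_zero_effects(self, rng):
        M = make_markers(rng, n=8, p=3)
        y = Phenotypes(M.individual_ids, np.full(8, 1.3))
        tab = backsolve_interaction_effects(M, y, VarianceComponents(0.5, 1.0))
        assert np.allclose(tab.effects, 0.0, atol=1e-12)

    def test_matches_mixed_model_equations(self, rng):
        M = make_markers(rng, n=8, p=3)
        y = random_phenotypes(rng, M)
        vc = VarianceComponents(0.7, 0.9)
        tab = backsolve_interaction_effects(M, y, vc)
        # oracle: full MME with the explicit pairwise design matrix
        pairs = list(itertools.combinations_with_replacement(range(3), 2))
        Z = np.column_stack([M.values[:, j] * M.values[:, k] for j, k in pairs])
        q = Z.shape[1]
        lhs = np.block([
            [np.array([[8.0]]), Z.sum(axis=0)[None, :]],
            [Z.sum(axis=0)[:, None], Z.T @ Z + vc.lam * np.eye(q)],
        ])
        sol = np.linalg.solve(lhs, np.concatenate([[y.y.sum()], Z.T @ y.y]))
        for (j, k), h in zip(pairs, sol[1:]):
            assert tab.effects[j, k] == pytest.approx(h, abs=1e-9)

    def test_active_pair_dominates_in_correct_orientation(self):
        # one planted (1,1)-configuration effect among binary markers: the
        # back-solved table should rank that pair first, with positive sign
        hits = 0
        for rep in range(100):
            r = np.random.default_rng(2000 + rep)
            M = make_binary_markers(r, n=200, p=6)
            X = M.values
            y = Phenotypes(M.individual_ids, 1.0 * ((X[:, 0] == 1) & (X[:, 3] == 1)) + r.normal(0, 0.1, 200))
            vc = estimate_variance_components(build_egblup(M), y)
            mk, ml, h = backsolve_interaction_effects(M, y, vc).top_pair()
            if {mk, ml} == {"m0", "m3"} and h > 0:
                hits += 1
        assert hits >= 90
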