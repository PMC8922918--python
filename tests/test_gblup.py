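import numpy as np
import pytest

from topsel import (
    GBLUP,
    SimulationConfig,
    VarianceComponents,
    compute_kinship,
    gblup_predict,
    kfold_self_predictions,
    prediction_accuracy,
    reml_fit,
    simulate_ncii_genotypes,
    simulate_phenotypes,
)
from topsel.gblup import KinshipMatrix


class TestKinship:
    def test_two_individuals_closed_form(self):
        K = compute_kinship(np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(K.K, [[1.0, -1.0], [-1.0, 1.0]])

    def test_identical_rows_identical_kinship(self, rng):
        X = rng.integers(0, 3, size=(5, 12)).astype(float)
        X[3] = X[1]
        K = compute_kinship(X).K
        np.testing.assert_allclose(K[1], K[3])
        np.testing.assert_allclose(K[:, 1], K[:, 3])

    def test_matches_direct_summation(self, rng):
        X = rng.integers(0, 3, size=(5, 8)).astype(float)
        K = compute_kinship(X)
        Wc = X - X.mean(axis=0)
        poly = X.std(axis=0) > 0
        m = poly.sum()
        brute = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                brute[i, j] = sum(
                    Wc[i, k] * Wc[j, k] for k in range(8) if poly[k]
                ) / m
        np.testing.assert_allclose(K.K, brute, atol=1e-12)

    def test_allele_flip_invariance(self, rng):
        X = rng.integers(0, 3, size=(6, 10)).astype(float)
        np.testing.assert_allclose(
            compute_kinship(X).K, compute_kinship(2.0 - X).K, atol=1e-10
        )

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            compute_kinship(np.ones((3, 4)))


class TestREML:
    def test_recovers_h2_from_its_own_model(self):
        # g drawn with covariance exactly proportional to K, so the REML
        # parametrization is correctly specified
        cfg = SimulationConfig(n_maternal=50, n_paternal=10, n_markers=300,
                               n_qtl=300, h2=np.array([0.5]), seed=21)
        _, hybrids, _ = simulate_ncii_genotypes(cfg)
        K = compute_kinship(hybrids)
        rng = np.random.default_rng(22)
        lam, U = np.linalg.eigh(K.K)
        # normalise K so that sigma_g2 = sigma_e2 = 1 corresponds to h2 = 0.5
        # in the estimator's own parametrization
        lam = np.clip(lam, 0, None) / np.diag(K.K).mean()
        # averaged over a handful of draws; a single n=500 replicate has
        # sampling error comparable to the tolerance
        h2_hat = []
        for _ in range(10):
            g = U @ (np.sqrt(lam) * rng.standard_normal(lam.size))
            y = g + rng.standard_normal(lam.size)
            h2_hat.append(reml_fit(y, (lam, U)).h2)
        assert abs(np.mean(h2_hat) - 0.5) < 0.1

    def test_pure_fixed_effect_pushes_sigma_g_to_zero(self, rng):
        n = 80
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        y = 2.0 + 3.0 * x + 1e-6 * rng.standard_normal(n)
        K = compute_kinship(rng.integers(0, 3, size=(n, 50)).astype(float))
        vc = reml_fit(y, K, X)
        assert vc.h2 < 1e-3

    def test_permutation_invariance(self, rng):
        n = 40
        X = rng.integers(0, 3, size=(n, 60)).astype(float)
        K = compute_kinship(X)
        y = rng.standard_normal(n) + X[:, :5].sum(axis=1)
        vc = reml_fit(y, K)
        perm = rng.permutation(n)
        vc_p = reml_fit(y[perm], K.K[np.ix_(perm, perm)])
        assert vc.sigma_g2 == pytest.approx(vc_p.sigma_g2, rel=1e-4)
        assert vc.sigma_e2 == pytest.approx(vc_p.sigma_e2, rel=1e-4)

    def test_constant_phenotype_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            reml_fit(np.ones(10), np.eye(10))


class TestPredict:
    def test_identity_kinship_scalar_shrinkage(self, rng):
        n = 30
        y = rng.standard_normal(n) * 3 + 5
        vc = VarianceComponents(sigma_g2=0.7, sigma_e2=0.3, h2=0.7,
                                beta=np.array([y.mean()]), loglike=0.0)
        mu, _ = gblup_predict(y, np.eye(n), vc)
        np.testing.assert_allclose(mu, 0.7 * (y - y.mean()), atol=1e-10)

    def test_zero_residual_variance_limit(self, rng):
        n = 20
        X = rng.integers(0, 3, size=(n, 40)).astype(float)
        K = compute_kinship(X).K + 1e-8 * np.eye(n)
        y = rng.standard_normal(n)
        vc = VarianceComponents(sigma_g2=1.0, sigma_e2=1e-12, h2=1.0,
                                beta=np.array([y.mean()]), loglike=0.0)
        _, yhat = gblup_predict(y, K, vc)
        np.testing.assert_allclose(yhat, y, atol=1e-4)

    def test_unrelated_individual_predicted_at_mean(self, rng):
        n = 15
        y = rng.standard_normal(n) + 10
        K = np.eye(n)
        vc = VarianceComponents(sigma_g2=0.5, sigma_e2=0.5, h2=0.5,
                                beta=np.array([y.mean()]), loglike=0.0)
        mu, yhat = gblup_predict(y, K, vc, K_cross=np.zeros((1, n)))
        assert mu[0] == pytest.approx(0.0)
        assert yhat[0] == pytest.approx(y.mean())


class TestGBLUPModel:
    def test_summary_reports_all_traits(self, small_population):
        K = compute_kinship(small_population["hybrids"])
        res = GBLUP(small_population["phenotypes"], K).fit()
        text = res.summary()
        assert "trait01" in text and "h2" in text
        assert res.h2.shape == (3,)
        assert np.all(res.sigma_g2 >= 0) and np.all(res.sigma_e2 > 0)

    def test_predictions_invariant_to_kinship_scaling(self, small_population):
        ph = small_population["phenotypes"]
        K = compute_kinship(small_population["hybrids"])
        pred1 = GBLUP(ph, K).fit().predict()
        K10 = KinshipMatrix(K.individual_ids, 10.0 * K.K)
        pred2 = GBLUP(ph, K10).fit().predict()
        np.testing.assert_allclose(pred1, pred2, rtol=1e-4, atol=1e-6)


class TestKFold:
    def test_folds_partition_and_each_predicted_once(self, small_prediction_set,
                                                     small_population):
        ps = small_prediction_set
        assert ps.individual_ids == small_population["phenotypes"].individual_ids
        assert np.isfinite(ps.predicted).all()

    def test_k_equals_n_matches_explicit_loo(self):
        cfg = SimulationConfig(n_maternal=6, n_paternal=5, n_markers=120, n_qtl=60,
                               h2=np.array([0.6]), seed=13)
        _, hybrids, _ = simulate_ncii_genotypes(cfg)
        ph, _ = simulate_phenotypes(hybrids, cfg)
        K = compute_kinship(hybrids)
        n = ph.n_individuals
        ps = kfold_self_predictions(ph, K, k=n, seed=3)
        # explicit leave-one-out oracle
        y = ph.values[:, 0]
        loo = np.empty(n)
        for i in range(n):
            rest = np.delete(np.arange(n), i)
            K_rr = K.K[np.ix_(rest, rest)]
            vc = reml_fit(y[rest], K_rr)
            _, yhat = gblup_predict(y[rest], K_rr, vc,
                                    K_cross=K.K[np.ix_([i], rest)])
            loo[i] = yhat[0]
        np.testing.assert_allclose(ps.predicted[:, 0], loo, rtol=1e-6, atol=1e-8)

    def test_too_many_folds_rejected(self, small_population):
        K = compute_kinship(small_population["hybrids"])
        with pytest.raises(ValueError):
            kfold_self_predictions(small_population["phenotypes"], K, k=10_000)


class TestAccuracy:
    def test_perfect_and_inverted(self, rng):
        y = rng.standard_normal(50)
        assert prediction_accuracy(y, y) == pytest.approx(1.0)
        assert prediction_accuracy(y, -y) == pytest.approx(-1.0)

    def test_textbook_formula_oracle(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.array([1.0, 2.0, 4.0, 3.0])
        co = obs - obs.mean()
        cp = pred - pred.mean()
        expected = (co @ cp) / np.sqrt((co @ co) * (cp @ cp))
        assert prediction_accuracy(obs, pred) == pytest.approx(expected, rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            prediction_accuracy([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_accuracy_increases_with_heritability():
    """Averaged over seeds, higher h2 gives higher prediction accuracy."""
    means = []
    for h2 in (0.2, 0.5, 0.8):
        accs = []
        for seed in range(20):
            cfg = SimulationConfig(n_maternal=15, n_paternal=6, n_markers=150,
                                   n_qtl=150, h2=np.array([h2]), seed=100 + seed)
            _, hybrids, _ = simulate_ncii_genotypes(cfg)
            ph, _ = simulate_phenotypes(hybrids, cfg)
            K = compute_kinship(hybrids)
            n = ph.n_individuals
            train = np.arange(0, n, 2)
            test = np.arange(1, n, 2)
            y = ph.values[:, 0]
            vc = reml_fit(y[train], K.K[np.ix_(train, train)])
            _, yhat = gblup_predict(y[train], K.K[np.ix_(train, train)], vc,
                                    K_cross=K.K[np.ix_(test, train)])
            accs.append(prediction_accuracy(y[test], yhat))
        means.append(np.mean(accs))
    assert means[0] < means[1] < means[2]
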