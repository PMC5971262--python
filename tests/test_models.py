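"""The three generative classifiers: fitting, discriminant scores,
degeneracies, serialization, and the scikit-learn cross-check."""

import numpy as np
import pytest

from ecgbayes import (
    GNB, LDA, QDA,
    FeatureSpaceSpec, fit, generate_features, load_model, log_scores,
    predict, save_model,
)
from ecgbayes.features import FeatureDataset


def _dataset(X, labels):
    return FeatureDataset(matrix=np.asarray(X, float),
                          labels=np.array(labels, dtype=object))


class TestFit:
    def test_priors_are_class_fractions(self):
        rng = np.random.default_rng(40)
        X = rng.normal(size=(1000, 3))
        labels = ["NB"] * 700 + ["OB"] * 200 + ["PVC"] * 100
        model = fit(GNB, _dataset(X, labels))
        assert model.classes == ["NB", "OB", "PVC"]
        assert [p.prior for p in model.params] == pytest.approx([0.7, 0.2, 0.1])

    def test_single_feature_hand_example(self):
        data = _dataset([[0.0], [2.0], [10.0], [12.0]], ["NB", "NB", "PVC", "PVC"])
        model = fit(GNB, data)
        means = [p.mean[0] for p in model.params]
        variances = [p.covariance[0] for p in model.params]
        assert means == pytest.approx([1.0, 11.0])
        assert variances == pytest.approx([2.0, 2.0])

    def test_missing_class_rejected(self):
        data = _dataset(np.zeros((4, 2)), ["NB"] * 4)
        with pytest.raises(ValueError, match="2 classes"):
            fit(QDA, data)

    def test_qda_parameter_recovery(self):
        """QDA fit on simulated Gaussians recovers the parameters.

        Mean recovery is checked jointly: n * (mu_hat - mu)' Sigma^-1
        (mu_hat - mu) is asymptotically chi-square(d), so it must fall below
        the 99.9% quantile.  Covariance entries must sit within 10% of their
        natural scale sqrt(sigma_ii sigma_jj) at n = 5000/class.
        """
        from scipy.stats import chi2

        rng = np.random.default_rng(41)
        d, n = 5, 5000
        true = {}
        means, covs = {}, {}
        for cls in ("NB", "PVC"):
            mu = rng.normal(0, 2, size=d)
            A = rng.normal(size=(d, d))
            sigma = A @ A.T + d * np.eye(d)
            true[cls] = (mu, sigma)
            means[cls], covs[cls] = mu, sigma
        spec = FeatureSpaceSpec(means=means, covariances=covs,
                                counts={"NB": n, "PVC": n})
        data = generate_features(spec, seed=77)
        model = fit(QDA, data)
        for p in model.params:
            mu, sigma = true[p.class_label]
            diff = p.mean - mu
            stat = n * diff @ np.linalg.solve(sigma, diff)
            assert stat < chi2.ppf(0.999, d)
            scale = np.sqrt(np.outer(np.diag(sigma), np.diag(sigma)))
            assert np.all(np.abs(p.covariance - sigma) / scale < 0.10)


class TestLogScores:
    def test_symmetry_equal_distance(self):
        data = _dataset([[-1.0], [-3.0], [1.0], [3.0]], ["NB", "NB", "PVC", "PVC"])
        model = fit(LDA, data)
        s = log_scores(model, np.array([0.0]))
        assert s[0] == pytest.approx(s[1])

    def test_gnb_univariate_gap(self):
        """Classes N(0,1) and N(4,1), equal priors: at x=0 the score gap is
        (16-0)/2 = 8 in favor of the class centered at 0."""
        rng = np.random.default_rng(42)
        a = rng.normal(0, 1, size=4000)
        b = rng.normal(4, 1, size=4000)
        data = _dataset(np.r_[a, b][:, None], ["NB"] * 4000 + ["PVC"] * 4000)
        model = fit(GNB, data)
        # overwrite with the exact generating parameters for a crisp check
        for p, mu in zip(model.params, [0.0, 4.0]):
            p.mean = np.array([mu])
            p.covariance = np.array([1.0])
            p.prior = 0.5
        model._cache.clear()
        s = log_scores(model, np.array([0.0]))
        assert s[0] - s[1] == pytest.approx(8.0)

    def test_qda_matches_brute_force_density(self):
        """QDA discriminants equal log MVN density + log prior up to the
        class-constant (d/2) log 2pi that the discriminant drops."""
        from scipy.stats import multivariate_normal

        rng = np.random.default_rng(43)
        d = 4
        data = _dataset(rng.normal(size=(300, d)),
                        rng.choice(["NB", "PVC"], size=300))
        model = fit(QDA, data)
        const = 0.5 * d * np.log(2 * np.pi)
        for _ in range(20):
            x = rng.normal(size=d)
            s = log_scores(model, x)
            for k, p in enumerate(model.params):
                brute = multivariate_normal.logpdf(x, p.mean, p.covariance) \
                    + np.log(p.prior)
                assert s[k] == pytest.approx(brute + const, rel=1e-8)

    def test_non_finite_input_rejected(self):
        data = _dataset(np.random.default_rng(0).normal(size=(10, 2)),
                        ["NB"] * 5 + ["PVC"] * 5)
        model = fit(GNB, data)
        with pytest.raises(ValueError, match="non-finite"):
            log_scores(model, np.array([np.nan, 0.0]))


class TestPredict:
    def test_tie_breaks_by_class_order(self):
        data = _dataset([[-1.0], [-3.0], [1.0], [3.0]], ["NB", "NB", "PVC", "PVC"])
        model = fit(LDA, data)
        assert predict(model, np.array([0.0])) == "NB"

    def test_class_mean_predicts_itself(self):
        rng = np.random.default_rng(44)
        X = np.vstack([rng.normal(0, 1, (100, 3)), rng.normal(6, 1, (100, 3))])
        model = fit(LDA, _dataset(X, ["NB"] * 100 + ["PVC"] * 100))
        for p in model.params:
            assert predict(model, p.mean) == p.class_label

    def test_qda_approximates_bayes_rule(self):
        """On two known heteroscedastic Gaussians 10 SD apart, fitted-QDA
        predictions agree with the true-density Bayes rule on >= 95% of
        points."""
        from scipy.stats import multivariate_normal

        rng = np.random.default_rng(45)
        d = 3
        mu = {"NB": np.zeros(d), "PVC": np.full(d, 10.0 / np.sqrt(d))}
        cov = {"NB": np.eye(d), "PVC": 2.5 * np.eye(d)}
        spec = FeatureSpaceSpec(means=mu, covariances=cov,
                                counts={"NB": 1000, "PVC": 1000})
        data = generate_features(spec, seed=46)
        model = fit(QDA, data)
        pred = predict(model, data.matrix)
        bayes = np.where(
            multivariate_normal.logpdf(data.matrix, mu["NB"], cov["NB"])
            >= multivariate_normal.logpdf(data.matrix, mu["PVC"], cov["PVC"]),
            "NB", "PVC")
        assert np.mean(pred == bayes) >= 0.95


class TestDegeneracies:
    @staticmethod
    def _pooled_cov(model_lda, data):
        return model_lda.shared_covariance

    def test_qda_with_pooled_covariance_equals_lda(self):
        """Forcing one shared covariance into QDA collapses it onto LDA."""
        rng = np.random.default_rng(47)
        X = np.vstack([rng.normal(0, 1, (200, 6)), rng.normal(1.5, 1, (200, 6))])
        data = _dataset(X, ["NB"] * 200 + ["PVC"] * 200)
        lda = fit(LDA, data)
        qda = fit(QDA, data)
        for p in qda.params:
            p.covariance = lda.shared_covariance.copy()
        qda._cache.clear()
        Xtest = rng.normal(0.7, 2.0, size=(10_000, 6))
        assert np.array_equal(predict(qda, Xtest), predict(lda, Xtest))

    def test_qda_with_diagonal_covariance_equals_gnb(self):
        """QDA restricted to diagonal per-class covariances matches GNB."""
        rng = np.random.default_rng(48)
        X = np.vstack([rng.normal(0, 1, (200, 6)), rng.normal(2, 1.4, (200, 6))])
        data = _dataset(X, ["NB"] * 200 + ["PVC"] * 200)
        gnb = fit(GNB, data)
        qda = fit(QDA, data)
        for pq, pg in zip(qda.params, gnb.params):
            pq.covariance = np.diag(pg.covariance)
        qda._cache.clear()
        Xtest = rng.normal(1.0, 2.0, size=(10_000, 6))
        assert np.array_equal(predict(qda, Xtest), predict(gnb, Xtest))

    def test_prior_monotonicity_on_grid(self):
        """Raising one class's prior never shrinks its decision region."""
        rng = np.random.default_rng(49)
        X = np.r_[rng.normal(0, 1, 300), rng.normal(3, 1, 300)][:, None]
        data = _dataset(X, ["NB"] * 300 + ["PVC"] * 300)
        model = fit(GNB, data)
        grid = np.linspace(-5, 8, 400)[:, None]
        region_sizes = []
        for prior_nb in (0.3, 0.5, 0.8):
            model.params[0].prior = prior_nb
            model.params[1].prior = 1 - prior_nb
            model._cache.clear()
            region_sizes.append(np.sum(predict(model, grid) == "NB"))
        assert region_sizes == sorted(region_sizes)

    def test_feature_permutation_invariance(self):
        rng = np.random.default_rng(50)
        X = rng.normal(size=(200, 8))
        labels = rng.choice(["NB", "PVC"], size=200)
        perm = rng.permutation(8)
        m1 = fit(QDA, _dataset(X, labels))
        m2 = fit(QDA, _dataset(X[:, perm], labels))
        x = rng.normal(size=8)
        assert np.allclose(log_scores(m1, x), log_scores(m2, x[perm]), atol=1e-8)


@pytest.fixture(scope="module")
def oracle_data():
    rng = np.random.default_rng(51)
    X = np.vstack([rng.normal(0, 1, (300, 5)),
                   rng.normal(2, 1.3, (300, 5)),
                   rng.normal(-2, 0.8, (300, 5))])
    labels = ["NB"] * 300 + ["OB"] * 300 + ["PVC"] * 300
    return _dataset(X, labels)


class TestSklearnOracle:
    """scikit-learn is the independent oracle; the shipped classifiers are
    written from the discriminant equations."""

    def test_gnb_agrees_with_sklearn(self, oracle_data):
        from sklearn.naive_bayes import GaussianNB

        sk = GaussianNB(var_smoothing=0.0).fit(oracle_data.matrix,
                                               oracle_data.labels.astype(str))
        ours = fit(GNB, oracle_data)
        Xt = np.random.default_rng(52).normal(0, 2, size=(2000, 5))
        assert np.mean(predict(ours, Xt) == sk.predict(Xt)) > 0.999

    def test_lda_agrees_with_sklearn(self, oracle_data):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        sk = LinearDiscriminantAnalysis(solver="lsqr", store_covariance=True)
        sk.fit(oracle_data.matrix, oracle_data.labels.astype(str))
        ours = fit(LDA, oracle_data)
        Xt = np.random.default_rng(53).normal(0, 2, size=(2000, 5))
        assert np.mean(predict(ours, Xt) == sk.predict(Xt)) > 0.995

    def test_qda_agrees_with_sklearn(self, oracle_data):
        from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

        sk = QuadraticDiscriminantAnalysis(store_covariance=True)
        sk.fit(oracle_data.matrix, oracle_data.labels.astype(str))
        ours = fit(QDA, oracle_data)
        Xt = np.random.default_rng(54).normal(0, 2, size=(2000, 5))
        assert np.mean(predict(ours, Xt) == sk.predict(Xt)) > 0.995


class TestSerialization:
    def test_round_trip_scores_identical(self, tmp_path):
        rng = np.random.default_rng(55)
        X = rng.normal(size=(100, 4))
        data = _dataset(X, rng.choice(["NB", "OB", "PVC"], size=100))
        for kind in (GNB, LDA, QDA):
            model = fit(kind, data)
            path = tmp_path / f"{kind}.json"
            save_model(model, path)
            back = load_model(path)
            x = rng.normal(size=4)
            assert np.array_equal(log_scores(model, x), log_scores(back, x))

    def test_truncated_payload_rejected(self, tmp_path):
        data = _dataset(np.random.default_rng(56).normal(size=(20, 2)),
                        ["NB"] * 10 + ["PVC"] * 10)
        text = save_model(fit(GNB, data))
        with pytest.raises(ValueError, match="corrupt"):
            load_model(text[: len(text) // 2])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            load_model('{"format": "ecgbayes-model", "version": 1, '
                       '"kind": "SVM", "classes": [], "feature_dim": 0, '
                       '"params": [], "shared_covariance": null}')

    def test_wrong_format_rejected(self):
        with pytest.raises(ValueError, match="not an ecgbayes"):
            load_model('{"format": "something-else"}')
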