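import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirnapanel.discriminant import (CancerProbabilityClassifier,
                                     DiscriminantInputs, cancer_probability,
                                     conditional_subset, crossvalidated_auc,
                                     roc_auc, sigma_total)
from mirnapanel.model import McmcSettings
from mirnapanel.simulate import SimulationConfig, make_fixture, realistic_parameters, simulate_dataset


from oracles import bayes_discriminant_oracle as _bayes_oracle


def _random_instance(rng, K):
    A = rng.normal(size=(K, K))
    Sigma = A @ A.T + K * np.eye(K)
    return (rng.normal(size=K), rng.normal(size=K), Sigma,
            rng.normal(size=K), np.exp(rng.normal()))


class TestSigmaTotal:
    def test_identity_case(self):
        assert np.allclose(sigma_total(np.eye(2), np.ones(2)), 2 * np.eye(2))

    def test_zero_noise(self):
        Omega = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert np.allclose(sigma_total(Omega, np.zeros(2)), Omega)

    def test_spd(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(3, 3))
        np.linalg.cholesky(sigma_total(A @ A.T + 3 * np.eye(3),
                                       np.abs(rng.normal(size=3))))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            sigma_total(np.eye(3), np.ones(2))


class TestCancerProbability:
    def test_class_midpoint_leaves_prior_odds(self):
        mu, beta = np.array([0.3, -0.2]), np.array([1.0, 0.4])
        inputs = DiscriminantInputs(mu=mu, beta_dis=beta, Sigma=np.eye(2))
        p = cancer_probability(mu + beta / 2, inputs)
        assert p == pytest.approx(0.333 / 1.333, abs=1e-4)

    def test_derived_example(self):
        inputs = DiscriminantInputs(mu=np.zeros(2), beta_dis=np.array([1.0, 0.0]),
                                    Sigma=np.eye(2))
        p = cancer_probability(np.array([1.0, 0.0]), inputs)
        oracle = _bayes_oracle(np.array([1.0, 0.0]), np.zeros(2),
                               np.array([1.0, 0.0]), np.eye(2), 0.333)
        assert p == pytest.approx(oracle, abs=1e-10)
        assert p == pytest.approx(0.3544, abs=5e-4)

    def test_no_information_when_beta_zero(self):
        inputs = DiscriminantInputs(mu=np.array([0.5]), beta_dis=np.zeros(1),
                                    Sigma=np.eye(1))
        for y in (-3.0, 0.0, 4.0):
            assert cancer_probability(np.array([y]), inputs) == \
                pytest.approx(0.333 / 1.333, abs=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(1, 5))
    def test_equals_bayes_oracle(self, seed, K):
        rng = np.random.default_rng(seed)
        mu, beta, Sigma, y, odds = _random_instance(rng, K)
        inputs = DiscriminantInputs(mu=mu, beta_dis=beta, Sigma=Sigma,
                                    prior_log_odds=np.log(odds))
        assert cancer_probability(y, inputs) == pytest.approx(
            _bayes_oracle(y, mu, beta, Sigma, odds), abs=1e-10)

    def test_monotone_in_discriminant_score(self):
        rng = np.random.default_rng(5)
        mu, beta, Sigma, _, _ = _random_instance(rng, 3)
        inputs = DiscriminantInputs(mu=mu, beta_dis=beta, Sigma=Sigma)
        w = np.linalg.solve(Sigma, beta)
        probs = [cancer_probability(mu + t * w, inputs) for t in np.linspace(-3, 3, 25)]
        assert np.all(np.diff(probs) > 0)


class TestConditionalSubset:
    def test_full_mask_unchanged(self):
        rng = np.random.default_rng(6)
        mu, beta, Sigma, _, _ = _random_instance(rng, 3)
        inputs = DiscriminantInputs(mu=mu, beta_dis=beta, Sigma=Sigma)
        out = conditional_subset(inputs, np.ones(3, bool))
        assert np.allclose(out.Sigma, Sigma) and np.allclose(out.mu, mu)

    def test_marginalization_consistency(self):
        # restricting dims == computing on a problem where they never existed
        rng = np.random.default_rng(7)
        mu, beta, Sigma, y, odds = _random_instance(rng, 4)
        mask = np.array([True, False, True, False])
        restricted = conditional_subset(
            DiscriminantInputs(mu=mu, beta_dis=beta, Sigma=Sigma,
                               prior_log_odds=np.log(odds)), mask)
        direct = DiscriminantInputs(mu=mu[mask], beta_dis=beta[mask],
                                    Sigma=Sigma[np.ix_(mask, mask)],
                                    prior_log_odds=np.log(odds))
        assert cancer_probability(y[mask], restricted) == pytest.approx(
            cancer_probability(y[mask], direct), abs=1e-12)

    def test_matches_hand_computed_1d(self):
        # diagonal Sigma, keep dim 0: logit = log odds - (2 mu + b) b / (2 v) + y b / v
        inputs = DiscriminantInputs(mu=np.array([0.2, 9.0]),
                                    beta_dis=np.array([0.8, -3.0]),
                                    Sigma=np.diag([0.25, 4.0]),
                                    prior_log_odds=np.log(0.333))
        sub = conditional_subset(inputs, np.array([True, False]))
        y = 0.9
        logit = np.log(0.333) - 0.5 * (2 * 0.2 + 0.8) * 0.8 / 0.25 + y * 0.8 / 0.25
        assert cancer_probability(np.array([y]), sub) == pytest.approx(
            1 / (1 + np.exp(-logit)), abs=1e-12)

    def test_empty_mask_rejected(self):
        inputs = DiscriminantInputs(mu=np.zeros(2), beta_dis=np.ones(2),
                                    Sigma=np.eye(2))
        with pytest.raises(ValueError):
            conditional_subset(inputs, np.zeros(2, bool))


class TestRocAuc:
    @pytest.mark.parametrize("scores,labels,expected", [
        ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),
        ([0.9, 0.4, 0.8, 0.1], [1, 1, 0, 0], 0.75),
        ([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0], 0.5),
    ])
    def test_enumerated_examples(self, scores, labels, expected):
        assert roc_auc(scores, labels) == pytest.approx(expected)

    def test_pair_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            scores = rng.integers(0, 6, 30) / 5.0  # forces ties
            labels = rng.integers(0, 2, 30)
            if labels.sum() in (0, 30):
                continue
            cases, ctrls = scores[labels == 1], scores[labels == 0]
            brute = np.mean([(c > d) + 0.5 * (c == d)
                             for c in cases for d in ctrls])
            assert roc_auc(scores, labels) == pytest.approx(brute, abs=1e-12)

    def test_label_complement_sums_to_one(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels) + roc_auc(scores, 1 - labels) == \
            pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        base = roc_auc(scores, labels)
        for f in (np.exp, np.tanh, lambda s: 3 * s + 7):
            assert roc_auc(f(scores), labels) == pytest.approx(base, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(11)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


FAST = McmcSettings(chains=2, iterations=500, burn_in=200, thin=2, seed=17)


@pytest.fixture(scope="module")
def strong_effect_cv():
    # one near-separating miRNA (d ~ 3)
    rng = np.random.default_rng(12)
    params = realistic_parameters(3, rng, beta_dis=np.array([3.5, 0.0, 0.2]))
    params.sigma = np.array([0.4, 0.6, 0.6])
    cfg = SimulationConfig(K=3, I=90, seed=13, dis_missing_rate=0,
                           age_missing_rate=0, bw_missing_rate=0)
    ds, cov, _ = simulate_dataset(params, cfg)
    return ds, cov, crossvalidated_auc(ds, cov, [0, 1, 2], folds=10,
                                       settings=FAST, seed=14)


class TestCrossValidatedAuc:

    def test_folds_partition_subjects(self, strong_effect_cv):
        _, cov, cv = strong_effect_cv
        assert np.all(cv.fold_assignment >= 0)
        assert len(cv.fold_assignment) == np.isfinite(cov.disease).sum()
        assert set(cv.fold_assignment) == set(range(10))

    def test_large_effect_discriminates(self, strong_effect_cv):
        _, _, cv = strong_effect_cv
        assert np.median(cv.auc_draws) > 0.9

    def test_fold_assignment_deterministic(self, strong_effect_cv):
        ds, cov, cv = strong_effect_cv
        cv2 = crossvalidated_auc(ds, cov, [0], folds=10,
                                 settings=McmcSettings(chains=2, iterations=150,
                                                       burn_in=50, seed=17),
                                 seed=14)
        assert np.array_equal(cv.fold_assignment, cv2.fold_assignment)

    def test_probabilities_in_unit_interval(self, strong_effect_cv):
        _, _, cv = strong_effect_cv
        p = cv.prob_draws[np.isfinite(cv.prob_draws)]
        assert np.all((p > 0) & (p < 1))


class TestClassifierApi:
    def test_sklearn_contract(self):
        from sklearn.base import clone
        clf = CancerProbabilityClassifier(chains=2, iterations=100, burn_in=40)
        assert clone(clf).get_params()["iterations"] == 100

    def test_fit_predict_shapes(self):
        rng = np.random.default_rng(15)
        params = realistic_parameters(2, rng, beta_dis=np.array([2.0, 0.0]))
        cfg = SimulationConfig(K=2, I=60, seed=16, dis_missing_rate=0,
                               age_missing_rate=0, bw_missing_rate=0)
        ds, cov, _ = simulate_dataset(params, cfg)
        X = np.hstack([ds.replicate_matrix(1), ds.replicate_matrix(2)])
        y = cov.disease
        clf = CancerProbabilityClassifier(chains=2, iterations=250, burn_in=100,
                                          seed=3).fit(X, y)
        proba = clf.predict_proba(X)
        assert proba.shape == (60, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert set(clf.predict(X)) <= {0, 1}
        # in-sample ranking should beat chance comfortably with beta = 2
        assert roc_auc(proba[:, 1], y.astype(int)) > 0.8
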