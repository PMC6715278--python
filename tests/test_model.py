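import math

import numpy as np
import pytest

from mirnapanel import CovariateTable, ExpressionDataset
from mirnapanel.model import (McmcSettings, ModelParameters, PriorSpec,
                              fit, gelman_rubin, log_joint,
                              monitored_parameters, split_rhat)
from mirnapanel.simulate import SimulationConfig, make_fixture, realistic_parameters, simulate_dataset


def _random_params(K, I, rng, with_missing=(0, 0, 0)):
    A = rng.normal(size=(K, K))
    Q = A @ A.T + K * np.eye(K)
    n_dis, n_age, n_bw = with_missing
    return ModelParameters(
        mu=rng.normal(size=K), beta_dis=rng.normal(size=K),
        beta_age=rng.normal(size=K), beta_bw=rng.normal(size=K),
        sigma=np.abs(rng.normal(size=K)) + 0.1,
        zeta=np.abs(rng.normal(size=K)) + 0.1, Q=Q,
        eta=rng.normal(size=(I, K)),
        dis_imputed=rng.integers(0, 2, n_dis).astype(float) if n_dis else None,
        age_imputed=rng.normal(size=n_age) if n_age else None,
        bw_imputed=rng.normal(size=n_bw) if n_bw else None)


from oracles import oracle_log_joint as _oracle_log_joint


class TestLogJoint:
    def test_single_standard_normal_observation(self):
        ds = ExpressionDataset(y=np.array([0.0]), mirna_index=np.array([0]),
                               subject_index=np.array([0]), replicate=np.array([1]),
                               mirna_names=["m1", "m2"], subject_ids=["s"])
        cov = CovariateTable(disease=np.array([0.0]), age_std=np.array([0.0]),
                             bw_std=np.array([0.0]))
        params = ModelParameters(mu=np.zeros(2), beta_dis=np.zeros(2),
                                 beta_age=np.zeros(2), beta_bw=np.zeros(2),
                                 sigma=np.ones(2), zeta=np.ones(2), Q=np.eye(2),
                                 eta=np.zeros((1, 2)))
        comp = log_joint(params, ds, cov, components=True)
        assert comp["likelihood"] == pytest.approx(-0.5 * math.log(2 * math.pi),
                                                   abs=1e-12)

    def test_likelihood_doubles_with_duplicated_data(self, toy_k2):
        ds, cov = toy_k2
        rng = np.random.default_rng(3)
        params = _random_params(2, 3, rng, with_missing=(1, 1, 1))
        double = ExpressionDataset(
            y=np.tile(ds.y, 2),
            mirna_index=np.tile(ds.mirna_index, 2),
            subject_index=np.concatenate([ds.subject_index, ds.subject_index + 3]),
            replicate=np.tile(ds.replicate, 2),
            mirna_names=ds.mirna_names,
            subject_ids=ds.subject_ids + ["s4", "s5", "s6"])
        cov2 = CovariateTable(disease=np.tile(cov.disease, 2),
                              age_std=np.tile(cov.age_std, 2),
                              bw_std=np.tile(cov.bw_std, 2))
        params2 = _random_params(2, 6, rng, with_missing=(2, 2, 2))
        for attr in ("mu", "beta_dis", "beta_age", "beta_bw", "sigma", "zeta", "Q"):
            setattr(params2, attr, getattr(params, attr))
        params2.eta = np.vstack([params.eta, params.eta])
        params2.dis_imputed = np.tile(params.dis_imputed, 2)
        params2.age_imputed = np.tile(params.age_imputed, 2)
        params2.bw_imputed = np.tile(params.bw_imputed, 2)
        c1 = log_joint(params, ds, cov, components=True)
        c2 = log_joint(params2, double, cov2, components=True)
        assert c2["likelihood"] == pytest.approx(2 * c1["likelihood"], abs=1e-10)

    def test_matches_independent_oracle(self, toy_k2):
        ds, cov = toy_k2
        priors = PriorSpec()
        rng = np.random.default_rng(7)
        for _ in range(5):
            params = _random_params(2, 3, rng, with_missing=(1, 1, 1))
            assert log_joint(params, ds, cov, priors) == pytest.approx(
                _oracle_log_joint(params, ds, cov, priors), abs=1e-10)

    def test_subject_permutation_invariance(self, toy_k2):
        ds, cov = toy_k2
        rng = np.random.default_rng(11)
        params = _random_params(2, 3, rng, with_missing=(1, 1, 1))
        perm = np.array([2, 0, 1])
        inv = np.argsort(perm)
        ds_p = ExpressionDataset(y=ds.y, mirna_index=ds.mirna_index,
                                 subject_index=inv[ds.subject_index],
                                 replicate=ds.replicate,
                                 mirna_names=ds.mirna_names,
                                 subject_ids=[ds.subject_ids[j] for j in perm])
        cov_p = CovariateTable(disease=cov.disease[perm],
                               age_std=cov.age_std[perm], bw_std=cov.bw_std[perm])
        params_p = _random_params(2, 3, rng)
        for attr in ("mu", "beta_dis", "beta_age", "beta_bw", "sigma", "zeta", "Q",
                     "dis_imputed", "age_imputed", "bw_imputed"):
            setattr(params_p, attr, getattr(params, attr))
        params_p.eta = params.eta[perm]
        assert log_joint(params_p, ds_p, cov_p) == pytest.approx(
            log_joint(params, ds, cov), abs=1e-12)


class TestSplitRhat:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 4000))
        assert split_rhat(x) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        x = np.stack([rng.normal(0, 1, 1000), rng.normal(5, 1, 1000)])
        assert split_rhat(x) > 1.2

    def test_constant_chains_do_not_crash(self):
        assert split_rhat(np.zeros((2, 100))) == 1.0
        assert split_rhat(np.vstack([np.zeros(100), np.ones(100)])) == np.inf

    def test_matches_arviz_split_formula(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (3, 500)) + np.linspace(0, 0.5, 3)[:, None]
        ours = split_rhat(x)
        theirs = float(np.asarray(az.rhat(az.convert_to_dataset(x),
                                          method="split")["x"]))
        assert ours == pytest.approx(theirs, rel=1e-6)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            split_rhat(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            gelman_rubin({"x": np.zeros((1, 100, 1))})


class TestMonitoredParameters:
    def test_label_scheme(self):
        labels = monitored_parameters(2)
        assert "beta_dis[1]" in labels and "beta_dis[2]" in labels
        omega_entries = [l for l in labels if l.startswith("Omega[")]
        assert len(omega_entries) == 3  # symmetric 2x2 -> 3 unique entries

    def test_labels_round_trip_through_draws_file(self, tiny_fit, tmp_path):
        _, _, _, draws = tiny_fit
        draws.save(tmp_path)
        import pandas as pd
        stored = pd.read_csv(tmp_path / "draws.csv")
        assert "mu[1]" in set(stored["parameter"])
        assert set(stored["chain"]) == {0, 1}


class TestFit:
    def test_recovers_strong_effect(self, tiny_fit):
        _, _, truth, draws = tiny_fit
        bd = draws.stacked("beta_dis")
        lo, hi = np.percentile(bd[:, 0], [5, 95])
        assert lo <= truth.params.beta_dis[0] <= hi
        assert truth.params.beta_dis[0] == 1.5

    def test_convergence_report_attached(self, tiny_fit):
        _, _, _, draws = tiny_fit
        assert draws.converged
        assert (draws.rhat[np.isfinite(draws.rhat)] < 1.2).all()

    def test_deterministic_given_seed(self):
        ds, cov, _ = make_fixture("tiny-k3")
        settings = McmcSettings(chains=2, iterations=120, burn_in=40, thin=2,
                                seed=21)
        d1 = fit(ds, cov, settings=settings)
        d2 = fit(ds, cov, settings=settings)
        for name in ("mu", "beta_dis", "sigma", "zeta", "Q"):
            assert np.array_equal(d1.draws[name], d2.draws[name])

    def test_empty_data_returns_prior(self):
        ds = ExpressionDataset(y=np.empty(0), mirna_index=np.empty(0, int),
                               subject_index=np.empty(0, int),
                               replicate=np.empty(0, int),
                               mirna_names=["a", "b"], subject_ids=["s1", "s2"])
        cov = CovariateTable(disease=np.array([0.0, 1.0]), age_std=np.zeros(2),
                             bw_std=np.zeros(2))
        draws = fit(ds, cov, settings=McmcSettings(chains=2, iterations=3500,
                                                   burn_in=500, thin=1, seed=2))
        assert draws.stacked("sigma").mean() == pytest.approx(
            np.sqrt(2 / np.pi), rel=0.05)
        assert draws.stacked("mu").std() == pytest.approx(5.0, rel=0.05)

    def test_imputed_age_shrinks_and_shifts(self):
        # strong positive age effect; one subject with high y and masked age:
        # its imputed age should shift positive yet stay within the prior SD
        K, I = 2, 120
        rng = np.random.default_rng(31)
        params = realistic_parameters(K, rng,
                                      beta_dis=np.zeros(K))
        params.beta_age = np.array([1.5, 1.5])
        cfg = SimulationConfig(K=K, I=I, seed=32, dis_missing_rate=0,
                               age_missing_rate=0, bw_missing_rate=0)
        ds, cov, truth = simulate_dataset(params, cfg)
        target = int(np.argmax(truth.age))  # very positive true age
        cov.age_std[target] = np.nan
        draws = fit(ds, cov, settings=McmcSettings(chains=2, iterations=600,
                                                   burn_in=200, thin=1, seed=33))
        imp = draws.stacked("age_imputed")[:, 0]
        assert imp.std() <= 1.0
        assert imp.mean() > 0.3
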