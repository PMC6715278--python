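"""Bayesian multilevel model of a standardized miRNA panel.

Observation model
-----------------
Each standardized log level ``y_n`` (subject ``i``, miRNA ``k``, one of two
replicates) follows

    y_n ~ N(mu_k + b_dis_k * DIS_i + b_age_k * AGE_i + b_bw_k * BW_i
            + eta_{i,k},  sigma_k)

with subject random effects ``eta_i ~ MVN(0, Omega)`` coupling all K miRNAs.
``Omega`` carries a scaled inverse-Wishart prior: ``Omega =
diag(zeta) Q diag(zeta)`` with ``Q ~ InvWishart_{K+1}(I_K)`` and half-normal
scale factors ``zeta_k``, which decouples the per-miRNA scales from the
correlation structure.  Weakly-informative priors shrink the per-miRNA
effects toward zero: ``mu_k ~ N(0,5)``, all regression coefficients
``~ N(0,1)``, ``sigma_k`` half-normal(1).  Missing covariates are latent:
disease status Bernoulli(prevalence), age / weight standard normal.  Missing
wells simply contribute no likelihood term (ignorable missingness).

Sampler
-------
A parameter-expanded Gibbs sampler: writing ``eta_i = diag(zeta) xi_i`` with
``xi_i ~ MVN(0, Q)`` makes every conditional standard — Gaussian for the
regression block, the ``xi_i`` and the missing continuous covariates,
truncated-Gaussian for ``zeta_k``, conjugate inverse-Wishart for ``Q``,
Bernoulli for the missing disease status — except ``sigma_k``, which is
updated by univariate slice sampling on the log scale.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from sklearn.base import BaseEstimator

from .dataio import CovariateTable, ExpressionDataset

logger = logging.getLogger(__name__)

SCALE_FLOOR = 1e-6  # lower bound for sigma and zeta during sampling


@dataclass
class PriorSpec:
    """Fixed hyperparameters of the hierarchical prior."""

    sd_sigma: float = 1.0
    sd_mu: float = 5.0
    sd_beta: float = 1.0
    sd_zeta: float = 1.0
    prevalence: float = 0.33
    covariate_prior_sd: float = 1.0
    iw_df: int | None = None          # None -> K + 1
    iw_scale: np.ndarray | None = None  # None -> identity

    def resolve(self, K: int) -> "PriorSpec":
        df = self.iw_df if self.iw_df is not None else K + 1
        if df < K:
            raise ValueError(f"inverse-Wishart df {df} < K={K} is improper")
        scale = self.iw_scale if self.iw_scale is not None else np.eye(K)
        return replace(self, iw_df=df, iw_scale=np.asarray(scale, dtype=float))


@dataclass
class ModelParameters:
    """One point in parameter space (a single draw or a simulation truth)."""

    mu: np.ndarray
    beta_dis: np.ndarray
    beta_age: np.ndarray
    beta_bw: np.ndarray
    sigma: np.ndarray
    zeta: np.ndarray
    Q: np.ndarray
    eta: np.ndarray | None = None
    dis_imputed: np.ndarray | None = None
    age_imputed: np.ndarray | None = None
    bw_imputed: np.ndarray | None = None

    @property
    def K(self) -> int:
        return self.mu.size

    @property
    def omega(self) -> np.ndarray:
        """Between-subject SD per miRNA: |zeta_k| * sqrt(Q_kk)."""
        return np.abs(self.zeta) * np.sqrt(np.diag(self.Q))

    @property
    def Omega(self) -> np.ndarray:
        return np.diag(self.zeta) @ self.Q @ np.diag(self.zeta)


@dataclass
class McmcSettings:
    """Chain schedule.  The scaled-down default keeps desk-scale fits fast."""

    chains: int = 3
    iterations: int = 3000
    burn_in: int = 1000
    thin: int = 2
    seed: int = 0
    save_q: bool = True
    save_eta: bool = False

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def retained(self) -> int:
        return (self.iterations - self.burn_in + self.thin - 1) // self.thin


@dataclass
class PosteriorDraws:
    """Posterior draws indexed (chain, retained iteration, ...)."""

    draws: dict
    settings: McmcSettings
    rhat: pd.Series
    converged: bool
    eta_mean: np.ndarray | None = None
    mirna_names: list = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_retained(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws for one parameter with chains flattened: (chains*T, ...)."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def parameters_at(self, chain: int, t: int) -> ModelParameters:
        d = self.draws
        return ModelParameters(
            mu=d["mu"][chain, t], beta_dis=d["beta_dis"][chain, t],
            beta_age=d["beta_age"][chain, t], beta_bw=d["beta_bw"][chain, t],
            sigma=d["sigma"][chain, t], zeta=d["zeta"][chain, t],
            Q=d["Q"][chain, t],
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Tabular (chain, iteration, parameter, value) export of scalar draws."""
        records = []
        for name, arr in self.draws.items():
            C, T = arr.shape[:2]
            flat = arr.reshape(C, T, -1)
            labels = _labels_for(name, arr.shape[2:])
            for c in range(C):
                for j, lab in enumerate(labels):
                    records.append(pd.DataFrame({
                        "chain": c, "iteration": np.arange(T),
                        "parameter": lab, "value": flat[c, :, j]}))
        return pd.concat(records, ignore_index=True)

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.to_long_frame().to_csv(out_dir / "draws.csv", index=False)
        meta = {
            "settings": {k: v for k, v in self.settings.__dict__.items()},
            "rhat": {str(k): (None if not np.isfinite(v) else float(v))
                     for k, v in self.rhat.items()},
            "converged": bool(self.converged),
            "mirna_names": list(self.mirna_names),
        }
        (out_dir / "draws_meta.json").write_text(json.dumps(meta, indent=2))


def _labels_for(name: str, shape) -> list:
    if shape == ():
        return [name]
    if len(shape) == 1:
        return [f"{name}[{j + 1}]" for j in range(shape[0])]
    return [f"{name}[{idx}]" for idx in
            (",".join(str(j + 1) for j in t) for t in itertools.product(
                *(range(s) for s in shape)))]


def monitored_parameters(K: int, I: int = 0, include_eta: bool = False) -> list:
    """Stable label scheme for scalarized draws (1-based bracket indices)."""
    labels = []
    for name in ("mu", "beta_dis", "beta_age", "beta_bw", "sigma", "zeta", "omega"):
        labels += [f"{name}[{k + 1}]" for k in range(K)]
    labels += [f"Omega[{a + 1},{b + 1}]" for a in range(K) for b in range(a, K)]
    if include_eta:
        labels += [f"eta[{i + 1},{k + 1}]" for i in range(I) for k in range(K)]
    return labels


# ---------------------------------------------------------------------------
# Joint density


def _halfnorm_logpdf(x, sd):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        return -np.inf
    return np.sum(stats.halfnorm.logpdf(x, scale=sd))


def filled_covariates(cov: CovariateTable, params: ModelParameters):
    """Covariate vectors with missing slots filled from the imputed values."""
    dis = cov.disease.copy()
    age = cov.age_std.copy()
    bw = cov.bw_std.copy()
    m_dis, m_age, m_bw = cov.missing_masks()
    for mask, arr, vals in ((m_dis, dis, params.dis_imputed),
                            (m_age, age, params.age_imputed),
                            (m_bw, bw, params.bw_imputed)):
        if mask.any():
            if vals is None:
                raise ValueError("missing covariates present but no imputed values")
            arr[mask] = vals
    return dis, age, bw


def log_joint(params: ModelParameters, dataset: ExpressionDataset,
              cov: CovariateTable, priors: PriorSpec | None = None,
              components: bool = False):
    """Unnormalized log joint density of data and parameters.

    With ``components=True`` returns a dict with the ``likelihood``,
    ``eta_prior``, ``parameter_priors`` and ``covariate_priors`` terms, plus
    their ``total``.
    """
    priors = (priors or PriorSpec()).resolve(params.K)
    if params.eta is None:
        raise ValueError("log_joint requires eta in ModelParameters")
    dis, age, bw = filled_covariates(cov, params)

    k = dataset.mirna_index
    i = dataset.subject_index
    pred = (params.mu[k] + params.beta_dis[k] * dis[i]
            + params.beta_age[k] * age[i] + params.beta_bw[k] * bw[i]
            + params.eta[i, k])
    lik = float(np.sum(stats.norm.logpdf(dataset.y, loc=pred,
                                         scale=params.sigma[k])))

    Omega = params.Omega
    try:
        eta_prior = float(np.sum(stats.multivariate_normal.logpdf(
            params.eta, mean=np.zeros(params.K), cov=Omega)))
    except np.linalg.LinAlgError as exc:
        raise ValueError("Omega is not positive definite") from exc

    par_prior = (
        _halfnorm_logpdf(params.sigma, priors.sd_sigma)
        + _halfnorm_logpdf(params.zeta, priors.sd_zeta)
        + float(np.sum(stats.norm.logpdf(params.mu, scale=priors.sd_mu)))
        + float(np.sum(stats.norm.logpdf(params.beta_dis, scale=priors.sd_beta)))
        + float(np.sum(stats.norm.logpdf(params.beta_age, scale=priors.sd_beta)))
        + float(np.sum(stats.norm.logpdf(params.beta_bw, scale=priors.sd_beta)))
        + float(stats.invwishart.logpdf(params.Q, df=priors.iw_df,
                                        scale=priors.iw_scale))
    )

    cov_prior = 0.0
    m_dis, m_age, m_bw = cov.missing_masks()
    if m_dis.any():
        d = np.asarray(params.dis_imputed, dtype=float)
        cov_prior += float(np.sum(stats.bernoulli.logpmf(d.astype(int),
                                                         priors.prevalence)))
    for mask, vals in ((m_age, params.age_imputed), (m_bw, params.bw_imputed)):
        if mask.any():
            cov_prior += float(np.sum(stats.norm.logpdf(
                np.asarray(vals, dtype=float), scale=priors.covariate_prior_sd)))

    total = lik + eta_prior + par_prior + cov_prior
    if components:
        return {"likelihood": lik, "eta_prior": eta_prior,
                "parameter_priors": par_prior, "covariate_priors": cov_prior,
                "total": total}
    return total


# ---------------------------------------------------------------------------
# Gibbs sampler


def _slice_sample_log_scale(logf, x0: float, rng, w: float = 0.5,
                            max_steps: int = 50,
                            lo: float = np.log(SCALE_FLOOR)) -> float:
    """One slice-sampling update (stepping out + shrinkage) on a log scale."""
    y = logf(x0) - rng.exponential()
    left = x0 - w * rng.uniform()
    right = left + w
    steps = max_steps
    while left > lo and logf(left) > y and steps > 0:
        left -= w
        steps -= 1
    left = max(left, lo)
    steps = max_steps
    while logf(right) > y and steps > 0:
        right += w
        steps -= 1
    while True:
        x1 = left + (right - left) * rng.uniform()
        if logf(x1) > y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


class _GibbsState:
    """Mutable chain state; gamma stacks (mu, beta_dis, beta_age, beta_bw)."""

    def __init__(self, K, I, rng, priors, m_dis, m_age, m_bw, dis, age, bw):
        self.gamma = np.zeros((K, 4))
        self.sigma = np.ones(K)
        self.zeta = np.ones(K)
        self.Q = np.eye(K)
        self.xi = np.zeros((I, K))
        self.dis = dis.copy()
        self.age = age.copy()
        self.bw = bw.copy()
        self.dis[m_dis] = (rng.uniform(size=m_dis.sum()) < priors.prevalence)
        self.age[m_age] = 0.0
        self.bw[m_bw] = 0.0

    def design(self):
        return np.column_stack([np.ones_like(self.dis), self.dis, self.age, self.bw])


def _run_chain(dataset, cov, priors, settings, rng, collect):
    K, I = dataset.K, dataset.I
    M, S, SS = dataset.cell_stats()
    m_dis, m_age, m_bw = cov.missing_masks()
    st = _GibbsState(K, I, rng, priors, m_dis, m_age, m_bw,
                     np.nan_to_num(cov.disease), np.nan_to_num(cov.age_std),
                     np.nan_to_num(cov.bw_std))
    prior_prec_gamma = np.diag([1.0 / priors.sd_mu ** 2] + [1.0 / priors.sd_beta ** 2] * 3)
    n_k = M.sum(axis=0)
    iw_df_post = priors.iw_df + I
    eta_sum = np.zeros((I, K))
    n_kept = 0

    for it in range(settings.iterations):
        X = st.design()                       # (I, 4)
        inv_var = 1.0 / st.sigma ** 2         # (K,)

        # --- regression block gamma_k | rest: Gaussian, batched over k
        Wk = M * inv_var                      # (I, K)
        P = np.einsum("ip,ik,iq->kpq", X, Wk, X) + prior_prec_gamma
        resid = (S - M * (st.zeta * st.xi)) * inv_var
        b = np.einsum("ip,ik->kp", X, resid)
        L = np.linalg.cholesky(P)
        mean = np.linalg.solve(P, b[:, :, None])[:, :, 0]
        z = rng.standard_normal((K, 4))
        st.gamma = mean + np.linalg.solve(np.transpose(L, (0, 2, 1)), z[:, :, None])[:, :, 0]

        a_mean = X @ st.gamma.T               # (I, K) fixed-effect predictor

        # --- subject effects xi_i | rest: Gaussian; factor once per unique
        #     missingness pattern (all subjects share one when data complete)
        Qc = cho_factor(st.Q, lower=True)
        Qinv = cho_solve(Qc, np.eye(K))
        d = M * (st.zeta ** 2 * inv_var)      # (I, K) likelihood precisions
        bxi = (st.zeta * inv_var) * (S - M * a_mean)
        pattern, inverse = np.unique(d, axis=0, return_inverse=True)
        z = rng.standard_normal((I, K))
        for g in range(pattern.shape[0]):
            rows = np.where(inverse == g)[0]
            Prec = Qinv + np.diag(pattern[g])
            Lg = np.linalg.cholesky(Prec)
            mean_g = cho_solve((Lg, True), bxi[rows].T).T
            st.xi[rows] = mean_g + solve_triangular(Lg.T, z[rows].T, lower=False).T

        # --- scale factors zeta_k | rest: truncated normal on (0, inf)
        e = S - M * a_mean
        p = (M * st.xi ** 2).T @ np.ones(I) * inv_var + 1.0 / priors.sd_zeta ** 2
        lin = np.einsum("ik,ik->k", st.xi, e) * inv_var
        mu_z, sd_z = lin / p, 1.0 / np.sqrt(p)
        st.zeta = np.maximum(stats.truncnorm.rvs(
            -mu_z / sd_z, np.inf, loc=mu_z, scale=sd_z, random_state=rng), SCALE_FLOOR)

        # --- unscaled covariance Q | xi: conjugate inverse-Wishart
        st.Q = stats.invwishart.rvs(df=iw_df_post,
                                    scale=priors.iw_scale + st.xi.T @ st.xi,
                                    random_state=rng)
        if K == 1:
            st.Q = np.atleast_2d(st.Q)

        # --- residual scales sigma_k | rest: slice sampling on log sigma
        theta = a_mean + st.zeta * st.xi
        rss = np.einsum("ik->k", SS - 2.0 * theta * S + M * theta ** 2)
        rss = np.maximum(rss, 0.0)
        for k in range(K):
            nk, rk = n_k[k], rss[k]
            sd2 = priors.sd_sigma ** 2

            def logf(t, nk=nk, rk=rk, sd2=sd2):
                # density of log(sigma): likelihood * half-normal prior * Jacobian
                return -(nk - 1.0) * t - 0.5 * rk * np.exp(-2.0 * t) \
                    - 0.5 * np.exp(2.0 * t) / sd2

            st.sigma[k] = np.exp(_slice_sample_log_scale(logf, np.log(st.sigma[k]), rng))
        inv_var = 1.0 / st.sigma ** 2

        # --- missing covariates
        eta_now = st.zeta * st.xi
        if m_age.any() or m_bw.any():
            theta = st.design() @ st.gamma.T + eta_now
        for mask, col, bcol in ((m_age, st.age, st.gamma[:, 2]),
                                (m_bw, st.bw, st.gamma[:, 3])):
            if not mask.any():
                continue
            rows = np.where(mask)[0]
            theta_wo = theta[rows] - np.outer(col[rows], bcol)
            prec = 1.0 / priors.covariate_prior_sd ** 2 + (M[rows] * bcol ** 2) @ inv_var
            lin = ((S[rows] - M[rows] * theta_wo) * bcol) @ inv_var
            col[rows] = lin / prec + rng.standard_normal(rows.size) / np.sqrt(prec)
            theta[rows] = theta_wo + np.outer(col[rows], bcol)
        if m_dis.any():
            rows = np.where(m_dis)[0]
            bd = st.gamma[:, 1]
            theta = st.design() @ st.gamma.T + eta_now
            theta0 = theta[rows] - np.outer(st.dis[rows], bd)
            delta = ((S[rows] - M[rows] * theta0 - 0.5 * M[rows] * bd) * bd) @ inv_var
            logit = np.log(priors.prevalence / (1 - priors.prevalence)) + delta
            st.dis[rows] = (rng.uniform(size=rows.size)
                            < 1.0 / (1.0 + np.exp(-logit))).astype(float)

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            eta_sum += st.zeta * st.xi
            n_kept += 1
            collect(st, m_dis, m_age, m_bw)

    return eta_sum / max(n_kept, 1)


def fit(dataset: ExpressionDataset, cov: CovariateTable,
        priors: PriorSpec | None = None,
        settings: McmcSettings | None = None) -> PosteriorDraws:
    """Draw from the posterior by parameter-expanded Gibbs sampling.

    Returns :class:`PosteriorDraws` with a split-Rhat convergence report; a
    fit whose worst Rhat is at or above 1.2 is flagged ``converged=False``
    (never silently).
    """
    settings = settings or McmcSettings()
    priors = (priors or PriorSpec()).resolve(dataset.K)
    K, I = dataset.K, dataset.I
    m_dis, m_age, m_bw = cov.missing_masks()
    C, T = settings.chains, settings.retained

    out = {name: np.empty((C, T, K)) for name in
           ("mu", "beta_dis", "beta_age", "beta_bw", "sigma", "zeta")}
    if settings.save_q:
        out["Q"] = np.empty((C, T, K, K))
    if settings.save_eta:
        out["eta"] = np.empty((C, T, I, K))
    for name, mask in (("dis_imputed", m_dis), ("age_imputed", m_age),
                       ("bw_imputed", m_bw)):
        if mask.any():
            out[name] = np.empty((C, T, int(mask.sum())))
    omega_draws = np.empty((C, T, K))

    seeds = np.random.SeedSequence(settings.seed).spawn(C)
    eta_mean = np.zeros((I, K))
    for c in range(C):
        rng = np.random.default_rng(seeds[c])
        slot = {"t": 0}

        def collect(st, m_dis, m_age, m_bw, c=c, slot=slot):
            t = slot["t"]
            out["mu"][c, t] = st.gamma[:, 0]
            out["beta_dis"][c, t] = st.gamma[:, 1]
            out["beta_age"][c, t] = st.gamma[:, 2]
            out["beta_bw"][c, t] = st.gamma[:, 3]
            out["sigma"][c, t] = st.sigma
            out["zeta"][c, t] = st.zeta
            omega_draws[c, t] = st.zeta * np.sqrt(np.diag(st.Q))
            if settings.save_q:
                out["Q"][c, t] = st.Q
            if settings.save_eta:
                out["eta"][c, t] = st.zeta * st.xi
            if m_dis.any():
                out["dis_imputed"][c, t] = st.dis[m_dis]
            if m_age.any():
                out["age_imputed"][c, t] = st.age[m_age]
            if m_bw.any():
                out["bw_imputed"][c, t] = st.bw[m_bw]
            slot["t"] += 1

        logger.info("chain %d/%d: %d iterations (%d burn-in)", c + 1, C,
                    settings.iterations, settings.burn_in)
        eta_mean += _run_chain(dataset, cov, priors, settings, rng, collect)
    eta_mean /= C

    # Convergence is monitored on the *identified* parameters: the expansion
    # factors zeta and Q trade off along an unidentified direction (only
    # Omega = diag(zeta) Q diag(zeta) is interpretable), so their individual
    # chains mix slowly by construction and are not part of the report.
    rhat = {}
    for name in ("mu", "beta_dis", "beta_age", "beta_bw", "sigma"):
        for k in range(K):
            rhat[f"{name}[{k + 1}]"] = split_rhat(out[name][:, :, k])
    for k in range(K):
        rhat[f"omega[{k + 1}]"] = split_rhat(omega_draws[:, :, k])
    if settings.save_q:
        zq = out["zeta"]
        Om = out["Q"] * zq[..., None, :] * zq[..., :, None]
        for a in range(K):
            for b_ in range(a + 1, K):
                rhat[f"Omega[{a + 1},{b_ + 1}]"] = split_rhat(Om[:, :, a, b_])
    rhat = pd.Series(rhat, name="rhat")
    finite = rhat[np.isfinite(rhat)]
    converged = bool((finite < 1.2).all()) and C >= 2
    if not converged:
        logger.warning("fit flagged non-converged: max Rhat %.3f",
                       float(finite.max()) if len(finite) else float("nan"))
    out["omega"] = omega_draws
    return PosteriorDraws(draws=out, settings=settings, rhat=rhat,
                          converged=converged, eta_mean=eta_mean,
                          mirna_names=list(dataset.mirna_names))


# ---------------------------------------------------------------------------
# Convergence diagnostics


def split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one scalar parameter.

    ``x`` has shape (chains, iterations); each chain is split in half, so m =
    2*chains sequences enter the classic between/within variance ratio.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need draws of shape (chains >= 2, iterations)")
    n = x.shape[1] // 2
    if n < 5:
        raise ValueError("need at least 10 iterations per chain")
    halves = np.concatenate([x[:, :n], x[:, n:2 * n]], axis=0)
    if np.allclose(halves, halves[0, 0]):
        return 1.0  # constant everywhere: trivially converged
    means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    B_over_n = means.var(ddof=1)
    if W == 0:
        return np.inf
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def gelman_rubin(draws: PosteriorDraws | dict) -> pd.Series:
    """Per-scalar split-Rhat table for a set of posterior draws."""
    if isinstance(draws, PosteriorDraws):
        if draws.n_chains < 2:
            raise ValueError("Gelman-Rubin requires at least 2 chains")
        return draws.rhat
    out = {}
    for name, arr in draws.items():
        arr = np.asarray(arr, dtype=float)
        if arr.shape[0] < 2:
            raise ValueError("Gelman-Rubin requires at least 2 chains")
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
        for lab, j in zip(_labels_for(name, arr.shape[2:]), range(flat.shape[2])):
            out[lab] = split_rhat(flat[:, :, j])
    return pd.Series(out, name="rhat")


# ---------------------------------------------------------------------------
# Estimator facade


class BayesianHierarchicalModel(BaseEstimator):
    """Sklearn-style front end for the multilevel panel model.

    Parameters mirror :class:`PriorSpec` and :class:`McmcSettings`; after
    ``fit`` the posterior is available as ``draws_`` plus convenience
    attributes (``rhat_``, ``converged_``, ``eta_mean_``).
    """

    def __init__(self, chains: int = 3, iterations: int = 3000,
                 burn_in: int = 1000, thin: int = 2, seed: int = 0,
                 prevalence: float = 0.33, sd_mu: float = 5.0,
                 sd_beta: float = 1.0, sd_sigma: float = 1.0,
                 sd_zeta: float = 1.0, save_eta: bool = False):
        self.chains = chains
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.prevalence = prevalence
        self.sd_mu = sd_mu
        self.sd_beta = sd_beta
        self.sd_sigma = sd_sigma
        self.sd_zeta = sd_zeta
        self.save_eta = save_eta

    def _priors(self) -> PriorSpec:
        return PriorSpec(sd_sigma=self.sd_sigma, sd_mu=self.sd_mu,
                         sd_beta=self.sd_beta, sd_zeta=self.sd_zeta,
                         prevalence=self.prevalence)

    def _settings(self) -> McmcSettings:
        return McmcSettings(chains=self.chains, iterations=self.iterations,
                            burn_in=self.burn_in, thin=self.thin,
                            seed=self.seed, save_eta=self.save_eta)

    def fit(self, dataset: ExpressionDataset, cov: CovariateTable
            ) -> "BayesianHierarchicalModel":
        self.draws_ = fit(dataset, cov, self._priors(), self._settings())
        self.rhat_ = self.draws_.rhat
        self.converged_ = self.draws_.converged
        self.eta_mean_ = self.draws_.eta_mean
        self.mirna_names_ = list(dataset.mirna_names)
        return self
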