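"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately re-derive each quantity from first principles (explicit
loops, library density calls, pair enumeration) and never call the package
code paths they are used to check.
"""

import math

import numpy as np
from scipy import stats
from scipy.stats import multivariate_normal


def bayes_discriminant_oracle(y, mu, beta, Sigma, prior_odds):
    """Two-class Gaussian posterior: normalized density ratio with prior odds."""
    f1 = multivariate_normal.pdf(y, mean=mu + beta, cov=Sigma)
    f0 = multivariate_normal.pdf(y, mean=mu, cov=Sigma)
    return prior_odds * f1 / (prior_odds * f1 + f0)


def bh_stepup_oracle(p):
    """Textbook Benjamini-Hochberg step-up adjustment (sorted-loop form)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * n / rank)
        adjusted[idx] = running_min
    return adjusted


def auc_pair_enumeration_oracle(scores, labels):
    """AUC by enumerating all (case, control) pairs, ties at 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    cases = scores[labels == 1]
    ctrls = scores[labels == 0]
    wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in ctrls)
    return wins / (cases.size * ctrls.size)


def oracle_log_joint(params, dataset, cov, priors):
    """Term-by-term log joint density with explicit per-item loops."""
    pri = priors.resolve(params.K)
    dis = cov.disease.copy()
    age = cov.age_std.copy()
    bw = cov.bw_std.copy()
    if params.dis_imputed is not None:
        dis[~np.isfinite(dis)] = params.dis_imputed
    if params.age_imputed is not None:
        age[~np.isfinite(age)] = params.age_imputed
    if params.bw_imputed is not None:
        bw[~np.isfinite(bw)] = params.bw_imputed
    total = 0.0
    for n in range(dataset.N):
        k, i = dataset.mirna_index[n], dataset.subject_index[n]
        mean = (params.mu[k] + params.beta_dis[k] * dis[i]
                + params.beta_age[k] * age[i] + params.beta_bw[k] * bw[i]
                + params.eta[i, k])
        total += stats.norm.logpdf(dataset.y[n], mean, params.sigma[k])
    Omega = np.diag(params.zeta) @ params.Q @ np.diag(params.zeta)
    for i in range(dataset.I):
        total += stats.multivariate_normal.logpdf(params.eta[i],
                                                  np.zeros(params.K), Omega)
    for k in range(params.K):
        total += math.log(2) + stats.norm.logpdf(params.sigma[k], 0, pri.sd_sigma)
        total += math.log(2) + stats.norm.logpdf(params.zeta[k], 0, pri.sd_zeta)
        total += stats.norm.logpdf(params.mu[k], 0, pri.sd_mu)
        for b in (params.beta_dis, params.beta_age, params.beta_bw):
            total += stats.norm.logpdf(b[k], 0, pri.sd_beta)
    total += stats.invwishart.logpdf(params.Q, df=pri.iw_df, scale=pri.iw_scale)
    if params.dis_imputed is not None:
        for d in np.atleast_1d(params.dis_imputed):
            total += math.log(pri.prevalence if d == 1 else 1 - pri.prevalence)
    for vals in (params.age_imputed, params.bw_imputed):
        if vals is not None:
            for v in np.atleast_1d(vals):
                total += stats.norm.logpdf(v, 0, pri.covariate_prior_sd)
    return total
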