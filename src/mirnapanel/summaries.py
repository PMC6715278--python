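"""Derived posterior quantities: Omega, omega, rho, effect sizes, fold changes.

All derived quantities are computed per posterior draw and only then
summarized (percentiles of the derived draws), so the full inferential
uncertainty propagates into every reported number.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import PosteriorDraws

PERCENTILES = (5, 25, 50, 75, 95)


def covariance_from_factors(zeta, Q):
    """Between-subject covariance Omega = diag(zeta) Q diag(zeta)."""
    zeta = np.asarray(zeta, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (zeta.size, zeta.size):
        raise ValueError("zeta/Q dimension mismatch")
    np.linalg.cholesky(Q)  # raises if Q is not SPD
    return zeta[:, None] * Q * zeta[None, :]


def omega_rho(zeta, Q):
    """Per-miRNA between-subject SD and the between-miRNA correlation matrix.

    ``omega_k = |zeta_k| sqrt(Q_kk)``;  ``rho`` is the correlation matrix of
    ``Omega``, so ``diag(omega) rho diag(omega)`` reconstructs ``Omega``.
    """
    zeta = np.asarray(zeta, dtype=float)
    Q = np.asarray(Q, dtype=float)
    omega = np.abs(zeta) * np.sqrt(np.diag(Q))
    if np.any((omega == 0) & (np.abs(Q - np.diag(np.diag(Q))).sum(axis=1) > 0)):
        raise ValueError("zero omega with nonzero off-diagonal covariance")
    denom = np.outer(omega, omega)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (zeta[:, None] * Q * zeta[None, :]) / denom
    np.fill_diagonal(rho, 1.0)
    return omega, rho


def effect_size(beta_dis, omega, sigma):
    """Disease effect on the scale of total variability: d = beta / sqrt(omega^2 + sigma^2).

    Scale-free: invariant under a common rescaling of (beta, omega, sigma).
    """
    beta_dis = np.asarray(beta_dis, dtype=float)
    omega = np.asarray(omega, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    denom2 = omega ** 2 + sigma ** 2
    if np.any(denom2 == 0):
        raise ValueError("omega and sigma both zero: effect size undefined")
    return beta_dis / np.sqrt(denom2)


def fold_change(beta_dis, global_sd: float):
    """Multiplicative group difference exp(SD * beta) on the natural scale.

    ``global_sd`` is the pre-standardization SD of the log levels, so the
    exponent undoes the global standardization; values > 1 mean the miRNA is
    higher in patients.
    """
    return np.exp(float(global_sd) * np.asarray(beta_dis, dtype=float))


def summarize_draws(draws, reference: float = 0.0, alpha: float = 0.10) -> dict:
    """Percentile record plus probability-of-direction for one quantity.

    ``credible`` is True when the equal-tailed (1-alpha) interval (default
    5th-95th percentiles) lies entirely above or below ``reference``.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 20:
        raise ValueError("need at least 20 draws to summarize")
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    pct = np.percentile(draws, PERCENTILES)  # linear (type-7) interpolation
    p_lo, p_hi = np.percentile(draws, [lo, hi])
    rec = {f"p{p}": float(v) for p, v in zip(PERCENTILES, pct)}
    rec["prob_direction"] = float(np.mean(draws > reference))
    rec["credible"] = bool(p_lo > reference or p_hi < reference)
    return rec


def derived_summary_table(draws: PosteriorDraws, global_sd: float = 1.0
                          ) -> pd.DataFrame:
    """Plot-ready per-miRNA summary of fold change, effect size, omega, sigma.

    One row per (miRNA, quantity) with the 5/25/50/75/95 percentiles, the
    posterior probability of direction and the credibility flag (reference 1
    for fold changes, 0 for effect sizes).
    """
    beta = draws.stacked("beta_dis")          # (draws, K)
    sigma = draws.stacked("sigma")
    omega = draws.stacked("omega")
    d = effect_size(beta, omega, sigma)
    fc = fold_change(beta, global_sd)
    names = draws.mirna_names or [f"mirna_{k + 1}" for k in range(beta.shape[1])]

    rows = []
    for k, name in enumerate(names):
        for qty, arr, ref in (("fold_change", fc[:, k], 1.0),
                              ("d", d[:, k], 0.0),
                              ("omega", omega[:, k], None),
                              ("sigma", sigma[:, k], None)):
            rec = summarize_draws(arr, reference=ref if ref is not None else 0.0)
            if ref is None:
                rec["prob_direction"] = np.nan
                rec["credible"] = False
            rows.append({"mirna": name, "quantity": qty, **rec})
    return pd.DataFrame(rows)


def rho_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior median correlation for every miRNA pair (requires Q draws)."""
    if "Q" not in draws.draws:
        raise ValueError("Q draws were not saved; refit with save_q=True")
    zeta = draws.stacked("zeta")
    Q = draws.stacked("Q")
    T, K = zeta.shape
    rhos = np.empty((T, K, K))
    for t in range(T):
        _, rhos[t] = omega_rho(zeta[t], Q[t])
    rho_med = np.median(rhos, axis=0)
    names = draws.mirna_names or [f"mirna_{k + 1}" for k in range(K)]
    return pd.DataFrame(rho_med, index=names, columns=names)
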