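"""Closed-form Gaussian discriminant for cancer probability and CV'd AUC.

Under the fitted model a subject's single-replicate profile on a miRNA subset
j is Gaussian with covariance ``Sigma = Omega + diag(sigma^2)`` and mean
``mu_j`` (control) or ``mu_j + beta_dis_j`` (case).  The posterior probability
of cancer is the two-class Bayes rule with prior odds ``exp(prior_log_odds)``:

    logit(p) = prior_log_odds - 1/2 (2 mu + beta)' Sigma^-1 beta
               + y' Sigma^-1 beta

The out-of-sample discrimination of a subset is summarized by 10-fold
cross-validation: the hierarchical model is refit without the held-out fold,
each retained posterior draw scores the held-out subjects through the rule
above, and the pooled per-draw probabilities give a posterior distribution of
the Mann-Whitney AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import KFold, StratifiedKFold

from .dataio import CovariateTable, ExpressionDataset
from .model import McmcSettings, PosteriorDraws, PriorSpec, fit as fit_model

logger = logging.getLogger(__name__)

#: Printed prior-odds constant (close to the 59/178 ~ 0.331 case fraction).
DEFAULT_PRIOR_ODDS = 0.333


@dataclass
class DiscriminantInputs:
    """Per-draw parameters of the two-class Gaussian rule on a miRNA subset."""

    mu: np.ndarray
    beta_dis: np.ndarray
    Sigma: np.ndarray
    prior_log_odds: float = np.log(DEFAULT_PRIOR_ODDS)

    def __post_init__(self) -> None:
        k = self.mu.size
        if self.beta_dis.size != k or self.Sigma.shape != (k, k):
            raise ValueError("mu/beta/Sigma dimension mismatch")
        np.linalg.cholesky(self.Sigma)  # SPD check


def sigma_total(Omega, sigma):
    """Total single-replicate covariance: between-subject plus assay noise."""
    Omega = np.asarray(Omega, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if Omega.shape != (sigma.size, sigma.size):
        raise ValueError("Omega/sigma dimension mismatch")
    return Omega + np.diag(sigma ** 2)


def cancer_probability(y_obs, inputs: DiscriminantInputs) -> float:
    """Posterior probability of cancer for one single-replicate profile."""
    y = np.asarray(y_obs, dtype=float)
    if y.size != inputs.mu.size:
        raise ValueError("observation length does not match subset")
    w = np.linalg.solve(inputs.Sigma, inputs.beta_dis)
    logit = (inputs.prior_log_odds
             - 0.5 * (2.0 * inputs.mu + inputs.beta_dis) @ w + y @ w)
    return float(1.0 / (1.0 + np.exp(-logit)))


def conditional_subset(inputs: DiscriminantInputs, observed_mask) -> DiscriminantInputs:
    """Marginalize the Gaussian rule to the observed dimensions only."""
    mask = np.asarray(observed_mask, dtype=bool)
    if mask.size != inputs.mu.size:
        raise ValueError("mask length does not match subset")
    if not mask.any():
        raise ValueError("no observed dimensions")
    return replace(inputs, mu=inputs.mu[mask], beta_dis=inputs.beta_dis[mask],
                   Sigma=inputs.Sigma[np.ix_(mask, mask)])


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(case score > control score), ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)  # midranks handle ties at 1/2
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class CvAucResult:
    """Pooled cross-validated probabilities and the per-draw AUC posterior."""

    fold_assignment: np.ndarray
    prob_mean: np.ndarray            # per evaluable subject, posterior mean p
    prob_draws: np.ndarray           # (n_draws, n_subjects)
    labels: np.ndarray
    auc_draws: np.ndarray
    subject_ids: list

    def auc_summary(self) -> dict:
        p5, p50, p95 = np.percentile(self.auc_draws, [5, 50, 95])
        return {"auc_median": float(p50), "auc_p5": float(p5),
                "auc_p95": float(p95)}

    def probability_table(self) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": self.subject_ids,
                             "fold": self.fold_assignment,
                             "disease": self.labels,
                             "p_cancer": self.prob_mean})


def _subset_indices(dataset: ExpressionDataset, subset) -> np.ndarray:
    if all(isinstance(s, (int, np.integer)) for s in subset):
        idx = np.asarray(subset, dtype=int)
    else:
        lookup = {m: j for j, m in enumerate(dataset.mirna_names)}
        missing = [s for s in subset if s not in lookup]
        if missing:
            raise KeyError(f"miRNAs not in dataset: {missing}")
        idx = np.asarray([lookup[s] for s in subset], dtype=int)
    if len(set(idx.tolist())) != idx.size or idx.size == 0:
        raise ValueError("subset must be non-empty without duplicates")
    return idx


def _restrict(dataset: ExpressionDataset, keep_subjects) -> tuple:
    """Dataset/index mapping restricted to a subject subset (for CV refits)."""
    keep = np.asarray(keep_subjects, dtype=int)
    remap = -np.ones(dataset.I, dtype=int)
    remap[keep] = np.arange(keep.size)
    sel = np.isin(dataset.subject_index, keep)
    return ExpressionDataset(
        y=dataset.y[sel], mirna_index=dataset.mirna_index[sel],
        subject_index=remap[dataset.subject_index[sel]],
        replicate=dataset.replicate[sel], mirna_names=list(dataset.mirna_names),
        subject_ids=[dataset.subject_ids[j] for j in keep],
        scaling=dataset.scaling, n_replicates=dataset.n_replicates,
    )


def score_subjects(draws: PosteriorDraws, y_matrix: np.ndarray,
                   subset_idx: np.ndarray,
                   prior_log_odds: float = np.log(DEFAULT_PRIOR_ODDS)
                   ) -> np.ndarray:
    """Per-draw cancer probabilities for rows of ``y_matrix`` (NaN = missing).

    Missing miRNAs within the subset are marginalized out of the Gaussian.
    Returns an array of shape (n_draws, n_subjects).
    """
    sub = y_matrix[:, subset_idx]
    n_subj = sub.shape[0]
    mu_d = draws.stacked("mu")[:, subset_idx]
    beta_d = draws.stacked("beta_dis")[:, subset_idx]
    sigma_d = draws.stacked("sigma")[:, subset_idx]
    zeta_d = draws.stacked("zeta")
    Q_d = draws.stacked("Q")
    T = mu_d.shape[0]

    probs = np.full((T, n_subj), np.nan)
    patterns = {}
    for s in range(n_subj):
        key = tuple(np.isfinite(sub[s]))
        patterns.setdefault(key, []).append(s)

    for t in range(T):
        Omega = (zeta_d[t][:, None] * Q_d[t] * zeta_d[t][None, :])
        Sigma = Omega[np.ix_(subset_idx, subset_idx)] + np.diag(sigma_d[t] ** 2)
        base = DiscriminantInputs(mu=mu_d[t], beta_dis=beta_d[t], Sigma=Sigma,
                                  prior_log_odds=prior_log_odds)
        for key, rows in patterns.items():
            mask = np.asarray(key)
            if not mask.any():
                continue
            inp = conditional_subset(base, mask) if not mask.all() else base
            w = np.linalg.solve(inp.Sigma, inp.beta_dis)
            const = (inp.prior_log_odds
                     - 0.5 * (2.0 * inp.mu + inp.beta_dis) @ w)
            logit = const + sub[np.ix_(rows, np.where(mask)[0])] @ w
            probs[t, rows] = 1.0 / (1.0 + np.exp(-logit))
    return probs


def crossvalidated_auc(dataset: ExpressionDataset, cov: CovariateTable,
                       subset, folds: int = 10, settings: McmcSettings | None = None,
                       priors: PriorSpec | None = None, seed: int = 0,
                       replicate: int | str = 1, stratified: bool = True,
                       prior_log_odds: float = np.log(DEFAULT_PRIOR_ODDS)
                       ) -> CvAucResult:
    """K-fold cross-validated AUC of a miRNA subset with posterior uncertainty.

    Each fold refits the hierarchical model on the remaining subjects, then
    scores the held-out subjects' single-replicate profiles per posterior
    draw.  Subjects with unknown disease status are never scored (AUC needs a
    label); all subjects participate in every training fit through their
    covariates and measurements.
    """
    settings = settings or McmcSettings(chains=2, iterations=1200, burn_in=500,
                                        thin=2, seed=seed)
    subset_idx = _subset_indices(dataset, subset)
    labeled = np.where(np.isfinite(cov.disease))[0]
    labels = cov.disease[labeled].astype(int)
    if min(np.bincount(labels, minlength=2)) < folds:
        raise ValueError("need at least `folds` subjects in each class")

    splitter = (StratifiedKFold(folds, shuffle=True, random_state=seed)
                if stratified else KFold(folds, shuffle=True, random_state=seed))
    split_iter = (splitter.split(labeled, labels) if stratified
                  else splitter.split(labeled))

    y_mat = dataset.replicate_matrix(replicate)
    fold_of = np.full(dataset.I, -1)
    prob_draws = np.full((settings.chains * settings.retained, labeled.size),
                         np.nan)

    for f, (train_loc, test_loc) in enumerate(split_iter):
        test_subjects = labeled[test_loc]
        train_subjects = np.setdiff1d(np.arange(dataset.I), test_subjects)
        fold_of[test_subjects] = f
        logger.info("CV fold %d/%d: fitting on %d subjects", f + 1, folds,
                    train_subjects.size)
        train_data = _restrict(dataset, train_subjects)
        train_cov = CovariateTable(
            disease=cov.disease[train_subjects],
            age_std=cov.age_std[train_subjects], bw_std=cov.bw_std[train_subjects],
            age_center=cov.age_center, age_scale=cov.age_scale,
            bw_center=cov.bw_center, bw_scale=cov.bw_scale,
            subject_ids=[cov.subject_ids[j] for j in train_subjects])
        fold_settings = replace(settings, seed=settings.seed + 1000 * (f + 1))
        draws = fit_model(train_data, train_cov, priors, fold_settings)
        probs = score_subjects(draws, y_mat[test_subjects], subset_idx,
                               prior_log_odds)
        prob_draws[:, test_loc] = probs

    scored = ~np.all(np.isnan(prob_draws), axis=0)
    if not scored.all():
        logger.warning("%d labeled subject(s) had no observed subset miRNA",
                       int((~scored).sum()))
    auc_draws = np.array([
        roc_auc(prob_draws[t, scored], labels[scored])
        for t in range(prob_draws.shape[0])
        if np.all(np.isfinite(prob_draws[t, scored]))])
    return CvAucResult(
        fold_assignment=fold_of[labeled],
        prob_mean=np.nanmean(prob_draws, axis=0),
        prob_draws=prob_draws, labels=labels, auc_draws=auc_draws,
        subject_ids=[cov.subject_ids[j] for j in labeled])


class CancerProbabilityClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn classifier wrapping the hierarchical fit + Gaussian rule.

    ``X`` is a (subjects, K * replicates) matrix of standardized levels with
    the replicate blocks stacked column-wise and NaN marking missing wells;
    ``y`` is the 0/1 disease status.  ``fit`` runs the Gibbs sampler on the
    long-format view of ``X``; ``predict_proba`` scores the first-replicate
    block through the closed-form discriminant, averaging over posterior
    draws.  This makes the model usable with sklearn model selection
    (e.g. ``cross_val_score(..., scoring="roc_auc")``).
    """

    def __init__(self, subset=None, n_mirnas: int | None = None,
                 replicates: int = 2, prior_log_odds: float = np.log(DEFAULT_PRIOR_ODDS),
                 chains: int = 2, iterations: int = 1200, burn_in: int = 500,
                 thin: int = 2, seed: int = 0, prevalence: float = 0.33):
        self.subset = subset
        self.n_mirnas = n_mirnas
        self.replicates = replicates
        self.prior_log_odds = prior_log_odds
        self.chains = chains
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.prevalence = prevalence

    def _to_long(self, X, y):
        X = np.asarray(X, dtype=float)
        I = X.shape[0]
        K = self.n_mirnas or X.shape[1] // self.replicates
        if X.shape[1] != K * self.replicates:
            raise ValueError(f"X has {X.shape[1]} columns, expected "
                             f"{K * self.replicates}")
        cube = X.reshape(I, self.replicates, K).transpose(0, 2, 1)
        ii, kk, rr = np.nonzero(np.isfinite(cube))
        dataset = ExpressionDataset(
            y=cube[ii, kk, rr], mirna_index=kk, subject_index=ii,
            replicate=rr + 1, mirna_names=[f"m{k + 1}" for k in range(K)],
            subject_ids=list(range(I)), n_replicates=self.replicates)
        cov = CovariateTable(disease=np.asarray(y, dtype=float),
                             age_std=np.zeros(I), bw_std=np.zeros(I),
                             age_center=0.0, age_scale=1.0,
                             bw_center=0.0, bw_scale=1.0)
        return dataset, cov

    def fit(self, X, y):
        dataset, cov = self._to_long(X, y)
        settings = McmcSettings(chains=self.chains, iterations=self.iterations,
                                burn_in=self.burn_in, thin=self.thin,
                                seed=self.seed)
        priors = PriorSpec(prevalence=self.prevalence)
        self.draws_ = fit_model(dataset, cov, priors, settings)
        self.n_mirnas_ = dataset.K
        self.subset_idx_ = (_subset_indices(dataset, self.subset)
                            if self.subset is not None
                            else np.arange(dataset.K))
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        rep1 = X[:, :self.n_mirnas_]
        probs = score_subjects(self.draws_, rep1, self.subset_idx_,
                               self.prior_log_odds)
        p1 = np.nanmean(probs, axis=0)
        p1 = np.where(np.isfinite(p1), p1,
                      1.0 / (1.0 + np.exp(-self.prior_log_odds)))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
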