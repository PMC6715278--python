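"""Synthetic miRNA panel generator with known ground truth.

Datasets are drawn from the same generative process the model assumes: per
subject a disease indicator (Bernoulli, prevalence 0.33), standardized age and
body-weight covariates, a multivariate-normal random effect coupling all K
miRNAs, and two independent replicate measurements per (subject, miRNA) cell.
Missingness is applied afterwards — MCAR with per-miRNA rates by default
(matching the model's ignorability assumption), or an optional MNAR mode that
censors wells below a level threshold to emulate a qPCR detection limit.

Levels are generated directly on the standardized scale (mean ~0, SD ~1); an
optional ScalingInfo maps them back to CT values for end-to-end I/O tests.

The ``panel-k49`` fixture mimics the dimensions and missingness texture
of a 49-miRNA x 178-subject ovarian-cancer panel: a handful of strongly
affected, highly correlated miRNAs, most miRNAs nearly complete, and a few
measured in almost no subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataio import CovariateTable, ExpressionDataset, ScalingInfo, expression_to_ct
from .model import ModelParameters, PriorSpec

#: Raw-scale covariate centers/scales used to dress standardized covariates
#: in realistic units (years / kg) for demographics-level tests.
AGE_CENTER, AGE_SCALE = 52.7, 13.7
BW_CENTER, BW_SCALE = 67.3, 11.7


@dataclass
class SimulationConfig:
    """Study-design knobs; defaults mirror the emulated case-control panel."""

    K: int
    I: int
    replicates: int = 2
    prevalence: float = 0.33
    missingness: np.ndarray | None = None     # per-miRNA MCAR rates in [0, 1)
    mnar_threshold: float | None = None       # censor levels below this value
    dis_missing_rate: float = 0.006
    age_missing_rate: float = 0.022
    bw_missing_rate: float = 0.365
    seed: int = 0
    mirna_names: list = field(default_factory=list)
    scaling: ScalingInfo | None = None        # set to emit CT-scale values

    def __post_init__(self) -> None:
        if self.K < 1 or self.I < 2:
            raise ValueError("need K >= 1 and I >= 2")
        if self.missingness is not None:
            rates = np.asarray(self.missingness, dtype=float)
            if rates.shape != (self.K,) or np.any((rates < 0) | (rates >= 1)):
                raise ValueError("missingness must be K rates in [0, 1)")
            self.missingness = rates
        if not self.mirna_names:
            self.mirna_names = [f"miR-sim-{k + 1:02d}" for k in range(self.K)]


@dataclass
class SimulationTruth:
    """Ground-truth manifest for recovery tests."""

    params: ModelParameters
    dis: np.ndarray
    age: np.ndarray
    bw: np.ndarray
    well_mask: np.ndarray        # (I, K, R) True = observed
    config: SimulationConfig


def draw_parameters_from_priors(K: int, rng=None,
                                priors: PriorSpec | None = None) -> ModelParameters:
    """Draw one full parameter set from the model's own prior."""
    from scipy import stats

    rng = np.random.default_rng(rng)
    priors = (priors or PriorSpec()).resolve(K)
    Q = stats.invwishart.rvs(df=priors.iw_df, scale=priors.iw_scale,
                             random_state=rng)
    Q = np.atleast_2d(Q)
    return ModelParameters(
        mu=rng.normal(0.0, priors.sd_mu, K),
        beta_dis=rng.normal(0.0, priors.sd_beta, K),
        beta_age=rng.normal(0.0, priors.sd_beta, K),
        beta_bw=rng.normal(0.0, priors.sd_beta, K),
        sigma=np.abs(rng.normal(0.0, priors.sd_sigma, K)),
        zeta=np.abs(rng.normal(0.0, priors.sd_zeta, K)),
        Q=Q,
    )


def realistic_parameters(K: int, rng=None, beta_dis=None,
                         base_correlation: float = 0.5,
                         correlated_block=(), block_loading: float = 0.98
                         ) -> ModelParameters:
    """Fixed truth resembling a globally standardized qPCR panel.

    The scales are chosen so the emulated panel matches the relationships a
    real standardized panel exhibits: per-miRNA between-subject SD omega
    ~0.45-0.70 and assay SD sigma ~0.35-0.60 give a per-subject total SD near
    0.66 (so a disease shift of beta ~0.42 standardized units is an effect
    size d ~0.6 — the regime of a usable but imperfect plasma marker), while
    the spread of the per-miRNA means mu_k (SD 0.6) brings the *pooled*
    variance over all miRNAs to ~1, as global standardization forces.
    Correlations follow a single-factor structure ``rho = ll' + diag(1-l^2)``
    (positive definite by construction); indices in ``correlated_block`` get
    a loading of ``block_loading`` so their pairwise correlations approach 1.
    """
    rng = np.random.default_rng(rng)
    lam = np.full(K, np.sqrt(base_correlation))
    if len(correlated_block):
        lam[np.asarray(correlated_block, dtype=int)] = block_loading
    rho = np.outer(lam, lam)
    np.fill_diagonal(rho, 1.0)
    omega = rng.uniform(0.45, 0.70, K)
    Q = omega[:, None] * rho * omega[None, :]
    if beta_dis is None:
        beta_dis = rng.normal(0.0, 0.25, K)
    return ModelParameters(
        mu=rng.normal(0.0, 0.6, K),
        beta_dis=np.asarray(beta_dis, dtype=float),
        beta_age=rng.normal(0.0, 0.12, K),
        beta_bw=rng.normal(0.0, 0.12, K),
        sigma=rng.uniform(0.35, 0.60, K),
        zeta=np.ones(K),
        Q=Q,
    )


def simulate_dataset(params: ModelParameters, config: SimulationConfig):
    """Generate one dataset; returns (ExpressionDataset, CovariateTable, truth)."""
    rng = np.random.default_rng(config.seed)
    K, I, R = config.K, config.I, config.replicates
    if params.K != K:
        raise ValueError("params/config dimension mismatch")

    dis = (rng.uniform(size=I) < config.prevalence).astype(float)
    age = rng.standard_normal(I)
    bw = rng.standard_normal(I)

    Omega = params.Omega
    if np.any(np.diag(Omega) > 0):
        try:
            L = np.linalg.cholesky(Omega + 1e-12 * np.eye(K))
        except np.linalg.LinAlgError as exc:
            raise ValueError("Omega is not positive semi-definite") from exc
        eta = rng.standard_normal((I, K)) @ L.T
    else:
        eta = np.zeros((I, K))

    cell_mean = (params.mu[None, :] + np.outer(dis, params.beta_dis)
                 + np.outer(age, params.beta_age) + np.outer(bw, params.beta_bw)
                 + eta)
    y = cell_mean[:, :, None] + params.sigma[None, :, None] * \
        rng.standard_normal((I, K, R))

    mask = np.ones((I, K, R), dtype=bool)
    if config.missingness is not None:
        mask &= rng.uniform(size=(I, K, R)) >= config.missingness[None, :, None]
    if config.mnar_threshold is not None:
        mask &= y >= config.mnar_threshold

    ii, kk, rr = np.nonzero(mask)
    dataset = ExpressionDataset(
        y=y[ii, kk, rr], mirna_index=kk, subject_index=ii, replicate=rr + 1,
        mirna_names=list(config.mirna_names),
        subject_ids=[f"S{j + 1:03d}" for j in range(I)],
        scaling=config.scaling, n_replicates=R,
    )

    dis_obs, age_obs, bw_obs = dis.copy(), age.copy(), bw.copy()
    dis_obs[rng.uniform(size=I) < config.dis_missing_rate] = np.nan
    age_obs[rng.uniform(size=I) < config.age_missing_rate] = np.nan
    bw_obs[rng.uniform(size=I) < config.bw_missing_rate] = np.nan
    covariates = CovariateTable(
        disease=dis_obs, age_std=age_obs, bw_std=bw_obs,
        age_center=AGE_CENTER, age_scale=AGE_SCALE,
        bw_center=BW_CENTER, bw_scale=BW_SCALE,
        subject_ids=list(dataset.subject_ids),
    )
    truth = SimulationTruth(params=replace(params, eta=eta), dis=dis, age=age,
                            bw=bw, well_mask=mask, config=config)
    return dataset, covariates, truth


def to_ct_frame(dataset: ExpressionDataset, scaling: ScalingInfo):
    """Long-format frame with levels mapped back to the CT scale."""
    df = dataset.to_frame()
    level = df.pop("level") * scaling.global_sd + scaling.global_mean
    df["ct"] = expression_to_ct(level.to_numpy(), offset=scaling.ct_offset)
    return df


def _panel49_names(K: int) -> list:
    names = [f"miR-sim-{k + 1:02d}" for k in range(K)]
    for idx, real in ((3, "miR-101-3p"), (8, "miR-142-5p"), (12, "miR-148a-3p"),
                      (20, "miR-140-3p"), (30, "miR-221-5p"), (31, "miR-346"),
                      (40, "miR-604")):
        if idx < K:
            names[idx] = real
    return names


def _panel49_missingness(K: int) -> np.ndarray:
    """Mostly-complete profile with a few near-empty miRNAs, spanning 0-0.99."""
    rates = np.linspace(0.0, 0.10, K)
    fixed = {3: 0.0449, 8: 0.0, 12: 0.264, 20: 0.02,
             30: 0.9438, 31: 0.9551, 40: 0.9888}
    for idx, r in fixed.items():
        if idx < K:
            rates[idx] = r
    return rates


FIXTURES = {
    "tiny-k3": dict(K=3, I=40, seed=1301,
                    beta_dis=np.array([1.5, 0.0, -0.7])),
    "null-effect": dict(K=5, I=60, seed=1302, beta_dis=np.zeros(5)),
    "panel-k49": dict(K=49, I=178, seed=1303),
}


def make_fixture(name: str, **overrides):
    """Deterministic named dataset; returns (dataset, covariates, truth)."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    entry = {**FIXTURES[name], **overrides}
    seed = entry.pop("seed")
    beta_dis = entry.pop("beta_dis", None)
    K, I = entry.pop("K"), entry.pop("I")
    rng = np.random.default_rng(seed)

    if name == "panel-k49":
        # three strong, almost collinear disease markers (fold change ~2.2 on
        # a raw-data SD of 1.93 corresponds to beta ~ ln(2.24)/1.93 ~ 0.42)
        beta = rng.normal(0.0, 0.12, K)
        beta[[3, 8, 12]] = (0.418, 0.387, 0.414)
        beta[20] = 0.36
        params = realistic_parameters(K, rng, beta_dis=beta,
                                      correlated_block=(3, 8, 12))
        config = SimulationConfig(K=K, I=I, seed=seed + 1,
                                  missingness=_panel49_missingness(K),
                                  mirna_names=_panel49_names(K),
                                  scaling=ScalingInfo(global_mean=4.03,
                                                      global_sd=1.93), **entry)
    else:
        params = realistic_parameters(K, rng, beta_dis=beta_dis)
        config = SimulationConfig(K=K, I=I, seed=seed + 1,
                                  dis_missing_rate=0.0, age_missing_rate=0.0,
                                  bw_missing_rate=0.0, **entry)
    return simulate_dataset(params, config)
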