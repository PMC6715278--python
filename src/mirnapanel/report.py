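"""Model diagnostics, raw-data summaries and end-to-end pipeline orchestration."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataio, discriminant, fdr as fdr_mod, simulate, summaries
from .dataio import CovariateTable, ExpressionDataset
from .model import McmcSettings, PosteriorDraws, PriorSpec, fit as fit_model

logger = logging.getLogger(__name__)


def weighted_residuals(draws: PosteriorDraws, dataset: ExpressionDataset,
                       cov: CovariateTable) -> pd.DataFrame:
    """Conditional weighted residuals: (y - fitted) / sigma per observation.

    The fitted value is the posterior mean of the full linear predictor
    *including* the subject effect eta, and sigma is the posterior mean
    residual SD — so for a well-specified model the residuals scatter around
    zero with SD near one for every miRNA.
    """
    if draws.eta_mean is None or draws.eta_mean.shape != (dataset.I, dataset.K):
        raise ValueError("draws do not match dataset dimensions")
    mu = draws.stacked("mu").mean(axis=0)
    bd = draws.stacked("beta_dis").mean(axis=0)
    ba = draws.stacked("beta_age").mean(axis=0)
    bw = draws.stacked("beta_bw").mean(axis=0)
    sigma = draws.stacked("sigma").mean(axis=0)

    dis = np.nan_to_num(cov.disease)
    age = np.nan_to_num(cov.age_std)
    wt = np.nan_to_num(cov.bw_std)
    m_dis, m_age, m_bw = cov.missing_masks()
    for mask, arr, name in ((m_dis, dis, "dis_imputed"), (m_age, age, "age_imputed"),
                            (m_bw, wt, "bw_imputed")):
        if mask.any() and name in draws.draws:
            arr[mask] = draws.stacked(name).mean(axis=0)

    k = dataset.mirna_index
    i = dataset.subject_index
    fitted = (mu[k] + bd[k] * dis[i] + ba[k] * age[i] + bw[k] * wt[i]
              + draws.eta_mean[i, k])
    resid = (dataset.y - fitted) / sigma[k]
    return pd.DataFrame({
        "mirna": [dataset.mirna_names[j] for j in k],
        "fitted": fitted, "residual": resid,
    })


def raw_data_summary(dataset: ExpressionDataset, cov: CovariateTable
                     ) -> pd.DataFrame:
    """Per-miRNA, per-group quantile summary of the standardized levels.

    Uses the median as the center line (quartile boxplot convention); rows
    with no observations keep n = 0 and NaN quantiles.
    """
    rows = []
    for k, name in enumerate(dataset.mirna_names):
        sel = dataset.mirna_index == k
        dis_per_obs = cov.disease[dataset.subject_index[sel]]
        vals = dataset.y[sel]
        for group, lab in ((0.0, "control"), (1.0, "case")):
            v = vals[dis_per_obs == group]
            rec = {"mirna": name, "group": lab, "n": int(v.size)}
            if v.size:
                q25, q50, q75 = np.percentile(v, [25, 50, 75])
                rec.update(q25=q25, median=q50, q75=q75, mean=float(v.mean()))
            else:
                rec.update(q25=np.nan, median=np.nan, q75=np.nan, mean=np.nan)
            rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """One end-to-end run: where the data are, how to fit, what to report."""

    data_dir: str | None = None          # canonical dataset directory
    fixture: str | None = None           # or a named synthetic fixture
    out_dir: str = "pipeline_out"
    seed: int = 0
    chains: int = 2
    iterations: int = 1200
    burn_in: int = 500
    thin: int = 2
    subset: list = field(default_factory=list)  # miRNA names for classify-cv
    folds: int = 10
    alpha: float = 0.05
    replicate: int | str = 1
    run_cv: bool = True

    def validate(self) -> None:
        if (self.data_dir is None) == (self.fixture is None):
            raise ValueError("set exactly one of data_dir / fixture")
        if self.data_dir is not None and not Path(self.data_dir).exists():
            raise FileNotFoundError(self.data_dir)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps({k: str(v) for k, v in config.__dict__.items()
                       if k != "out_dir"}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """load -> fit -> summarize -> classify-cv -> fdr -> diagnostics.

    Writes every table plus a JSON manifest (seed, config hash, Rhat,
    runtimes) to ``config.out_dir`` and returns the in-memory results.
    Failures carry the stage name; tables written before the failure remain.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": _config_hash(config), "seed": config.seed,
                "stages": {}}
    results = {}
    stage = "load"
    t0 = time.time()
    try:
        if config.fixture is not None:
            dataset, cov, truth = simulate.make_fixture(config.fixture)
            results["truth"] = truth
        else:
            dataset, cov = dataio.load_canonical(config.data_dir)
        results["dataset"], results["covariates"] = dataset, cov
        global_sd = dataset.scaling.global_sd if dataset.scaling else 1.0
        dataio.summarize_demographics(cov).to_csv(out / "demographics.csv",
                                                  index=False)
        dataio.missingness_by_mirna(dataset).to_csv(out / "missingness.csv")
        raw_data_summary(dataset, cov).to_csv(out / "raw_summary.csv", index=False)
        manifest["stages"][stage] = round(time.time() - t0, 2)

        stage = "fit"
        t0 = time.time()
        settings = McmcSettings(chains=config.chains, iterations=config.iterations,
                                burn_in=config.burn_in, thin=config.thin,
                                seed=config.seed)
        draws = fit_model(dataset, cov, PriorSpec(), settings)
        results["draws"] = draws
        manifest["rhat_max"] = float(draws.rhat[np.isfinite(draws.rhat)].max())
        manifest["converged"] = draws.converged
        manifest["stages"][stage] = round(time.time() - t0, 2)

        stage = "summarize"
        t0 = time.time()
        table = summaries.derived_summary_table(draws, global_sd=global_sd)
        table.insert(0, "config_hash", manifest["config_hash"])
        table.to_csv(out / "posterior_summaries.csv", index=False)
        results["summary_table"] = table
        manifest["stages"][stage] = round(time.time() - t0, 2)

        stage = "diagnostics"
        t0 = time.time()
        resid = weighted_residuals(draws, dataset, cov)
        resid.to_csv(out / "weighted_residuals.csv", index=False)
        results["residuals"] = resid
        manifest["stages"][stage] = round(time.time() - t0, 2)

        stage = "fdr"
        t0 = time.time()
        fdr_res = fdr_mod.fdr_analysis(dataset, cov, alpha=config.alpha)
        fdr_res.table.to_csv(out / "fdr.csv", index=False)
        results["fdr"] = fdr_res
        manifest["fdr_significant"] = fdr_res.significant()
        manifest["stages"][stage] = round(time.time() - t0, 2)

        if config.run_cv and config.subset:
            stage = "classify-cv"
            t0 = time.time()
            cv = discriminant.crossvalidated_auc(
                dataset, cov, config.subset, folds=config.folds,
                settings=settings, seed=config.seed,
                replicate=config.replicate)
            cv.probability_table().to_csv(out / "cv_probabilities.csv",
                                          index=False)
            results["cv"] = cv
            manifest["cv_auc"] = cv.auc_summary()
            manifest["stages"][stage] = round(time.time() - t0, 2)
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
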