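"""Reading, validation and transformation of long-format qPCR miRNA panels.

The canonical in-memory objects are :class:`ExpressionDataset` (one row per
observed well: subject x miRNA x replicate, on the globally standardized log
scale) and :class:`CovariateTable` (per-subject disease status and standardized
age / body weight, with missing entries kept as NaN rather than filled).

Quantification cycles are mapped to log levels via ``(offset - CT) * ln 2``,
i.e. one PCR cycle corresponds to a doubling of template, expressed in natural
log units.  Standardization is *global*: a single mean and a single standard
deviation over every non-missing observation in the panel, so that effect
sizes and fold changes for all miRNAs live on one common scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

LN2 = math.log(2.0)

#: Column roles of the canonical on-disk layout.  ``value_type`` may be
#: ``"level"`` (already on the (offset-CT)*ln2 scale) or ``"ct"``.
DEFAULT_SCHEMA = {
    "subject": "subject_id",
    "mirna": "mirna",
    "replicate": "replicate",
    "value": "level",
    "value_type": "level",
    "disease": "disease",
    "age": "age",
    "weight": "weight",
}

#: Spike-in cDNA synthesis control excluded from analysis when present.
CONTROL_MIRNAS = ("UniSp6",)


class DataError(ValueError):
    """Raised for malformed input tables."""


@dataclass
class ScalingInfo:
    """Constants of the CT -> level -> standardized-level transform chain."""

    global_mean: float
    global_sd: float
    ct_offset: float = 40.0
    log_base_factor: float = LN2

    def __post_init__(self) -> None:
        if not self.global_sd > 0:
            raise DataError(f"global_sd must be positive, got {self.global_sd}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingInfo":
        return cls(**d)


def ct_to_expression(ct, offset: float = 40.0):
    """Convert quantification cycles to natural-log expression levels.

    ``level = (offset - ct) * ln 2``: a well crossing threshold one cycle
    earlier had twice the template, hence +ln 2 on the log scale.
    """
    ct = np.asarray(ct, dtype=float)
    if not np.all(np.isfinite(ct)):
        raise DataError("non-finite CT value encountered")
    out = (offset - ct) * LN2
    return out if out.ndim else float(out)


def expression_to_ct(level, offset: float = 40.0):
    """Inverse of :func:`ct_to_expression`."""
    level = np.asarray(level, dtype=float)
    out = offset - level / LN2
    return out if out.ndim else float(out)


def standardize(levels):
    """Globally center and scale a vector of log levels.

    Returns ``(z, ScalingInfo)`` where ``z = (levels - mean) / sd`` with the
    single mean and SD taken over all non-missing entries.
    """
    levels = np.asarray(levels, dtype=float)
    finite = levels[np.isfinite(levels)]
    if finite.size < 2:
        raise DataError("need at least 2 finite values to standardize")
    mean = float(finite.mean())
    sd = float(finite.std(ddof=1))
    if sd <= 0:
        raise DataError("zero variance: cannot standardize")
    return (levels - mean) / sd, ScalingInfo(global_mean=mean, global_sd=sd)


def destandardize(z, scaling: ScalingInfo):
    """Map standardized values back to the log-level scale."""
    return np.asarray(z, dtype=float) * scaling.global_sd + scaling.global_mean


@dataclass
class ExpressionDataset:
    """Long-format standardized panel: one entry per observed well.

    Indices are 0-based internally; ``mirna_names[mirna_index[n]]`` labels
    observation ``n``.  Missing wells are simply absent (no sentinel values).
    """

    y: np.ndarray
    mirna_index: np.ndarray
    subject_index: np.ndarray
    replicate: np.ndarray
    mirna_names: list
    subject_ids: list
    scaling: ScalingInfo | None = None
    n_replicates: int = 2

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.mirna_index = np.asarray(self.mirna_index, dtype=int)
        self.subject_index = np.asarray(self.subject_index, dtype=int)
        self.replicate = np.asarray(self.replicate, dtype=int)
        self.validate()

    @property
    def N(self) -> int:
        return self.y.size

    @property
    def K(self) -> int:
        return len(self.mirna_names)

    @property
    def I(self) -> int:
        return len(self.subject_ids)

    def validate(self) -> None:
        n = self.y.size
        for name, arr in (("mirna_index", self.mirna_index),
                          ("subject_index", self.subject_index),
                          ("replicate", self.replicate)):
            if arr.size != n:
                raise DataError(f"{name} length {arr.size} != {n} observations")
        if n and (self.mirna_index.min() < 0 or self.mirna_index.max() >= self.K):
            raise DataError("mirna_index out of range")
        if n and (self.subject_index.min() < 0 or self.subject_index.max() >= self.I):
            raise DataError("subject_index out of range")
        triples = set(zip(self.subject_index.tolist(), self.mirna_index.tolist(),
                          self.replicate.tolist()))
        if len(triples) != n:
            raise DataError("duplicate (subject, miRNA, replicate) triple")

    def cell_stats(self):
        """Per-(subject, miRNA) sufficient statistics.

        Returns ``(M, S, SS)``: replicate counts, sums and sums of squares,
        each of shape (I, K).  These are all the likelihood needs.
        """
        I, K = self.I, self.K
        flat = self.subject_index * K + self.mirna_index
        M = np.bincount(flat, minlength=I * K).reshape(I, K).astype(float)
        S = np.bincount(flat, weights=self.y, minlength=I * K).reshape(I, K)
        SS = np.bincount(flat, weights=self.y ** 2, minlength=I * K).reshape(I, K)
        return M, S, SS

    def replicate_matrix(self, replicate: int | str = 1) -> np.ndarray:
        """(I, K) matrix of levels for one replicate (or ``"mean"``), NaN = missing."""
        I, K = self.I, self.K
        if replicate == "mean":
            M, S, _ = self.cell_stats()
            with np.errstate(invalid="ignore"):
                return np.where(M > 0, S / np.maximum(M, 1), np.nan)
        mat = np.full((I, K), np.nan)
        sel = self.replicate == int(replicate)
        mat[self.subject_index[sel], self.mirna_index[sel]] = self.y[sel]
        return mat

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": [self.subject_ids[i] for i in self.subject_index],
            "mirna": [self.mirna_names[k] for k in self.mirna_index],
            "replicate": self.replicate,
            "level": self.y,
        })


@dataclass
class CovariateTable:
    """Per-subject covariates on the model scale (disease 0/1, z-scored age/weight).

    NaN marks a missing entry; the raw-scale centers and scales are retained so
    demographics can be reported in years and kilograms.
    """

    disease: np.ndarray
    age_std: np.ndarray
    bw_std: np.ndarray
    age_center: float = np.nan
    age_scale: float = np.nan
    bw_center: float = np.nan
    bw_scale: float = np.nan
    subject_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.disease = np.asarray(self.disease, dtype=float)
        self.age_std = np.asarray(self.age_std, dtype=float)
        self.bw_std = np.asarray(self.bw_std, dtype=float)
        if not (self.disease.size == self.age_std.size == self.bw_std.size):
            raise DataError("covariate columns must have equal length")
        obs = self.disease[np.isfinite(self.disease)]
        if obs.size and not np.all(np.isin(obs, (0.0, 1.0))):
            raise DataError("disease status must be 0, 1 or missing")
        if not self.subject_ids:
            self.subject_ids = list(range(self.disease.size))

    @property
    def I(self) -> int:
        return self.disease.size

    def missing_masks(self):
        return (~np.isfinite(self.disease), ~np.isfinite(self.age_std),
                ~np.isfinite(self.bw_std))


def standardize_covariates(ages, weights):
    """Z-score age and body weight from their non-missing entries.

    Missing values stay NaN (they become latent parameters in the model, not
    filled here).  Returns ``(age_std, bw_std, centers_and_scales)``.
    """
    out = []
    stats = {}
    for name, col in (("age", ages), ("bw", weights)):
        col = np.asarray(col, dtype=float)
        obs = col[np.isfinite(col)]
        if obs.size == 0:
            raise DataError(f"all {name} values missing")
        mean = float(obs.mean())
        sd = float(obs.std(ddof=1)) if obs.size > 1 else 0.0
        if sd <= 0:
            raise DataError(f"zero variance in {name}")
        out.append((col - mean) / sd)
        stats[f"{name}_center"] = mean
        stats[f"{name}_scale"] = sd
    return out[0], out[1], stats


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def load_raw(measurements_path, covariates_path=None, schema: dict | None = None,
             ct_missing_threshold: float | None = None,
             do_standardize: bool = True):
    """Load a long-format qPCR export and return the standardized dataset.

    Parameters
    ----------
    measurements_path
        Delimited text with one row per well; columns named by ``schema``.
    covariates_path
        Per-subject table (disease / age / weight).  May be the same file as
        the measurements (covariates repeated per row).
    schema
        Role -> column-name mapping; see :data:`DEFAULT_SCHEMA`.  The
        ``value_type`` role selects CT-scale vs level-scale input.
    ct_missing_threshold
        If the input stores CT and this is set, wells with CT at or above the
        threshold are treated as missing (detector limit rule).
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = _read_table(measurements_path)
    needed = [schema["subject"], schema["mirna"], schema["replicate"], schema["value"]]
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise DataError(f"missing column(s) {missing_cols}; present: {list(df.columns)}")

    df = df[~df[schema["mirna"]].isin(CONTROL_MIRNAS)].copy()

    values = pd.to_numeric(df[schema["value"]], errors="coerce")
    if schema["value_type"] == "ct":
        if ct_missing_threshold is not None:
            values = values.where(values < ct_missing_threshold)
        keep = values.notna()
        levels = ct_to_expression(values[keep].to_numpy())
    elif schema["value_type"] == "level":
        keep = values.notna()
        levels = values[keep].to_numpy()
    else:
        raise DataError(f"unknown value_type {schema['value_type']!r}")
    df = df[keep.to_numpy()]

    mirna_names = list(pd.unique(df[schema["mirna"]]))
    subject_ids = list(pd.unique(df[schema["subject"]]))
    k_idx = df[schema["mirna"]].map({m: j for j, m in enumerate(mirna_names)}).to_numpy()
    i_idx = df[schema["subject"]].map({s: j for j, s in enumerate(subject_ids)}).to_numpy()
    reps = df[schema["replicate"]].to_numpy(dtype=int)

    scaling = None
    y = np.asarray(levels, dtype=float)
    if do_standardize:
        y, scaling = standardize(y)

    dataset = ExpressionDataset(
        y=y, mirna_index=k_idx, subject_index=i_idx, replicate=reps,
        mirna_names=mirna_names, subject_ids=subject_ids, scaling=scaling,
        n_replicates=int(reps.max()) if reps.size else 2,
    )

    covariates = None
    if covariates_path is not None:
        cdf = _read_table(covariates_path)
        for role in ("subject", "disease", "age", "weight"):
            if schema[role] not in cdf.columns:
                raise DataError(f"covariate table lacks column {schema[role]!r}")
        cdf = (cdf.drop_duplicates(subset=schema["subject"])
                  .set_index(schema["subject"]).reindex(subject_ids))
        dis = pd.to_numeric(cdf[schema["disease"]], errors="coerce").to_numpy(dtype=float)
        obs = dis[np.isfinite(dis)]
        if obs.size and not np.all(np.isin(obs, (0.0, 1.0))):
            bad = sorted(set(obs) - {0.0, 1.0})
            raise DataError(f"disease codes must be 0/1, found {bad}")
        age_raw = pd.to_numeric(cdf[schema["age"]], errors="coerce").to_numpy(dtype=float)
        bw_raw = pd.to_numeric(cdf[schema["weight"]], errors="coerce").to_numpy(dtype=float)
        age_std, bw_std, stats = standardize_covariates(age_raw, bw_raw)
        covariates = CovariateTable(disease=dis, age_std=age_std, bw_std=bw_std,
                                    subject_ids=subject_ids, **stats)
    return dataset, covariates


def missingness_by_mirna(dataset: ExpressionDataset) -> pd.Series:
    """Percent of missing wells per miRNA (denominator I x replicates)."""
    denom = dataset.I * dataset.n_replicates
    counts = np.bincount(dataset.mirna_index, minlength=dataset.K)
    pct = 100.0 * (denom - counts) / denom
    return pd.Series(pct, index=dataset.mirna_names, name="pct_missing")


def summarize_demographics(cov: CovariateTable) -> pd.DataFrame:
    """Table-style demographic summary: mean (SD) on raw scale, percent missing."""
    rows = []
    dis = cov.disease
    rows.append({
        "covariate": "health_status",
        "mean": float(np.nanmean(dis)) if np.isfinite(dis).any() else np.nan,
        "sd": np.nan,
        "n_control": int(np.nansum(dis == 0)),
        "n_case": int(np.nansum(dis == 1)),
        "pct_missing": 100.0 * float(np.mean(~np.isfinite(dis))),
    })
    for name, std, center, scale in (
            ("age", cov.age_std, cov.age_center, cov.age_scale),
            ("weight", cov.bw_std, cov.bw_center, cov.bw_scale)):
        raw = std * scale + center
        obs = raw[np.isfinite(raw)]
        rows.append({
            "covariate": name,
            "mean": float(obs.mean()) if obs.size else np.nan,
            "sd": float(obs.std(ddof=1)) if obs.size > 1 else np.nan,
            "n_control": np.nan, "n_case": np.nan,
            "pct_missing": 100.0 * float(np.mean(~np.isfinite(raw))),
        })
    return pd.DataFrame(rows)


def write_canonical(dataset: ExpressionDataset, covariates: CovariateTable | None,
                    out_dir) -> dict:
    """Write the canonical measurement/covariate tables plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"measurements": out_dir / "measurements.csv",
             "covariates": out_dir / "covariates.csv",
             "sidecar": out_dir / "dataset.json"}
    dataset.to_frame().to_csv(paths["measurements"], index=False)
    if covariates is not None:
        pd.DataFrame({
            "subject_id": covariates.subject_ids,
            "disease": covariates.disease,
            "age": covariates.age_std * covariates.age_scale + covariates.age_center,
            "weight": covariates.bw_std * covariates.bw_scale + covariates.bw_center,
        }).to_csv(paths["covariates"], index=False)
    sidecar = {
        "K": dataset.K, "I": dataset.I, "N": dataset.N,
        "n_replicates": dataset.n_replicates,
        "scaling": dataset.scaling.to_dict() if dataset.scaling else None,
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2))
    return {k: str(v) for k, v in paths.items()}


def load_canonical(directory):
    """Round-trip partner of :func:`write_canonical`.

    Levels in the canonical file are already standardized, so no re-scaling is
    applied; the sidecar's ScalingInfo is re-attached for back-transformation.
    """
    directory = Path(directory)
    dataset, covariates = load_raw(
        directory / "measurements.csv",
        directory / "covariates.csv" if (directory / "covariates.csv").exists() else None,
        do_standardize=False,
    )
    sidecar = json.loads((directory / "dataset.json").read_text())
    if sidecar.get("scaling"):
        dataset.scaling = ScalingInfo.from_dict(sidecar["scaling"])
    dataset.n_replicates = sidecar.get("n_replicates", dataset.n_replicates)
    return dataset, covariates
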