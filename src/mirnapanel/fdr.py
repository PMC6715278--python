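"""Frequentist comparison arm: per-miRNA two-group tests with BH-FDR control.

Each miRNA is tested one-at-a-time on per-subject replicate-averaged
standardized levels (complete cases only: subjects with known disease status
and at least one observed well).  Raw two-sided p-values come from Welch's
two-sample t-test; the Benjamini-Hochberg step-up adjustment multiplies each
ranked p-value by the number of panel variables and divides by its rank,
enforcing monotonicity from the largest rank down.  The raw-data effect size
``d_fdr`` is Cohen's d with pooled SD on the same per-subject means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import CovariateTable, ExpressionDataset, missingness_by_mirna


@dataclass
class FdrResult:
    """Per-miRNA table of the frequentist analysis."""

    table: pd.DataFrame
    alpha: float

    def significant(self) -> list:
        sel = self.table[self.table["significant"]]
        return list(sel.sort_values("p_adj")["mirna"])


def _group_means(dataset: ExpressionDataset, cov: CovariateTable, k: int):
    """Per-subject replicate means for miRNA k, split by disease status."""
    sel = dataset.mirna_index == k
    subj = dataset.subject_index[sel]
    vals = dataset.y[sel]
    sums = np.bincount(subj, weights=vals, minlength=dataset.I)
    counts = np.bincount(subj, minlength=dataset.I)
    have = (counts > 0) & np.isfinite(cov.disease)
    means = sums[have] / counts[have]
    dis = cov.disease[have]
    return means[dis == 0], means[dis == 1]


def per_mirna_test(dataset: ExpressionDataset, cov: CovariateTable, mirna):
    """Welch t-test of patients vs controls for one miRNA.

    Returns a dict with the two-sided p-value, group means/SDs and n; the
    p-value is NaN when fewer than 2 complete cases exist in either group.
    """
    k = (dataset.mirna_names.index(mirna) if not isinstance(mirna, (int, np.integer))
         else int(mirna))
    ctrl, case = _group_means(dataset, cov, k)
    rec = {
        "mirna": dataset.mirna_names[k],
        "n_control": ctrl.size, "n_case": case.size,
        "mean_control": float(ctrl.mean()) if ctrl.size else np.nan,
        "mean_case": float(case.mean()) if case.size else np.nan,
        "sd_control": float(ctrl.std(ddof=1)) if ctrl.size > 1 else np.nan,
        "sd_case": float(case.std(ddof=1)) if case.size > 1 else np.nan,
    }
    if ctrl.size < 2 or case.size < 2:
        rec["p_raw"] = np.nan
        return rec
    rec["p_raw"] = float(stats.ttest_ind(case, ctrl, equal_var=False).pvalue)
    return rec


def bh_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    ``adj_(r) = min_{s >= r} ( p_(s) * m / s )`` capped at 1, returned in the
    input order.  ``m`` defaults to the number of non-missing p-values but may
    be set larger (e.g. the panel size when some tests were untestable).
    NaN entries pass through as NaN and do not consume ranks.
    """
    p = np.asarray(pvalues, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    vals = p[finite]
    n = vals.size
    m_eff = n if m is None else int(m)
    if m_eff < n:
        raise ValueError("m must be at least the number of p-values")
    order = np.argsort(vals, kind="mergesort")
    ranked = vals[order] * m_eff / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.full_like(p, np.nan)
    idx = np.where(finite)[0]
    out[idx[order]] = adj
    return out


def cohens_d_raw(dataset: ExpressionDataset, cov: CovariateTable, mirna) -> float:
    """Cohen's d (pooled SD) of patients vs controls on per-subject means."""
    k = (dataset.mirna_names.index(mirna) if not isinstance(mirna, (int, np.integer))
         else int(mirna))
    ctrl, case = _group_means(dataset, cov, k)
    if ctrl.size < 2 or case.size < 2:
        raise ValueError("need at least 2 complete cases per group")
    n0, n1 = ctrl.size, case.size
    pooled = np.sqrt(((n0 - 1) * ctrl.var(ddof=1) + (n1 - 1) * case.var(ddof=1))
                     / (n0 + n1 - 2))
    if pooled == 0:
        raise ValueError("zero pooled SD")
    return float((case.mean() - ctrl.mean()) / pooled)


def significant_set(adjusted, names=None, alpha: float = 0.05) -> list:
    """miRNAs with adjusted p strictly below alpha, ordered by adjusted p."""
    adjusted = np.asarray(adjusted, dtype=float)
    names = list(names) if names is not None else list(range(adjusted.size))
    sel = np.where(np.isfinite(adjusted) & (adjusted < alpha))[0]
    return [names[j] for j in sel[np.argsort(adjusted[sel], kind="mergesort")]]


def fdr_analysis(dataset: ExpressionDataset, cov: CovariateTable,
                 alpha: float = 0.05, m: int | None = None) -> FdrResult:
    """Full panel analysis: tests, BH adjustment (m = panel size K), d_fdr."""
    rows = [per_mirna_test(dataset, cov, k) for k in range(dataset.K)]
    table = pd.DataFrame(rows)
    m_eff = m if m is not None else dataset.K
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy(), m=m_eff)
    table["significant"] = np.isfinite(table["p_adj"]) & (table["p_adj"] < alpha)
    d = []
    for k in range(dataset.K):
        try:
            d.append(cohens_d_raw(dataset, cov, k))
        except ValueError:
            d.append(np.nan)
    table["d_fdr"] = d
    table["pct_missing"] = missingness_by_mirna(dataset).to_numpy()
    return FdrResult(table=table, alpha=alpha)
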