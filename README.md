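# mirnapanel

Bayesian multilevel analysis of circulating-miRNA qPCR panels in
case-control studies — built for the setting where a few dozen preselected
miRNAs are measured in duplicate wells across a few hundred subjects, with
substantial and uneven missingness, and the question is which miRNAs differ
between patients and controls and how useful they would be as diagnostic
markers.

## The model

Quantification cycles are mapped to natural-log expression levels,
`level = (40 − CT)·ln 2`, then globally centered and standardized (one mean
and one SD over the whole panel).  Each standardized observation — subject
*i*, miRNA *k*, one of two replicates — follows a hierarchical model:

```
y_n     ~ N( μ_k + β_DIS,k·DIS_i + β_AGE,k·AGE_i + β_BW,k·BW_i + η_{i,k} , σ_k )
η_i     ~ MVN( 0 , Ω )                        Ω = diag(ζ) Q diag(ζ)
Q       ~ InvWishart_{K+1}( I_K )             ζ_k, σ_k ~ half-N(0, 1)
μ_k     ~ N(0, 5)        β·,k ~ N(0, 1)
```

The multivariate-normal subject effect `η_i` couples all K miRNAs through
the scaled inverse-Wishart covariance `Ω`, separating per-miRNA
between-subject scales `ω_k = ζ_k√Q_kk` from the correlation matrix `ρ`.
Missing covariates are latent parameters (disease status Bernoulli(0.33),
standardized age and weight N(0, 1)); missing wells simply contribute no
likelihood term.  Inference is by a parameter-expanded Gibbs sampler with
split-R̂ convergence monitoring.

Posterior draws feed three kinds of downstream quantities, each computed
per draw so uncertainty propagates:

- **fold changes** `exp(SD·β_DIS,k)` (SD = the pre-standardization global SD)
  and **effect sizes** `d_k = β_DIS,k / √(ω_k² + σ_k²)`;
- a closed-form **probability of cancer** for a subject's single-replicate
  profile on a miRNA subset *j* — the two-class Gaussian discriminant
  `logit(p) = log(0.333) − ½(2μ+β)ᵀΣ⁻¹β + yᵀΣ⁻¹β` with `Σ = Ω + diag(σ²)`,
  summarized as a 10-fold cross-validated AUC with credible interval;
- a frequentist comparison arm: per-miRNA Welch tests on replicate-averaged
  levels with Benjamini–Hochberg adjustment and raw-data Cohen's `d`.

A synthetic-data generator reproduces the whole design — prevalence,
replicate structure, dense inter-miRNA correlation, per-miRNA missingness
from 0 to 99%, missing covariates — with known ground truth, so every stage
is testable without any study data.

## Worked example

```python
import numpy as np
from mirnapanel import fit_hierarchical, McmcSettings, make_fixture
from mirnapanel.summaries import derived_summary_table

dataset, covariates, truth = make_fixture("tiny-k3", I=200)
draws = fit_hierarchical(dataset, covariates,
                         settings=McmcSettings(chains=2, iterations=900,
                                               burn_in=300, seed=5))
print("converged:", draws.converged)
table = derived_summary_table(draws, global_sd=1.93)
cols = ["mirna", "quantity", "p5", "p50", "p95", "credible"]
print(table.loc[table.quantity.isin(["fold_change", "d"]), cols]
      .round(2).to_string(index=False))
```

prints

```
converged: True
     mirna    quantity    p5   p50   p95  credible
miR-sim-01 fold_change 17.39 22.89 29.68      True
miR-sim-01           d  2.06  2.30  2.54      True
miR-sim-02 fold_change  0.90  1.30  1.81     False
miR-sim-02           d -0.07  0.16  0.38     False
miR-sim-03 fold_change  0.18  0.24  0.31      True
miR-sim-03           d -1.28 -1.07 -0.85      True
```

The fixture plants disease effects (1.5, 0, −0.7) on the standardized
scale.  The first miRNA's 90% interval for the fold change excludes 1
(`credible`), the null one does not, and the negative effect is recovered
as a fold change below 1.  An effect size `|d| > 1.5` would indicate
nearly separated patient/control distributions; `d ≈ 2.3` here reflects
the deliberately strong planted effect.

The same stages run from the shell:

```sh
mirnapanel simulate --fixture panel-k49 --out data49
mirnapanel fit --data data49 --chains 3 --iters 3000 --out fit49
mirnapanel fdr --data data49 --out fdr.csv
mirnapanel classify-cv --data data49 --subset "miR-101-3p,miR-142-5p,miR-148a-3p" --out cv49
mirnapanel run-all --fixture tiny-k3 --out run
```

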