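# Methods

## Data representation and transforms

A panel is a long-format collection of wells: subject × miRNA × replicate.
Quantification cycles become natural-log levels through
`(offset − CT)·ln 2` (offset 40 by default): each earlier cycle means twice
the template.  Standardization is **global** — a single mean and SD over
every non-missing observation — not per-miRNA.  This matters downstream:
the effect size `d_k` and the fold change `exp(SD·β)` only make sense if
all miRNAs share one scale, and it implies that per-miRNA variances need
not be 1 (the spread of the per-miRNA means `μ_k` absorbs part of the
pooled variance).

Missing wells are represented by absent rows, never sentinel CT values; an
optional rule treats CT at or above a threshold as missing for exports that
encode censoring that way.  Covariates are z-scored from their non-missing
entries; missing entries stay NaN and become latent model parameters.

## The hierarchical model

Standardized level `y_n` for subject `i`, miRNA `k`:

    y_n ~ N(mu_k + b_dis_k DIS_i + b_age_k AGE_i + b_bw_k BW_i + eta_{i,k}, sigma_k)
    eta_i ~ MVN(0, Omega),   Omega = diag(zeta) Q diag(zeta)

Priors: `mu_k ~ N(0,5)`, all regression coefficients `N(0,1)`, `sigma_k`
and `zeta_k` half-normal(1), `Q ~ InvWishart_{K+1}(I_K)`.  The scaled
inverse-Wishart decouples the per-miRNA between-subject scales
`omega_k = |zeta_k| sqrt(Q_kk)` from the correlation structure, avoiding
the overly informative marginals a plain Wishart/inverse-Wishart imposes
when scales vary.  Missing disease status is Bernoulli(0.33) (the cohort
case fraction), missing standardized age/weight N(0,1).  Absent wells
contribute no likelihood term — missingness is treated as ignorable.
miRNAs with ~99% missingness stay in the model; their effect posteriors are
prior-dominated by design, which is exactly the honest statement about
them.

### Sampler

A parameter-expanded Gibbs sampler, writing `eta_i = diag(zeta) xi_i` with
`xi_i ~ MVN(0, Q)`.  Conditionals:

- regression block `(mu_k, b_dis_k, b_age_k, b_bw_k)`: 4-dimensional
  Gaussian, batched over k;
- `xi_i`: K-dimensional Gaussian; the precision differs between subjects
  only through their missingness pattern, so one Cholesky factorization is
  shared per unique pattern (a single factorization for complete data);
- `zeta_k`: truncated normal on (0, ∞) — the likelihood is linear in
  `zeta_k` given `xi`;
- `Q`: conjugate inverse-Wishart, `InvWishart(K+1+I, I_K + Σ xi_i xi_iᵀ)`;
- `sigma_k`: univariate slice sampling (stepping-out + shrinkage) on
  `log sigma_k`, the only non-standard conditional;
- missing age/weight: Gaussian; missing disease status: a Bernoulli draw
  from the two-component conditional.

`sigma` and `zeta` are floored at 1e-6 to avoid singular scales.  All
randomness flows from one `SeedSequence`, so a given seed reproduces draws
exactly.  Default schedule: 3 chains × 3000 iterations, 1000 burn-in,
thin 2 — deliberately desk-scale; heavier schedules are a setting, not a
code change.

### Convergence monitoring

Split-R̂ (each chain halved, classic between/within variance ratio) is
computed for the **identified** parameters: `mu`, the three coefficient
vectors, `sigma`, `omega`, and the entries of `Omega`.  On panels with near-empty
miRNAs (≳ 95% missing wells) the slowest-mixing quantities are precisely
the covariance entries linking those miRNAs to the rest: they are
prior-dominated and weakly identified, and at desk-scale schedules their
split-R̂ can hover around 1.2 while every well-measured quantity has long
converged — a diagnostic worth reading per-parameter rather than as a
single worst-case number.  The expansion
factors `zeta` and `Q` are excluded on purpose: only their product
`diag(zeta) Q diag(zeta)` is interpretable, and the factors random-walk
along the unidentified direction, so their individual R̂ stays high long
after every estimable quantity has converged.  A fit whose worst monitored
R̂ is ≥ 1.2 is returned with an explicit non-converged flag, never
silently.  Constant chains yield R̂ = 1 (trivially converged); chains
constant at different values yield infinity.

## Derived quantities

All derived quantities are computed per posterior draw, then summarized by
5/25/50/75/95 percentiles (linear, type-7 interpolation — stated here
because percentile conventions differ across software).  A quantity is
flagged "credible" when its equal-tailed 90% interval excludes the
reference (1 for fold changes, 0 for effect sizes); the flag's α is
configurable.  Fold changes are exponentiated per draw — never the
exponential of a summarized coefficient — so the interval is the image of
the coefficient interval.

`d_k = b_dis_k / sqrt(omega_k² + sigma_k²)` expresses the disease shift on
the scale of total single-well variability; it is exactly invariant under
common rescaling of its three inputs.  `|d| > 1.5` roughly corresponds to
nearly separated group distributions.

## Classification and cross-validated AUC

Under the model, a subject's single-replicate profile on subset `j` is
`MVN(mu_j, Sigma_j)` (control) or `MVN(mu_j + b_dis_j, Sigma_j)` (case)
with `Sigma = Omega + diag(sigma²)`.  Bayes' rule with prior odds 0.333
(the printed constant, close to the cohort's case/total ratio 59/178;
configurable — case/control odds would be ≈ 0.496) gives

    logit(p) = log(0.333) − ½ (2 mu + b)ᵀ Sigma⁻¹ b + yᵀ Sigma⁻¹ b

Age and weight coefficients are deliberately absent from the rule.  Missing
miRNAs within the subset are marginalized out of the Gaussian — the unique
coherent treatment under the model.  Scoring uses replicate 1 by default
(replicate 2 or the replicate mean are options).

10-fold cross-validation refits the full hierarchical model without each
held-out fold (stratified by disease by default, which prevents
single-class folds at small n; a plain random split is available).  Each
retained posterior draw of the training fit scores the held-out subjects;
probabilities pooled across folds give one Mann–Whitney AUC per draw
(ties counted ½), hence a posterior AUC distribution rather than a point
estimate.  Subjects with unknown disease status are never scored (an AUC
needs labels) but keep informing every training fit.

## Frequentist arm

Per-miRNA Welch t-tests on per-subject replicate means, complete cases
only.  The test choice is a documented convention (a permutation oracle in
the tests bounds its error); Benjamini–Hochberg adjustment uses m = K (the
panel size) even when some miRNAs were untestable, and significance is a
strict `p_adj < α` comparison.  The raw-data effect `d_fdr` is Cohen's d
with pooled SD on the same per-subject means.  Because averaging two
replicates halves the assay variance, `d_fdr` converges to
`b / sqrt(omega² + sigma²/2)` — systematically larger in magnitude than the
model's `d` whenever `sigma > 0`; the suite asserts this relationship
numerically.

## Diagnostics

Weighted residuals are conditional: `(y − fitted)/sigma` with the fitted
value the posterior mean of the full linear predictor *including* `eta`.
Conditioning on the posterior-mean subject effect absorbs part of the assay
noise, so these residuals are slightly under-dispersed relative to a unit
normal (SD ≈ 0.8 with two replicates) — the tests therefore check a SD band
of [0.7, 1.3] and an upper bound on the |r| > 2 tail rather than an exact
normal tail fraction.  Marginal residuals would instead be over-dispersed
by `sqrt(omega² + sigma²)/sigma`.

## Synthetic data

The generator draws the design exactly as the model assumes: disease
Bernoulli(0.33), standardized covariates, subject effects MVN(0, Omega),
two independent replicates, then a missingness mask.  Default masking is
MCAR with per-miRNA rates (matching the model's ignorability assumption);
an MNAR mode that censors levels below a threshold emulates a detection
limit and exists purely as a stress test.  Covariate masking defaults —
disease 0.6%, age 2.2%, weight 36.5% — mirror a realistic plasma-panel
cohort, as does the `panel-k49` fixture: 49 miRNAs × 178 subjects,
three strong, almost collinear markers (pairwise correlation ≈ 0.96), a
missingness profile spanning 0–99%, and nominal raw-scale constants
(mean 4.03, SD 1.93) attached for back-transformation.

Realistic parameter scales are derived from the relationships a globally
standardized panel must satisfy rather than guessed independently: a marker
with fold change ≈ 2.2 at raw SD 1.93 has `beta ≈ 0.42` standardized units,
and for such a marker to show a raw-data effect size ≈ 0.6 the per-subject
total SD must be ≈ 0.66 — hence `omega ~ U(0.45, 0.70)` and
`sigma ~ U(0.35, 0.60)`, with the `mu_k` spread (SD 0.6) restoring pooled
variance ≈ 1.  What the generator does **not** emulate: plate/batch
effects, amplification-efficiency differences, non-normal tails, and
informative missingness beyond the threshold mode.  Passing tests
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to those real-data violations.

## Problem sizes and numerical choices in the test suite

The suite runs at desk scale by choice: recovery studies use K = 5,
I = 300, 20 replications with 2 chains × 1100 iterations (coverage of 90%
intervals ≥ 70%, worst split-R̂ < 1.2); the null study uses K = 3–20 with
a 10-fold CV at 2 × 500 iterations; prior-recovery uses an empty dataset
and 10,000 retained draws (moments within 5%).  Truths for the recovery
study fix the variance components at realistic panel scale while drawing
`beta_dis` from its N(0,1) prior — full prior draws of the heavy-tailed
covariance prior routinely produce degenerate panels that no desk-scale
chain schedule can traverse, without adding information about the sampler's
correctness.  Closed-form identities (discriminant vs. density-ratio Bayes
rule, covariance reconstruction, BH step-up, Mann–Whitney AUC, joint
density) are checked against independently coded brute-force oracles at
1e-10 or exactly.

## Known limitations

- No qPCR efficiency correction and no endogenous-control normalization;
  the global standardization presumes comparable assay behavior across the
  panel.
- The Gibbs sampler updates one block at a time; for panels far larger than
  K ≈ 50 a gradient-based sampler would mix faster per second.
- The discriminant assumes the model's Gaussian equal-covariance classes;
  it is not a general-purpose classifier.
- Cross-validation refits at scaled-down chain schedules; AUC intervals
  inherit that Monte-Carlo noise.
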