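# Methods

## The synthetic cohort: a stated world

The generator emulates a cross-sectional study of 137 normoglycemic adults in
three groups — G1 lean (BMI < 25, n = 82), G2 obese (BMI > 30, n = 24), G3
obese with ultrasound-diagnosed NAFLD (n = 31). Its calibration
(`src/metabosem/data/default_config.yaml`) encodes the study's printed
descriptive tables: per-group means with 95% CIs for anthropometrics, OGTT
glucose, lipids, liver enzymes, CRP/IL-6/TNFα and the 31-analyte metabolite
panel, and per-group family-history counts.

**CI → SD.** A mean's 95% CI at group size n implies
`sd = √n·(hi − lo)/(2·1.96)`. Printed CIs that are asymmetric about their
mean are treated as back-transformed from log10 (the original analysis
log-normalized skewed variables and recovered values by antilogarithm); the
conversion is then done on log10 endpoints and the variable is generated
log-normally with the printed mean as geometric mean. A variable is
log-scale if *any* group's CI is asymmetric beyond 10% of its width —
deciding from one group alone misclassifies high-CV markers such as IL-6
(G2 CV ≈ 1.8), whose truncated-normal simulation would bias group means.
Arithmetic-scale positive variables are floored at 1% of the group mean;
with the calibrated mean/SD ratios this clips < 2% of draws for the worst
rows and shifts group means by ≪ 1 SE.

**Printed-table corrections.** The extracted tables carry obvious
typographical defects which the calibration repairs: TNFα G2 mean 75 → 0.75
pg/dl; HDL G3 mean 49 → 39 mg/dl (the printed CI (36, 42) and the
homogeneous-group letters require G3 lowest); C12 G1 mean 0.38 → 0.038 μM;
C6 G1 CI upper 0.173 → 0.0173; garbled CIs for C10:1 G2, C10:2 G1 and C18OH
G1 replaced by the nearest plausible reading. Where a printed CI fails to
bracket its mean (%FAT G3, phenylalanine G2, C10), the loader mechanically
recentres the printed width on the mean. Two amino-acid cells printed as
mean (SD) rather than mean (CI) are taken as SDs directly.

**OGTT insulin.** The insulin series is not printed. Per-group basal
medians (8.9/10.9/15.7 μU/ml), a fixed (1, 6, 5, 4, 3) within-test profile
and a log10-SD of 0.28 were derived once so that the implied geometric-mean
Matsuda index and its dispersion reproduce the printed Matsuda row
(6.1/4.8/3.1 with its CIs). Glucose and insulin time points are
equicorrelated at ρ = 0.6 within each series, a typical OGTT autocorrelation.

**Metabolite block structure.** The 31 metabolites are drawn from a joint
correlation matrix with ρ = 0.6 inside each factor block (AA1, AA2, AC1–AC4,
memberships as in the study's factor column) and ρ = 0.1 between blocks —
within-class acylcarnitine correlations of 0.4–0.8 are typical of targeted
panels, and this choice leaves the four acylcarnitine population eigenvalues
(7.2, 2.8, 2.0, 1.5) above the parallel-analysis threshold at n ≈ 1000.

**Exact counts.** Family-history flags are assigned by sampling *which*
subjects carry each flag, with per-group counts fixed: mother 14/13/5,
father 13/6/5 (the printed per-group values are internally inconsistent with
their total of 24; the total is preserved), indirect 30/10/14, and overlaps
chosen so the printed direct (23/14/9) and any-FHO (38/14/20) margins also
reproduce exactly. Diabetes family history is a single overall fraction
(0.66) apportioned across groups by largest remainder. Sex counts are exact
per group. One global seed feeds stable per-variable substreams
(`default_rng([seed, crc32(name)])`), so adding a variable never perturbs
another variable's draws.

**What the generator does not emulate.** Assay noise mechanisms, batch
effects, non-normal marginal shapes beyond log-normality, longitudinal
structure, and — deliberately — any built-in family-history → metabolite or
family-history → obesity effect. Green tests therefore establish that the
pipeline's statistics behave correctly on data with the study's marginal and
correlation structure, not that the study's substantive effects are
recoverable from real data.

## Group contrasts

ANOVA runs on log10 values for variables flagged skewed; group summaries are
back-transformed. Fisher LSD means unadjusted pairwise t tests on the pooled
ANOVA MSE with its df. Homogeneous-group letters follow the descriptive-table
convention: groups sorted by decreasing mean, 'a' on the largest, maximal
runs of mutually non-different (p ≥ α) groups share a letter. Pearson
chi-square is used without continuity correction — this reproduces the
printed direct-family-history p = 0.02 from its own counts. BH-FDR is
computed over all rows below the anthropometric block, matching the table's
NA entries; the printed FDR column itself is internally inconsistent and is
recomputed, not force-matched. The Matsuda index uses the composite 5-point
form with arithmetic means over 0–120 min.

## Factor analysis

Principal-axis factoring on the correlation matrix, starting communalities
from squared multiple correlations, iterated to 1e-6. Communalities are
hard-capped at 0.999 (a Heywood flag is raised when the cap binds), the
update is averaged with the previous iterate whenever the step size stops
shrinking (this kills the period-2 cycles the cap can induce), and up to
5000 iterations are allowed: a 2-indicator block such as AC4 is weakly
identified and its communality converges linearly at rate ≈ 0.995, needing
~1700 iterations of ~50 µs each. Varimax rotation;
factors sign-oriented to positive loading sums; assignment by maximum
|loading| with ties to the lower factor index. Extraction, rotation and
retention rule are unstated in the source analysis and pinned here for
reproducibility; when replicating the published pipeline the factor counts
are fixed at 4 (acylcarnitines) and 2 (amino acids), with parallel analysis
(95th percentile of eigenvalues from 100 null datasets) available for de-novo
use.

## PLS-DA

Predictors are autoscaled and classes one-hot coded; components come from
NIPALS-with-deflation PLS2 (scikit-learn's `PLSRegression` provides the
core regression). R² is computed on the full fit; Q² = 1 − PRESS/SS_tot and
classification accuracy (argmax of predicted indicators) from stratified
K-fold CV — 10-fold by default, 8-fold in the packaged pipeline so the
smallest group (24) spreads across folds. The permutation test shuffles
labels only and reports `(1 + #{perm ≥ obs})/(n_perm + 1)` with CV accuracy
as the default statistic; the original analysis ran 1000 permutations, which
is the pipeline default. VIP weights squared normalized weights by the
Y-variance each component explains, so mean(VIP²) = 1 identically.

## SEM engine

RAM parameterization over observed + latent variables: Σ(θ) =
F(I−A)⁻¹S(I−A)⁻ᵀFᵀ. Identification defaults to fixing each latent's first
indicator loading at 1; fixing latent variances at 1 and a fully-free "none"
mode (for data generation) are available. The parser rejects cyclic directed
graphs and duplicate scale fixing.

Fitting minimizes F_ML with analytic gradients
(dF/dS = BᵀFᵀCFB, dF/dA = 2BᵀFᵀCFBSBᵀ, C = Σ⁻¹ − Σ⁻¹SΣ⁻¹): one BFGS pass
(max 500 iterations, gtol 1e-6), then damped Fisher scoring
(Levenberg–Marquardt on the expected information) to polish. Start values:
loadings 1, paths 0, observed residual variances at half the sample
variance, latent variances at 5% of the mean observed variance. On
near-singular problems — Heywood-boundary or collinear-factor solutions, as
the large full models routinely produce at n = 137 — the gradient cannot
reach gtol along statistically unidentified directions; a fit is then
declared converged when the attainable χ² improvement in quadratic
approximation, (n−1)/2·gᵀI⁺g, is below 0.05, i.e. flat far beneath sampling
noise. Negative variance estimates are flagged, never constrained;
standardized estimates touching a non-positive implied variance are reported
as NaN with a warning rather than aborting the fit.

χ² = (n−1)·F_ML at the minimum; SEs from the inverse expected information
(2/(n−1))·[tr(Σ⁻¹Δ_jΣ⁻¹Δ_k)]⁻¹; standardized β = b·sd(source)/sd(target)
using model-implied SDs, with |β| > 0.2 flagged as relevant. RMSEA CI bounds
invert the noncentral χ² CDF by bracketing + Brent root finding. Modification
indices are univariate score tests u_c²/(I_cc − I_cf I_ff⁻¹ I_fc) over
cross-loadings, absent latent-to-latent paths and absent residual
covariances; candidates with singular conditional information are NaN with a
warning.

Binary family-history and ultrasound indicators enter as numeric 0/1 columns
under normal-theory ML — faithful to the original analysis, with the usual
caveat that their loadings are attenuated relative to a threshold model. The
pipeline's SEM stage log10-transforms log-generated variables and z-scores
every column first; under fix-first-loading identification the standardized
solution is invariant to this rescaling, and it is numerically essential
given metabolite scales spanning five orders of magnitude. Raw-data input
uses listwise deletion.

## Model catalog

The three shipped models reconstruct the published diagrams conservatively:
arrows named in the text or legends are included, others are not. CRP is kept
as a standalone observed outcome of Obesity and NAFLD (the study's table
lists CRP as its own factor; the figure legends list it separately from
INFL). In the family-history-first model, obesity is endogenous
(FHOB + AA1 + AA2 → Obesity), expressing that hypothesis's premise that
obesity follows the metabolite disruption. Where the text quotes two
coefficients for three amino-acid → acylcarnitine paths, only the
unambiguous path–value pairs enter the reference-β table.

Recovery sub-models fix all loadings at 0.8 standardized with unit exogenous
latent variance, so the single structural path *is* its standardized value by
construction; `run_recovery` simulates at n = 137, refits under
fix-first-loading, and compares the mean recovered standardized path with the
generating value (0.32 for family history → obesity, 0.37 for obesity → AA1).

## Power simulation

Skewed draws Beta(α = 1, β = 7) scaled to a (min, max) range; the treated
group is shifted by 20% of the control population mean (the simplest reading
of "at least 20% difference"); two-sided two-sample t test at α = 0.05;
power = rejection fraction with its Monte-Carlo SE. The default range (0, 1)
is a placeholder scale — power depends only on the shift/SD ratio, which the
Beta shape fixes.

## Numerical choices and limitations

- Zero-width CIs yield SD 0 (constant variable) rather than an error;
  reversed CIs are rejected.
- The ×4-insulin scaling law divides the Matsuda index by 4 (insulin enters
  the product twice); tests assert the formula's own algebra.
- Parallel analysis at n = 137 cannot resolve the 2-member AC4 block (its
  population eigenvalue 1.5 sits below the Marchenko–Pastur edge at p = 20);
  factor-count recovery checks therefore run at n ≈ 1000, scaling group
  sizes 7.3× with the marginal SDs frozen at their original-n values.
- Letter assignment is deterministic but the G1/G2 Matsuda homogeneity at
  n = 137 is intrinsically marginal (t ≈ 1.8 in the calibrated population);
  the test asserts the pattern's frequency over seeds, not a single draw.
- The full models' RMSEA on synthetic data (~0.05–0.06) is not expected to
  match values fitted to the undeposited real data; no test asserts it.
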