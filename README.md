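# metabosem

Reusable analysis pipeline for a three-group obesity/NAFLD cohort design with
targeted metabolomics (20 acylcarnitines, 11 amino acids), inflammatory
markers and OGTT-derived insulin sensitivity — the kind of study that asks
whether family history of obesity drives the metabolite profile directly, or
acts through the obesity phenotype.

Because subject-level data for such studies are rarely deposited, the package
is driven by a **calibrated synthetic-cohort generator**: a three-group cohort
(lean G1, obese G2, obese+NAFLD G3; n = 82/24/31) whose per-group means, 95%
CIs, family-history counts and metabolite factor-block correlation structure
are encoded in a packaged YAML calibration. On top of it sit the four analysis
stages used in this field:

1. **Group contrasts** (`metabosem.group_stats`) — one-way ANOVA on log10
   scale where skewed, Fisher-LSD homogeneous-group letters, Pearson
   chi-square for categorical rows, Benjamini–Hochberg FDR over the
   metabolic/inflammatory family, and the composite (Matsuda) insulin
   sensitivity index `10000 / √(G₀·I₀·Ḡ·Ī)`.
2. **Exploratory factor analysis** (`metabosem.factors`) — principal-axis
   extraction with iterated communalities, varimax rotation, factor counts by
   Horn's parallel analysis or the Kaiser rule; recovers the AA1/AA2 and
   AC1–AC4 metabolite blocks.
3. **PLS-DA** (`metabosem.plsda`) — R², cross-validated Q² and accuracy,
   VIP scores `VIP_j = √(p·Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)`, and a
   label-permutation test.
4. **Structural equation models** (`metabosem.sem`) — a from-scratch
   covariance-structure engine: plain-text model syntax, RAM parameterization
   `Σ(θ) = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ`, maximum-likelihood fitting of
   `F_ML = ln|Σ| − ln|S| + tr(SΣ⁻¹) − p` with analytic gradients and a damped
   Fisher-scoring polish, expected-information standard errors, standardized
   β with a |β| > 0.2 relevance flag, RMSEA `√(max(χ²−df,0)/(df(n−1)))` with
   noncentral-χ² confidence limits, and score-test modification indices.

`metabosem.models` ships three competing structural hypotheses as plain-text
model files (obesity-first; family-history-first; family history → obesity →
metabolites) plus small fully-parameterised sub-models for parameter-recovery
simulation. `metabosem.pipeline` orchestrates everything and adds the
a-priori Monte-Carlo power simulation on Beta(1, 7)-skewed data.

## Worked example

```python
from metabosem import CohortConfig, generate_cohort, fit_ml, parse_model, models
from metabosem.pipeline import sem_analysis_matrix

config = CohortConfig.default()          # packaged 137-subject calibration
cohort = generate_cohort(config, seed=1) # 82/24/31 in groups G1/G2/G3

spec = models.model2_spec()              # family-history-first hypothesis
data = sem_analysis_matrix(cohort, config, list(spec.observed_vars))
fit = fit_ml(spec, data)
print(fit.chi2, fit.df, fit.rmsea, fit.standardized["Obesity~FHOB"])
```

At seed 1 this prints a converged fit with χ² ≈ 1244 on df = 876,
RMSEA 0.056 (90% CI 0.048, 0.062) and a standardized family-history → obesity
path of 0.10 — i.e. on synthetic data generated *without* a built-in
family-history effect, the model correctly finds little signal there while
fitting the measurement structure well.

Parameter recovery closes the loop: simulating the two-latent
family-history → obesity sub-model at n = 137 with standardized path 0.32 and
refitting 200 times gives a mean recovered path of 0.327 (SD 0.094); the
obesity → amino-acid sub-model generated at 0.37 recovers 0.367 (SD 0.084).

The same pipeline is available from the shell:

```bash
metabosem run --seed 1 --out out/            # full pipeline, all artifacts
metabosem sem --model model2 --seed 1 --out fit.json
metabosem power --seed 1 --out power.tsv
```

The power verb reproduces the a-priori design calculation: with a 20% shift
of the control mean on Beta(1, 7)-skewed data, power rises from 0.16 at
n = 20 per group to 0.51 at n = 137.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates the default synthetic cohort at the given seed and runs the full
pipeline end to end (contrasts → EFA → PLS-DA with permutation test → the
three SEM fits with RMSEA and modification indices → power simulation),
writing all stage artifacts under `scratch/acceptance_run/` and the results
JSON to `--out`.
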