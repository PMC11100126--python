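# Methods

This note records the models, defaults and numerical choices behind
`prseval`, and what its synthetic experiments do and do not demonstrate.

## Metrics

All three R² definitions are implemented exactly as the sums that define
them (no variance shortcuts), so sample-vs-population variance conventions
cannot change a result and the algebraic identities hold to machine
precision:

* `r² = [Σ(y_i−ȳ)(ŷ_i−ȳ̂)]² / [Σ(y_i−ȳ)² Σ(ŷ_i−ȳ̂)²]`;
* `R²_{1-A} = 1 − Σ(y_i−ŷ_i)² / Σ(y_i−ȳ_train)²`;
* `R²_{1-B} = 1 − Σ(y_i−ŷ_i)² / Σ(y_i−ȳ_test)²`;
* `MSPE = (1/n) Σ(y_i−ŷ_i)²`.

The identity `Σ(y−ȳ_train)² = Σ(y−ȳ_test)² + n(ȳ_test−ȳ_train)²` gives
`R²_{1-A} ≥ R²_{1-B}` with equality iff the two reference means coincide; a
larger train/test mean gap widens the spread between them while leaving the
residuals — and hence the MSPE — untouched.

`mae` is the **median** absolute prediction error, the robust companion
statistic to the MSPE (not the mean absolute error).

Degenerate inputs raise typed errors instead of returning NaN or 0:
zero-variance observed or predicted vectors make the correlation undefined;
a constant observed vector at the reference mean makes the MSPE-based
denominators vanish; a missing training mean makes `R²_{1-A}` *absent* (with
a machine-readable reason), never zero. Silent zeros would corrupt method
rankings, the metrics' central use.

Uncertainty is quantified by a paired case-resampling bootstrap (individual
(y, ŷ) pairs resampled with replacement, percentile intervals, default level
0.95, mandatory explicit seed). This is the simplest defensible choice; no
asymptotic approximations are attempted. Replicates on which a metric is
undefined are dropped; if more than half fail, the interval is refused with
the reason. One consequence worth knowing: a percentile interval for `r²`
can never contain 0 (every bootstrap replicate of a squared quantity is
positive), so coverage checks against a zero-correlation truth must use the
signed correlation `r`, which is also reported.

## Synthetic cohorts

The generator emulates the structure a cross-ancestry PRS evaluation needs:
one large homogeneous training population and several smaller diverged
targets, a heritable continuous trait, sex and age covariates, missing
genotypes.

* **Divergence.** Population-specific allele frequencies follow the
  Balding–Nichols model: `p_pop ~ Beta(p(1−F)/F, (1−p)(1−F)/F)` with mean
  `p` and variance `F p(1−p)`, where `F` is the population's F_ST from the
  ancestral pool (ancestral frequencies uniform on the configured range,
  default 0.05–0.5). Genotypes are binomial(2, p_pop): Hardy–Weinberg,
  linkage equilibrium. LD is deliberately absent — it is irrelevant to how
  the three R² definitions relate to each other, which is what this package
  studies.
* **Architecture.** A fraction `causal_fraction` of variants is causal.
  Each causal variant carries an equal share `h²/n_causal` of the trait
  variance in the training population (magnitude set by its allele
  frequency, random sign). This makes "causal" synonymous with "carrying
  signal": an oligogenic trait (`causal_fraction` near 0) is a few sizeable
  effects, a polygenic one spreads the same heritability thinly. A draw with
  unbounded mass near zero would instead label effectively-null variants
  causal, which makes notions like causal-variant recall meaningless. None
  of the metric phenomena depend on this choice — they flow through
  aggregate genetic values.
* **Portability degradation**, two separate mechanisms:
  1. target-population causal effects are `ρ β_train + √(1−ρ²) ε` with
     `ε ~ N(0, sd(β_train))` — imperfect effect correlation `ρ` attenuates
     *discrimination* (r²), not just calibration;
  2. an additive environmental offset `env_shift` (in ≈ trait SD units,
     since genetic + noise variance is normalised to 1) that no
     genotype-based model can see — pure *miscalibration*, the driver of
     negative MSPE-based R².
  Allele-frequency divergence additionally shifts the genetic mean between
  populations by `2 Σ_j β_j (p_pop,j − p_train,j)`, computable in closed
  form from the retained truth (`true_betas`, `population_frequencies`).
* **Covariates.** Sex ~ Bernoulli(0.5) (effect 0.3 trait units by default),
  age uniform on 40–69 years (effect 0.01/year, centred at 54.5), matching
  a middle-aged cohort recruitment window.
* **Noise.** Gaussian with variance `1 − h²`, so the genetic fraction of
  genetic-plus-noise variance in the training population equals `h²`
  exactly.
* **Default desk scale:** 2,000 training individuals, 500 per target
  population, 5,000 variants, 2% missing genotypes. These sizes keep a full
  study to a few seconds while leaving all the qualitative phenomena
  clearly visible; nothing in the implementation is tied to them.

What passing tests on these cohorts do **not** show: behaviour under LD
(weight selection, pruning and PC structure are all easier in linkage
equilibrium), under continuous/admixed ancestry gradients (populations here
are discrete clusters), or at biobank scale. The metric algebra is
scale-free; the trainers' absolute accuracies are not.

## PRS trainers and scoring

The trainers are transparent stand-ins, not reimplementations of production
PRS methods — the package's subject is the *evaluation* of scores, and it
needs at least two competing methods with realistic out-of-target
miscalibration:

* **Pruning + thresholding (`pt`).** Marginal GWAS (vectorised OLS per
  variant via partialling-out of the covariates, exact t-tests), then greedy
  pruning in (p-value, variant id) order removing variants whose squared
  dosage correlation with a kept variant exceeds `r2_prune` (default 0.5),
  then a p-value cutoff chosen from a grid (default 1e-5 … 0.1) to minimise
  validation-set MSPE. Ties prefer the smaller p (pruning) and the smaller
  cutoff (selection), making the trainer fully deterministic. The grid tops
  out at 0.1 rather than 1.0 so pruning operates on the associated slice;
  permissive settings (`r2_prune = 1`, grid `{1.0}`) remain available.
* **Ridge (`ridge`).** Closed-form ridge on standardised dosages via one
  SVD, penalty selected by validation MSPE, weights mapped back to
  per-allele scale. A rank-deficient design at penalty 0 is reported as
  singular rather than silently pseudo-inverted.

Model selection uses the validation MSPE of a univariate
`phenotype ~ PRS` calibration fitted on the training split — consistent
with the fact that MSPE-based and R²-based selection order candidate models
identically on shared data.

**Scoring** follows `plink --score` semantics exactly: score =
Σ weight × effect-allele dosage; a variant stored with the opposite allele
orientation contributes `2 − dosage`; a missing dosage is replaced by twice
the effect-allele frequency *of the scored cohort*; an allele matching
neither stored allele is an error.

**Final model.** As in standard practice, the deployable predictor is an
OLS regression of the phenotype on PRS, sex, age and the first ten genotype
PCs, fitted on the combined training + validation data. The
training-phenotype mean is stored on the model because `R²_{1-A}` needs it
at evaluation time. Genotype PCs come from a truncated SVD of the
frequency-standardised training dosage matrix (missing → mean, component
signs fixed deterministically); target-population individuals are
*projected* onto the training basis — nothing is ever refitted on test
data. Whether the GWAS itself adjusts for PCs is a configuration switch
(`gwas_covariates`), defaulting to no adjustment; neither mode is claimed
to be canonical.

Variant QC keeps variants with call rate and minor allele frequency at or
above the thresholds (defaults 0.90 / 0.001; a stringent 0.99 / 0.01
setting mirrors a typical sensitivity analysis), computed on the training
individuals, with per-variant removal reasons reported.

## Ancestry assignment

Cluster centers are geometric medians (the point minimising summed
Euclidean distances) of labelled reference individuals in PC space,
computed by Weiszfeld iteration (tolerance 1e-8, max 1,000 iterations) with
the Vardi–Zhang step for iterates landing on a data point. Individuals are
assigned to the nearest center by Euclidean distance; exact ties break by
cluster-name order with a warning; an optional cutoff labels remote
individuals `unassigned`. The number of PCs used for assignment is a
parameter (the pipeline's diagnostic uses 4).

In the pipeline, the regression covariates use training-only PCs with
projection (above), but the optional ancestry-reassignment diagnostic uses
a *global* PCA over all individuals: a PCA of a single homogeneous training
population captures within-population noise directions and need not
separate target clusters, whereas reference-panel assignment in practice
operates in a global PC space.

## Pipeline conventions

* Residuals are `observed − predicted` throughout.
* Calibration slope and intercept are the OLS coefficients of observed
  regressed on predicted within each population (slope 1 / intercept 0 =
  perfect calibration); the reverse orientation is intentionally not
  offered.
* The training-population split is 50/25/25% into training, validation and
  test; target populations are evaluated in their entirety and never touch
  training or selection.
* Rankings are computed per population under `r²`, `R²_{1-A}`, `R²_{1-B}`
  and MSPE; a conflict flag marks populations where the `r²` order differs
  from the `R²_{1-B}` order. Report files state which definition each
  number refers to — reporting an unlabelled "R²" on test data is exactly
  the practice this package exists to discourage.
* One top-level seed drives simulation, splits and the PC solver and is
  logged in every report.

## Limitations

* Only the three stated definitions are implemented; other test-data R²
  variants exist and are deliberately out of scope, as are binary-trait
  metrics (AUC, Brier score) and heritability-scale transformations.
* No recalibration product is shipped; the affine-recalibration identity is
  verified in the test suite, but correcting a miscalibrated score is left
  to the analyst.
* The stand-in trainers' out-of-sample calibration slopes shrink below 1 at
  small sample sizes (winner's-curse inflation of selected weights); this
  is a property of simple trainers, visible in the diagnostics, and does
  not affect the metric algebra.
* Population clusters are a simplification; real genetic structure is
  continuous, and portability degrades along gradients the generator does
  not model.
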