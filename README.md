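# prseval

**Which "R²" did you mean?** When a polygenic score (PRS) for a continuous
trait is trained on one population and evaluated on a test set — especially a
test population with a different genetic ancestry — the reported "R²" can be
any of three different quantities, and they can disagree dramatically.
`prseval` implements the three definitions, the algebra connecting them, and
a fully synthetic multi-ancestry study pipeline for exploring when and why
they diverge. It is aimed at statistical geneticists and biostatisticians
evaluating PRS portability.

## The three definitions

For observed test phenotypes `y_1..y_n` with mean `ȳ_test`, predictions
`ŷ_1..ŷ_n`, and training-phenotype mean `ȳ_train`:

* **Squared correlation**
  `r² = [Σ(y_i−ȳ)(ŷ_i−ȳ̂)]² / [Σ(y_i−ȳ)² Σ(ŷ_i−ȳ̂)²]` — discrimination
  only; invariant to any affine recalibration of `ŷ`; always in [0, 1].
* **Training-referenced** `R²_{1-A} = 1 − Σ(y_i−ŷ_i)² / Σ(y_i−ȳ_train)²` —
  prediction error relative to the intercept model fitted on the *training*
  data; needs `ȳ_train`; unbounded below.
* **Test-referenced** `R²_{1-B} = 1 − Σ(y_i−ŷ_i)² / Σ(y_i−ȳ_test)²` —
  prediction error relative to the intercept model on the *test* data;
  unbounded below.

Key facts the package encodes and tests:

* `R²_{1-A} ≥ R²_{1-B}` always, with equality iff `ȳ_train = ȳ_test`;
* on an OLS fit's own training data all three equal the classical
  coefficient of determination;
* least-squares recalibration of `ŷ` on the test set turns `R²_{1-B}` into
  `r²` exactly;
* a constant prediction bias `c` leaves `r²` untouched but lowers `R²_{1-B}`
  by `(n c² − 2c Σ(y_i−ŷ_i)) / Σ(y_i−ȳ_test)²` — a bias of two phenotype SDs
  forces `R²_{1-B} < 0`;
* rankings of methods trained on the same data by `R²_{1-A}`, `R²_{1-B}` and
  the MSPE always coincide (both R²s are rescaled MSPEs); the `r²` ranking
  can conflict with them.

A negative MSPE-based R² is a signal, not a bug: the model predicts worse
than a constant at the reference mean — the signature of a miscalibrated
score on an out-of-target population.

## What's in the box

| module | contents |
| --- | --- |
| `prseval.metrics` | the three R² definitions, MSPE, median absolute error, percentile-bootstrap CIs; degenerate inputs raise explicit errors |
| `prseval.synth` | Balding–Nichols multi-population cohort generator (F_ST divergence, cross-population effect correlation, environmental shifts, sex/age covariates, missingness) |
| `prseval.prs` | variant QC filters, marginal GWAS, pruning+thresholding and ridge stand-in trainers, `plink --score` scoring semantics, genotype PCs, and the final PRS+sex+age+10 PC regression as a statsmodels-style `PolygenicModel`/`PolygenicResults` pair |
| `prseval.ancestry` | Weiszfeld geometric medians and nearest-center cluster assignment in PC space |
| `prseval.pipeline` | study orchestration, per-population metric tables, calibration diagnostics, method rankings with conflict flags, TSV/plot reports |

A thin CLI (`prseval evaluate/simulate/train/predict/assign/run`) wraps the
same functions.

## Worked example

```python
from prseval.pipeline import default_scenario, run_study

study = run_study(default_scenario(seed=1))
cols = ["population", "method", "r_squared", "r2_1a", "r2_1b", "mspe"]
print(study.metrics_frame()[cols].round(3).to_string(index=False))
```

prints (pt = pruning+thresholding):

```
 population method  r_squared  r2_1a  r2_1b  mspe
  train_pop     pt      0.157  0.151  0.148 0.899
  train_pop  ridge      0.050  0.038  0.035 1.019
target_near     pt      0.221  0.214  0.122 0.896
target_near  ridge      0.045  0.011 -0.105 1.128
 target_mid     pt      0.140  0.087 -0.717 1.489
 target_mid  ridge      0.040 -0.163 -1.186 1.896
 target_far     pt      0.175 -0.013 -2.093 2.978
 target_far  ridge      0.051 -0.079 -2.296 3.173
```

On the in-target test set the three definitions agree to the second decimal.
On the diverged target populations the squared correlation stays positive —
the score still *ranks* individuals — while the test-referenced `R²_{1-B}`
goes negative: the shifted, miscalibrated predictions are worse than a
constant at the test mean. Note `target_mid`/pt: the training-referenced
`R²_{1-A}` (0.087) is still positive while `R²_{1-B}` (−0.717) is strongly
negative — the two MSPE-based definitions answer different questions when
the population means differ. `study.get("target_mid", "pt").calibration_intercept`
(≈ −0.96 here) quantifies the bias, and `study.report(out_dir)` writes the
metric/ranking/residual tables and observed-vs-predicted diagnostics.

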