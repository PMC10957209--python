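# mimicsem

Lasso-regularized MIMIC structural equation models for asking how much of
the variance in a latent outcome is explained by competing sets of many
correlated predictors — and how much of that information the sets share.

The package grew out of a question in developmental cognitive
neuroscience: do gray-matter morphometry (cortical thickness CT, surface
area SA, volume GMV over cortical regions) and white-matter structure
(fractional anisotropy FA, mean diffusivity MD, tract volume WMV over
tracts) carry *redundant*, *independent*, or *partially overlapping*
information about a child's cognitive performance? It is written for
researchers who have region-by-metric feature tables and a multi-task
cognitive battery, and who want latent-variable modeling (to suppress
measurement error) combined with sparse selection (to survive a hundred
and more collinear predictors).

## The model

Five task scores y₁…y₅ measure one latent factor η; p brain features x
predict it:

    y_k = ν_k + λ_k η + ε_k          (measurement, λ₁ = 1 fixed)
    η   = Σ_j γ_j x_j + ζ            (structural paths γ)

Estimation is full-information maximum likelihood (missing task scores
handled row-wise, no deletion), with Huber–White sandwich standard
errors. Regularized fits minimize `F_ML + λ_pen Σ|γ_j|`, pushing small or
redundant paths to *exactly* zero via coordinate-wise soft-thresholding;
the penalty weight is chosen by BIC over a warm-started path. A 15%
model-building sample drives selection; the surviving predictors define
unpenalized models refitted on the held-out 85%, whose adjusted R² and
likelihood-ratio tests settle the variance partition:

* redundant — R²(joint) ≈ max(R²(gray), R²(white))
* independent — R²(joint) ≈ R²(gray) + R²(white)
* partially overlapping — strictly between.

Repeating the selection over many random subsamples yields per-region
*survival percentages*, a stability map of which regions contribute
distinct information. Because real consortium data are access-controlled,
the package ships a synthetic generator with matched structure (block-
correlated features, GMV composed from CT and SA, MCAR missingness,
archived latent ground truth) and a closed-form population-R² oracle that
every estimator is tested against.

## Worked example

```python
import mimicsem as ms

cfg = ms.partial_overlap_config(n_participants=12000, seed=4)
ds = ms.generate_dataset(cfg)
report = ms.run_study(ds.cognition, ds.brain,
                      ms.StudyConfig(build_fraction=0.15, seed=4),
                      per_roi=False)
print(report.r2_table.round(4))
print(report.overlap_class)
```

prints (numbers from this exact invocation):

```
          n_predictors      r2  r2_adj          aic          bic
model
gray                 8  0.1346  0.1340  353501.0199  353985.4395
white                7  0.1163  0.1157  327889.3510  328301.4691
combined            11  0.1773  0.1764  436225.8086  436970.5133
partially_overlapping
```

Read: of the unit-variance latent factor, the surviving gray-matter
regions explain ~13% on the validation sample, the white-matter tracts
~12%, and the combined model ~18% — more than either tissue alone but
well short of their 25% sum, so the two tissues carry partially
overlapping information (the generating population triple here is
0.154/0.124/0.190; the survivor models recover slightly less because
selection on the 1,800-row building sample misses the weakest paths).
`report.lrt_results` shows that constraining either tissue's paths to
zero is rejected decisively (Δχ² = 632.9 on 8 df dropping gray,
365.7 on 3 df dropping white, both p < 0.001).

The `examples/` directory walks each capability separately: generating
data (`01`), the FIML measurement model (`02`), a regularized path with
BIC selection (`03`), stability selection (`04`) and the full study
(`05`). Each script prints its numbers with a line on what they mean.

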