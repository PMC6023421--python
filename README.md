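# pestwarn

Early warning of vegetable pest outbreaks from multi-sensor field data.

Field campaigns that pair daily yellow-trap pest counts with environmental
sensors (rain gauge, soil/air temperature, soil moisture, leaf wetness, air
humidity) produce gappy multivariate series from which growers want a daily
**warning level** — an ordinal severity class I–IV — predicted from the
environment alone. `pestwarn` implements that analysis end to end:

1. **Imputation** — missing sensor cells are filled by local Lagrange
   polynomial interpolation along the time axis
   (`L(x) = Σᵢ yᵢ Πⱼ≠ᵢ (x−xⱼ)/(xᵢ−xⱼ)` over the nearest observed
   neighbours).
2. **Level discretization** — daily counts are clustered by
   one-dimensional k-means (k = 4), minimizing the within-cluster sum of
   squares `E = Σₖ Σ_{x∈cₖ} (x−mₖ)²`; cluster gaps become integer cut
   points defining levels I–IV. The default solver is the exact
   dynamic-programming formulation of 1-D k-means (optimal clusters are
   contiguous in sorted order), with classical seeded k-means++/Lloyd
   available as an option.
3. **Feature selection** — every factor is scored against the level
   sequence by Pearson correlation `r` and by the grey relational degree
   `ρ = mean_k (Δmin + ∂·Δmax)/(Δ(k) + ∂·Δmax)` (resolution coefficient
   ∂ = 0.5), and the two are fused into the impact factor
   `E_k = minmax(|r|) + minmax(ρ) ∈ [0, 2]`; factors with `E_k ≥ 0.5`
   enter the model.
4. **Classification** — a from-scratch three-layer back-propagation
   network (default 5-13-4, logistic sigmoid, 134 parameters) is trained
   by full-batch gradient descent on `E = ½Σ(y−d)²` for 10,000 epochs and
   decodes the warning level by argmax over its one-hot output layer.
5. **Evaluation** — a rows-true/columns-predicted confusion matrix with
   one-vs-rest TP/FN/FP/TN, precision, recall and F1 per level.

A synthetic-campaign generator (`pestwarn.synthetic`) produces sensor
series with the statistical structure the analysis assumes — five factors
driving a log-linear count model with four separable abundance regimes,
plus one null factor — so the whole pipeline is testable without field
data.

## Worked example

```sh
pestwarn run-all --out-dir demo --seed 1
```

logs the stages and ends with

```
INFO:pestwarn:level cut points: [60, 143, 286]
INFO:pestwarn:selected factors: ['precipitation', 'soil_temperature',
    'air_temperature', 'soil_moisture', 'leaf_wetness']
INFO:pestwarn:test accuracy 0.9225 on 761 held-out records
overall accuracy 0.9225; per-level F1 [0.98, 0.9, 0.78, 0.89]
```

Reading: the 2,536-day synthetic campaign was clustered into four warning
levels with integer cut points 60/143/286; the near-null air-humidity
factor was the only one rejected by the impact-factor screen; and the
5-13-4 network, trained on a stratified 70 % split of the z-scored
selected factors, classified 92.25 % of the 761 held-out days into the
correct warning level. `demo/` holds every intermediate artifact
(`data.csv`, `imputed.csv`, `scheme.json`, `scores.csv`, `model.json`,
`report.json`). The same run is available stage by stage via the
`simulate`, `preprocess`, `select-features`, `train` and `evaluate`
subcommands, or from Python:

```python
import pestwarn as pw
report = pw.run_pipeline(pw.PipelineConfig(seed=1, out_dir="demo"))
print(report.overall_accuracy)
```

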