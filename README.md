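# daycast

Day-length-informed prediction of days-to-heading (DTH) in multi-
environment trials.

## The problem

Heading date is a phenology trait with an intermediate optimum: breeders
need its *value* in a specific environment, not just a genotype ranking.
Conventional genomic selection (GBLUP) handles rankings well, but when no
phenotype from the target environment is available its prediction
collapses onto an overall mean — random environment effects are centered
on zero — so every unobserved environment gets essentially the same
predicted environmental mean, and the bias can reach weeks. Day length
(DL) is the one environmental driver that is computable *in advance* from
latitude and planting date alone, which makes it usable for exactly this
gap.

`daycast` implements two DL-coupled predictors alongside the GBLUP
baseline, for two cross-validation scenarios:

- **CV0** (tested genotype, unobserved environment) — the **C method**:
  fit a cubic `dl = b0 + b1·t + b2·t² + b3·t³` to the genotype's
  DL-at-heading vs DTH across its training environments, fit a second
  cubic to the target environment's daily DL curve from planting, and
  take the intersection abscissa as the DTH estimate. No markers needed.
- **CV00** (untested genotype, unobserved environment) — the **CB
  method**: average C-method estimates over the training genotypes to get
  the target environment's expected mean, then add the untested
  genotype's genomic BLUP ĝ from the model
  `Y_ij = μ + E_j + g_i + e_ij`, `g ~ N(0, G σ²_g)`, `G = XX′/p`.
- **GS baseline**: `μ̂ + ĝ` (the conventional genomic-selection answer).

Everything is exercisable without private trial data through a bundled
mechanistic simulator in which photoperiod-sensitive development
(`d_t = r·max(0, 1 − s·(DL_t − critical)⁺)`, heading when the accumulated
total reaches 1) generates the DTH values, so the DL-at-heading curves
the C method relies on emerge from the mechanism rather than being
assumed. See `docs/methods.md` for models, defaults, and limitations.

## Worked example

```python
from daycast import daylength, markers, predict, simulate

print(round(daylength.day_length(36.0, 172), 2))   # 14.61 h near solstice

cfg = simulate.SimConfig(n_genotypes=30, n_markers=200,
                         n_environments=12, seed=42)
dataset, truth = simulate.simulate_met(cfg)
series = simulate.build_series(dataset)
rel = markers.grm(markers.qc_filter(dataset.markers))

# untested genotype G007 in unobserved environment E05 (CV00, CB method)
task = predict.PredictionTask("cv00", "cb", "G007", "E05")
res = predict.predict_cv00_cb(dataset, series, rel, task)
print(f"E-mean {res.e_mean_used:.1f}  blup {res.blup_used:+.1f}  "
      f"predicted {res.predicted_dth:.1f}  observed {res.observed_dth}")
# E-mean 87.7  blup -1.3  predicted 86.4  observed 87

# tested genotypes in unobserved environments (CV0, C method)
c_results, _ = predict.run_cv0_c(dataset, series)
rep = predict.evaluate(c_results)
print(f"C across-env RMSE {rep.across_env['rmse']:.2f} "
      f"PC {rep.across_env['pearson']:.2f}")
# C across-env RMSE 4.53 PC 0.93
```

The CB prediction decomposes exactly into the curve-derived environmental
mean plus the marker-derived genomic deviation; the C method alone
reaches a few days of RMSE because the target environment's day-length
curve pins down *when* the season is, which markers alone cannot.

The same operations are available from a shell:

```
daycast simulate --seed 42 --out sim/
daycast predict --scheme cv00 --method cb \
    --phenotypes sim/phenotypes.csv --markers sim/markers.csv --out out/
daycast evaluate --predictions out/predictions.csv
```

Subcommands: `simulate`, `daylength`, `qc`, `grm`, `gblup`, `cmethod`,
`predict`, `evaluate`. Every run writes a `provenance.json` with the
effective configuration and input checksums.

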