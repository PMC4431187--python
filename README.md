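# nirpls

Multivariate calibration for online near-infrared (NIR) monitoring of batch
extraction processes. The package quantifies analyte concentrations
(mg/mL) from absorbance spectra recorded by an in-line NIR probe, the way a
process analytical technology (PAT) team would calibrate a sensor watching a
pilot-scale herbal extraction: flavonoids (naringin, hesperidin,
neohesperidin) leaching from *Fructus aurantii* into hot water over three
sequential batches, with a chromatographic assay supplying the reference
values.

## What it implements

* **NIPALS PLS1 regression** (`nirpls.pls`). Mean-centred predictors and
  response, components extracted as
  `w_a = X_a'y_a / ‖X_a'y_a‖`, `t_a = X_a w_a`, `p_a = X_a't_a / t_a't_a`,
  `q_a = y_a't_a / t_a't_a`, with deflation `X_{a+1} = X_a − t_a p_a'`; the
  regression vector is `b = W(P'W)⁻¹q`. The number of latent factors A is
  chosen by leave-one-out cross-validation: PRESS(a) = Σᵢ (yᵢ − ŷ₋ᵢ,ₐ)², A =
  argmin PRESS (ties to the smaller A). Models report RMSEC / RMSECV / RMSEP
  and the matching R² values.
* **Kennard–Stone sample partitioning** (`nirpls.sampling`): deterministic
  max–min Euclidean selection of a representative calibration set (default
  50 of 75 samples).
* **Preprocessing menu** (`nirpls.preprocess`): RAW, Savitzky–Golay
  smoothing (9 or 11 points), SG with first/second derivative, unit-norm
  normalisation, MSC and SNV — with calibration statistics frozen before
  they touch prediction data.
* **Interval selection** (`nirpls.intervals`): SiPLS (exhaustive search over
  all C(20,3) = 1140 combinations of 3 of 20 equidistant subintervals,
  ranked by RMSECV) and MWPLS (windows of 13–41 variables slid across the
  spectrum, mapped by RMSECV against the full-spectrum baseline).
* **Bagging-PLS** (`nirpls.bagging`): ensembles of up to 500 PLS members fit
  on bootstrap resamples of the calibration set (full-spectrum or
  SiPLS-masked), mean-aggregated, with the RMSEP-versus-iterations
  convergence curve.
* **Synthetic data with ground truth** (`nirpls.simulate`): a seeded
  generator emulating the three-batch extraction — first-order kinetics
  C(t) = C∞(1 − e^(−kt)) on the batch sampling schedule, Beer–Lambert
  mixtures of Gaussian pure-component bands under a dominant water band at
  1950 nm, multiplicative scatter, baseline drift, heteroscedastic noise,
  transient probe artefacts and reference-assay error. Every latent draw is
  recorded, so each pipeline stage can be tested against known truth.
* **Workflow + CLI** (`nirpls.workflow`, `nirpls` command): the end-to-end
  comparison — KS split, eight-method preprocessing table, SiPLS vs PLS,
  MWPLS summary, single vs bagging comparison — as delimited-text reports,
  fully reproducible from a YAML config and a seed.

## Worked example

```python
import nirpls as n

spectra, references, _ = n.default_fixture()      # 75 samples x 2800 variables
split = n.kennard_stone(spectra, 50)              # 50 calibration / 25 prediction

metrics, model, curve = n.evaluate(spectra, references, "naringin", split)
print(f"naringin PLS: A={metrics.n_factors}  RMSEC={metrics.rmsec:.4f}  "
      f"RMSECV={metrics.rmsecv:.4f}  RMSEP={metrics.rmsep:.4f} mg/mL  "
      f"R2_pre={metrics.r2_pre:.4f}")

cal = split.calibration_sorted()
y = references.column("naringin")
result = n.sipls_search(spectra.absorbance[cal], y[cal],
                        n_intervals=20, combo_size=3)
grid = n.WavelengthGrid()
best = ", ".join(result.interval_set.nm_label(i, grid)
                 for i in result.best.intervals)
print(f"SiPLS best combination: {best}  "
      f"RMSECV={result.best.rmsecv:.4f} (full spectrum {result.baseline_rmsecv:.4f})")
```

prints

```
naringin PLS: A=5  RMSEC=0.0697  RMSECV=0.0899  RMSEP=0.0723 mg/mL  R2_pre=0.9648
SiPLS best combination: 870–940 nm, 1780–1850 nm, 1850–1920 nm  RMSECV=0.0767 (full spectrum 0.0899)
```

Reading: a five-factor full-spectrum PLS model predicts naringin on the
held-out samples to 0.072 mg/mL (R² 0.96); restricting the model to three
twentieths of the spectrum lowers the cross-validated error from 0.090 to
0.077 mg/mL. Note the selected combination pairs an analyte band region
(870–940 nm) with shoulders of the water band — the latter act as an
internal reference for the per-sample scatter factor.

The same pipeline runs from the shell:

```bash
nirpls simulate --seed 1 --out data/
nirpls split --spectra data/spectra.csv --out data/split.csv
nirpls run --config config.yaml
```

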