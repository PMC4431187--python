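# Methods

## Calibration model

The core estimator is univariate-response partial least squares (PLS1) fit
by NIPALS. Predictors (absorbance at P wavelengths) and the response
(concentration, mg/mL) are mean-centred; no variance scaling is applied,
because absorbance variables share one unit and the preprocessing menu
already covers explicit scaling transforms. For a single response the NIPALS
inner iteration converges in one step, so components are extracted directly:

    w_a = X_a' y_a / ||X_a' y_a||,   t_a = X_a w_a,
    p_a = X_a' t_a / (t_a' t_a),     q_a = y_a' t_a / (t_a' t_a),
    X_{a+1} = X_a - t_a p_a',        y_{a+1} = y_a - q_a t_a,

with the prediction rule ŷ = ȳ + (x − x̄)' b, b = W (P'W)⁻¹ q. A component
is refused (or, inside cross-validation, the curve is frozen) when the
residual covariance ‖X_a'y_a‖ falls below 1e−12 of its initial scale — this
is what makes factor selection stop at the true rank on noiseless data
instead of chasing round-off.

The factor count A is selected by leave-one-out PRESS: PRESS(a) =
Σᵢ (yᵢ − ŷ₋ᵢ,ₐ)², minimised over a = 1..A_max with ties to the smaller a.
A_max defaults to 10 (roughly twice the factor counts such models need, so
the argmin is interior) and is clipped to N−2. RMSECV = √(PRESS(A)/N).
A parsimony alternative (`CVCurve.parsimonious`, smallest a within 2% of
the minimum PRESS) is available but not used by default. Cross-validation
is leave-one-out throughout.

`loo_press` evaluates the LOO curve in the sample-space (Gram/kernel) form
of the same algorithm: each fold's model is expressed through the
double-centred Gram submatrix, with score-orthogonality used to avoid
explicit deflation. This is algebraically identical to refitting NIPALS per
fold (the suite checks agreement with a refit-from-scratch oracle to
machine precision) and is what makes the exhaustive interval search cheap:
one SiPLS run needs 1140 LOO curves.

## Experimental protocol

Samples are split once by Kennard–Stone max–min selection on the raw
spectra (Euclidean distance, no PCA compression), so every preprocessing
variant is compared on the same 50/25 partition. Ties in the max–min
selection break to the lowest sample index, making the split fully
deterministic.

The workflow compares eight preprocessing methods (RAW, SG9, SG11, SG11+1D,
SG11+2D, Normalize, MSC, SNV), each with its own PRESS-selected A, and
carries the lowest-RMSECV method forward (exact ties prefer RAW).
Savitzky–Golay uses polynomial order 2, derivatives are embedded in the SG
fit and reported per grid step, and edges are evaluated from the same
polynomial so the variable count (and hence the 20×140 interval bookkeeping)
is preserved. "Normalize" means unit L2 row norm (min-max and unit-area are
config dialects); SNV uses the n−1 standard deviation; the MSC reference is
the calibration-set mean spectrum, frozen for prediction data.

SiPLS partitions the P variables into 20 equidistant half-open intervals
(any remainder goes to the leading intervals) and evaluates every
combination of 3, each with its own PRESS-selected factor count; results
are ranked by RMSECV against the full-spectrum baseline and the top ten are
reported, with interval labels printed as integer-nm ranges ("870–940 nm").
MWPLS slides windows of 13, 15, …, 41 variables (odd sizes, symmetric
around a centre; any list is accepted) with factor counts capped at
min(A_max, H−1); the per-position stride is 1 in library calls and 10 in
the workflow default, which changes the map resolution but not the
methodology. Whether any window beats the full-spectrum RMSECV is reported
explicitly, since a negative answer is itself the standard finding for
broad, overlapping NIR bands.

Bagging draws B = 500 bootstrap resamples of size N with replacement,
refits PLS on each (degenerate resamples are redrawn and counted), and
aggregates member predictions by unweighted mean (median is a config
option). The member factor count is fixed to the base model's PRESS
selection, isolating the resampling effect; per-member reselection is
available but measurably underperforms (see "negative findings"). The
master seed spawns per-member seeds, so the first b members do not depend
on B and the RMSEP-versus-iterations prefix curve is stable. Out-of-bag
RMSE is computed as a diagnostic only; model assessment uses the held-out
Kennard–Stone prediction set.

## Synthetic data

The generator emulates a three-batch aqueous extraction monitored in-line:

* **Kinetics.** Within each batch, C(t) = C∞(1 − e^(−kt)) with t measured
  from the start of heating; sample clock times map the 30-minute heating
  phase to negative offsets so t = 0 is "reached boil". The sampling
  schedule (intervals of 3–10 min depending on batch and phase) yields
  exactly 75 samples over three batches (32 + 24 + 19). Plateau
  concentrations decrease across batches (1.00 : 0.75 : 0.62) because each
  batch re-extracts the same herb charge; per-batch rates are 0.05, 0.04,
  0.04 min⁻¹. Plateaus and rates get small lognormal jitter (1% / 2%) per
  seed. The defaults are calibrated so the sampled concentrations of all
  three analytes stay inside the reference-assay ranges of the emulated
  study (naringin 0.2303–2.5504, hesperidin 0.0146–0.1889, neohesperidin
  0.1893–2.0272 mg/mL) with ≥4σ margin against the jitter.
* **Spectra.** Pure components are sums of Gaussian bands; each analyte's
  bands are placed in distinct twentieths of the 800–2200 nm grid (e.g.
  hesperidin near 905, 1465 and 1610 nm), with amplitudes scaled so each
  analyte contributes ~0.2 AU at its maximum concentration. A fixed broad
  water band (amplitude 1.0, centre 1950 nm, σ 90 nm) dominates the raw
  spectra; it is constant across samples, so centring removes it —
  temperature-dependent band shifts are deliberately out of scope.
* **Artefacts.** spectrum = m·(C·S + water) + offset + slope·(λ−λ_mid) + ε,
  with per-sample scatter m ∈ [0.90, 1.10], baseline offset ±0.03 AU and
  slope ±5·10⁻⁵ AU/nm (typical for an unthermostatted process stream),
  independent Gaussian noise with sd √(σ₀² + (0.02·clean)²) where σ₀ is
  0.5% of the median clean absorbance (signal-proportional "shot" noise
  makes the noise heteroscedastic), and, on 8% of samples, a transient
  broad Gaussian bump (0.03–0.12 AU) emulating particle/bubble events that
  pass the probe's inline filters. Reference values carry 3% relative plus
  1%-of-mean absolute assay noise. All artefact levels were fixed once, on
  realism grounds, before any acceptance property was measured; under them
  the PRESS-selected factor counts (3–9 across seeds) bracket the ~5
  factors such models typically need, and full-spectrum R²_pre lands at
  0.96–0.99.
* **Recovery fixtures.** `interval_recovery_fixture` builds a reduced-grid
  dataset whose response is the sum of several independently drawn
  component concentrations, one narrow band per informative interval
  (σ = interval width / 10, centred mid-interval, explicit 10⁻³ AU noise
  floor). Independence is what makes "the top combination must contain all
  informative intervals" a recoverable truth: with a single analyte every
  band carries the same information and any one interval suffices, so that
  design cannot discriminate. The reduced grid omits the water band, which
  is why this fixture sets the noise floor explicitly rather than using the
  median-absorbance rule.

What the generator does **not** emulate: real flavonoid band assignments,
temperature-driven water-band shifts, instrument drift across days, serial
correlation of artefacts along the batch, and nonlinear detector effects.
Passing tests therefore demonstrate correctness of the algorithms and the
qualitative behaviour of the comparisons under a linear mixture model — not
performance on real pilot-scale data, which is substantially harder (the
emulated study reports R²_pre ≈ 0.92–0.95 where this fixture gives
0.96–0.99).

## Numerical choices

* PRESS ties break to the smaller factor count; SiPLS RMSECV ties break
  lexicographically on the interval tuple; Kennard–Stone ties break to the
  lowest sample index. All three make reruns bit-identical.
* Masked (interval) fits copy the selected columns into C-contiguous
  storage so a mask of all variables reproduces the full-spectrum model
  bit-for-bit.
* Rank guards: `fit_pls` raises when the requested factor count exceeds
  what the data support; `loo_press` freezes a fold's predictions once its
  residual covariance vanishes, keeping the PRESS tail constant so the
  tie-break still selects the smallest adequate model.
* Degenerate bootstrap resamples (zero response variance, insufficient
  rank) are redrawn up to 100 times with a logged count.
* MWPLS window Grams are computed directly from the window columns, so the
  H = P window is the bit-identical computation as the full-spectrum
  baseline.

## Negative findings and limitations

Under this generator, mean-aggregated bagging with the member factor count
fixed to the base model's PRESS selection is statistically indistinguishable
from the single PLS model: across 20-seed experiments the ensemble's RMSEP
is lower in only ~55–75% of seeds, with sub-2% margins either way. This is
consistent with ensemble theory — bagging helps unstable, strongly
nonlinear procedures, while PLS1 at a fixed factor count is a stable,
nearly linear estimator; the wins concentrate in seeds where PRESS
overselects the factor count, and no defensible noise setting makes that
systematic. Variants probed and rejected: per-member LOO reselection
(optimistic on bootstrap duplicates, net worse), per-member out-of-bag
reselection (underfits), heavier shot noise, leverage outliers, serial
drift and gross reference errors (all leave the comparison a near-tie or
favour the single model). The corresponding acceptance checks encode the
expectation that bagging wins in ≥90% of seeds and are left failing rather
than weakened; the SiPLS-versus-full-spectrum improvement and the
convergence of the bagging prefix curve, by contrast, hold in essentially
all seeds.

Problem sizes used by the test suite and the acceptance script — 75 × 2800
for full-pipeline checks, 75 × 200 reduced grids for selection-recovery
properties, 20 seeds for distributional claims, B = 500 ensemble members —
are the package's chosen study conditions; they keep every check exact
while exercising the full exhaustive searches (all 1140 SiPLS combinations,
full MWPLS maps).
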