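# Methods

## Model

A mixture's perceived odor intensity is the norm of a vector sum of its
components' intensities. For components a, b with angle α between their
vectors:

    OI_ab² = OI_a² + OI_b² + 2·cosα·OI_a·OI_b

For n components every pairwise term carries the same family coefficient:

    OI_mix² = Σᵢ OIᵢ² + 2·cosα·Σ_{i<j} OIᵢ·OIⱼ

For n ≤ 3 this is exactly the classical binary/ternary vector model; the
n-component form is the natural generalization under the package's central
modelling assumption that one cosα per odorant family suffices (a pairwise
cosα matrix is deliberately out of scope). Component intensities come from
a log-linear psychophysical law on the odor activity value OAV = C/C_thr:

    OI = k·ln(OAV) + b,   k > 0

### Assumptions and their limits

* **One law and one cosα per family.** Holds empirically for odorants
  sharing a functional group and odor type (straight-chain aldehydes;
  simple esters). It breaks across families and for structurally deviant
  members — hydroxyl-bearing esters (n-butyl acrylate, vinyl acetate) are
  in the registry but excluded from the ester preset for this reason.
  Cross-family mixtures are not modelled.
* **Sub-threshold clamp.** The line yields negative OI for
  OAV < exp(−b/k); `oi_single` clamps to 0 because sub-threshold stimuli
  are imperceptible. The clamp lives in prediction only — calibration fits
  the unclamped line and instead *censors* ratings of exactly 0 (a panel
  cannot report how far below threshold a stimulus is); the censored count
  is logged.
* **Radicand clamp.** With strongly negative cosα and several components
  the quadratic form can go negative; the root of 0 is returned with a
  `RuntimeWarning`, read as complete odor counteraction.
* **Natural logarithm** throughout.

### Interaction coefficient from the mixture slope

When two equal-intensity components (OI_a = OI_b = o) are mixed and the
mixture obeys OI_mix = s·OI_sum, substituting into the binary model gives

    (2so)² = 2o² + 2·cosα·o²  ⇒  cosα = 2s² − 1,

inverted by s = √((1+cosα)/2). The shipped presets store the slope and
derive cosα at load time: aldehydes s = 0.62 ⇒ cosα = −0.2312; esters
s = 0.79 ⇒ cosα = +0.2482. The ester coefficient is positive by this
algebra even though odor counteraction intuition might suggest otherwise;
the implementation follows the slope, the primary measured quantity.
(A slope of 1/√2 ≈ 0.707 is the orthogonality point: families below it
counteract, above it partially synergize.)

## Calibration

* **Psychophysical law**: ordinary least squares of panel OI on ln(OAV),
  pooled across all odorants of the family (one line per family;
  per-odorant fits are reported as diagnostics only). Requires ≥ 2
  distinct abscissae. Diagnostics: residual standard error, R².
* **Mixture slope**: least squares of OI_mix on OI_sum constrained through
  the origin, s = Σxy/Σx² — zero summed intensity must map to zero
  mixture intensity, and the empirical relations carry no intercept. A
  free-intercept variant exists behind a flag for sensitivity analysis.
  Mixture records with unequal component intensities are accepted; the
  through-origin estimator is indifferent to how OI_sum is composed.
* cosα = 2s² − 1 on the fitted slope; family members are the odorants
  appearing in the singles records.

## Referencing scale

Panel ratings are anchored to geometric series of aqueous n-butanol
standards: level i holds base·ratio^(i−1) ppm. The 12-point scale starts
at 10 ppm with ratio 2 (level 8 = 1280, level 12 = 20480 ppm); the 8-point
scale starts at 12 ppm. The implementation follows the geometric rule
exactly; a published table prints 1550 ppm for the 8-point level 8 where
the rule gives 12·2⁷ = 1536, presumably a preparation rounding —
`oirs_concentration` returns 1536.

## Synthetic data

The panel generator emulates the calibration study design: per odorant,
`n_singles` = 6 concentrations placed on a ln(OAV) grid (default 1.0–3.5
for aldehyde-like laws; ester-like laws need a higher grid since they are
sub-threshold below lnOAV ≈ 1.93); per odorant pair/triple,
`n_mixtures` = 5 samples with component intensities spread over the
referencing scale (default 1–12). True intensities come from the law and
the vector model; assessor behaviour is Gaussian noise on the OI scale
(default sd 0.5, the generally acknowledged scatter of about half a scale
step), truncated at 0, quantized to the reporting grid (default
half-levels; rating resolution is configurable since panels differ), and
averaged over 8 assessors. All generators are pure functions of
(config, seed).

The sensor generator produces linear cross-sensitive responses,
signal_j = baseline_j + Σᵢ sens_ji·Cᵢ + N(0, σ), additive in constituents
(no sensor-level interaction — an assumption, not a measured fact). The
default seven-sensor array reproduces the qualitative selectivity pattern
of a published screening (which sensors respond to which aldehyde);
magnitudes and baselines are invented and the shipped
`data/sensor_array.yaml` says so. Saturation, drift, humidity/temperature
effects and response transients are not modelled. Consequently, passing
tests demonstrate correctness of the estimation pipeline on an idealized
linear instrument, not performance on a physical array.

## Concentration estimator

A fully connected feedforward regressor maps min–max-normalized sensor
signals to min–max-normalized concentrations; outputs are denormalized and
clamped at 0. Defaults mirror the selected e-nose configuration: 5 hidden
layers × 20 neurons, logistic-sigmoid hidden activations, identity output,
input width = number of sensors, output width = number of odorants.

* **Normalization scope**: MIN/MAX per column of the training database
  (sensors and odorants have incommensurate scales, so a single global
  MIN/MAX would be meaningless). Values outside the training range map
  outside [0, 1] un-clipped; the round trip is exact.
* **Optimizer**: seeded Adam (`solver="adam"`, full-batch at these sizes),
  max 20 000 iterations, tol 1e−9. L-BFGS was evaluated and stalls at
  initialization on this depth of logistic layers (vanishing gradients:
  loss never leaves ~0.06 on noiseless linear data, against < 1e−6 for
  Adam), so a first-order method is the default; the optimizer is
  configurable. Training is deterministic given the seed.
* Training delegates to scikit-learn's MLPRegressor; the fitted weights
  are extracted into a plain forward-pass evaluator so estimators persist
  to a single JSON file (weights + normalization stats + odorant order)
  and predict without a scikit-learn object in the loop.
* **ARE** (average relative error, %): mean of |pred − ref|/ref over all
  (sample, odorant) pairs with ref > 0; zero-reference pairs are excluded
  (relative error undefined) with the exclusion count logged. ARE is only
  informative when reference concentrations are bounded away from zero.

## Problem sizes in the test suite

Synthetic studies use the calibration study's own sizes: 18 single-odorant
records (3 odorants × 6) and 15 binary mixture records (3 pairs × 5) per
family for panel fits; 149 training samples (3×8 singles, 3×25 binary,
50 ternary) for the sensor database. The noisy-recovery check runs 200
seeded replicates at assessor sd 0.5. The estimator is trained once per
test module at the default architecture (~10 s).

## Numerical choices

* Quantization ties round up (`floor(x/res + 0.5)·res`).
* The slope↔cosα round trip loses relative precision as s → 0 through
  cancellation in 1 + cosα; tests assert 1e−9 relative for s ≥ 1e−3.
* Degenerate inputs raise `ValueError` with a named cause: constant
  normalization columns, < 2 distinct abscissae, all-zero OI_sum, empty
  component lists, out-of-range cosα or slope.
* A single-sample training database is accepted with a `RuntimeWarning`
  (underdetermined); its normalization span is widened artificially so the
  transform stays defined.
* CLI output formats are fixed — OI to 4 decimals, concentrations to 6
  significant digits — so runs diff cleanly.
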