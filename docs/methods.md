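# Methods

## Measurement model

A must sample in a 5 mm transmission flow cell is measured at 10, 14 and
18 °C against a water blank recorded at 20 °C. The working representation
is referenced absorbance `A(λ) = −log10(I_sample/I_water)` on a wavelength
grid inside the instrument's 1100–1350 nm window. The calibration chain
assumes:

1. analyte contributions are additive and linear in concentration
   (Beer–Lambert) over the must concentration ranges;
2. scatter from turbid must acts per spectrum as a multiplicative gain
   plus an offset on absorbance (what SNV removes);
3. the water background varies smoothly with temperature, and measuring at
   fixed temperatures turns that variation into a small number of
   reproducible spectral components a few latent variables can absorb.

## Preprocessing

* **SNV**: `x → (x − mean x)/sd x` per spectrum, with the sample (n−1)
  standard deviation. The denominator choice is arbitrary but fixed and
  documented; either convention satisfies the mean-0/sd-1 contract.
* **Savitzky–Golay first derivative**, window 7, polynomial order 2,
  applied after SNV (that processing order is the package's single
  supported chain). The convolution weights are computed from first
  principles (pseudoinverse of the local Vandermonde design), are exact
  for polynomials up to the fitted order, and are scaled by 1/Δλ so the
  derivative is per nm and grid-step independent. Output is truncated to
  interior points (3 dropped per edge; 126-point spectra become
  120-point predictor rows) — extrapolated edge derivatives are
  artifact-prone and never used.
* **Outlier screening** (before preprocessing): score each spectrum by the
  robust z-distance of its median absorbance from the collection median
  (1.4826·MAD scaling); spectra with score > k = 3.5 are excluded. The
  rule targets the failure mode seen in practice — insufficient water
  referencing shifting whole spectra — and the threshold is the
  conventional robust cut. Collections smaller than 3 are passed through
  with a warning.

## PLS1 calibration and validation

One PLS1 model per variety × analyte (four independent single-response
models rather than one PLS2: per-analyte models are what the application
reports, and the single-response algebra is simpler to falsify). NIPALS
with X-deflation and y-residualization; coefficients assembled as
`b = W(PᵀW)⁻¹q`; at fit time the sequential-score and coefficient
prediction routes are compared and must agree to 1e−8 — a cheap internal
consistency check that catches deflation bugs. The component count is
fixed at 6 by configuration rather than auto-selected (reproducibility;
`rmsecv_by_components` exists as a diagnostic). Temperature is not a
predictor column by default — the three temperatures enter as replicate
spectra, matching the calibration protocol; `RunConfig.temperature_feature`
appends it for the harvester use case where each sample is measured once
at ambient temperature.

Validation is leave-one-out grouped by sample id: all temperature
replicates of a sample leave together, so no fold can leak
near-duplicate spectra of the held-out sample into training.
(`analysis/04_sensitivity_checks.py` demonstrates the optimism of the
ungrouped variant.) Reported metrics: RMSEP = √(mean (ŷ−y)²) over
held-out spectra, R² = 1 − SSres/SStot in percent (the squared-Pearson
alternative is computed and stored on the CVResult but is not the
headline number), and RMSEP as % of the analyte's observed value range —
ranges are taken from the actual reference data of the modeled samples,
not from configuration.

Method comparison (primary vs secondary reference tables) is ordinary
least squares of B on A per analyte with r² and residual RMSE. The limit
of quantification follows the ICH convention LOQ = 10·σ/S with σ the
n−2 residual standard deviation of the calibration line and S its slope.

## The synthetic-data generator

The generator's defaults are the study conditions: 4 varieties with the
published concentration ranges and sample counts (26/22/23/18 samples
over 6 weekly time points), 3 spectra per sample at 10/14/18 °C, water
reference at 20 °C, 2 nm grid (126 points — the sensor's 12–16 nm optical
resolution makes the sampling step a free choice; 2 nm keeps the SG
window comfortable at desk scale), 5 mm path, additive noise sd = (water
background peak)/15 000.

Simulated absorbance per spectrum:

```
A(λ) = Σ_a c_a ε_a(λ) L                      analyte bands (Gaussian, acids
                                             1100–1160 nm, sugars 1300–1350 nm)
     + t·C_total·s(λ)                        turbidity slope, ∝ total solutes
     + η·w(λ, 20 °C)                         matrix/referencing residual
     + w(λ, T) − w(λ, 20 °C)                 temperature effect
→ gain·A + offset + N(0, σ_noise)            scatter jitter and detector noise
```

with `w` a two-lobe water background (1190 nm combination band plus the
shoulder of the 1450 nm overtone, peak ≈ 0.9 AU) whose centers shift
0.15 nm/°C and amplitude changes 0.15 %/°C relative to the reference
temperature. Band positions/widths/absorptivities are configurable; the
defaults put full-range analyte contributions at 0.01–0.05 AU and place
acids in the low window and sugars in the high window (the
band-attribution statement supported by the results; the literature also
contains the reverse assignment, and swapping is one config edit).

Two magnitudes deserve justification because they control how linear the
SNV-normalized problem is. The matrix residual `η ≈ 0.35` (≈ 0.31 AU)
represents unclarified must against a clear water blank — turbid must at
5 mm genuinely transmits far less than water — and provides the stable
per-spectrum scale that keeps SNV's division from turning concentration
information into a strong nonlinearity. Its per-spectrum drift
(sd 0.001) models routine referencing variation; gross referencing
failures are precisely the outliers the screening rule exists for and are
not part of routine spectra. A design study (varying these two knobs with
everything else fixed) showed the drift term dominates recovery error,
and the chosen values give stable recovery across seeds; they were fixed
once and are not tuned per run.

Ripening trajectories: with time fraction τ ∈ [0,1] over the season,
sugars follow a normalized logistic from range-min to range-max
(steepness 6), malic acid decays as `(1−e^{−2τ})/(1−e^{−2})` from max to
min, tartaric acid declines linearly (its relative span is smaller —
dilution, not metabolism). Per-sample jitter (sd = 7 % of the range,
independent per analyte, clipped to the range) makes the four analytes
individually identifiable rather than perfectly collinear in time. The
secondary reference table adds homoscedastic Gaussian disagreement per
analyte (sd 3.4/4.8/1.25/0.9 g/L), matching the magnitude of reported
HPLC-vs-FTIR residuals. Synthetic calibration series for the LOQ mirror
the four-stage dilution design (1.5–90 g/L sugars, 0.15–9 g/L acids) with
a linear response and repeatability noise of 0.35/0.07 g/L.

**What the generator does not emulate** — and hence what passing tests do
not show about field data: real absorptivity spectra (bands are Gaussian
stand-ins), water displacement by solutes, variety-specific matrix
effects (anthocyanins, phenolics), drifting instrument response over the
season, non-Gaussian reference errors, and any nonlinearity of the true
concentration–absorbance relation. Recovery numbers on synthetic data
(R² ≈ 99 %, RMSEP ≤ ~3 % of range) are therefore an upper bound on
fidelity, not a field-performance claim; they demonstrate that the
pipeline recovers what the forward model encodes, with honest grouped
validation.

## Numerical and interface choices

* Degenerate inputs fail loudly: constant spectra (SNV), zero-variance y,
  non-uniform grids, even SG windows, nonpositive blank intensities,
  nonpositive calibration slopes all raise typed errors rather than
  returning NaN.
* Beer–Lambert additivity of the simulator holds machine-exactly with the
  concentration-independent backgrounds switched off
  (`SimulationConfig.noise_free()`); with them on, a sum of single-analyte
  simulations would count the shared background once per analyte.
* `ripening_trajectory` returns one row per sample (n_samples total,
  spread over time points via ⌊i·T/n⌋), which is what makes the published
  per-variety sample/spectra counts (e.g. 22/66) reproducible exactly.
* Varieties are modeled independently (no pooled model by default;
  `RunConfig.pooled` adds a pooled set to a separate report). Varieties
  with too few samples for the fold structure are skipped with a logged
  warning and absent from the report.
* Pipeline artifacts (report, CV tables, model JSONs, run log) are
  stamped with a config hash and seed; reruns under a fixed seed are
  byte-identical, and the report is a pure aggregation of the persisted
  per-fold CV tables (a test recomputes it).
* Problem sizes throughout (89 samples / 267 spectra / 120 predictors per
  run) keep any full pipeline execution to a couple of seconds, chosen so
  the whole chain is exercisable interactively.
* The package's interface is the library plus the numbered `analysis/`
  drivers; no separate console entry point is shipped, since every
  operation is a one-line script or function call.

## Known limitations

* PLS1-vs-PLS2 and the exact grouping of the original leave-one-out
  protocol are interpretation choices (sample-level grouping is implied
  by the sample/spectra bookkeeping and is the honest default here).
* The validation R² definition (1 − SSres/SStot on held-out predictions)
  is one of two conventions in use; the squared-correlation variant is
  computed alongside.
* The spectra file format stores wavelengths in column names at 2-decimal
  precision; grids needing more precision would not round-trip.
* SNV on derivative-free absorbance with a concentration-dependent total
  intensity is intrinsically slightly nonlinear; the residual curvature
  is part of the simulated problem and bounded by the design above.
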