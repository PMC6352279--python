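# Methods

This note documents the models and procedures implemented in `spectrocal`,
the parameter choices that matter, and what the synthetic data can and
cannot establish.

## Measurement model and preprocessing

Spectra are diffuse-reflectance curves in arbitrary reflectance units on a
1-nm wavelength grid nominally spanning 250–2000 nm, three replicates per
sample. Reflectance is modelled directly — no absorbance or Kubelka-Munk
transformation — because the calibration workflow operates on the recorded
reflectance values as measured.

Two regions of the raw curve are unusable and are removed by **closed**
interval trimming before anything else: below 270 nm the detector saturates,
and near 900 nm the UV-Vis→NIR detector change leaves a sharp spike that
would dominate any derivative. The default zero-order intervals are
[270, 850] and [907, 2000] nm (1675 of the 1751 grid points). Replicates are
averaged (arithmetic mean) **before** preprocessing and modelling; averaging
k replicates cuts independent replicate-noise variance by a factor of k,
which is the stated purpose of measuring replicates.

### Derivative filters

First derivatives (reflectance · nm⁻¹) suppress baseline offsets and sharpen
overlapping bands. Two filters are provided behind one interface; both are
exact for polynomials up to their configured degree and linear in the input,
and both operate per maximal contiguous constant-step grid segment, so
trimmed spectra are differentiated without bridging the detector gap.

**Golay-Savitzky (GS).** The classic symmetric filter: least-squares fit of
a degree-*d* polynomial to the 2m+1 points around each grid point, derivative
taken at the center. Weights come from the standard closed form
(`scipy.signal.savgol_coeffs`), scaled by the grid step at application time.
*Window parameter mapping:* the configured `window` is interpreted as the
**half-window m** (window 10 → 21-point footprint, m points lost at each
end). The alternative reading (window = total width) does not yield an
integer-symmetric loss for even widths; the mapping is isolated in
`gs_half_window` so the other convention is a one-line change. Default:
window 10, degree 2 — the setting at which the smoothing/information
trade-off was found empirically acceptable in the motivating study
(5 points: visibly noisy; 15 points: attenuated peaks).

**Step-by-step filter (SBSF).** The exact published recurrence of this
filter is not available, so the implementation realises its *observable
contract*: a one-sided, forward-looking derivative with a small window, no
attenuation of long-wavelength bands, point loss only at the red end, and
exactness on cubics at degree 3. Concretely, a degree-*d* polynomial is
least-squares fitted over the `window + d` points ahead of each grid point
(the differencing step plus the smoothing span) and its derivative evaluated
at the window's blue edge; `window + d` points are lost at the red end.
Default: window 2, degree 3. The filter is pluggable behind `apply_filter`
should a different recurrence need to be substituted.

After differentiation the method-specific retained intervals are applied as
**configured trims** (defaults: [270, 850] ∪ [935, 1920] nm for GS,
[270, 850] ∪ [935, 1980] nm for SBSF). They are deliberately not derived
from the loss formulas: the published interval ends do not coincide with the
filters' nominal point loss, so the package treats them as part of the
method configuration.

The `snr_gain` diagnostic quantifies what a filter buys: the RMS error of
naive two-point differencing divided by the RMS error of the filtered
derivative, both scored against the derivative of a noise-free reference
curve (guarded so that the noise-free case reports ≈ 1 rather than 0/0).

## Calibration

For each component, X is the n × p matrix of preprocessed spectra and y the
reference concentrations (mg/g). Both are mean centered; centering is
recomputed inside every cross-validation fold from the training rows only,
so no information about the held-out sample leaks into the preprocessing
(a property explicitly tested against a deliberately leaky variant).

The regression is **PLS1** per component by default (deterministic NIPALS,
`scale=False`), with **PCR** (SVD scores + least squares) as an alternative
behind the same interface; reports name the algorithm used. The published
workflow says only "principal components", which both algorithms satisfy;
PLS1 is the conventional default of the commercial software family involved.

**LOOCV.** For each latent-variable count k = 1..max_pc, each sample is
predicted by a model refitted on the other n − 1 samples; RMSECV is
sqrt(Σ(ŷᵢ−yᵢ)²/n). `max_pc` defaults to n − 2: one sample is spent on the
fold and one degree of freedom on centering, so n − 2 is the largest count
for which every fold's fit is determined. (Published grids of this kind
sometimes list 9–10 PCs for n = 10 under LOOCV, which fold-wise refitting
cannot produce; the package clips and logs instead of emulating it.)

**Model selection** takes the RMSECV argmin, ties broken toward fewer
latent variables; a `monotone_decrease` flag marks profiles whose optimum
may lie beyond `max_pc`. R² is the squared Pearson correlation between
cross-validated predictions and reference values — the phrase "square root
of the correlation coefficient" in the source material is garbled, and
squared correlation is the statistic its software reports.

**Outlier screening.** Before calibration, each component's concentration
column is screened with a robust score |xᵢ − median| / (1.4826 · MAD);
samples above the threshold (default 3.5) are excluded *from that
component's calibration only*. On the packaged reference table this flags
exactly sample H for quercetin (score ≈ 12.9) and sample G for kaempferol
(≈ 7.4). Three further columns show one sample each above 3.5 (caffeic
acid F ≈ 5.0, isoquercitrin I ≈ 4.0, luteolin-7-glucoside J ≈ 3.6); the
threshold is configurable, and the default is kept at the conventional 3.5
rather than adjusted around these borderline cases. Missing entries
(printed "-", stored as NaN) are never flagged and always excluded.

## The synthetic study

Real spectra for this material were never deposited, so the generator
produces studies with the statistical structure the pipeline assumes:

* **Background** (composition-independent): a constant offset plus broad
  Gaussian bands at 500, 650, 1450, 1720 and 1920 nm (σ 40–70 nm), with
  amplitudes chosen so each listed center is a local maximum of the
  noiseless background — the qualitative morphology of the real curves.
* **Component signal:** each of the 14 components carries 2–4 narrow
  Gaussian bands (centers 300–1980 nm, σ 10–30 nm, amplitude −4..−1 per
  mg/g; negative = absorption dip), drawn reproducibly per component from
  the library seed. With noise off the spectrum matrix is an exact linear
  function of the concentration matrix.
* **Replicate noise:** one multiplicative scatter factor per replicate
  (σ = 0.03), a random quadratic baseline drift (amplitude 2 reflectance
  units), white additive noise (σ = 0.2 units against a background of tens
  of units), a deterministic detector-spike Gaussian at 900 nm (amplitude
  10, σ 3 nm) and saturation below 270 nm (ceiling 95 units plus inflated
  noise). The noise magnitudes were chosen once to make the visible region
  noticeably more variable between replicates than the NIR — the pattern
  described for the real powders — while keeping component signal
  recoverable.

All randomness derives from one integer seed through `SeedSequence` spawn
keys (per component for the library; per sample × replicate for noise), so
studies are bitwise reproducible.

**What the generator does not emulate:** the true band positions and
overlap structure of the real plant matrix (the library is a statistical
stand-in, not a spectral database), wavelength-dependent instrument response
beyond the detector spike, and any nonlinearity between concentration and
reflectance. Passing recovery tests therefore demonstrate that the
*pipeline* is correct and unbiased under its own assumptions — not that the
real material is calibratable to any particular accuracy.

## What n = 10 samples can and cannot support

A point that shapes several test outcomes: with ten samples (nine per
training fold, eight effective dimensions after centering) and fourteen
quasi-independent component signatures, the exact concentration-to-spectrum
inverse is not identifiable from any training fold. Leave-one-out
predictions are projections onto an (at most) eight-dimensional span, so
even **noise-free** synthetic studies have a strictly positive RMSECV floor
and per-component cross-validated R² far below 1 for many components. This
is a property of the fixed ten-sample concentration geometry, not of the
filters, the regression or the noise level — and it is consistent with the
moderate R² values (≈ 0.6–0.96) the motivating study itself reports. The
test suite asserts the attainable consequences (RMSECV decreases as additive
noise is halved; the LOOCV machinery agrees exactly with an independent
naive implementation) rather than perfect noiseless recovery. Relatedly,
when the structure floor dominates a component's error, halving the noise
leaves its RMSECV nearly unchanged; for some band-library draws this can
hold at the median across components.

## Reporting conventions

The comparison report has one cell per component × method (42 for the full
study); failures are recorded per cell without aborting the rest. The
best-method tally uses the **strict minimum**: a component whose two best
methods tie exactly — or within an optional relative tolerance — is credited
to neither. The packaged published-statistics grid uses its own row
numbering, which differs from the concentration table's for rows 7–14
(row 7 there is luteolin-7-glucoside, not isoquercitrin); the tally
defaults to rows 1–13, the "monitored active components" convention.
Note that on that grid the strict-minimum rule credits the one-sided filter
with eight components — the grid's own row 9 has the lowest SBSF error even
though the accompanying narrative calls it "similar" and counts seven; the
package reports what the numbers give.

The reference table's SD column is stored but unused: its label is
ambiguous between absolute and relative standard deviation and nothing in
the workflow depends on it.

## Numerical choices

* Written CSV uses 17 significant digits and is read back with the
  round-trip float parser, so spectrum I/O is lossless for float64.
* Filter weights are computed in index space and divided by the grid step
  (nm) at application time; derivative units are reflectance · nm⁻¹.
* Centering tolerance: column means of a centered matrix are zero to 1e-10.
* PLS1/PCR fits are deterministic; LOOCV agreement with an independent
  NIPALS/eigendecomposition oracle is asserted to 1e-10.
* Degenerate inputs: zero-variance y, fewer than 3 usable samples,
  infeasible latent-variable counts and empty trims raise informative
  errors; `max_pc` beyond n − 2 is clipped with a logged warning.
* Problem sizes in the tests (10 samples × 3 replicates, 1751-point grid,
  5 noise seeds, 100 SNR draws, 20 random LOOCV problems) are desk-scale
  choices that keep the full suite to about a minute while exercising every
  contract at the study's true dimensions.
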