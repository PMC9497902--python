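# Methods

This note documents the models, conventions and design choices behind
`hsiph`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Spectral conventions

**Wavelength grid.** Bands are indexed 1-based: band *i* sits at
`start + (i−1)·step` nm. The default acquisition grid is 350–1100 nm at
5 nm (151 bands), so band 70 — the segmentation band — is 695 nm. Grids are
inclusive at both ends, and a range not divisible by the step is an error.

**Reflectance calibration.** `R = (R_r − R_d)/(R_w − R_d)` with dark and
white references either full images or per-band vectors (vectors broadcast
over pixels). Any non-positive `R_w − R_d` element aborts with the
offending band, since it would silently produce meaningless reflectance.

**Absorbance.** `A = −log10(R)`, the decadic (Beer–Lambert) convention
standard in chemometrics. Non-positive reflectance is an error by default;
`clip=True` floors reflectance at 1e-6 first. The round trip
`R → A → R` is exact to ~1e-16 for R in (0, 1].

## Segmentation and region extraction

Foreground is `reflectance > 0.075` (strict; ties are background) at band
70, followed by retention of the largest 4-connected component — the
threshold alone admits isolated bright noise pixels. The five "equal-area"
regions are produced by projecting mask pixels onto the mask's major
principal axis (leading eigenvector of the pixel-coordinate covariance),
sorting, and cutting into five contiguous bins whose sizes differ by at
most one pixel (remainder to the earliest bins). This realizes crosswise
slices of a cylindrical sausage; the original description names no
algorithm, so the partition rule is this package's choice and all of its
pieces (band, threshold, k) are parameters. All five region rows share the
sausage's single reference pH, matching how a homogenized-slice pH
measurement is made.

## Pretreatments

* **SNV**: per-spectrum `(x − mean)/sd` with the sample (n−1) standard
  deviation. Constant spectra are an error.
* **MSC**: OLS regression `x ≈ a + b·ref` per spectrum, corrected to
  `(x − a)/b`. The reference defaults to the calibration-set mean *after
  any preceding chain steps* and is frozen for prediction rows and
  cross-validation test folds, so no statistic leaks from evaluation data.
  `|b| < 1e-12` is an error.
* **Normalization**: unit absolute area `x/Σ|x|`. Area normalization was
  chosen over max- or vector-norm variants because the workflow's purpose
  for it is equal area under the curve; the variant is selectable in code.
* **Derivatives**: Savitzky–Golay, window 7, polynomial order 2 (first
  derivative) or 3 (second), derivative step = one band, same-length output
  with polynomial edge interpolation. Window and order are parameters; the
  derivative is per *band*, not per nm (multiply by 1/step_nm to convert).

Chains compose these left to right and are parsed from labels such as
`"2nd Derivative + Normalization"` (case-insensitive). The ten standard
labels times two domains (reflectance, absorbance) give the twenty
configurations the pipeline tabulates.

## PLSR

PLS1 via NIPALS on mean-centered X and y with deflation; weight-vector
convergence tolerance 1e-10, max 500 iterations per component (for a
single response the inner loop converges in one pass). The model is
collapsed to `ŷ = b₀ + x·b` with `b = W(PᵀW)⁻¹q`; tests verify the
collapsed form equals the latent path, that score vectors are mutually
orthogonal (< 1e-8), and that predictions match both a normal-equations
oracle at full rank and scikit-learn's PLSRegression (test-only oracle).

Splitting is row-wise (region-spectrum) at calibration fraction 2/3 with
`ceil`: 165 rows → 110 + 55. Grouped (per-sausage) splitting is available
via `by_sample=True`. R² always uses the evaluated set's own mean;
cross-validation (leave-one-out by default; k-fold optional) refits the
*entire* chain + model inside every fold and pools out-of-fold
predictions. `select_n_latent` takes the smallest component count whose
RMSECV is within 2 % of the global minimum — a parsimony rule, since the
original latent-variable count is unstated.

A caution on a tempting invariant: adding pure-noise predictor columns at
a *fixed small* component count can worsen the training fit of PLS,
because noise variance dilutes the covariance-maximizing weight vector.
Only in the full-latent-rank limit (where PLS reaches the least-squares
fit) does column nesting guarantee a non-increasing training RMSE, and
that is what the suite asserts.

## Feature wavelengths and the reduced model

"Important" wavelengths are local extrema of the collapsed coefficient
vector b — interior bands where the first difference strictly changes
sign — ranked by |b|, kept greedily subject to a minimum separation
(default 2 bands), truncated to k = 12 and sorted. Extremum detection,
ranking and separation are this package's concrete reading of "peaks and
valleys"; all three are parameters, and a published 12-wavelength rule
(365–1060 nm, with its intercept 5.335 and coefficients) ships as a preset
that bypasses selection entirely. The reduced PLSR refit on the selected
columns is collapsed to `LinearSpectralModel`, whose evaluation is tested
to agree with the matrix prediction path to 1e-10. The preset is tagged
reflectance-domain and refuses absorbance input.

## Prediction maps

Masked pixels are unfolded to an (n_pixels × k) matrix at the model
wavelengths, multiplied by the coefficients plus intercept, and refolded;
background is NaN in memory, −999 in CSV export, transparent in PNG. The
vectorized path is tested against a per-pixel double loop to 1e-12. The
default display range is the map's own min/max; a fixed range (e.g.
4.4–6.5, spanning the pH values such sausages exhibit) keeps color
comparable across samples. Rendering fixes dpi and PNG metadata so
re-renders are byte-identical.

## Central composite design and ANOVA

The five-factor design is a half-fraction 2⁵⁻¹ factorial core with
defining relation X₅ = X₁X₂X₃X₄ (derived from the published run table,
which satisfies it in all 16 factorial rows), 10 axial runs at α = 2 and 6
center replicates: 32 runs. Factor coding is exactly affine,
`uncoded = center + coded·halfrange`, with centers (3.16 % lecithin,
1.78 % oil, 0.26 % extracts, 19.50 mL/kg lactic acid, 75 min) taken from
the center runs and half-ranges (1.04, 0.60, 0.14, 1.50, 15) from the ±1
factorial levels. The published table prints a few internally inconsistent
rounded levels (e.g. an X₁ axial of 5.16 where exact coding gives 5.24); a
verbatim copy is kept in `hsiph.rsm.PRESET_TABLE_UNCODED` and the tests
show it is the same design within 0.1 uncoded units. The soaking-time
factor applies identically to both treatment stages and is one factor.

The quadratic surface (21 coefficients in uncoded units) is fit by
`numpy.linalg.lstsq` on the explicit polynomial basis. ANOVA uses adjusted
(Type III, drop-term-refit) sums of squares — matching the convention of
the commercial DOE software that popularized this table layout — with F
tests against the residual mean square and p-values from the F survival
function (star at p < 0.05). Pure error comes from replicated design
points (the center runs); lack of fit is the remainder of the residual,
`F = (SS_LoF/df_LoF)/(SS_PE/df_PE)`. With an exact fit or no replicates
the undefined F ratios are NaN (and missing replicates additionally warn).
Single-term F values are cross-checked against statsmodels' Type III ANOVA
in the suite.

## Synthetic phantoms

The generators exist so that every stage has ground truth:

* **Hypercube phantom**: an ellipse ("sausage") on a flat dark background
  (reflectance 0.04 ≪ the 0.075 threshold). The sausage spectrum is a
  monotone-smooth (PCHIP) meat-like baseline times Gaussian absorption
  dips at 418/544/574/582 nm (heme pigments) and 780/980 nm (water).
  Dip depth varies linearly with the latent pH around pH 5.45 — a fixture
  convention standing in for pigment loss under proteolysis, **not** a
  chemical model. Per-pixel multiplicative gain (sd 0.03) and additive
  offset (sd 0.01) exercise MSC/SNV; i.i.d. spectral noise (sd 0.003)
  exercises thresholds. The spec is rejected up front if the sausage/
  background contrast at 695 nm cannot survive 3σ of the scatter. pH
  fields are constant or a linear gradient along the major axis; defaults
  span 4.44–6.46, the range such storage experiments report.
* **Spectra table**: smooth random reflectance spectra (random level,
  slope, and 3–6 Gaussian bumps, clipped to (0.05, 0.9)); pH is a known
  linear rule evaluated on each row plus Gaussian noise. With zero noise,
  refitting restricted to the rule's wavelengths recovers its coefficients
  to ~1e-13, which is how the preset rule's printed coefficients are
  validated end to end.
* **CCD responses**: a known quadratic surface evaluated on the design
  plus noise; zero noise recovers all 21 coefficients to < 1e-6 relative.

Every generator is a pure function of (spec, seed). What passing these
tests does *not* show: performance on real sausages, whose spectra have
instrument artifacts, non-Gaussian scatter, and a pH–spectrum link that is
neither linear nor noiseless; the published full-data R² ≈ 0.68–0.73
regime is far from the phantoms' near-exact recovery.

## Pipeline and problem sizes

The `run` pipeline simulates 33 scenes of 48×72 pixels by default (165
region rows, matching the reference experiment's table size), evaluates
all 20 chain/domain configurations with 10-fold cross-validation, selects
feature wavelengths from the raw-reflectance model, refits 20 reduced
models, and renders maps for two scenes — a few seconds on one CPU. Tests
use smaller scenes (32–64 px sides) and the same statistical settings; the
choices keep recovery properties sharp while staying quick to iterate.

## Known limitations

* One sausage per scene; no multi-object scene parsing.
* The pixel-wise map applies the reduced linear rule to raw pixel
  reflectance; chains that require whole-spectrum context are not applied
  per pixel, so reduced models intended for mapping should use the raw
  reflectance chain.
* ENVI I/O supports the little-endian float32/float64, BIL/BIP/BSQ subset
  this workflow produces — not the full ENVI zoo.
* `select_n_latent` is a heuristic; with strongly correlated bands the
  RMSECV curve can be flat and the parsimony rule intentionally errs low.
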