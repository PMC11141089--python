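# Methods

## α-opic photometry

All spectral quantities are computed by Δλ-weighted rectangular summation
on a canonical 380–780 nm, 1 nm grid (`spd.CANONICAL_GRID`), the
tabulated-summation convention of standard-observer photometry; trapezoid
integration would change fourth-digit reproductions of published condition
tables. Spectra are resampled to the grid by linear interpolation and are
defined to be zero outside their measured support (physical sources emit
nothing where unmeasured). Negative measured values are rejected at read
time; `read_spd(..., clip_negative=True)` opts into clipping at zero for
spectrometer noise floors.

An α-opic irradiance is E_α = 1000·Δλ·Σ E(λ)·s_α(λ) (mW·m⁻²); photopic
illuminance is 683·Δλ·Σ E(λ)·V(λ) (lx). The equivalent daylight
illuminance is EDI_α = E_α/K_α with K_α the α-opic irradiance of D65 per
lux of D65.

### Observer data: a reconstruction, and two bases for K_α

The normative 1 nm α-opic tabulations are not redistributable with this
package, so `data/observer_reconstructed_1nm.csv` is a documented
*synthetic reconstruction*, built by `scripts/build_observer_tables.py`
and verified by checksum at load:

* V(λ) and scotopic V′(λ) (the rhodopic action spectrum) are transcribed
  classic 5 nm / 10 nm tabulations, interpolated with a monotone cubic in
  log10;
* D65 is the transcribed 5 nm relative power table, linearly interpolated;
* the three cone-opic curves are Govardovskii A1 pigment nomograms
  (α + β band, quantal → energy conversion) at pigment peaks
  420.7/530.3/558.9 nm with photopigment self-screening (peak optical
  densities 0.30/0.38/0.38), filtered by an analytic lens template and a
  wide-field macular pigment term (peak density 0.095 at 460 nm);
* the melanopic curve is the 480 nm nomogram filtered by the same lens
  template, whose single density scale is solved so the melanopic D65
  efficacy equals the published constant 1.3262 mW·lm⁻¹.

Validation against the published efficacy constants that were *not* used
in the calibration: rhodopic 1.4541 vs 1.4497 (0.3 %), M-cone 1.4892 vs
1.4558 (2.3 %), L-cone 1.5944 vs 1.6289 (2.1 %), S-cone 0.8998 vs 0.8173
(10 %). Curve peaks land at 454/547/573/492/507 nm. Spectrally resolved
cone quantities therefore carry a few-percent model error; this is ample
for metamer design (a ratio-level computation) but not for standard-exact
EDI conversion.

Hence two bases for K_α. `d65_efficacy(alpha, basis="tables")` derives
K_α from the packaged tables; `full_report` uses it by default, which
makes a spectral report exactly self-consistent (a D65-shaped input gives
EDI_α ≡ illuminance and DER_α ≡ 1 to machine precision).
`basis="published"` returns the standard's printed constants
(sc 0.8173, mc 1.4558, lc 1.6289, rh 1.4497, mel 1.3262 mW·lm⁻¹);
`alpha_opic_edi` uses it by default because converting a *measured or
published scalar irradiance* should follow the standard's exact
convention, independent of any reconstruction error. Reproducing a
published mEDI from a published melanopic irradiance requires K_mel to
about 7 parts in 10⁵ (the brightest condition pair, 193.62 mW·m⁻² →
146.00 lx, is the binding case), which only the published constant
guarantees.

Degenerate DERs (zero illuminance) are reported as NaN, never infinity.
Luminance is supported by applying the photopic kernel to radiance-tagged
spectra; published screen luminances are treated as inputs, since the
screen's primary spectra are not tabulated.

## Metamer design

For a fixed 3-primary subset, matching a cone-opic target is a 3×3 linear
solve of the receptor matrix (receptors × primaries at full drive);
singular subsets raise a degeneracy error, and solutions outside [0, 1]
drive raise a gamut error naming the violating primary (with 1e-12 slack
for rounding). Matching residuals are verified at 1e-9 relative. Contrast
maximization is deliberately not a general LP: with both subsets fixed
(the study's structure), melanopsin contrast is invariant to a common
rescaling of the cone target, so the design routine fixes the target
*direction* — by default the cone coordinates of D65, the natural white
of a display — and scales it to the gamut boundary, reporting the binding
primary; an optional photometric level selects a smaller scale.

Because the display's LED spectra are not published, the package models
them as Gaussians at the five dominant wavelengths (430/480/500/550/630
nm) with 25 nm FWHM, within the 20–30 nm range typical of single-color
LEDs; measured primary files can be substituted for real use. With this
model and subsets 430/550/630 (low-melanopic) vs 480/500/630
(high-melanopic), the achieved melanopsin contrast is 278 %, inside the
2–3× band the physical screen realized. The rod channel is deliberately
not silenced (mirroring the study, which kept rods free to preserve
melanopsin contrast); rhodopic irradiance is reported, not constrained.
Published condition tables show ~1–5 % cone mismatches between the two
arms — physical calibration error; the solver targets exact matches and
does not attempt to reproduce measured residuals.

## Pupil pipeline

Samples (3-D model diameters with confidence, nominal 200 Hz) are
filtered by *retaining* confidence ≥ 0.6 and 2 mm ≤ d ≤ 10 mm; the
boundary semantics follow a strict reading of the exclusion rules
("confidence < 0.6", "less than 2 mm and greater than 10 mm"), so
boundary values are kept. One median per test part is the analysis unit
(bin length configurable, default 20 min); the even-count median is the
mean of the two central values. Parts with a valid fraction strictly
below 2 % are flagged excluded; the denominator is the *nominal* sample
count (duration × rate), not the recorded count, so storage dropouts —
the study's stated loss mode — count against quality. Only 3-D model
output is consumed; 2-D pipeline data are ignored.

## Retinal dose

Conventional trolands are luminance × pupil area. The α-opic troland is
defined here as α-opic radiance (mW·m⁻²·sr⁻¹) × pupil area (mm²); no
standard fixes its absolute unit, and only relative comparisons enter the
downstream statistics, so the convention cancels. Irradiance→radiance
conversion assumes a uniform extended source, L(λ) = E(λ)/Ω, with Ω from
the screen geometry helper (a 27-inch 16:9 display at 60 cm gives
Ω ≈ 0.558 sr). Nonpositive doses under log10 are hard errors — no +ε
offsets. Stiles–Crawford apodization and ocular media differences between
observers are out of scope.

## Dose–response statistics

OLS slope/intercept and Pearson r are computed in closed form (normal
equations), deliberately without a fitting library, and cross-checked in
the test suite against an independent implementation. Melatonin AUC is
the trapezoid on the half-hourly grid over the light-exposure window
(−4 h to −0.5 h relative to habitual bedtime). The predictor comparison
reports the mEDI fit, the melanopic-troland fit and Δ|r|, with no
inferential test — mirroring the descriptive comparison it reimplements.
The mixed-model/ANOVA layer of the original analysis is intentionally out
of scope (routine, package-fitted, not reproducible without the cohort).

## Synthetic study generator

The generator emulates the study design: 4 luminance groups × 18
subjects × 2 counterbalanced sessions, with the published condition grid
(luminances, α-opic irradiances, mEDIs) as default inputs.

Steady-state pupil diameter is logistic in log melanopic EDI,
d(E) = d_min + (d_max − d_min)/(1 + (E/E50)^h), defaults d_max = 7.0 mm,
d_min = 2.2 mm, E50 = 25 lx, h = 0.55. A logistic nests the log-linear
decline observed over the study's 3.7–146 lx range and saturates sanely
outside it; the defaults put the noiseless LM-vs-HM diameter increase at
18.0/20.6/21.5/20.2 % across the four groups, inside the observed
16–23 % band. Samples add a per-subject normal offset (SD 0.30 mm),
stationary AR(1) noise (SD 0.15 mm, coefficient 0.95), Poisson blink
events (0.2 s⁻¹, 0.3 s) that emit low-confidence samples with sub-2 mm
diameters (exercising both filter clauses), and a 2 % scattered
low-confidence fraction. The within-condition variance of the real cohort
is not published; these noise defaults are nominal. Traces default to
10 Hz, a decimated export of the nominal 200 Hz tracker, purely for
tractability of whole-study simulation; the valid-fraction denominator
uses the configured rate consistently, and single-trace tests exercise
the full 200 Hz path.

Melatonin is a logistic baseline rise (peak 25 pg/ml, center 2 h before
bedtime, τ = 0.6 h — shape is plumbing; only the suppression factor
matters for recovery) times s(dose) = 1/(1 + (dose/S50)^k) with
multiplicative lognormal noise (σ = 0.15) and a per-subject lognormal
amplitude (σ = 0.30). The driving dose is mEDI (`corneal`, S50 = 100 lx)
or melanopic trolands computed from the subject's model pupil
(`retinal`); this switch is what makes the corneal-vs-retinal predictor
question testable: with dose-driven pupil variation the two predictors
fit melatonin AUC nearly identically (median Δ|r| < 0.05), while a
retinal driver plus strong independent pupil variation (subject SD 1 mm)
makes the troland predictor win.

All randomness flows from one seed through `SeedSequence` substreams per
subject, so a bundle is bit-reproducible. Ground truth (per-session
latent diameters, trolands, suppression factors, generating parameters)
is stored alongside the outputs.

### Parameter recovery

The recovery harness fits the logistic pupil model to the 144
subject-session medians. The study's dose range reaches neither
asymptote, so d_max/d_min trade off strongly against E50 in a free
4-parameter fit; `recover_pupil_model` therefore accepts the known
asymptotes and recovers the identifiable parameters (E50, hill). At the
default conditions E50 is recovered within a few percent (tested at
±25 %), and the dose-response slope sign is always negative. What passing
these tests shows is that the *pipeline* (filtering, binning, exclusion,
regression) is unbiased under the generator's assumptions — it cannot
certify the generator against features of real data it does not model
(pupil transients and slow drifts, task-evoked dilation, assay noise
structure, circadian phase differences between subjects).

## Numerical choices and limitations

* Rectangular Δλ summation everywhere; matching residual tolerance 1e-9
  relative; gamut slack 1e-12; half-up rounding when comparing to printed
  precision.
* Printed condition-table values are 2-dp roundings of full-precision
  spectra integrals; recomputing an EDI from a *printed* irradiance can
  therefore legitimately differ from the printed EDI by up to one unit in
  the last place, and reproduction checks use that tolerance.
* The observer tables are reconstructions (above); cone-channel spectral
  results carry a few-percent model error by construction.
* Age-dependent prereceptoral filtering, CIE 1931 colorimetry (x, y,
  CCT), display gamma/temporal calibration, per-observer fundamentals,
  blink interpolation and pupil-transient analysis are out of scope.
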