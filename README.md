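# melanophot

α-opic photometry, silent-substitution metamer design, and the
pupil/melatonin dose–response pipeline for evening-light research.

## The scientific problem

Evening light suppresses melatonin and constricts the pupil largely through
melanopsin, the photopigment of intrinsically photosensitive retinal
ganglion cells (peak sensitivity near 480 nm). Quantifying that pathway
requires three linked computations:

1. **α-opic photometry.** A corneal spectral irradiance E(λ) is weighted by
   each photoreceptor's sensitivity s_α(λ) (S-, M-, L-cone-opic, rhodopic,
   melanopic) to give the α-opic irradiance
   E_α = 1000·Δλ·Σ E(λ)·s_α(λ) in mW·m⁻², and re-expressed as the α-opic
   equivalent daylight illuminance EDI_α = E_α / K_α (lx), where
   K_α = E_α(D65)/illuminance(D65) is the daylight efficacy constant
   (melanopic: 1.3262 mW·lm⁻¹). The melanopic EDI (mEDI) is the standard
   dose metric for non-visual light effects.
2. **Silent substitution.** Photoreceptor univariance makes receptor
   responses linear in a display's primary drive weights, so a five-primary
   screen can produce pairs of spectra with identical L-, M-, S-cone-opic
   irradiance but a 2–3× melanopsin difference: a 3×3 linear solve per
   condition plus a scan of the cone target along the drive gamut.
3. **Dose–response.** Cleaned steady-state pupil diameters (median of
   artifact-filtered samples per test part) and melatonin AUCs are
   regressed on log10 dose, with the dose expressed either at the cornea
   (mEDI) or at the retina (melanopic trolands: melanopic radiance × pupil
   area), to ask whether accounting for pupil size changes the picture.

No raw recordings are distributed with the study this reimplements, so the
package ships a first-class synthetic-study generator (4 luminance groups ×
2 metameric conditions × 18 subjects) with known ground truth: a logistic
steady-state pupil model in log mEDI with AR(1) noise and blink artifacts,
and a logistic evening melatonin rise attenuated by a dose-dependent
suppression factor whose driving dose (corneal vs retinal) is a config
switch. Every pipeline stage is tested by parameter recovery against it.

## Worked example

```python
>>> import melanophot as mp
>>> mp.alpha_opic_edi(4.91, "mel")    # dimmest low-melanopic condition
3.702307344291962
>>> mp.alpha_opic_edi(193.62, "mel")  # brightest high-melanopic condition
145.99607902277182
>>> mp.melanopsin_contrast(20.11, 4.91)
309.5723014256619
>>> pair = mp.maximize_melanopsin_contrast(mp.example_device())
>>> round(pair.contrast_mel, 1), pair.cone_residual < 1e-9
(278.0, True)
```

The first two numbers convert published melanopic irradiances (mW·m⁻²)
into mEDI (3.70 lx and 146.00 lx): dividing by the melanopic daylight
efficacy constant expresses each test light as the illuminance of daylight
with the same melanopic drive. The contrast call reproduces the ~310 %
melanopsin contrast of the dimmest condition pair, and the metamer design
on the package's five-LED Gaussian screen model (430/480/500/550/630 nm)
achieves a 278 % melanopsin contrast with cone channels matched to better
than 1 part in 10⁹.

A full synthetic study with analysis:

```python
>>> from melanophot.synthetic import SimConfig, generate_study, study_outcomes
>>> out = study_outcomes(generate_study(SimConfig(seed=1)))
>>> fit = mp.fit_dose_response(out.medi_lx, out.pupil_median_mm)
>>> round(fit.slope, 2), round(fit.r, 2)
(-1.41, -0.92)
```

— pupil size declines with log10 mEDI (here −1.41 mm per decade), the
dose–response structure the generator encodes and the pipeline recovers.

There is also a CLI: `melanophot aopic --spd FILE`, `melanophot design`,
`melanophot pupil --in FILE`, `melanophot dose`, `melanophot fit`,
`melanophot simulate`.

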