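# Methods

## Model

The observer model composes three physiological stages on a fixed 390–830 nm,
5 nm grid (89 points): prereceptoral filtering by the lens/ocular media and by
the macular pigment, and self-screened absorption in the three cone
photopigments.  Ten inputs parameterize an observer: age `a`, field size `v`,
and eight deviations from the population average — five multiplicative
percentage deviations (`d_lens`, `d_macula`, `d_L`, `d_M`, `d_S`, each acting
as a factor `1 + d/100` on the corresponding optical density) and three
additive peak-wavelength shifts (`s_L`, `s_M`, `s_S`, in nm, realized by
evaluating the tabulated low-density absorbance at `λ − s` with a natural
cubic spline).  Quantal sensitivities are converted to the energy basis by
multiplying with wavelength, and each of l̄, m̄, s̄ is scaled to unit maximum
*after* that conversion, so the normalization is the final step.  With all
eight deviations at zero the pipeline is algebraically identical to the
average-observer computation; the test suite checks this against a separate
flat transcription of the recipe (`tests/oracle_ciepo06.py`).

Assumptions inherited from the average-observer framework and kept here: the
lens aging factor is piecewise linear with a breakpoint at age 60 (the two
branches agree exactly there); the linear branch is applied to all ages below
60, including ages under 20, and ages above 80 are accepted although outside
the framework's validated range; field sizes are restricted to (0, 10°]
because the peak-density formulas and basis tabulations are not meant beyond
that.  L- and M-cone peak optical densities share one formula, so their
deviations are separate parameters with a common average.

Domain guards: percentage deviations ≤ −100 are rejected (they would imply
negative optical density); |shifts| are capped at 30 nm, beyond which the
peak-normalized absorbance tables lose support (population SDs put 30 nm at
more than 15 σ, so the cap never binds in practice).  Spline evaluations
outside a table's span return 0 rather than extrapolating — extrapolating a
steep lens-density flank or a pigment tail is the one place a cubic spline is
genuinely unsafe.

## Synthetic basis tables

The canonical basis tabulations (two lens-density components, relative macular
density, three low-density pigment absorbances) and the CIE 1964 10° observer
are licensed/distributed data and are not shipped.  The packaged tables are
synthetic stand-ins constructed analytically in `indivobs/synthbasis.py`:

* **absorbances** — the Govardovskii et al. (2000) A1 visual-pigment template
  (α and β bands) at peak wavelengths 560/530/420 nm, peak-normalized on the
  grid;
* **relative macular density** — a three-Gaussian mixture peaking near 458 nm
  with a 487 nm shoulder and a violet wing, peak-normalized, effectively zero
  beyond ~550 nm;
* **lens/ocular media** — a UV chromophore Gaussian (center 360 nm, σ 46 nm,
  amplitude 1.4) plus a weak `(400/λ)⁴` scatter tail; 60% of the chromophore
  band forms the age-dependent component, the remainder plus the scatter tail
  the age-independent one;
* **CIE 1964 CMFs** — the Wyman–Sloan–Shirley (2013) multi-lobe analytic fits,
  accurate to a few percent of peak.

These reproduce the *structure* real data would have (grids, units,
normalization, monotonicity, rough shapes and magnitudes), so every algorithm
in the package runs unchanged on the real tables via
`load_basis_tables(<directory>)`.  What they do not reproduce: the exact
spectral shapes, so absolute outputs (peak wavelengths of the fundamentals,
Rayleigh mixture values, predicted SD magnitudes) are *not* comparisons
against published numbers.  Tests therefore assert contracts, invariants and
statistical recoveries, not agreement with published observer data.  Tables
ship as two-column CSVs with a sha256 manifest verified at load time.

## Population sampling

Each deviation parameter is sampled independently from `Normal(0, SD)`; no
covariance structure is imposed.  Draws violating the physical bounds are
rejected and redrawn, making the realized distributions truncated normals.  At
the default (step-2) SDs the only bound within reach is the macular one
(−100% at 2.74 σ), whose rejection shrinks the realized SD by ≈1.3%
(`truncated_sd` computes this analytically via `scipy.stats.truncnorm`);
statistical tests of the sampler compare against that truncated SD, since it
is the distribution the sampler is specified to produce.  A rejection rate
above 1% triggers a warning (it means the supplied SDs are pathological).

One seed drives a hierarchical `SeedSequence`: one child stream for ages, then
one per parameter, so a parameter's draws do not depend on another parameter's
rejection count and adding parameters later would not reshuffle earlier
streams.  Explicit age lists are used verbatim when `n` equals the list
length, subsampled without replacement when `n` is smaller, and resampled with
replacement when larger.

## Step-1 pooling

Published per-study SDs (percent of mean; nm for shifts) are pooled by
converting to variances, averaging without weights, and taking the square
root.  The packaged literature table (`data/literature_sds.csv`) pools to
19.1 / 37.2 / 17.9 / 17.9 / 14.7 / 4.0 / 3.0 / 2.5.  For lens studies that
report subject-level (age, density) records, `lens_windowed_sds` first
controls for age: at every integer age center whose ±5-year window holds at
least two subjects, SD% = sample SD (n−1) ÷ windowed mean × 100, averaged
over all feasible centers.  The n−1 convention is used for every sample SD in
the package.  Table comparisons are made at one decimal place (|Δ| ≤ 0.05);
full precision is kept internally.

## Step-2 scalar fit

Two scalars in [0,1] scale the step-1 SDs — `c1` the two prereceptoral
parameters, `c2` the six photopigment parameters — to minimize
`Σᵢ |SD_meas,i − SD_prd,i(c1, c2)|` over a battery of five matches
(city-block metric by default; Euclidean available).  `SD_prd,i` is the mean
of the a\* and b\* SDs over a Monte Carlo population of observers (default
10,000; 2,000 in the packaged recovery experiments, which keeps a full fit
under a minute on one core without changing the recovered values at the 0.05
level).

The objective is made deterministic by common random numbers: ages and an
(attempts × n × 8) block of standard normals are frozen per fit, deviations
are `z·SD`, and a draw that violates a bound takes the first valid pre-drawn
attempt (8 attempts; the probability of exhausting them is ~0.003⁸, in which
case the mean 0 is used).  Without CRN the argmin is not well defined at
finite Monte Carlo size.  Optimization is a coarse grid scan (step 0.2) to
pick a start, then Nelder–Mead with inputs clipped to the unit box
(xatol 10⁻³, fatol 3·10⁻³, evaluation budget 250); non-convergence raises an
error carrying the best point and the full evaluation trace.  Recovery
experiments (planted scalars, target generated by the same forward predictor
under the same draws) recover the truth to well within ±0.05.

`synthetic_target` stands in for the unpublished experimental matching data:
it forward-simulates a finite cohort (default 75 observers) and adds zero-mean
Gaussian intra-observer noise to each observer's a\*/b\* (default SD 1.4
CIELAB units, the magnitude of typical repeat variability).  With that noise
the fitted scalars are strongly seed-dependent at n = 75 — the noise floor
dominates matches whose true SD is ~1 CIELAB unit — which is why the
acceptance script reports a noise-free planted-scalar recovery instead of a
noisy-cohort fit.

## Match simulation

Stimuli live on 380–780 nm at 1 nm (401 points); observer fundamentals are
spline-resampled from the 5 nm model grid to that grid (zero below 390 nm,
clipped at 0).  For observer `C` (3×401) a match is the exact solve
`R = (C·S_max)⁻¹·C·S_ref`; negative components of `R` are permitted (logged at
debug level), and a primary matrix with condition number above 10¹⁰ raises a
labeled singular-match error.  Matched spectra are integrated against the CIE
1964 observer with the 683 lm/W factor (the 1 nm step is absorbed into the
common scale) — deliberately *not* against the matching observer, so matches
of different individuals land in one shared color space.  The per-match
reference white keeps the reference's spectral shape for neutral references
and is equal-energy for saturated ones, scaled so the reference stimulus sits
at L\* = 50 (equivalently Y_ref/Y_n = ((50+16)/116)³).  CIELAB uses the
standard cube-root function with the linear toe below (6/29)³.  A setup's
variability scalar is the mean of its a\* and b\* SDs; where one number per
battery is needed, those per-match values are averaged again.

Rayleigh matches solve the 2×2 system in L and M for unit-radiance
monochromatic primaries (700/550/589 nm by default, evaluated off-grid by
spline) and report the red fraction `w_R/(w_R + w_G)` ∈ [0,1].  This is a
fixed linear instrument scale; mapping to a particular anomaloscope's display
units would need that instrument's (unpublished) affine calibration, so
SDs are reported in red-fraction units.  The lms→rgb transform inverts the
3×3 matrix of lms values at 645.2/526.3/444.4 nm, making each rgb function
exactly 1 at its primary and 0 at the other two.

## Validation scenarios

`predict_population_sd` repeats a cohort draw `n_repeats` times (default 100)
and averages the per-repeat SDs; the per-repeat values are returned for
dispersion diagnostics.  Scenario kinds and their default problem sizes mirror
the three classic settings for such models: 49 observers at 10° evaluated as
rgb CMFs at 35 wavelengths equally spaced in wavenumber between 392.2 and
714.3 nm (105 SD cells averaged; an optional per-observer area-normalized
variant serves figure-style comparisons); 76 observers at 8.5° on the
five-match battery (mean of the 10 a\*/b\* SDs); 113 observers at 2° Rayleigh
matching.  Measured-versus-predicted comparisons use a two-sample, two-tailed
F-test (`F = var_a/var_b`, n−1 convention, p doubling the smaller tail);
ingesting the measured datasets themselves is left to the user, as they are
not redistributable.

## Synthetic five-match battery

The experimental spectra of the five-match battery are unpublished, so
`generate_fixture_stimuli("five_matches")` builds a synthetic battery with the
same character: three Gaussian display-like primaries (610/540/450 nm peaks,
σ 25/28/18 nm) and five references — flat, cool-sloped and warm-sloped
broadband (neutral; reference-shaped white, hence exactly a\* = b\* = 0 for
the CIE 1964 observer) plus saturated cyan (Gaussian at 490 nm) and orange
(600 nm) under an equal-energy white.  Dominant wavelengths of the saturated
references are verified in the tests (cyan within 480–500 nm).  The battery is
deterministic; a seeded `toy` variant exists for quick experiments.

## Numerical choices

* Natural cubic splines everywhere (`CubicSpline(..., bc_type="natural")`),
  zero fill outside the source span, negative spline undershoot clipped to 0
  where the quantity is a sensitivity or absorbance.
* Unit-peak normalization divides by the array maximum, so the peak sample is
  exactly 1.0 in floating point.
* SD computations use ddof=1 throughout; a single-observer "population"
  falls back to ddof=0 rather than dividing by zero.
* Condition-number limit 10¹⁰ for every 3×3 (and 2×2) solve; beyond it the
  operation raises rather than returning amplified noise.
* Batched paths (`cone_fundamentals_batch`, `lms_to_rgb_batch`,
  `rayleigh_match_batch`) are exact vectorizations of the per-observer
  functions and are tested for bit-level agreement with them.

## Limitations

* The packaged basis tables and match battery are synthetic; absolute outputs
  are structurally realistic but not comparable to published measurements
  (see above).  Passing tests demonstrate correctness of the machinery and
  the statistical behavior of the Monte Carlo pipeline, not agreement with
  real observer populations.
* Parameters are sampled independently; real physiological parameters may
  covary (e.g., lens density with age beyond the modeled mean trend).
* Known covariates of the parameters — gender, ethnicity, smoking, diet,
  genetics, pupil entry, retinal illuminance — are not model inputs; they are
  not yet quantified well enough to parameterize.
* Intra-observer (repeat) variability is modeled only as additive CIELAB
  noise in the synthetic target generator, not as a property of the observer
  model itself.
* The Rayleigh scale is the red fraction of mixture radiance, not any
  specific anomaloscope's display unit.
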