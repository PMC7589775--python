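# Methods

## Scope and model overview

`swirauth` implements a non-targeted authentication workflow for binary
powder mixtures imaged by a line-scan SWIR hyperspectral system, with almond
powder as the target class and apricot or peanut powder as adulterants. Two
models carry the science: a one-class classifier (DD-SIMCA) that answers
"is this specimen pure almond?", and a PLS1 regression that answers "how
much adulterant does it contain?". Everything else — simulation,
calibration, segmentation, extraction, pretreatment, mapping — exists to
feed those two models reproducibly.

## The synthetic acquisition model

No public data set exists for this problem, so the simulator is a
first-class component, not a test fixture. It emulates:

- **Spectral axis**: 275 bands, 900–2494 nm (uniform, step ≈ 5.82 nm);
  analysis restricted to 935–1965 nm (177 bands) downstream.
- **Endmembers**: pure-powder reflectance is a flat baseline (0.6) minus
  Gaussian absorption dips at the lipid (1165, 1395, 1692, 1734 nm),
  protein (995, 1200, 1800 nm) and O–H water (1450, 1940 nm) bands.
  Amplitudes are qualitative but obey the compositional ordering that
  drives the problem: peanut > almond at 1165/1395 (peroxide value) and
  1200 nm (protein); almond deepest at 1734 nm (long-chain fatty acids);
  apricot lipid amplitudes 0.6× almond (lower oil). Consequently the
  almond–apricot spectral distance is about twice the almond–peanut
  distance, which reproduces the observed difficulty ordering (peanut is
  harder to screen and to quantify).
- **Varieties**: the second almond variety scales the water-band amplitudes
  by 1 + 0.05 (per-band variety signs, +1 on the O–H bands, 0 elsewhere).
  This choice is deliberate: cultivar/origin differences show up strongly in
  moisture, and a moisture-borne difference is nearly orthogonal to both
  adulteration directions. The emulated consequence — varieties are
  spectrally distinct, yet a concentration model calibrated on variety 1
  transfers to variety 2 with only a small bias — matches the behaviour the
  workflow is designed around. A uniform amplitude shift would instead be
  ~0.7-collinear with the adulterant directions and make cross-variety
  quantification fail, which is not what is observed in practice.
- **Mixing**: binary mixtures mix linearly in the mass fraction, exactly,
  before corruption. No particle-size or nonlinear radiative effects.
- **Noise** (per pixel, reflectance units): measured spectrum =
  `b·s + a + tilt·λ_norm + ε` with `b ~ N(1, 0.05)` (multiplicative
  scatter), `a ~ N(0, 0.02)` (offset), `tilt ~ N(0, 0.01)` (illumination
  drift across the band axis), `ε ~ N(0, 0.01)` iid per band (1 % sensor
  noise). All four are per-pixel; well-averaged spectra are correspondingly
  cleaner (≈ 1/√400 for a half-well).
- **Geometry**: 5×5 plates of circular wells, 32 px diameter at 40 px
  pitch on a 324-px scan line (≈ 1.3 px/mm for 25 mm wells, ≈ 800 powder
  pixels per well). Background sits near the dark level.
- **Radiometry**: white reference at 0.9 and dark current at 0.05 of full
  scale, so reflectance calibration is non-trivial and exactly invertible
  by construction.
- **Determinism**: one seed per design; per-well generators are spawned
  from it (`numpy` `SeedSequence`), so cubes are bit-reproducible.

What the simulator does *not* emulate: particle-size scattering physics,
nonlinear mixing, spatial within-well gradients, detector nonlinearity,
wavelength miscalibration, stray light. Tests passing on this generator
therefore demonstrate the correctness and calibration of the analysis chain
under a linear-mixing, Gaussian-noise acquisition — not performance on real
instrument data.

## DD-SIMCA

Training on pure-almond spectra only. After optional pretreatment, PCA of
the centered matrix gives loadings for `A` components with eigenvalues
`s_a²/(n−1)`. Each sample yields a score distance
`h = Σ_a t_a²/λ_a` (leverage) and orthogonal distance `v = ‖residual‖²`.
Both are modelled as scaled chi-squares; their degrees of freedom are
estimated from the training distances by moments, `N = round(2·mean²/var)`
clipped to [1, 250] (a zero-variance sample logs a warning and takes the
cap). The total distance `c = N_h·h/h₀ + N_v·v/v₀` is referred to a
`χ²(N_h+N_v)` quantile: acceptance cutoff at `1−α`, outlier cutoff at the
order-statistic-corrected `(1−γ)^(1/n)` so that a clean training set of
size `n` produces a spurious outlier call with probability ≈ γ. Boundaries
are inclusive (`c ≤ cutoff` is inside). Classical (non-robust) moment
estimators are used throughout.

Numerical notes: with eigenvalues defined over `n−1`, the training score
distances average to exactly `A(n−1)/n`; degrees of freedom are rounded to
integers for stable quantiles; `A` must stay below the rank of the centered
matrix or fitting refuses.

**Factor selection.** `select_factors` picks the `A` whose training extreme
count is closest to its expectation `α·n` (ties to fewer factors). Because
the moment-based normalizers self-calibrate, this criterion has little
resolving power when the target class is smooth and unimodal — it
identifies the true dimension only when unmodelled structure visibly breaks
the chi-square calibration (e.g. clustered scores). The bundled study
therefore fixes the factor count instead of relying on automatic selection.

**Defaults in the bundled study: SNV pretreatment, A = 2.** The acquisition
model's dominant nuisance is per-spectrum multiplicative scatter plus
offset, which SNV removes exactly; what remains of the pure class is the
cultivar contrast and a residual tilt direction — two structured modes,
hence two factors. Derivative pretreatments were considered and rejected
for the screen: a second derivative amplifies uncorrelated band noise while
shrinking the broad absorption differences that separate adulterated from
pure spectra, which measurably raises the screen's detection floor. Both
choices are config-exposed (`ddsimca_preprocess`, `ddsimca_factors`).

## PLS1

NIPALS with a single response, centering only (no per-band scaling — the
spectroscopy convention; derivative pretreatments already equalize scale).
One fit extracts factors sequentially, so leave-one-out cross-validation
obtains held-out predictions for every candidate factor count from a single
fit per fold; the factor count minimizing RMSECV is selected (ties to fewer
factors). The fitted model collapses to `ŷ = intercept + x·β`, which is the
form the per-pixel mapping consumes. Validation R² is computed about the
validation set's own mean; SEC/SEP are plain RMSEs on
calibration/validation residuals. A vanishing NIPALS weight norm signals
rank exhaustion and refuses the factor count.

## Pretreatments

All row-local except MSC, whose reference (the calibration-set mean
spectrum) is learned in `fit` and frozen — validation data never informs
the transform. Savitzky–Golay filters (default window 11, polynomial order
2, sensible at ≈ 5.8 nm spacing) are applied in valid mode: edge bands
where the full window does not fit are dropped (band axis shrinks by
window − 1) rather than padded, keeping derivative semantics exact;
derivatives are per band index, not per nm, since only shapes feed the
models. Degenerate rows (constant under SNV/range, zero mean/max, vanishing
MSC slope) raise by default; the mapping stage masks such pixels as missing
instead.

## Segmentation and extraction

The powder/background threshold is the midpoint of the two cluster means of
a 1-D two-means clustering of the mean-over-bands image (Lloyd iteration
initialized at the extremes — deterministic), then foreground components
under 10 px are discarded. Wells are assigned by nearest truth-table
center. Each well splits about its centroid column; the centroid column
itself goes to the left half (documented tie-break; halves of an
odd-column disk are therefore unequal by one column). Reflectance is never
clipped; values outside [0, 1] (noise, specular) are carried as-is.

## The bundled study design

Mirrors the screening study's sample bookkeeping, two half-spectra per
well: DD-SIMCA calibration 100 pure half-spectra (25 wells × 2 varieties);
validation-1 110 at 0–50 % in 5 % steps (variety 1); validation-2 50 at
{0, 7, 15, 22, 30} % (variety 2); external blind sets 80 at
{0, 7, 15, 22, 30, 40, 45, 50} % with doubled scatter-slope spread
(perturbed illumination); PLS1 calibration 66 (3 wells per concentration),
validation-1 44 (variety 1), validation-2 44 (variety 2; well counts
5,5,4,4,4 over the coarse concentrations, since 44 spectra do not divide
evenly over five levels). Where replicate bookkeeping in the source design
is ambiguous, ten half-spectra per concentration is used throughout. Runs
are deterministic given the study seed; per-set seeds derive from it.

One run renders 22 plates (≈ 210×324×275 rasters); cubes are processed in
memory and the on-disk artifacts are the extracted spectra (CSV), models
(YAML + npz), decisions/predictions (CSV), concentration maps (PNG + JSON)
and the report JSON. A full default run takes on the order of one to two
minutes on a single CPU.

## Known limitations

- The simulator's endmember amplitudes are ordinal, not fitted to measured
  spectra; absolute SEC/SEP values depend on them, only orderings and
  calibration properties are meaningful.
- The extremes-matching factor-selection rule is weakly identifying on
  smooth classes (see above).
- DD-SIMCA here is the classical variant: no robust estimators, no
  multi-class extension, no PLS-DA comparison.
- ENVI I/O covers band-sequential float rasters with the header fields the
  simulator writes; it is not a general ENVI reader.
- Per-pixel mapping assumes the model's pretreatment is meaningful on
  single-pixel spectra; for nonlinear pretreatments the well mean of pixel
  predictions need not equal the prediction of the well-mean spectrum.
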