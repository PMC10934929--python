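# Methods

## The classification model

`candlepls` treats egg-fertility discrimination as regression-then-threshold.
Mean transmittance spectra (n eggs × 167 bands) form X; the response is the
numeric class coding y ∈ {1 (fertile), 0 (non-fertile)}. A NIPALS PLS1 model
is fitted on mean-centered X and y — no variance scaling by default, since
transmittance bands share units and comparable scales (an `autoscale` switch
exists for sensitivity studies). Only X is deflated; y-deflation is redundant
for a single response. Extraction stops early if the residual covariance
‖X'y‖ falls below 1e−12 of its initial value, so requesting more components
than the data's rank silently yields the deepest available model (the
effective count is recorded in `PLSModel.A`).

The continuous prediction ŷ = X·b + intercept is unclipped; classification
is a moving threshold: **ŷ < TR ⇒ non-fertile, ŷ ≥ TR ⇒ fertile** (ties go
to fertile, making TR a strict lower bound for the fertile call). Under this
coding, raising TR can only convert fertile calls to non-fertile ones, so
non-fertile recall (TPR) is non-decreasing and fertile recall (TNR)
non-increasing in TR — a property the tests verify over 1000 random score
vectors. The direction and coding are the unique combination consistent with
the published behaviour of the threshold grid 0.50–0.85 (raising TR from
0.55 to 0.81 raises TPR while FPR grows).

## Component selection

Candidate component counts (default 5, 10, …, 50) are scored by full
leave-one-out cross-validation: sample i is predicted by a model fitted to
the other n−1 samples, the pooled out-of-fold predictions are classified at
a fixed selection threshold (default TR = 0.80), and one confusion-matrix
rate (TPR by default; TNR or OVA selectable) ranks the candidates. The
chosen count is the **smallest grid member attaining the grid maximum**
(within a configurable tie tolerance, default 0) — a first-plateau rule:
adding components beyond the plateau buys nothing and costs robustness.
Pooling the singleton folds is the only coherent way to form rates from LOO.

Because NIPALS components are nested (the first a columns of W, P, q do not
depend on how many more are requested), each fold is fitted once at the
largest grid value and every smaller candidate is read from the same fit;
the sweep over a 10-point grid costs one fit per fold, not ten.

## Rare-class evaluation

Non-fertile is the positive class: it is the rare class (≈1:13) and the one
an industrial rejector must catch. Rates are percentages computed in full
precision; rounding (half-up, two decimals) happens only at presentation.
A rate with a zero denominator is reported as *undefined* rather than 0 —
silent zeros would corrupt monotonicity checks on single-class folds. ERR
is defined as 100 − OVA, which reproduces every published (OVA, ERR) pair.
One published day-0 table (white eggs, TR 0.81, 5 components) is internally
inconsistent — its false-positive cell reads 0/314 while its TNR reads
310/314 — so no value from it is asserted anywhere in this package.

OVA satisfies the identity OVA = (P·TPR + N·TNR)/(P+N) with P = TP+FN,
N = TN+FP; the property suite fuzzes this along with the complementarity
relations TPR+FNR = 100 and TNR+FPR = 100.

## Image processing

Frames are segmented once, on band 38 (the transmittance maximum), by global
Otsu thresholding followed by 4-connected component labelling; components
below 0.5% of the frame area are discarded and the four largest survive
(decreasing area, row-major top-left pixel breaking ties). The resulting
mask is reused verbatim at every band — never re-thresholded per band — and
the egg's mean spectrum is the per-band arithmetic mean over its pixels.

The wavelength axis is linear with inclusive endpoints 900 and 1700 nm and
1-based band indexing: 166 intervals of ≈4.82 nm, matching the instrument's
stated ≈4.79 nm resolution to rounding. Band 38 maps to ≈1078.3 nm under
this convention; instrument documentation that quotes 1076 nm for the same
band is treated as approximate, and the convention is recorded in all output
metadata. ENVI I/O supports BSQ and BIL interleaves with integer and IEEE
float sample types; anything else is rejected loudly. No spectral
pre-processing (smoothing, SNV, normalisation) is applied before PLS.

## The synthetic generator

Real imaging data were never deposited, so the generator emulates the
statistical structure the analysis assumes. Each mean spectrum is

  baseline(λ) + amp(class, day) · exp(−(λ − λ₃₈)²/2σ²) + noise(λ),

truncated at zero. Defaults, chosen once as field-realistic values:

| parameter | default | meaning |
|---|---|---|
| n_fertile / n_nonfertile | 312 / 23 | day-0 cohort imbalance |
| n_bands, range | 167, 900–1700 nm | instrument axis |
| peak_band / peak_width | 38 / 12 bands | transmittance peak position/σ |
| fertile_amp | 1.00, 0.90, 0.80, 0.72, 0.65 | peak amplitude, days 0–4 |
| nonfertile_profile | 1.00, 0.85, 1.05, 1.00, 0.90 | day shape of the class gap |
| separation (δ) | 0.20 | class mean-amplitude gap |
| noise_sd | 0.02 | per-band within-class sd |
| noise_modes | 8 | rank of the deviation field |
| baseline level / tilt | 0.20 / −0.08 | smooth additive profile |

The fertile amplitude is constrained non-increasing over days 0–3 (the
developing embryo absorbs progressively more light); the non-fertile day
profile multiplies δ and may be non-monotone. δ = 0 is an exact null: both
classes then share one distribution. The default δ = 10 × noise_sd is the
benchmark's stated recovery condition.

**Noise model.** Within-class variation is a smooth random field of exact
rank `noise_modes`: a random combination of 8 broad Gaussian modes spanning
the axis, scaled to per-band sd `noise_sd`. This reflects what mean spectra
actually look like — averaging ~10³ ROI pixels suppresses independent
per-band sensor noise, and the egg-to-egg variation that remains (shell
thickness, pigmentation, albumen volume) is spectrally smooth. The finite
rank also matters statistically: adaptive PLS fitted to high-dimensional
unstructured noise produces wildly spread cross-validation predictions at
the null (the overfitting is scale-free in the noise magnitude), whereas
with a finite-rank field the NIPALS extraction exhausts the covariance,
early-stops, and null predictions concentrate at the class-prevalence mean —
the behaviour the published 5-component operating points show on real data
(everything called fertile, OVA = prevalence).

**What passing the synthetic benchmark shows — and does not.** It shows the
machinery is correct: segmentation recovers known footprints, the PLS/LOO
code matches independent oracles, thresholds behave monotonically, a 10σ
class gap is recovered perfectly under the study's imbalance, and a null
cohort yields prevalence-level accuracy rather than optimistic artefacts.
It does not show that real eggs are separable on day 0: the generator's
effect size is its own, not an estimate of the real one, and real spectra
carry structure the generator omits (pigmentation differences between
brown and white shells, scattering, instrument drift, pixel-level
heterogeneity within an egg). Published accuracies that lack printed
confusion counts are not reproduced here; printed counts can be verified
through the counts-only entry point.

## Numerical choices

- Weight vectors are unit-norm; scores orthogonal to ≤1e−8 relative.
- b = W(P'W)⁻¹q via `numpy.linalg.solve`; with A = rank(X), predictions
  coincide with least squares to ≤1e−8.
- Rounding half-up at two decimals via `decimal` on the repr of the float,
  so 2.675 → 2.68 despite binary representation.
- Segmentation tie-break: equal-area components order by row-major top-left
  pixel. Blank frames (no contrast, or nothing above min_area) return an
  empty mask list with a warning rather than an error.
- Degenerate responses (constant y, or X carrying no covariance with y)
  raise a dedicated error; LOO propagates it with the fold index.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
study's day-0 cohort size (335 spectra × 167 bands, component grid to 50)
and use reduced cohorts (40–68 spectra, grids to 10) for property tests
that repeat the pipeline many times; oracle comparisons use n ≤ 30 where
enumeration is exact. The complete suite runs in a few seconds on one CPU.

## Known limitations

- The generator models transmittance intensity additively; no Beer–Lambert
  inversion, radiometric calibration, or shell-optics modelling.
- Masks are connected components, not egg-shape models; touching eggs would
  merge.
- Only PLS1 with a single binary response; no PLS2, kernel or sparse
  variants, and no cost-sensitive threshold optimisation — thresholds are
  swept and inspected, mirroring the workflow this package implements.
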