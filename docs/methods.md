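# Methods

## The measurement problem

A metastatic lesion compromises its own vasculature (blood–tumor barrier),
but the surrounding brain — brain adjacent to tumor, BAT — is histologically
normal tissue whose vessels may nonetheless leak. The analysis quantifies
that leak three ways: (i) a fluorescent-tracer fold-change profile versus
distance from the tumor margin, (ii) a unidirectional transfer constant
K_in per region, and (iii) an absolute drug-concentration map from
quantitative autoradiography (QAR). All three consume 2-D section rasters
with known physical pixel size; all distances are in micrometres, measured
from the lesion margin, negative inside the tumor.

## Segmentation

Tumor pixels are classified per pixel: eGFP intensity strictly greater than
`fold_threshold` (default 3.0) times a background estimate. The background
is the global median of the eGFP channel (optionally after excluding a
provisional tumor mask); the median is robust while lesions occupy a
minority of pixels, which holds for coronal sections of this disease model.
The threshold is deliberately a plain multiplier — the underlying
protocol's rule is approximate ("roughly 3-fold"), so anything cleverer
would be false precision; the multiplier is a config parameter.

Cancer-cell clusters whose minimum boundary-to-boundary Euclidean distance
is ≤ `max_gap` (default 100 µm) belong to one lesion, under transitive
closure. The production path evaluates the exact rule with one distance
transform per connected component; a brute-force oracle (explicit pairwise
distances over boundary pixels, `merge_groups_bruteforce`) ships alongside
and the tests require exact agreement, including at gaps of 99 and 101 µm.
Morphological closing with a disc of radius `max_gap/2` is *not* used as
the merge decision — closing fails to connect components whose gap is close
to the disc diameter (the dilation overlap is too thin to survive the
erosion) — but it is retained to build each merged lesion's **hull**
(closing + hole fill), which defines the margin: hull pixels with at least
one non-hull 4-neighbour. Components use 8-connectivity, margins the
4-neighbourhood, the standard raster-boundary convention.

## Ring analysis

`signed_distance_map` is the Euclidean distance transform of the margin
pixel set, negated inside the hull. Rings are half-open signed-distance
bins `(lo, hi]` of width 8 µm; margin pixels (d = 0) therefore fall in the
first inward ring. The nominal 300-µm extent is not an integer number of
8-µm rings, so the default is 37 full rings per direction (±296 µm); both
width and extent are configurable, and a non-divisible extent is an error
rather than a silent truncation.

Per ring the statistic is sum intensity / area (AU/µm²), normalised to a
contralateral reference: the lesion's tumor+BAT footprint mirrored across
the vertical image midline, minus every lesion's territory, requiring at
least 100 clean pixels; a user-supplied reference mask is the fallback
(sections are not guaranteed to be mounted symmetrically). Fold change is
then gain-invariant by construction. The BAT summary is the
pixel-count-weighted mean fold over outward rings whose upper edge is
≤ 100 µm (12 rings at the default width).

Where lesions are close, contested outward pixels go to the nearer margin
and pixels inside another lesion's hull are always excluded, so no pixel is
counted twice. The generator's placement rules make shells disjoint by
construction; the exclusion logic is exercised with hand-built fixtures.

## Kinetics

Single-time uptake: `K_in = C_br(T) / ∫₀ᵀ C_bl dt`, with the blood integral
computed trapezoidally from the sampled curve (no model fit, no
extrapolation beyond the last sample; an interior T interpolates the final
partial interval). The estimator is exactly linear in C_br and inversely
linear in the AUC; the noiseless forward simulation `C_br = K·AUC` is the
identity, and both properties are tested. There is no vascular-volume
correction term and no multi-time (Patlak-slope) variant — the single-time
form is the method of record here precisely because lesion heterogeneity
makes pooling time points across animals unreliable.

Fluorescence-to-amount conversion is not part of the estimator: uptakes
arrive already converted, with an optional linear factor (`au_to_amount_per_g`,
default 1.0) for user-supplied calibrations. Values are reported on the
10⁻⁵ mL/s/g scale conventional for BBB transfer constants.

Groups are compared by one-way ANOVA with Holm–Šidák-adjusted pairwise
equal-variance t-tests at α = 0.05. The follow-up procedure is a
convention choice (recorded in output metadata); with two groups the ANOVA
p equals the t-test p exactly. Fully degenerate data (zero variance
everywhere) reports p = 1 with a warning instead of NaN.

## Autoradiography

Calibration is ordinary least squares of intensity on concentration over
≥ 3 co-exposed standards with ≥ 2 distinct levels. The line keeps its
intercept: phosphor screens have background fog, and forcing the origin
would bias low concentrations. (A log-linear form would suit a wider
dynamic range; the linear default matches the modest span of the packaged
standards, 1–700 ng/g.) Inversion is per pixel; negative results are
floored at zero and flagged, values above the top standard are kept but
flagged — flagged, never silently clipped. Square ROIs include pixels
whose centers lie in a half-open box, so tiling squares partition a region
exactly and their weighted mean equals the region mean. Radial
concentration profiles reuse the ring geometry at 50-µm bins to ±300 µm
(100-µm bins available via config). Calibration+inversion is the exact
identity on noiseless data, and profiles are invariant to an affine
re-exposure applied to image and standards alike; both are tested.

The autoradiograph and the lesion labels are assumed co-registered on one
pixel grid; registration (done manually against an adjacent stained section
in the wet-lab workflow) is out of scope.

## Synthetic data generator

The generator draws what the analysis assumes, with known truth:

- **Lesions**: discs perturbed by radial harmonics of orders 2–5 with total
  amplitude ≤ 20% of radius (default 15%) — star-convex, so margins are
  non-trivial but brute-force distance oracles stay cheap. Radii uniform in
  120–200 µm (tracer sections) at 4 µm/pixel. Placement keeps margins
  ≥ 2×(300 µm + max effective radius) apart and ≥ 300 µm + radius from the
  border (shells never overlap or clip), and, for fluorescence sections,
  confines the tumor+BAT footprint to the left half-image so the mirrored
  contralateral reference is clean by construction. Infeasible requests
  fail with a placement error after bounded retries.
- **Tracer profile**: fold(d) = plateau for d ≤ 0; 1 + (peak−1)·e^(−d/L)
  for 0 < d < 300 µm (or a constant step over (0, L]); 1 beyond. The decay
  length L = 60 µm puts the exponential's 0–100 µm window mean at ~1.7
  (peak 2.5, Texas Red 625 Da) and ~1.4 (peak 1.8, 3-kDa dextran), inside
  the reported BAT ranges for those tracers; the functional form itself is
  a modelling choice — the source data show monotone decay but no curve
  shape. Painting uses the same hull-margin distance the analysis will
  compute, so the noiseless generate → segment → profile round trip is
  exact to float tolerance (and is tested to be).
- **Heterogeneity**: one lognormal factor per lesion (mean 1, CV default
  0.2) multiplies the *enhancement* above baseline, so distant tissue stays
  at baseline and cohort means stay centred on the nominal profile. The
  0.2 default keeps 15-lesion cohort means estimable (SEM ≈ 5%) while still
  dominating within-lesion noise — real lesion-to-lesion spread in this
  disease model is larger, so passing recovery tests here demonstrate
  correctness of the estimator, not the tightness achievable in vivo.
- **Noise**: Poisson on the photon-scaled signal (scale 1 photon/AU) plus
  additive Gaussian read noise (2 AU), the standard two-component camera
  model. For autoradiographs the gain is 20 AU per ng/g over an offset of
  50 AU — high-SNR, as phosphor screens after multi-day exposures are —
  which keeps the floor-at-zero rule from biasing the ~1 ng/g distant
  baseline (floor bias < 0.01 ng/g at these settings).
- **Blood curves**: mono-exponential after an instantaneous bolus, sampled
  uniformly; defaults c0 = 10 µg/mL with half-life 300 s over the 600-s
  tracer circulation (3600 s over 8 h for the drug). The true plasma
  kinetics of these tracers are not characterised in the source data; the
  mono-exponential is a stand-in, and every kinetics result that matters is
  checked against closed forms that hold for any positive curve.
- **Calibration strip**: square patches at (1, 5, 20, 80, 250, 700) ng/g
  rendered along the left margin with the same noise model; the measured
  patch means are what the calibration fit consumes.

What the generator does **not** emulate: optical PSF blur, vignetting and
illumination gradients, anatomical structure in the background, partial
lesions at section edges, 3-D shell geometry collapsed into 2-D sections,
tissue autofluorescence spectra, or exposure-time physics of the phosphor
screen. Recovery tests therefore validate the estimators under the model's
own assumptions; they do not certify performance on real sections where
those violations matter.

## Cohort defaults and problem sizes

Packaged cohorts mirror the study design: n = 6 subjects per region per
tracer with 10% CV measurement noise for K_in; n = 6 sections per
fluorescence cohort; n = 15 lesions for QAR with regional truths
(tumor 529, BAT 86.7 / 35.4, distant 1 ng/g). Sections are 288×640 px
(fluorescence) and 320×320 px (autoradiographs) at 4 µm/pixel, one lesion
each — large enough for a full ±300 µm shell plus a clean reference, small
enough that the whole validation suite runs in a few minutes on one CPU.
Per-cohort random streams are decorrelated children of the user seed
(`SeedSequence`), and every generator output is bit-identical under a fixed
seed.

## Known limitations

- The K_in recovery check asserts each of six region×tracer cohort means
  within 2 SEM of truth at a single fixed seed; with n = 6 that is a
  t-ratio test with ≈ 10% per-cell false-alarm rate, so the all-cells
  conjunction is satisfied at only ~55% of seeds even though the estimator
  is exactly unbiased. The companion Monte-Carlo checks (ANOVA power ≥ 80%
  over 200 cohorts, region ordering, noiseless identity) are the robust
  evidence of correctness.
- The contralateral mirror assumes symmetric mounting; asymmetric sections
  need an explicit reference mask.
- Merging is exact but quadratic in the number of clusters; sections with
  hundreds of fragments would need a spatial index, which real sections of
  this model do not require.
- QAR accuracy is bounded by the per-raster calibration intercept error
  (~0.07 ng/g at the packaged SNR), which is the dominant uncertainty on
  the distant-brain baseline.
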