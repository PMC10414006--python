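# Methods

This note documents the models, conventions and design choices behind
`bbbhotspots`, and what the synthetic validation does and does not show
about real data.

## Patlak model and estimation

Each voxel's tissue concentration curve is modelled as

C_t(t) = v_P · C_p(t) + PS · ∫₀ᵗ C_p(τ) dτ

where C_p is the plasma (vascular input) concentration, v_P the fractional
plasma volume and PS the permeability surface area product in min⁻¹ (the
plasma integral is carried in mM·min). The model assumes cerebral blood
flow high relative to the leakage rate and negligible backflux of contrast
over the acquisition; no intercept or efflux term is fitted.

Estimation is ordinary least squares on the two-column design
[C_p(t), ∫C_p]. The fit is linear, so noise-free synthetic curves are
recovered to machine precision and i.i.d. Gaussian concentration noise
yields unbiased estimates. Negative PS and out-of-range v_P estimates are
genuine small-signal noise outcomes (whole-group mean PS can be negative in
low-leakage tissue) and are reported unmodified; quality control drops
non-finite curves from the fit mask rather than imputing. The fit window
defaults to all post-arrival frames; early-frame exclusion is configurable.

Display convention: PS and v_P are reported ×10⁴ in tables, CVR ×10².

## Vascular input function

A population biexponential, cp(t) = a1·e^(−m1·(t−t0)) + a2·e^(−m2·(t−t0))
for t ≥ t0 and zero before arrival, stands in for a measured
superior-sagittal-sinus time course. Defaults: a1 = 2.5 mM, m1 = 0.01 s⁻¹
(fast distribution), a2 = 0.8 mM, m2 = 2×10⁻⁴ s⁻¹ (slow washout), arrival
30 s, giving a plausible ~3.3 mM post-bolus plasma peak. No hematocrit
correction is applied. The DCE sampling grid (20 min at 24 s per volume) is
a configurable convention of the synthetic protocol, chosen to resemble
leakage-oriented low-temporal-resolution protocols; it is not asserted to
match any particular scanner product.

## Synthetic phantoms and what they emulate

Phantoms are ellipsoidal brains (default 48³ voxels of 2 mm) with grey
matter shell, white matter interior, lateral ventricles, brainstem and
cerebellum, plus three lesion classes: lacunes (CSF-filled cavities strictly
inside WM, mutually separated so each is one connected component),
periventricular/confluent WMH blobs grown from the ventricle surface, and
1–2-voxel-radius microbleeds. A geometric atlas partitions the brain into
cerebellum, internal capsule, temporal, anterior/posterior ventricle-horn
WM and centrum semiovale, split left/right.

PS/vP truth is piecewise constant per tissue class (defaults: NAWM PS
0.43×10⁻⁴ min⁻¹, WMH 0.91×10⁻⁴; v_P 41×10⁻⁴ and 62×10⁻⁴), optionally
multiplied in white matter by a smooth log-normal texture (Gaussian field,
correlation scale 1.5 voxels, log-SD 1.0 in cohort conditions). The texture
matters: a per-patient *relative* decile applied to near-constant truth
plus i.i.d. fit noise selects 10% of voxels at random, which percolates
under 26-connectivity into fragmented, implausible clusters; real PS maps
are spatially structured and produce tens of compact hotspots per patient.
The log-normal form keeps truth non-negative. Planted foci add a fixed PS
amplitude (default 5×10⁻⁴ min⁻¹, radius 2 voxels, clipped to the WM-class
mask) at configurable attachments: lacune rim, inside WMH, WMH rim, CMB
rim, or random white matter; the focus index records ground truth for
recovery scoring.

DCE synthesis is the exact forward model plus i.i.d. Gaussian concentration
noise (default SD 0.005–0.01 mM). The generator does not emulate: MR
signal/relaxometry and T1-to-concentration conversion, motion or
registration artefacts, spatially correlated or Rician noise, perivascular
space geometry, or partial-volume effects. Passing tests therefore
demonstrate correctness of the estimator, geometry and statistics under the
stated noise model — not robustness to acquisition physics.

Two-arm cohorts (sporadic SVD vs CADASIL, default 69 patients with 27/69
CADASIL) draw age, sex, risk factors, lesion counts and CVR from
arm-specific distributions shaped like a typical sporadic/monogenic SVD
cohort; CADASIL patients are younger with fewer vascular risk factors but
heavier lesion burden and lower WMH CVR. Fazekas grades are mapped
monotonically from WMH burden, not rated from images; CVR is a sampled
covariate, not computed from BOLD; missingness (~9%) is marked NaN, never
imputed. The planted colocalization effect makes each lacune's probability
of carrying a rim focus a logistic function of the patient's WMH CVR
(default −0.25 log-odds per display unit above the cohort mean).

## Masks, hotspots, colocalization

- "One voxel-kernel erosion" uses the full 3×3×3 structuring element
  (26-neighbourhood); the 6-neighbourhood cross is configurable.
- The erosion is applied to the WM ∪ WMH mask with internal lesion cavities
  (lacunes, CMBs) treated as filled, then interiors are removed. This
  strips the partial-volume-prone outer boundary without deleting the WM
  rim around each cavity — without cavity filling, no hotspot could ever
  touch a lacune edge by construction. Lesion "deep white matter"
  membership tests the lesion centroid against the eroded filled mask.
- Decile threshold: k = round(0.10·N) with N the mask size, threshold at
  the k-th largest PS, ties at the threshold included. The threshold is
  per-patient (relative), making hotspot sets invariant under strictly
  monotone transforms of the map.
- Contiguity is 26-connectivity by default ("contiguous" read most
  inclusively); minimum cluster size 5 voxels. Component labels follow
  raster-scan order, so outputs are bit-reproducible.
- Regional load per side: 0 hotspots → 0 (absence), 1–2 → 1 (low), 3–5 → 2
  (medium), ≥6 → 3 (high); left+right sums span 0–6. The count boundaries
  are this package's convention and are surfaced in output metadata.
- Edge contact = overlap with the lesion or its one-voxel outer band
  (26-neighbourhood dilation minus the lesion); the radius is configurable.
  "Within WMH" demands full containment of every hotspot voxel, which makes
  within/at-edge mutually exclusive per hotspot; a majority-containment
  rule is available since borderline readings plainly exist in practice.
  Flags combine freely across lesion classes (a hotspot can be at a lacune
  edge and within WMH simultaneously).
- WMH-subgroup eligibility: more than minimal WMH (deep Fazekas > 0 or
  periventricular Fazekas > 1) and NAWM ≥ 10% of the WM mask ("minimal NAWM
  left" has no published cut-off; 10% is a configurable default).

## Statistics

Total SVD score (0–4): one point each for ≥1 lacune, ≥1 CMB, deep Fazekas
2–3 or periventricular Fazekas 3, and basal-ganglia PVS grade 2–4.
Weighted kappa uses linear disagreement weights |i−j|/(k−1) and is
undefined for fewer than two observed categories. Descriptive tables print
mean (SD) for normal continuous variables (Shapiro check at α = 0.05;
samples under 4 report mean (SD)), median (IQR) for ordinal/non-normal, and
n (%) for binary. Group comparisons: Student t / ANOVA, Mann-Whitney /
Kruskal-Wallis, Pearson chi-square with Fisher's exact when an expected
2×2 cell is below 5, Spearman for ordinal pairs. The univariable screen
keeps p < 0.1 (strict) plus the vascular function measures regardless.

Multivariable models: logistic regression for hotspot presence,
proportional-odds ordinal regression for hotspot count (raw counts as
levels, the tail above the cohort's 90th percentile collapsed into one top
category for fit stability; the link is labelled in the output). Model 1
adjusts for age, log10 normalized WMH volume, lacune and CMB counts;
model 2 adds SVD type. Missing CVR is handled complete-case with n
reported. VIF = 1/(1−R²) per covariate, acceptable below 5, infinite on
exact dependence. Non-convergence and separation (caught exception, or
|coefficient| > 15 / non-finite SE) are flagged, never silently returned.
No multiple-testing correction is applied; α = 0.05 two-sided.

## Validation problem sizes

The test suite and reproduction script run on 48³-voxel phantoms, 500
Monte-Carlo replicates for estimator calibration, 20 patients per arm for
the planted-enrichment comparison, and 100 replicate cohorts of n = 200 for
regression recovery — sizes chosen so the full suite completes in about a
minute on one CPU while leaving the Monte-Carlo bounds meaningful.

## Known limitations

- The phantom geometry is schematic; atlas regions are geometric wedges,
  not anatomy, so regional load scores validate bookkeeping rather than
  localization accuracy.
- The chance rate of lesion-hotspot contact in small phantoms is higher
  than in full-size brains (the mask is ~16k voxels versus ~10⁵); the
  enrichment experiment therefore compares arms rather than asserting
  absolute contact fractions.
- The regional load count boundaries and the 10% NAWM-remaining cut-off
  are package conventions where no published constant exists; both are
  configuration values echoed in outputs.
- Ordinal-model level handling (top-decile collapse) is a stability
  convention; alternative level schemes may shift count-model estimates.
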