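# Methods

This note documents the models, numerical choices and limitations behind
`wmcvol`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Segmentation model

The pipeline reproduces a semi-automatic FLAIR volumetry workflow in which an
operator thresholds the image, paints corrections with a brush, and outlines
the ventricles and two brain masks.

**Normalization.** Intensities are rescaled linearly so the minimum within
the brain mask maps to 0 and the maximum to 100; voxels outside the mask pass
through the same transform. Interpreting the threshold ceiling as "100% in
all subjects" therefore means "the per-subject in-brain maximum". Because a
single hot voxel can stretch this scale on noisy data, a robust variant
(`ceiling_percentile`, e.g. 99.9, with clipping) is available behind a flag;
the default remains the true maximum so that noise-free behaviour is exactly
linear.

**Threshold.** Segmentation keeps the voxels of the search mask whose
normalized intensity lies in the closed interval `[min%, max%]`, with
`max% = 100` by convention. The per-subject minimum is a required choice: the
workflow it models selected it interactively per subject, and no numeric rule
for that choice is defined. `auto_min_percent` offers Otsu's threshold over
the in-brain intensities above a floor as a default, but every entry point
accepts an explicit value (either on the percent scale or as a raw intensity
converted through the same normalization).

**Brush strokes.** A stroke's membership weight is the product of a linear
spatial falloff, `max(0, 1 − d/r_spatial)` with `d` the Euclidean distance to
the nearest stroke voxel (mm, anisotropy-aware), and a linear range falloff,
`max(0, 1 − |I − Ī|/r_range)` with `Ī` the stroke's mean intensity. Voxels
with weight ≥ 0.5 are added or removed. Only the monotonicity of the kernel
in both distances is contractual — any strictly decreasing pair of falloffs
would satisfy the same guarantees — so the kernel is isolated in one function
(`_stroke_weights`). The effective reach of a stroke on its own tissue class
is r_spatial/2; edits are provably local (nothing beyond r_spatial changes)
and inverse pairs of add/remove strokes restore the prior mask on uniform
regions.

**Ventricles.** Seeded region growing: candidate voxels differ from the mean
seed intensity by at most a tolerance (default 20 percent units, i.e. the
CSF–white-matter midpoint on the normalized scale); connected components
(26-neighbourhood by default, 6 optional) not containing a seed are
discarded. Seeds brighter than a CSF ceiling (default 35) are rejected by
name, catching seeds accidentally placed in lesions or parenchyma.

**Pencil-thin rim removal.** The thin ependymal lining around the ventricles
is a normal ageing finding and must not count as lesion volume. Candidate
voxels lie within `max_thickness` (default 2 mm) of the ventricle surface by
Euclidean distance transform. A connected candidate component is removed when
it touches the ventricle surface and has no face/edge/corner adjacency to WMC
deeper than `max_thickness`. This component-support rule was chosen over a
purely per-voxel distance rule because thick ventricle-adjacent lesions (caps,
halos) taper: their outermost margin is locally thin, and a per-voxel rule
would clip it, whereas the component rule retains any thin shell that is
connected to deep lesion tissue and removes exactly the isolated rim. On
constructed phantoms this makes rim removal voxel-exact.

**Noise handling.** An optional edge-preserving pre-filter (median over the
6-neighbourhood-plus-centre; Gaussian available) precedes normalization on
noisy inputs, and a cleanup step removes speckle components below 10 voxels
and fills enclosed holes below 64 voxels. Both are identities on noise-free
segmentations, preserving the exact-recovery guarantee; the median filter
relocates class boundaries only through local majority, so threshold
placement at the white-matter/lesion midpoint stays unbiased at flat
interfaces (curvature induces a small inward bias on small spheres, which
bounds how small a deep lesion the 5% recovery guarantee covers).

## Partition model

The periventricular search mask is `(ventricles ⊕ w) ∩ brain ∖ ventricles`,
with dilation implemented as a Euclidean distance-transform threshold so that
it stays isotropic under anisotropic voxels. The width *w* is per-subject and
operator-chosen in the modelled workflow ("adjusted to the width of the
periventricular changes"); for phantoms the scripted stand-in is the midpoint
between the true periventricular extent and the deep-lesion clearance. The
mask rule (PVH = WMC ∩ mask) is the default; the continuity-to-ventricle rule
is provided as a named comparator because the two rules disagree exactly on
confluent lesions spanning both zones, and recording both supports agreement
analysis between them. Under either rule, deep volume is total minus
periventricular volume at the voxel-count level, so conservation is exact.

## Phantom generator

Geometry (all defaults in mm on a 96×112×96 grid of 1 mm voxels): an
ellipsoidal brain (semi-axes 40/52/40) with a 3 mm cortical shell; two
lateral-ventricle ellipsoids (8/22/10, centres ±12 lateral); one
periventricular cap per ventricle pole (ellipsoids 11/8/11 centred on the
pole, so about half protrudes into white matter); two isolated deep spheres
(radii 7 and 5) placed with ≥ 10 mm of normal white matter between their
surface and the ventricles; a 1-voxel ependymal rim kept 3 mm clear of the
caps so that "thin rim" and "thick lesion" are geometrically unambiguous; an
optional full halo shell (`pvh_halo_width`). Intensity means: background 0,
CSF 10, white and grey matter 50, WMC 90, plus i.i.d. Gaussian noise. Grey
matter defaults to the white-matter mean so that any threshold strictly
between WM and WMC separates lesions exactly on noise-free phantoms; setting
it higher (e.g. 60) emulates the hyperintense cortex that brush editing must
then remove. A compact variant (48×60×48) with the same structure serves
fast tests. Seeded jitter (`random_phantom_spec`) perturbs ventricle/cap axes
and sphere radii/positions a few percent, rejecting geometries that violate
the clearance invariants.

Truth masks are voxelized analytically, so true volumes are exact integer
multiples of the voxel volume, and the generator validates that deep lesions
never intersect the periventricular zone (the error names the offending
sphere). Identical specs, including the seed, give bit-identical output.

What the phantom does **not** emulate: bias fields, partial-volume mixing,
anatomical ventricle shape, multi-sequence contrast, scanner
inhomogeneities. Passing phantom tests demonstrates correctness of the
geometric and statistical operators, not robustness to real-scanner
artefacts.

## Cohort generator

One row per simulated patient, seeded and deterministic. Defaults are frozen
to the population structure the analyses assume:

* **Demographics.** Age ~ Normal(74.8, 6.5) clipped to [50, 89] (mean ≈ 75);
  male fraction 141/253; waiting time lognormal with median 6 months and
  quartile ratio 2 (IQR ≈ 4–8).
* **Volumes.** Log-normal, moment-matched to printed medians/IQRs: PVH median
  14.7 ml (quartile spread 5.8–28.7), DWMH median 1.85 ml, ventricles mean
  129 ml SD 42. A log-normal cannot match a median and both quartiles unless
  the median is their geometric midpoint, so the generator anchors the median
  and the quartile ratio. Log-scale correlation 0.767 between the two lesion
  compartments yields a Spearman rank correlation ≈ 0.752 (r = 2 sin(π r_s/6)
  for bivariate normals); 0.30 against ventricle volume.
* **Scores.** The baseline total is drawn from a linear model (default:
  intercept 49.8, residual SD 19.0) truncated — not resampled — at [0, 100],
  preserving the linear-model coefficient for recovery tests away from the
  bounds. Domains are then decomposed around the total with per-domain
  offsets matching the published domain means and a per-patient shift found
  by bisection so that the gait-double-weighted mean of the clipped domains
  reproduces the total exactly; without this, clipping at the bounds would
  compress the recomputed total's SD below its nominal value. Per-domain
  missingness is independent Bernoulli with rates from the published
  per-domain n (cognition assessed in ≈ 39%).
* **Outcome.** Δtotal = intercept + Σβ·covariates + β_vol·log2(volume) +
  Normal(0, σ). The default carries β = −1.2 per doubling of PVH volume with
  residual SD 20.9 and an intercept giving ≈ 51% responders at the ≥ 5 cut
  and ≈ 60% improved — the anchor proportions. The responder label is never
  stored; it is derived downstream by the scoring module.
* **Biomarkers.** Log-normal via log2-scale linear models from printed
  medians/IQRs; total tau carries a −0.474 per-doubling coefficient on
  ventricular volume (the dilution effect), the others default to null
  models. Missingness per marker from the published per-row n (NfL assessed
  in a ≈ 30% subset).
* **Flags.** DESH and comorbidities are Bernoulli with the published
  prevalences; Evans' index Normal(0.38, 0.035) truncated to (0.2, 0.5);
  complication flags at the published rates; exclusion reasons ("non-shunt
  event", "artifact") assigned to a configurable number of leading records so
  the exclusion filter can be exercised (e.g. 262 simulated, 6 + 3 flagged,
  253 analyzed).

Only population-level structure is claimed: every anchor is a cohort summary
statistic, not per-patient data, so parameter-recovery tests validate the
estimation machinery, not any patient-level realism.

## Statistical battery

* One OLS per (outcome, volume) pair rather than a joint model over the three
  volumes: the volumes are strongly inter-correlated (r_s ≈ 0.75), and the
  reporting layout pairs each volume with its own coefficient under a shared
  covariate footnote.
* Covariate sets are frozen: Δ-score models adjust for age, sex, waiting
  time, preoperative total score, Evans' index and DESH; baseline-score and
  biomarker models for age, sex, Evans' index and DESH. Sex and DESH enter as
  binary indicators; no interactions. Complete-case analysis per model, which
  is why per-row n varies across outcomes.
* Biomarker outcomes are log2-transformed by default (coefficients are then
  per-doubling on a log2 outcome); a `log2_biomarkers=False` toggle fits raw
  outcomes instead, since the transform convention on the left-hand side is a
  reporting choice.
* Mann–Whitney U: exact null distribution for combined n ≤ 20 without ties;
  otherwise the normal approximation with tie correction and without
  continuity correction (so identical groups report p = 1 exactly). Wilcoxon
  signed-rank: zeros dropped, exact for ≤ 25 nonzero differences without
  tied magnitudes, normal approximation beyond. Spearman uses average ranks.
  Degenerate inputs (zero-variance paired differences, all-zero differences,
  constant rank inputs, zero total variance for the ICC) raise errors rather
  than returning NaN.
* ICC is ICC(A,1) — two-way random effects, absolute agreement, single
  rater — computed from the two-way ANOVA mean squares, with the
  F-distribution confidence interval (Satterthwaite degrees of freedom for
  the mixed term). This form fits comparing two measurement systems on the
  same subjects with one coefficient; the limits-of-agreement multiplier is
  fixed at 1.96 with no repeated-measures correction (one pair per subject).
* No multiple-testing adjustment anywhere; the report states this in its
  footnote. Significance is flagged `*` (p < 0.05) and `**` (p < 0.01).
* The responder cut Δtotal ≥ 5 is inclusive and compared with a 1e-9 epsilon:
  clinically scores carry at most one decimal, and the epsilon keeps a
  computed gain of exactly 5 points from falling on the wrong side of the cut
  through float rounding.

## Reproducibility and problem sizes

All randomness flows from explicit integer seeds; the pipeline derives one
substream per stage from a master seed via SHA-256, and re-running a config
reproduces byte-identical manifests (artifact hashes included). The test
suite and acceptance script use 10 full-size phantoms per noise condition,
100 simulated cohorts of n = 250 for coefficient-recovery coverage, 1000
null replicates for the Mann–Whitney size check, and n = 10,000 for
distributional-convergence checks — sizes at which the Monte-Carlo error of
each check is small relative to its tolerance.

## Known limitations

* The brush-stroke kernel is one admissible choice; published interactive
  tools use related but not identical weightings, so stroke-level outputs are
  comparable in behaviour, not in exact voxel sets.
* The per-subject minimum threshold and periventricular mask width have no
  numeric ground truth in the modelled workflow; both are explicit inputs,
  and results depend on them exactly as the manual workflow depends on its
  operator.
* Recovery guarantees under noise are curvature-limited: deep lesions much
  smaller than the default spheres (radius ≲ 3 mm at 1 mm voxels) lose a
  larger volume fraction to boundary effects than the 5% bound.
* The cohort generator draws independent patients; it does not model
  selection into surgery, informative missingness, or measurement drift
  between baseline and follow-up.
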