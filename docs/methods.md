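# Methods

## Model and assumptions

The wall-thickness-ratio method treats the contralateral healthy limb
as the patient's own reference anatomy. Its central assumptions are:

1. both limbs are scanned in one session with one protocol, so HU
   calibration and voxel spacing are shared (the pipeline refuses pairs
   with mismatched spacing and records the HU window used for both);
2. bone reconstructed from the same threshold window is comparable
   across limbs — the ratios are only meaningful *under identical
   threshold conditions*, which is why the window is a logged, required
   parameter rather than a constant baked into the volume;
3. cortical regrowth at the fracture manifests as recovery of the wall
   thickness distribution toward the healthy side, summarized by the
   median.

A phase is processed as: threshold segmentation → connected-component
filtering → (optionally) metal removal → marching-cubes surface →
isotropic remeshing → per-triangle inward ray casting → area-weighted
median thickness, mean HU over the mask, and their product (healing
index). Ratios R2/R4/R5 are simulated/basic quotients; R5 = R2·R4 holds
algebraically and is asserted, not assumed.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| HU window | [226, 3070] | HU | de-facto adult-bone preset of clinical segmentation tools; never printed by the method's source, so exposed and logged |
| metal threshold | 2500 | HU | above cortical bone (≤ ~1800), below implant alloys; removal includes a one-voxel halo to strip the partial-volume rim |
| component filter | 0.5% of foreground | — | drops noise specks but keeps *both* fragments of a nonunion, which a keep-largest rule would silently discard |
| mask smoothing | σ = 0.5 voxel | — | suppresses marching-cubes terracing that biases thickness medians; small enough not to close a fracture gap |
| remesh target edge | 1.0 | mm | the sampling density at which the thickness statistic is defined; one ray per ~0.43 mm² of surface |
| thickness cap | 10,000 | mm | bounds the ray search; far beyond any skeletal dimension, so it censors nothing on real bone |
| healing cutoff | R2 ≥ 0.84 | — | classification threshold for attained healing |
| nonunion cutoff | R2 < 0.74 | — | strictly below; R2 = 0.74 itself is poor healing |
| trend slope | 0.01 | /month | minimum recent R2 slope regarded as active progress |

## Wall-thickness statistic

One ray per triangle, from the centroid along the inward normal,
origin offset 10⁻⁴ mm into the material and hits closer than 10⁻³ mm
discarded as numerical self-intersections. Rays that miss (open
meshes: a diaphyseal segment spanning the scan window has open tube
ends) or exceed the cap are *excluded and counted*, not clamped — this
keeps the median finite on open meshes and is operationally identical
to clamping at the 10,000 mm cap on bone-scale inputs.

The median is area-weighted (smallest thickness at which cumulative
triangle area reaches half the total), making it invariant to
remeshing density; the unweighted per-triangle median is exposed
(`median_thickness(dist, weighted=False)`) for sensitivity analysis
against tools whose weighting convention is unknown. Misses aside, the
statistic is exactly scale-equivariant and rigid-motion invariant,
which the test suite checks at 10⁻⁹ and 10⁻⁶ respectively.

The ray caster is a brute-force Möller–Trumbore kernel (numba), with a
10⁻⁹ barycentric slack so rays striking a shared edge register on both
adjacent triangles. Brute force is O(rays × triangles) but entirely
adequate at the 10⁴-triangle meshes a 1 mm edge length produces.

## Remeshing

Marching cubes at 0.625 mm voxels yields ~0.6 mm edges; the thickness
statistic is defined at 1 mm sampling, so surfaces are remeshed by
incremental isotropic remeshing: edges longer than 4/3·L split at
midpoints, edges shorter than 4/5·L collapsed where the link condition
holds, edge flips toward regular valence (6 interior / 4 boundary),
and tangential-only Laplacian relaxation (boundary vertices fixed),
iterated five times. Tangent-plane restriction of the smoothing keeps
shrinkage second-order; measured symmetric surface deviation against
the input stays well under half the target edge, and enclosed volume
within ~1–3%. Uniform (rather than curvature-adaptive) sizing is
deliberate: the quantity that matters downstream is thickness sampling
density, not feature fidelity of corners.

## Phantom generator

`generate_limb` emulates a diaphyseal CT window: a circular cortical
tube (default 1400 HU) around marrow (100 HU) in a soft-tissue cuff
(40 HU) against air background (−1000 HU), spanning the full z extent
of the grid like a clinical segment reconstruction — so extracted
surfaces are open tubes, matching the geometry the ray caster must
tolerate. An affected limb may carry a transverse gap slab in which
the cortical ring is replaced by callus (700 HU) over a contiguous
angular sector of fraction `healing_fraction` and by soft tissue
elsewhere; hardware is an intramedullary rod or an abutting lateral
plate at 3200 HU. Gaussian HU noise is added last, seeded, and clipped
to [−1024, 4096].

Voxels take the HU of the material at their center — no partial-volume
averaging — so noiseless phantoms are exactly piecewise constant and
voxel-count and thickness oracles are exact. Defaults are desk-scale
(128×128 transverse at 0.625 mm; the acceptance sweep uses 96×96×80)
rather than the clinical 512² matrix, which adds nothing to validation.

What the phantom deliberately does **not** model: trabecular texture,
anatomically curved shafts, beam hardening and metal artifacts,
partial-volume blur. Passing tests therefore demonstrate correctness
of the geometry/statistics pipeline, not robustness to scanner
physics; on real data the segmentation window and metal threshold
would interact with artifacts the phantom cannot produce.

## Longitudinal trend

The trend call uses the most recent three follow-ups. A series is
*progressing* if the latest R2 has reached the healing cutoff with a
net rise over the window, or if the recent slope reaches 0.01/month —
taken conservatively as the smaller of the Theil–Sen estimate over the
three points and the slope of the final interval, so that one early
jump cannot mask a late flattening (the grafting-decision scenario).
A plain Theil–Sen slope over the last three points classifies both
published reference courses wrongly (a healing course that decelerates
after crossing the cutoff reads as plateau; a stalled course with one
early jump reads as progressing); the combined rule reproduces both.
The threshold is an overridable default, not a clinical claim.

## Cohort statistics

Kruskal–Wallis is the primary omnibus (the ratios are not normally
distributed); one-way ANOVA is reported alongside for parity with
normal-theory pipelines. Pairwise Mann–Whitney p-values are
Holm-adjusted; for combined samples ≤ 14 an exact enumeration with
midranks is used (the usual exact algorithms reject ties). The ROC is
empirical over all distinct score cutoffs with "score ≥ cutoff ⇒
positive" (higher ratio = more healed); the AUC is trapezoidal
(= tie-corrected Mann–Whitney probability) with a DeLong 95% CI, and
the operating point maximizes Youden's J with ties broken toward the
smallest cutoff (deterministic, sensitivity-conservative). ICC(2,1) —
two-way random effects, absolute agreement, single measures — is
computed via pingouin and cross-checked in tests against the explicit
mean-square formula.

`simulate_cohort` draws per-scan ratios lognormally around fixed group
medians (0.907/0.799/0.667 for R2 in healed/poor/nonunion, sd 0.1 on
the log scale; R4 medians ~0.93 with sd 0.05, reflecting that R4
separates groups poorly), sizes 49/37/26. This reproduces the
qualitative cohort structure (ordered medians, significant omnibus,
AUC in the mid-0.8s) and is used as a sanity corridor — AUC ∈
[0.75, 0.95] across seeds — never as an equality claim against any
particular cohort.

## Numerical choices and degenerate inputs

- Weighted median: smallest sample with cumulative weight ≥ half the
  total (stable sort; deterministic under ties).
- Ratio reporting: full precision internally; two-decimal display uses
  round-half-away-from-zero, the convention of the published tables.
- Orientation: marching-cubes gradient normals define "out of the
  material" for open and closed components alike; closed components
  are verified to have positive signed volume.
- Empty masks, all-foreground masks, single-class ROC labels,
  zero-variance correlations/ICC, sub-3-point trend series, and
  non-positive basic-phase metrics all raise informative errors rather
  than returning NaN.
- Determinism: all randomness flows from explicit seeds
  (phantom noise, cohort simulation); analysis stages are
  deterministic, and repeated runs produce byte-identical JSON reports.

## Known limitations

- Brute-force ray casting scales quadratically; meshes far above ~10⁵
  triangles would need an acceleration structure.
- The remesher assumes reasonably clean marching-cubes input; it is
  not a repair tool for arbitrary scanned meshes.
- Hardware removal is thresholding plus halo stripping; screw tracks
  through the cortex are left as holes, not infilled.
- R1/R3 (target-phase ratios) are not defined in this method and are
  not computed; target-phase metrics are logged for completeness only.
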