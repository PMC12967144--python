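# Methods

`vemmorph` analyses segmented volume-EM data of dividing cells: an integer
label volume (object ID per voxel) with an object index, optionally a
co-registered grayscale volume, and a per-cell mitotic-phase annotation.
This note records the models, conventions and numerical choices behind
each stage, and what the synthetic phantoms do and do not establish.

## Coordinates and units

Arrays are indexed `(z, y, x)` with per-axis voxel sizes `(sz, sy, sx)` in
nanometres; anisotropic voxels are supported throughout.  The physical
centre of voxel `(k, j, i)` is `((i+0.5)·sx, (j+0.5)·sy, (k+0.5)·sz)`,
origin at the corner of voxel (0,0,0) — the half-voxel offset removes the
centre/corner ambiguity.  All internal quantities are nm / nm² / nm³;
conversion to μm-based units happens exactly once, at reporting
boundaries (volumes μm³, areas μm², displacements and neighbour distances
μm, distance matrices nm).

## Morphometry

* **Volume** is the exact voxel count times the physical voxel volume.
  A cell's territory includes every object parented to it, so cellular
  volume counts the organelles and chromosomes it contains; nuclear
  volume excludes chromosomes carved out of the nucleoplasm.
* **Surface area** uses a normal-weighted boundary-face estimator: the
  local surface normal is the gradient of the indicator function smoothed
  with a σ = 1 voxel Gaussian, and every exposed voxel face contributes
  its physical area times |n̂·ê| (faces with |n̂·ê| ≥ 0.9 count fully, so
  axis-aligned planar patches are exact).  For any planar surface the
  weights integrate to the true area identically; for smooth bodies the
  estimate converges with resolution (digital spheres of radius 10/25/40
  voxels are recovered within 5.4/4.2/3.9%).  Plain face counting
  overestimates smooth bodies by up to ~27%, and a marching-cubes mesh of
  the binary mask chamfers sharp edges (−6% on a 10-voxel cube), which is
  why neither is the default; the marching-cubes mesh area remains
  available as `method="mesh"`.
* **Centre of mass** is geometric — the unweighted mean of member-voxel
  centres — matching quantification of segmented model objects rather
  than an intensity-weighted moment.
* **Stain intensity**: integrated density is the plain sum of grayscale
  values over the mask (identical whether accumulated per slice or in one
  pass); mean intensity is integrated density per voxel.  The mean is
  per-voxel within the object, not a per-slice average of slice means —
  the two differ when the object's cross-section varies along z.  The
  grayscale is used as stored; `invert_intensity` is available for stacks
  where dense chromatin is dark.  Objects flagged as truncated by the
  stack boundary stay in all tables but are excluded from phase
  statistics by default.

## Karyotyping

Metaphase chromatids are karyotyped from volume plus centromere
morphology:

1. **Centromere localisation.** The mask is skeletonised; the longest
   geodesic path through the skeleton (double-sweep Dijkstra over the
   26-connected skeleton graph, physical edge lengths) is the chromatid
   axis, implicitly pruning side branches.  The centromere is the point
   of minimal cross-sectional width — twice the Euclidean distance
   transform — searched within the central 90% of arclength.  Skeletons
   erode by roughly one inscribed radius at each tip, so each arm length
   is extended by the EDT value at its endpoint before the ratio is
   taken.  Masks that are not elongated (path < 4 voxels, or total length
   under three inscribed radii) return `unresolved` rather than raising.
2. **Classification** uses the Levan arm-ratio convention: metacentric
   ≤ 1.7 < submetacentric ≤ 3.0 < acrocentric.
3. **Homolog pairing** is a minimum-cost matching with cost
   `0.7·|ΔV|/V̄ + 0.2·[classes differ] + 0.1·(COM distance / cell
   diameter)` and a hard constraint forbidding pairs whose volume
   difference exceeds 35% of the pair mean.  The weights encode the
   priority order volume ≫ morphology ≫ proximity.  The matching
   maximises `10 − cost` per edge over allowed pairs
   (`networkx.max_weight_matching`, non-maximum-cardinality), so every
   beneficial pair forms while chromatids without a volume-compatible
   partner stay unpaired — this is what leaves X and Y single in a male
   complement instead of force-matching them to autosomes.
4. **Sex chromosomes**: X is the largest-volume submetacentric among
   unpaired chromatids, Y the smallest-volume acrocentric; ties break by
   larger surface area, then lower object ID; either may be absent
   without error.
5. **Grouping and numbering**: autosome pairs are numbered 1..26 by
   strictly non-increasing pair mean volume (ties by mean surface area,
   then object ID) and binned as metacentric, acrocentric I (> 3 μm³,
   strict), II (2–3 μm³ inclusive of both bounds) and III (< 2 μm³,
   strict) — the unique boundary reading consistent with all three
   range phrases.  A consistency check against the published ovine
   composition (3 metacentric + 23 acrocentric pairs, submetacentric X,
   acrocentric Y) warns on deviation and is on by default.

## Spatial statistics

Distances are Euclidean on physical COM coordinates.  The chromosome
network uses mutual k-nearest-neighbours with k = 3 by default — the rule
is a named, logged parameter (an absolute-distance threshold rule is
available) because no canonical criterion exists for such figures; ties
break by lower index via stable argsort, making the graph deterministic
and its edge set monotone in k.  K-means runs 10 seeded restarts per
candidate k (scikit-learn's re-seeding handles empty clusters) over
k ∈ 2..min(10, n−1) by default, keeping the k with the highest mean
silhouette width; ties prefer the smaller k.  Gaussian mixtures are
full-covariance, component count by BIC over 1..k_max, singular fits
skipped with a warning.  The GMM clusters COMs only; volume-augmented
features were considered and deliberately left out of the default since
mixing units (nm and μm³) requires an arbitrary scaling.  Every
stochastic operation takes an explicit seed (package default 1729).

## Density maps

Cells are rotated into a canonical frame by principal-axis analysis of
the member-voxel covariance: x = longest axis, y = second.  Axis signs
follow the convention skewness ≥ 0 (ties +), which pins orientation for
asymmetric cells; masks whose eigenvalues agree within 1% are flagged
degenerate and left unrotated.  After z-projection, the projected cell's
bounding box is split 3×3 into equal rectangles (bounding-box framing
shape-normalises the grid across cells; mask-area-equalised regions are a
possible alternative not implemented).  Raw counts assign each organelle
centroid to exactly one region — centroids outside the cell mask are
counted in the nearest region and flagged — and always sum to the
centroid count.  The voxel correction divides each count by the physical
projected cell area inside the region, measured by rasterising projected
member voxels at the native voxel pitch, so cells imaged at different
binning are directly comparable (count per μm² of projected cell).
Hotspot maps are Gaussian KDEs of projected centroids on a 64×64 grid
over the same bounding box; default bandwidth is Silverman's rule per
axis (σ·n^(−1/6)), with a fixed override for cross-cell comparability.
The field integrates to the centroid count when kernels lie inside the
window.  ER fragments can optionally be voxel-mass-weighted instead of
centroid-counted.

## Group statistics

Phase comparisons use the two-tailed unpaired t-test with Welch's
correction; s.d. uses the n−1 denominator; p-values come from the
Student-t survival function with Welch–Satterthwaite degrees of freedom.
Significance stars: * p ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001, **** ≤ 0.0001.
No multiple-testing adjustment is applied by default (pairwise tests are
reported unadjusted); Holm correction is available behind a flag.  Two
constant equal groups return p = 1 by convention.  Cells are pooled
across follicles/groups as annotated by the user; follicle-level nesting
(mixed effects) is a known limitation, not implemented.

## Synthetic phantoms

The generator produces label + intensity volumes with complete ground
truth.  The reference scene is a 15×15×12 μm ellipsoidal cell at 30 nm
isotropic voxels; tests and examples run the same physical scene at
90 nm (binned by three) for speed — the problem sizes quoted in tests are
this 90 nm scene.  Structure:

* a nucleus (0.55× the cell semi-axes) exists through prophase and is
  absent from metaphase on;
* chromosomes are ellipsoidal bodies placed at a planted radial
  displacement from the cell COM (inside the nucleus while it exists);
  non-dividing cells carry none (chromatin uncondensed).  Failed
  placements probe radii alternating symmetrically around the target so
  crowded shells spread without biasing the planted mean.  Separately,
  `generate_chromatid` voxelises bent-rod chromatids with a centromeric
  waist at the arclength fraction implied by a target arm ratio, volume
  calibrated within 5%, for closed-loop karyotype tests;
* organelle populations (mitochondria ~0.15 μm³ fragments, ER ~0.05,
  vesicles ~0.02) with per-phase count/volume multipliers and spatial
  patterns: uniform, central hotspot, cortical shell, or clustered;
* a stain model assigning per-class mean grayscale (chromatin brightest)
  plus Gaussian noise (s.d. 8), uint8 — fixed, documented as
  non-physical.

The planted phase trends are: mitochondrial count/volume rising through
prophase and peaking around metaphase, with a central concentration at
telophase; ER fragment counts dipping into metaphase then rebounding
sharply from anaphase while ER volume rises; vesicles peaking at
metaphase; chromosome displacement increasing monotonically from
prophase I (2.0 μm) to cytokinesis (4.6 μm); dividing cells 18–30%
larger in volume than non-dividing ones — about three pooled standard
deviations at the generator's 2% per-axis size jitter, so the effect is
detectable at p ≤ 0.01 with 8 vs 9 cells in nearly every run.  The
displacement ladder starts at 2 μm because ten non-overlapping chromosome
bodies cannot all sit nearer the centre of a nucleus this size; the
packing constraint, not the analysis, sets the floor.

Power and type-I simulations use the generator's distribution-level mode
(`sample_phase_morphometry`), which draws per-cell summary quantities
from the same per-phase parameters without voxelising; the voxel path is
exercised once per phase in the closed-loop tests.

**What the phantoms do not emulate**: real SEM contrast and noise
structure (charging, curtaining), membrane-resolved ultrastructure, a
connected ER reticulum (fragments only — the analysis consumes counts,
volumes and centroids), segmentation errors, and truncation by the stack
boundary.  Passing closed-loop tests therefore demonstrates that the
measurement chain is correct on known geometry, not that segmentation of
real micrographs would be accurate.

## Determinism and degenerate inputs

Same seed → bit-identical phantom volumes and identical clustering
results.  Empty masks raise; a label volume with labels missing from the
object index is rejected at construction; a missing voxel size is an
explicit error, never assumed.  All-identical points are a degenerate
configuration for silhouette selection and raise.  The pipeline writes a
manifest (resolved config, its hash, seed, package versions) whose bytes
are reproducible across re-runs; timings go to the log only.
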