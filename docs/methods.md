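# Methods

## Masks and geometry conventions

A lesion mask is a binary 3D voxel grid with a 4x4 voxel-to-world affine
(mm). Spacing is always derived from the affine's column norms, so the
two can never disagree. Every mask carries a one-voxel background margin
(added idempotently on load) so that isosurfaces are closed. Voxel
indices are 0-based; lengths are mm, volumes mL. Connected components
use 26-neighbour connectivity — maximal merging, so areas that look
continuous but touch only at voxel corners count as one lesion; a
lesion's "largest area" is the component with the greatest physical
volume (count x voxel volume, which matters when comparing components
defined on different grids), with ties broken deterministically by the
lowest minimal voxel index.

## Isotropic resampling

Shape analysis needs cubical voxels, so masks are resampled by linear
interpolation of the binary field followed by a 0.5 threshold; the
analysis spacing defaults to the finest axis among the pair of masks,
floored at 0.5 mm so both acquisition arms are measured on the same
grid. For strongly anisotropic inputs (axis spacing more than 1.5x the
target — clinical 3–5 mm slices) plain interpolation extrudes each slice
contour into a slab with vertical cliffs at every contour change. These
cliffs are reconstruction artefacts at the slice scale that read as
surface complexity: on a plain ball they depress convexity by ~0.06 and
inflate the fractal dimension by up to ~0.09. The resampler therefore
smooths the interpolated field before thresholding — sigma 0.75x the
source voxel length along coarse axes and one target voxel along the
others — the volume-preserving surrogate of shape-based slice
interpolation; with it the residual artefact on a ball is below 0.02 in
FD and 0.015 in convexity. Near-isotropic inputs are never smoothed, and
a component that would vanish entirely under smoothing (single-slice
fragments) is kept unsmoothed instead.

## Surface, hull and ratio markers

Surfaces are marching-cubes isosurfaces at level 0.5 of the binary
field, computed on the largest component, followed by five Taubin
(lambda/mu = 0.5/−0.53) smoothing passes. The smoothing removes the
half-voxel staircase — which otherwise inflates the area of oblique
surfaces by ~8% — while moving coplanar (axis-aligned) faces not at all
and leaving relief of three voxels and larger largely intact; five
passes recover a 10 mm ball's area to +0.8% and a 10 mm cube's to −3.8%.
Meshes with fewer than 50 vertices (single voxels, tiny fragments) are
at the smoother's wavelength and are left unsmoothed. Mesh area and
enclosed volume come from triangle cross-products and the divergence
theorem; winding is normalised so enclosed volume is positive.

The convex hull is computed on the mesh vertices (sub-voxel accuracy)
with Qhull. Convexity is `A_H / A`; no upper bound is enforced because
values slightly above 1 are geometrically legitimate for bodies
dominated by thin protrusions (a few long spikes enlarge the hull more
than the surface). Solidity is mesh enclosed volume over hull volume,
which cannot exceed 1 beyond numerical slack (the hull encloses the
mesh); violations beyond a 2% discretization slack are hard errors,
never clamps. The concavity index `2 − (C + S)/2` is 1 for a solid
convex body and grows with complexity.

## Box-counting fractal dimension

Boundary voxels are foreground voxels with at least one background
6-neighbour. Boxes live on a fixed-origin grid anchored at the
boundary's bounding-box corner (no origin averaging), with dyadic edge
sizes from 2 up to half the largest bounding-box edge and an unweighted
least-squares fit of log N(s) on log s; at least three scales (a
16-voxel bounding box) are required. The single-voxel scale is excluded
deliberately: N(1) counts the multiplicity of the one-to-two-voxel-thick
digital shell, which drags a smooth sphere's fitted slope to ~1.85;
without it, digital balls of radius 16–64 voxels fit between 1.91 and
2.09. Grid-aligned plane surfaces remain biased upward at practical
scales (an axis-aligned cube shell meets exactly m³−(m−2)³ boxes, so a
64³ cube fits near 2.35); curved and irregular boundaries, which is what
lesions are, do not share this alignment pathology.

## Paired statistics

Differences are high-quality minus clinical throughout. The Wilcoxon
signed-rank test drops zero differences (classical treatment), uses
mid-ranks for ties, and reports `W = min(W+, W−)`. For up to 25
effective pairs the two-sided p is exact — the distribution of `2 W+` is
built by convolution over the doubled (hence integer) ranks, equivalent
to enumerating all 2^n sign assignments; beyond that a normal
approximation with tie variance and continuity correction is used (its
absolute error versus the exact p is below 0.01 at n = 25). Fewer than
five effective pairs yield W with an undefined p. Percentiles use linear
interpolation (the convention matters for IQR endpoints at n = 28 and is
recorded in report metadata); Bland–Altman limits are mean ± 1.96 sample
standard deviations of the differences. Five markers are tested at a
common alpha with no multiple-testing correction (noted in the report
metadata). The sensitivity analysis drops a subject when *either*
condition's volume falls below the threshold (default 10 cm³), keeping
the paired design intact; small lesions carry few voxels and unstable
shape markers, which is the reason for the filter.

## Synthetic lesions

The generator works at the segmentation level — no MR signal physics —
and emulates three features of glioma T2-hyperintense morphology:

* a star-convex core: a ball (`base_radius`, drawn 13–25 mm in the
  default scenario) modulated by six broad lobes (lobulated outline) and
  `spike_count` narrow fissures — grooves 0.8–1.8 mm wide carved along
  random great-circle arcs, with depth scaled by `spike_amplitude`
  (drawn 0.4–0.8). Fissures are the complexity carriers: large surface
  area at little volume cost, which is what puts convexity in the 0.7–0.9
  range and solidity near 0.5 for realistic amplitudes. The radius field
  is floored at 12% of the base radius, so the body stays star-convex
  and one connected component;
* capsule tendrils (radius 2–3 mm, length 0.4–0.8x the base radius)
  roughly aligned with a random tract axis, and with 30% probability a
  thin bridge (radius 1.5 mm) ending in a distal blob — the cross-midline
  spread pattern. These extensions are infiltrative tissue and get a
  reduced contrast level (0.7 of the core) in the lesion's intensity
  image;
* observation = blur-then-threshold of the intensity image: Gaussian
  PSF, sampling onto the scan grid at a random sub-voxel offset (scan
  positioning), threshold 0.5. The high-quality arm is 0.75 mm isotropic
  with a 1 mm PSF; the clinical arm has a 0.4 x 0.4 x 5 mm grid with a
  2.8 x 2.8 x 6 mm PSF. The clinical PSF models the *segmentation-
  effective* resolution — acquisition blur plus the detail a rater can
  actually trace at 1.5/3 T — which is far coarser than the recon voxel.

Under these conditions the clinical arm fills in the fissures (narrower
than 1.35 sigma of the PSF in some direction), loses the low-contrast
extensions (blurred intensity drops below threshold), and slightly
erodes convex caps; the high-quality arm keeps all three. That yields
the directional pattern of interest: larger volume, lower convexity and
solidity, higher concavity index and fractal dimension in the
high-quality condition, each significant on a simulated 28-subject
cohort.

The ground truth is voxelized at 0.4 mm (matching the finest observation
axis, which bounds voxelization error below both observation grids) in
the default scenario. What the generator does *not* emulate: image
noise, intensity inhomogeneity, rater variability beyond the PSF proxy,
anatomical context (ventricles, prior resections), or any particular
patient geometry — passing tests show the pipeline detects the modelled
resolution effect, not that it reproduces any clinical cohort's values.

## Scenarios and study sizes

* `default` — the full-scale study conditions above; one 28-subject
  cohort takes roughly a minute of CPU.
* `null` — zero-complexity balls with *both* arms observed under the
  same (high-quality) acquisition geometry, differing only in grid
  offset. This is deliberate: with the true 7T/clinical pair even ideal
  balls acquire a small systematic volume bias (differential PSF
  curvature shrinkage), so exchangeability — the premise of a type-I
  error measurement — only holds with matched arms.
* `fast` / `fast-null` — scaled versions for replicate studies
  (radius 13–15 mm, truth grid 0.5 mm, and 8–10 mm balls respectively).
  Replicate counts in the test suite (25 effect cohorts, 200 null
  cohorts) and the acceptance script (20 and 60) are sized to the cost
  of regenerating thousands of lesions; with per-cohort p-values around
  1e-5 under the effect scenario, 20–30 replicates already bound the
  power tightly, while the null band needs the larger count.

13 mm is the smallest base radius at which the fractal-dimension
contrast between the two arms survives: below it the clinical lesion
spans too few slices and the marker differences drown in box-count
quantisation noise — the same small-lesion instability that motivates
the 10 cm³ sensitivity filter.

## Known limitations

* Convexity can exceed 1 for protrusion-dominated shapes; compare it
  across conditions, not against an absolute bound.
* The FD estimator has a resolution of roughly ±0.01–0.05 depending on
  lesion size (dyadic scale quantisation); per-step monotonicity against
  small amplitude changes is below its resolution, and values saturate
  near 2.2 for very deep relief.
* Axis-aligned plane surfaces (cubes) read high FD at practical scales;
  see the box-counting section.
* The acquisition simulator treats segmentation as deterministic
  thresholding; real inter-rater variability adds noise it does not
  model.
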