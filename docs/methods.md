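# Methods

This note documents the measurement model behind `cvmorph`, the
parameters that matter, the numerical choices where the design was
open, and what the phantom-based validation does and does not show.

## Measurement model

The object of measurement is the *lumen* of a cerebral artery as it
appears in bright-blood angiography: a tubular region of elevated
intensity. The pipeline estimates, at every 0.284 mm along each vessel,
nine local descriptors — cross-sectional area, maximal inscribed sphere
radius (MISR), minimal and maximal Feret diameter, their ratio, Frenet
curvature and torsion of the centerline, contour perimeter, and
circularity `4*pi*A/P^2` — and aggregates them as unweighted point
means over named arterial territories ("chunks"). Longitudinal change
is the percent change of a chunk mean between two acquisitions of the
same subject, tested with the paired Wilcoxon signed-rank statistic.

### Segmentation

Region growing collects all voxels with intensity in `[lower, upper]`
that are 26-connected to a user seed. 26-connectivity is used because
thin vessels oblique to the grid disconnect under 6-connectivity. The
method has no regularization: the mask is exactly the thresholded
connected component, which makes it reproducible and easy to reason
about, but also means the threshold choice directly moves calibers by
up to about half a voxel. The default recommendation for `lower` is
mean + 2 SD of a user-marked background region; no automatic seeding
is attempted.

### Surface extraction

A binary mask's marching-cubes iso-surface carries a strong octagonal
anisotropy: measured on a radius-2 mm tube at 0.284 mm voxels, min and
max Feret diameters of its cross-sections disagree by ~8% and
circularity saturates near 0.97 no matter how long a shrink-free mesh
filter runs. `extract_surface` therefore extracts the zero level of the
*signed distance field* (SDF) of the mask after Gaussian smoothing with
`sdf_sigma_vox` voxels (default 2.0, capped at 60% of the maximal
inscribed radius so thin vessels survive). Gaussian smoothing shifts a
curved level set inward by approximately `sigma^2 * kappa / 2`; this
bias is removed analytically by displacing each vertex along its
outward normal by `(sigma^2 / 2) * laplacian(f)` evaluated at the
vertex (for a level set of a smoothed SDF, `laplacian(f) ~ 2H`, twice
the mean curvature). On the reference tube this leaves enclosed volume
within 0.4%, area within 1.3%, diameters within ±2.5% and circularity
at 0.994. Taubin smoothing (`lambda = 0.5, nu = 0.526`, satisfying the
pass-band condition) remains available as a mesh-domain post-filter.
Masks are padded before extraction so surfaces always close; a mask
with no fully interior voxel is rejected as degenerate.

### Centerline

The centerline is found as the minimal-cost path between user-supplied
endpoints over the foreground voxel graph, with edge cost
`step_length / (mean EDT of the endpoints + eps)`. Since the EDT is the
distance to the lumen boundary, the cheapest path per unit length runs
along the medial ridge. The voxel path is then refined by gradient
ascent on the Gaussian-smoothed EDT (sigma 1.5 voxels, 24 steps of
0.25 voxels, displacement projected perpendicular to the local tangent
so points cannot slide along the vessel). On straight-tube phantoms the
refined path sits within ~0.15 voxel RMS of the true axis. The
`misr_mm` carried by the centerline is the interpolated EDT value at
each path point — within one voxel of truth away from branch ends —
while the feature table recomputes MISR against the extracted surface
(distance-to-mesh, maximized locally perpendicular to the tangent),
which is consistent with the mesh-derived diameters to ~2%.

### Resampling

Branches are resampled at a uniform arc-length pitch (default
0.284 mm, one voxel) on a cubic spline fit with a small smoothing
budget (0.08 mm RMS per point) that absorbs residual voxel jitter.
Points sit at exact integer multiples of the pitch from the branch
start; a sub-pitch tail at the far end is dropped rather than letting
the last interval deviate from the pitch. (Exact-pitch spacing and
exact far-endpoint preservation are mutually exclusive for generic
branch lengths; uniform spacing is the property downstream derivative
estimation relies on, so it wins.) Branches shorter than two pitches
are dropped with a logged warning.

### Frenet geometry

Curvature and torsion come from first/second/third derivatives of the
uniformly resampled curve estimated by a quintic Savitzky–Golay filter
over a 9 mm window (defaults `window_mm = 9.0`, polynomial order 5).
Local polynomial derivatives were chosen over a global smoothing
spline: spline knot placement under a residual budget proved erratic
for third derivatives, with helix torsion errors that *grew* with the
smoothing parameter, while the fixed-window local fit recovers a
noiseless circle's `1/R` well within 1% and the voxelized helix's
torsion within ~3%. The window should stay a few times shorter than
the tightest bend radius of interest; at 9 mm it is matched to basal
cerebral artery geometry (bend radii ~5–15 mm). Where `|r' x r''|`
vanishes the curve is flagged straight and torsion is reported as 0,
since torsion is undefined at zero curvature; on near-straight vessels
the torsion estimate is noise-dominated and should not be interpreted.

### Cross-sections

At each centerline point the surface is cut by the plane normal to the
local tangent; of the closed intersection loops, the one enclosing the
point is the lumen contour (counterclockwise, in-plane coordinates).
Area is the shoelace sum, perimeter the edge-length sum, min/max
diameter the min/max caliper (Feret) widths of the contour's convex
hull by rotating calipers. Points whose contour extraction fails —
typically at bifurcation apices, where the normal plane cuts both
daughters — are recorded as missing rather than dropped; a branch with
more than 20% failures raises a quality error. Points within `trim_mm`
of a branch end are excluded the same way because a phantom's flat end
cap (or a real acquisition's volume edge) distorts the section there.

### Territories and summaries

Branch labels are semi-automatic: the user marks one point per
anatomical branch and labels propagate along the centerline
connectivity graph (branches joined where they pass within 0.5 mm, as
at junctions) to the topologically nearest seed, ties to the lower
branch id. The shipped atlas maps 74 named branches into 19 chunks
built from standard Circle-of-Willis nomenclature (basilar, left/right
ICA, basal and pial ACA/MCA/PCA, cerebellar, vertebral groups); it is
a plain CSV and is meant to be edited per site. Chunk means are
unweighted over member *points* (not branch means): a chunk is treated
as a bundle of fine segments, so longer branches legitimately weigh
more. Excluded branches (e.g. a symptomatic segment) and missing
points are left out of means; empty chunks are emitted with missing
means rather than dropped.

### Longitudinal statistics

Percent change follows the convention
`(mean_initial - mean_followup)/mean_initial * 100`, which is negative
when a quantity increases; because increases are conventionally quoted
as positive percentages, every output table carries both
`pct_change_paper_sign` and `pct_increase` columns, explicitly named.
The paired Wilcoxon signed-rank test drops zero differences (the
classic convention; keeping them — Pratt's method — changes p and is
deliberately not used), mid-ranks ties, and computes the exact null of
the positive-rank sum by convolution over doubled ranks for n <= 25
(two-sided p as twice the smaller tail, capped at 1), switching to a
continuity- and tie-corrected normal approximation beyond. The exact
path is verified against brute-force enumeration of all `2^n` sign
patterns. Covariate models are OLS with intercept and t-based 95% CIs,
complete-case per model with n reported; rank-deficient designs are
rejected naming the collinear columns. A Benjamini–Hochberg column is
emitted alongside raw p-values but never gates any output.

## Phantoms and the synthetic cohort

`make_tube_phantom` rasterizes parametric tubes by a voxel-center
membership test with flat end caps, so the foreground voxel count
converges to `pi r^2 L` exactly as spacing shrinks — this is the
volume oracle for segmentation and surface tests. Ground truth
curvature/torsion are closed forms (cylinder 0/0, torus `1/R`/0, helix
`a/(a^2+b^2)` and `b/(a^2+b^2)`). Noise is Rician (magnitude of
complex Gaussian), the correct model for magnitude MR, with an explicit
seed everywhere. Default spacing is 0.284 mm isotropic, the target
acquisition resolution.

The longitudinal cohort simulator has two levels. The *image-level*
cohort (30 subjects by default, baseline lumen radius ~ N(1.8, 0.25)
mm as for basal cerebral arteries, Rician noise at 5% of foreground,
+6% injected diameter change at follow-up) runs the full image pipeline
per subject-timepoint; each acquisition sits at an independent random
sub-voxel grid offset, as two scans of a real head would, which turns
grid-alignment bias (~±2–3% in area, oscillating with radius) into
paired measurement noise instead of a systematic term. The
*summary-level* cohort draws chunk summaries directly with ~1%
multiplicative measurement noise (the observed run-to-run variability
of the image pipeline) and exists so that many-repeat error-rate
simulations — 100 null cohorts for the type-I check — finish in
seconds; the statistics under test are identical in both modes.

What passing phantoms shows: the geometric estimators are unbiased to
a few percent for circular-section tubes at clinical caliber and
resolution, and the statistical chain detects a 6% caliber change at
n = 30 with correct null behaviour. What it does not show: performance
on non-circular (stenotic, dissected) lumina, touching/kissing
vessels, intensity inhomogeneity or flow artifacts, segmentation
sensitivity to threshold choice on real TOF contrast, or anatomical
labeling accuracy — real-data validation is still required for those.

## Parameter summary

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| `spacing_mm` | 0.284 | mm | phantom / target voxel size (isotropic) |
| `lower` | mean + 2 SD of background | intensity | region-growing threshold |
| `sdf_sigma_vox` | 2.0 (capped at 0.6 × max inradius) | voxels | SDF smoothing before marching cubes |
| `smoothing_iterations` | 20 | — | Taubin mesh post-filter passes |
| `pitch_mm` | 0.284 | mm | centerline resampling pitch |
| `window_mm` | 9.0 | mm | Savitzky–Golay window for curvature/torsion |
| `trim_mm` | 1.0 (pipeline), 2–3 (phantom tests) | mm | branch-end exclusion |
| `junction_tol_mm` | 0.5 | mm | branch-graph joining distance for label propagation |
| `max_missing_fraction` | 0.2 | — | per-branch contour failure tolerance |

## Known limitations

- Circular-section calibration: all tolerances were established on
  tubes with circular cross-sections; strongly eccentric lumina will
  have larger Feret/MISR disagreement by construction.
- The centerline requires user endpoints and one connected mask; it
  does not discover the vascular tree automatically.
- Torsion is reported for completeness but is undefined at zero
  curvature and noise-dominated on nearly straight segments.
- The shipped atlas is a naming scaffold, not a validated anatomical
  template; branch labels are only as good as the user's seed points.
- Problem sizes in the validation suite (tube lengths 15–40 mm, 30
  subjects, 100 null repeats at 4 chunks) were chosen as the smallest
  that make the statistical assertions sharp; all scale linearly if
  larger checks are wanted.
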