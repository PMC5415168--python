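# Methods

This note documents the models, conventions and numerical choices behind
`rootone`, what the synthetic phantoms do and do not emulate, and the
known limitations.

## Conventions

Volumes are 3-D grids indexed `(z, y, x)`, with `z` walking down the soil
column (slice 0 = top of the pot).  Voxels are isotropic with a physical
side length in μm; anisotropic voxels are not supported.  Lengths are μm
internally; reported totals are cm, depths mm, and root length density
(RLD) cm·cm⁻³.  Supported grey depths are 8- and 16-bit unsigned and
32-bit float; 32-bit data is brought onto the 16-bit scale with a
user-windowed linear map (round-half-up, clipped), which fixes a common
grey scale before any cross-scan comparison.

## Inter-scan normalization and stitching

Sequential scans of one column drift in grey assignment.  The corrective
transform is a pure additive shift: each scan's histogram (default 1024
bins over its own range) is smoothed with a 5-bin moving average, the
highest local maximum inside a user window — the soil-matrix peak in
rooted soil — is taken as the scan's reference grey, and the scan is
shifted so that grey lands on a user target.  A shift is the minimal
transform consistent with assuming the histogram *variance* is stable
between scans; no gain correction is applied, so samples whose
attenuation spread changes between scans need histogram equalisation
instead (out of scope here).

Peak detection details: ties between equal smoothed maxima break toward
the lower grey value; bins at the edge of the support count as peaks only
when the histogram is not monotone (in noise-free data the dominant phase
sits exactly at the grey maximum, i.e. in the last bin); strictly
monotone histograms raise an explicit "no peak" error.  The peak is
reported as a bin centre, so shifts are quantized to the bin width.  With
heavy noise the soil peak spreads over many bins and its located centre
jitters by a few bins between scans; the drift *mechanism* is still
inverted exactly up to this quantization (the noise-free phantom
round-trips within one bin), and after alignment the re-detected peak of
every scan equals the target within one bin width by construction.

Stitching assumes purely axial overlap (no lateral shift or rotation
between scans).  For every candidate overlap `k` up to a user maximum,
the mean normalized cross-correlation between the last `k` slices of the
upper scan and the first `k` slices of the lower scan is computed; the
best `k` wins (ties toward the larger overlap), the upper scan's copy of
the duplicated band is kept, and a best similarity below `min_similarity`
(default 0.9) is reported as "no overlap detected" rather than guessed.

## Segmentation

The stage order is fixed: resize → gradient mask → bilevel threshold →
median → erosion → seeded extraction → re-binning.

* **×2 resize.** Linear interpolation doubles every dimension (8× the
  voxels) so that fine roots carry enough voxels to survive the median
  and erosion filters without fragmenting.  Output sample `j` sits at
  input coordinate `j/2`: even samples copy grid values, odd samples are
  neighbour midpoints, and the last sample clamps to the grid edge.  This
  origin-aligned mapping reproduces exact midpoints on ramps and leaves
  constants untouched.
* **Partial-volume mask.** A voxel spanning two phases receives their
  volume-weighted mean grey, so air:soil boundary voxels frequently land
  in the root grey range.  Air:soil interfaces are, however, much sharper
  than root:soil ones, so a per-slice Sobel gradient magnitude
  (`sqrt(Gx²+Gy²)`, edge replication) thresholded with the isodata
  iterative-intermeans fixed point `T = (mean(g ≤ T) + mean(g > T))/2`
  (iterated from the midrange until the update is below half a grey
  level) isolates exactly the sharp interfaces.  An all-constant gradient
  yields an empty mask by convention.  The mask is not effective around
  pores smaller than roughly three voxels, whose boundary gradients are
  no sharper than root edges.
* **Bilevel threshold.** Root grey bounds are user-set and inclusive on
  both ends; masked voxels are excluded.
* **Median and erosion.** The 3×3×3 median on binary data is a
  27-neighbourhood majority vote (edge replication), removing pore
  "tabs" and speckle while large structures persist.  The optional
  erosion uses a diameter-3 structuring element, by default the
  6-face-neighbour cross (a 3×3×3 cube has diameter > 3 along diagonals;
  the cube is available as an option).  Out-of-bounds neighbours count as
  foreground, consistent with the median's edge replication, so volume
  faces do not erode spontaneously.  Because the volume was resized,
  each erosion step removes only half an original voxel from the root
  surface.
* **Seeded extraction.** The root system is the single connected
  component containing a user seed voxel (given at original resolution,
  scaled ×2 internally).  Connectivity defaults to 26 — retaining thin
  diagonal roots — and can be set to 6 or 18.  A background seed is an
  explicit error carrying the nearest foreground voxel as a suggestion.
  The pipeline report flags extractions that capture less than a
  configurable fraction (default 5%) of the thresholded foreground,
  which usually means the seed landed on a pore fragment.
* **Re-binning.** 2×2×2 blocks map to their maximum, restoring the
  original voxel size while preserving thin structure (a block with any
  foreground voxel stays foreground).

Filtering runs as whole-array vectorized passes and components are
labelled with a union-find pass, so columns of ~10⁹ voxels at the
original resolution are bounded by memory, not recursion depth.

## Skeleton metrics

Thinning (Lee's 3-D iterative boundary peeling, via scikit-image)
preserves the 26-connectivity of every component and reduces tubular
structure to one-voxel paths.  Skeleton voxels are classified by their
26-neighbour count: 1 → tip, 2 → slab, ≥3 → junction; isolated voxels
are tips (logged).  Branches are maximal slab runs delimited by
tips/junctions; every slab voxel belongs to exactly one branch, and pure
slab cycles are emitted as closed branches.

Branch length is the calibrated sum of Euclidean inter-voxel steps (1,
√2, √3 voxel sides).  Plain voxel counting — branch voxel count × voxel
size — is available as `length_mode="count"`, but overestimates oblique
roots by up to ~1.5× and is not the default.  Even step sums carry a
small voxel-grid bias: a centerline that zig-zags between adjacent
columns (as happens when a root axis runs exactly along a voxel
boundary) reads a few percent long.

Depth profiles apportion half of every step's length to the slice of
either endpoint — exactly conservative and orientation-unbiased — and
divide by (column cross-section × slice thickness) for RLD.  Adjacent
junction voxels are merged into one branching site (26-connected
clusters, placed at their centroid) before branching-density counts,
since a single physical branching point often thins to a small junction
cluster.  The 3-D RLD map uses the same half-step apportioning on
non-overlapping cubic bins (default 2 mm); optional Gaussian smoothing is
off by default because it does not conserve mass at the map border.  The
slice RLD denominator is the full slice volume, not a soil-only volume.
Total length, the depth-profile sum and the RLD-map mass agree to 1e-6
relative by construction.

Branch angles are deliberately manual, matching field practice: the user
picks a point on the parent root, the branch vertex, and a point on the
daughter branch on the exported overlay volume (labels: 0 background,
1 root, 2 slab, 3 junction, 4 tip), and the angle is the arccos of the
normalized dot product at the vertex, in degrees.  Which angle is
measured (e.g. against the downstream parent) is enforced by the user's
choice of points.

## Phantoms

The generator emulates the imaging effects the pipeline must survive:

* geometry: root segments as capsules (watertight junctions), spherical
  air pores placed by seeded rejection sampling (non-overlapping, kept
  ≥ 2 voxels clear of roots so the analytic truth stays exact);
* partial volume: phases are rasterized on a supersampled grid (default
  4³ sub-voxels) and block-averaged, so boundary voxels receive genuine
  phase-mixture greys;
* noise and drift: additive Gaussian noise, and a splitter that cuts the
  column into sequential sub-scans with duplicated overlap slices and
  per-scan additive grey drift.

Default conditions: greys air 5000, root 22000, soil 30000 on the 16-bit
scale (air ≪ root < soil, with root:soil contrast well below air:soil, as
in real rooted soil), noise sd 800 (≈ 10:1 root:soil
contrast-to-noise), pore fraction 0.05 with 2–4 voxel radii (plausible
for repacked soil imaged at ~60 μm).  Identical spec and seed give
bit-identical phantoms.

What the phantom does **not** emulate: beam hardening and cupping, ring
artifacts, scattered radiation, moisture redistribution, grey gradients
with depth, root tissue heterogeneity (e.g. aerenchyma) and non-straight
root paths.  Real soil is therefore harder than the phantom, and
phantom-based recoveries are upper bounds: passing the detection-limit
test shows the chain is correct and self-consistent, not that any
particular field scan will reach the same limit.

## Detection-limit experiment

A single vertical cylinder (axis through a voxel centre — an axis on the
boundary between voxel columns makes the thinned centerline zig-zag
degenerately between the two symmetric columns) spans the column with an
8-voxel cap margin, at diameters {2, 3, 4, 5, 6, 8} voxels, default
noise and pores, 128×128×256 voxels per phantom — small enough to sweep
in a few minutes on one CPU while leaving ~250 slices of centerline to
measure.  Each phantom is split into two overlapping sub-scans with
drifts +500/−300, and the full chain runs with root bounds root ± 4000
(5 sd of noise), one erosion iteration, and the seed at the column
centre.  Recovery is skeleton length / analytic centerline length; a
pipeline failure (fragmented root, seed on background) counts as zero.
The detection limit is the smallest diameter from which recovery stays
≥ 90%.  Under the default conditions diameters ≥ 4 voxels are recovered
essentially completely, diameter 3 is marginal (seed-dependent) and 2 is
lost — a limit of 3–4 voxels, i.e. 195–260 μm at the 65 μm calibration.

## Known limitations

* Additive-only normalization; no gain or variance matching.
* Axial-only stitching; no sub-pixel or lateral registration.
* Whether threshold bounds should be inclusive is a convention; both
  bounds are inclusive here and documented as such.
* Skeleton lengths inherit voxel-grid bias (a few percent, orientation
  dependent); branch angles are only as good as the picked points.
* No root diameter estimation, root-order classification or time-series
  tracking.
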