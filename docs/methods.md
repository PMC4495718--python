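# Methods

This note documents the models, conventions and numerical choices behind
`mtmesh`, and what the synthetic data do and do not emulate.

## Coordinates and units

Everything internal is in nanometers, right-handed, with z along the slab
depth (the tomogram's optical axis). Voxel grids are 0-based with
`index = floor(coord / voxel_nm)` and voxel centers at
`(index + 0.5) * voxel_nm`; intervals are half-open. Volumes are written
as MRC2014 maps (via gemmi) with the voxel size in the header; label
volumes are stored as float32 maps holding integer values and cast back
to int32 on read (MRC has no native int32 mode in this writer). Distance
thresholds ("within r") are closed balls (≤ r) throughout, except the
10-nm radial parallelism threshold, which is strict (< 10 nm).

## Synthetic fiber generator

The generator emulates the tomogram-derived inputs of a K-fiber study:
cross-sectional MT center coordinates at the slab midplane, per-MT
bottom/top 3D coordinates across a 28.8–66.4 nm slab (default 45.6 nm),
a connector hypergraph, and optionally a rendered density volume.

**Packing.** MT centers are sites of a hexagonal lattice scaled to the
requested spacing, taken nearest-origin-first, with isotropic Gaussian
jitter (default σ = 4 nm). Jittering biases nearest-neighbour (NN)
distances low — each MT takes the minimum over ~6 jittered neighbours —
so the jittered set is rescaled isotropically until the empirical median
NN distance equals the requested spacing exactly; draws that bring any
pair closer than one MT diameter (25 nm) are rejected, and a bounded
number of failures signals an infeasibly dense spec. The hexagonal base
reproduces both near-regular packing and occasional doublet/triplet
clusters without a physics simulation.

**Trajectories.** Every MT runs along the bundle direction (the fiber
tilt, a polar/azimuthal pair applied to the whole bundle); a planted
subset of exactly `ceil(deviant_fraction × n)` MTs receives an extra
polar deviation drawn uniformly from (0, `deviant_polar_max_rad`] at a
uniform random azimuth. Each MT passes through its cross-section center
at the slab midplane and spans the full slab thickness in z.
Non-deviant MTs are *exactly* on-axis; real MTs always wobble slightly,
so statistics that are degenerate under exact parallelism (e.g. a
per-fiber *median* polar angle when deviants are a minority) must be
replaced by non-degenerate analogues (the acceptance script uses the
per-fiber *mean* polar angle for its cross-condition comparison).

**Connectors.** Hyperedge size k ∈ {2, 3, 4} is drawn from the polarity
mix (default 75/15/10%, dominated by bipolar connectors); the member set
is sampled uniformly from the k-cliques of the 105-nm proximity graph, so
connectors only join mutually proximal MTs (the bundle-neighbour bound).
The edge count is `round(connectors_per_mt × n_mts)`. Because cliques
concentrate in dense neighbourhoods, chains cluster more strongly than in
tomogram data; chain-size maxima therefore run somewhat above the
emulation targets at equal connector counts.

**Preset regimes.** `CONTROL_REGIME` (spacing 56.1 nm, 10% deviants up to
0.15 rad, 0.35 connectors/MT) and `OE_REGIME` (48.1 nm, 40% deviants up
to 0.35 rad, 0.8 connectors/MT) mirror the control vs
TACC3-overexpression contrast: the spacings are the reported condition
medians, the deviant parameters set the planted trajectory contrast, and
the connector rates were fixed from the reported chain-size ranges
(sparse, mostly 2–3-MT chains with many singles vs chains reaching ~12
MTs).

**Rendering.** MTs become hollow tubes: outer radius 12.5 nm, wall 5 nm
at density 1.0, lumen 0.2, background 0.0. A k-polar connector becomes k
struts of radius 2.5 nm (≈ 5 nm thickness) meeting at a junction placed
near the centroid of the member MT axes at a stratified random slab
depth, carved outside all MT tubes; a placement whose voxels would touch
a non-member MT or another planted connector is re-drawn (golden-ratio
z-sweep) so the planted per-connector voxel sets are mutually
26-disconnected and touch exactly their declared MT sets. Additive
Gaussian noise is applied last. The density levels are arbitrary but
fixed, chosen so MT-anchored thresholding is exercised nontrivially
(connector density 0.8 sits above the MT mean gray value ≈ 0.71 but well
below the wall). These minimal cylindrical struts carry much less volume
than real mesh connectors (which are blobby and heterogeneous, with mean
bipolar volumes near 6,700 nm³); the rendered mesh fraction of the fiber
volume is therefore an order of magnitude below tomogram values, and no
attempt is made to fit the reported connector-volume means — strut
thickness and geometry are exposed as parameters instead.

## Mesh segmentation

The anchor threshold is `threshold_factor` (default 1.0) × the mean
density over MT-labeled voxels — MT masks are inputs, as in hand-rendered
tomogram models. Mesh voxels are members of 26-connected components that
(a) contain at least one voxel at or above the anchor threshold, (b)
26-touch an MT surface (unattached density is the "non-mesh" control and
is discarded), and (c) contain at least `min_component_voxels` voxels
(default 8 ≈ one (5 nm)³ strut element at 2 nm voxels). 26-connectivity
is used throughout because ~5 nm struts at realistic voxel sizes break
under 6-connectivity.

The anchor threshold alone leaves only a 0.09 density margin over the
synthetic connector level, so at 20% noise thin struts fragment (≈ 87%
of planted connectors recovered). The package's refinement rule is
**hysteresis growth**: the candidate set is taken down to
`hysteresis_low_factor` (default 0.65) × threshold, but only components
seeded by an anchor-threshold voxel are kept. Noise-free behaviour is
unchanged (the mesh mask still equals the planted voxel set exactly);
recovery at 20% noise exceeds 95%. Setting the factor to 1.0 restores
the plain anchor threshold. Raising `threshold_factor` scales both
levels, so mesh volume is monotone non-increasing in it.

Components touching exactly one MT are reported as *pendants*, not
connectors; components are never merged (two disjoint struts between the
same MT pair are two connectors). Volume bookkeeping: mesh volume =
voxel count × voxel³; MT wall volume is the analytic hollow cylinder
(outer Ø 25 nm, wall 5 nm) × each MT's actual axis length, since the
synthetic label masks carry no wall/lumen distinction; filled-MT volume
uses solid cylinders; fiber volume is the 2D convex hull of the MT
centers dilated by one MT radius (12.5 nm) × slab thickness — "fiber
volume" has no standard definition, and this choice is recorded in the
report provenance.

## Packing analysis

Convex hulls are over MT *centers* (not dilated disks); density is
n / hull area, reported per µm². Bundles are connected components of the
105-nm proximity graph; the K-fiber flag requires ≥ 10 members. Search
radii are always explicit parameters because different analyses use
80/105 nm and 100 nm conventions. Heat maps are nearest-seed (Voronoi)
interpolations of per-MT neighbour counts on a regular grid covering the
padded bounding box, exact at the seed positions.

## Chain connectivity and the rank-sum test

Chains are connected components of the connector hypergraph's 2-section
(each hyperedge contributes its pairwise edges); chain-size histograms
exclude singles by definition. The chained-vs-single comparison computes
per-MT neighbour counts at each radius of a 20–120 nm sweep (10 nm steps)
and applies a two-sided Wilcoxon–Mann–Whitney test. The variant is not
standardised anywhere, so the package implements both: exact permutation
enumeration over all group assignments for pooled n ≤ 20 (valid under
ties, since the permutation distribution is built from the observed
values), and the tie-corrected normal approximation with continuity
correction otherwise. The randomisation control permutes chained/single
labels uniformly (group sizes preserved; default 1000 permutations, seed
required) and reports the per-radius median null p-value. At the
pipeline level MTs are pooled across a condition's fibers for the test
(fibers offset far beyond any search radius), with per-fiber results also
available.

## Trajectory analysis

The MT vector is the unit direction from bottom to top coordinate,
translated to the origin. Rotations follow R = R_z(α)·R_y(β)·R_x(γ)
acting on **row** vectors (v′ = v·R), the convention of the array
languages this style of analysis comes from: the azimuthal rotation is
applied before the polar one, which is what makes the α search
meaningful (with the opposite action R_z would be applied last and could
not change any vector's x-y projection magnitude, leaving the objective
independent of α and azimuthal tilts unrecoverable). The grid is
α ∈ [0, 2π), β ∈ [0, π/2] in 1° steps (γ = 0); the objective is
Σ‖(x′, y′)‖ over unit directions, and ties are broken toward the
smallest β, then α, so an already-normalized set returns the identity.
The search is exhaustive and fully vectorized (~33k rotations).

The bundle center is the minimax (1-center) point — the solved objective
of farthest-point clustering with one cluster, equal to the center of the
smallest enclosing circle (computed via shapely's minimum bounding
circle). Spherical angles use θ = arccos(z/r) and a quadrant-aware
two-argument arctangent for φ (defined 0 at the zenith). Plane
intersections scale each direction to z = 100 nm; directions with z ≤ 0
are excluded and counted. The parallelism index is the fraction of
intersections with radius strictly < 10 nm; the threshold corresponds to
θ ≈ 0.0997 rad (100·tan θ = 10). Angle-vs-distance relations are
ordinary least squares with r² and 95% confidence-band parameters.

## Pipeline

A single global seed deterministically derives per-condition, per-fiber
sub-seeds (SHA-256 of `seed/label/index`, truncated below 2³¹), so the
same config + seed yields a byte-identical report; a failure in one fiber
is flagged without aborting the others. Cross-condition comparisons are
rank-sum tests on per-fiber summary metrics (median NN distance, hull
area, median polar angle, parallelism fraction, largest chain).

## Problem sizes and limitations

The test suite and acceptance script run on desk-scale problems: cohorts
of 12 fibers of ~30 MTs, rendered volumes near 10⁶ voxels at 2 nm, 100
seeded trials for recovery/contrast properties, and 500 simulations for
type-I-error control of the proximity test. Passing these shows the
algorithms are correct on data with known ground truth under the stated
noise model (additive Gaussian); it does not demonstrate robustness to
tomographic artifacts the generator omits — missing-wedge anisotropy,
CTF, granular cytoplasm, curved or interrupted MTs — nor does it
reproduce tomogram-derived magnitudes such as connector-volume means or
mesh volume fractions, which depend on the real mesh's morphology.
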