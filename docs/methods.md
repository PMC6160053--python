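# Methods

`trabnet` reconstructs and quantifies the trabecular (beam) architecture of
echinoderm stereom from binary micro-CT subvolumes. This note documents the
models, conventions, parameters and numerical choices behind each stage, and
what the synthetic-data tests do and do not demonstrate about real scans.

## The measurement model

The stereom is treated as a spatial network: **segments** (trabeculae) are
centerline polylines with per-point radii, meeting at **nodes**
(intersections). Eight descriptors characterize the network:

| descriptor | definition | units |
|---|---|---|
| chord length `l_c` | straight distance between a segment's endpoint nodes | µm |
| curved length `l_t` | arc length along the centerline polyline | µm |
| tortuosity `τ` | `l_t / l_c`; 1 for a straight beam | — |
| mean radius `r` | mean of all point radii along the segment | µm |
| slenderness `R_S` | `L / g_r` with `g_r = d_t / 4` (circular section, `d_t = 2r`) | — |
| inter-trabecular angle (ITA) | `arccos(â·b̂)` for every unordered pair of chord directions at a node | deg |
| node configuration | valence (segments per node; self-loops count twice) | — |
| θ, φ | chord angle to the z-axis folded to [0°, 90°]; azimuth of the horizontal projection in [0°, 360°) | deg |

Conventions, chosen once and fixed:

- **Directions are chord-based**: the direction of a segment at a node points
  from that node straight to the other endpoint. A local-tangent mode exists
  (`direction_mode="tangent"`), but with τ ≈ 1.03 the difference is
  negligible and the chord is robust to voxel noise in the first polyline
  step. A node of valence *n* yields exactly *n(n−1)/2* ITAs.
- **θ** uses `arccos(|ẑ·d̂|)`, so θ = 0° is a beam perpendicular to the
  plate surface and θ = 90° a beam in the plate plane.
- **φ** is measured counterclockwise from +x after orienting the chord to
  non-negative z (horizontal chords fall back to +x, then +y). θ and φ
  together reconstruct the oriented chord direction exactly; this round-trip
  is property-tested to 1e-9.
- **Zero-chord segments** (closed loops; `l_c` below 1e-6 µm) have undefined
  τ, θ, φ (reported as NaN and excluded from those summaries) but keep their
  curved length and radii, so summary Ns can legitimately differ per column.
- **Summaries** report median, unscaled MAD (no 1.4826 consistency factor),
  min, max and N. The ITA "mode" per valence class is the midpoint of the
  tallest histogram bin (width 5°, anchored at 0°, ties to the lower bin).
- **Mechanics**: `I = πr⁴/4`, `F_E = nπ²EI/L²` with `n = 4` (both ends
  fixed) and `L` the curved length, consistent with the slenderness choice.
  Young's modulus defaults to 1 (dimensionless): no calcite stereom modulus
  is assumed, so absolute forces are meaningful only with a user-supplied E.

## Volume preprocessing

Input volumes are 8-bit grids with isotropic voxel size (default 3 µm);
arrays are indexed `[z, y, x]`, physical coordinates are `(x, y, z)` µm and
the center of voxel (0,0,0) sits at `origin + voxel_size/2`, so image and
graph space share one convention.

The binarization chain is: optional edge-preserving denoise → inclusive
band threshold (default 76–172) → removal of foreground components smaller
than 1000 voxels at 26-connectivity (inclusive boundary: a component of
exactly the minimum size survives). The denoise step is a 3-D median filter
over the chosen neighborhood (26 → 3³ cube; defaults size 3 px) followed by
a linear stretch of the remaining range to [0, 255]; it is idempotent on
two-valued volumes and exposes a bypass. Proprietary "delineate"-style
sharpening is not replicated — only its role (suppressing speckle without
blurring the material/air edge) is.

## Skeletonization and graph extraction

The mask is thinned with the homotopic 3-D thinning of scikit-image
(Lee's method), which preserves the connected-component count and topology.
The voxel skeleton is converted to a graph by classifying voxels on their
26-neighbor count (1 endpoint, 2 path, ≥3 junction), after removing
diagonal adjacencies that are implied by two lower-order steps (otherwise a
26-connected digital path reads as a chain of spurious junctions).
Junction-voxel clusters collapse to one node; with a radius field present
the node anchors at the thickest member voxel (junctions are local maxima
of thickness; a plain centroid drifts into the widest incident beam).
Pure cycles with no junction anchor at their lexicographically smallest
voxel. Per-point radii come from the Euclidean distance field of the mask;
the volume faces count as background so the field is defined everywhere.

The distance-to-background-center **brackets** the true surface distance.
`radius_map` supports three conventions: `center` (−h/2, floored at h/2 —
a single voxel reads half a voxel), `midpoint` (−h/4, the bracket midpoint)
and `none`. At this study's beam/voxel ratio (~1.5-voxel-thick beams) the
`center` convention underestimates radii by roughly a third and `none`
overestimates similarly; `midpoint` is nearly unbiased on synthetic
capsules, so the pipeline uses it by default.

At the study's resolution (16 µm beams, ~4.6 µm diameter, 3 µm voxels),
raw thinning output systematically distorts the graph. `skeleton_to_graph`
therefore applies a cleaning sequence of voxel-scaled rules (h = voxel
size):

1. merge nodes closer than 1.5 h (split junctions);
2. drop self-loops shorter than 5 h (sub-resolution tunnels at thick
   junction blobs survive homotopic thinning as tiny cycles);
3. collapse multi-edges to the shortest strand (trabecular networks are
   simple graphs at the segment scale; extra strands are double-stranded
   thinning artifacts);
4. contract junction–junction segments shorter than 2 h (one anatomical
   junction split in two);
5. bridge leaf tips closer than 3 h whose outgoing directions face each
   other (thin beams rasterize with small gaps);
6. prune leaf twigs shorter than 2 h, and prune *interior* free ends of any
   length — the stereom is a fully connected lattice, so a trabecula ending
   freely away from the subvolume faces is a reconstruction artifact,
   whereas beams truncated by the faces are real and kept;
7. weld the two segments at every remaining 2-valent node into one;
8. re-estimate each junction's position as the least-squares intersection
   of its arms' centerlines fitted over the 1–3.5 h arc window (clamped to
   1.5 h), undoing the systematic chord shortening caused by thinning
   placing junction voxels inside the blob;
9. smooth polyline interiors with 2 Laplacian iterations (endpoints fixed):
   voxel-center polylines follow the digital staircase, which otherwise
   inflates curved length (and τ by ~0.1) at ~5-voxel segments.

A `split_fused_junctions` utility (off by default) can additionally split
high-valence nodes whose arms form two separable bundles.

Avizo SpatialGraph ASCII exports can be imported directly
(VERTEX/EDGE/POINT dialect); the point `thickness` attribute is read as a
radius, with a flag to interpret it as a diameter. Imported graphs are
cleaned only by explicit `deduplicate` (exact node/segment duplicates), not
by the voxel-scale rules above.

## Statistics

Two-group comparisons use the subsampled Wilcoxon rank-sum protocol: each
of 10000 iterations draws N = 300 per group without replacement, runs the
two-sided rank-sum test (normal approximation with tie and continuity
correction, matching R's `wilcox.test` defaults), and the mean p-value is
reported. The mean p is an unconventional summary, so the full p
distribution and its quantiles are retained. Caveat: within one pair of
fixed samples the iteration p-values are strongly dependent — they all
reflect the same realized difference between the two samples — so the
fraction of iterations below α is *not* a calibrated rejection rate for a
single dataset; calibration statements in the test suite are therefore
made over independent replicate parents.

Shapiro–Wilk is run on the full sample up to N = 5000, beyond which a
seeded subsample is used (the published coefficient tables degrade for very
large N; the subsampling is recorded in the result). Skewness is
`m₃/m₂^1.5` and kurtosis the non-excess `m₄/m₂²` (Gaussian = 3), with
biased moment estimators, matching R's `moments` package. Azimuth
uniformity uses a χ² test over 36 equal half-open sectors with
df = bins − 1 (a χ² written with "36" degrees of freedom for 36 bins
appears in the source literature; the standard df is used here). Rose
diagrams are plotted from the same sector counts and carry no preferred
orientation.

## Synthetic trabecular networks

The generator emulates the statistical structure of stereom subvolumes:
a 90 µm cube, median chord ≈ 16.4 µm, lognormal per-segment radii with
median 2.3 µm (σ_log 0.35, floored at half a voxel so rasterization stays
well-posed), τ ≈ 1.03, valence mix 3N/4N/5N = 0.66/0.21/0.13, θ spread
over [0°, 90°] with mode at 90°, and uniform or directional φ.

Construction: nodes sit on a jittered cubic lattice (pitch 0.92× the chord
target — jitter lengthens edges, the factor was calibrated once against the
generator's own truth tables; Gaussian jitter σ = 0.35× pitch; pairs closer
than 0.45× pitch are pushed apart, since such pairs would fuse into one
blob at scan resolution). Candidate edges come from the Delaunay
tetrahedralization (length ≤ 1.8× pitch); per-node target valences are
drawn from the mix, and edges are selected greedily by a weight combining
length preference and the orientation model (plate-like θ weighting and/or
an axial von-Mises-style φ concentration). Remaining deficits are repaired
in passes that keep interior nodes exactly on target by letting deficits
migrate to boundary nodes (whose valence is not part of the emulated mix);
connectivity is restored with shortest bridges and any resulting interior
overfill is shed again. Tortuosity is injected as a single-period sinusoid
orthogonal to the chord with amplitude `A = (L/2π)·√(4(τ−1))` (first-order
arc-length calibration). Every truth quantity is recorded per segment and
node.

`voxelize_network` rasterizes the network as a union of linearly tapered
capsules: a voxel is foreground exactly when its center lies within the
interpolated radius of the swept centerline. Geometry is clipped at the
volume faces; a segment more than one voxel outside the volume is an error.

What the synthetic model does **not** emulate: the real stereom's spatial
autocorrelation and growth structure, multi-lobed azimuth patterns (the
directional φ model is unimodal-axial — qualitatively directional, not a
fit), galleried/labyrinthic microfabric differences, CT noise, beam
hardening and partial-volume gray levels (the voxelization is a clean
binary mask). Passing recovery tests therefore demonstrates that the
skeletonization and descriptor chain is unbiased at the study's geometry
and resolution for clean binary input — not that any particular scanner's
gray-scale artifacts are handled.

## Parameter recovery and its limits

`recovery_report` compares recovered descriptor medians and interior
valence-class fractions against generator truth, with tolerance bands of
±15% (chord), ±20% (radius), ±0.05 (τ) and ±7 percentage points per
valence class. Both sides are restricted to the domain interior (margin
0.6× chord target): voxelization clips beams at the faces, so boundary
stubs carry no information about the emulated medians. Because a single
90 µm cube holds only ~60 interior nodes (±6-point class noise), the
headline recovery test pools five independently seeded subvolumes — the
same pooling the original five-plates-per-region protocol used. Typical
pooled errors at the default spec: chord −1 to −6%, radius −1 to −5%,
τ within 0.01, valence classes within ~5 points.

Known limitations: junctions closer than ~2 beam diameters fuse
irrecoverably (the cleaning rules mitigate but cannot eliminate this, which
is why 6N+ classes appear in recovered — and published — tables); chord
medians carry a small negative bias from residual junction displacement;
sub-voxel radii are only recoverable up to the bracket ambiguity described
above.

## Reproducibility

Every stochastic step takes an explicit seed (generator, subsampled tests,
Shapiro subsampling); rerunning a pipeline config reproduces all numbers
exactly, and run reports embed the full configuration and seeds.
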