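# Methods

`morphomovie` reconstructs hypothetical 2D tissue movement maps of the early
mouse limb bud from an hourly sequence of outlines, simulates virtual clonal
fate maps on them, selects the map that best explains experimental clone
data, and derives growth tensors, progenitor maps and growth-only
gene-expression predictions from the selected map. The outline sequence
constrains the boundary but leaves the internal movements underdetermined
(tissue can slide along a featureless boundary), so the method is a
reverse-engineering loop: generate candidate velocity fields consistent with
the outlines, simulate the clonal experiment on each, and keep the candidate
that matches the observed clones.

## Coordinate frame and the synthetic trajectory

All geometry lives in a dimensionless model frame: the proximo-distal (PD)
axis along +x (distal = larger x), the antero-posterior (AP) axis along y.
The bud protrudes from a flat body flank at the minimal-x side; the flank is
an artificial rectangular strip so the deep body tissue can be pinned.

The real morphometric outline trajectory this kind of study uses is not
publicly deposited, so the package ships a parametric generator
(`trajectory.generate_synthetic_trajectory`) that emulates its qualitative
course: 72 hourly frames labeled mE9:00 … mE11:23 in morphometric-stage
notation (hour 36 = mE10:12, the stage conventionally equated with E10.5;
"E12" aliases the final frame). Frame 0 is a semicircular bud of radius 1
(model units) on a flank of depth 0.5; the profile is a stretched
half-circle whose tip advances 0.045 radii per hour (≈4× elongation over
the window) and whose AP half-width is modulated by a Gaussian bump at ~70%
of the PD extent — the distal paddle — ramping in smoothly from hour 36
over 24 h to 50% relative widening. The bud base width is held constant so
every frame shares a congruent flank. These defaults were chosen once to
look like a limb bud: monotone area growth, smooth convex-ish shape, distal
widening in the second half of the window. What the generator does *not*
emulate: AP asymmetry of the real bud, outline measurement noise (a smooth
seeded perturbation is available but off by default), and any real staging
variation. Tests passing on this trajectory therefore validate the
machinery, not any biological number.

## Meshing

Each outline is discretized by a deterministic mesher
(`meshing.triangulate`): the outline is resampled at the target edge length
(sharp corners, e.g. the flank rectangle's, are pinned), the interior is
filled with a hexagonal lattice kept ≥0.7·h away from the boundary,
the point set is Delaunay-triangulated, triangles with exterior centroids
are discarded, and four Laplacian smoothing passes on the interior raise the
worst angles. Invariants enforced: positive CCW triangles, triangle areas
partitioning the boundary-polygon area to 1e-6 relative, single component,
disc topology (V−E+F=1), and a 15° minimum-angle quality floor.
`REFERENCE_EDGE_LENGTH = 0.042` is the documented resolution at which the
E9 frame meshes into ~3.2k triangles — the scale used by full
map-evaluation workload counts; the working resolution for the shipped
studies is 0.3 (tens to ~200 triangles per frame), chosen so that whole
72-frame movies build in seconds.

## Boundary mapping

Correspondence between consecutive outlines is defined by user-supplied
*boundary control splines* (file-based polylines; three default sets ship:
straight distal rays, a deeper fanning-out focus, and an anteriorly shifted
focus that twists growth posteriorly). The k-th intersection of a spline
with outline t is paired with its k-th intersection with outline t+1
(mismatched counts are an error naming the spline); flank intersections are
excluded. The control vectors are interpolated onto all non-flank boundary
nodes by two Gaussian RBF least-squares fits (one per displacement
component), basis `exp(−|p−p_k|²/(2σ²))`, σ defaulting to the mean
nearest-neighbor spacing of the control origins and ridge 1e-10 for
conditioning (ridge 0 on a nonsingular system interpolates exactly).

Displaced boundary nodes are then snapped onto the next outline so the
deformed mesh boundary lies exactly on it. Closest-point projection alone
can fold or collapse adjacent nodes, so snapping goes through arc-length
coordinates on the target ring, made cyclically monotone with a minimum gap
(0.25× the mean node spacing) by weighted isotonic regression with flank
nodes pinned. Flank nodes always receive zero displacement — they represent
deep body tissue.

## Spring-analogy deformation

Interior displacements come from a lineal edge-spring equilibrium: node i
settles at the stiffness-weighted average of its neighbors,
`d_i = Σ_j k_ij d_j / Σ_j k_ij`, a convex combination, so interior
displacement components obey a discrete maximum principle. The spring
analogy is a device for generating smooth hypothetical maps, not a
mechanical tissue model. Edge stiffness is `k_e = f(x_e)/ℓ_e` — inverse
edge length (preserving element quality) times a PD profile `f`:
constant, sigmoid (distally stiff, restricting distal expansion) or
inverted sigmoid (distally soft, enhancing it), with midpoint at 2/3 of the
frame's PD extent, steepness 10/extent and amplitude 4 (f ∈ [1, 5]).
Combining the 3 spline sets with the 3 profiles spans the canonical nine
candidate maps.

The solver computes the exact fixed point by a direct sparse solve of the
interior equilibrium system (the damped Jacobi iteration is implemented,
selectable, and tested to converge to the same fixed point; the direct
solve is the default because the fixed point, not the iteration path, is
the contract, and whole-movie builds solve the system 71 times). After each
step an element-inversion check runs; on inversion the step retries as two
half steps (depth ≤ 3) before raising.

## Conservative remapping and the MorphoMovie

To avoid accumulating element distortion over 72 h, each frame is re-meshed
and per-triangle quantities are transferred conservatively: deformed source
triangle i contributes its overlap area with target triangle j as weight
w_ij, and transfer is the area-weighted convex combination
`v'_j = Σ_i v_i w_ij / a_j` — linear, positivity-, constant- and
maximum-principle-preserving. Candidate pairs come from an STR packed
R-tree; exact areas from polygon clipping.

Two implementation points matter for exactness. First, the fresh mesh of
frame t+1 is built directly **on the deformed boundary ring** of frame t
(long segments split by collinear insertions, which leaves the polygon
geometrically unchanged; interior regenerated fresh). Consecutive meshes
therefore share an identical boundary polygon and the raw overlap weights
already satisfy both partition invariants (row sums = deformed source
areas, column sums = target areas) to clipping precision; a short iterative
proportional fitting pass polishes them to exact margins. If instead the
new mesh were resampled independently from the smooth outline, the two
boundaries would be different chord polygons and boundary triangles would
carry O(h²/R) sliver defects — percent-level, unrepairable. Second, both
triangle sets are snapped to a 1e-12 precision grid before clipping:
the polygon-overlay backend is not robust when nearly identical vertices
differ in the last ulp, which is exactly what regenerated interiors
produce. Numerical tolerances: weights below 1e-12 of the mean triangle
area are dropped before balancing; split insertions are nudged inward by
1e-8·h so the Delaunay step cannot emit exactly degenerate boundary
slivers.

A `MorphoMovie` bundles the mesh sequence, the hourly displacement (=
velocity) fields and the interpolation maps, and serializes to a text
directory (OFF meshes, CSV velocities, `i j w` sparse maps, JSON manifest
with a config hash).

## Virtual clones, mixing, and scoring

A virtual clone starts as density 1 on one seed triangle. Each simulated
hour applies (i) finite-volume diffusion on the current mesh — two-point
flux across shared edges, flux ∝ D·edge length·Δvalue/centroid distance,
zero-flux outer boundary, explicit Euler substeps held at half the
stability limit (substeps auto-increase) — modeling isotropic mesenchymal
cell mixing, then (ii) conservative transfer to the next mesh. The order
(diffuse, then advect) is a first-order operator split; swapping it changes
results at O(dt). Mass is conserved to rounding. Hourly re-meshing itself
contributes an unavoidable numerical mixing, which is part of the modeled
cell mixing; the diffusion constant D adds mixing on top. The literature
values D = 0.03 and 0.08 come without units; this package converts them at
`DIFFUSION_UNIT_SCALE = 0.02` (model-area units per published unit), fixed
once so that the lower constant yields an rms mixing displacement
√(2Dt) ≈ 7% of the final PD length over the full window — clones disperse
visibly but stay within one or two PD segments. Only the calibration
*logic* is reproduced, not the numerals' physical meaning.

An experimental clone is a triangle set on the final mesh (rasterized from
an aligned binary mask: a triangle is included when ≥50% of its pixels are
labeled). A virtual density p is scored against clone E_c as

    score = [ Σ_{i∈E_c∩S} p_i a_i / Σ_i p_i a_i ] · [ |E_c∩S| / n_c ]

— the probability that a labeled cell drawn from the virtual distribution
lies in the clone, times the fraction of clone triangles inside the virtual
support S. The support is *relative*: S = {p_i > 0.05·max p}. Two design
points were forced by experiment. (a) The first factor must be the
*normalized* mass, not a mean of raw densities: densities scale with how
concentrated a movie keeps its fields, and a raw-density score lets the
more concentrated candidate map beat the generating map on every clone
(observed 10/10 before the fix). (b) The support must be relative: after
dozens of re-meshings every field carries ≥1e-4-level tails over the whole
mesh, so any absolute cutoff near zero makes the containment factor inert.
The movie's total score is the product of the per-clone best scores from an
exhaustive scan over all seed triangles (ties to the lowest index), so one
unexplained clone collapses the total — a map must explain all clones at
once. The scan is affordable because advection and diffusion are linear:
propagating the identity matrix yields every seed's final density in one
pass.

Two kinds of synthetic "experimental" clones are used in studies.
Thresholded clones (triangles above 30% of the field max) are clean cores,
used for seed-identifiability studies. Sampled clones draw N=60 cells
multinomially from density×area and keep the triangles containing ≥1 cell —
the faithful emulation of a clone as a stochastic realization of the
density, tails included; these are what map-selection studies need, because
thresholded cores systematically favor whichever map is more concentrated.
Exact recovery of the generating seed triangle is only identifiable over
short horizons: after ~35 hourly re-meshings the densities of edge-adjacent
seeds nearly coincide (every observed miss in long-window studies is an
adjacent triangle). The shipped recovery study therefore uses a 25-hour
window at working resolution; shipped fixture clones are likewise seeded
25 h before the final frame.

Clone mixing is quantified by the overlap of two estimated clone
probability distributions. Distributions are estimated from binary clones
by an iterated mean filter (average over self + edge-adjacent triangles,
renormalized to sum 1 each round; default 10 rounds); overlap is the
Bhattacharyya coefficient `Σ √(p_i q_i)` — symmetric, 0 for disjoint
supports, 1 for identical distributions. Pairwise overlap of virtual clones
grows monotonically with D, so the mixing constant is calibrated by
bisection on the overlap-vs-D curve against the experimentally estimated
target (`clones.calibrate_mixing`).

## Growth tensors

Assuming linear velocity variation per triangle, the velocity gradient L is
the unique 2×2 matrix mapping the two edge vectors to their velocity
differences (exact for affine fields). Its symmetric part gives the area
expansion rate (trace) and the anisotropy — the normalized eigenvalue gap
(λ₁−λ₂)/(λ₁+λ₂), with the principal direction; the anisotropy is flagged
NaN when the expansion rate is non-positive (pure shear/rotation). The
antisymmetric part gives the rigid rotation rate. Expansion translates to a
cell-cycle time T = ln2 / expansion rate (∞ when non-positive): the time to
double a triangle's area if expansion were entirely proliferative.
`tensor_report` emits the per-triangle table with anisotropy-ellipse
semi-axes exp(λ·Δt) at Δt = 1 h; heat-map displays clamp cell-cycle times
to 10–42 h, and regional summaries average the distal third of the PD axis
(from the tip) against the proximal two-thirds. Regional cell-cycle values
on the synthetic trajectory are reported for orientation only; they depend
on the synthetic growth rates and are not comparable to measured limb
values.

## Expression transport and regulation calls

A thresholded expression domain on one frame is an indicator field.
Growth-only prediction transports it forward through the interpolation maps
or backward through their transposes (exact adjoints of forward transport
under the area-weighted inner product; reverse maps are built by
transposition, which guarantees that the reverse transport of the all-ones
field is all-ones — the partition-of-unity property progenitor maps rely
on). Expression transport defaults to D = 0 — domains are tissue marks, not
dispersing labeled cells. Differencing prediction against observation at
threshold θ = 0.5 classifies each triangle: observed ON but predicted < θ →
"up" (active up-regulation required), observed OFF but predicted > θ →
"down", else "consistent". Binarizing a prediction at θ and differencing it
against itself yields all-consistent at any θ — the self-consistency
anchor.

Progenitor maps run the movie backwards from a partition of the final
frame (e.g. PD thirds standing in for stylopod/zeugopod/autopod):
reverse-transfer then diffuse, per hour. Membership probabilities sum to
one everywhere at every frame; mixing strictly widens every progenitor
region wherever it has not already saturated the (early, small) bud —
saturation itself being the statement that early on, any cell could
contribute to every segment.

## Reproducibility and scale choices

Everything is single-threaded and deterministic given configs and seeds;
artifact directories carry a config hash. The shipped studies run at
working resolution h = 0.3 with 72-frame movies (conservation, progenitors,
calibration) and 25-frame movies (recovery/selection); full-scale
(~3.2k-triangle) meshing is exercised for the single reference frame. Known
limitations: clone extents are axis-aligned (rotated clones are
under-measured); the synthetic trajectory is AP-symmetric; exact seed
recovery degrades gracefully to neighbor-level recovery on long horizons;
and the mesher is not a guaranteed-quality constrained Delaunay — its
quality floor is enforced by validation, not by construction.
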