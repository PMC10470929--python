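# Methods

## Data model and conventions

Volumes are `(z, y, x)` arrays, 0-based, with physical spacing in nm per
voxel carried on a `VoxelGrid`. The default analysis grid is 10 nm
isotropic; the orthogonal-reslice operations (`yz`, `zx`) refuse
anisotropic grids because a 2D model trained on one plane family is
only transferable to the others when voxels are cubes. Slice
directories must be zero-padded, lexicographically ordered, gap-free
PNG or TIFF; integer volumes round-trip bit-exactly (binary masks are
stored as 0/255 bytes, label volumes promote to 16-bit when ids exceed
255).

## Three-axes prediction and confidence coding

`predict_plane_stack` applies a pluggable 2D predictor (any callable
mapping a grayscale plane to a same-shape probability plane in [0, 1])
along each axis and restacks. Two fusion modes are exposed because both
are legitimate readings of the procedure: per-voxel probability
averaging expanded to bytes, `round(255·mean)` with
round-half-away-from-zero (the default), and an explicit 2-of-3
majority vote on thresholded masks. For binary per-view votes the two
agree exactly (averaging {0,1,1} gives byte 170 > 127). Averaging is
fixed *before* byte expansion; the alternative order differs only in
rounding and is not exposed.

Byte classification: 0 is confident background, codes strictly above
127 are foreground, and [1, 127] is low confidence. The boundary byte
127 sits in an assignment gap between the two published rules
(">127 foreground" vs "[1,126] low confidence"); it is assigned to low
confidence so an exactly ambiguous voxel is flagged for human review
rather than silently accepted.

Training support is deliberately thin: the BCE + (1 − Dice) loss used
to train the 2D networks is implemented (with ε-clipped predictions),
the border-exclusion mask trims `floor(fraction·extent)` pixels per
side (default 10%; predictions near image borders lack context), and
`rank_slices_for_correction` orders slices by descending low-confidence
fraction as a proxy for the human choice of poorly predicted sections
during iterative human-in-the-loop training. Network training itself is
out of scope; a reference configuration for the original 2D UNet++
setup (RMSprop, 400 epochs, batch 4, learning rate 1e-4, 512×512 crops)
is recorded here for users who bring their own trained model behind the
`Predictor2D` contract.

## Agreement metrics

Precision, recall, F1, and IoU, with conventions chosen so empty
phantom slices are well-defined: precision/recall are 1 when their
denominator is 0, and F1 and IoU of two empty masks are 1. These make
the identity F1 = 2·IoU/(1+IoU) exact in all cases. The
slice-continuity statistic is the population variance (a sample-variance
flag exists) of IoU between consecutive xy slices over a window of
`n_pairs` pairs starting at `start_pair`; the window start is exposed
rather than fixed because published analyses used both pairs [2,6] and
[3,7]. Every slice in the window must contain foreground; the first
empty slice aborts with its index.

## Morphometry

Objects are 26-connected components (6-connectivity face tests define
the surface — the standard 3D foreground/boundary duality), relabeled
1..K by descending size for determinism. Components under 20 voxels are
removed as misannotations. Volume is voxel count × voxel volume (μm³).
Surface is the count of boundary voxels — component voxels with a
6-neighbour outside — times one voxel face area (μm²). This
boundary-voxel convention under-measures curved surfaces relative to a
mesh (a digitized sphere's MCI comes out below the analytic minimum
9/(4π) ≈ 0.716); the bias is uniform across shapes measured the same
way, so comparative statistics are unaffected, but absolute
surface-derived values should not be compared against mesh-based
measurements. For anisotropic grids the mean of the three face areas is
used. A meshed surface is out of scope.

Principal axes come from the eigen-decomposition of the population
covariance of voxel-centre coordinates in physical units; axes are
unit-norm, descending by eigenvalue, with each axis's first non-zero
coefficient made positive (eigenvector sign is arbitrary). Axis length
is the projected extent along each axis **plus one voxel pitch along
that direction**, so a single voxel has length one voxel rather than
zero; lengths sort to L_max ≥ L_mid ≥ L_min and the aspect ratio is
L_max/L_min. The extent-plus-one-voxel choice is a convention (the
alternative, raw extent, differs by one voxel and is trivially derived
by subtraction). MCI = SA³/(16π²V²) is dimensionless and
scale-invariant.

## Cristae

Crista class labels (lamellar vs tubular) are *inputs* — they come from
the two prediction channels or from the phantom; no geometric
re-classifier is included. The gap channel is the set of non-crista
voxels within 60 nm Euclidean distance (physical units, via the exact
distance transform) of a crista voxel; it exists to keep closely
stacked lamellae from being annotated into each other during training.

Touching lamellae are separated by one 6-connected erosion (count
configurable) followed by 26-connected labeling; components under the
20-voxel floor are dropped, and a warning is raised if erosion removes
everything (plates thinner than 2·iterations+1 voxels vanish). The
plate normal is PC3 of the lamella's voxel cloud; the orientation angle
is arccos|normal·long-axis| folded to [0, 90]° — 0° means the crista
plane is perpendicular to the mitochondrial orientation. A perfectly
flat plate (λ3 = 0) has an exact normal and is kept (its 1/λ3 plot
weight becomes infinite); only λ2 ≈ λ3 (no unique normal, e.g. a rod)
is skipped with a warning. The per-mitochondrion summary is the
*unweighted* mean of plate angles; the 1/λ3 weight is retained on each
record purely as a plot magnitude. Whether the original per-mito
average was weighted is not recoverable from the published text; the
unweighted mean was fixed here.

## Crista junctions

For erosion depths 3, 4, 5 (voxels; 30/40/50 nm on the 10 nm grid), in
this order: the mitochondrion is eroded with the 6-connected cross
element iterated `d` times; voxels on the eroded surface overlapping
the crista mask are junction candidates; each candidate's nearest
original-surface voxel (Euclidean; ties broken lexicographically in
(z,y,x)) is its anchor; the discrete 3D line between them (voxel-centre
DDA, endpoints excluded) is traversed and the candidate is confirmed
only if every line voxel's intensity lies in [0, 126]. The confirmation
field is by default the registered raw EM grayscale, where membranes
are dark — so the test asks whether the path from crista terminus to
surface is membranous, i.e. actually contiguous. The field is an
explicit parameter because a probability map is an equally
implementable reading. Anchors claimed in an earlier depth cycle
disqualify later candidates (each boundary point yields one junction).
Confirmed voxels are grouped at 26-connectivity across shells;
single-voxel groups are dismissed ("smaller than 2 voxels" read
literally as dismissing only singletons). One practical consequence,
verified in tests: a crista whose cross-section is a single voxel
yields no junction — the depth-3 anchor claim plus the singleton
dismissal remove it.

CJ density is the junction count divided by a reference area — crista
surface area by default, total mitochondrial (inner-membrane) surface
as an alternative mode; per-class densities divide class junction
counts by class surface areas.

## Septa

Each separated lamella is tested per mitochondrion: erode the
mitochondrion by 4 voxels (removing the boundary-membrane region, so a
plate that merely approaches the surface does not spuriously
partition), subtract the plate, and count 6-connected components
(6-connectivity so a 1-voxel-thick plate actually separates; at 26 the
matrix would leak diagonally through it). With ≥2 components, the
record is flagged a potential septum when the smaller compartment
exceeds 15% of the partitioned (eroded) mitochondrial volume. The
denominator is the eroded volume rather than the original: the eroded
body is the object actually split, the fraction then reflects the
geometric split itself (a 40/60 bisection reads ≈0.4), and for large
mitochondria — where the 4-voxel rind is negligible — the two readings
coincide. Perforated plates leave the matrix connected and are never
flagged.

## Subvolumes, features, unsupervised analyses

K-means on voxel physical coordinates partitions each mitochondrion
into K = max(1, round(V / 5×10⁻³ μm³)) subvolumes ("around 5×10⁻³ μm³"
made reproducible by fixed rounding), k-means++ initialisation with a
single run under the supplied seed. Per-subvolume tubular/lamellar
percentages quantify spatial class segregation.

The feature table has nine columns in fixed order: mitochondrial
volume, surface, aspect ratio, MCI, crista volume, crista surface,
tubular volume ratio, tubular surface ratio, CJ density. Mitochondria
without cristae are excluded (their tubular ratio is undefined) with a
logged reason; a size-outlier rule (volume beyond median ± k·MAD,
default k = 5) exists but is **disabled by default** since the original
"deviated size" criterion is unspecified. Standardization (zero mean,
unit variance) and the PCA are fitted on the control group only and
applied to all rows, so treatment mitochondria are expressed in control
feature space; component signs are fixed by making the
largest-|loading| feature positive. Ward linkage with Euclidean
distance on the standardized features provides the hierarchical view.

## Phantoms

The generator voxelizes ellipsoidal mitochondria (centre, semi-axes,
optional rotation) containing lamellar plates (slab around a centre
with a chosen normal, thickness, lateral extent, optional central
perforation), tubular cylinders (segment + radius) and full septa.
Structures marked junction-contacting overshoot the boundary and are
clipped to the mitochondrion, guaranteeing a membranous bridge at the
surface; detached structures are kept ≥70 nm from the boundary (beyond
the deepest 50 nm detection shell), so the planted junction count is
exact by construction. The truth ledger records junction counts and
classes, plate normals with planted angles against the long axis,
septum hosts, and analytic volumes/surfaces (Thomsen approximation for
ellipsoid area).

Grayscale rendering assigns membrane voxels (cristae + 1-voxel boundary
shell) value 40 and everything else 200 — straddling the 126 junction
confirmation bound with ≥3σ headroom at the default noise sd of 10 gray
levels — plus clipped Gaussian noise. Probability rendering draws, per
axis view and per voxel independently, a correct call with probability
`fidelity` (default 0.8), yielding 1.0/0.0 fields; a mock plane
predictor replays the field plane-by-plane so the fusion stack can be
exercised end-to-end without a trained network.

What the phantoms do *not* emulate: EM texture, spatially correlated
prediction errors (real model errors cluster at boundaries; the
per-voxel independence here is exactly what makes the 10.4%
majority-vote law hold), anisotropic point-spread, membrane thickness
variation, and touching mitochondria. Passing tests therefore establish
the correctness of the geometry and bookkeeping of the algorithms, not
segmentation performance on real EM.

Default phantom scales follow the biology: mitochondria with semi-axes
of 200–450 nm (volumes 0.04–0.13 μm³), crista plates ~30 nm thick,
tubules 30–40 nm radius, on 10 nm isotropic grids of 64³–16·10⁶ voxels
— small enough that the full suite runs in well under a minute per
module while every detector still sees multi-voxel structures.

## Numerical choices and degenerate inputs

- Rounding for byte expansion is half-away-from-zero, stated for bit
  reproducibility.
- Nearest-anchor ties and candidate iteration order are lexicographic
  in (z, y, x); component ids sort by descending size then first
  occurrence — all outputs are deterministic given config + seed, and
  the pipeline writes byte-identical files on re-run.
- Phantom slab faces are kept off lattice planes where plates may be
  tilted (35 nm thickness on the 10 nm grid) so that floating-point
  residue in a rotated normal cannot flip voxels exactly on a face.
- Empty masks: gap of an empty crista set is empty; junction detection
  on an empty mitochondrion returns no records; tubular ratio of a
  crista-free mitochondrion is missing (excluded downstream), and
  density over zero area is missing rather than infinite.

## Known limitations

Surface areas inherit the boundary-voxel bias described above. The CJ
detector assumes an isotropic grid (erosion depths are voxel counts)
and refuses anisotropic input. Downsampling from acquisition resolution
(e.g. 4.88 nm lateral) to the 10 nm analysis grid is left to the user.
Statistical group comparisons (rank tests etc.) are downstream of the
feature table and not part of the package.
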