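# Methods

This note documents the modelling choices in `artissm`: the articulation
model, the correspondence and normalization procedures, the statistical
core, the biometrics, the synthetic study design, and the numerical
decisions and limitations a user should know before trusting results on
real data.

## Articulation model

Each of the four skeleton bones carries a right-handed orthonormal frame:
the y-axis along the bone's elongation, the z-axis perpendicular to its
sagittal plane, the x-axis dorsal. The frame origin c_b is the centre of a
circle fitted (least squares, Kåsa algebraic form) to the bone's proximal
articular surface projected into the sagittal plane; the flexion axis a_b
of bone b is parallel to the parent's z-axis and passes through c_b.
Flexion by θ is the conjugated rotation `T R_z(θ) T⁻¹`, where T has the
parent's orientation and translation c_b, applied to the bone and
everything distal to it; components mapped to the same skeleton bone
always receive the identical transform, preserving joint spaces. Spherical
joint angles decompose the parent-to-bone relative rotation as intrinsic
z–x–y (flexion α about parent z, abduction β about y_b×z_p, internal
rotation γ about the bone's own y); the order is a convention — the
decomposition is exactly invertible, which is what the tests pin down.
Gimbal lock (bone y parallel to parent z, β = ±π/2) raises an error rather
than returning an arbitrary split.

## Correspondence

The reference components are registered per component (M independent
registrations per subject):

1. **Placement.** Components arrive labelled, so the ten labelled
   component centroids give a global similarity fit (Umeyama) with no
   symmetry ambiguity. The global scale is estimated once per limb from
   those centroids and then locked — a limb has one scale, and per-group
   free-scale ICP is unstable on partially mismatched shapes. Each bone
   group is then placed by fixed-scale rigid ICP: groups with three
   non-collinear component centroids (P1 + sesamoids; P3 + distal sesamoid
   + capsule) start from their own centroid fit, the rest from their
   parent's converged placement, so each step absorbs at most one joint's
   flexion offset. Finally the placement is re-anchored against the
   *correspondence* rather than the surface: normal-shoot correspondence
   (below) alternates with a Procrustes re-fit, because a surface-distance
   ICP optimum is biased by the subject's shape deformation while the
   Procrustes fit of a correspondence is not.
2. **Elastic registration.** Stiffness-annealed non-rigid ICP: per level,
   the displacement field minimizes point-to-closest-surface-point
   distance plus a graph-Laplacian smoothness penalty (three decoupled
   sparse SPD solves per iteration), with the stiffness annealed
   geometrically (default 50 → 0.4 over six levels, four closest-point
   updates per level, 25 mm displacement cap). Fully deterministic;
   closest-point ties break at the lowest triangle index.
3. **Normal-shoot re-anchoring.** Point-to-surface registration fixes the
   normal offset of every vertex but leaves the tangential parametrization
   gauge-free on smooth regions, so the elastic result can slide across
   the target. Each vertex of the rigidly placed reference is therefore
   shot along the outward direction field (vertex normals averaged over a
   fixed 12 mm metric radius — smooth, and consistent across re-meshings
   of the same surface) onto the target (exact ray casting, smallest
   offset within 15 mm); the elastic position is kept only where the shot
   misses. A scalar offset along a fixed direction field cannot slide
   tangentially.

A second pass repeats the elastic step with the vertex-wise mean of the
pose/scale-normalized first-pass results as reference (reducing bias
toward the chosen reference subject), initialized from the first-pass
transforms. Registered outputs stay in each subject's world pose. The
signed geometric error scores the result: per-vertex distance to the
target surface, negative inside the closed target (generalized winding
number), positive outside; vertex-weighted averages (the choice between
vertex- and area-weighting was open; vertex weighting matches the
correspondence semantics).

## Normalization

Scale is removed by matching the subject's third-metacarpal length
(extent along the bone frame y-axis — "length" operationalized as a
max–min projection) to the reference's. Pose is removed by aligning the
root through its registration transform and then, proximal to distal,
applying the closed-form optimal flexion angle per joint
(`θ* = atan2(Σ (b×a)·ẑ, Σ (a·b − a_z b_z))`, verified against brute-force
grid search). Only flexion is optimized; abduction/adduction and internal
rotation remain in the data as remnant posture, and they remain
*measurable*: each normalized subject carries an estimated skeleton whose
bone frames come from per-bone least-squares rotations against the
reference and whose joint centres are the reference centres transported by
the mean correspondence displacement of the articular patch (a linear,
well-conditioned estimate; re-fitting the joint circle per subject
amplifies patch deformation into centre jitter).

## Statistical core

Shape vectors concatenate all component coordinates (3 numbers per
vertex) with, per bone, the log-mapped axis direction and the Euclidean
joint centre (axis directions live on S²; centres are points, so they are
*not* log-mapped). Intrinsic means are Karcher means by iterated
tangent-space averaging (tolerance 1e-12 on the step, with sub-1e-8
stalls accepted — the log/exp round trip floors near √ε radians for
tightly clustered data); non-hemispherical data are refused. No extra
weighting is applied between millimetre coordinates and radian logs
(a block-scaling option exists, default 1).

PCA runs through the L×L Gram matrix; mode variances use the L−1 sample
divisor, eigenvector signs are fixed (largest-magnitude entry positive),
and the mode matrix is re-orthonormalized by QR — columns belonging to
near-null Gram eigenvalues are numerical noise and need not come out
orthogonal, which would otherwise corrupt projections. Modes with
σ < 1e-12·σ₁ are excluded from fitting. Posed reconstruction rebuilds the
instance's own skeleton from its axis/centre entries (y from the
component geometry's principal elongation, sign fixed by a stored
reference hint; an axis parallel to the elongation is an error) and then
articulates — so the skeleton used is the instance's, not the mean's.

## Biometrics

All Table-style measures are functions of landmark vertex sets on the
reference topology, which transfer to every registered subject and
synthesized instance for free. Angles are measured against a ground plane
(the annotated ground-contact set when present, else a least-squares
plane through the lowest 2 % of capsule vertices); lengths are distances
between landmark centroids or extents along bone-frame axes; joint
curvature radii reuse the joint-circle fit; derived measures (underrun =
heel − toe angle, capsule deviation = coffin − toe angle) are computed
from their parts, so their identities hold exactly. The toe-to-heel
support ratio uses the distal bone's frame origin as the centre of
articulation, projected to the ground plane, as a percentage of the
support length. Biometric ids can also be arbitrary callables, which is
how the linearity analysis is validated: a biometric constructed as an
exactly affine functional of the weights must give a ~zero-width
recomputation interval, a quadratic one must not.

The weight regression fits each mode weight independently on [1, k] over
n = 1000 simulated instances (equivalent to the stacked multivariate
form); the linearity check rebuilds instances on a 25-point grid over
mean ± 3 sd and reports the signed range of (k̃ − k).

## Synthetic study design

The generator is the package's test bed and defines its study
conditions. The reference limb is procedural: superellipsoid-like bones
with a fixed single-lobe dorsal-ridge asymmetry (perfectly symmetric
primitives would make surface registration ill-posed in a way real bones
are not), articular patches snapped onto analytic cylinders (joint-circle
truth exact: radii 12/10/8 mm at MCP/PIP/DIP), and a two-walled hoof
capsule whose dorsal and heel wall meridians lie exactly at configurable
angles to the ground plane (defaults: toe 50°, heel 40°, coffin 50°,
palmar 5°). Default resolution is ~900 vertices over the ten components
(the study-scale stand-in for the reference's ~36k vertices); re-meshed
subjects are generated at twice the resolution from the same continuous
surfaces.

Population structure: three orthonormal latent shape modes, built from
smooth ambient sinusoids (wavelengths 60–120 mm) acting along the
smoothed outward normal — tangential fields only re-parametrize a
surface, so genuine shape modes are normal fields — weighted
allometrically by component size, zero on the metacarpal group (the
root defines the scale/pose datum), and projected orthogonal to every
per-bone similarity generator, i.e. the modes live in the Procrustes
quotient where shape is separated from pose and alignment by
construction. Mode amplitude defaults are 1.0 / 0.7 / 0.4 mm RMS over the
vertices the fields act on, roughly 3–8 % of local bone dimensions — the
magnitude morphometric studies report for scale-normalized within-
population variation. Per subject: standard-normal latent weights,
uniform flexion offsets ±0.35 rad per joint, uniform scale 0.9–1.1, a
random world pose, and optional vertex noise, abduction remnants and
axis-direction cone perturbations (all default 0). Everything is
reproducible from the config seed.

What passing tests do and do not show: the generator emulates the
*statistical structure* the pipeline assumes (low-rank smooth variation,
rigid grouping, single-axis pose offsets, global scale) with exact ground
truth, but not real anatomy — no segmentation artifacts, no soft-tissue
ambiguity, no correlated noise, and far fewer vertices. Green tests
validate the mathematics and the implementation, not clinical accuracy.

## Known limitations

* Correspondence from surface registration carries an irreducible
  pose-dependent error floor at this mesh scale (~0.2–0.45 mm per
  vertex): root alignment, the MC3-length scale factor and flexion angles
  are all estimated from surfaces registered to ~0.1 mm, and fractional
  errors there become millimetre-scale fields at the extremities of a
  250 mm limb. Consequently the latent subspace recovered through the
  remeshed + registration route is reliable only where mode amplitudes
  dominate that floor; with anatomically realistic amplitudes the
  recovered modes mix substantially with registration noise, and the
  package reports this honestly in its evaluation outputs. The
  exact-correspondence route recovers the subspace to numerical
  precision.
* Pose is a mathematical construction, not statistically modelled; mode
  weights do not change the range of motion, and only flexion is
  articulated (no abduction/internal-rotation degrees of freedom).
* Biometrics assume the neutral (unloaded, unposed) configuration and a
  synthetic-style ground contact; they are measured on meshes, not
  radiographs.
* STL I/O cannot preserve vertex correspondence (the format has no shared
  vertex indexing); use PLY/OBJ/VTK for pipeline data.
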