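# Methods

`limbmech` turns watertight polygonal reconstructions of bones and muscle
bellies into muscle moment-arm curves for a pelvis + lower-limb
musculoskeletal model. This note documents the model, its assumptions, the
parameters that matter, and the numerical and design choices made where the
design was genuinely open.

## Geometric mass properties

Volume, centroid and inertia of a closed, consistently oriented triangle
mesh are computed by the divergence theorem (signed tetrahedra against the
origin; inertia via trimesh's equivalent polyhedron integrals). These are
exact for the polyhedron and therefore invariant to re-tessellation. Open
meshes are *rejected* for volume/inertia work — the error names the number
of boundary edges — rather than healed silently, because holes in a
digitized belly usually indicate a digitization problem a user should see.
A separate `repair` utility (vertex merge, hole fill) logs every action it
takes. Inward-oriented closed meshes are flipped with a logged warning.

Muscle mass is belly volume × a homogeneous tissue density of
1060 kg m⁻³ (the standard skeletal-muscle value; per-muscle override
available). Convex-hull segment masses use a separate default density of
1000 kg m⁻³. Hull masses systematically under-estimate segment mass, so a
multiplicative per-segment correction factor scales mass and inertia
(centre of mass unchanged). No published correction values are bundled:
the factor is a required user input, and leaving it at 1.0 — the raw-hull
baseline — triggers a warning.

Units: metres, kilograms and degrees in every public interface and file.
Mesh readers take `units='mm'` because scan meshes are customarily
digitized in millimetres.

## Joint coordinate systems and kinematics

Segments form a tree rooted at the pelvis, whose frame is the world frame
with its origin at the pelvis centre; the midsagittal plane is x = 0, and
left-side structures are produced by mirroring x ↦ −x (an exact
involution). Each joint carries an orthonormal right-handed axis triad in
the parent frame — X abduction/adduction, Y long-axis rotation, Z
flexion–extension — plus a per-DOF range of motion and a sign mapping the
anatomical angle convention onto the right-hand rule (hip flexion
positive, knee flexion negative, ankle dorsiflexion negative, MTP
dorsiflexion positive by default). The hip has three rotational DOFs;
knee, ankle and MTP are single-axis hinges; there are no translational
DOFs, no patellofemoral joint and no knee long-axis rotation. At the
neutral pose (all angles 0°) every child frame coincides with its parent
frame up to the joint-location translation.

Rotations within a joint compose intrinsically Z → X → Y
(flexion–extension first). The order only matters at the 3-DOF hip; it is
declared here and testable rather than left implicit. Poses outside the
configured ROM are rejected, or clamped with a warning when requested.

Joint centres come from least-squares primitive fits: spheres (hip) via an
algebraic linear fit refined by one Gauss–Newton pass — deterministic, no
initial guess — and cylinders (knee, ankle) via a principal-axis
initialization refined on point-to-axis distance. Degenerate point sets
(coplanar; no preferred axis) raise errors carrying the singular-value
anisotropy, because a silent bad fit would corrupt every downstream moment
arm. The vertex subsets to fit are user-selected; no automatic
articular-surface segmentation is attempted.

Two osteometric helpers operate on explicit landmark picks: bi-acetabular
diameter (distance between the two fitted acetabular sphere centres, in
the input units) and subpubic angle (angle between the ramus direction
lines after projecting out the anteroposterior coordinate — the coronal
plane; the landmarking protocol is the caller's, not guessed by the
package).

## Centroid threading and path points

A muscle's line of action is threaded through its belly: the belly is
sliced by `n_slices` (default 20) planes perpendicular to the
origin-centroid → insertion-centroid chord, evenly spaced between 2.5% and
97.5% of the chord (avoiding degenerate tip intersections); each slice
contributes the area centroid of its largest cross-section loop, computed
in the slicing plane with shapely. The chord, not the principal component,
is the slicing axis: PCA axes swing on curved bellies, while the chord is
stable and matches the operational description of threading. Largest-loop
selection is the deterministic tie-break near bifurcations and is logged.
Empty slices (belly shorter than its chord span) are skipped with a
warning; all-empty is an error.

Threaded lines are downsampled to model path points greatest-deviation
first (Douglas–Peucker style), endpoints kept exactly, with a warning if
the downsampled length deviates more than 1% from the threaded line. The
count and spacing of path points is explicit and configurable because no
single convention exists.

Residual belly–belly interpenetration (inter-muscle spacing is resolved at
the volumetric modelling stage, not here) is reported by a seeded Monte
Carlo containment estimate of pairwise overlap volume.

Multi-head units (e.g. the long digital flexors/extensors, one belly with
one insertion per digit) carry one belly and one mass, and one line of
action per head sharing the proximal course — masses are never double
counted.

## Path resolution and wrapping

A musculotendon unit is an ordered sequence of points fixed in segment
frames. Between consecutive points the path is straight unless an assigned
wrap object obstructs it. Wrapping is the single-obstacle analytic
obstacle-set construction:

* **sphere** — tangent segments joined by a great-circle arc in the plane
  through both endpoints and the centre;
* **cylinder** — the gap is projected perpendicular to the cylinder axis;
  in-plane the route is tangent–arc–tangent, and the axial coordinate
  varies linearly along the unrolled path (the on-surface portion is a
  helix), so the total length is `hypot(planar length, axial travel)` —
  the planar-geodesic optimum.

Engagement is hysteresis-free: a wrap engages iff the straight candidate
penetrates the surface, and at tangency the wrapped and straight lengths
agree, making path length continuous in pose (C⁰, piecewise C¹; the
derivative jumps only at engagement boundaries). An endpoint inside a wrap
surface is an error naming the point and object.

Wrap direction is chosen by the declared active side, encoded as a signed
half-plane in the wrap frame; the *entire* contact arc must lie in the
half-plane (a midpoint-only test would accept wrapping the long way
around and make every side constraint trivially satisfiable). With no
declared side, the shorter arc is taken and logged. One wrap routes each
gap; multiple wraps assigned to a gap are tried in declaration order and
the first engaged one wins — a documented single-obstacle limitation.
There is no bone-mesh collision detection beyond wrap objects, and no
ellipsoid/torus wraps or muscle–muscle contact.

## Moment arms

The moment arm of an MTU about a joint coordinate is computed by tendon
excursion: r(θ) = −dL/dθ, length in metres, angle in radians. A muscle
that shortens as the coordinate increases has a positive arm and drives
that rotation; combined with the per-joint sign conventions this makes
"flexor" positive wherever flexion is the positive rotation.

The derivative uses fourth-order finite-difference stencils at a 0.5° step
— central in the grid interior, one-sided of matching order at the grid
ends (end samples never require poses outside the grid). The fourth-order
scheme holds the error against the analytic straight-line lever formula,
r = p̂ · (ω̂ × q) with p̂ the pull direction at the moment-bearing point,
below 10⁻⁶ m across randomized muscles and poses; a second-order scheme at
the same step leaves ~10⁻⁵ m interior and ~10⁻³ m end-sample errors, which
is why the higher order is the default. The default curve grid is 1°
across the configured ROM, fine enough to resolve peak postures to their
reported precision.

Functional classification maps the dominant sign of the arm over the ROM
(through the joint's sign convention) to the anatomical label pair of the
axis; curves that cross zero mid-ROM get the dominant label plus a
`switches_function` flag. Group membership itself is config-driven — the
automated classification is a cross-check, with mismatches logged, not
fatal.

Group curves: N(θ) = Σᵢ rᵢ(θ) / Σᵢ maxθ rᵢ(θ), with member curves oriented
(negated as needed) so the group's action is positive, and the peak taken
as the maximum of the signed, oriented curve — not |r|. N reaches 1 only
where every member peaks simultaneously. Signed summation is the default
for members that switch function mid-ROM; absolute-value summation is
available (`use_abs=True`) as the alternative reading.

## Sensitivity and Monte Carlo error margins

* **Attachment placement** — each end point is moved exactly ±1 cm
  (worst case of "up to 1 cm"; magnitude overridable) along two anatomical
  axes, mediolateral and anteroposterior by default, proximodistal for
  shaft attachments: four variant curves per muscle with max-absolute and
  percentage deviations. Anatomical directions are taken from the parent
  joint's axis triad (the flexion axis is mediolateral, the
  abduction/adduction axis anteroposterior, the long axis proximodistal).
  A variant whose moved point makes the path unresolvable (e.g. inside a
  wrap) is flagged failed; the others proceed. Note that moving a
  joint-crossing endpoint parallel to a hinge axis changes the
  tendon-excursion arm at second order in the move (the line of action
  tilts out of the hinge plane; the perpendicular-distance lever alone is
  exactly invariant) — the package reports this honestly rather than
  forcing a zero.
* **Wrap dimensions** — each wrap radius is changed by ±2 cm and every
  assigned muscle recomputed; shrinks below a 1 mm floor are clamped with
  a warning.
* **Mass** — muscle and segment mass tables scaled by +10% and +15% and
  the between-model comparison re-run, reporting which comparisons flip.

The Monte Carlo simulated error margin perturbs each member curve of a
group by a single uniform factor 1 + u, u ~ U(−0.20, +0.20) — one draw per
muscle per iteration, so every perturbed curve keeps its shape — re-sums
the group over 1000 iterations and takes the pointwise min–max envelope
(2.5–97.5 percentile available). Normalization uses the *nominal*
unperturbed peaks: renormalizing inside each iteration cancels a single
muscle's factor exactly and collapses its envelope to zero width, which
contradicts the visibly non-zero margins the method is meant to produce;
the per-iteration mode is still available behind a flag as the alternative
reading. Envelopes are seeded and bit-reproducible, and are clipped to
contain the nominal curve, so containment holds for every seed and
iteration count.

## Synthetic study conditions

The synthetic generator provides every input the pipeline needs with a
closed-form oracle attached: a pelvis block + thigh/shank rods (ball hip +
hinge knee, hominin-limb scale: thigh 0.25 m, shank 0.22 m), a fusiform
belly of revolution r(z) = r₀ sin(πz/L) (volume πr₀²L/2; defaults r₀ =
0.02 m, L = 0.3 m → mass ≈ 0.1998 kg at tissue density), a hinge-spanning
muscle with a coaxial wrap cylinder (arm ≡ radius while engaged, with the
engagement interval precomputed; the fixture declares a wrap side because
at the neutral pose the chord passes exactly through the axis and the
shorter-arc rule is degenerate there), and planted-peak raised-cosine
group curves. Geometry is exact by default; vertex jitter is opt-in and
seeded.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: digitization noise and holes in scanned
meshes, non-tubular belly topology (bifurcations beyond the largest-loop
rule), fossil-specific reconstruction choices, fibre architecture, and any
force or moment-generating capacity. The oracles validate the geometry and
calculus of the pipeline, not anatomical truth.

## Problem sizes

Default analysis sizes are chosen so a full run is interactive on one
core: 20 randomized oracle muscles × 50 poses, 1° curve grids, belly
resolution 64, 1000 Monte Carlo iterations. All are parameters, not
constants.

## Known limitations

One wrap object per path gap; no translational DOFs or kinematic loops;
subpubic-angle and joint-fit landmarking are the caller's responsibility;
hull correction factors must be supplied to reproduce published segment
masses; OpenSim-style XML export is one-way (for cross-validation, not
re-import fidelity).
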