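# Methods

## Viewing geometry and coordinate conventions

All computations live in a right-handed Euclidean frame: x toward the right
eye, y upward, z from the cyclopean origin toward fixation. The nodal points
sit at (±i/2, 0, 0), fixation at F = (0, 0, D), and both eyes project
centrally onto a shared fronto-parallel screen at z = D (the "coplanar
retinae" simplification, which makes epipolar lines horizontal). Vergence,
version, cyclovergence and cyclotorsion of the eyes are out of scope, as are
non-Euclidean models of visual space. Lengths are centimetres throughout and
the time step is 1, so displacement vectors are numerically velocities.

Defaults i = 6.5 cm and D = 57 cm are the standard psychophysics bench
configuration (57 cm makes 1 cm on the screen subtend ~1°).

Spherical motion coordinates are defined operationally: azimuth α and
elevation β of 0° denote a horizontal, fronto-parallel trajectory to the
left (−x); positive α rotates toward the observer (−z), positive β upward
(+y); speed is the vector norm. Zero-speed motions report α = β = 0. The
branch cut folds azimuth into (−180°, 180°], and a purely vertical velocity
(azimuth undefined) reports α = 0.

## Stimulus synthesis

A stimulus is an oriented line through fixation with controlled cyclopean
tilt θ ∈ (0°, 180°) and orientation disparity δ (left-minus-right image
orientation), moving rigidly along a trajectory (α, β, s). The generator
back-projects the two requested image orientations θ_L = θ + δ/2 and
θ_R = θ − δ/2 to one plane per eye (nodal point + image line through the
screen origin) and intersects the planes; the symmetric split keeps the
cyclopean orientation at θ. Horizontal lines (θ = 0) lie in an epipolar
plane, leave the two planes coincident, and are rejected as degenerate. The
"diagonal line" of the reference configuration is taken as θ = 45°
(configurable).

This generator produces exactly the idealised geometry the theory is about:
infinite lines, noise-free projections, a rigid unit-time displacement. It
does not emulate aperture occlusion masks, finite contrast-defined contours,
eye movements, or sensory noise — so passing tests certify the geometry of
the predictions, not their robustness on real psychophysical stimuli.

## The strategies

**VN.** Each eye's constraint plane is built from its nodal point and the
two projected end-line points, in Hessian normal form. The intersection
line **p** is obtained from the c_L/c_R scalars (README) and the prediction
is the perpendicular foot of F on **p**, minus F. The true 3D end line lies
in both planes by construction, so **p** coincides with it in general
position; consequently the VN velocity is always perpendicular to **p**,
which is why sweeping δ traces an approximate semi-circle of predicted
velocities. Parallel or coincident planes (epipolar stimuli) return status
`undefined`.

**CA.** Each eye first computes its 2D default — the normal component of
image motion, i.e. the perpendicular foot of the start anchor on the end
image line. The two endpoint vectors are averaged componentwise into a
cyclopean endpoint; horizontal disparity η = x_left − x_right is sampled on
the *end-position* image lines at the cyclopean endpoint's height (the
start/end choice is genuinely open; end-position is used and fixed here,
and no epipolar-refined disparity constraint is attempted). The endpoint is
split into screen points b, d offset by ±η/2, whose back-projected
constraint lines share a vertical coordinate and therefore intersect; the
intersection minus F is the prediction. Positive η means crossed disparity
(nearer than fixation): η = i (D/z − 1).

**Equivalence at δ = 0.** For a fronto-parallel line and a horizontal
trajectory (β = 0) VN and CA agree exactly; the randomized suite bounds the
discrepancy below 1e−9 cm, and the closed form for tilt θ,

    v_pred = (v_x sin²θ, −v_x sinθ cosθ, v_z),

re-derived symbolically in the test suite, matches both. Whether the
equivalence extends to β ≠ 0 is not asserted anywhere in the suite; measured
numerically it continues to hold to ~1e−10 cm for elevations up to ±40°, and
this is recorded here as an observation only.

**IOVD.** The per-eye normal endpoints are back-projected to constraint
lines through the nodal points and classified. The lines intersect iff the
endpoints have equal vertical image coordinates (zero vertical disparity of
the motion vectors); for a tilted line moving in depth the horizontal image
translations differ between the eyes, the condition fails, and the lines
are skew — reported with the perpendicular gap as a diagnostic.

**CDOT.** Horizontal disparity is sampled at a fixed screen height
(default: fixation height, configurable) at both time steps and converted
to depth by z = iD/(i + η); the output velocity is confined to the
cyclopean line of sight. A consequence worth noting: lateral translation of
a slanted line leaves the depth profile at every image height unchanged, so
CDOT reports exactly zero motion for it — the lateral component is not
merely misestimated but invisible. The canonical demonstration therefore
probes 1 cm above fixation, where disparity is nonzero yet static.

**JEMD.** A point trajectory is sampled at K + 1 instants (default K = 10)
and each step contributes one activation: the depth bin of the segment
midpoint (bin width 0.1 cm) and the binned magnitudes of the left- and
right-eye image displacements (bin width 0.01 cm). The signature is the
multiset of activations — deliberately orderless, mirroring a population
read-out over a temporal window. A trajectory and its time reversal
traverse the same segments with the same binocular speeds and so produce
identical signatures; the bin widths are demonstration-grade choices, as no
quantitative read-out model is specified for this scheme.

**Triangulation.** The exact reference for unambiguous point features:
project the displaced point into both eyes, back-project the two constraint
lines, intersect. Round-trip recovery is exact to < 1e−8 cm and the
reference front-left displacement (−0.5417, 0, −0.8406) cm recovers azimuth
+57.2°, elevation 0°.

## Numerical choices

* Line–line classification normalises the triple product
  (d₁ × d₂)·(p₂ − p₁) by ‖d₁ × d₂‖·‖p₂ − p₁‖ and compares to a scale-free
  tolerance (default 1e−9); the skew gap is |triple| / ‖d₁ × d₂‖.
  Intersection points are solved by least squares on the two parametric
  equations and symmetrised as the midpoint of the mutually closest points.
* Planes are parallel when ‖n_L × n_R‖ ≤ 1e−9 with unit normals, coincident
  when additionally the signed offsets agree after aligning normal signs.
* The geometry layer preserves the floating dtype of its inputs. The VN
  chain runs in extended precision (`np.longdouble`): at shallow tilts the
  two constraint planes are nearly coincident and intersecting them
  amplifies rounding error by the reciprocal of the dihedral angle; with an
  80-bit mantissa the randomized VN–CA discrepancy stays below ~1e−11 cm
  where float64 could reach ~1e−8.
* The foot-of-perpendicular computations are anchor-invariant: representing
  the same line by any two distinct parameter values gives the same foot
  (tested explicitly, u ∈ {0, 1} vs {−3.7, 12.2}).
* Degenerate inputs raise typed errors (coincident line points, collinear
  plane points, points behind the eyes, epipolar stimuli); field sweeps
  record per-row `undefined` status instead of aborting.

## Disparity-grid fields

The reference field sweeps δ from −6° to +6° in 0.1° steps. The inclusive
grid has 121 points; a `drop-last` endpoint mode yields 120. Both are
supported because either convention is defensible; inclusive is the
default. Field generation is deterministic and repeated runs are
byte-identical (CSV written with a fixed float format and LF endings).

## Problem sizes

The randomized suites use 500 events/instances per property (the VN≡CA
equivalence, the IOVD skew condition, the geometry oracles) with seeded
generators, and 121-point disparity grids per trajectory; the whole suite
and the acceptance script each run in seconds on a single CPU.

## Known limitations

* Fixed fixation and coplanar image planes: no vergence-dependent epipolar
  geometry, vertical disparity from eccentric gaze, or cyclotorsion.
* The stimulus is a line through fixation; motion events starting elsewhere
  are representable via the geometry layer but not by the high-level
  stimulus specification.
* CA's disparity attachment implements one (documented) reading of
  "disparity at the same retinal coordinates"; alternatives (start-position
  lines, epipolar-constrained matching) would shift CA predictions for
  slanted stimuli.
* The JEMD and CDOT demonstrators are deliberately minimal realisations of
  their processing principles, sufficient for the qualitative failure
  demonstrations but not physiological models (no motion-energy or
  disparity-energy front end, no population decoding).
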