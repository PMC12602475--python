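# Methods

`tibfem` simulates the passive mechanics of the tibiofemoral joint as a
quasi-static multibody system: two rigid bodies (femur and tibia-with-fibula,
each carrying bone and cartilage surface meshes), fifteen nonlinear tensile
elements for the ligaments and capsule, and frictionless penalty contact
between the cartilage surfaces.  Flexion is prescribed; the remaining five
joint coordinates equilibrate.

## Joint coordinates

Body frames follow the clinical convention: the femoral frame has its origin
at the distal intercondylar point, Z along the mechanical axis toward the hip
centre, Y anterior (normalised cross product of Z with the posterior-condyle
chord), X completing a right-handed triad laterally (right limb) or medially
(left limb).  The tibial frame is built the same way from the ankle centre,
the eminence midpoint and the tibial condyle centres.

The relative pose is decomposed into a two-fixed-axes-plus-floating-axis
joint coordinate system: flexion `α` about the femoral X, internal-external
rotation `γ` about the tibial Z, and adduction `π/2 − β` about the floating
axis `e2 ∝ Z_T × X_F`.  The origin-to-origin vector `H` is resolved twice:

* joint translations `S1..S3` solve `H = S1·e1 + S2·e2 + S3·e3` in the
  (generally non-orthogonal) joint basis,
* clinical translations `q_i = H·e_i` are orthogonal projections.

Under this reading the drawer identity `S2 = q2` holds at every pose and
`S1 = q1`, `S3 = q3` exactly at zero adduction; both are enforced by tests.
Flexion is positive when the shank swings posteriorly.  For left limbs the
signs of adduction, internal rotation and medial-lateral translation are
flipped at the decomposition so coordinates are mirror-invariant.  Angles are
radians internally and degrees at every file boundary; lengths are mm,
forces N.

## Ligament law

Each element runs in a straight line between its femoral and tibial
insertion (no wrapping).  Tension follows the two-branch force-elongation
law standard in multibody knee models: zero below the slack length `L0`, a
quadratic toe region `K_Q (L − L0)²`, and a linear region
`K_L (L − L0(1 + ε1))`.  The transition strain is computed per element as

    ε1 = K_L / (4 · K_Q · L0)

which is the unique choice making the two branches continuous in value *and*
slope at strain `2·ε1` (the branches switch there).  A `literal` mode that
switches at `ε1` itself — discontinuous, as the law is sometimes printed —
is available for comparison but never used by the solver.

Slack lengths are initialised from the full-extension configuration:
`L0 = e · Le`, with `Le` the insertion-to-insertion length at zero flexion
and `e` the per-element expansion constant.  Because imaging is rarely
acquired in full extension, the model is first driven to `α = 0` under
contact alone (ligaments inactive).  Contact forces only push, and
frictionless sliding on a flat plateau leaves near-zero-stiffness
directions, so that phase alone is ill-posed; a seating regularizer — 50 N
of axial compression plus centering springs (5 N/mm translational,
500 N·mm/rad rotational) — stands in for the examiner holding the joint
reduced.  At these stiffnesses the springs bias the measured `Le` by well
under 0.1 mm (the continuation-step invariance test bounds the total
variability at that level).

Per-element `K_Q`, `K_L` and `e` are **package defaults, not literature
measurements**: linear stiffnesses of 35–120 N/mm per bundle and expansion
constants within ±8% of unity, in the range multibody knee models typically
use.  They are fully overridable through the parameter YAML.

## Contact

Contact force follows a penalty law on penetration depth `δ`:

    F_c = k·δ^p + δ̇·C·h(δ, δ_c),   δ ≥ 0   (zero otherwise, clamped ≥ 0)

with `k = 500 N/mm^p`, `p = 1.5`, damping `C = 5 kg/s` gated by a unity-gain
cubic step `h` over `δ_c = 0.01 mm`.  The damping term contributes only when
penetration rates are non-zero (dynamic relaxation); quasi-static solves use
`δ̇ = 0`.

Penetration is evaluated per tibial-cartilage vertex against the femoral
cartilage surface.  `δ` is the distance to the nearest surface point, found
by a KD-tree over triangle centroids plus exact point-triangle tests, run
*per connected surface patch*: a vertex squeezed between the two condyle
patches must not change classification because the other patch's open border
happens to be globally nearer.  Total force is the tributary-area-weighted
sum (one third of incident triangle areas per vertex), which converges under
mesh refinement; a `deepest`-point aggregation mode reproduces the
single-contact convention of general-purpose multibody codes.

Two choices matter numerically and were driven by solver behaviour on
faceted meshes:

* **Smoothed normals.**  Seen from inside a faceted convex surface, the
  distance field has gradient-discontinuity ridges under every mesh edge
  (the two planar feet differ by the dihedral angle).  Using the raw offset
  direction as the contact normal puts a floor of roughly
  `force × dihedral angle` under the achievable equilibrium residual.  The
  normal is therefore Phong-interpolated (barycentric vertex normals), which
  makes the force field continuous across edges.
* **Smooth border weight.**  Whether a vertex is "inside" an open patch is
  decided by the alignment of its offset with the inward normal; a binary
  test would switch whole point forces on and off at patch borders.  The
  alignment ratio instead ramps a weight from 0 to 1 over [0.35, 0.65].

## Equilibrium and the passive-flexion protocol

At each commanded flexion angle the five free coordinates
`(γ, adduction, S1, S2, S3)` are solved so the generalized force — the
tibial wrench projected onto each coordinate's rigid-body tangent — vanishes
to tolerance (10⁻³ N for translations, 10⁻³ N·mm for rotations).  The femur
is hinged to ground about its X axis at the femoral origin, so ground
coincides with the femoral frame at extension and the tibia carries the five
dependent motions, matching the hinged-femur protocol used for cadaver
passive-flexion recordings.  The tibia is left fully free in those five
coordinates (no artificial guide joint), because any such constraint would
suppress one of the reported dependent motions.

The solver is a Levenberg-damped Newton iteration on the analytic
generalized force, with a finite-difference Jacobian that is cached across
continuation steps, updated by Broyden rank-1 corrections after each
accepted step, and rebuilt only when progress degrades.  The damping matters
because frictionless contact on a flat plateau produces directions of zero
or slightly negative stiffness where undamped Newton diverges.  Cold starts
are globalized by a bounded L-BFGS descent on the total potential energy
(ligament strain energy plus the contact penalty potential) before the
Newton stage; the box bounds keep line searches away from the gimbal
degeneracy at |adduction| = 90°.  Continuation runs at 0.5° with
warm starts extrapolated linearly from the two previous solutions; a failing
sample triggers step-halving sub-continuation (to a floor of 1/16°) unless
its residual is already within 50× tolerance — such near-misses stall on a
local micro-feature of the faceted landscape that step halving cannot
change, and are flagged instead.  Flagged samples are reported, excluded
from validation, and are rare (≲1% of samples on the default preset).

During the sweep a constant axial compression of 20 N (configurable) acts
along the tibial axis coordinate.  It stands in for the examiner keeping the
joint reduced during manual manipulation: without it, a pose in which every
ligament is slack and the surfaces separate is a legitimate — and
meaningless — equilibrium.  Gravity and inertia remain off.

## Synthetic knee generator

The generator emulates the content of a cadaver-knee data repository at the
fidelity this model class needs, with no claim of anatomical accuracy
beyond its qualitative features:

* **Femoral condyles**: two patches whose sagittal profile is an ellipse arc
  — radius of curvature varying continuously from ≈32.5 mm at the distal
  (extension) contact to ≈19–20 mm posteriorly, the flexion-varying
  curvature real condyles show — swept with an 18 mm circular cross-section.
  The ellipse replaced an earlier blended-radius sweep whose profile was
  locally non-convex, which put interior distance-field ridges at the
  surface and stalled the solver.  The medial condyle is slightly larger.
* **Tibial plateaus**: a concave medial dish (spherical height profile,
  R = 40 mm) and a flat lateral plateau, 17 mm discs.
* **Cartilage** surfaces are offset 2.5 mm outward from the bone surfaces.
* **Landmarks** are placed so the frames rebuilt from them coincide exactly
  with the generator's canonical axes (the frame-defining pairs are
  symmetric; seeded noise goes on non-frame-defining points and on a global
  ±4% size factor).
* **Attachments**: tibial points are anatomical footprints; femoral points
  cluster in the sagittal plane near the centre of the extension-contact
  arc, i.e. near the effective flexion axis, which keeps insertion-to-
  insertion excursions within a few mm across the flexion range.  The
  residual offsets were calibrated against the model's own coupled
  flexion path so that the engagement pattern reproduces the passive-flexion
  behaviour reported for real knees: posterior capsule, popliteals, pACL
  and LCL loaded near extension and slackening with flexion; PCL bundles
  (posterior dominant), dMCLa and ALL engaging and growing with flexion;
  collaterals near-isometric.  Peak tensions on the default preset are
  ≈130 N — passive-manipulation magnitudes, not activity loads.
* **Flexion profiles**: four cycles ≈7° → ≈111° → ≈7° sampled at 0.5°, with
  seeded sub-degree wander of the turning points emulating repeat manual
  cycles.  Cycle-to-cycle variance in the outputs comes only from these
  profile differences; the quasi-static solver itself is deterministic.

Presets `default` (≈2.4k cartilage vertices per body), `coarse` (test
fixture) and `fine` (refinement studies) differ only in mesh resolution.
What passing tests on this fixture do **not** show: anatomical fidelity of
any specific knee, menisci or patellofemoral effects, soft-tissue wrapping,
or the absolute kinematic magnitudes of a real specimen.  The fixture's role
is to exercise every code path with physically coherent geometry.

## Validation pipeline

Dependent motions are re-parametrized on a uniform flexion grid: each
cycle's ascending and descending limbs are resampled separately by linear
interpolation and pooled; an automated spurious-point screen (residual from
a 5-sample rolling median, flagged beyond 5 MAD with a 0.5-unit floor)
replaces manual visual inspection.  Cycle means and unbiased variances are
taken pointwise.  Experimental-vs-simulated comparison fits `y = b0 + b1·x`
(y experimental) by OLS per motion and flexion range (7–90° and 7–112° by
convention), reporting slope, intercept, RMSE, adjusted R², the two-sided
slope-test p-value, and Pearson's r.  For simple OLS the slope t-test, the
model F-test and the correlation test coincide, so the choice of "the"
p-value is immaterial; the slope test is reported.

## Numerical choices and limitations

* Residual tolerance 10⁻³ N / N·mm; continuation step 0.5°; angle
  coordinates scaled by a 20 mm lever arm inside the optimizer.
* Problem sizes: the shipped analyses use the `default` preset (≈4.6k
  cartilage vertices per pair) for the four-cycle sweep and the `coarse`
  preset for unit tests.
* Degenerate inputs (coincident landmarks, collinear axes, gimbal poses,
  non-watertight meshes) raise typed errors or log warnings; penetration
  queries reject far-field vertices only on the outside half-space so deep
  interpenetration always remains visible to the solver.
* Ligament elements are straight lines: no wrapping around bone or
  cartilage, no viscoelasticity, no cross-section mechanics.
* Menisci, patella and muscle action are out of scope; results describe
  passive manipulation only.
* The validation against real cadaver kinematics requires an external
  dataset; the shipped pipeline demonstrates the complete mechanism on the
  synthetic knee, where the self-comparison limit (a trajectory validated
  against itself) must and does reproduce the identity regression row.
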