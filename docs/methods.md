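# Methods

## Model and assumptions

`gazekin` implements a *static kinematic* account of head-unrestrained gaze
shifts: it derives the desired final orientations and the stage rotations
that connect them, and discretizes those rotations in time. It deliberately
stops short of dynamics — no torques, no muscle or motoneuron models, no
velocity realism — and of binocular geometry: the eye and head rotate about
a common center, targets are directions (not depths), and the VOR is ideal
(gain 1, driven by the planned head rotation rather than a vestibular
signal).

Frames and conventions:

* Right-handed space frame with **x forward** (the reference gaze
  direction), **y left**, **z up**. All rotations are active; orientation
  matrices map reference-condition vectors to current vectors. Positive
  azimuth maps to +y; whether a plot renders that as "right" is a display
  choice.
* Angles are degrees at public interfaces, radians internally. Rotation
  vectors (axis × magnitude) are radians, since displacement commands are
  their differences. Distances are cm, times ms.
* Torsion metrics: *Listing torsion* of an eye-in-head orientation is the
  x component of its rotation vector (zero iff the rotation axis lies in
  Listing's plane); *Fick torsion* of a head orientation is the third
  angle ψ of the Rz(θ)·Ry(φ)·Rx(ψ) gimbal decomposition. Positive torsion
  is counterclockwise about +x by the right-hand rule; no physiological
  sign claim is attached.

The planner enforces the constraints only at fixation endpoints. Initial
states need not be compliant — the solution drives the final state into
Listing's plane and the zero-ψ Fick surface regardless — but the fixture
generator produces compliant initial states, which is the behavioral
regime the model describes.

## Parameters

| parameter | meaning | range | default |
|---|---|---|---|
| α | head share of the horizontal gaze displacement | [0, 1] | 0.5 |
| β | head share of the vertical gaze displacement | [0, 1] | 0.5 |
| δ | fraction of the head rotation completed before gaze stabilization (the "head contribution" phase) | [0, 1] | 0.5 |
| t | eye-to-screen distance | > 0 cm | 100 cm |

The defaults put α, β, δ midway in their range, which is the canonical
equal-contribution condition for the simulation suites. The interval
endpoints are admitted as exact limits: α = β = 0 reduces the model to a
head-fixed saccade (H_d = H_i, Rt = I); α = β = 1 points the head at the
target and returns the eye to primary position (E_d = I); δ = 1 removes
the VOR phase (Rw = Rv = I). The screen distance never appears in the
paper-style "degree" target mode; it only matters for cm-specified screen
targets and for reporting gaze-screen intersections.

## Solution pipeline and its invariants

All target modes (screen point, angular direction, retinal error) are
first resolved to a desired gaze direction; the retinal-error mode maps
the eye-frame error vector through the initial gaze orientation,
g_d = G_i·g_RE. The stages then follow the ordering described in the
README. Two structural consequences are worth stating because the test
suite leans on them:

* **δ-invariance.** E_d, H_d, G_d depend only on (state, target, α, β); δ
  enters after the endpoints are fixed and only redistributes rotation
  between the saccade/VOR pair (Re, Rv) and the head phases (Rh, Rw).
* **Exactness of accuracy.** G_d·x̂ = H_d·e_d = g_d algebraically, so gaze
  accuracy holds to round-off (∼1e-14 deg), not to a solver tolerance.

## Trajectory discretization

Each non-VOR rotation keeps its planned fixed axis and grows its magnitude
by a monotone scalar function of normalized time (smoothstep by default,
linear available; both satisfy g(0)=0, g(1)=1). The head executes Rt
continuously across its two phases — the phase boundary is a labeled time
point, not a kinematic event — with phase 1 covering the fraction δ of the
magnitude. During phase 2 the eye is re-solved each sample as
E(t) = H(t)⁻¹·G_stage2 ("online" ideal VOR): this is equivalent to
integrating the ideal angular-velocity command but exact, and it freezes
the full 3-D gaze orientation, not merely its direction. Default timing
(saccade 0–100 ms; head 0–150 ms and 150–400 ms) is an arbitrary,
configurable convention; the only structural requirement is that the
saccade end no later than phase 2 begins, so the VOR substitution is
unambiguous. Endpoints are provably timing-independent, and the suite
checks this across five distinct profiles.

## Synthetic inputs

There is no external data; inputs are generated. The fixture generator
draws eye orientations as rotations about uniformly random axes in
Listing's plane with magnitude uniform below 45°, and head orientations as
zero-ψ Fick orientations whose forward direction has eccentricity uniform
below 45° — exactly constraint-compliant by construction, bounded so that
planned intermediate directions stay inside the front hemisphere. Target
grids are uniform in the (−40°, 40°)² angular square (41×41 for
figure-quality scans, 9×9–21×21 in fast tests), and the accuracy suite
uses ±40 cm horizontal screen targets at five altitudes (0, ±20, ±40 cm)
at the default 100 cm screen distance, or a fixed 60° rightward retinal
error from the same initial fixations.

What the generator does *not* emulate: measurement noise, main-sequence
velocity profiles, VOR gain below 1, vestibular dynamics, initial states
violating the constraints, or inter-subject variability in α, β, δ beyond
the swept values. Passing tests therefore certify the kinematic structure
of the model — accuracy, constraint satisfaction, transients, and the
coordination-strategy effects on eye-in-space torsion — not a fit to any
recorded behavioral dataset.

## Numerical choices

* Axis–angle extraction uses atan2(‖skew‖, tr−1), which keeps full
  precision near the identity where arccos of the trace loses half the
  significant digits; near 180° the axis comes from the symmetric part
  with a deterministic sign convention (largest-magnitude component
  positive). The identity maps to axis [0, 0, 1], angle 0 by convention.
* The Listing orientation for a direction e uses sin τ = hypot(e_y, e_z)
  rather than sin(arccos(e_x)); this makes the α = β = 1 closure
  (E_d = identity) exact instead of accurate to ∼1e-8.
* Rotation validity is orthonormality and det = +1 within 1e-9 (Frobenius);
  `orthonormalize` projects drifting matrices back via SVD.
* Gimbal lock (|φ| = 90°) and directions outside the front hemisphere
  raise typed errors rather than returning principal values; the planner
  converts these into a reachability error instead of guessing what a
  more-than-90°-eccentric plan should do.
* Screen↔gaze conversion defaults to the self-consistent central
  projection a = t·g_y/g_x; the small-angle variant a = t·g_y is exposed
  behind a flag for comparison but is not an exact inverse and is never
  used internally.
* The twist score is an ordinary least-squares coefficient k in
  torsion ≈ k·(horizontal·vertical) on rotation-vector components in
  radians; for an ideal Fick range k ≈ −0.5 (from the small-angle limit of
  the quaternion identity −sin(θ/2)sin(φ/2)), for a Helmholtz-like range
  k > 0, and an identically-zero torsion column short-circuits to k = 0.

## Problem sizes

Figure-quality range scans use 41×41 targets; the test suite uses 9×9 or
21×21 grids and 50–100 random problems per property, and trajectory checks
use 60–200 samples per movement — sizes chosen so the full suite and the
acceptance computation each complete in seconds while exercising every
code path at full precision.

## Known limitations

The model treats eye and head rotation centers as coincident, so screen
geometry is exact only under that idealization. The initial head position
influences the final head position only through the α/β interpolation. The
trajectory's growth functions carry no dynamic content; quantities that
depend on velocity profiles (peak velocities, main-sequence relations,
phase-plane shapes) are outside the model's scope. Head-only gaze shifts
with deliberate Fick violations, and Listing-like head constraints, are
not implemented.
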