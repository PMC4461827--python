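# gazekin

A static kinematic model and simulator for **3-D head-free gaze shifts**.

When humans or other primates redirect their line of sight, the movement is
a coordinated combination of a rapid saccade of the eye in the head, a
slower head rotation, and a vestibulo-ocular reflex (VOR) that
counter-rotates the eye during the late head movement so gaze stays on
target. In three dimensions this coordination is nontrivial: rotations do
not commute, retinal error is coded in an eye-fixed frame while the motor
commands live in head- and shoulder-fixed frames, and the final
orientations obey behavioral constraints — the eye-in-head orientation lies
in **Listing's plane** (zero torsion about the forward axis), while the
head obeys the **Fick strategy** (zero torsion in a vertical-then-horizontal
gimbal decomposition).

`gazekin` plans such gaze shifts, simulates their full orientation
trajectories, and analyzes the resulting 3-D orientation ranges. It is
aimed at researchers in oculomotor control and sensorimotor neuroscience
who want an exact, testable kinematic reference for head-unrestrained gaze
behavior.

## The model

Orientations are active rotation matrices relative to a straight-ahead
reference condition: eye-in-head **E**, head-in-space **H**, gaze
**G = H·E**. A gaze shift decomposes into three stage rotations applied to
the initial state (E_i, H_i):

| stage | eye-in-head | head | gaze |
|---|---|---|---|
| saccade | Re·E_i | H_i | H_i·Re·E_i |
| eye-carrying head rotation | Re·E_i | Rh·H_i | Rh·H_i·Re·E_i |
| VOR-stabilized head rotation | Rv·Re·E_i | Rw·Rh·H_i | unchanged |

Given a target (screen point, angular direction, or retinal error) and
coordination parameters α, β ∈ [0, 1] (head's horizontal / vertical share
of the gaze displacement) and δ ∈ [0, 1] (fraction of the head rotation
that contributes to the gaze shift before the VOR takes over), the planner
solves, in order:

1. desired gaze direction g_d and desired head angles
   (componentwise interpolation by α, β);
2. the unique **zero-Fick-torsion** head orientation H_d pointing along the
   desired head direction;
3. the single fixed-axis head rotation Rt = H_d·H_i⁻¹, split coaxially into
   Rh (magnitude δτ) and Rw (magnitude (1−δ)τ);
4. the unique **Listing's-plane** eye orientation E_d pointing along
   e_d = H_d⁻¹·g_d;
5. the predicted ideal VOR Rv = H_i⁻¹·Rh⁻¹·Rw⁻¹·Rh·H_i from gaze stability
   during stage 3, and the saccade Re = Rv⁻¹·E_d·E_i⁻¹.

The saccade therefore carries a predictive torsional component that exactly
offsets the oncoming VOR — the eye transiently leaves Listing's plane
mid-movement and re-enters it at fixation, and the head transiently leaves
the static Fick surface on its single-axis path between two Fick-compliant
endpoints. Both transients, and the characteristic "bow-tie" torsion range
of the Fick-constrained head (quaternion torsion exactly
−sin(θ/2)·sin(φ/2)), are reproduced by the trajectory and range-scan
drivers.

## Worked example

```python
import gazekin as gk

state = gk.EyeHeadState.reference()
params = gk.PlannerParams(alpha=0.5, beta=0.5, delta=0.5)
plan = gk.plan_gaze_shift(state, gk.AngularPosition2D(60.0, 0.0), params)

for name in ("Rh", "Re", "Rv"):
    aa = gk.axis_angle_of(getattr(plan, name))
    print(f"{name}: {aa.angle_deg:+.1f} deg about {aa.axis.round().astype(int)}")
print(f"final eye-in-head: {gk.axis_angle_of(plan.E_d).angle_deg:.1f} deg")
print(f"final head:        {gk.axis_angle_of(plan.H_d).angle_deg:.1f} deg")
```

prints

```
Rh: +15.0 deg about [0 0 1]
Re: +45.0 deg about [0 0 1]
Rv: +15.0 deg about [ 0  0 -1]
final eye-in-head: 30.0 deg
final head:        30.0 deg
```

For a purely horizontal 60° target with equal eye/head contributions, the
head takes half the gaze shift (30°), of which δ = 0.5 contributes before
gaze lands (Rh = 15°); the saccade covers the remaining 45° and the VOR
rotates the eye back 15° while the head finishes. An oblique shift shows
the torsion transient:

```python
plan2 = gk.plan_gaze_shift(state, gk.AngularPosition2D(40.0, 40.0), params)
samples = gk.simulate(plan2, state, gk.TimingProfile(), n=200)
tors = [gk.listing_torsion_deg(s.state.E) for s in samples]
print(f"eye torsion start {tors[0]:.2f}, peak {max(abs(t) for t in tors):.2f}, "
      f"end {abs(tors[-1]):.1e} deg")
# eye torsion start 0.00, peak 2.23, end 2.1e-16 deg
```

A CLI wraps the same library:

```bash
gazekin plan --config config.yaml     # solve one shift, write plan.json
gazekin simulate --config config.yaml # write trajectory.csv
gazekin figures fig5                  # orientation-range scan tables + panels
gazekin selftest                      # invariant checks on random problems
```

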