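# Methods

## The model problem

Large soaring birds gain altitude by circling inside thermals — columns of
rising warm air that drift with the horizontal wind.  `thermosoar` packages
that problem as a closed simulation-and-learning system: a point-mass
glider, a drifting thermal, an episodic control task with shaped rewards, a
deterministic actor-critic learner, and the analysis tools (efficiency
metric, kinematic estimators, activation clustering) needed to interrogate
the result.  Everything below is computable on a desk machine; no external
flight data are required.

## Atmosphere

The updraft is a single "chimney" thermal in cylindrical coordinates:

    w(r, z)   = w_core(z) exp(-(r/R)^2) (1 - (r/R)^2)
    w_core(z) = w* (z/z*)^(1/3) (1 - 1.1 z/z*)
    R(z)      = 0.08 (z/z*)^(1/3) (1 - z/(4 z*)) z*

with defaults `w* = 5 m/s`, `z* = 2000 m`.  The radial factor gives a rising
core surrounded by a ring of sink beyond `r = R(z)`; the vertical profile
peaks near `z ≈ 0.23 z*` (about 2.3 m/s at z = 500 m for the defaults) and
the formula is taken literally above `z = z*/1.1`, where the core amplitude
goes negative — episodes never reach that regime.  The horizontal wind `u`
blows along +x, uniform in space and altitude (soaring altitudes sit above
the boundary-layer shear that would give `u` a logarithmic profile).  The
thermal center starts at the origin and drifts at `u`, keeping a vertical
centerline (no leaning).  Optional gusts resample the wind the glider feels
from Normal(u, gust_std) every 20 s, truncated at zero; the thermal center
keeps drifting at the *mean* wind so the column stays coherent — gustiness
is sensed, not structural.

## Glider

A point mass with state (x, y, z, V, γ, χ): speed, glide angle (velocity
below horizon) and side angle (heading).  Controls are bank angle σ,
angle-of-attack α, and sideslip β (kept at 0; the side-force law is in the
model but the nominal agent does not use it).  The equations of motion are
the standard 3-DOF glider set: kinematics from (V, γ, χ), `V̇` from drag
and gravity, `γ̇` from lift and gravity, `χ̇` from the banked lift
component.  Forces come from a quasi-steady closure on the *air-relative*
speed (ground velocity minus local air velocity), which is how the updraft
and wind enter the dynamics:

    C_L = C_L0 + C_Lα α,   C_D = C_D0 + k_ind C_L²,   C_Y = C_Yβ β

### Calibration

The shipped "vulture" preset (m = 7.75 kg, S = 0.87 m², ρ = 1.225 kg/m³)
does not pretend its coefficients are wind-tunnel measurements.  They are
*effective* constants pinned by three performance anchors:

1. best steady straight glide of −0.75 m/s, reached at (σ=0°, α=6°);
2. α = 6° is the min-sink point (anchor 1 is the *best* the glider can do
   without lift from the air — otherwise the efficiency baseline would be
   inconsistent);
3. the best constant-control circle in the reference thermal at z = 500 m
   climbs at +0.72 m/s.

With the lift slope fixed at C_Lα = 2.0 rad⁻¹ — chosen so the optimal
circle comes out vulture-like (R ≈ 31 m, V ≈ 15 m/s, σ ≈ 36°) — the three
anchors determine C_L0 = 0.2723, C_D0 = 0.00524, k_ind = 0.0680
(`calibrate_coefficients` reproduces them).  The steady-state solvers are
closed-form: balancing lift against weight and drag against the
along-path gravity component gives dynamic pressure, speed, glide angle,
turn radius and sink without iteration.  The optimal-climb solver scans
the (σ, α) control box ([0°, 50°] × [−5°, 15°], 0.5° grid) and polishes
the gridded argmax by golden-section search; halving the grid moves the
optimum by < 0.01 m/s.  With this closure the optimum sits on the α = 15°
box edge: a quadratic polar never stalls, so the admissible α range is
what bounds slow, tight circling.  That boundary is part of the model
definition here, as is the z = 500 m evaluation altitude (the episode
start altitude, where the core updraft is 2.3 m/s).

### Integration and instability

Classical RK4 at 0.05 s between 1 s control updates.  Over a 200 s
trajectory the endpoint moves < 0.1 m when the step is refined tenfold.
The model leaves its domain of validity when the speed falls below 2 m/s
(stall guard, the quasi-steady closure has no post-stall aerodynamics) or
|γ| reaches 90° (the heading parametrization is singular there); both are
reported as instability events, as is a cumulative same-direction pitch
rotation reaching 360° (tracked at the physics rate; a direction change
resets the accumulator — the windowed-versus-cumulative choice is not
externally fixed, the cumulative variant is this package's).

## The soaring task

Episodes last 200 s at 1 Hz control.  The glider starts at z = 500 m,
V = 15 m/s, γ = −5°, random heading, on a random annulus 80–150 m from the
thermal center — close enough to find the thermal within the first
5–20 s of search, far enough to start outside the positive-updraft core
(80 m).  The wind is drawn uniformly from the episode's [u_min, u_max].

**Observation.**  {V, v_z, σ, α, θ, u} each mapped affinely to [−1, 1]
from fixed ranges (V: 0–30 m/s, v_z: ±5 m/s, σ: ±50°, α: ±30°, θ: ±180°,
u: 0–10 m/s; the ranges are this package's choice) and clipped, plus a
memory buffer of the previous B = 8 control steps (front-padded with the
initial frame).  θ is the signed angle between the planar velocity and
the upwind direction: 0 = headwind, ±180° = tailwind, with the sign
mirrored by the circling direction (estimated from the mean heading rate
over the last 5 s) so θ always increases along the circle.  Optional
sensor noise is Gaussian in physical units, drawn once per measurement
(the memory replays the same noisy reading); noise levels are expressed
relative to per-variable trajectory-scale standard deviations
(V: 2.3 m/s, v_z: 2.6 m/s, θ: 116.4°, σ: 11.9°, α: 5.9°; u in absolute
m/s).

**Action.**  (Δσ, Δα) clipped to ±15° and ±10° per step; σ and α clipped
to ±50° and ±30°.

**Reward.**  v_z (as the realized Δz over the control second) plus the
centering penalty −d/50 (d = horizontal distance to the drifted center,
in meters, measured at the end of the step), a stability penalty of −1
per second left when the episode ends in an instability event, and −1000
on ground impact.  The center distance is *not* observable by the agent;
it shapes learning only.

## Learner

A self-contained DDPG in numpy: actor (obs → 200 → 200 → 2, ReLU hidden,
tanh output scaled to the action limits) and critic (obs+action → 200 →
200 → 1), target copies with Polyak τ = 0.005, replay buffer (2·10⁵),
Adam (actor 10⁻⁴, critic 10⁻³), batch 64, one update per environment
step, rewards scaled by 0.05 for critic conditioning,
Ornstein-Uhlenbeck exploration noise (σ = 0.15 of the action scale,
θ = 0.15/step; temporally correlated noise holds a turn long enough to
feel an updraft, which matters here).  Gradients are hand-written
backpropagation, verified against finite differences in the test suite.
The networks being plain arrays is deliberate: the activation analysis
reads them directly.

Curriculum: the wind band widens stage by stage (nominally 0–2, 0–4,
0–6 m/s) with weights carried across stages and checkpoints tagged by
cumulative simulated time.  Full-scale budgets are several 10⁶ simulated
seconds per stage; the package's scaled-down protocol
(`scripts/curriculum_eval.py`) uses 2·10⁵ s per stage — about an hour on
one CPU — and checks that the trained agent reaches positive mean
soaring efficiency at every wind speed 0–6 m/s; the test suite exercises
the same pipeline at 1.5·10⁴ s per stage, where stable full-length
flight and a many-fold gain in thermal occupancy are already reliable
but a positive η across the whole wind range is not yet.  A fully
converged η ≈ 0.8 policy remains a full-budget result.  The reward
structure makes the second bottleneck deceptive: far from the thermal,
the centering penalty accumulated over a full episode outweighs the
stability penalty for ending early, so under-trained policies can
rationally prefer early termination — visible in reduced-scale logs as a
stability dip after the initial rise, before thermalling skill makes
staying aloft profitable.

## Efficiency metric

    η = (v_z^agent − v_z^baseline) / (v_z^optimal − v_z^baseline)

with the calibrated bounds −0.75 / +0.72 m/s.  η = 1 exploits the whole
updraft, η = 0 is no better than gliding straight in still air, η < 0 is
worse; values outside [0, 1] are legal.  v_z^agent is the mean climb rate
over a flight; "fraction in thermal" counts 1 Hz samples within 80 m of
the drifted center (where the updraft is still positive).

## Kinematic estimators (1 Hz tracks)

These consume position-only trajectories — simulator output or GPS-like
bird tracks.

* **Bank angle**: in steady banked circling, tan σ = a_r/g after
  neglecting drag and vertical acceleration.  a_r is the component of the
  second-difference acceleration perpendicular to the planar velocity;
  σ is averaged over the trajectory.  On simulated constant-control
  fixtures the mean relative error is well under the 7 % validation
  bound; 1 Hz discretization (chord-versus-arc) is the dominant residual.
* **Wind**: the mean planar velocity over a whole number of circles
  (located by interpolating the unwrapped heading); over closed loops the
  circling component cancels exactly, and trimming to whole turns removes
  the partial-circle bias.  Exactly translation-invariant and
  rotation-equivariant.
* **Thermalling diameter**: crossings of θ = 0 (against the wind, type B)
  and θ = ±180° (with the wind, type A) are located by interpolation on a
  midpoint-time θ series (assigning finite-difference velocities to
  interval midpoints removes a half-sample lag).  Consecutive ABA / BAB
  triangles each yield one local diameter: the altitude from the middle
  vertex onto the outer base, or the distance to the outer points'
  midpoint when the base is shorter than 2 m (at vanishing drift the
  base direction is noise).  On analytic circles the estimates converge
  to 2R within the ~2 % discretization floor.
* **Segment selection**: maximal runs of consistent circling — per-second
  heading change above 1°/s in the dominant direction, at most 10 %
  non-conforming samples, at least 2 net turns and 100 s.  The selection
  rule for "characteristic thermalling" in bird data is not uniquely
  defined anywhere; this criterion is a documented stand-in with exposed
  parameters.

## Network inspection

Hidden-layer activations (2 × 200, ReLU, hence non-negative) of the
*actor* are concatenated per timestep — the actor is the behaving network;
inspecting it rather than the critic is an interpretation choice.
k-means (10 restarts, fixed seed) runs for k = 1..10; k is chosen at the
knee of the SSE curve (normalize both axes to [0, 1], flip the SSE axis,
take the largest gap above the diagonal).  Activations are clustered raw
by default; a z-scored variant is a flag.  Cluster-versus-θ structure is
summarized by 24-bin histograms per cluster and an association score: the
mean over clusters of the mass inside the cluster's best contiguous 90°
arc of θ (≈ 0.25 for θ-independent labels, → 1 for quadrant-aligned
labels; the 90° arc width is a fixed convention).

## Numerical conventions

Angles are degrees at every file and API boundary, radians internally.
Positions are meters, speeds m/s.  Trajectory CSVs are written at full
float precision and round-trip exactly.  All stochastic entry points
(episode reset, gusts, sensor noise, exploration, k-means, fixtures) take
integer seeds and are bit-reproducible given one.

## Known limitations

* The aerodynamic closure has no stall, no post-stall moments, and no
  6-DOF attitude dynamics; "instability" is a domain-exit event, not a
  spin model.
* The thermal is a single non-leaning column with a fixed analytic
  profile; real convection is intermittent and multi-scale.
* Synthetic circling fixtures start on the steady solution, so estimator
  validation excludes transient-dominated tracks; real bird tracks add
  GPS noise that is not modeled here (the estimators' documented accuracy
  is for clean 1 Hz sampling).
* Reduced-budget training shows the bottleneck structure and learning
  progress, not the converged full-budget policy.
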