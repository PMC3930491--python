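# Methods

`spiralpath` simulates how a population of spiral-tuned neurons, of the
kind found in primate dorsal medial superior temporal area (MSTd), can
jointly encode the instantaneous heading and the curvature of the
travelled path from optic flow alone.  This note documents the model,
the synthetic displays, the numerical choices, and the places where the
design was genuinely open.

## Model

### First-order flow (model V1)

Scenes are clouds of static dots; the observer is a pin-hole camera
(focal length 1, so image coordinates are tangents of visual angle; `x`
rightward, `y` upward, `z` along the optical axis).  For a dot at
camera-frame position `(X, Y, Z)`, a camera translating at `T` (camera
frame) and yawing at rate `phi_dot` (positive leftward) the image
velocity is the classical first-order expansion

    u = (x*Tz - f*Tx)/Z + phi_dot * (f + x^2/f)
    v = (y*Tz - f*Ty)/Z + phi_dot * x*y/f

Flow is evaluated only at the projections of visible dots (those in
front of the camera and inside the 110° × 94° field of view); dots that
leave the view are clipped, as in the emulated displays.  The analytic
flow is contracted against a finite-difference re-projection oracle in
the tests; that oracle, not any sign convention, is the correctness
contract.

### Spatial pooling (model MT)

Each flow sample is replaced by a normalized Gaussian-weighted average
of its neighbours (σ = 3°, truncated at 9°), evaluated at the dot sites
themselves.  This stage only coarsens the field; it has no direction or
speed tuning.

### Eye-velocity gain field

During smooth pursuit the extra-retinal eye-velocity signal adds, at
every sample site, `g` times the pure-rotation flow of the negated eye
velocity — compensation proportional to pursuit speed, directed opposite
the eye movement.  `g = 1` (full compensation) is the default; `g = 0`
disables the pathway.

### Spiral templates and matching (model MSTd)

A template with pattern angle `phi` and center of motion (CoM) `C` has
unit direction `cos(phi)*rhat + sin(phi)*chat` at every image point,
where `rhat` points away from `C` and `chat` is its +90° rotation:
`phi = 0` is radial expansion, `pi/2` a CCW center, `pi` contraction,
`3pi/2` a CW center; intermediate angles are spirals.  Spirality
`s ∈ [0, 1]` is the angular distance to the nearest radial pole.  The
bank enumerates 23 pattern angles × a 25 × 20 CoM grid spanning 1.5× the
field of view in each dimension — 11 500 units; CoMs beyond the display
are harmless because their templates present only laminar flow inside
the view and match poorly.

The match between the pooled flow and a template is a distance-weighted
mean cosine:

    S = (1/N) * sum_i exp(-d_i / sigma_d) * <F_i/|F_i|, T(p_i)>

with `d_i` the distance from dot `i` to the CoM, `N` the number of
visible dots and `sigma_d = 12°`.  `sigma_d` controls how local the
match is; it is sized so that typical scores land in the dynamic range
of the network's transfer function (with much smaller `sigma_d` every
score sits at the activation threshold and the winner is decided by
sampling noise).

### Competitive dynamics

Each unit obeys a shunting membrane equation with on-center,
off-surround recurrence:

    dz_c/dt = A * [ -D*z_c + (U - z_c) * (f(z_c) + f(S_c))
                    - z_c * ( Σ_spiral f(z) + Σ_orient f(z)
                              + W * Σ_spatial f(z) ) ]

where `f(x) = h^2 / (beta^2 + h^2)`, `h = max(x - Gamma, 0)` is a
quadratic Naka–Rushton signal with threshold `Gamma`.  The pools are:
*spiral* — same CoM and orientation side, different pattern angle
(radial units border both sides); *orientation* — same CoM, opposite
CW/CCW side; *spatial* — every unit at a different CoM, weighted `W`.
Constants: `A = 1.0` (1/s), `D = 3.25`, `U = 1.0`, `W = 2.5`,
`Gamma = 0.01`, `beta = 0.07`.  Activity is *not* reset between frames;
the ~0.3 s effective memory is what turns a drifting flow singularity
into spiral-pattern activation (the temporal-accumulation mechanism).

Numerics: for coefficients frozen over a step the equation is linear in
`z`, so each step applies the exact exponential relaxation toward its
instantaneous equilibrium, with adaptive sub-stepping capped at
`rate * h ≤ 0.5`.  A fixed-step scheme (explicit Euler or full
exponential jumps) oscillates with period 2 when the global spatial
inhibition is strong — hundreds of active units times `W` make the
instantaneous relaxation rate far exceed the step — whereas the capped
update relaxes smoothly and keeps `z ∈ [0, U]` unconditionally.  The
nominal step is `dt = 0.005` s (10 per frame).

### Readouts

* `readout_curvature` — spirality of the single most active unit, signed
  by its CW/CCW orientation (ties break toward lower spirality, then
  lower CoM eccentricity).  This is the per-cell readout; it flips sign
  under mirror reflection of the world and path.
* `readout_heading` — azimuth/elevation of the most active unit's CoM.
* `readout_path_spirality` — the population readout used by the
  psychophysics protocols: the activity profile across the one-sided
  spiral continuum (radial plus the orientation congruent with the path
  rotation, maximized over CoMs), summarized by its baseline-subtracted
  activity-weighted centroid.  Two facts motivate it.  First, for
  rotation-bearing ground-plane flow, two template interpretations
  (CCW center above the horizon, CW center below) are near-degenerate,
  so the *orientation* of the single most active unit is bistable even
  though the profile along the continuum is stable; the experiments
  therefore compare positions on the one-sided continuum.  Second, the
  single-unit abscissa is quantized to 12 levels, which makes
  condition-mean comparisons jump; the centroid varies smoothly with the
  rotation content of the flow.  Path error is the difference of this
  estimate between a condition and the gaze-along-heading calibration —
  no further transformation.

## Synthetic displays (the study conditions)

The stimulus module generates the displays of the emulated experiments;
its defaults define the study conditions and are not tuning knobs.

* **Ground plane** — 200 dots, uniform in azimuth (over the FOV, centred
  on the initial gaze direction, since the emulated displays fill the
  screen whatever the simulated gaze) and uniform in sight-line distance
  1.4–25 m; eye height 1.6 m.  Image density is roughly constant across
  depth, as in the emulated displays.
* **Circular paths** — radii 12, 16, 20 m at a walking speed of 2 m/s
  (path rotation 9.5/7.2/5.7 deg/s), 60 frames at 20 Hz (3 s; traversal
  at most 29°, well under the quarter-circle guard).  Five gaze
  conditions: Z-axis (gaze fixed in the world), outside/on/inside-path
  (gaze on a fixed target 12 m ahead: on the future path, or displaced
  ±15° of visual angle away from/toward the circle centre), and gaze
  along heading (the calibration).  These values sit in the regime the
  emulated experiments occupied: the calibration peak lies
  mid-continuum, the Z-axis singularity drift per trial is small, and
  the target approach makes the inside-target fixation rotation ramp
  above the path rate while the outside-target rotation turns against
  it — the geometry behind the over/underestimation pattern.  With
  radii of a few metres every condition saturates at the center-pattern
  end of the continuum and the pattern disappears.
* **Pursuit conditions** — both share one camera motion (yaw at half the
  path rate) and differ only in the extra-retinal signal (±ω/2:
  exterior-ward pursuit in orientation-along-heading, interior-ward in
  orientation-along-Z).  With `g = 1` the gain field restores
  calibration-equivalent flow in the first condition and nulls rotation
  in the second; with `g = 0` the two conditions are bit-identical.
* **Simulated rotation** — 220 dots on fronto-parallel planes at 10 and
  20 m, straight travel at 2 m/s with added yaw of ±1–5 deg/s.
* **Sled** — a 2 m circle inside an 8 m half-width dotted room (300
  dots on three walls), no body or eye rotation; traversal rates
  2–64 deg/s, with fast trials shortened to keep the traversal within a
  quarter circle.
* **Replication** — experiments are seeded; one base seed fans out to
  per-trial scene seeds through a seed-sequence counter scheme, and the
  same scene seed is shared across conditions within a (radius, rep)
  cell so every condition sees the same dots.

## What the generator does and does not emulate

The displays reproduce the geometry, dot counts, frame counts and
clipping of the emulated psychophysics, but not luminance, dot lifetime,
pixelation, or any retinal front end (flow is analytic, evaluated at
exact dot projections).  Passing tests therefore speak to the model's
population-coding claims under ideal first-order flow, not to robustness
against measurement noise in real motion processing.

## Known limitations

* The printed forms of the matching and dynamics equations were not
  available; the implementation follows the documented reconstruction.
  Within it, the three competitive pools are strongly unbalanced — the
  spatial pool sums thousands of units at weight 2.5 while the
  within-CoM pools sum at most 22 at weight 1 — so silencing the
  spiral-space or orientation pool barely perturbs the condition
  pattern, and only the spatial lesion reproduces the reported
  convergence/breakdown.  A pattern-specific variant of the spatial pool
  (competition only among like-tuned units across the map) balances the
  pools but destroys the five-condition pattern, and was rejected.
* Heading biases in the chosen stimulus regime are dominated by the
  pseudo-singularity displacement (≈ ω·Z/v radians, tens of degrees
  here), so the on-path condition reads an inward (positive) heading
  bias and the outside condition a late counter-rotation (negative)
  bias; only the inside-positive bias and the stability of bias
  direction across radii match the emulated findings.  A regime with
  low rotation ratio would shrink heading biases but does not express
  the path-curvature pattern under this reconstruction.
* The simulated-rotation bias curve is monotone and well fit by a
  hyperbolic tangent, but within ±5 deg/s it operates in the near-linear
  part of the curve; saturation is not reached.
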