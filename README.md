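# spiralpath

A simulator of how primate area MSTd can encode heading and the
curvature of the travelled path *simultaneously* from optic flow.

Most MSTd neurons respond best not to the radial expansion associated
with straight-ahead heading but to patterns along a **spiral continuum**
— interpolations between radial (expansion/contraction) and center
(CW/CCW circular) motion.  `spiralpath` implements a three-stage neural
model that gives those spiral-tuned cells a function: first-order optic
flow (model V1) is spatially pooled (model MT) and matched against a
bank of 11 500 spiral-space templates spanning pattern angle × visuotopic
center-of-motion (CoM) position; the templates compete in a shunting
recurrent network (model MSTd) whose activity accumulates across frames.
The **spirality** of the most active subpopulation encodes path
curvature, and the **visuotopic position** of its CoM encodes heading.
An extra-retinal eye-velocity gain field compensates rotation from
smooth-pursuit eye movements; rotation caused by path curvature is not
compensated, which is exactly what lets it drive the curvature code.

The package is aimed at computational neuroscientists and vision
researchers who want a tested, scriptable implementation of the model
and of the classic simulated-psychophysics protocols around it: circular
travel under five gaze conditions, pursuit conditions with matched
retinal flow, the simulated-rotation illusion, the circular-sled
("path cell") paradigm, dot-density robustness, and competitive-pool
lesions.

## The model in brief

For a dot at camera-frame depth `Z` projecting to `(x, y)`, with
translation `T` and yaw rate `Ω`, the flow is first-order:

    u = (x·T_z − f·T_x)/Z + Ω(f + x²/f)
    v = (y·T_z − f·T_y)/Z + Ω·x·y/f

Each MSTd unit is a template `cos φ · r̂ + sin φ · ĉ` about its CoM
(`φ = 0` expansion, `π/2` CCW center, spirals in between) and receives
the distance-weighted cosine match

    S = (1/N) Σᵢ exp(−dᵢ/σ_d) ⟨Fᵢ/‖Fᵢ‖, T(pᵢ)⟩ .

Unit activities obey a shunting recurrent competitive field

    dz/dt = A[ −D·z + (U − z)(f(z) + f(S)) − z·(Σ f(z) over competitors) ]

with a quadratic Naka–Rushton signal `f(x) = max(x−Γ,0)² / (β² + …)` and
three competitive pools (same-CoM spiral space, opposite orientation,
and cross-CoM spatial competition at weight `W`).  Constants:
`A = 1, D = 3.25, U = 1, W = 2.5, Γ = 0.01, β = 0.07`.  Path error in
an experiment is the shift of the spiral-continuum peak relative to the
gaze-along-heading calibration; no other transformation is applied.
See `docs/methods.md` for the full account.

## Worked example

Run the five-condition gaze experiment at one radius (12 m, walking
speed 2 m/s, 200-dot ground plane, 60-frame trials):

```python
from spiralpath.experiments import run_gaze_experiment, check_gaze_pattern

rep = run_gaze_experiment(radii=(12.0,), reps=5, seed=1)
print(rep.summary[["condition", "radius", "n", "mean_path_error",
                   "sem_path_error", "mean_heading_error"]]
      .round(3).to_string(index=False))
print("pattern reproduced:", check_gaze_pattern(rep)["pattern_ok"])
```

prints

```
         condition  radius  n  mean_path_error  sem_path_error  mean_heading_error
gaze_along_heading    12.0  5            0.000           0.000              24.587
       inside_path    12.0  5            0.117           0.032              65.432
           on_path    12.0  5           -0.059           0.033              43.853
      outside_path    12.0  5           -0.121           0.012             -22.187
            z_axis    12.0  5           -0.136           0.021              -1.704
pattern reproduced: True
```

Path error is in spirality units on the spiral continuum: the model
*underestimates* path curvature when the simulated gaze is fixed in the
world (`z_axis`), on a target outside the path, or on a target on the
future path, *overestimates* it when gaze is held inside the path, and
is calibrated (zero) when gaze travels with the heading — the ordering
reported for human observers.  Heading error is in degrees, positive
toward the inside of the path.

The same protocols are available from the shell:

```
spiralpath stimulus preview --condition z_axis --radius 12 --seed 1 --out flow.csv
spiralpath mstd run-trial --condition inside_path --radius 12 --seed 3 --out activity.csv
spiralpath experiments gaze --seed 1 --reps 20 --out gaze.csv
```

Reports are tidy CSV tables (one row per trial) with a JSON summary
side-car; every run is bit-reproducible from its seed.

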