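"""Frozen default study conditions for the simulated psychophysics.

These values define the displays and observer motion the experiments
emulate.  Values that the emulated studies state directly (200 dots,
60-frame trials, 220 dots for the two-plane rotation display, five gaze
conditions) are fixed; the remaining geometry uses one set of defaults
chosen to put the stimuli in the regime of the emulated experiments
(slow path rotation of a few deg/s at walking speed, i.e. gentle
curvatures) — see docs/methods.md for the reasoning.
"""

# Display / camera
FOV_H_DEG = 110.0
FOV_V_DEG = 94.0
FRAME_RATE_HZ = 20.0
FRAMES_PER_TRIAL = 60

# Ground-plane scene
N_DOTS = 200
DEPTH_RANGE_M = (1.4, 25.0)
EYE_HEIGHT_M = 1.6

# Circular-path protocol: fixed translation speed, radius sweep.
TRANSLATION_SPEED_MS = 2.0
RADII_M = (12.0, 16.0, 20.0)
PATH_DIRECTION = 1  # +1 = CCW (leftward) traversal

# Fixation-target geometry (target conditions)
ON_PATH_DISTANCE_M = 12.0
LATERAL_OFFSET_DEG = 15.0

# Simulated-rotation protocol (two fronto-parallel planes)
ROTATION_RATES_DEG = (-5.0, -4.0, -3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
ROTATION_N_DOTS = 220
ROTATION_PLANE_DEPTHS_M = (10.0, 20.0)
ROTATION_SPEED_MS = 2.0

# Sled protocol (circular translation without rotation in a dotted room)
SLED_RATES_DEG = (2.0, 4.0, 8.0, 16.0, 32.0, 64.0)
SLED_RADIUS_M = 2.0
SLED_ROOM_HALF_M = 8.0
SLED_N_DOTS = 300

# Density sweep
DOT_COUNTS = (25, 50, 100, 200, 400)
REFERENCE_DOT_COUNT = 200

# Replication
DEFAULT_REPS = 20
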