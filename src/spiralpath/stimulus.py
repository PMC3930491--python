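"""Synthetic scenes, observer trajectories and first-order optic flow.

This module is the model's "V1": it generates the random-dot displays used
in simulated psychophysics of heading and path perception and evaluates
the instantaneous image velocity of every visible dot analytically
(first-order flow of a moving pin-hole camera, the classical
Longuet-Higgins & Prazdny equations restricted to yaw rotation).

World frame: ``x`` rightward, ``y`` upward, ``z`` forward.  Observer
motion is parallel to the XZ (ground) plane.  Camera yaw ``phi`` is
measured about the vertical axis, positive when the optical axis swings
from ``+z`` toward ``-x`` (a leftward turn, counter-clockwise when viewed
from above); the camera forward vector is ``(-sin phi, 0, cos phi)``.

Circular paths with direction ``lam = +1`` turn leftward (CCW from above)
and with ``lam = -1`` rightward (CW).  The analytic flow is contracted
against a finite-difference re-projection oracle in the test suite; that
oracle, not any sign convention, is the correctness contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .camera import CameraModel

__all__ = [
    "SCENE_KINDS",
    "GAZE_CONDITIONS",
    "SingularGeometryError",
    "Scene",
    "Trajectory",
    "FlowField",
    "TargetSpec",
    "make_scene",
    "make_circular_trajectory",
    "make_straight_rotation_trajectory",
    "target_rotation_rate",
    "target_position",
    "compute_flow",
    "rotational_flow",
    "flow_to_frame",
    "write_flow_csv",
]

SCENE_KINDS = ("ground_plane", "frontoparallel_planes", "room_walls")

#: Gaze conditions for circular-path travel.  The first five replicate the
#: simulated-gaze psychophysics; the two pursuit conditions share one
#: retinal flow (camera yaw at half the path rate) and differ only in the
#: extra-retinal pursuit signal carried by the trajectory.
GAZE_CONDITIONS = (
    "z_axis",
    "outside_path",
    "on_path",
    "inside_path",
    "gaze_along_heading",
    "orient_along_heading_pursuit",
    "orient_along_z_pursuit",
)


class SingularGeometryError(ValueError):
    """Raised when the observer coincides with (or passes through) a
    fixation target, making the fixation rotation rate undefined."""


@dataclass(frozen=True)
class Scene:
    """A static cloud of world dots.

    ``dots`` has shape ``(n_dots, 3)`` in metres.  Ground-plane dots all
    lie at world height 0, with the observer eye ``eye_height`` metres
    above the plane.  Regeneration with the same seed is bit-identical.
    """

    kind: str
    dots: np.ndarray
    depth_range: tuple[float, float]
    eye_height: float
    seed: int

    @property
    def n_dots(self) -> int:
        return int(self.dots.shape[0])

    def mirrored_x(self) -> "Scene":
        """The scene reflected through the x = 0 plane."""
        dots = self.dots.copy()
        dots[:, 0] *= -1.0
        return Scene(self.kind, dots, self.depth_range, self.eye_height, self.seed)


@dataclass(frozen=True)
class TargetSpec:
    """Geometry of the fixation target for target-gaze conditions.

    The on-path target sits on the future path ``on_path_distance``
    metres (straight-line/world distance) from the start position.
    Outside/inside targets are displaced ``lateral_offset_deg`` of visual
    angle away from/toward the centre of the circle, at the same distance
    from the start.  A close target makes the inside-target fixation
    rotation ramp up strongly as the observer approaches, while the
    outside-target rotation starts opposed to the path rotation — the
    geometry behind the over/underestimation pattern.
    """

    on_path_distance: float = 8.0
    lateral_offset_deg: float = 10.0


@dataclass(frozen=True)
class Trajectory:
    """Per-frame observer state along a parametric path.

    ``positions`` are eye positions (m), ``velocities`` the translation
    vector ``T`` (m/s), ``yaw``/``yaw_rate`` the camera orientation (rad,
    rad/s; positive = leftward).  ``pursuit_rate`` is the extra-retinal
    smooth-pursuit (eye-in-head) yaw rate in rad/s, zero except in the
    pursuit conditions.  ``position_fn``/``yaw_fn`` evaluate the
    underlying continuous path at arbitrary times (used by oracles).
    """

    frames: int
    frame_rate: float
    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    yaw: np.ndarray
    yaw_rate: np.ndarray
    gaze_condition: str
    kind: str = "circular"
    radius: float = np.nan
    direction: int = 0
    angular_rate: float = 0.0
    speed: float = 0.0
    pursuit_rate: float = 0.0
    position_fn: Callable[[float], np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )
    yaw_fn: Callable[[float], float] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def duration(self) -> float:
        return self.frames / self.frame_rate

    def heading_yaw(self, frame: int) -> float:
        """World-frame yaw of the instantaneous heading at ``frame``."""
        T = self.velocities[frame]
        return float(np.arctan2(-T[0], T[2]))


@dataclass(frozen=True)
class FlowField:
    """Sparse optic flow for one frame: image positions and velocities of
    every visible dot (``xy``, ``uv`` both ``(n_visible, 2)``)."""

    frame: int
    xy: np.ndarray
    uv: np.ndarray
    dot_indices: np.ndarray

    @property
    def n_visible(self) -> int:
        return int(self.xy.shape[0])


# ---------------------------------------------------------------------------
# Scenes


def make_scene(
    kind: str,
    n_dots: int = 200,
    depth_range: tuple[float, float] = (1.4, 25.0),
    eye_height: float = 1.6,
    seed: int = 0,
    camera: CameraModel | None = None,
    center_azimuth_deg: float = 0.0,
) -> Scene:
    """Sample a random-dot scene.

    ``ground_plane`` dots are uniform in (azimuth, depth) within the
    camera FOV as seen from the start pose, which keeps the image-plane
    dot density roughly constant across depths (matching the displays the
    simulated psychophysics emulate).  ``center_azimuth_deg`` rotates the
    sampled azimuth sector (positive toward -x, matching the camera yaw
    convention) so the dot field can be centred on the initial *gaze*
    direction of a condition rather than on the initial heading — in the
    emulated displays the dots fill the screen whatever the simulated
    gaze.  ``frontoparallel_planes`` places half the dots on each of two
    planes at the near/far depths.  ``room_walls`` scatters dots over
    three walls (left, right, distal) of a square room of half-size
    ``depth_range[1]``.
    """
    if kind not in SCENE_KINDS:
        raise ValueError(f"unknown scene kind {kind!r}; expected one of {SCENE_KINDS}")
    if n_dots < 1:
        raise ValueError("n_dots must be >= 1")
    near, far = depth_range
    if not (0.0 < near <= far):
        raise ValueError("depth_range must satisfy 0 < near <= far")
    cam = camera if camera is not None else CameraModel()
    rng = np.random.default_rng(seed)
    half_h = np.radians(cam.fov_h / 2.0)

    if kind == "ground_plane":
        # yaw-positive is toward -x, so the gaze azimuth enters negated
        az = rng.uniform(-half_h, half_h, size=n_dots) - np.radians(center_azimuth_deg)
        rho = rng.uniform(near, far, size=n_dots)  # distance along the sight line
        dots = np.column_stack([rho * np.sin(az), np.zeros(n_dots), rho * np.cos(az)])
    elif kind == "frontoparallel_planes":
        half_v = np.radians(cam.fov_v / 2.0)
        n_near = n_dots // 2
        counts = (n_near, n_dots - n_near)
        parts = []
        for depth, n in zip((near, far), counts):
            az = rng.uniform(-half_h, half_h, size=n)
            el = rng.uniform(-half_v, half_v, size=n)
            parts.append(
                np.column_stack(
                    [
                        depth * np.tan(az),
                        eye_height + depth * np.tan(el),
                        np.full(n, depth),
                    ]
                )
            )
        dots = np.concatenate(parts)
    else:  # room_walls
        half = far
        wall_top = 2.0 * eye_height
        n_per = n_dots // 3
        counts = (n_per, n_per, n_dots - 2 * n_per)
        ys = [rng.uniform(0.0, wall_top, size=n) for n in counts]
        # distal wall (z = half), left wall (x = -half), right wall (x = +half)
        spans = [rng.uniform(-half, half, size=n) for n in counts]
        distal = np.column_stack([spans[0], ys[0], np.full(counts[0], half)])
        left = np.column_stack([np.full(counts[1], -half), ys[1], spans[1]])
        right = np.column_stack([np.full(counts[2], half), ys[2], spans[2]])
        dots = np.concatenate([distal, left, right])

    return Scene(kind, dots, (float(near), float(far)), float(eye_height), int(seed))


# ---------------------------------------------------------------------------
# Trajectories


def _circle_position(t: float, r: float, lam: int, omega: float, h: float) -> np.ndarray:
    """Eye position at time ``t`` on a circle starting at the origin with
    initial heading +z; ``lam = +1`` turns leftward (CCW from above)."""
    return np.array(
        [-lam * r * (1.0 - np.cos(omega * t)), h, r * np.sin(omega * t)]
    )


def _circle_velocity(t: float, r: float, lam: int, omega: float) -> np.ndarray:
    s = r * omega
    return np.array([-lam * s * np.sin(omega * t), 0.0, s * np.cos(omega * t)])


def target_position(
    r: float,
    lam: int,
    eye_height: float,
    condition: str,
    target_spec: TargetSpec | None = None,
) -> np.ndarray:
    """World position of the fixation target for a target-gaze condition.

    Targets lie at eye height so that fixation only requires yaw.  The
    outside target is displaced away from the circle centre, the inside
    target toward it, both by ``lateral_offset_deg`` of initial visual
    angle at the same distance from the start position.
    """
    spec = target_spec if target_spec is not None else TargetSpec()
    if spec.on_path_distance > 2.0 * r:
        raise ValueError(
            f"on-path target distance {spec.on_path_distance} m exceeds the "
            f"circle diameter {2 * r} m"
        )
    # circle point whose chord from the start equals the target distance
    theta = 2.0 * np.arcsin(spec.on_path_distance / (2.0 * r))
    q_on = np.array(
        [-lam * r * (1.0 - np.cos(theta)), eye_height, r * np.sin(theta)]
    )
    if condition == "on_path":
        return q_on
    start = np.array([0.0, eye_height, 0.0])
    d = q_on - start
    dist = float(np.hypot(d[0], d[2]))
    az_on = float(np.arctan2(d[0], d[2]))  # positive toward +x
    off = np.radians(spec.lateral_offset_deg)
    if condition == "outside_path":
        az = az_on + lam * off
    elif condition == "inside_path":
        az = az_on - lam * off
    else:
        raise ValueError(f"no fixation target for condition {condition!r}")
    return start + dist * np.array([np.sin(az), 0.0, np.cos(az)])


def target_rotation_rate(
    position: np.ndarray, velocity: np.ndarray, target: np.ndarray
) -> float:
    """Yaw rate (rad/s) that keeps ``target`` fixated while translating.

    Equals the time derivative of the observer-to-target azimuth; under
    this rotation the target's image position is stationary.
    """
    w = -(target[0] - position[0])
    u = target[2] - position[2]
    denom = u * u + w * w
    if denom < 1e-12:
        raise SingularGeometryError("observer coincides with fixation target")
    w_dot = velocity[0]
    u_dot = -velocity[2]
    return float((w_dot * u - u_dot * w) / denom)


def _fixation_yaw(position: np.ndarray, target: np.ndarray) -> float:
    w = -(target[0] - position[0])
    u = target[2] - position[2]
    if u * u + w * w < 1e-12:
        raise SingularGeometryError("observer coincides with fixation target")
    return float(np.arctan2(w, u))


def make_circular_trajectory(
    r: float,
    lam: int,
    omega: float,
    gaze_condition: str = "gaze_along_heading",
    target_spec: TargetSpec | None = None,
    frames: int = 60,
    frame_rate: float = 20.0,
    eye_height: float = 1.6,
) -> Trajectory:
    """Observer travel along a circular path under one gaze condition.

    The eye starts at the world origin (height ``eye_height``) heading
    along +z and traverses the circle of radius ``r`` at angular rate
    ``omega`` (rad/s) in direction ``lam`` (+1 CCW/leftward, -1
    CW/rightward).  Total traversal must not exceed a quarter circle.

    Gaze per condition: ``z_axis`` keeps yaw fixed at 0;
    ``gaze_along_heading`` yaws with the heading (rate ``lam * omega``);
    the target conditions fixate a fixed world target; the two pursuit
    conditions yaw at half the path rate (their shared retinal flow) and
    carry opposite extra-retinal pursuit signals of magnitude
    ``omega / 2``.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    if lam not in (-1, 1):
        raise ValueError("lam must be +1 (CCW) or -1 (CW)")
    if omega < 0:
        raise ValueError("omega must be non-negative")
    if gaze_condition not in GAZE_CONDITIONS:
        raise ValueError(
            f"unknown gaze condition {gaze_condition!r}; expected one of {GAZE_CONDITIONS}"
        )
    duration = frames / frame_rate
    if omega * duration > np.pi / 2.0 + 1e-9:
        raise ValueError(
            "traversal exceeds a quarter circle "
            f"(omega * duration = {omega * duration:.3f} rad > pi/2)"
        )
    if omega < 1e-12:
        traj = make_straight_rotation_trajectory(
            speed=r * omega, rotation_rate=0.0, frames=frames,
            frame_rate=frame_rate, eye_height=eye_height,
        )
        return Trajectory(
            frames=frames, frame_rate=frame_rate, times=traj.times,
            positions=traj.positions, velocities=traj.velocities,
            yaw=traj.yaw, yaw_rate=traj.yaw_rate,
            gaze_condition=gaze_condition, kind="circular", radius=r,
            direction=lam, angular_rate=0.0, speed=0.0,
            position_fn=traj.position_fn, yaw_fn=traj.yaw_fn,
        )

    times = np.arange(frames) / frame_rate
    positions = np.stack([_circle_position(t, r, lam, omega, eye_height) for t in times])
    velocities = np.stack([_circle_velocity(t, r, lam, omega) for t in times])

    pursuit_rate = 0.0
    if gaze_condition == "z_axis":
        yaw = np.zeros(frames)
        yaw_rate = np.zeros(frames)
        yaw_fn = lambda t: 0.0  # noqa: E731
    elif gaze_condition == "gaze_along_heading":
        yaw = lam * omega * times
        yaw_rate = np.full(frames, lam * omega)
        yaw_fn = lambda t: lam * omega * t  # noqa: E731
    elif gaze_condition in ("orient_along_heading_pursuit", "orient_along_z_pursuit"):
        half = 0.5 * lam * omega
        yaw = half * times
        yaw_rate = np.full(frames, half)
        yaw_fn = lambda t: half * t  # noqa: E731
        # Eye-in-head pursuit: toward the path exterior (against the turn)
        # in the orientation-along-heading condition, toward the interior
        # in the orientation-along-Z condition.
        sign = -1.0 if gaze_condition == "orient_along_heading_pursuit" else 1.0
        pursuit_rate = sign * 0.5 * lam * omega
    else:  # fixation on a world target
        target = target_position(r, lam, eye_height, gaze_condition, target_spec)
        yaw = np.array([_fixation_yaw(p, target) for p in positions])
        yaw_rate = np.array(
            [target_rotation_rate(p, v, target) for p, v in zip(positions, velocities)]
        )
        yaw_fn = lambda t: _fixation_yaw(  # noqa: E731
            _circle_position(t, r, lam, omega, eye_height), target
        )

    return Trajectory(
        frames=frames,
        frame_rate=frame_rate,
        times=times,
        positions=positions,
        velocities=velocities,
        yaw=yaw,
        yaw_rate=yaw_rate,
        gaze_condition=gaze_condition,
        kind="circular",
        radius=float(r),
        direction=int(lam),
        angular_rate=float(omega),
        speed=float(r * omega),
        pursuit_rate=float(pursuit_rate),
        position_fn=lambda t: _circle_position(t, r, lam, omega, eye_height),
        yaw_fn=yaw_fn,
    )


def make_straight_rotation_trajectory(
    speed: float,
    rotation_rate: float,
    frames: int = 60,
    frame_rate: float = 20.0,
    eye_height: float = 1.6,
) -> Trajectory:
    """Straight travel along +z with a constant added yaw rotation.

    ``rotation_rate`` is in rad/s, positive for rightward rotation (the
    camera swings toward +x, so image content and the pseudo-FoE shift
    rightward).  This is the simulated-rotation display: the flow is
    rendered for a rotating camera while the observer translates straight.
    """
    times = np.arange(frames) / frame_rate
    positions = np.column_stack(
        [np.zeros(frames), np.full(frames, eye_height), speed * times]
    )
    velocities = np.tile(np.array([0.0, 0.0, speed]), (frames, 1))
    phi_rate = -float(rotation_rate)  # yaw positive = leftward
    yaw = phi_rate * times
    yaw_rate = np.full(frames, phi_rate)
    return Trajectory(
        frames=frames,
        frame_rate=frame_rate,
        times=times,
        positions=positions,
        velocities=velocities,
        yaw=yaw,
        yaw_rate=yaw_rate,
        gaze_condition="simulated_rotation",
        kind="straight",
        radius=np.inf,
        direction=0,
        angular_rate=float(rotation_rate),
        speed=float(speed),
        position_fn=lambda t: np.array([0.0, eye_height, speed * t]),
        yaw_fn=lambda t: phi_rate * t,
    )


# ---------------------------------------------------------------------------
# First-order flow


def _camera_basis(phi: float) -> np.ndarray:
    """Rows: camera right, up, forward expressed in world coordinates."""
    s, c = np.sin(phi), np.cos(phi)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def compute_flow(
    scene: Scene,
    trajectory: Trajectory,
    camera: CameraModel,
    frame: int,
) -> FlowField:
    """Analytic first-order optic flow of every visible dot at ``frame``.

    For a static dot at camera-frame position ``(X, Y, Z)`` and a camera
    translating at ``T`` (camera frame) while yawing at ``phi_dot``::

        u = (x * Tz - f * Tx) / Z + phi_dot * (f + x**2 / f)
        v = (y * Tz - f * Ty) / Z + phi_dot * x * y / f

    Dots behind the camera or outside the FOV are excluded (clipped), not
    an error.
    """
    if not (0 <= frame < trajectory.frames):
        raise ValueError(f"frame {frame} outside trajectory of {trajectory.frames} frames")
    phi = float(trajectory.yaw[frame])
    phi_dot = float(trajectory.yaw_rate[frame])
    R = _camera_basis(phi)
    rel = scene.dots - trajectory.positions[frame]
    pts_cam = rel @ R.T
    T_cam = R @ trajectory.velocities[frame]
    xy, visible = camera.project(pts_cam)

    f = camera.focal_length
    x = xy[visible, 0]
    y = xy[visible, 1]
    Z = pts_cam[visible, 2]
    u = (x * T_cam[2] - f * T_cam[0]) / Z + phi_dot * (f + x * x / f)
    v = (y * T_cam[2] - f * T_cam[1]) / Z + phi_dot * x * y / f
    return FlowField(
        frame=frame,
        xy=xy[visible],
        uv=np.column_stack([u, v]),
        dot_indices=np.flatnonzero(visible),
    )


def rotational_flow(xy: np.ndarray, yaw_rate: float, camera: CameraModel) -> np.ndarray:
    """Flow of a pure yaw rotation (translation 0) at image points ``xy``."""
    f = camera.focal_length
    x = xy[:, 0]
    y = xy[:, 1]
    return np.column_stack([yaw_rate * (f + x * x / f), yaw_rate * x * y / f])


# ---------------------------------------------------------------------------
# Serialization


def flow_to_frame(flows: Sequence[FlowField]) -> pd.DataFrame:
    """Tidy table of flow samples: one row per dot per frame."""
    rows = []
    for fl in flows:
        rows.append(
            pd.DataFrame(
                {
                    "frame": fl.frame,
                    "x_img": fl.xy[:, 0],
                    "y_img": fl.xy[:, 1],
                    "u": fl.uv[:, 0],
                    "v": fl.uv[:, 1],
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["frame", "x_img", "y_img", "u", "v"])
    return pd.concat(rows, ignore_index=True)


def write_flow_csv(flows: Sequence[FlowField], path) -> None:
    flow_to_frame(flows).to_csv(path, index=False)
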