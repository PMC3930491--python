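"""Model MSTd: spiral-template matching and recurrent competition.

Each model MSTd unit is a template on the spiral continuum — an
interpolation between a radial field (expansion/contraction) and a center
field (CW/CCW circular motion) about a preferred center of motion (CoM)
in the visual field.  Afferent flow from model MT is compared against
every template by a distance-weighted cosine match, optionally after an
extra-retinal eye-velocity gain field that compensates smooth-pursuit
rotation.  The match scores drive a shunting recurrent competitive field
(a soft winner-take-all network with on-center, off-surround recurrence)
whose activity accumulates across frames; the spirality of the most
active unit encodes path curvature and its CoM encodes heading.

Pattern-angle convention: ``phi = 0`` is radial expansion, ``pi/2`` a CCW
center, ``pi`` radial contraction, ``3*pi/2`` a CW center; intermediate
angles are spirals.  Spirality ``s`` in [0, 1] is the normalized angular
distance to the nearest radial pole.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .camera import CameraModel
from .mt import PoolingParams, pool_flow
from .stimulus import FlowField, Scene, Trajectory, compute_flow, rotational_flow

__all__ = [
    "LESION_POOLS",
    "NoEstimateError",
    "ModelParams",
    "SpiralTemplate",
    "TemplateBankConfig",
    "TemplateBank",
    "make_template",
    "build_template_bank",
    "apply_gain_field",
    "match_score",
    "match_scores",
    "transfer",
    "MSTdNetwork",
    "step_dynamics",
    "ActivityState",
    "run_trial",
    "readout_curvature",
    "readout_heading",
    "readout_path_spirality",
    "lesion",
    "activity_to_frame",
]

logger = logging.getLogger(__name__)

LESION_POOLS = ("spiral_space", "orientation", "spatial")


class NoEstimateError(RuntimeError):
    """Raised when a readout is requested from all-zero activity."""


# ---------------------------------------------------------------------------
# Parameters


@dataclass(frozen=True)
class ModelParams:
    """Constants of the MSTd network dynamics.

    ``A`` is the inverse membrane time constant (1/s), ``D`` the passive
    decay rate, ``U`` the activation upper bound, ``W`` the strength of
    inhibition from spatial competition, ``gamma`` the presynaptic
    threshold on inputs, and ``beta`` the sigmoid shape parameter.
    ``sigma_d`` is the exponential distance-weighting decay of the
    template match in degrees of visual angle (sized so typical match
    scores land in the sigmoid's dynamic range above ``gamma``), ``gain`` the eye-velocity
    gain-field strength (1 = full-speed compensation), and ``dt`` the
    integration step in seconds.  ``lesions`` lists competitive pools
    whose inhibition is zeroed.
    """

    A: float = 1.0
    D: float = 3.25
    U: float = 1.0
    W: float = 2.5
    gamma: float = 0.01
    beta: float = 0.07
    sigma_d: float = 12.0
    gain: float = 1.0
    dt: float = 0.005
    lesions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.A <= 0 or self.U <= 0:
            raise ValueError("A and U must be positive")
        if min(self.D, self.W, self.gamma, self.beta, self.sigma_d) < 0:
            raise ValueError("D, W, gamma, beta, sigma_d must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in self.lesions:
            if name not in LESION_POOLS:
                raise ValueError(f"unknown lesion pool {name!r}")


def lesion(params: ModelParams, pool_name: str) -> ModelParams:
    """Return a copy of ``params`` with one competitive pool silenced."""
    if pool_name not in LESION_POOLS:
        raise ValueError(
            f"unknown pool {pool_name!r}; expected one of {LESION_POOLS}"
        )
    if pool_name in params.lesions:
        return params
    return replace(params, lesions=params.lesions + (pool_name,))


# ---------------------------------------------------------------------------
# Templates


def _spirality(phi: float) -> float:
    phi = float(phi) % (2.0 * np.pi)
    d = min(phi, abs(phi - np.pi), 2.0 * np.pi - phi)
    return d / (np.pi / 2.0)


def _orientation_sign(phi: float) -> int:
    s = np.sin(phi)
    if abs(s) < 1e-12:
        return 0
    return 1 if s > 0 else -1


@dataclass(frozen=True)
class SpiralTemplate:
    """One spiral-space motion template.

    The direction field at image point ``p`` is
    ``cos(phi) * rhat + sin(phi) * chat`` where ``rhat`` is the unit
    radial vector away from the CoM and ``chat`` its +90-degree (CCW)
    rotation; the field is unit length everywhere except exactly at the
    CoM, where it is undefined (returned as the zero vector and excluded
    from matching).
    """

    pattern_angle: float
    com: tuple[float, float]

    @property
    def spirality(self) -> float:
        return _spirality(self.pattern_angle)

    @property
    def orientation(self) -> str | None:
        o = _orientation_sign(self.pattern_angle)
        return {1: "ccw", -1: "cw", 0: None}[o]

    @property
    def sense(self) -> str:
        return "expand" if np.cos(self.pattern_angle) >= 0 else "contract"

    def field(self, points: np.ndarray) -> np.ndarray:
        """Unit direction vectors of the template at image ``points`` (n, 2)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rel = pts - np.asarray(self.com)
        r = np.hypot(rel[:, 0], rel[:, 1])
        out = np.zeros_like(rel)
        ok = r > 1e-12
        rx = rel[ok, 0] / r[ok]
        ry = rel[ok, 1] / r[ok]
        c, s = np.cos(self.pattern_angle), np.sin(self.pattern_angle)
        out[ok, 0] = c * rx - s * ry
        out[ok, 1] = c * ry + s * rx
        return out


def make_template(phi: float, com: tuple[float, float]) -> SpiralTemplate:
    """Spiral template with pattern angle ``phi`` (radians) about ``com``."""
    return SpiralTemplate(pattern_angle=float(phi) % (2.0 * np.pi), com=tuple(com))


@dataclass(frozen=True)
class TemplateBankConfig:
    """Enumeration grid of the template bank.

    ``n_pattern`` uniform pattern angles over [0, 2*pi) crossed with an
    ``n_x`` by ``n_y`` CoM grid spanning ``span_factor`` times the field
    of view in each dimension (CoM selectivities extend beyond the
    display).  The default 23 x 25 x 20 grid enumerates 11500 units.
    """

    n_pattern: int = 23
    n_x: int = 25
    n_y: int = 20
    span_factor: float = 1.5

    def __post_init__(self) -> None:
        if min(self.n_pattern, self.n_x, self.n_y) < 1:
            raise ValueError("grid sizes must be >= 1")


@dataclass(frozen=True)
class TemplateBank:
    """Enumerated spiral-space units: full cross product of a pattern-angle
    grid and a spatial CoM grid.

    Units are indexed CoM-major: ``unit = com_index * n_pattern +
    pattern_index``.  ``orientation_sign`` is +1 for CCW patterns, -1 for
    CW, 0 for radial.
    """

    config: TemplateBankConfig
    pattern_angles: np.ndarray
    coms: np.ndarray
    spirality: np.ndarray = field(init=False, repr=False)
    orientation_sign: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "spirality",
            np.array([_spirality(p) for p in self.pattern_angles]),
        )
        object.__setattr__(
            self,
            "orientation_sign",
            np.array([_orientation_sign(p) for p in self.pattern_angles]),
        )

    @property
    def n_pattern(self) -> int:
        return len(self.pattern_angles)

    @property
    def n_com(self) -> int:
        return len(self.coms)

    @property
    def n_units(self) -> int:
        return self.n_pattern * self.n_com

    def template(self, unit: int) -> SpiralTemplate:
        com_idx, pat_idx = divmod(int(unit), self.n_pattern)
        return make_template(self.pattern_angles[pat_idx], tuple(self.coms[com_idx]))

    def unit_index(self, com_idx: int, pat_idx: int) -> int:
        return int(com_idx) * self.n_pattern + int(pat_idx)


def build_template_bank(
    config: TemplateBankConfig | None = None,
    camera: CameraModel | None = None,
) -> TemplateBank:
    """Enumerate the template bank over the configured grid."""
    cfg = config if config is not None else TemplateBankConfig()
    cam = camera if camera is not None else CameraModel()
    phis = 2.0 * np.pi * np.arange(cfg.n_pattern) / cfg.n_pattern
    half_x = cfg.span_factor * cam.half_width
    half_y = cfg.span_factor * cam.half_height
    xs = np.linspace(-half_x, half_x, cfg.n_x) if cfg.n_x > 1 else np.array([0.0])
    ys = np.linspace(-half_y, half_y, cfg.n_y) if cfg.n_y > 1 else np.array([0.0])
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    coms = np.column_stack([gx.ravel(), gy.ravel()])
    return TemplateBank(config=cfg, pattern_angles=phis, coms=coms)


# ---------------------------------------------------------------------------
# Gain field and template matching


def apply_gain_field(
    flow: FlowField,
    eye_velocity: float,
    g: float = 1.0,
    camera: CameraModel | None = None,
) -> FlowField:
    """Extra-retinal compensation of smooth-pursuit rotation.

    Adds, at every sample site, ``g`` times the pure-rotation first-order
    flow of the *negated* eye yaw velocity (rad/s, leftward positive) —
    rotation proportional to pursuit speed, directed opposite the eye
    movement.  ``eye_velocity = 0`` or ``g = 0`` is the identity.
    """
    if eye_velocity == 0.0 or g == 0.0:
        return flow
    cam = camera if camera is not None else CameraModel()
    comp = rotational_flow(flow.xy, -eye_velocity, cam)
    return FlowField(
        frame=flow.frame,
        xy=flow.xy,
        uv=flow.uv + g * comp,
        dot_indices=flow.dot_indices,
    )


def match_score(
    flow: FlowField,
    template: SpiralTemplate,
    sigma_d: float = 12.0,
    camera: CameraModel | None = None,
) -> float:
    """Distance-weighted cosine match between a flow field and one template.

    ``S = (1/N) * sum_i exp(-d_i / sigma_d) * <F_i / |F_i|, T(p_i)>``
    where ``d_i`` is the distance from dot ``i`` to the template CoM and
    ``N`` the number of visible dots; zero-length flow vectors contribute
    0.  ``sigma_d`` is in degrees of visual angle.  ``|S| <= 1`` always.
    """
    if flow.n_visible == 0:
        raise ValueError("match score undefined for an empty flow field")
    cam = camera if camera is not None else CameraModel()
    sig = cam.deg_to_image(sigma_d)
    norms = np.hypot(flow.uv[:, 0], flow.uv[:, 1])
    unit = np.zeros_like(flow.uv)
    ok = norms > 1e-15
    unit[ok] = flow.uv[ok] / norms[ok, None]
    tvec = template.field(flow.xy)
    d = np.hypot(flow.xy[:, 0] - template.com[0], flow.xy[:, 1] - template.com[1])
    w = np.exp(-d / sig)
    return float(np.sum(w * np.einsum("ij,ij->i", unit, tvec)) / flow.n_visible)


def match_scores(
    flow: FlowField,
    bank: TemplateBank,
    sigma_d: float = 12.0,
    camera: CameraModel | None = None,
) -> np.ndarray:
    """Match of the flow against every unit, shape ``(n_com, n_pattern)``.

    Exploits the template interpolation: for each CoM only the weighted
    radial and center cosine sums are accumulated, and every pattern
    angle is a cosine/sine combination of the two.
    """
    if flow.n_visible == 0:
        raise ValueError("match score undefined for an empty flow field")
    cam = camera if camera is not None else CameraModel()
    sig = cam.deg_to_image(sigma_d)
    norms = np.hypot(flow.uv[:, 0], flow.uv[:, 1])
    unit = np.zeros_like(flow.uv)
    ok = norms > 1e-15
    unit[ok] = flow.uv[ok] / norms[ok, None]

    dx = flow.xy[None, :, 0] - bank.coms[:, 0, None]  # (n_com, n)
    dy = flow.xy[None, :, 1] - bank.coms[:, 1, None]
    r = np.hypot(dx, dy)
    safe = np.where(r > 1e-12, r, 1.0)
    rx, ry = dx / safe, dy / safe
    rx[r <= 1e-12] = 0.0
    ry[r <= 1e-12] = 0.0
    w = np.exp(-r / sig)
    a = (w * (rx * unit[None, :, 0] + ry * unit[None, :, 1])).sum(axis=1)
    b = (w * (-ry * unit[None, :, 0] + rx * unit[None, :, 1])).sum(axis=1)
    c = np.cos(bank.pattern_angles)
    s = np.sin(bank.pattern_angles)
    return (a[:, None] * c[None, :] + b[:, None] * s[None, :]) / flow.n_visible


# ---------------------------------------------------------------------------
# Dynamics


def transfer(x: np.ndarray | float, gamma: float = 0.01, beta: float = 0.07):
    """Quadratic Naka-Rushton signal function with threshold ``gamma``.

    ``f(x) = h**2 / (beta**2 + h**2)`` with ``h = max(x - gamma, 0)``:
    zero at and below threshold, half-saturated at ``x = gamma + beta``,
    saturating to 1.
    """
    h = np.maximum(np.asarray(x, dtype=float) - gamma, 0.0)
    out = h * h / (beta * beta + h * h)
    return out if out.ndim else float(out)


class MSTdNetwork:
    """Shunting recurrent competitive field over a template bank.

    Per unit ``c`` the membrane equation is::

        dz_c/dt = A * [ -D * z_c
                        + (U - z_c) * (f(z_c) + f(S_c))
                        - z_c * ( sum_spiral f(z) + sum_orient f(z)
                                  + W * sum_spatial f(z) ) ]

    with pools: *spiral* (same CoM and orientation side, different
    pattern angle; radial units border both sides), *orientation* (same
    CoM, opposite CW/CCW side) and *spatial* (every unit at a different
    CoM, weight ``W``).  Lesion switches zero the corresponding pool.
    Integration uses a per-step linearized exponential update (the
    equation is linear in ``z`` for frozen coefficients), which keeps
    ``z`` in ``[0, U]`` unconditionally.
    """

    def __init__(self, bank: TemplateBank, params: ModelParams):
        self.bank = bank
        self.params = params
        o = bank.orientation_sign
        same = (o[:, None] * o[None, :] >= 0) & ~np.eye(bank.n_pattern, dtype=bool)
        opp = o[:, None] * o[None, :] < 0
        self._same = same.astype(float)
        self._opp = opp.astype(float)

    def initial_state(self) -> np.ndarray:
        return np.zeros((self.bank.n_com, self.bank.n_pattern))

    def step(self, z: np.ndarray, S: np.ndarray, dt: float) -> np.ndarray:
        """Advance the state ``z`` by ``dt`` under match input ``S``
        (both ``(n_com, n_pattern)``).

        For coefficients frozen over a step the membrane equation is
        linear in ``z``, so each sub-step applies the exact exponential
        relaxation toward its instantaneous equilibrium.  Because the
        coefficients themselves depend on ``z``, a step is accepted only
        while ``rate * h <= 0.5``; stiffer moments (strong transient
        inhibition) are subdivided adaptively, which prevents the
        overshoot oscillations of a fixed-step scheme.
        """
        p = self.params
        if not (np.all(np.isfinite(z)) and np.all(np.isfinite(S))):
            raise FloatingPointError("non-finite network state or input")
        f_in = transfer(S, p.gamma, p.beta)
        remaining = float(dt)
        while remaining > 0.0:
            F = transfer(z, p.gamma, p.beta)
            inhib = np.zeros_like(z)
            if "spiral_space" not in p.lesions:
                inhib += F @ self._same.T
            if "orientation" not in p.lesions:
                inhib += F @ self._opp.T
            if "spatial" not in p.lesions:
                per_com = F.sum(axis=1, keepdims=True)
                inhib += p.W * (F.sum() - per_com)
            excit = F + f_in
            rate = p.A * (p.D + excit + inhib)
            h = min(remaining, 0.5 / float(rate.max()))
            z_inf = p.U * p.A * excit / rate
            z = z_inf + (z - z_inf) * np.exp(-rate * h)
            np.clip(z, 0.0, p.U, out=z)
            remaining -= h
        return z

    def integrate_frame(self, z: np.ndarray, S: np.ndarray, frame_interval: float) -> np.ndarray:
        n_sub = max(1, int(round(frame_interval / self.params.dt)))
        dt = frame_interval / n_sub
        for _ in range(n_sub):
            z = self.step(z, S, dt)
        return z


def step_dynamics(
    z: np.ndarray,
    S: np.ndarray,
    bank: TemplateBank,
    params: ModelParams,
    dt: float,
) -> np.ndarray:
    """Functional wrapper around :meth:`MSTdNetwork.step`."""
    return MSTdNetwork(bank, params).step(z, S, dt)


# ---------------------------------------------------------------------------
# Trials and readouts


@dataclass(frozen=True)
class ActivityState:
    """Per-unit activation over a trial, ``(frames, n_com, n_pattern)``,
    with the per-frame argmax unit trajectory (flat unit indices)."""

    bank: TemplateBank
    history: np.ndarray
    argmax_trajectory: np.ndarray

    @property
    def frames(self) -> int:
        return int(self.history.shape[0])

    @property
    def final(self) -> np.ndarray:
        return self.history[-1]


def _peak_unit(state: ActivityState) -> tuple[int, int]:
    """(com_idx, pattern_idx) of the globally maximal unit at trial end.

    Ties are broken deterministically toward lower spirality, then lower
    CoM eccentricity, then lower index.
    """
    z = state.final
    zmax = z.max()
    if zmax <= 0.0:
        raise NoEstimateError("all-zero MSTd activity; no readout available")
    cand = np.argwhere(z == zmax)
    bank = state.bank
    keys = [
        (
            bank.spirality[pi],
            float(np.hypot(*bank.coms[ci])),
            ci * bank.n_pattern + pi,
        )
        for ci, pi in cand
    ]
    best = int(np.lexsort(tuple(np.array([k[i] for k in keys]) for i in (2, 1, 0)))[0])
    ci, pi = cand[best]
    return int(ci), int(pi)


def readout_curvature(state: ActivityState) -> float:
    """Signed spirality of the peak unit: positive for CCW spirals,
    negative for CW, zero for radial."""
    ci, pi = _peak_unit(state)
    bank = state.bank
    return float(bank.spirality[pi] * (bank.orientation_sign[pi] or 0))


def readout_path_spirality(state: ActivityState, direction: int) -> float:
    """Peak abscissa on the one-sided spiral continuum for a given path
    direction.

    The continuum runs from the radial pole (0) toward the center
    patterns whose orientation is congruent with the path rotation
    (``direction`` +1 = CCW/leftward travel, whose congruent spiral side
    is CW in image terms; -1 the reverse).  The spiral-space profile is
    the per-spirality maximum over CoMs of the final activity among
    radial and congruent-orientation units; the estimate is the
    activity-weighted centroid of that profile (baseline-subtracted), a
    population readout of the peak's position that varies smoothly with
    the rotation content of the flow.  Incongruent-side units are the
    mirror population and are read out for the mirrored traversal.
    """
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 (CCW) or -1 (CW)")
    z = state.final
    bank = state.bank
    if z.max() <= 0.0:
        raise NoEstimateError("all-zero MSTd activity; no readout available")
    congruent = -direction
    mask = (bank.orientation_sign == congruent) | (bank.orientation_sign == 0)
    profile = z[:, mask].max(axis=0)
    s_vals = bank.spirality[mask]
    w = np.maximum(profile - profile.min(), 0.0)
    total = w.sum()
    if total <= 0.0:
        return 0.0
    return float((s_vals * w).sum() / total)


def readout_heading(
    state: ActivityState, camera: CameraModel | None = None
) -> tuple[float, float]:
    """(azimuth, elevation) in degrees of the peak unit's CoM; azimuth is
    positive rightward."""
    cam = camera if camera is not None else CameraModel()
    ci, _ = _peak_unit(state)
    cx, cy = state.bank.coms[ci]
    return float(cam.image_to_deg(cx)), float(cam.image_to_deg(cy))


def run_trial(
    scene: Scene,
    trajectory: Trajectory,
    camera: CameraModel | None = None,
    params: ModelParams | None = None,
    bank: TemplateBank | None = None,
    pooling: PoolingParams | None = None,
    record_history: bool = True,
) -> ActivityState:
    """Run the full V1 -> MT -> MSTd pipeline over one trial.

    Per frame: analytic flow, Gaussian MT pooling, pursuit gain field (if
    the trajectory carries a pursuit signal), spiral-template matching,
    then integration of the competitive dynamics across the frame
    interval.  Activity is *not* reset between frames — the temporal
    accumulation is the mechanism.  A frame with every dot clipped
    contributes zero input (logged, not an error).
    """
    cam = camera if camera is not None else CameraModel()
    params = params if params is not None else ModelParams()
    bank = bank if bank is not None else build_template_bank(camera=cam)
    net = MSTdNetwork(bank, params)
    z = net.initial_state()
    interval = cam.frame_interval
    history = (
        np.empty((trajectory.frames, bank.n_com, bank.n_pattern), dtype=np.float32)
        if record_history
        else None
    )
    argmax = np.empty(trajectory.frames, dtype=np.int64)
    for frame in range(trajectory.frames):
        flow = compute_flow(scene, trajectory, cam, frame)
        if flow.n_visible == 0:
            logger.warning("frame %d: all dots clipped; zero input", frame)
            S = np.zeros((bank.n_com, bank.n_pattern))
        else:
            pooled = pool_flow(flow, pooling, cam)
            if trajectory.pursuit_rate != 0.0:
                pooled = apply_gain_field(
                    pooled, trajectory.pursuit_rate, params.gain, cam
                )
            S = match_scores(pooled, bank, params.sigma_d, cam)
        z = net.integrate_frame(z, S, interval)
        if history is not None:
            history[frame] = z
        argmax[frame] = int(np.argmax(z))
    if history is None:
        history = z[None, :, :].astype(np.float32)
    return ActivityState(bank=bank, history=history, argmax_trajectory=argmax)


def activity_to_frame(state: ActivityState) -> "pd.DataFrame":
    """Tidy dump of the final-frame activity (unit id, pattern angle,
    spirality, orientation, CoM, activation)."""
    import pandas as pd

    bank = state.bank
    z = state.final
    com_idx = np.repeat(np.arange(bank.n_com), bank.n_pattern)
    pat_idx = np.tile(np.arange(bank.n_pattern), bank.n_com)
    orient = np.array(["radial", "ccw", "cw"])[bank.orientation_sign[pat_idx]]
    return pd.DataFrame(
        {
            "unit": np.arange(bank.n_units),
            "pattern_angle": bank.pattern_angles[pat_idx],
            "spirality": bank.spirality[pat_idx],
            "orientation": orient,
            "com_x": bank.coms[com_idx, 0],
            "com_y": bank.coms[com_idx, 1],
            "z": z.ravel(),
        }
    )
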