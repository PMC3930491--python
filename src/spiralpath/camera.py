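"""Pin-hole camera model used to project world dots onto the image plane.

Conventions
-----------
The camera frame is ``x`` rightward, ``y`` upward, ``z`` forward (the
optical axis).  A world point ``(X, Y, Z)`` expressed in the camera frame
projects to image coordinates ``x = f * X / Z``, ``y = f * Y / Z`` with
focal length ``f`` in image-plane units (default 1, so image coordinates
are tangents of visual angle).  Only points with ``Z > 0`` that fall
inside the field of view are visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CameraModel"]


@dataclass(frozen=True)
class CameraModel:
    """Planar pin-hole camera.

    Parameters
    ----------
    focal_length : float
        Focal length in image-plane units.
    fov_h, fov_v : float
        Horizontal and vertical field of view in degrees, each in
        (0, 180).
    frame_rate : float
        Sampling rate of the flow in Hz.
    """

    focal_length: float = 1.0
    fov_h: float = 110.0
    fov_v: float = 94.0
    frame_rate: float = 20.0

    def __post_init__(self) -> None:
        if not (0.0 < self.fov_h < 180.0 and 0.0 < self.fov_v < 180.0):
            raise ValueError("field of view must lie in (0, 180) degrees")
        if self.focal_length <= 0:
            raise ValueError("focal_length must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def frame_interval(self) -> float:
        """Duration of one frame in seconds."""
        return 1.0 / self.frame_rate

    @property
    def half_width(self) -> float:
        """Image half-extent in x (image units) at the horizontal FOV edge."""
        return self.focal_length * np.tan(np.radians(self.fov_h / 2.0))

    @property
    def half_height(self) -> float:
        """Image half-extent in y (image units) at the vertical FOV edge."""
        return self.focal_length * np.tan(np.radians(self.fov_v / 2.0))

    def deg_to_image(self, deg: float) -> float:
        """Convert a visual angle (degrees) to image-plane units at the fovea."""
        return self.focal_length * np.tan(np.radians(deg))

    def image_to_deg(self, img: np.ndarray | float) -> np.ndarray | float:
        """Convert image-plane coordinates to visual angle in degrees."""
        return np.degrees(np.arctan2(img, self.focal_length))

    def project(self, points_cam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project camera-frame points ``(n, 3)`` to image coordinates.

        Returns ``(xy, visible)`` where ``xy`` has shape ``(n, 2)`` (rows for
        invisible points hold the raw projection or NaN for ``Z <= 0``) and
        ``visible`` is a boolean mask combining the depth and FOV tests.
        """
        pts = np.asarray(points_cam, dtype=float)
        Z = pts[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            x = self.focal_length * pts[:, 0] / Z
            y = self.focal_length * pts[:, 1] / Z
        in_front = Z > 1e-9
        visible = (
            in_front
            & (np.abs(x) <= self.half_width)
            & (np.abs(y) <= self.half_height)
        )
        return np.column_stack([x, y]), visible
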