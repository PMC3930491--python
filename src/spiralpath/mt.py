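"""Model MT: spatial pooling of the sparse flow field.

MT units pool the V1 flow vectors component-wise with a truncated
Gaussian receptive-field kernel.  Pooling is evaluated at the dot
projection sites themselves (the flow is sparse, mirroring the random-dot
displays), with kernel weights normalized to sum to one over the visible
dots within the truncation radius of each site.  This stage has no
direction or speed tuning; it only enlarges receptive fields relative to
V1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .camera import CameraModel
from .stimulus import FlowField

__all__ = ["PoolingParams", "pool_flow"]


@dataclass(frozen=True)
class PoolingParams:
    """Gaussian pooling kernel, sized in degrees of visual angle.

    ``kernel_sigma`` is the Gaussian width and ``kernel_radius`` the
    truncation radius (both degrees; radius must be >= sigma).  Angles are
    converted to image-plane units through the camera's focal length.
    """

    kernel_sigma: float = 3.0
    kernel_radius: float = 9.0

    def __post_init__(self) -> None:
        if self.kernel_sigma < 0 or self.kernel_radius < self.kernel_sigma:
            raise ValueError("require 0 <= kernel_sigma <= kernel_radius")


def pool_flow(
    flow: FlowField,
    params: PoolingParams | None = None,
    camera: CameraModel | None = None,
) -> FlowField:
    """Kernel-weighted average of neighbouring dot vectors at each site.

    The output has the same sample locations as the input; only the
    vectors change.  A ``kernel_sigma`` of zero degenerates to the
    identity mapping.  An empty flow field is returned unchanged with a
    warning.
    """
    params = params if params is not None else PoolingParams()
    cam = camera if camera is not None else CameraModel()
    if flow.n_visible == 0:
        warnings.warn("pooling an empty flow field", stacklevel=2)
        return flow
    sigma = cam.deg_to_image(params.kernel_sigma)
    radius = cam.deg_to_image(params.kernel_radius)
    if sigma <= 0.0:
        return flow

    d = cdist(flow.xy, flow.xy)
    w = np.exp(-0.5 * (d / sigma) ** 2)
    w[d > radius] = 0.0
    norm = w.sum(axis=1, keepdims=True)  # >= 1 always (self weight is 1)
    pooled = (w @ flow.uv) / norm
    return FlowField(
        frame=flow.frame, xy=flow.xy, uv=pooled, dot_indices=flow.dot_indices
    )
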