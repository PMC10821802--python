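"""Learnable Sobel edge channel.

The lower channel of the dual transformer does not see the raw photograph:
it sees an edge image.  The pipeline is grayscale conversion, cross-correlation
with a pair of 3x3 gradient kernels initialized to the classical Sobel
operators (horizontal G_x, vertical G_y = G_x^T), the per-pixel gradient
magnitude, and replication of the magnitude map into three channels so both
transformer channels share one patch-embedding geometry.

The kernels are ordinary trainable parameters: the whole map from image to
edge input is differentiable with respect to them, so back-propagation can
refine the edge detector during training.  A ``trainable=False`` flag freezes
them to reproduce a fixed-Sobel ablation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, take
from .nn import Module, Parameter

__all__ = [
    "SOBEL_GX",
    "SOBEL_GY",
    "SobelKernels",
    "to_grayscale",
    "sobel_response",
    "edge_magnitude",
    "make_edge_input",
    "SobelEdgeLayer",
]

#: Horizontal-gradient kernel (responds to left-right intensity change).
SOBEL_GX = np.array([[1.0, 0.0, -1.0],
                     [2.0, 0.0, -2.0],
                     [1.0, 0.0, -1.0]])

#: Vertical-gradient kernel; the transpose of :data:`SOBEL_GX`.
SOBEL_GY = SOBEL_GX.T.copy()

# ITU-R BT.601 luminance weights.
_LUMA = np.array([0.299, 0.587, 0.114])

# Smoothing constant for the magnitude: sqrt(gx^2+gy^2+EPS^2)-EPS is
# differentiable at zero and exactly zero on a flat image.
_MAG_EPS = 1e-6
_NORM_EPS = 1e-8


@dataclass
class SobelKernels:
    """The pair of 3x3 gradient kernels, optionally trainable."""

    gx: Tensor
    gy: Tensor
    trainable: bool = True

    @classmethod
    def initialized(cls, trainable: bool = True, dtype=np.float32) -> "SobelKernels":
        return cls(
            gx=Parameter(SOBEL_GX.astype(dtype), requires_grad=trainable),
            gy=Parameter(SOBEL_GY.astype(dtype), requires_grad=trainable),
            trainable=trainable,
        )


def _check_image(image: Tensor) -> None:
    if image.ndim < 3 or image.shape[-1] != 3:
        raise ValueError(f"expected an RGB image with 3 trailing channels, got shape {image.shape}")


def to_grayscale(image: Tensor) -> Tensor:
    """BT.601 luminance: 0.299 R + 0.587 G + 0.114 B.

    Accepts ``(..., H, W, 3)`` and returns ``(..., H, W)``.
    """
    image = image if isinstance(image, Tensor) else Tensor(image)
    _check_image(image)
    luma = Tensor(_LUMA.astype(image.dtype))
    return (image * luma).sum(axis=-1)


def _conv3x3_same(gray: Tensor, kernel: Tensor) -> Tensor:
    """2-D cross-correlation with a 3x3 kernel, replicate-padded borders.

    Written as nine shifted slices so the gradient flows into every kernel
    element exactly.
    """
    h, w = gray.shape[-2], gray.shape[-1]
    if h < 3 or w < 3:
        raise ValueError(f"image {h}x{w} is smaller than the 3x3 kernel")
    idx_h = np.clip(np.arange(-1, h + 1), 0, h - 1)
    idx_w = np.clip(np.arange(-1, w + 1), 0, w - 1)
    padded = take(take(gray, idx_h, axis=-2), idx_w, axis=-1)
    out = None
    for i in range(3):
        for j in range(3):
            sl = [slice(None)] * (padded.ndim - 2) + [slice(i, i + h), slice(j, j + w)]
            term = padded[tuple(sl)] * kernel[i, j]
            out = term if out is None else out + term
    return out


def sobel_response(gray: Tensor, kernels: SobelKernels) -> tuple[Tensor, Tensor]:
    """Cross-correlate the gray image with both kernels (same spatial size)."""
    gray = gray if isinstance(gray, Tensor) else Tensor(gray)
    return _conv3x3_same(gray, kernels.gx), _conv3x3_same(gray, kernels.gy)


def edge_magnitude(gx_map: Tensor, gy_map: Tensor) -> Tensor:
    """Per-pixel gradient magnitude, rescaled to [0, 1] by the per-image max.

    A flat image (both responses zero) maps to an exactly-zero output.  The
    square root is smoothed by a tiny epsilon and the per-image maximum is
    itself differentiated, so finite differences and autodiff agree.
    """
    gx_map = gx_map if isinstance(gx_map, Tensor) else Tensor(gx_map)
    gy_map = gy_map if isinstance(gy_map, Tensor) else Tensor(gy_map)
    if gx_map.shape != gy_map.shape:
        raise ValueError(f"response maps differ in shape: {gx_map.shape} vs {gy_map.shape}")
    mag = (gx_map * gx_map + gy_map * gy_map + _MAG_EPS ** 2) ** 0.5 - _MAG_EPS
    peak = mag.max(axis=(-2, -1), keepdims=True)
    return mag / (peak + _NORM_EPS)


def make_edge_input(image: Tensor, kernels: SobelKernels) -> Tensor:
    """Assemble the lower-channel input: magnitude replicated to 3 channels."""
    image = image if isinstance(image, Tensor) else Tensor(image)
    _check_image(image)
    gray = to_grayscale(image)
    gx_map, gy_map = sobel_response(gray, kernels)
    mag = edge_magnitude(gx_map, gy_map)
    expanded = mag.reshape(*mag.shape, 1)
    return expanded * Tensor(np.ones(3, dtype=mag.dtype))


class SobelEdgeLayer(Module):
    """Module wrapper so the kernels are registered as model parameters."""

    def __init__(self, trainable: bool = True):
        super().__init__()
        kernels = SobelKernels.initialized(trainable=trainable)
        self.gx = kernels.gx
        self.gy = kernels.gy
        self.trainable = trainable

    @property
    def kernels(self) -> SobelKernels:
        return SobelKernels(gx=self.gx, gy=self.gy, trainable=self.trainable)

    def forward(self, image: Tensor) -> Tensor:
        return make_edge_input(image, self.kernels)
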