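"""Retina layer: grayscale conversion and Gaussian blur producing P(x, y, t).

Each ommatidium is mapped to one pixel; photoreceptors grayscale the input
(ITU-R 601 luma weights) and smooth it with an isotropic Gaussian of width
sigma1. The blurred stack P feeds both the motion branch (lamina band-pass)
and the contrast branch (centre/surround pooling) downstream.
"""

from __future__ import annotations

import numpy as np

from .kernels import convolve_spatial, make_gaussian2d

__all__ = ["rgb_to_gray", "blur"]

_LUMA = np.array([0.2989, 0.5870, 0.1140])


def rgb_to_gray(frames: np.ndarray) -> np.ndarray:
    """Luma-weighted grayscale; gray input passes through unchanged.

    Accepts a single frame (H, W) or (H, W, 3) or a stack (T, H, W) or
    (T, H, W, 3). Output is floating point (no re-quantization, which would
    double-round ahead of the filters).
    """
    a = np.asarray(frames, dtype=float)
    if a.ndim in (2, 3) and (a.ndim == 2 or a.shape[-1] != 3):
        return a  # already gray (frame or stack)
    if a.ndim in (3, 4) and a.shape[-1] == 3:
        return a @ _LUMA
    raise ValueError(f"cannot interpret shape {a.shape} as gray or RGB frames")


def blur(frames: np.ndarray, sigma1: float = 1.0) -> np.ndarray:
    """Per-frame Gaussian smoothing with the unit-sum sigma1 kernel.

    No temporal mixing: every frame is filtered independently.
    """
    a = np.asarray(frames, dtype=float)
    if a.size == 0:
        raise ValueError("empty frame sequence")
    kern = make_gaussian2d(sigma1)
    if a.ndim == 2:
        return convolve_spatial(a, kern)
    if a.ndim == 3:
        return np.stack([convolve_spatial(f, kern) for f in a])
    raise ValueError("expected (H, W) or (T, H, W)")
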