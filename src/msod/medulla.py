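"""Medulla layer: second-order lateral inhibition (Tm3/Tm2) and gamma delays.

Tm3 (ON) and Tm2 (OFF) convolve their input with the composite kernel
W1 = A*[DoG]+ + B*[DoG]- and rectify the result; with B > A the kernel's net
sum is negative, so extended (wide-field) inputs are suppressed while small
blobs survive - this is the model's size selectivity. Mi1 and Tm1 are the
gamma-delayed copies of Tm3 and Tm2 that the correlator multiplies against.
"""

from __future__ import annotations

import numpy as np

from .kernels import (
    DiscreteKernel1D,
    DiscreteKernel2D,
    convolve_spatial,
    convolve_temporal_causal,
    make_dog,
)

__all__ = ["make_w1", "second_order_inhibition", "gamma_delay"]


def make_w1(
    a: float = 1.0, b: float = 3.0, sigma2: float = 1.5, sigma3: float = 2.0
) -> DiscreteKernel2D:
    """Second-order inhibition kernel W1 = A*[DoG]+ + B*[DoG]-."""
    _, w_sp, w_sn = make_dog(sigma2, sigma3)
    return DiscreteKernel2D(a * w_sp.weights + b * w_sn.weights, norm_policy="raw")


def second_order_inhibition(stack: np.ndarray, w1: DiscreteKernel2D) -> np.ndarray:
    """Per-frame convolution with W1 followed by half-wave rectification."""
    a = np.asarray(stack, dtype=float)
    if a.ndim == 2:
        return np.maximum(convolve_spatial(a, w1), 0.0)
    return np.stack([np.maximum(convolve_spatial(f, w1), 0.0) for f in a])


def gamma_delay(stack: np.ndarray, kernel: DiscreteKernel1D) -> np.ndarray:
    """Causal unit-sum gamma convolution: the delayed Mi1/Tm1 copies."""
    return convolve_temporal_causal(stack, kernel)
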