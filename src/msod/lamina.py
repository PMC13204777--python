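"""Lamina layer: temporal band-pass (LMC), lateral inhibition, ON/OFF split.

The large monopolar cell (LMC) signals luminance *change*: the blurred retina
output is convolved causally in time with the zero-sum band-pass H, so any
temporally constant input is annihilated once the filter has filled. Lateral
inhibition then convolves the LMC stack with a separable spatio-temporal
kernel W_I = W_SP*W_TP + W_SN*W_TN (excitatory DoG half paired with a fast
exponential, inhibitory half with a slow one), and the result is half-wave
rectified into parallel ON (luminance-increase) and OFF (luminance-decrease)
pathways.
"""

from __future__ import annotations

import numpy as np

from .kernels import (
    DiscreteKernel1D,
    DiscreteKernel2D,
    convolve_spatial,
    convolve_temporal_causal,
)

__all__ = ["temporal_bandpass", "lateral_inhibition", "split_on_off"]


def temporal_bandpass(P: np.ndarray, h: DiscreteKernel1D) -> np.ndarray:
    """Causal temporal convolution of the retina stack with the band-pass H."""
    return convolve_temporal_causal(P, h)


def lateral_inhibition(
    lmc: np.ndarray,
    w_sp: DiscreteKernel2D,
    w_sn: DiscreteKernel2D,
    w_tp: DiscreteKernel1D,
    w_tn: DiscreteKernel1D,
) -> np.ndarray:
    """Spatio-temporal surround suppression of the LMC stack.

    Exploits the separable form of the inhibition kernel: each additive term
    is a temporal filter followed by a spatial one, which agrees with direct
    3-D convolution but costs two 1-D passes and two 2-D passes.
    """
    excit = convolve_temporal_causal(lmc, w_tp)
    inhib = convolve_temporal_causal(lmc, w_tn)
    out = np.empty_like(excit)
    for t in range(lmc.shape[0]):
        out[t] = convolve_spatial(excit[t], w_sp) + convolve_spatial(inhib[t], w_sn)
    return out


def split_on_off(lmci: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Half-wave rectification into non-negative ON and OFF channels.

    S_ON = max(LMCI, 0), S_OFF = max(-LMCI, 0); the two have disjoint support
    and S_ON - S_OFF reconstructs LMCI exactly.
    """
    return np.maximum(lmci, 0.0), np.maximum(-lmci, 0.0)
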