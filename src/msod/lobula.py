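"""Lobula layer: the feedback Hassenstein-Reichardt correlator (LC11).

Two half-correlators multiply an undelayed medulla signal with the delayed
copy of its partner:

    LC11_1(t) = (S_Tm3 + k*F1) * (S_Tm1 + k*F1)
    LC11_2(t) = (S_Tm2 + k*F2) * (S_Mi1 + k*F2)
    LC11      = LC11_1 - LC11_2

where F_i is the gamma-weighted sum of that half-correlator's own *strictly
past* outputs (lags >= 1), making the recursion explicit rather than a
fixed-point equation, and k is a small feedback gain. The subtraction of the
ON-derived and OFF-derived halves gives a signed, non-directional response
selective for small moving objects; with k = 0 the recursion reduces exactly
to the feedforward product correlator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import DiscreteKernel1D

__all__ = ["LC11State", "lc11_step", "run_lc11"]


def _feedback_taps(kernel: DiscreteKernel1D) -> np.ndarray:
    """Strictly-past gamma weights: lag-0 tap dropped, remainder unit-sum."""
    taps = kernel.taps.copy()
    taps[0] = 0.0
    s = taps.sum()
    if s <= 0:
        raise ValueError("feedback kernel has no mass at lags >= 1")
    return taps / s


@dataclass
class LC11State:
    """Ring buffers of past half-correlator outputs plus the feedback weights."""

    feedback: DiscreteKernel1D
    k: float = 0.01
    buf1: list = field(default_factory=list)  # newest last
    buf2: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("feedback gain k must be non-negative")
        self._taps = _feedback_taps(self.feedback)

    def _feedback_map(self, buf: list, shape) -> np.ndarray:
        out = np.zeros(shape)
        if self.k == 0.0:
            return out
        n = len(buf)
        for j in range(1, min(len(self._taps), n + 1)):
            w = self._taps[j]
            if w != 0.0:
                out += w * buf[n - j]
        return out

    def _push(self, buf: list, value: np.ndarray) -> None:
        buf.append(value)
        if len(buf) > len(self._taps):
            buf.pop(0)


def lc11_step(
    s_tm3: np.ndarray,
    s_tm2: np.ndarray,
    s_mi1: np.ndarray,
    s_tm1: np.ndarray,
    state: LC11State,
) -> np.ndarray:
    """Advance the correlator by one frame; returns the signed LC11 map."""
    maps = [np.asarray(m, dtype=float) for m in (s_tm3, s_tm2, s_mi1, s_tm1)]
    if len({m.shape for m in maps}) != 1:
        raise ValueError("medulla maps must share one shape")
    s_tm3, s_tm2, s_mi1, s_tm1 = maps
    f1 = state._feedback_map(state.buf1, s_tm3.shape)
    f2 = state._feedback_map(state.buf2, s_tm3.shape)
    lc1 = (s_tm3 + state.k * f1) * (s_tm1 + state.k * f1)
    lc2 = (s_tm2 + state.k * f2) * (s_mi1 + state.k * f2)
    state._push(state.buf1, lc1)
    state._push(state.buf2, lc2)
    return lc1 - lc2


def run_lc11(
    s_tm3: np.ndarray,
    s_tm2: np.ndarray,
    s_mi1: np.ndarray,
    s_tm1: np.ndarray,
    feedback: DiscreteKernel1D,
    k: float = 0.01,
) -> np.ndarray:
    """Frame-ordered correlator over full medulla stacks (T, H, W)."""
    state = LC11State(feedback=feedback, k=k)
    T = s_tm3.shape[0]
    out = np.empty_like(np.asarray(s_tm3, dtype=float))
    for t in range(T):
        out[t] = lc11_step(s_tm3[t], s_tm2[t], s_mi1[t], s_tm1[t], state)
    return out
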