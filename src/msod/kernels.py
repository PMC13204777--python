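"""Discrete spatial and temporal kernels shared by every stage of the model.

All continuous kernel forms used by the visual pathway live here, together
with their sampled/truncated discrete realizations and the two convolution
engines (spatial "same"-size with replicate padding, and strictly causal
temporal convolution over a frame history).

Normalization policies
----------------------
``unit_sum``
    Taps are rescaled so they sum to exactly 1 (smoothing / delay kernels:
    Gaussian, exponential low-pass, gamma).
``zero_sum``
    Negative taps are rescaled so the discrete sum is exactly 0 while the
    positive lobe keeps its sampled shape (temporal band-pass).
``raw``
    Taps are used as sampled (rectified DoG halves, composite kernels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "DiscreteKernel1D",
    "DiscreteKernel2D",
    "gaussian2d_continuous",
    "bandpass_continuous",
    "exp_lowpass_continuous",
    "gamma_continuous",
    "make_gaussian2d",
    "make_dog",
    "make_bandpass",
    "make_exp_lowpass",
    "make_gamma",
    "convolve_spatial",
    "convolve_temporal_causal",
]

_TOL = 1e-9


@dataclass(frozen=True)
class DiscreteKernel1D:
    """Sampled temporal kernel; tap ``j`` applies to the frame ``j`` lags back."""

    taps: np.ndarray
    dt: float = 1.0
    norm_policy: str = "raw"

    def __post_init__(self) -> None:
        taps = np.asarray(self.taps, dtype=float)
        object.__setattr__(self, "taps", taps)
        if taps.ndim != 1 or taps.size < 1:
            raise ValueError("taps must be a non-empty 1-D array")
        if not np.all(np.isfinite(taps)):
            raise ValueError("taps must be finite")
        s = taps.sum()
        if self.norm_policy == "unit_sum" and abs(s - 1.0) > _TOL:
            raise ValueError(f"unit_sum kernel sums to {s!r}")
        if self.norm_policy == "zero_sum" and abs(s) > _TOL:
            raise ValueError(f"zero_sum kernel sums to {s!r}")

    def __len__(self) -> int:
        return self.taps.size

    def dump(self) -> str:
        """Plain-text tap dump for debugging."""
        head = f"# 1D kernel, dt={self.dt}, policy={self.norm_policy}\n"
        return head + "\n".join(f"{j}\t{v:.12g}" for j, v in enumerate(self.taps))


@dataclass(frozen=True)
class DiscreteKernel2D:
    """Square odd-sided spatial kernel centred at offset (0, 0)."""

    weights: np.ndarray
    norm_policy: str = "raw"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] % 2 == 0:
            raise ValueError("weights must be square with odd side")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        s = w.sum()
        if self.norm_policy == "unit_sum" and abs(s - 1.0) > _TOL:
            raise ValueError(f"unit_sum kernel sums to {s!r}")
        if self.norm_policy == "zero_sum" and abs(s) > _TOL:
            raise ValueError(f"zero_sum kernel sums to {s!r}")

    @property
    def radius(self) -> int:
        return self.weights.shape[0] // 2

    def dump(self) -> str:
        head = f"# 2D kernel, radius={self.radius}, policy={self.norm_policy}\n"
        return head + "\n".join(
            "\t".join(f"{v:.12g}" for v in row) for row in self.weights
        )


# ---------------------------------------------------------------------------
# continuous forms (used for sampling and as oracles in tests)

def gaussian2d_continuous(x, y, sigma: float):
    """Isotropic 2-D Gaussian, unit integral over the plane."""
    return np.exp(-(np.asarray(x) ** 2 + np.asarray(y) ** 2) / (2.0 * sigma**2)) / (
        2.0 * math.pi * sigma**2
    )


def bandpass_continuous(t, n1: float, n2: float):
    """Temporal band-pass H(t) = (n2!·t^n1 − n1!·t^n2)/(n1!·n2!)·e^−t for t ≥ 0.

    H(0) = 0 and the continuous integral over [0, ∞) vanishes, so the filter
    rejects DC; the single sign change sits at t = (n2!/n1!)^(1/(n2−n1)).
    """
    t = np.asarray(t, dtype=float)
    f1, f2 = math.gamma(n1 + 1.0), math.gamma(n2 + 1.0)
    return (f2 * t**n1 - f1 * t**n2) / (f1 * f2) * np.exp(-t)


def exp_lowpass_continuous(t, lam: float):
    """First-order low-pass (1/λ)·e^(−t/λ), unit integral."""
    return np.exp(-np.asarray(t, dtype=float) / lam) / lam


def gamma_continuous(t, n: int, tau: float):
    """Gamma delay kernel of order n, unit integral, mode at t = τ.

    Γ_{n,τ}(t) = nⁿ·tⁿ·exp(−n·t/τ) / ((n−1)!·τⁿ⁺¹)
    """
    t = np.asarray(t, dtype=float)
    return n**n * t**n * np.exp(-n * t / tau) / (math.factorial(n - 1) * tau ** (n + 1))


# ---------------------------------------------------------------------------
# discrete builders

def make_gaussian2d(sigma: float, radius: int | None = None) -> DiscreteKernel2D:
    """Sampled isotropic Gaussian, renormalized to unit sum.

    ``radius`` defaults to ceil(3σ), which keeps truncation loss of the
    continuous mass below 0.1%.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if radius is None:
        radius = math.ceil(3.0 * sigma)
    if radius < math.ceil(3.0 * sigma):
        raise ValueError("radius must be at least ceil(3*sigma)")
    ax = np.arange(-radius, radius + 1)
    xx, yy = np.meshgrid(ax, ax, indexing="xy")
    w = gaussian2d_continuous(xx, yy, sigma)
    return DiscreteKernel2D(w / w.sum(), norm_policy="unit_sum")


def make_dog(
    sigma2: float, sigma3: float, radius: int | None = None
) -> tuple[DiscreteKernel2D, DiscreteKernel2D, DiscreteKernel2D]:
    """Difference-of-Gaussians and its rectified halves.

    Returns ``(dog, w_sp, w_sn)`` where dog = G_{σ2} − G_{σ3} (each unit-sum
    before subtraction, so dog is zero-sum), w_sp = max(dog, 0) is the spatial
    excitatory half and w_sn = min(dog, 0) the inhibitory half.
    """
    if not (sigma3 > sigma2 > 0):
        raise ValueError("need sigma3 > sigma2 > 0")
    if radius is None:
        radius = math.ceil(3.0 * sigma3)
    g2 = make_gaussian2d(sigma2, radius)
    g3 = make_gaussian2d(sigma3, radius)
    d = g2.weights - g3.weights
    dog = DiscreteKernel2D(d, norm_policy="zero_sum")
    w_sp = DiscreteKernel2D(np.maximum(d, 0.0), norm_policy="raw")
    w_sn = DiscreteKernel2D(np.minimum(d, 0.0), norm_policy="raw")
    return dog, w_sp, w_sn


def _coverage_length(f, dt: float, target: float = 0.999, t_max: float = 2000.0) -> int:
    """Smallest lag count whose span covers >= target of the absolute continuous mass."""
    tt = np.linspace(0.0, t_max, 200_001)
    m = np.abs(f(tt))
    cum = np.cumsum(m)
    cum /= cum[-1]
    t_star = tt[int(np.searchsorted(cum, target))]
    return int(math.ceil(t_star / dt)) + 1


def make_bandpass(
    n1: float, n2: float, length: int | None = None, dt: float = 1.0
) -> DiscreteKernel1D:
    """Sampled temporal band-pass H with exact discrete DC rejection.

    After sampling at lags 0, dt, 2·dt, ... the negative taps are rescaled so
    the discrete sum is exactly zero; the positive lobe keeps its sampled
    shape (mean-subtraction would break H(0) = 0).
    """
    if n2 <= n1 or n1 <= 0:
        raise ValueError("need n2 > n1 > 0")
    if length is None:
        length = max(31, _coverage_length(lambda t: bandpass_continuous(t, n1, n2), dt))
    taps = bandpass_continuous(np.arange(length) * dt, n1, n2) * dt
    pos = taps > 0
    s_pos, s_neg = taps[pos].sum(), taps[~pos].sum()
    if s_neg < 0:
        taps = taps.copy()
        taps[~pos] *= s_pos / (-s_neg)
    else:  # degenerate truncation: fall back to mean removal
        taps = taps - taps.mean()
    return DiscreteKernel1D(taps, dt=dt, norm_policy="zero_sum")


def make_exp_lowpass(lam: float, length: int | None = None, dt: float = 1.0) -> DiscreteKernel1D:
    """Sampled exponential low-pass, truncated and renormalized to unit sum."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if length is None:
        # exact tail mass of the exponential: e^(−T/λ) < 0.1% at T = λ·ln(1000)
        length = int(math.ceil(lam * math.log(1000.0) / dt)) + 1
    taps = exp_lowpass_continuous(np.arange(length) * dt, lam) * dt
    return DiscreteKernel1D(taps / taps.sum(), dt=dt, norm_policy="unit_sum")


def make_gamma(n: int, tau: float, length: int | None = None, dt: float = 1.0) -> DiscreteKernel1D:
    """Sampled gamma delay kernel, truncated and renormalized to unit sum."""
    if n < 1 or int(n) != n:
        raise ValueError("n must be a positive integer")
    if tau <= 0:
        raise ValueError("tau must be positive")
    n = int(n)
    if length is None:
        length = _coverage_length(
            lambda t: gamma_continuous(t, n, tau), dt, t_max=max(2000.0, 20.0 * tau)
        )
    taps = gamma_continuous(np.arange(length) * dt, n, tau) * dt
    return DiscreteKernel1D(taps / taps.sum(), dt=dt, norm_policy="unit_sum")


# ---------------------------------------------------------------------------
# convolution engines

def convolve_spatial(arr: np.ndarray, kernel: DiscreteKernel2D) -> np.ndarray:
    """"Same"-size 2-D convolution with replicate padding at the borders."""
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D map")
    if min(arr.shape) < kernel.weights.shape[0]:
        raise ValueError("kernel larger than map")
    # all model kernels are point-symmetric, but flip anyway: this is convolution
    return ndimage.correlate(arr, kernel.weights[::-1, ::-1], mode="nearest")


def convolve_temporal_causal(history: np.ndarray, kernel: DiscreteKernel1D) -> np.ndarray:
    """Strictly causal temporal convolution along axis 0 of a (T, ...) stack.

    out[t] = Σ_j taps[j] · history[t−j], with zero padding before the start of
    the sequence; frame t never depends on frames later than t.
    """
    x = np.asarray(history)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(float)
    taps = np.asarray(kernel.taps, dtype=x.dtype)
    if len(taps) % 2 == 0:  # odd length so the causal origin shift is legal
        taps = np.concatenate([taps, np.zeros(1, x.dtype)])
    return ndimage.convolve1d(x, taps, axis=0, mode="constant", origin=-(len(taps) // 2))
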