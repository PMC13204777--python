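"""Contrast pathway: AMC centre/surround pooling and the T1 local contrast.

The amacrine cell pools the raw retina output P over a small central window
(default 11 x 11) and over the surrounding annulus of a larger window
(default 31 x 31 minus the centre); T1 reports surround mean minus centre
mean, so a dark target on a brighter surround gives positive contrast and the
sign flips when foreground/background luminances are exchanged. Borders use
replicate padding so T1 is defined at every pixel.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["amc_pool", "t1_contrast", "local_contrast"]


def _box_sum(a: np.ndarray, side: int) -> np.ndarray:
    return ndimage.uniform_filter(a, size=side, mode="nearest") * (side * side)


def amc_pool(P: np.ndarray, psi: int = 11, pi: int = 31) -> tuple[np.ndarray, np.ndarray]:
    """Box sums over the central window (psi) and surrounding annulus (pi \\ psi).

    Window sides must be odd with pi > psi. Works on one frame (H, W) or a
    stack (T, H, W), per frame.
    """
    if psi % 2 == 0 or pi % 2 == 0:
        raise ValueError("window sides must be odd")
    if pi <= psi:
        raise ValueError("outer window must strictly contain the central one")
    a = np.asarray(P, dtype=float)
    if a.ndim == 2:
        cln = _box_sum(a, psi)
        sln = _box_sum(a, pi) - cln
        return cln, sln
    if a.ndim == 3:
        pooled = [amc_pool(f, psi, pi) for f in a]
        return np.stack([p[0] for p in pooled]), np.stack([p[1] for p in pooled])
    raise ValueError("expected (H, W) or (T, H, W)")


def t1_contrast(
    amc_cln: np.ndarray, amc_sln: np.ndarray, psi: int = 11, pi: int = 31
) -> np.ndarray:
    """T1 = annulus mean - centre mean.

    The annulus divisor is pi^2 - psi^2 (the pixels actually summed there)
    and the centre divisor psi^2.
    """
    n_psi = psi * psi
    n_pi_annulus = pi * pi - n_psi
    return np.asarray(amc_sln) / n_pi_annulus - np.asarray(amc_cln) / n_psi


def local_contrast(P: np.ndarray, psi: int = 11, pi: int = 31) -> np.ndarray:
    """Convenience: pool then contrast in one call."""
    cln, sln = amc_pool(P, psi, pi)
    return t1_contrast(cln, sln, psi, pi)
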