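"""Mushroom-body stage: trajectories, contrast series, SD-based confirmation.

The central brain fuses the motion pathway (LC11) with the contrast pathway
(T1). Thresholded LC11 maxima are linked frame-to-frame into motion
trajectories; each trajectory samples the T1 map along its path (the contrast
trajectory CT) and keeps the running sample standard deviation of CT. A
genuinely moving object sweeps across changing background, so its local
contrast fluctuates and the SD grows; a background-locked pseudo-object sees
the same surround forever, its CT stays flat, and it is never confirmed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Detection",
    "Trajectory",
    "threshold_detections",
    "link_trajectories",
    "attach_contrast",
    "contrast_sd",
    "confirm_objects",
]


@dataclass(frozen=True)
class Detection:
    frame: int
    x: int
    y: int
    score: float


@dataclass
class Trajectory:
    """Linked detections with their contrast series and its running SD."""

    traj_id: int
    frames: list[int] = field(default_factory=list)
    xs: list[int] = field(default_factory=list)
    ys: list[int] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)
    ct: np.ndarray | None = None
    sd: np.ndarray | None = None
    status: str = "candidate"

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def last(self) -> tuple[int, int, int]:
        return self.frames[-1], self.xs[-1], self.ys[-1]

    def to_dict(self) -> dict:
        return {
            "traj_id": self.traj_id,
            "frames": list(self.frames),
            "xs": list(self.xs),
            "ys": list(self.ys),
            "scores": [float(s) for s in self.scores],
            "ct": None if self.ct is None else [float(v) for v in self.ct],
            "sd": None if self.sd is None else [float(v) for v in self.sd],
            "status": self.status,
        }


def threshold_detections(
    lc11: np.ndarray,
    th: float = 0.2,
    nms_window: int = 5,
    normalize: bool = True,
    use_abs: bool = False,
    border_margin: int = 0,
) -> list[list[Detection]]:
    """Per-frame thresholding of the LC11 stack with non-maximum suppression.

    The positive part of each frame (or |LC11| when ``use_abs``) is divided
    by its own maximum when ``normalize`` so the threshold is scale-free;
    survivors above ``th`` are reduced to local maxima over an
    nms_window x nms_window neighbourhood. Ties are broken deterministically
    by (score desc, y, x). ``border_margin`` pixels at the frame edges are
    excluded: the viewport border continually reveals new scene content,
    which produces motion responses that do not correspond to objects.
    """
    if th < 0:
        raise ValueError("threshold must be non-negative")
    out: list[list[Detection]] = []
    for t in range(lc11.shape[0]):
        r = np.abs(lc11[t]) if use_abs else np.maximum(lc11[t], 0.0)
        r = np.asarray(r, dtype=float)
        if border_margin > 0:
            b = border_margin
            r = r.copy()
            r[:b, :] = 0.0
            r[-b:, :] = 0.0
            r[:, :b] = 0.0
            r[:, -b:] = 0.0
        peak = r.max()
        if normalize and peak > 0:
            r = r / peak
        cand = (r > th) & (r == ndimage.maximum_filter(r, size=nms_window, mode="nearest"))
        ys, xs = np.nonzero(cand)
        order = np.lexsort((xs, ys, -r[ys, xs]))
        kept: list[Detection] = []
        half = nms_window  # greedy suppression radius (Chebyshev)
        for i in order:
            y, x = int(ys[i]), int(xs[i])
            if all(max(abs(x - d.x), abs(y - d.y)) >= half for d in kept):
                kept.append(Detection(t, x, y, float(r[y, x])))
        out.append(kept)
    return out


def link_trajectories(
    detections: list[list[Detection]],
    link_radius: float = 10.0,
    gap_max: int = 0,
) -> list[Trajectory]:
    """Greedy nearest-neighbour association of detections across frames.

    Candidate (trajectory, detection) pairs within the gating distance are
    assigned in order of increasing distance, ties resolved by trajectory
    creation index; unmatched detections open new trajectories; a trajectory
    unmatched for more than ``gap_max`` consecutive frames is closed. The
    gating distance is ``link_radius`` per elapsed frame, so a trajectory
    bridging a missed frame may cover proportionally more ground. Every
    detection belongs to exactly one trajectory.
    """
    if link_radius <= 0:
        raise ValueError("link radius must be positive")
    trajectories: list[Trajectory] = []
    active: list[Trajectory] = []
    for t, dets in enumerate(detections):
        active = [tr for tr in active if t - tr.last[0] <= gap_max + 1]
        pairs = []
        for ti, tr in enumerate(active):
            lt, lx, ly = tr.last
            gate = link_radius * (t - lt)
            for di, d in enumerate(dets):
                dist = float(np.hypot(d.x - lx, d.y - ly))
                if dist <= gate:
                    pairs.append((dist, ti, di))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            tr, d = active[ti], dets[di]
            tr.frames.append(d.frame)
            tr.xs.append(d.x)
            tr.ys.append(d.y)
            tr.scores.append(d.score)
        for di, d in enumerate(dets):
            if di not in used_d:
                tr = Trajectory(traj_id=len(trajectories))
                tr.frames.append(d.frame)
                tr.xs.append(d.x)
                tr.ys.append(d.y)
                tr.scores.append(d.score)
                trajectories.append(tr)
                active.append(tr)
    return trajectories


def attach_contrast(traj: Trajectory, t1: np.ndarray) -> Trajectory:
    """Sample the T1 stack along the trajectory: CT[i] = T1(t_i, y_i, x_i)."""
    T, H, W = t1.shape
    ct = np.empty(len(traj))
    for i, (t, x, y) in enumerate(zip(traj.frames, traj.xs, traj.ys)):
        if not (0 <= t < T and 0 <= x < W and 0 <= y < H):
            raise IndexError("trajectory point outside the T1 stack")
        ct[i] = t1[t, y, x]
    traj.ct = ct
    return traj


def contrast_sd(traj: Trajectory) -> Trajectory:
    """Running sample SD (ddof=1) of CT from the trajectory start.

    SD[i] is the SD of CT[0..i]; fewer than two points give 0.
    """
    if traj.ct is None:
        raise ValueError("attach_contrast must run first")
    ct = traj.ct
    n = np.arange(1, len(ct) + 1, dtype=float)
    csum = np.cumsum(ct)
    csum2 = np.cumsum(ct * ct)
    var = np.zeros_like(ct)
    m = n > 1
    var[m] = np.maximum(csum2[m] - csum[m] ** 2 / n[m], 0.0) / (n[m] - 1.0)
    traj.sd = np.sqrt(var)
    return traj


def confirm_objects(
    trajectories: list[Trajectory],
    th2: float = 4.0,
    min_length: int = 3,
) -> pd.DataFrame:
    """Confirm trajectory points whose running contrast SD exceeds th2.

    A point at index i is confirmed iff the trajectory has at least
    ``min_length`` points by then and SD[i] > th2. Returns a DataFrame with
    columns frame, x, y, score, trajectory_id and updates each trajectory's
    status to confirmed/rejected. Raising th2 never adds confirmed points.
    """
    if th2 <= 0:
        raise ValueError("th2 must be positive")
    rows = []
    for tr in trajectories:
        if tr.sd is None:
            contrast_sd(tr)
        confirmed_any = False
        for i, (t, x, y, s) in enumerate(zip(tr.frames, tr.xs, tr.ys, tr.scores)):
            if i + 1 >= min_length and tr.sd[i] > th2:
                rows.append((t, x, y, s, tr.traj_id))
                confirmed_any = True
        tr.status = "confirmed" if confirmed_any else "rejected"
    return pd.DataFrame(rows, columns=["frame", "x", "y", "score", "trajectory_id"])
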