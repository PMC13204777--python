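"""Detection metrics: DR (5-px rule), pixel Pr/Rc/F1, and SNR/VN.

DR counts the fraction of evaluated frames in which some confirmed detection
lies within a pixel tolerance (default 5 px) of the true target centre.
Pr/Rc/F1 are pixel-level: predicted masks are object-sized boxes stamped at
confirmed detections, compared against the true target boxes.

SNR and VN measure output map quality. Their exact formulas are a convention
of this package (labelled non-canonical in the docs): per frame, SNR is the
peak response inside the tolerance-dilated truth region over the RMS of the
response outside it, averaged over frames; VN is the percentage of total
absolute response mass lying outside the dilated truth region. Only orderings
of SNR/VN across pipeline stages are meaningful, never absolute values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "EvalReport",
    "detection_rate",
    "stamp_mask",
    "truth_mask",
    "pixel_prf",
    "snr_vn",
    "evaluate",
]


@dataclass(frozen=True)
class EvalReport:
    DR: float
    Pr: float
    Rc: float
    F1: float
    SNR: float
    VN: float
    TP: int
    FP: int
    FN: int
    TN: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_row(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(self)])


def _real_targets(truth: pd.DataFrame) -> pd.DataFrame:
    return truth[~truth["is_pseudo"].astype(bool)]


def detection_rate(
    confirmed: pd.DataFrame,
    truth: pd.DataFrame,
    tol: float = 5.0,
    warmup: int = 0,
) -> float:
    """Fraction of post-warm-up target frames with a confirmed hit within tol px."""
    targets = _real_targets(truth)
    if targets.empty:
        raise ValueError("ground truth contains no real (non-pseudo) target")
    targets = targets[targets["frame"] >= warmup]
    if targets.empty:
        raise ValueError("no ground-truth frames after warm-up")
    hits = 0
    frames = 0
    for t, grp in targets.groupby("frame"):
        frames += 1
        dets = confirmed[confirmed["frame"] == t] if len(confirmed) else confirmed
        if len(dets) == 0:
            continue
        dx = dets["x"].to_numpy()[:, None] - grp["x"].to_numpy()[None, :]
        dy = dets["y"].to_numpy()[:, None] - grp["y"].to_numpy()[None, :]
        if np.any(np.hypot(dx, dy) <= tol):
            hits += 1
    return hits / frames


def stamp_mask(
    detections: pd.DataFrame,
    shape: tuple[int, int, int],
    box_w: int = 5,
    box_h: int = 5,
) -> np.ndarray:
    """Boolean (T, H, W) stack with box_w x box_h boxes at each detection."""
    T, H, W = shape
    mask = np.zeros(shape, dtype=bool)
    for _, row in detections.iterrows():
        t = int(row["frame"])
        if not (0 <= t < T):
            continue
        x0 = int(round(row["x"] - (box_w - 1) / 2))
        y0 = int(round(row["y"] - (box_h - 1) / 2))
        mask[t, max(0, y0) : y0 + box_h, max(0, x0) : x0 + box_w] = True
    return mask


def truth_mask(truth: pd.DataFrame, shape: tuple[int, int, int]) -> np.ndarray:
    """Boolean stack of the real (non-pseudo) target boxes."""
    t = _real_targets(truth).rename(columns={})
    mask = np.zeros(shape, dtype=bool)
    T, H, W = shape
    for _, row in t.iterrows():
        fr = int(row["frame"])
        if not (0 <= fr < T):
            continue
        w, h = int(row["width"]), int(row["height"])
        x0 = int(round(row["x"] - (w - 1) / 2))
        y0 = int(round(row["y"] - (h - 1) / 2))
        mask[fr, max(0, y0) : y0 + h, max(0, x0) : x0 + w] = True
    return mask


def pixel_prf(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float, float, int, int, int, int]:
    """Pixel-level precision, recall, F1 and the raw TP/FP/FN/TN counts."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("mask shapes differ")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    pr = tp / (tp + fp) if tp + fp else 0.0
    rc = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * pr * rc / (pr + rc) if pr + rc else 0.0
    return pr, rc, f1, tp, fp, fn, tn


def snr_vn(
    response: np.ndarray,
    truth: np.ndarray,
    tol: int = 5,
    warmup: int = 0,
) -> tuple[float, float]:
    """Output-quality measures on a non-negative response stack.

    SNR: mean over evaluated frames of (peak inside the tol-dilated truth
    region) / (RMS outside it); frames with an empty truth region or zero
    outside RMS are skipped. VN: 100 * (absolute response mass outside the
    dilated truth) / (total absolute mass). All-zero response gives (0, 0).
    """
    r = np.abs(np.asarray(response, dtype=float))[warmup:]
    m = np.asarray(truth, dtype=bool)[warmup:]
    if r.shape != m.shape:
        raise ValueError("response/truth shapes differ")
    size = 2 * tol + 1
    dil = np.stack([ndimage.maximum_filter(f, size=size, mode="nearest") for f in m])
    total = r.sum()
    if total == 0:
        return 0.0, 0.0
    vn = 100.0 * r[~dil].sum() / total
    ratios = []
    for t in range(r.shape[0]):
        inside = r[t][dil[t]]
        outside = r[t][~dil[t]]
        if inside.size == 0 or outside.size == 0:
            continue
        rms = np.sqrt(np.mean(outside**2))
        if rms > 0:
            ratios.append(inside.max() / rms)
    snr = float(np.mean(ratios)) if ratios else 0.0
    return snr, float(vn)


def evaluate(
    confirmed: pd.DataFrame,
    truth: pd.DataFrame,
    response: np.ndarray,
    shape: tuple[int, int, int],
    tol: float = 5.0,
    warmup: int = 0,
    box: tuple[int, int] = (5, 5),
) -> EvalReport:
    """Full scorecard for one sequence (warm-up frames excluded everywhere)."""
    dr = detection_rate(confirmed, truth, tol=tol, warmup=warmup)
    pred_m = stamp_mask(confirmed, shape, box_w=box[0], box_h=box[1])[warmup:]
    truth_m = truth_mask(truth, shape)
    pr, rc, f1, tp, fp, fn, tn = pixel_prf(pred_m, truth_m[warmup:])
    snr, vn = snr_vn(response, truth_m, tol=int(tol), warmup=warmup)
    return EvalReport(dr, pr, rc, f1, snr, vn, tp, fp, fn, tn)
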