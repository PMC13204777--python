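"""End-to-end pipeline: retina -> lamina (+contrast) -> medulla -> lobula ->
mushroom body, with a single parameter object carrying every model constant.

Temporal resolution
-------------------
All temporal constants of the model (band-pass shape n1=1, n2=6; inhibition
time constants lambda1=3, lambda2=9; gamma delays tau3=tau4=25) are
*milliseconds*: that is the only unit system in which the band-pass, the
lateral inhibition and the correlator delay are mutually consistent - the
25 ms delay then matches the ~20 ms transit of a 5 px target at 250 px/s,
which is precisely the coincidence the correlator detects. A video frame at
30 FPS is however a 33 ms sample-and-hold snapshot (a display holds each
frame), so the model integrates each frame over ``substeps`` equal sub-frame
steps of dt = 1000/(fps*substeps) ms. Luminance steps at block transitions
produce the millisecond ON/OFF bursts the correlator pairs.

The burst caused by the scene advancing from frame t to frame t+1 appears
during block t+1 and is localized at the frame-t object footprint, so the
per-frame LC11 map for frame t aggregates block t+1 (magnitude extremum over
its substeps); the final frame has no subsequent transition and stays zero.

``time_unit='frame'`` switches to single-step processing with all constants
read in frame units (dt = 1 frame, no upsampling) for sensitivity studies;
in that reading the 25-frame delay exceeds a 21-frame sequence and the
correlator output is negligible, which is why 'ms' is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import kernels as K
from . import medulla, retina
from .contrast_pathway import local_contrast
from .lamina import split_on_off
from .mushroom_body import (
    Trajectory,
    attach_contrast,
    confirm_objects,
    contrast_sd,
    link_trajectories,
    threshold_detections,
)
from .stimulus import FrameSequence

__all__ = ["ModelParams", "StageOutputs", "PipelineResult", "run_pipeline", "profile_row"]

# canonical spelling of each model symbol -> ModelParams field
_TABLE_SYMBOLS = {
    "sigma1": "sigma1",
    "n1": "n1",
    "n2": "n2",
    "sigma2": "sigma2",
    "sigma3": "sigma3",
    "lambda1": "lambda1",
    "lambda2": "lambda2",
    "psi": "psi",
    "pi": "pi",
    "A": "A",
    "B": "B",
    "n3": "n3",
    "tau3": "tau3",
    "n4": "n4",
    "tau4": "tau4",
    "k": "k",
    "Th": "th",
    "Th2": "th2",
}


@dataclass(frozen=True)
class ModelParams:
    """Model constants (benchmark defaults) plus numerical/detection settings."""

    sigma1: float = 1.0
    n1: float = 1.0
    n2: float = 6.0
    sigma2: float = 1.5
    sigma3: float = 2.0
    lambda1: float = 3.0
    lambda2: float = 9.0
    psi: int = 11
    pi: int = 31
    A: float = 1.0
    B: float = 3.0
    n3: int = 5
    tau3: float = 25.0
    n4: int = 10
    tau4: float = 25.0
    k: float = 0.01
    th: float = 0.2
    th2: float = 4.0
    link_radius: float = 10.0
    nms_window: int = 5
    min_traj_length: int = 3
    gap_max: int = 2
    border_margin: int = 10
    time_unit: str = "ms"
    substeps: int = 12
    fps: float = 30.0
    use_abs_lc11: bool = False
    normalize_lc11: bool = True
    warmup_frames: int | None = None
    seed: int = 0

    @property
    def dt(self) -> float:
        """Model integration step in the active time unit."""
        if self.time_unit == "ms":
            return 1000.0 / (self.fps * self.substeps)
        if self.time_unit == "frame":
            return 1.0
        raise ValueError(f"unknown time_unit {self.time_unit!r}")

    # -- config round-trip --------------------------------------------------
    def to_yaml(self) -> str:
        d = asdict(self)
        table3 = {sym: d.pop(fld) for sym, fld in _TABLE_SYMBOLS.items()}
        return yaml.safe_dump({"table3": table3, **d}, sort_keys=False)

    @classmethod
    def from_yaml(cls, text_or_path) -> "ModelParams":
        text = str(text_or_path)
        if "\n" not in text and text.endswith((".yaml", ".yml")):
            with open(text) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(text)
        return cls.from_dict(data or {})

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        data = dict(data)
        table3 = data.pop("table3", {})
        kw = {}
        for sym, value in table3.items():
            if sym not in _TABLE_SYMBOLS:
                raise KeyError(f"unknown model symbol {sym!r}")
            kw[_TABLE_SYMBOLS[sym]] = value
        kw.update(data)
        return cls(**kw)


@dataclass
class StageOutputs:
    """Named per-frame response stacks retained for layer-wise inspection."""

    P: np.ndarray | None = None
    LMC: np.ndarray | None = None
    LMCI: np.ndarray | None = None
    S_ON: np.ndarray | None = None
    S_OFF: np.ndarray | None = None
    T1: np.ndarray | None = None
    S_Tm3: np.ndarray | None = None
    S_Tm2: np.ndarray | None = None
    S_Mi1: np.ndarray | None = None
    S_Tm1: np.ndarray | None = None
    LC11: np.ndarray | None = None

    def names(self) -> list[str]:
        return [k for k, v in self.__dict__.items() if v is not None]


@dataclass
class PipelineResult:
    lc11: np.ndarray
    confirmed: pd.DataFrame
    trajectories: list[Trajectory]
    t1: np.ndarray
    stages: StageOutputs
    warmup: int
    params: ModelParams


def _cascade_t95(kernels: list[np.ndarray], dt: float) -> float:
    """Settle time of the temporal cascade: the lag by which the convolved
    end-to-end impulse response has delivered 95% of its absolute mass."""
    imp = np.array([1.0])
    for taps in kernels:
        imp = np.convolve(imp, np.asarray(taps, dtype=float))
    m = np.abs(imp)
    cum = np.cumsum(m) / m.sum()
    return (int(np.searchsorted(cum, 0.95)) + 1) * dt

def _block_extremum(stack: np.ndarray, T: int, m: int) -> np.ndarray:
    """Per-frame magnitude extremum (signed) over each frame's substep block."""
    blocks = stack.reshape(T, m, *stack.shape[1:])
    bmax = blocks.max(axis=1)
    bmin = blocks.min(axis=1)
    return np.where(bmax > -bmin, bmax, bmin)


def _spatial_all(stack: np.ndarray, kernel: K.DiscreteKernel2D) -> np.ndarray:
    """Replicate-padded 2-D convolution of every map in a (T, H, W) stack."""
    w = np.ascontiguousarray(kernel.weights[::-1, ::-1])[None].astype(stack.dtype)
    return ndimage.correlate(stack, w, mode="nearest")


def run_pipeline(
    frames: FrameSequence | np.ndarray,
    params: ModelParams | None = None,
    keep_stages: bool = False,
) -> PipelineResult:
    """Run every stage in order on a frame sequence.

    ``frames`` may be a FrameSequence or a raw (T, H, W) / (T, H, W, 3)
    stack. With ``keep_stages`` every intermediate response stack is retained
    (downsampled to frame rate by per-block magnitude extremum) for
    row-profile inspection. The run is deterministic: identical input and
    parameters give bit-identical outputs.
    """
    p = params or ModelParams()
    if isinstance(frames, FrameSequence):
        stack = frames.frames
        p = replace(p, fps=frames.fps)
    else:
        stack = np.asarray(frames, dtype=float)
    if stack.ndim not in (3, 4):
        raise ValueError("expected a (T, H, W[, 3]) stack")
    T = stack.shape[0]
    m = p.substeps if p.time_unit == "ms" else 1
    dt = p.dt

    # retina and the (frame-rate) contrast pathway
    P = retina.blur(retina.rgb_to_gray(stack), p.sigma1)
    t1 = local_contrast(P, p.psi, p.pi)

    # temporal kernels at the model step
    h = K.make_bandpass(p.n1, p.n2, dt=dt)
    e_fast = K.make_exp_lowpass(p.lambda1, dt=dt)
    e_slow = K.make_exp_lowpass(p.lambda2, dt=dt)
    g_delay = K.make_gamma(p.n3, p.tau3, dt=dt)
    g_fb = K.make_gamma(p.n4, p.tau4, dt=dt)
    _, w_sp, w_sn = K.make_dog(p.sigma2, p.sigma3)
    w1 = medulla.make_w1(p.A, p.B, p.sigma2, p.sigma3)

    # sample-and-hold upsampling to the model step
    work = np.repeat(P.astype(np.float32), m, axis=0) if m > 1 else P.astype(np.float32)

    lmc = K.convolve_temporal_causal(work, h)
    del work
    f_fast = K.convolve_temporal_causal(lmc, e_fast)
    f_slow = K.convolve_temporal_causal(lmc, e_slow)
    lmc_frames = _block_extremum(lmc, T, m) if keep_stages else None
    del lmc
    lmci = _spatial_all(f_fast, w_sp)
    del f_fast
    lmci += _spatial_all(f_slow, w_sn)
    del f_slow
    s_on, s_off = split_on_off(lmci)
    lmci_frames = _block_extremum(lmci, T, m) if keep_stages else None
    del lmci
    s_tm3 = np.maximum(_spatial_all(s_on, w1), 0.0)
    s_tm2 = np.maximum(_spatial_all(s_off, w1), 0.0)
    if keep_stages:
        son_frames = _block_extremum(s_on, T, m)
        soff_frames = _block_extremum(s_off, T, m)
    del s_on, s_off
    s_mi1 = K.convolve_temporal_causal(s_tm3, g_delay)
    s_tm1 = K.convolve_temporal_causal(s_tm2, g_delay)

    lc11_sub = _run_lc11_fast(s_tm3, s_tm2, s_mi1, s_tm1, g_fb, p.k)
    if keep_stages:
        stages = StageOutputs(
            P=P,
            LMC=lmc_frames,
            LMCI=lmci_frames,
            S_ON=son_frames,
            S_OFF=soff_frames,
            T1=t1,
            S_Tm3=_block_extremum(s_tm3, T, m),
            S_Tm2=_block_extremum(s_tm2, T, m),
            S_Mi1=_block_extremum(s_mi1, T, m),
            S_Tm1=_block_extremum(s_tm1, T, m),
        )
    del s_tm3, s_tm2, s_mi1, s_tm1

    # frame t's response is the burst of the t -> t+1 transition (block t+1),
    # localized at the frame-t footprint; the last frame has no transition.
    agg = _block_extremum(lc11_sub, T, m)
    del lc11_sub
    lc11 = np.zeros_like(agg)
    lc11[: T - 1] = agg[1:]
    if keep_stages:
        stages.LC11 = lc11
    else:
        stages = StageOutputs(T1=t1, LC11=lc11)

    dets = threshold_detections(
        lc11,
        th=p.th,
        nms_window=p.nms_window,
        normalize=p.normalize_lc11,
        use_abs=p.use_abs_lc11,
        border_margin=p.border_margin,
    )
    trajs = link_trajectories(dets, link_radius=p.link_radius, gap_max=p.gap_max)
    for tr in trajs:
        contrast_sd(attach_contrast(tr, t1))
    confirmed = confirm_objects(trajs, th2=p.th2, min_length=p.min_traj_length)

    if p.warmup_frames is not None:
        warmup = p.warmup_frames
    else:
        frame_span = dt * m  # duration of one frame in the active unit
        settle = _cascade_t95([h.taps, e_slow.taps, g_delay.taps, g_fb.taps], dt)
        warmup = min(int(np.ceil(settle / frame_span)), max(T - 1, 0))
    return PipelineResult(
        lc11=lc11, confirmed=confirmed, trajectories=trajs,
        t1=t1, stages=stages, warmup=warmup, params=p,
    )


def _run_lc11_fast(s_tm3, s_tm2, s_mi1, s_tm1, g_fb: K.DiscreteKernel1D, k: float) -> np.ndarray:
    """Feedback correlator over substep stacks with ring-buffered history.

    Same recursion as :func:`msod.lobula.run_lc11` (cross-checked in tests)
    but vectorized over the history axis for long substep sequences.
    """
    taps = g_fb.taps.copy()
    taps[0] = 0.0
    taps = (taps / taps.sum()).astype(s_tm3.dtype)
    Lg = len(taps)
    S = s_tm3.shape[0]
    shape = s_tm3.shape[1:]
    out = np.empty_like(s_tm3)
    if k == 0.0:
        np.multiply(s_tm3, s_tm1, out=out)
        out -= s_tm2 * s_mi1
        return out
    buf1 = np.zeros((Lg,) + shape, s_tm3.dtype)
    buf2 = np.zeros_like(buf1)
    gr = taps[1:]
    head = -1
    lags = np.arange(1, Lg)  # buf[head] is the lag-1 entry
    for s in range(S):
        idx = (head - (lags - 1)) % Lg
        f1 = np.tensordot(gr, buf1[idx], axes=(0, 0))
        f2 = np.tensordot(gr, buf2[idx], axes=(0, 0))
        l1 = (s_tm3[s] + k * f1) * (s_tm1[s] + k * f1)
        l2 = (s_tm2[s] + k * f2) * (s_mi1[s] + k * f2)
        head = (head + 1) % Lg
        buf1[head] = l1
        buf2[head] = l2
        out[s] = l1 - l2
    return out


def profile_row(stages: StageOutputs, y0: int, t0: int) -> dict[str, np.ndarray]:
    """Row-y0, frame-t0 cross-section of every retained stage map."""
    out = {}
    for name in stages.names():
        arr = getattr(stages, name)
        if not (0 <= t0 < arr.shape[0] and 0 <= y0 < arr.shape[1]):
            raise IndexError(f"y0/t0 out of range for stage {name}")
        out[name] = np.asarray(arr[t0, y0, :], dtype=float).copy()
    if not out:
        raise ValueError("no stages were retained")
    return out
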