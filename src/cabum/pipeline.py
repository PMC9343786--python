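"""Session orchestration: calibration block, 1-min frames, stitching, QC.

A session runs as the device does: conditioning is causal, so filtering the
whole recording equals streaming with persistent filter state. The first 10
minutes form the calibration block — processed as one frame so the initial
contraction detection sees enough data (contractions are rare events) —
after which every new 1-min frame is processed independently using only data
up to its end:

    per channel:  peaks -> refinement -> SNR screen/repair -> surrogate
    per frame:    channel weighting (multi-start GD) on a trailing context
                  window -> fusion -> stitching onto the session trace

Frames never rewrite history (prefix property): the surrogate chunks, the
weights and the stitched trace for minutes 1..k are identical whether or not
minute k+1 is ever processed. The final UA trace is unitless (% change in
activity from baseline) at 4 samples/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contraction_id import (
    Contraction,
    DetectorConfig,
    confidence_measures,
    contraction_scores,
    detect_contractions,
    filter_outliers,
)
from .fusion import FrameContext, FusionConfig, WeightVector, optimize_frame, stitch
from .heartbeats import beat_snr, build_template, detect_initial_peaks, refine_peaks, repair_noise
from .preprocess import ChannelSet, PreprocConfig, condition_recording
from .signal_io import RawRecording
from .ua_surrogate import (
    FS_SURROGATE,
    MIN_WINDOW,
    combine_up_down,
    interpolate_peaks,
    moving_rms,
)

__all__ = ["PipelineConfig", "UATrace", "SessionResult", "PipelineState", "run_frame", "run_session"]


@dataclass
class PipelineConfig:
    """Session-level configuration bundling the per-stage configs."""

    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    # UA traces are on the fractional-change-from-baseline scale, so an
    # absolute sub-physiological-ripple floor applies on top of the relative
    # prominence threshold
    detector: DetectorConfig = field(
        default_factory=lambda: DetectorConfig(min_peak_amplitude=0.05)
    )
    frame_s: float = 60.0
    calibration_s: float = 600.0
    context_s: float = 600.0  # trailing window the weighting stage sees
    motion_threshold: float = 5.0  # x baseline motion RMS
    seed: int = 0

    def __post_init__(self) -> None:
        self.fusion.kmeans_seed = self.seed
        self.fusion.detector = self.detector


@dataclass
class UATrace:
    """Final fused, stitched, unitless UA time series at 4 samples/s."""

    values: np.ndarray
    fs: float = FS_SURROGATE
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fs


@dataclass
class SessionResult:
    ua: UATrace
    weights_history: list[tuple[int, WeightVector]]
    contractions: list[Contraction]
    qc: dict


@dataclass
class PipelineState:
    """Mutable state carried across frames."""

    channels: ChannelSet
    cfg: PipelineConfig
    motion_rms: np.ndarray | None  # per-second motion level
    smoothed_history: np.ndarray | None = None  # channels x samples (4 Hz), pre-shift
    surrogate_history: np.ndarray | None = None  # channels x samples (4 Hz), enhanced
    ua: np.ndarray | None = None
    ctx: FrameContext = field(default_factory=FrameContext)
    weights_history: list[tuple[int, WeightVector]] = field(default_factory=list)
    qc: dict = field(default_factory=lambda: {"frames": [], "rejected_channels": []})
    t_processed_s: float = 0.0


def _motion_level(rec: RawRecording) -> np.ndarray | None:
    """Per-second RMS of the high-passed 3-axis accelerometer magnitude."""
    if rec.motion is None or rec.motion.size == 0:
        return None
    acc = rec.motion[:3] - rec.motion[:3].mean(axis=1, keepdims=True)
    mag = np.sqrt(np.sum(acc**2, axis=0))
    n_sec = int(mag.size / rec.fs_motion)
    step = int(rec.fs_motion)
    return np.array([np.sqrt(np.mean(mag[i * step : (i + 1) * step] ** 2)) for i in range(n_sec)])


def _channel_segment(
    ch, start_s: float, end_s: float, fs: float, motion_norm: np.ndarray | None, cfg: PipelineConfig
) -> tuple[np.ndarray, list[str]]:
    """Smoothed (pre-shift) surrogate chunk for one channel over [start_s, end_s).

    Runs beats -> refinement -> repair -> interpolation -> up+|down| ->
    moving RMS. The baseline shift, scaling and squaring happen in
    :func:`run_frame` against the trailing history, so contractions spanning
    frame boundaries keep their baseline context. NaN marks a channel with
    no usable beats in the frame.
    """
    n_out = int(round((end_s - start_s) * FS_SURROGATE))
    x = ch.data[int(start_s * fs) : int(end_s * fs)]
    peaks = detect_initial_peaks(x, fs, modality=ch.modality)
    if peaks.size < 2:
        return np.full(n_out, np.nan), ["no_beats"]
    series = refine_peaks(x, peaks, fs, modality=ch.modality, channel=ch.label)
    if len(series) >= 2:
        beat_snr(x, series, fs)
    template = build_template(x, series, fs)
    mot = None
    if motion_norm is not None:
        a = int(start_s)
        mot = motion_norm[a : a + int(np.ceil(end_s - start_s))]
    series = repair_noise(
        x, series, template, motion_level=mot, fs=fs, motion_threshold=cfg.motion_threshold
    )
    if series.removed or len(series) < 2:
        return np.full(n_out, np.nan), ["removed"]
    # shift beat times from frame-relative to absolute seconds
    series.upward[:, 0] += start_s
    series.downward[:, 0] += start_s
    span = (start_s, end_s - 1.0 / FS_SURROGATE)
    up, dn = interpolate_peaks(series, span=span)
    if up.values.size == 0:
        return np.full(n_out, np.nan), ["dropped"]
    trace = moving_rms(combine_up_down(up, dn))
    v = trace.values
    if v.size < n_out:
        v = np.pad(v, (0, n_out - v.size), mode="edge") if v.size else np.full(n_out, np.nan)
    return v[:n_out], trace.flags or []


def _causal_moving_min(x: np.ndarray, window: int) -> np.ndarray:
    """min over [i-window+1, i] per sample (expanding at the left edge)."""
    import pandas as pd

    return pd.Series(x).rolling(window, min_periods=1).min().to_numpy()


def _enhance_chunks(
    hist: np.ndarray, seg_len: int, ctx_n: int, min_window: int = MIN_WINDOW
) -> np.ndarray:
    """Baseline-shift, scale and square the newest chunk against history.

    The baseline is a causal moving minimum (window 120 s) over the smoothed
    history; the scale is each channel's median smoothed level over the
    trailing context window. Channels with NaN chunks (no beats this frame)
    come out as zeros.
    """
    n_ch, n_s = hist.shape
    out = np.zeros((n_ch, seg_len))
    a = n_s - seg_len
    for c in range(n_ch):
        row = hist[c]
        chunk = row[a:]
        if np.isnan(chunk).all():
            continue
        tail = row[max(0, n_s - ctx_n) :]
        med = float(np.nanmedian(tail)) if np.isfinite(tail).any() else 0.0
        lo = max(0, a - (min_window - 1))
        local = row[lo:]
        filled = np.where(np.isnan(local), np.inf, local)
        mn = _causal_moving_min(filled, min_window)[-seg_len:]
        mn = np.where(np.isfinite(mn), mn, 0.0)
        shifted = np.clip(np.nan_to_num(chunk) - mn, 0.0, None)
        if med > 0:
            shifted = shifted / med
        out[c] = shifted**2
    return out


def run_frame(state: PipelineState, start_s: float, end_s: float) -> PipelineState:
    """Process one frame: extend surrogates, re-weight, fuse, stitch."""
    cfg = state.cfg
    fs = cfg.preproc.fs
    kept = state.channels.kept
    motion_norm = None
    if state.motion_rms is not None:
        upto = state.motion_rms[: max(1, int(end_s))]
        base = float(np.median(upto)) or 1.0
        motion_norm = state.motion_rms / base

    segs, seg_flags = [], []
    for ch in kept:
        seg, fl = _channel_segment(ch, start_s, end_s, fs, motion_norm, cfg)
        segs.append(seg)
        seg_flags.append(fl)
    segs = np.array(segs)
    state.smoothed_history = (
        segs if state.smoothed_history is None else np.hstack([state.smoothed_history, segs])
    )
    ctx_n = int(cfg.context_s * FS_SURROGATE)
    enhanced = _enhance_chunks(state.smoothed_history, segs.shape[1], ctx_n)
    state.surrogate_history = (
        enhanced
        if state.surrogate_history is None
        else np.hstack([state.surrogate_history, enhanced])
    )
    frame_qc = {
        "frame": state.ctx.k,
        "span_s": (start_s, end_s),
        "channel_flags": {ch.label: fl for ch, fl in zip(kept, seg_flags) if fl},
    }
    if not np.any(enhanced):
        frame_qc["rejected"] = True
        state.qc["frames"].append(frame_qc)
        state.t_processed_s = end_s
        return state

    window = state.surrogate_history[:, -ctx_n:]
    modalities = [ch.modality for ch in kept]
    per_channel_contractions: list[list[Contraction]] = []
    for row in window:
        contrs = detect_contractions(row, cfg.detector)
        for c in contrs:
            confidence_measures(c, row, contrs, cfg.detector)
        per_channel_contractions.append(filter_outliers(contrs, cfg.detector))
    try:
        fused_window, weights, metrics = optimize_frame(
            window, modalities, per_channel_contractions, state.ctx, cfg.fusion
        )
    except ValueError:
        frame_qc["rejected"] = True
        state.qc["frames"].append(frame_qc)
        state.t_processed_s = end_s
        return state

    seg_len = segs.shape[1]
    new_segment = fused_window[-seg_len:]
    state.ua = stitch(state.ua, new_segment, cfg.fusion)
    state.weights_history.append((state.ctx.k, weights))
    state.qc["frames"].append(frame_qc)
    state.ctx = FrameContext(k=state.ctx.k + 1, prev_weights=weights.w, prev_ua=fused_window)
    state.t_processed_s = end_s
    return state


def run_session(rec: RawRecording, cfg: PipelineConfig | None = None) -> SessionResult:
    """Run the full algorithm on a recording.

    Recordings shorter than calibration + one frame are processed with the
    calibration block spanning the whole recording (flagged). Raises when
    every channel fails the integrity screen during conditioning.
    """
    cfg = cfg or PipelineConfig()
    channels = condition_recording(rec, cfg.preproc)
    if not channels.kept:
        raise ValueError(
            "all channels rejected by the integrity screen; QC: "
            f"{[(c.label, c.features) for c in channels.channels]}"
        )
    duration = rec.duration_s
    state = PipelineState(channels=channels, cfg=cfg, motion_rms=_motion_level(rec))
    state.qc["rejected_channels"] = [c.label for c in channels.channels if not c.keep]

    calib_end = min(cfg.calibration_s, duration)
    if duration < cfg.calibration_s + cfg.frame_s:
        calib_end = duration
        state.qc["short_session"] = True
    state = run_frame(state, 0.0, calib_end)
    t = calib_end
    while t + cfg.frame_s <= duration + 1e-9:
        state = run_frame(state, t, t + cfg.frame_s)
        t += cfg.frame_s

    ua_values = state.ua if state.ua is not None else np.array([])
    # session-level adaptive baseline correction: junction alignment during
    # stitching accumulates a slow random level drift, so the final unitless
    # trace is re-zeroed by a causal moving minimum (120 s), preserving
    # contraction shapes while restoring the %-change-from-baseline scale
    ua_values = np.asarray(ua_values, dtype=float)
    if ua_values.size:
        ua_values = ua_values - _causal_moving_min(ua_values, MIN_WINDOW)
    ua = UATrace(ua_values)
    contrs = detect_contractions(ua.values, cfg.detector)
    for c in contrs:
        confidence_measures(c, ua.values, contrs, cfg.detector)
        contraction_scores(c, ua.values, cfg.detector)
    contrs = filter_outliers(contrs, cfg.detector)
    return SessionResult(
        ua=ua,
        weights_history=state.weights_history,
        contractions=contrs,
        qc=state.qc,
    )
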