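"""Heartbeat peak refinement into upward/downward amplitude series, and noise repair.

The contraction information lives in the slow amplitude modulation of the
maternal heartbeat peaks, so each conditioned channel is reduced to two
timestamped amplitude series: the *upward series* (local maxima at each beat)
and the *downward series* (local minima, found on the inverted signal so that
leads with downward-pointing R waves still contribute). Biopotential beats
also carry Q/R/S landmarks; acoustic beats are taken on whichever of the
S1/S2 bursts dominates, without labeling which ("heartbeat peaks").

A per-beat SNR (RMS of the QRS window over the mean inter-complex RMS) and a
template-correlation screen drive noise repair: isolated corrupt beats are
replaced by the channel median amplitude, longer runs are rejected, and
channels dominated by low-SNR stretches are removed for the frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "HeartbeatSeries",
    "BeatTemplate",
    "detect_initial_peaks",
    "refine_peaks",
    "beat_snr",
    "build_template",
    "repair_noise",
]

#: physiological inter-beat interval bounds (s); beats outside are flagged
IBI_MIN_S = 0.3
IBI_MAX_S = 2.0

#: refinement search half-window (s) by modality — QRS vs S1/S2 burst widths
SEARCH_HALF_S = {"biopotential": 0.06, "acoustic": 0.10}

#: QRS complex window for SNR: peak +/- 50 ms
QRS_HALF_S = 0.05

SNR_CAP = 1e6


@dataclass
class HeartbeatSeries:
    """Per-channel upward/downward heartbeat amplitude series.

    ``upward`` rows are (time_s, amplitude); ``downward`` rows preserve the
    sign of the minima. ``flags`` marks degenerate/noisy/edge beats; ``snr``
    holds per-beat SNR once computed.
    """

    channel: str
    upward: np.ndarray  # (n, 2)
    downward: np.ndarray  # (n, 2)
    qrs: np.ndarray | None = None  # (n, 3) Q, R, S sample indices (biopotential)
    flags: list[str] = field(default_factory=list)
    snr: np.ndarray | None = None
    removed: bool = False

    def __post_init__(self) -> None:
        self.upward = np.asarray(self.upward, dtype=float).reshape(-1, 2)
        self.downward = np.asarray(self.downward, dtype=float).reshape(-1, 2)
        if not self.flags:
            self.flags = [""] * len(self.upward)

    def __len__(self) -> int:
        return len(self.upward)

    @property
    def times(self) -> np.ndarray:
        return self.upward[:, 0]


@dataclass
class BeatTemplate:
    """Unit-energy averaged heartbeat waveform centered on the peak."""

    waveform: np.ndarray
    window: int
    n_beats: int

    def __post_init__(self) -> None:
        w = np.asarray(self.waveform, dtype=float)
        e = np.sqrt(np.sum(w**2))
        self.waveform = w / e if e > 0 else w


def detect_initial_peaks(
    x: np.ndarray, fs: float = 250.0, modality: str = "biopotential"
) -> np.ndarray:
    """Provisional maternal beat positions via energy-envelope thresholding.

    Stand-in for the upstream heart-rate module that normally supplies these:
    the squared signal is smoothed (80 ms moving average), and peaks are taken
    with a 0.3 s refractory period and an adaptive height floor. Returns
    sample indices; empty when nothing qualifies.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0 or np.ptp(x) == 0:
        return np.array([], dtype=int)
    env = np.convolve(x**2, np.ones(int(round(0.08 * fs))) / round(0.08 * fs), mode="same")
    floor = 0.2 * np.percentile(env, 95)
    if floor <= 0:
        return np.array([], dtype=int)
    peaks, _ = sps.find_peaks(env, height=floor, distance=int(round(IBI_MIN_S * fs)))
    return peaks


def refine_peaks(
    x: np.ndarray,
    provisional: np.ndarray,
    fs: float = 250.0,
    modality: str = "biopotential",
    channel: str = "",
) -> HeartbeatSeries:
    """Refine provisional beat times to exact extrema; split up/down series.

    For each provisional beat a search window (+/-60 ms biopotential,
    +/-100 ms acoustic) is scanned: the upward amplitude/time is the maximum
    in the window and the downward amplitude/time is the minimum of the
    window (equivalently the maximum of the inverted signal), sign preserved.
    For biopotential channels Q/R/S landmarks are stored (Q = minimum before
    R, S = minimum after R within the window). Refinement never moves a peak
    outside its window and is idempotent.
    """
    x = np.asarray(x, dtype=float)
    half = int(round(SEARCH_HALF_S.get(modality, 0.06) * fs))
    up, down, flags, qrs = [], [], [], []
    for p in np.asarray(provisional, dtype=int):
        lo, hi = p - half, p + half + 1
        flag = ""
        if lo < 0 or hi > x.size:
            lo, hi = max(0, lo), min(x.size, hi)
            flag = "edge"
        if hi <= lo:
            continue
        seg = x[lo:hi]
        if np.ptp(seg) == 0:
            flag = (flag + ",degenerate").strip(",")
            i_max = i_min = seg.size // 2
        else:
            i_max = int(np.argmax(seg))
            i_min = int(np.argmin(seg))
        r = lo + i_max
        up.append((r / fs, x[r]))
        down.append(((lo + i_min) / fs, x[lo + i_min]))
        flags.append(flag)
        if modality == "biopotential":
            q = lo + int(np.argmin(seg[: i_max + 1])) if i_max >= 0 else lo
            s = lo + i_max + int(np.argmin(seg[i_max:])) if i_max < seg.size else r
            qrs.append((q, r, s))
    up_a = np.array(up, dtype=float).reshape(-1, 2)
    down_a = np.array(down, dtype=float).reshape(-1, 2)
    # enforce strictly increasing times: drop duplicate refinements landing on
    # the same extremum
    if len(up_a) > 1:
        keep = np.concatenate([[True], np.diff(up_a[:, 0]) > 0])
        up_a, down_a = up_a[keep], down_a[keep]
        flags = [f for f, k in zip(flags, keep) if k]
        if qrs:
            qrs = [q for q, k in zip(qrs, keep) if k]
    ibi = np.diff(up_a[:, 0]) if len(up_a) > 1 else np.array([])
    for i, d in enumerate(ibi):
        if not (IBI_MIN_S <= d <= IBI_MAX_S):
            flags[i + 1] = (flags[i + 1] + ",ibi").strip(",")
    return HeartbeatSeries(
        channel=channel,
        upward=up_a,
        downward=down_a,
        qrs=np.array(qrs, dtype=int) if qrs else None,
        flags=flags,
    )


def beat_snr(x: np.ndarray, series: HeartbeatSeries, fs: float = 250.0) -> np.ndarray:
    """Per-beat SNR: RMS of the QRS complex over the mean inter-complex RMS."""
    x = np.asarray(x, dtype=float)
    n = len(series)
    if n < 2:
        raise ValueError("beat_snr requires >= 2 beats")
    half = int(round(QRS_HALF_S * fs))
    idx = np.round(series.times * fs).astype(int)
    windows = [(max(0, p - half), min(x.size, p + half + 1)) for p in idx]
    gap_rms = []
    for (a0, a1), (b0, b1) in zip(windows[:-1], windows[1:]):
        if b0 > a1:
            gap = x[a1:b0]
            gap_rms.append(float(np.sqrt(np.mean(gap**2))))
    mean_gap = float(np.mean(gap_rms)) if gap_rms else 0.0
    snr = np.empty(n)
    for i, (a, b) in enumerate(windows):
        c_rms = float(np.sqrt(np.mean(x[a:b] ** 2))) if b > a else 0.0
        if mean_gap == 0.0:
            snr[i] = SNR_CAP
            series.flags[i] = (series.flags[i] + ",snr_cap").strip(",")
        else:
            snr[i] = c_rms / mean_gap
    series.snr = snr
    return snr


def build_template(
    x: np.ndarray, series: HeartbeatSeries, fs: float = 250.0, min_beats: int = 4
) -> BeatTemplate | None:
    """Average heartbeat waveform over the frame, outlier-trimmed (10% tails).

    Returns None when fewer than ``min_beats`` full windows are available.
    """
    x = np.asarray(x, dtype=float)
    half = int(round(QRS_HALF_S * fs)) * 2  # template spans peak +/- 100 ms
    idx = np.round(series.times * fs).astype(int)
    segs = [x[p - half : p + half + 1] for p in idx if p - half >= 0 and p + half + 1 <= x.size]
    if len(segs) < min_beats:
        return None
    segs = np.array(segs)
    amp = segs.max(axis=1)
    lo, hi = np.percentile(amp, [10, 90])
    sel = (amp >= lo) & (amp <= hi)
    if sel.sum() < min_beats:
        sel = np.ones(len(segs), dtype=bool)
    return BeatTemplate(segs[sel].mean(axis=0), window=2 * half + 1, n_beats=int(sel.sum()))


def _template_corr(x: np.ndarray, p: int, template: BeatTemplate) -> float:
    half = (template.window - 1) // 2
    if p - half < 0 or p + half + 1 > x.size:
        return 1.0  # edge beats are not screened by the template
    seg = x[p - half : p + half + 1]
    s = seg - seg.mean()
    t = template.waveform - template.waveform.mean()
    denom = np.sqrt(np.sum(s**2) * np.sum(t**2))
    return float(np.sum(s * t) / denom) if denom > 0 else 0.0


def repair_noise(
    x: np.ndarray,
    series: HeartbeatSeries,
    template: BeatTemplate | None = None,
    motion_level: np.ndarray | None = None,
    fs: float = 250.0,
    corr_threshold: float = 0.6,
    snr_threshold: float = 1.5,
    motion_threshold: float = 5.0,
    max_run_replace: int = 3,
    max_low_snr_span_s: float = 30.0,
) -> HeartbeatSeries:
    """Mark, repair or reject noise-corrupted beats.

    Beats whose normalized correlation with the averaged template falls below
    ``corr_threshold`` are marked noisy; if none are, the per-beat SNR screen
    runs instead (below ``snr_threshold`` = noisy). Beats coincident with
    high maternal motion (``motion_level`` per 1 s above
    ``motion_threshold``) are treated as noisy. Isolated noisy beats
    (< ``max_run_replace`` consecutive) have their amplitudes replaced by the
    channel's median for the corresponding series; longer runs are rejected
    (dropped). A channel whose contiguous low-SNR span exceeds
    ``max_low_snr_span_s`` is removed entirely for the frame. Never increases
    the beat count.
    """
    x = np.asarray(x, dtype=float)
    n = len(series)
    if n == 0:
        series.removed = True
        return series
    noisy = np.zeros(n, dtype=bool)
    idx = np.round(series.times * fs).astype(int)
    if template is not None:
        for i, p in enumerate(idx):
            if _template_corr(x, p, template) < corr_threshold:
                noisy[i] = True
    if not noisy.any():
        snr = series.snr
        if snr is None and n >= 2:
            snr = beat_snr(x, series, fs)
        if snr is not None:
            noisy |= snr < snr_threshold
    if motion_level is not None and len(motion_level):
        sec = np.minimum(series.times.astype(int), len(motion_level) - 1)
        noisy |= np.asarray(motion_level)[sec] > motion_threshold

    # channel-level removal: contiguous low-SNR span longer than threshold
    if noisy.any():
        t = series.times
        run_start = None
        for i in range(n):
            if noisy[i] and run_start is None:
                run_start = t[i]
            elif not noisy[i] and run_start is not None:
                if t[i - 1] - run_start > max_low_snr_span_s:
                    series.removed = True
                run_start = None
        if run_start is not None and t[-1] - run_start > max_low_snr_span_s:
            series.removed = True
    if series.removed or noisy.all():
        series.removed = True
        return series

    # replace isolated noisy beats; reject (drop) longer runs
    med_up = float(np.median(series.upward[~noisy, 1]))
    med_down = float(np.median(series.downward[~noisy, 1]))
    drop = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        if noisy[i]:
            j = i
            while j < n and noisy[j]:
                j += 1
            if j - i < max_run_replace:
                for k in range(i, j):
                    series.upward[k, 1] = med_up
                    series.downward[k, 1] = med_down
                    series.flags[k] = (series.flags[k] + ",replaced").strip(",")
            else:
                drop[i:j] = True
            i = j
        else:
            i += 1
    if drop.any():
        keep = ~drop
        series.upward = series.upward[keep]
        series.downward = series.downward[keep]
        series.flags = [f for f, k in zip(series.flags, keep) if k]
        if series.snr is not None:
            series.snr = series.snr[keep]
        if series.qrs is not None and len(series.qrs) == n:
            series.qrs = series.qrs[keep]
    return series
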