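"""Contraction detection on UA-like traces, with confidence measures and scores.

Contractions are transient, roughly Gaussian bumps lasting tens of seconds to
a few minutes. The detector finds local maxima whose topographic prominence
exceeds an adaptive (relative) threshold, places onset/offset at the
prominence-base contour crossings nearest the peak, and discards intervals
outside a physiological duration band (30-180 s by default). Because the
threshold is relative, detection is invariant to positive rescaling of the
trace.

Three confidence measures (relative energy, peak-to-range, range ratio
against the non-contractile signal) screen out outlier detections, and two
scores (baseline delta and normalized prominence) feed the channel-weighting
stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "Contraction",
    "DetectorConfig",
    "detect_contractions",
    "confidence_measures",
    "contraction_scores",
    "filter_outliers",
    "contractions_to_mask",
]

CAP = 1e6  # value used when a measure's denominator is exactly zero


@dataclass
class DetectorConfig:
    """Tunable detection/screening parameters (all time units seconds).

    ``prominence_rel`` scales the frame's 90th-percentile value into the
    prominence floor; ``base_rel_height`` places onset/offset at the contour
    ``base_rel_height * prominence`` below the peak (slightly below 1.0 so
    the asymptotic tail of a near-Gaussian bump does not inflate durations).
    Confidence thresholds are calibration defaults; the screening formulas
    are fixed.
    """

    fs: float = 4.0
    prominence_rel: float = 0.3
    base_rel_height: float = 0.95
    min_duration_s: float = 30.0
    max_duration_s: float = 180.0
    pre_post_window_s: float = 30.0
    # confidence thresholds (filter_outliers)
    min_rel_energy: float = 0.005
    min_peak_to_range: float = 0.3
    min_range_ratio: float = 1.2
    #: absolute peak floor in trace units; 0 keeps screening scale-invariant.
    #: On the surrogate's fractional-change-from-baseline scale, 0.05 rejects
    #: sub-physiological ripples (a ~22% RMS change at the peak).
    min_peak_amplitude: float = 0.0


@dataclass
class Contraction:
    """One detected contraction interval with features, measures and scores."""

    onset_s: float
    offset_s: float
    peak_time_s: float
    peak_amplitude: float
    confidence: tuple[float, float, float] | None = None  # rel_energy, peak_to_range, range_ratio
    scores: tuple[float, float] | None = None  # baseline_delta_score, normalized_prominence
    kurtosis: float = 0.0
    energy: float = 0.0
    skewness: float = 0.0
    rise_time_s: float = 0.0
    fall_time_s: float = 0.0

    def __post_init__(self) -> None:
        if not (self.onset_s < self.peak_time_s < self.offset_s):
            # clamp the peak inside the open interval (discrete grids can tie)
            eps = 1e-9
            self.peak_time_s = min(max(self.peak_time_s, self.onset_s + eps), self.offset_s - eps)

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    @property
    def interval(self) -> tuple[float, float]:
        return (self.onset_s, self.offset_s)

    def feature_vector(self) -> np.ndarray:
        return np.array(
            [self.kurtosis, self.energy, self.skewness, self.rise_time_s, self.fall_time_s,
             self.duration_s]
        )


def detect_contractions(
    trace: np.ndarray, cfg: DetectorConfig | None = None, t0: float = 0.0
) -> list[Contraction]:
    """Detect candidate contractions on a non-negative 4 Hz trace.

    Returns contractions ordered by onset; empty for flat/empty traces.
    """
    cfg = cfg or DetectorConfig()
    x = np.asarray(trace, dtype=float).ravel()
    if x.size == 0 or np.ptp(x) == 0:
        return []
    floor = cfg.prominence_rel * float(np.percentile(x, 90))
    if floor <= 0:
        floor = cfg.prominence_rel * float(np.max(x))
    min_w = int(round(cfg.min_duration_s * cfg.fs))
    peaks, props = sps.find_peaks(x, prominence=floor, distance=max(1, min_w // 2))
    if peaks.size == 0:
        return []
    widths, _, left_ips, right_ips = sps.peak_widths(
        x,
        peaks,
        rel_height=cfg.base_rel_height,
        prominence_data=(props["prominences"], props["left_bases"], props["right_bases"]),
    )
    out: list[Contraction] = []
    for p, w, li, ri in zip(peaks, widths, left_ips, right_ips):
        dur = w / cfg.fs
        if not (cfg.min_duration_s <= dur <= cfg.max_duration_s):
            continue
        a, b = int(np.floor(li)), int(np.ceil(ri))
        seg = x[a : b + 1]
        # direct central-moment formulas (Fisher kurtosis, biased skewness)
        d = seg - seg.mean()
        m2 = float(np.mean(d**2))
        if m2 > 0:
            skew = float(np.mean(d**3)) / m2**1.5
            kurt = float(np.mean(d**4)) / m2**2 - 3.0
        else:
            skew = kurt = 0.0
        out.append(
            Contraction(
                onset_s=t0 + li / cfg.fs,
                offset_s=t0 + ri / cfg.fs,
                peak_time_s=t0 + p / cfg.fs,
                peak_amplitude=float(x[p]),
                kurtosis=kurt,
                energy=float(np.sum(seg**2)),
                skewness=skew,
                rise_time_s=(p - li) / cfg.fs,
                fall_time_s=(ri - p) / cfg.fs,
            )
        )
    out.sort(key=lambda c: c.onset_s)
    return out


def _sample_slice(c: Contraction, t0: float, fs: float, n: int) -> slice:
    a = int(np.floor((c.onset_s - t0) * fs))
    b = int(np.ceil((c.offset_s - t0) * fs)) + 1
    return slice(max(0, a), min(n, b))


def confidence_measures(
    c: Contraction,
    trace: np.ndarray,
    all_contractions: list[Contraction] | None = None,
    cfg: DetectorConfig | None = None,
    t0: float = 0.0,
) -> tuple[float, float, float]:
    """The three per-contraction confidence measures.

    1. relative energy: area under the curve over [onset, offset] divided by
       the total trace area;
    2. peak-to-range: mean of the samples in the upper third of the
       contraction's value range, divided by that range;
    3. range ratio: contraction value range over the value range of the
       non-contractile signal (trace outside all contraction intervals).

    A zero denominator yields the capped maximum (flag value ``CAP``).
    """
    cfg = cfg or DetectorConfig()
    x = np.asarray(trace, dtype=float).ravel()
    sl = _sample_slice(c, t0, cfg.fs, x.size)
    seg = x[sl]
    total_auc = float(np.sum(x))
    rel_energy = float(np.sum(seg)) / total_auc if total_auc > 0 else CAP
    rng = float(np.ptp(seg)) if seg.size else 0.0
    if rng > 0:
        upper = seg[seg >= seg.max() - rng / 3.0]
        peak_to_range = float(np.mean(upper)) / rng
    else:
        peak_to_range = CAP
    mask = np.ones(x.size, dtype=bool)
    for other in all_contractions or [c]:
        mask[_sample_slice(other, t0, cfg.fs, x.size)] = False
    out_rng = float(np.ptp(x[mask])) if mask.any() else 0.0
    range_ratio = rng / out_rng if out_rng > 0 else CAP
    c.confidence = (rel_energy, peak_to_range, range_ratio)
    return c.confidence


def contraction_scores(
    c: Contraction, trace: np.ndarray, cfg: DetectorConfig | None = None, t0: float = 0.0
) -> tuple[float, float] | None:
    """Baseline-delta score and normalized prominence.

    baseline_delta = (mean UA after - mean UA before) / peak amplitude;
    normalized prominence = (peak - mean of pre+post baseline) / peak.
    Pre/post windows default to 30 s, truncated at trace edges. Returns None
    (contraction discarded) for zero peak amplitude.
    """
    cfg = cfg or DetectorConfig()
    if c.peak_amplitude == 0:
        return None
    x = np.asarray(trace, dtype=float).ravel()
    w = int(round(cfg.pre_post_window_s * cfg.fs))
    a = int(np.floor((c.onset_s - t0) * cfg.fs))
    b = int(np.ceil((c.offset_s - t0) * cfg.fs)) + 1
    pre = x[max(0, a - w) : max(0, a)]
    post = x[min(x.size, b) : min(x.size, b + w)]
    m_pre = float(np.mean(pre)) if pre.size else 0.0
    m_post = float(np.mean(post)) if post.size else 0.0
    both = np.concatenate([pre, post])
    m_base = float(np.mean(both)) if both.size else 0.0
    delta = (m_post - m_pre) / c.peak_amplitude
    norm_prom = (c.peak_amplitude - m_base) / c.peak_amplitude
    c.scores = (delta, norm_prom)
    return c.scores


def filter_outliers(
    contractions: list[Contraction], cfg: DetectorConfig | None = None
) -> list[Contraction]:
    """Drop contractions failing any confidence threshold; order preserved."""
    cfg = cfg or DetectorConfig()
    out = []
    for c in contractions:
        if c.peak_amplitude < cfg.min_peak_amplitude:
            continue
        if c.confidence is None:
            out.append(c)
            continue
        e, p2r, rr = c.confidence
        if e >= cfg.min_rel_energy and p2r >= cfg.min_peak_to_range and rr >= cfg.min_range_ratio:
            out.append(c)
    return out


def contractions_to_mask(
    contractions: list[Contraction], n: int, fs: float = 4.0, t0: float = 0.0
) -> np.ndarray:
    """Boolean per-sample mask marking contraction intervals (for voting)."""
    mask = np.zeros(n, dtype=bool)
    for c in contractions:
        mask[_sample_slice(c, t0, fs, n)] = True
    return mask
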