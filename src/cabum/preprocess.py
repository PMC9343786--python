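"""Filtering and conditioning of biopotential and acoustic channels.

The conditioning chain mirrors the device's front end: signals are sampled at
1000 samples/s, low-pass filtered at 120 Hz and decimated 1:4 to the canonical
250 samples/s. Biopotential channels then pass a DC block, a recursive
power-line notch (stopband +/-0.5 Hz around 50 or 60 Hz) and an inverse
moving-average high-pass (201 ms Hamming-weighted sliding mean, subtracted).
Acoustic channels pass a 50 Hz low-pass and are replicated across five
high-pass cut-offs (10/15/20/25/30 Hz), broadening the spectral search for
heart-sound modulation; the 4 physical microphones thus become 20 working
channels. A sensor-contact integrity check screens channels on three features
(raw RMS, pre-processed SNR, heartbeat-peak energy vs background) with a
packaged linear classifier.

All filters are causal (no forward-backward filtering): the algorithm is
designed to run on 1-min frames immediately during data collection, and a
zero-phase pass would use future samples.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
import numpy as np
from scipy import signal

__all__ = [
    "PreprocConfig",
    "ConditionedChannel",
    "ChannelSet",
    "antialias_downsample",
    "dc_block",
    "notch_powerline",
    "inverse_moving_average",
    "acoustic_band_split",
    "integrity_features",
    "integrity_check",
    "condition_recording",
]


@dataclass
class PreprocConfig:
    """Constants of the conditioning chain.

    ``powerline_hz`` is a site property (50 Hz in Europe/Israel, 60 Hz in the
    US); the notch stopband spans ``powerline_hz`` +/- ``notch_halfwidth_hz``.
    ``inverse_ma_window_ms`` is the duration of the Hamming sliding-average
    window (forced to an odd sample count). The antialias low-pass cuts at
    ``antialias_hz`` before 1:``decimation`` downsampling.
    """

    powerline_hz: float = 50.0
    notch_halfwidth_hz: float = 0.5
    inverse_ma_window_ms: float = 201.0
    acoustic_lp_hz: float = 50.0
    acoustic_hp_cutoffs_hz: tuple[float, ...] = (10.0, 15.0, 20.0, 25.0, 30.0)
    antialias_hz: float = 120.0
    decimation: int = 4
    fs_raw: float = 1000.0
    fs: float = 250.0
    butter_order: int = 4
    # integrity screen
    integrity_enabled: bool = True
    integrity_coeffs: dict | None = None  # {"w": [...], "b": float, "mu": [...], "sd": [...]}

    def __post_init__(self) -> None:
        cuts = tuple(self.acoustic_hp_cutoffs_hz)
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("acoustic_hp_cutoffs_hz must be strictly increasing")
        if self.decimation < 1:
            raise ValueError("decimation must be >= 1")
        if self.inverse_ma_window_ms <= 0:
            raise ValueError("inverse_ma_window_ms must be positive")
        if self.powerline_hz >= self.fs / 2:
            raise ValueError("powerline frequency at or above Nyquist")


@dataclass
class ConditionedChannel:
    """One conditioned working channel at 250 samples/s."""

    data: np.ndarray
    modality: str  # "biopotential" | "acoustic"
    label: str
    band_hz: float | None = None  # high-pass cut-off tag for acoustic replicas
    raw_rms: float = 0.0
    keep: bool = True
    features: tuple[float, float, float] | None = None
    edge_flag: bool = False


@dataclass
class ChannelSet:
    """Conditioned working channels for one recording (<= 8 bio + 20 acoustic)."""

    channels: list[ConditionedChannel]
    fs: float = 250.0

    def __len__(self) -> int:
        return len(self.channels)

    @property
    def kept(self) -> list[ConditionedChannel]:
        return [c for c in self.channels if c.keep]


def antialias_downsample(x: np.ndarray, cfg: PreprocConfig | None = None) -> np.ndarray:
    """120 Hz low-pass then 1:4 decimation (1000 -> 250 samples/s).

    The low-pass is a causal Chebyshev-II design whose stopband starts at the
    post-decimation Nyquist (125 Hz), so aliased content is suppressed by
    >40 dB while the 0-100 Hz passband stays flat.
    """
    cfg = cfg or PreprocConfig()
    x = np.asarray(x, dtype=float)
    if cfg.decimation == 1:
        return x.copy()
    ws = cfg.fs_raw / cfg.decimation / 2.0  # stopband edge = output Nyquist
    sos = signal.cheby2(8, 45, ws, btype="low", fs=cfg.fs_raw, output="sos")
    y = signal.sosfilt(sos, x)
    return y[:: cfg.decimation]


def dc_block(x: np.ndarray) -> np.ndarray:
    """Subtract the signal average; idempotent."""
    x = np.asarray(x, dtype=float)
    return x - x.mean() if x.size else x.copy()


def notch_powerline(x: np.ndarray, cfg: PreprocConfig | None = None) -> np.ndarray:
    """Recursive (IIR) notch at the power-line frequency, stopband +/-0.5 Hz."""
    cfg = cfg or PreprocConfig()
    bw = 2.0 * cfg.notch_halfwidth_hz
    q = cfg.powerline_hz / bw
    b, a = signal.iirnotch(cfg.powerline_hz, q, fs=cfg.fs)
    return signal.lfilter(b, a, np.asarray(x, dtype=float))


def _odd_window_samples(ms: float, fs: float) -> int:
    n = int(round(ms / 1000.0 * fs))
    return n + 1 if n % 2 == 0 else n


def inverse_moving_average(
    x: np.ndarray, cfg: PreprocConfig | None = None
) -> tuple[np.ndarray, bool]:
    """High-pass by subtracting a Hamming-weighted sliding average (201 ms).

    The sliding average extracts the low-frequency components; subtracting it
    leaves the higher-frequency cardiac content. Edges use reflective padding;
    the returned flag is True when the signal was shorter than the window.
    """
    cfg = cfg or PreprocConfig()
    x = np.asarray(x, dtype=float)
    w = _odd_window_samples(cfg.inverse_ma_window_ms, cfg.fs)
    h = np.hamming(w)
    h /= h.sum()
    short = x.size < w
    half = w // 2
    xp = np.pad(x, half, mode="reflect") if x.size > 1 else np.repeat(x, w)
    avg = np.convolve(xp, h, mode="valid")
    avg = avg[: x.size]
    return x - avg, short


def acoustic_band_split(
    x: np.ndarray, cfg: PreprocConfig | None = None
) -> list[tuple[float, np.ndarray]]:
    """50 Hz low-pass, then five high-pass replicas at 10/15/20/25/30 Hz.

    Returns ``[(band_hz, signal), ...]`` — five spectrally distinct versions
    of one acoustic channel, all derived deterministically from the input.
    """
    cfg = cfg or PreprocConfig()
    x = np.asarray(x, dtype=float)
    sos_lp = signal.butter(cfg.butter_order, cfg.acoustic_lp_hz, "low", fs=cfg.fs, output="sos")
    low = signal.sosfilt(sos_lp, x)
    out = []
    for fc in cfg.acoustic_hp_cutoffs_hz:
        sos_hp = signal.butter(cfg.butter_order, fc, "high", fs=cfg.fs, output="sos")
        out.append((fc, signal.sosfilt(sos_hp, low)))
    return out


# ---------------------------------------------------------------------------
# sensor-contact integrity screen


def _load_default_coeffs() -> dict:
    with resources.files("cabum.data").joinpath("integrity_coeffs.json").open() as f:
        return json.load(f)


def integrity_features(
    raw: np.ndarray, conditioned: np.ndarray, peaks: np.ndarray | None, fs: float = 250.0
) -> tuple[float, float, float]:
    """The three contact-failure features.

    1. RMS of the raw signal (saturated / detached sensors show extreme RMS);
    2. SNR of the conditioned signal: heartbeat-band power around detected
       peaks over residual power (0 without peaks);
    3. heartbeat peak energy relative to background power.
    """
    raw = np.asarray(raw, dtype=float)
    cond = np.asarray(conditioned, dtype=float)
    rms_raw = float(np.sqrt(np.mean(raw**2))) if raw.size else 0.0
    if peaks is None or len(peaks) == 0:
        return (rms_raw, 0.0, 0.0)
    half = int(round(0.05 * fs))
    mask = np.zeros(cond.size, dtype=bool)
    idx = np.asarray(peaks, dtype=int)
    for p in idx:
        mask[max(0, p - half) : min(cond.size, p + half + 1)] = True
    in_pow = float(np.mean(cond[mask] ** 2)) if mask.any() else 0.0
    out_pow = float(np.mean(cond[~mask] ** 2)) if (~mask).any() else 0.0
    snr = in_pow / out_pow if out_pow > 0 else (1e6 if in_pow > 0 else 0.0)
    peak_energy = float(np.mean(cond[idx.clip(0, cond.size - 1)] ** 2))
    bg = float(np.mean(cond**2))
    ratio = peak_energy / bg if bg > 0 else 0.0
    return (rms_raw, snr, ratio)


def _score_features(
    feats: tuple[float, float, float], cfg: PreprocConfig, has_peaks: bool
) -> bool:
    coeffs = cfg.integrity_coeffs or _load_default_coeffs()
    w = np.asarray(coeffs["w"], dtype=float)
    mu = np.asarray(coeffs["mu"], dtype=float)
    sd = np.asarray(coeffs["sd"], dtype=float)
    x = np.log1p(np.asarray(feats, dtype=float))
    if not has_peaks:
        # low-confidence path: only RMS and SNR inform the decision
        x = x.copy()
        x[2] = mu[2]
    z = (x - mu) / np.where(sd > 0, sd, 1.0)
    return float(z @ w + coeffs["b"]) > 0


def integrity_check(
    raw: np.ndarray,
    conditioned: np.ndarray,
    peaks: np.ndarray | None,
    cfg: PreprocConfig | None = None,
) -> tuple[bool, tuple[float, float, float]]:
    """Classify a channel as usable (True) or contact-failed (False).

    Applies a packaged linear decision over standardized log-features; the
    coefficients were fit on a labeled synthetic corpus (see
    ``scripts/train_integrity.py``). A channel with zero variance after DC
    blocking is always rejected. Without peaks the decision uses features 1-2
    only (low-confidence path).
    """
    cfg = cfg or PreprocConfig()
    feats = integrity_features(raw, conditioned, peaks, cfg.fs)
    cond = np.asarray(conditioned, dtype=float)
    if cond.size == 0 or float(np.std(cond)) < 1e-12 * max(1.0, abs(float(np.mean(cond)))):
        return False, feats
    keep = _score_features(feats, cfg, has_peaks=peaks is not None and len(peaks) > 0)
    return keep, feats


def condition_recording(rec, cfg: PreprocConfig | None = None) -> ChannelSet:
    """Full conditioning of a RawRecording into the working ChannelSet.

    Decimates 1000 -> 250 samples/s if needed, applies the biopotential chain
    (DC block, notch, inverse moving average) to every biopotential channel
    and the acoustic chain (50 Hz LP + five HP replicas) to every acoustic
    channel. Integrity screening is applied when enabled.
    """
    cfg = cfg or PreprocConfig()
    from .heartbeats import detect_initial_peaks  # deferred: avoids cycle at import

    def _to_250(x: np.ndarray) -> np.ndarray:
        if rec.fs_signal == cfg.fs_raw:
            return antialias_downsample(x, cfg)
        if rec.fs_signal == cfg.fs:
            return np.asarray(x, dtype=float).copy()
        raise ValueError(f"unsupported input rate {rec.fs_signal}")

    if rec.fs_signal not in (cfg.fs_raw, cfg.fs):
        raise ValueError(f"unsupported input rate {rec.fs_signal}")
    if rec.fs_signal == cfg.fs:
        warnings.warn("input already at 250 samples/s; decimation skipped", stacklevel=2)

    channels: list[ConditionedChannel] = []
    bio_labels = [l for l in rec.channel_labels if l.startswith("BIO")]
    acu_labels = [l for l in rec.channel_labels if l.startswith("ACU")]
    for i in range(rec.n_biopotential):
        raw = rec.biopotential[i]
        x = _to_250(raw)
        x = dc_block(x)
        x = notch_powerline(x, cfg)
        x, edge = inverse_moving_average(x, cfg)
        label = bio_labels[i] if i < len(bio_labels) else f"BIO{i+1}"
        channels.append(
            ConditionedChannel(
                x, "biopotential", label, raw_rms=float(np.sqrt(np.mean(raw**2))),
                edge_flag=edge,
            )
        )
    for i in range(rec.n_acoustic):
        raw = rec.acoustic[i]
        x = _to_250(raw)
        x = dc_block(x)
        label = acu_labels[i] if i < len(acu_labels) else f"ACU{i+1}"
        for band, y in acoustic_band_split(x, cfg):
            channels.append(
                ConditionedChannel(
                    y, "acoustic", f"{label}@{band:g}Hz", band_hz=band,
                    raw_rms=float(np.sqrt(np.mean(raw**2))),
                )
            )

    if cfg.integrity_enabled:
        for ch in channels:
            if float(np.std(ch.data)) < 1e-12 * max(1.0, abs(float(np.mean(ch.data)))):
                ch.keep, ch.features = False, (ch.raw_rms, 0.0, 0.0)
                continue
            peaks = detect_initial_peaks(ch.data, cfg.fs, modality=ch.modality)
            _, feats = integrity_check(ch.data, ch.data, peaks, cfg)
            # raw-RMS feature uses the stored pre-conditioning value
            feats = (ch.raw_rms, feats[1], feats[2])
            ch.keep = _score_features(feats, cfg, has_peaks=peaks is not None and len(peaks) > 0)
            ch.features = feats
    return ChannelSet(channels, fs=cfg.fs)
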