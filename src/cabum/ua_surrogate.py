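"""Per-channel surrogate uterine-activity trace from heartbeat amplitude series.

Each channel's discrete beat amplitudes are turned into a continuous 4 Hz
envelope — the surrogate UA — through a fixed pipeline:

    cubic-spline interpolation (up and down series separately, 4 samples/s)
    -> up + |down| addition
    -> moving-RMS smoothing (101-sample window)
    -> baseline shift by a centered moving minimum (all values >= 0)
    -> squaring (non-linear contraction enhancement)

Squaring stretches the transient, near-Gaussian contraction bumps while
keeping inter-contraction baseline low, without moving peak positions. The
trace is unitless; per-channel scaling divides by the frame's median value
before enhancement so channels with different gains are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .heartbeats import HeartbeatSeries

__all__ = [
    "SurrogateTrace",
    "FS_SURROGATE",
    "interpolate_peaks",
    "combine_up_down",
    "moving_rms",
    "baseline_shift",
    "enhance_square",
    "prepare_surrogate",
]

FS_SURROGATE = 4.0  # samples/s of every surrogate-UA trace

#: moving-RMS window (samples at 4 Hz -> 25.25 s)
RMS_WINDOW = 101

#: centered moving-minimum window for the baseline shift: 120 s (481 samples
#: at 4 Hz) — longer than a typical contraction so contractions survive
MIN_WINDOW = 481


@dataclass
class SurrogateTrace:
    """Continuous unitless 4 Hz envelope standing in for UA on one channel."""

    channel: str
    values: np.ndarray
    t0: float = 0.0
    stage: str = "interpolated"  # interpolated -> smoothed -> shifted -> enhanced
    flags: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.flags = self.flags or []

    @property
    def fs(self) -> float:
        return FS_SURROGATE

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / FS_SURROGATE


def _grid(t_start: float, t_end: float) -> np.ndarray:
    n = int(np.floor((t_end - t_start) * FS_SURROGATE)) + 1
    return t_start + np.arange(n) / FS_SURROGATE


def _spline_eval(times: np.ndarray, amps: np.ndarray, grid: np.ndarray, flags: list[str]) -> np.ndarray:
    """Natural cubic spline through the knots, edge values held outside."""
    if len(times) < 2:
        return np.array([])
    if len(times) < 4:
        flags.append("linear_fallback")
        out = np.interp(grid, times, amps)
    else:
        cs = CubicSpline(times, amps, bc_type="natural")
        out = cs(grid)
        out[grid < times[0]] = amps[0]
        out[grid > times[-1]] = amps[-1]
    return out


def interpolate_peaks(
    series: HeartbeatSeries, span: tuple[float, float] | None = None
) -> tuple[SurrogateTrace, SurrogateTrace]:
    """Cubic-spline both amplitude series onto a common 4 Hz grid.

    With fewer than 4 beats a linear fallback is used (flagged); with fewer
    than 2 the traces are empty and the channel is dropped for the frame.
    No extrapolation: values beyond the outermost knots hold the edge value.
    """
    flags: list[str] = []
    t_up, a_up = series.upward[:, 0], series.upward[:, 1]
    t_dn, a_dn = series.downward[:, 0], series.downward[:, 1]
    if span is None:
        if len(t_up) < 2:
            e = SurrogateTrace(series.channel, np.array([]), flags=["dropped"])
            return e, e
        span = (t_up[0], t_up[-1])
    grid = _grid(*span)
    up = _spline_eval(t_up, a_up, grid, flags)
    order = np.argsort(t_dn)
    dn = _spline_eval(t_dn[order], a_dn[order], grid, flags)
    if up.size == 0 or dn.size == 0:
        e = SurrogateTrace(series.channel, np.array([]), t0=span[0], flags=["dropped"])
        return e, e
    return (
        SurrogateTrace(series.channel, up, t0=span[0], stage="interpolated", flags=flags),
        SurrogateTrace(series.channel, dn, t0=span[0], stage="interpolated", flags=list(flags)),
    )


def combine_up_down(up: SurrogateTrace, down: SurrogateTrace) -> SurrogateTrace:
    """Initial surrogate: upward series plus absolute downward series."""
    n = min(up.values.size, down.values.size)
    flags = list(up.flags or [])
    if up.values.size != down.values.size:
        flags.append("length_mismatch")
    vals = up.values[:n] + np.abs(down.values[:n])
    return SurrogateTrace(up.channel, vals, t0=up.t0, stage="interpolated", flags=flags)


def moving_rms(trace: SurrogateTrace, window: int = RMS_WINDOW) -> SurrogateTrace:
    """Centered sliding-window RMS smoothing (reflective edges)."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    x = trace.values
    flags = list(trace.flags or [])
    if x.size == 0:
        return SurrogateTrace(trace.channel, x, t0=trace.t0, stage="smoothed", flags=flags)
    if x.size < window:
        flags.append("short_global_rms")
        out = np.full_like(x, np.sqrt(np.mean(x**2)))
    else:
        half = window // 2
        xp = np.pad(x**2, half, mode="reflect")
        kern = np.ones(window) / window
        out = np.sqrt(np.clip(np.convolve(xp, kern, mode="valid"), 0.0, None))
    return SurrogateTrace(trace.channel, out, t0=trace.t0, stage="smoothed", flags=flags)


def baseline_shift(trace: SurrogateTrace, min_window: int = MIN_WINDOW) -> SurrogateTrace:
    """Subtract the centered moving minimum point-wise; result is >= 0."""
    if min_window % 2 == 0:
        raise ValueError("min_window must be odd")
    from scipy.ndimage import minimum_filter1d

    x = trace.values
    if x.size == 0:
        return SurrogateTrace(trace.channel, x, t0=trace.t0, stage="shifted", flags=trace.flags)
    mn = minimum_filter1d(x, size=min(min_window, 2 * x.size - 1), mode="reflect")
    return SurrogateTrace(trace.channel, x - mn, t0=trace.t0, stage="shifted", flags=trace.flags)


def enhance_square(trace: SurrogateTrace) -> SurrogateTrace:
    """Square the (non-negative) trace; order- and argmax-preserving."""
    if trace.values.size and trace.values.min() < 0:
        raise ValueError("enhance_square requires non-negative input (run baseline_shift first)")
    return SurrogateTrace(
        trace.channel, trace.values**2, t0=trace.t0, stage="enhanced", flags=trace.flags
    )


def prepare_surrogate(
    series: HeartbeatSeries,
    span: tuple[float, float] | None = None,
    scale: bool = True,
) -> SurrogateTrace:
    """Full surrogate pipeline for one channel.

    interpolate -> combine -> moving RMS -> baseline shift -> (median scale)
    -> square. ``scale`` divides by the frame's median value before
    enhancement so the unitless traces are cross-channel comparable.
    """
    up, dn = interpolate_peaks(series, span=span)
    if up.values.size == 0:
        return SurrogateTrace(series.channel, np.array([]), flags=["dropped"])
    t = combine_up_down(up, dn)
    t = moving_rms(t)
    # scaling unit: the frame's median smoothed level, so after the shift the
    # trace reads as fractional change from the channel's cardiac baseline
    # (division commutes with the moving-minimum subtraction)
    med = float(np.median(t.values)) if scale else 1.0
    t = baseline_shift(t)
    if scale and med > 0:
        t = SurrogateTrace(t.channel, t.values / med, t0=t.t0, stage=t.stage, flags=t.flags)
    return enhance_square(t)
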