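"""Ground-truthed synthetic sessions: modulated beat trains, noise, references.

The generator emulates the statistical structure the extraction algorithm
assumes: quasi-periodic maternal heartbeat trains — QRS-like wavelets on the
biopotential channels, paired S1/S2 tone bursts on the acoustic channels —
whose per-beat amplitudes are multiplicatively modulated by a slow,
non-periodic contraction envelope built from near-Gaussian bumps:

    a_i = A * (1 + d * env(t_i)),   env in [0, 1],  d = modulation depth.

Additive white noise, baseline wander, a power-line tone, scheduled
broadband motion artifacts with correlated accelerometer activity, and
sensor-dropout segments exercise the conditioning and repair stages. Paired
reference traces are generated: a faithful IUPC-like pressure trace (mmHg)
and a TOCO-like trace with per-contraction Bernoulli misses and attenuation,
emulating the external transducer's insensitivity to some contractions.

Everything is deterministic under a fixed seed. By default signals are
synthesized directly at the canonical 250 samples/s; ``fs_signal=1000``
produces raw-rate signals for exercising the antialias/decimation path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import ContractionAnnotations, RawRecording, ReferenceTrace

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "simulate_envelope",
    "simulate_biopotential",
    "simulate_acoustic",
    "simulate_references",
    "inject_artifacts",
    "simulate_session",
]

FS_ENV = 4.0


@dataclass
class SynthConfig:
    """Study conditions for a synthetic session.

    Defaults are the standard 30-min scenario: 8 near-Gaussian contractions
    (sigma 15-25 s, so base-to-base durations of roughly 70-120 s), heart
    rate 72 bpm with 2% beat-to-beat jitter, modulation depth 0.5, and
    modest additive noise. ``n_contractions`` fixes the event count; set it
    to None to draw counts from a Poisson process at
    ``contraction_rate_per_10min`` with the same minimum separation.
    """

    duration_s: float = 1800.0
    seed: int = 0
    # contraction envelope
    n_contractions: int | None = 8
    contraction_rate_per_10min: float = 4.0
    contraction_sigma_s: tuple[float, float] = (15.0, 25.0)
    min_separation_s: float = 150.0
    event_times_s: tuple[float, ...] | None = None
    # heartbeat train
    heart_rate_bpm: float = 72.0
    hr_jitter: float = 0.02
    modulation_depth: float = 0.5
    modulation_depth_bio: float | None = None  # None -> modulation_depth
    modulation_depth_acu: float | None = None
    # biopotential channels (microvolts)
    n_bio: int = 8
    bio_amp_uv: float = 100.0
    bio_gains: tuple[float, ...] = (1.0, 0.9, 1.1, 0.8, 1.2, 0.7, 1.0, 0.6)
    bio_inverted: tuple[int, ...] = (2, 5)  # channels with downward R waves
    bio_noise_uv: float = 5.0
    powerline_hz: float = 50.0
    powerline_uv: float = 5.0
    wander_uv: float = 10.0
    wander_hz: float = 0.05
    # acoustic channels (arbitrary units)
    n_acu: int = 4
    acu_amp: float = 1.0
    acu_gains: tuple[float, ...] = (1.0, 0.8, 1.1, 0.9)
    acu_noise: float = 0.05
    s1_hz: float = 25.0
    s2_hz: float = 35.0
    s1_s2_gap_s: float = 0.3
    # references
    iupc_scale_mmhg: float = 60.0
    iupc_baseline_mmhg: float = 10.0
    iupc_noise_mmhg: float = 0.5
    toco_miss_prob: float = 0.6
    toco_attenuation: tuple[float, float] = (0.5, 1.0)
    toco_wander_mmhg: float = 3.0
    # artifacts
    artifact_intervals_s: tuple[tuple[float, float], ...] = ()
    artifact_gain: float = 10.0
    dropout: tuple[tuple[str, int, float, float], ...] = ()  # (modality, ch, start, end)
    fs_signal: float = 250.0
    fs_motion: float = 50.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation depth must be in [0, 1]")
        if self.contraction_rate_per_10min < 0:
            raise ValueError("contraction rate must be >= 0")

    @property
    def d_bio(self) -> float:
        return self.modulation_depth if self.modulation_depth_bio is None else self.modulation_depth_bio

    @property
    def d_acu(self) -> float:
        return self.modulation_depth if self.modulation_depth_acu is None else self.modulation_depth_acu


@dataclass
class GroundTruth:
    """Everything the generator knows that the algorithm must recover."""

    envelope: np.ndarray  # 4 Hz, in [0, 1]
    intervals: ContractionAnnotations
    beat_times_s: np.ndarray | None = None
    bio_beat_amps: np.ndarray | None = None  # channels x beats
    acu_beat_amps: np.ndarray | None = None
    informative_bio: bool = True
    informative_acu: bool = True
    artifact_intervals_s: list[tuple[float, float]] = field(default_factory=list)
    dropout: list[tuple[str, int, float, float]] = field(default_factory=list)


def _event_times(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.event_times_s is not None:
        return np.asarray(cfg.event_times_s, dtype=float)
    margin = cfg.contraction_sigma_s[1] * 3.0
    lo, hi = margin, cfg.duration_s - margin
    if hi <= lo:
        return np.array([])
    if cfg.n_contractions is not None:
        # fixed count, uniform placement thinned to the minimum separation
        times: list[float] = []
        for _ in range(10_000):
            if len(times) >= cfg.n_contractions:
                break
            t = rng.uniform(lo, hi)
            if all(abs(t - u) >= cfg.min_separation_s for u in times):
                times.append(t)
        return np.sort(np.array(times))
    # Poisson process thinned to the minimum separation
    rate = cfg.contraction_rate_per_10min / 600.0
    if rate <= 0:
        return np.array([])
    t, times = lo, []
    while True:
        t += rng.exponential(1.0 / rate)
        if t >= hi:
            break
        if not times or t - times[-1] >= cfg.min_separation_s:
            times.append(t)
    return np.array(times)


def simulate_envelope(
    cfg: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, GroundTruth]:
    """Contraction envelope at 4 Hz: sum of Gaussian bumps, baseline 0.

    Truth intervals span each bump's +/- 2.45 sigma (the 5%-of-peak contour,
    matching the detector's base placement on a noiseless bump).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n = int(cfg.duration_s * FS_ENV)
    t = np.arange(n) / FS_ENV
    env = np.zeros(n)
    events = _event_times(cfg, rng)
    intervals = []
    half_width_sigmas = np.sqrt(2.0 * np.log(20.0))  # 5%-of-peak crossing
    for tc in events:
        sigma = rng.uniform(*cfg.contraction_sigma_s)
        amp = rng.uniform(0.7, 1.0)
        env += amp * np.exp(-0.5 * ((t - tc) / sigma) ** 2)
        hw = half_width_sigmas * sigma
        intervals.append((max(0.0, tc - hw), min(cfg.duration_s, tc + hw), tc, amp))
    if env.max() > 1.0:
        env /= env.max()
    truth = GroundTruth(envelope=env, intervals=ContractionAnnotations(intervals, source="truth"))
    return env, truth


def _beat_times(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    mean_ibi = 60.0 / cfg.heart_rate_bpm
    n_max = int(cfg.duration_s / mean_ibi) + 10
    ibis = mean_ibi * (1.0 + cfg.hr_jitter * rng.standard_normal(n_max))
    times = np.cumsum(np.clip(ibis, 0.3, 2.0))
    return times[times < cfg.duration_s - 0.2]


def _env_at(env: np.ndarray, times: np.ndarray) -> np.ndarray:
    grid = np.arange(env.size) / FS_ENV
    return np.interp(times, grid, env)


def _qrs_wavelet(fs: float) -> np.ndarray:
    """Mexican-hat-like QRS: ~30 ms central deflection with side lobes."""
    half = int(round(0.04 * fs))
    tt = np.arange(-half, half + 1) / fs
    s = 0.012
    x = tt / s
    return (1.0 - x**2) * np.exp(-0.5 * x**2)


def _burst(fs: float, freq: float, dur_s: float) -> np.ndarray:
    n = int(round(dur_s * fs))
    tt = np.arange(n) / fs
    return np.hanning(n) * np.sin(2.0 * np.pi * freq * tt)


def _add_at(sig: np.ndarray, kernel: np.ndarray, center: int, gain: float) -> None:
    half = kernel.size // 2
    a, b = center - half, center - half + kernel.size
    ka, kb = max(0, -a), kernel.size - max(0, b - sig.size)
    a, b = max(0, a), min(sig.size, b)
    if b > a:
        sig[a:b] += gain * kernel[ka:kb]


def simulate_biopotential(
    envelope: np.ndarray,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
    beats: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """8 amplitude-modulated QRS-train channels.

    Returns (channels, beat_times_s, beat_amps) where ``beat_amps`` is the
    channels x beats matrix of injected (signed) peak amplitudes. Channels in
    ``cfg.bio_inverted`` have negative polarity so the downward series
    carries their modulation. ``beats`` shares one heartbeat train across
    modalities; drawn from the generator when omitted.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    fs = cfg.fs_signal
    n = int(cfg.duration_s * fs)
    if beats is None:
        beats = _beat_times(cfg, rng)
    mod = 1.0 + cfg.d_bio * _env_at(envelope, beats)
    wavelet = _qrs_wavelet(fs)
    wavelet = wavelet / wavelet.max()
    t = np.arange(n) / fs
    channels = np.zeros((cfg.n_bio, n))
    amps = np.zeros((cfg.n_bio, beats.size))
    for c in range(cfg.n_bio):
        gain = cfg.bio_gains[c % len(cfg.bio_gains)] * cfg.bio_amp_uv
        pol = -1.0 if c in cfg.bio_inverted else 1.0
        sig = np.zeros(n)
        beat_gains = gain * mod * (1.0 + 0.01 * rng.standard_normal(beats.size))
        for bt, bg in zip(beats, beat_gains):
            _add_at(sig, wavelet, int(round(bt * fs)), pol * bg)
        amps[c] = pol * beat_gains
        sig += cfg.bio_noise_uv * rng.standard_normal(n)
        sig += cfg.wander_uv * np.sin(2 * np.pi * cfg.wander_hz * t + rng.uniform(0, 2 * np.pi))
        sig += cfg.powerline_uv * np.sin(2 * np.pi * cfg.powerline_hz * t + rng.uniform(0, 2 * np.pi))
        channels[c] = sig
    return channels, beats, amps


def simulate_acoustic(
    envelope: np.ndarray,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
    beats: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """4 amplitude-modulated S1/S2 burst channels (band content 10-50 Hz)."""
    rng = rng or np.random.default_rng(cfg.seed + 2)
    fs = cfg.fs_signal
    n = int(cfg.duration_s * fs)
    if beats is None:
        beats = _beat_times(cfg, rng)
    mod = 1.0 + cfg.d_acu * _env_at(envelope, beats)
    s1 = _burst(fs, cfg.s1_hz, 0.08)
    s2 = _burst(fs, cfg.s2_hz, 0.06)
    channels = np.zeros((cfg.n_acu, n))
    amps = np.zeros((cfg.n_acu, beats.size))
    for c in range(cfg.n_acu):
        gain = cfg.acu_gains[c % len(cfg.acu_gains)] * cfg.acu_amp
        sig = np.zeros(n)
        beat_gains = gain * mod * (1.0 + 0.01 * rng.standard_normal(beats.size))
        for bt, bg in zip(beats, beat_gains):
            _add_at(sig, s1, int(round(bt * fs)), bg)
            _add_at(sig, s2, int(round((bt + cfg.s1_s2_gap_s) * fs)), 0.6 * bg)
        amps[c] = beat_gains
        sig += cfg.acu_noise * rng.standard_normal(n)
        channels[c] = sig
    return channels, beats, amps


def simulate_references(
    envelope: np.ndarray,
    truth: GroundTruth,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ReferenceTrace, ReferenceTrace, ContractionAnnotations]:
    """IUPC-like (faithful, mmHg) and TOCO-like (lossy) reference traces.

    The TOCO trace misses each contraction with probability
    ``toco_miss_prob`` and attenuates the rest by a random factor, with added
    baseline wander; its annotations list only the surviving contractions.
    """
    rng = rng or np.random.default_rng(cfg.seed + 3)
    n = envelope.size
    t = np.arange(n) / FS_ENV
    iupc_vals = (
        cfg.iupc_baseline_mmhg
        + cfg.iupc_scale_mmhg * envelope
        + cfg.iupc_noise_mmhg * rng.standard_normal(n)
    )
    iupc = ReferenceTrace(iupc_vals, fs=FS_ENV, kind="IUPC")
    toco_env = np.zeros(n)
    kept = []
    for onset, offset, peak_t, amp in truth.intervals:
        keep = rng.uniform() >= cfg.toco_miss_prob
        att = rng.uniform(*cfg.toco_attenuation)
        sigma = (offset - onset) / (2.0 * np.sqrt(2.0 * np.log(20.0)))
        if keep:
            toco_env += att * amp * np.exp(-0.5 * ((t - peak_t) / sigma) ** 2)
            kept.append((onset, offset, peak_t, att * amp * cfg.iupc_scale_mmhg))
    toco_vals = (
        cfg.iupc_baseline_mmhg
        + cfg.iupc_scale_mmhg * toco_env
        + cfg.toco_wander_mmhg * np.sin(2 * np.pi * 0.003 * t + rng.uniform(0, 2 * np.pi))
        + cfg.iupc_noise_mmhg * rng.standard_normal(n)
    )
    toco = ReferenceTrace(toco_vals, fs=FS_ENV, kind="TOCO")
    return iupc, toco, ContractionAnnotations(kept, source="toco")


def inject_artifacts(
    bio: np.ndarray,
    acu: np.ndarray,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply scheduled motion artifacts and dropouts; synthesize motion channels.

    Motion-artifact intervals add broadband bursts (``artifact_gain`` x the
    channel RMS) to every signal channel and raise the accelerometer RMS
    within the interval well above baseline. Dropout intervals flatline the
    named channel. Returns (bio, acu, motion) with copies of the inputs.
    """
    rng = rng or np.random.default_rng(cfg.seed + 4)
    bio = bio.copy()
    acu = acu.copy()
    fs = cfg.fs_signal
    n_mot = int(cfg.duration_s * cfg.fs_motion)
    motion = 0.02 * rng.standard_normal((6, n_mot))
    motion[:3] += np.array([0.0, 0.0, 1.0])[:, None]  # gravity on z
    for a, b in cfg.artifact_intervals_s:
        sl = slice(int(a * fs), int(b * fs))
        for arr in (bio, acu):
            for c in range(arr.shape[0]):
                rms = float(np.sqrt(np.mean(arr[c] ** 2))) or 1.0
                arr[c, sl] += cfg.artifact_gain * rms * rng.standard_normal(sl.stop - sl.start)
        msl = slice(int(a * cfg.fs_motion), int(b * cfg.fs_motion))
        motion[:3, msl] += 1.0 * rng.standard_normal((3, msl.stop - msl.start))
    for modality, c, a, b in cfg.dropout:
        arr = bio if modality == "biopotential" else acu
        if 0 <= c < arr.shape[0]:
            arr[c, int(a * fs) : int(b * fs)] = 0.0
    return bio, acu, motion


def simulate_session(
    cfg: SynthConfig | None = None,
) -> tuple[RawRecording, GroundTruth, ReferenceTrace, ReferenceTrace, ContractionAnnotations]:
    """Full deterministic synthetic session.

    Returns (recording, truth, iupc, toco, toco_annotations); truth carries
    the injected envelope, contraction intervals, beat times and per-channel
    beat amplitudes.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    env, truth = simulate_envelope(cfg, rng)
    beats = _beat_times(cfg, rng)
    bio, _, bio_amps = simulate_biopotential(env, cfg, rng, beats=beats)
    acu, _, acu_amps = simulate_acoustic(env, cfg, rng, beats=beats)
    bio, acu, motion = inject_artifacts(bio, acu, cfg, rng)
    iupc, toco, toco_ann = simulate_references(env, truth, cfg, rng)
    truth.beat_times_s = beats
    truth.bio_beat_amps = bio_amps
    truth.acu_beat_amps = acu_amps
    truth.informative_bio = cfg.d_bio > 0
    truth.informative_acu = cfg.d_acu > 0
    truth.artifact_intervals_s = list(cfg.artifact_intervals_s)
    truth.dropout = list(cfg.dropout)
    rec = RawRecording(
        biopotential=bio,
        acoustic=acu,
        fs_signal=cfg.fs_signal,
        motion=motion,
        fs_motion=cfg.fs_motion,
        subject_id=f"synthetic-{cfg.seed}",
    )
    return rec, truth, iupc, toco, toco_ann
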