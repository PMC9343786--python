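"""Channel weighting and fusion of per-channel surrogate traces into one UA trace.

Each processing frame fuses the per-channel surrogate-UA traces by a weighted
average. The weights come from a multi-start gradient-descent (GD) scheme:
four channel subsets are seeded (biopotential-only, acoustic-only, all
channels, and a contractions-based subset chosen by K-means clustering of
per-channel contraction features), each with two initial weight vectors
(contraction-voting weights and all-equal 1/N weights). Every start point is
optimized by

    w_{n+1} = | w_n - gamma_n * J(w_n) |

with a sigmoidally decaying step size; the absolute value keeps weights
non-negative. The objective is built from the cost components

    C(w) = 1 + 1/2 * (E_cont/E_tot + A_cont/R)

computed on the temporary fused trace (contraction energy over total energy,
plus mean contraction amplitude over mean contraction range). The printed
cost grows with contraction prominence, so the default GD direction maximizes
the bracketed contrast term; the literal minimize-C behavior is available via
``cost_direction="literal_minimize"``.

Candidates compete on selection metrics (UA SNR, cost, mean contraction
confidence, and a difference index ``1 - max(0, spearman(prev, current))``),
then the winner's channels are enhanced (channels dissimilar from the fused
average are zeroed), blended with the previous frame's weights by a
contribution weight CW = 1/frame-number, and the fused segment is stitched
onto the session trace with baseline leveling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .contraction_id import (
    Contraction,
    DetectorConfig,
    confidence_measures,
    contractions_to_mask,
    detect_contractions,
)

__all__ = [
    "WeightVector",
    "GDSchedule",
    "CostComponents",
    "SelectionMetrics",
    "FrameContext",
    "FusionConfig",
    "build_subsets",
    "initial_weights_voting",
    "initial_weights_equal",
    "cost",
    "gd_optimize",
    "selection_metrics",
    "enhance_channels",
    "blend_previous",
    "select_final",
    "fuse",
    "stitch",
    "optimize_frame",
]

SUBSET_ORDER = ("biopotential", "acoustic", "combined", "contractions_based")


@dataclass
class WeightVector:
    """Non-negative per-channel weights; channels outside the subset stay 0."""

    w: np.ndarray
    subset: str = "combined"
    init: str = "all_equal"  # "voting" | "all_equal"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float).ravel()
        if np.any(self.w < 0):
            raise ValueError("weights must be non-negative")

    @property
    def active(self) -> np.ndarray:
        return self.w > 0

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.w))

    def normalized(self) -> "WeightVector":
        s = self.w.sum()
        if s <= 0:
            raise ValueError("cannot normalize an all-zero weight vector")
        return replace(self, w=self.w / s)


@dataclass
class GDSchedule:
    """Sigmoidally decaying step sizes gamma_n = gamma0 / (1 + exp((n-mid)/s))."""

    gamma0: float = 0.1
    n_mid: float = 15.0
    steepness: float = 3.0
    max_iter: int = 40
    tol: float = 1e-5
    fd_step: float = 1e-3  # central finite-difference step on normalized weights

    def step(self, n: int) -> float:
        return self.gamma0 / (1.0 + np.exp((n - self.n_mid) / self.steepness))

    def steps(self) -> np.ndarray:
        return np.array([self.step(n) for n in range(self.max_iter)])


@dataclass
class CostComponents:
    """Energy/amplitude components of the fusion cost on a temporary UA."""

    e_tot: float
    e_cont: float
    a_cont: float
    r: float

    @property
    def c(self) -> float:
        """C = 1 + 1/2 (E_cont/E_tot + A_cont/R); C = 1 with no contractions."""
        if self.e_cont == 0.0 or self.r == 0.0:
            return 1.0
        return 1.0 + 0.5 * (self.e_cont / self.e_tot + self.a_cont / self.r)

    @property
    def contrast(self) -> float:
        """The bracketed term 1/2 (E_cont/E_tot + A_cont/R); 0 without contractions."""
        return self.c - 1.0


@dataclass
class SelectionMetrics:
    """Metrics used in candidate competition."""

    ua_snr: float
    cost_value: float
    mean_confidence: float
    difference_index: float
    flags: list[str] = field(default_factory=list)


@dataclass
class FrameContext:
    """Carry-over state between processing frames (k is 1-based)."""

    k: int = 1
    prev_weights: np.ndarray | None = None
    prev_ua: np.ndarray | None = None

    @property
    def cw(self) -> float:
        """Contribution weight of the current frame: CW = 1/k."""
        return 1.0 / max(1, self.k)


@dataclass
class FusionConfig:
    """Configuration for subset construction, GD and selection."""

    cost_direction: str = "maximize_contrast"  # or "literal_minimize"
    kmeans_seed: int = 0
    kmeans_restarts: int = 10
    damping_prev: float = 0.6
    damping_curr: float = 0.4
    # channel-enhancement thresholds
    enh_min_corr: float = 0.5
    enh_slope_range: tuple[float, float] = (0.3, 3.0)
    enh_max_rel_residual: float = 0.5
    stitch_level_window: int = 10
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    schedule: GDSchedule = field(default_factory=GDSchedule)


# ---------------------------------------------------------------------------
# subsets and initial weights


def build_subsets(
    modalities: list[str],
    per_channel_contractions: list[list[Contraction]] | None,
    cfg: FusionConfig | None = None,
) -> list[WeightVector]:
    """Construct the four start-point subsets as equal-weight seeds.

    ``modalities`` tags each working channel "biopotential" or "acoustic".
    The contractions-based subset clusters the per-channel mean contraction
    features (kurtosis, energy, skewness, rise, fall, duration) into three
    K-means groups and keeps the cluster holding the largest number of
    per-feature maxima; with fewer than 3 channels carrying contractions it
    falls back to all channels (flagged).
    """
    cfg = cfg or FusionConfig()
    modalities = list(modalities)
    n = len(modalities)
    if n == 0:
        raise ValueError("no working channels")
    bio = np.array([m == "biopotential" for m in modalities])
    acu = np.array([m == "acoustic" for m in modalities])
    out: list[WeightVector] = []
    for name, mask in (("biopotential", bio), ("acoustic", acu), ("combined", np.ones(n, bool))):
        if mask.any():
            w = np.where(mask, 1.0 / mask.sum(), 0.0)
            out.append(WeightVector(w, subset=name))

    # contractions-based subset via K-means on per-channel mean features
    flags: list[str] = []
    feat_rows, feat_idx = [], []
    for i, contrs in enumerate(per_channel_contractions or []):
        if contrs:
            feat_rows.append(np.mean([c.feature_vector() for c in contrs], axis=0))
            feat_idx.append(i)
    if len(feat_rows) < 3:
        mask = np.ones(n, bool)
        flags.append("contractions_fallback_all")
    else:
        from sklearn.cluster import KMeans

        X = np.asarray(feat_rows)
        mu, sd = X.mean(axis=0), X.std(axis=0)
        Z = (X - mu) / np.where(sd > 0, sd, 1.0)
        km = KMeans(
            n_clusters=min(3, len(feat_rows)),
            n_init=cfg.kmeans_restarts,
            random_state=cfg.kmeans_seed,
        ).fit(Z)
        centers = km.cluster_centers_
        # best cluster: the one holding the maximal center value for the most features
        wins = np.bincount(np.argmax(centers, axis=0), minlength=centers.shape[0])
        best = int(np.argmax(wins))
        chosen = [feat_idx[j] for j in range(len(feat_idx)) if km.labels_[j] == best]
        mask = np.zeros(n, bool)
        mask[chosen] = True
    w = np.where(mask, 1.0 / mask.sum(), 0.0)
    out.append(WeightVector(w, subset="contractions_based", flags=flags))
    return out


def vote_fractions(masks: np.ndarray) -> np.ndarray:
    """Per-channel contraction vote fractions from per-sample boolean masks.

    For channel c the fraction of the *other* voting channels marking a
    contraction, averaged over the samples where c itself marks one; 0 for a
    channel without contraction samples, 1 for a lone voter.
    """
    masks = np.atleast_2d(np.asarray(masks, dtype=bool))
    n_ch = masks.shape[0]
    votes_total = masks.sum(axis=0)
    out = np.zeros(n_ch)
    for c in range(n_ch):
        own = masks[c]
        if not own.any():
            continue
        if n_ch == 1:
            out[c] = 1.0
        else:
            out[c] = float(np.mean((votes_total[own] - 1) / (n_ch - 1)))
    return out


def initial_weights_voting(
    subset: WeightVector,
    per_channel_contractions: list[list[Contraction]],
    traces: np.ndarray,
    fs: float = 4.0,
    prev_weights: np.ndarray | None = None,
    cfg: FusionConfig | None = None,
) -> WeightVector:
    """Contraction-voting initial weights (with 0.6/0.4 damping beyond calibration).

    Per channel, the vote fraction is the fraction of the other voting
    channels that agree a contraction exists, averaged over the channel's own
    contraction samples. The reliability term is the mean, over the channel's
    contractions, of contraction area over the channel's total signal area.
    The initial weight is the mean of the two; for frames beyond the first,
    w01 = 0.6 * w_previous + 0.4 * w_current.
    """
    cfg = cfg or FusionConfig()
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n_ch, n_s = traces.shape
    active = np.flatnonzero(subset.w > 0)
    masks = np.zeros((n_ch, n_s), dtype=bool)
    for i in active:
        masks[i] = contractions_to_mask(per_channel_contractions[i], n_s, fs=fs)
    if not masks.any():
        eq = initial_weights_equal(subset)
        eq.flags.append("voting_fallback_equal")
        eq.init = "voting"
        return eq
    w = np.zeros(n_ch)
    fracs = vote_fractions(masks[active])
    for k, i in enumerate(active):
        vote_frac = float(fracs[k])
        total_auc = float(np.sum(np.abs(traces[i])))
        if per_channel_contractions[i] and total_auc > 0:
            rel = [
                float(np.sum(traces[i, contractions_to_mask([c], n_s, fs=fs)])) / total_auc
                for c in per_channel_contractions[i]
            ]
            reliability = float(np.mean(rel))
        else:
            reliability = 0.0
        w[i] = 0.5 * (vote_frac + reliability)
    out = WeightVector(w, subset=subset.subset, init="voting")
    if prev_weights is not None:
        out = replace(
            out, w=np.abs(cfg.damping_prev * np.asarray(prev_weights) + cfg.damping_curr * out.w)
        )
        out.w[~subset.active] = 0.0
    if out.w.sum() <= 0:
        eq = initial_weights_equal(subset)
        eq.flags.append("voting_fallback_equal")
        eq.init = "voting"
        return eq
    return out


def initial_weights_equal(subset: WeightVector) -> WeightVector:
    """All-equal initial weights w02 = 1/N over the subset's N channels."""
    n = subset.n_active
    if n == 0:
        raise ValueError("empty subset")
    w = np.where(subset.active, 1.0 / n, 0.0)
    return WeightVector(w, subset=subset.subset, init="all_equal")


# ---------------------------------------------------------------------------
# cost and gradient descent


def fuse(w: WeightVector | np.ndarray, traces: np.ndarray) -> np.ndarray:
    """Weighted average of the channel traces: UA = sum_c w_c * trace_c."""
    wv = w.w if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    return wv @ traces


def cost(
    w: WeightVector | np.ndarray,
    traces: np.ndarray,
    detector: DetectorConfig | None = None,
) -> CostComponents:
    """Cost components of the temporary UA fused with (normalized) weights w.

    E_tot is the energy of the fused trace; contraction detection runs on it
    to give the contraction energy E_cont, mean peak amplitude A_cont and
    mean per-contraction range R. With no detections E_cont = A_cont = 0 and
    C = 1. E_tot = 0 raises (candidate discarded upstream).
    """
    detector = detector or DetectorConfig()
    wv = w.w if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    s = wv.sum()
    if s <= 0:
        raise ValueError("all-zero weights")
    ua = fuse(wv / s, traces)
    e_tot = float(np.sum(ua**2))
    if e_tot == 0.0:
        raise ValueError("zero-energy fused trace")
    contrs = detect_contractions(ua, detector)
    contrs = [c for c in contrs if c.peak_amplitude >= detector.min_peak_amplitude]
    if not contrs:
        return CostComponents(e_tot=e_tot, e_cont=0.0, a_cont=0.0, r=0.0)
    fs = detector.fs
    e_cont, amps, rngs = 0.0, [], []
    for c in contrs:
        a = max(0, int(np.floor(c.onset_s * fs)))
        b = min(ua.size, int(np.ceil(c.offset_s * fs)) + 1)
        seg = ua[a:b]
        e_cont += float(np.sum(seg**2))
        amps.append(c.peak_amplitude)
        rngs.append(float(np.ptp(seg)) if seg.size else 0.0)
    return CostComponents(
        e_tot=e_tot,
        e_cont=min(e_cont, e_tot),
        a_cont=float(np.mean(amps)),
        r=float(np.mean(rngs)),
    )


def _objective(w: np.ndarray, traces: np.ndarray, cfg: FusionConfig) -> float:
    try:
        comp = cost(w, traces, cfg.detector)
    except ValueError:
        return np.inf
    if cfg.cost_direction == "literal_minimize":
        return comp.c
    return -comp.contrast  # maximize the contraction-contrast term


def gd_optimize(
    w0: WeightVector,
    traces: np.ndarray,
    sched: GDSchedule | None = None,
    cfg: FusionConfig | None = None,
    objective=None,
) -> WeightVector:
    """Gradient descent w_{n+1} = |w_n - gamma_n * J(w_n)| on the objective.

    The gradient is estimated by central finite differences over the active
    (non-zero-subset) weights; zeroed channels never move. Stops at the
    iteration cap or when the weight change drops below the tolerance. A
    non-finite gradient aborts the iteration and returns the last valid
    weights (flagged). ``objective(w, traces) -> float`` replaces the
    contraction-contrast objective when given.
    """
    cfg = cfg or FusionConfig()
    sched = sched or cfg.schedule
    obj = objective if objective is not None else (lambda w_, t_: _objective(w_, t_, cfg))
    w = w0.w.copy()
    active = np.flatnonzero(w0.active)
    flags = list(w0.flags)
    h = sched.fd_step
    for n in range(sched.max_iter):
        g = np.zeros_like(w)
        base_s = w.sum()
        if base_s <= 0:
            flags.append("collapsed")
            break
        ok = True
        for i in active:
            wp, wm = w.copy(), w.copy()
            wp[i] += h
            wm[i] = max(0.0, wm[i] - h)
            denom = wp[i] - wm[i]
            if denom <= 0:
                continue
            fp = obj(wp, traces)
            fm = obj(wm, traces)
            if not (np.isfinite(fp) and np.isfinite(fm)):
                ok = False
                break
            g[i] = (fp - fm) / denom
        if not ok:
            flags.append("nonfinite_gradient")
            break
        step = sched.step(n)
        w_new = np.abs(w - step * g)
        w_new[~w0.active] = 0.0
        delta = float(np.max(np.abs(w_new - w)))
        w = w_new
        if delta < sched.tol:
            break
    return WeightVector(w, subset=w0.subset, init=w0.init, flags=flags)


# ---------------------------------------------------------------------------
# selection


def selection_metrics(
    candidate_ua: np.ndarray,
    cost_components: CostComponents,
    contractions: list[Contraction],
    prev_ua: np.ndarray | None = None,
    fs: float = 4.0,
) -> SelectionMetrics:
    """Metrics for candidate competition.

    UA SNR is contraction power over non-contraction power on the candidate
    trace; the difference index is 1 - max(0, spearman(prev, current)) and 0
    without a previous UA (constant candidates get index 1, flagged).
    """
    ua = np.asarray(candidate_ua, dtype=float).ravel()
    flags: list[str] = []
    mask = contractions_to_mask(contractions, ua.size, fs=fs)
    if mask.any() and (~mask).any():
        p_in = float(np.mean(ua[mask] ** 2))
        p_out = float(np.mean(ua[~mask] ** 2))
        ua_snr = p_in / p_out if p_out > 0 else np.inf
    else:
        ua_snr = 0.0
    confs = [np.mean(c.confidence) for c in contractions if c.confidence is not None]
    mean_conf = float(np.mean(confs)) if confs else 0.0
    if prev_ua is None:
        diff_idx = 0.0
    else:
        prev = np.asarray(prev_ua, dtype=float).ravel()
        m = min(prev.size, ua.size)
        if m < 2 or np.ptp(ua[:m]) == 0 or np.ptp(prev[:m]) == 0:
            diff_idx = 1.0
            flags.append("constant_segment")
        else:
            rho = float(stats.spearmanr(prev[:m], ua[:m]).statistic)
            diff_idx = 1.0 - max(0.0, rho)
    return SelectionMetrics(
        ua_snr=ua_snr,
        cost_value=cost_components.c,
        mean_confidence=mean_conf,
        difference_index=diff_idx,
        flags=flags,
    )


def _beats(a: SelectionMetrics, b: SelectionMetrics, cfg: FusionConfig) -> int:
    """Count of the four metrics on which candidate a beats candidate b."""
    cost_better = (
        (a.cost_value < b.cost_value)
        if cfg.cost_direction == "literal_minimize"
        else (a.cost_value > b.cost_value)
    )
    wins = int(a.ua_snr > b.ua_snr)
    wins += int(cost_better)
    wins += int(a.mean_confidence > b.mean_confidence)
    wins += int(a.difference_index < b.difference_index)
    return wins


def select_final(
    candidates: list[tuple[WeightVector, SelectionMetrics]],
    cfg: FusionConfig | None = None,
) -> tuple[WeightVector, SelectionMetrics]:
    """Tournament selection of the final weight vector.

    Within each subset the voting-init and equal-init candidates compete
    first; the subset winners then compete pairwise in the fixed order
    biopotential < acoustic < combined < contractions-based. A candidate
    wins a pairing by taking the majority of the four metrics; ties break to
    lower cost, then lower difference index, then earlier subset order.
    """
    cfg = cfg or FusionConfig()
    if not candidates:
        raise ValueError("no candidates")

    def duel(a, b):
        wa, ma = a
        wb, mb = b
        na, nb = _beats(ma, mb, cfg), _beats(mb, ma, cfg)
        if na != nb:
            return a if na > nb else b
        if ma.cost_value != mb.cost_value:
            return a if ma.cost_value < mb.cost_value else b
        if ma.difference_index != mb.difference_index:
            return a if ma.difference_index < mb.difference_index else b
        oa = SUBSET_ORDER.index(wa.subset) if wa.subset in SUBSET_ORDER else 99
        ob = SUBSET_ORDER.index(wb.subset) if wb.subset in SUBSET_ORDER else 99
        return a if oa <= ob else b

    by_subset: dict[str, list] = {}
    for cand in candidates:
        by_subset.setdefault(cand[0].subset, []).append(cand)
    winners = []
    for name in SUBSET_ORDER:
        group = by_subset.pop(name, [])
        if group:
            best = group[0]
            for other in group[1:]:
                best = duel(best, other)
            winners.append(best)
    for group in by_subset.values():  # subsets outside the fixed order, if any
        best = group[0]
        for other in group[1:]:
            best = duel(best, other)
        winners.append(best)
    final = winners[0]
    for other in winners[1:]:
        final = duel(final, other)
    return final


def enhance_channels(
    w: WeightVector,
    traces: np.ndarray,
    cfg: FusionConfig | None = None,
) -> WeightVector:
    """Zero channels dissimilar from the fused average; rescale; one GD step.

    Per active channel three similarity metrics against the weighted average
    are tested: Pearson correlation (>= threshold), the slope of the
    first-degree polynomial fit (within range), and the relative residual of
    that fit (<= threshold). Channels failing any test are zeroed; surviving
    weights are rescaled to sum 1 and one further GD iteration is applied.
    If every channel fails, the pre-enhancement weights are returned flagged.
    """
    cfg = cfg or FusionConfig()
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    wn = w.normalized()
    ua = fuse(wn, traces)
    keep = np.zeros_like(wn.w, dtype=bool)
    ua_c = ua - ua.mean()
    ua_ss = float(np.sum(ua_c**2))
    for i in np.flatnonzero(wn.active):
        x = traces[i]
        x_c = x - x.mean()
        x_ss = float(np.sum(x_c**2))
        if x_ss == 0 or ua_ss == 0:
            continue
        corr = float(np.sum(x_c * ua_c) / np.sqrt(x_ss * ua_ss))
        slope = float(np.sum(x_c * ua_c) / x_ss)  # first parameter of the degree-1 fit
        resid = ua - (slope * x_c + ua.mean())
        rel_resid = float(np.sqrt(np.mean(resid**2)) / (np.sqrt(np.mean(ua_c**2)) or 1.0))
        lo, hi = cfg.enh_slope_range
        if corr >= cfg.enh_min_corr and lo <= slope <= hi and rel_resid <= cfg.enh_max_rel_residual:
            keep[i] = True
    if not keep.any():
        out = replace(wn, flags=wn.flags + ["enhancement_reverted"])
        return out
    w2 = np.where(keep, wn.w, 0.0)
    w2 /= w2.sum()
    seed = WeightVector(w2, subset=w.subset, init=w.init, flags=list(w.flags))
    one_step = replace(cfg.schedule, max_iter=1)
    out = gd_optimize(seed, traces, one_step, cfg)
    return out.normalized() if out.w.sum() > 0 else seed


def blend_previous(w: WeightVector, ctx: FrameContext) -> WeightVector:
    """Blend with previous-frame weights: out = CW*w_curr + (1-CW)*w_prev, CW=1/k."""
    if ctx.k <= 1 or ctx.prev_weights is None:
        flags = list(w.flags)
        if ctx.k > 1 and ctx.prev_weights is None:
            flags = flags + ["cw_forced_1"]
        return replace(w, flags=flags)
    cw = ctx.cw
    blended = cw * w.w + (1.0 - cw) * np.asarray(ctx.prev_weights, dtype=float)
    return WeightVector(blended, subset=w.subset, init=w.init, flags=list(w.flags))


def stitch(
    prev_ua: np.ndarray | None,
    new_segment: np.ndarray,
    cfg: FusionConfig | None = None,
) -> np.ndarray:
    """Append a new UA segment with baseline leveling and junction alignment.

    The baseline correction factor is the difference between the medians of
    the junction-adjacent windows of the concatenated signal, applied to the
    new segment only; the segment is then offset so its first sample matches
    the last sample of the existing trace (zero junction jump). First frame:
    returned unchanged.
    """
    cfg = cfg or FusionConfig()
    seg = np.asarray(new_segment, dtype=float).ravel()
    if prev_ua is None or len(prev_ua) == 0:
        return seg.copy()
    prev = np.asarray(prev_ua, dtype=float).ravel()
    wd = min(cfg.stitch_level_window, prev.size, seg.size)
    level = float(np.median(prev[-wd:]) - np.median(seg[:wd])) if wd else 0.0
    seg = seg + level
    seg = seg + (prev[-1] - seg[0])
    return np.concatenate([prev, seg])


# ---------------------------------------------------------------------------
# frame-level driver


def optimize_frame(
    traces: np.ndarray,
    modalities: list[str],
    per_channel_contractions: list[list[Contraction]],
    ctx: FrameContext,
    cfg: FusionConfig | None = None,
) -> tuple[np.ndarray, WeightVector, SelectionMetrics]:
    """Full weighting pipeline for one frame: subsets -> GD -> selection ->
    enhancement -> CW blending -> fusion. Returns (segment, weights, metrics).
    """
    cfg = cfg or FusionConfig()
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    subsets = build_subsets(modalities, per_channel_contractions, cfg)
    candidates: list[tuple[WeightVector, SelectionMetrics]] = []
    for subset in subsets:
        seeds = [
            initial_weights_voting(
                subset,
                per_channel_contractions,
                traces,
                fs=cfg.detector.fs,
                prev_weights=ctx.prev_weights if ctx.k > 1 else None,
                cfg=cfg,
            ),
            initial_weights_equal(subset),
        ]
        for seed in seeds:
            if seed.w.sum() <= 0:
                continue
            opt = gd_optimize(seed, traces, cfg.schedule, cfg)
            if opt.w.sum() <= 0:
                continue
            try:
                comp = cost(opt, traces, cfg.detector)
            except ValueError:
                continue
            ua = fuse(opt.normalized(), traces)
            contrs = detect_contractions(ua, cfg.detector)
            for c in contrs:
                confidence_measures(c, ua, contrs, cfg.detector)
            m = selection_metrics(ua, comp, contrs, prev_ua=ctx.prev_ua, fs=cfg.detector.fs)
            candidates.append((opt, m))
    if not candidates:
        raise ValueError("no viable weight candidates in frame")
    best_w, _ = select_final(candidates, cfg)
    best_w = enhance_channels(best_w, traces, cfg)
    best_w = blend_previous(best_w, ctx)
    best_w = best_w.normalized()
    segment = fuse(best_w, traces)
    comp = cost(best_w, traces, cfg.detector)
    contrs = detect_contractions(segment, cfg.detector)
    for c in contrs:
        confidence_measures(c, segment, contrs, cfg.detector)
    metrics = selection_metrics(segment, comp, contrs, prev_ua=ctx.prev_ua, fs=cfg.detector.fs)
    return segment, best_w, metrics
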