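"""Agreement evaluation: contraction matching, PPA/FDR statistics, trace correlation.

A test-device contraction matches a reference contraction when their temporal
overlap is at least 30 s or 50% of the reference contraction's duration,
whichever is shorter. Matching is one-to-one: when several test contractions
overlap one reference contraction, the pair with maximal overlap wins
(enforced greedily over all candidate pairs in descending overlap order,
which on interval sets of this size equals exhaustive maximum-overlap
assignment).

Positive percent agreement (PPA, the sensitivity analogue) is computed per
patient and pooled with weights n_ref_i / sum(n_ref) — algebraically the
pooled ratio sum(matched)/sum(ref). The false discovery rate (FDR) is the
pooled fraction of unmatched test contractions over all test detections; a
per-patient weighted variant is available. Waveform correspondence uses the
Pearson correlation per session, averaged over sessions. Sessions qualify
for antepartum analysis only when the reference TOCO trace shows at least
one significant contraction (peak >= 15 mmHg above local baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .contraction_id import DetectorConfig, detect_contractions
from .signal_io import ContractionAnnotations, ReferenceTrace

__all__ = [
    "MatchConfig",
    "MatchResult",
    "AgreementStats",
    "overlap_s",
    "match_contractions",
    "ppa",
    "fdr",
    "trace_correlation",
    "significant_session_filter",
    "evaluate_sessions",
]


@dataclass
class MatchConfig:
    """Matching-rule parameters.

    ``duration_ref``: whose duration anchors the 50% criterion — "reference"
    (default), "test", or "min" (the shorter of the two).
    """

    overlap_floor_s: float = 30.0
    overlap_frac: float = 0.5
    duration_ref: str = "reference"


@dataclass
class MatchResult:
    """One-to-one matching between test and reference contraction lists."""

    pairs: list[tuple[int, int, float]] = field(default_factory=list)  # (test, ref, overlap_s)
    false_discoveries: list[int] = field(default_factory=list)  # unmatched test indices
    misses: list[int] = field(default_factory=list)  # unmatched reference indices
    patient: str = ""

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


@dataclass
class AgreementStats:
    ppa_percent: float
    ppa_sd: float
    fdr_percent: float
    fdr_sd: float
    pearson_r: float | None
    n_ref: int
    n_test: int
    n_matched: int


def overlap_s(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Temporal overlap of two half-open intervals in seconds (>= 0)."""
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


def _required_overlap(
    ref_iv: tuple[float, float], test_iv: tuple[float, float], cfg: MatchConfig
) -> float:
    d_ref = ref_iv[1] - ref_iv[0]
    d_test = test_iv[1] - test_iv[0]
    if cfg.duration_ref == "test":
        d = d_test
    elif cfg.duration_ref == "min":
        d = min(d_ref, d_test)
    else:
        d = d_ref
    return min(cfg.overlap_floor_s, cfg.overlap_frac * d)


def match_contractions(
    test: ContractionAnnotations,
    ref: ContractionAnnotations,
    cfg: MatchConfig | None = None,
    patient: str = "",
) -> MatchResult:
    """One-to-one matching of test contractions to reference contractions.

    Candidate pairs must overlap by at least min(30 s, 50% of the reference
    duration); assignment is greedy by descending overlap, ties broken by
    (ref index, test index) for determinism.
    """
    cfg = cfg or MatchConfig()
    test_iv = [(iv[0], iv[1]) for iv in test.intervals]
    ref_iv = [(iv[0], iv[1]) for iv in ref.intervals]
    cands: list[tuple[float, int, int]] = []
    for j, r in enumerate(ref_iv):
        for i, t in enumerate(test_iv):
            ov = overlap_s(t, r)
            if ov > 0 and ov >= _required_overlap(r, t, cfg):
                cands.append((ov, j, i))
    cands.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_t: set[int] = set()
    used_r: set[int] = set()
    pairs = []
    for ov, j, i in cands:
        if i in used_t or j in used_r:
            continue
        pairs.append((i, j, ov))
        used_t.add(i)
        used_r.add(j)
    pairs.sort(key=lambda p: p[1])
    return MatchResult(
        pairs=pairs,
        false_discoveries=[i for i in range(len(test_iv)) if i not in used_t],
        misses=[j for j in range(len(ref_iv)) if j not in used_r],
        patient=patient,
    )


def _weighted_stats(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    w = weights / weights.sum()
    mean = float(np.sum(w * values))
    var = float(np.sum(w * (values - mean) ** 2))
    return mean, float(np.sqrt(var))


def ppa(per_patient: list[tuple[int, int]]) -> tuple[float, float]:
    """Positive percent agreement over patients, reference-count weighted.

    ``per_patient`` holds (n_matched, n_ref) tuples. Weighting each patient's
    PPA by n_ref_i / sum(n_ref) makes the mean equal the pooled ratio
    sum(matched)/sum(ref); the SD is weighted the same way. Patients with
    n_ref = 0 are excluded.
    """
    rows = [(m, r) for m, r in per_patient if r > 0]
    if not rows:
        return 0.0, 0.0
    matched = np.array([m for m, _ in rows], dtype=float)
    n_ref = np.array([r for _, r in rows], dtype=float)
    vals = 100.0 * matched / n_ref
    mean, sd = _weighted_stats(vals, n_ref)
    return mean, sd


def fdr(
    per_patient: list[tuple[int, int]], weighted: bool = False
) -> tuple[float, float]:
    """False discovery rate: unmatched test contractions over all test detections.

    ``per_patient`` holds (n_false, n_test) tuples. Default is the pooled
    form sum(false)/sum(test)*100; ``weighted=True`` weights per-patient FDRs
    by each patient's test-detection count. Patients with n_test = 0 are
    excluded.
    """
    rows = [(f, t) for f, t in per_patient if t > 0]
    if not rows:
        return 0.0, 0.0
    false = np.array([f for f, _ in rows], dtype=float)
    n_test = np.array([t for _, t in rows], dtype=float)
    vals = 100.0 * false / n_test
    if weighted:
        return _weighted_stats(vals, n_test)
    pooled = 100.0 * false.sum() / n_test.sum()
    _, sd = _weighted_stats(vals, n_test)
    return float(pooled), sd


def trace_correlation(
    test_trace: ReferenceTrace | np.ndarray,
    ref_trace: ReferenceTrace | np.ndarray,
    fs_test: float | None = None,
    fs_ref: float | None = None,
) -> float | None:
    """Pearson correlation between two UA traces on a common grid.

    Traces are linearly resampled onto the coarser rate over the shared span.
    Returns None (session excluded) when either trace is constant.
    """
    if isinstance(test_trace, ReferenceTrace):
        x, fx = test_trace.values, test_trace.fs
    else:
        x, fx = np.asarray(test_trace, dtype=float), fs_test or 4.0
    if isinstance(ref_trace, ReferenceTrace):
        y, fy = ref_trace.values, ref_trace.fs
    else:
        y, fy = np.asarray(ref_trace, dtype=float), fs_ref or 4.0
    span = min(x.size / fx, y.size / fy)
    fs = min(fx, fy)
    n = int(span * fs)
    if n < 2:
        return None
    t = np.arange(n) / fs
    xi = np.interp(t, np.arange(x.size) / fx, x)
    yi = np.interp(t, np.arange(y.size) / fy, y)
    if np.ptp(xi) == 0 or np.ptp(yi) == 0:
        return None
    return float(stats.pearsonr(xi, yi).statistic)


def significant_session_filter(
    toco: ReferenceTrace, threshold_mmhg: float = 15.0, cfg: DetectorConfig | None = None
) -> bool:
    """True iff the TOCO trace shows >= 1 contraction peaking >= 15 mmHg above baseline.

    The contraction detector runs on the trace; per detected contraction the
    local baseline is the mean of the pre/post windows, and the session
    qualifies when any peak rises at least ``threshold_mmhg`` above it
    (inclusive).
    """
    cfg = cfg or DetectorConfig(fs=toco.fs)
    x = toco.values
    contrs = detect_contractions(x, cfg)
    if not contrs:
        return False
    from .contraction_id import contractions_to_mask

    outside = ~contractions_to_mask(contrs, x.size, fs=cfg.fs)
    baseline = float(np.median(x[outside])) if outside.any() else float(np.min(x))
    return any(c.peak_amplitude - baseline >= threshold_mmhg for c in contrs)


def evaluate_sessions(
    sessions: list[tuple[str, ContractionAnnotations, ContractionAnnotations]],
    traces: list[tuple[np.ndarray, np.ndarray]] | None = None,
    cfg: MatchConfig | None = None,
) -> AgreementStats:
    """Cohort-level agreement from (patient, test, reference) annotation triples."""
    cfg = cfg or MatchConfig()
    ppa_rows, fdr_rows = [], []
    n_ref = n_test = n_matched = 0
    for patient, test, ref in sessions:
        res = match_contractions(test, ref, cfg, patient=patient)
        ppa_rows.append((res.n_matched, len(ref)))
        fdr_rows.append((len(res.false_discoveries), len(test)))
        n_ref += len(ref)
        n_test += len(test)
        n_matched += res.n_matched
    ppa_m, ppa_sd = ppa(ppa_rows)
    fdr_m, fdr_sd = fdr(fdr_rows)
    r = None
    if traces:
        rs = [trace_correlation(t, rf) for t, rf in traces]
        rs = [v for v in rs if v is not None]
        r = float(np.mean(rs)) if rs else None
    return AgreementStats(
        ppa_percent=ppa_m,
        ppa_sd=ppa_sd,
        fdr_percent=fdr_m,
        fdr_sd=fdr_sd,
        pearson_r=r,
        n_ref=n_ref,
        n_test=n_test,
        n_matched=n_matched,
    )
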