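# Methods

## Signal model and assumptions

The package assumes the contraction signal is carried by slow *amplitude
modulation* of the maternal heartbeat as seen from the abdominal wall: a
beat at time t_i on channel c has peak amplitude

    a_i^c = A_c · (1 + d · env(t_i)) + ε,

where env(t) ≥ 0 is a non-periodic envelope composed of transient,
near-Gaussian bumps (individual contractions, tens of seconds to ~3 min),
d is the modulation depth and ε measurement noise. Frequency modulation of
the heart rate is not used (it exists in some patients but amplitude
modulation is the dominant mechanism). The algorithm therefore reduces each
channel to beat-peak amplitude series and treats everything faster than the
beat rate as carrier, everything slower as candidate UA.

Two sensor modalities carry the same modulation with different noise:
biopotential channels (QRS complexes, some leads with downward-pointing R
waves — hence separate upward and downward peak series) and acoustic
channels (S1/S2 heart-sound bursts, deliberately not disambiguated). Each
acoustic channel is replicated through five high-pass cut-offs (10–30 Hz)
to diversify spectral content before channel selection; the 4 microphones
become 20 working channels, for at most 28 in total.

## Processing chain and defaults

Sampling: ingest at 1000 samples/s, Chebyshev-II low-pass (order 8, 45 dB,
stopband from 125 Hz, "120 Hz cut-off") then 1:4 decimation to the
canonical 250 samples/s. The filter family and order are our choice; the
cut-off and decimation factor are fixed by the device chain being modeled.
All filtering is causal — the pipeline is designed to run per 1-min frame
during acquisition, and a zero-phase pass would need future samples.

Biopotential conditioning: DC block (mean subtraction), IIR notch at the
power-line frequency (config, 50/60 Hz; stopband ±0.5 Hz → Q = f₀/1 Hz),
and an inverse moving average: subtract a Hamming-weighted 201-ms sliding
mean (51 samples at 250 Hz, forced odd; reflective padding). Acoustic
conditioning: 4th-order Butterworth 50 Hz low-pass, then the five 4th-order
high-pass replicas.

Integrity screen: a logistic decision over standardized log1p features
(raw RMS, conditioned SNR around detected beats, beat-peak energy over
background power), trained once on a labeled synthetic corpus
(`scripts/train_integrity.py`, 240 channels, both modalities, failure modes:
flatline, saturation, broadband noise, dropout) and shipped as JSON
coefficients. Zero-variance channels are rejected unconditionally; channels
without detectable beats are scored on the first two features only.

Heartbeats: provisional peaks from an 80-ms energy envelope with a 0.3 s
refractory period (a stand-in for the upstream heart-rate tracker, which is
out of scope); refinement searches ±60 ms (biopotential) / ±100 ms
(acoustic) around each provisional time for the maximum (upward series) and
minimum (downward series). Per-beat SNR = RMS(peak ± 50 ms) / mean RMS of
the inter-complex gaps. Repair: beats are marked noisy by template
correlation < 0.6 (template = trimmed mean of beat windows, 10 % tails), by
SNR < 1.5 if nothing is flagged by the template, or by coincidence with
motion (per-second accelerometer RMS > 5× the session-median baseline).
Runs of < 3 noisy beats are replaced by the series median; longer runs are
rejected; a contiguous noisy span > 30 s removes the channel for the frame.

Surrogate UA (4 samples/s): natural cubic spline through each series'
(time, amplitude) knots (linear fallback below 4 beats, drop below 2; edge
values held, no extrapolation), then up + |down|, moving RMS (101 samples =
25.25 s), baseline shift by a centered moving minimum (481 samples =
120 s — longer than a typical contraction so contractions survive), scaling
by the frame's median smoothed level, and squaring. Because the scale
divisor is the *pre-shift* level, the enhanced trace reads as squared
fractional change from the cardiac baseline, which is what makes an
absolute detection floor meaningful. Division by the median commutes with
the moving-minimum subtraction, so the stage order
interpolate → combine → RMS → shift → square is preserved literally.

Contraction detection: local maxima with topographic prominence ≥ 0.3 × the
trace's 90th percentile (relative, hence scale-invariant), onset/offset at
the contour 0.95 × prominence below the peak, duration band 30–180 s. The
contour sits slightly above the literal prominence base because the base of
an isolated near-Gaussian bump on a zero baseline lies in its asymptotic
tail, which would inflate durations past the maximum. Confidence measures
per contraction: relative energy (AUC fraction), peak-to-range (mean of the
top third of the value range over the range), and range ratio against the
non-contractile remainder; screening thresholds default to 0.005 / 0.3 /
1.2. On UA-scale traces the pipeline adds an absolute peak floor of 0.05
(≈ 22 % RMS change at the peak) — without it, the screen cannot separate
real contractions from smoothed noise ripples, because every relative
measure is scale-invariant. These thresholds were calibrated once on the
synthetic generator's default conditions and then frozen.

Fusion: four subsets × two initializations, central finite-difference
gradients (step 1e-3), sigmoidal step schedule γ_n = γ₀ / (1 + e^{(n−15)/3})
with γ₀ = 0.1, 40 iterations max, tolerance 1e-5. The printed cost
C = 1 + ½(E_cont/E_tot + A_cont/R) *increases* with contraction prominence
while the procedure is described as minimization; we default to maximizing
the bracketed contrast term (minimizing its negation), with the literal
direction available via `FusionConfig.cost_direction`. Voting weights damp
across frames as w01 = 0.6·w_prev + 0.4·w_curr; the winner is enhanced
(channels kept only if correlation ≥ 0.5, fit slope in [0.3, 3], relative
residual ≤ 0.5 against the fused average; weights rescaled to sum 1 and one
further GD step applied, then renormalized), blended with the previous
frame at contribution weight CW = 1/k, and normalized.

Session orchestration: a 10-min calibration block is processed as one frame
(contractions are rare, so the first weighting needs that much context),
then 1-min frames. Per frame, channel chunks are carried through the
smoothing stage only; the baseline shift uses a *causal* 120-s moving
minimum over the accumulated smoothed history and the scale uses the
trailing 10-min median, so contractions spanning frame boundaries keep
their baseline context and the prefix property holds exactly (minutes 1..k
are bit-identical whether or not minute k+1 is ever processed). Weighting
sees the trailing 10-min window; only the newest chunk is fused and
stitched (junction-aligned to the existing trace). Because junction
alignment accumulates a slow random level drift over many frames, the final
trace receives a session-level adaptive baseline correction — subtraction
of its own causal 120-s moving minimum — before detection; this is also
what keeps the published trace on the %-change-from-baseline scale.

Evaluation: candidate pairs must overlap ≥ min(30 s, 50 % of the reference
contraction's duration); one-to-one assignment is greedy by descending
overlap (verified against exhaustive matching up to 10 intervals). PPA is
pooled across patients with reference-count weights (algebraically
Σmatched/Σref); FDR defaults to the pooled form Σfalse/Σtest, with a
per-patient-weighted variant available — the two differ in general and the
published three-way numbers are consistent with the pooled form only to
within rounding. Sessions qualify for antepartum analysis when the TOCO
trace shows a contraction peaking ≥ 15 mmHg above the median of its
non-contractile samples (inclusive).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the features the algorithm *relies on*: a shared
beat train across modalities (72 bpm, 2 % jitter), multiplicative amplitude
modulation with per-channel gains and polarities (two inverted leads
exercise the downward series), Mexican-hat QRS wavelets, paired 25/35 Hz
S1/S2 tone bursts 0.3 s apart, white noise, 0.05 Hz baseline wander, a
power-line tone, scheduled broadband motion artifacts with correlated
accelerometer activity, channel dropouts, and lossy TOCO references
(per-contraction Bernoulli misses, default probability 0.6, matching the
low external-transducer sensitivity that motivates the method). The default
scenario is 30 min with 8 contractions (σ 15–25 s, ≥ 150 s apart) at
modulation depth 0.5 — a testing choice, as no quantitative depth is
established; signals are synthesized directly at 250 samples/s (1000 is
available to exercise decimation).

It does **not** emulate: realistic ECG morphology (P/T waves), fetal
signals, EMG/gastric interference, electrode impedance drift, correlated
(non-white) noise, or tissue-propagation physics. Passing tests therefore
demonstrate that the algorithm recovers amplitude-modulated envelopes under
controlled corruption — not clinical performance. The published clinical
agreement numbers are reproduced at the metric layer only (the estimators
fed with the published match counts), since the underlying recordings are
not available.

## Numerical choices and degenerate inputs

Ties in peak refinement resolve to the first extremum (argmax). Duplicate
refined beat times collapse to one beat. Zero inter-complex RMS caps the
per-beat SNR at 1e6 (flagged); zero denominators in confidence measures cap
at 1e6 (flagged); a zero-amplitude contraction is discarded rather than
scored. Constant candidate traces get difference index 1 (flagged).
An all-zero weight vector is never normalized — candidates that collapse are
discarded and a frame with no viable candidate is recorded as a QC gap.
K-means uses a fixed seed and 10 restarts for determinism; with fewer than
3 contraction-bearing channels the contractions-based subset falls back to
all channels. The windowed operators use reflective padding, flagged when a
signal is shorter than the window.

## Problem sizes

The test suite and the acceptance script run sessions of 5–30 minutes with
28 working channels; oracle-equivalence checks use ≥ 100 randomized cases
per operator. These sizes exercise every code path (calibration, frame
streaming, damping, CW blending, stitching) while keeping a full run in the
low minutes on a single core.

## Known limitations

- The gradient of the contraction-contrast objective is estimated by finite
  differences through a non-smooth detector; GD therefore behaves as a
  local perturbative search, and weight trajectories can stall at detector
  discontinuities. The absolute-value update also reflects at 0, which is
  intended (weights cannot go negative) but makes step sizes near zero
  crossings effectively smaller.
- The integrity classifier is trained on synthetic failure modes only.
- The greedy matcher is verified exhaustively only up to 10 intervals per
  set; beyond that its optimality is assumed (candidate overlaps in real
  sessions are sparse).
- Per-channel surrogates rely on ≥ 2 usable beats per minute per channel;
  sustained tachycardia/bradycardia outside 0.3–2.0 s inter-beat intervals
  is flagged but not specially handled.
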