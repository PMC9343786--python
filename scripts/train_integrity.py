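"""Train the sensor-contact integrity classifier on a labeled synthetic corpus.

Generates short synthetic channels in two classes — usable (clean modulated
beat trains at several noise levels) and contact-failed (flatline,
saturation, pure noise, dropout) — conditions them with the standard chain,
computes the three integrity features (raw RMS, pre-processed SNR, heartbeat
peak energy over background) and fits a logistic decision on standardized
log1p features. The resulting coefficients are frozen into
``src/cabum/data/integrity_coeffs.json``.

Run from the repository root:  python scripts/train_integrity.py [--seed 0]
"""

from __future__ import annotations

import argparse
import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sklearn.linear_model import LogisticRegression

from cabum.heartbeats import detect_initial_peaks
from cabum.preprocess import (
    PreprocConfig,
    acoustic_band_split,
    dc_block,
    integrity_features,
    inverse_moving_average,
    notch_powerline,
)
from cabum.synthdata import SynthConfig, simulate_acoustic, simulate_biopotential, simulate_envelope


def _condition_bio(x: np.ndarray, cfg: PreprocConfig) -> np.ndarray:
    y = dc_block(x)
    y = notch_powerline(y, cfg)
    y, _ = inverse_moving_average(y, cfg)
    return y


def _features(raw: np.ndarray, cond: np.ndarray, cfg: PreprocConfig):
    peaks = detect_initial_peaks(cond, cfg.fs)
    return integrity_features(raw, cond, peaks, cfg.fs)


def build_corpus(seed: int = 0, n_per_class: int = 120):
    rng = np.random.default_rng(seed)
    cfg = PreprocConfig()
    rows, labels = [], []
    dur = 60.0
    n = int(dur * cfg.fs)
    for i in range(n_per_class):
        # usable: clean-to-noisy beat trains, both modalities
        scfg = SynthConfig(
            duration_s=dur,
            seed=seed * 10_000 + i,
            n_contractions=0,
            bio_noise_uv=float(rng.uniform(2.0, 25.0)),
            acu_noise=float(rng.uniform(0.02, 0.2)),
            powerline_uv=float(rng.uniform(0.0, 10.0)),
            heart_rate_bpm=float(rng.uniform(60.0, 95.0)),
        )
        env, _ = simulate_envelope(scfg, np.random.default_rng(scfg.seed))
        if i % 2 == 0:
            bio, _, _ = simulate_biopotential(env, scfg, np.random.default_rng(scfg.seed + 1))
            raw = bio[rng.integers(0, scfg.n_bio)]
            cond = _condition_bio(raw, cfg)
        else:
            acu, _, _ = simulate_acoustic(env, scfg, np.random.default_rng(scfg.seed + 2))
            raw = acu[rng.integers(0, scfg.n_acu)]
            bands = acoustic_band_split(dc_block(raw), cfg)
            cond = bands[rng.integers(0, len(bands))][1]
        rows.append(_features(raw, cond, cfg))
        labels.append(1)
    for i in range(n_per_class):
        kind = i % 4
        scale = float(rng.uniform(0.1, 100.0))  # contact failures occur at any gain
        if kind == 0:  # flatline (detached sensor)
            raw = np.full(n, rng.uniform(-10, 10)) + 1e-3 * scale * rng.standard_normal(n)
        elif kind == 1:  # rail saturation
            raw = 50.0 * scale * np.sign(np.sin(2 * np.pi * 0.2 * np.arange(n) / cfg.fs))
            raw += 0.5 * scale * rng.standard_normal(n)
        elif kind == 2:  # pure broadband noise, no cardiac content
            raw = scale * rng.standard_normal(n)
        else:  # intermittent dropout
            raw = scale * rng.standard_normal(n)
            raw[n // 4 : 3 * n // 4] = 0.0
        if i % 2 == 0:
            cond = _condition_bio(raw, cfg)
        else:
            cond = acoustic_band_split(dc_block(raw), cfg)[2][1]
        rows.append(_features(raw, cond, cfg))
        labels.append(0)
    return np.asarray(rows), np.asarray(labels)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument(
        "--out",
        default=str(Path(__file__).resolve().parents[1] / "src/cabum/data/integrity_coeffs.json"),
    )
    args = ap.parse_args()
    X, y = build_corpus(args.seed)
    Xl = np.log1p(np.clip(X, 0, None))
    mu, sd = Xl.mean(axis=0), Xl.std(axis=0)
    Z = (Xl - mu) / np.where(sd > 0, sd, 1.0)
    clf = LogisticRegression(C=1.0, max_iter=2000).fit(Z, y)
    acc = clf.score(Z, y)
    coeffs = {
        "comment": f"logistic integrity classifier; training accuracy {acc:.3f}",
        "w": clf.coef_[0].round(6).tolist(),
        "b": round(float(clf.intercept_[0]), 6),
        "mu": mu.round(6).tolist(),
        "sd": sd.round(6).tolist(),
    }
    Path(args.out).write_text(json.dumps(coeffs, indent=1) + "\n")
    print(json.dumps(coeffs, indent=1))


if __name__ == "__main__":
    main()
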