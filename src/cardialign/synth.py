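"""Synthetic phonocardiogram generator with prior-consistent physiology.

Generates labelled heart-sound records whose spectral structure matches
the clinical band priors: normal records are periodic S1/S2 tone bursts
with energy in the 20-150 Hz fundamental zone plus weak high-frequency
nuisance noise; abnormal records add a systolic murmur — band-limited
noise confined to 200-600 Hz, placed between S1 and S2 of each cycle.
Every record is deterministic given ``(seed, draw_index)``, and the
abnormal record with a given index shares its normal template with the
normal record of the same index, so degenerate murmur gain reproduces the
paired normal waveform exactly.

These are caricatures, not simulations: no stethoscope transfer function,
no pediatric physiology, no real-world noise environments.  Their purpose
is to make the full pipeline testable and to give the alignment
regularizer data for which the clinical priors are approximately correct.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .features import AudioRecord, save_wav

__all__ = ["SynthConfig", "synth_normal", "synth_abnormal", "synth_records",
           "synth_dataset"]


@dataclass
class SynthConfig:
    n_records: int = 400
    prevalence: float = 0.5          # fraction abnormal
    duration_s: tuple[float, float] = (3.0, 6.0)
    heart_rate_bpm: tuple[float, float] = (60.0, 100.0)
    s1s2_band: tuple[float, float] = (20.0, 150.0)
    murmur_band: tuple[float, float] = (200.0, 600.0)
    noise_band: tuple[float, float] = (600.0, 950.0)
    murmur_snr_db: float = 0.0   # murmur-to-S1/S2 power ratio; -inf disables
    noise_snr_db: float = 15.0   # S1/S2-to-noise power ratio
    sample_rate: int = 2000
    seed: int = 0

    def __post_init__(self):
        for name in ("s1s2_band", "murmur_band", "noise_band", "duration_s",
                     "heart_rate_bpm"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be a non-degenerate interval")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")


def _bandlimited_noise(rng: np.random.Generator, n: int, band, fs: float):
    lo, hi = band
    hi = min(hi, 0.499 * fs)
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, rng.standard_normal(n))


def _gauss_burst(t: np.ndarray, center: float, width: float, freq: float,
                 amp: float) -> np.ndarray:
    env = np.exp(-0.5 * ((t - center) / width) ** 2)
    return amp * env * np.sin(2.0 * np.pi * freq * (t - center))


def _base_waveform(cfg: SynthConfig, draw_index: int):
    """Shared normal template: (waveform, heart power, systolic windows)."""
    rng = np.random.default_rng([cfg.seed, draw_index])
    fs = cfg.sample_rate
    dur = rng.uniform(*cfg.duration_s)
    hr = rng.uniform(*cfg.heart_rate_bpm)
    cycle = 60.0 / hr
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    lo, hi = cfg.s1s2_band
    mid = 0.5 * (lo + hi)
    f_s1 = rng.uniform(lo + 0.05 * (hi - lo), mid)
    f_s2 = rng.uniform(mid, hi - 0.05 * (hi - lo))
    x = np.zeros(n)
    systole = []  # (start, end) of each S1->S2 interval
    t_s1 = 0.05
    while t_s1 < dur:
        jitter = rng.normal(0.0, 0.01 * cycle)
        t1 = t_s1 + jitter
        t2 = t1 + 0.35 * cycle
        x += _gauss_burst(t, t1, 0.020, f_s1, rng.uniform(0.9, 1.1))
        if t2 < dur:
            x += _gauss_burst(t, t2, 0.015, f_s2, 0.7 * rng.uniform(0.9, 1.1))
        systole.append((t1 + 0.06, t2 - 0.03))
        t_s1 += cycle
    p_heart = float(np.mean(x ** 2))
    noise = _bandlimited_noise(rng, n, cfg.noise_band, fs)
    p_noise_target = p_heart * 10.0 ** (-cfg.noise_snr_db / 10.0)
    noise *= np.sqrt(p_noise_target / max(np.mean(noise ** 2), 1e-30))
    return x + noise, p_heart, systole, t


def synth_normal(cfg: SynthConfig, draw_index: int) -> AudioRecord:
    """One normal record: S1/S2 bursts plus high-frequency nuisance noise."""
    x, _, _, _ = _base_waveform(cfg, draw_index)
    x = x / np.max(np.abs(x))
    return AudioRecord(id=f"syn{draw_index:05d}", samples=x,
                       sample_rate=float(cfg.sample_rate), label=0)


def synth_abnormal(cfg: SynthConfig, draw_index: int) -> AudioRecord:
    """One abnormal record: the paired normal template plus a systolic murmur."""
    x, p_heart, systole, t = _base_waveform(cfg, draw_index)
    rng = np.random.default_rng([cfg.seed, draw_index, 1])
    gain = 10.0 ** (cfg.murmur_snr_db / 20.0)  # -inf -> exactly 0
    if gain > 0.0:
        raw = _bandlimited_noise(rng, len(t), cfg.murmur_band, cfg.sample_rate)
        env = np.zeros(len(t))
        for start, end in systole:
            if end <= start:
                continue
            win = (t >= start) & (t <= end)
            # raised-cosine envelope over each systolic interval
            env[win] = 0.5 * (1 - np.cos(2 * np.pi * (t[win] - start)
                                         / (end - start)))
        murmur = raw * env
        p_m = np.mean(murmur ** 2)
        if p_m > 0:
            murmur *= np.sqrt(p_heart / p_m) * gain
        x = x + murmur
    x = x / np.max(np.abs(x))
    return AudioRecord(id=f"syn{draw_index:05d}", samples=x,
                       sample_rate=float(cfg.sample_rate), label=1)


def synth_records(cfg: SynthConfig) -> list[AudioRecord]:
    """In-memory dataset: ``round(prevalence * n)`` abnormal records.

    Label placement is a seeded permutation so classes interleave; record
    ``i`` is always generated from stream ``(seed, i)`` regardless of its
    label, keeping per-record determinism.
    """
    n = cfg.n_records
    k = int(round(cfg.prevalence * n))
    labels = np.zeros(n, dtype=int)
    labels[np.random.default_rng([cfg.seed, 10**6]).permutation(n)[:k]] = 1
    return [synth_abnormal(cfg, i) if labels[i] else synth_normal(cfg, i)
            for i in range(n)]


def synth_dataset(cfg: SynthConfig, out_dir: str | Path,
                  split_ratio: float = 0.9,
                  split_seed: int = 2025) -> pd.DataFrame:
    """Write WAV files (16-bit PCM) plus a manifest CSV with splits."""
    from .training import split_records

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in synth_records(cfg):
        path = out_dir / f"{rec.id}.wav"
        try:
            save_wav(path, rec.samples, cfg.sample_rate)
        except OSError as e:
            raise OSError(f"failed writing {path}: {e}") from e
        rows.append({"id": rec.id, "path": str(path), "label": rec.label})
    manifest = split_records(pd.DataFrame(rows), ratio=split_ratio,
                             seed=split_seed)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
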