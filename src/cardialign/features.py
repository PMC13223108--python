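"""Audio loading and log-Mel spectrogram extraction for heart-sound records.

The preprocessing contract, in pipeline order: resample to 2 kHz, peak
normalize, compute a 128-bin log-Mel spectrogram (50 ms Hann window, 25 ms
hop, 256-point FFT, 25–1000 Hz), then zero-pad spectrograms batch-wise to
the longest sample.  Padding is exact zero in the feature domain so that
padded frames carry no attribution downstream (gradient x input vanishes
where the input is zero).

Frames follow the no-centering convention: frame ``t`` starts at sample
``t * hop``, so ``T = floor((n - win) / hop) + 1`` exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.io import wavfile
from scipy.signal import get_window, resample_poly

__all__ = [
    "AudioRecord", "Spectrogram", "SpectrogramBatch", "FeatureConfig",
    "resample", "normalize_amplitude", "logmel", "batch_pad",
    "mel_filterbank", "hz_to_mel", "mel_to_hz",
    "load_wav", "save_wav", "read_manifest", "prepare_record",
]


@dataclass
class AudioRecord:
    """A single-channel heart-sound recording with its clinical label."""

    id: str
    samples: np.ndarray
    sample_rate: float
    label: int | None = None  # 0 = Normal, 1 = Abnormal
    split: str | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError(f"record {self.id!r}: samples must be 1-D")
        if self.sample_rate <= 0:
            raise ValueError(f"record {self.id!r}: sample_rate must be positive")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class Spectrogram:
    """T x F grid of log-Mel magnitudes for one record."""

    values: np.ndarray  # (T, F)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError("Spectrogram requires a (T, F) grid with T >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Spectrogram contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_mels(self) -> int:
        return self.values.shape[1]


@dataclass
class SpectrogramBatch:
    """Padded batch: X is (B, 1, T_max, F); padded frames are exactly zero."""

    X: np.ndarray
    y: np.ndarray
    valid_frames: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.intp)
        self.valid_frames = np.asarray(self.valid_frames, dtype=np.intp)
        if self.X.ndim != 4 or self.X.shape[1] != 1:
            raise ValueError("batch X must have shape (B, 1, T, F)")
        if self.X.shape[0] < 1:
            raise ValueError("batch must contain at least one sample")

    def __len__(self) -> int:
        return self.X.shape[0]


@dataclass
class FeatureConfig:
    """Feature-extraction settings (times in ms, frequencies in Hz)."""

    sample_rate: int = 2000
    win_ms: float = 50.0
    hop_ms: float = 25.0
    n_fft: int = 256
    n_mels: int = 128
    fmin: float = 25.0
    fmax: float = 1000.0
    log_floor: float = 1e-6
    mel_variant: str = "htk"  # "htk" or "slaney"

    @property
    def win_length(self) -> int:
        return int(round(self.win_ms * self.sample_rate / 1000.0))

    @property
    def hop_length(self) -> int:
        return int(round(self.hop_ms * self.sample_rate / 1000.0))


# --------------------------------------------------------------------------
# Waveform operations
# --------------------------------------------------------------------------


def resample(record: AudioRecord, target_rate: int = 2000) -> AudioRecord:
    """Anti-aliased polyphase resampling to ``target_rate`` Hz.

    A record already at the target rate is returned unchanged (bitwise).
    """
    if len(record.samples) == 0:
        raise ValueError(f"record {record.id!r}: cannot resample an empty signal")
    if record.sample_rate == target_rate:
        return record
    from math import gcd

    sr = int(round(record.sample_rate))
    tr = int(round(target_rate))
    g = gcd(sr, tr)
    out = resample_poly(record.samples, tr // g, sr // g)
    return replace(record, samples=out, sample_rate=float(target_rate))


def normalize_amplitude(record: AudioRecord) -> AudioRecord:
    """Scale so that max(|samples|) == 1 exactly."""
    peak = np.max(np.abs(record.samples)) if len(record.samples) else 0.0
    if peak == 0.0:
        raise ValueError(
            f"record {record.id!r}: all-zero signal cannot be peak-normalized")
    return replace(record, samples=record.samples / peak)


# --------------------------------------------------------------------------
# Mel filterbank
# --------------------------------------------------------------------------


def hz_to_mel(f, variant: str = "htk"):
    f = np.asarray(f, dtype=np.float64)
    if variant == "htk":
        return 2595.0 * np.log10(1.0 + f / 700.0)
    if variant == "slaney":
        # linear below 1 kHz, logarithmic above
        f_sp = 200.0 / 3
        brk = 1000.0
        logstep = np.log(6.4) / 27.0
        return np.where(f < brk, f / f_sp,
                        brk / f_sp + np.log(np.maximum(f, brk) / brk) / logstep)
    raise ValueError(f"unknown mel variant {variant!r}")


def mel_to_hz(m, variant: str = "htk"):
    m = np.asarray(m, dtype=np.float64)
    if variant == "htk":
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)
    if variant == "slaney":
        f_sp = 200.0 / 3
        brk_mel = 1000.0 / f_sp
        logstep = np.log(6.4) / 27.0
        return np.where(m < brk_mel, m * f_sp,
                        1000.0 * np.exp(logstep * (np.maximum(m, brk_mel) - brk_mel)))
    raise ValueError(f"unknown mel variant {variant!r}")


_warned_empty_filters = False


def mel_filterbank(cfg: FeatureConfig) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, n_fft // 2 + 1).

    With 128 filters over 25-1000 Hz on a 129-bin FFT grid, some
    low-frequency filters can span no FFT bin; these stay all-zero (their
    log-Mel output is the floor) and trigger a one-time warning, because
    the band partition requires the full structural F = 128.
    """
    global _warned_empty_filters
    n_bins = cfg.n_fft // 2 + 1
    fft_freqs = np.linspace(0.0, cfg.sample_rate / 2.0, n_bins)
    mel_pts = np.linspace(hz_to_mel(cfg.fmin, cfg.mel_variant),
                          hz_to_mel(cfg.fmax, cfg.mel_variant),
                          cfg.n_mels + 2)
    hz_pts = mel_to_hz(mel_pts, cfg.mel_variant)
    fb = np.zeros((cfg.n_mels, n_bins))
    for i in range(cfg.n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    empty = np.sum(fb.sum(axis=1) == 0)
    if empty and not _warned_empty_filters:
        warnings.warn(
            f"{empty} of {cfg.n_mels} mel filters span no FFT bin at "
            f"n_fft={cfg.n_fft}; their output is the log floor", stacklevel=2)
        _warned_empty_filters = True
    return fb


# --------------------------------------------------------------------------
# Spectrogram extraction and batching
# --------------------------------------------------------------------------


def logmel(record: AudioRecord, cfg: FeatureConfig | None = None) -> Spectrogram:
    """Log-Mel spectrogram of a resampled, peak-normalized record."""
    cfg = cfg or FeatureConfig()
    if record.sample_rate != cfg.sample_rate:
        raise ValueError(
            f"record {record.id!r} is at {record.sample_rate} Hz; resample to "
            f"{cfg.sample_rate} Hz first")
    win, hop = cfg.win_length, cfg.hop_length
    if len(record.samples) < win:
        raise ValueError(
            f"record {record.id!r} is shorter than one window "
            f"({cfg.win_ms} ms = {win} samples); minimum duration not met")
    frames = sliding_window_view(record.samples, win)[::hop]
    window = get_window("hann", win, fftbins=True)
    spec = np.abs(np.fft.rfft(frames * window, n=cfg.n_fft)) ** 2
    mel = spec @ mel_filterbank(cfg).T
    return Spectrogram(np.log(mel + cfg.log_floor))


def batch_pad(specs: list[Spectrogram], labels) -> SpectrogramBatch:
    """Zero-pad spectrograms to the longest in the batch (dynamic padding)."""
    if not specs:
        raise ValueError("batch_pad: empty spectrogram list")
    n_mels = specs[0].n_mels
    if any(s.n_mels != n_mels for s in specs):
        raise ValueError("batch_pad: inconsistent mel dimension across batch")
    t_max = max(s.n_frames for s in specs)
    X = np.zeros((len(specs), 1, t_max, n_mels))
    valid = np.zeros(len(specs), dtype=np.intp)
    for i, s in enumerate(specs):
        X[i, 0, :s.n_frames] = s.values
        valid[i] = s.n_frames
    return SpectrogramBatch(X=X, y=np.asarray(labels), valid_frames=valid)


def prepare_record(record: AudioRecord, cfg: FeatureConfig | None = None) -> Spectrogram:
    """Full preprocessing chain: resample -> peak-normalize -> log-Mel."""
    cfg = cfg or FeatureConfig()
    return logmel(normalize_amplitude(resample(record, cfg.sample_rate)), cfg)


# --------------------------------------------------------------------------
# File I/O
# --------------------------------------------------------------------------

_LABEL_MAP = {"0": 0, "1": 1, "normal": 0, "abnormal": 1}


def load_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a PCM 16/32-bit or float WAV as float64 in [-1, 1]."""
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        data = data / 32768.0
    elif data.dtype == np.int32:
        data = data / 2147483648.0
    elif data.dtype == np.uint8:
        data = (data.astype(np.float64) - 128.0) / 128.0
    return np.asarray(data, dtype=np.float64), float(rate)


def save_wav(path: str | Path, samples: np.ndarray, rate: int):
    """Write 16-bit PCM."""
    x = np.clip(np.asarray(samples, dtype=np.float64), -1.0, 1.0)
    wavfile.write(str(path), int(rate), (x * 32767.0).astype(np.int16))


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Dataset manifest CSV with columns id, path, label[, split]."""
    df = pd.read_csv(path, dtype={"id": str})
    required = {"id", "path", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path}: missing columns {sorted(missing)}")
    df["label"] = df["label"].astype(str).str.strip().str.lower().map(_LABEL_MAP)
    if df["label"].isna().any():
        raise ValueError(f"manifest {path}: labels must be normal/abnormal or 0/1")
    df["label"] = df["label"].astype(int)
    return df


def load_manifest_records(df: pd.DataFrame, root: str | Path | None = None) -> list[AudioRecord]:
    """Instantiate AudioRecords from a manifest dataframe."""
    records = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if root is not None and not p.is_absolute():
            p = Path(root) / p
        samples, rate = load_wav(p)
        split = getattr(row, "split", None)
        records.append(AudioRecord(id=str(row.id), samples=samples,
                                   sample_rate=rate, label=int(row.label),
                                   split=split))
    return records
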