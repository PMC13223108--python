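"""Spectral band partition and class-conditional frequency priors.

The 128 mel bins are split into four contiguous 32-bin bands with distinct
auscultation semantics: the fundamental zone of S1/S2 (band 1), a
transitional zone (band 2), the pathological murmur zone (band 3), and a
noise zone (band 4).  Clinical priors encode the consensus "normal sounds
are low-frequency; murmurs are mid-to-high frequency; the top of the
spectrum is noise" as 4-vectors on the probability simplex:

    normal   pi(0) = [0.70, 0.20, 0.10, 0.00]
    abnormal pi(1) = [0.15, 0.35, 0.50, 0.00]

Band 4 mass is exactly zero in both classes — any attribution landing
there is penalized through the epsilon-guarded KL term, which is the
intended noise-suppression mechanism; the priors are deliberately not
smoothed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import mel_to_hz, hz_to_mel

__all__ = [
    "BandPartition", "PriorTable", "make_band_partition",
    "clinical_priors", "uniform_prior", "wrong_priors", "get_prior_table",
    "select_prior",
]

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class BandPartition:
    """Ordered half-open mel-index ranges covering all bins exactly once."""

    bands: tuple[tuple[int, int], ...]
    hz_annotations: tuple[tuple[float, float], ...] = ()

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def n_mels(self) -> int:
        return self.bands[-1][1]

    def band_slices(self) -> list[slice]:
        return [slice(lo, hi) for lo, hi in self.bands]

    def band_of(self, mel_index: int) -> int:
        for k, (lo, hi) in enumerate(self.bands):
            if lo <= mel_index < hi:
                return k
        raise IndexError(f"mel index {mel_index} outside partition")


def make_band_partition(n_mels: int = 128, n_bands: int = 4,
                        fmin: float = 25.0, fmax: float = 1000.0,
                        mel_variant: str = "htk") -> BandPartition:
    """Equal-width contiguous partition of ``n_mels`` bins into ``n_bands``.

    Hz annotations are informational, recomputed from the configured mel
    variant by mapping band-edge bin indices back to physical frequency.
    """
    if n_mels % n_bands != 0:
        raise ValueError(
            f"n_mels={n_mels} is not divisible by n_bands={n_bands}")
    width = n_mels // n_bands
    bands = tuple((k * width, (k + 1) * width) for k in range(n_bands))
    m_lo, m_hi = hz_to_mel(fmin, mel_variant), hz_to_mel(fmax, mel_variant)
    edges_mel = m_lo + (m_hi - m_lo) * np.arange(n_bands + 1) * width / n_mels
    edges_hz = mel_to_hz(edges_mel, mel_variant)
    hz = tuple((float(edges_hz[k]), float(edges_hz[k + 1]))
               for k in range(n_bands))
    return BandPartition(bands=bands, hz_annotations=hz)


@dataclass(frozen=True)
class PriorTable:
    """Class-conditional band priors: pi0 for Normal, pi1 for Abnormal."""

    pi0: np.ndarray
    pi1: np.ndarray
    name: str = "custom"

    def __post_init__(self):
        for attr in ("pi0", "pi1"):
            v = np.asarray(getattr(self, attr), dtype=np.float64)
            if v.ndim != 1:
                raise ValueError(f"{attr} must be a 1-D probability vector")
            if np.any(v < 0):
                raise ValueError(f"{attr} has negative entries")
            if abs(v.sum() - 1.0) > _SIMPLEX_TOL:
                raise ValueError(f"{attr} must sum to 1 (got {v.sum()!r})")
            object.__setattr__(self, attr, v)

    def for_label(self, label: int) -> np.ndarray:
        return self.pi0 if label == 0 else self.pi1


def clinical_priors() -> PriorTable:
    """The physiology-informed class priors."""
    return PriorTable(pi0=np.array([0.7, 0.2, 0.1, 0.0]),
                      pi1=np.array([0.15, 0.35, 0.5, 0.0]),
                      name="clinical")


def uniform_prior() -> PriorTable:
    """Uninformed sanity-check prior: equal band weight for both classes."""
    q = np.full(4, 0.25)
    return PriorTable(pi0=q, pi1=q.copy(), name="uniform")


def wrong_priors() -> PriorTable:
    """Deliberately inverted prior: the clinical table with classes swapped.

    The wrong abnormal prior places its maximum weight (0.7) on band 1,
    the fundamental zone — the opposite of murmur physiology.  Applying
    the swap twice recovers the clinical table.
    """
    c = clinical_priors()
    return PriorTable(pi0=c.pi1.copy(), pi1=c.pi0.copy(), name="wrong")


_TABLES = {"clinical": clinical_priors, "uniform": uniform_prior,
           "wrong": wrong_priors}


def get_prior_table(name: str) -> PriorTable:
    try:
        return _TABLES[name]()
    except KeyError:
        raise ValueError(
            f"unknown prior table {name!r}; choose from {sorted(_TABLES)}")


def select_prior(labels, table: PriorTable) -> np.ndarray:
    """Per-sample prior matrix: row i is the class prior of label y_i."""
    labels = np.asarray(labels)
    if labels.size and not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0 = Normal, 1 = Abnormal)")
    out = np.empty((labels.shape[0], table.pi0.shape[0]))
    out[labels == 0] = table.pi0
    out[labels == 1] = table.pi1
    return out
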