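"""Scale-consistent attribution: saliency, band aggregation, and the KL loss.

The training objective is

    L = L_CE + lambda_sca * L_SCA,

where L_SCA is the mean KL divergence from each sample's gradient x input
band-attribution distribution p_i to its class prior pi_{y_i}:

    s      = sum_i z_{i, y_i}                  (summed true-class logits)
    G      = ds / dX
    A      = |G . X|                           (elementwise, non-negative)
    A~_f   = sum_t A[:, :, t, f]               (time aggregation)
    p_ik   = sum_{f in band_k} A~_if / (sum_j sum_{f in band_j} A~_if + eps)
    L_SCA  = (1/B) sum_i sum_k p_ik * log(p_ik / (pi_ik + eps))

Because samples are independent, the gradient of the summed score s with
respect to X_i equals the gradient of z_{i, y_i} alone, so one backward
pass attributes the whole batch.  When the result feeds the training loss
the saliency must stay differentiable with respect to the model parameters
(double backpropagation); the ``differentiable`` flag on :class:`SCAConfig`
controls whether that higher-order graph is built.

Natural logarithms throughout; the epsilon placement follows the loss
definition exactly (inside the normalization denominator and inside the
prior denominator) with no additional smoothing of p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .features import SpectrogramBatch
from .priors import BandPartition, PriorTable, select_prior

__all__ = [
    "SCAConfig", "AttributionResult", "LossBreakdown",
    "true_class_score", "gradient_x_input", "band_attribution",
    "kl_alignment_loss", "kl_per_sample", "total_loss", "sca_objective",
]


@dataclass
class SCAConfig:
    lambda_sca: float = 0.3
    epsilon: float = 1e-8
    differentiable: bool = False

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.lambda_sca < 0:
            raise ValueError("lambda_sca must be non-negative")


@dataclass
class AttributionResult:
    """Saliency A, its time aggregate, and the normalized band mass.

    ``saliency``/``time_aggregate``/``band_mass`` are plain arrays for
    inspection; when built with ``differentiable=True`` the private tensor
    handles keep the graph alive for the training loss.
    """

    saliency: np.ndarray                      # (B, 1, T, F), >= 0
    time_aggregate: np.ndarray | None = None  # (B, F)
    band_mass: np.ndarray | None = None       # (B, n_bands), simplex rows
    saliency_t: Tensor | None = None
    band_mass_t: Tensor | None = None


@dataclass
class LossBreakdown:
    ce: float
    sca: float
    lambda_sca: float
    total: float
    total_t: Tensor | None = None


def true_class_score(logits, labels) -> Tensor:
    """s = sum_i z_{i, y_i}, the summed true-class logits (a scalar node)."""
    logits = ad.astensor(logits)
    labels = np.asarray(labels, dtype=np.intp)
    if logits.ndim != 2 or logits.shape[0] != labels.shape[0]:
        raise ValueError(
            f"logits {logits.shape} incompatible with {labels.shape[0]} labels")
    return ad.tsum(ad.take_along_rows(logits, labels))


def gradient_x_input(model, batch: SpectrogramBatch,
                     cfg: SCAConfig | None = None) -> AttributionResult:
    """Gradient x input saliency A = |ds/dX . X| for a batch.

    With ``cfg.differentiable`` the saliency tensor retains its dependence
    on the model parameters so a loss built on it can be optimized; without
    it the result is a detached evaluation artifact.
    """
    cfg = cfg or SCAConfig()
    X = Tensor(batch.X, requires_grad=True)
    logits = model(X)
    if logits.ndim != 2 or logits.shape != (batch.X.shape[0], 2):
        raise ValueError(
            f"model output has shape {logits.shape}; expected ({len(batch)}, 2)")
    s = true_class_score(logits, batch.y)
    (G,) = ad.grad(s, [X], create_graph=cfg.differentiable)
    if not np.all(np.isfinite(G.data)):
        raise FloatingPointError(
            "non-finite input gradients; model may have diverged")
    A = ad.tabs(ad.mul(G, X))
    return AttributionResult(
        saliency=A.data,
        saliency_t=A if cfg.differentiable else None,
    )


def band_attribution(att: AttributionResult, partition: BandPartition,
                     epsilon: float = 1e-8) -> AttributionResult:
    """Fill ``time_aggregate`` and ``band_mass`` by band-summing saliency."""
    A = att.saliency_t if att.saliency_t is not None else Tensor(att.saliency)
    if A.shape[-1] != partition.n_mels:
        raise ValueError(
            f"saliency F={A.shape[-1]} does not match partition "
            f"n_mels={partition.n_mels}")
    agg = ad.tsum(A, axis=(1, 2))  # (B, F)
    sums = [ad.tsum(ad.narrow(agg, 1, lo, hi - lo), axis=1, keepdims=True)
            for lo, hi in partition.bands]
    band_tot = ad.concat(sums, axis=1)              # (B, K)
    denom = ad.add(ad.tsum(band_tot, axis=1, keepdims=True),
                   Tensor(float(epsilon)))
    p = ad.div(band_tot, denom)
    if np.any(band_tot.data.sum(axis=1) == 0.0):
        warnings.warn(
            "all-zero saliency for at least one sample; its band mass "
            "degenerates toward zero (pathological model?)", stacklevel=2)
    att.time_aggregate = agg.data
    att.band_mass = p.data
    att.band_mass_t = p if att.saliency_t is not None else None
    return att


def _kl_rows(p: Tensor, priors: np.ndarray, epsilon: float) -> Tensor:
    """Per-sample KL(p_i || pi_i) with the 0*log(0/.) = 0 convention."""
    zero_mask = Tensor((p.data == 0.0).astype(np.float64))  # detached
    log_ratio = ad.sub(ad.tlog(ad.add(p, zero_mask)),
                       Tensor(np.log(priors + epsilon)))
    return ad.tsum(ad.mul(p, log_ratio), axis=1)


def kl_alignment_loss(band_mass, priors, epsilon: float = 1e-8) -> Tensor:
    """(1/B) sum_i KL(p_i || pi_i + eps), natural log."""
    p = ad.astensor(band_mass)
    priors = np.asarray(priors, dtype=np.float64)
    if p.shape != priors.shape:
        raise ValueError(f"band_mass {p.shape} vs priors {priors.shape}")
    if np.any(p.data < 0) or np.any(priors < 0):
        raise ValueError("band_mass and priors must be non-negative")
    return ad.tmean(_kl_rows(p, priors, epsilon))


def kl_per_sample(band_mass: np.ndarray, priors: np.ndarray,
                  epsilon: float = 1e-8) -> np.ndarray:
    """Evaluation-time per-sample KL values as a plain array."""
    with ad.no_grad():
        return _kl_rows(Tensor(band_mass), np.asarray(priors), epsilon).data


def total_loss(logits, labels, band_mass, priors,
               cfg: SCAConfig | None = None) -> LossBreakdown:
    """Joint objective L = L_CE + lambda_sca * L_SCA for one batch."""
    cfg = cfg or SCAConfig()
    logits = ad.astensor(logits)
    ce = ad.cross_entropy(logits, labels)
    sca = kl_alignment_loss(band_mass, priors, cfg.epsilon)
    tot = ad.add(ce, ad.mul(Tensor(float(cfg.lambda_sca)), sca))
    return LossBreakdown(ce=ce.item(), sca=sca.item(),
                         lambda_sca=cfg.lambda_sca, total=tot.item(),
                         total_t=tot)


def sca_objective(model, batch: SpectrogramBatch, table: PriorTable,
                  partition: BandPartition,
                  cfg: SCAConfig | None = None
                  ) -> tuple[LossBreakdown, AttributionResult]:
    """One forward pass computing the full joint objective for a batch.

    Drop-in loss component: the returned breakdown's ``total_t`` is ready
    for a backward pass over the model parameters (saliency is built with
    a higher-order graph when ``cfg.differentiable``).
    """
    cfg = cfg or SCAConfig()
    X = Tensor(batch.X, requires_grad=True)
    logits = model(X)
    if logits.ndim != 2 or logits.shape[1] != 2:
        raise ValueError(f"model output has shape {logits.shape}; expected (B, 2)")
    s = true_class_score(logits, batch.y)
    (G,) = ad.grad(s, [X], create_graph=cfg.differentiable)
    if not np.all(np.isfinite(G.data)):
        raise FloatingPointError("non-finite input gradients")
    A = ad.tabs(ad.mul(G, X))
    att = AttributionResult(saliency=A.data,
                            saliency_t=A if cfg.differentiable else None)
    att = band_attribution(att, partition, cfg.epsilon)
    priors = select_prior(batch.y, table)
    p = att.band_mass_t if att.band_mass_t is not None else Tensor(att.band_mass)
    ce = ad.cross_entropy(logits, batch.y)
    sca = kl_alignment_loss(p, priors, cfg.epsilon)
    tot = ad.add(ce, ad.mul(Tensor(float(cfg.lambda_sca)), sca))
    breakdown = LossBreakdown(ce=ce.item(), sca=sca.item(),
                              lambda_sca=cfg.lambda_sca, total=tot.item(),
                              total_t=tot)
    return breakdown, att
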