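"""Classification metrics with uncertainty, and explainability evaluation.

Classification: accuracy, sensitivity TP/(TP+FN), specificity TN/(TN+FP),
percentile-bootstrap 95% confidence intervals over recordings, and
McNemar's paired test between two classifiers.

Explainability: per-sample KL divergence of the gradient x input band mass
to the class prior, cosine similarity to the prior, the fraction of
samples whose KL improves relative to a baseline model (delta-KL > 0), and
per-class mean band masses.  Sanity-check variants rescore the *same*
attributions against the uniform or deliberately wrong prior tables; the
band-masking ablation zeroes the low or high half of the mel axis to probe
which bands the trained model's decisions rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from . import autodiff as ad
from .autodiff import Tensor
from .features import SpectrogramBatch, batch_pad
from .priors import BandPartition, PriorTable, select_prior
from .sca import SCAConfig, band_attribution, gradient_x_input, kl_per_sample

__all__ = [
    "ConfusionCounts", "EvalReport", "classification_metrics", "bootstrap_ci",
    "mcnemar_test", "explanation_metrics", "delta_kl_fraction",
    "band_mass_report", "band_mask_eval", "sanity_check", "predictions",
]

MASK_MODES = ("none", "low_band", "high_band")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def acc(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sens(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def spec(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None


@dataclass
class EvalReport:
    """Classification metrics with CIs plus explainability statistics."""

    acc: float
    sens: float | None
    spec: float | None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    mcnemar_p: float | None = None
    mean_kl: dict[str, float] = field(default_factory=dict)      # per class
    mean_cos: dict[str, float] = field(default_factory=dict)
    delta_kl_pos_fraction: dict[str, float] = field(default_factory=dict)
    band_mass_mean: dict[str, list[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "acc": self.acc, "sens": self.sens, "spec": self.spec,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "mcnemar_p": self.mcnemar_p,
            "mean_kl": self.mean_kl, "mean_cos": self.mean_cos,
            "delta_kl_pos_fraction": self.delta_kl_pos_fraction,
            "band_mass_mean": self.band_mass_mean,
        }


def _check_binary(x, name):
    x = np.asarray(x)
    if x.size and not np.isin(x, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1")
    return x.astype(np.intp)


def classification_metrics(preds, labels):
    """Confusion counts and (acc, sens, spec); undefined metrics are None."""
    preds = _check_binary(preds, "preds")
    labels = _check_binary(labels, "labels")
    if preds.shape != labels.shape:
        raise ValueError("preds and labels must have equal length")
    counts = ConfusionCounts(
        tp=int(np.sum((preds == 1) & (labels == 1))),
        tn=int(np.sum((preds == 0) & (labels == 0))),
        fp=int(np.sum((preds == 1) & (labels == 0))),
        fn=int(np.sum((preds == 0) & (labels == 1))),
    )
    return counts, (counts.acc, counts.sens, counts.spec)


def bootstrap_ci(preds, labels, n_boot: int = 10000, seed: int = 0,
                 alpha: float = 0.05):
    """Percentile-bootstrap CIs for acc/sens/spec over recordings.

    Replicates with an empty class skip that metric (the skip count is
    reported under ``"skipped"``).
    """
    preds = _check_binary(preds, "preds")
    labels = _check_binary(labels, "labels")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(preds)
    stats: dict[str, list[float]] = {"acc": [], "sens": [], "spec": []}
    skipped = {"sens": 0, "spec": 0}
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        counts, (a, s, sp) = classification_metrics(preds[idx], labels[idx])
        stats["acc"].append(a)
        if s is None:
            skipped["sens"] += 1
        else:
            stats["sens"].append(s)
        if sp is None:
            skipped["spec"] += 1
        else:
            stats["spec"].append(sp)
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    ci = {k: (float(np.percentile(v, lo)), float(np.percentile(v, hi)))
          for k, v in stats.items() if v}
    return ci, skipped


def mcnemar_test(preds_a, preds_b, labels, exact: bool | None = None):
    """McNemar's paired test on two classifiers' discordant predictions.

    Exact two-sided binomial when the discordant count b + c < 25 (or when
    ``exact=True``), continuity-corrected chi-square otherwise.  Returns
    ``(p_value, (b, c))`` where b counts samples a got right and b wrong.
    """
    preds_a = _check_binary(preds_a, "preds_a")
    preds_b = _check_binary(preds_b, "preds_b")
    labels = _check_binary(labels, "labels")
    if not (len(preds_a) == len(preds_b) == len(labels)):
        raise ValueError("all three sequences must have equal length")
    a_ok = preds_a == labels
    b_ok = preds_b == labels
    b = int(np.sum(a_ok & ~b_ok))
    c = int(np.sum(~a_ok & b_ok))
    if b + c == 0:
        return 1.0, (b, c)  # no discordance: no information
    use_exact = exact if exact is not None else (b + c) < 25
    table = [[0, b], [c, 0]]  # only discordant cells matter
    res = _sm_mcnemar(table, exact=use_exact, correction=True)
    return float(min(res.pvalue, 1.0)), (b, c)


# --------------------------------------------------------------------------
# Explainability metrics
# --------------------------------------------------------------------------


def _batched_band_mass(model, data, partition: BandPartition,
                       epsilon: float = 1e-8, batch_size: int = 32,
                       mask_mode: str = "none") -> tuple[np.ndarray, np.ndarray]:
    """Band-mass rows and labels for a dataset, in the dataset's order.

    Samples are batched *by native length*, never padded: global pooling
    runs over every frame the model sees, so padding a sample to a longer
    batch would shift its logits and hence its saliency.  Length-grouped
    batching keeps per-sample values exactly independent of batch
    ordering and batch size.
    """
    model.eval()
    by_len: dict[int, list[int]] = {}
    for i, (spec, _) in enumerate(data):
        by_len.setdefault(spec.n_frames, []).append(i)
    mass = np.empty((len(data), partition.n_bands))
    labels = np.empty(len(data), dtype=np.intp)
    for indices in by_len.values():
        for start in range(0, len(indices), batch_size):
            idx = indices[start:start + batch_size]
            batch = batch_pad([data[i][0] for i in idx],
                              [data[i][1] for i in idx])
            if mask_mode != "none":
                batch = SpectrogramBatch(X=apply_band_mask(batch.X, mask_mode),
                                         y=batch.y,
                                         valid_frames=batch.valid_frames)
            att = gradient_x_input(model, batch, SCAConfig(epsilon=epsilon))
            att = band_attribution(att, partition, epsilon)
            mass[idx] = att.band_mass
            labels[idx] = batch.y
    return mass, labels


def _cosine_rows(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Row-wise cosine similarity on the raw (unsmoothed) vectors."""
    num = np.sum(p * q, axis=1)
    den = np.linalg.norm(p, axis=1) * np.linalg.norm(q, axis=1)
    out = np.full(len(p), np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def explanation_metrics(model, data, table: PriorTable,
                        partition: BandPartition, epsilon: float = 1e-8,
                        batch_size: int = 32):
    """Per-sample KL and cosine to the class prior, plus per-class means.

    Returns a dict with arrays ``kl``, ``cos``, ``labels`` and per-class
    means under ``mean_kl`` / ``mean_cos`` keyed by "normal"/"abnormal".
    Samples with zero-norm band mass get cosine NaN (reported missing).
    """
    mass, labels = _batched_band_mass(model, data, partition, epsilon,
                                      batch_size)
    priors = select_prior(labels, table)
    kl = kl_per_sample(mass, priors, epsilon)
    cos = _cosine_rows(mass, priors)
    out = {"kl": kl, "cos": cos, "labels": labels, "band_mass": mass,
           "mean_kl": {}, "mean_cos": {}}
    for name, lbl in (("normal", 0), ("abnormal", 1)):
        sel = labels == lbl
        if sel.any():
            out["mean_kl"][name] = float(np.mean(kl[sel]))
            out["mean_cos"][name] = float(np.nanmean(cos[sel]))
    return out


def delta_kl_fraction(kl_baseline, kl_model, labels):
    """Percentage of samples per class with KL improvement over baseline."""
    kl_baseline = np.asarray(kl_baseline, dtype=np.float64)
    kl_model = np.asarray(kl_model, dtype=np.float64)
    labels = _check_binary(labels, "labels")
    if not (len(kl_baseline) == len(kl_model) == len(labels)):
        raise ValueError("per-sample KL vectors must share the sample set")
    delta = kl_baseline - kl_model
    out = {}
    for name, lbl in (("normal", 0), ("abnormal", 1)):
        sel = labels == lbl
        if sel.any():
            out[name] = float(100.0 * np.mean(delta[sel] > 0))
    return out


def band_mass_report(model, data, partition: BandPartition,
                     epsilon: float = 1e-8, batch_size: int = 32):
    """Per-class mean band-mass 4-vectors (the bar-chart summary)."""
    mass, labels = _batched_band_mass(model, data, partition, epsilon,
                                      batch_size)
    out = {}
    for name, lbl in (("normal", 0), ("abnormal", 1)):
        sel = labels == lbl
        if sel.any():
            out[name] = np.mean(mass[sel], axis=0)
    return out


def apply_band_mask(X: np.ndarray, mode: str) -> np.ndarray:
    """Hard masking on the mel axis: zero outside the kept half.

    ``low_band`` keeps mel indices 0..F/2-1 (bands 1+2); ``high_band``
    keeps F/2..F-1 (bands 3+4).  Zero is the pad value of the feature
    domain, so masked bins also receive zero attribution.
    """
    if mode not in MASK_MODES:
        raise ValueError(f"unknown mask mode {mode!r}; valid: {MASK_MODES}")
    if mode == "none":
        return X
    F = X.shape[-1]
    out = X.copy()
    if mode == "low_band":
        out[..., F // 2:] = 0.0
    else:
        out[..., :F // 2] = 0.0
    return out


def predictions(model, data, batch_size: int = 32,
                mask_mode: str = "none") -> tuple[np.ndarray, np.ndarray]:
    """Argmax predictions (optionally under a hard band mask) and labels."""
    model.eval()
    preds, labels = [], []
    with ad.no_grad():
        for start in range(0, len(data), batch_size):
            chunk = data[start:start + batch_size]
            batch = batch_pad([s for s, _ in chunk], [l for _, l in chunk])
            X = apply_band_mask(batch.X, mask_mode)
            z = model(Tensor(X))
            preds.append(np.argmax(z.data, axis=1))
            labels.append(batch.y)
    return np.concatenate(preds), np.concatenate(labels)


def band_mask_eval(model, data, partition: BandPartition, mode: str = "none",
                   batch_size: int = 32):
    """(acc, sens, spec) of the unmodified model on masked inputs."""
    preds, labels = predictions(model, data, batch_size, mask_mode=mode)
    _, metrics = classification_metrics(preds, labels)
    return metrics


def sanity_check(model, data, partition: BandPartition, variant: str,
                 epsilon: float = 1e-8, batch_size: int = 32):
    """Rescore the same attributions against a named prior table.

    The model and its attributions are unchanged; only the reference
    distribution varies ("clinical", "uniform" or "wrong").
    """
    from .priors import get_prior_table

    table = get_prior_table(variant)
    return explanation_metrics(model, data, table, partition, epsilon,
                               batch_size)
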