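"""Training protocols, seeded splitting, and the lambda grid search.

Protocols
---------
``CE-30``    30 epochs of plain cross-entropy.
``CE-60``    60 epochs of plain cross-entropy.
``SCA-long`` 30 epochs of cross-entropy, then 30 epochs with the
             attribution-alignment term switched on (same optimizer state,
             no restart).
``SCA-all``  the joint objective for all 60 epochs from random init.
``L2-feat``  60 epochs of cross-entropy plus an L2 penalty on the
             penultimate features h (an uninformed-regularization baseline).

The alignment term is only computed on epochs where lambda > 0, since it
requires a second-order backward pass.  Randomness is split across three
named seeds — split, init, shuffle — so ablations can vary one source at a
time; everything is NumPy-based and fully deterministic under fixed seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .backbones import BackboneSpec, build_backbone
from .features import FeatureConfig, Spectrogram, batch_pad
from .priors import get_prior_table, make_band_partition
from .sca import SCAConfig, sca_objective

__all__ = ["TrainingProtocol", "RunConfig", "make_protocol", "split_records",
           "run_protocol", "grid_search_lambda", "PROTOCOL_NAMES"]

PROTOCOL_NAMES = ("CE-30", "CE-60", "SCA-long", "SCA-all", "L2-feat")

L2_GRID = (0.05, 0.1, 0.2, 0.3, 0.5)
LAMBDA_GRID = (0.05, 0.1, 0.2, 0.3, 0.5)


@dataclass
class TrainingProtocol:
    name: str
    total_epochs: int
    lambda_schedule: list[float]   # one lambda_sca per epoch
    l2_weight: float = 0.0

    def __post_init__(self):
        if len(self.lambda_schedule) != self.total_epochs:
            raise ValueError("lambda_schedule length must equal total_epochs")


def make_protocol(name: str, lambda_sca: float = 0.3, l2_weight: float = 0.1,
                  total_epochs: int | None = None) -> TrainingProtocol:
    """Instantiate a named protocol; ``total_epochs`` rescales desk runs.

    For ``SCA-long`` the first half of the epochs is plain cross-entropy
    and the second half adds the alignment term.
    """
    if name == "CE-30":
        n = total_epochs or 30
        return TrainingProtocol(name, n, [0.0] * n)
    if name == "CE-60":
        n = total_epochs or 60
        return TrainingProtocol(name, n, [0.0] * n)
    if name == "SCA-long":
        n = total_epochs or 60
        warm = n // 2
        return TrainingProtocol(name, n, [0.0] * warm + [lambda_sca] * (n - warm))
    if name == "SCA-all":
        n = total_epochs or 60
        return TrainingProtocol(name, n, [lambda_sca] * n)
    if name == "L2-feat":
        n = total_epochs or 60
        if l2_weight <= 0:
            raise ValueError("L2-feat requires a positive l2_weight")
        return TrainingProtocol(name, n, [0.0] * n, l2_weight=l2_weight)
    raise ValueError(f"unknown protocol {name!r}; valid: {PROTOCOL_NAMES}")


@dataclass
class RunConfig:
    protocol: str = "SCA-all"
    backbone: str = "smallcnn"
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 32
    lambda_sca: float = 0.3
    l2_weight: float = 0.1
    epsilon: float = 1e-8
    precision: str = "float32"  # training dtype; evaluation stays float64
    total_epochs: int | None = None
    prior: str = "clinical"
    split_seed: int = 2025
    init_seed: int = 0
    shuffle_seed: int = 0
    features: FeatureConfig = field(default_factory=FeatureConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def split_records(manifest: pd.DataFrame, ratio: float = 0.9,
                  seed: int = 2025, force: bool = False) -> pd.DataFrame:
    """Record-level random train/val split at ``ratio``, seeded.

    The train count is ``round(ratio * n)`` so it differs from the exact
    ratio by at most one record (3240 records at 9:1 give 2916/324).
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"split ratio must be in (0, 1), got {ratio}")
    if "split" in manifest.columns and manifest["split"].notna().any() and not force:
        raise ValueError("manifest already has split assignments; pass force=True")
    n = len(manifest)
    n_train = int(round(ratio * n))
    order = np.random.default_rng(seed).permutation(n)
    split = np.empty(n, dtype=object)
    split[order[:n_train]] = "train"
    split[order[n_train:]] = "val"
    out = manifest.copy()
    out["split"] = split
    return out


# --------------------------------------------------------------------------
# Training loop
# --------------------------------------------------------------------------

Dataset = list[tuple[Spectrogram, int]]


def _batches(data: Dataset, batch_size: int, rng: np.random.Generator | None):
    order = (rng.permutation(len(data)) if rng is not None
             else np.arange(len(data)))
    for start in range(0, len(data), batch_size):
        idx = order[start:start + batch_size]
        specs = [data[i][0] for i in idx]
        labels = [data[i][1] for i in idx]
        yield batch_pad(specs, labels)


def predict(model, data: Dataset, batch_size: int = 32) -> np.ndarray:
    """Argmax class predictions in evaluation mode."""
    model.eval()
    preds = []
    with ad.no_grad():
        for batch in _batches(data, batch_size, None):
            z = model(Tensor(batch.X))
            preds.append(np.argmax(z.data, axis=1))
    return np.concatenate(preds) if preds else np.empty(0, dtype=np.intp)


def run_protocol(cfg: RunConfig, train_data: Dataset, val_data: Dataset,
                 protocol: TrainingProtocol | None = None,
                 verbose: bool = False):
    """Train a backbone under a protocol; returns (model, per-epoch log).

    The log records the mean cross-entropy, the mean alignment loss (zero
    on epochs where lambda is zero — the second-order pass is skipped
    entirely then), the combined objective, and validation accuracy.
    """
    protocol = protocol or make_protocol(
        cfg.protocol, lambda_sca=cfg.lambda_sca, l2_weight=cfg.l2_weight,
        total_epochs=cfg.total_epochs)
    dtype = np.float32 if cfg.precision == "float32" else np.float64
    with ad.default_dtype(dtype):
        return _run_protocol_inner(cfg, protocol, train_data, val_data,
                                   verbose)


def _run_protocol_inner(cfg: RunConfig, protocol: TrainingProtocol,
                        train_data: Dataset, val_data: Dataset,
                        verbose: bool):
    model = build_backbone(BackboneSpec(name=cfg.backbone,
                                        init_seed=cfg.init_seed))
    table = get_prior_table(cfg.prior)
    partition = make_band_partition(cfg.features.n_mels, 4,
                                    cfg.features.fmin, cfg.features.fmax,
                                    cfg.features.mel_variant)
    opt = Adam(model.parameters(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    params = model.parameters()
    log: list[dict] = []
    for epoch, lam in enumerate(protocol.lambda_schedule, start=1):
        model.train()
        rng = np.random.default_rng([cfg.shuffle_seed, epoch])
        ce_vals, sca_vals, tot_vals = [], [], []
        for batch in _batches(train_data, cfg.batch_size, rng):
            if lam > 0:
                sca_cfg = SCAConfig(lambda_sca=lam, epsilon=cfg.epsilon,
                                    differentiable=True)
                breakdown, _ = sca_objective(model, batch, table, partition,
                                             sca_cfg)
                loss_t = breakdown.total_t
                ce_vals.append(breakdown.ce)
                sca_vals.append(breakdown.sca)
                del breakdown
            else:
                z = model(Tensor(batch.X))
                loss_t = ad.cross_entropy(z, batch.y)
                ce_vals.append(loss_t.item())
                if protocol.l2_weight > 0:
                    h = model.features(Tensor(batch.X))
                    pen = ad.tmean(ad.tsum(ad.power(h, 2.0), axis=1))
                    loss_t = ad.add(loss_t, ad.mul(
                        Tensor(protocol.l2_weight), pen))
            tot_vals.append(loss_t.item())
            if not np.isfinite(loss_t.item()):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; aborting")
            grads = ad.grad(loss_t, params)
            opt.step(grads)
            del loss_t, grads  # release the step's graph before the next one
        val_preds = predict(model, val_data, cfg.batch_size)
        val_labels = np.array([lbl for _, lbl in val_data])
        val_acc = float(np.mean(val_preds == val_labels)) if len(val_data) else float("nan")
        entry = {"epoch": epoch, "lambda_sca": lam,
                 "ce": float(np.mean(ce_vals)),
                 "sca": float(np.mean(sca_vals)) if sca_vals else 0.0,
                 "total": float(np.mean(tot_vals)),
                 "val_acc": val_acc}
        log.append(entry)
        if verbose:
            print(f"epoch {epoch:3d} lam={lam:.2f} "
                  f"ce={entry['ce']:.4f} sca={entry['sca']:.4f} "
                  f"val_acc={val_acc:.4f}")
    model.eval()
    return model, log


def _mean_val_kl(model, val_data: Dataset, cfg: RunConfig) -> float:
    """Mean per-sample KL of attributions to the configured prior table."""
    from .evaluation import explanation_metrics

    table = get_prior_table(cfg.prior)
    partition = make_band_partition(cfg.features.n_mels, 4,
                                    cfg.features.fmin, cfg.features.fmax,
                                    cfg.features.mel_variant)
    if not val_data:
        return float("nan")
    exp = explanation_metrics(model, val_data, table, partition,
                              epsilon=cfg.epsilon, batch_size=cfg.batch_size)
    return float(np.mean(exp["kl"]))


def l2_feature_protocol(cfg: RunConfig, train_data: Dataset,
                        val_data: Dataset, verbose: bool = False):
    """Train the uninformed-regularization baseline: CE + l2 * ||h||^2.

    ``h`` is the penultimate feature vector; the penalty is the batch mean
    of the squared norms.  Same logging contract as :func:`run_protocol`.
    """
    sub = RunConfig(**{**cfg.to_dict(), "protocol": "L2-feat",
                       "features": cfg.features})
    return run_protocol(sub, train_data, val_data, verbose=verbose)


def grid_search_lambda(cfg: RunConfig, train_data: Dataset, val_data: Dataset,
                       candidates=LAMBDA_GRID, verbose: bool = False):
    """Train one model per lambda with shared seeds, pick by val accuracy.

    Ties break toward lower mean validation KL, then toward smaller lambda.
    Returns ``(best_lambda, table)`` where the table has one row per
    candidate with its final validation metrics.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("grid search needs at least one candidate lambda")
    rows = []
    for lam in candidates:
        sub = RunConfig(**{**cfg.to_dict(), "lambda_sca": lam,
                           "features": cfg.features})
        model, log = run_protocol(sub, train_data, val_data)
        rows.append({"lambda_sca": lam,
                     "val_acc": log[-1]["val_acc"],
                     "val_mean_kl": _mean_val_kl(model, val_data, sub)})
        if verbose:
            print(rows[-1])
    table = pd.DataFrame(rows)
    best = table.sort_values(
        ["val_acc", "val_mean_kl", "lambda_sca"],
        ascending=[False, True, True]).iloc[0]
    return float(best["lambda_sca"]), table
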