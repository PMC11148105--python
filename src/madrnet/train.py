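"""Training, evaluation, and prediction runtime.

The training protocol defaults mirror the study conditions: Adam with
learning rate 1e-3, batch size 16, up to 500 epochs with an 80/10/10
train/validation/test split and reduce-on-plateau learning-rate decay.
Runs are fully seeded: the same configuration and seed reproduce the same
parameter trajectory and logs.

Checkpoints are a binary ``.npz`` weights file plus a JSON sidecar holding
the model configuration and the layer registry, so a checkpoint is
self-describing.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import metrics as _metrics
from .losses import LossConfig, hybrid_components, hybrid_loss
from .model import MADRNet, ModelConfig, build_model
from .optim import Adam, ReduceLROnPlateau
from .synthetic import masks_to_targets, split_dataset


@dataclass
class TrainConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 500
    max_steps: int | None = None
    seed: int = 0
    threshold: float = 0.5
    reduce_on_plateau: bool = True
    plateau_factor: float = 0.5
    plateau_patience: int = 20

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.epochs < 1 or self.epochs > 500:
            raise ValueError("epochs must be in [1, 500]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"] = self.model.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        model = d.pop("model", {})
        if not isinstance(model, ModelConfig):
            model = ModelConfig.from_dict(model)
        loss = d.pop("loss", {})
        if not isinstance(loss, LossConfig):
            loss = LossConfig(**{k: tuple(v) if k == "weights" else v
                                 for k, v in loss.items()})
        return cls(model=model, loss=loss, **d)


# ----------------------------------------------------------------- checkpoint
def save_checkpoint(model: MADRNet, path: str | Path, extra: dict | None = None) -> Path:
    """Write ``<path>.npz`` (weights) and ``<path>.json`` (config sidecar)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    sidecar = {
        "model_config": model.cfg.to_dict(),
        "layer_registry": model.registry.to_list(),
    }
    if extra:
        sidecar.update(extra)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npz")


def load_checkpoint(path: str | Path) -> tuple[MADRNet, dict]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    model, _ = build_model(ModelConfig.from_dict(sidecar["model_config"]))
    with np.load(path.with_suffix(".npz")) as npz:
        model.load_state_dict({k: npz[k] for k in npz.files})
    return model, sidecar


# ----------------------------------------------------------------- inference
def predict_probabilities(model: MADRNet, images: np.ndarray,
                          batch_size: int = 16) -> np.ndarray:
    """Forward a (N, C, H, W) stack in eval mode; returns probabilities."""
    model.eval()
    outs = []
    for i in range(0, len(images), batch_size):
        outs.append(model(images[i : i + batch_size]).numpy())
    return np.concatenate(outs, axis=0)


def probabilities_to_labels(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Sigmoid maps -> {0,1} by threshold; softmax maps -> per-pixel argmax."""
    if probs.shape[1] == 1:
        return (probs[:, 0] >= threshold).astype(np.uint8)
    return probs.argmax(axis=1).astype(np.uint8)


def _mean_dsc(model: MADRNet, images: np.ndarray, masks: np.ndarray,
              threshold: float, batch_size: int = 16) -> float:
    probs = predict_probabilities(model, images, batch_size)
    pred = probabilities_to_labels(probs, threshold)
    M = model.cfg.num_classes
    scores = []
    for gt, pr in zip(masks, pred):
        if M == 1:
            scores.append(_metrics.dsc(_metrics.confusion_counts(gt, pr)))
        else:
            rep = _metrics.multiclass_report(gt, pr, M, include_background=False)
            scores.append(rep["macro"]["dsc"])
    return float(np.mean(scores))


# ------------------------------------------------------------------- training
class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def train(cfg: TrainConfig, images: np.ndarray, masks: np.ndarray,
          out_dir: str | Path, verbose: bool = False) -> dict:
    """Train a model; returns a summary dict.

    Writes ``training_log.csv`` (per-epoch loss components, validation DSC,
    learning rate) and retains the best-validation-DSC checkpoint as
    ``best`` plus the final state as ``last`` under ``out_dir``.

    With fewer than 10 samples no split is made and the full set serves as
    both training and validation data (the overfitting regime used for
    capacity checks).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = len(images)
    if n >= 10:
        tr, va, _te = split_dataset(n, cfg.seed)
    else:
        tr = va = np.arange(n)
    x_tr, m_tr = images[tr], masks[tr]
    x_va, m_va = images[va], masks[va]
    t_tr = masks_to_targets(m_tr, cfg.model.num_classes)

    model, _ = build_model(cfg.model)
    opt = Adam(list(model.parameters()), lr=cfg.learning_rate)
    sched = ReduceLROnPlateau(opt, mode="max", factor=cfg.plateau_factor,
                              patience=cfg.plateau_patience)
    rng = np.random.default_rng(cfg.seed + 1)
    bs = min(cfg.batch_size, len(x_tr))

    log_path = out_dir / "training_log.csv"
    best_dsc, best_epoch = -1.0, -1
    step = 0
    history = []
    with open(log_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "step", "loss", "ce", "dice", "focal_tversky",
                         "val_dsc", "lr"])
        for epoch in range(cfg.epochs):
            model.train()
            order = rng.permutation(len(x_tr))
            epoch_loss, comps_acc, n_batches = 0.0, None, 0
            for i in range(0, len(order), bs):
                batch = order[i : i + bs]
                probs = model(x_tr[batch])
                loss = hybrid_loss(probs, t_tr[batch], cfg.loss)
                value = loss.item()
                if not np.isfinite(value):
                    raise DivergenceError(
                        f"non-finite loss {value} at epoch {epoch}, step {step}"
                    )
                comps = hybrid_components(probs.detach(), t_tr[batch], cfg.loss)
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += value
                comps_acc = (comps if comps_acc is None else
                             {k: comps_acc[k] + v for k, v in comps.items()})
                n_batches += 1
                step += 1
                if cfg.max_steps is not None and step >= cfg.max_steps:
                    break
            val_dsc = _mean_dsc(model, x_va, m_va, cfg.threshold)
            writer.writerow([
                epoch, step, f"{epoch_loss / n_batches:.6f}",
                f"{comps_acc['ce'] / n_batches:.6f}",
                f"{comps_acc['dice'] / n_batches:.6f}",
                f"{comps_acc['focal_tversky'] / n_batches:.6f}",
                f"{val_dsc:.6f}", f"{opt.lr:.2e}",
            ])
            history.append({"epoch": epoch, "loss": epoch_loss / n_batches,
                            "val_dsc": val_dsc})
            if verbose:
                print(f"epoch {epoch:4d}  loss {epoch_loss / n_batches:.4f}  "
                      f"val DSC {val_dsc:.4f}")
            if val_dsc > best_dsc:
                best_dsc, best_epoch = val_dsc, epoch
                save_checkpoint(model, out_dir / "best",
                                {"epoch": epoch, "val_dsc": val_dsc})
            if cfg.reduce_on_plateau:
                sched.step(val_dsc)
            if cfg.max_steps is not None and step >= cfg.max_steps:
                break
    save_checkpoint(model, out_dir / "last", {"epoch": epoch})
    (out_dir / "train_config.json").write_text(json.dumps(cfg.to_dict(), indent=1))
    return {"best_val_dsc": best_dsc, "best_epoch": best_epoch, "steps": step,
            "epochs_run": epoch + 1, "log": str(log_path), "history": history,
            "model": model}


# ----------------------------------------------------------------- evaluation
def evaluate(model: MADRNet, images: np.ndarray, masks: np.ndarray,
             threshold: float = 0.5) -> dict:
    """Per-image and summary metrics for a model on labelled data.

    Binary: DSC/IoU/accuracy/precision/recall per image.  Multiclass: the
    same macro metrics plus per-class dice columns.  The summary row is the
    mean of the per-image metrics.
    """
    M = model.cfg.num_classes
    if masks.max() >= max(M, 2):
        raise ValueError(f"mask labels exceed the model's {M} classes")
    probs = predict_probabilities(model, images)
    pred = probabilities_to_labels(probs, threshold)
    rows = []
    for i, (gt, pr) in enumerate(zip(masks, pred)):
        if M == 1:
            row = {"image": i, **_metrics.all_metrics(_metrics.confusion_counts(gt, pr))}
        else:
            rep = _metrics.multiclass_report(gt, pr, M, include_background=False)
            row = {"image": i, **rep["macro"]}
            for m in range(1, M):
                row[f"dsc_class{m}"] = rep["per_class"][m]["dsc"]
        rows.append(row)
    keys = [k for k in rows[0] if k != "image"]
    summary = {k: float(np.mean([r[k] for r in rows])) for k in keys}
    return {"per_image": rows, "summary": summary, "threshold": threshold}


def write_report(report: dict, out_dir: str | Path, stem: str = "metrics") -> None:
    """Write an evaluation report as CSV (per-image + summary rows) and JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / f"{stem}.json").write_text(json.dumps(report, indent=1))
    rows = report["per_image"]
    keys = list(rows[0].keys())
    with open(out_dir / f"{stem}.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        writer.writerows(rows)
        writer.writerow({"image": "mean", **report["summary"]})
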