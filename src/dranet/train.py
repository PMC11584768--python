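"""Training and evaluation loops.

Defaults follow the published recipe: Adam (weight decay 1e-4), initial
learning rate 1e-3 cosine-annealed to 1e-5, batch size 4, 400 epochs,
224x224 inputs, with rotation / flip / contrast augmentation.  One master
seed drives the train/val split, shuffling, augmentation and weight
initialization, and is recorded in the checkpoint.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .data import load_dataset, save_mask_png
from .errors import InvalidInputError
from .losses import total_loss
from .metrics import (aggregate_reports, confusion_counts, evaluate_metrics,
                      metrics_from_counts, write_reports)
from .model import DRANet, ModelConfig, assemble, load_checkpoint, save_checkpoint
from .nn import Adam, cosine_annealing

logger = logging.getLogger("dranet")

__all__ = ["TrainConfig", "train", "evaluate", "predict", "sweep_k"]


@dataclass
class TrainConfig:
    lr: float = 1e-3
    lr_min: float = 1e-5
    schedule: str = "cosine"
    optimizer: str = "adam"
    weight_decay: float = 1e-4
    batch_size: int = 4
    epochs: int = 400
    input_size: int = 224
    augmentations: tuple[str, ...] = ("rotate", "flip", "contrast")
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not self.lr > self.lr_min > 0:
            raise InvalidInputError("need lr > lr_min > 0")
        if self.epochs < 1:
            raise InvalidInputError("epochs must be >= 1")

    def to_dict(self):
        return dataclasses.asdict(self)


def _augment(img: np.ndarray, mask: np.ndarray, kinds, rng: np.random.Generator):
    """Right-angle rotation, horizontal/vertical flips (p=0.5 each), and
    +/-20% contrast jitter about the image mean."""
    if "rotate" in kinds:
        k = int(rng.integers(0, 4))
        if k:
            img, mask = np.rot90(img, k, axes=(0, 1)), np.rot90(mask, k, axes=(0, 1))
    if "flip" in kinds:
        if rng.random() < 0.5:
            img, mask = img[::-1], mask[::-1]
        if rng.random() < 0.5:
            img, mask = img[:, ::-1], mask[:, ::-1]
    if "contrast" in kinds:
        f = 1.0 + rng.uniform(-0.2, 0.2)
        mean = img.mean()
        img = np.clip(mean + (img - mean) * f, 0.0, 1.0)
    return np.ascontiguousarray(img), np.ascontiguousarray(mask)


def _mean_val_dice(model: DRANet, samples, threshold: float = 0.5) -> float:
    dices = []
    for s in samples:
        pred = model(s.image).data
        dices.append(evaluate_metrics(pred, s.mask, threshold).dice)
    return float(np.mean(dices)) / 100.0


def train(model_cfg: ModelConfig, train_cfg: TrainConfig, data_root,
          out_dir, log_every: int = 1) -> dict:
    """Train on the ``train`` split, validating on a held-out fraction.

    Writes the best-validation-Dice checkpoint (``checkpoint.npz``), the
    final-epoch checkpoint and a per-epoch loss curve CSV to ``out_dir``.
    Returns the history dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(train_cfg.seed)
    samples = load_dataset(data_root, "train", input_size=train_cfg.input_size)
    if not samples:
        raise InvalidInputError(f"no training samples under {data_root}")
    order = rng.permutation(len(samples))
    n_val = max(1, int(round(train_cfg.val_fraction * len(samples)))) if len(samples) > 1 else 0
    val = [samples[i] for i in order[:n_val]]
    tr = [samples[i] for i in order[n_val:]]

    model = assemble(model_cfg, seed=train_cfg.seed)
    opt = Adam(model.parameters(), lr=train_cfg.lr, weight_decay=train_cfg.weight_decay)
    history = {"epoch": [], "lr": [], "loss": [], "val_dice": []}
    best = {"dice": -1.0, "epoch": -1}

    for epoch in range(train_cfg.epochs):
        lr = (cosine_annealing(epoch, train_cfg.epochs, train_cfg.lr, train_cfg.lr_min)
              if train_cfg.schedule == "cosine" else train_cfg.lr)
        opt.lr = lr
        idx = rng.permutation(len(tr))
        losses = []
        for start in range(0, len(tr), train_cfg.batch_size):
            batch = [tr[i] for i in idx[start:start + train_cfg.batch_size]]
            imgs, masks = zip(*(_augment(s.image, s.mask, train_cfg.augmentations, rng)
                                for s in batch))
            x = np.stack(imgs)
            y = np.stack(masks).astype(np.float64)
            pred = model(x)
            loss = total_loss(pred, y)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch images "
                    f"{[s.name for s in batch]}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        val_dice = _mean_val_dice(model, val) if val else float("nan")
        history["epoch"].append(epoch)
        history["lr"].append(lr)
        history["loss"].append(float(np.mean(losses)))
        history["val_dice"].append(val_dice)
        if epoch % log_every == 0:
            logger.info("epoch %d lr %.2e loss %.4f val_dice %.4f",
                        epoch, lr, history["loss"][-1], val_dice)
        if not val or val_dice >= best["dice"]:
            best = {"dice": val_dice, "epoch": epoch}
            save_checkpoint(model, out / "checkpoint.npz",
                            extra={"epoch": epoch, "val_dice": val_dice,
                                   "seed": train_cfg.seed,
                                   "train_config": train_cfg.to_dict()})
    save_checkpoint(model, out / "checkpoint_final.npz",
                    extra={"epoch": train_cfg.epochs - 1, "val_dice": history["val_dice"][-1],
                           "seed": train_cfg.seed, "train_config": train_cfg.to_dict()})
    with open(out / "loss_curve.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "lr", "loss", "val_dice"])
        writer.writerows(zip(*history.values()))
    history["best"] = best
    return history


def evaluate(checkpoint, data_root, split: str = "test", out_dir=None,
             threshold: float = 0.5, aggregate: str = "per_image") -> dict:
    """Run inference over a split; write per-image + aggregate metrics
    (JSON/CSV) and predicted masks (PNG) when ``out_dir`` is given."""
    model, extra = (checkpoint, {}) if isinstance(checkpoint, DRANet) \
        else load_checkpoint(checkpoint)
    size = model.cfg.input_size[0]
    samples = load_dataset(data_root, split, input_size=size)
    reports, counts, names = [], [], []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        (out / "predictions").mkdir(parents=True, exist_ok=True)
    for s in samples:
        pred = model(s.image).data
        counts.append(confusion_counts(pred, s.mask, threshold))
        reports.append(metrics_from_counts(counts[-1]))
        names.append(s.name)
        if out is not None:
            save_mask_png(pred >= threshold, out / "predictions" / f"{s.name}.png")
    agg = aggregate_reports(reports, counts, mode=aggregate)
    result = {"aggregate": agg.to_dict(), "per_image": {n: r.to_dict()
              for n, r in zip(names, reports)}, "mode": aggregate}
    if out is not None:
        write_reports(out / "metrics", names, reports, agg)
    return result


def predict(checkpoint, image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    model, _ = (checkpoint, None) if isinstance(checkpoint, DRANet) \
        else load_checkpoint(checkpoint)
    prob = model(image).data
    return (prob >= threshold).astype(np.uint8)


def sweep_k(model_cfg: ModelConfig, train_cfg: TrainConfig, data_root, out_dir,
            k_values=(5, 10, 15, 20, 25), plot: bool = True) -> list[dict]:
    """Train/evaluate one model per region count ``k`` under identical seeds
    and emit a k-vs-metrics comparison table (CSV) and plot."""
    if not k_values:
        raise InvalidInputError("k_values must be nonempty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    shared = {"seed": train_cfg.seed, "epochs": train_cfg.epochs,
              "lr": train_cfg.lr, "mode": model_cfg.dra.mode,
              "input_size": train_cfg.input_size}
    rows = []
    for k in k_values:
        cfg_k = dataclasses.replace(model_cfg, dra=replace(model_cfg.dra, k=k))
        run_dir = out / f"k{k}"
        train(cfg_k, train_cfg, data_root, run_dir)
        result = evaluate(run_dir / "checkpoint.npz", data_root, "test", run_dir)
        rows.append({"k": k, **result["aggregate"], **shared})
        logger.info("k=%d -> %s", k, result["aggregate"])
    with open(out / "sweep_k.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    (out / "sweep_k.json").write_text(json.dumps(rows, indent=2))
    if plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        ks = [r["k"] for r in rows]
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.plot(ks, [r["iou"] for r in rows], "o-", label="IoU")
        ax.plot(ks, [r["dice"] for r in rows], "s-", label="Dice")
        ax.set_xlabel("region count k")
        ax.set_ylabel("%")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "sweep_k.png", dpi=120)
        plt.close(fig)
    return rows
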