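"""Training loop, evaluation and the five-variant ablation harness."""

from __future__ import annotations

import csv
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .backbone import SegmentationModel, predict_mask, save_checkpoint
from .config import VARIANT_LABELS, VARIANTS, ModelConfig, TrainConfig
from .losses import combined_loss
from .metrics import ConfusionCounts, confusion, metrics_row
from .nn import Adam, Tensor
from .nn.modules import DTYPE
from .synthetic import SamplePair, augment_flip

__all__ = ["EpochRecord", "TrainResult", "train", "evaluate", "run_ablation"]


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    train_precision_pct: float
    val_dice_pct: float
    val_precision_pct: float


@dataclass
class TrainResult:
    model: SegmentationModel
    history: list[EpochRecord]
    checkpoint: Path | None = None
    history_csv: Path | None = None


def _to_batch(pairs: list[SamplePair]) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([p.image for p in pairs])[:, None].astype(DTYPE)
    masks = np.stack([p.mask for p in pairs])[:, None].astype(DTYPE)
    return images, masks


def _pooled_confusion(
    model: SegmentationModel, pairs: list[SamplePair], batch_size: int = 8
) -> ConfusionCounts:
    total = ConfusionCounts()
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start : start + batch_size]
        images, masks = _to_batch(chunk)
        prob = model.predict_proba(images)
        pred = predict_mask(prob)
        total = total + confusion(pred.ravel(), masks.astype(np.uint8).ravel())
    return total


def train(
    train_cfg: TrainConfig,
    model_cfg: ModelConfig,
    corpus: dict[str, list[SamplePair]],
    out_dir: str | Path | None = None,
    *,
    log: bool = False,
) -> TrainResult:
    """Train a model on ``corpus`` ({"train": [...], "val": [...]}).

    Writes a checkpoint and per-epoch history CSV to ``out_dir`` when given.
    Raises on NaN loss, naming the offending step.
    """
    train_pairs = corpus.get("train", [])
    if not train_pairs:
        raise ValueError("empty training corpus")
    val_pairs = corpus.get("val", [])

    model = SegmentationModel(model_cfg, seed=train_cfg.seed)
    opt = Adam(model.parameters(), lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed + 1)

    history: list[EpochRecord] = []
    n = len(train_pairs)
    step = 0
    for epoch in range(1, train_cfg.epochs + 1):
        if train_cfg.cosine_decay:
            opt.lr = train_cfg.learning_rate * 0.5 * (
                1.0 + np.cos(np.pi * (epoch - 1) / train_cfg.epochs)
            )
        model.train()
        order = rng.permutation(n)
        losses = []
        epoch_counts = ConfusionCounts()
        for start in range(0, n, train_cfg.batch_size):
            batch = [train_pairs[i] for i in order[start : start + train_cfg.batch_size]]
            if train_cfg.augment:
                batch = [
                    SamplePair(*augment_flip(p.image, p.mask, rng)) for p in batch
                ]
            images, masks = _to_batch(batch)
            step += 1
            scores = model(Tensor(images))
            prob = model.probability(scores)
            loss = combined_loss(prob, Tensor(masks), train_cfg.loss)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss {loss.item()} at step {step} "
                    f"(epoch {epoch})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            pred = predict_mask(np.clip(prob.data, 0.0, 1.0))
            epoch_counts = epoch_counts + confusion(
                pred.ravel(), masks.astype(np.uint8).ravel()
            )
        train_prec = metrics_row(epoch_counts)["precision_pct"]
        if val_pairs and epoch % train_cfg.val_every == 0:
            vrow = metrics_row(_pooled_confusion(model, val_pairs))
        else:
            vrow = {"dice_pct": float("nan"), "precision_pct": float("nan")}
        rec = EpochRecord(
            epoch=epoch,
            train_loss=float(np.mean(losses)),
            train_precision_pct=train_prec,
            val_dice_pct=vrow["dice_pct"],
            val_precision_pct=vrow["precision_pct"],
        )
        history.append(rec)
        if log:
            print(
                f"epoch {epoch:3d}  loss {rec.train_loss:.4f}  "
                f"val dice {rec.val_dice_pct:.2f}%"
            )

    result = TrainResult(model=model, history=history)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.checkpoint = save_checkpoint(model, out_dir / "checkpoint.npz")
        result.history_csv = out_dir / "history.csv"
        with result.history_csv.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["epoch", "train_loss", "train_precision_pct", "val_dice_pct", "val_precision_pct"]
            )
            for r in history:
                writer.writerow(
                    [r.epoch, r.train_loss, r.train_precision_pct, r.val_dice_pct, r.val_precision_pct]
                )
        (out_dir / "train_config.json").write_text(
            json.dumps(
                {
                    "epochs": train_cfg.epochs,
                    "batch_size": train_cfg.batch_size,
                    "learning_rate": train_cfg.learning_rate,
                    "optimizer": train_cfg.optimizer,
                    "alpha": train_cfg.loss.alpha,
                    "beta": train_cfg.loss.beta,
                    "seed": train_cfg.seed,
                    "variant": model_cfg.variant,
                },
                indent=2,
            )
        )
    return result


def evaluate(
    model: SegmentationModel,
    pairs: list[SamplePair],
    *,
    macro_average: bool = False,
) -> dict[str, float]:
    """Metrics row over a corpus split.

    Default is the micro average (metrics of the pooled pixel counts);
    ``macro_average`` averages per-image metrics instead, skipping images
    where a metric is undefined.
    """
    if macro_average:
        rows = [metrics_row(_pooled_confusion(model, [p])) for p in pairs]
        return {
            k: float(np.nanmean([r[k] for r in rows])) for k in rows[0]
        }
    return metrics_row(_pooled_confusion(model, pairs))


def run_ablation(
    train_cfg: TrainConfig,
    model_cfg: ModelConfig,
    corpus: dict[str, list[SamplePair]],
    *,
    variants: tuple[str, ...] = VARIANTS,
    split: str = "val",
    log: bool = False,
) -> list[dict]:
    """Train/evaluate the ablation variants on identical data and schedule.

    Returns one row per variant: label, the four metrics, parameter count
    and wall time.  All rows share the seed and corpus.
    """
    for v in variants:
        if v not in VARIANTS:
            raise ValueError(
                f"unknown variant {v!r}; valid: {', '.join(VARIANTS)}"
            )
    rows = []
    for v in variants:
        cfg_v = ModelConfig.from_dict({**model_cfg.to_dict(), "variant": v})
        t0 = time.perf_counter()
        result = train(train_cfg, cfg_v, corpus, log=log)
        row = {"variant": VARIANT_LABELS[v], **evaluate(result.model, corpus[split])}
        row["n_parameters"] = result.model.n_parameters()
        row["seconds"] = time.perf_counter() - t0
        rows.append(row)
        if log:
            print(row)
    return rows
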