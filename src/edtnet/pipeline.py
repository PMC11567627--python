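"""Training, evaluation and prediction.

The training loop follows the reference procedure: resize inputs to the
model's image size, split 80/20 into train/validation, optimize the hybrid
Dice + cross-entropy loss with Adam, log per-epoch train/validation loss
and validation IoU, and write a checkpoint plus a loss-curve plot. All
randomness (split, shuffling, parameter init) derives from the run seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from . import autodiff as ad
from .losses import hybrid_loss
from .metrics import MetricsReport, evaluate_masks, reports_to_frame
from .model import EDTNet, ModelConfig, build_edtnet
from .nn import Adam
from .phantoms import (ImageSample, load_dataset, split_dataset,
                       _resize_image, _resize_mask)

__all__ = ["RunConfig", "TrainResult", "train", "fit_samples", "evaluate",
           "evaluate_model", "predict", "save_checkpoint", "load_checkpoint"]

logger = logging.getLogger("edtnet")


@dataclass(frozen=True)
class RunConfig:
    """Optimization and bookkeeping settings for one training run."""

    model: ModelConfig = field(default_factory=ModelConfig)
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 64
    epochs: int = 200
    train_fraction: float = 0.8
    leak_free: bool = True
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer.lower() != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")

    @classmethod
    def tiny(cls, **overrides) -> "RunConfig":
        """Desk-scale preset: tiny model, batch 8, Adam lr 1e-3."""
        base = dict(model=ModelConfig.tiny(), batch_size=8,
                    learning_rate=1e-3, epochs=25)
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"] = self.model.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["model"] = ModelConfig.from_dict(d["model"])
        return cls(**d)


@dataclass
class TrainResult:
    checkpoint_path: Path
    records: pd.DataFrame  # epoch, train_loss, val_loss, val_iou
    model: EDTNet


# -- sample <-> array plumbing ------------------------------------------

def _resize_sample(sample: ImageSample, size: int) -> ImageSample:
    if sample.mask.shape[0] == size and sample.mask.shape[1] == size:
        return sample
    return ImageSample(id=sample.id, image=_resize_image(sample.image, size),
                       mask=_resize_mask(sample.mask, size),
                       source_id=sample.source_id)

def _stack(samples: Sequence[ImageSample]) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([s.image.transpose(2, 0, 1) for s in samples])
    masks = np.stack([s.mask.astype(np.float64) for s in samples])
    return images, masks


# -- checkpoints --------------------------------------------------------

def save_checkpoint(model: EDTNet, path: str | Path) -> Path:
    """Serialize parameters and the embedded ModelConfig to one .npz file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)
    return path


def load_checkpoint(path: str | Path) -> EDTNet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(path) as data:
        cfg = ModelConfig.from_dict(
            json.loads(bytes(data["__config__"].tobytes()).decode()))
        state = {k: data[k] for k in data.files if k != "__config__"}
    model = build_edtnet(cfg)
    model.load_state_dict(state)
    return model


# -- optimization core ---------------------------------------------------

def _loss_on_batch(model: EDTNet, images: np.ndarray, masks: np.ndarray,
                   alpha: float):
    logits = model(images)
    probs = ad.sigmoid(logits).reshape(*masks.shape)
    return hybrid_loss(probs, masks, alpha=alpha)


def fit_samples(model: EDTNet, samples: Sequence[ImageSample], steps: int,
                learning_rate: float, batch_size: int | None = None,
                seed: int = 0, warmup_steps: int = 0) -> list[float]:
    """Run ``steps`` Adam updates of the hybrid loss on ``samples``.

    Used for small-scale fitting (e.g. deliberate overfitting on a
    handful of phantoms); returns the per-step loss history. A linear
    learning-rate warmup over ``warmup_steps`` is optional.
    """
    if len(samples) == 0:
        raise ValueError("cannot fit on an empty sample set")
    size = model.config.image_size
    samples = [_resize_sample(s, size) for s in samples]
    images, masks = _stack(samples)
    bs = len(samples) if batch_size is None else min(batch_size, len(samples))
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=learning_rate)
    history: list[float] = []
    for step in range(steps):
        if warmup_steps:
            opt.lr = learning_rate * min(1.0, (step + 1) / warmup_steps)
        idx = rng.permutation(len(samples))[:bs]
        opt.zero_grad()
        loss = _loss_on_batch(model, images[idx], masks[idx], model.config.alpha)
        value = float(loss.data)
        if not math.isfinite(value):
            raise RuntimeError(f"non-finite loss {value} at step {step}; aborting")
        loss.backward()
        opt.step()
        history.append(value)
    return history


def train(run: RunConfig, data_dir: str | Path, out_dir: str | Path) -> TrainResult:
    """Full training procedure: load, resize, split, optimize, log, save."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = load_dataset(data_dir)
    size = run.model.image_size
    samples = [_resize_sample(s, size) for s in samples]
    train_set, val_set = split_dataset(samples, run.train_fraction,
                                       seed=run.seed, leak_free=run.leak_free)
    if len(train_set) == 0:
        raise ValueError("training partition is empty")
    logger.info("training on %d samples, validating on %d",
                len(train_set), len(val_set))

    model = build_edtnet(run.model)
    opt = Adam(model.parameters(), lr=run.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([run.seed, 1]))
    tr_images, tr_masks = _stack(train_set)
    va_images, va_masks = (_stack(val_set) if val_set else (None, None))

    records = []
    for epoch in range(1, run.epochs + 1):
        order = rng.permutation(len(train_set))
        epoch_losses = []
        for start in range(0, len(train_set), run.batch_size):
            idx = order[start:start + run.batch_size]
            opt.zero_grad()
            loss = _loss_on_batch(model, tr_images[idx], tr_masks[idx],
                                  run.model.alpha)
            value = float(loss.data)
            if not math.isfinite(value):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; aborting")
            loss.backward()
            opt.step()
            epoch_losses.append(value)
        train_loss = float(np.mean(epoch_losses))
        if va_images is not None:
            val_loss = float(_loss_on_batch(model, va_images, va_masks,
                                            run.model.alpha).detach().data)
            pred = model.predict_mask(va_images, run.threshold)
            ious = [evaluate_masks(pred[i], val_set[i].mask).iou
                    for i in range(len(val_set))]
            val_iou = float(np.mean(ious))
        else:
            val_loss, val_iou = float("nan"), float("nan")
        records.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss, "val_iou": val_iou})
        logger.info("epoch %d: train_loss=%.4f val_loss=%.4f val_iou=%.4f",
                    epoch, train_loss, val_loss, val_iou)

    frame = pd.DataFrame(records, columns=["epoch", "train_loss",
                                           "val_loss", "val_iou"])
    frame.to_csv(out_dir / "train_record.csv", index=False)
    ckpt = save_checkpoint(model, out_dir / "checkpoint.npz")
    _plot_loss(frame, out_dir / "loss_curve.png")
    return TrainResult(checkpoint_path=ckpt, records=frame, model=model)


def _plot_loss(frame: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(frame["epoch"], frame["train_loss"], label="training loss")
    if np.isfinite(frame["val_loss"]).any():
        ax.plot(frame["epoch"], frame["val_loss"], label="validation loss")
    ax.set_xlabel("epoch")
    ax.set_ylabel("hybrid loss")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def overfit_benchmark(train_seed: int = 42, holdout_seed: int = 43,
                      model_seed: int = 0, steps: int = 200,
                      n_train: int = 8, n_holdout: int = 8) -> dict:
    """Deliberate-overfitting benchmark on tiny ROI phantoms.

    Trains the tiny network on ``n_train`` phantoms (expanded by the
    sixfold augmentation set) for ``steps`` Adam updates — batch 32,
    learning rate 5e-3 with a 20-step warmup — then evaluates with
    test-time averaging on the training phantoms and on freshly generated
    held-out phantoms from the same generator. Returns the loss history
    and both mean metric sets.
    """
    from .model import ModelConfig, build_edtnet
    from .phantoms import PhantomSpec, augment_dataset, generate_dataset

    spec = PhantomSpec.roi(64)
    train_set = generate_dataset(n_train, spec, seed=train_seed)
    holdout = generate_dataset(n_holdout, spec, seed=holdout_seed)
    model = build_edtnet(ModelConfig.tiny(seed=model_seed))
    history = fit_samples(model, augment_dataset(train_set), steps=steps,
                          learning_rate=5e-3, batch_size=32,
                          seed=model_seed, warmup_steps=20)
    return {
        "model": model,
        "loss_history": history,
        "train": evaluate_model(model, train_set, tta=True)["mean"],
        "holdout": evaluate_model(model, holdout, tta=True)["mean"],
    }


# -- evaluation ----------------------------------------------------------

def evaluate_model(model: EDTNet, samples: Sequence[ImageSample],
                   threshold: float = 0.5, tta: bool = False) -> dict:
    """Per-sample metrics plus their unweighted mean across samples."""
    if len(samples) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    size = model.config.image_size
    samples = [_resize_sample(s, size) for s in samples]
    images, _ = _stack(samples)
    preds = model.predict_mask(images, threshold, tta=tta)
    per_sample: dict[str, MetricsReport] = {}
    for i, s in enumerate(samples):
        per_sample[s.id] = evaluate_masks(preds[i], s.mask)
    mean = {m: float(np.mean([getattr(r, m) for r in per_sample.values()]))
            for m in ("precision", "sensitivity", "iou", "dsc")}
    return {"per_sample": per_sample, "mean": mean}


def evaluate(checkpoint: str | Path, data_dir: str | Path,
             threshold: float = 0.5, out_dir: str | Path | None = None) -> dict:
    """Evaluate a checkpoint on a persisted dataset; optionally write reports."""
    model = load_checkpoint(checkpoint)
    samples = load_dataset(data_dir)
    result = evaluate_model(model, samples, threshold)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        reports_to_frame(result["per_sample"]).to_csv(
            out_dir / "metrics.csv", index=False)
        payload = {"mean": result["mean"],
                   "per_sample": {k: v.to_dict()
                                  for k, v in result["per_sample"].items()}}
        (out_dir / "metrics.json").write_text(json.dumps(payload, indent=2))
    return result


# -- prediction ----------------------------------------------------------

def predict(checkpoint: str | Path, image_path: str | Path,
            threshold: float = 0.5, out_dir: str | Path = ".") -> dict[str, Path]:
    """Segment one image file; write the binary mask and probability map.

    The image is resized to the model size for inference and the outputs
    are resized back to the input resolution (mask nearest-neighbour).
    """
    image_path = Path(image_path)
    if not image_path.exists():
        raise FileNotFoundError(f"input image not found: {image_path}")
    model = load_checkpoint(checkpoint)
    raw = np.asarray(Image.open(image_path).convert("RGB")).astype(np.float64) / 255.0
    h0, w0 = raw.shape[:2]
    size = model.config.image_size
    resized = _resize_image(raw, size) if (h0, w0) != (size, size) else raw
    probs = model.predict_proba(resized.transpose(2, 0, 1)[None])[0]
    mask = (probs > threshold).astype(np.uint8)
    if (h0, w0) != (size, size):
        prob_img = Image.fromarray((probs * 255).astype(np.uint8), mode="L").resize(
            (w0, h0), Image.BILINEAR)
        mask_img = Image.fromarray((mask * 255).astype(np.uint8), mode="L").resize(
            (w0, h0), Image.NEAREST)
    else:
        prob_img = Image.fromarray((probs * 255).astype(np.uint8), mode="L")
        mask_img = Image.fromarray((mask * 255).astype(np.uint8), mode="L")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = image_path.stem
    mask_path = out_dir / f"{stem}_mask.png"
    prob_path = out_dir / f"{stem}_prob.png"
    mask_img.save(mask_path)
    prob_img.save(prob_path)
    return {"mask": mask_path, "probability": prob_path}
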