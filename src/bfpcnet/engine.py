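"""Training, evaluation and prediction engine.

Defaults follow the published training recipe: 256x256 inputs, Adam at
learning rate 0.001, batch size 32, 100 epochs, binary cross entropy on
label-smoothed targets (v=0.1, K=8).  No early stopping; instead the
best-validation-loss epoch is checkpointed.  A configurable validation
fraction (default 10%) is carved out of the training manifest when no
separate validation manifest is given, purely to draw learning curves
and pick the best epoch.

Checkpoints are single ``.npz`` files carrying every weight plus a JSON
metadata block with the full backbone/fusion/enhancement configuration,
so ``predict`` can rebuild the exact preprocessing + model pipeline from
the file alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import losses_metrics, model as model_mod, preprocess
from .data_io import CLASSES, ManifestData, read_manifest
from .losses_metrics import (ConfusionCounts, SmoothingParams, confusion,
                             metrics, metrics_report, smooth_labels,
                             smoothed_binary_loss, smoothed_categorical_loss)
from .model import BackboneConfig, BFPCNet, FusionConfig, AttentionParams
from .preprocess import EnhanceParams

logger = logging.getLogger("bfpcnet")


def configure_logging(level=logging.INFO, logfile: Path | None = None):
    """Structured logging to stderr, optionally teed to a run-dir file."""
    handlers = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    root = logging.getLogger("bfpcnet")
    root.setLevel(level)
    root.handlers = []
    for h in handlers:
        h.setFormatter(fmt)
        root.addHandler(h)


@dataclass
class TrainConfig:
    image_size: int = 256
    optimizer: str = "adam"
    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 32
    loss: str = "smoothed_binary"          # or "smoothed_categorical"
    seed: int = 0
    checkpoint_dir: Path = Path("runs/default")
    val_fraction: float = 0.1
    threshold: float = 0.5
    smoothing_v: float = 0.1
    interpolation: str = "bilinear"
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    enhance: EnhanceParams = field(default_factory=EnhanceParams)

    def validate(self):
        if self.epochs < 0 or self.batch_size <= 0 or self.image_size < 32:
            raise ValueError("epochs >= 0, batch_size > 0, image_size >= 32 required")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the Adam optimizer is supported")
        if self.loss not in ("smoothed_binary", "smoothed_categorical"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if not (0.0 <= self.val_fraction < 1.0):
            raise ValueError("val_fraction must lie in [0, 1)")
        self.backbone.validate()
        self.fusion.validate()
        self.enhance.validate()


def load_train_config(path) -> TrainConfig:
    """Build a TrainConfig from a YAML file mirroring the dataclass keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key, cls in (("backbone", BackboneConfig), ("fusion", FusionConfig),
                     ("enhance", EnhanceParams)):
        if key in raw and isinstance(raw[key], dict):
            sub = dict(raw[key])
            if key == "backbone" and isinstance(sub.get("attention"), dict):
                sub["attention"] = AttentionParams(**sub["attention"])
            if key == "fusion" and "weights" in sub:
                sub["weights"] = tuple(sub["weights"])
            raw[key] = cls(**sub)
    cfg = TrainConfig(**raw)
    cfg.checkpoint_dir = Path(cfg.checkpoint_dir)
    return cfg


# ---------------------------------------------------------------------------
# data loading


def _load_image(path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"))
    except (FileNotFoundError, OSError) as exc:
        raise FileNotFoundError(f"cannot read image {path}: {exc}") from exc


def preprocess_pair(record, size, enhance, interpolation="bilinear"):
    """Load, resize, apply recorded augmentations, enhance; both eyes."""
    out = []
    for path in (record.left_path, record.right_path):
        img = preprocess.normalize_image(_load_image(path), size, interpolation)
        img = preprocess.materialize(img, record)
        img = preprocess.weighted_enhance(img, enhance)
        out.append(img.astype(np.float32).transpose(2, 0, 1) / 255.0)
    return out[0], out[1]


def _records(manifest) -> list:
    if isinstance(manifest, (str, Path)):
        data = read_manifest(manifest)
        if data.errors:
            logger.warning("manifest %s: %d rows rejected", manifest, len(data.errors))
        return data.records
    if isinstance(manifest, ManifestData):
        return manifest.records
    return list(manifest)


def _load_tensors(records, config: TrainConfig):
    lefts, rights, labels = [], [], []
    for r in records:
        l, rt = preprocess_pair(r, config.image_size, config.enhance,
                                config.interpolation)
        lefts.append(l)
        rights.append(rt)
        labels.append(r.labels)
    return (np.stack(lefts), np.stack(rights),
            np.asarray(labels, dtype=float))


# ---------------------------------------------------------------------------
# loss + gradient


def _loss_and_grad(net: BFPCNet, xl, xr, y_smooth, loss_kind):
    """One training forward/backward; returns (loss, probabilities)."""
    n = xl.shape[0]
    if net.fusion_config.mode == "prediction_average":
        p = net.forward_pair(xl, xr, train=True)
        kind, el, er, zl, zr, pl, pr = net._cache
        w1, w2 = net.fusion_config.weights
        t = net.fusion_config.T
        if loss_kind == "smoothed_binary":
            loss = smoothed_binary_loss(y_smooth, p)
            pc = np.clip(p, 1e-7, 1 - 1e-7)
            dp = (pc - y_smooth) / (pc * (1 - pc)) / n
            dzl = dp * (w1 / t) * pl * (1 - pl)
            dzr = dp * (w2 / t) * pr * (1 - pr)
        else:
            loss = smoothed_categorical_loss(y_smooth, p)
            dp = -y_smooth / np.clip(p, 1e-7, None) / n
            dzl = (w1 / t) * pl * (dp - (dp * pl).sum(axis=1, keepdims=True))
            dzr = (w2 / t) * pr * (dp - (dp * pr).sum(axis=1, keepdims=True))
        net.backward_pred(dzl, dzr)
        return loss, p
    z = net.forward_logits(xl, xr, train=True)
    if loss_kind == "smoothed_binary":
        p = model_mod.sigmoid(z)
        loss = smoothed_binary_loss(y_smooth, p)
        dz = (p - y_smooth) / n
    else:
        p = model_mod.softmax(z)
        loss = smoothed_categorical_loss(y_smooth, p)
        dz = (p * y_smooth.sum(axis=1, keepdims=True) - y_smooth) / n
    net.backward_logits(dz)
    return loss, p


def _eval_loss(probs, y_smooth, loss_kind):
    if loss_kind == "smoothed_binary":
        return smoothed_binary_loss(y_smooth, probs)
    return smoothed_categorical_loss(y_smooth, probs)


def _micro_accuracy(y_true, probs, threshold):
    counts = confusion(y_true.astype(int), probs, threshold)
    return metrics(counts, "micro")["accuracy"]


# ---------------------------------------------------------------------------
# train / evaluate / predict


from . import nn as _nn  # noqa: E402  (optimizer import kept local to the engine)


def train(config: TrainConfig, train_manifest, val_manifest=None):
    """Seeded mini-batch training; returns (checkpoint_path, history).

    History is one row per epoch (epoch, train_loss, train_acc, val_loss,
    val_acc), also written as CSV next to the checkpoint.  The checkpoint
    stores the best-validation-loss weights (initial weights when
    epochs=0).
    """
    config.validate()
    records = _records(train_manifest)
    if not records:
        raise ValueError("training manifest contains no usable records")
    rng = np.random.default_rng(config.seed)

    if val_manifest is not None:
        val_records = _records(val_manifest)
    elif config.val_fraction > 0 and len(records) > 1:
        idx = rng.permutation(len(records))
        n_val = max(1, int(round(config.val_fraction * len(records))))
        val_records = [records[i] for i in idx[:n_val]]
        records = [records[i] for i in idx[n_val:]]
    else:
        val_records = []

    logger.info("training on %d patients (%d validation)",
                len(records), len(val_records))
    xl, xr, y = _load_tensors(records, config)
    smoothing = SmoothingParams(config.smoothing_v, len(CLASSES))
    y_smooth = smooth_labels(y, smoothing)
    if val_records:
        vxl, vxr, vy = _load_tensors(val_records, config)
        vy_smooth = smooth_labels(vy, smoothing)

    net = BFPCNet(config.backbone, config.fusion, seed=config.seed)
    opt = _nn.Adam(net.parameters(), lr=config.learning_rate)

    history = []
    best = (np.inf, net.state_dict())
    order_rng = np.random.default_rng(rng.integers(2 ** 31))
    for epoch in range(config.epochs):
        order = order_rng.permutation(len(records))
        losses, accs = [], []
        for start in range(0, len(records), config.batch_size):
            b = order[start:start + config.batch_size]
            opt.zero_grad()
            loss, probs = _loss_and_grad(net, xl[b], xr[b], y_smooth[b], config.loss)
            opt.step()
            losses.append(loss)
            accs.append(_micro_accuracy(y[b], probs, config.threshold))
        row = {"epoch": epoch + 1,
               "train_loss": float(np.mean(losses)),
               "train_acc": float(np.mean(accs))}
        if val_records:
            vprobs = _forward_all(net, vxl, vxr, config.batch_size)
            row["val_loss"] = _eval_loss(vprobs, vy_smooth, config.loss)
            row["val_acc"] = _micro_accuracy(vy, vprobs, config.threshold)
            if row["val_loss"] < best[0]:
                best = (row["val_loss"], net.state_dict())
        else:
            row["val_loss"] = np.nan
            row["val_acc"] = np.nan
            best = (row["train_loss"], net.state_dict())
        history.append(row)
        logger.info("epoch %d/%d train_loss=%.4f train_acc=%.4f val_loss=%s",
                    epoch + 1, config.epochs, row["train_loss"], row["train_acc"],
                    f"{row['val_loss']:.4f}" if np.isfinite(row["val_loss"]) else "-")

    net.load_state_dict(best[1])
    if config.epochs > 0:
        _refresh_bn_stats(net, xl, xr, config.batch_size)
    config.checkpoint_dir = Path(config.checkpoint_dir)
    config.checkpoint_dir.mkdir(parents=True, exist_ok=True)
    ckpt = config.checkpoint_dir / "model.npz"
    save_checkpoint(net, config, ckpt)
    hist = pd.DataFrame(history,
                        columns=["epoch", "train_loss", "train_acc",
                                 "val_loss", "val_acc"])
    hist.to_csv(config.checkpoint_dir / "history.csv", index=False)
    return ckpt, hist


def _refresh_bn_stats(net: BFPCNet, xl, xr, batch_size):
    """Re-estimate batchnorm running statistics over a dataset.

    Running averages lag the weights during fast optimization; a final
    calibration pass (cumulative averaging, no gradient steps) brings
    inference-mode statistics in line with the trained weights.
    """
    bns = [m for m in net.modules() if isinstance(m, _nn.BatchNorm2d)]
    if not bns:
        return
    saved = [(bn.momentum,) for bn in bns]
    for bn in bns:
        bn.running_mean[...] = 0.0
        bn.running_var[...] = 0.0
    for i, start in enumerate(range(0, xl.shape[0], batch_size)):
        for bn in bns:
            bn.momentum = 1.0 / (i + 1)
        net.forward_pair(xl[start:start + batch_size],
                         xr[start:start + batch_size], train=True)
    for bn, (mom,) in zip(bns, saved):
        bn.momentum = mom


def _forward_all(net, xl, xr, batch_size):
    probs = []
    for start in range(0, xl.shape[0], batch_size):
        probs.append(net.forward_pair(xl[start:start + batch_size],
                                      xr[start:start + batch_size], train=False))
    return np.concatenate(probs, axis=0)


def save_checkpoint(net: BFPCNet, config: TrainConfig, path) -> Path:
    path = Path(path)
    meta = asdict(config)
    meta["checkpoint_dir"] = str(meta["checkpoint_dir"])
    meta["backbone"]["insertion_points"] = (
        None if config.backbone.insertion_points is None
        else list(config.backbone.insertion_points))
    meta["fusion"]["weights"] = list(config.fusion.weights)
    arrays = {"w::" + k: v for k, v in net.state_dict().items()}
    arrays["__meta__"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)
    return path


def load_checkpoint(path):
    """Rebuild (net, TrainConfig) from a checkpoint file."""
    path = Path(path)
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        weights = {k[3:]: data[k] for k in data.files if k.startswith("w::")}
    meta["backbone"]["attention"] = AttentionParams(**meta["backbone"]["attention"])
    backbone = BackboneConfig(**meta["backbone"])
    meta["fusion"]["weights"] = tuple(meta["fusion"]["weights"])
    fusion = FusionConfig(**meta["fusion"])
    enhance = EnhanceParams(**meta["enhance"])
    cfg = TrainConfig(**{**meta, "backbone": backbone, "fusion": fusion,
                         "enhance": enhance,
                         "checkpoint_dir": Path(meta["checkpoint_dir"])})
    net = BFPCNet(backbone, fusion, seed=cfg.seed)
    net.load_state_dict(weights)
    return net, cfg


def evaluate(checkpoint, manifest, threshold: float | None = None):
    """Forward every pair of a manifest; returns (report, counts, probs).

    The report is the per-class + micro/macro metrics table of
    :func:`bfpcnet.losses_metrics.metrics_report`.
    """
    net, cfg = (checkpoint if isinstance(checkpoint, tuple)
                else load_checkpoint(checkpoint))
    if net.head.bias.data.shape[0] != len(CLASSES):
        raise ValueError("checkpoint head does not match the 8-class label set")
    threshold = cfg.threshold if threshold is None else threshold
    records = _records(manifest)
    if not records:
        raise ValueError("evaluation manifest contains no usable records")
    xl, xr, y = _load_tensors(records, cfg)
    probs = _forward_all(net, xl, xr, cfg.batch_size)
    counts = confusion(y.astype(int), probs, threshold)
    return metrics_report(counts), counts, probs


def predict(checkpoint, left_image, right_image) -> dict:
    """Probabilities for one binocular pair, keyed by class in fixed order."""
    net, cfg = (checkpoint if isinstance(checkpoint, tuple)
                else load_checkpoint(checkpoint))
    xs = []
    for path in (left_image, right_image):
        img = preprocess.normalize_image(_load_image(path), cfg.image_size,
                                         cfg.interpolation)
        img = preprocess.weighted_enhance(img, cfg.enhance)
        xs.append(img.astype(np.float32).transpose(2, 0, 1)[None] / 255.0)
    probs = net.forward_pair(xs[0], xs[1], train=False)[0]
    return {c: float(p) for c, p in zip(CLASSES, probs)}
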