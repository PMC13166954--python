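"""Training, evaluation and inference orchestration.

The training loop is deterministic given (seed, config, dataset):
single-threaded data order, seeded shuffling and augmentation, seeded
weight init.  Normalization statistics come from the training split
only and are stored inside the checkpoint.  Checkpoint selection is by
best validation mAP@0.5, evaluated every ``eval_interval`` epochs.

Ablation switches mirror the architecture study: ``aug`` disables the
affine augmentation, ``deform`` replaces deformable blocks with plain
convolutions, ``elastic`` ignores the depth/width multipliers (fixed
base schedule).
"""

from __future__ import annotations

import dataclasses
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from eyolo import preprocess
from eyolo.elastic_net import ElasticScale, EYOLONet, build_network, load_config
from eyolo.eval_metrics import (
    background_true_negatives, confusion_matrix, evaluate_detections,
)
from eyolo.loss import LossWeights, assign_targets, detection_loss_and_grads
from eyolo.nn import SGD
from eyolo.postprocess import (
    decode, detections_to_jsonl, generate_report, nms, render_overlay,
)
from eyolo.smear_synth import read_yolo_dataset


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 16
    lr: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 0.0
    optimizer: str = "sgd"
    seed: int = 0
    scale: ElasticScale = dataclasses.field(default_factory=ElasticScale)
    input_size: int = 256
    split_ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    augment: bool = True
    loss_weights: LossWeights = dataclasses.field(default_factory=LossWeights)
    epsilon: float = 0.01
    conf_threshold: float = 0.25
    nms_iou: float = 0.5
    focal_gamma: float = 0.0
    eval_interval: int = 5
    num_classes: int = 6
    ablate: tuple[str, ...] = ()
    network_config: dict | None = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.input_size % 32:
            raise ValueError("input size must be divisible by 32")
        bad = set(self.ablate) - {"aug", "deform", "elastic"}
        if bad:
            raise ValueError(f"unknown ablation flags: {sorted(bad)}")


def _prepare_split(items, input_size):
    """Resize (if needed) and scale images to [0, 1] float32."""
    images, anns = [], []
    for image, a in items:
        if image.shape[0] != input_size or image.shape[1] != input_size:
            image = np.asarray(Image.fromarray(image).resize(
                (input_size, input_size), Image.BILINEAR))
        images.append(np.asarray(image, dtype=np.float32) / 255.0)
        anns.append(list(a))
    return images, anns


def build_from_config(config: TrainConfig, seed_offset: int = 0) -> EYOLONet:
    net_cfg = dict(config.network_config or load_config())
    if "deform" in config.ablate:
        net_cfg["deformable"] = False
    scale = ElasticScale() if "elastic" in config.ablate else config.scale
    net_cfg["epsilon"] = config.epsilon
    return EYOLONet(net_cfg, scale, num_classes=config.num_classes,
                    seed=config.seed + seed_offset)


def _forward_loss(net, images, anns_batch, config, train_mode):
    """One forward pass + loss (and gradients when training)."""
    tape, outputs = net.forward_train(np.stack(images))
    raw = {s: v.data for s, v in outputs.items()}
    offset_fields = [d.last_offsets for d in net.deform_layers()
                     if d.last_offsets is not None]
    breakdown, grads, off_grads = detection_loss_and_grads(
        raw, anns_batch, (config.input_size, config.input_size),
        num_classes=config.num_classes,
        offset_fields=offset_fields,
        weights=config.loss_weights, focal_gamma=config.focal_gamma)
    return tape, outputs, breakdown, grads, off_grads


def _epoch_val_loss(net, images, anns, config):
    net.eval()
    losses = []
    bs = max(config.batch_size, 8)
    for i in range(0, len(images), bs):
        _, _, breakdown, _, _ = _forward_loss(
            net, images[i:i + bs], anns[i:i + bs], config, train_mode=False)
        losses.append(breakdown.total(config.loss_weights))
    return float(np.mean(losses)) if losses else float("nan")


def _records_from_split(net, images, anns, config, collect_cneg=False):
    """Run forward -> decode -> NMS over a split; build metric records."""
    net.eval()
    det_records, truth_records = [], []
    c_neg = 0
    size = (config.input_size, config.input_size)
    bs = max(config.batch_size, 8)
    for start in range(0, len(images), bs):
        chunk = images[start:start + bs]
        raw = net.forward(np.stack(chunk))
        for bi in range(len(chunk)):
            img_id = start + bi
            single = {s: o[:, bi] for s, o in raw.items()}
            dets = nms(decode(single, size, config.conf_threshold),
                       config.nms_iou)
            for det in dets:
                det_records.append((img_id, int(det.cell_class),
                                    det.score, det.box))
            for ann in anns[img_id]:
                truth_records.append((img_id, int(ann.cell_class),
                                      ann.to_pixels(*size[::-1])))
            if collect_cneg:
                targets = assign_targets(size, anns[img_id])
                score_maps, target_maps = [], []
                for stride, out in single.items():
                    obj = 1.0 / (1.0 + np.exp(-out[4].astype(np.float64)))
                    logits = out[5:].astype(np.float64)
                    logits -= logits.max(axis=0, keepdims=True)
                    e = np.exp(logits)
                    probs = e / e.sum(axis=0, keepdims=True)
                    score_maps.append(obj * probs.max(axis=0))
                    target_maps.append(targets[stride][0])
                c_neg += background_true_negatives(
                    score_maps, target_maps, config.conf_threshold)
    return det_records, truth_records, c_neg


def train(config: TrainConfig, dataset_root: str | Path,
          out_dir: str | Path) -> tuple[Path, pd.DataFrame]:
    """Train on a YOLO-format dataset; returns (checkpoint path, epoch log)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = read_yolo_dataset(dataset_root)
    if not data.get("train"):
        raise ValueError("empty training split")
    train_images, train_anns = _prepare_split(data["train"], config.input_size)
    val_items = data.get("val") or data["train"]
    val_images, val_anns = _prepare_split(val_items, config.input_size)

    stats = preprocess.compute_norm_stats(train_images)
    train_norm = [preprocess.normalize(im, stats).astype(np.float32)
                  for im in train_images]
    val_norm = [preprocess.normalize(im, stats).astype(np.float32)
                for im in val_images]

    net = build_from_config(config)
    params = net.params()
    if config.optimizer != "sgd":
        raise ValueError(f"unsupported optimizer {config.optimizer!r}")
    opt = SGD(params, lr=config.lr, momentum=config.momentum,
              weight_decay=config.weight_decay)

    rng = np.random.default_rng(config.seed)
    aug_rng = np.random.default_rng(config.seed + 1)
    n = len(train_norm)
    steps_per_epoch = max(1, (n + config.batch_size - 1) // config.batch_size)
    total_steps = steps_per_epoch * config.epochs
    augment = config.augment and "aug" not in config.ablate

    log_rows = []
    best_map, best_epoch = -1.0, -1
    ckpt_path = out_dir / "checkpoint.npz"
    step = 0
    t_start = time.time()
    for epoch in range(1, config.epochs + 1):
        net.train()
        order = rng.permutation(n)
        comp_sums = np.zeros(3)  # det, cls, reg
        tot_w = tot_u = 0.0
        for bstart in range(0, n, config.batch_size):
            idx = order[bstart:bstart + config.batch_size]
            images, anns_batch = [], []
            for i in idx:
                im, anns = train_norm[i], train_anns[i]
                if augment:
                    p = preprocess.sample_affine(aug_rng, config.input_size)
                    im, anns = preprocess.apply_affine(im, anns, p)
                    im = im.astype(np.float32)
                images.append(im)
                anns_batch.append(anns)
            opt.set_cosine_lr(step, total_steps)
            opt.zero_grad()
            tape, outputs, breakdown, grads, off_grads = _forward_loss(
                net, images, anns_batch, config, train_mode=True)
            for layer, g in zip(net.deform_layers(), off_grads):
                layer.pending_offset_grad = g
            tape.backward({outputs[s].vid: grads[s] for s in outputs})
            opt.step()
            step += 1
            comp_sums += (breakdown.l_det, breakdown.l_cls, breakdown.l_reg)
            tot_w += breakdown.total(config.loss_weights)
            tot_u += breakdown.total_unweighted
        nb = steps_per_epoch
        row = {"epoch": epoch,
               "train_loss": tot_w / nb,
               "l_det": comp_sums[0] / nb, "l_cls": comp_sums[1] / nb,
               "l_reg": comp_sums[2] / nb,
               "l_total_weighted": tot_w / nb,
               "l_total_unweighted": tot_u / nb,
               "lr": opt.lr,
               "val_loss": np.nan, "train_acc": np.nan, "val_acc": np.nan,
               "val_map50": np.nan}
        if epoch % config.eval_interval == 0 or epoch == config.epochs:
            row["val_loss"] = _epoch_val_loss(net, val_norm, val_anns, config)
            dets, truths, c_neg = _records_from_split(
                net, val_norm, val_anns, config, collect_cneg=True)
            try:
                report = evaluate_detections(dets, truths, c_neg=c_neg)
                row["val_map50"] = report.map50
                row["val_acc"] = report.accuracy
            except ValueError:
                row["val_map50"] = 0.0
            if row["val_map50"] >= best_map:
                best_map, best_epoch = row["val_map50"], epoch
                _save_checkpoint(net, stats, config, ckpt_path,
                                 best_epoch=epoch, val_map50=best_map)
        log_rows.append(row)
        net.train()
    if best_epoch < 0:  # no eval epoch ever ran (epochs < interval)
        _save_checkpoint(net, stats, config, ckpt_path,
                         best_epoch=config.epochs, val_map50=float("nan"))
    log = pd.DataFrame(log_rows)
    log.to_csv(out_dir / "epoch_log.csv", index=False)
    (out_dir / "train_meta.yaml").write_text(yaml.safe_dump({
        "seed": config.seed, "epochs": config.epochs,
        "best_epoch": best_epoch, "best_val_map50": float(best_map),
        "wall_seconds": round(time.time() - t_start, 1)}))
    return ckpt_path, log


def _save_checkpoint(net, stats, config, path, **meta):
    arrays = net.state_arrays()
    arrays["norm_mean"] = stats.mean
    arrays["norm_std"] = stats.std
    arrays["_config_yaml"] = np.frombuffer(yaml.safe_dump({
        "config": net.config,
        "scale": {"lambda_d": net.scale.lambda_d, "lambda_w": net.scale.lambda_w},
        "num_classes": net.num_classes,
        "seed": net.seed,
        "train": {
            "input_size": config.input_size,
            "conf_threshold": config.conf_threshold,
            "nms_iou": config.nms_iou,
            "ablate": list(config.ablate),
            **{k: (float(v) if isinstance(v, (int, float)) else v)
               for k, v in meta.items()},
        },
    }).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[EYOLONet,
                                               preprocess.NormalizationStats,
                                               dict]:
    net = EYOLONet.load(path)
    with np.load(path) as data:
        stats = preprocess.NormalizationStats(data["norm_mean"], data["norm_std"])
        import io as _io
        meta = yaml.safe_load(_io.BytesIO(data["_config_yaml"].tobytes()))
    return net, stats, meta.get("train", {})


def evaluate(checkpoint: str | Path | EYOLONet, dataset_root: str | Path,
             split: str = "test", config: TrainConfig | None = None,
             prune: bool = False):
    """forward -> decode -> NMS -> metric suite over one dataset split."""
    if isinstance(checkpoint, EYOLONet):
        net = checkpoint
        if config is None:
            raise ValueError("config required when passing a bare network")
        stats = None
    else:
        net, stats, meta = load_checkpoint(checkpoint)
        if config is None:
            config = TrainConfig(
                input_size=int(meta.get("input_size", 256)),
                conf_threshold=float(meta.get("conf_threshold", 0.25)),
                nms_iou=float(meta.get("nms_iou", 0.5)),
                scale=net.scale, ablate=tuple(meta.get("ablate", ())))
    data = read_yolo_dataset(dataset_root)
    if split not in data or not data[split]:
        raise ValueError(f"empty or missing split {split!r}")
    images, anns = _prepare_split(data[split], config.input_size)
    if stats is None:
        stats = preprocess.compute_norm_stats(images)
    norm = [preprocess.normalize(im, stats).astype(np.float32) for im in images]
    if prune:
        net.prune()
    dets, truths, c_neg = _records_from_split(net, norm, anns, config,
                                              collect_cneg=True)
    report = evaluate_detections(dets, truths, c_neg=c_neg)
    cm = confusion_matrix(dets, truths, tau_iou=0.5)
    return report, cm


def detect(checkpoint: str | Path, image_folder: str | Path,
           out_dir: str | Path) -> list[dict]:
    """Run inference on a folder: overlay + JSON-lines + report per image."""
    net, stats, meta = load_checkpoint(checkpoint)
    input_size = int(meta.get("input_size", 256))
    conf = float(meta.get("conf_threshold", 0.25))
    nms_iou = float(meta.get("nms_iou", 0.5))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results = []
    jsonl_lines = []
    for path in sorted(Path(image_folder).iterdir()):
        if path.suffix.lower() not in (".png", ".jpg", ".jpeg"):
            continue
        try:
            image = np.asarray(Image.open(path).convert("RGB"))
        except Exception as exc:  # unreadable image: skip with a warning
            print(f"warning: skipping unreadable image {path}: {exc}")
            continue
        if image.shape[0] != input_size or image.shape[1] != input_size:
            image = np.asarray(Image.fromarray(image).resize(
                (input_size, input_size), Image.BILINEAR))
        norm = preprocess.normalize(image / 255.0, stats).astype(np.float32)
        raw = net.forward(norm[None])
        single = {s: o[:, 0] for s, o in raw.items()}
        dets = nms(decode(single, (input_size, input_size), conf), nms_iou)
        overlay = render_overlay(image, dets)
        overlay.save(out_dir / f"{path.stem}_overlay.png")
        report = generate_report(dets)
        (out_dir / f"{path.stem}_report.txt").write_text(report.to_text())
        jsonl_lines.extend(detections_to_jsonl(dets, path.stem))
        results.append({"image": path.stem, "detections": dets,
                        "report": report})
    (out_dir / "detections.jsonl").write_text(
        "\n".join(jsonl_lines) + ("\n" if jsonl_lines else ""))
    return results
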