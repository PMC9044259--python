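"""Training loop: Adam + cosine annealing, on-the-fly augmentation,
per-epoch validation mAP and best-checkpoint tracking."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .dataio import TrainConfig, cosine_lr, save_checkpoint
from .evaluation import evaluate
from .losses import LossWeights, assign_targets, detection_loss
from .neck import STRIDES
from .nn import Adam
from .synth import Scene, augment, mosaic

log = logging.getLogger("wheatear")


def _scene_to_input(scene: Scene):
    img = scene.image.astype(np.float32) / 255.0
    return img.transpose(2, 0, 1), scene.boxes


def _grid_shapes(size: int):
    return [(size // s, size // s) for s in STRIDES]


def train(model, scenes: list[Scene], cfg: TrainConfig,
          val_scenes: list[Scene] | None = None,
          checkpoint_path=None,
          loss_weights: LossWeights = LossWeights(),
          eval_conf_threshold: float = 0.1):
    """Optimise ``model`` on in-memory scenes.

    Returns a history dict with per-epoch loss components, learning rates
    and (when a validation set is given) mAP@0.5.  The checkpoint with the
    best validation mAP (or simply the last epoch, without validation) is
    written to ``checkpoint_path`` when given.  Raises on NaN loss.
    """
    if not scenes:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    if cfg.optimizer.lower() != "adam":
        raise ValueError(f"unsupported optimizer {cfg.optimizer!r}")
    size = cfg.input_size
    grids = _grid_shapes(size)
    history = {"loss": [], "box": [], "objectness": [], "class": [],
               "lr": [], "val_map": []}
    best_map = -1.0
    for epoch in range(cfg.epochs):
        lr = cosine_lr(cfg, epoch)
        opt.lr = lr
        order = rng.permutation(len(scenes))
        model.train()
        epoch_tot, epoch_comp, n_batches = 0.0, None, 0
        for start in range(0, len(order), cfg.batch_size):
            batch_idx = order[start:start + cfg.batch_size]
            images, targets = [], []
            for k in batch_idx:
                scene = scenes[k]
                if cfg.mosaic_prob > 0 and rng.random() < cfg.mosaic_prob:
                    others = rng.integers(0, len(scenes), size=3)
                    scene = mosaic([scene] + [scenes[int(o)] for o in others],
                                   seed=int(rng.integers(2 ** 31)))
                if cfg.augment_ops:
                    ops = [op for op in cfg.augment_ops
                           if op != "scale" and rng.random() < 0.5]
                    if ops:
                        scene = augment(scene, ops,
                                        seed=int(rng.integers(2 ** 31)))
                img, boxes = _scene_to_input(scene)
                if img.shape[1] != size or img.shape[2] != size:
                    raise ValueError("scene size does not match input_size")
                images.append(img)
                targets.append(assign_targets(boxes, model.anchors, grids,
                                              cfg.iou_threshold))
            x = ad.Tensor(np.stack(images))
            preds = model(x)
            loss, comps = detection_loss(preds, targets, model.anchors,
                                         loss_weights)
            if not np.isfinite(comps["total"]):
                raise FloatingPointError(
                    f"loss diverged at epoch {epoch}: {comps}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_tot += comps["total"]
            n_batches += 1
            if epoch_comp is None:
                epoch_comp = {k: comps[k] for k in ("box", "objectness", "class")}
            else:
                for k in epoch_comp:
                    epoch_comp[k] += comps[k]
        history["loss"].append(epoch_tot / n_batches)
        for k in ("box", "objectness", "class"):
            history[k].append(epoch_comp[k] / n_batches)
        history["lr"].append(lr)
        if val_scenes:
            metrics = evaluate(model,
                               [(s.image, s.boxes) for s in val_scenes],
                               conf_threshold=eval_conf_threshold,
                               iou_threshold=cfg.iou_threshold)
            history["val_map"].append(metrics.map50)
            log.info("epoch %d lr %.5f loss %.4f val mAP@.5 %.3f",
                     epoch, lr, history["loss"][-1], metrics.map50)
            if checkpoint_path and metrics.map50 > best_map:
                best_map = metrics.map50
                save_checkpoint(checkpoint_path, model,
                                meta={"epoch": epoch,
                                      "val_map": metrics.map50})
        else:
            log.info("epoch %d lr %.5f loss %.4f",
                     epoch, lr, history["loss"][-1])
            if checkpoint_path:
                save_checkpoint(checkpoint_path, model,
                                meta={"epoch": epoch})
    return history


def overfit_single_scene(model, scene: Scene, steps: int = 50,
                         lr: float = 5e-3,
                         loss_weights: LossWeights = LossWeights(),
                         iou_threshold: float = 0.5) -> list[float]:
    """Repeated gradient steps on one image; returns the loss trace.

    A sanity probe for the full differentiation path: on an easy scene the
    composite loss must fall steadily.
    """
    img, boxes = _scene_to_input(scene)
    size = img.shape[1]
    targets = [assign_targets(boxes, model.anchors, _grid_shapes(size),
                              iou_threshold)]
    opt = Adam(model.parameters(), lr=lr)
    x = ad.Tensor(img[None])
    trace = []
    model.train()
    for _ in range(steps):
        preds = model(x)
        loss, comps = detection_loss(preds, targets, model.anchors,
                                     loss_weights)
        if not np.isfinite(comps["total"]):
            raise FloatingPointError("loss diverged during overfit probe")
        trace.append(comps["total"])
        opt.zero_grad()
        loss.backward()
        opt.step()
    return trace
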