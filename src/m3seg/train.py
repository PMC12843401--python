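"""Training loop: SGD with momentum, polynomial learning-rate decay,
per-iteration loss logging and resumable checkpoints.

The protocol follows the reference recipe — SGD (lr 0.01, momentum 0.9,
weight decay 1e-4), polynomial decay ``lr = lr0 * (1 - it/max_it)**0.9`` —
scaled to whatever iteration budget the config sets. Batches are uniform
random draws (with replacement) over the training slices; augmentation,
when enabled, is re-seeded per (master seed, iteration, slot) so a run is
a pure function of its config, and resuming from a checkpoint reproduces
the uninterrupted run exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .augment import augment
from .config import AugmentationPolicy, LossConfig, ModelConfig, TrainConfig
from .data import SegmentationSample
from .losses import ce_loss, dice_loss, one_hot
from .metrics import dsc
from .model import SegmentationModel, build_model
from .nn import SGD
from .autodiff import softmax

__all__ = ["RunLog", "Trainer", "save_checkpoint", "load_checkpoint"]


@dataclass
class RunLog:
    rows: list = field(default_factory=list)

    def append(self, iteration: int, lr: float, total: float, ce: float, dice: float):
        self.rows.append({"iteration": iteration, "lr": lr, "total": total,
                          "ce": ce, "dice": dice})

    def write_jsonl(self, path: str):
        with open(path, "w") as fh:
            for row in self.rows:
                fh.write(json.dumps(row) + "\n")

    def write_csv(self, path: str):
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["iteration", "lr", "total", "ce", "dice"])
            writer.writeheader()
            writer.writerows(self.rows)


def _config_fingerprint(config: ModelConfig) -> str:
    import hashlib
    from dataclasses import asdict

    blob = json.dumps(asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def save_checkpoint(path: str, model: SegmentationModel, optimizer: SGD | None = None,
                    iteration: int = 0, extra: dict | None = None):
    payload = {f"model/{k}": v for k, v in model.state_dict().items()}
    if optimizer is not None:
        payload.update({f"opt/{k}": v for k, v in optimizer.state_dict().items()})
    payload["meta/iteration"] = np.array(iteration)
    payload["meta/config"] = np.array(json.dumps(
        {**{k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(model.config).items()},
         "in_channels": model.in_channels,
         "fingerprint": _config_fingerprint(model.config),
         **(extra or {})}))
    np.savez(path, **payload)


def load_checkpoint(path: str):
    """Rebuild the model (and optimizer state, if stored) from a checkpoint."""
    with np.load(path) as archive:
        meta = json.loads(str(archive["meta/config"]))
        in_channels = meta.pop("in_channels")
        meta.pop("fingerprint", None)
        extra = {k: meta.pop(k) for k in list(meta) if k not in ModelConfig.__dataclass_fields__}
        config = ModelConfig(**meta)
        model = build_model(config, in_channels=in_channels)
        model.load_state_dict(
            {k[len("model/"):]: archive[k] for k in archive.files if k.startswith("model/")}
        )
        opt_state = {k[len("opt/"):]: archive[k] for k in archive.files if k.startswith("opt/")}
        iteration = int(archive["meta/iteration"])
    return model, opt_state, iteration, extra


class Trainer:
    def __init__(self, model: SegmentationModel, samples: list[SegmentationSample],
                 train_cfg: TrainConfig | None = None,
                 loss_cfg: LossConfig | None = None,
                 policy: AugmentationPolicy | None = None):
        self.model = model
        self.samples = list(samples)
        if not self.samples:
            raise ValueError("no training samples")
        self.cfg = train_cfg or TrainConfig()
        self.loss_cfg = loss_cfg or LossConfig()
        self.policy = policy or AugmentationPolicy(seed=self.cfg.seed)
        self.optimizer = SGD(model.parameters(), lr=self.cfg.lr,
                             momentum=self.cfg.momentum,
                             weight_decay=self.cfg.weight_decay)
        self.log = RunLog()
        self.iteration = 0

    # -- deterministic per-iteration sampling --------------------------------
    def _batch(self, iteration: int):
        rng = np.random.default_rng(
            np.random.SeedSequence([self.cfg.seed, iteration, 0xBA7C]))
        idx = rng.integers(0, len(self.samples), size=self.cfg.batch_size)
        images, masks = [], []
        for slot, i in enumerate(idx):
            s = self.samples[int(i)]
            if self.cfg.augment:
                draw = int(np.random.SeedSequence(
                    [self.cfg.seed, iteration, slot, 0xA06]).generate_state(1)[0] % (2**31))
                s = augment(s, self.policy, draw)
            img = s.image
            if img.ndim == 2:
                img = img[None]  # (1, H, W)
            else:
                img = np.moveaxis(img, -1, 0)
            images.append(img)
            masks.append(s.mask)
        return np.stack(images), np.stack(masks)

    def lr_at(self, iteration: int) -> float:
        frac = min(iteration / max(1, self.cfg.max_iterations), 1.0 - 1e-12)
        return self.cfg.lr * (1.0 - frac) ** self.cfg.lr_decay_power

    def step(self) -> dict:
        """One optimisation step; returns the logged row."""
        images, masks = self._batch(self.iteration)
        y = one_hot(masks, self.model.config.num_classes)
        self.model.train()
        logits = self.model(images)
        probs = softmax(logits.swapaxes(1, 3), axis=-1).swapaxes(1, 3)
        ce = ce_loss(probs, y)
        dice = dice_loss(probs, y, self.loss_cfg)
        total = self.loss_cfg.lambda_ce * ce + self.loss_cfg.lambda_dice * dice
        self.optimizer.zero_grad()
        total.backward()
        self.optimizer.lr = self.lr_at(self.iteration)
        self.optimizer.step()
        self.iteration += 1
        self.log.append(self.iteration, self.optimizer.lr, total.item(),
                        ce.item(), dice.item())
        return self.log.rows[-1]

    def train(self, iterations: int, checkpoint_dir: str | None = None,
              stop_fn=None, eval_every: int = 50) -> RunLog:
        """Run ``iterations`` steps; optionally checkpoint and early-stop.

        ``stop_fn(trainer) -> bool`` is polled every ``eval_every`` steps.
        """
        for _ in range(iterations):
            self.step()
            if checkpoint_dir and self.iteration % self.cfg.checkpoint_every == 0:
                self.checkpoint(os.path.join(checkpoint_dir,
                                             f"ckpt_{self.iteration:06d}.npz"))
            if stop_fn is not None and self.iteration % eval_every == 0:
                if stop_fn(self):
                    break
        return self.log

    def checkpoint(self, path: str):
        save_checkpoint(path, self.model, self.optimizer, self.iteration)

    def resume(self, path: str):
        model, opt_state, iteration, _ = load_checkpoint(path)
        self.model.load_state_dict(model.state_dict())
        if opt_state:
            self.optimizer.load_state_dict(opt_state)
        self.iteration = iteration

    # -- evaluation helpers ---------------------------------------------------
    def train_set_dsc(self) -> float:
        """Mean foreground DSC of the current model over the training samples."""
        scores = []
        for s in self.samples:
            img = s.image[None] if s.image.ndim == 2 else np.moveaxis(s.image, -1, 0)
            pred = self.model.predict_mask(img[None])[0]
            for label in range(1, self.model.config.num_classes):
                if (s.mask == label).any() or (pred == label).any():
                    scores.append(dsc(pred == label, s.mask == label) / 100.0)
        return float(np.mean(scores)) if scores else float("nan")
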