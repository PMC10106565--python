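"""Training loop, optimizer, checkpointing and inference."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autograd import Tensor
from .config import ModelConfig, TrainConfig, _to_plain
from .decoder import GLSegNet, build_model
from .exceptions import GLSegnetError
from .losses import hybrid
from .metrics import MetricsReport, evaluate_set

__all__ = ["SGD", "RunRecord", "train", "predict", "save_checkpoint",
           "load_checkpoint"]


class SGD:
    """Stochastic gradient descent with momentum and L2 weight decay:
    v <- m v + g + wd p;  p <- p - lr v."""

    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


@dataclass
class RunRecord:
    """Per-epoch loss terms, validation metrics and checkpoint paths."""

    epochs: list[dict] = field(default_factory=list)
    val_reports: list[dict] = field(default_factory=list)
    best_checkpoint: str | None = None
    last_checkpoint: str | None = None
    best_dice: float = -1.0
    seed: int = 0
    config: dict = field(default_factory=dict)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def save_checkpoint(model: GLSegNet, cfg: ModelConfig, path) -> None:
    """Flat map of named parameter/buffer arrays plus the model config."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    path.with_suffix(".config.json").write_text(json.dumps(_to_plain(cfg), indent=2))


def load_checkpoint(path, dtype=np.float32) -> tuple[GLSegNet, ModelConfig]:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    cfg = ModelConfig(**json.loads(path.with_suffix("").with_suffix(
        ".config.json").read_text()))
    model = build_model(cfg, dtype=dtype)
    with np.load(path) as archive:
        model.load_state_dict({k: archive[k] for k in archive.files})
    return model, cfg


def _check_finite(report, epoch: int) -> None:
    for term, value in (("dice", report.l1), ("bce", report.l2),
                        ("ssim", report.l3), ("edge", report.l4)):
        if not np.isfinite(value):
            raise GLSegnetError(
                f"non-finite {term} loss term at epoch {epoch}: {value}")


def train(cfg: TrainConfig, train_set, val_set=None, out_dir=None,
          model: GLSegNet | None = None, log=None) -> tuple[GLSegNet, RunRecord]:
    """Minimize the hybrid loss with SGD-with-momentum.

    ``train_set``/``val_set`` are (images (N,3,S,S), masks (N,1,S,S), names)
    triples as returned by :func:`glsegnet.data.load_split`.
    """
    images, masks = np.asarray(train_set[0]), np.asarray(train_set[1])
    if images.shape[0] == 0:
        raise GLSegnetError("empty training set")
    if model is None:
        model = build_model(cfg.model, seed=cfg.seed)
    model.train()
    opt = SGD(model.parameters(), lr=cfg.learning_rate, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    record = RunRecord(seed=cfg.seed, config=_to_plain(cfg))
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    n = images.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        sums = np.zeros(5)
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = Tensor(images[idx])
            yb = Tensor(masks[idx])
            opt.zero_grad()
            pred = model(xb)
            total, rep = hybrid(pred, yb, cfg.loss, ssim_window=cfg.ssim_window,
                                edge_norm=cfg.edge_norm)
            _check_finite(rep, epoch)
            total.backward()
            opt.step()
            sums += (rep.l1, rep.l2, rep.l3, rep.l4, rep.total)
            n_batches += 1
        terms = sums / n_batches
        entry = {"epoch": epoch, "dice": terms[0], "bce": terms[1],
                 "ssim": terms[2], "edge": terms[3], "total": terms[4]}
        record.epochs.append(entry)
        if log:
            log(f"epoch {epoch:3d}  total {terms[4]:.4f}  dice {terms[0]:.4f}  "
                f"bce {terms[1]:.4f}  ssim {terms[2]:.4f}  edge {terms[3]:.4f}")

        if val_set is not None:
            report = evaluate_model(model, val_set)
            record.val_reports.append({"epoch": epoch, **report.means})
            dice = report.means["dice"]
            if dice > record.best_dice:
                record.best_dice = dice
                if out is not None:
                    best = out / "best"
                    save_checkpoint(model, cfg.model, best)
                    record.best_checkpoint = str(best.with_suffix(".npz"))

    if out is not None:
        last = out / "last"
        save_checkpoint(model, cfg.model, last)
        record.last_checkpoint = str(last.with_suffix(".npz"))
        record.save(out / "run_record.json")
    return model, record


def evaluate_model(model: GLSegNet, dataset) -> MetricsReport:
    images, masks = np.asarray(dataset[0]), np.asarray(dataset[1])
    probs = predict(model, images)
    return evaluate_set(list(probs[:, 0]), list(masks[:, 0].astype(np.uint8)))


def predict(model: GLSegNet, images, batch_size: int = 8) -> np.ndarray:
    """Probability maps (N,1,S,S) for a stack of images, order preserved."""
    images = np.asarray(images)
    outs = [model.predict_proba(images[i:i + batch_size])
            for i in range(0, images.shape[0], batch_size)]
    return np.concatenate(outs, axis=0)
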