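"""Training, evaluation, prediction, and checkpointing.

The protocol: binary cross-entropy on logits, Adam at learning rate 1e-4,
no augmentation, no schedule. Reference batch sizes are 4 for the retinal
and X-ray settings and 8 for polyps, with 300/150/150 epochs; desk-scale
runs use smaller presets. The checkpoint with the best validation Dice is
retained. Every source of randomness (init, shuffling) hangs off integer
seeds, so two runs with the same seeds produce identical logs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import metrics as M
from .data import crop_back, load_image, pad_to_stride, to_batch
from .decoder import MHANet, ModelConfig, assemble_mhanet
from .nn import Adam
from .nn import autograd as ag
from .nn.autograd import Tensor
from .synth import SampleRecord

logger = logging.getLogger(__name__)

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (loss is fixed: binary cross-entropy)."""

    learning_rate: float = 1e-4
    batch_size: int = 4
    epochs: int = 150
    seed: int = 0
    threshold: float = 0.5
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size >= 1, epochs >= 1 and learning_rate > 0 required")

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunLog:
    """Per-epoch record of the optimization."""

    seed: int
    config_hash: str
    epochs: list[dict] = field(default_factory=list)

    @property
    def losses(self) -> list[float]:
        return [e["loss"] for e in self.epochs]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"seed": self.seed, "config_hash": self.config_hash, "epochs": self.epochs}, indent=2))


def _img_mask(rec) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(rec, SampleRecord):
        return rec.image, rec.mask
    if isinstance(rec, tuple) and len(rec) == 3:  # (name, image, mask)
        return rec[1], rec[2]
    return rec  # (image, mask)


def _padded_pair(rec) -> tuple[np.ndarray, np.ndarray]:
    img, msk = _img_mask(rec)
    img_p, _ = pad_to_stride(img)
    msk_p, _ = pad_to_stride(msk)
    return img_p, msk_p


def mean_val_dice(model: MHANet, records, threshold: float, batch_size: int = 4) -> float:
    """Macro-averaged Dice of thresholded predictions over ``records``."""
    scores = []
    for rec in records:
        img, msk = _img_mask(rec)
        img_p, crop = pad_to_stride(img)
        prob = model.predict_proba(to_batch([img_p]))[0, 0]
        pred = (crop_back(prob, crop) >= threshold).astype(np.uint8)
        scores.append(M.dice(M.confusion_counts(pred, msk)))
    return float(np.mean(scores))


def train(
    model: MHANet,
    train_set,
    val_set,
    cfg: TrainConfig,
) -> tuple[dict[str, np.ndarray], RunLog]:
    """Optimize ``model`` in place; returns (best state dict, run log).

    The returned state is the snapshot with the best validation Dice (the
    final state if ``val_set`` is empty). If ``cfg.checkpoint_dir`` is set
    the best snapshot is also written to ``best.npz`` there.
    """
    if not train_set:
        raise ValueError("train_set is empty")
    pairs = [_padded_pair(r) for r in train_set]
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    log = RunLog(seed=cfg.seed, config_hash=cfg.config_hash())
    best = {k: v.copy() for k, v in model.state_dict().items()}
    best_dice = -1.0
    model.train()
    for epoch in range(cfg.epochs):
        t0 = time.time()
        order = rng.permutation(len(pairs))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            x = to_batch([pairs[i][0] for i in idx])
            t = np.stack([pairs[i][1] for i in idx])[:, None].astype(np.float32)
            opt.zero_grad()
            loss = ag.bce_with_logits(model(Tensor(x)), t)
            lv = loss.item()
            if not np.isfinite(lv):
                raise RuntimeError(
                    f"loss became {lv} at epoch {epoch}: check that images lie in "
                    "[0, 1] and consider a smaller learning rate"
                )
            loss.backward()
            opt.step()
            losses.append(lv)
        entry = {"epoch": epoch, "loss": float(np.mean(losses)), "time": time.time() - t0}
        if val_set:
            vd = mean_val_dice(model, val_set, cfg.threshold, cfg.batch_size)
            entry["val_dice"] = vd
            model.train()
            if vd > best_dice:
                best_dice = vd
                best = {k: v.copy() for k, v in model.state_dict().items()}
        logger.info("epoch %d: loss %.4f%s", epoch, entry["loss"],
                    f" val_dice {entry.get('val_dice'):.4f}" if val_set else "")
        log.epochs.append(entry)
    if not val_set:
        best = {k: v.copy() for k, v in model.state_dict().items()}
    if cfg.checkpoint_dir is not None:
        path = Path(cfg.checkpoint_dir)
        path.mkdir(parents=True, exist_ok=True)
        save_checkpoint(model.config, best, path / "best.npz")
        log.to_json(path / "runlog.json")
    return best, log


# -- checkpoints -----------------------------------------------------------


def save_checkpoint(config: ModelConfig, state: dict[str, np.ndarray], path: str | Path) -> Path:
    """Single checkpoint format: npz with the full ModelConfig embedded."""
    path = Path(path)
    meta = json.dumps({"version": CHECKPOINT_VERSION, "model_config": config.to_dict()})
    np.savez_compressed(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)
    return path


def load_checkpoint(path: str | Path) -> MHANet:
    """Rebuild the model from a checkpoint without any external config."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')} in {path}")
        model = assemble_mhanet(ModelConfig.from_dict(meta["model_config"]))
        model.load_state_dict({k: z[k] for k in z.files if k != "__meta__"})
    return model


# -- evaluation and prediction ---------------------------------------------


def evaluate(
    model: MHANet,
    test_set,
    threshold: float = 0.5,
) -> tuple[dict[str, M.MetricReport], dict[str, float]]:
    """Pad, predict, crop back, and report metrics per image + macro mean."""
    per_image: dict[str, M.MetricReport] = {}
    for i, rec in enumerate(test_set):
        name = rec[0] if isinstance(rec, tuple) and len(rec) == 3 else f"sample{i:04d}"
        img, msk = _img_mask(rec)
        img_p, crop = pad_to_stride(img)
        prob = crop_back(model.predict_proba(to_batch([img_p]))[0, 0], crop)
        per_image[name] = M.metric_report(prob, msk, threshold=threshold)
    return per_image, M.aggregate_reports(list(per_image.values()))


def predict(
    model: MHANet,
    image_path: str | Path,
    out_dir: str | Path,
    threshold: float = 0.5,
) -> tuple[Path, Path]:
    """Write the probability map (16-bit PNG) and the thresholded mask
    ({0,255} 8-bit PNG), both crop-corrected to the input size.

    The stored mask is derived from the *quantized* probability map, so
    re-thresholding the written 16-bit PNG reproduces the written mask.
    """
    image_path, out_dir = Path(image_path), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img = load_image(image_path)
    img_p, crop = pad_to_stride(img)
    prob = crop_back(model.predict_proba(to_batch([img_p]))[0, 0], crop)
    q = np.round(prob * 65535).astype(np.uint16)
    mask = ((q / 65535.0) >= threshold).astype(np.uint8) * 255
    prob_path = out_dir / f"{image_path.stem}_prob.png"
    mask_path = out_dir / f"{image_path.stem}_mask.png"
    Image.fromarray(q, mode="I;16").save(prob_path)
    Image.fromarray(mask, mode="L").save(mask_path)
    return prob_path, mask_path
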