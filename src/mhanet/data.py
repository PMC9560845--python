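"""Dataset I/O, stride padding, and split logic.

Real datasets are an image directory plus a mask directory with matching
file stems (masks single-channel PNG, foreground > 127), or a manifest
directory written by :mod:`mhanet.synth`. Images whose sides are not
divisible by 32 (e.g. 584x565 retinal images) are reflection-padded on the
bottom/right edges to the next multiple; the crop record inverts the
padding exactly on the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

IMAGE_EXTS = (".png", ".tif", ".tiff", ".jpg", ".jpeg")


@dataclass(frozen=True)
class CropRecord:
    """Original spatial size before :func:`pad_to_stride`."""

    height: int
    width: int

    @property
    def empty(self) -> bool:
        return False  # kept for clarity; cropping a same-size array is a no-op


def pad_to_stride(image: np.ndarray, stride: int = 32) -> tuple[np.ndarray, CropRecord]:
    """Reflection-pad the first two axes up to the next multiple of ``stride``."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    h, w = image.shape[:2]
    ph = (-h) % stride
    pw = (-w) % stride
    rec = CropRecord(h, w)
    if ph == 0 and pw == 0:
        return image, rec
    pad_width = [(0, ph), (0, pw)] + [(0, 0)] * (image.ndim - 2)
    return np.pad(image, pad_width, mode="reflect"), rec


def crop_back(arr: np.ndarray, rec: CropRecord) -> np.ndarray:
    """Undo :func:`pad_to_stride` on an array with leading (H, W) axes."""
    return arr[: rec.height, : rec.width]


def load_image(path: str | Path) -> np.ndarray:
    """(H, W, 3) float32 in [0, 1]."""
    try:
        img = Image.open(path).convert("RGB")
    except OSError as e:
        raise OSError(f"cannot read image {path}: {e}") from e
    return (np.asarray(img) / 255.0).astype(np.float32)


def load_mask(path: str | Path) -> np.ndarray:
    """(H, W) uint8 in {0, 1}; foreground is > 127 in the stored PNG."""
    try:
        msk = Image.open(path).convert("L")
    except OSError as e:
        raise OSError(f"cannot read mask {path}: {e}") from e
    return (np.asarray(msk) > 127).astype(np.uint8)


def load_pairs(image_dir: str | Path, mask_dir: str | Path) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Match images to masks by file stem; every image must have a partner."""
    image_dir, mask_dir = Path(image_dir), Path(mask_dir)
    masks = {p.stem: p for p in sorted(mask_dir.iterdir()) if p.suffix.lower() in IMAGE_EXTS}
    out = []
    for p in sorted(image_dir.iterdir()):
        if p.suffix.lower() not in IMAGE_EXTS:
            continue
        if p.stem not in masks:
            raise FileNotFoundError(f"no mask partner for image {p} under {mask_dir}")
        out.append((p.stem, load_image(p), load_mask(masks[p.stem])))
    if not out:
        raise FileNotFoundError(f"no images found under {image_dir}")
    return out


def split_indices(
    n: int, fractions: tuple[float, float, float], seed: int
) -> dict[str, np.ndarray]:
    """Seeded shuffle split into train/val/test index arrays."""
    if abs(sum(fractions) - 1.0) > 1e-8:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return {
        "train": order[:n_train],
        "val": order[n_train : n_train + n_val],
        "test": order[n_train + n_val :],
    }


def to_batch(images: list[np.ndarray]) -> np.ndarray:
    """Stack (H, W, 3) images into a (B, 3, H, W) float32 batch."""
    shapes = {im.shape for im in images}
    if len(shapes) != 1:
        raise ValueError(f"cannot batch images of mixed sizes: {sorted(shapes)}")
    return np.ascontiguousarray(np.stack(images).transpose(0, 3, 1, 2)).astype(np.float32)
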