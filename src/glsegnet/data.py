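"""Dataset I/O: name-matched ``images/`` + ``masks/`` PNG directories."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .exceptions import DataError

__all__ = ["load_dataset", "load_split"]

_IMAGE_EXTS = (".png", ".jpg", ".jpeg", ".tif", ".tiff")


def _listing(d: Path) -> dict[str, Path]:
    if not d.is_dir():
        raise DataError(f"missing directory: {d}")
    return {p.stem: p for p in sorted(d.iterdir())
            if p.suffix.lower() in _IMAGE_EXTS}


def image_to_chw(img: Image.Image, image_size: int) -> np.ndarray:
    """Resize to a square, scale to [0, 1], return channels-first (3, S, S).

    Color images keep their RGB channels; grayscale is replicated to 3.
    """
    if img.mode in ("RGB", "RGBA", "P"):
        img = img.convert("RGB").resize((image_size, image_size), Image.BILINEAR)
        arr = np.asarray(img, dtype=np.float32).transpose(2, 0, 1) / 255.0
        return arr
    img = img.convert("F").resize((image_size, image_size), Image.BILINEAR)
    arr = np.asarray(img, dtype=np.float32)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return np.repeat(arr[None], 3, axis=0)


def load_split(split_dir, image_size: int) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Load one split directory into arrays.

    Images are bilinearly resized to ``image_size`` square, scaled to [0, 1]
    and replicated to 3 channels; masks are resized with nearest neighbor and
    re-binarized at 0.5.  Returns (images (N,3,S,S), masks (N,1,S,S), names).
    """
    split_dir = Path(split_dir)
    images = _listing(split_dir / "images")
    masks = _listing(split_dir / "masks")
    unmatched = sorted(set(images) ^ set(masks))
    if unmatched:
        raise DataError(
            f"unmatched image/mask names in {split_dir}: {unmatched}")
    xs, ys, names = [], [], []
    for name in sorted(images):
        try:
            img = Image.open(images[name])
            mask = Image.open(masks[name])
        except OSError as exc:
            raise DataError(f"unreadable file for sample {name!r}: {exc}") from exc
        arr = image_to_chw(img, image_size)
        mask = mask.convert("F").resize((image_size, image_size), Image.NEAREST)
        m = np.asarray(mask, dtype=np.float32)
        if m.max() > 1.0:
            m = m / 255.0
        xs.append(arr)
        ys.append((m >= 0.5).astype(np.float32)[None])
        names.append(name)
    if not xs:
        raise DataError(f"no samples found in {split_dir}")
    return np.stack(xs), np.stack(ys), names


def load_dataset(data_dir, image_size: int) -> dict[str, tuple]:
    """Load ``train/`` and ``test/`` splits, asserting they are disjoint."""
    data_dir = Path(data_dir)
    out = {}
    for split in ("train", "test"):
        if (data_dir / split).is_dir():
            out[split] = load_split(data_dir / split, image_size)
    if not out:
        raise DataError(f"no train/ or test/ split found under {data_dir}")
    if "train" in out and "test" in out:
        overlap = set(out["train"][2]) & set(out["test"][2])
        if overlap:
            raise DataError(f"train/test leakage, shared names: {sorted(overlap)[:5]}")
    return out
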