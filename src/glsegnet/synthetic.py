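"""Deterministic synthetic lesion-on-background image/mask generator.

Each sample is one or more irregular blobs (superellipses with a low-frequency
radial perturbation, a crude analog of irregular lesion margins) on a darker
background, with optional intensity gradient, band-limited texture, boundary
blur and additive Gaussian noise.  The binary mask is exact by construction.
``(spec.seed, index)`` fully determine a sample, so any subset of a dataset is
reproducible independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .exceptions import GenerationError

__all__ = ["SyntheticSpec", "generate_pair", "generate_dataset", "load_manifest"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; radii are fractions of the image size."""

    image_size: int = 256
    n_blobs: tuple[int, int] = (1, 3)
    blob_radius: tuple[float, float] = (0.09, 0.18)
    boundary_blur_sigma: float = 1.5
    texture_amplitude: float = 0.06
    noise_sigma: float = 0.03
    intensity_gradient: float = 0.15
    background_level: float = 0.30
    foreground_offset: float = 0.35
    margin: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.image_size % 16:
            raise GenerationError("image_size must be divisible by 16")
        if self.blob_radius[1] + self.margin >= 0.5:
            raise GenerationError(
                "largest blob radius plus margin must leave room inside the frame")


def _rng_for(spec: SyntheticSpec, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, int(index)]))


def _blob_mask(size: int, rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    r_lo, r_hi = spec.blob_radius
    r0 = rng.uniform(r_lo, r_hi) * size
    # maximum radial excursion of the perturbed superellipse
    amps = rng.uniform(0.0, 0.05, size=4) * np.array([1.0, 0.8, 0.6, 0.4])
    r_max = r0 * (1.0 + amps.sum())
    lo = spec.margin * size + r_max
    hi = size - spec.margin * size - r_max
    if hi <= lo:
        raise GenerationError(
            f"blob of radius {r_max:.1f}px cannot fit a {size}px frame "
            f"with margin {spec.margin}")
    cy, cx = rng.uniform(lo, hi, size=2)
    p = rng.uniform(1.6, 3.0)                     # superellipse exponent
    phases = rng.uniform(0, 2 * np.pi, size=4)
    ecc = rng.uniform(0.7, 1.3)                   # axis ratio
    rot = rng.uniform(0, np.pi)

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    ry = dy * np.cos(rot) - dx * np.sin(rot)
    rx = dy * np.sin(rot) + dx * np.cos(rot)
    theta = np.arctan2(ry, rx * ecc)
    radius = r0 * (1.0 + sum(a * np.cos((k + 1) * theta + ph)
                             for k, (a, ph) in enumerate(zip(amps, phases))))
    dist = (np.abs(rx * ecc / radius) ** p + np.abs(ry / radius) ** p) ** (1.0 / p)
    return dist <= 1.0


def generate_pair(spec: SyntheticSpec, index: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (image float64 in [0,1] of shape (S,S), mask uint8 {0,1})."""
    rng = _rng_for(spec, index)
    size = spec.image_size
    n = rng.integers(spec.n_blobs[0], spec.n_blobs[1] + 1)
    mask = np.zeros((size, size), dtype=bool)
    for _ in range(int(n)):
        mask |= _blob_mask(size, rng, spec)

    two_level = spec.background_level + spec.foreground_offset * mask.astype(np.float64)
    if spec.boundary_blur_sigma > 0:
        two_level = ndimage.gaussian_filter(two_level, spec.boundary_blur_sigma)

    img = two_level
    if spec.intensity_gradient > 0:
        angle = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:size, 0:size].astype(np.float64) / max(size - 1, 1)
        ramp = (yy - 0.5) * np.sin(angle) + (xx - 0.5) * np.cos(angle)
        img = img + spec.intensity_gradient * ramp
    if spec.texture_amplitude > 0:
        tex = ndimage.gaussian_filter(rng.standard_normal((size, size)), 3.0)
        tex_std = tex.std()
        if tex_std > 0:
            img = img + spec.texture_amplitude * tex / tex_std
    if spec.noise_sigma > 0:
        img = img + spec.noise_sigma * rng.standard_normal((size, size))
    return np.clip(img, 0.0, 1.0), mask.astype(np.uint8)


def generate_dataset(spec: SyntheticSpec, n_train: int, n_test: int,
                     out_dir) -> dict:
    """Write a ``train/``+``test/`` PNG dataset and its JSON manifest.

    Train items use indices ``0..n_train-1``, test items the following range,
    so the splits are disjoint by construction.
    """
    out = Path(out_dir)
    manifest = {"spec": dataclasses.asdict(spec), "splits": {}}
    offsets = {"train": (0, n_train), "test": (n_train, n_train + n_test)}
    for split, (start, stop) in offsets.items():
        img_dir = out / split / "images"
        mask_dir = out / split / "masks"
        img_dir.mkdir(parents=True, exist_ok=True)
        mask_dir.mkdir(parents=True, exist_ok=True)
        items = []
        for idx in range(start, stop):
            img, mask = generate_pair(spec, idx)
            name = f"sample_{idx:04d}.png"
            iio.imwrite(img_dir / name, np.round(img * 255).astype(np.uint8))
            iio.imwrite(mask_dir / name, (mask * 255).astype(np.uint8))
            items.append({"name": name, "index": idx})
        manifest["splits"][split] = items
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_manifest(data_dir) -> dict:
    return json.loads((Path(data_dir) / "manifest.json").read_text())


def dataset_checksum(data_dir) -> str:
    """SHA-256 over all PNG bytes, for reproducibility checks."""
    h = hashlib.sha256()
    for path in sorted(Path(data_dir).rglob("*.png")):
        h.update(path.name.encode())
        h.update(path.read_bytes())
    return h.hexdigest()
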