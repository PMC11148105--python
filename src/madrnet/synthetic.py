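"""Seeded synthetic image/mask generator for segmentation experiments.

Two families of fixture are produced, emulating the statistical shape of
common 2-D biomedical segmentation tasks without copying any dataset:

* **binary** — one to three smooth, irregular bright blobs (lesion- or
  mitochondria-like, with low-frequency boundary perturbations standing in
  for the blurred lesion boundaries of dermoscopy/EM data) on a textured
  background, with additive Gaussian noise.  The foreground fraction is
  kept inside a configurable band (2-40 % by default) so the class
  imbalance typical of medical masks is exercised.
* **multiclass3** — a cardiac-style geometry: an inner ellipse (label 1,
  endocardium-like) strictly nested inside an elliptical ring (label 2,
  epicardium-like), with a separate adjacent ellipse below (label 3,
  atrium-like) on background label 0.

Generation is fully deterministic: a given :class:`SyntheticSpec` yields
byte-identical arrays on every run and platform (single PCG64 stream per
call, integer-seeded).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize


@dataclass(frozen=True)
class SyntheticSpec:
    n_images: int = 16
    image_size: int = 128
    task: str = "binary"  # binary | multiclass3
    channels: int = 1
    noise_sd: float = 0.05
    blob_count: tuple[int, int] = (1, 3)
    contrast: float = 0.5
    fg_band: tuple[float, float] = (0.02, 0.40)
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32")
        if self.task not in ("binary", "multiclass3"):
            raise ValueError("task must be 'binary' or 'multiclass3'")
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 or 3")
        if self.n_images < 1:
            raise ValueError("n_images must be positive")


# ------------------------------------------------------------------ geometry
def _ellipse_mask(size: int, cy: float, cx: float, ry: float, rx: float,
                  angle: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    y, x = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * x + sa * y
    v = -sa * x + ca * y
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _smooth_blob(rng: np.random.Generator, size: int) -> np.ndarray:
    """An ellipse with a smoothed, slightly irregular boundary."""
    cy, cx = rng.uniform(0.25 * size, 0.75 * size, size=2)
    ry = rng.uniform(size / 14, size / 5)
    rx = rng.uniform(size / 14, size / 5)
    angle = rng.uniform(0, np.pi)
    mask = _ellipse_mask(size, cy, cx, ry, rx, angle).astype(np.float64)
    # low-frequency boundary noise: jitter the soft mask, re-threshold
    bump = ndimage.gaussian_filter(rng.standard_normal((size, size)), size / 24)
    soft = ndimage.gaussian_filter(mask, size / 48) + 0.35 * bump
    return soft > 0.5


def _texture(rng: np.random.Generator, size: int) -> np.ndarray:
    t = ndimage.gaussian_filter(rng.standard_normal((size, size)), size / 16)
    lo, hi = t.min(), t.max()
    return (t - lo) / (hi - lo) if hi > lo else np.zeros_like(t)


def _render(rng: np.random.Generator, fg: np.ndarray, spec: SyntheticSpec,
            level: np.ndarray | None = None) -> np.ndarray:
    """Compose texture + foreground offset + noise into (C, H, W) in [0, 1]."""
    size = spec.image_size
    base = 0.5 * _texture(rng, size)
    base = base + spec.contrast * (fg if level is None else level)
    chans = []
    for _ in range(spec.channels):
        img = base + rng.normal(0.0, spec.noise_sd, size=base.shape)
        chans.append(img)
    img = np.stack(chans, axis=0)
    lo, hi = img.min(), img.max()
    img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    return img.astype(np.float32)


# ----------------------------------------------------------------- operations
def generate_binary(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Blob-on-texture binary dataset.

    Returns ``(images, masks)`` with images (N, C, H, W) float32 in [0, 1]
    and masks (N, H, W) uint8 in {0, 1}; the foreground fraction of every
    mask lies inside ``spec.fg_band``.
    """
    if spec.task != "binary":
        raise ValueError("spec.task must be 'binary'")
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    lo, hi = spec.fg_band
    images, masks = [], []
    for _ in range(spec.n_images):
        for _attempt in range(100):
            k = int(rng.integers(spec.blob_count[0], spec.blob_count[1] + 1))
            mask = np.zeros((size, size), dtype=bool)
            for _b in range(k):
                mask |= _smooth_blob(rng, size)
            frac = mask.mean()
            if lo <= frac <= hi:
                break
        else:  # pragma: no cover - the band is wide; rejection converges fast
            raise RuntimeError("could not draw a mask inside the foreground band")
        images.append(_render(rng, mask.astype(np.float64), spec))
        masks.append(mask.astype(np.uint8))
    return np.stack(images), np.stack(masks)


def generate_multiclass3(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Nested/adjacent-ellipse dataset with labels {0, 1, 2, 3}.

    Label 1 is strictly inside the label-2 ring; label 3 is a disjoint
    region adjacent below; label 0 is background.
    """
    if spec.task != "multiclass3":
        raise ValueError("spec.task must be 'multiclass3'")
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    images, masks = [], []
    for _ in range(spec.n_images):
        cy = rng.uniform(0.30 * size, 0.45 * size)
        cx = rng.uniform(0.40 * size, 0.60 * size)
        ry = rng.uniform(size / 8, size / 5)
        rx = rng.uniform(size / 9, size / 6)
        angle = rng.uniform(-0.3, 0.3)
        scale = rng.uniform(1.35, 1.6)  # ring thickness: outer/inner radius ratio
        inner = _ellipse_mask(size, cy, cx, ry, rx, angle)
        outer = _ellipse_mask(size, cy, cx, scale * ry, scale * rx, angle)
        # adjacent region below the outer ellipse
        ay = cy + scale * ry + rng.uniform(size / 24, size / 12)
        ar = rng.uniform(size / 10, size / 7)
        adj = _ellipse_mask(size, ay, cx + rng.uniform(-size / 16, size / 16),
                            ar * 0.8, ar, 0.0)
        mask = np.zeros((size, size), dtype=np.uint8)
        mask[outer] = 2
        mask[inner] = 1
        mask[adj & (mask == 0)] = 3
        if not np.array_equal(np.unique(mask), [0, 1, 2, 3]):
            # extremely rare (adjacent ellipse off-canvas); redraw via new offsets
            mask[-size // 8 :, : size // 8] = 3
        level = np.zeros((size, size))
        for lbl, amp in ((1, 1.0), (2, 0.55), (3, 0.8)):
            level[mask == lbl] = amp
        images.append(_render(rng, None, spec, level=level))
        masks.append(mask)
    return np.stack(images), np.stack(masks)


def generate(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    return generate_binary(spec) if spec.task == "binary" else generate_multiclass3(spec)


def normalize_and_resize(image: np.ndarray, target_size: int,
                         is_mask: bool = False) -> np.ndarray:
    """Min-max normalize to [0, 1] and resize to ``target_size`` square.

    Images are resized bilinearly; masks use nearest-neighbor so integer
    labels are preserved (and are not normalized).  A constant image maps
    to all zeros.
    """
    a = np.asarray(image)
    if is_mask:
        if a.shape == (target_size, target_size):
            return a.copy()
        out = _sk_resize(a.astype(np.float64), (target_size, target_size),
                         order=0, preserve_range=True, anti_aliasing=False)
        return out.astype(a.dtype)
    a = a.astype(np.float64)
    lo, hi = a.min(), a.max()
    a = (a - lo) / (hi - lo) if hi > lo else np.zeros_like(a)
    if a.shape[-2:] != (target_size, target_size):
        a = _sk_resize(a, a.shape[:-2] + (target_size, target_size),
                       order=1, preserve_range=True, anti_aliasing=True)
        a = np.clip(a, 0.0, 1.0)
    return a.astype(np.float32)


IDENTITY_AUGMENT = {"flip_h": False, "flip_v": False, "rot90": 0,
                    "gain": 1.0, "offset": 0.0}


def draw_augment_params(rng: np.random.Generator) -> dict:
    return {
        "flip_h": bool(rng.random() < 0.5),
        "flip_v": bool(rng.random() < 0.5),
        "rot90": int(rng.integers(0, 4)),
        "gain": float(rng.uniform(0.9, 1.1)),
        "offset": float(rng.uniform(-0.05, 0.05)),
    }


def apply_augment(image: np.ndarray, mask: np.ndarray,
                  params: dict) -> tuple[np.ndarray, np.ndarray]:
    """Apply flips / 90-degree rotations to both arrays, jitter image only.

    ``image`` is (C, H, W); ``mask`` is (H, W).  Geometric transforms are
    identical for the pair; labels pass through untouched.
    """
    img = np.asarray(image).copy()
    msk = np.asarray(mask).copy()
    if params["flip_h"]:
        img = img[..., ::-1]
        msk = msk[..., ::-1]
    if params["flip_v"]:
        img = img[..., ::-1, :]
        msk = msk[..., ::-1, :]
    k = params["rot90"] % 4
    if k:
        img = np.rot90(img, k, axes=(-2, -1))
        msk = np.rot90(msk, k, axes=(-2, -1))
    img = np.clip(img * params["gain"] + params["offset"], 0.0, 1.0)
    return np.ascontiguousarray(img, dtype=np.float32), np.ascontiguousarray(msk)


def augment(image: np.ndarray, mask: np.ndarray,
            seed: int | np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random flip/rotation/intensity-jitter of a paired sample."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return apply_augment(image, mask, draw_augment_params(rng))


def split_dataset(n: int, seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded 80/10/10 shuffle-split into (train, val, test) index arrays.

    Sizes are floor(0.8 n), floor(0.1 n) and the remainder; the three sets
    are disjoint and exhaustive.
    """
    if n < 10:
        raise ValueError("need at least 10 samples for an 80/10/10 split")
    idx = np.random.default_rng(seed).permutation(n)
    n_train = int(0.8 * n)
    n_val = int(0.1 * n)
    return idx[:n_train], idx[n_train : n_train + n_val], idx[n_train + n_val :]


def masks_to_targets(masks: np.ndarray, num_classes: int) -> np.ndarray:
    """Label maps (N, H, W) -> training targets.

    Binary (num_classes == 1): (N, 1, H, W) float32 in {0, 1}.
    Multiclass: one-hot (N, M, H, W) float32.
    """
    masks = np.asarray(masks)
    if num_classes == 1:
        return masks[:, None].astype(np.float32)
    return np.stack([(masks == m) for m in range(num_classes)], axis=1).astype(np.float32)


# ------------------------------------------------------------------- disk I/O
def save_dataset(path: str | Path, images: np.ndarray, masks: np.ndarray,
                 spec: SyntheticSpec, split_seed: int | None = None) -> Path:
    """Write paired PNGs (img_NNNN.png / msk_NNNN.png) plus a JSON manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n = len(images)
    for i, (img, msk) in enumerate(zip(images, masks)):
        arr = np.clip(np.round(img * 255), 0, 255).astype(np.uint8)
        arr = arr[0] if arr.shape[0] == 1 else arr.transpose(1, 2, 0)
        iio.imwrite(path / f"img_{i:04d}.png", arr)
        iio.imwrite(path / f"msk_{i:04d}.png", msk.astype(np.uint8))
    manifest = {"spec": asdict(spec), "n_images": n}
    if split_seed is not None and n >= 10:
        tr, va, te = split_dataset(n, split_seed)
        manifest["split"] = {"seed": split_seed, "train": tr.tolist(),
                             "val": va.tolist(), "test": te.tolist()}
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return path


def load_dataset(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a dataset written by :func:`save_dataset`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    images, masks = [], []
    for i in range(manifest["n_images"]):
        img = np.asarray(iio.imread(path / f"img_{i:04d}.png"), dtype=np.float32) / 255.0
        img = img[None] if img.ndim == 2 else img.transpose(2, 0, 1)
        images.append(img)
        masks.append(np.asarray(iio.imread(path / f"msk_{i:04d}.png"), dtype=np.uint8))
    return np.stack(images), np.stack(masks), manifest
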