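"""Synthetic leaf-image generation and dataset I/O.

Real ligneous leaf-disease photographs (22 imbalanced classes of apple,
cherry, grape, citrus and peach leaves, each disease graded *general* or
*serious*) cannot ship with the package, so this module generates labeled
stand-ins that preserve the properties the model cares about: an elliptical
leaf blade with a class-specific hue on a textured background, and — for
diseased classes — lesions scattered across the entire blade rather than
clustered in one spot, with *serious* grades denser than *general* ones.
Everything is driven by explicit seeds, so regenerating a dataset yields
bit-identical files.

The class manifest mirrors the source dataset's bookkeeping: 22 classes,
11,603 training and 1,668 testing images.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "ManifestEntry",
    "ClassManifest",
    "dataset_manifest",
    "LeafClassSpec",
    "class_specs",
    "generate_leaf_image",
    "generate_class_arrays",
    "generate_dataset",
    "load_image_folder",
]


@dataclass(frozen=True)
class ManifestEntry:
    label_index: int
    label_name: str
    train_count: int
    test_count: int


@dataclass(frozen=True)
class ClassManifest:
    entries: tuple[ManifestEntry, ...]

    def __post_init__(self):
        names = [e.label_name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")
        if any(e.train_count < 0 or e.test_count < 0 for e in self.entries):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def train_total(self) -> int:
        return sum(e.train_count for e in self.entries)

    @property
    def test_total(self) -> int:
        return sum(e.test_count for e in self.entries)


_MANIFEST_ROWS = [
    ("Apple healthy", 1185, 169),
    ("Apple_Scab general", 211, 30),
    ("Apple_Scab serious", 152, 22),
    ("Apple Frogeye Spot", 427, 61),
    ("Cedar Apple Rust general", 142, 20),
    ("Cedar Apple Rust serious", 40, 6),
    ("Cherry healthy", 598, 85),
    ("Cherry_Powdery Mildew general", 116, 12),
    ("Cherry_Powdery Mildew serious", 110, 18),
    ("Grape healthy", 294, 42),
    ("Grape Black Rot Fungus general", 381, 54),
    ("Grape Black Rot Fungus serious", 462, 66),
    ("Grape Black Measles Fungus general", 503, 74),
    ("Grape Black Measles Fungus serious", 419, 59),
    ("Grape Leaf Blight Fungus general", 61, 9),
    ("Grape Leaf Blight Fungus serious", 630, 90),
    ("Citrus healthy", 367, 52),
    ("Citrus Greening June general", 1828, 269),
    ("Citrus Greening June serious", 1799, 262),
    ("Peach healthy", 251, 36),
    ("Peach_Bacterial Spot general", 857, 122),
    ("Peach_Bacterial Spot serious", 770, 110),
]


def dataset_manifest() -> ClassManifest:
    """The 22-class train/test distribution of the source dataset."""
    return ClassManifest(tuple(
        ManifestEntry(i, name, tr, te) for i, (name, tr, te) in enumerate(_MANIFEST_ROWS)))


@dataclass(frozen=True)
class LeafClassSpec:
    """Generative parameters for one class of synthetic leaf images."""

    name: str
    hue: float                    # base blade hue in [0, 1) (HSV circle)
    hue_jitter: float = 0.02
    blade_aspect: float = 0.68    # minor/major semi-axis ratio
    lesion_rate: float = 0.0      # expected lesion count; 0 -> healthy
    lesion_radius: tuple[float, float] = (0.02, 0.05)   # fraction of image side
    lesion_color: tuple[float, float, float] = (0.45, 0.27, 0.12)
    severity: str = "healthy"     # healthy | general | serious

    def __post_init__(self):
        if not 0.0 <= self.hue < 1.0:
            raise ValueError("hue must lie in [0, 1)")
        if self.lesion_rate < 0:
            raise ValueError("lesion rate must be non-negative")
        if self.severity == "healthy" and self.lesion_rate != 0:
            raise ValueError("healthy classes place zero lesions")


_SPECIES_HUE = {
    "Apple": 0.30, "Cedar": 0.30, "Cherry": 0.36, "Grape": 0.26,
    "Citrus": 0.22, "Peach": 0.33,
}
# Disease severity shows as both scattered lesions and chlorosis: the blade
# hue drifts from green toward yellow as the disease progresses, and serious
# grades carry denser, larger lesions than general ones.
_GENERAL_RATE = 15.0
_SERIOUS_RATE = 35.0
_GENERAL_HUE_SHIFT = 0.06
_SERIOUS_HUE_SHIFT = 0.13
_GENERAL_RADIUS = (0.02, 0.05)
_SERIOUS_RADIUS = (0.03, 0.08)


def class_specs(manifest: ClassManifest | None = None) -> list[LeafClassSpec]:
    """Derive a distinct generative spec for every manifest class."""
    manifest = manifest or dataset_manifest()
    specs = []
    for e in manifest.entries:
        species = e.label_name.split("_")[0].split()[0]
        hue = _SPECIES_HUE.get(species, 0.3)
        # nudge hue per class index so every class is a distinct tuple
        hue = (hue + 0.012 * (e.label_index % 5)) % 1.0
        name_l = e.label_name.lower()
        if "healthy" in name_l:
            severity, rate, radius = "healthy", 0.0, (0.02, 0.05)
        elif "serious" in name_l:
            severity, rate, radius = "serious", _SERIOUS_RATE, _SERIOUS_RADIUS
            hue = max(0.10, hue - _SERIOUS_HUE_SHIFT)
        else:
            severity, rate, radius = "general", _GENERAL_RATE, _GENERAL_RADIUS
            hue = max(0.10, hue - _GENERAL_HUE_SHIFT)
        lesion_color = (0.45 + 0.02 * (e.label_index % 3), 0.27, 0.10 + 0.015 * (e.label_index % 4))
        specs.append(LeafClassSpec(
            name=e.label_name, hue=hue, blade_aspect=0.6 + 0.02 * (e.label_index % 5),
            lesion_rate=rate, lesion_radius=radius, lesion_color=lesion_color, severity=severity))
    return specs


def _smooth_noise(rng: np.random.Generator, size: int, cells: int = 8) -> np.ndarray:
    coarse = rng.random((cells, cells))
    return ndimage.zoom(coarse, size / cells, order=1, mode="nearest")[:size, :size]


def _hsv_pixelwise(h: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Vectorized HSV -> RGB on full-size maps."""
    i = np.floor(h * 6.0).astype(int) % 6
    f = h * 6.0 - np.floor(h * 6.0)
    p = v * (1 - s)
    q = v * (1 - f * s)
    t = v * (1 - (1 - f) * s)
    rgb = np.zeros(h.shape + (3,))
    for k, (r_, g_, b_) in enumerate([(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)]):
        m = i == k
        rgb[m, 0], rgb[m, 1], rgb[m, 2] = r_[m], g_[m], b_[m]
    return rgb


def generate_leaf_image(spec: LeafClassSpec, size: int = 224, seed: int = 0,
                        return_info: bool = False):
    """Render one synthetic leaf image in [0, 1] RGB.

    Diseased specs scatter lesions uniformly over the whole blade (a seeded
    point process), emulating disease whose affected areas are dispersed
    across the entire leaf rather than confined to one region.
    """
    if size < 32:
        raise ValueError("size must be at least 32")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = cx = (size - 1) / 2.0

    # textured background (soil-like)
    bg_base = np.array([0.52, 0.44, 0.36])
    noise = _smooth_noise(rng, size)
    image = bg_base[None, None, :] * (0.85 + 0.3 * noise[..., None])

    # elliptical blade, randomly rotated
    angle = rng.uniform(0, np.pi)
    a = size * rng.uniform(0.38, 0.44)
    b = a * spec.blade_aspect
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(angle) + dy * np.sin(angle)
    v = -dx * np.sin(angle) + dy * np.cos(angle)
    blade = (u / a) ** 2 + (v / b) ** 2 <= 1.0

    hue = (spec.hue + rng.uniform(-spec.hue_jitter, spec.hue_jitter)) % 1.0
    hue_map = np.full((size, size), hue) + 0.01 * _smooth_noise(rng, size)
    sat_map = 0.55 + 0.25 * _smooth_noise(rng, size)
    val_map = 0.45 + 0.3 * _smooth_noise(rng, size)
    # vein shading along the major axis
    val_map = val_map * (0.9 + 0.1 * np.cos(v / max(b, 1) * np.pi * 6) ** 2)
    blade_rgb = _hsv_pixelwise(hue_map % 1.0, np.clip(sat_map, 0, 1), np.clip(val_map, 0, 1))
    image[blade] = blade_rgb[blade]

    # lesions: seeded point process uniform over the blade
    lesion_mask = np.zeros((size, size), dtype=bool)
    centers: list[tuple[float, float]] = []
    n_lesions = 0 if spec.lesion_rate == 0 else max(1, int(rng.poisson(spec.lesion_rate)))
    if n_lesions:
        blade_idx = np.flatnonzero(blade)
        picks = rng.choice(blade_idx, size=n_lesions, replace=True)
        base_color = np.array(spec.lesion_color)
        for flat in picks:
            ly, lx = divmod(int(flat), size)
            centers.append((ly, lx))
            r = size * rng.uniform(*spec.lesion_radius)
            d2 = (yy - ly) ** 2 + (xx - lx) ** 2
            disk = d2 <= r * r
            disk &= blade
            alpha = np.clip(1.0 - np.sqrt(d2) / max(r, 1e-9), 0, 1)[..., None]
            color = np.clip(base_color + rng.normal(0, 0.03, 3), 0, 1)
            image = np.where(disk[..., None], (1 - alpha) * image + alpha * color[None, None, :], image)
            lesion_mask |= disk
    image = np.clip(image, 0.0, 1.0)
    if return_info:
        return image, {"blade_mask": blade, "lesion_mask": lesion_mask, "lesion_centers": centers}
    return image


def generate_class_arrays(specs: list[LeafClassSpec], counts: list[int], size: int = 224,
                          seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """In-memory dataset: stacked images and integer labels (seeded)."""
    root = np.random.SeedSequence(seed)
    images, labels = [], []
    for ci, (spec, n) in enumerate(zip(specs, counts)):
        for j in range(n):
            child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(ci, j))
            images.append(generate_leaf_image(spec, size=size, seed=child))
            labels.append(ci)
    return np.stack(images).astype(np.float32), np.asarray(labels, dtype=np.int64)


def _slug(name: str) -> str:
    return name.replace(" ", "-")


def generate_dataset(manifest: ClassManifest, scale: float, out_dir, seed: int = 0,
                     size: int = 224) -> Path:
    """Write an image-folder dataset scaled down from the manifest counts.

    Layout: ``<out>/<split>/<class_name>/<class>_<index>.png`` with per-class
    counts ``ceil(scale * manifest count)`` and a ``manifest.csv`` of columns
    (label_index, label_name, split, count).  Fully seeded: the same call
    regenerates byte-identical files.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    specs = class_specs(manifest)
    rows = []
    root = np.random.SeedSequence(seed)
    for e, spec in zip(manifest.entries, specs):
        for split_idx, (split, total) in enumerate([("train", e.train_count), ("test", e.test_count)]):
            n = math.ceil(scale * total)
            cls_dir = out / split / _slug(e.label_name)
            cls_dir.mkdir(parents=True, exist_ok=True)
            for j in range(n):
                child = np.random.SeedSequence(
                    entropy=root.entropy, spawn_key=(e.label_index, split_idx, j))
                img = generate_leaf_image(spec, size=size, seed=child)
                arr = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
                Image.fromarray(arr).save(cls_dir / f"{_slug(e.label_name)}_{j:05d}.png")
            rows.append((e.label_index, e.label_name, split, n))
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label_index", "label_name", "split", "count"])
        writer.writerows(rows)
    return out


def load_image_folder(root, size: int | None = 224) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read an image-folder tree into ``(images, labels, class_names)``.

    Classes are the sorted sub-directory names; images are resized (bilinear)
    to ``size`` x ``size`` when requested and scaled to [0, 1] float32.
    Unreadable files are skipped with a warning.
    """
    import warnings

    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise FileNotFoundError(f"no class directories under {root}")
    images, labels = [], []
    names = [d.name for d in class_dirs]
    for ci, d in enumerate(class_dirs):
        for f in sorted(d.iterdir()):
            if f.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            try:
                with Image.open(f) as im:
                    im = im.convert("RGB")
                    if size is not None:
                        im = im.resize((size, size), Image.BILINEAR)
                    images.append(np.asarray(im, dtype=np.float32) / 255.0)
                    labels.append(ci)
            except OSError as exc:
                warnings.warn(f"skipping unreadable image {f}: {exc}")
    return np.stack(images), np.asarray(labels, dtype=np.int64), names
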