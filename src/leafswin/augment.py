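"""Training-time augmentation: RandomFlip, ColorJitter, Mixup, CutMix.

Augmentation acts on the raw image before the edge channel is computed, so
both transformer channels always see geometrically consistent inputs.  Mixup
and CutMix produce soft label vectors; the cross-entropy loss accepts them
directly.  All randomness flows through an explicit ``numpy`` generator so a
fixed seed reproduces batches bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv

__all__ = ["AugSample", "AugPolicy", "random_flip", "color_jitter", "mixup", "cutmix", "augment_batch"]


@dataclass
class AugSample:
    """An image with its (possibly soft) label and mixing coefficient."""

    image: np.ndarray            # (H, W, 3) in [0, 1]
    label: np.ndarray            # simplex vector over num_classes
    lam: float = 1.0
    box: tuple[int, int, int, int] | None = None  # CutMix paste region (y0, y1, x0, x1)

    def __post_init__(self):
        self.label = np.asarray(self.label, dtype=np.float64)
        if np.any(self.label < -1e-9) or abs(self.label.sum() - 1.0) > 1e-6:
            raise ValueError("label must be a probability simplex vector")


@dataclass
class AugPolicy:
    """Which augmentations run and with what strengths."""

    flip_prob: float = 0.5
    brightness: float = 0.4
    contrast: float = 0.4
    saturation: float = 0.4
    hue: float = 0.1
    mixup_alpha: float = 0.8
    cutmix_alpha: float = 1.0
    mix_prob: float = 0.5        # probability a batch gets mixup OR cutmix
    seed: int = 0

    def __post_init__(self):
        for name in ("flip_prob", "mix_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("mixup_alpha", "cutmix_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def random_flip(image: np.ndarray, policy: AugPolicy, rng: np.random.Generator) -> np.ndarray:
    """Horizontal mirror with probability ``policy.flip_prob``."""
    if rng.random() < policy.flip_prob:
        return image[:, ::-1, :].copy()
    return image


def color_jitter(image: np.ndarray, policy: AugPolicy, rng: np.random.Generator) -> np.ndarray:
    """Randomly perturb brightness, contrast, saturation and hue.

    Factor ranges follow the torchvision convention: brightness/contrast/
    saturation factors are drawn from ``[max(0, 1-r), 1+r]``, hue offsets from
    ``[-hue, hue]`` (fraction of the hue circle).  Output is clipped to [0,1].
    """
    out = image.astype(np.float64)
    if policy.brightness:
        out = out * rng.uniform(max(0.0, 1 - policy.brightness), 1 + policy.brightness)
    if policy.contrast:
        f = rng.uniform(max(0.0, 1 - policy.contrast), 1 + policy.contrast)
        mean = out.mean()
        out = (out - mean) * f + mean
    out = np.clip(out, 0.0, 1.0)
    if policy.saturation or policy.hue:
        hsv = rgb2hsv(out)
        if policy.saturation:
            hsv[..., 1] = np.clip(
                hsv[..., 1] * rng.uniform(max(0.0, 1 - policy.saturation), 1 + policy.saturation), 0, 1)
        if policy.hue:
            hsv[..., 0] = (hsv[..., 0] + rng.uniform(-policy.hue, policy.hue)) % 1.0
        out = hsv2rgb(hsv)
    return np.clip(out, 0.0, 1.0)


def mixup(sample_a: AugSample, sample_b: AugSample, alpha: float,
          rng: np.random.Generator, lam: float | None = None) -> AugSample:
    """Convex combination of two samples with Beta(alpha, alpha) coefficient."""
    if sample_a.image.shape != sample_b.image.shape:
        raise ValueError("mixup requires images of identical shape")
    if sample_a.label.shape != sample_b.label.shape:
        raise ValueError("mixup requires labels of identical length")
    if lam is None:
        lam = float(rng.beta(alpha, alpha))
    image = lam * sample_a.image + (1.0 - lam) * sample_b.image
    label = lam * sample_a.label + (1.0 - lam) * sample_b.label
    return AugSample(image=image, label=label, lam=lam)


def cutmix(sample_a: AugSample, sample_b: AugSample, alpha: float,
           rng: np.random.Generator, lam: float | None = None) -> AugSample:
    """Paste a rectangle of ``b`` into ``a``; mix labels by unmasked area.

    The box targets area ``(1 - lam) * H * W`` but is clipped at the image
    border, so the label coefficient is recomputed from the exact pasted
    area: ``lam_adjusted = 1 - box_area / (H * W)``.
    """
    if sample_a.image.shape != sample_b.image.shape:
        raise ValueError("cutmix requires images of identical shape")
    if sample_a.label.shape != sample_b.label.shape:
        raise ValueError("cutmix requires labels of identical length")
    if lam is None:
        lam = float(rng.beta(alpha, alpha))
    h, w = sample_a.image.shape[:2]
    cut_ratio = np.sqrt(1.0 - lam)
    cut_h, cut_w = int(round(h * cut_ratio)), int(round(w * cut_ratio))
    cy, cx = int(rng.integers(h)), int(rng.integers(w))
    y0, y1 = np.clip(cy - cut_h // 2, 0, h), np.clip(cy + (cut_h + 1) // 2, 0, h)
    x0, x1 = np.clip(cx - cut_w // 2, 0, w), np.clip(cx + (cut_w + 1) // 2, 0, w)
    image = sample_a.image.copy()
    image[y0:y1, x0:x1] = sample_b.image[y0:y1, x0:x1]
    lam_adj = 1.0 - (y1 - y0) * (x1 - x0) / (h * w)
    label = lam_adj * sample_a.label + (1.0 - lam_adj) * sample_b.label
    return AugSample(image=image, label=label, lam=lam_adj, box=(int(y0), int(y1), int(x0), int(x1)))


def augment_batch(images: np.ndarray, labels: np.ndarray, policy: AugPolicy,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Apply the full policy to one batch.

    Per image: random flip then color jitter.  Per batch: with probability
    ``mix_prob``, one of Mixup or CutMix (chosen with equal probability) is
    applied against a random permutation of the batch.  ``labels`` may be
    class indices or soft vectors; the output is always soft vectors.
    """
    n = images.shape[0]
    if labels.ndim == 1:
        n_classes = int(labels.max()) + 1 if labels.size else 0
        soft = np.zeros((n, n_classes), dtype=np.float64)
        soft[np.arange(n), labels.astype(int)] = 1.0
    else:
        soft = np.asarray(labels, dtype=np.float64)
    out_images = np.empty_like(images, dtype=np.float64)
    for i in range(n):
        img = random_flip(images[i], policy, rng)
        out_images[i] = color_jitter(img, policy, rng)
    out_labels = soft.copy()
    if n > 1 and rng.random() < policy.mix_prob:
        use_cutmix = rng.random() < 0.5
        perm = rng.permutation(n)
        mixed = np.empty_like(out_images)
        mixed_labels = np.empty_like(out_labels)
        for i in range(n):
            a = AugSample(out_images[i], out_labels[i])
            b = AugSample(out_images[perm[i]], out_labels[perm[i]])
            s = cutmix(a, b, policy.cutmix_alpha, rng) if use_cutmix else mixup(a, b, policy.mixup_alpha, rng)
            mixed[i] = s.image
            mixed_labels[i] = s.label
        out_images, out_labels = mixed, mixed_labels
    return out_images, out_labels
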