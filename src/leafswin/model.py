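"""The dual-channel classifier.

Two structurally identical hierarchical transformer channels with no shared
weights: the upper channel consumes the raw RGB image, the lower channel
consumes the learnable-Sobel edge image derived from it.  Each channel ends
in a globally pooled feature vector; the two vectors are concatenated (upper
first), mapped by a single fully-connected head to class logits, and
normalized by softmax.  Training minimizes cross-entropy, which accepts both
hard class indices and the soft label vectors produced by Mixup/CutMix.

``load_pretrained`` imports an externally distributed Swin-T backbone weight
archive (timm-style parameter names) into one or both channels through an
explicit name-mapping table; the classification head and the Sobel kernels
are never taken from the archive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concatenate, no_grad, softmax
from .nn import Linear, Module
from .sobel import SobelEdgeLayer
from .swin import ModelConfig, SwinChannel

__all__ = [
    "Prediction",
    "DualSwinTransformer",
    "cross_entropy",
    "LoadReport",
    "timm_name_map",
    "load_pretrained",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class Prediction:
    """Per-image output: class probabilities, raw logits, fused features."""

    probabilities: np.ndarray
    logits: np.ndarray
    features: np.ndarray


class DualSwinTransformer(Module):
    """Two-channel model: raw-image and learnable-Sobel-edge transformers fused by concatenation."""

    def __init__(self, config: ModelConfig, seed: int = 0, trainable_sobel: bool = True):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        self.sobel = SobelEdgeLayer(trainable=trainable_sobel)
        self.upper = SwinChannel(config, rng)
        self.lower = SwinChannel(config, rng)
        # zero-initialized head: an untrained model predicts the uniform
        # distribution, and early training skips the collapse-to-uniform phase
        self.head = Linear(2 * config.feature_dim, config.num_classes, rng=rng)
        self.head.weight.data[:] = 0.0
        self.head.bias.data[:] = 0.0

    def _standardize(self, x: Tensor) -> Tensor:
        return (x - self.config.norm_mean) * (1.0 / self.config.norm_std)

    def features(self, image: Tensor) -> Tensor:
        """Fused pre-head feature vector, shape ``(B, 2 * 8C)``, upper first.

        The raw image (values in [0, 1]) feeds the upper channel; the Sobel
        edge image derived from it feeds the lower channel.  Both are
        standardized with the shared ``norm_mean`` / ``norm_std`` statistics
        before their patch embeddings.
        """
        image = image if isinstance(image, Tensor) else Tensor(image)
        if image.ndim == 3:
            image = image.reshape(1, *image.shape)
        upper_feat = self.upper(self._standardize(image))
        edge = self.sobel(image)
        lower_feat = self.lower(self._standardize(edge))
        return concatenate([upper_feat, lower_feat], axis=-1)

    def forward(self, image: Tensor) -> Tensor:
        """Class logits, shape ``(B, num_classes)``."""
        return self.head(self.features(image))

    def predict(self, image) -> Prediction:
        """Inference-mode forward pass returning numpy arrays."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                feats = self.features(image if isinstance(image, Tensor) else Tensor(image))
                logits = self.head(feats)
                probs = softmax(logits, axis=-1)
        finally:
            self.train(was_training)
        return Prediction(probabilities=probs.data, logits=logits.data, features=feats.data)


def cross_entropy(logits: Tensor, target) -> Tensor:
    """Mean cross-entropy over the batch.

    ``target`` is either an integer class-index array or an array of soft
    label vectors (rows on the probability simplex, e.g. from Mixup/CutMix).
    """
    n_classes = logits.shape[-1]
    t = np.asarray(target)
    if t.ndim == logits.ndim - 1 and np.issubdtype(t.dtype, np.integer):
        if t.min() < 0 or t.max() >= n_classes:
            raise ValueError(f"class index out of range [0, {n_classes})")
        onehot = np.zeros(logits.shape, dtype=logits.dtype)
        onehot[np.arange(t.size).reshape(t.shape), t] = 1.0
        t = onehot
    else:
        t = t.astype(logits.dtype)
        if t.shape != tuple(logits.shape):
            raise ValueError(f"soft target shape {t.shape} != logits shape {logits.shape}")
        if np.any(t < -1e-6) or np.any(np.abs(t.sum(axis=-1) - 1.0) > 1e-5):
            raise ValueError("soft targets must be non-negative and sum to 1")
    shift = Tensor(logits.data.max(axis=-1, keepdims=True))
    z = logits - shift
    log_prob = z - z.exp().sum(axis=-1, keepdims=True).log()
    nll = -(Tensor(t) * log_prob).sum(axis=-1)
    return nll.mean()


# -- pretrained-weight import ----------------------------------------------


@dataclass
class LoadReport:
    loaded: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)


def timm_name_map(config: ModelConfig) -> dict[str, tuple[str, str]]:
    """Map external (timm-style) Swin parameter names to channel names.

    Returns ``{external_name: (internal_name, transform)}`` where transform is
    one of ``"copy"``, ``"transpose"`` (torch Linear stores (out, in); ours is
    (in, out)) or ``"conv_embed"`` (torch patch-embed conv weight (C, 3, p, p)
    reordered to our flattened-patch linear layout (p*p*3, C)).
    """
    mapping: dict[str, tuple[str, str]] = {
        "patch_embed.proj.weight": ("patch_embed.proj.weight", "conv_embed"),
        "patch_embed.proj.bias": ("patch_embed.proj.bias", "copy"),
        "patch_embed.norm.weight": ("patch_embed.norm.weight", "copy"),
        "patch_embed.norm.bias": ("patch_embed.norm.bias", "copy"),
        "norm.weight": ("norm.weight", "copy"),
        "norm.bias": ("norm.bias", "copy"),
    }
    for s, depth in enumerate(config.depths):
        for j in range(depth):
            ext = f"layers.{s}.blocks.{j}."
            own = f"stages.{s}.{j}."
            mapping.update({
                ext + "norm1.weight": (own + "norm1.weight", "copy"),
                ext + "norm1.bias": (own + "norm1.bias", "copy"),
                ext + "attn.qkv.weight": (own + "attn.qkv.weight", "transpose"),
                ext + "attn.qkv.bias": (own + "attn.qkv.bias", "copy"),
                ext + "attn.proj.weight": (own + "attn.proj.weight", "transpose"),
                ext + "attn.proj.bias": (own + "attn.proj.bias", "copy"),
                ext + "attn.relative_position_bias_table": (own + "attn.bias_table", "copy"),
                ext + "norm2.weight": (own + "norm2.weight", "copy"),
                ext + "norm2.bias": (own + "norm2.bias", "copy"),
                ext + "mlp.fc1.weight": (own + "mlp.fc1.weight", "transpose"),
                ext + "mlp.fc1.bias": (own + "mlp.fc1.bias", "copy"),
                ext + "mlp.fc2.weight": (own + "mlp.fc2.weight", "transpose"),
                ext + "mlp.fc2.bias": (own + "mlp.fc2.bias", "copy"),
            })
        if s < len(config.depths) - 1:
            ext = f"layers.{s}.downsample."
            own = f"downsamples.{s}."
            mapping.update({
                ext + "norm.weight": (own + "norm.weight", "copy"),
                ext + "norm.bias": (own + "norm.bias", "copy"),
                ext + "reduction.weight": (own + "reduction.weight", "transpose"),
            })
    return mapping


def _apply_transform(arr: np.ndarray, transform: str, config: ModelConfig) -> np.ndarray:
    if transform == "copy":
        return arr
    if transform == "transpose":
        return arr.T
    if transform == "conv_embed":
        p = config.patch_size
        c = config.embed_dim
        if arr.shape != (c, 3, p, p):
            raise ValueError(f"patch-embed conv weight has shape {arr.shape}, expected {(c, 3, p, p)}")
        # (C, rgb, ph, pw) -> token order (ph, pw, rgb) flattened -> (p*p*3, C)
        return arr.transpose(2, 3, 1, 0).reshape(p * p * 3, c)
    raise ValueError(f"unknown transform {transform!r}")


def load_pretrained(model: DualSwinTransformer, archive, channel: str = "both") -> LoadReport:
    """Copy backbone weights from an external archive into the channels.

    ``archive`` is a mapping name -> array or a path to an ``.npz`` file.  The
    classification head and Sobel kernels are never overwritten; archive
    entries with no mapped destination (e.g. ``head.*``, attention-mask
    buffers, relative-position index buffers) are reported as skipped.  A
    shape mismatch on a mapped name raises, naming the parameter.
    """
    if channel not in ("upper", "lower", "both"):
        raise ValueError("channel must be 'upper', 'lower' or 'both'")
    if isinstance(archive, (str, bytes)) or hasattr(archive, "__fspath__"):
        archive = dict(np.load(archive))
    mapping = timm_name_map(model.config)
    targets = [model.upper] if channel == "upper" else [model.lower] if channel == "lower" else [model.upper, model.lower]
    report = LoadReport()
    params = [dict(t.named_parameters()) for t in targets]
    for ext_name, arr in archive.items():
        if ext_name not in mapping:
            report.skipped.append(ext_name)
            continue
        own_name, transform = mapping[ext_name]
        value = _apply_transform(np.asarray(arr), transform, model.config)
        for target_params in params:
            p = target_params[own_name]
            if p.data.shape != value.shape:
                raise ValueError(
                    f"shape mismatch loading {ext_name!r} -> {own_name!r}: "
                    f"{value.shape} vs parameter {p.data.shape}")
            p.data = value.astype(p.data.dtype).copy()
        report.loaded.append(ext_name)
    return report


# -- checkpoints ------------------------------------------------------------


def save_checkpoint(model: DualSwinTransformer, path, metadata: dict | None = None) -> None:
    """Flat named-parameter archive (.npz) with a JSON metadata block."""
    meta = dict(metadata or {})
    meta.setdefault("config", model.config.__dict__ | {
        "depths": list(model.config.depths), "num_heads": list(model.config.num_heads)})
    arrays = {f"param:{k}": v for k, v in model.state_dict().items()}
    arrays["__meta__"] = np.frombuffer(json.dumps(meta, default=str).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path, trainable_sobel: bool = True) -> tuple[DualSwinTransformer, dict]:
    """Rebuild a model from :func:`save_checkpoint` output."""
    archive = np.load(path)
    meta = json.loads(bytes(archive["__meta__"]).decode())
    cfg_dict = dict(meta["config"])
    cfg_dict["depths"] = tuple(cfg_dict["depths"])
    cfg_dict["num_heads"] = tuple(cfg_dict["num_heads"])
    config = ModelConfig(**{k: v for k, v in cfg_dict.items() if k in ModelConfig.__dataclass_fields__})
    model = DualSwinTransformer(config, trainable_sobel=trainable_sobel)
    state = {k[len("param:"):]: archive[k] for k in archive.files if k.startswith("param:")}
    model.load_state_dict(state)
    return model, meta
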