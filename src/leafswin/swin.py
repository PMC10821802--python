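"""Hierarchical shifted-window transformer channel.

One channel of the dual model: 4x4 patch partition, linear embedding to C
dimensions, four stages of windowed-attention blocks (depths 2/2/6/2 by
default) separated by patch-merging downsampling, ending in a layer-normalized
globally-pooled feature vector.  Within a stage, blocks alternate between
regular-window attention (W-MSA) and shifted-window attention (SW-MSA); the
shifted variant cyclically rolls the token grid by half a window and masks
attention so tokens from different pre-shift windows never interact.

The block recurrence is the standard pre-norm residual form::

    x  <-  x + (S)W-MSA(LN(x))
    x  <-  x + MLP(LN(x))

Also provided: the closed-form multiply-accumulate counts of global
self-attention versus window-restricted self-attention,

    omega_MSA   = 4 h w C^2 + 2 (h w)^2 C
    omega_W-MSA = 4 h w C^2 + 2 M^2 h w C,

which quantify why restricting attention to M x M windows makes the model
linear rather than quadratic in the number of tokens h w.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concatenate, roll, softmax, take
from .nn import LayerNorm, Linear, Mlp, Module, ModuleList, Parameter, trunc_normal_

__all__ = [
    "ModelConfig",
    "ComplexityReport",
    "patch_partition",
    "window_partition",
    "window_reverse",
    "shift_attention_mask",
    "PatchEmbedding",
    "WindowAttention",
    "SwinBlock",
    "PatchMerging",
    "SwinChannel",
    "complexity_estimate",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters of one transformer channel."""

    image_size: int = 224
    patch_size: int = 4
    embed_dim: int = 96            # C
    window_size: int = 7           # M
    depths: tuple[int, ...] = (2, 2, 6, 2)
    num_heads: tuple[int, ...] = (3, 6, 12, 24)
    num_classes: int = 22
    mlp_ratio: float = 4.0
    drop_path_rate: float = 0.0
    rel_pos_bias: bool = True
    qkv_bias: bool = True
    # shared input-normalization statistics: both the raw image and the
    # [0, 1] edge image are standardized as (x - mean) / std before their
    # patch embeddings, keeping the two channels on one numeric scale
    norm_mean: float = 0.5
    norm_std: float = 0.25

    def __post_init__(self):
        n_merges = len(self.depths) - 1
        factor = self.patch_size * (2 ** n_merges)
        if self.image_size % factor != 0:
            raise ValueError(
                f"image size {self.image_size} must be divisible by patch_size * 2^merges = {factor}")
        if len(self.depths) != len(self.num_heads):
            raise ValueError("depths and num_heads must have the same length")
        for s in range(len(self.depths)):
            grid = self.grid_size(s)
            if grid % self.window_size != 0:
                raise ValueError(
                    f"stage {s + 1} token grid {grid} is not divisible by window size {self.window_size}")
        for s, (d, h) in enumerate(zip(self.depths, self.num_heads)):
            if self.stage_dim(s) % h != 0:
                raise ValueError(f"stage {s + 1} dim {self.stage_dim(s)} not divisible by {h} heads")
            if d < 1:
                raise ValueError("every stage needs at least one block")

    def grid_size(self, stage: int) -> int:
        """Token-grid side length at a given stage (0-based)."""
        return self.image_size // self.patch_size // (2 ** stage)

    def stage_dim(self, stage: int) -> int:
        """Channel width at a given stage; doubles at every merge."""
        return self.embed_dim * (2 ** stage)

    @property
    def patch_dim(self) -> int:
        return self.patch_size * self.patch_size * 3

    @property
    def feature_dim(self) -> int:
        """Width of the pooled per-channel feature (8C for four stages)."""
        return self.stage_dim(len(self.depths) - 1)


@dataclass(frozen=True)
class ComplexityReport:
    """Multiply-accumulate counts for global vs window-restricted attention."""

    omega_msa: int
    omega_wmsa: int


def complexity_estimate(h: int, w: int, C: int, M: int) -> ComplexityReport:
    """Closed-form attention cost: global is quadratic in hw, windowed linear."""
    if min(h, w, C, M) <= 0:
        raise ValueError("h, w, C, M must all be positive")
    omega_msa = 4 * h * w * C ** 2 + 2 * (h * w) ** 2 * C
    omega_wmsa = 4 * h * w * C ** 2 + 2 * M ** 2 * h * w * C
    return ComplexityReport(omega_msa=omega_msa, omega_wmsa=omega_wmsa)


# -- token geometry ---------------------------------------------------------


def patch_partition(image: Tensor, patch_size: int) -> Tensor:
    """Split ``(B, H, W, 3)`` into non-overlapping patches.

    Each patch becomes one token whose features are the patch's pixel values
    concatenated row-major (then channel), so a 4x4 RGB patch yields a
    48-dimensional token.  Returns ``(B, H/p, W/p, p*p*3)``.
    """
    image = image if isinstance(image, Tensor) else Tensor(image)
    if image.ndim == 3:
        image = image.reshape(1, *image.shape)
    b, h, w, c = image.shape
    p = patch_size
    if h % p or w % p:
        raise ValueError(f"image {h}x{w} not divisible by patch size {p}")
    x = image.reshape(b, h // p, p, w // p, p, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b, h // p, w // p, p * p * c)


def window_partition(grid: Tensor, window_size: int, shift: int = 0) -> Tensor:
    """Tile ``(B, H, W, C)`` into ``(B * nW, M*M, C)`` windows.

    With ``shift > 0`` the grid is first rolled cyclically by ``(-shift,
    -shift)`` so that shifted windows can be processed with the regular
    tiling; :func:`shift_attention_mask` records which token pairs then
    belong to different pre-shift windows.
    """
    m = window_size
    b, h, w, c = grid.shape
    if h % m or w % m:
        raise ValueError(f"grid {h}x{w} not divisible by window size {m}")
    if shift:
        grid = roll(grid, (-shift, -shift), axis=(1, 2))
    x = grid.reshape(b, h // m, m, w // m, m, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b * (h // m) * (w // m), m * m, c)


def window_reverse(windows: Tensor, window_size: int, h: int, w: int, shift: int = 0) -> Tensor:
    """Invert :func:`window_partition` back to ``(B, H, W, C)``."""
    m = window_size
    nw = (h // m) * (w // m)
    b = windows.shape[0] // nw
    c = windows.shape[-1]
    x = windows.reshape(b, h // m, w // m, m, m, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    grid = x.reshape(b, h, w, c)
    if shift:
        grid = roll(grid, (shift, shift), axis=(1, 2))
    return grid


def _window_provenance(h: int, w: int, window_size: int, shift: int) -> np.ndarray:
    """Label each post-roll grid cell with its pre-shift window id."""
    m, s = window_size, shift
    ids = np.zeros((h, w), dtype=np.int64)
    cnt = 0
    slices = (slice(0, -m), slice(-m, -s), slice(-s, None))
    for hs in slices:
        for ws in slices:
            ids[hs, ws] = cnt
            cnt += 1
    return ids


def shift_attention_mask(h: int, w: int, window_size: int, shift: int) -> np.ndarray:
    """Additive attention mask of shape ``(nW, M*M, M*M)``.

    Entries are 0 where both tokens of a pair originate from the same
    pre-shift window and ``-inf`` where they do not; adding the mask to the
    attention logits before the softmax makes cross-provenance attention mass
    exactly zero.
    """
    m = window_size
    if shift == 0:
        return np.zeros(((h // m) * (w // m), m * m, m * m), dtype=np.float32)
    ids = _window_provenance(h, w, m, shift)
    ids = np.roll(ids, (-shift, -shift), axis=(0, 1))
    ids = ids.reshape(h // m, m, w // m, m).transpose(0, 2, 1, 3).reshape(-1, m * m)
    diff = ids[:, :, None] != ids[:, None, :]
    mask = np.zeros(diff.shape, dtype=np.float32)
    mask[diff] = -np.inf
    return mask


# -- modules ----------------------------------------------------------------


class PatchEmbedding(Module):
    """Patch partition followed by the linear embedding to C dimensions."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.patch_size = config.patch_size
        self.proj = Linear(config.patch_dim, config.embed_dim, rng=rng)
        self.norm = LayerNorm(config.embed_dim)

    def forward(self, image: Tensor) -> Tensor:
        tokens = patch_partition(image, self.patch_size)
        return self.norm(self.proj(tokens))


def relative_position_index(window_size: int) -> np.ndarray:
    """Index into the (2M-1)^2 bias table for every token pair in a window."""
    m = window_size
    coords = np.stack(np.meshgrid(np.arange(m), np.arange(m), indexing="ij"))  # (2, M, M)
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]          # (2, M^2, M^2)
    rel = rel + (m - 1)
    return (rel[0] * (2 * m - 1) + rel[1]).astype(np.int64)


class WindowAttention(Module):
    """Multi-head scaled-dot-product attention inside one window.

    Supports a learned relative-position bias shared across windows and an
    additive provenance mask for the shifted variant.
    """

    def __init__(self, dim: int, num_heads: int, window_size: int,
                 rng: np.random.Generator, rel_pos_bias: bool = True, qkv_bias: bool = True):
        super().__init__()
        if dim % num_heads:
            raise ValueError(f"dim {dim} not divisible by {num_heads} heads")
        self.dim = dim
        self.num_heads = num_heads
        self.window_size = window_size
        self.scale = (dim // num_heads) ** -0.5
        self.qkv = Linear(dim, 3 * dim, bias=qkv_bias, rng=rng)
        self.proj = Linear(dim, dim, rng=rng)
        self.rel_pos_bias = rel_pos_bias
        if rel_pos_bias:
            n = (2 * window_size - 1) ** 2
            self.bias_table = Parameter(trunc_normal_((n, num_heads), 0.02, rng))
            self._rel_index = relative_position_index(window_size).reshape(-1)

    def forward(self, windows: Tensor, mask: np.ndarray | None = None,
                return_attn: bool = False):
        bw, n, c = windows.shape
        h = self.num_heads
        d = c // h
        qkv = self.qkv(windows).reshape(bw, n, 3, h, d).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]                       # (bw, h, n, d)
        attn = (q @ k.swapaxes(-2, -1)) * self.scale           # (bw, h, n, n)
        if self.rel_pos_bias:
            bias = take(self.bias_table, self._rel_index, axis=0)
            bias = bias.reshape(n, n, h).transpose(2, 0, 1)
            attn = attn + bias.reshape(1, h, n, n)
        if mask is not None:
            nw = mask.shape[0]
            attn = attn.reshape(bw // nw, nw, h, n, n) + Tensor(mask.reshape(1, nw, 1, n, n))
            attn = attn.reshape(bw, h, n, n)
        attn = softmax(attn, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(bw, n, c)
        out = self.proj(out)
        if return_attn:
            return out, attn.data
        return out


class SwinBlock(Module):
    """One pre-norm residual block: (S)W-MSA then MLP."""

    def __init__(self, dim: int, grid_size: int, num_heads: int, window_size: int,
                 shift: int, mlp_ratio: float, rng: np.random.Generator,
                 rel_pos_bias: bool = True, qkv_bias: bool = True, drop_path: float = 0.0):
        super().__init__()
        self.grid_size = grid_size
        self.window_size = window_size
        # A window covering the whole grid makes the cyclic shift a pure token
        # permutation; standard practice is to disable the shift there.
        self.shift = 0 if grid_size <= window_size else shift
        self.drop_path = drop_path
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, num_heads, window_size, rng,
                                    rel_pos_bias=rel_pos_bias, qkv_bias=qkv_bias)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), rng)
        if self.shift:
            self._mask = shift_attention_mask(grid_size, grid_size, window_size, self.shift)
        else:
            self._mask = None
        self._drop_rng = np.random.default_rng(int(rng.integers(2 ** 31)))

    def _attend(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        windows = window_partition(x, self.window_size, self.shift)
        windows = self.attn(windows, mask=self._mask)
        return window_reverse(windows, self.window_size, h, w, self.shift)

    def _maybe_drop(self, residual: Tensor) -> Tensor:
        # Stochastic depth on the residual branch (training mode only).
        if self.training and self.drop_path > 0.0:
            if self._drop_rng.random() < self.drop_path:
                return residual * 0.0
        return residual

    def forward(self, x: Tensor) -> Tensor:
        x = x + self._maybe_drop(self._attend(self.norm1(x)))
        x = x + self._maybe_drop(self.mlp(self.norm2(x)))
        return x


class PatchMerging(Module):
    """Concatenate each 2x2 token neighborhood, normalize, reduce 4C -> 2C."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.norm = LayerNorm(4 * dim)
        self.reduction = Linear(4 * dim, 2 * dim, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"grid {h}x{w} must have even sides for merging")
        x0 = x[:, 0::2, 0::2, :]
        x1 = x[:, 1::2, 0::2, :]
        x2 = x[:, 0::2, 1::2, :]
        x3 = x[:, 1::2, 1::2, :]
        merged = concatenate([x0, x1, x2, x3], axis=-1)
        return self.reduction(self.norm(merged))


class SwinChannel(Module):
    """One full channel: embed, four stages, final norm and global pooling."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.patch_embed = PatchEmbedding(config, rng)
        n_blocks = sum(config.depths)
        dp_rates = np.linspace(0.0, config.drop_path_rate, n_blocks)
        stages = []
        downsamples = []
        k = 0
        for s, (depth, heads) in enumerate(zip(config.depths, config.num_heads)):
            dim = config.stage_dim(s)
            grid = config.grid_size(s)
            blocks = []
            for j in range(depth):
                shift = 0 if j % 2 == 0 else config.window_size // 2
                blocks.append(SwinBlock(
                    dim, grid, heads, config.window_size, shift, config.mlp_ratio, rng,
                    rel_pos_bias=config.rel_pos_bias, qkv_bias=config.qkv_bias,
                    drop_path=float(dp_rates[k])))
                k += 1
            stages.append(ModuleList(blocks))
            if s < len(config.depths) - 1:
                downsamples.append(PatchMerging(dim, rng))
        self.stages = ModuleList(stages)
        self.downsamples = ModuleList(downsamples)
        self.norm = LayerNorm(config.feature_dim)

    def stage_grids(self, x: Tensor) -> list[Tensor]:
        """Run the hierarchy, returning every stage's output token grid."""
        x = self.patch_embed(x)
        outputs = []
        for s, stage in enumerate(self.stages):
            for block in stage:
                x = block(x)
            outputs.append(x)
            if s < len(self.downsamples):
                x = self.downsamples[s](x)
        return outputs

    def forward(self, image: Tensor) -> Tensor:
        """Pooled feature vector of shape ``(B, 8C)``."""
        last = self.stage_grids(image)[-1]
        last = self.norm(last)
        return last.mean(axis=(1, 2))
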