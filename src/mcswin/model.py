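"""Multi-channel shifted-window encoder–decoder segmentation network.

The network maps a 48×48 multi-channel tile to per-pixel class logits:

    depthwise patch embed → [swin stage, patch merge] × 2 → bottleneck
    → [patch expand, skip fusion, swin stage] × 2 → 4× pixel expand
    → per-pixel linear head

Each biomarker channel is embedded by its own bank of 4×4 kernels
(``filters_per_channel`` each, no cross-channel mixing), honouring the
design goal of treating every biomarker separately at the input.  Swin
stages alternate plain and shifted window attention; the bottleneck grid
fits inside a single window, so it holds one (unshifted) block.  Exactly
two skip connections concatenate encoder features into the decoder.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import nn
from .config import ConfigurationError, ModelConfig
from .nn.tensor import Tensor

__all__ = [
    "ShapeError",
    "window_partition",
    "window_reverse",
    "cyclic_shift",
    "inverse_cyclic_shift",
    "multi_head_self_attention",
    "shifted_window_attention_mask",
    "relative_position_index",
    "SwinBlock",
    "PatchEmbed",
    "PatchMerge",
    "PatchExpand",
    "SegmenterModel",
    "build_model",
    "count_trainable_parameters",
    "forward_segment",
    "save_checkpoint",
    "load_checkpoint",
]


class ShapeError(ValueError):
    """Raised when an input's shape violates an operation's contract."""


# ---------------------------------------------------------------------------
# token-grid primitives (work on numpy arrays and on autodiff tensors)
# ---------------------------------------------------------------------------


def _hw(x) -> tuple[int, int, bool]:
    """Return (H, W, batched) for a (H, W, D) or (B, H, W, D) grid."""
    if x.ndim == 3:
        return x.shape[0], x.shape[1], False
    if x.ndim == 4:
        return x.shape[1], x.shape[2], True
    raise ShapeError(f"expected a (H, W, D) or (B, H, W, D) token grid, got shape {x.shape}")


def window_partition(x, window: int):
    """Split a token grid into non-overlapping ``window``×``window`` blocks.

    Returns shape (num_windows, w, w, D); for batched input the leading
    axis is B·num_windows with windows in row-major order per image.
    """
    H, W, batched = _hw(x)
    if H % window or W % window:
        raise ShapeError(f"grid {H}×{W} not divisible by window {window}")
    D = x.shape[-1]
    if batched:
        B = x.shape[0]
        x = x.reshape(B, H // window, window, W // window, window, D)
        x = x.transpose(0, 1, 3, 2, 4, 5)
        return x.reshape(B * (H // window) * (W // window), window, window, D)
    x = x.reshape(H // window, window, W // window, window, D)
    x = x.transpose(0, 2, 1, 3, 4)
    return x.reshape((H // window) * (W // window), window, window, D)


def window_reverse(windows, window: int, H: int, W: int, batch: int | None = None):
    """Inverse of :func:`window_partition`."""
    D = windows.shape[-1]
    nh, nw = H // window, W // window
    if batch is None:
        x = windows.reshape(nh, nw, window, window, D)
        x = x.transpose(0, 2, 1, 3, 4)
        return x.reshape(H, W, D)
    x = windows.reshape(batch, nh, nw, window, window, D)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(batch, H, W, D)


def _roll(x, shifts: tuple[int, int], axes: tuple[int, int]):
    if isinstance(x, Tensor):
        return x.roll(shifts, axes)
    return np.roll(x, shifts, axis=axes)


def cyclic_shift(x, shift: int):
    """Toroidal roll of the grid toward the upper-left by ``shift`` tokens."""
    if shift == 0:
        return x
    _, _, batched = _hw(x)
    axes = (1, 2) if batched else (0, 1)
    return _roll(x, (-shift, -shift), axes)


def inverse_cyclic_shift(x, shift: int):
    if shift == 0:
        return x
    _, _, batched = _hw(x)
    axes = (1, 2) if batched else (0, 1)
    return _roll(x, (shift, shift), axes)


def relative_position_index(window: int) -> np.ndarray:
    """Standard (w², w²) lookup into a (2w−1)² relative-position table."""
    coords = np.stack(np.meshgrid(np.arange(window), np.arange(window), indexing="ij"))
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]
    rel = rel.transpose(1, 2, 0) + (window - 1)
    return (rel[:, :, 0] * (2 * window - 1) + rel[:, :, 1]).astype(np.int64)


def shifted_window_attention_mask(
    H: int, W: int, window: int, shift: int, neg: float = -1e9
) -> np.ndarray | None:
    """Additive mask excluding token pairs split by the wrap boundary.

    After the cyclic shift, tokens from opposite image borders share a
    window; their pairwise scores receive a large negative offset before
    the softmax.  Shape (num_windows, w², w²); ``None`` when shift is 0.
    """
    if shift == 0:
        return None
    img = np.zeros((H, W), dtype=np.int64)
    cnt = 0
    for hs in (slice(0, H - window), slice(H - window, H - shift), slice(H - shift, H)):
        for ws in (slice(0, W - window), slice(W - window, W - shift), slice(W - shift, W)):
            img[hs, ws] = cnt
            cnt += 1
    win = window_partition(img[:, :, None], window).reshape(-1, window * window)
    diff = win[:, None, :] - win[:, :, None]
    return np.where(diff != 0, neg, 0.0).astype(np.float32)


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------


class WindowAttention(nn.Module):
    """Multi-head self-attention over the tokens of one window.

    Query/key/value projections are fused into one linear map; scores are
    scaled by the inverse square root of the per-head depth (the
    ``full_depth`` option divides by the full latent depth instead), an
    optional learned relative-position bias is added per head, and head
    outputs are concatenated and output-projected.
    """

    def __init__(
        self,
        dim: int,
        heads: int,
        window: int,
        *,
        qkv_bias: bool = True,
        use_relative_position_bias: bool = True,
        attention_scale: str = "per_head_sqrt",
        rng: np.random.Generator,
    ):
        if dim % heads != 0:
            raise ConfigurationError(f"heads ({heads}) must divide depth ({dim})")
        self.dim = dim
        self.heads = heads
        self.window = window
        if attention_scale == "per_head_sqrt":
            self.scale = (dim // heads) ** -0.5
        else:
            self.scale = 1.0 / dim
        self.qkv = nn.Linear(dim, 3 * dim, bias=qkv_bias, rng=rng)
        self.proj = nn.Linear(dim, dim, rng=rng)
        if use_relative_position_bias:
            self.relative_position_bias_table = nn.Parameter(
                nn.trunc_normal_(rng, ((2 * window - 1) ** 2, heads))
            )
            self._rel_index = relative_position_index(window).reshape(-1)
        else:
            self.relative_position_bias_table = None
            self._rel_index = None

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        B_, N, D = x.shape
        h = self.heads
        d = D // h
        qkv = self.qkv(x).reshape(B_, N, 3, h, d).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # each (B_, h, N, d)
        scores = nn.matmul(q * self.scale, k.transpose(0, 1, 3, 2))  # (B_, h, N, N)
        if self.relative_position_bias_table is not None:
            bias = nn.gather(self.relative_position_bias_table, self._rel_index)
            bias = bias.reshape(N, N, h).transpose(2, 0, 1)  # (h, N, N)
            scores = scores + bias
        if mask is not None:
            nW = mask.shape[0]
            scores = scores.reshape(B_ // nW, nW, h, N, N) + mask[:, None, :, :]
            scores = scores.reshape(B_, h, N, N)
        attn = nn.softmax(scores, axis=-1)
        self.last_attention_ = attn.data  # (B_, h, N, N); diagnostic only
        out = nn.matmul(attn, v)  # (B_, h, N, d)
        out = out.transpose(0, 2, 1, 3).reshape(B_, N, D)
        return self.proj(out)


def multi_head_self_attention(
    tokens: np.ndarray,
    attn: WindowAttention,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Functional wrapper: (n, C) or (B, n, C) token sequence → same shape."""
    arr = np.asarray(tokens, dtype=np.float32)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None]
    out = attn(Tensor(arr), mask=mask).data
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------


class Mlp(nn.Module):
    def __init__(self, dim: int, hidden: int, *, rng: np.random.Generator):
        self.fc1 = nn.Linear(dim, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, dim, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(nn.gelu(self.fc1(x)))


class SwinBlock(nn.Module):
    """One transformer block: (shifted-)window attention + MLP, pre-norm.

    ``shift`` is forced to 0 when the grid fits inside one window (the
    shifted partner would attend to the same token set).
    """

    def __init__(
        self,
        dim: int,
        heads: int,
        grid: tuple[int, int],
        window: int,
        shift: int,
        mlp_ratio: float,
        *,
        qkv_bias: bool,
        use_relative_position_bias: bool,
        attention_scale: str,
        rng: np.random.Generator,
    ):
        H, W = grid
        if min(H, W) <= window:
            window = min(H, W)
            shift = 0
        if shift >= window:
            raise ConfigurationError(f"shift ({shift}) must be smaller than window ({window})")
        self.grid = (H, W)
        self.window = window
        self.shift = shift
        self.norm1 = nn.LayerNorm(dim)
        self.attn = WindowAttention(
            dim,
            heads,
            window,
            qkv_bias=qkv_bias,
            use_relative_position_bias=use_relative_position_bias,
            attention_scale=attention_scale,
            rng=rng,
        )
        self.norm2 = nn.LayerNorm(dim)
        self.mlp = Mlp(dim, int(mlp_ratio * dim), rng=rng)
        self._mask = shifted_window_attention_mask(H, W, window, shift)

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, H·W, D) → same shape."""
        B, L, D = x.shape
        H, W = self.grid
        shortcut = x
        y = self.norm1(x).reshape(B, H, W, D)
        y = cyclic_shift(y, self.shift)
        wins = window_partition(y, self.window)
        wins = wins.reshape(-1, self.window * self.window, D)
        wins = self.attn(wins, mask=self._mask)
        wins = wins.reshape(-1, self.window, self.window, D)
        y = window_reverse(wins, self.window, H, W, batch=B)
        y = inverse_cyclic_shift(y, self.shift)
        x = shortcut + y.reshape(B, L, D)
        return x + self.mlp(self.norm2(x))


class PatchEmbed(nn.Module):
    """Depthwise separable 4×4/stride-4 embedding.

    Each input channel is convolved with its own ``filters_per_channel``
    kernels (no cross-channel mixing); outputs are concatenated
    channel-wise to latent depth C = in_channels × filters_per_channel.
    """

    def __init__(self, cfg: ModelConfig, *, rng: np.random.Generator):
        P = cfg.patch_size
        self.patch = P
        self.in_channels = cfg.in_channels
        self.fpc = cfg.filters_per_channel
        self.weight = nn.Parameter(nn.trunc_normal_(rng, (cfg.in_channels, P * P, cfg.filters_per_channel)))
        self.bias = nn.Parameter(np.zeros(cfg.embed_dim, dtype=np.float32)) if cfg.embed_bias else None
        self.norm = nn.LayerNorm(cfg.embed_dim) if cfg.embed_norm else None

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, C_in, H, W) → token grid (B, H/P, W/P, C)."""
        B, Cin, H, W = x.shape
        P = self.patch
        if Cin != self.in_channels:
            raise ShapeError(f"expected {self.in_channels} channels, got {Cin}")
        if H % P or W % P:
            raise ShapeError(f"image {H}×{W} not divisible by patch size {P}")
        hp, wp = H // P, W // P
        y = x.reshape(B, Cin, hp, P, wp, P)
        y = y.transpose(1, 0, 2, 4, 3, 5).reshape(Cin, B * hp * wp, P * P)
        y = nn.matmul(y, self.weight)  # (Cin, B·hp·wp, fpc)
        y = y.transpose(1, 0, 2).reshape(B, hp, wp, Cin * self.fpc)
        if self.bias is not None:
            y = y + self.bias
        if self.norm is not None:
            y = self.norm(y)
        return y


class PatchMerge(nn.Module):
    """2×2 token neighbourhoods concatenated to 4d, normalised, reduced to 2d."""

    def __init__(self, dim: int, *, rng: np.random.Generator):
        self.dim = dim
        self.norm = nn.LayerNorm(4 * dim)
        self.reduction = nn.Linear(4 * dim, 2 * dim, bias=False, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, H, W, d) → (B, H/2, W/2, 2d)."""
        B, H, W, D = x.shape
        if H % 2 or W % 2:
            raise ShapeError(f"grid {H}×{W} has an odd side; cannot merge 2×2 groups")
        x0 = x[:, 0::2, 0::2, :]
        x1 = x[:, 1::2, 0::2, :]
        x2 = x[:, 0::2, 1::2, :]
        x3 = x[:, 1::2, 1::2, :]
        y = nn.concat([x0, x1, x2, x3], axis=-1)
        return self.reduction(self.norm(y))


class PatchExpand(nn.Module):
    """Linear projection then 2×2 rearrangement: (H, W, d) → (2H, 2W, d/2)."""

    def __init__(self, dim: int, *, rng: np.random.Generator):
        if dim % 2:
            raise ConfigurationError(f"patch expansion needs an even depth, got {dim}")
        self.dim = dim
        self.expand = nn.Linear(dim, 2 * dim, bias=False, rng=rng)
        self.norm = nn.LayerNorm(dim // 2)

    def __call__(self, x: Tensor) -> Tensor:
        B, H, W, D = x.shape
        y = self.expand(x)  # (B, H, W, 2d)
        y = y.reshape(B, H, W, 2, 2, D // 2)
        y = y.transpose(0, 1, 3, 2, 4, 5).reshape(B, 2 * H, 2 * W, D // 2)
        return self.norm(y)


class FinalExpand(nn.Module):
    """4× spatial expansion back to pixel resolution, keeping depth."""

    def __init__(self, dim: int, scale: int, *, rng: np.random.Generator):
        self.scale = scale
        self.expand = nn.Linear(dim, scale * scale * dim, bias=False, rng=rng)
        self.norm = nn.LayerNorm(dim)

    def __call__(self, x: Tensor) -> Tensor:
        B, H, W, D = x.shape
        s = self.scale
        y = self.expand(x).reshape(B, H, W, s, s, D)
        y = y.transpose(0, 1, 3, 2, 4, 5).reshape(B, s * H, s * W, D)
        return self.norm(y)


# ---------------------------------------------------------------------------
# the full network
# ---------------------------------------------------------------------------


def _make_stage(
    cfg: ModelConfig, scale: int, depth: int, rng: np.random.Generator
) -> list[SwinBlock]:
    dim = cfg.scale_dim(scale)
    side = cfg.scale_side(scale)
    heads = cfg.heads_per_stage[scale]
    blocks = []
    for i in range(depth):
        shift = 0 if i % 2 == 0 else cfg.effective_shift
        blocks.append(
            SwinBlock(
                dim,
                heads,
                (side, side),
                cfg.window_size,
                shift,
                cfg.mlp_ratio,
                qkv_bias=cfg.qkv_bias,
                use_relative_position_bias=cfg.use_relative_position_bias,
                attention_scale=cfg.attention_scale,
                rng=rng,
            )
        )
    return blocks


class SegmenterModel(nn.Module):
    """The assembled encoder–decoder; built via :func:`build_model`."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        config.validate()
        rng = np.random.default_rng(seed)
        self.config = config
        n_enc = config.num_scales - 1  # scales with a merge after them
        self.patch_embed = PatchEmbed(config, rng=rng)
        self.encoder_stages = [
            _make_stage(config, s, config.stage_depths[s], rng) for s in range(n_enc)
        ]
        self.merges = [PatchMerge(config.scale_dim(s), rng=rng) for s in range(n_enc)]
        self.bottleneck = _make_stage(config, n_enc, config.stage_depths[n_enc], rng)
        self.encoder_norm = nn.LayerNorm(config.scale_dim(n_enc))
        dec_depths = config.resolved_decoder_depths()
        self.expands = []
        self.fusions = []
        self.decoder_stages = []
        for j, scale in enumerate(range(n_enc - 1, -1, -1)):
            self.expands.append(PatchExpand(config.scale_dim(scale + 1), rng=rng))
            self.fusions.append(
                nn.Linear(2 * config.scale_dim(scale), config.scale_dim(scale), rng=rng)
            )
            self.decoder_stages.append(_make_stage(config, scale, dec_depths[j], rng))
        self.decoder_norm = nn.LayerNorm(config.embed_dim)
        self.final_expand = FinalExpand(config.embed_dim, config.patch_size, rng=rng)
        self.head = nn.Linear(config.embed_dim, config.num_classes, bias=False, rng=rng)

    # -- forward ---------------------------------------------------------
    def __call__(self, x, *, skip_ablation: Sequence[int] = ()) -> Tensor:
        """x: (B, C_in, S, S) array or Tensor → logits (B, num_classes, S, S).

        ``skip_ablation`` zeroes the listed skip connections (0 = the
        deepest); used only for diagnostics.
        """
        if not isinstance(x, Tensor):
            x = Tensor(np.ascontiguousarray(x, dtype=np.float32))
        cfg = self.config
        if x.ndim != 4 or x.shape[2] != cfg.input_size or x.shape[3] != cfg.input_size:
            raise ShapeError(
                f"expected (B, {cfg.in_channels}, {cfg.input_size}, {cfg.input_size}), got {x.shape}"
            )
        B = x.shape[0]
        g = cfg.grid_size
        y = self.patch_embed(x)  # (B, g, g, C)
        skips = []
        for s, (stage, merge) in enumerate(zip(self.encoder_stages, self.merges)):
            side = cfg.scale_side(s)
            dim = cfg.scale_dim(s)
            t = y.reshape(B, side * side, dim)
            skips.append(t)  # stage input feeds the same-scale decoder stage
            for blk in stage:
                t = blk(t)
            y = merge(t.reshape(B, side, side, dim))
        n_enc = cfg.num_scales - 1
        side = cfg.scale_side(n_enc)
        dim = cfg.scale_dim(n_enc)
        t = y.reshape(B, side * side, dim)
        for blk in self.bottleneck:
            t = blk(t)
        t = self.encoder_norm(t)
        y = t.reshape(B, side, side, dim)
        for j, scale in enumerate(range(n_enc - 1, -1, -1)):
            y = self.expands[j](y)  # (B, side, side, dim) at this scale
            side = cfg.scale_side(scale)
            dim = cfg.scale_dim(scale)
            t = y.reshape(B, side * side, dim)
            skip = skips[scale]
            if scale in skip_ablation:
                skip = skip * 0.0
            t = self.fusions[j](nn.concat([t, skip], axis=-1))
            for blk in self.decoder_stages[j]:
                t = blk(t)
            y = t.reshape(B, side, side, dim)
        t = self.decoder_norm(y.reshape(B, g * g, cfg.embed_dim))
        y = self.final_expand(t.reshape(B, g, g, cfg.embed_dim))
        logits = self.head(y)  # (B, S, S, num_classes)
        return logits.transpose(0, 3, 1, 2)

    # -- prediction helpers ----------------------------------------------
    def predict_logits(self, tiles: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Forward a stack of tiles (N, C, S, S) without building a graph."""
        outs = []
        for i in range(0, tiles.shape[0], batch_size):
            outs.append(self(tiles[i : i + batch_size].astype(np.float32)).data)
        return np.concatenate(outs, axis=0)

    def predict_labels(self, tiles: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return np.argmax(self.predict_logits(tiles, batch_size), axis=1)


def build_model(config: ModelConfig, seed: int = 0) -> SegmenterModel:
    """Build the network with parameters drawn from ``seed``."""
    return SegmenterModel(config, seed=seed)


def count_trainable_parameters(model: SegmenterModel) -> int:
    """Total size of all trainable parameter arrays (a pure function of config)."""
    return model.num_parameters()


def forward_segment(model: SegmenterModel, tile: np.ndarray) -> np.ndarray:
    """Per-pixel class logits (num_classes, S, S) for one (C_in, S, S) tile."""
    tile = np.asarray(tile, dtype=np.float32)
    if tile.ndim != 3:
        raise ShapeError(f"expected a (C, S, S) tile, got shape {tile.shape}")
    return model(tile[None]).data[0]


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: SegmenterModel, path) -> None:
    """Named-parameter archive with the config embedded as YAML + hash."""
    cfg_yaml = model.config.to_yaml()
    state = model.state_dict()
    np.savez(
        path,
        __config_yaml__=np.frombuffer(cfg_yaml.encode(), dtype=np.uint8),
        __config_sha256__=np.frombuffer(model.config.config_hash().encode(), dtype=np.uint8),
        **state,
    )


def load_checkpoint(path) -> SegmenterModel:
    with np.load(path) as z:
        cfg_yaml = bytes(z["__config_yaml__"]).decode()
        stored_hash = bytes(z["__config_sha256__"]).decode()
        cfg = ModelConfig.from_yaml(cfg_yaml)
        if cfg.config_hash() != stored_hash:
            raise ValueError("checkpoint refused: config hash mismatch")
        state = {k: z[k] for k in z.files if not k.startswith("__")}
    model = build_model(cfg, seed=0)
    model.load_state_dict(state)
    return model
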