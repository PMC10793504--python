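"""Architecture primitives: embedding, windowing, attention, merge/expand,
model assembly and the parameter-count contract."""

import numpy as np
import pytest

from mcswin.config import ConfigurationError, ModelConfig, reference_config
from mcswin.model import (
    PatchEmbed,
    PatchExpand,
    PatchMerge,
    SwinBlock,
    ShapeError,
    WindowAttention,
    build_model,
    count_trainable_parameters,
    cyclic_shift,
    forward_segment,
    inverse_cyclic_shift,
    load_checkpoint,
    save_checkpoint,
    window_partition,
    window_reverse,
)
from mcswin.nn.tensor import Tensor

from conftest import tiny_config


# ---------------------------------------------------------------------------
# patch embedding
# ---------------------------------------------------------------------------


def _embed(cfg):
    return PatchEmbed(cfg, rng=np.random.default_rng(3))


def test_patch_embed_zero_tile_gives_bias_everywhere():
    cfg = tiny_config(embed_norm=False)
    emb = _embed(cfg)
    emb.bias.data = np.arange(cfg.embed_dim, dtype=np.float32)  # distinguishable bias
    out = emb(Tensor(np.zeros((1, cfg.in_channels, 48, 48), dtype=np.float32))).data
    assert out.shape == (1, 12, 12, cfg.embed_dim)
    np.testing.assert_allclose(
        out, np.broadcast_to(emb.bias.data, out.shape), atol=0
    )


def test_patch_embed_impulse_is_local_to_one_token():
    cfg = tiny_config(embed_norm=False)
    emb = _embed(cfg)
    zero = np.zeros((1, cfg.in_channels, 48, 48), dtype=np.float32)
    impulse = zero.copy()
    impulse[0, 0, 0, 0] = 1.0
    base = emb(Tensor(zero)).data
    hit = emb(Tensor(impulse)).data
    diff = np.abs(hit - base).sum(axis=-1)[0]
    assert diff[0, 0] > 0
    assert np.count_nonzero(diff) == 1  # stride-4 non-overlapping windows


def test_patch_embed_channel_separability():
    # perturbing channel 1 only changes that channel's filter block
    cfg = tiny_config(embed_norm=False, embed_bias=False)
    emb = _embed(cfg)
    rng = np.random.default_rng(0)
    x = rng.standard_normal((1, cfg.in_channels, 48, 48)).astype(np.float32)
    y0 = emb(Tensor(x)).data
    x2 = x.copy()
    x2[0, 1] += 1.0
    y1 = emb(Tensor(x2)).data
    fpc = cfg.filters_per_channel
    changed = np.abs(y1 - y0).sum(axis=(0, 1, 2))
    assert (changed[:fpc] == 0).all()
    assert (changed[fpc : 2 * fpc] > 0).all()


def test_patch_embed_rejects_wrong_channel_count():
    cfg = tiny_config()
    emb = _embed(cfg)
    with pytest.raises(ShapeError):
        emb(Tensor(np.zeros((1, cfg.in_channels + 1, 48, 48), dtype=np.float32)))


def test_reference_embedding_depth_is_96():
    cfg = reference_config()
    assert cfg.embed_dim == 96
    assert cfg.grid_size == 12


# ---------------------------------------------------------------------------
# windowing and shifting
# ---------------------------------------------------------------------------


def test_window_partition_counts_and_identity(rng):
    g = rng.standard_normal((12, 12, 5))
    wins = window_partition(g, 6)
    assert wins.shape == (4, 6, 6, 5)
    np.testing.assert_array_equal(window_reverse(wins, 6, 12, 12), g)

    g1 = rng.standard_normal((6, 6, 3))
    wins1 = window_partition(g1, 6)
    assert wins1.shape == (1, 6, 6, 3)
    np.testing.assert_array_equal(wins1[0], g1)


def test_window_partition_covers_each_token_once(rng):
    g = np.arange(12 * 12).reshape(12, 12, 1)
    wins = window_partition(g, 6)
    assert sorted(wins.ravel().tolist()) == list(range(144))


def test_window_partition_rejects_indivisible_grid(rng):
    with pytest.raises(ShapeError):
        window_partition(rng.standard_normal((10, 12, 3)), 6)


def test_cyclic_shift_round_trip_and_relocation(rng):
    g = rng.standard_normal((12, 12, 2))
    assert cyclic_shift(g, 0) is g
    np.testing.assert_array_equal(inverse_cyclic_shift(cyclic_shift(g, 3), 3), g)
    shifted = cyclic_shift(g, 3)
    np.testing.assert_array_equal(shifted[12 - 3, 12 - 3], g[0, 0])


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------


def dense_attention_oracle(x, attn: WindowAttention):
    """Explicit-loop evaluation of scaled dot-product multi-head attention."""
    n, C = x.shape
    h = attn.heads
    d = C // h
    Wqkv = attn.qkv.weight.data
    bqkv = attn.qkv.bias.data if attn.qkv.bias is not None else np.zeros(3 * C)
    qkv = x @ Wqkv + bqkv
    q, k, v = qkv[:, :C], qkv[:, C : 2 * C], qkv[:, 2 * C :]
    heads_out = []
    for i in range(h):
        qi = q[:, i * d : (i + 1) * d]
        ki = k[:, i * d : (i + 1) * d]
        vi = v[:, i * d : (i + 1) * d]
        scores = np.zeros((n, n))
        for a in range(n):
            for b in range(n):
                scores[a, b] = attn.scale * float(qi[a] @ ki[b])
        if attn.relative_position_bias_table is not None:
            bias = attn.relative_position_bias_table.data[attn._rel_index].reshape(n, n, h)
            scores = scores + bias[:, :, i]
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        p = e / e.sum(axis=1, keepdims=True)
        heads_out.append(p @ vi)
    out = np.concatenate(heads_out, axis=1)
    return out @ attn.proj.weight.data + attn.proj.bias.data


@pytest.mark.parametrize("use_bias", [True, False])
def test_windowed_attention_matches_dense_loop_oracle(rng, use_bias):
    n, C, h = 16, 8, 2
    attn = WindowAttention(
        C, h, 4, use_relative_position_bias=use_bias, rng=np.random.default_rng(5)
    )
    x = rng.standard_normal((n, C)).astype(np.float32)
    got = attn(Tensor(x[None])).data[0]
    want = dense_attention_oracle(x.astype(np.float64), attn)
    np.testing.assert_allclose(got, want, atol=1e-5)


def test_attention_rows_sum_to_one(rng):
    attn = WindowAttention(8, 2, 3, rng=np.random.default_rng(5))
    x = rng.standard_normal((2, 9, 8)).astype(np.float32)
    attn(Tensor(x))
    rows = attn.last_attention_.sum(axis=-1)
    np.testing.assert_allclose(rows, 1.0, atol=1e-6)


def test_single_token_attention_is_projected_value(rng):
    attn = WindowAttention(6, 3, 1, use_relative_position_bias=False, rng=np.random.default_rng(2))
    x = rng.standard_normal((1, 1, 6)).astype(np.float32)
    out = attn(Tensor(x)).data[0, 0]
    C = 6
    qkv = x[0, 0] @ attn.qkv.weight.data + attn.qkv.bias.data
    v = qkv[2 * C :]
    want = v @ attn.proj.weight.data + attn.proj.bias.data
    np.testing.assert_allclose(out, want, atol=1e-5)


def test_attention_is_permutation_equivariant_without_position_bias(rng):
    attn = WindowAttention(8, 2, 4, use_relative_position_bias=False, rng=np.random.default_rng(7))
    x = rng.standard_normal((1, 10, 8)).astype(np.float32)
    perm = np.random.default_rng(3).permutation(10)
    out = attn(Tensor(x)).data[0]
    out_perm = attn(Tensor(x[:, perm])).data[0]
    np.testing.assert_allclose(out_perm, out[perm], atol=1e-5)


def test_attention_rejects_indivisible_heads():
    with pytest.raises(ConfigurationError):
        WindowAttention(8, 3, 4, rng=np.random.default_rng(0))


# ---------------------------------------------------------------------------
# transformer blocks
# ---------------------------------------------------------------------------


def _block(shift=0, grid=(12, 12), dim=8, heads=2, window=6, seed=0):
    return SwinBlock(
        dim,
        heads,
        grid,
        window,
        shift,
        mlp_ratio=2.0,
        qkv_bias=True,
        use_relative_position_bias=True,
        attention_scale="per_head_sqrt",
        rng=np.random.default_rng(seed),
    )


@pytest.mark.parametrize("shift", [0, 3])
def test_block_preserves_shape(rng, shift):
    blk = _block(shift=shift)
    x = rng.standard_normal((2, 144, 8)).astype(np.float32)
    assert blk(Tensor(x)).shape == (2, 144, 8)


def test_block_with_zeroed_branches_is_identity(rng):
    blk = _block()
    blk.attn.proj.weight.data[:] = 0
    blk.attn.proj.bias.data[:] = 0
    blk.mlp.fc2.weight.data[:] = 0
    blk.mlp.fc2.bias.data[:] = 0
    x = rng.standard_normal((1, 144, 8)).astype(np.float32)
    np.testing.assert_array_equal(blk(Tensor(x)).data, x)


def test_block_on_single_window_equals_dense_attention(rng):
    # grid side == window: the attention branch is one dense window
    blk = _block(grid=(6, 6), window=6)
    x = rng.standard_normal((1, 36, 8)).astype(np.float32)
    normed = blk.norm1(Tensor(x)).data[0]
    want_branch = dense_attention_oracle(normed.astype(np.float64), blk.attn)
    got = blk(Tensor(x)).data[0]
    after_attn = x[0] + want_branch
    mlp_in = blk.norm2(Tensor(after_attn[None].astype(np.float32))).data
    want = after_attn + blk.mlp(Tensor(mlp_in)).data[0]
    np.testing.assert_allclose(got, want, atol=1e-4)


def test_shifted_block_forces_no_shift_on_small_grid():
    blk = _block(shift=3, grid=(6, 6), window=6)
    assert blk.shift == 0  # one window covers the grid; shifting is a no-op


# ---------------------------------------------------------------------------
# merge / expand
# ---------------------------------------------------------------------------


def test_patch_merge_shapes_and_constant_invariance(rng):
    merge = PatchMerge(8, rng=np.random.default_rng(1))
    x = rng.standard_normal((1, 4, 4, 8)).astype(np.float32)
    out = merge(Tensor(x))
    assert out.shape == (1, 2, 2, 16)
    const = np.ones((1, 4, 4, 8), dtype=np.float32)
    out_c = merge(Tensor(const)).data
    np.testing.assert_allclose(
        out_c, np.broadcast_to(out_c[0, 0, 0], out_c.shape), atol=1e-5
    )


def test_patch_merge_selection_projection_by_hand(rng):
    d = 3
    merge = PatchMerge(d, rng=np.random.default_rng(1))
    # make the norm transparent and the projection select the first 2d coords
    merge.norm.weight.data[:] = 1
    merge.norm.bias.data[:] = 0
    w = np.zeros((4 * d, 2 * d), dtype=np.float32)
    w[: 2 * d, : 2 * d] = np.eye(2 * d)
    merge.reduction.weight.data = w
    x = rng.standard_normal((1, 2, 2, d)).astype(np.float32)
    out = merge(Tensor(x)).data[0, 0, 0]
    concat = np.concatenate([x[0, 0, 0], x[0, 1, 0], x[0, 0, 1], x[0, 1, 1]])
    mu, sd = concat.mean(), concat.std()
    want = ((concat - mu) / np.sqrt(sd**2 + 1e-5))[: 2 * d]
    np.testing.assert_allclose(out, want, atol=1e-5)


def test_patch_merge_rejects_odd_grid(rng):
    merge = PatchMerge(4, rng=np.random.default_rng(0))
    with pytest.raises(ShapeError):
        merge(Tensor(rng.standard_normal((1, 3, 4, 4)).astype(np.float32)))


def test_expand_merge_shape_round_trip(rng):
    merge = PatchMerge(8, rng=np.random.default_rng(0))
    expand = PatchExpand(16, rng=np.random.default_rng(1))
    x = rng.standard_normal((1, 6, 6, 8)).astype(np.float32)
    out = expand(merge(Tensor(x)))
    assert out.shape == x.shape


def test_patch_expand_zero_input_gives_norm_bias(rng):
    expand = PatchExpand(8, rng=np.random.default_rng(1))
    expand.norm.bias.data[:] = 0.5
    out = expand(Tensor(np.zeros((1, 2, 2, 8), dtype=np.float32))).data
    assert out.shape == (1, 4, 4, 4)
    np.testing.assert_allclose(out, 0.5, atol=1e-6)


# ---------------------------------------------------------------------------
# assembled model
# ---------------------------------------------------------------------------


def test_reference_model_has_exact_parameter_count():
    model = build_model(reference_config(), seed=0)
    assert count_trainable_parameters(model) == 4_990_032


def test_parameter_count_is_seed_invariant():
    cfg = tiny_config()
    n0 = count_trainable_parameters(build_model(cfg, seed=0))
    n1 = count_trainable_parameters(build_model(cfg, seed=99))
    assert n0 == n1


def test_binary_head_swap_changes_only_head_parameters():
    full = build_model(reference_config(num_classes=11), seed=0)
    binary = build_model(reference_config(num_classes=2), seed=0)
    d_full = dict(full.named_parameters())
    d_bin = dict(binary.named_parameters())
    assert set(d_full) == set(d_bin)
    for k in d_full:
        if k.startswith("head."):
            continue
        assert d_full[k].data.shape == d_bin[k].data.shape
    # head is a bias-free per-pixel linear map: the count difference is C·ΔK
    diff = count_trainable_parameters(full) - count_trainable_parameters(binary)
    assert diff == 96 * (11 - 2)


def test_parameter_count_monotone_in_width():
    cfg1 = tiny_config()
    cfg2 = tiny_config(filters_per_channel=4, heads_per_stage=(1, 2, 4))
    assert count_trainable_parameters(build_model(cfg2, 0)) > count_trainable_parameters(
        build_model(cfg1, 0)
    )


def test_toy_parameter_count_matches_hand_formula():
    # single-scale model: embed -> one block -> norms -> expand -> head
    cfg = ModelConfig(
        in_channels=1,
        filters_per_channel=4,
        stage_depths=(1,),
        heads_per_stage=(1,),
        mlp_ratio=1.0,
        num_classes=2,
        window_size=6,
        use_relative_position_bias=False,
    )
    C = 4
    embed = 1 * 4 * 16 + C + 2 * C
    block = 2 * C + (3 * C * C + 3 * C) + (C * C + C) + 2 * C + (C * C + C) + (C * C + C)
    norms = 2 * C + 2 * C  # encoder-end and decoder-end layer norms
    final = 16 * C * C + 2 * C
    head = C * 2
    model = build_model(cfg, seed=0)
    assert count_trainable_parameters(model) == embed + block + norms + final + head


def test_invalid_configs_report_violated_invariant():
    with pytest.raises(ConfigurationError, match="divisible"):
        ModelConfig(input_size=50)
    with pytest.raises(ConfigurationError, match="shift"):
        ModelConfig(shift_size=6)
    with pytest.raises(ConfigurationError, match="heads"):
        ModelConfig(heads_per_stage=(5, 6, 12))


def test_forward_is_deterministic_and_finite(tiny_model, rng):
    x = rng.standard_normal((1, 2, 48, 48)).astype(np.float32)
    a = tiny_model(x).data
    b = tiny_model(x).data
    assert a.shape == (1, 3, 48, 48)
    assert np.isfinite(a).all()
    np.testing.assert_array_equal(a, b)  # bitwise repeatable


def test_forward_zero_tile_finite(tiny_model):
    logits = forward_segment(tiny_model, np.zeros((2, 48, 48), dtype=np.float32))
    assert logits.shape == (3, 48, 48)
    assert np.isfinite(logits).all()


def test_argmax_labels_in_range(tiny_model, rng):
    x = rng.standard_normal((2, 2, 48, 48)).astype(np.float32)
    labels = tiny_model.predict_labels(x)
    assert labels.min() >= 0 and labels.max() <= 2


def test_skip_connections_contribute(tiny_model, rng):
    x = rng.standard_normal((1, 2, 48, 48)).astype(np.float32)
    full = tiny_model(x).data
    for scale in (0, 1):
        ablated = tiny_model(x, skip_ablation=(scale,)).data
        assert np.abs(full - ablated).max() > 1e-6


def test_forward_rejects_wrong_shape(tiny_model):
    with pytest.raises(ShapeError):
        tiny_model(np.zeros((1, 2, 40, 48), dtype=np.float32))


def test_checkpoint_round_trip(tmp_path, tiny_model, rng):
    path = tmp_path / "model.npz"
    save_checkpoint(tiny_model, path)
    loaded = load_checkpoint(path)
    x = rng.standard_normal((1, 2, 48, 48)).astype(np.float32)
    np.testing.assert_array_equal(tiny_model(x).data, loaded(x).data)


def test_checkpoint_refuses_config_tamper(tmp_path, tiny_model):
    import numpy as np_

    path = tmp_path / "model.npz"
    save_checkpoint(tiny_model, path)
    with np_.load(path) as z:
        data = {k: z[k] for k in z.files}
    other = tiny_config(num_classes=5).to_yaml()
    data["__config_yaml__"] = np_.frombuffer(other.encode(), dtype=np_.uint8)
    np_.savez(tmp_path / "bad.npz", **data)
    with pytest.raises(ValueError, match="hash"):
        load_checkpoint(tmp_path / "bad.npz")
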