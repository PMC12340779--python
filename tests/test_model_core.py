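"""Dual-encoder contracts: LoRA injection, parameter counting, MIL pooling,
contrastive and cross-entropy losses, and the paired forward pass."""

import numpy as np
import pytest

from noduleclip import nn
from noduleclip.model import (EncoderConfig, LoRAConfig, MILHead, build_model,
                              clip_loss, compute_losses, count_trainable,
                              info_nce, inject_lora, l2_normalize,
                              load_checkpoint, mil_aggregate, save_checkpoint,
                              weighted_ce)
from noduleclip.nn import Tensor
from noduleclip.semantics import WhitespaceHashTokenizer

TOK = WhitespaceHashTokenizer(vocab_size=512, context_length=64)


@pytest.fixture(scope="module")
def tiny_model():
    return build_model("tiny", seed=0)


@pytest.fixture(scope="module")
def tiny_batch():
    rng = np.random.default_rng(0)
    views = rng.standard_normal((3, 9, 3, 56, 56)).astype(np.float32)
    tokens, eots = TOK.encode_batch(["This nodule margin is smooth.",
                                     "There is pleural attachment.",
                                     "No findings."])
    return views, tokens, eots, np.array([0, 1, 0])


# ---------------------------------------------------------------------- LoRA
def test_lora_identity_at_init_and_freeze(tiny_batch):
    views, tokens, eots, labels = tiny_batch
    model = build_model("tiny", seed=1).eval()
    before = model.forward_pair(views, tokens, eots)
    inject_lora(model, LoRAConfig())
    model.eval()
    after = model.forward_pair(views, tokens, eots)
    for a, b in zip(before[:4], after[:4]):
        assert np.array_equal(a.data, b.data)

    # freeze audit: backprop leaves every frozen tensor without a gradient
    model.train()
    bundle = compute_losses(model, views, tokens, eots, labels)
    bundle.total_tensor.backward()
    for name, p in model.named_parameters():
        if p.requires_grad:
            assert p.grad is not None, name
        else:
            assert p.grad is None, name


def test_lora_adds_2dr_parameters_per_projection():
    model = build_model("tiny", seed=0)
    before = count_trainable(model).n_total
    inject_lora(model, LoRAConfig(rank=2))
    after = count_trainable(model)
    d = model.cfg.vision_width  # == text width in the tiny preset
    n_proj = (model.cfg.vision_depth + model.cfg.text_depth) * 3
    assert after.n_adapters == n_proj * 2 * d * 2  # 2*d*r per adapted layer
    assert after.n_total == before + after.n_adapters


def test_lora_config_validation():
    with pytest.raises(ValueError):
        LoRAConfig(rank=0)
    with pytest.raises(ValueError):
        LoRAConfig(dropout=1.0)


def test_count_trainable_breakdowns(tiny_model):
    pc = count_trainable(tiny_model)
    assert pc.percent == pytest.approx(100.0)
    assert pc.n_trainable == pc.n_total
    # one extra trainable scalar increments the count by exactly one
    tiny_model.extra = nn.Parameter(np.zeros(()))
    try:
        assert count_trainable(tiny_model).n_trainable == pc.n_trainable + 1
    finally:
        del tiny_model.extra


# ----------------------------------------------------------------------- MIL
def test_mil_uniform_attention_for_identical_instances():
    head = MILHead(4, hidden=3, rng=np.random.default_rng(0))
    h = np.tile(np.array([1.0, -2.0, 0.5, 3.0], dtype=np.float32), (9, 1))
    z, a = mil_aggregate(h, head)
    assert np.allclose(a, 1.0 / 9)
    assert np.allclose(z, h[0], atol=1e-6)


def test_mil_two_instance_hand_oracle():
    head = MILHead(1, hidden=1)
    head.V.data = np.array([[1.0]], dtype=np.float32)
    head.w.data = np.array([1.0], dtype=np.float32)
    z, a = mil_aggregate(np.array([[1.0], [2.0]]), head)
    assert a == pytest.approx([0.4496, 0.5504], abs=1e-4)
    assert z[0] == pytest.approx(1.5504, abs=1e-4)


def test_mil_permutation_equivariance():
    rng = np.random.default_rng(1)
    head = MILHead(5, hidden=4, rng=rng)
    h = rng.standard_normal((9, 5)).astype(np.float32)
    perm = rng.permutation(9)
    z1, a1 = mil_aggregate(h, head)
    z2, a2 = mil_aggregate(h[perm], head)
    assert np.allclose(a2, a1[perm], atol=1e-6)
    assert np.allclose(z1, z2, atol=1e-6)


def test_mil_rejects_nonfinite_features():
    head = MILHead(2, hidden=2, rng=np.random.default_rng(0))
    with pytest.raises(ValueError):
        mil_aggregate(np.array([[np.nan, 0.0], [1.0, 1.0]]), head)


# -------------------------------------------------------------------- losses
@pytest.mark.parametrize("b", [2, 3, 8, 16, 64])
def test_info_nce_equals_log_b_for_uniform_similarity(b):
    loss = info_nce(np.zeros((b, b)), 1.0)
    assert float(loss.data) == pytest.approx(np.log(b), abs=1e-9)


def test_info_nce_identity_matrix_closed_form():
    val = float(info_nce(np.eye(2), 1.0).data)
    assert val == pytest.approx(np.log(1 + np.exp(-1)), abs=1e-9)


def test_info_nce_semantic_direction_is_transpose():
    rng = np.random.default_rng(2)
    m = rng.standard_normal((5, 5))
    a = float(info_nce(m, 0.5, "semantic").data)
    b = float(info_nce(m.T, 0.5, "image").data)
    assert a == pytest.approx(b, rel=1e-12)


def test_info_nce_nonnegative_property():
    rng = np.random.default_rng(3)
    for _ in range(20):
        m = rng.uniform(-1, 1, (6, 6))
        assert float(info_nce(m, 0.1).data) >= 0.0


def test_info_nce_rejects_nonpositive_temperature():
    with pytest.raises(ValueError):
        info_nce(np.eye(2), 0.0)


def test_clip_loss_is_mean_of_directions_and_shift_invariant():
    rng = np.random.default_rng(4)
    m = rng.standard_normal((4, 4))
    sym = (m + m.T) / 2
    li = float(info_nce(sym, 1.0, "image").data)
    ls = float(info_nce(sym, 1.0, "semantic").data)
    lc = float(clip_loss(sym, 1.0).data)
    assert lc == pytest.approx(li) == pytest.approx(ls)
    # adding a constant to every entry leaves the softmax unchanged
    assert float(clip_loss(m + 3.7, 1.0).data) == pytest.approx(
        float(clip_loss(m, 1.0).data), abs=1e-9)


def test_weighted_ce_uniform_weights_is_mean_ce():
    logits = np.array([[2.0, -1.0], [0.5, 0.5], [-3.0, 1.0]])
    labels = np.array([0, 1, 1])
    expect = []
    for lg, y in zip(logits, labels):
        z = lg - lg.max()
        expect.append(-(z[y] - np.log(np.exp(z).sum())))
    assert float(weighted_ce(logits, labels).data) == pytest.approx(np.mean(expect))


def test_weighted_ce_perfect_prediction_is_zero():
    logits = np.array([[100.0, -100.0], [-100.0, 100.0]])
    assert float(weighted_ce(logits, [0, 1]).data) == pytest.approx(0.0, abs=1e-12)


def test_weighted_ce_hand_weighted_example():
    logits = np.array([[1.0, 0.0], [0.0, 2.0]])
    labels = np.array([0, 1])
    l0 = -np.log(np.exp(1) / (np.exp(1) + 1))
    l1 = -np.log(np.exp(2) / (np.exp(2) + 1))
    out = float(weighted_ce(logits, labels, [1.0, 3.0]).data)
    assert out == pytest.approx((l0 + 3 * l1) / 4)


def test_weighted_ce_rejects_bad_labels_and_weights():
    with pytest.raises(ValueError):
        weighted_ce(np.zeros((2, 2)), [0, 2])
    with pytest.raises(ValueError):
        weighted_ce(np.zeros((2, 2)), [0, 1], [1.0, 0.0])


def test_loss_gradients_match_finite_differences():
    rng = np.random.default_rng(5)
    m0 = rng.standard_normal((3, 3))

    def clip_at(m):
        return float(clip_loss(Tensor(m), 0.7).data)

    x = Tensor(m0.copy(), requires_grad=True)
    clip_loss(x, 0.7).backward()
    num = np.zeros_like(m0)
    for i in np.ndindex(m0.shape):
        e = np.zeros_like(m0)
        e[i] = 1e-6
        num[i] = (clip_at(m0 + e) - clip_at(m0 - e)) / 2e-6
    assert np.abs(x.grad - num).max() / np.abs(num).max() < 1e-4

    logits0 = rng.standard_normal((4, 2))
    labels = np.array([0, 1, 1, 0])
    w = np.array([1.0, 2.5])

    def ce_at(lg):
        return float(weighted_ce(Tensor(lg), labels, w).data)

    x = Tensor(logits0.copy(), requires_grad=True)
    weighted_ce(x, labels, w).backward()
    num = np.zeros_like(logits0)
    for i in np.ndindex(logits0.shape):
        e = np.zeros_like(logits0)
        e[i] = 1e-6
        num[i] = (ce_at(logits0 + e) - ce_at(logits0 - e)) / 2e-6
    assert np.abs(x.grad - num).max() / np.abs(num).max() < 1e-4


def test_gradient_through_learnable_temperature():
    tau = Tensor(np.asarray(0.5), requires_grad=True)
    m = np.array([[1.0, -0.2], [-0.4, 0.8]])
    clip_loss(Tensor(m), tau).backward()
    eps = 1e-6
    num = (float(clip_loss(Tensor(m), 0.5 + eps).data)
           - float(clip_loss(Tensor(m), 0.5 - eps).data)) / (2 * eps)
    assert float(tau.grad) == pytest.approx(num, rel=1e-4)


# ------------------------------------------------------------- forward pass
def test_forward_pair_contracts(tiny_model, tiny_batch):
    views, tokens, eots, _ = tiny_batch
    tiny_model.eval()
    img, txt, img_logits, txt_logits, a = tiny_model.forward_pair(views, tokens, eots)
    assert img.shape == (3, 256) and txt.shape == (3, 256)
    assert img_logits.shape == (3, 2) and txt_logits.shape == (3, 2)
    assert np.allclose(a.data.sum(axis=1), 1.0, atol=1e-6)
    img2, *_ = tiny_model.forward_pair(views, tokens, eots)
    assert np.array_equal(img.data, img2.data)


def test_normalized_embeddings_unit_length(tiny_model, tiny_batch):
    views, tokens, eots, _ = tiny_batch
    img, *_ = tiny_model.eval().forward_pair(views, tokens, eots)
    norms = np.linalg.norm(l2_normalize(img).data, axis=1)
    assert np.allclose(norms, 1.0, atol=1e-5)


def test_token_sequence_over_context_rejected(tiny_model):
    tokens = np.zeros((1, tiny_model.cfg.context_length + 1), dtype=np.int64)
    with pytest.raises(ValueError):
        tiny_model.encode_text(tokens, np.array([0]))


def test_one_step_decreases_total_loss(tiny_batch):
    views, tokens, eots, labels = tiny_batch
    model = build_model("tiny", seed=3)
    model.train()
    before = compute_losses(model, views, tokens, eots, labels)
    opt = nn.AdamW([p for p in model.parameters() if p.requires_grad],
                   lr=1e-3, weight_decay=0.0)
    before.total_tensor.backward()
    opt.step()
    model.zero_grad()
    after = compute_losses(model, views, tokens, eots, labels)
    assert after.total < before.total


def test_tau_clamped_into_range(tiny_model):
    tiny_model.tau.data = np.asarray(5.0, dtype=np.float32)
    tiny_model.clamp_tau()
    assert float(tiny_model.tau.data) == 1.0
    tiny_model.tau.data = np.asarray(1e-9, dtype=np.float32)
    tiny_model.clamp_tau()
    assert float(tiny_model.tau.data) == pytest.approx(1e-3)
    tiny_model.tau.data = np.asarray(0.03, dtype=np.float32)


def test_checkpoint_roundtrip(tmp_path, tiny_batch):
    views, tokens, eots, _ = tiny_batch
    model = build_model("tiny", seed=4).eval()
    out = model.forward_pair(views, tokens, eots)[0].data
    path = tmp_path / "ckpt.npz"
    save_checkpoint(model, path)
    back = load_checkpoint(path).eval()
    out2 = back.forward_pair(views, tokens, eots)[0].data
    assert np.allclose(out, out2)


def test_encoder_config_presets():
    cfg = EncoderConfig.preset("vitb32")
    assert (cfg.vision_width, cfg.vision_depth, cfg.patch_size) == (768, 12, 32)
    assert (cfg.text_width, cfg.text_depth) == (512, 12)
    with pytest.raises(KeyError):
        EncoderConfig.preset("nope")
    with pytest.raises(ValueError):
        EncoderConfig(vision_width=30, vision_heads=4)
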