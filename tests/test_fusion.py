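"""Attention fusion: oracle equivalence, invariants, training behavior."""

import numpy as np
import pytest

from pmmd.fusion import (AttentionConfig, DegenerateLabelsError, FusionModel,
                         _init_model, cross_attention, self_attention,
                         tokenize, train_fusion)


# -------------------------------------------------------- brute-force oracle

def oracle_attention(xq, xk, xv, wq, wk, wv, n_heads, scale):
    """Scalar-loop multi-head scaled dot-product attention."""
    tq, d = xq.shape
    tk = xk.shape[0]
    dh = d // n_heads
    q = xq @ wq
    k = xk @ wk
    v = xv @ wv
    out = np.zeros((tq, d))
    for h in range(n_heads):
        sl = slice(h * dh, (h + 1) * dh)
        for i in range(tq):
            scores = np.empty(tk)
            for j in range(tk):
                scores[j] = float(q[i, sl] @ k[j, sl]) / scale
            e = np.exp(scores - scores.max())
            weights = e / e.sum()
            assert weights.sum() == pytest.approx(1.0, abs=1e-6)
            assert ((weights >= 0) & (weights <= 1)).all()
            for j in range(tk):
                out[i, sl] += weights[j] * v[j, sl]
    return out


def random_params(rng, d, cross=False):
    if cross:
        keys = ("wq1", "wk1", "wv1", "wq2", "wk2", "wv2")
    else:
        keys = ("wq", "wk", "wv")
    p = {k: rng.normal(size=(d, d)) for k in keys}
    if not cross:
        p["wo"] = np.eye(d)
    return p


class TestSelfAttention:
    def test_single_token_is_value_projection(self, rng):
        cfg = AttentionConfig(model_dim=8, n_heads=2)
        p = random_params(rng, 8)
        x = rng.normal(size=(1, 8))
        out = self_attention(x, p, cfg)
        assert np.allclose(out, x @ p["wv"], atol=1e-12)

    def test_uniform_weights_when_keys_equal(self, rng):
        cfg = AttentionConfig(model_dim=8, n_heads=2)
        p = random_params(rng, 8)
        p["wk"] = np.zeros((8, 8))  # all keys identical -> uniform rows
        x = rng.normal(size=(5, 8))
        out = self_attention(x, p, cfg)
        expected = np.repeat((x @ p["wv"]).mean(axis=0, keepdims=True), 5, axis=0)
        assert np.allclose(out, expected, atol=1e-10)

    @pytest.mark.parametrize("n_tokens,n_heads", [(6, 2), (8, 4), (3, 1)])
    def test_matches_scalar_oracle(self, rng, n_tokens, n_heads):
        d = 8
        cfg = AttentionConfig(model_dim=d, n_heads=n_heads)
        p = random_params(rng, d)
        x = rng.normal(size=(n_tokens, d))
        out = self_attention(x, p, cfg)
        exp = oracle_attention(x, x, x, p["wq"], p["wk"], p["wv"], n_heads,
                               cfg.scale)
        assert np.allclose(out, exp, atol=1e-6)

    def test_literal_d_scale_mode(self, rng):
        d = 8
        cfg = AttentionConfig(model_dim=d, n_heads=2, scale_mode="d")
        assert cfg.scale == d
        p = random_params(rng, d)
        x = rng.normal(size=(4, d))
        exp = oracle_attention(x, x, x, p["wq"], p["wk"], p["wv"], 2, float(d))
        assert np.allclose(self_attention(x, p, cfg), exp, atol=1e-6)

    def test_token_permutation_consistency(self, rng):
        cfg = AttentionConfig(model_dim=8, n_heads=2)
        p = random_params(rng, 8)
        x = rng.normal(size=(6, 8))
        perm = rng.permutation(6)
        out = self_attention(x, p, cfg)
        out_perm = self_attention(x[perm], p, cfg)
        assert np.allclose(out[perm], out_perm, atol=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        cfg = AttentionConfig(model_dim=8, n_heads=2)
        with pytest.raises(ValueError):
            self_attention(rng.normal(size=(3, 5)), random_params(rng, 8), cfg)


class TestCrossAttention:
    def test_single_token_passes_values_through(self, rng):
        cfg = AttentionConfig(model_dim=8, n_heads=2)
        p = random_params(rng, 8, cross=True)
        xa = rng.normal(size=(1, 8))
        xb = rng.normal(size=(1, 8))
        out_a, out_b = cross_attention(xa, xb, p, cfg)
        assert np.allclose(out_a, xa @ p["wv1"], atol=1e-10)
        assert np.allclose(out_b, xb @ p["wv2"], atol=1e-10)

    def test_mismatched_token_counts_rejected(self, rng):
        cfg = AttentionConfig(model_dim=8, n_heads=2)
        p = random_params(rng, 8, cross=True)
        with pytest.raises(ValueError):
            cross_attention(rng.normal(size=(5, 8)), rng.normal(size=(2, 8)), p, cfg)

    def test_matches_scalar_oracle(self, rng):
        cfg = AttentionConfig(model_dim=8, n_heads=2)
        p = random_params(rng, 8, cross=True)
        xa = rng.normal(size=(7, 8))
        xb = rng.normal(size=(7, 8))
        out_a, out_b = cross_attention(xa, xb, p, cfg)
        exp_a = oracle_attention(xa, xb, xa, p["wq1"], p["wk1"], p["wv1"], 2, cfg.scale)
        exp_b = oracle_attention(xb, xa, xb, p["wq2"], p["wk2"], p["wv2"], 2, cfg.scale)
        assert np.allclose(out_a, exp_a, atol=1e-6)
        assert np.allclose(out_b, exp_b, atol=1e-6)

    def test_role_swap_symmetry(self, rng):
        cfg = AttentionConfig(model_dim=8, n_heads=2)
        p = random_params(rng, 8, cross=True)
        # mirror the projections so both paths share weights
        for w in ("wq", "wk", "wv"):
            p[f"{w}2"] = p[f"{w}1"]
        xa = rng.normal(size=(6, 8))
        xb = rng.normal(size=(6, 8))
        out_a, out_b = cross_attention(xa, xb, p, cfg)
        swapped_b, swapped_a = cross_attention(xb, xa, p, cfg)
        assert np.allclose(out_a, swapped_a, atol=1e-12)
        assert np.allclose(out_b, swapped_b, atol=1e-12)


class TestTokenize:
    def test_chunking_and_padding(self):
        x = np.arange(10, dtype=float).reshape(1, 10)
        toks = tokenize(x, n_tokens=4)
        assert toks.shape == (1, 4, 3)
        assert toks[0, 3, 1] == 0.0  # zero padding
        assert np.allclose(toks.reshape(1, -1)[0, :10], np.arange(10))


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        cfg = AttentionConfig(model_dim=8, n_heads=2, n_tokens=3, seed=1)
        feats = {"handwriting": rng.normal(size=(5, 7)),
                 "clinical": rng.normal(size=(5, 9))}
        y = np.array([0, 1, 0, 1, 1])
        model = _init_model({m: x.shape[1] for m, x in feats.items()}, cfg)
        model.params["head_w"] = rng.normal(0, 0.1, model.params["head_w"].shape)
        _, _, caches, probs, _ = model._forward(feats, y)
        grads = model._backward(caches, probs, y)
        checked = 0
        for key in sorted(grads):
            w = model.params[key]
            idx = tuple(rng.integers(0, s) for s in w.shape)
            eps, orig = 1e-6, w[idx]
            w[idx] = orig + eps
            lp = model._forward(feats, y)[4]
            w[idx] = orig - eps
            lm = model._forward(feats, y)[4]
            w[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert grads[key][idx] == pytest.approx(num, abs=1e-5)
            checked += 1
        assert checked == len(grads)


class TestFuseShapes:
    def test_single_modality_length(self, rng):
        cfg = AttentionConfig(model_dim=16, n_heads=2, epochs=0)
        feats = {"drawing": rng.normal(size=(6, 5))}
        model = train_fusion(feats, np.array([0, 1, 0, 1, 0, 1]), cfg)
        assert model.fuse(feats).shape == (6, 16)

    def test_three_modalities_length(self, rng):
        cfg = AttentionConfig(model_dim=16, n_heads=2, epochs=0)
        feats = {"handwriting": rng.normal(size=(6, 10)),
                 "drawing": rng.normal(size=(6, 5)),
                 "clinical": rng.normal(size=(6, 8))}
        model = train_fusion(feats, np.array([0, 1, 0, 1, 0, 1]), cfg)
        # 3 self blocks + 3 pairs x 2 paths = 9 pooled vectors
        assert model.fuse(feats).shape == (6, 9 * 16)

    def test_missing_modality_rejected(self, rng):
        cfg = AttentionConfig(epochs=0)
        feats = {"handwriting": rng.normal(size=(4, 6)),
                 "clinical": rng.normal(size=(4, 6))}
        model = train_fusion(feats, np.array([0, 1, 0, 1]), cfg)
        with pytest.raises(ValueError):
            model.fuse({"handwriting": feats["handwriting"]})


class TestTraining:
    def make_separable(self, rng, n=60):
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        feats = {"handwriting": rng.normal(size=(n, 8)) + 2.5 * y[:, None],
                 "clinical": rng.normal(size=(n, 6)) - 2.0 * y[:, None]}
        return feats, y

    def test_separable_data_fits_perfectly(self, rng):
        feats, y = self.make_separable(rng)
        model = train_fusion(feats, y, AttentionConfig(epochs=200, seed=3))
        assert (model.predict(feats) == y).mean() == 1.0
        smoothed = np.convolve(model.training_log, np.ones(10) / 10, mode="valid")
        assert smoothed[-1] < smoothed[0]

    def test_seeded_determinism(self, rng):
        feats, y = self.make_separable(rng, n=30)
        cfg = AttentionConfig(epochs=20, seed=11)
        a = train_fusion(feats, y, cfg)
        b = train_fusion(feats, y, cfg)
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)
        assert a.training_log == b.training_log

    def test_zero_epochs_chance_loss(self, rng):
        feats, y = self.make_separable(rng, n=40)
        model = train_fusion(feats, y, AttentionConfig(epochs=0, seed=5))
        assert model.training_log == []
        _, _, _, _, loss = model._forward(feats, y)
        assert loss == pytest.approx(np.log(2), abs=1e-12)

    def test_single_class_rejected(self, rng):
        feats = {"clinical": rng.normal(size=(6, 4))}
        with pytest.raises(DegenerateLabelsError):
            train_fusion(feats, np.zeros(6, int), AttentionConfig(epochs=1))

    def test_string_labels_accepted(self, rng):
        feats, y = self.make_separable(rng, n=20)
        labels = np.where(y == 1, "PD", "HC")
        model = train_fusion(feats, labels, AttentionConfig(epochs=5, seed=0))
        assert model.fuse(feats).shape[0] == 20

    def test_save_load_round_trip(self, tmp_path, rng):
        feats, y = self.make_separable(rng, n=20)
        model = train_fusion(feats, y, AttentionConfig(epochs=5, seed=2))
        path = tmp_path / "fusion.npz"
        model.save(path)
        loaded = FusionModel.load(path)
        assert loaded.modalities == model.modalities
        assert np.allclose(loaded.fuse(feats), model.fuse(feats))
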