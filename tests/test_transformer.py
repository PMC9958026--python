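import math

import numpy as np
import pytest

from ramanformer import transformer_model as tm
from ramanformer._autograd import Adam, Tensor, cross_entropy_mean
from ramanformer.evaluation import train_val_split


def attention_bruteforce(Q, K, V):
    """Index-by-index reference implementation of scaled dot-product attention."""
    n, d = Q.shape
    out = np.zeros_like(V, dtype=float)
    for i in range(n):
        scores = np.empty(n)
        for j in range(n):
            scores[j] = sum(Q[i, t] * K[j, t] for t in range(d)) / math.sqrt(d)
        w = np.exp(scores - scores.max())
        w /= w.sum()
        for j in range(n):
            out[i] += w[j] * V[j]
    return out


class TestAttention:
    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(1, 8))
            d = int(rng.integers(1, 6))
            Q, K, V = (rng.normal(size=(n, d)) for _ in range(3))
            np.testing.assert_allclose(
                tm.scaled_dot_attention(Q, K, V), attention_bruteforce(Q, K, V),
                atol=1e-10)

    def test_identical_keys_give_column_means(self):
        rng = np.random.default_rng(1)
        Q = rng.normal(size=(4, 3))
        K = np.tile(rng.normal(size=(1, 3)), (4, 1))
        V = rng.normal(size=(4, 3))
        out = tm.scaled_dot_attention(Q, K, V)
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (4, 1)), atol=1e-12)

    def test_single_token_returns_value(self):
        rng = np.random.default_rng(2)
        Q, K, V = (rng.normal(size=(1, 5)) for _ in range(3))
        np.testing.assert_allclose(tm.scaled_dot_attention(Q, K, V), V, atol=1e-14)


@pytest.fixture(scope="module")
def scaled_model(tiny_axis):
    cfg = tm.TransformerConfig(n_classes=4, preset="scaled", dropout=0.0)
    return tm.TransformerClassifier(cfg, tiny_axis, seed=1, dtype=np.float64)


class TestArchitecture:
    def test_config_invariants(self):
        with pytest.raises(ValueError, match="divisible"):
            tm.TransformerConfig(n_classes=2, n_blocks=1, n_heads=5, d_model=64)
        cfg = tm.TransformerConfig(n_classes=8, preset="scaled")
        assert (cfg.n_blocks, cfg.n_heads, cfg.d_model, cfg.d_ff) == (2, 4, 64, 256)
        paper = tm.TransformerConfig(n_classes=8, preset="paper")
        assert (paper.n_blocks, paper.n_heads, paper.d_model) == (12, 12, 768)

    def test_patch_count(self, scaled_model):
        # L=320, patch 16 -> 20 patches + class token
        tokens = tm.patch_embed(np.zeros(320), scaled_model.params, scaled_model.cfg)
        assert tokens.shape == (1, 21, 64)
        # L=1000 pads to 63 patches
        cfg = tm.TransformerConfig(n_classes=4, preset="scaled")
        m = tm.TransformerClassifier(cfg, np.arange(1000.0), seed=0)
        tokens = tm.patch_embed(np.zeros(1000, dtype=np.float32), m.params, m.cfg)
        assert tokens.shape == (1, 64, 64)

    def test_too_short_spectrum(self, scaled_model):
        with pytest.raises(ValueError, match="shorter than one patch"):
            tm.patch_embed(np.zeros(7), scaled_model.params, scaled_model.cfg)

    def test_zero_weights_make_patch_rows_the_bias(self, tiny_axis):
        cfg = tm.TransformerConfig(n_classes=4, preset="scaled")
        m = tm.TransformerClassifier(cfg, tiny_axis, seed=0, dtype=np.float64)
        m.params["patch_projection.weight"].data[:] = 0
        m.params["patch_projection.bias"].data[:] = 0.5
        m.params["position_embeddings"].data[:] = 0
        tokens = tm.patch_embed(np.random.default_rng(0).normal(size=320),
                                m.params, cfg)
        np.testing.assert_allclose(tokens.data[0, 1:], 0.5)

    def test_single_head_reduces_to_plain_attention(self, tiny_axis):
        cfg = tm.TransformerConfig(n_classes=4, n_blocks=1, n_heads=1, d_model=16,
                                   d_ff=32, dropout=0.0)
        m = tm.TransformerClassifier(cfg, tiny_axis, seed=3, dtype=np.float64)
        d = cfg.d_model
        for name in ("q", "k", "v", "out"):
            m.params[f"block0.mha.{name}.weight"].data = np.eye(d)
            m.params[f"block0.mha.{name}.bias"].data[:] = 0
        rng = np.random.default_rng(4)
        tokens = rng.normal(size=(5, d))
        out = tm.multi_head_attention(tokens, m.params, "block0.mha", cfg)
        np.testing.assert_allclose(out.data, tm.scaled_dot_attention(tokens, tokens, tokens),
                                   atol=1e-12)

    def test_multi_head_permutation_equivariance(self, tiny_axis):
        """Without position information, permuting tokens permutes outputs."""
        cfg = tm.TransformerConfig(n_classes=4, preset="scaled", dropout=0.0)
        m = tm.TransformerClassifier(cfg, tiny_axis, seed=5, dtype=np.float64)
        rng = np.random.default_rng(6)
        tokens = rng.normal(size=(9, cfg.d_model))
        perm = rng.permutation(9)
        out = tm.multi_head_attention(tokens, m.params, "block0.mha", cfg).data
        out_perm = tm.multi_head_attention(tokens[perm], m.params, "block0.mha", cfg).data
        np.testing.assert_allclose(out_perm, out[perm], atol=1e-10)

    def test_zero_weight_blocks_are_identity(self, tiny_axis):
        cfg = tm.TransformerConfig(n_classes=4, preset="scaled", dropout=0.0)
        m = tm.TransformerClassifier(cfg, tiny_axis, seed=7, dtype=np.float64)
        for k, t in m.params.items():
            if k.startswith("block") and ("weight" in k or ".w" in k):
                t.data[:] = 0
        rng = np.random.default_rng(8)
        x = rng.normal(size=(3, 10, cfg.d_model))
        y = tm.encoder_block(Tensor(x), m.params, "block0", cfg)
        y = tm.encoder_block(y, m.params, "block1", cfg)
        np.testing.assert_allclose(y.data, x, atol=1e-12)


class TestForward:
    def test_probabilities_sum_to_one(self, scaled_model):
        rng = np.random.default_rng(9)
        probs = scaled_model.forward(rng.normal(size=(5, 320)))
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_head_gives_uniform_eighths(self, tiny_axis):
        cfg = tm.TransformerConfig(n_classes=8, preset="scaled")
        m = tm.TransformerClassifier(cfg, tiny_axis, seed=10)
        # head is zero-initialised by construction
        probs = m.forward(np.random.default_rng(11).normal(size=320))
        np.testing.assert_allclose(probs, 0.125, atol=1e-7)

    def test_inference_is_deterministic(self, scaled_model):
        x = np.random.default_rng(12).normal(size=320)
        a = scaled_model.forward(x)
        b = scaled_model.forward(x)
        np.testing.assert_array_equal(a, b)

    def test_grid_mismatch_rejected(self, scaled_model, separable_2class):
        with pytest.raises(ValueError, match="does not match model grid"):
            tm.predict(scaled_model, separable_2class["clean"])


class TestCrossEntropy:
    def test_analytic_values(self):
        assert tm.cross_entropy(np.array([0.0, 1.0]), 1) == 0.0
        assert tm.cross_entropy(np.full(8, 0.125), 3) == pytest.approx(math.log(8))

    def test_monotone_in_correct_probability(self):
        losses = [tm.cross_entropy(np.array([p, 1 - p]), 0)
                  for p in (0.1, 0.3, 0.5, 0.9)]
        assert all(a > b for a, b in zip(losses, losses[1:]))


class TestTraining:
    def test_gradients_match_central_differences(self, scaled_model):
        m = scaled_model
        rng = np.random.default_rng(13)
        # informative head so gradients reach every layer
        m.params["head.weight"].data = rng.normal(0, 0.05,
                                                  m.params["head.weight"].shape)
        X = rng.normal(size=(3, 320))
        y = np.array([0, 1, 2])

        for t in m.params.values():
            t.zero_grad()
        cross_entropy_mean(m.logits(X), y).backward()

        names = list(m.params)
        check_rng = np.random.default_rng(14)
        checked = 0
        while checked < 20:
            t = m.params[names[check_rng.integers(len(names))]]
            idx = tuple(check_rng.integers(s) for s in t.data.shape)
            if t.grad is None or abs(t.grad[idx]) < 1e-6:
                continue  # round-off would dominate a near-zero gradient
            checked += 1
            h = 1e-5
            orig = t.data[idx]
            t.data[idx] = orig + h
            lp = float(cross_entropy_mean(m.logits(X), y).data)
            t.data[idx] = orig - h
            lm = float(cross_entropy_mean(m.logits(X), y).data)
            t.data[idx] = orig
            numeric = (lp - lm) / (2 * h)
            analytic = 0.0 if t.grad is None else t.grad[idx]
            rel = abs(numeric - analytic) / max(abs(numeric), abs(analytic), 1e-8)
            assert rel < 1e-4
        m.params["head.weight"].data[:] = 0  # restore module fixture

    def test_adam_zero_gradient_is_fixed_point(self):
        p = Tensor(np.array([1.0, 2.0]), requires_grad=True)
        opt = Adam([p])
        p.grad = np.zeros(2)
        opt.step()
        np.testing.assert_array_equal(p.data, [1.0, 2.0])

    def test_separable_training_reaches_high_accuracy(self, separable_2class):
        clean = separable_2class["clean"]
        axis = separable_2class["axis"]
        tr, va = train_val_split(np.arange(clean.n_spectra), clean.labels, 0.8, 0)
        cfg = tm.TransformerConfig(n_classes=2, preset="scaled")
        model = tm.TransformerClassifier(cfg, axis, seed=0)
        tcfg = tm.TrainConfig(epochs=20, batch_size=16, seed=0)
        params, log = tm.train_model(clean.subset(tr), clean.subset(va), model, tcfg)
        pred, probs = tm.predict(model, clean.subset(tr))
        acc = float(np.mean(pred == clean.labels[tr]))
        assert acc >= 0.99
        # prediction on the validation split reproduces the logged accuracy
        best = max(e["val_accuracy"] for e in log)
        vpred, _ = tm.predict(model, clean.subset(va))
        assert float(np.mean(vpred == clean.labels[va])) == pytest.approx(best)

    def test_training_determinism(self, separable_2class):
        clean = separable_2class["clean"]
        axis = separable_2class["axis"]
        tr, va = train_val_split(np.arange(clean.n_spectra), clean.labels, 0.8, 1)
        cfg = tm.TransformerConfig(n_classes=2, preset="scaled")
        tcfg = tm.TrainConfig(epochs=2, batch_size=16, seed=3)
        runs = []
        for _ in range(2):
            model = tm.TransformerClassifier(cfg, axis, seed=3)
            params, _ = tm.train_model(clean.subset(tr), clean.subset(va), model, tcfg)
            runs.append({k: v.data.copy() for k, v in params.items()})
        for k in runs[0]:
            np.testing.assert_array_equal(runs[0][k], runs[1][k])

    def test_single_class_rejected(self, separable_2class):
        clean = separable_2class["clean"]
        only = np.flatnonzero(clean.labels == 0)
        sub = clean.subset(only)
        cfg = tm.TransformerConfig(n_classes=2, preset="scaled")
        model = tm.TransformerClassifier(cfg, clean.axis, seed=0)
        with pytest.raises(ValueError, match="degenerate label set"):
            tm.train_model(sub, sub, model, tm.TrainConfig(epochs=1))


class TestPredict:
    def test_tie_breaks_to_lowest_index(self, separable_2class):
        clean = separable_2class["clean"]

        class TiedModel:
            def check_axis(self, axis):
                pass

            def logits(self, x, train=False, rng=None):
                z = np.full((x.shape[0], 8), -5.0)
                z[:, 2] = z[:, 5] = 1.0  # exact tie between classes 2 and 5
                return Tensor(z)

        labels, probs = tm.predict(TiedModel(), clean)
        assert np.all(labels == 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_checkpoint_roundtrip(self, tmp_path, tiny_axis):
        cfg = tm.TransformerConfig(n_classes=3, preset="scaled")
        m = tm.TransformerClassifier(cfg, tiny_axis, seed=4, class_names=list("abc"))
        rng = np.random.default_rng(15)
        for t in m.params.values():
            t.data = rng.normal(0, 0.05, t.data.shape).astype(t.data.dtype)
        tm.save_checkpoint(m, tmp_path / "m.npz")
        m2 = tm.load_checkpoint(tmp_path / "m.npz")
        x = rng.normal(size=(2, tiny_axis.size))
        np.testing.assert_allclose(m2.forward(x), m.forward(x), atol=1e-7)
        assert m2.class_names == ["a", "b", "c"]
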