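import numpy as np
import pytest

from dicersite._autodiff import AdamW, Parameter, Tensor, cross_entropy
from dicersite.encoding import build_vocab, sinusoidal_pe, tokenize_3mer
from dicersite.io_formats import ValidationError
from dicersite.model import (
    DualStreamClassifier,
    EncoderUnitConfig,
    MSCAM,
    ModelConfig,
    aff_combine,
    aff_weight_diagnostics,
    load_checkpoint,
    predict_topk,
    save_checkpoint,
)

SMALL_ENC = EncoderUnitConfig(ff_dim=32, out_dim=16, dropout=0.0)


def small_cfg(fusion="aff", n_classes=6):
    return ModelConfig(n_classes=n_classes, encoder=SMALL_ENC, fusion=fusion)


def token_batch(rng, n, length):
    seq = rng.integers(1, 85, size=(n, length))
    struct = rng.integers(1, 40, size=(n, length))
    mask = np.ones((n, length), dtype=bool)
    return seq, struct, mask


class TestMSCAMAndAFF:
    def test_weights_in_unit_interval(self):
        rng = np.random.default_rng(0)
        block = MSCAM(16, 4, rng)
        w = block(Tensor(rng.normal(size=(5, 16)))).numpy()
        assert w.shape == (5, 16)
        assert (w > 0).all() and (w < 1).all()

    def test_zero_input_zero_bottleneck_gives_half(self):
        rng = np.random.default_rng(0)
        block = MSCAM(8, 4, rng)
        for lin in (block.g1, block.g2, block.l1, block.l2):
            lin.W.data[...] = 0.0
            lin.b.data[...] = 0.0
        w = block(Tensor(np.zeros((3, 8)))).numpy()
        assert np.allclose(w, 0.5)

    def test_aff_limit_w_one_returns_x(self):
        rng = np.random.default_rng(1)
        X, Y = Tensor(rng.normal(size=(4, 8))), Tensor(rng.normal(size=(4, 8)))
        Z = aff_combine(X, Y, Tensor(np.ones((4, 8))))
        assert np.allclose(Z.numpy(), X.numpy(), atol=1e-7)

    def test_aff_limit_w_zero_returns_y(self):
        rng = np.random.default_rng(2)
        X, Y = Tensor(rng.normal(size=(4, 8))), Tensor(rng.normal(size=(4, 8)))
        Z = aff_combine(X, Y, Tensor(np.zeros((4, 8))))
        assert np.allclose(Z.numpy(), Y.numpy(), atol=1e-7)

    def test_aff_equal_inputs_invariant_to_w(self):
        rng = np.random.default_rng(3)
        X = Tensor(rng.normal(size=(4, 8)))
        for w in (0.0, 0.3, 1.0):
            Z = aff_combine(X, X, Tensor(np.full((4, 8), w)))
            assert np.allclose(Z.numpy(), X.numpy(), atol=1e-6)

    def test_aff_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            aff_combine(Tensor(np.zeros((2, 3))), Tensor(np.zeros((2, 4))),
                        Tensor(np.zeros((2, 3))))


class TestFusionModes:
    def test_concat_order_and_dims(self):
        rng = np.random.default_rng(4)
        model = DualStreamClassifier(small_cfg("concat"), seed=0)
        X = Tensor(rng.normal(size=(3, 16)))
        Y = Tensor(rng.normal(size=(3, 16)))
        fused = model.fuse(X, Y).numpy()
        assert fused.shape == (3, 32)
        assert np.allclose(fused[:, :16], X.numpy())
        assert np.allclose(fused[:, 16:], Y.numpy())
        swapped = model.fuse(Y, X).numpy()
        assert not np.allclose(fused, swapped)

    def test_aff_diagnostics_require_aff(self):
        with pytest.raises(ValidationError):
            aff_weight_diagnostics(None)

    def test_aff_diagnostics_summary(self):
        w = np.array([[0.2, 0.4], [0.8, 0.6]])
        d = aff_weight_diagnostics(w)
        assert d["n"] == 2
        assert d["mean"] == pytest.approx(0.5)
        assert d["min"] == pytest.approx(0.3) and d["max"] == pytest.approx(0.7)


class TestForward:
    def _streams(self, rng, n=3, pat_len=8, seq_len=30):
        return (*token_batch(rng, n, pat_len), *token_batch(rng, n, seq_len))

    @pytest.mark.parametrize("fusion", ["aff", "concat"])
    def test_probs_sum_to_one(self, fusion):
        rng = np.random.default_rng(5)
        model = DualStreamClassifier(small_cfg(fusion), seed=0)
        ps, pst, pm, ss, sst, sm = self._streams(rng)
        logits = model.forward_tokens(ps, pst, pm, ss, sst, sm)
        probs = logits.softmax(axis=-1).numpy()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert ((0 <= probs.argmax(axis=1)) & (probs.argmax(axis=1) < 6)).all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        args = self._streams(rng)
        out1 = DualStreamClassifier(small_cfg(), seed=9).forward_tokens(*args)
        out2 = DualStreamClassifier(small_cfg(), seed=9).forward_tokens(*args)
        assert np.array_equal(out1.numpy(), out2.numpy())

    def test_pad_invariance(self):
        """Predictions must not depend on how far the hairpin is padded."""
        rng = np.random.default_rng(7)
        model = DualStreamClassifier(small_cfg(), seed=0)
        ps, pst, pm = token_batch(rng, 2, 8)
        ss, sst, _ = token_batch(rng, 2, 25)
        for pad in (25, 40, 64):
            s2 = np.zeros((2, pad), dtype=np.int64)
            t2 = np.zeros((2, pad), dtype=np.int64)
            m2 = np.zeros((2, pad), dtype=bool)
            s2[:, :25], t2[:, :25], m2[:, :25] = ss, sst, True
            out = model.forward_tokens(ps, pst, pm, s2, t2, m2).numpy()
            if pad == 25:
                ref = out
            else:
                assert np.allclose(out, ref, atol=2e-4)

    def test_all_pad_input_rejected(self):
        rng = np.random.default_rng(8)
        model = DualStreamClassifier(small_cfg(), seed=0)
        ps, pst, pm = token_batch(rng, 2, 8)
        with pytest.raises(ValidationError, match="padding"):
            model.forward_tokens(ps, pst, pm,
                                 np.zeros((2, 10), np.int64),
                                 np.zeros((2, 10), np.int64),
                                 np.zeros((2, 10), bool))

    def test_seq_gather_matches_expanded(self):
        """Hairpin deduplication must reproduce the expanded computation."""
        rng = np.random.default_rng(9)
        model = DualStreamClassifier(small_cfg(), seed=0)
        ps, pst, pm = token_batch(rng, 4, 8)
        ss, sst, sm = token_batch(rng, 2, 20)
        gather = np.array([0, 1, 0, 1])
        deduped = model.forward_tokens(ps, pst, pm, ss, sst, sm,
                                       seq_gather=gather).numpy()
        expanded = model.forward_tokens(ps, pst, pm, ss[gather], sst[gather],
                                        sm[gather]).numpy()
        assert np.allclose(deduped, expanded, atol=1e-5)

    def test_tiny_overfit_capacity(self):
        """The network can memorize 32 random samples (loss < 0.01)."""
        rng = np.random.default_rng(10)
        cfg = small_cfg(n_classes=4)
        model = DualStreamClassifier(cfg, seed=1)
        ps, pst, pm = token_batch(rng, 32, 8)
        ss, sst, sm = token_batch(rng, 32, 16)
        labels = rng.integers(0, 4, size=32)
        opt = AdamW(model.parameters(), lr=1e-3)
        loss_val = np.inf
        for step in range(200):
            logits = model.forward_tokens(ps, pst, pm, ss, sst, sm)
            loss = cross_entropy(logits, labels)
            opt.zero_grad()
            loss.backward()
            opt.step()
            loss_val = loss.item()
            if loss_val < 0.01:
                break
        assert loss_val < 0.01
        probs = model.predict_proba(
            model.embed_stream(ps, pst, pm), pm,
            model.embed_stream(ss, sst, sm), sm)
        assert (probs.argmax(axis=1) == labels).mean() == 1.0


class TestPredictTopK:
    def test_ranking(self):
        assert predict_topk(np.array([0.1, 0.7, 0.2]), 1).tolist() == [[1]]

    def test_full_permutation(self):
        out = predict_topk(np.array([0.3, 0.1, 0.4, 0.2]), 4)[0]
        assert sorted(out.tolist()) == [0, 1, 2, 3]
        assert out.tolist() == [2, 0, 3, 1]

    def test_tie_breaks_by_ascending_class(self):
        probs = np.array([0.0, 0.0, 0.5, 0.0, 0.0, 0.5])
        assert predict_topk(probs, 2)[0].tolist() == [2, 5]

    def test_k_validated(self):
        with pytest.raises(ValidationError):
            predict_topk(np.array([0.5, 0.5]), 3)


class TestCheckpoint:
    def test_roundtrip_bitwise(self, tmp_path):
        rng = np.random.default_rng(11)
        model = DualStreamClassifier(small_cfg(), seed=3)
        ps, pst, pm = token_batch(rng, 2, 8)
        ss, sst, sm = token_batch(rng, 2, 16)
        ref = model.forward_tokens(ps, pst, pm, ss, sst, sm).numpy()
        save_checkpoint(model, tmp_path / "ckpt", meta={"seed": 3})
        loaded, meta = load_checkpoint(tmp_path / "ckpt")
        assert meta["seed"] == 3
        out = loaded.forward_tokens(ps, pst, pm, ss, sst, sm).numpy()
        assert np.array_equal(ref, out)
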