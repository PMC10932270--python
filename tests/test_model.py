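import numpy as np
import pytest

from rnamod.autodiff import Tensor
from rnamod.model import (
    ClassifierHead,
    EncoderConfig,
    FusionGateParams,
    MaskedLMHead,
    SequenceClassifier,
    TransformerEncoder,
    classify,
    fusion_gate,
    masked_lm_step,
)
from rnamod.tokenization import build_vocab, encode_tokens


def _toks(seq="GAUUACAUGG", k=3, max_len=16):
    return encode_tokens(seq, build_vocab(k), max_len=max_len)


class TestEncoderConfig:
    def test_tiny_preset_geometry(self):
        cfg = EncoderConfig.tiny()
        assert (cfg.n_layers, cfg.hidden_dim, cfg.n_heads) == (2, 64, 4)

    def test_hidden_must_divide_heads(self):
        with pytest.raises(ValueError):
            EncoderConfig(n_heads=5, hidden_dim=64)

    def test_json_roundtrip(self, tmp_path):
        cfg = EncoderConfig.tiny(vocab_size=1029)
        cfg.to_json(tmp_path / "c.json")
        assert EncoderConfig.from_json(tmp_path / "c.json") == cfg


class TestEncoder:
    def test_output_shapes_match_config(self, tiny_encoder):
        toks = _toks(max_len=32)
        out = tiny_encoder.encode(toks)
        assert out.hidden_states.shape == (32, 64)
        assert out.pooled.shape == (64,)
        assert len(out.attentions) == 2
        assert out.attentions[0].shape == (4, 32, 32)

    def test_forward_is_deterministic(self, tiny_encoder):
        toks = _toks(max_len=32)
        a = tiny_encoder.encode(toks)
        b = tiny_encoder.encode(toks)
        assert np.array_equal(a.hidden_states, b.hidden_states)
        assert np.array_equal(a.attentions[1], b.attentions[1])

    def test_attention_rows_sum_to_one_over_unmasked(self, tiny_encoder):
        toks = _toks(max_len=32)
        out = tiny_encoder.encode(toks)
        content = int(toks.attention_mask.sum())
        for layer in out.attentions:
            rows = layer[:, :content, :]
            assert np.allclose(rows.sum(axis=-1), 1.0, atol=1e-5)
            # no attention leaks onto padding
            assert layer[:, :content, content:].max() < 1e-9

    def test_out_of_vocab_id_is_an_error(self, tiny_encoder):
        ids = np.array([[0, 9999]])
        with pytest.raises(ValueError):
            tiny_encoder.forward(ids, np.ones_like(ids))

    def test_pooled_is_cls_position(self, tiny_encoder):
        toks = _toks(max_len=32)
        out = tiny_encoder.encode(toks)
        assert np.array_equal(out.pooled, out.hidden_states[0])


class TestFusionGate:
    def test_zero_maps_give_half_gate_and_midpoint(self):
        params = FusionGateParams(W1=Tensor(np.zeros((4, 4))), W2=Tensor(np.zeros((4, 4))))
        h1, h2 = np.arange(4.0), np.ones(4)
        F, hm = fusion_gate(h1, h2, params)
        assert np.allclose(F, 0.5)
        assert np.allclose(hm, (h1 + h2) / 2)

    def test_equal_inputs_pass_through(self, rng):
        params = FusionGateParams.init(6, rng)
        h = rng.normal(size=6)
        _, hm = fusion_gate(h, h, params)
        assert np.allclose(hm, h, atol=1e-12)

    def test_matches_scalar_loop_oracle(self, rng):
        d = 8
        params = FusionGateParams.init(d, rng)
        h1, h2 = rng.normal(size=d), rng.normal(size=d)
        F, hm = fusion_gate(h1, h2, params)
        W1, W2 = params.W1.data, params.W2.data
        for i in range(d):
            z = sum(h1[j] * W1[j, i] for j in range(d)) + sum(
                h2[j] * W2[j, i] for j in range(d)
            )
            f = 1.0 / (1.0 + np.exp(-z))
            assert abs(F[i] - f) < 1e-10
            assert abs(hm[i] - (f * h1[i] + (1 - f) * h2[i])) < 1e-10

    def test_gate_strictly_inside_unit_interval(self, rng):
        params = FusionGateParams.init(5, rng)
        F, _ = fusion_gate(rng.normal(size=5), rng.normal(size=5), params)
        assert np.all((F > 0) & (F < 1))

    def test_convexity_bound_elementwise(self, rng):
        params = FusionGateParams.init(6, rng)
        for _ in range(100):
            h1, h2 = rng.normal(size=6), rng.normal(size=6)
            _, hm = fusion_gate(h1, h2, params)
            assert np.all(hm >= np.minimum(h1, h2) - 1e-12)
            assert np.all(hm <= np.maximum(h1, h2) + 1e-12)

    def test_dimension_mismatch_is_an_error(self, rng):
        params = FusionGateParams.init(4, rng)
        with pytest.raises(ValueError):
            fusion_gate(np.ones(4), np.ones(5), params)
        with pytest.raises(ValueError):
            fusion_gate(np.ones(3), np.ones(3), params)

    def test_scalar_gate_broadcasts_one_weight(self, rng):
        params = FusionGateParams.init(6, rng, scalar_gate=True)
        F, _ = fusion_gate(rng.normal(size=6), rng.normal(size=6), params)
        assert np.allclose(F, F[0])


class TestClassify:
    def test_zero_weights_give_half(self, rng):
        head = ClassifierHead(8, rng)
        head.w.data[:] = 0.0
        head.b.data[:] = 0.0
        assert np.allclose(classify(np.ones(8), head), 0.5)

    def test_probability_in_open_interval(self, rng):
        head = ClassifierHead(8, rng)
        p = classify(rng.normal(size=(20, 8)) * 100, head)
        assert np.all((p > 0) & (p < 1))

    def test_deterministic(self, rng):
        head = ClassifierHead(8, rng)
        x = rng.normal(size=8)
        assert classify(x, head) == classify(x, head)


class TestMaskedLM:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        vocab = build_vocab(3)
        cfg = EncoderConfig.tiny(vocab_size=len(vocab), max_tokens=16)
        enc = TransformerEncoder(cfg, rng)
        head = MaskedLMHead(cfg.hidden_dim, cfg.vocab_size, rng)
        return enc, head, vocab

    def test_loss_nonnegative_and_seeded(self):
        enc, head, vocab = self._setup()
        batch = [encode_tokens("GAUUACAUGG", vocab, max_len=16)]
        a = masked_lm_step(enc, head, batch, seed=3).item()
        b = masked_lm_step(enc, head, batch, seed=3).item()
        assert a >= 0 and a == b

    def test_uniform_logits_give_log_vocab_size(self):
        enc, head, vocab = self._setup()
        head.W.data[:] = 0.0
        head.b.data[:] = 0.0
        batch = [encode_tokens("GAUUACAUGG", vocab, max_len=16)]
        loss = masked_lm_step(enc, head, batch, mask_prob=0.99, seed=0).item()
        assert abs(loss - np.log(len(vocab))) < 1e-9

    def test_at_least_one_token_masked_even_at_tiny_prob(self):
        enc, head, vocab = self._setup()
        batch = [encode_tokens("GAUUACAUGG", vocab, max_len=16)]
        loss = masked_lm_step(enc, head, batch, mask_prob=1e-9, seed=0)
        assert np.isfinite(loss.item())

    def test_invalid_mask_prob(self):
        enc, head, vocab = self._setup()
        batch = [encode_tokens("GAUUAC", vocab, max_len=16)]
        with pytest.raises(ValueError):
            masked_lm_step(enc, head, batch, mask_prob=1.5, seed=0)


class TestSequenceClassifier:
    def test_layer_counts_by_preset(self):
        tiny = SequenceClassifier(EncoderConfig.tiny(vocab_size=69, max_tokens=16))
        assert tiny.encoders[0].n_layers == 2

    def test_separate_encoders_when_not_shared(self):
        cfg = EncoderConfig.tiny(vocab_size=69, max_tokens=16)
        m = SequenceClassifier(cfg, n_scales=2, shared_encoder=False)
        assert len(m.encoders) == 2
        assert m.encoders[0] is not m.encoders[1]

    def test_checkpoint_roundtrip_preserves_predictions(self, tmp_path):
        cfg = EncoderConfig.tiny(vocab_size=69, max_tokens=16)
        m = SequenceClassifier(cfg, n_scales=1, seed=4)
        toks = _toks(max_len=16)
        batch = [(toks.ids[None, :], toks.attention_mask[None, :])]
        p0 = m.predict_proba_tokens(batch)
        m.save(tmp_path / "w.npz", tmp_path / "c.json")
        m2 = SequenceClassifier.load(tmp_path / "w.npz", tmp_path / "c.json")
        assert np.array_equal(m2.predict_proba_tokens(batch), p0)

    def test_mean_pooling_differs_from_cls(self):
        cfg = EncoderConfig.tiny(vocab_size=69, max_tokens=16)
        toks = _toks(max_len=16)
        batch = [(toks.ids[None, :], toks.attention_mask[None, :])]
        p_cls = SequenceClassifier(cfg, pooling="cls", seed=4).predict_proba_tokens(batch)
        p_mean = SequenceClassifier(cfg, pooling="mean", seed=4).predict_proba_tokens(batch)
        assert p_cls != p_mean
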