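"""Conditional transformer: architecture, loss, causality, sampling."""

import math

import numpy as np
import pytest

from biochemlm.autodiff import Adam
from biochemlm.model import (BiochemLM, ConfigurationError, ModelConfig,
                             build_model)
from biochemlm.tokenization import SmilesVocabulary


class TestConfig:
    def test_default_architecture_is_three_plus_three(self):
        cfg = ModelConfig()
        assert cfg.n_encoder_layers == 3
        assert cfg.n_decoder_layers == 3
        assert cfg.d_model == 1024
        assert cfg.d_feedforward == 4 * 1024

    def test_heads_must_divide_d_model(self):
        with pytest.raises(ValueError, match="divide"):
            ModelConfig(d_model=128, n_heads=7)

    @pytest.mark.parametrize("kw", [{"n_encoder_layers": 0}, {"dropout": 1.0}])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            ModelConfig(**kw)

    def test_embedder_dimension_contract(self, tiny_vocab):
        with pytest.raises(ConfigurationError, match="1024"):
            build_model(ModelConfig(), tiny_vocab, embedder_dim=1024 + 1)


class TestArchitecture:
    def test_layer_stacks_instantiated(self, tiny_config, tiny_vocab):
        model = BiochemLM(tiny_config, tiny_vocab)
        enc = {k for k in model.params if k.startswith("enc")}
        dec = {k for k in model.params if k.startswith("dec")}
        assert {k.split(".")[0] for k in enc if k[3].isdigit()} == {"enc0", "enc1", "enc2"}
        assert {k.split(".")[0] for k in dec if k[3].isdigit()} == {"dec0", "dec1", "dec2"}

    def test_conditional_model_has_852_row_potency_table(self, tiny_config, tiny_vocab):
        model = BiochemLM(tiny_config, tiny_vocab)
        assert model.params["pot_emb"].data.shape[0] == 852
        assert model.config.encoder_input_length == 2

    def test_unconditional_model_lacks_potency_table(self, tiny_vocab):
        cfg = ModelConfig(d_model=32, n_heads=2, d_feedforward=64, conditional=False)
        model = BiochemLM(cfg, tiny_vocab)
        assert "pot_emb" not in model.params
        assert model.config.encoder_input_length == 1


class TestForwardLoss:
    def test_untrained_loss_near_log_vocab(self, tiny_config, tiny_vocab, protein_vec):
        model = BiochemLM(tiny_config, tiny_vocab, seed=1)
        ids = tiny_vocab.encode("CCc1ccc2ccccc2c1")
        loss = float(model.forward_loss(protein_vec, 100, ids).data)
        assert loss == pytest.approx(math.log(len(tiny_vocab)), rel=0.2)

    def test_deterministic_without_dropout(self, tiny_config, tiny_vocab, protein_vec):
        model = BiochemLM(tiny_config, tiny_vocab, seed=1)
        ids = tiny_vocab.encode("CCl")
        l1 = float(model.forward_loss(protein_vec, 10, ids).data)
        l2 = float(model.forward_loss(protein_vec, 10, ids).data)
        assert l1 == l2

    def test_empty_target_rejected(self, tiny_config, tiny_vocab, protein_vec):
        model = BiochemLM(tiny_config, tiny_vocab)
        with pytest.raises(ValueError):
            model.forward_loss(protein_vec, 0, [])

    def test_conditional_model_requires_bin(self, tiny_config, tiny_vocab, protein_vec):
        model = BiochemLM(tiny_config, tiny_vocab)
        with pytest.raises(ValueError):
            model.forward_loss(protein_vec, None, [5])

    def test_wrong_embedding_dimension_rejected(self, tiny_config, tiny_vocab):
        model = BiochemLM(tiny_config, tiny_vocab)
        with pytest.raises(ConfigurationError):
            model.forward_loss(np.zeros(33), 0, [5])


class TestCausality:
    def test_future_tokens_never_affect_past_logits(self, tiny_config, tiny_vocab,
                                                    protein_vec):
        model = BiochemLM(tiny_config, tiny_vocab, seed=2)
        ids = tiny_vocab.encode("CCc1ccc2ccccc2c1")
        dec_in = [tiny_vocab.start_id] + ids
        memory = model.encode(protein_vec, 50)
        base = model.decoder_logits(memory, dec_in).data
        for t in range(len(dec_in) - 1):
            perturbed = list(dec_in)
            perturbed[t + 1] = (perturbed[t + 1] + 1) % len(tiny_vocab)
            out = model.decoder_logits(model.encode(protein_vec, 50), perturbed).data
            np.testing.assert_allclose(out[: t + 1], base[: t + 1],
                                       rtol=1e-10, atol=1e-10)


class TestConditioning:
    def test_potency_token_shifts_next_token_distribution(self, trained_model,
                                                          protein_vec):
        """After training, distant potency bins induce different decoder
        distributions for the same protein (total variation > 0)."""
        model = trained_model
        lo = model.encode_batch(protein_vec[None], np.array([100]))
        hi = model.encode_batch(protein_vec[None], np.array([700]))
        assert not np.allclose(lo, hi)

    def test_unconditional_model_invariant_to_potency(self, tiny_vocab, protein_vec):
        cfg = ModelConfig(d_model=32, n_heads=2, d_feedforward=64, dropout=0.0,
                          conditional=False)
        model = BiochemLM(cfg, tiny_vocab)
        m1 = model.encode_batch(protein_vec[None], None)
        m2 = model.encode_batch(protein_vec[None], None)
        np.testing.assert_array_equal(m1, m2)


class TestSampling:
    def test_same_seed_same_tokens(self, trained_model, protein_vec):
        a = trained_model.sample(protein_vec, 100, seed=9)
        b = trained_model.sample(protein_vec, 100, seed=9)
        assert a.tokens == b.tokens
        assert a.log_probability == b.log_probability

    def test_memorizing_model_reproduces_training_compound(self, trained_model,
                                                           protein_vec):
        seqs, _ = trained_model.sample_batch(
            np.repeat(protein_vec[None], 50, axis=0), np.full(50, 100),
            np.random.default_rng(0))
        decoded = {trained_model.vocab.decode(s) for s in seqs}
        from tests.conftest import TINY_SMILES
        assert decoded & set(TINY_SMILES)

    def test_incremental_decoder_matches_teacher_forcing(self, trained_model,
                                                         protein_vec):
        """The cached sampling path computes the same distributions as the
        training path (up to float32 inference precision)."""
        model = trained_model
        ids = model.vocab.encode("Cc1cc2ccccc2o1")
        memory = model.encode(protein_vec, 100)
        logits = model.decoder_logits(memory, [model.vocab.start_id] + ids).data
        probs_tf = np.exp(logits - logits.max(-1, keepdims=True))
        probs_tf /= probs_tf.sum(-1, keepdims=True)

        w = model._w32()
        mem = model.encode_batch(protein_vec[None], np.array([100]), w)
        # greedy single-step check at position 0
        x = (w["tok_emb"][np.array([model.vocab.start_id])]
             * np.float32(math.sqrt(model.config.d_model)) + model._pe.astype(
                 np.float32)[0])[:, None, :]
        for i in range(model.config.n_decoder_layers):
            pre = f"dec{i}"
            k = model._np_heads(model._np_linear(w, x, pre + ".sa.k"))
            v = model._np_heads(model._np_linear(w, x, pre + ".sa.v"))
            x = model._np_ln(w, x + model._np_attention(w, x, k, v, pre + ".sa"),
                             pre + ".ln1")
            mk = model._np_heads(model._np_linear(w, mem, pre + ".ca.k"))
            mv = model._np_heads(model._np_linear(w, mem, pre + ".ca.v"))
            x = model._np_ln(w, x + model._np_attention(w, x, mk, mv, pre + ".ca"),
                             pre + ".ln2")
            x = model._np_ln(w, x + model._np_ffn(w, x, pre), pre + ".ln3")
        step_logits = model._np_linear(w, x[:, 0, :], "out")[0]
        p = np.exp(step_logits - step_logits.max())
        p /= p.sum()
        np.testing.assert_allclose(p, probs_tf[0], atol=1e-4)

    def test_per_step_distribution_normalized(self, trained_model, protein_vec):
        model = trained_model
        memory = model.encode(protein_vec, 100)
        logits = model.decoder_logits(memory, [model.vocab.start_id]).data
        p = np.exp(logits - logits.max(-1, keepdims=True))
        p /= p.sum(-1, keepdims=True)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_length_cap_respected(self, tiny_config, tiny_vocab, protein_vec):
        model = BiochemLM(tiny_config, tiny_vocab, seed=3)  # untrained: rambles
        seqs, _ = model.sample_batch(protein_vec[None], np.array([0]),
                                     np.random.default_rng(1), max_len=10)
        assert len(seqs[0]) <= 10


class TestPersistence:
    def test_checkpoint_self_describing_round_trip(self, trained_model, protein_vec,
                                                   tmp_path):
        path = tmp_path / "model.npz"
        trained_model.save(path)
        restored = BiochemLM.load(path)
        ids = trained_model.vocab.encode("CCl")
        l1 = float(trained_model.forward_loss(protein_vec, 5, ids).data)
        l2 = float(restored.forward_loss(protein_vec, 5, ids).data)
        assert l1 == pytest.approx(l2, abs=1e-12)
        assert restored.vocab.token_to_id == trained_model.vocab.token_to_id


def test_overfitting_single_triple_drives_loss_down(tiny_config, tiny_vocab,
                                                    protein_vec):
    """Loss on a memorized example decreases in smoothed trend and the
    memorized SMILES becomes the modal sample."""
    model = BiochemLM(tiny_config, tiny_vocab, seed=0)
    ids = tiny_vocab.encode("CCc1ccc2ccccc2c1")
    opt = Adam(model.params, lr=1e-3)
    losses = []
    for _ in range(400):
        opt.zero_grad()
        loss = model.forward_loss(protein_vec, 100, ids)
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
    smoothed = np.convolve(losses, np.ones(10) / 10, mode="valid")
    diffs = np.diff(smoothed)
    assert (diffs < 0).mean() > 0.8
    assert losses[-1] < 0.05
    seqs, _ = model.sample_batch(np.repeat(protein_vec[None], 20, axis=0),
                                 np.full(20, 100), np.random.default_rng(0))
    decoded = [tiny_vocab.decode(s) for s in seqs]
    assert decoded.count("CCc1ccc2ccccc2c1") >= 12
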