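"""The conditional encoder-decoder transformer over (protein, potency) inputs.

The encoder reads a length-2 sequence of d_model vectors — the pooled
protein embedding and the potency-bin token embedding (length 1 without
conditioning) — through three self-attention + feed-forward layers.  The
decoder autoregressively emits SMILES tokens through three layers of masked
self-attention, cross-attention to the encoder memory, and feed-forward
sublayers, with residual connections and layer normalisation throughout.
The embedder dimension must equal d_model so no information is lost at the
connection between the two components.

Training uses the recorded-tape autodiff engine one sequence at a time
(micro-batch 1); generation uses a batched pure-NumPy incremental decoder
with per-layer key/value caches, drawing tokens multinomially from the
softmax distribution at temperature 1.0 until the end token.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .autodiff import Tensor, attention, linear, get_default_dtype
from .curation import canonical_smiles
from .tokenization import SmilesVocabulary, PotencyBinner

_NEG_INF = -1e30


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The full-scale profile uses d_model 1024 (matching the ProtT5 embedding
    dimension); the desk-scale profile used throughout the tests uses 128.
    """

    n_encoder_layers: int = 3
    n_decoder_layers: int = 3
    d_model: int = 1024
    n_heads: int = 8
    d_feedforward: int | None = None  # defaults to 4 * d_model
    dropout: float = 0.1
    smiles_vocab_size: int = 0
    potency_vocab_size: int = field(default_factory=lambda: PotencyBinner().n_bins)
    conditional: bool = True
    max_len: int = 150

    def __post_init__(self):
        if self.d_feedforward is None:
            self.d_feedforward = 4 * self.d_model
        if self.n_encoder_layers < 1 or self.n_decoder_layers < 1:
            raise ValueError("layer counts must be >= 1")
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"n_heads={self.n_heads} must divide d_model={self.d_model}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @classmethod
    def desk(cls, **kw) -> "ModelConfig":
        """Small CPU profile used for tests and the synthetic-world probe."""
        kw.setdefault("d_model", 128)
        kw.setdefault("n_heads", 2)
        return cls(**kw)

    @property
    def encoder_input_length(self) -> int:
        return 2 if self.conditional else 1


class ConfigurationError(ValueError):
    pass


def sinusoidal_positions(n: int, d: int) -> np.ndarray:
    """Standard sinusoidal positional encodings, shape (n, d)."""
    pos = np.arange(n)[:, None]
    i = np.arange(d // 2)[None, :]
    angles = pos / np.power(10000.0, 2 * i / d)
    pe = np.zeros((n, d))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe


@dataclass
class DecodedCompound:
    """One sampled decoder output."""

    tokens: list[str]
    smiles: str | None  # canonical, or None when the string is not a valid molecule
    log_probability: float

    @property
    def valid(self) -> bool:
        return self.smiles is not None


class BiochemLM:
    """Conditional (or unconditional control) compound generator."""

    def __init__(self, config: ModelConfig, vocab: SmilesVocabulary, seed: int = 0):
        if config.smiles_vocab_size == 0:
            config.smiles_vocab_size = len(vocab)
        if config.smiles_vocab_size != len(vocab):
            raise ConfigurationError("config vocab size disagrees with vocabulary")
        self.config = config
        self.vocab = vocab
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(seed))
        self._pe = sinusoidal_positions(config.max_len + 2, config.d_model).astype(
            get_default_dtype())
        self._mask_cache: dict[int, np.ndarray] = {}

    # -- parameters -----------------------------------------------------------
    def _linear_init(self, rng, name: str, fan_in: int, fan_out: int) -> None:
        self.params[name + ".W"] = Tensor(
            rng.standard_normal((fan_in, fan_out)) / math.sqrt(fan_in), requires_grad=True
        )
        self.params[name + ".b"] = Tensor(np.zeros(fan_out), requires_grad=True)

    def _ln_init(self, name: str, d: int) -> None:
        self.params[name + ".g"] = Tensor(np.ones(d), requires_grad=True)
        self.params[name + ".b"] = Tensor(np.zeros(d), requires_grad=True)

    def _init_params(self, rng) -> None:
        cfg = self.config
        d, ff = cfg.d_model, cfg.d_feedforward
        self.params["tok_emb"] = Tensor(
            rng.standard_normal((cfg.smiles_vocab_size, d)) / math.sqrt(d),
            requires_grad=True,
        )
        if cfg.conditional:
            # separate trainable table for the 852 potency conditioning
            # tokens, initialised sinusoidally over the bin index so nearby
            # potency values start with similar embeddings (bins are ordinal;
            # random rows would make the sparse bins mutually unrelated)
            self.params["pot_emb"] = Tensor(
                sinusoidal_positions(cfg.potency_vocab_size, d) / math.sqrt(d),
                requires_grad=True,
            )
        # learned position vectors for the (short) encoder input
        self.params["enc_pos"] = Tensor(
            rng.standard_normal((cfg.encoder_input_length, d)) * 0.02, requires_grad=True
        )
        for i in range(cfg.n_encoder_layers):
            p = f"enc{i}"
            for sub in ("sa.q", "sa.k", "sa.v", "sa.o"):
                self._linear_init(rng, f"{p}.{sub}", d, d)
            self._linear_init(rng, f"{p}.ff1", d, ff)
            self._linear_init(rng, f"{p}.ff2", ff, d)
            self._ln_init(f"{p}.ln1", d)
            self._ln_init(f"{p}.ln2", d)
        for i in range(cfg.n_decoder_layers):
            p = f"dec{i}"
            for sub in ("sa.q", "sa.k", "sa.v", "sa.o", "ca.q", "ca.k", "ca.v", "ca.o"):
                self._linear_init(rng, f"{p}.{sub}", d, d)
            self._linear_init(rng, f"{p}.ff1", d, ff)
            self._linear_init(rng, f"{p}.ff2", ff, d)
            self._ln_init(f"{p}.ln1", d)
            self._ln_init(f"{p}.ln2", d)
            self._ln_init(f"{p}.ln3", d)
        self._linear_init(rng, "out", d, cfg.smiles_vocab_size)
        self.params["out.W"].data *= 0.1

    def _causal_mask(self, t: int) -> np.ndarray:
        mask = self._mask_cache.get(t)
        if mask is None:
            mask = np.triu(np.full((t, t), _NEG_INF,
                                   dtype=self.params["tok_emb"].data.dtype), k=1)
            self._mask_cache[t] = mask
        return mask

    # -- tape-forward building blocks -----------------------------------------
    def _linear(self, x: Tensor, name: str) -> Tensor:
        return linear(x, self.params[name + ".W"], self.params[name + ".b"])

    def _ln(self, x: Tensor, name: str) -> Tensor:
        return x.layer_norm(self.params[name + ".g"], self.params[name + ".b"])

    def _attention(self, x_q: Tensor, x_kv: Tensor, prefix: str,
                   mask: np.ndarray | None) -> Tensor:
        p = self.params
        return attention(
            x_q, x_kv,
            p[prefix + ".q.W"], p[prefix + ".q.b"], p[prefix + ".k.W"],
            p[prefix + ".k.b"], p[prefix + ".v.W"], p[prefix + ".v.b"],
            p[prefix + ".o.W"], p[prefix + ".o.b"],
            self.config.n_heads, mask,
        )

    def _ffn(self, x: Tensor, prefix: str) -> Tensor:
        return self._linear(self._linear(x, prefix + ".ff1").relu(), prefix + ".ff2")

    def encoder_input(self, protein_vec: np.ndarray,
                      potency_bin: int | None) -> Tensor:
        cfg = self.config
        if protein_vec.shape != (cfg.d_model,):
            raise ConfigurationError(
                f"protein embedding dim {protein_vec.shape} != d_model {cfg.d_model}"
            )
        rows = [Tensor(protein_vec[None, :])]
        if cfg.conditional:
            if potency_bin is None:
                raise ValueError("conditional model requires a potency bin")
            rows.append(self.params["pot_emb"].rows([int(potency_bin)]))
        x = Tensor.concat_rows(rows)
        return x + self.params["enc_pos"]

    def encode(self, protein_vec: np.ndarray, potency_bin: int | None,
               rng: np.random.Generator | None = None) -> Tensor:
        p = self.config.dropout
        x = self.encoder_input(protein_vec, potency_bin).dropout(p, rng)
        for i in range(self.config.n_encoder_layers):
            pre = f"enc{i}"
            x = self._ln(x + self._attention(x, x, pre + ".sa", None).dropout(p, rng),
                         pre + ".ln1")
            x = self._ln(x + self._ffn(x, pre).dropout(p, rng), pre + ".ln2")
        return x

    def decoder_logits(self, memory: Tensor, dec_in: Sequence[int],
                       rng: np.random.Generator | None = None) -> Tensor:
        """Logits (T, V) for decoder input token ids under teacher forcing."""
        cfg = self.config
        t = len(dec_in)
        p = cfg.dropout
        x = self.params["tok_emb"].rows(list(dec_in)) * math.sqrt(cfg.d_model)
        x = (x + Tensor(self._pe[:t])).dropout(p, rng)
        causal = self._causal_mask(t)
        for i in range(cfg.n_decoder_layers):
            pre = f"dec{i}"
            x = self._ln(x + self._attention(x, x, pre + ".sa", causal).dropout(p, rng),
                         pre + ".ln1")
            x = self._ln(x + self._attention(x, memory, pre + ".ca", None).dropout(p, rng),
                         pre + ".ln2")
            x = self._ln(x + self._ffn(x, pre).dropout(p, rng), pre + ".ln3")
        return self._linear(x, "out")

    def forward_loss(self, protein_vec: np.ndarray, potency_bin: int | None,
                     target_ids: Sequence[int],
                     rng: np.random.Generator | None = None) -> Tensor:
        """Mean token cross-entropy of one (embedding, potency, SMILES) triple.

        Teacher forcing: the decoder reads <start> + targets and predicts
        targets + <end>.  Pass `rng` to enable dropout (training mode).
        """
        if len(target_ids) == 0:
            raise ValueError("empty target token sequence")
        memory = self.encode(protein_vec, potency_bin, rng)
        dec_in = [self.vocab.start_id] + list(target_ids)
        dec_tgt = list(target_ids) + [self.vocab.end_id]
        logits = self.decoder_logits(memory, dec_in, rng)
        return logits.cross_entropy(dec_tgt)

    # -- batched tape forward (training) ---------------------------------------
    def encode_chunk(self, protein_vecs: np.ndarray, potency_bins,
                     rng: np.random.Generator | None = None) -> Tensor:
        """Tape encoder for a chunk: (B, d) proteins (+ bins) -> (B, M, d)."""
        cfg = self.config
        p = cfg.dropout
        parts = [Tensor(protein_vecs[:, None, :])]
        if cfg.conditional:
            if potency_bins is None:
                raise ValueError("conditional model requires potency bins")
            b = protein_vecs.shape[0]
            parts.append(self.params["pot_emb"].rows(np.asarray(potency_bins))
                         .reshape(b, 1, cfg.d_model))
        x = Tensor.concat(parts, axis=1) + self.params["enc_pos"]
        x = x.dropout(p, rng)
        for i in range(cfg.n_encoder_layers):
            pre = f"enc{i}"
            x = self._ln(x + self._attention(x, x, pre + ".sa", None).dropout(p, rng),
                         pre + ".ln1")
            x = self._ln(x + self._ffn(x, pre).dropout(p, rng), pre + ".ln2")
        return x

    def forward_loss_chunk(self, protein_vecs: np.ndarray, potency_bins,
                           target_ids: Sequence[Sequence[int]],
                           rng: np.random.Generator | None = None,
                           ) -> tuple[Tensor, np.ndarray]:
        """Mean-over-sequences teacher-forced loss for a chunk of triples.

        Sequences are right-padded; padded positions carry zero loss weight,
        and the causal mask keeps them from influencing real positions.
        Returns the scalar loss (mean over sequences of per-sequence mean
        token cross-entropy — identical to averaging `forward_loss` over the
        chunk) plus the per-sequence losses for logging.
        """
        cfg = self.config
        b = len(target_ids)
        if b == 0 or any(len(t) == 0 for t in target_ids):
            raise ValueError("empty chunk or empty target sequence")
        lens = np.array([len(t) + 1 for t in target_ids])  # + end token
        tmax = int(lens.max())
        dec_in = np.full((b, tmax), self.vocab.pad_id, dtype=np.intp)
        dec_tgt = np.full((b, tmax), self.vocab.pad_id, dtype=np.intp)
        weights = np.zeros((b, tmax))
        for i, ids in enumerate(target_ids):
            seq = [self.vocab.start_id] + list(ids)
            dec_in[i, :len(seq)] = seq
            dec_tgt[i, :len(seq)] = list(ids) + [self.vocab.end_id]
            weights[i, :len(seq)] = 1.0 / (lens[i] * b)

        memory = self.encode_chunk(protein_vecs, potency_bins, rng)
        p = cfg.dropout
        x = self.params["tok_emb"].rows(dec_in) * math.sqrt(cfg.d_model)
        x = (x + Tensor(self._pe[:tmax])).dropout(p, rng)
        causal = self._causal_mask(tmax)
        for i in range(cfg.n_decoder_layers):
            pre = f"dec{i}"
            x = self._ln(x + self._attention(x, x, pre + ".sa", causal).dropout(p, rng),
                         pre + ".ln1")
            x = self._ln(x + self._attention(x, memory, pre + ".ca", None).dropout(p, rng),
                         pre + ".ln2")
            x = self._ln(x + self._ffn(x, pre).dropout(p, rng), pre + ".ln3")
        logits = self._linear(x, "out")
        loss = logits.cross_entropy_weighted(dec_tgt, weights)

        # per-sequence losses for logging, straight from the forward logits
        z = logits.data - logits.data.max(axis=-1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
        picked = np.take_along_axis(logp, dec_tgt[..., None], axis=-1)[..., 0]
        per_seq = -(picked * (weights > 0)).sum(axis=1) / lens
        return loss, per_seq

    # -- batched pure-NumPy inference ------------------------------------------
    # Generation casts the weights to float32 once per call: sampling needs no
    # gradients and the draw is reproducible because the arithmetic is fixed.
    def _w32(self) -> dict[str, np.ndarray]:
        return {k: v.data.astype(np.float32) for k, v in self.params.items()}

    @staticmethod
    def _np_linear(w, x: np.ndarray, name: str) -> np.ndarray:
        return x @ w[name + ".W"] + w[name + ".b"]

    @staticmethod
    def _np_ln(w, x: np.ndarray, name: str) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        xhat = (x - mu) / np.sqrt(var + 1e-5)
        return xhat * w[name + ".g"] + w[name + ".b"]

    def _np_heads(self, x: np.ndarray) -> np.ndarray:
        b, t, d = x.shape
        h = self.config.n_heads
        return x.reshape(b, t, h, d // h).transpose(0, 2, 1, 3)

    def _np_attention(self, w, xq: np.ndarray, k: np.ndarray, v: np.ndarray,
                      prefix: str) -> np.ndarray:
        """Batched attention; k, v already projected and head-split."""
        dh = self.config.d_model // self.config.n_heads
        q = self._np_heads(self._np_linear(w, xq, prefix + ".q"))
        scores = (q @ k.swapaxes(-1, -2)) / math.sqrt(dh)
        scores -= scores.max(axis=-1, keepdims=True)
        p = np.exp(scores)
        p /= p.sum(axis=-1, keepdims=True)
        out = p @ v
        b, h, t, _ = out.shape
        out = out.transpose(0, 2, 1, 3).reshape(b, t, h * dh)
        return self._np_linear(w, out, prefix + ".o")

    def _np_ffn(self, w, x: np.ndarray, prefix: str) -> np.ndarray:
        return self._np_linear(
            w, np.maximum(self._np_linear(w, x, prefix + ".ff1"), 0.0), prefix + ".ff2"
        )

    def encode_batch(self, protein_vecs: np.ndarray,
                     potency_bins: np.ndarray | None,
                     w: dict[str, np.ndarray] | None = None) -> np.ndarray:
        """Encoder memory for a batch: (B, d) proteins (+ (B,) bins) -> (B, M, d)."""
        cfg = self.config
        w = w or self._w32()
        rows = [protein_vecs.astype(np.float32)[:, None, :]]
        if cfg.conditional:
            rows.append(w["pot_emb"][np.asarray(potency_bins)][:, None, :])
        x = np.concatenate(rows, axis=1) + w["enc_pos"][None]
        for i in range(cfg.n_encoder_layers):
            pre = f"enc{i}"
            k = self._np_heads(self._np_linear(w, x, pre + ".sa.k"))
            v = self._np_heads(self._np_linear(w, x, pre + ".sa.v"))
            x = self._np_ln(w, x + self._np_attention(w, x, k, v, pre + ".sa"), pre + ".ln1")
            x = self._np_ln(w, x + self._np_ffn(w, x, pre), pre + ".ln2")
        return x

    def sample_batch(self, protein_vecs: np.ndarray,
                     potency_bins: np.ndarray | None,
                     rng: np.random.Generator,
                     max_len: int | None = None) -> tuple[list[list[int]], np.ndarray]:
        """Draw one token sequence per batch row by multinomial sampling.

        Tokens are drawn from the softmax distribution at temperature 1.0
        step by step until the end token or the length cap.  Returns the
        token-id sequences (without start/end) and their log-probabilities.
        Finished rows are dropped from the working batch as they terminate.
        """
        cfg = self.config
        max_len = max_len or cfg.max_len
        w = self._w32()
        b = protein_vecs.shape[0]
        memory = self.encode_batch(protein_vecs, potency_bins, w)
        mem_kv = []
        for i in range(cfg.n_decoder_layers):
            pre = f"dec{i}.ca"
            mem_kv.append([self._np_heads(self._np_linear(w, memory, pre + ".k")),
                           self._np_heads(self._np_linear(w, memory, pre + ".v"))])
        self_kv: list[list[np.ndarray] | None] = [None] * cfg.n_decoder_layers

        pe32 = self._pe.astype(np.float32)
        scale = np.float32(math.sqrt(cfg.d_model))
        active = np.arange(b)                       # original row of each working row
        cur = np.full(b, self.vocab.start_id, dtype=np.intp)
        logprob = np.zeros(b)
        seqs: list[list[int]] = [[] for _ in range(b)]
        end_id, vmax = self.vocab.end_id, 0
        for step in range(max_len + 1):
            x = (w["tok_emb"][cur] * scale + pe32[step])[:, None, :]
            for i in range(cfg.n_decoder_layers):
                pre = f"dec{i}"
                k_new = self._np_heads(self._np_linear(w, x, pre + ".sa.k"))
                v_new = self._np_heads(self._np_linear(w, x, pre + ".sa.v"))
                if self_kv[i] is None:
                    self_kv[i] = [k_new, v_new]
                else:
                    self_kv[i] = [np.concatenate([self_kv[i][0], k_new], axis=2),
                                  np.concatenate([self_kv[i][1], v_new], axis=2)]
                x = self._np_ln(
                    w, x + self._np_attention(w, x, *self_kv[i], pre + ".sa"), pre + ".ln1"
                )
                x = self._np_ln(
                    w, x + self._np_attention(w, x, *mem_kv[i], pre + ".ca"), pre + ".ln2"
                )
                x = self._np_ln(w, x + self._np_ffn(w, x, pre), pre + ".ln3")
            logits = self._np_linear(w, x[:, 0, :], "out").astype(np.float64)
            logits -= logits.max(axis=-1, keepdims=True)
            probs = np.exp(logits)
            probs /= probs.sum(axis=-1, keepdims=True)
            # vectorized multinomial draw via inverse CDF
            u = rng.random(len(active))
            nxt = (probs.cumsum(axis=-1) < u[:, None]).sum(axis=-1).astype(np.intp)
            nxt = np.minimum(nxt, probs.shape[-1] - 1)
            step_lp = np.log(np.maximum(probs[np.arange(len(active)), nxt], 1e-300))
            done = nxt == end_id
            if step == max_len:
                done[:] = True  # length cap: discard the overflow token
                keep_lp = nxt == end_id
                logprob[active[keep_lp]] += step_lp[keep_lp]
            else:
                logprob[active] += step_lp
                for j in np.flatnonzero(~done):
                    seqs[active[j]].append(int(nxt[j]))
            if done.all():
                break
            if done.any():
                live = ~done
                active = active[live]
                nxt = nxt[live]
                for i in range(cfg.n_decoder_layers):
                    self_kv[i] = [self_kv[i][0][live], self_kv[i][1][live]]
                    mem_kv[i] = [mem_kv[i][0][live], mem_kv[i][1][live]]
            cur = nxt
        return seqs, logprob

    def sample(self, protein_vec: np.ndarray, potency_bin: int | None,
               max_len: int | None = None, seed: int = 0) -> DecodedCompound:
        """Sample a single compound (seeded, reproducible)."""
        rng = np.random.default_rng(seed)
        bins = None if not self.config.conditional else np.asarray([potency_bin])
        seqs, lp = self.sample_batch(protein_vec[None], bins, rng, max_len)
        toks = [self.vocab.id_to_token[i] for i in seqs[0]]
        smi = canonical_smiles(self.vocab.decode(seqs[0])) if seqs[0] else None
        return DecodedCompound(tokens=toks, smiles=smi, log_probability=float(lp[0]))

    # -- persistence ------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = state[k].copy()

    def save(self, path: str | Path) -> None:
        """Self-describing checkpoint: config + vocabulary + weights."""
        meta = json.dumps({"config": asdict(self.config), "vocab": self.vocab.token_to_id})
        arrays = {k: v.data for k, v in self.params.items()}
        with open(path, "wb") as fh:
            np.savez(fh, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "BiochemLM":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            model = cls(ModelConfig(**meta["config"]),
                        SmilesVocabulary.from_json(json.dumps(meta["vocab"])))
            model.load_state_dict({k: npz[k] for k in npz.files if k != "__meta__"})
        return model


def build_model(config: ModelConfig, vocab: SmilesVocabulary, seed: int = 0,
                embedder_dim: int | None = None) -> BiochemLM:
    """Instantiate the generator, checking the embedder/d_model contract."""
    if embedder_dim is not None and embedder_dim != config.d_model:
        raise ConfigurationError(
            f"embedder dimension {embedder_dim} != d_model {config.d_model}; "
            "the connection between the two components must preserve dimensionality"
        )
    return BiochemLM(config, vocab, seed=seed)
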