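"""Pre-training on pooled target-compound triples and per-class fine-tuning.

Training minimises teacher-forced cross-entropy with Adam at micro-batch 1
and gradient accumulation to an effective batch of 64.  A checkpoint is
recorded at the end of every epoch and the final model is the one with
minimal cross-entropy loss (ties broken by earliest epoch).  Fine-tuning
updates all weights with the same procedure; tokens absent from the
pre-trained vocabulary map to ``<unk>`` with a warning.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .autodiff import Adam
from .model import BiochemLM, ModelConfig
from .tokenization import SmilesVocabulary

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Triple:
    """One training example: (protein embedding, potency bin, compound)."""

    target_id: str
    protein_vec: np.ndarray
    potency_bin: int
    smiles: str


@dataclass
class TrainingPlan:
    """Optimisation schedule.

    The full-scale profile is Adam at learning rate 1e-5 with micro-batch 1
    accumulated to an effective batch of 64, for at least 50 epochs.  The
    desk profile used by tests raises the learning rate and shortens the run
    to suit tiny corpora (see docs/methods.md).
    """

    learning_rate: float = 1e-5
    micro_batch: int = 1
    grad_accumulation: int = 64
    epochs: int = 50
    seed: int = 0
    dropout_enabled: bool = True
    checkpoint_dir: str | Path | None = None

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.micro_batch != 1:
            raise ValueError("training processes one sequence at a time (micro-batch 1)")

    @property
    def effective_batch(self) -> int:
        return self.micro_batch * self.grad_accumulation

    @classmethod
    def desk(cls, **kw) -> "TrainingPlan":
        kw.setdefault("learning_rate", 1e-3)
        kw.setdefault("grad_accumulation", 8)
        kw.setdefault("epochs", 20)
        return cls(**kw)


@dataclass
class Checkpoint:
    """Model weights at the end of one epoch together with its loss."""

    epoch: int
    loss: float
    state: dict[str, np.ndarray]
    config: ModelConfig
    vocab: SmilesVocabulary
    loss_log: list[float] = field(default_factory=list)

    def build(self) -> BiochemLM:
        model = BiochemLM(copy.deepcopy(self.config), self.vocab)
        model.load_state_dict(self.state)
        return model


def _encode_triples(triples: Sequence[Triple], vocab: SmilesVocabulary,
                    warn_unknown: bool = False):
    enc = []
    for t in triples:
        ids = vocab.encode(t.smiles, warn_unknown=warn_unknown)
        enc.append((t.protein_vec, t.potency_bin, ids))
    return enc


def _run_epochs(model: BiochemLM, triples: Sequence[Triple], plan: TrainingPlan,
                start_epoch: int = 0) -> Checkpoint:
    if not triples:
        raise ValueError("no training triples")
    vocab = model.vocab
    encoded = _encode_triples(triples, vocab, warn_unknown=start_epoch > 0)
    vecs = np.stack([e[0] for e in encoded])
    bins = np.array([e[1] for e in encoded])
    opt = Adam(model.params, lr=plan.learning_rate)
    rng = np.random.default_rng(plan.seed)
    drop_rng = np.random.default_rng(plan.seed + 1) if plan.dropout_enabled else None
    conditional = model.config.conditional

    ckpt_dir = Path(plan.checkpoint_dir) if plan.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    best: Checkpoint | None = None
    loss_log: list[float] = []
    order = np.arange(len(encoded))
    for epoch in range(plan.epochs):
        rng.shuffle(order)
        total = 0.0
        # each accumulation group is evaluated as one padded chunk; the
        # gradient equals accumulating micro-batch-1 gradients scaled 1/N
        # (asserted exactly in the test suite)
        for lo in range(0, len(order), plan.grad_accumulation):
            idx = order[lo:lo + plan.grad_accumulation]
            opt.zero_grad()
            loss, per_seq = model.forward_loss_chunk(
                vecs[idx], bins[idx] if conditional else None,
                [encoded[i][2] for i in idx], rng=drop_rng)
            if not np.all(np.isfinite(per_seq)):
                bad = idx[int(np.argmax(~np.isfinite(per_seq)))]
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} on example "
                    f"({triples[bad].target_id}: {triples[bad].smiles})"
                )
            loss.backward()
            opt.step()
            total += float(per_seq.sum())
        mean_loss = total / len(encoded)
        loss_log.append(mean_loss)
        logger.info("epoch %d: loss %.5f", start_epoch + epoch, mean_loss)
        if ckpt_dir:
            model.save(ckpt_dir / f"epoch{start_epoch + epoch:04d}.npz")
        if best is None or mean_loss < best.loss:
            best = Checkpoint(
                epoch=start_epoch + epoch, loss=mean_loss, state=model.state_dict(),
                config=model.config, vocab=vocab,
            )
    if best is None:  # zero-epoch run: checkpoint equals the input model
        best = Checkpoint(epoch=start_epoch - 1, loss=float("nan"),
                          state=model.state_dict(), config=model.config, vocab=vocab)
    best.loss_log = loss_log
    if ckpt_dir:
        (ckpt_dir / "loss.log").write_text(
            "".join(f"{start_epoch + i}\t{l:.6f}\n" for i, l in enumerate(loss_log))
        )
    return best


def pretrain(triples: Sequence[Triple], plan: TrainingPlan, config: ModelConfig,
             init_seed: int | None = None,
             vocab: SmilesVocabulary | None = None) -> Checkpoint:
    """Train from random initialisation on the pooled corpus.

    The SMILES vocabulary is corpus-derived: by default from the pre-training
    triples, or pass `vocab` built from the full training data (pre-training
    plus fine-tuning compounds) so later fine-tuning stages are covered.
    Returns the minimum-loss epoch checkpoint.
    """
    if not triples:
        raise ValueError("pretrain requires at least one triple")
    if vocab is None:
        vocab = SmilesVocabulary.from_corpus(t.smiles for t in triples)
    model = BiochemLM(replace(config, smiles_vocab_size=len(vocab)), vocab,
                      seed=plan.seed if init_seed is None else init_seed)
    return _run_epochs(model, triples, plan)


def finetune(checkpoint: Checkpoint, class_triples: Sequence[Triple],
             plan: TrainingPlan) -> Checkpoint:
    """Continue training all weights on one activity class.

    With ``plan.epochs == 0`` the input checkpoint is returned unchanged
    (the no-fine-tuning control path).
    """
    if plan.epochs == 0:
        return checkpoint
    model = checkpoint.build()
    return _run_epochs(model, class_triples, plan, start_epoch=checkpoint.epoch + 1)


def batch_loss(model: BiochemLM, triples: Sequence[Triple]):
    """Mean of per-sequence losses over a batch, as one differentiable scalar."""
    encoded = _encode_triples(triples, model.vocab)
    conditional = model.config.conditional
    total = None
    for vec, pbin, ids in encoded:
        loss = model.forward_loss(vec, pbin if conditional else None, ids)
        total = loss if total is None else total + loss
    return total * (1.0 / len(encoded))
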