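"""Tokenizers for the three input modalities.

Protein sequences are tokenized per residue over a 21-symbol vocabulary
(20 natural amino acids plus ``X`` for rare residues).  SMILES strings are
tokenized greedily left to right: bracketed expressions (``[nH]``, ``[O-]``)
and the two-character organic-subset halogens (``Cl``, ``Br``) are single
tokens, as are ``%nn`` ring-closure labels.  Potency values (pKi) are
discretized into 852 conditioning bins of width 0.01 spanning the globally
observed range [4.00, 12.52].
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

# 20 natural amino acids, alphabetical one-letter codes, plus "X" for rare residues.
NATURAL_AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_TOKENS = NATURAL_AMINO_ACIDS + ("X",)

START, END, PAD, UNK = "<start>", "<end>", "<pad>", "<unk>"

_SMILES_TOKEN = re.compile(r"\[[^\[\]]*\]|Br|Cl|%\d{2}|.")


class TokenizationError(ValueError):
    pass


def tokenize_protein(seq: str) -> list[str]:
    """One token per residue; nonstandard residues collapse to ``X``."""
    if not seq:
        raise TokenizationError("empty protein sequence")
    out = []
    for ch in seq.upper():
        out.append(ch if ch in NATURAL_AMINO_ACIDS else "X")
    return out


def tokenize_smiles(s: str) -> list[str]:
    """Greedy left-to-right SMILES tokenization.

    Raises :class:`TokenizationError` naming the offending position for
    unbalanced brackets.
    """
    tokens: list[str] = []
    pos = 0
    for m in _SMILES_TOKEN.finditer(s):
        tok = m.group(0)
        if tok == "[":
            raise TokenizationError(f"unbalanced '[' at position {m.start()} in {s!r}")
        if tok == "]":
            raise TokenizationError(f"unbalanced ']' at position {m.start()} in {s!r}")
        tokens.append(tok)
        pos = m.end()
    if pos != len(s):  # pragma: no cover - finditer covers the string
        raise TokenizationError(f"could not tokenize {s!r} past position {pos}")
    return tokens


def detokenize(tokens: Sequence[str]) -> str:
    """Concatenate tokens between the start marker and the first end marker."""
    out: list[str] = []
    for tok in tokens:
        if tok in (START, PAD):
            continue
        if tok == END:
            break
        out.append(tok)
    return "".join(out)


@dataclass(frozen=True)
class ProteinVocabulary:
    """The 21 residue tokens (special markers excluded)."""

    tokens: tuple[str, ...] = PROTEIN_TOKENS

    def __len__(self) -> int:
        return len(self.tokens)


class SmilesVocabulary:
    """Corpus-derived SMILES token vocabulary with special markers.

    Ids 0-3 are reserved for ``<pad>``, ``<start>``, ``<end>`` and ``<unk>``;
    unseen tokens at inference map to ``<unk>``.
    """

    SPECIALS = (PAD, START, END, UNK)

    def __init__(self, tokens: Iterable[str]):
        ordered = sorted(set(tokens) - set(self.SPECIALS))
        self.id_to_token: list[str] = list(self.SPECIALS) + ordered
        self.token_to_id: dict[str, int] = {t: i for i, t in enumerate(self.id_to_token)}

    @classmethod
    def from_corpus(cls, smiles: Iterable[str]) -> "SmilesVocabulary":
        toks: set[str] = set()
        for s in smiles:
            toks.update(tokenize_smiles(s))
        return cls(toks)

    def __len__(self) -> int:
        return len(self.id_to_token)

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def start_id(self) -> int:
        return self.token_to_id[START]

    @property
    def end_id(self) -> int:
        return self.token_to_id[END]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    def encode(self, s: str, warn_unknown: bool = False) -> list[int]:
        """Token ids for a SMILES string, without start/end markers."""
        ids = []
        for tok in tokenize_smiles(s):
            i = self.token_to_id.get(tok)
            if i is None:
                if warn_unknown:
                    logger.warning("token %r not in vocabulary; mapped to <unk>", tok)
                i = self.unk_id
            ids.append(i)
        return ids

    def decode(self, ids: Sequence[int]) -> str:
        return detokenize([self.id_to_token[i] for i in ids])

    def to_json(self) -> str:
        return json.dumps(self.token_to_id)

    @classmethod
    def from_json(cls, text: str) -> "SmilesVocabulary":
        mapping = json.loads(text)
        vocab = cls.__new__(cls)
        vocab.id_to_token = [t for t, _ in sorted(mapping.items(), key=lambda kv: kv[1])]
        vocab.token_to_id = dict(mapping)
        return vocab


@dataclass(frozen=True)
class PotencyBinner:
    """Discretize pKi into conditioning-token bins.

    The globally observed potency range [4.00, 12.52] pKi units is divided
    into 852 bins of constant width 0.01 — the resolution of experimental
    potency annotations.  Bins are half-open ``[lo + k*w, lo + (k+1)*w)``
    with the top bin closed at ``hi``; out-of-range values are clamped with
    a warning rather than rejected, since new data may fall outside the
    historically observed range.
    """

    lo: float = 4.00
    hi: float = 12.52
    width: float = 0.01

    # guards against 0.01 not being exactly representable in binary
    _EPS: float = field(default=1e-9, repr=False)

    @property
    def n_bins(self) -> int:
        return int(round((self.hi - self.lo) / self.width))

    def bin(self, pki: float) -> int:
        if math.isnan(pki):
            raise ValueError("pKi is NaN")
        if pki < self.lo or pki > self.hi:
            logger.warning("pKi %.4f outside [%.2f, %.2f]; clamped", pki, self.lo, self.hi)
            pki = min(max(pki, self.lo), self.hi)
        idx = int(math.floor((pki - self.lo) / self.width + self._EPS))
        return min(idx, self.n_bins - 1)

    def bin_center(self, idx: int) -> float:
        if not 0 <= idx < self.n_bins:
            raise ValueError(f"bin index {idx} out of range")
        return self.lo + (idx + 0.5) * self.width
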