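"""Fixed-size protein-sequence embeddings behind a pluggable backend contract.

The generator consumes one pooled vector per target, so any backend that
maps a residue string to a fixed-dimension vector can drive the model.  The
built-in backend hashes overlapping 3-mers (taken circularly, so repeating
a sequence leaves the normalized profile unchanged) into an 8000-slot
profile, projects it with a seed-determined fixed random matrix and
L2-normalizes — fully deterministic, no downloads.  A ProtT5 adapter is
provided for environments where the `transformers` ProtTrans weights are
installed; the embedder is inference-only and never trained.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

MAX_SEQUENCE_LENGTH = 4000
_PROFILE_SLOTS = 8000


@dataclass(frozen=True)
class ProteinEmbedding:
    target_id: str
    vector: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("embedding contains non-finite entries")


@runtime_checkable
class EmbedderBackend(Protocol):
    """Contract every embedding backend satisfies."""

    name: str
    dim: int
    deterministic: bool

    def embed(self, seq: str) -> np.ndarray:  # pragma: no cover - protocol
        ...


class BuiltinKmerEmbedder:
    """Deterministic 3-mer-profile embedder.

    Overlapping 3-mers are taken circularly (the window wraps around the
    sequence end), hashed with CRC-32 into a fixed 8000-slot count profile,
    projected to `dim` dimensions by a fixed Gaussian matrix drawn from
    `seed`, and L2-normalized.  Identical (seq, dim, seed) gives bitwise
    identical vectors, and a sequence repeated k times maps to exactly the
    same vector as the original (every circular 3-mer count scales by k,
    which the normalization removes).
    """

    deterministic = True

    def __init__(self, dim: int = 1024, seed: int = 7):
        if dim < 8:
            raise ValueError("embedding dimension must be >= 8")
        self.dim = dim
        self.seed = seed
        self.name = f"builtin-kmer-d{dim}-s{seed}"
        self._projection: np.ndarray | None = None

    def _matrix(self) -> np.ndarray:
        if self._projection is None:
            rng = np.random.default_rng(self.seed)
            self._projection = rng.standard_normal((_PROFILE_SLOTS, self.dim)) / np.sqrt(
                _PROFILE_SLOTS
            )
        return self._projection

    def profile(self, seq: str) -> np.ndarray:
        """Circular 3-mer count profile over 8000 hash slots."""
        if not seq:
            raise ValueError("empty sequence")
        seq = seq.upper()
        ext = seq + seq[:2]  # wrap the 3-mer window
        counts = np.zeros(_PROFILE_SLOTS)
        for i in range(len(seq)):
            kmer = ext[i:i + 3]
            counts[zlib.crc32(kmer.encode()) % _PROFILE_SLOTS] += 1.0
        return counts

    def embed(self, seq: str) -> np.ndarray:
        v = self.profile(seq) @ self._matrix()
        norm = np.linalg.norm(v)
        if norm == 0.0:  # pragma: no cover - cannot happen with nonzero counts
            return v
        return v / norm


class ProtT5Embedder:
    """Adapter for the ProtTrans ProtT5-XL-UniRef50 model (optional backend).

    Mean-pools the last hidden state along the length axis.  Requires the
    `transformers` package and the pre-trained weights; this class only
    performs inference and exposes no trainable state.
    """

    deterministic = True
    name = "prott5-xl-uniref50"
    dim = 1024

    def __init__(self):
        try:
            import transformers  # noqa: F401
        except ImportError as exc:
            raise RuntimeError(
                "backend 'prott5-xl-uniref50' unavailable: the 'transformers' "
                "package is not installed"
            ) from exc
        raise NotImplementedError(
            "ProtT5 weights must be supplied locally; see docs/methods.md"
        )


def embed_sequence(seq: str, backend: EmbedderBackend,
                   target_id: str = "") -> ProteinEmbedding:
    """Embed one protein sequence with the given backend.

    The per-residue representations of the backend are pooled (mean) along
    the length dimension into a single fixed-size vector.
    """
    if not 1 <= len(seq) <= MAX_SEQUENCE_LENGTH:
        raise ValueError(
            f"sequence length {len(seq)} outside [1, {MAX_SEQUENCE_LENGTH}]"
        )
    return ProteinEmbedding(target_id=target_id, vector=np.asarray(backend.embed(seq)))


class EmbeddingCache:
    """One protein, one vector: embeddings keyed by (backend, sequence hash).

    Optionally persisted to a directory of .npy files so repeated runs and
    all triples of a target reuse the same computation.
    """

    def __init__(self, backend: EmbedderBackend, directory: str | Path | None = None):
        self.backend = backend
        self.directory = Path(directory) if directory else None
        if self.directory:
            self.directory.mkdir(parents=True, exist_ok=True)
        self._mem: dict[str, np.ndarray] = {}

    def _key(self, seq: str) -> str:
        h = hashlib.sha1(seq.upper().encode()).hexdigest()[:16]
        return f"{self.backend.name}-{h}"

    def get(self, seq: str) -> np.ndarray:
        key = self._key(seq)
        if key in self._mem:
            return self._mem[key]
        if self.directory:
            fn = self.directory / f"{key}.npy"
            if fn.exists():
                vec = np.load(fn)
                self._mem[key] = vec
                return vec
        vec = embed_sequence(seq, self.backend).vector
        self._mem[key] = vec
        if self.directory:
            np.save(self.directory / f"{key}.npy", vec)
        return vec
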