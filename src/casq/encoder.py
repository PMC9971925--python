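"""Text-to-embedding contract and the deterministic reference encoder.

All composition math downstream (path, entity and query embeddings) is
defined over any encoder satisfying :class:`Encoder`: a deterministic map
from non-empty text to a fixed-dimension real vector.  Production use plugs
in a pretrained sentence-transformer behind the same contract; the test and
default backend is :class:`ReferenceEncoder`, a seeded character-trigram
hashing encoder whose geometry is analytically predictable — texts sharing
surface vocabulary land on overlapping hash buckets and score positive
cosine, disjoint vocabularies score (near) zero.

The reference encoder emits unit-norm vectors, mirroring cosine-optimised
sentence encoders.  Composition operations must not rely on that: averages
of unit vectors are not unit vectors.
"""

from __future__ import annotations

import hashlib
from typing import Protocol, runtime_checkable

import numpy as np

from .errors import ConfigurationError, ValidationError

Embedding = np.ndarray  # 1-D float64 vector; finite entries


@runtime_checkable
class Encoder(Protocol):
    """Deterministic text encoder: identical text -> identical vector."""

    dim: int

    def encode(self, text: str) -> Embedding: ...


def _validate_text(text: str) -> str:
    if not text or not text.strip():
        raise ValidationError("cannot encode empty text")
    return text


class ReferenceEncoder:
    """Seeded character-trigram hashing encoder with signed buckets.

    The lowercased text is decomposed into character trigrams; each trigram
    is hashed (keyed BLAKE2b, so identical across machines and runs) to a
    bucket index and a sign, counts are accumulated, and the vector is
    scaled to unit norm.  Texts shorter than three characters contribute the
    whole text as a single token.
    """

    def __init__(self, dim: int = 64, seed: int = 0):
        if dim < 8:
            raise ConfigurationError(f"reference encoder dim must be >= 8, got {dim}")
        self.dim = int(dim)
        self.seed = int(seed)
        self._key = self.seed.to_bytes(8, "little", signed=False)

    def _tokens(self, text: str) -> list[str]:
        t = text.lower()
        if len(t) < 3:
            return [t]
        return [t[i:i + 3] for i in range(len(t) - 2)]

    def _bucket(self, token: str) -> tuple[int, float]:
        digest = hashlib.blake2b(token.encode("utf-8"), digest_size=8, key=self._key).digest()
        value = int.from_bytes(digest, "little")
        return value % self.dim, 1.0 if (value >> 32) & 1 else -1.0

    def encode(self, text: str) -> Embedding:
        text = _validate_text(text)
        v = np.zeros(self.dim, dtype=np.float64)
        for token in self._tokens(text):
            idx, sign = self._bucket(token)
            v[idx] += sign
        norm = float(np.linalg.norm(v))
        if norm == 0.0:
            # adversarial cancellation: fall back to a deterministic one-hot
            idx, sign = self._bucket("\x00" + text.lower())
            v[idx] = sign
            norm = 1.0
        return v / norm


def make_encoder(kind: str = "reference", dim: int = 64, seed: int = 0, model: str | None = None) -> Encoder:
    """Encoder factory used by configuration and the CLI.

    ``kind='external'`` expects a sentence-transformers model name and
    requires that optional dependency; ``reference`` needs nothing.
    """
    if kind == "reference":
        return ReferenceEncoder(dim=dim, seed=seed)
    if kind == "external":
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:
            raise ConfigurationError("external encoder requires sentence-transformers") from exc

        class _Adapter:
            def __init__(self, name: str):
                self._model = SentenceTransformer(name)
                self.dim = int(self._model.get_sentence_embedding_dimension())

            def encode(self, text: str) -> Embedding:
                _validate_text(text)
                return np.asarray(self._model.encode(text), dtype=np.float64)

        return _Adapter(model or "multi-qa-MiniLM-L6-cos-v1")
    raise ConfigurationError(f"unknown encoder kind {kind!r}")
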