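"""Entity-embedding composition and the managed embedding list.

The composition model
---------------------

For one root-to-class path, let ``e_c`` be the mean of the ontology class's
feature embeddings (preferred label + synonyms) and ``e_p`` the mean of the
path's predicate-phrase embeddings.  The path embedding blends the two with
a predicate weight ``w_p`` in [0, 1]::

    e_pt = (e_c + w_p * e_p) / (1 + w_p)

so the class always dominates and ``w_p = 0`` ignores predicates entirely.
The entity embedding is the plain average of its path embeddings.  Two
standard lists are built from the same corpus: ``L1`` with ``w_p = 0`` and
``L2`` with ``w_p = 0.22`` — small against the class weight of 1 but enough
to register the predicates.

Entity embeddings are stored unnormalised; cosine similarity at query time
divides by magnitudes, so no information is lost.  Composition runs in
float64; the on-disk store is float32 with a documented round-trip tolerance
of 1e-6.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path as FsPath

import numpy as np

from .annotation_graph import CompositeAnnotation
from .encoder import Embedding, Encoder
from .errors import CorpusError, LookupError_, ValidationError
from .lexicon import Lexicon

log = logging.getLogger(__name__)

STORE_DTYPE = np.float32
STORE_RTOL = 1e-6  # float32 round-trip tolerance


def cosine_similarity(a: Embedding, b: Embedding) -> float:
    """Cosine similarity ``a.b / (|a||b|)``; undefined for zero vectors."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValidationError(f"dim mismatch: {a.shape} vs {b.shape}")
    na, nb = float(np.linalg.norm(a)), float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        raise ValidationError("cosine similarity is undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


@dataclass(frozen=True)
class PathEmbeddingParams:
    """Predicate weight for path composition; 0 <= w_p <= 1."""

    w_p: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.w_p <= 1.0:
            raise ValidationError(f"w_p must be in [0, 1], got {self.w_p}")


def class_embedding(features: list[str], encoder: Encoder) -> Embedding:
    """Mean of the encodings of a class's feature texts."""
    if not features:
        raise ValidationError("class features must be non-empty")
    return np.mean([encoder.encode(f) for f in features], axis=0)


def predicate_embedding(predicates: list[str], encoder: Encoder) -> Embedding:
    """Mean of the encodings of a path's normalized predicate phrases."""
    if not predicates:
        raise ValidationError("predicate list must be non-empty")
    return np.mean([encoder.encode(p) for p in predicates], axis=0)


def path_embedding(e_c: Embedding, e_p: Embedding | None, params: PathEmbeddingParams) -> Embedding:
    """Blend class and predicate embeddings: ``(e_c + w_p * e_p)/(1 + w_p)``.

    With no predicates on the path (``e_p`` absent) or ``w_p = 0`` the result
    is exactly ``e_c``.
    """
    if e_p is None or params.w_p == 0.0:
        return np.array(e_c, dtype=np.float64, copy=True)
    e_c = np.asarray(e_c, dtype=np.float64)
    e_p = np.asarray(e_p, dtype=np.float64)
    if e_c.shape != e_p.shape:
        raise ValidationError(f"dim mismatch: {e_c.shape} vs {e_p.shape}")
    return (e_c + params.w_p * e_p) / (1.0 + params.w_p)


def entity_embedding(
    annotation: CompositeAnnotation,
    lexicon: Lexicon,
    encoder: Encoder,
    params: PathEmbeddingParams,
) -> Embedding:
    """Average of the entity's path embeddings."""
    if not annotation.paths:
        raise ValidationError(f"entity {annotation.entity_id} has no paths; cannot embed")
    parts = []
    for path in annotation.paths:
        e_c = class_embedding(lexicon.features_or_fallback(path.class_id), encoder)
        e_p = predicate_embedding(list(path.predicates), encoder) if path.predicates else None
        parts.append(path_embedding(e_c, e_p, params))
    return np.mean(parts, axis=0)


@dataclass
class EmbeddingList:
    """Ordered store of (entity_id, embedding) rows built under one ``w_p``.

    The list structure keeps index maintenance cheap: append, replace and
    delete touch single rows, with no inverted-index bookkeeping.
    """

    name: str
    w_p: float
    entity_ids: list[str] = field(default_factory=list)
    matrix: np.ndarray = field(default_factory=lambda: np.empty((0, 0), dtype=np.float64))
    class_ids: list[str] = field(default_factory=list)  # distinct classes of the indexed corpus

    def __len__(self) -> int:
        return len(self.entity_ids)

    @property
    def dim(self) -> int:
        return int(self.matrix.shape[1]) if self.matrix.size else 0

    def index_of(self, entity_id: str) -> int:
        try:
            return self.entity_ids.index(entity_id)
        except ValueError:
            raise LookupError_(entity_id) from None

    def embedding_of(self, entity_id: str) -> Embedding:
        return self.matrix[self.index_of(entity_id)]

    def upsert(self, entity_id: str, embedding: Embedding) -> None:
        """Replace an existing row in place, or append a new one."""
        embedding = np.asarray(embedding, dtype=np.float64)
        if self.matrix.size and embedding.shape != (self.matrix.shape[1],):
            raise ValidationError(f"dim mismatch: {embedding.shape} vs dim {self.matrix.shape[1]}")
        if entity_id in self.entity_ids:
            self.matrix[self.entity_ids.index(entity_id)] = embedding
        else:
            self.entity_ids.append(entity_id)
            if self.matrix.size == 0:
                self.matrix = embedding[None, :].copy()
            else:
                self.matrix = np.vstack([self.matrix, embedding])

    def remove(self, entity_id: str) -> None:
        i = self.index_of(entity_id)
        del self.entity_ids[i]
        self.matrix = np.delete(self.matrix, i, axis=0)


def build_list(
    corpus: list[CompositeAnnotation],
    lexicon: Lexicon,
    encoder: Encoder,
    params: PathEmbeddingParams,
    name: str = "L1",
) -> EmbeddingList:
    """Embed every embeddable entity of a corpus, preserving input order.

    Entities without paths are skipped with a log entry; duplicate entity
    ids are a hard corpus error.
    """
    seen = set()
    for ann in corpus:
        if ann.entity_id in seen:
            raise CorpusError(f"duplicate entity_id {ann.entity_id!r} in corpus")
        seen.add(ann.entity_id)

    ids, rows = [], []
    classes: list[str] = []
    for ann in corpus:
        if not ann.embeddable:
            log.warning("skipping entity %s: no ontology-class paths", ann.entity_id)
            continue
        ids.append(ann.entity_id)
        rows.append(entity_embedding(ann, lexicon, encoder, params))
        for p in ann.paths:
            if p.class_id not in classes:
                classes.append(p.class_id)
    matrix = np.vstack(rows) if rows else np.empty((0, encoder.dim), dtype=np.float64)
    return EmbeddingList(name=name, w_p=params.w_p, entity_ids=ids, matrix=matrix, class_ids=classes)


def save_list(elist: EmbeddingList, path: str | FsPath) -> None:
    """Persist as a JSON sidecar plus a flat float32 row-major matrix."""
    path = FsPath(path)
    binary = path.with_suffix(path.suffix + ".bin")
    sidecar = {
        "name": elist.name,
        "w_p": elist.w_p,
        "dim": elist.dim,
        "entity_ids": elist.entity_ids,
        "class_ids": elist.class_ids,
        "matrix_file": binary.name,
        "dtype": "float32",
    }
    path.write_text(json.dumps(sidecar, sort_keys=True, indent=None))
    binary.write_bytes(np.ascontiguousarray(elist.matrix, dtype=STORE_DTYPE).tobytes())


def load_list(path: str | FsPath) -> EmbeddingList:
    path = FsPath(path)
    sidecar = json.loads(path.read_text())
    binary = path.parent / sidecar["matrix_file"]
    raw = np.frombuffer(binary.read_bytes(), dtype=STORE_DTYPE)
    n, dim = len(sidecar["entity_ids"]), sidecar["dim"]
    matrix = raw.reshape(n, dim).astype(np.float64) if n else np.empty((0, dim), dtype=np.float64)
    return EmbeddingList(
        name=sidecar["name"],
        w_p=sidecar["w_p"],
        entity_ids=list(sidecar["entity_ids"]),
        matrix=matrix,
        class_ids=list(sidecar.get("class_ids", [])),
    )
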