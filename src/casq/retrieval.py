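"""Cosine ranking over embedding lists and the seven retrieval variants.

Variants pair a query-embedding method with an entity list: ``macro``,
``micro`` and ``mixed`` search ``L1`` (predicates ignored, ``w_p = 0``);
their ``WP`` counterparts search ``L2`` (``w_p = 0.22``) and additionally
fold auxiliary phrases into the query.  ``mixedCl`` routes each query to L1
or L2 through a query classifier and then behaves as ``mixed``/``mixedWP``.

The classifier is a pluggable contract; the shipped baseline is a
nearest-centroid model over query embeddings, trained on labels produced by
:func:`generate_qc_labels` (each training query is labelled with whichever
list gives it the higher AP@10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .embedding_core import EmbeddingList, cosine_similarity
from .encoder import Encoder
from .errors import ConfigurationError, ValidationError
from .lexicon import Lexicon
from .query_pipeline import Extractor, QueryEmbeddingParams, class_embedding_matrix, query_embedding

__all__ = [
    "RankedResult",
    "ListChoice",
    "cosine_similarity",
    "search",
    "generate_qc_labels",
    "NearestCentroidQueryClassifier",
    "classify_query",
    "retrieve",
    "VARIANTS",
]

log = logging.getLogger(__name__)


@dataclass
class RankedResult:
    """Ranked entities with scores, best first; ties broken by entity id."""

    entries: list[tuple[str, float]] = field(default_factory=list)
    query_id: str | None = None

    def entity_ids(self) -> list[str]:
        return [e for e, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ListChoice:
    label: str  # "L1" | "L2"


def search(e_q: np.ndarray, elist: EmbeddingList, k: int) -> RankedResult:
    """Top-k entities of a list by cosine similarity to the query embedding.

    Deterministic: equal scores are ordered by ascending entity id.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    e_q = np.asarray(e_q, dtype=np.float64)
    if len(elist) == 0:
        raise ValidationError("cannot search an empty embedding list")
    if e_q.shape != (elist.dim,):
        raise ValidationError(f"dim mismatch: query {e_q.shape} vs list dim {elist.dim}")
    qn = float(np.linalg.norm(e_q))
    if qn == 0.0:
        raise ValidationError("cosine similarity is undefined for a zero query vector")
    row_norms = np.linalg.norm(elist.matrix, axis=1)
    if np.any(row_norms == 0.0):
        bad = [elist.entity_ids[i] for i in np.nonzero(row_norms == 0.0)[0]]
        raise ValidationError(f"zero-vector entity embeddings: {bad}")
    scores = (elist.matrix @ e_q) / (row_norms * qn)
    order = sorted(range(len(elist)), key=lambda i: (-scores[i], elist.entity_ids[i]))
    top = order[: min(k, len(order))]
    return RankedResult(entries=[(elist.entity_ids[i], float(scores[i])) for i in top])


class NearestCentroidQueryClassifier:
    """Baseline L1/L2 classifier: cosine to per-label centroids of query embeddings."""

    def __init__(self, encoder: Encoder):
        self._encoder = encoder
        self._centroids: dict[str, np.ndarray] = {}

    @property
    def trained(self) -> bool:
        return bool(self._centroids)

    def fit(self, labelled_queries: list[tuple[str, "ListChoice"]]) -> "NearestCentroidQueryClassifier":
        groups: dict[str, list[np.ndarray]] = {}
        for query, choice in labelled_queries:
            groups.setdefault(choice.label, []).append(self._encoder.encode(query))
        self._centroids = {label: np.mean(vs, axis=0) for label, vs in groups.items()}
        return self

    def predict(self, query: str) -> ListChoice:
        if not self.trained:
            raise ConfigurationError("classifier has not been fitted")
        e = self._encoder.encode(query)
        best_label, best_sim = None, -np.inf
        for label in sorted(self._centroids):  # "L1" first, so ties resolve to L1
            sim = cosine_similarity(e, self._centroids[label])
            if sim > best_sim:
                best_label, best_sim = label, sim
        return ListChoice(best_label)


def classify_query(query: str, classifier=None) -> ListChoice:
    """Choose an embedding list for a query; unconfigured -> L1 with a warning."""
    if classifier is None or not getattr(classifier, "trained", True):
        log.warning("query classifier unconfigured; defaulting to L1")
        return ListChoice("L1")
    return classifier.predict(query)


def generate_qc_labels(
    pairs,
    l1: EmbeddingList,
    l2: EmbeddingList,
    lexicon: Lexicon,
    encoder: Encoder,
    params: QueryEmbeddingParams | None = None,
    k: int = 10,
) -> list[tuple[str, ListChoice]]:
    """Label training queries with the list (L1/L2) that retrieves them best.

    Per query, AP@k is computed against both lists; the argmax decides the
    label and an exact tie goes to L1.  Queries with no relevant entity in
    the corpus are excluded with a log entry.
    """
    from .evaluation import ap_at_k  # deferred: evaluation imports this module

    params = params or QueryEmbeddingParams(method="mixed")
    indexed = set(l1.entity_ids) | set(l2.entity_ids)
    class_embs = class_embedding_matrix(lexicon, encoder, l1.class_ids or None)
    out: list[tuple[str, ListChoice]] = []
    for pair in pairs:
        if not (pair.relevant_entity_ids & indexed):
            log.warning("query %r has no relevant entity in the corpus; excluded", pair.query)
            continue
        e_q = query_embedding(pair.query, params, lexicon, encoder, class_embeddings=class_embs)
        ap1 = ap_at_k(search(e_q, l1, k), pair.relevant_entity_ids, k)
        ap2 = ap_at_k(search(e_q, l2, k), pair.relevant_entity_ids, k)
        out.append((pair.query, ListChoice("L2" if ap2 > ap1 else "L1")))
    return out


#: variant -> (query method, list label, use auxiliary phrases)
VARIANTS: dict[str, tuple[str, str, bool]] = {
    "macro": ("macro", "L1", False),
    "macroWP": ("macro", "L2", False),
    "micro": ("micro", "L1", False),
    "microWP": ("micro", "L2", True),
    "mixed": ("mixed", "L1", False),
    "mixedWP": ("mixed", "L2", True),
}


def retrieve(
    query: str,
    indexes: dict[str, EmbeddingList],
    lexicon: Lexicon,
    encoder: Encoder,
    variant: str = "mixed",
    k: int = 10,
    m_e: float = 1.9,
    w_p: float = 0.22,
    classifier=None,
    extractor: Extractor | None = None,
) -> RankedResult:
    """Run one retrieval variant end to end for a single query."""
    if variant == "mixedCl":
        choice = classify_query(query, classifier)
        variant = "mixed" if choice.label == "L1" else "mixedWP"
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown variant {variant!r}")
    method, list_label, use_aux = VARIANTS[variant]
    if list_label not in indexes:
        raise ConfigurationError(f"variant {variant!r} requires index {list_label!r}")
    elist = indexes[list_label]
    params = QueryEmbeddingParams(m_e=m_e, method=method, use_auxiliary_phrases=use_aux, w_p=w_p)
    class_embs = None
    if method != "macro":
        class_embs = class_embedding_matrix(lexicon, encoder, elist.class_ids or None)
    e_q = query_embedding(query, params, lexicon, encoder, class_embeddings=class_embs, extractor=extractor)
    return search(e_q, elist, k)
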