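"""Ranked-retrieval metrics, the Okapi BM25 baseline, and evaluation reports.

Metrics
-------

For a ranked result and a set of relevant entity ids::

    AP@k = (1/R) * sum_{i=1..k} P@i * r@i
    mAP@k = mean over queries of AP@k
    RR    = 1 / rank of the first relevant entity (0 if none retrieved)
    mRR   = mean over queries of RR

``r@i`` is 1 iff the entity at rank i is relevant and ``P@i`` is the
fraction of relevant entities within the top i.  ``R`` counts the relevant
entities *within the retrieved top-k* (``r_definition="retrieved"``, the
default); this inflates AP when recall < 1 relative to the textbook
normalisation ``R = min(|relevant|, k)``, which is available as
``r_definition="standard"`` — the two agree whenever every relevant entity
is retrieved within the top k.

BM25 baseline
-------------

Okapi BM25 over per-entity bag-of-words documents, with the standard
+0.5-smoothed IDF, ``idf(t) = ln(1 + (N - df + 0.5)/(df + 0.5))``, and
defaults k1 = 1.2, b = 0.75.  Each entity's document is the concatenation
of its class labels and synonyms, normalized predicate phrases, and literal
descriptions — the same information the embedding side sees.
"""

from __future__ import annotations

import csv
import json
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable

import numpy as np
import pandas as pd

from .annotation_graph import CompositeAnnotation
from .embedding_core import EmbeddingList, cosine_similarity
from .encoder import Encoder
from .errors import ValidationError
from .lexicon import Lexicon
from .retrieval import RankedResult, retrieve, search

_WORD_RE = re.compile(r"[0-9A-Za-z]+")


@dataclass(frozen=True)
class QueryEntitySet:
    """One evaluation query and the entity ids considered relevant to it."""

    query_id: str
    query: str
    relevant_entity_ids: frozenset[str]
    variant: str = "noPredicate"  # noPredicate | withPredicate

    def __post_init__(self):
        if not self.query or not self.query.strip():
            raise ValidationError("query text must be non-empty")
        if not self.relevant_entity_ids:
            raise ValidationError(f"query {self.query_id}: relevant set must be non-empty")


def ap_at_k(result: RankedResult, relevant: set[str] | frozenset[str], k: int, r_definition: str = "retrieved") -> float:
    """Average precision over the top-k of a ranked result."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if r_definition not in ("retrieved", "standard"):
        raise ValidationError(f"unknown r_definition {r_definition!r}")
    top = result.entries[:k]
    hits = [1 if eid in relevant else 0 for eid, _ in top]
    if r_definition == "retrieved":
        r_norm = sum(hits)
    else:
        r_norm = min(len(relevant), k)
    if r_norm == 0:
        return 0.0
    total, seen = 0.0, 0
    for i, h in enumerate(hits, start=1):
        seen += h
        if h:
            total += seen / i
    return total / r_norm


def map_at_k(ap_values: Iterable[float]) -> float:
    """Mean of per-query AP@k values."""
    values = list(ap_values)
    if not values:
        raise ValidationError("mAP@k requires at least one query")
    return float(np.mean(values))


def rr(result: RankedResult, relevant: set[str] | frozenset[str]) -> float:
    """Reciprocal rank of the first relevant entity; 0 when none retrieved."""
    for i, (eid, _) in enumerate(result.entries, start=1):
        if eid in relevant:
            return 1.0 / i
    return 0.0


def mrr(rr_values: Iterable[float]) -> float:
    """Mean of per-query reciprocal ranks."""
    values = list(rr_values)
    if not values:
        raise ValidationError("mRR requires at least one query")
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# BM25 baseline


def tokenize(text: str) -> list[str]:
    return [t.lower() for t in _WORD_RE.findall(text)]


def entity_document_text(annotation: CompositeAnnotation, lexicon: Lexicon) -> str:
    """Bag-of-words document for one entity, mirroring the embedding inputs."""
    parts: list[str] = []
    for path in annotation.paths:
        parts.extend(lexicon.features_or_fallback(path.class_id))
        parts.extend(path.predicates)
    parts.extend(annotation.descriptions)
    return " ".join(parts)


def bm25_search(
    query: str,
    documents: list[tuple[str, str]],
    k: int = 10,
    k1: float = 1.2,
    b: float = 0.75,
) -> RankedResult:
    """Okapi BM25 ranking of ``(entity_id, text)`` documents for a query."""
    if not documents:
        raise ValidationError("BM25 requires a non-empty corpus")
    q_terms = tokenize(query)
    if not q_terms:
        return RankedResult(entries=[])
    doc_tokens = {eid: tokenize(text) for eid, text in documents}
    n_docs = len(documents)
    avgdl = sum(len(t) for t in doc_tokens.values()) / n_docs
    df = Counter()
    for toks in doc_tokens.values():
        df.update(set(toks))
    scores: dict[str, float] = {}
    for eid, toks in doc_tokens.items():
        tf = Counter(toks)
        dl = len(toks)
        score = 0.0
        for term in q_terms:
            f = tf.get(term, 0)
            if f == 0:
                continue
            idf = math.log(1.0 + (n_docs - df[term] + 0.5) / (df[term] + 0.5))
            denom = f + k1 * (1.0 - b + b * dl / avgdl) if avgdl > 0 else f + k1
            score += idf * f * (k1 + 1.0) / denom
        scores[eid] = score
    order = sorted(scores, key=lambda eid: (-scores[eid], eid))
    return RankedResult(entries=[(eid, scores[eid]) for eid in order[:k]])


# ---------------------------------------------------------------------------
# Reports


@dataclass
class EvalReport:
    """Per-query and aggregate retrieval quality for one method."""

    method: str
    k: int
    per_query: list[dict] = field(default_factory=list)  # query_id, ap, rr

    @property
    def map_at_k(self) -> float:
        return map_at_k(q["ap"] for q in self.per_query)

    @property
    def mrr(self) -> float:
        return mrr(q["rr"] for q in self.per_query)

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "k": self.k,
                "map_at_k": self.map_at_k,
                "mrr": self.mrr,
                "n_queries": len(self.per_query),
                "per_query": self.per_query,
            },
            sort_keys=True,
        )


def evaluate(
    pairs: list[QueryEntitySet],
    indexes: dict[str, EmbeddingList],
    lexicon: Lexicon,
    encoder: Encoder,
    variant: str = "mixed",
    k: int = 10,
    r_definition: str = "retrieved",
    classifier=None,
    m_e: float = 1.9,
    w_p: float = 0.22,
) -> EvalReport:
    """Run one retrieval variant over a pair set and aggregate the metrics."""
    report = EvalReport(method=variant, k=k)
    for pair in pairs:
        result = retrieve(
            pair.query, indexes, lexicon, encoder,
            variant=variant, k=k, m_e=m_e, w_p=w_p, classifier=classifier,
        )
        report.per_query.append(
            {
                "query_id": pair.query_id,
                "ap": ap_at_k(result, pair.relevant_entity_ids, k, r_definition),
                "rr": rr(result, pair.relevant_entity_ids),
            }
        )
    return report


def evaluate_bm25(
    pairs: list[QueryEntitySet],
    corpus: list[CompositeAnnotation],
    lexicon: Lexicon,
    k: int = 10,
    r_definition: str = "retrieved",
    k1: float = 1.2,
    b: float = 0.75,
) -> EvalReport:
    """BM25 baseline over the same pairs, for side-by-side comparison."""
    documents = [(ann.entity_id, entity_document_text(ann, lexicon)) for ann in corpus if ann.embeddable]
    report = EvalReport(method="BM25", k=k)
    for pair in pairs:
        result = bm25_search(pair.query, documents, k=k, k1=k1, b=b)
        report.per_query.append(
            {
                "query_id": pair.query_id,
                "ap": ap_at_k(result, pair.relevant_entity_ids, k, r_definition),
                "rr": rr(result, pair.relevant_entity_ids),
            }
        )
    return report


def similarity_binned_report(
    pairs: list[QueryEntitySet],
    elist: EmbeddingList,
    lexicon: Lexicon,
    encoder: Encoder,
    k: int = 10,
    bin_width: float = 0.1,
    r_definition: str = "retrieved",
) -> pd.DataFrame:
    """mAP@k broken down by query difficulty.

    Each query is placed in a similarity bin by the maximum cosine between
    its whole-query (macro) embedding and its relevant entities' embeddings;
    retrieval quality within each bin separates easy look-alike queries from
    paraphrased ones.  Bins of width ``bin_width`` partition [-1, 1]; empty
    bins are reported with count 0 and NaN mAP.
    """
    edges = np.arange(-1.0, 1.0 + 1e-9, bin_width)
    n_bins = len(edges) - 1
    binned_aps: dict[int, list[float]] = {i: [] for i in range(n_bins)}
    indexed = set(elist.entity_ids)
    for pair in pairs:
        rel_in = [eid for eid in pair.relevant_entity_ids if eid in indexed]
        if not rel_in:
            continue
        e_q = encoder.encode(pair.query)
        sim = max(cosine_similarity(e_q, elist.embedding_of(eid)) for eid in rel_in)
        idx = min(int((sim - (-1.0)) / bin_width), n_bins - 1)
        ap = ap_at_k(search(e_q, elist, k), pair.relevant_entity_ids, k, r_definition)
        binned_aps[idx].append(ap)
    rows = []
    for i in range(n_bins):
        aps = binned_aps[i]
        rows.append(
            {
                "bin_low": round(edges[i], 10),
                "bin_high": round(edges[i + 1], 10),
                "query_count": len(aps),
                "map_at_k": float(np.mean(aps)) if aps else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pairs file IO (TSV: query_id, query, variant, '|'-joined relevant ids)


def write_pairs(pairs: Iterable[QueryEntitySet], stream: IO[str]) -> None:
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(["query_id", "query", "variant", "relevant_entity_ids"])
    for p in pairs:
        writer.writerow([p.query_id, p.query, p.variant, "|".join(sorted(p.relevant_entity_ids))])


def read_pairs(stream: IO[str]) -> list[QueryEntitySet]:
    reader = csv.DictReader(stream, delimiter="\t")
    out = []
    for row in reader:
        out.append(
            QueryEntitySet(
                query_id=row["query_id"],
                query=row["query"],
                relevant_entity_ids=frozenset(row["relevant_entity_ids"].split("|")),
                variant=row["variant"],
            )
        )
    return out
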