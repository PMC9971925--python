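"""Query-to-embedding conversion: macro, micro and mixed methods.

A free-text query such as ``"triose phosphate concentration in astrocytes"``
is treated two ways at once:

* *macro* — the whole query is encoded as one sentence, capturing word
  order, prepositions and phrase relationships;
* *micro* — phrases naming physiological/biochemical concepts are pulled
  out, encoded individually and averaged; the average is damped by ``w_ph``,
  the mean over phrases of each phrase's best cosine similarity to the
  ontology-class embeddings, so phrase evidence only counts in proportion to
  how ontology-like the phrases are::

      e_ph = (w_ph / n) * sum_i e_i

* *mixed* — both, with the whole-query embedding amplified by a multiplier
  ``m_e`` (default 1.9; the whole query is the stronger signal)::

      e_q = m_e * e + e_ph

Phrases with no domain meaning ("auxiliary" phrases — in predicate-style
queries these are typically the inserted predicate words) can optionally be
folded into the core phrase they complement, weighted by the same ``w_p``
used for predicate paths on the entity side.

Phrase extraction is a pluggable contract.  The shipped reference extractor
is lexicon-driven: case-insensitive longest match of ontology-class features
(with trivial plural tolerance), left to right; any external NER model can
be wrapped to return the same :class:`PhraseSet` shape.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .embedding_core import class_embedding, cosine_similarity
from .encoder import Embedding, Encoder
from .errors import ConfigurationError, QueryError, ValidationError
from .lexicon import Lexicon

STOPWORDS = frozenset(
    """a an and are as at be by for from in into is it its of on or that the
    their there these this to was were which with within""".split()
)

_TOKEN_RE = re.compile(r"[0-9A-Za-z]+")


@dataclass(frozen=True)
class QueryEmbeddingParams:
    m_e: float = 1.9
    method: str = "mixed"  # macro | micro | mixed
    use_auxiliary_phrases: bool = False
    w_p: float = 0.22  # weight for auxiliary-phrase merging

    def __post_init__(self):
        if self.m_e <= 0:
            raise ValidationError(f"m_e must be positive, got {self.m_e}")
        if self.method not in ("macro", "micro", "mixed"):
            raise ValidationError(f"unknown query method {self.method!r}")


@dataclass
class PhraseSet:
    """Extracted query phrases: domain-bearing cores plus auxiliaries.

    ``auxiliary`` holds ``(text, core_index)`` pairs, each attached to the
    core phrase it complements.
    """

    core: list[str] = field(default_factory=list)
    auxiliary: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        for _, i in self.auxiliary:
            if not 0 <= i < len(self.core):
                raise ValidationError(f"auxiliary phrase attached to invalid core index {i}")


def _match_tokens(query_tokens: list[str], feature_tokens: list[str], start: int) -> bool:
    if start + len(feature_tokens) > len(query_tokens):
        return False
    for qt, ft in zip(query_tokens[start:start + len(feature_tokens)], feature_tokens):
        if not (qt == ft or qt == ft + "s" or qt + "s" == ft):
            return False
    return True


class LexiconPhraseExtractor:
    """Longest-match phrase extractor over the lexicon's feature texts.

    Core phrases are reported in canonical (lowercased feature) form;
    remaining contiguous non-stopword token runs become auxiliary phrases
    attached to the nearest preceding core phrase, or the following one when
    none precedes.
    """

    def __init__(self, lexicon: Lexicon):
        self._features: list[list[str]] = []
        seen: set[tuple[str, ...]] = set()
        for text in lexicon.all_features():
            toks = [t.lower() for t in _TOKEN_RE.findall(text)]
            if toks and tuple(toks) not in seen:
                seen.add(tuple(toks))
                self._features.append(toks)
        # longest first so multi-word features beat their own prefixes
        self._features.sort(key=len, reverse=True)

    def __call__(self, query: str) -> PhraseSet:
        tokens = [t.lower() for t in _TOKEN_RE.findall(query)]
        core: list[str] = []
        # for each token: index of the core phrase covering it, or None
        cover: list[int | None] = [None] * len(tokens)
        i = 0
        while i < len(tokens):
            matched = False
            for ftoks in self._features:
                if _match_tokens(tokens, ftoks, i):
                    idx = len(core)
                    core.append(" ".join(ftoks))
                    for j in range(i, i + len(ftoks)):
                        cover[j] = idx
                    i += len(ftoks)
                    matched = True
                    break
            if not matched:
                i += 1

        auxiliary: list[tuple[str, int]] = []
        if core:
            run: list[str] = []
            run_start = 0
            for j, tok in enumerate(tokens + [None]):  # sentinel flushes last run
                leftover = tok is not None and cover[j] is None and tok not in STOPWORDS
                if leftover:
                    if not run:
                        run_start = j
                    run.append(tok)
                elif run:
                    prev = [c for c in cover[:run_start] if c is not None]
                    attach = prev[-1] if prev else next(c for c in cover if c is not None)
                    auxiliary.append((" ".join(run), attach))
                    run = []
        return PhraseSet(core=core, auxiliary=auxiliary)


Extractor = Callable[[str], PhraseSet]


def class_embedding_matrix(lexicon: Lexicon, encoder: Encoder, class_ids: list[str] | None = None) -> np.ndarray:
    """Stack class embeddings for the given ids (default: whole lexicon)."""
    ids = list(lexicon.records) if class_ids is None else class_ids
    if not ids:
        raise ConfigurationError("class set for phrase weighting is empty")
    return np.vstack([class_embedding(lexicon.features_or_fallback(cid), encoder) for cid in ids])


def phrase_weight(core_phrases: list[str], class_embeddings: np.ndarray, encoder: Encoder) -> float:
    """Mean over phrases of the best cosine similarity to any class embedding."""
    if not core_phrases:
        raise ValidationError("phrase_weight requires at least one core phrase")
    if class_embeddings is None or len(class_embeddings) == 0:
        raise ConfigurationError("class set for phrase weighting is empty")
    maxima = []
    for phrase in core_phrases:
        e = encoder.encode(phrase)
        maxima.append(max(cosine_similarity(e, c) for c in class_embeddings))
    return float(np.mean(maxima))


def query_embedding(
    query: str,
    params: QueryEmbeddingParams,
    lexicon: Lexicon,
    encoder: Encoder,
    class_embeddings: np.ndarray | None = None,
    extractor: Extractor | None = None,
) -> Embedding:
    """Convert a query to its embedding under the configured method.

    ``class_embeddings`` restricts the phrase-weight class set (typically to
    the classes referenced by the indexed corpus); when absent, the whole
    lexicon is used.
    """
    if not query or not query.strip():
        raise ValidationError("query must be non-empty")
    if params.method == "macro":
        return encoder.encode(query)

    extractor = extractor or LexiconPhraseExtractor(lexicon)
    phrases = extractor(query)

    if not phrases.core:
        if params.method == "micro":
            raise QueryError("no phrases extracted; use the macro or mixed method for this query")
        return params.m_e * encoder.encode(query)  # mixed degrades gracefully

    core_embs = [encoder.encode(p) for p in phrases.core]
    if params.use_auxiliary_phrases and phrases.auxiliary:
        aux_by_core: dict[int, list[Embedding]] = {}
        for text, idx in phrases.auxiliary:
            aux_by_core.setdefault(idx, []).append(encoder.encode(text))
        for idx, encs in aux_by_core.items():
            merged = np.mean(encs, axis=0)
            core_embs[idx] = (core_embs[idx] + params.w_p * merged) / (1.0 + params.w_p)

    if class_embeddings is None:
        class_embeddings = class_embedding_matrix(lexicon, encoder)
    w_ph = phrase_weight(phrases.core, class_embeddings, encoder)
    e_ph = w_ph * np.mean(core_embs, axis=0)

    if params.method == "micro":
        return e_ph
    return params.m_e * encoder.encode(query) + e_ph
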