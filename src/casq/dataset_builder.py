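"""Query–entity pair construction and the synthetic benchmark generator.

Real benchmark sets are built from an annotation corpus: every distinct
literal description becomes a *noPredicate* query whose relevant entities
are all entities carrying that description, and a *withPredicate* variant of
each query is derived by inserting one predicate phrase (e.g. ``is property
of``) taken from a relevant entity's paths — directly before the query words
matching that path's class, mimicking how a SPARQL-minded user would phrase
a structured query.

The synthetic generator emulates the same shape offline: pseudo-word
vocabularies, ontology classes with 1–3 features, entities with 1–4
predicate paths, and descriptions composed from class features (optionally
shared between entities).  In *disjoint-vocabulary* mode no two entities
share a pseudo-word, so under the trigram reference encoder cross-entity
similarity is negligible by construction — a corpus on which any sane
retriever must achieve perfect scores, which the acceptance suite exploits.
"""

from __future__ import annotations

import io
import logging
import random
import re
import string
from dataclasses import dataclass, field
from typing import Callable
from xml.sax.saxutils import escape

from .annotation_graph import CompositeAnnotation, Path, extract_annotations, parse_rdf
from .errors import ConfigurationError
from .evaluation import QueryEntitySet
from .lexicon import Lexicon, OntologyClassRecord, load_lexicon, write_lexicon

log = logging.getLogger(__name__)

PREDICATE_PHRASES = ("is", "is version of", "is part of", "is property of", "occurs in")
_PHRASE_TO_QUALIFIER = {
    "is": "bqbiol:is",
    "is version of": "bqbiol:isVersionOf",
    "is part of": "bqbiol:isPartOf",
    "is property of": "bqbiol:isPropertyOf",
    "occurs in": "bqbiol:occursIn",
}

_TOKEN_RE = re.compile(r"[0-9A-Za-z]+")


def _normalize_ws(text: str) -> str:
    return " ".join(text.split())


def build_nopredicate(corpus: list[CompositeAnnotation], exclude: set[str] | None = None) -> list[QueryEntitySet]:
    """One pair per distinct description; relevant = all entities sharing it.

    ``exclude`` holds description texts curated as inaccurate; matching
    queries are dropped.
    """
    exclude = {_normalize_ws(e) for e in (exclude or set())}
    grouped: dict[str, list[str]] = {}
    for ann in corpus:
        for desc in ann.descriptions:
            text = _normalize_ws(desc)
            if not text or text in exclude:
                continue
            grouped.setdefault(text, [])
            if ann.entity_id not in grouped[text]:
                grouped[text].append(ann.entity_id)
    return [
        QueryEntitySet(
            query_id=f"q{i + 1}",
            query=text,
            relevant_entity_ids=frozenset(entities),
            variant="noPredicate",
        )
        for i, (text, entities) in enumerate(grouped.items())
    ]


def _feature_token_match(query: str, feature: str) -> int | None:
    """Character offset of the first token-wise match of a feature in a query.

    Token-based and plural-tolerant, so ``glyceraldehyde 3-phosphate``
    matches the hyphenated ``glyceraldehyde-3-phosphate``.
    """
    q_tokens = [(m.group().lower(), m.start()) for m in _TOKEN_RE.finditer(query)]
    f_tokens = [t.lower() for t in _TOKEN_RE.findall(feature)]
    if not f_tokens:
        return None
    for i in range(len(q_tokens) - len(f_tokens) + 1):
        ok = all(
            qt == ft or qt == ft + "s" or qt + "s" == ft
            for (qt, _), ft in zip(q_tokens[i:i + len(f_tokens)], f_tokens)
        )
        if ok:
            return q_tokens[i][1]
    return None


def insert_predicate_phrase(query: str, phrase: str, class_features: list[str], rng: random.Random) -> str:
    """Insert a predicate phrase before the query words naming the class.

    Falls back to a seeded-uniform token boundary when no feature of the
    path's class occurs in the query.
    """
    for feature in class_features:
        offset = _feature_token_match(query, feature)
        if offset is not None:
            return query[:offset] + phrase + " " + query[offset:]
    starts = [m.start() for m in _TOKEN_RE.finditer(query)] or [0]
    offset = rng.choice(starts)
    return query[:offset] + phrase + " " + query[offset:]


Selector = Callable[[QueryEntitySet, list[CompositeAnnotation]], tuple[Path, str]]


def build_withpredicate(
    pairs: list[QueryEntitySet],
    corpus: list[CompositeAnnotation],
    lexicon: Lexicon,
    seed: int = 0,
    selector: Selector | None = None,
) -> list[QueryEntitySet]:
    """Derive withPredicate pairs by inserting one predicate phrase per query.

    The default selector draws, seeded-uniformly, one relevant entity, one
    of its predicate-bearing paths and one phrase of that path; ``selector``
    overrides the draw (used to pin down worked examples).  Input pairs are
    left untouched; pairs whose entities have no predicate-bearing path are
    skipped with a log entry.
    """
    rng = random.Random(seed)
    by_id = {ann.entity_id: ann for ann in corpus}
    out: list[QueryEntitySet] = []
    for pair in pairs:
        entities = [by_id[eid] for eid in sorted(pair.relevant_entity_ids) if eid in by_id]
        candidates = [(ann, p) for ann in entities for p in ann.paths if p.predicates]
        if not candidates:
            log.warning("pair %s: no predicate-bearing path among relevant entities; skipped", pair.query_id)
            continue
        if selector is not None:
            path, phrase = selector(pair, entities)
        else:
            _, path = candidates[rng.randrange(len(candidates))]
            phrase = path.predicates[rng.randrange(len(path.predicates))]
        features = lexicon.features_or_fallback(path.class_id)
        new_query = insert_predicate_phrase(pair.query, phrase, features, rng)
        out.append(
            QueryEntitySet(
                query_id=pair.query_id + "-wp",
                query=new_query,
                relevant_entity_ids=pair.relevant_entity_ids,
                variant="withPredicate",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Synthetic corpus generation


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic benchmark.

    Defaults mirror a desk-scale slice of a curated model repository: a
    shared pool of 50 ontology classes over a 500 pseudo-word vocabulary,
    100 entities with 1–4 paths each, roughly a third of entities carrying a
    literal description (the observed repository fraction), and occasional
    description sharing between entities.
    """

    n_classes: int = 50
    n_entities: int = 100
    paths_per_entity: tuple[int, int] = (1, 4)
    vocab_size: int = 500
    fraction_with_description: float = 0.35
    share_description_prob: float = 0.1
    disjoint_vocabulary: bool = False
    seed: int = 0

    def __post_init__(self):
        if min(self.n_classes, self.n_entities, self.vocab_size) < 1:
            raise ConfigurationError("all counts must be positive")
        lo, hi = self.paths_per_entity
        if not 1 <= lo <= hi:
            raise ConfigurationError(f"invalid paths_per_entity range {self.paths_per_entity}")
        if not self.disjoint_vocabulary and self.n_classes < hi:
            raise ConfigurationError("n_classes must cover the maximum paths per entity")
        if self.vocab_size < self.n_classes:
            raise ConfigurationError("vocabulary too small for the requested class count")


@dataclass
class SyntheticDataset:
    """Generated fixture: lexicon CSV, RDF/XML document, and gold pairs."""

    lexicon_csv: str
    rdf_xml: str
    pairs: list[QueryEntitySet] = field(default_factory=list)

    def lexicon(self) -> Lexicon:
        return load_lexicon(self.lexicon_csv)

    def corpus(self) -> list[CompositeAnnotation]:
        return extract_annotations(parse_rdf(self.rdf_xml, dialect="rdfxml"))


_RDF_HEADER = (
    '<?xml version="1.0" encoding="utf-8"?>\n'
    '<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"\n'
    '         xmlns:bqbiol="http://biomodels.net/biology-qualifiers/"\n'
    '         xmlns:dcterms="http://purl.org/dc/terms/">\n'
)

_CLASS_PREFIXES = ("CHEBI", "FMA", "OPB", "GO")


def _class_uri(class_id: str) -> str:
    prefix, local = class_id.split(":", 1)
    return f"https://identifiers.org/{prefix.lower()}/{prefix}_{local}"


def _new_word(rng: random.Random, used: set[str]) -> str:
    while True:
        word = "".join(rng.choice(string.ascii_lowercase) for _ in range(rng.randint(5, 8)))
        if word not in used:
            used.add(word)
            return word


def _make_class(rng: random.Random, class_id: str, vocab: list[str]) -> OntologyClassRecord:
    n_features = rng.randint(1, 3)
    features = [" ".join(rng.choice(vocab) for _ in range(rng.randint(1, 2))) for _ in range(n_features)]
    # features within a class must be distinct
    features = list(dict.fromkeys(features)) or [rng.choice(vocab)]
    return OntologyClassRecord(class_id, features[0], tuple(features[1:]))


def generate_synthetic(config: SyntheticConfig = SyntheticConfig()) -> SyntheticDataset:
    """Generate a seeded, fully self-consistent benchmark corpus.

    The emitted RDF/XML is written by a deterministic template, so two runs
    with the same config are byte-identical; round-tripping it through
    :mod:`casq.annotation_graph` and :func:`build_nopredicate` recovers
    exactly the returned gold pairs.
    """
    rng = random.Random(config.seed)
    used_words: set[str] = set()
    doc = "synthetic.cellml"

    classes: list[OntologyClassRecord] = []
    if not config.disjoint_vocabulary:
        vocab = [_new_word(rng, used_words) for _ in range(config.vocab_size)]
        for i in range(config.n_classes):
            prefix = _CLASS_PREFIXES[i % len(_CLASS_PREFIXES)]
            classes.append(_make_class(rng, f"{prefix}:{90000 + i}", vocab))

    lo, hi = config.paths_per_entity
    blocks: list[str] = []
    annotations: list[tuple[str, list[OntologyClassRecord], list[str]]] = []  # id, classes, descriptions
    described: list[tuple[str, str]] = []  # (description, entity_id), for sharing

    for i in range(config.n_entities):
        frag = f"v{i:04d}"
        entity_id = f"{doc}#{frag}"
        n_paths = rng.randint(lo, hi)

        if config.disjoint_vocabulary:
            private = [_new_word(rng, used_words) for _ in range(4 * n_paths)]
            own_classes = []
            for j in range(n_paths):
                prefix = _CLASS_PREFIXES[(len(classes) + j) % len(_CLASS_PREFIXES)]
                own_classes.append(_make_class(rng, f"{prefix}:{90000 + len(classes) + j}", private))
            classes.extend(own_classes)
            chosen = own_classes
        else:
            chosen = rng.sample(classes, n_paths)

        lines = [f'  <rdf:Description rdf:about="./{doc}#{frag}">\n']
        tail_lines: list[str] = []
        for j, cls in enumerate(chosen):
            # direct class attachment, or a chain through 1-2 intermediates
            shape = rng.choice(("direct", "via1", "via2"))
            uri = escape(_class_uri(cls.class_id), {'"': "&quot;"})
            if shape == "direct":
                qualifier = _PHRASE_TO_QUALIFIER[rng.choice(PREDICATE_PHRASES[1:])]
                lines.append(f'    <{qualifier} rdf:resource="{uri}"/>\n')
                continue
            n1 = f"{frag}_n{j}a"
            q1 = _PHRASE_TO_QUALIFIER[rng.choice(PREDICATE_PHRASES[1:])]
            lines.append(f'    <{q1} rdf:resource="./{doc}#{n1}"/>\n')
            if shape == "via1":
                tail_lines.append(
                    f'  <rdf:Description rdf:about="./{doc}#{n1}">\n'
                    f'    <bqbiol:is rdf:resource="{uri}"/>\n'
                    f"  </rdf:Description>\n"
                )
            else:
                n2 = f"{frag}_n{j}b"
                q2 = _PHRASE_TO_QUALIFIER[rng.choice(PREDICATE_PHRASES[1:])]
                tail_lines.append(
                    f'  <rdf:Description rdf:about="./{doc}#{n1}">\n'
                    f'    <{q2} rdf:resource="./{doc}#{n2}"/>\n'
                    f"  </rdf:Description>\n"
                    f'  <rdf:Description rdf:about="./{doc}#{n2}">\n'
                    f'    <bqbiol:is rdf:resource="{uri}"/>\n'
                    f"  </rdf:Description>\n"
                )

        descriptions: list[str] = []
        if rng.random() < config.fraction_with_description:
            share = (
                not config.disjoint_vocabulary
                and described
                and rng.random() < config.share_description_prob
            )
            if share:
                text = rng.choice(described)[0]
            else:
                text = " ".join(cls.preferred_label for cls in chosen)
            descriptions.append(text)
            described.append((text, entity_id))
            lines.append(f"    <dcterms:description>{escape(text)}</dcterms:description>\n")

        lines.append("  </rdf:Description>\n")
        blocks.append("".join(lines) + "".join(tail_lines))
        annotations.append((entity_id, chosen, descriptions))

    rdf_xml = _RDF_HEADER + "".join(blocks) + "</rdf:RDF>\n"

    buf = io.StringIO()
    write_lexicon(classes, buf)

    grouped: dict[str, list[str]] = {}
    for text, entity_id in described:
        grouped.setdefault(text, [])
        if entity_id not in grouped[text]:
            grouped[text].append(entity_id)
    pairs = [
        QueryEntitySet(f"q{i + 1}", text, frozenset(entities), "noPredicate")
        for i, (text, entities) in enumerate(grouped.items())
    ]
    return SyntheticDataset(lexicon_csv=buf.getvalue(), rdf_xml=rdf_xml, pairs=pairs)
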