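"""Parsing of RDF composite annotations and reduction to predicate paths.

A composite annotation describes one model entity (a variable, reaction or
component of a CellML/SBML model) as a small RDF tree: the root is the
entity, the leaves are ontology classes (OPB, FMA, ChEBI, GO, ...), and the
edges are BioModels qualifiers such as ``bqbiol:isPropertyOf``.  Intermediate
nodes (``entity_1`` and friends) are anonymous connectors that carry no
meaning of their own, so each root-to-class walk is reduced to a *path*: the
ordered predicate phrases traversed, minus the final predicate whenever its
subject is an intermediate node (that predicate describes the connector, not
the entity), terminating in the ontology class identifier.

Entities may additionally carry free-text ``dcterms:description`` literals;
these are kept verbatim and later serve as realistic user queries.
"""

from __future__ import annotations

import json
import re
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import rdflib

from .errors import CasqError, CycleError, ParseError, ConfigurationError, ValidationError

log = logging.getLogger(__name__)

#: Well-known namespaces mapped to the prefixes used throughout PMR/BioModels
#: annotation exports.
KNOWN_NAMESPACES = {
    "http://biomodels.net/biology-qualifiers/": "bqbiol",
    "http://biomodels.net/model-qualifiers/": "bqmodel",
    "http://purl.org/dc/terms/": "dcterms",
    "http://purl.org/dc/elements/1.1/": "dc",
    "http://www.w3.org/1999/02/22-rdf-syntax-ns#": "rdf",
    "http://www.w3.org/2000/01/rdf-schema#": "rdfs",
}

DEFAULT_ONTOLOGY_PREFIXES = frozenset({"OPB", "FMA", "CHEBI", "GO", "PR", "CL", "UBERON"})
DEFAULT_DESCRIPTION_PREDICATE = "dcterms:description"

#: Hard ceiling on predicate hops per path; deeper graphs are malformed.
MAX_PATH_DEPTH = 16

_DIALECTS = {"rdfxml": "xml", "turtle": "turtle"}

_CLASS_SUFFIX_RE = re.compile(r"([A-Za-z]+)[_:]([A-Za-z0-9.\-]+)$")


@dataclass(frozen=True)
class RdfTriple:
    """One RDF statement with the predicate kept as a qualified term."""

    subject: str
    predicate: str
    object: str
    is_literal: bool = False

    def __post_init__(self):
        if not self.subject or not self.predicate or not self.object:
            raise ValidationError("triple fields must be non-empty")


@dataclass(frozen=True)
class Path:
    """Ordered predicate phrases from an entity to one ontology class."""

    predicates: tuple[str, ...]
    class_id: str

    def __post_init__(self):
        if not re.fullmatch(r"[A-Za-z]+:[A-Za-z0-9.\-]+", self.class_id):
            raise ValidationError(f"class_id not in PREFIX:LOCAL form: {self.class_id!r}")


@dataclass
class CompositeAnnotation:
    """An entity's pruned path tree plus its optional literal descriptions."""

    entity_id: str
    paths: list[Path] = field(default_factory=list)
    descriptions: list[str] = field(default_factory=list)

    @property
    def embeddable(self) -> bool:
        return bool(self.paths)

    def to_json(self) -> str:
        return json.dumps(
            {
                "entity_id": self.entity_id,
                "paths": [{"predicates": list(p.predicates), "class_id": p.class_id} for p in self.paths],
                "descriptions": self.descriptions,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, line: str) -> "CompositeAnnotation":
        d = json.loads(line)
        return cls(
            entity_id=d["entity_id"],
            paths=[Path(tuple(p["predicates"]), p["class_id"]) for p in d["paths"]],
            descriptions=list(d["descriptions"]),
        )


def normalize_predicate(term: str) -> str:
    """Strip the prefix and split a camelCase qualifier into a lowercase phrase.

    ``bqbiol:isVersionOf`` -> ``is version of``.
    """
    local = term.rsplit(":", 1)[-1].rsplit("/", 1)[-1].rsplit("#", 1)[-1]
    if not local:
        raise ValidationError(f"predicate has empty local name: {term!r}")
    words = re.sub(r"(?<=[a-z0-9])(?=[A-Z])", " ", local)
    return words.lower()


def _qualify(uri: str) -> str:
    """Render a predicate URI as prefix:local where the namespace is known."""
    for ns, prefix in KNOWN_NAMESPACES.items():
        if uri.startswith(ns):
            return f"{prefix}:{uri[len(ns):]}"
    return uri


def _relativize(uri: str, base: str) -> str:
    """Reduce an absolute resource URI to its document-relative form."""
    if base and uri.startswith(base):
        uri = uri[len(base):]
    return uri.lstrip("/")


def parse_rdf(document: bytes | str | IO, dialect: str = "rdfxml", base: str = "file:///") -> list[RdfTriple]:
    """Parse an RDF document into triples, preserving qualified predicates.

    Parameters
    ----------
    document:
        The document content (bytes or str) or an open binary stream.
    dialect:
        ``rdfxml`` or ``turtle``.
    base:
        Base URI used to resolve relative references; resource identifiers
        are reported relative to it (e.g. ``cloutier_2009.cellml#GAPg_GAPg``).
    """
    if dialect not in _DIALECTS:
        raise ConfigurationError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    graph = rdflib.Graph()
    if hasattr(document, "read"):
        document = document.read()
    try:
        graph.parse(data=document, format=_DIALECTS[dialect], publicID=base)
    except Exception as exc:  # rdflib raises dialect-specific parse errors
        raise ParseError(f"malformed {dialect} document: {exc}") from exc

    triples: list[RdfTriple] = []
    for s, p, o in graph:
        subject = _relativize(str(s), base)
        predicate = _qualify(str(p))
        if isinstance(o, rdflib.Literal):
            triples.append(RdfTriple(subject, predicate, str(o), is_literal=True))
        else:
            triples.append(RdfTriple(subject, predicate, _relativize(str(o), base)))
    # rdflib iteration order is not guaranteed; fix it for reproducibility
    triples.sort(key=lambda t: (t.subject, t.predicate, t.object))
    return triples


def class_id_of(resource: str, ontology_prefixes: Iterable[str] = DEFAULT_ONTOLOGY_PREFIXES) -> str | None:
    """Map a resource identifier to PREFIX:LOCAL if it denotes an ontology class.

    Accepts both identifiers.org shapes seen in the wild
    (``.../opb/OPB_00340`` and ``.../chebi/CHEBI:17138``) as well as OBO purl
    style (``.../obo/CHEBI_17138``); the separator is normalised to a colon.
    """
    tail = resource.rsplit("/", 1)[-1].rsplit("#", 1)[-1]
    m = _CLASS_SUFFIX_RE.search(tail)
    if not m:
        return None
    prefix = m.group(1).upper()
    if prefix not in {p.upper() for p in ontology_prefixes}:
        return None
    return f"{prefix}:{m.group(2)}"


def extract_annotations(
    triples: list[RdfTriple],
    ontology_prefixes: Iterable[str] = DEFAULT_ONTOLOGY_PREFIXES,
    description_predicate: str = DEFAULT_DESCRIPTION_PREDICATE,
) -> list[CompositeAnnotation]:
    """Reduce a triple set to one :class:`CompositeAnnotation` per root entity.

    Roots are subjects that never appear as the object of a non-description
    triple.  Each root-to-class walk becomes a :class:`Path`; the final
    predicate is dropped when its subject is an intermediate node, because it
    describes the connector rather than the entity.  Root-level predicates
    that link the entity directly to a class are kept.
    """
    desc_triples = [t for t in triples if t.predicate == description_predicate and t.is_literal]
    edge_triples = [t for t in triples if not t.is_literal and t.predicate != description_predicate]

    objects = {t.object for t in edge_triples}
    roots = sorted({t.subject for t in edge_triples} - objects)

    out: list[CompositeAnnotation] = []
    edges_by_subject: dict[str, list[RdfTriple]] = {}
    for t in edge_triples:
        edges_by_subject.setdefault(t.subject, []).append(t)

    prefixes = frozenset(ontology_prefixes)

    def walk(node: str, is_root: bool, phrases: tuple[str, ...], seen: tuple[str, ...], paths: list[Path]):
        if len(phrases) > MAX_PATH_DEPTH:
            raise CasqError(f"path deeper than {MAX_PATH_DEPTH} predicate hops at node {node!r}")
        for t in edges_by_subject.get(node, []):
            cid = class_id_of(t.object, prefixes)
            phrase = normalize_predicate(t.predicate)
            if cid is not None:
                # drop the class-attachment predicate only off intermediates
                final = phrases if not is_root else phrases + (phrase,)
                paths.append(Path(final, cid))
            else:
                if t.object in seen:
                    raise CycleError(seen[seen.index(t.object):] + (t.object,))
                walk(t.object, False, phrases + (phrase,), seen + (t.object,), paths)

    for root in roots:
        paths: list[Path] = []
        walk(root, True, (), (root,), paths)
        deduped = sorted(set(paths), key=lambda p: (p.predicates, p.class_id))
        descriptions = [t.object for t in desc_triples if t.subject == root]
        ann = CompositeAnnotation(root, deduped, descriptions)
        if not ann.embeddable:
            log.warning("entity %s has no reachable ontology class; flagged as non-embeddable", root)
        out.append(ann)
    return out


def write_corpus(annotations: Iterable[CompositeAnnotation], stream: IO[str]) -> None:
    """Write annotations as JSON-lines, one entity per line."""
    for ann in annotations:
        stream.write(ann.to_json() + "\n")


def read_corpus(stream: IO[str]) -> Iterator[CompositeAnnotation]:
    """Read a JSON-lines annotation corpus."""
    for line in stream:
        line = line.strip()
        if line:
            yield CompositeAnnotation.from_json(line)
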