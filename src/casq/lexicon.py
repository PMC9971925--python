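"""Ontology-class lexicon: preferred labels and synonyms.

Class embeddings are built from exactly two feature kinds — the preferred
label and the synonyms — which in practice outperforms also mixing in parent
labels or textual definitions.  The lexicon is a plain delimited table
(``class_id``, ``preferred_label``, ``synonyms`` with ``|``-separated cells),
typically exported from an ontology dump; OBO/OWL parsing is deliberately
out of scope here.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable

from .errors import LookupError_, SchemaError, ValidationError

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("class_id", "preferred_label", "synonyms")


@dataclass(frozen=True)
class OntologyClassRecord:
    class_id: str
    preferred_label: str
    synonyms: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.preferred_label:
            raise ValidationError(f"{self.class_id}: preferred_label must be non-empty")


@dataclass
class Lexicon:
    """In-memory store of ontology-class features, keyed by class id."""

    records: dict[str, OntologyClassRecord] = field(default_factory=dict)

    def __contains__(self, class_id: str) -> bool:
        return class_id in self.records

    def __len__(self) -> int:
        return len(self.records)

    def add(self, record: OntologyClassRecord) -> None:
        if record.class_id in self.records:
            log.warning("duplicate class_id %s: last definition wins", record.class_id)
        self.records[record.class_id] = record

    def features_of(self, class_id: str) -> list[str]:
        """Return ``[preferred_label, *synonyms]`` for a stored class."""
        try:
            rec = self.records[class_id]
        except KeyError:
            raise LookupError_(class_id) from None
        return [rec.preferred_label, *rec.synonyms]

    def features_or_fallback(self, class_id: str) -> list[str]:
        """Features of the class, or a pseudo-feature built from its local id.

        Keeps indexing total when a corpus references a class absent from the
        lexicon: ``CHEBI:17138`` degrades to the phrase ``chebi 17138``.
        """
        try:
            return self.features_of(class_id)
        except LookupError_:
            log.warning("class %s not in lexicon; falling back to identifier text", class_id)
            return [" ".join(re.split(r"[^0-9A-Za-z]+", class_id.lower())).strip()]

    def all_features(self) -> list[str]:
        """Every feature text in the lexicon, in stored order."""
        out: list[str] = []
        for rec in self.records.values():
            out.append(rec.preferred_label)
            out.extend(rec.synonyms)
        return out


def load_lexicon(table: IO[str] | str, delimiter: str | None = None) -> Lexicon:
    """Load a lexicon from CSV/TSV text with a header row.

    The delimiter is sniffed from the header when not given; synonyms are
    ``|``-separated within their cell and empty cells mean no synonyms.
    """
    if isinstance(table, str):
        table = io.StringIO(table)
    text = table.read()
    if not text.strip():
        return Lexicon()
    if delimiter is None:
        header = text.splitlines()[0]
        delimiter = "\t" if "\t" in header else ","
    reader = csv.DictReader(io.StringIO(text), delimiter=delimiter)
    missing = [c for c in REQUIRED_COLUMNS if c not in (reader.fieldnames or [])]
    if missing:
        raise SchemaError(f"lexicon table missing columns: {', '.join(missing)}")
    lex = Lexicon()
    for row in reader:
        synonyms = tuple(s.strip() for s in (row["synonyms"] or "").split("|") if s.strip())
        lex.add(OntologyClassRecord(row["class_id"].strip(), row["preferred_label"].strip(), synonyms))
    return lex


def write_lexicon(records: Iterable[OntologyClassRecord], stream: IO[str]) -> None:
    writer = csv.writer(stream)
    writer.writerow(REQUIRED_COLUMNS)
    for rec in records:
        writer.writerow([rec.class_id, rec.preferred_label, "|".join(rec.synonyms)])
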