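"""Bundled worked-example fixtures.

Two annotation trees from the brain energy metabolism CellML model (the
``GAPg/GAPg`` and ``dAMP_dATPn.ATPn`` variables) plus a five-class lexicon
covering their ontology terms.  Each variable ships as its own RDF/XML
document because the two trees reuse an intermediate node name
(``entity_1``) with different edges; parsed separately, each stays the tree
it is drawn as.
"""

from __future__ import annotations

from importlib import resources

from .annotation_graph import CompositeAnnotation, extract_annotations, parse_rdf
from .lexicon import Lexicon, load_lexicon

_DATA = resources.files(__name__.rsplit(".", 1)[0]) / "data"

TABLE_FILES = ("cloutier_gapg.rdf", "cloutier_damp.rdf")


def load_example_corpus() -> list[CompositeAnnotation]:
    """Parse the two bundled annotation documents into one corpus."""
    corpus: list[CompositeAnnotation] = []
    for name in TABLE_FILES:
        triples = parse_rdf((_DATA / name).read_text(), dialect="rdfxml")
        corpus.extend(extract_annotations(triples))
    return corpus


def load_example_lexicon() -> Lexicon:
    """Lexicon for the bundled example's five ontology classes."""
    return load_lexicon((_DATA / "pmr_lexicon.csv").read_text())
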