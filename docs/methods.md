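# Methods

## Problem and representation

A compositely annotated entity is an RDF tree: root = the model entity,
leaves = ontology classes, edges = BioModels qualifiers, plus optional
`dcterms:description` literals on the root. The engine reduces each tree
to predicate **paths** and embeds those; retrieval is cosine ranking of
query embeddings against the stored entity embeddings.

Pruning rules, in order:

1. Intermediate subjects/objects (connector nodes like `entity_1`) are
   generic across annotations and never appear in output.
2. The final predicate of a walk is dropped when its subject is an
   intermediate node — it describes the connector, not the entity. A
   predicate linking the *root* directly to a class is kept: it does
   describe the entity. (The drop rule's stated scope is intermediate
   subjects only; extending it to roots would erase real information on
   one-triple annotations.)
3. Qualifier prefixes are stripped and camelCase is split to lowercase
   phrases (`bqbiol:isVersionOf` → `is version of`).

Composite annotations are trees by definition, so a cycle among
intermediate nodes is a hard error naming the nodes, not silently broken;
path depth is capped at 16 hops to bound malformed graphs. Ontology
classes are recognised by URI suffix against a configurable prefix
registry, accepting both identifiers.org shapes (`.../opb/OPB_00340`,
`.../chebi/CHEBI:17138`) and OBO purls, normalising the separator to
`PREFIX:LOCAL`. Entities annotated only with a description (no reachable
class) are kept in the corpus but flagged and excluded from indexing —
they have no class signal to embed.

## Embedding composition

For a path with class embedding `e_c` (mean of preferred label + synonym
encodings — exactly two feature kinds, which outperforms adding parents or
definitions) and predicate embedding `e_p` (mean of phrase encodings):

```
e_pt = (e_c + w_p·e_p) / (1 + w_p),  0 ≤ w_p ≤ 1;   e_e = mean_i e_pt_i
```

`w_p` bounds the predicate's role below the class's (weight 1). The two
shipped operating points are `L1: w_p = 0` and `L2: w_p = 0.22` — small
against 1 but enough to register predicates. A path with zero predicates
contributes `e_c` alone, the `w_p → 0` limit of the same form. Entity
embeddings are stored **unnormalised**; cosine divides by magnitudes at
query time, and composition must not assume unit inputs (means of unit
vectors are not unit vectors).

Query side: `macro` is `encode(query)`; `micro` is
`e_ph = (w_ph/n) Σ e_i` over extracted concept phrases, where `w_ph` is
the mean over phrases of the best cosine against a class-embedding set;
`mixed` is `m_e·e + e_ph` with `m_e = 1.9` by default (the whole query is
the stronger signal, so `m_e` exceeds `w_ph`, which is cosine-bounded by
1). Mixed with zero extracted phrases degrades to `m_e·e` — the same
ranking as macro, since cosine ignores scale; micro with zero phrases is
an error instructing fallback. Auxiliary (non-concept) phrases, when
enabled, merge into their attached core phrase as
`(e_core + w_p·mean(aux)) / (1 + w_p)` — the same bounded-additive form as
the path blend, reusing `w_p`; no separate weight is introduced.

The class set for `w_ph` defaults to the classes referenced by the indexed
corpus (bounded work, matches the retrieval context); a full-lexicon
override exists.

## Encoder

The text→vector contract requires only determinism and a fixed dimension.
The shipped reference encoder hashes lowercase character trigrams into
`dim` signed buckets (keyed BLAKE2b, so identical across machines and
independent of `PYTHONHASHSEED`) and scales to unit norm. Character
trigrams give the robustness to inflection and hyphenation that subword
tokenisers provide, at test scale: shared vocabulary → positive cosine,
disjoint vocabulary → zero up to rare bucket collisions. Texts shorter
than three characters hash as a single token; `dim ≥ 8` is enforced; the
degenerate case of full sign cancellation falls back to a deterministic
one-hot so no encoding is ever the zero vector. A sentence-transformer
adapter can be plugged behind the same contract but is not required by
anything in the package.

## Retrieval, classification, metrics

Search is exact cosine top-k over the list (no ANN structures at this
scale), with ties broken by ascending entity id so rankings are
reproducible across platforms. Zero-similarity entries are returned;
cosine of a zero vector is an error, never silently 0.

`mixedCl` routes queries to L1 or L2 through a classifier trained on
labels produced by the engine itself: each training query is searched
against both lists and labelled with the argmax of AP@10 (ties → L1). The
baseline classifier is nearest-centroid by cosine over query embeddings —
hand-rolled (~15 lines) because the embeddings are not unit-norm, so the
metric matters. Transformer-based classifiers fit the same contract.

`AP@k` follows the normalisation "R = relevant entities in the results",
i.e. retrieved-relevant within the top k. This inflates AP relative to
the standard `R = min(|relevant|, k)` whenever recall < 1; both are
implemented (`r_definition`), they agree when all relevant entities are
retrieved within k (property-tested), and the retrieved-R form is the
default. RR of a miss is 0 (a mean over queries needs a value). `k = 10`
throughout: one results page.

BM25 (Okapi, `k1 = 1.2`, `b = 0.75`, IDF `ln(1 + (N−df+0.5)/(df+0.5))`) is
the bag-of-words baseline. Each entity's document concatenates its class
labels, synonyms, predicate phrases and descriptions — the same
information the embedding side sees. Tokenisation is lowercase split on
non-alphanumerics; deliberately no stemming or stopword removal, since
avoiding that preprocessing stack is part of the embedding approach's
point of comparison.

## Phrase extraction

The reference extractor is lexicon-driven longest match, left to right,
case-insensitive, with trivial plural tolerance (`astrocytes` matches
`Astrocyte`); matched spans become core phrases in canonical (lowercased
feature) form, and remaining contiguous non-stopword runs become auxiliary
phrases attached to the nearest preceding core phrase (or the following
one when none precedes). It is deterministic by construction. Whether the
original span boundaries of any particular NER model are reproduced is a
non-goal; external extractors wrap to the same `PhraseSet` shape.

## Synthetic data

The generator emulates repository structure: pseudo-word vocabulary,
classes with 1–3 features, entities with 1–4 paths (direct class
attachment or chains through 1–2 intermediates), descriptions composed
from class features. Defaults: 100 entities, 50 classes, 500 words,
description fraction 0.35 (the observed repository fraction of described
entities), occasional description sharing (p = 0.1). RDF/XML is emitted by
a deterministic template writer — byte-identical output across processes
is a tested guarantee, which a generic graph serialiser does not give —
and read back through the ordinary rdflib-based parser.

*Disjoint-vocabulary mode* gives every entity private classes over private
pseudo-words. Under the trigram encoder, cross-entity similarity is then
negligible by construction while each description query shares its
entity's full vocabulary, so any correct implementation must score
mAP@10 = mRR = 1.0 on the gold pairs; the acceptance suite runs this at
100 entities with a 256-dim encoder. What synthetic corpora do **not**
emulate: real ontology synonymy (paraphrase without surface overlap),
inaccurate descriptions, annotation sparsity/noise, and pretrained-encoder
semantics — so passing these tests validates the composition and ranking
machinery, not expected retrieval quality on repository dumps.

## Numerical and storage choices

All composition in float64. The on-disk store is a JSON sidecar (name,
`w_p`, dim, entity order, corpus class ids) plus a flat float32 row-major
matrix; the documented round-trip tolerance is 1e-6, and rebuilds from the
same inputs are byte-identical. Duplicate corpus ids are a hard error;
duplicate lexicon rows are last-wins with a warning; unknown classes at
embedding time fall back to their identifier text as a pseudo-feature
(keeps indexing total) with a warning.

## Known limitations

- The reference encoder is a surface-form model: it cannot rank true
  paraphrases with zero character overlap, so absolute scores on real
  repository text are meaningful only with a pretrained encoder adapter.
- The pruning rules assume tree-shaped annotations; shared intermediate
  nodes across entities in one document would conflate trees (the bundled
  example ships its two trees as separate documents for exactly this
  reason).
- `w_p`, `m_e` and the classifier operating point are fixed constants, not
  adapted per query.
- Test problem sizes (100-entity corpora, 64–256-dim encoders, 1,000-trial
  oracle sweeps) are the package's chosen desk-scale defaults.
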