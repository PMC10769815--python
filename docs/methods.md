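# Methods

## Graph model

All layers share one record type: the RDF triple with URI subject and
predicate and URI-or-literal object. URIs are prefixed names
(`kegg:C00780`) expanded through a per-store prefix table; the default
bases for the project-specific prefixes (`ketfact`, `ketcept`,
`ketrela`, `mikg`, `ppkg`, `drugbank`) are placeholders under one host
and can be overridden when constructing a `TripleStore`. Blank nodes
are not supported: every node that reifies a relation or reaction gets
a minted URI, which keeps sameAs closure and pattern matching decidable
and makes every graph serializable to plain N-Triples. Literals carry
an optional language tag or datatype and compare lexically; an explicit
`xsd:string` datatype is normalized away so equality agrees with RDF
1.1. Named graphs are plain sets of triples, so insertion is idempotent
and the union graph is just the set union. N-Triples and Turtle I/O is
delegated to rdflib; triples are sorted before serialization so that
serialize → parse → serialize is a fixed point.

## KGML ingestion

KGML carries three payload element families — entries, relations,
reactions — plus layout, which is ignored. Parsing validates that all
relation endpoints, reaction participants and group components resolve
to declared entry ids, and reports every dangling id at once. The
triple mapping is:

- entry → type triple + link triple (2 per non-group entry). Entry URIs
  are `kegg:<pathway>/entry/<id>-<kegg-name>`: the KGML-local id
  disambiguates entries sharing a KEGG name, and the first
  whitespace-separated token of the KGML `name` attribute is used.
- relation *n* (document order) → node `kegg:<pathway>/relation/<n>`
  with one type triple per subtype (token `unspecified` when KGML gives
  none) and `entry1`/`entry2` triples.
- reaction → node `kegg:<pathway>/reaction/<id>` with one
  `hasSubstrate` per substrate, one `hasProduct` per product, one
  `reactionType` literal and one KEGG linkage: |substrates| +
  |products| + 2 triples, which is the count formula the property tests
  verify by brute-force enumeration.

Group entries are flattened: a relation touching a group is expanded to
every component, preserving the connectivity that the
literature-vs-database path check depends on; the group node itself
emits no triples.

## Curated facts

A curated fact is a directed edge with relation type restricted to
`activation` or `inhibition` (the two arrow conventions of pathway
figures). Reification emits exactly four triples; the node URI is a
stable SHA-1 hash of (subject, relation type, object, source), so
re-ingesting a fact is a no-op rather than a duplicate — preferred over
a counter precisely for that idempotence. Entities without a database
match keep a label-derived URI in the curated-facts namespace (spaces
and punctuation → underscores); entities with a match get explicit
`owl:sameAs` triples, possibly to several databases at once, merged
later by the closure.

## Dictionary NER

The matcher is a compiled alternation of all surface forms, longest
first, with alphanumeric-boundary lookarounds; under left-to-right
scanning this yields the documented longest-match policy and prevents
substring hits inside longer words ("serotonin" inside "serotonergic").
Matching is case-insensitive by default with the exact-case entry
preferred on ties. This is a deliberate, documented stand-in for
transducer-based concept identification systems; nested/overlapping
concept handling, misspelling normalization and abbreviation expansion
are out of scope. Duplicate sentences within a document are annotated
(and later counted) independently.

## Relation dataset and evaluation

One instance = one sentence + one (drug, partner) pair, with the first
mention of each replaced by `@<surface>$`. Instance ids are stable
hashes of (doc id, sentence, entity1, entity2) so external prediction
files align by id regardless of row order. Metrics are percentages;
any 0/0 ratio is defined as 0, which makes F1 = 0 exactly when TP = 0.
Table display uses round-half-up to integer percent (59.13 → 59,
74.31 → 74); unrounded values are retained internally.

Stratified k-fold: per-fold target sizes are n//k (+1 for the first
n mod k folds, so larger blocks come first); each class is shuffled
with the seed and dealt to folds, with class remainders assigned to the
folds furthest below target. This guarantees simultaneously that fold
sizes differ by ≤ 1 *and* per-fold class counts differ by ≤ 1 from
exact proportion — for 2143 = 1267 + 876 and k = 5 the sizes are
{429, 429, 429, 428, 428}. A generic per-class remainder-to-first-folds
allocation would stack both class remainders on fold 0 and break the
size guarantee, which is why the fold builder is written here rather
than taken from a general-purpose library.

Cross-validation defaults to the inverted orientation: round *i* trains
on fold *i* alone (428 or 429 instances) and tests on the union of the
other four (1715 or 1714). This is intentional and kept as the default
(`orientation="paper"` vs `"conventional"`), since the harness exists
to reproduce that protocol; the conventional switch is the escape
hatch. Means and standard deviations (ddof = 1) are taken over the k
per-round metric rows.

No trainable transformer is bundled. External model predictions are
scored through the id-aligned labels file. The `KeywordPredictor`
(relational-verb lookup between the two tags, verbs selected on the
training fold) exists purely as a cross-validation smoke test and makes
no claim of matching any published model.

## Fusion and queries

sameAs closure is union–find with the lexicographically smallest
rendered URI as class representative, giving a deterministic, order-
independent partition that is a fixed point under re-closure. The BGP
matcher canonicalizes the union graph and the query constants through
the closure, then joins patterns left to right using subject/predicate
indexes; results are deduplicated and sorted by binding values. It
covers conjunctive patterns only — no OPTIONAL, FILTER or property
paths. Query templates ship as editable data files (one pattern per
line, `?var` tokens), with caller-side variable pre-binding for
parameters such as the drug URI.

The literature-vs-database diff treats curated edges as directed:
*shared* requires a same-direction database relation edge between the
endpoint classes (an opposite-direction edge does not count);
*indirect* means a directed database path of length ≥ 2 over relation
edges only (reactions excluded), breadth-first with a configurable
depth cap of 10 — the criterion is undefined upstream, so the cap and
edge set are this package's documented choice.

## Synthetic data

The generators define the study conditions and are not tuning knobs.
The relation corpus defaults to 1267 related + 876 co-mention-only
sentences (2143 total); each sentence instantiates a relational or
neutral template with the drug and exactly one neurotransmitter from
the seven-element panel (glutamate, GABA, serotonin, dopamine,
noradrenaline, acetylcholine, histamine), and sentences are dealt to
synthetic PMIDs five at a time. Gold labels follow from the template
family, so generator bookkeeping is an exact oracle for downstream
counts. The curated-pathway preset is handcrafted rather than sampled:
reaching 26 relations over only 22 entities requires entity reuse, and
the preset keeps all database out-edges on the hub drug (plus
database-only intermediates) so that no literature-only relation can
pick up an accidental directed path; the random diff generator instead
uses disjoint entity pairs and serves as the construction-as-oracle
property test. Microbe layers carry 13 microbiota→neurotransmitter and
17 microbe→BDNF statements with per-row provenance documents.

What the toy data does *not* emulate: real sentence syntax and
ambiguity, thesaurus scale and synonymy, entity frequency skew, OCR or
typographical noise, multi-relation sentences, and annotation errors.
Green tests therefore certify the bookkeeping, algebra and evaluation
machinery — not NER or relation-extraction quality on real literature.

## Numerical and degenerate-input choices

- All randomness flows through explicit integer seeds
  (`random.Random` / `numpy.random.default_rng`); same seed ⇒
  byte-identical fixtures.
- Metrics of an all-zero confusion matrix are an error, not NaN.
- An empty named graph serializes to an empty document; parsing an
  empty document adds nothing.
- Unknown drug in the action query returns empty results rather than
  erroring; missing *layers* (named graphs) are errors that name the
  graph.
- Depth cap 10 on indirect-path search; pattern matching deduplicates
  bindings before sorting.

## Problem sizes

The default test suite and the acceptance script run the full
2143-instance dataset end to end, 200 random BGP graphs of up to 50
triples against the exhaustive oracle, and a few dozen randomized
closure/serialization/count-formula checks; the whole suite completes
in a few seconds on a single core.

## Known limitations

- The relation classifier interface is evaluation-only; no fine-tuned
  language model is included, and polarity (activation vs inhibition)
  classification of extracted relations is out of scope.
- The BGP engine is an in-memory matcher, not a SPARQL endpoint; OWL
  reasoning beyond sameAs is not performed.
- KGML ingestion drops graphics and treats multi-id entry names by
  their first identifier.
- Full IRI bases behind the project prefixes are placeholders; override
  them if dereferenceable URIs are needed.
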