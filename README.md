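# pathkg

Layered biomedical pathway knowledge graphs in Python: convert KGML
pathway maps to RDF, reify manually curated pathway facts, recognize
entities in literature sentences with a thesaurus, build and score a
binary relation-extraction dataset, fuse all layers with `owl:sameAs`
alignment, and answer pathway questions with a sameAs-aware basic
graph pattern matcher.

## The problem

Up-to-date pathway knowledge for a drug — here the running example is
ketamine's antidepressant pharmacology and the role of neurotransmitters
and gut microbiota in it — is split between structured databases (KEGG,
DrugBank) and unstructured literature (pathway figures, abstract
sentences). `pathkg` represents each evidence source as a *named graph*
of RDF triples:

- **kgml_ingest** — KGML pathway XML → triples. A reaction becomes a
  node with one `kegg:hasSubstrate` triple per substrate, one
  `kegg:hasProduct` per product, a `kegg:reactionType` triple
  (reversible/irreversible) and a linkage back to KEGG; a relation
  becomes a node typed by its subtype (activation, inhibition, …)
  connecting two entry URIs.
- **fact_curation** — a figure-curated fact `(subject, activation |
  inhibition, object, source)` is *reified*: the relation itself is a
  minted node `T = (S, P, O)` carrying its type, its two participants
  and its provenance — exactly 4 triples per fact, with deterministic
  (hash-based, idempotent) node minting.
- **text_annotation** — dictionary NER over sentence corpora. A paper
  is `P = [A1 … An]`; each annotation `Ai = [Si, Ei,1 … Ei,m]` pairs the
  sentence with recognized entity spans (longest match, word-bounded,
  case-insensitive with exact-case preference).
- **relation_extraction** — from each sentence containing the drug and
  a partner entity, one instance per pair with the two mentions tagged
  `@entity$` (e.g. `@ketamine$ increased @serotonin$`), gold label 1
  (related) or 0 (co-mention only). Evaluation reports recall
  TP/(TP+FN), precision TP/(TP+FP), specificity TN/(TN+FP) and
  F1 = 2PR/(P+R) as percentages, with stratified 5-fold
  cross-validation that — deliberately — trains on a single fold and
  tests on the union of the other four.
- **fusion_query** — union–find closure over `owl:sameAs` statements,
  a basic-graph-pattern matcher that canonicalizes both graph and query
  through the closure, and four canned query cases (co-occurrence with
  labels; drug actions plus touched pathway elements; the
  literature-vs-database relation diff; microbe–mediator rows across
  microbiome layers).
- **fixtures** — deterministic generators for every input format, sized
  to the study conditions (a 2143-sentence corpus with 1267 related /
  876 unrelated pairs; a 26-relation / 22-entity curated-pathway preset;
  13 + 17 microbe-layer rows).

## Worked example

```python
from pathkg import fixtures as fx
from pathkg.relation_extraction import (
    baseline_predict, confusion, metrics_from_confusion,
    cross_validate, ConstantPredictor,
)

instances, corpus = fx.table1_dataset(seed=42)   # 2143 tagged sentences
gold = [i.gold_label for i in instances]

cm = confusion(baseline_predict(instances, "all"), gold)
print(cm)                                  # ConfusionMatrix(tp=1267, fp=876, tn=0, fn=0)
print(metrics_from_confusion(cm).rounded())  # (100, 59, 0, 74)

cv = cross_validate(instances, ConstantPredictor(1), k=5, seed=1)
print(cv.test_sizes)       # (1714, 1714, 1714, 1715, 1715)
print(cv.sd.recall)        # 0.0
```

The predict-all baseline labels every co-mentioned pair as related, so
its confusion row is exactly the class composition: recall 100%,
precision 59% (= 1267/2143), specificity 0%, F1 74%. The predict-none
baseline gives (0, 0, 876, 1267): specificity 100%, everything else 0.
Each cross-validation round trains on one stratified fold (428 or 429
instances) and tests on the remaining 1714 or 1715.

The same numbers are available from the shell:

```sh
pathkg fixtures --preset table1 --seed 42 --out fx/
pathkg evaluate --dataset fx/dataset.tsv --model baseline-all
pathkg fixtures --preset querycase3 --seed 42 --out qc3/
pathkg query --case 3 --store qc3/ --facts qc3/facts.tsv
# -> {"shared": 10, "literature_only": 16, "indirect": 5}
```

A curated relation is *shared* when a database relation connects the
sameAs classes of its endpoints in the same direction, *literature-only*
otherwise, and *indirect* when a directed database path of length ≥ 2
still joins them.

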