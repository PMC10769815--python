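"""Deterministic toy-data generators for every layer of the graph.

Real inputs to this toolkit are KGML pathway files, UMLS/SNOMED-scale
thesauri, PubMed-derived sentence corpora and manually curated fact
tables.  None of those can be redistributed here, so each has a small
deterministic generator whose *composition* matches the study
conditions the toolkit is evaluated under: the synthetic relation
corpus contains 2143 sentences (1267 related, 876 co-mention-only) each
mentioning the drug and exactly one neurotransmitter; the curated-fact
preset has 26 relations over 22 entities engineered so that 10 are
shared with the database layer, 16 are literature-only and 5 of those
are indirectly connected; the microbe layers carry 13 + 17 provenance
rows.  Generators are pure functions of their spec (seed included):
same seed, byte-identical output.

Sentence realism is a non-goal — templates are grammatical but minimal,
exercising entity tagging and matching rather than NLP quality.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .core_model import OWL_SAMEAS, RDF_TYPE, Literal, Triple, Uri, ValidationError
from .fact_curation import CuratedFact, map_to_kegg
from .kgml_ingest import (
    PathwayEntry,
    PathwayGraph,
    PathwayReaction,
    PathwayRelation,
    write_kgml,
)
from .text_annotation import Thesaurus, annotate_corpus
from .relation_extraction import RelationInstance, build_dataset

__all__ = [
    "NEUROTRANSMITTERS",
    "CorpusSpec",
    "CorpusResult",
    "generate_corpus",
    "toy_thesaurus",
    "DRUG",
    "nt_uri",
    "table1_dataset",
    "generate_kgml",
    "DiffFixture",
    "generate_diff_fixture",
    "querycase3_preset",
    "microbe_fixture",
    "drug_action_fixture",
]

#: The neurotransmitter panel used throughout the toy corpus.
NEUROTRANSMITTERS = (
    "glutamate",
    "GABA",
    "serotonin",
    "dopamine",
    "noradrenaline",
    "acetylcholine",
    "histamine",
)

DRUG = Uri("ketcept", "ketamine")


def nt_uri(label: str) -> Uri:
    return Uri("ketcept", label)


RELATIONAL_TEMPLATES = (
    "{drug} increased {nt} release in the prefrontal cortex.",
    "{drug} administration elevated extracellular {nt} levels.",
    "treatment with {drug} enhanced {nt} signalling in rodents.",
    "{drug} blocked the reuptake of {nt} at the synapse.",
    "a single dose of {drug} triggered a burst of {nt}.",
)

NEUTRAL_TEMPLATES = (
    "{drug} and {nt} were measured in plasma samples.",
    "levels of {nt} were recorded before {drug} infusion.",
    "the study assessed {drug} as well as {nt} in both cohorts.",
    "{nt} was quantified in patients receiving {drug}.",
)


@dataclass(frozen=True, slots=True)
class CorpusSpec:
    """Composition of the synthetic relation corpus."""

    n_pos: int = 1267
    n_neg: int = 876
    neurotransmitters: tuple[str, ...] = NEUROTRANSMITTERS
    relational_templates: tuple[str, ...] = RELATIONAL_TEMPLATES
    neutral_templates: tuple[str, ...] = NEUTRAL_TEMPLATES
    drug: str = "ketamine"
    sentences_per_doc: int = 5
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValidationError("n_pos and n_neg must be non-negative")
        if (self.n_pos or self.n_neg) and (
            not self.relational_templates
            or not self.neutral_templates
            or not self.neurotransmitters
        ):
            raise ValidationError("template and neurotransmitter lists must be non-empty")
        for tmpl in self.relational_templates + self.neutral_templates:
            if "{drug}" not in tmpl or "{nt}" not in tmpl:
                raise ValidationError(
                    f"template must contain {{drug}} and {{nt}} slots: {tmpl!r}"
                )


@dataclass(frozen=True, slots=True)
class CorpusResult:
    """Generated corpus plus the bookkeeping that serves as test oracle."""

    records: tuple[dict, ...]  # {"doc_id":…, "sentence":…}
    labels: tuple[dict, ...]   # {"doc_id","sentence","nt","label"}
    per_nt_counts: dict[str, dict[int, int]]

    def jsonl(self) -> str:
        return "\n".join(json.dumps(r, sort_keys=True) for r in self.records) + (
            "\n" if self.records else ""
        )

    def labels_tsv(self) -> str:
        lines = ["doc_id\tsentence\tnt\tlabel"]
        for rec in self.labels:
            lines.append(f"{rec['doc_id']}\t{rec['sentence']}\t{rec['nt']}\t{rec['label']}")
        return "\n".join(lines) + "\n"


def generate_corpus(spec: CorpusSpec) -> CorpusResult:
    """Emit ``n_pos`` relational sentences (label 1) and ``n_neg``
    neutral co-mentions (label 0); every sentence contains the drug and
    exactly one neurotransmitter."""
    rng = random.Random(spec.seed)
    drafts: list[tuple[str, str, int]] = []  # (sentence, nt, label)
    for _ in range(spec.n_pos):
        nt = rng.choice(spec.neurotransmitters)
        tmpl = rng.choice(spec.relational_templates)
        drafts.append((tmpl.format(drug=spec.drug, nt=nt), nt, 1))
    for _ in range(spec.n_neg):
        nt = rng.choice(spec.neurotransmitters)
        tmpl = rng.choice(spec.neutral_templates)
        drafts.append((tmpl.format(drug=spec.drug, nt=nt), nt, 0))
    rng.shuffle(drafts)

    records: list[dict] = []
    labels: list[dict] = []
    per_nt: dict[str, dict[int, int]] = {
        nt: {0: 0, 1: 0} for nt in spec.neurotransmitters
    }
    for i, (sentence, nt, label) in enumerate(drafts):
        doc_id = f"PMID{1000000 + i // spec.sentences_per_doc}"
        records.append({"doc_id": doc_id, "sentence": sentence})
        labels.append({"doc_id": doc_id, "sentence": sentence, "nt": nt, "label": label})
        per_nt[nt][label] += 1
    return CorpusResult(
        records=tuple(records), labels=tuple(labels), per_nt_counts=per_nt
    )


def toy_thesaurus() -> Thesaurus:
    """Drug + neurotransmitter lexicon mapping surface forms to the
    annotation-layer URIs (a miniature stand-in for UMLS/SNOMED CT)."""
    entries = {"ketamine": DRUG}
    for nt in NEUROTRANSMITTERS:
        entries[nt] = nt_uri(nt)
    # a few multiword forms to exercise longest-match
    entries["serotonin transporter"] = Uri("ketcept", "serotonin_transporter")
    entries["BDNF"] = Uri("ketcept", "BDNF")
    return Thesaurus(entries)


def table1_dataset(
    seed: int = 42, n_pos: int = 1267, n_neg: int = 876
) -> tuple[list[RelationInstance], CorpusResult]:
    """The labelled relation dataset: corpus → annotation → tagged
    instances with gold labels attached from generator bookkeeping."""
    spec = CorpusSpec(n_pos=n_pos, n_neg=n_neg, seed=seed)
    corpus = generate_corpus(spec)
    docs = annotate_corpus(corpus.jsonl(), toy_thesaurus())
    partners = {nt_uri(nt) for nt in NEUROTRANSMITTERS}
    instances = build_dataset(docs, DRUG, partners)
    gold = {
        (rec["doc_id"], rec["sentence"]): rec["label"] for rec in corpus.labels
    }
    out: list[RelationInstance] = []
    for inst in instances:
        key = (inst.doc_id, inst.sentence)
        if key not in gold:
            raise ValidationError(f"instance without generator label: {key}")
        out.append(replace(inst, gold_label=gold[key]))
    if len(out) != n_pos + n_neg:
        raise ValidationError(
            f"expected {n_pos + n_neg} instances, built {len(out)}"
        )
    return out, corpus


# ---------------------------------------------------------------------------
# KGML


def generate_kgml(
    n_entries: int, n_relations: int, n_reactions: int, seed: int = 7
) -> str:
    """A well-formed toy KGML document with exactly the requested
    element counts."""
    if n_entries < 0 or n_relations < 0 or n_reactions < 0:
        raise ValidationError("element counts must be non-negative")
    if (n_relations > 0 or n_reactions > 0) and n_entries < 2:
        raise ValidationError(
            "relations/reactions require at least 2 entries"
        )
    rng = random.Random(seed)
    entries = []
    for i in range(n_entries):
        if i % 2 == 0:
            entries.append(
                PathwayEntry(
                    entry_id=str(i + 1),
                    name=f"cpd:C{10000 + i}",
                    entry_type="compound",
                    link=f"https://www.kegg.jp/entry/C{10000 + i}",
                )
            )
        else:
            entries.append(
                PathwayEntry(
                    entry_id=str(i + 1),
                    name=f"hsa:{100 + i}",
                    entry_type="gene",
                    link=f"https://www.kegg.jp/entry/hsa:{100 + i}",
                )
            )
    ids = [e.entry_id for e in entries]
    subtype_cycle = ("activation", "inhibition", "expression")
    relations = []
    for i in range(n_relations):
        e1, e2 = rng.sample(ids, 2)
        relations.append(
            PathwayRelation(entry1=e1, entry2=e2, subtypes=(subtype_cycle[i % 3],))
        )
    reactions = []
    for i in range(n_reactions):
        n_sub = rng.randint(1, min(2, n_entries - 1))
        n_prod = rng.randint(1, min(2, n_entries - 1))
        substrates = tuple(rng.sample(ids, n_sub))
        products = tuple(rng.sample(ids, n_prod))
        reactions.append(
            PathwayReaction(
                reaction_id=f"rx{i + 1}",
                reaction_type=rng.choice(("reversible", "irreversible")),
                substrates=substrates,
                products=products,
                name=f"rn:R{90000 + i}",
            )
        )
    pg = PathwayGraph(
        pathway_id=f"toy{seed % 1000:03d}",
        entries=entries,
        relations=relations,
        reactions=reactions,
    )
    pg.validate()
    return write_kgml(pg)


# ---------------------------------------------------------------------------
# literature-vs-database diff fixtures


@dataclass(frozen=True, slots=True)
class DiffFixture:
    facts: tuple[CuratedFact, ...]
    db_triples: frozenset[Triple]
    sameas_triples: frozenset[Triple]


def _db_relation_node(n: int) -> Uri:
    return Uri("kegg", f"dbrel/{n}")


def _db_edge_triples(n: int, e1: Uri, e2: Uri, subtype: str) -> set[Triple]:
    node = _db_relation_node(n)
    return {
        Triple(node, RDF_TYPE, Uri("kegg", subtype)),
        Triple(node, Uri("kegg", "entry1"), e1),
        Triple(node, Uri("kegg", "entry2"), e2),
    }


def generate_diff_fixture(
    n_shared: int, n_lit_only: int, n_indirect: int, seed: int = 7
) -> DiffFixture:
    """A curated-fact table plus database graph engineered so the
    literature-vs-database diff returns exactly
    ``(n_shared, n_lit_only, n_indirect)``.

    Entity pairs are disjoint, so no accidental database paths arise;
    indirect facts get a 2-step database chain through an intermediate
    node that exists only in the database layer.
    """
    if min(n_shared, n_lit_only, n_indirect) < 0:
        raise ValidationError("fixture sizes must be non-negative")
    if n_indirect > n_lit_only:
        raise ValidationError("n_indirect cannot exceed n_lit_only")
    rng = random.Random(seed)
    rel_cycle = ("activation", "inhibition")
    facts: list[CuratedFact] = []
    db: set[Triple] = set()
    sameas: set[Triple] = set()
    node_counter = 0

    def kegg_uri(label: str) -> Uri:
        return Uri("kegg", f"X{label}")

    def add_pair(i: int, kind: str) -> tuple[Uri, Uri]:
        a, b = f"{kind}{i}A", f"{kind}{i}B"
        fact = CuratedFact(
            subject_label=a,
            relation_type=rel_cycle[i % 2],
            object_label=b,
            source=f"fig{i}",
        )
        facts.append(fact)
        sameas.add(map_to_kegg(fact.subject, kegg_uri(a)))
        sameas.add(map_to_kegg(fact.object, kegg_uri(b)))
        return kegg_uri(a), kegg_uri(b)

    for i in range(n_shared):
        ka, kb = add_pair(i, "S")
        db |= _db_edge_triples(node_counter, ka, kb, rel_cycle[i % 2])
        node_counter += 1
    for i in range(n_lit_only):
        ka, kb = add_pair(i, "L")
        if i < n_indirect:
            mid = Uri("kegg", f"MID{i}")
            db |= _db_edge_triples(node_counter, ka, mid, "activation")
            node_counter += 1
            db |= _db_edge_triples(node_counter, mid, kb, "activation")
            node_counter += 1
    rng.shuffle(facts)
    return DiffFixture(
        facts=tuple(facts),
        db_triples=frozenset(db),
        sameas_triples=frozenset(sameas),
    )


def querycase3_preset() -> DiffFixture:
    """The handcrafted curated-pathway fixture: 26 directed relations
    over 22 entities, of which 10 have a direct database counterpart,
    16 are literature-only, and 5 of those are bridged by a 2-step
    database chain through a database-only intermediate.

    The hub drug carries all database out-edges, so literature-only
    relations between downstream entities can never pick up an
    accidental database path.
    """
    drug = "ketamine"
    direct = [  # ketamine → target with a database counterpart
        ("inhibition", "NMDAR"),
        ("activation", "AMPAR"),
        ("activation", "D2R"),
        ("activation", "D3R"),
        ("inhibition", "NET"),
        ("inhibition", "SERT"),
        ("activation", "VDCC"),
        ("inhibition", "eEF2"),
        ("activation", "glutamate"),
        ("inhibition", "GABA"),
    ]
    bridged = [  # ketamine → target, database path via an intermediate
        ("activation", "BDNF"),
        ("activation", "TrkB"),
        ("activation", "mTOR"),
        ("activation", "ERK"),
        ("activation", "dopamine"),
    ]
    downstream = [  # literature-only edges among downstream entities
        ("glutamate", "activation", "serotonin"),
        ("GABA", "inhibition", "noradrenaline"),
        ("NMDAR", "activation", "acetylcholine"),
        ("AMPAR", "activation", "histamine"),
        ("D2R", "activation", "MEK"),
        ("D3R", "activation", "AKT"),
        ("NET", "inhibition", "SERT"),
        ("VDCC", "activation", "eEF2"),
        ("BDNF", "activation", "TrkB"),
        ("mTOR", "activation", "ERK"),
        ("dopamine", "activation", "GABA"),
    ]

    def kegg_uri(label: str) -> Uri:
        safe = "".join(c if c.isalnum() or c in "_.-" else "_" for c in label)
        return Uri("kegg", f"K_{safe}")

    facts: list[CuratedFact] = []
    db: set[Triple] = set()
    sameas: set[Triple] = set()
    entities: set[str] = set()
    node = 0

    def add_fact(s: str, rel: str, o: str, source: str) -> CuratedFact:
        fact = CuratedFact(
            subject_label=s, relation_type=rel, object_label=o, source=source
        )
        facts.append(fact)
        for label, uri in ((s, fact.subject), (o, fact.object)):
            if label not in entities:
                entities.add(label)
                sameas.add(map_to_kegg(uri, kegg_uri(label)))
        return fact

    for rel, target in direct:
        add_fact(drug, rel, target, "fig:direct")
        db |= _db_edge_triples(node, kegg_uri(drug), kegg_uri(target), rel)
        node += 1
    for rel, target in bridged:
        add_fact(drug, rel, target, "fig:bridged")
        mid = Uri("kegg", f"MID_{target}")
        db |= _db_edge_triples(node, kegg_uri(drug), mid, "activation")
        node += 1
        db |= _db_edge_triples(node, mid, kegg_uri(target), "activation")
        node += 1
    for s, rel, o in downstream:
        add_fact(s, rel, o, "fig:literature")

    assert len(facts) == 26 and len(entities) == 22
    return DiffFixture(
        facts=tuple(facts),
        db_triples=frozenset(db),
        sameas_triples=frozenset(sameas),
    )


# ---------------------------------------------------------------------------
# microbe layers and drug actions


_MIKG_ROWS = (
    ("L_rhamnosus", "GABA"),
    ("L_brevis", "GABA"),
    ("L_plantarum", "GABA"),
    ("L_paracasei", "GABA"),
    ("L_delbrueckii", "GABA"),
    ("L_helveticus", "serotonin"),
    ("L_casei", "serotonin"),
    ("L_reuteri", "serotonin"),
    ("L_fermentum", "glutamate"),
    ("L_gasseri", "glutamate"),
    ("B_longum", "dopamine"),
    ("B_breve", "acetylcholine"),
    ("B_infantis", "histamine"),
)

_PPKG_MICROBES = (
    "L_rhamnosus", "L_plantarum", "L_helveticus", "L_casei", "L_reuteri",
    "L_paracasei", "L_fermentum", "L_gasseri", "L_brevis", "L_acidophilus",
    "L_bulgaricus", "B_longum", "B_breve", "B_infantis", "B_bifidum",
    "B_lactis", "B_adolescentis",
)


def microbe_fixture(
    n_mikg: int = 13, n_ppkg: int = 17, seed: int = 0
) -> tuple[set[Triple], set[Triple]]:
    """Microbiota (microbe increases neurotransmitter) and
    pre-/probiotics (microbe affects BDNF) layer triples, each row with
    a distinct provenance document."""
    if n_mikg > len(_MIKG_ROWS) or n_ppkg > len(_PPKG_MICROBES):
        raise ValidationError(
            f"at most {len(_MIKG_ROWS)} microbiota and {len(_PPKG_MICROBES)} "
            "pre-/probiotics rows available"
        )
    rng = random.Random(seed)
    mikg: set[Triple] = set()
    for i, (microbe, nt) in enumerate(_MIKG_ROWS[:n_mikg]):
        st = Uri("mikg", f"st{i}")
        mikg |= {
            Triple(st, RDF_TYPE, Uri("mikg", "Increases")),
            Triple(st, Uri("mikg", "microbe"), Uri("mikg", microbe)),
            Triple(st, Uri("mikg", "mediator"), nt_uri(nt)),
            Triple(st, Uri("mikg", "doc"), Literal(f"PMID{2000000 + rng.randint(0, 99999)}")),
        }
    ppkg: set[Triple] = set()
    for i, microbe in enumerate(_PPKG_MICROBES[:n_ppkg]):
        st = Uri("ppkg", f"st{i}")
        ppkg |= {
            Triple(st, RDF_TYPE, Uri("ppkg", "Affects")),
            Triple(st, Uri("ppkg", "microbe"), Uri("ppkg", microbe)),
            Triple(st, Uri("ppkg", "mediator"), Uri("ketcept", "BDNF")),
            Triple(st, Uri("ppkg", "doc"), Literal(f"DOI10.{3000000 + rng.randint(0, 99999)}")),
        }
    return mikg, ppkg


def drug_action_fixture() -> tuple[set[Triple], set[Triple]]:
    """Seven pharmacological actions of the drug on receptors and
    transporters of five neurotransmitter systems (DrugBank-style), plus
    the sameAs triples aligning the action layer with the others."""
    drug = Uri("drugbank", "ketamine")
    actions = (
        ("antagonist", "NMDAR"),
        ("antagonist", "mAChR"),
        ("agonist", "D2R"),
        ("agonist", "sigma1R"),
        ("inhibitor", "NET"),
        ("inhibitor", "SERT"),
        ("inhibitor", "DAT"),
    )
    triples = {
        Triple(drug, Uri("drugbank", act), Uri("drugbank", target))
        for act, target in actions
    }
    sameas = {
        Triple(drug, OWL_SAMEAS, DRUG),
        Triple(Uri("drugbank", "NMDAR"), OWL_SAMEAS, Uri("kegg", "K_NMDAR")),
        Triple(Uri("drugbank", "SERT"), OWL_SAMEAS, Uri("kegg", "K_SERT")),
        Triple(Uri("drugbank", "NET"), OWL_SAMEAS, Uri("kegg", "K_NET")),
        Triple(Uri("drugbank", "D2R"), OWL_SAMEAS, Uri("kegg", "K_D2R")),
    }
    return triples, sameas
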