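"""sameAs closure, BGP matching against a brute-force oracle, and the
four query cases."""

import itertools
import random

import pytest

from pathkg import fixtures as fx
from pathkg.core_model import (
    OWL_SAMEAS,
    RDF_TYPE,
    Literal,
    Triple,
    TripleStore,
    Uri,
    ValidationError,
)
from pathkg.fusion_query import (
    GRAPHS,
    AlignmentClosure,
    diff_literature_db,
    load_template,
    match_bgp,
    parse_patterns,
    query_case_1,
    query_case_2,
    query_case_4,
    sameas_closure,
    substitute,
)
from pathkg.fact_curation import CuratedFact, map_to_kegg
from pathkg.kgml_ingest import parse_kgml, pathway_to_triples
from pathkg.relation_extraction import build_dataset, relations_to_triples
from pathkg.text_annotation import annotate_corpus, annotations_to_triples


def u(tok: str) -> Uri:
    return Uri(*tok.split(":", 1))


def sameas(a: str, b: str) -> Triple:
    return Triple(u(a), OWL_SAMEAS, u(b))


class TestSameasClosure:
    def test_transitivity(self):
        closure = sameas_closure([sameas("kegg:a", "kegg:b"), sameas("kegg:b", "kegg:c")])
        assert closure.class_of(u("kegg:a")) == {u("kegg:a"), u("kegg:b"), u("kegg:c")}

    def test_cross_database_alignment(self):
        triples = [
            map_to_kegg(u("ketfact:Serotonin"), u("kegg:C00780")),
            map_to_kegg(u("ketfact:Serotonin"), u("umls:C0036751")),
        ]
        closure = sameas_closure(triples)
        assert len(closure.class_of(u("kegg:C00780"))) == 3

    def test_no_sameas_all_singletons(self):
        closure = sameas_closure([Triple(u("kegg:a"), RDF_TYPE, u("kegg:compound"))])
        assert closure.classes == ()
        assert closure.rep(u("kegg:a")) == u("kegg:a")

    def test_idempotent_and_order_independent(self):
        rng = random.Random(17)
        nodes = [u(f"kegg:n{i}") for i in range(12)]
        edges = [
            sameas(a.render(), b.render())
            for a, b in (rng.sample(nodes, 2) for _ in range(10))
        ]
        base = sameas_closure(edges)
        for _ in range(5):
            shuffled = edges[:]
            rng.shuffle(shuffled)
            assert sameas_closure(shuffled).classes == base.classes
        # closure of its own induced sameAs statements is a fixed point
        induced = [
            Triple(m, OWL_SAMEAS, base.rep(m)) for cls in base.classes for m in cls
        ]
        assert sameas_closure(induced).classes == base.classes


def oracle_bgp(triples, patterns, closure=None):
    """Exhaustive enumeration over all pattern->triple assignments."""
    def canon(term):
        if closure is None or isinstance(term, (Literal, str)):
            return term
        return closure.rep(term)

    facts = [
        (canon(t.subject), canon(t.predicate),
         canon(t.object) if isinstance(t.object, Uri) else t.object)
        for t in triples
    ]
    results = set()
    for combo in itertools.product(facts, repeat=len(patterns)):
        binding = {}
        ok = True
        for pat, fact in zip(patterns, combo):
            for p, f in zip(pat, fact):
                if isinstance(p, str):
                    if binding.get(p, f) != f:
                        ok = False
                        break
                    binding[p] = f
                elif canon(p) != f:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            results.add(frozenset((k, v.render()) for k, v in binding.items()))
    return results


def as_set(bindings):
    return {frozenset((k, v.render()) for k, v in b.items()) for b in bindings}


class TestMatchBgp:
    def test_single_pattern_two_matches(self):
        triples = {
            Triple(u("kegg:r1"), u("kegg:hasSubstrate"), u("kegg:C00780")),
            Triple(u("kegg:r2"), u("kegg:hasSubstrate"), u("kegg:C00780")),
            Triple(u("kegg:r3"), u("kegg:hasSubstrate"), u("kegg:C99999")),
        }
        bindings = match_bgp(triples, [("?x", u("kegg:hasSubstrate"), u("kegg:C00780"))])
        assert [b["?x"].render() for b in bindings] == ["kegg:r1", "kegg:r2"]

    def test_alias_query_equals_canonical_query(self):
        triples = {
            Triple(u("kegg:r1"), u("kegg:hasSubstrate"), u("kegg:C00780")),
            sameas("ketfact:Serotonin", "kegg:C00780"),
        }
        closure = sameas_closure(triples)
        via_alias = match_bgp(
            triples, [("?x", u("kegg:hasSubstrate"), u("ketfact:Serotonin"))], closure
        )
        via_canon = match_bgp(
            triples, [("?x", u("kegg:hasSubstrate"), u("kegg:C00780"))], closure
        )
        assert as_set(via_alias) == as_set(via_canon) != set()

    def test_zero_variable_pattern_is_boolean(self):
        triples = {Triple(u("kegg:a"), RDF_TYPE, u("kegg:compound"))}
        hit = match_bgp(triples, [(u("kegg:a"), RDF_TYPE, u("kegg:compound"))])
        miss = match_bgp(triples, [(u("kegg:a"), RDF_TYPE, u("kegg:gene"))])
        assert hit == [{}] and miss == []

    def test_join_matches_brute_force_on_random_graphs(self):
        rng = random.Random(2024)
        subjects = [u(f"kegg:s{i}") for i in range(5)]
        preds = [u(f"kegg:p{i}") for i in range(3)]
        objects = subjects + [Literal("x"), Literal("y")]
        for _ in range(25):
            triples = {
                Triple(rng.choice(subjects), rng.choice(preds), rng.choice(objects))
                for _ in range(rng.randint(3, 30))
            }
            patterns = []
            for _ in range(rng.randint(1, 3)):
                pat = tuple(
                    rng.choice(["?a", "?b", "?c"]) if rng.random() < 0.5
                    else rng.choice([subjects, preds, objects][pos])
                    for pos in range(3)
                )
                patterns.append(pat)
            got = as_set(match_bgp(triples, patterns))
            assert got == oracle_bgp(triples, patterns)

    def test_variable_token_must_start_with_question_mark(self):
        with pytest.raises(ValidationError):
            match_bgp(set(), [("x", u("kegg:p"), u("kegg:o"))])


class TestTemplates:
    def test_parse_patterns_terms(self):
        patterns = parse_patterns(
            "# comment\n?s kegg:entry1 ?e1\n?s rdfs:label \"free text\"\n"
        )
        assert patterns == [
            ("?s", u("kegg:entry1"), "?e1"),
            ("?s", u("rdfs:label"), Literal("free text")),
        ]

    def test_substitute_prebinds(self):
        patterns = parse_patterns("?s ketcept:mentions ?drug\n")
        bound = substitute(patterns, {"?drug": u("ketcept:ketamine")})
        assert bound == [("?s", u("ketcept:mentions"), u("ketcept:ketamine"))]

    @pytest.mark.parametrize(
        "name", ["case1", "case2", "case3", "case4_mikg", "case4_ppkg"]
    )
    def test_shipped_templates_parse(self, name):
        assert len(load_template(name)) >= 1


def _corpus_store(n_pos, n_neg, seed):
    corpus = fx.generate_corpus(fx.CorpusSpec(n_pos=n_pos, n_neg=n_neg, seed=seed))
    docs = annotate_corpus(corpus.jsonl(), fx.toy_thesaurus())
    partners = {fx.nt_uri(n) for n in fx.NEUROTRANSMITTERS}
    instances = build_dataset(docs, fx.DRUG, partners)
    labels = {"manual": [rec["label"] for rec in corpus.labels]}
    store = TripleStore()
    store.add_triples(GRAPHS["ketcept"], annotations_to_triples(docs))
    store.add_triples(GRAPHS["ketrela"], relations_to_triples(instances, labels))
    return store, corpus, partners


class TestQueryCase1:
    def test_rows_join_labels(self):
        store, corpus, partners = _corpus_store(3, 2, seed=5)
        rows = query_case_1(store, fx.DRUG, partners)
        assert len(rows) == 5
        assert sum(r.labels["manual"] for r in rows) == 3

    def test_corpus_without_drug(self):
        thes = fx.toy_thesaurus()
        docs = annotate_corpus(
            ['{"doc_id": "p1", "sentence": "serotonin was measured"}'], thes
        )
        store = TripleStore()
        store.add_triples(GRAPHS["ketcept"], annotations_to_triples(docs))
        store.add_triples(GRAPHS["ketrela"], set())
        rows = query_case_1(store, fx.DRUG, {fx.nt_uri("serotonin")})
        assert rows == []

    def test_per_neurotransmitter_tallies_match_generator(self):
        store, corpus, partners = _corpus_store(25, 15, seed=8)
        rows = query_case_1(store, fx.DRUG, partners)
        tallies = {nt: 0 for nt in fx.NEUROTRANSMITTERS}
        for r in rows:
            tallies[r.partner.local] += 1
        expected = {nt: sum(c.values()) for nt, c in corpus.per_nt_counts.items()}
        assert tallies == expected

    def test_missing_layer_is_named(self):
        store = TripleStore()
        store.add_triples(GRAPHS["ketcept"], set())
        with pytest.raises(ValidationError, match="graph:ketrela"):
            query_case_1(store, fx.DRUG, set())


class TestQueryCase2:
    def _store(self):
        actions, sameas_t = fx.drug_action_fixture()
        preset = fx.querycase3_preset()
        store = TripleStore()
        store.add_triples(GRAPHS["drugbank"], actions)
        store.add_triples(GRAPHS["sameas"], sameas_t | preset.sameas_triples)
        store.add_triples(GRAPHS["kegg"], preset.db_triples)
        return store

    def test_seven_drug_actions(self):
        actions, subgraph = query_case_2(self._store(), fx.DRUG)
        assert len(actions) == 7
        assert {a.action.local for a in actions} == {"antagonist", "agonist", "inhibitor"}

    def test_unaligned_target_gives_actions_but_no_subgraph(self):
        action_triples, _ = fx.drug_action_fixture()
        store = TripleStore()
        store.add_triples(GRAPHS["drugbank"], action_triples)
        store.add_triples(GRAPHS["kegg"], set())
        actions, subgraph = query_case_2(store, u("drugbank:ketamine"))
        assert len(actions) == 7 and subgraph == set()

    def test_target_feeding_one_reaction_pulls_its_four_triples(self):
        kgml = """<pathway name="path:toy">
          <entry id="1" name="cpd:C00025" type="compound"/>
          <entry id="2" name="cpd:C00334" type="compound"/>
          <reaction id="r1" name="rn:R1" type="irreversible">
            <substrate id="1" name="cpd:C00025"/>
            <product id="2" name="cpd:C00334"/>
          </reaction>
        </pathway>"""
        pg = parse_kgml(kgml)
        store = TripleStore()
        store.add_triples(GRAPHS["kegg"], pathway_to_triples(pg))
        store.add_triples(
            GRAPHS["drugbank"],
            {Triple(u("drugbank:ketamine"), u("drugbank:agonist"), u("drugbank:target"))},
        )
        store.add_triples(
            GRAPHS["sameas"],
            {sameas("drugbank:target", "kegg:toy/entry/1-cpd_C00025")},
        )
        actions, subgraph = query_case_2(store, u("drugbank:ketamine"))
        assert len(actions) == 1
        reaction_triples = {t for t in subgraph if "/reaction/" in t.subject.local}
        assert len(reaction_triples) == 4

    def test_unknown_drug_empty(self):
        actions, subgraph = query_case_2(self._store(), u("drugbank:aspirin"))
        assert actions == [] and subgraph == set()


class TestDiff:
    def test_direct_edge_is_shared(self):
        fixture = fx.generate_diff_fixture(1, 0, 0, seed=1)
        closure = sameas_closure(fixture.sameas_triples)
        diff = diff_literature_db(fixture.facts, fixture.db_triples, closure)
        assert diff.sizes() == (1, 0, 0)

    def test_two_step_path_is_literature_only_and_indirect(self):
        fixture = fx.generate_diff_fixture(0, 1, 1, seed=1)
        closure = sameas_closure(fixture.sameas_triples)
        diff = diff_literature_db(fixture.facts, fixture.db_triples, closure)
        assert diff.sizes() == (0, 1, 1)

    def test_opposite_direction_edge_is_literature_only(self):
        fact = CuratedFact("A", "activation", "B", source="f")
        sameas_t = {
            map_to_kegg(fact.subject, u("kegg:KA")),
            map_to_kegg(fact.object, u("kegg:KB")),
        }
        db = {
            Triple(u("kegg:rel0"), u("kegg:entry1"), u("kegg:KB")),  # B -> A
            Triple(u("kegg:rel0"), u("kegg:entry2"), u("kegg:KA")),
        }
        closure = sameas_closure(sameas_t)
        diff = diff_literature_db([fact], db, closure)
        assert diff.sizes() == (0, 1, 0)

    def test_partition_identities_on_random_fixtures(self):
        rng = random.Random(99)
        for _ in range(10):
            n_lit = rng.randint(0, 6)
            spec = (rng.randint(0, 6), n_lit, rng.randint(0, n_lit))
            fixture = fx.generate_diff_fixture(*spec, seed=rng.randint(0, 999))
            closure = sameas_closure(fixture.sameas_triples)
            diff = diff_literature_db(fixture.facts, fixture.db_triples, closure)
            assert diff.sizes() == spec
            assert set(diff.shared) | set(diff.literature_only) == set(fixture.facts)
            assert set(diff.shared) & set(diff.literature_only) == set()
            assert set(diff.indirect) <= set(diff.literature_only)

    def test_engineered_partition_10_16_5(self):
        preset = fx.querycase3_preset()
        closure = sameas_closure(preset.sameas_triples)
        diff = diff_literature_db(preset.facts, preset.db_triples, closure)
        assert diff.sizes() == (10, 16, 5)


class TestQueryCase4:
    def test_union_of_microbe_layers(self):
        mikg, ppkg = fx.microbe_fixture(13, 17, seed=0)
        store = TripleStore()
        store.add_triples(GRAPHS["mikg"], mikg)
        store.add_triples(GRAPHS["ppkg"], ppkg)
        rows = query_case_4(store)
        assert len(rows) == 30
        by_graph = {}
        for r in rows:
            by_graph[r.source_graph.render()] = by_graph.get(r.source_graph.render(), 0) + 1
        assert by_graph == {"graph:mikg": 13, "graph:ppkg": 17}

    def test_empty_layers(self):
        store = TripleStore()
        store.add_triples(GRAPHS["mikg"], set())
        store.add_triples(GRAPHS["ppkg"], set())
        assert query_case_4(store) == []

    def test_duplicate_doc_across_layers_counts_once_per_graph(self):
        mk = lambda g, st_id, typ, microbe, mediator, doc: {
            Triple(u(f"{g}:{st_id}"), RDF_TYPE, u(f"{g}:{typ}")),
            Triple(u(f"{g}:{st_id}"), u(f"{g}:microbe"), u(f"{g}:{microbe}")),
            Triple(u(f"{g}:{st_id}"), u(f"{g}:mediator"), u("ketcept:GABA")),
            Triple(u(f"{g}:{st_id}"), u(f"{g}:doc"), Literal(doc)),
        }
        store = TripleStore()
        store.add_triples(GRAPHS["mikg"], mk("mikg", "s1", "Increases", "Lr", "GABA", "PMID1"))
        store.add_triples(GRAPHS["ppkg"], mk("ppkg", "s1", "Affects", "Lr", "BDNF", "PMID1"))
        rows = query_case_4(store)
        assert len(rows) == 2
        assert {r.source_graph.render() for r in rows} == {"graph:mikg", "graph:ppkg"}

    def test_missing_graph_errors(self):
        store = TripleStore()
        store.add_triples(GRAPHS["mikg"], set())
        with pytest.raises(ValidationError, match="graph:ppkg"):
            query_case_4(store)
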