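"""sameAs alignment, basic-graph-pattern matching, and the query cases.

The layers of the knowledge graph name the same real-world entities with
different URIs (a curated label, a KEGG compound, a UMLS concept).
``owl:sameAs`` statements align them; their reflexive–symmetric–
transitive closure partitions URIs into equivalence classes, each with a
deterministic canonical representative.  Queries are conjunctions of
triple patterns (a *basic graph pattern*) matched against the union
graph after canonicalization, so querying via any alias returns the
same bindings as via the canonical URI.

Four canned query cases mirror common questions over a drug-centred
pathway graph: (1) which partner entities co-occur with the drug in
text and with what relation labels; (2) what are the drug's
pharmacological actions and which pathway elements do the targets touch;
(3) how do literature-curated relations compare to database relations
(shared / literature-only / indirectly connected); (4) which microbes
relate to the drug's mediators (neurotransmitters, BDNF) across the
microbiome layers.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence, Union

import networkx as nx

from .core_model import (
    OWL_SAMEAS,
    RDF_TYPE,
    Literal,
    Term,
    Triple,
    TripleStore,
    Uri,
    ValidationError,
)
from .fact_curation import CuratedFact
from .kgml_ingest import ENTRY1, ENTRY2, HAS_PRODUCT, HAS_SUBSTRATE
from . import text_annotation as ta
from . import relation_extraction as rx

__all__ = [
    "AlignmentClosure",
    "sameas_closure",
    "TriplePattern",
    "PatternTerm",
    "match_bgp",
    "parse_patterns",
    "load_template",
    "substitute",
    "RelationDiff",
    "diff_literature_db",
    "query_case_1",
    "query_case_2",
    "query_case_3",
    "query_case_4",
    "GRAPHS",
]

#: Conventional named-graph names for the layers.
GRAPHS = {
    "ketfact": Uri("graph", "ketfact"),
    "ketcept": Uri("graph", "ketcept"),
    "ketrela": Uri("graph", "ketrela"),
    "kegg": Uri("graph", "kegg"),
    "drugbank": Uri("graph", "drugbank"),
    "mikg": Uri("graph", "mikg"),
    "ppkg": Uri("graph", "ppkg"),
    "sameas": Uri("graph", "sameas"),
}


# ---------------------------------------------------------------------------
# sameAs closure


@dataclass(frozen=True)
class AlignmentClosure:
    """Equivalence classes induced by sameAs statements.

    ``canonical`` maps every mentioned URI to its class representative
    (the lexicographically smallest rendered form, for determinism);
    URIs never mentioned in a sameAs statement are implicit singletons.
    """

    classes: tuple[frozenset[Uri], ...]
    canonical: Mapping[Uri, Uri]

    def rep(self, uri: Uri) -> Uri:
        return self.canonical.get(uri, uri)

    def rep_term(self, term: Term) -> Term:
        return self.rep(term) if isinstance(term, Uri) else term

    def same(self, a: Uri, b: Uri) -> bool:
        return self.rep(a) == self.rep(b)

    def class_of(self, uri: Uri) -> frozenset[Uri]:
        rep = self.rep(uri)
        for cls in self.classes:
            if rep in cls:
                return cls
        return frozenset({uri})


def sameas_closure(triples: Iterable[Triple]) -> AlignmentClosure:
    """Union–find closure over the ``owl:sameAs`` edges of the input.

    Only sameAs triples are consumed; the closure is idempotent and
    independent of triple order.
    """
    parent: dict[Uri, Uri] = {}

    def find(u: Uri) -> Uri:
        root = u
        while parent[root] != root:
            root = parent[root]
        while parent[u] != root:  # path compression
            parent[u], u = root, parent[u]
        return root

    def union(a: Uri, b: Uri) -> None:
        for x in (a, b):
            parent.setdefault(x, x)
        ra, rb = find(a), find(b)
        if ra != rb:
            # deterministic root: smaller rendered form wins
            if rb.render() < ra.render():
                ra, rb = rb, ra
            parent[rb] = ra

    for t in triples:
        if t.predicate == OWL_SAMEAS and isinstance(t.object, Uri):
            union(t.subject, t.object)

    groups: dict[Uri, set[Uri]] = {}
    for u in parent:
        groups.setdefault(find(u), set()).add(u)
    canonical: dict[Uri, Uri] = {}
    classes: list[frozenset[Uri]] = []
    for members in groups.values():
        rep = min(members, key=Uri.render)
        classes.append(frozenset(members))
        for m in members:
            canonical[m] = rep
    classes.sort(key=lambda c: min(c, key=Uri.render).render())
    return AlignmentClosure(classes=tuple(classes), canonical=canonical)


# ---------------------------------------------------------------------------
# basic graph patterns

#: A pattern term is a URI, a literal, or a ``?var`` token.
PatternTerm = Union[Uri, Literal, str]
TriplePattern = tuple[PatternTerm, PatternTerm, PatternTerm]
Binding = dict[str, Term]


def _is_var(term: PatternTerm) -> bool:
    return isinstance(term, str)


def _check_var(term: PatternTerm) -> None:
    if isinstance(term, str) and not term.startswith("?"):
        raise ValidationError(f"variable tokens must start with '?': {term!r}")


def substitute(
    patterns: Sequence[TriplePattern], binding: Mapping[str, Term]
) -> list[TriplePattern]:
    """Pre-bind variables in patterns (used to parametrize templates)."""
    out: list[TriplePattern] = []
    for pat in patterns:
        out.append(
            tuple(
                binding.get(t, t) if isinstance(t, str) else t for t in pat
            )  # type: ignore[arg-type]
        )
    return out


def _canon_triples(
    triples: Iterable[Triple], closure: Optional[AlignmentClosure]
) -> set[tuple[Term, Term, Term]]:
    if closure is None:
        return {(t.subject, t.predicate, t.object) for t in triples}
    return {
        (closure.rep(t.subject), closure.rep(t.predicate), closure.rep_term(t.object))
        for t in triples
    }


def _render_term(term: Term) -> str:
    return term.render()


def match_bgp(
    store: Union[TripleStore, Iterable[Triple]],
    patterns: Sequence[TriplePattern],
    closure: Optional[AlignmentClosure] = None,
    graphs: Optional[Sequence[Uri]] = None,
) -> list[Binding]:
    """All bindings of the pattern conjunction over the (canonicalized)
    union graph, deterministically ordered by binding values.

    A pattern with zero variables degenerates to a boolean: the result
    is one empty binding if it is entailed, none otherwise.
    """
    for pat in patterns:
        if len(pat) != 3:
            raise ValidationError(f"pattern must have 3 terms: {pat!r}")
        for term in pat:
            _check_var(term)
    if isinstance(store, TripleStore):
        if graphs is not None:
            triples: set[Triple] = set()
            for g in graphs:
                triples |= store.graph(g)
        else:
            triples = store.union()
    else:
        triples = set(store)
    facts = _canon_triples(triples, closure)

    # canonicalize constants in patterns as well
    def canon_pat(term: PatternTerm) -> PatternTerm:
        if isinstance(term, str):
            return term
        if closure is not None:
            return closure.rep_term(term)
        return term

    cpatterns = [tuple(canon_pat(t) for t in pat) for pat in patterns]

    # positional indexes so joins touch only candidate facts
    idx_sp: dict[tuple[Term, Term], list[tuple[Term, Term, Term]]] = {}
    idx_p: dict[Term, list[tuple[Term, Term, Term]]] = {}
    idx_s: dict[Term, list[tuple[Term, Term, Term]]] = {}
    for fact in facts:
        idx_sp.setdefault((fact[0], fact[1]), []).append(fact)
        idx_p.setdefault(fact[1], []).append(fact)
        idx_s.setdefault(fact[0], []).append(fact)

    def candidates(
        pat: tuple[PatternTerm, PatternTerm, PatternTerm], binding: Binding
    ) -> Iterable[tuple[Term, Term, Term]]:
        def resolve(t: PatternTerm) -> Optional[Term]:
            if isinstance(t, str):
                return binding.get(t)
            return t

        s, p = resolve(pat[0]), resolve(pat[1])
        if s is not None and p is not None:
            return idx_sp.get((s, p), ())
        if p is not None:
            return idx_p.get(p, ())
        if s is not None:
            return idx_s.get(s, ())
        return facts

    results: list[Binding] = []

    def extend(i: int, binding: Binding) -> None:
        if i == len(cpatterns):
            results.append(dict(binding))
            return
        pat = cpatterns[i]
        for fact in candidates(pat, binding):
            new = dict(binding)
            ok = True
            for p_term, f_term in zip(pat, fact):
                if isinstance(p_term, str):
                    if p_term in new:
                        if new[p_term] != f_term:
                            ok = False
                            break
                    else:
                        new[p_term] = f_term
                elif p_term != f_term:
                    ok = False
                    break
            if ok:
                extend(i + 1, new)

    extend(0, {})
    # dedupe and order deterministically
    seen: set[tuple[tuple[str, str], ...]] = set()
    unique: list[Binding] = []
    for b in results:
        key = tuple(sorted((v, _render_term(t)) for v, t in b.items()))
        if key not in seen:
            seen.add(key)
            unique.append(b)
    unique.sort(
        key=lambda b: tuple(
            _render_term(b[v]) for v in sorted(b)
        )
    )
    return unique


def parse_patterns(text: str) -> list[TriplePattern]:
    """Parse a query template: one pattern per line, whitespace-separated
    terms, ``?var`` tokens, ``prefix:local`` URIs, double-quoted
    literals; ``#`` starts a comment."""
    patterns: list[TriplePattern] = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = _tokenize(line, line_no)
        if len(tokens) != 3:
            raise ValidationError(
                f"template line {line_no}: expected 3 terms, got {len(tokens)}"
            )
        patterns.append(tuple(tokens))  # type: ignore[arg-type]
    return patterns


def _tokenize(line: str, line_no: int) -> list[PatternTerm]:
    out: list[PatternTerm] = []
    i = 0
    while i < len(line):
        if line[i].isspace():
            i += 1
            continue
        if line[i] == '"':
            j = line.index('"', i + 1)
            out.append(Literal(line[i + 1 : j]))
            i = j + 1
        else:
            j = i
            while j < len(line) and not line[j].isspace():
                j += 1
            token = line[i:j]
            if token.startswith("?"):
                out.append(token)
            elif ":" in token:
                prefix, _, local = token.partition(":")
                out.append(Uri(prefix, local))
            else:
                raise ValidationError(
                    f"template line {line_no}: cannot parse term {token!r}"
                )
            i = j
    return out


def load_template(name: str) -> list[TriplePattern]:
    """Load a shipped query template (e.g. ``case1``) or a file path."""
    if name.endswith(".bgp"):
        with open(name, encoding="utf-8") as fh:
            return parse_patterns(fh.read())
    text = (
        resources.files("pathkg").joinpath("templates", f"{name}.bgp").read_text("utf-8")
    )
    return parse_patterns(text)


# ---------------------------------------------------------------------------
# query cases


def _require_graphs(store: TripleStore, names: Sequence[Uri]) -> None:
    missing = [g.render() for g in names if not store.has_graph(g)]
    if missing:
        raise ValidationError(f"missing named graph(s): {missing}")


@dataclass(frozen=True, slots=True)
class CooccurrenceRow:
    doc_id: str
    sentence: str
    partner: Uri
    labels: Mapping[str, int]


def query_case_1(
    store: TripleStore,
    drug: Uri,
    partners: set[Uri],
    closure: Optional[AlignmentClosure] = None,
) -> list[CooccurrenceRow]:
    """Sentences co-mentioning the drug and a partner entity, joined with
    the per-source relation labels from the relation layer."""
    _require_graphs(store, [GRAPHS["ketcept"], GRAPHS["ketrela"]])
    closure = closure or sameas_closure(store.union())
    cept = store.graph(GRAPHS["ketcept"])
    rela = store.graph(GRAPHS["ketrela"])

    # sentence nodes mentioning the drug
    base = load_template("case1")
    patterns = substitute(base, {"?drug": drug})
    sent_bindings = match_bgp(cept, patterns, closure=closure)

    # label lookup: (doc, sentence, canonical partner) -> {source: label}
    label_map: dict[tuple[str, str, Uri], dict[str, int]] = {}
    by_node: dict[Uri, dict[Uri, Term]] = {}
    for t in rela:
        by_node.setdefault(t.subject, {})[t.predicate] = t.object
    for node, props in by_node.items():
        if props.get(RDF_TYPE) != rx.RELATION_TYPE:
            continue
        doc = props.get(rx.DOC_PRED)
        sent = props.get(rx.SENTENCE_PRED)
        e2 = props.get(rx.ENTITY2_PRED)
        if not (isinstance(doc, Literal) and isinstance(sent, Literal) and isinstance(e2, Uri)):
            continue
        labels = {
            p.local[len("label_"):]: int(o.text)
            for p, o in props.items()
            if p.prefix == "ketrela" and p.local.startswith("label_")
            and isinstance(o, Literal)
        }
        label_map[(doc.text, sent.text, closure.rep(e2))] = labels

    mentions_by_node: dict[Term, set[Uri]] = {}
    for t in cept:
        if t.predicate == ta.MENTIONS_PRED and isinstance(t.object, Uri):
            mentions_by_node.setdefault(closure.rep(t.subject), set()).add(t.object)

    partner_reps = {closure.rep(p): p for p in partners}
    rows: list[CooccurrenceRow] = []
    seen: set[tuple[str, str, str]] = set()
    for b in sent_bindings:
        node = b["?s"]
        doc = b["?doc"]
        text = b["?text"]
        assert isinstance(doc, Literal) and isinstance(text, Literal)
        mentioned = mentions_by_node.get(node, set())
        for m in sorted(mentioned, key=Uri.render):
            rep = closure.rep(m)
            if rep not in partner_reps or closure.same(m, drug):
                continue
            # duplicated sentences are distinct nodes and keep their rows
            key = (node.render(), rep.render())
            if key in seen:
                continue
            seen.add(key)
            rows.append(
                CooccurrenceRow(
                    doc_id=doc.text,
                    sentence=text.text,
                    partner=m,
                    labels=label_map.get((doc.text, text.text, rep), {}),
                )
            )
    rows.sort(key=lambda r: (r.doc_id, r.sentence, r.partner.render()))
    return rows


@dataclass(frozen=True, slots=True)
class DrugActionRow:
    drug: Uri
    action: Uri
    target: Uri


def query_case_2(
    store: TripleStore,
    drug: Uri,
    closure: Optional[AlignmentClosure] = None,
) -> tuple[list[DrugActionRow], set[Triple]]:
    """Drug actions plus the pathway subgraph their targets touch.

    Step 1 retrieves ``(drug, action, target)`` triples from the
    drug-action layer; step 2 expands, via sameAs-canonical URIs, to all
    pathway entries, relations and reactions that reference a target.
    An unknown drug yields empty actions and an empty subgraph.
    """
    _require_graphs(store, [GRAPHS["drugbank"], GRAPHS["kegg"]])
    closure = closure or sameas_closure(store.union())
    actions: list[DrugActionRow] = []
    for t in sorted(store.graph(GRAPHS["drugbank"]), key=Triple.render):
        if closure.same(t.subject, drug) and t.predicate != OWL_SAMEAS and isinstance(t.object, Uri):
            actions.append(DrugActionRow(drug=t.subject, action=t.predicate, target=t.object))

    target_reps = {closure.rep(a.target) for a in actions}
    kegg = store.graph(GRAPHS["kegg"])
    by_node: dict[Uri, set[Triple]] = {}
    for t in kegg:
        by_node.setdefault(t.subject, set()).add(t)

    subgraph: set[Triple] = set()
    for node, triples in by_node.items():
        refs = {
            closure.rep(t.object)
            for t in triples
            if t.predicate in (HAS_SUBSTRATE, HAS_PRODUCT, ENTRY1, ENTRY2)
            and isinstance(t.object, Uri)
        }
        if refs & target_reps:
            subgraph |= triples  # the whole reaction/relation node
        if closure.rep(node) in target_reps:
            subgraph |= triples  # the entry's own triples
    return actions, subgraph


@dataclass(frozen=True, slots=True)
class RelationDiff:
    """Partition of curated relations against a database graph."""

    shared: tuple[CuratedFact, ...]
    literature_only: tuple[CuratedFact, ...]
    indirect: tuple[CuratedFact, ...]

    def sizes(self) -> tuple[int, int, int]:
        return (len(self.shared), len(self.literature_only), len(self.indirect))


def _db_edges(
    db_graph: Iterable[Triple], closure: AlignmentClosure
) -> set[tuple[Uri, Uri]]:
    """Directed relation edges of a database graph, canonicalized.

    A relation node contributes one edge per (entry1, entry2) pair of
    its triples; reaction substrate/product triples are deliberately not
    treated as relation edges.
    """
    e1s: dict[Uri, set[Uri]] = {}
    e2s: dict[Uri, set[Uri]] = {}
    for t in db_graph:
        if not isinstance(t.object, Uri):
            continue
        if t.predicate == ENTRY1:
            e1s.setdefault(t.subject, set()).add(closure.rep(t.object))
        elif t.predicate == ENTRY2:
            e2s.setdefault(t.subject, set()).add(closure.rep(t.object))
    edges: set[tuple[Uri, Uri]] = set()
    for node, sources in e1s.items():
        for s in sources:
            for o in e2s.get(node, ()):  # pairs within one relation node
                edges.add((s, o))
    return edges


def diff_literature_db(
    curated: Sequence[CuratedFact],
    db_graph: Iterable[Triple],
    closure: AlignmentClosure,
    max_depth: int = 10,
) -> RelationDiff:
    """Compare curated (literature) relations with database relations.

    A curated ``e1 → e2`` is *shared* iff a direct database relation
    connects their sameAs classes in the same direction (curated edges
    are directed; an opposite-direction database edge does not count).
    Remaining facts are *literature-only*; those whose endpoints are
    joined by a directed database path of length ≥ 2 (over relation
    edges only, depth-capped) are additionally flagged *indirect*.
    """
    edges = _db_edges(db_graph, closure)
    g = nx.DiGraph()
    g.add_edges_from(edges)

    shared: list[CuratedFact] = []
    lit_only: list[CuratedFact] = []
    indirect: list[CuratedFact] = []
    for fact in curated:
        s = closure.rep(fact.subject)
        o = closure.rep(fact.object)
        if (s, o) in edges:
            shared.append(fact)
            continue
        lit_only.append(fact)
        if s in g:
            reach = nx.single_source_shortest_path_length(g, s, cutoff=max_depth)
            if o in reach and reach[o] >= 2:
                indirect.append(fact)
    return RelationDiff(
        shared=tuple(shared),
        literature_only=tuple(lit_only),
        indirect=tuple(indirect),
    )


def query_case_3(
    store: TripleStore,
    curated: Sequence[CuratedFact],
    closure: Optional[AlignmentClosure] = None,
) -> RelationDiff:
    """The literature-vs-database relation diff over the store's KEGG
    layer (convenience wrapper around :func:`diff_literature_db`)."""
    _require_graphs(store, [GRAPHS["kegg"]])
    closure = closure or sameas_closure(store.union())
    return diff_literature_db(curated, store.graph(GRAPHS["kegg"]), closure)


@dataclass(frozen=True, slots=True)
class MicrobeRow:
    microbe: Uri
    mediator: Uri
    doc: str
    source_graph: Uri


def query_case_4(
    store: TripleStore,
    microbe_graphs: Optional[Sequence[Uri]] = None,
) -> list[MicrobeRow]:
    """Microbe–mediator relations with provenance, unioned across the
    microbiome layers.

    Rows from the microbiota layer state that a microbe increases a
    neurotransmitter; rows from the pre-/probiotics layer state that a
    microbe affects BDNF.  Each row carries its provenance document and
    source graph; a document referenced from both layers contributes one
    row per (statement, graph) pair.
    """
    graphs = list(microbe_graphs) if microbe_graphs else [GRAPHS["mikg"], GRAPHS["ppkg"]]
    _require_graphs(store, graphs)
    rows: list[MicrobeRow] = []
    seen: set[tuple[str, str, str, str]] = set()
    for gname in graphs:
        template = "case4_mikg" if gname == GRAPHS["mikg"] else "case4_ppkg"
        patterns = load_template(template)
        for b in match_bgp(store.graph(gname), patterns):
            microbe = b["?microbe"]
            mediator = b["?mediator"]
            doc = b["?doc"]
            assert isinstance(microbe, Uri) and isinstance(mediator, Uri)
            assert isinstance(doc, Literal)
            key = (microbe.render(), mediator.render(), doc.text, gname.render())
            if key in seen:
                continue
            seen.add(key)
            rows.append(
                MicrobeRow(
                    microbe=microbe, mediator=mediator, doc=doc.text, source_graph=gname
                )
            )
    rows.sort(key=lambda r: (r.source_graph.render(), r.microbe.render(),
                             r.mediator.render(), r.doc))
    return rows
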