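"""URIs, triples and a named-graph triple store.

A layered pathway knowledge graph keeps each evidence layer — curated
pathway facts, recognized entities in text, extracted relations, and
public-database exports — as its own *named graph* inside one in-memory
store, so that layers stay separable but can be queried as a union.
The record type everywhere is the RDF triple ``(subject, predicate,
object)``: subjects and predicates are prefixed URIs, objects are URIs
or plain literals.

Serialization to and from the W3C exchange formats (N-Triples, Turtle)
is delegated to :mod:`rdflib`; this module owns the compact in-memory
representation and the prefix table that expands ``kegg:C00780``-style
names to full IRIs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Optional, Union

import rdflib

__all__ = [
    "ValidationError",
    "Uri",
    "Literal",
    "Term",
    "Triple",
    "TripleStore",
    "DEFAULT_PREFIXES",
]


class ValidationError(ValueError):
    """Raised when a URI, triple, record or file fails validation."""


#: Default prefix table.  The layer prefixes follow the naming convention
#: of the curated-facts / concepts / relations layers; IRI bases for the
#: non-W3C prefixes are placeholders and may be overridden per store.
DEFAULT_PREFIXES: dict[str, str] = {
    "ketfact": "http://wasp.cs.vu.nl/ketfact#",
    "ketcept": "http://wasp.cs.vu.nl/ketcept#",
    "ketrela": "http://wasp.cs.vu.nl/ketrela#",
    "mikg": "http://wasp.cs.vu.nl/mikg#",
    "ppkg": "http://wasp.cs.vu.nl/ppkg#",
    "drugbank": "http://wasp.cs.vu.nl/drugbank#",
    "graph": "http://wasp.cs.vu.nl/graph#",
    "kegg": "https://www.kegg.jp/entry/",
    "umls": "https://uts.nlm.nih.gov/umls/concept/",
    "owl": "http://www.w3.org/2002/07/owl#",
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "xsd": "http://www.w3.org/2001/XMLSchema#",
}

_PREFIX_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_-]*$")
_LOCAL_RE = re.compile(r"^[A-Za-z0-9_][A-Za-z0-9_.\-/%@]*$")

_XSD_STRING_EXPANDED = DEFAULT_PREFIXES["xsd"] + "string"


@dataclass(frozen=True, slots=True)
class Uri:
    """A prefixed name such as ``kegg:C00780``.

    Expansion to a full IRI is total given a prefix table.  Equality is
    by (prefix, local) pair; with distinct IRI bases per prefix this
    coincides with equality of expanded forms.
    """

    prefix: str
    local: str

    def __post_init__(self) -> None:
        if not _PREFIX_RE.match(self.prefix):
            raise ValidationError(f"malformed URI prefix token: {self.prefix!r}")
        if not _LOCAL_RE.match(self.local):
            raise ValidationError(f"malformed URI local token: {self.local!r}")

    def render(self) -> str:
        return f"{self.prefix}:{self.local}"

    def expand(self, prefixes: Mapping[str, str]) -> str:
        try:
            base = prefixes[self.prefix]
        except KeyError:
            raise ValidationError(
                f"unknown prefix {self.prefix!r} (no IRI base registered)"
            ) from None
        return base + self.local

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


@dataclass(frozen=True, slots=True)
class Literal:
    """A plain-text literal with an optional language tag or datatype.

    Comparisons are lexical.  An explicit ``xsd:string`` datatype is
    normalized away so that value equality matches RDF 1.1 semantics.
    """

    text: str
    lang: Optional[str] = None
    datatype: Optional[Uri] = None

    def __post_init__(self) -> None:
        if self.lang is not None and self.datatype is not None:
            raise ValidationError("a literal cannot carry both lang and datatype")
        if self.datatype is not None and (
            self.datatype.prefix,
            self.datatype.local,
        ) == ("xsd", "string"):
            object.__setattr__(self, "datatype", None)

    def render(self) -> str:
        out = '"' + self.text.replace("\\", "\\\\").replace('"', '\\"') + '"'
        if self.lang:
            out += f"@{self.lang}"
        elif self.datatype:
            out += f"^^{self.datatype.render()}"
        return out


Term = Union[Uri, Literal]


@dataclass(frozen=True, slots=True)
class Triple:
    """A subject–predicate–object statement with value (set) semantics."""

    subject: Uri
    predicate: Uri
    object: Term

    def __post_init__(self) -> None:
        if not isinstance(self.subject, Uri):
            raise ValidationError(f"triple subject must be a Uri, got {self.subject!r}")
        if not isinstance(self.predicate, Uri):
            raise ValidationError(
                f"triple predicate must be a Uri, got {self.predicate!r}"
            )
        if not isinstance(self.object, (Uri, Literal)):
            raise ValidationError(
                f"triple object must be a Uri or Literal, got {self.object!r}"
            )

    def render(self) -> str:
        return (
            f"{self.subject.render()} {self.predicate.render()} "
            f"{self.object.render()} ."
        )


_FORMAT_TOKENS = {"ntriples": "nt", "turtle": "turtle"}


class TripleStore:
    """An in-memory collection of named graphs over one prefix table.

    Insertion is idempotent (graphs are sets of value-equal triples) and
    the union over all named graphs is queryable as a single graph.
    """

    def __init__(self, prefixes: Optional[Mapping[str, str]] = None) -> None:
        self.prefixes: dict[str, str] = dict(DEFAULT_PREFIXES)
        if prefixes:
            self.prefixes.update(prefixes)
        self._graphs: dict[Uri, set[Triple]] = {}

    # -- container protocol -------------------------------------------------

    def graph_names(self) -> list[Uri]:
        return list(self._graphs)

    def has_graph(self, name: Uri) -> bool:
        return name in self._graphs

    def graph(self, name: Uri) -> frozenset[Triple]:
        if name not in self._graphs:
            raise ValidationError(f"no such named graph: {name.render()}")
        return frozenset(self._graphs[name])

    def union(self) -> set[Triple]:
        out: set[Triple] = set()
        for triples in self._graphs.values():
            out |= triples
        return out

    def __len__(self) -> int:
        return sum(len(g) for g in self._graphs.values())

    def __iter__(self) -> Iterator[Triple]:
        return iter(self.union())

    # -- mutation ------------------------------------------------------------

    def add_triples(self, graph: Uri, triples: Iterable[Triple]) -> int:
        """Add triples to a named graph; return the count newly inserted."""
        if not isinstance(graph, Uri):
            raise ValidationError(f"graph name must be a Uri, got {graph!r}")
        target = self._graphs.setdefault(graph, set())
        added = 0
        for t in triples:
            if not isinstance(t, Triple):
                raise ValidationError(f"not a Triple: {t!r}")
            if t not in target:
                target.add(t)
                added += 1
        return added

    # -- rdflib bridge -------------------------------------------------------

    def _to_rdflib(self, triples: Iterable[Triple]) -> rdflib.Graph:
        g = rdflib.Graph()
        for prefix, base in self.prefixes.items():
            g.bind(prefix, rdflib.Namespace(base))
        for t in triples:
            g.add(
                (
                    rdflib.URIRef(t.subject.expand(self.prefixes)),
                    rdflib.URIRef(t.predicate.expand(self.prefixes)),
                    self._term_to_rdflib(t.object),
                )
            )
        return g

    def _term_to_rdflib(self, term: Term) -> rdflib.term.Node:
        if isinstance(term, Uri):
            return rdflib.URIRef(term.expand(self.prefixes))
        if term.lang:
            return rdflib.Literal(term.text, lang=term.lang)
        if term.datatype:
            return rdflib.Literal(
                term.text, datatype=rdflib.URIRef(term.datatype.expand(self.prefixes))
            )
        return rdflib.Literal(term.text)

    def compact(self, iri: str) -> Uri:
        """Compact a full IRI to a prefixed Uri by longest matching base."""
        best: Optional[tuple[str, str]] = None
        for prefix, base in self.prefixes.items():
            if iri.startswith(base) and (best is None or len(base) > len(best[1])):
                best = (prefix, base)
        if best is None:
            # Auto-register a namespace for foreign IRIs so that parsing
            # third-party documents does not fail outright.
            cut = max(iri.rfind("/"), iri.rfind("#")) + 1
            if cut <= 0 or cut >= len(iri):
                raise ValidationError(f"cannot compact IRI: {iri!r}")
            prefix = f"ns{len(self.prefixes)}"
            self.prefixes[prefix] = iri[:cut]
            best = (prefix, iri[:cut])
        return Uri(best[0], iri[len(best[1]):])

    def _term_from_rdflib(self, node: rdflib.term.Node) -> Term:
        if isinstance(node, rdflib.URIRef):
            return self.compact(str(node))
        if isinstance(node, rdflib.Literal):
            if node.language:
                return Literal(str(node), lang=node.language)
            if node.datatype and str(node.datatype) != _XSD_STRING_EXPANDED:
                return Literal(str(node), datatype=self.compact(str(node.datatype)))
            return Literal(str(node))
        raise ValidationError(f"unsupported RDF node (blank nodes not allowed): {node!r}")

    # -- serialization -------------------------------------------------------

    def serialize(self, graph: Uri, format: str = "ntriples") -> str:
        """Render one named graph as N-Triples or Turtle text."""
        if format not in _FORMAT_TOKENS:
            raise ValidationError(
                f"unknown serialization format {format!r}; "
                f"expected one of {sorted(_FORMAT_TOKENS)}"
            )
        triples = self.graph(graph)
        if not triples:
            return ""
        return self._to_rdflib(sorted(triples, key=Triple.render)).serialize(
            format=_FORMAT_TOKENS[format]
        )

    def parse(self, text: str, graph: Uri, format: str = "ntriples") -> int:
        """Parse serialized RDF into a named graph; return triples added."""
        if format not in _FORMAT_TOKENS:
            raise ValidationError(
                f"unknown serialization format {format!r}; "
                f"expected one of {sorted(_FORMAT_TOKENS)}"
            )
        g = rdflib.Graph()
        if text.strip():
            g.parse(data=text, format=_FORMAT_TOKENS[format])
        triples = [
            Triple(
                self._term_from_rdflib(s),  # type: ignore[arg-type]
                self._term_from_rdflib(p),  # type: ignore[arg-type]
                self._term_from_rdflib(o),
            )
            for s, p, o in g
        ]
        return self.add_triples(graph, triples)


# Frequently used vocabulary terms.
RDF_TYPE = Uri("rdf", "type")
RDFS_LABEL = Uri("rdfs", "label")
RDFS_SEEALSO = Uri("rdfs", "seeAlso")
OWL_SAMEAS = Uri("owl", "sameAs")
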