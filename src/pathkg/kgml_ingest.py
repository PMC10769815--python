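"""KGML pathway parsing and mapping to the RDF pathway schema.

KEGG distributes pathway maps as KGML, an XML dialect whose payload is
three element families: *entries* (genes, compounds, maps, groups),
*relations* between entries (with subtypes such as activation or
inhibition) and *reactions* with substrates and products.  This module
parses KGML into a validated :class:`PathwayGraph` and maps it onto a
triple schema in which a reaction is a node carrying one
``kegg:hasSubstrate`` triple per substrate, one ``kegg:hasProduct``
triple per product, a ``kegg:reactionType`` triple and a linkage back to
KEGG, and a relation is a node typed by its subtype connecting the two
entry URIs.

Layout and graphics attributes of KGML are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from lxml import etree

from .core_model import (
    RDF_TYPE,
    RDFS_SEEALSO,
    Literal,
    Triple,
    Uri,
    ValidationError,
)

__all__ = [
    "PathwayEntry",
    "PathwayRelation",
    "PathwayReaction",
    "PathwayGraph",
    "parse_kgml",
    "write_kgml",
    "pathway_to_triples",
    "HAS_SUBSTRATE",
    "HAS_PRODUCT",
    "REACTION_TYPE",
]

HAS_SUBSTRATE = Uri("kegg", "hasSubstrate")
HAS_PRODUCT = Uri("kegg", "hasProduct")
REACTION_TYPE = Uri("kegg", "reactionType")
ENTRY1 = Uri("kegg", "entry1")
ENTRY2 = Uri("kegg", "entry2")

_REACTION_TYPES = {"reversible", "irreversible"}


@dataclass(frozen=True, slots=True)
class PathwayEntry:
    entry_id: str
    name: str
    entry_type: str
    link: Optional[str] = None
    components: tuple[str, ...] = ()  # only for type == "group"


@dataclass(frozen=True, slots=True)
class PathwayRelation:
    entry1: str
    entry2: str
    subtypes: tuple[str, ...] = ()


@dataclass(frozen=True, slots=True)
class PathwayReaction:
    reaction_id: str
    reaction_type: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if self.reaction_type not in _REACTION_TYPES:
            raise ValidationError(
                f"reaction {self.reaction_id}: reaction_type must be one of "
                f"{sorted(_REACTION_TYPES)}, got {self.reaction_type!r}"
            )
        if not self.substrates or not self.products:
            raise ValidationError(
                f"reaction {self.reaction_id}: needs at least one substrate "
                "and one product"
            )


@dataclass(slots=True)
class PathwayGraph:
    pathway_id: str
    entries: list[PathwayEntry] = field(default_factory=list)
    relations: list[PathwayRelation] = field(default_factory=list)
    reactions: list[PathwayReaction] = field(default_factory=list)

    def entry_ids(self) -> set[str]:
        return {e.entry_id for e in self.entries}

    def validate(self) -> None:
        ids = self.entry_ids()
        if len(ids) != len(self.entries):
            seen: set[str] = set()
            dupes = sorted(
                e.entry_id for e in self.entries if e.entry_id in seen or seen.add(e.entry_id)
            )
            raise ValidationError(f"duplicate entry ids: {dupes}")
        dangling: set[str] = set()
        for rel in self.relations:
            dangling.update(x for x in (rel.entry1, rel.entry2) if x not in ids)
        for rx in self.reactions:
            dangling.update(x for x in rx.substrates + rx.products if x not in ids)
        for e in self.entries:
            dangling.update(c for c in e.components if c not in ids)
        if dangling:
            raise ValidationError(
                f"dangling entry references: {sorted(dangling)}"
            )


def parse_kgml(xml_text: str) -> PathwayGraph:
    """Parse a KGML document into a validated :class:`PathwayGraph`.

    Every entry/relation/reaction element of the file appears exactly
    once in the result; dangling entry references raise a
    :class:`ValidationError` listing the offending ids.
    """
    try:
        root = etree.fromstring(xml_text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise ValidationError(f"malformed KGML XML: {exc}") from exc
    if root.tag != "pathway":
        raise ValidationError(f"expected <pathway> root element, got <{root.tag}>")

    pathway_id = root.get("name", "") or root.get("title", "unknown")
    if pathway_id.startswith("path:"):
        pathway_id = pathway_id[len("path:"):]

    pg = PathwayGraph(pathway_id=pathway_id)
    for el in root.findall("entry"):
        components = tuple(c.get("id", "") for c in el.findall("component"))
        pg.entries.append(
            PathwayEntry(
                entry_id=el.get("id", ""),
                name=el.get("name", "") or "undefined",
                entry_type=el.get("type", "") or "other",
                link=el.get("link"),
                components=components,
            )
        )
    for el in root.findall("relation"):
        subtypes = tuple(s.get("name", "unspecified") for s in el.findall("subtype"))
        pg.relations.append(
            PathwayRelation(
                entry1=el.get("entry1", ""),
                entry2=el.get("entry2", ""),
                subtypes=subtypes,
            )
        )
    for el in root.findall("reaction"):
        substrates = tuple(s.get("id", "") for s in el.findall("substrate"))
        products = tuple(p.get("id", "") for p in el.findall("product"))
        pg.reactions.append(
            PathwayReaction(
                reaction_id=el.get("id", "") or el.get("name", ""),
                reaction_type=el.get("type", ""),
                substrates=substrates,
                products=products,
                name=el.get("name", ""),
            )
        )
    pg.validate()
    return pg


def write_kgml(pg: PathwayGraph) -> str:
    """Render the internal model back to KGML (round-trip counterpart)."""
    root = etree.Element("pathway", name=f"path:{pg.pathway_id}")
    for e in pg.entries:
        el = etree.SubElement(root, "entry", id=e.entry_id, name=e.name, type=e.entry_type)
        if e.link:
            el.set("link", e.link)
        for c in e.components:
            etree.SubElement(el, "component", id=c)
    for r in pg.relations:
        el = etree.SubElement(root, "relation", entry1=r.entry1, entry2=r.entry2, type="PPrel")
        for s in r.subtypes:
            etree.SubElement(el, "subtype", name=s, value="")
    for rx in pg.reactions:
        el = etree.SubElement(
            root, "reaction", id=rx.reaction_id, name=rx.name or rx.reaction_id,
            type=rx.reaction_type,
        )
        for s in rx.substrates:
            etree.SubElement(el, "substrate", id=s, name=s)
        for p in rx.products:
            etree.SubElement(el, "product", id=p, name=p)
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def _sanitize(token: str) -> str:
    out = "".join(c if c.isalnum() or c in "_.-/" else "_" for c in token)
    return out or "_"


def entry_uri(pg: PathwayGraph, entry: PathwayEntry) -> Uri:
    """Mint a deterministic URI for an entry.

    The first whitespace-separated KEGG identifier of the entry name is
    used (KGML packs alternatives into one attribute); the KGML-local
    numeric id disambiguates entries sharing a KEGG name.
    """
    kegg_name = _sanitize(entry.name.split()[0]) if entry.name.split() else "undefined"
    return Uri("kegg", f"{_sanitize(pg.pathway_id)}/entry/{entry.entry_id}-{kegg_name}")


def _flatten(pg: PathwayGraph) -> dict[str, list[PathwayEntry]]:
    """Map entry_id → concrete entries, expanding group entries."""
    by_id = {e.entry_id: e for e in pg.entries}
    out: dict[str, list[PathwayEntry]] = {}
    for e in pg.entries:
        if e.entry_type == "group":
            out[e.entry_id] = [by_id[c] for c in e.components]
        else:
            out[e.entry_id] = [e]
    return out


def pathway_to_triples(pg: PathwayGraph) -> set[Triple]:
    """Map a validated pathway onto the triple schema.

    Per reaction: one ``hasSubstrate`` triple per substrate, one
    ``hasProduct`` per product, one ``reactionType`` triple and one KEGG
    linkage triple — ``|substrates| + |products| + 2`` triples on the
    minted reaction node.  Per relation: a node typed by each subtype
    plus ``entry1``/``entry2`` triples.  Per non-group entry: a type
    triple and a link triple.  Relations touching a group entry are
    expanded to every component, preserving connectivity.
    """
    pg.validate()
    pid = _sanitize(pg.pathway_id)
    flat = _flatten(pg)
    triples: set[Triple] = set()

    for e in pg.entries:
        if e.entry_type == "group":
            continue
        u = entry_uri(pg, e)
        triples.add(Triple(u, RDF_TYPE, Uri("kegg", _sanitize(e.entry_type))))
        link = e.link or f"https://www.kegg.jp/entry/{e.name.split()[0] if e.name.split() else e.name}"
        triples.add(Triple(u, RDFS_SEEALSO, Literal(link)))

    for n, rel in enumerate(pg.relations):
        for e1 in flat[rel.entry1]:
            for e2 in flat[rel.entry2]:
                node = Uri("kegg", f"{pid}/relation/{n}")
                subtypes = rel.subtypes or ("unspecified",)
                for st in subtypes:
                    triples.add(Triple(node, RDF_TYPE, Uri("kegg", _sanitize(st))))
                triples.add(Triple(node, ENTRY1, entry_uri(pg, e1)))
                triples.add(Triple(node, ENTRY2, entry_uri(pg, e2)))

    for rx in pg.reactions:
        node = Uri("kegg", f"{pid}/reaction/{_sanitize(rx.reaction_id)}")
        by_id = {e.entry_id: e for e in pg.entries}
        for s in rx.substrates:
            triples.add(Triple(node, HAS_SUBSTRATE, entry_uri(pg, by_id[s])))
        for p in rx.products:
            triples.add(Triple(node, HAS_PRODUCT, entry_uri(pg, by_id[p])))
        triples.add(Triple(node, REACTION_TYPE, Literal(rx.reaction_type)))
        link = rx.name or rx.reaction_id
        triples.add(Triple(node, RDFS_SEEALSO, Literal(f"https://www.kegg.jp/entry/{link}")))

    return triples
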