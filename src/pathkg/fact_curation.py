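"""Curated pathway facts as reified triples.

Pathway figures in publications depict entities joined by arrow-headed
(activation) or bar-headed (inhibition) lines.  Each such fact is
normalized into triples by *reification*: the relation itself becomes a
minted node that carries its type (activation/inhibition), points at the
two participating entities, and records the figure or article it came
from.  Curated entities are mapped onto database entries (KEGG, UMLS)
with ``owl:sameAs`` statements, which is what lets the literature layer
be compared against database pathway graphs downstream.
"""

from __future__ import annotations

import csv
import hashlib
import io
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

from .core_model import (
    OWL_SAMEAS,
    RDF_TYPE,
    Literal,
    Triple,
    Uri,
    ValidationError,
)

__all__ = [
    "RELATION_TYPES",
    "CuratedFact",
    "CuratedReaction",
    "entity_uri",
    "reify_fact",
    "reify_reaction",
    "map_to_kegg",
    "load_facts_tsv",
    "facts_to_tsv",
]

RELATION_TYPES = ("activation", "inhibition")

SUBJECT_PRED = Uri("ketfact", "subject")
OBJECT_PRED = Uri("ketfact", "object")
SOURCE_PRED = Uri("ketfact", "source")
HAS_SUBSTRATE = Uri("ketfact", "hasSubstrate")
HAS_PRODUCT = Uri("ketfact", "hasProduct")
ANNOTATION_PRED = Uri("ketfact", "annotation")


def entity_uri(label: str, uri: Optional[Uri] = None) -> Uri:
    """The URI of a curated entity: the given one, or a label-derived
    ``ketfact:`` name (spaces → underscores) when no database match exists."""
    if uri is not None:
        return uri
    if not label:
        raise ValidationError("curated entity label must be non-empty")
    safe = "".join(c if c.isalnum() or c in "_.-" else "_" for c in label)
    return Uri("ketfact", safe)


@dataclass(frozen=True, slots=True)
class CuratedFact:
    """One directed activation/inhibition edge read off a pathway figure."""

    subject_label: str
    relation_type: str
    object_label: str
    source: str
    subject_uri: Optional[Uri] = None
    object_uri: Optional[Uri] = None

    def __post_init__(self) -> None:
        if not self.subject_label or not self.object_label:
            raise ValidationError("fact entity labels must be non-empty")
        if self.relation_type not in RELATION_TYPES:
            raise ValidationError(
                f"unknown relation_type {self.relation_type!r}; "
                f"expected one of {RELATION_TYPES}"
            )

    @property
    def subject(self) -> Uri:
        return entity_uri(self.subject_label, self.subject_uri)

    @property
    def object(self) -> Uri:
        return entity_uri(self.object_label, self.object_uri)


@dataclass(frozen=True, slots=True)
class CuratedReaction:
    """A figure-curated reaction: substrates, products, free-text notes."""

    substrates: tuple[str, ...]
    products: tuple[str, ...]
    annotations: tuple[str, ...] = ()
    source: str = ""

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise ValidationError("curated reaction needs substrates and products")


def _mint(kind: str, *fields_: str) -> Uri:
    digest = hashlib.sha1("\t".join(fields_).encode("utf-8")).hexdigest()[:12]
    return Uri("ketfact", f"{kind}_{digest}")


def fact_node(fact: CuratedFact) -> Uri:
    """Deterministic reified-node URI: a stable hash of the four fields,
    so re-ingesting the same fact never duplicates nodes."""
    return _mint(
        "rel", fact.subject_label, fact.relation_type, fact.object_label, fact.source
    )


def reify_fact(fact: CuratedFact) -> set[Triple]:
    """Reify one curated fact into exactly four triples.

    The relation expression becomes a subject node typed by its relation
    kind, connected to the two object entities, plus a provenance triple.
    """
    node = fact_node(fact)
    return {
        Triple(node, RDF_TYPE, Uri("ketfact", fact.relation_type)),
        Triple(node, SUBJECT_PRED, fact.subject),
        Triple(node, OBJECT_PRED, fact.object),
        Triple(node, SOURCE_PRED, Literal(fact.source)),
    }


def reify_reaction(reaction: CuratedReaction) -> set[Triple]:
    """Reify a curated n-ary reaction (node + one triple per participant)."""
    node = _mint(
        "rxn",
        ",".join(reaction.substrates),
        ",".join(reaction.products),
        reaction.source,
    )
    triples = {
        Triple(node, RDF_TYPE, Uri("ketfact", "reaction")),
        Triple(node, SOURCE_PRED, Literal(reaction.source)),
    }
    for s in reaction.substrates:
        triples.add(Triple(node, HAS_SUBSTRATE, entity_uri(s)))
    for p in reaction.products:
        triples.add(Triple(node, HAS_PRODUCT, entity_uri(p)))
    for a in reaction.annotations:
        triples.add(Triple(node, ANNOTATION_PRED, Literal(a)))
    return triples


def map_to_kegg(fact_entity: Union[str, Uri], kegg_uri: Uri) -> Triple:
    """One ``owl:sameAs`` triple aligning a curated entity with a database
    entry.  Mapping an entity to several targets yields several triples,
    merged later by the alignment closure."""
    subject = fact_entity if isinstance(fact_entity, Uri) else entity_uri(fact_entity)
    return Triple(subject, OWL_SAMEAS, kegg_uri)


_REQUIRED_COLUMNS = ("subject", "relation_type", "object", "source")


def load_facts_tsv(path_or_text: Union[str, "io.TextIOBase"]) -> list[CuratedFact]:
    """Read curated facts from TSV with header
    ``subject  relation_type  object  source`` (optional ``subject_uri``
    and ``object_uri`` columns hold prefixed names).

    Errors carry 1-based row numbers for curation feedback.
    """
    if isinstance(path_or_text, io.TextIOBase):
        handle = path_or_text
    elif "\t" in str(path_or_text) or "\n" in str(path_or_text):
        handle = io.StringIO(str(path_or_text))
    else:
        handle = open(path_or_text, newline="", encoding="utf-8")
    with handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError("facts TSV is empty (missing header)") from None
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing:
            raise ValidationError(f"facts TSV missing column(s): {missing}")
        idx = {c: header.index(c) for c in header}
        facts: list[CuratedFact] = []
        for row_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise ValidationError(
                    f"row {row_no}: expected {len(header)} columns, got {len(row)}"
                )
            def _uri(col: str) -> Optional[Uri]:
                if col in idx and row[idx[col]].strip():
                    prefix, _, local = row[idx[col]].partition(":")
                    return Uri(prefix, local)
                return None
            try:
                facts.append(
                    CuratedFact(
                        subject_label=row[idx["subject"]],
                        relation_type=row[idx["relation_type"]],
                        object_label=row[idx["object"]],
                        source=row[idx["source"]],
                        subject_uri=_uri("subject_uri"),
                        object_uri=_uri("object_uri"),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"row {row_no}: {exc}") from None
    return facts


def facts_to_tsv(facts: Sequence[CuratedFact]) -> str:
    """Serialize facts back to the TSV exchange format."""
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(["subject", "relation_type", "object", "source",
                     "subject_uri", "object_uri"])
    for f in facts:
        writer.writerow([
            f.subject_label, f.relation_type, f.object_label, f.source,
            f.subject_uri.render() if f.subject_uri else "",
            f.object_uri.render() if f.object_uri else "",
        ])
    return buf.getvalue()


def curate(facts: Iterable[CuratedFact]) -> set[Triple]:
    """Reify a batch of curated facts (union of per-fact triple sets)."""
    out: set[Triple] = set()
    for f in facts:
        out |= reify_fact(f)
    return out
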