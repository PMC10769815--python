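"""Lexicon-based named-entity recognition over sentence corpora.

A document is modelled as an ordered list of annotations, one per
sentence: ``P = [A1 .. An]`` where each annotation carries the source
sentence together with the entities recognized in it and their character
offsets.  Recognition here is dictionary matching against a thesaurus of
surface forms (a small stand-in for UMLS/SNOMED-scale terminologies):
longest match wins left to right, matching is case-insensitive with an
exact-case entry preferred on ties, and matches must start and end on
word boundaries so that "serotonin" does not fire inside "serotonergic".

The resulting annotation layer is exported as triples (one sentence
node per sentence, with its document id, text and mentioned entities)
for fusion with the other graph layers.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

from .core_model import RDF_TYPE, Literal, Triple, Uri, ValidationError

__all__ = [
    "Thesaurus",
    "EntityMention",
    "Annotation",
    "Document",
    "annotate_sentence",
    "annotate_corpus",
    "cooccurrence",
    "load_thesaurus_tsv",
    "annotations_to_triples",
]

SENTENCE_TYPE = Uri("ketcept", "Sentence")
DOC_PRED = Uri("ketcept", "doc")
TEXT_PRED = Uri("ketcept", "text")
MENTIONS_PRED = Uri("ketcept", "mentions")


@dataclass(frozen=True, slots=True)
class EntityMention:
    """One recognized span: 0-based half-open offsets into the sentence."""

    surface: str
    start: int
    end: int
    uri: Uri


class Thesaurus:
    """Surface-form → URI lexicon with deterministic lookup."""

    def __init__(
        self,
        entries: Mapping[str, Uri],
        case_policy: str = "insensitive",
    ) -> None:
        if case_policy not in ("insensitive", "exact"):
            raise ValidationError(f"unknown case_policy {case_policy!r}")
        for surface in entries:
            if not surface:
                raise ValidationError("thesaurus surface forms must be non-empty")
        self.entries: dict[str, Uri] = dict(entries)
        self.case_policy = case_policy
        self._lower: dict[str, Uri] = {}
        for surface, uri in self.entries.items():
            # First-listed form wins among case-insensitive duplicates.
            self._lower.setdefault(surface.lower(), uri)
        self._pattern = self._compile()

    def __len__(self) -> int:
        return len(self.entries)

    def _compile(self) -> Optional[re.Pattern[str]]:
        if not self.entries:
            return None
        terms = sorted(self.entries, key=len, reverse=True)
        body = "|".join(re.escape(t) for t in terms)
        flags = 0 if self.case_policy == "exact" else re.IGNORECASE
        # Word boundaries on alphanumeric edges; longest alternative first
        # gives longest-match-left-to-right under finditer.
        return re.compile(
            rf"(?<![A-Za-z0-9])(?:{body})(?![A-Za-z0-9])", flags
        )

    def lookup(self, surface: str) -> Optional[Uri]:
        if surface in self.entries:  # exact-case tie preferred
            return self.entries[surface]
        if self.case_policy == "insensitive":
            return self._lower.get(surface.lower())
        return None


def annotate_sentence(sentence: str, thesaurus: Thesaurus) -> "Annotation":
    """Recognize thesaurus terms in one sentence.

    Longest match wins at each position, scanning left to right; spans
    never overlap; a sentence with no thesaurus term yields an empty
    entity list.
    """
    if len(thesaurus) == 0:
        raise ValidationError("thesaurus must be non-empty")
    mentions: list[EntityMention] = []
    pattern = thesaurus._pattern
    assert pattern is not None
    for m in pattern.finditer(sentence):
        surface = m.group(0)
        uri = thesaurus.lookup(surface)
        if uri is None:  # pragma: no cover - defensive
            continue
        mentions.append(EntityMention(surface, m.start(), m.end(), uri))
    return Annotation(sentence=sentence, entities=tuple(mentions))


@dataclass(frozen=True, slots=True)
class Annotation:
    """A sentence with its recognized entity mentions."""

    sentence: str
    entities: tuple[EntityMention, ...] = ()

    def __post_init__(self) -> None:
        last_end = -1
        for e in self.entities:
            if not (0 <= e.start < e.end <= len(self.sentence)):
                raise ValidationError(
                    f"mention offsets [{e.start},{e.end}) outside sentence"
                )
            if e.start < last_end:
                raise ValidationError("mention spans must not overlap")
            if self.sentence[e.start : e.end] != e.surface:
                raise ValidationError(
                    f"surface {e.surface!r} does not match sentence span "
                    f"{self.sentence[e.start:e.end]!r}"
                )
            last_end = e.end

    def uris(self) -> set[Uri]:
        return {e.uri for e in self.entities}


@dataclass(frozen=True, slots=True)
class Document:
    """A paper (PMID-like id) with its sentence annotations in order."""

    doc_id: str
    annotations: tuple[Annotation, ...] = ()


def annotate_corpus(
    source: Union[str, Iterable[str]], thesaurus: Thesaurus
) -> list[Document]:
    """Annotate a JSONL corpus (records with ``doc_id`` and ``sentence``).

    ``source`` may be a file path or an iterable of JSONL lines.  One
    Document is produced per doc_id, grouping annotations in input
    order.  Duplicate sentences are annotated independently.
    """
    if isinstance(source, str) and "\n" not in source and source.endswith(".jsonl"):
        with open(source, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    elif isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in source]

    grouped: dict[str, list[Annotation]] = {}
    order: list[str] = []
    for line_no, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        try:
            record = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"line {line_no}: malformed JSON ({exc.msg})") from None
        if "doc_id" not in record or "sentence" not in record:
            raise ValidationError(
                f"line {line_no}: record needs 'doc_id' and 'sentence' fields"
            )
        doc_id = str(record["doc_id"])
        if doc_id not in grouped:
            grouped[doc_id] = []
            order.append(doc_id)
        grouped[doc_id].append(annotate_sentence(str(record["sentence"]), thesaurus))
    return [Document(doc_id=d, annotations=tuple(grouped[d])) for d in order]


def cooccurrence(
    documents: Sequence[Document], uri_a: Uri, uri_set_b: set[Uri]
) -> list[tuple[str, str, Uri]]:
    """All sentences mentioning ``uri_a`` together with a member of
    ``uri_set_b``: one row ``(doc_id, sentence, matched_uri)`` per
    (sentence, matched member) pair."""
    rows: list[tuple[str, str, Uri]] = []
    for doc in documents:
        for ann in doc.annotations:
            uris = ann.uris()
            if uri_a not in uris:
                continue
            for b in sorted(uri_set_b & uris, key=Uri.render):
                rows.append((doc.doc_id, ann.sentence, b))
    return rows


def load_thesaurus_tsv(path_or_text: str, case_policy: str = "insensitive") -> Thesaurus:
    """Read a thesaurus from TSV with header ``surface_form  uri``."""
    text = path_or_text
    if "\t" not in text and "\n" not in text:
        with open(path_or_text, encoding="utf-8") as fh:
            text = fh.read()
    reader = csv.reader(io.StringIO(text), delimiter="\t")
    header = next(reader, None)
    if header is None or header[:2] != ["surface_form", "uri"]:
        raise ValidationError(
            "thesaurus TSV must start with header: surface_form\turi"
        )
    entries: dict[str, Uri] = {}
    for row_no, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) < 2:
            raise ValidationError(f"row {row_no}: expected 2 columns")
        prefix, _, local = row[1].partition(":")
        entries[row[0]] = Uri(prefix, local)
    return Thesaurus(entries, case_policy=case_policy)


def sentence_node(doc_id: str, index: int) -> Uri:
    safe = "".join(c if c.isalnum() or c in "_.-" else "_" for c in doc_id)
    return Uri("ketcept", f"{safe}/s{index}")


def annotations_to_triples(documents: Sequence[Document]) -> set[Triple]:
    """Export the annotation layer as triples.

    Each sentence becomes a node with its type, document id, text, and
    one ``ketcept:mentions`` triple per distinct recognized entity.
    """
    triples: set[Triple] = set()
    for doc in documents:
        for i, ann in enumerate(doc.annotations):
            node = sentence_node(doc.doc_id, i)
            triples.add(Triple(node, RDF_TYPE, SENTENCE_TYPE))
            triples.add(Triple(node, DOC_PRED, Literal(doc.doc_id)))
            triples.add(Triple(node, TEXT_PRED, Literal(ann.sentence)))
            for uri in ann.uris():
                triples.add(Triple(node, MENTIONS_PRED, uri))
    return triples
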