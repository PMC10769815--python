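"""Binary relation-extraction dataset construction and evaluation.

From an annotated sentence containing a drug and one or more partner
entities, one *instance* is built per (drug, partner) pair: the two
target mentions are replaced in the sentence by ``@<surface>$`` tags, so
each instance carries exactly one candidate relation.  A gold label of 1
means the tagged pair stands in a stated relation, 0 means mere
co-mention.

Evaluation follows the confusion-matrix metrics recall, precision,
specificity and F1 (reported as percentages), with two naive baselines:
*predict-none* assumes no entity pair is related, *predict-all* assumes
every co-mentioned pair is related.  Cross-validation is stratified
k-fold with an unusual default orientation: each round trains on a
single fold and tests on the union of the remaining k−1 folds (the
conventional orientation is available as a switch).  Transformer-based
classifiers are deliberately not bundled; their per-instance predictions
can be scored through :func:`import_external_predictions`.
"""

from __future__ import annotations

import csv
import hashlib
import io
import math
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Protocol, Sequence, Union

import numpy as np

from .core_model import RDF_TYPE, Literal, Triple, Uri, ValidationError
from .text_annotation import Annotation, Document, EntityMention

__all__ = [
    "RelationInstance",
    "ConfusionMatrix",
    "MetricsRow",
    "CVReport",
    "build_instances",
    "build_dataset",
    "baseline_predict",
    "confusion",
    "metrics_from_confusion",
    "stratified_kfold",
    "cross_validate",
    "import_external_predictions",
    "ConstantPredictor",
    "KeywordPredictor",
    "relations_to_triples",
    "dataset_to_tsv",
    "load_dataset_tsv",
]


def instance_id(doc_id: str, sentence: str, e1: str, e2: str) -> str:
    """Stable instance identifier: hash of (doc_id, sentence, entity1,
    entity2), used to align external prediction files."""
    payload = "\t".join((doc_id, sentence, e1, e2)).encode("utf-8")
    return hashlib.sha1(payload).hexdigest()[:16]


@dataclass(frozen=True, slots=True)
class RelationInstance:
    """One tagged sentence with exactly one candidate entity pair."""

    sentence: str
    tagged_sentence: str
    entity1_label: str
    entity1_uri: Uri
    entity2_label: str
    entity2_uri: Uri
    doc_id: str = ""
    gold_label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.tagged_sentence.count("@") != 2 or self.tagged_sentence.count("$") != 2:
            raise ValidationError(
                "tagged_sentence must contain exactly two @...$ tags: "
                f"{self.tagged_sentence!r}"
            )
        if self.gold_label not in (None, 0, 1):
            raise ValidationError(f"gold_label must be 0/1, got {self.gold_label!r}")

    @property
    def id(self) -> str:
        return instance_id(
            self.doc_id, self.sentence, self.entity1_label, self.entity2_label
        )


def _tag(sentence: str, spans: Sequence[EntityMention]) -> str:
    out = sentence
    for m in sorted(spans, key=lambda m: m.start, reverse=True):
        out = out[: m.start] + f"@{m.surface}$" + out[m.end :]
    return out


def build_instances(
    annotation: Annotation,
    drug_uri: Uri,
    partner_uris: set[Uri],
    doc_id: str = "",
) -> list[RelationInstance]:
    """Enumerate (drug, partner) instances for one annotated sentence.

    The first mention of the drug and of each partner entity are the
    tagged spans; a sentence not mentioning the drug yields no
    instances.  Gold labels are left unset, to be supplied by a labels
    file or generator bookkeeping.
    """
    drug_mention = next((m for m in annotation.entities if m.uri == drug_uri), None)
    if drug_mention is None:
        return []
    instances: list[RelationInstance] = []
    seen: set[Uri] = set()
    for m in annotation.entities:
        if m.uri not in partner_uris or m.uri == drug_uri or m.uri in seen:
            continue
        seen.add(m.uri)
        instances.append(
            RelationInstance(
                sentence=annotation.sentence,
                tagged_sentence=_tag(annotation.sentence, [drug_mention, m]),
                entity1_label=drug_mention.surface,
                entity1_uri=drug_uri,
                entity2_label=m.surface,
                entity2_uri=m.uri,
                doc_id=doc_id,
            )
        )
    return instances


def build_dataset(
    documents: Sequence[Document], drug_uri: Uri, partner_uris: set[Uri]
) -> list[RelationInstance]:
    """Instances for a whole corpus, in document/sentence order."""
    out: list[RelationInstance] = []
    for doc in documents:
        for ann in doc.annotations:
            out.extend(build_instances(ann, drug_uri, partner_uris, doc_id=doc.doc_id))
    return out


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True, slots=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion-matrix cells must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def baseline_predict(
    instances: Sequence[RelationInstance], mode: str
) -> list[int]:
    """Naive baselines: ``none`` predicts no pair is related, ``all``
    predicts every pair is related."""
    if mode == "none":
        return [0] * len(instances)
    if mode == "all":
        return [1] * len(instances)
    raise ValidationError(f"unknown baseline mode {mode!r}; expected 'none' or 'all'")


def confusion(pred: Sequence[int], gold: Sequence[int]) -> ConfusionMatrix:
    """Tally the four confusion cells for binary labels."""
    if len(pred) != len(gold):
        raise ValidationError(
            f"prediction/gold length mismatch: {len(pred)} vs {len(gold)}"
        )
    bad = [v for v in (*pred, *gold) if v not in (0, 1)]
    if bad:
        raise ValidationError(f"labels must be 0/1; offending values: {bad[:5]}")
    p = np.asarray(pred, dtype=int)
    g = np.asarray(gold, dtype=int)
    return ConfusionMatrix(
        tp=int(np.sum((p == 1) & (g == 1))),
        fp=int(np.sum((p == 1) & (g == 0))),
        tn=int(np.sum((p == 0) & (g == 0))),
        fn=int(np.sum((p == 0) & (g == 1))),
    )


def _ratio(num: int, den: int) -> float:
    return 0.0 if den == 0 else 100.0 * num / den


def round_half_up(x: float) -> int:
    """Round-half-up to integer, as used for table display (59.13 → 59,
    74.31 → 74, 0.5 → 1)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True, slots=True)
class MetricsRow:
    """Recall, precision, specificity and F1 as percentages in [0, 100].

    Full precision is retained here; :meth:`rounded` gives the integer
    display form.
    """

    recall: float
    precision: float
    specificity: float
    f1: float

    def rounded(self) -> tuple[int, int, int, int]:
        return (
            round_half_up(self.recall),
            round_half_up(self.precision),
            round_half_up(self.specificity),
            round_half_up(self.f1),
        )


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsRow:
    """recall=TP/(TP+FN), precision=TP/(TP+FP), specificity=TN/(TN+FP),
    F1=2PR/(P+R); any 0/0 ratio is reported as 0, so F1 is 0 exactly
    when TP is 0."""
    if cm.n == 0:
        raise ValidationError("cannot compute metrics of an all-zero confusion matrix")
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    specificity = _ratio(cm.tn, cm.tn + cm.fp)
    f1 = 0.0 if (precision + recall) == 0 else 2 * precision * recall / (precision + recall)
    return MetricsRow(recall=recall, precision=precision, specificity=specificity, f1=f1)


# ---------------------------------------------------------------------------
# cross-validation


def stratified_kfold(
    n_items: int, gold_labels: Sequence[int], k: int, seed: int
) -> list[np.ndarray]:
    """Partition indices 0..n-1 into k stratified blocks.

    Block sizes differ by at most 1 (larger blocks first) and per-block
    positive counts differ by at most 1 from the exact class proportion.
    Remainders of each class are allocated to the blocks currently
    furthest below their target size, so the two guarantees hold
    simultaneously.  Deterministic given the seed.
    """
    if len(gold_labels) != n_items:
        raise ValidationError("gold_labels length must equal n_items")
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > n_items:
        raise ValidationError(f"k={k} exceeds number of items n={n_items}")
    labels = np.asarray(gold_labels, dtype=int)
    if not (np.any(labels == 0) and np.any(labels == 1)):
        raise ValidationError("both label classes must be present")

    rng = np.random.default_rng(seed)
    targets = [n_items // k + (1 if i < n_items % k else 0) for i in range(k)]
    alloc = [[0, 0] for _ in range(k)]  # per fold: [n_pos, n_neg]
    fold_members: list[list[int]] = [[] for _ in range(k)]
    for cls_idx, cls in enumerate((1, 0)):
        members = np.flatnonzero(labels == cls)
        rng.shuffle(members)
        base, rem = divmod(len(members), k)
        counts = [base] * k
        # extras go to folds with the largest remaining deficit
        deficits = sorted(
            range(k),
            key=lambda i: (-(targets[i] - sum(alloc[i]) - base), i),
        )
        for i in deficits[:rem]:
            counts[i] += 1
        pos = 0
        for i in range(k):
            fold_members[i].extend(members[pos : pos + counts[i]].tolist())
            alloc[i][cls_idx] += counts[i]
            pos += counts[i]
    return [np.sort(np.asarray(m, dtype=int)) for m in fold_members]


class Predictor(Protocol):
    def train(self, instances: Sequence[RelationInstance]) -> object: ...

    def predict(
        self, model: object, instances: Sequence[RelationInstance]
    ) -> Sequence[int]: ...


class ConstantPredictor:
    """Label-independent predictor emitting a fixed label (baselines)."""

    def __init__(self, label: int) -> None:
        if label not in (0, 1):
            raise ValidationError("constant label must be 0 or 1")
        self.label = label

    def train(self, instances: Sequence[RelationInstance]) -> object:
        return self.label

    def predict(
        self, model: object, instances: Sequence[RelationInstance]
    ) -> list[int]:
        return [int(model) for _ in instances]  # type: ignore[call-overload]


_TAG_RE = re.compile(r"@[^@$]*\$")


class KeywordPredictor:
    """Reference keyword-score predictor: labels an instance positive when
    a relational verb occurs between the two entity tags.

    This is a smoke-test classifier for the cross-validation harness,
    not a reproduction of any published model.  Training selects, from a
    fixed verb lexicon, the verbs over-represented between tags in
    positive training instances.
    """

    LEXICON = (
        "increase", "increased", "increases", "elevated", "elevates",
        "enhanced", "enhances", "blocked", "blocks", "inhibited",
        "inhibits", "activated", "activates", "triggered", "triggers",
        "reduced", "reduces", "released", "releases", "promoted",
        "promotes", "decreased", "decreases", "affects", "modulates",
    )

    @staticmethod
    def _between(tagged: str) -> str:
        tags = list(_TAG_RE.finditer(tagged))
        if len(tags) < 2:
            return ""
        return tagged[tags[0].end() : tags[-1].start()].lower()

    def train(self, instances: Sequence[RelationInstance]) -> frozenset[str]:
        chosen: set[str] = set()
        for verb in self.LEXICON:
            pos = neg = 0
            for inst in instances:
                if inst.gold_label is None:
                    continue
                hit = re.search(rf"\b{verb}\b", self._between(inst.tagged_sentence))
                if hit:
                    if inst.gold_label == 1:
                        pos += 1
                    else:
                        neg += 1
            if pos > neg:
                chosen.add(verb)
        return frozenset(chosen)

    def predict(
        self, model: object, instances: Sequence[RelationInstance]
    ) -> list[int]:
        verbs: frozenset[str] = model  # type: ignore[assignment]
        out = []
        for inst in instances:
            between = self._between(inst.tagged_sentence)
            out.append(
                1 if any(re.search(rf"\b{v}\b", between) for v in verbs) else 0
            )
        return out


@dataclass(frozen=True, slots=True)
class CVReport:
    per_round: tuple[MetricsRow, ...]
    mean: MetricsRow
    sd: MetricsRow
    confusions: tuple[ConfusionMatrix, ...] = ()
    test_sizes: tuple[int, ...] = ()


def _aggregate(rows: Sequence[MetricsRow]) -> tuple[MetricsRow, MetricsRow]:
    arr = np.array([[r.recall, r.precision, r.specificity, r.f1] for r in rows])
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if len(rows) > 1 else np.zeros(4)
    return MetricsRow(*mean), MetricsRow(*sd)


def cross_validate(
    instances: Sequence[RelationInstance],
    predictor: Predictor,
    k: int = 5,
    seed: int = 0,
    orientation: str = "paper",
) -> CVReport:
    """k-round stratified cross-validation.

    With the default ``paper`` orientation, round *i* trains on block *i*
    alone and tests on the union of the other k−1 blocks; the
    ``conventional`` orientation inverts this.  Gold labels must be set
    on every instance.
    """
    if orientation not in ("paper", "conventional"):
        raise ValidationError(f"unknown cv orientation {orientation!r}")
    gold = [inst.gold_label for inst in instances]
    if any(g is None for g in gold):
        raise ValidationError("all instances must carry gold labels for CV")
    folds = stratified_kfold(len(instances), gold, k, seed)  # type: ignore[arg-type]
    rows: list[MetricsRow] = []
    cms: list[ConfusionMatrix] = []
    sizes: list[int] = []
    for i in range(k):
        if orientation == "paper":
            train_idx = folds[i]
            test_idx = np.concatenate([folds[j] for j in range(k) if j != i])
        else:
            test_idx = folds[i]
            train_idx = np.concatenate([folds[j] for j in range(k) if j != i])
        train = [instances[j] for j in train_idx]
        test = [instances[j] for j in test_idx]
        try:
            model = predictor.train(train)
            pred = list(predictor.predict(model, test))
        except Exception as exc:
            raise RuntimeError(f"predictor failed in CV round {i}: {exc}") from exc
        cm = confusion(pred, [instances[j].gold_label for j in test_idx])  # type: ignore[misc]
        cms.append(cm)
        rows.append(metrics_from_confusion(cm))
        sizes.append(len(test))
    mean, sd = _aggregate(rows)
    return CVReport(
        per_round=tuple(rows),
        mean=mean,
        sd=sd,
        confusions=tuple(cms),
        test_sizes=tuple(sizes),
    )


# ---------------------------------------------------------------------------
# external predictions & exchange formats


def import_external_predictions(
    instances: Sequence[RelationInstance], labels_source: Union[str, Iterable[str]]
) -> list[int]:
    """Read a predictions TSV (``instance_id  label``) and align it to the
    instance list by stable id, independent of file order."""
    if isinstance(labels_source, str) and "\n" not in labels_source and "\t" not in labels_source:
        with open(labels_source, encoding="utf-8") as fh:
            text = fh.read()
    elif isinstance(labels_source, str):
        text = labels_source
    else:
        text = "\n".join(labels_source)
    mapping: dict[str, int] = {}
    reader = csv.reader(io.StringIO(text), delimiter="\t")
    header = next(reader, None)
    if header is None or header[:2] != ["instance_id", "label"]:
        raise ValidationError(
            "predictions TSV must start with header: instance_id\tlabel"
        )
    for row_no, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) < 2 or row[1] not in ("0", "1"):
            raise ValidationError(f"row {row_no}: expected 'instance_id\\tlabel(0/1)'")
        mapping[row[0]] = int(row[1])
    missing = [inst.id for inst in instances if inst.id not in mapping]
    if missing:
        raise ValidationError(
            f"predictions file missing {len(missing)} instance id(s): "
            f"{missing[:5]}"
        )
    return [mapping[inst.id] for inst in instances]


def dataset_to_tsv(instances: Sequence[RelationInstance]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(
        ["instance_id", "doc_id", "sentence", "tagged_sentence", "e1", "e1_uri",
         "e2", "e2_uri", "label"]
    )
    for inst in instances:
        writer.writerow([
            inst.id, inst.doc_id, inst.sentence, inst.tagged_sentence,
            inst.entity1_label, inst.entity1_uri.render(),
            inst.entity2_label, inst.entity2_uri.render(),
            "" if inst.gold_label is None else inst.gold_label,
        ])
    return buf.getvalue()


def load_dataset_tsv(path_or_text: str) -> list[RelationInstance]:
    text = path_or_text
    if "\t" not in text and "\n" not in text:
        with open(path_or_text, encoding="utf-8") as fh:
            text = fh.read()
    reader = csv.reader(io.StringIO(text), delimiter="\t")
    header = next(reader, None)
    expected = ["instance_id", "doc_id", "sentence", "tagged_sentence", "e1",
                "e1_uri", "e2", "e2_uri", "label"]
    if header != expected:
        raise ValidationError(f"dataset TSV header must be {expected}")
    out: list[RelationInstance] = []
    for row_no, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != len(expected):
            raise ValidationError(f"row {row_no}: expected {len(expected)} columns")
        def _uri(s: str) -> Uri:
            prefix, _, local = s.partition(":")
            return Uri(prefix, local)
        out.append(
            RelationInstance(
                sentence=row[2],
                tagged_sentence=row[3],
                entity1_label=row[4],
                entity1_uri=_uri(row[5]),
                entity2_label=row[6],
                entity2_uri=_uri(row[7]),
                doc_id=row[1],
                gold_label=None if row[8] == "" else int(row[8]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# triple export

RELATION_TYPE = Uri("ketrela", "Relation")
SENTENCE_PRED = Uri("ketrela", "sentence")
DOC_PRED = Uri("ketrela", "doc")
ENTITY1_PRED = Uri("ketrela", "entity1")
ENTITY2_PRED = Uri("ketrela", "entity2")


def relations_to_triples(
    instances: Sequence[RelationInstance],
    labels_by_source: dict[str, Sequence[int]],
) -> set[Triple]:
    """Export scored instances as the relation layer.

    ``labels_by_source`` maps a source name (e.g. ``manual`` or an
    external model name) to a per-instance 0/1 label vector; each source
    contributes one label triple per instance, so all combinations of
    manual and predicted relations stay retrievable side by side.
    """
    for name, labels in labels_by_source.items():
        if len(labels) != len(instances):
            raise ValidationError(
                f"label vector {name!r} has length {len(labels)}, "
                f"expected {len(instances)}"
            )
    triples: set[Triple] = set()
    for i, inst in enumerate(instances):
        node = Uri("ketrela", f"inst_{inst.id}")
        triples.add(Triple(node, RDF_TYPE, RELATION_TYPE))
        triples.add(Triple(node, SENTENCE_PRED, Literal(inst.sentence)))
        triples.add(Triple(node, DOC_PRED, Literal(inst.doc_id)))
        triples.add(Triple(node, ENTITY1_PRED, inst.entity1_uri))
        triples.add(Triple(node, ENTITY2_PRED, inst.entity2_uri))
        for name, labels in labels_by_source.items():
            triples.add(
                Triple(node, Uri("ketrela", f"label_{name}"), Literal(str(labels[i])))
            )
    return triples
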