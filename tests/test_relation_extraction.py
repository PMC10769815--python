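"""Entity tagging, confusion metrics, stratified CV and external
prediction import."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathkg import fixtures as fx
from pathkg.core_model import Uri, ValidationError
from pathkg.relation_extraction import (
    ConfusionMatrix,
    ConstantPredictor,
    KeywordPredictor,
    baseline_predict,
    build_instances,
    confusion,
    cross_validate,
    import_external_predictions,
    metrics_from_confusion,
    stratified_kfold,
)
from pathkg.text_annotation import Thesaurus, annotate_sentence

KET = Uri("ketcept", "ketamine")
SER = Uri("ketcept", "serotonin")
DOP = Uri("ketcept", "dopamine")

THES = Thesaurus({"ketamine": KET, "serotonin": SER, "dopamine": DOP})


class TestBuildInstances:
    def test_tags_replace_annotated_spans(self):
        ann = annotate_sentence("ketamine increased serotonin", THES)
        (inst,) = build_instances(ann, KET, {SER})
        assert inst.tagged_sentence == "@ketamine$ increased @serotonin$"

    def test_one_instance_per_partner(self):
        ann = annotate_sentence("ketamine raised serotonin and dopamine", THES)
        insts = build_instances(ann, KET, {SER, DOP})
        assert len(insts) == 2
        assert all(i.tagged_sentence.count("@") == 2 for i in insts)

    def test_sentence_without_drug(self):
        ann = annotate_sentence("serotonin and dopamine levels", THES)
        assert build_instances(ann, KET, {SER, DOP}) == []


class TestConfusion:
    def test_hand_counts(self):
        assert confusion([1, 1, 0], [1, 0, 0]) == ConfusionMatrix(1, 1, 1, 0)
        assert confusion([1] * 5, [1] * 5) == ConfusionMatrix(5, 0, 0, 0)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError, match="mismatch"):
            confusion([1], [1, 0])

    def test_random_vectors_match_loop_oracle(self):
        rng = random.Random(11)
        pred = [rng.randint(0, 1) for _ in range(200)]
        gold = [rng.randint(0, 1) for _ in range(200)]
        tp = fp = tn = fn = 0
        for p, g in zip(pred, gold):
            if p and g:
                tp += 1
            elif p and not g:
                fp += 1
            elif not p and not g:
                tn += 1
            else:
                fn += 1
        assert confusion(pred, gold) == ConfusionMatrix(tp, fp, tn, fn)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1))
    def test_complement_identity(self, pairs):
        """Flipping every prediction maps TP->FN, FP->TN, TN->FP, FN->TP."""
        pred = [p for p, _ in pairs]
        gold = [g for _, g in pairs]
        cm = confusion(pred, gold)
        flipped = confusion([1 - p for p in pred], gold)
        assert (flipped.tp, flipped.fp, flipped.tn, flipped.fn) == (
            cm.fn, cm.tn, cm.fp, cm.tp
        )


class TestMetrics:
    def test_predict_all_baseline_row(self):
        m = metrics_from_confusion(ConfusionMatrix(1267, 876, 0, 0))
        assert m.rounded() == (100, 59, 0, 74)

    def test_predict_none_baseline_row(self):
        m = metrics_from_confusion(ConfusionMatrix(0, 0, 876, 1267))
        assert m.rounded() == (0, 0, 100, 0)

    def test_perfect_classifier(self):
        m = metrics_from_confusion(ConfusionMatrix(10, 0, 10, 0))
        assert m.rounded() == (100, 100, 100, 100)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValidationError):
            metrics_from_confusion(ConfusionMatrix(0, 0, 0, 0))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        tn=st.integers(0, 50), fn=st.integers(0, 50),
    )
    def test_f1_zero_iff_tp_zero(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        m = metrics_from_confusion(ConfusionMatrix(tp, fp, tn, fn))
        assert (m.f1 == 0) == (tp == 0)
        assert m.f1 <= min(2 * m.precision, 2 * m.recall) + 1e-9

    def test_predict_all_precision_is_prevalence(self):
        instances, _ = fx.table1_dataset(seed=1, n_pos=30, n_neg=20)
        rng = random.Random(5)
        for _ in range(3):
            perm = instances[:]
            rng.shuffle(perm)
            gold = [i.gold_label for i in perm]
            cm = confusion(baseline_predict(perm, "all"), gold)
            m = metrics_from_confusion(cm)
            assert m.precision == pytest.approx(100 * 30 / 50)


class TestBaselinePredict:
    def test_modes(self):
        instances, _ = fx.table1_dataset(seed=1, n_pos=5, n_neg=3)
        assert baseline_predict(instances, "none") == [0] * 8
        assert baseline_predict(instances, "all") == [1] * 8
        assert baseline_predict([], "all") == []

    def test_unknown_mode(self):
        with pytest.raises(ValidationError, match="some"):
            baseline_predict([], "some")


class TestStratifiedKfold:
    def test_balanced_small_case(self):
        labels = [1] * 5 + [0] * 5
        folds = stratified_kfold(10, labels, 5, seed=0)
        assert all(len(f) == 2 for f in folds)
        for f in folds:
            assert sorted(labels[i] for i in f) == [0, 1]

    def test_fold_sizes_on_2143(self):
        labels = [1] * 1267 + [0] * 876
        folds = stratified_kfold(2143, labels, 5, seed=0)
        assert sorted((len(f) for f in folds), reverse=True) == [429, 429, 429, 428, 428]
        # partition property
        all_idx = np.concatenate(folds)
        assert sorted(all_idx.tolist()) == list(range(2143))
        # stratification: positive counts within 1 of exact proportion
        for f in folds:
            pos = sum(labels[i] for i in f)
            assert abs(pos - 1267 * len(f) / 2143) <= 1

    def test_deterministic_given_seed(self):
        labels = [1] * 40 + [0] * 25
        a = stratified_kfold(65, labels, 5, seed=3)
        b = stratified_kfold(65, labels, 5, seed=3)
        assert all((x == y).all() for x, y in zip(a, b))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValidationError):
            stratified_kfold(3, [0, 1, 1], 5, seed=0)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            stratified_kfold(4, [1, 1, 1, 1], 2, seed=0)


class TestCrossValidate:
    def test_constant_predictor_recall_sd_zero(self, table1):
        instances, _ = table1
        cv = cross_validate(instances, ConstantPredictor(1), k=5, seed=1)
        assert all(r.recall == 100 for r in cv.per_round)
        assert cv.sd.recall == 0
        assert cv.sd.specificity == 0

    def test_paper_orientation_test_sizes(self, table1):
        instances, _ = table1
        cv = cross_validate(instances, ConstantPredictor(1), k=5, seed=1)
        assert set(cv.test_sizes) <= {1714, 1715}
        assert sorted(cv.test_sizes, reverse=True)[:2] == [1715, 1715]

    def test_precision_tracks_prevalence_per_round(self, table1):
        instances, _ = table1
        cv = cross_validate(instances, ConstantPredictor(1), k=5, seed=1)
        for r in cv.per_round:
            assert abs(r.precision - 59.13) < 1.0

    def test_conventional_orientation_inverts(self, table1):
        instances, _ = table1
        cv = cross_validate(
            instances, ConstantPredictor(1), k=5, seed=1, orientation="conventional"
        )
        assert sorted(cv.test_sizes, reverse=True) == [429, 429, 429, 428, 428]

    def test_keyword_predictor_runs(self):
        instances, _ = fx.table1_dataset(seed=2, n_pos=60, n_neg=40)
        cv = cross_validate(instances, KeywordPredictor(), k=5, seed=2)
        assert len(cv.per_round) == 5
        assert 0 <= cv.mean.f1 <= 100

    def test_predictor_failure_reports_round(self, table1):
        class Broken:
            def train(self, instances):
                raise RuntimeError("boom")

            def predict(self, model, instances):
                return []

        instances, _ = fx.table1_dataset(seed=2, n_pos=10, n_neg=10)
        with pytest.raises(RuntimeError, match="round 0"):
            cross_validate(instances, Broken(), k=5, seed=0)


class TestExternalPredictions:
    def _file(self, instances, order=None):
        rows = ["instance_id\tlabel"]
        idx = order if order is not None else range(len(instances))
        for i in idx:
            rows.append(f"{instances[i].id}\t{instances[i].gold_label}")
        return "\n".join(rows) + "\n"

    def test_full_file_aligns(self):
        instances, _ = fx.table1_dataset(seed=3, n_pos=20, n_neg=15)
        labels = import_external_predictions(instances, self._file(instances))
        assert labels == [i.gold_label for i in instances]

    def test_shuffled_file_gives_same_vector(self):
        instances, _ = fx.table1_dataset(seed=3, n_pos=20, n_neg=15)
        order = list(range(len(instances)))
        random.Random(1).shuffle(order)
        labels = import_external_predictions(instances, self._file(instances, order))
        assert labels == [i.gold_label for i in instances]

    def test_missing_id_is_named(self):
        instances, _ = fx.table1_dataset(seed=3, n_pos=5, n_neg=5)
        text = self._file(instances[:-1])
        with pytest.raises(ValidationError, match=instances[-1].id):
            import_external_predictions(instances, text)
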