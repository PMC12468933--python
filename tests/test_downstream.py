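"""Task builders, metric panel oracle, cross-validated head training."""

import numpy as np
import pytest

from abcurriculum.downstream import (build_pair_task, build_specificity_task,
                                     classification_metrics, train_task,
                                     TaskConfig, TaskDataset, TaskExample,
                                     MUTATED, UNMUTATED, DIFFERENT)
from abcurriculum.records import SequenceRecord
from abcurriculum.synthdata import GeneratorConfig, generate, generate_classed


# ---- metric panel vs a hand-computed confusion table ----------------------

def brute_force_auc(y, p):
    pos = p[y == 1]
    neg = p[y == 0]
    wins = sum((pp > nn) + 0.5 * (pp == nn) for pp in pos for nn in neg)
    return wins / (len(pos) * len(neg))


def brute_force_ap(y, p):
    order = np.argsort(-p, kind="stable")
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    precision = tp / (np.arange(len(y)) + 1)
    recall = tp / y.sum()
    prev_r = 0.0
    ap = 0.0
    for pr, rc in zip(precision, recall):
        ap += pr * (rc - prev_r)
        prev_r = rc
    return ap


class TestMetricPanel:
    def test_matches_hand_computed_confusion_table(self):
        # TP=3, FP=1, FN=2, TN=4 on ten examples
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        p1 = np.array([0.9, 0.8, 0.7, 0.4, 0.3, 0.6, 0.2, 0.15, 0.1, 0.05])
        probs = np.column_stack([1 - p1, p1])
        panel = classification_metrics(y, probs)
        tp, fp, fn, tn = 3, 1, 2, 4
        assert panel["accuracy"] == pytest.approx((tp + tn) / 10)   # 0.7
        precision, recall = tp / (tp + fp), tp / (tp + fn)
        assert panel["f1"] == pytest.approx(
            2 * precision * recall / (precision + recall))
        mcc = (tp * tn - fp * fn) / np.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        assert panel["mcc"] == pytest.approx(mcc)
        assert panel["auc"] == pytest.approx(brute_force_auc(y, p1))
        assert panel["aupr"] == pytest.approx(brute_force_ap(y, p1))

    def test_multiclass_invariant_to_class_order(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 3, size=60)
        logits = rng.normal(size=(60, 3))
        probs = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
        panel = classification_metrics(y, probs)
        perm = np.array([2, 0, 1])
        y_perm = perm[y]
        probs_perm = probs[:, np.argsort(perm)]
        panel_perm = classification_metrics(y_perm, probs_perm)
        for k in ("auc", "aupr", "accuracy", "mcc"):
            assert panel[k] == pytest.approx(panel_perm[k])


# ---- pair task -------------------------------------------------------------

class TestPairTask:
    def test_minimal_four_records(self):
        recs = generate(GeneratorConfig(n_paired=4, seed=0))
        ds = build_pair_task(recs, rng=0, n_folds=2)
        labels = [ex.label for ex in ds.examples]
        assert labels.count(0) == 2 and labels.count(1) == 2
        natives = {(r.heavy_chain, r.light_chain) for r in recs}
        for ex in ds.examples:
            if ex.label == 1:
                assert (ex.record.heavy_chain, ex.record.light_chain) not in natives

    def test_negatives_never_collide_exhaustive(self, paired_records):
        ds = build_pair_task(paired_records, rng=1)
        natives = {(r.heavy_chain, r.light_chain) for r in paired_records}
        negs = [ex for ex in ds.examples if ex.label == 1]
        for ex in negs:
            assert (ex.record.heavy_chain, ex.record.light_chain) not in natives

    def test_each_light_chain_once_among_negatives(self, paired_records):
        ds = build_pair_task(paired_records, rng=2)
        lights = [ex.record.light_chain for ex in ds.examples if ex.label == 1]
        assert len(lights) == len(set(lights))

    def test_all_unmutated_gives_unmutated_subset(self):
        recs = generate(GeneratorConfig(n_paired=12, memory_fraction=0.0, seed=3))
        ds = build_pair_task(recs, rng=0, n_folds=2)
        assert all(ex.subset == UNMUTATED for ex in ds.examples)

    def test_subset_definition(self):
        recs = generate(GeneratorConfig(n_paired=60, memory_fraction=0.5,
                                        shm_rate=0.08, seed=4))
        ds = build_pair_task(recs, rng=0)
        for ex in ds.examples:
            h = ex.record.mutation_count_heavy >= 1
            l = ex.record.mutation_count_light >= 1
            expected = MUTATED if h and l else UNMUTATED if not (h or l) else DIFFERENT
            assert ex.subset == expected

    def test_fold_proportions_within_one_per_cell(self, paired_records):
        ds = build_pair_task(paired_records, rng=5)
        from collections import Counter
        cells = Counter((ex.label, ex.subset) for ex in ds.examples)
        for fold in range(5):
            fold_exs = [ex for ex in ds.examples if ex.fold == fold]
            fc = Counter((ex.label, ex.subset) for ex in fold_exs)
            for cell, total in cells.items():
                assert abs(fc.get(cell, 0) - total / 5) < 1.0 + 1e-9

    def test_too_few_records_raises(self):
        recs = generate(GeneratorConfig(n_paired=2, seed=0))
        with pytest.raises(ValueError):
            build_pair_task(recs, rng=0)


# ---- specificity task ------------------------------------------------------

class TestSpecificityTask:
    def _grouped(self, sizes, seed=0):
        cfg = GeneratorConfig(n_paired=sum(sizes), seed=seed)
        recs = generate(cfg)
        grouped, start = {}, 0
        for i, s in enumerate(sizes):
            grouped[f"c{i}"] = recs[start:start + s]
            start += s
        return grouped

    def test_classes_equalized(self):
        ds = build_specificity_task(self._grouped([100, 60, 80]), rng=0)
        counts = np.bincount([ex.label for ex in ds.examples])
        assert counts.tolist() == [60, 60, 60]

    def test_three_class_stratified_folds(self):
        ds = build_specificity_task(self._grouped([30, 30, 30]), rng=0)
        assert len(ds.classes) == 3
        for fold in range(5):
            labels = {ex.label for ex in ds.examples if ex.fold == fold}
            assert labels == {0, 1, 2}

    def test_binary_mode(self):
        ds = build_specificity_task(self._grouped([20, 20]), rng=0)
        assert len(ds.classes) == 2

    def test_heavy_only_strips_light_chain(self):
        ds = build_specificity_task(self._grouped([10, 10]),
                                    input_mode="heavy_only", rng=0)
        for ex in ds.examples:
            assert ex.record.chain_type == "heavy"
            assert ex.record.light_chain is None

    def test_heavy_only_without_heavy_chain_raises(self):
        light_only = [SequenceRecord(record_id=f"l{i}", light_chain="DIIK" * 5,
                                     chain_type="light") for i in range(10)]
        grouped = {"a": light_only[:5], "b": light_only[5:]}
        with pytest.raises(ValueError):
            build_specificity_task(grouped, input_mode="heavy_only", rng=0)

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            build_specificity_task({"a": [], "b": []}, rng=0)


# ---- head training ---------------------------------------------------------

class TestTrainTask:
    def test_single_class_fold_raises(self, tiny_encoder):
        recs = generate(GeneratorConfig(n_paired=8, seed=0))
        examples = [TaskExample(record=r, label=i % 2, fold=0 if i < 4 else 1)
                    for i, r in enumerate(recs)]
        examples[0].label = 0
        # make fold 1 single-class
        for ex in examples[4:]:
            ex.label = 0
        ds = TaskDataset(examples=examples, classes=["a", "b"], n_folds=2)
        with pytest.raises(ValueError, match="single class"):
            train_task(tiny_encoder, ds, TaskConfig(epochs=1, pad_to=256))

    def test_single_fold_reports_zero_se(self, tiny_encoder):
        recs = generate(GeneratorConfig(n_paired=12, seed=1))
        examples = [TaskExample(record=r, label=i % 2, fold=0 if i < 6 else -1)
                    for i, r in enumerate(recs)]
        ds = TaskDataset(examples=examples, classes=["a", "b"], n_folds=1)
        report = train_task(tiny_encoder, ds,
                            TaskConfig(epochs=1, pad_to=256, peak_lr=1e-3))
        for mean, se in report.metrics.values():
            assert se == 0.0
        assert report.n_folds == 1

    def test_report_serializes(self, tiny_encoder, tmp_path):
        cfg = GeneratorConfig(n_paired=40, seed=2, memory_fraction=0.5)
        ds = build_pair_task(generate(cfg), rng=0, n_folds=2)
        report = train_task(tiny_encoder, ds,
                            TaskConfig(epochs=1, pad_to=256, peak_lr=1e-3))
        path = tmp_path / "report.json"
        report.to_json(path)
        import json
        loaded = json.loads(path.read_text())
        assert set(loaded["metrics"]) == {"accuracy", "f1", "auc", "aupr", "mcc"}
        assert loaded["n_folds"] == 2
        # subset breakdown present for the pair task
        assert loaded["per_subset_accuracy"]
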