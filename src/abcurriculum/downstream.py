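"""Downstream classification tasks over a (frozen) encoder.

Two task builders mirror the standard antibody benchmarks:

- *native-vs-random pairing*: given a heavy+light pair, decide whether the
  chains come from the same cell.  Negatives are built by a derangement of
  light chains over a held-out half of the records, so labels are balanced
  1:1, no shuffled pair reproduces a native pairing, and each light chain
  appears exactly once among the negatives.  Examples are annotated by
  mutation status — *mutated* (both chains carry somatic mutations),
  *unmutated* (neither does) or *different* (one of each) — so accuracy can
  be broken down the same way.
- *specificity*: k-class antigen-specificity classification (e.g. healthy
  donor vs influenza vs coronavirus), classes downsampled to equal size,
  optionally using only the heavy chain.

Both use stratified 5-fold cross-validation; metrics (accuracy, F1, AUC,
AUPR, MCC) are averaged over folds with the standard error of the fold
values.  Heads are trained with the base encoder frozen by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (accuracy_score, average_precision_score, f1_score,
                             matthews_corrcoef, roc_auc_score)
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import label_binarize

from . import _autodiff as ad
from .model import TransformerEncoder, SequenceClassifier, attach_classifier
from .records import SequenceRecord, PAIRED, HEAVY
from .schedule import LRScheduleSpec, learning_rate
from .tokenizer import encode, VOCAB

__all__ = ["PairTaskDataset", "TaskDataset", "TaskExample", "TaskConfig",
           "TaskReport", "build_pair_task", "build_specificity_task",
           "train_task", "classification_metrics", "MUTATION_THRESHOLD"]

#: A chain counts as "mutated" when it carries at least this many substitutions.
MUTATION_THRESHOLD = 1

NATIVE, RANDOM = "native", "random"
MUTATED, UNMUTATED, DIFFERENT = "mutated", "unmutated", "different"


@dataclass
class TaskExample:
    record: SequenceRecord
    label: int
    subset: Optional[str] = None
    fold: int = -1


@dataclass
class TaskDataset:
    examples: list[TaskExample]
    classes: list[str]
    n_folds: int = 5

    def fold_split(self, fold: int):
        train = [ex for ex in self.examples if ex.fold != fold]
        test = [ex for ex in self.examples if ex.fold == fold]
        return train, test

    def to_csv(self, path: str | Path) -> None:
        rows = [{
            "record_id": ex.record.record_id,
            "heavy": ex.record.heavy_chain or "",
            "light": ex.record.light_chain or "",
            "label": self.classes[ex.label],
            "subset": ex.subset or "",
            "fold": ex.fold,
        } for ex in self.examples]
        pd.DataFrame(rows).to_csv(path, index=False)


class PairTaskDataset(TaskDataset):
    """Native-vs-random pair task (classes are ["native", "random"])."""


def _mutation_subset(heavy_mut: int, light_mut: int,
                     threshold: int = MUTATION_THRESHOLD) -> str:
    h = heavy_mut >= threshold
    l = light_mut >= threshold
    if h and l:
        return MUTATED
    if not h and not l:
        return UNMUTATED
    return DIFFERENT


def _stratified_folds(keys: Sequence[str], n_folds: int, seed: int) -> np.ndarray:
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = np.empty(len(keys), dtype=int)
    dummy = np.zeros(len(keys))
    for f, (_, test_idx) in enumerate(skf.split(dummy, keys)):
        folds[test_idx] = f
    return folds


def build_pair_task(paired_records: Sequence[SequenceRecord],
                    rng: np.random.Generator | int = 0,
                    n_folds: int = 5,
                    threshold: int = MUTATION_THRESHOLD) -> PairTaskDataset:
    """Build the native-vs-random pairing dataset.

    The records are split into two disjoint halves: the first supplies the
    native (positive) examples unchanged; in the second, light chains are
    deranged — permuted so no record keeps its own partner — to form the
    random (negative) examples.  Every record is used exactly once, as a
    native or as a shuffled pair.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    records = [r for r in paired_records if r.chain_type == PAIRED]
    if len(records) < 4:
        raise ValueError("need at least 4 paired records to build the pair task")
    order = rng.permutation(len(records))
    n = len(records) - (len(records) % 2)   # drop one if odd to keep 1:1 labels
    half = n // 2
    native = [records[i] for i in order[:half]]
    shuffle_pool = [records[i] for i in order[half:n]]
    native_pairs = {(r.heavy_chain, r.light_chain) for r in records}

    m = len(shuffle_pool)
    for _attempt in range(1000):
        perm = rng.permutation(m)
        if any(perm[i] == i for i in range(m)):
            continue
        candidate = [(shuffle_pool[i].heavy_chain,
                      shuffle_pool[perm[i]].light_chain) for i in range(m)]
        if any(pair in native_pairs for pair in candidate):
            continue
        break
    else:
        raise ValueError("could not derange light chains without reproducing "
                         "a native pairing (too few / too similar records)")

    examples: list[TaskExample] = []
    for rec in native:
        examples.append(TaskExample(
            record=rec, label=0,
            subset=_mutation_subset(rec.mutation_count_heavy,
                                    rec.mutation_count_light, threshold)))
    for i in range(m):
        h_rec, l_rec = shuffle_pool[i], shuffle_pool[perm[i]]
        rec = SequenceRecord(
            record_id=f"{h_rec.record_id}x{l_rec.record_id}",
            heavy_chain=h_rec.heavy_chain, light_chain=l_rec.light_chain,
            chain_type=PAIRED,
            heavy_regions=h_rec.heavy_regions, light_regions=l_rec.light_regions,
            mutation_count_heavy=h_rec.mutation_count_heavy,
            mutation_count_light=l_rec.mutation_count_light)
        examples.append(TaskExample(
            record=rec, label=1,
            subset=_mutation_subset(rec.mutation_count_heavy,
                                    rec.mutation_count_light, threshold)))
    keys = [f"{ex.label}|{ex.subset}" for ex in examples]
    folds = _stratified_folds(keys, n_folds, int(rng.integers(2 ** 31)))
    for ex, f in zip(examples, folds):
        ex.fold = int(f)
    return PairTaskDataset(examples=examples, classes=[NATIVE, RANDOM],
                           n_folds=n_folds)


def build_specificity_task(records_by_class: dict[str, Sequence[SequenceRecord]],
                           input_mode: str = "paired",
                           rng: np.random.Generator | int = 0,
                           n_folds: int = 5) -> TaskDataset:
    """Build a k-class specificity dataset with equal-size classes.

    ``input_mode="heavy_only"`` strips records down to their heavy chain
    (the unpaired variant of the task); records lacking a heavy chain are a
    validation error.
    """
    if input_mode not in ("paired", "heavy_only"):
        raise ValueError(f"unknown input_mode {input_mode!r}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    classes = sorted(records_by_class)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    sizes = {c: len(records_by_class[c]) for c in classes}
    if min(sizes.values()) == 0:
        raise ValueError(f"empty class among {sizes}")
    n_keep = min(sizes.values())
    examples: list[TaskExample] = []
    for label, cls in enumerate(classes):
        recs = list(records_by_class[cls])
        keep_idx = rng.permutation(len(recs))[:n_keep]
        for i in keep_idx:
            rec = recs[i]
            if input_mode == "heavy_only":
                if not rec.heavy_chain:
                    raise ValueError(
                        f"{rec.record_id}: no heavy chain for heavy_only mode")
                rec = SequenceRecord(
                    record_id=rec.record_id, heavy_chain=rec.heavy_chain,
                    chain_type=HEAVY, heavy_regions=rec.heavy_regions,
                    mutation_count_heavy=rec.mutation_count_heavy)
            examples.append(TaskExample(record=rec, label=label))
    keys = [str(ex.label) for ex in examples]
    folds = _stratified_folds(keys, n_folds, int(rng.integers(2 ** 31)))
    for ex, f in zip(examples, folds):
        ex.fold = int(f)
    return TaskDataset(examples=examples, classes=classes, n_folds=n_folds)


@dataclass
class TaskConfig:
    """Head-training hyperparameters for one classification task."""

    epochs: int = 10
    batch_size: int = 32
    peak_lr: float = 5e-5
    warmup_ratio: float = 0.1
    freeze_base: bool = True
    dialect: str = "cls"
    chain_order: str = "heavy_first"
    pad_to: int = 320
    seed: int = 0

    @classmethod
    def binary_specificity(cls, **kw) -> "TaskConfig":
        return cls(**{**dict(epochs=10, batch_size=32, peak_lr=5e-5), **kw})

    @classmethod
    def three_class_specificity(cls, **kw) -> "TaskConfig":
        return cls(**{**dict(epochs=5, batch_size=8, peak_lr=5e-5), **kw})

    @classmethod
    def pair_classification(cls, **kw) -> "TaskConfig":
        return cls(**{**dict(epochs=50, batch_size=256, peak_lr=1e-5), **kw})


@dataclass
class TaskReport:
    """Fold-averaged metric panel: mean and standard error per metric."""

    metrics: dict[str, tuple[float, float]]
    per_fold: dict[str, list[float]]
    n_folds: int
    per_subset_accuracy: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "metrics": {k: {"mean": m, "se": s} for k, (m, s) in self.metrics.items()},
            "per_fold": self.per_fold,
            "per_subset_accuracy": {
                k: {"mean": m, "se": s}
                for k, (m, s) in self.per_subset_accuracy.items()},
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def classification_metrics(y_true: np.ndarray, probs: np.ndarray) -> dict:
    """The five-metric panel on one evaluation split.

    ``probs`` has shape (n, k).  Binary tasks use the positive-class column
    for AUC/AUPR; multi-class tasks use macro one-vs-rest, which is
    invariant to class order.
    """
    y_true = np.asarray(y_true)
    probs = np.asarray(probs)
    k = probs.shape[1]
    y_pred = probs.argmax(axis=1)
    out = {
        "accuracy": accuracy_score(y_true, y_pred),
        "f1": f1_score(y_true, y_pred,
                       average="binary" if k == 2 else "macro"),
        "mcc": matthews_corrcoef(y_true, y_pred),
    }
    if k == 2:
        out["auc"] = roc_auc_score(y_true, probs[:, 1])
        out["aupr"] = average_precision_score(y_true, probs[:, 1])
    else:
        onehot = label_binarize(y_true, classes=np.arange(k))
        out["auc"] = roc_auc_score(onehot, probs, average="macro",
                                   multi_class="ovr")
        out["aupr"] = average_precision_score(onehot, probs, average="macro")
    return {k2: float(v) for k2, v in out.items()}


def _softmax_np(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _mean_se(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return mean, se


def _encode_all(dataset: TaskDataset, cfg: TaskConfig):
    ids, att = [], []
    for ex in dataset.examples:
        enc = encode(ex.record, dialect=cfg.dialect,
                     chain_order=cfg.chain_order, pad_to=cfg.pad_to)
        ids.append(enc.token_ids)
        att.append(enc.attention_mask)
    return np.stack(ids), np.stack(att)


def train_task(encoder: TransformerEncoder, dataset: TaskDataset,
               config: Optional[TaskConfig] = None) -> TaskReport:
    """Train and cross-validate a classification head on a task dataset.

    Per fold: a fresh head (and, if ``freeze_base=False``, a fresh copy of
    the encoder) is trained on the other folds and evaluated on the held-out
    fold.  With a frozen base the pooled start-token embeddings are
    precomputed once and the head trains on them directly — mathematically
    identical to running the full model every step.
    """
    config = config or TaskConfig()
    n_classes = len(dataset.classes)
    labels = np.array([ex.label for ex in dataset.examples])
    subsets = np.array([ex.subset or "" for ex in dataset.examples], dtype=object)
    folds = np.array([ex.fold for ex in dataset.examples])
    for f in range(dataset.n_folds):
        if len(np.unique(labels[folds == f])) < 2:
            raise ValueError(f"fold {f} contains a single class; "
                             "re-stratify or reduce n_folds")
    ids, att = _encode_all(dataset, config)

    pooled_all = None
    if config.freeze_base:
        clf_probe = attach_classifier(encoder, n_classes,
                                      freeze_base=True, seed=config.seed)
        chunks = [clf_probe.pooled(ids[s:s + 64], att[s:s + 64]).data
                  for s in range(0, len(ids), 64)]
        pooled_all = np.concatenate(chunks, axis=0)

    per_fold: dict[str, list[float]] = {}
    subset_fold: dict[str, list[float]] = {}
    rng = np.random.default_rng(config.seed)
    for fold in range(dataset.n_folds):
        train_idx = np.flatnonzero(folds != fold)
        test_idx = np.flatnonzero(folds == fold)
        if config.freeze_base:
            base = encoder
        else:
            base = TransformerEncoder(
                encoder.config,
                params={k: ad.param(v.data.copy())
                        for k, v in encoder.params.items()})
        clf = attach_classifier(base, n_classes,
                                freeze_base=config.freeze_base,
                                seed=config.seed + fold)
        opt = ad.Adam(clf.parameters(), lr=config.peak_lr)
        steps_per_epoch = max(1, int(np.ceil(len(train_idx) / config.batch_size)))
        total_steps = steps_per_epoch * config.epochs
        lr_spec = LRScheduleSpec(
            kind="linear", peak_lr=config.peak_lr,
            warmup_steps=int(config.warmup_ratio * total_steps),
            total_steps=total_steps)
        step = 0
        for _epoch in range(config.epochs):
            order = rng.permutation(train_idx)
            for s in range(0, len(order), config.batch_size):
                batch = order[s:s + config.batch_size]
                if config.freeze_base:
                    logits = clf.head_logits(ad.const(pooled_all[batch]))
                else:
                    logits = clf.forward(ids[batch], att[batch])
                loss, _ = ad.cross_entropy_logits(logits, labels[batch])
                opt.zero_grad()
                loss.backward()
                opt.step(lr=learning_rate(lr_spec, min(step, total_steps)))
                step += 1
        # held-out evaluation
        if config.freeze_base:
            test_logits = clf.head_logits(ad.const(pooled_all[test_idx])).data
        else:
            test_logits = np.concatenate(
                [clf.forward(ids[test_idx[s:s + 64]], att[test_idx[s:s + 64]]).data
                 for s in range(0, len(test_idx), 64)], axis=0)
        probs = _softmax_np(test_logits)
        panel = classification_metrics(labels[test_idx], probs)
        for name, val in panel.items():
            per_fold.setdefault(name, []).append(val)
        y_pred = probs.argmax(axis=1)
        for subset in np.unique(subsets[test_idx]):
            if not subset:
                continue
            m = subsets[test_idx] == subset
            acc = float((y_pred[m] == labels[test_idx][m]).mean())
            subset_fold.setdefault(str(subset), []).append(acc)

    return TaskReport(
        metrics={k: _mean_se(v) for k, v in per_fold.items()},
        per_fold=per_fold,
        n_folds=dataset.n_folds,
        per_subset_accuracy={k: _mean_se(v) for k, v in subset_fold.items()},
    )
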