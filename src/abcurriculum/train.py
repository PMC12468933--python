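"""Masked-language-model pretraining with schedule-driven data mixing.

One loop serves every strategy: the strategy only decides the shape of the
unpaired-probability curve.

- ``curriculum``: sigmoid decay, shift solved for the target total mixture;
- ``constant``: fixed mixture at the target (62.5% unpaired by default);
- ``finetuned``: all-unpaired then all-paired, switching at the target
  fraction of steps;
- ``unpaired_only`` / ``paired_only``: P(t) ≡ 1 / ≡ 0.

Each step, the sampler plans a batch (which indices from which corpus), the
planned examples are MLM-corrupted, and one Adam step is taken at the
learning rate the LR schedule dictates.  Because the batch plan retains
domain provenance, the loop logs unpaired and paired loss separately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import _autodiff as ad
from .model import EncoderConfig, TransformerEncoder, save_checkpoint
from .records import SequenceRecord
from .sampling import MixedSampler
from .schedule import (ScheduleSpec, LRScheduleSpec, learning_rate,
                       unpaired_probability, DEFAULT_TARGET_MEAN)
from .tokenizer import TokenizedExample, corrupt, encode_batch

__all__ = ["STRATEGIES", "schedule_for_strategy", "pretrain", "TrainResult"]

STRATEGIES = ("curriculum", "constant", "finetuned",
              "paired_only", "unpaired_only")


def schedule_for_strategy(strategy: str, total_steps: int,
                          target_mean: float = DEFAULT_TARGET_MEAN,
                          A: float = 0.4, B: float = 0.7,
                          k: float = 15.0) -> ScheduleSpec:
    """Map a training strategy name to its unpaired-probability schedule."""
    if strategy == "curriculum":
        return ScheduleSpec(kind="curriculum", A=A, B=B, k=k,
                            total_steps=total_steps, target_mean=target_mean)
    if strategy == "constant":
        return ScheduleSpec(kind="constant", total_steps=total_steps,
                            target_mean=target_mean)
    if strategy == "finetuned":
        return ScheduleSpec(kind="finetune", total_steps=total_steps,
                            target_mean=target_mean)
    if strategy == "paired_only":
        return ScheduleSpec(kind="constant", total_steps=total_steps,
                            target_mean=0.0)
    if strategy == "unpaired_only":
        return ScheduleSpec(kind="constant", total_steps=total_steps,
                            target_mean=1.0)
    raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")


@dataclass
class TrainResult:
    encoder: TransformerEncoder
    log: list[dict]
    final_step: int

    def write_log(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for row in self.log:
                fh.write(json.dumps(row) + "\n")


def _domain_loss(model: TransformerEncoder, ids, labels, att) -> Optional[float]:
    if len(ids) == 0:
        return None
    z = model.forward_mlm(np.stack(ids), np.stack(att)).data
    lab = np.stack(labels)
    mask = lab != -100
    if not mask.any():
        return None
    zz = z - z.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(zz).sum(axis=-1))
    rows = np.nonzero(mask)
    return float((lse[rows] - zz[rows + (lab[rows],)]).mean())


def pretrain(unpaired: Sequence[TokenizedExample],
             paired: Sequence[TokenizedExample],
             schedule: ScheduleSpec,
             lr_schedule: Optional[LRScheduleSpec] = None,
             encoder: Optional[TransformerEncoder] = None,
             encoder_config: Optional[EncoderConfig] = None,
             steps: Optional[int] = None,
             batch_size: int = 8,
             seed: int = 0,
             start_step: int = 0,
             log_every: int = 10,
             checkpoint_dir: Optional[str | Path] = None,
             checkpoint_every: Optional[int] = None) -> TrainResult:
    """Run the MLM pretraining loop over pre-encoded corpora.

    ``steps`` defaults to ``schedule.total_steps``; ``start_step`` resumes a
    run mid-schedule (P(t) and the LR depend only on the global step, so a
    resumed run continues the curves exactly).  Returns the trained encoder
    plus a JSONL-able log with separate unpaired/paired batch losses.
    """
    if encoder is None:
        encoder = TransformerEncoder(encoder_config or EncoderConfig.tiny(),
                                     seed=seed)
    if lr_schedule is None:
        lr_schedule = LRScheduleSpec(
            kind="linear", peak_lr=1e-3,
            warmup_steps=max(1, schedule.total_steps // 20),
            total_steps=schedule.total_steps)
    end_step = start_step + (steps if steps is not None
                             else schedule.total_steps - start_step)
    if end_step > schedule.total_steps:
        raise ValueError("steps would run past schedule.total_steps")
    sampler = MixedSampler(schedule, len(unpaired), len(paired),
                           batch_size, seed=seed)
    # replay the sampler to the resume point so index streams line up
    for s in range(start_step):
        sampler.plan(s)
    corrupt_rng = np.random.default_rng(
        np.random.SeedSequence([seed, 0xC0FFEE]).generate_state(1)[0] % (2 ** 31))
    opt = ad.Adam(encoder.parameters(), lr=lr_schedule.peak_lr)
    log: list[dict] = []
    if checkpoint_dir is not None:
        checkpoint_dir = Path(checkpoint_dir)
        checkpoint_dir.mkdir(parents=True, exist_ok=True)

    for step in range(start_step, end_step):
        plan = sampler.plan(step)
        batch_ids, batch_labels, batch_att, provenance = [], [], [], []
        for domain, pool, idxs in (("unpaired", unpaired, plan.unpaired_indices),
                                   ("paired", paired, plan.paired_indices)):
            for i in idxs:
                ex = pool[int(i)]
                cids, lab, _ = corrupt(ex, rng=corrupt_rng)
                batch_ids.append(cids)
                batch_labels.append(lab)
                batch_att.append(ex.attention_mask)
                provenance.append(domain)
        ids = np.stack(batch_ids)
        labels = np.stack(batch_labels)
        att = np.stack(batch_att)
        loss, n_sel = encoder.mlm_loss(ids, labels, att)
        opt.zero_grad()
        loss.backward()
        lr = learning_rate(lr_schedule, min(step, lr_schedule.total_steps))
        opt.step(lr=lr)

        if step % log_every == 0 or step == end_step - 1:
            prov = np.array(provenance)
            row = {
                "step": step,
                "t": step / schedule.total_steps,
                "p_unpaired": unpaired_probability(schedule, step),
                "lr": lr,
                "loss": float(loss.data),
                "n_selected": n_sel,
                "n_unpaired": plan.n_unpaired,
                "n_paired": plan.n_paired,
                "cum_unpaired_fraction": sampler.ledger.unpaired_fraction,
            }
            for domain in ("unpaired", "paired"):
                m = prov == domain
                dl = _domain_loss(encoder, [ids[j] for j in np.flatnonzero(m)],
                                  [labels[j] for j in np.flatnonzero(m)],
                                  [att[j] for j in np.flatnonzero(m)])
                row[f"loss_{domain}"] = dl
            log.append(row)
        if (checkpoint_dir is not None and checkpoint_every
                and (step + 1) % checkpoint_every == 0):
            save_checkpoint(encoder, checkpoint_dir / f"step{step + 1:08d}.npz")

    if checkpoint_dir is not None:
        save_checkpoint(encoder, checkpoint_dir / "final.npz")
    return TrainResult(encoder=encoder, log=log, final_step=end_step)
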