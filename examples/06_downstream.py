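"""Downstream tasks: planted-motif specificity and native-vs-random pairing.

Trains classification heads on a frozen tiny encoder with stratified 5-fold
cross-validation and prints the fold-averaged metric panels.
"""

from abcurriculum import GeneratorConfig, generate, generate_classed
from abcurriculum.downstream import (build_pair_task, build_specificity_task,
                                     train_task, TaskConfig)
from abcurriculum.model import EncoderConfig, TransformerEncoder

encoder = TransformerEncoder(EncoderConfig.tiny(), seed=0)

# --- specificity task with a planted CDRH3 motif per class -----------------
cfg = GeneratorConfig(n_paired=240, seed=3, memory_fraction=0.5,
                      planted_classes={"HD": "WWAAWW", "Flu": "KKGGKK",
                                       "CoV": "PPLLPP"})
dataset = build_specificity_task(generate_classed(cfg),
                                 input_mode="heavy_only", rng=0)
report = train_task(encoder, dataset,
                    TaskConfig(epochs=40, batch_size=16, peak_lr=5e-3,
                               pad_to=160, seed=0))
print("3-class specificity (planted CDRH3 motifs, frozen tiny encoder):")
for name, (mean, se) in report.metrics.items():
    print(f"  {name:<9} {mean:.3f} ± {se:.3f}")

# --- native-vs-random pair task --------------------------------------------
records = generate(GeneratorConfig(n_paired=200, memory_fraction=0.5,
                                   shm_rate=0.06, seed=4))
pair_ds = build_pair_task(records, rng=0)
pair_report = train_task(encoder, pair_ds,
                         TaskConfig(epochs=20, batch_size=32, peak_lr=5e-3,
                                    pad_to=256, seed=0))
print("\nnative-vs-random pairing (frozen random encoder):")
for name, (mean, se) in pair_report.metrics.items():
    print(f"  {name:<9} {mean:.3f} ± {se:.3f}")
print("accuracy by mutation-status subset:")
for subset, (mean, se) in pair_report.per_subset_accuracy.items():
    print(f"  {subset:<10} {mean:.3f} ± {se:.3f}")
# The planted motif is linearly recoverable from the frozen embeddings, so
# specificity accuracy approaches 1. The pair task carries no real signal for
# a random untrained encoder (synthetic pairing is random by construction),
# so its metrics hover near chance — matching the biological expectation that
# naive pairing is uninformative.
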