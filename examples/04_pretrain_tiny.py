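"""Pretrain a tiny encoder with the curriculum strategy (a few minutes, CPU).

Generates a small mixed corpus, runs 150 curriculum-scheduled MLM steps, and
compares held-out cross-entropy before and after.
"""

import numpy as np

from abcurriculum import GeneratorConfig, generate, encode
from abcurriculum.evaluate import masked_eval
from abcurriculum.model import EncoderConfig, TransformerEncoder
from abcurriculum.tokenizer import encode_batch
from abcurriculum.train import schedule_for_strategy, pretrain

records = generate(GeneratorConfig(n_paired=40, n_unpaired_heavy=40,
                                   n_unpaired_light=20, seed=5))
paired = encode_batch([r for r in records if r.is_paired], "cls", pad_to=240)
unpaired = encode_batch([r for r in records if not r.is_paired], "cls", pad_to=240)
held_out = paired[-6:] + unpaired[-6:]

schedule = schedule_for_strategy("curriculum", total_steps=150)
model = TransformerEncoder(EncoderConfig.tiny(), seed=0)
before = masked_eval(model, held_out, domain="mixed")
print(f"held-out CE before training: {before.ce_loss:.3f} "
      f"(uniform baseline ln 33 = {np.log(33):.3f})")

result = pretrain(unpaired[:-6], paired[:-6], schedule, encoder=model,
                  batch_size=6, seed=0, log_every=30)
for row in result.log:
    print(f"  step {row['step']:>3}  P(t)={row['p_unpaired']:.3f}  "
          f"lr={row['lr']:.2e}  loss={row['loss']:.3f}")

after = masked_eval(result.encoder, held_out, domain="mixed")
print(f"held-out CE after {result.final_step} steps: {after.ce_loss:.3f}, "
      f"accuracy {after.accuracy:.3f}")
# The loss drops quickly from the uniform baseline as the model learns the
# germline-templated framework regions, which dominate the residue positions.
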