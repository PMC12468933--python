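"""Separator-excluded evaluation and per-position CDRH3 inference.

Scores an untrained tiny encoder (so numbers sit at the uniform baseline)
and shows the per-region breakdown plus single-position CDRH3 inference.
"""

import numpy as np

from abcurriculum import GeneratorConfig, generate, encode
from abcurriculum.evaluate import (masked_eval, per_position_inference,
                                   region_profile, cdrh3_accuracy)
from abcurriculum.model import EncoderConfig, TransformerEncoder

records = generate(GeneratorConfig(n_paired=20, memory_fraction=0.5, seed=6))
examples = [encode(r, dialect="cls", pad_to=256) for r in records]
model = TransformerEncoder(EncoderConfig.tiny(), seed=0)

report = masked_eval(model, examples)
print(f"masked eval on {len(examples)} paired records: "
      f"CE {report.ce_loss:.3f} (ln 33 = {np.log(33):.3f}), "
      f"accuracy {report.accuracy:.3f}, positions {report.n_positions}")
print("per-region CE loss:")
for region in sorted(report.per_region):
    loss, acc, n = report.per_region[region]
    print(f"  {region:<8} loss {loss:.3f}  acc {acc:.3f}  n {n}")

frames = [per_position_inference(model, ex, region_filter="H:CDR3")
          for ex in examples[:5]]
profile = region_profile(frames, by="region")
print("\nCDRH3 per-position inference over 5 records:")
print(profile.to_string(index=False))
print(f"CDRH3 accuracy (record-averaged): "
      f"{cdrh3_accuracy(model, examples[:5]):.3f}")
# For an untrained model every region sits near the 1/33 uniform baseline;
# after pretraining, framework regions drop far below CDR3, which remains
# hardest because its junctions are non-templated.
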