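# Methods

## The unpaired-probability curve

The curriculum schedule is the sigmoid decay

P(t) = B − A / (1 + e^(−k·(t − shift))),  t = step / total_steps,

evaluated at batch start with 0-based steps, so P(0) is the mixture of the
first batch. Since the logistic term rises from 0 to 1, P decreases
monotonically from ≈B to ≈B−A; with 0 ≤ A ≤ B ≤ 1 the curve stays inside
[0, 1] without clamping (a clamp guards user-supplied extremes anyway).
Defaults A=0.4, B=0.7, k=15 give the 0.7→0.3 range and moderate slope that
worked best for unpaired-loss-optimized curricula.

Its exact time-average has the closed form

mean = B − (A/k)·[softplus(k·(1−shift)) − softplus(−k·shift)],

implemented with overflow-safe softplus. The mean is strictly increasing in
`shift`, so the shift solver is a bracketing root search (`scipy`'s brentq)
on the closed form over shift ∈ [−5, 6] with xtol 10⁻¹², which covers every
practically attainable mean; an unattainable target (outside (B−A, B))
raises an error naming the bounds. The default target mean is 0.625: with
it, all mixed strategies — curriculum, constant P≡0.625, and the
finetune-style step schedule switching from all-unpaired to all-paired at
t=0.625 — consume the same total amount of unpaired data, so comparisons
isolate the *shape* of the schedule. Constant schedules additionally admit
target 0 and 1 to express pure paired-only/unpaired-only baselines through
the same interface.

Learning-rate schedules share a linear warmup (lr(0)=0, lr(warmup)=peak):
`linear` decays affinely to 0; `wsd` holds the peak over a stable fraction
(default 0.8 of post-warmup steps) then decays linearly; `sgdr` runs
`n_restarts` (default 2) equal cosine half-periods restarting at the peak.
The stable fraction and restart count are configurable defaults, since no
single canonical value exists for them.

## Batch planning and epoch accounting

Given batch size m and p = P(t), the planner draws
n_unpaired = ⌊mp⌋ + Bernoulli(frac(mp)) — stochastic-remainder rounding,
which is unbiased with the smallest possible variance (at most one example
of jitter per batch, versus binomial noise for per-slot coin flips). Each
domain owns a shuffled index queue consumed without replacement and
reshuffled on exhaustion, so "one epoch of unpaired data" is a measurable
statement; the consumption ledger tracks per-domain counts and epoch
fractions. A single integer seed spawns three independent RNG streams
(unpaired shuffle, paired shuffle, rounding) via `SeedSequence`, making
batch-plan streams reproducible and resumable (resuming replays the plan
stream to the start step).

## Tokenization

The vocabulary is the standard 33-token protein-LM set with one unused
placeholder replaced by `<sep>`, keeping exactly 33 entries. Every example
is framed `<cls> … <eos>` and right-padded to 320 tokens (the longest
paired encoding). The separator dialect controls only the chain-boundary
marker: a dedicated `<sep>`, a reused `<cls>`, or none; placement is
between paired chains, after unpaired heavy chains, before unpaired light
chains. Region labels (H:FR1 … L:FR4) ride along per token position, using
0-based half-open intervals that must tile each chain exactly.

MLM corruption selects residue positions i.i.d. at 15% (special positions
are never eligible), then splits selections 80/10/10 into mask / random /
keep. Random replacements draw uniformly from the 20 canonical residue
tokens — never special tokens — and may coincide with the original residue
by chance, so the *branch* labels, not token comparisons, are the ground
truth for corruption bookkeeping and are returned alongside ids and labels.

## Encoder

A pre-LayerNorm bidirectional transformer with two presets: `pilot`
(5 layers, 20 heads, hidden 960, intermediate 3840 — the 55M-parameter
configuration, constructible but not exercised in tests) and `tiny`
(2/4/64/256) used throughout the test suite. The MLM head is
dense→GELU→LayerNorm with output weights tied to the input embedding.
Dropout is 0 everywhere for bit-reproducibility. The classification head
pools the start-token position through dense→tanh→projection; with
`freeze_base` (the default for downstream tasks) the encoder output is
detached so base weights are provably untouched, and head training operates
on precomputed pooled embeddings — mathematically identical, much faster.

Position information is switchable. RoPE rotates each query/key head in
2-dimensional subspaces by angles position·10000^(−2i/d) (rotate-half
layout, full head dimension), making attention logits functions of relative
offset only — the property behind cross-length generalization, verified
directly as logit invariance under a constant position shift. The absolute
baseline is a learned position-embedding table, which demonstrably breaks
that invariance.

The whole model runs on an in-package reverse-mode autodiff core over
float64 numpy arrays (broadcast add/mul, batched matmul, layer norm, GELU,
softmax, embedding gather, rotary rotation, fused softmax-cross-entropy).
Every primitive's backward rule is checked against central finite
differences in the test suite. Float64 keeps gradient checks tight at the
model sizes used; the optimizer is plain Adam (β = 0.9/0.999, ε = 10⁻⁸).

## Evaluation

Masked evaluation applies the training corruption once with a dedicated
fixed seed and micro-averages loss/accuracy over selected residue positions
only; start, separator, end and pad positions never enter the metrics. One
corruption draw is used per evaluation (multiple draws would shrink
corruption noise but cost proportionally more compute; the fixed seed makes
the single draw reproducible). Per-position inference masks one residue at
a time — optionally restricted to a region such as CDRH3 — and scores the
prediction at that position; batching packs independent single-mask copies
together and is exactly equivalent to the literal loop, which the tests
assert to 10⁻⁶. CDRH3 accuracy averages per-position accuracy within each
record, then across records, so loop length does not weight records.

## Downstream tasks

The pair task deranges light chains over a disjoint half of the records:
each record appears exactly once (as a native pair or as the heavy-chain
half of a shuffled pair), labels are balanced 1:1, each light chain appears
once among negatives, and no shuffled pair may reproduce any native pairing
(resampled until satisfied, exhaustively checked in tests). Mutation-status
subsets use the generator's exact substitution counts with threshold 1 per
chain: mutated = both chains ≥ 1, unmutated = both 0, different =
otherwise. Folds are stratified on label × subset so the subset breakdown
survives cross-validation; the specificity task stratifies on label after
downsampling all classes to the smallest class size, and its heavy-only
mode re-encodes records as unpaired heavy chains.

Metrics are computed with scikit-learn: accuracy, F1 (binary or macro),
ROC-AUC and average precision (macro one-vs-rest for k > 2, symmetric in
class order), and MCC, reported as fold mean ± standard error
(SD/√n_folds, ddof 1; a single fold reports SE 0). A hand-computed
confusion-table oracle and brute-force rank statistics cross-check the
panel in the tests. Preset configurations mirror the three reference
regimes (binary specificity: 10 epochs/batch 32/peak 5·10⁻⁵; 3-class:
5 epochs/batch 8; pair: 50 epochs/batch 256/peak 10⁻⁵), all overridable —
tests use larger learning rates and fewer epochs appropriate for training a
fresh head from scratch on a tiny encoder.

## Synthetic repertoires

The generator emulates the statistical skeleton of immune repertoires:
chains assemble from a bank of 4 heavy and 4 light hand-written toy
germline templates (framework regions with conserved anchors, CDR1/CDR2
fixed per template) plus a random CDR3 junction — heavy 8–20 aa beginning
with the canonical AR motif, light 8–11 aa — yielding heavy chains of
~115–127 aa and light chains of ~106–111 aa, within the 320-token paired
budget. A memory subset (default 50%) receives i.i.d. substitutions at a
per-residue rate (default 5%, a typical memory-B-cell order of magnitude);
substitutions always change the residue, and exact per-chain counts are
recorded, standing in for the annotation step a real pipeline would run.
Optional planted class motifs overwrite a fixed CDRH3 window (protected
from mutation) to create classification tasks with a known recoverable
signal.

Not modelled: V(D)J recombination statistics, germline gene usage
frequencies, indels, allelic variation, and any real germline alleles.
Consequently, passing tests demonstrate the *mechanics* — schedules,
sampling, tokenization, optimization, evaluation, task plumbing — not
biological performance; numbers obtained on synthetic repertoires say
nothing about accuracy on real antibody data.

## Problem sizes and numerical choices

The test suite and examples run tiny configurations as the package's own
operating point: the `tiny` encoder, corpora of tens to hundreds of
records, pretraining runs of ≤ 200 steps, pad lengths 136–256 where the
320 default is not needed, and 5-fold cross-validation over ~240 examples.
Quadrature checks use 10⁶-point midpoint Riemann sums (agreement with the
closed form to ≤ 10⁻⁸); the shift solver round-trips to ≤ 10⁻⁹; sampler
law-of-large-numbers checks run 10⁵ planned steps. Ties in argmax
predictions resolve to the lowest token id (numpy convention). Degenerate
inputs are defined, not errors, where a sensible value exists: empty region
filters yield empty frames, zero selected positions yield zero loss,
single-fold reports carry SE 0.

## Known limitations

- The encoder is CPU-bound numpy; it is meant for mechanism-scale
  experiments (≤ a few million parameters), not for pretraining at
  realistic scale.
- The finetune-style schedule shares one optimizer state across the domain
  switch; two-stage training with separate warmups is approximated by the
  single step-function schedule.
- Evaluation uses one corruption draw; variance across draws is not
  reported.
- The synthetic generator's diversity is bounded by its 8 toy templates;
  models can memorize frameworks quickly, which is intended (it makes tiny
  smoke tests fast) but unrealistic.
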