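# Methods

This note records the modelling choices behind the package: the corpus
protocol, the synthetic data model, the encoder and losses, the evaluation
conventions, and the places where the design was genuinely open.

## Corpus protocol and the confound

The data model mirrors an isolated-word dysarthria corpus: 15 dysarthric
speakers distributed 5/2/2/6 over four ordinal severity bands defined by
intelligibility (very low ≥76%, low 51–75%, medium 26–50%, high ≤25%; band
edges belong to the milder band so the bands partition [0, 100]). Each
speaker reads 3 blocks of 255 words — 155 *common* words repeated in every
block plus 100 *uncommon* words unique to that block — giving 765 utterances
and 455 distinct words per speaker. Severity is a property of the speaker:
one severity per speaker, denormalised onto utterance records, with the
speaker table authoritative. That one-to-one mapping is the speaker–severity
confound the training strategy targets.

Leave-one-subject-out (LOSO) folds are deterministic: one fold per speaker,
training on the *common*-word utterances of the other 14 speakers (14 × 465
= 6510) and testing on the held-out speaker's 300 uncommon words, so both
voice and vocabulary are novel at test time. A secondary `all_words` mode
tests on all 765 utterances of the held-out speaker (novel voice, partly
seen vocabulary). Uncommon words of training speakers are excluded in the
primary mode, matching the per-subject utterance counts above.

## Synthetic data model

Feature-mode utterance vectors are drawn from an additive factor model:

    x = β_word·W_w + β_sev·c_w·v_s·D + β_spk·U_s + κ·c_w·v_s·M_s + σ·e

with word templates W_w and speaker offsets U_s (i.i.d. N(0, I/d) draws,
expected norm ≈ 1), a shared unit severity direction D, ordinal severity
code v_s ∈ {0..3}, positive word-complexity scalars c_w (log-normal;
uncommon words ≈30% more complex on average, since rare vocabulary stresses
articulation harder), a per-speaker unit "manifestation" direction M_s that
makes severity expression speaker-idiosyncratic, and fresh unit Gaussian
noise e. Setting κ = 0 recovers the three pure factors plus noise, which is
what the closed-form generator oracles in the tests use.

Defaults (chosen once as the package's study conditions):

| parameter | default | rationale |
|---|---|---|
| β_word | 0.6 | word content present but not dominant |
| β_spk | 1.2 | speaker offsets dominate word differences, so same-speaker different-word pairs sit *closer* than same-word different-speaker pairs — the speaker-clustered geometry the regulariser is meant to fix |
| β_sev | 0.5 | adjacent severity classes separated by ≈0.5·c_w along D: decodable but with overlap from the c_w spread |
| κ | 0.3 | moderate speaker-specific severity expression |
| σ | 0.15 | per-dimension noise; noise vector norm ≈ 1.2 at d = 64, comparable to the speaker-offset scale, keeping linear probes off the ceiling |
| feature_dim | 64 | desk-scale stand-in for a transformer's 768-dim space |

With these defaults a linear oracle on the *raw* features decodes both
severity and speaker identity far above chance (the `describe_difficulty`
report), i.e. the confound exists before any training. Because v_s scales
the severity term, the very-low class (v = 0) carries no severity signal of
its own and is identified by the absence of displacement along D.

Waveform mode synthesises a harmonic stack (speaker-specific fundamental
90–220 Hz, word-specific partial amplitudes, severity-scaled cumulative
phase jitter, additive noise) at 8 kHz. It exercises the framing front-end
and WAV I/O; it is not meant to sound like speech, and no perceptual
calibration of the severity bands is attempted.

What the generator does **not** emulate: temporal structure and prosody,
channel/microphone effects, within-speaker drift across blocks, class-
dependent noise, and any phonetic notion of word identity (word ids are
opaque strings; "same word" is string equality). Passing tests therefore
demonstrate that the training mechanics behave as described *when the
confound is present in this factor form* — they are not evidence about real
dysarthric speech.

## Encoder and losses

The encoder is a deliberately small stand-in for a pretrained speech
transformer: features → linear(64) → ReLU → linear(embedding_dim), with a
waveform front-end (non-overlapping frames → linear → ReLU → mean-pool over
time) in waveform mode. The classification head is two linear layers with a
ReLU producing one logit per severity class; prediction is the argmax. "The
embedding" is defined as the single vector handed to the head — the same
vector used by the probe and distance diagnostics, so the regulariser acts
on exactly what the classifier sees. Embeddings are *not* L2-normalised
before distance computation; distances are raw Euclidean. Forward and
backward passes are written directly in numpy; the analytic gradients are
checked against central finite differences (tolerance 1e-4) in the suite.
Mean-pooling over time, and over-frame pooling before the trunk, are
declared choices — the pooling point is not prescribed by the method itself.

Triplet constraints: anchor and negative share the speaker but not the
word; positive and negative share the word; positive's speaker differs from
the anchor's but shares its severity. Mining is hierarchical-uniform —
uniform over valid anchor utterances, then uniform over that anchor's
(negative, positive) completions — seeded, with an exact combinatorial
count of valid triplets so small problems can be enumerated exhaustively
(the test oracle is a brute-force triple loop). Severity classes with fewer
than two training speakers cannot satisfy the constraints and contribute no
triplets; under LOSO this routinely happens for the two-speaker classes
when one of their speakers is held out, and is logged rather than treated
as an error. Triplets are mined from the whole training fold, not within
the size-4 classification batch, where valid triplets essentially never
co-occur; each optimisation step draws one classification batch and one
triplet batch.

The hinge is implemented in two variants. The default, `stated_aims`,
is `max(0, d(a,p) − d(a,n) + m)`: minimising it pushes the same-speaker
negative away and pulls the same-severity positive closer, which is the
mechanism the training strategy describes; with the small default margin
m = 0.05 it equalises d1 and d2 rather than separating them. The
`literal_printed` variant reverses the two distance terms; minimised
literally it would contract the anchor–negative distance, so it is retained
for fidelity experiments only. Per-triplet-batch L_reg is the mean of the
per-triplet hinges (batch-size invariance).

The combined loss is `ε·L_reg + γ(t)·L_CE` with ε = 0.01 applied
unconditionally, and γ(t) a step schedule: 0 for the warm-up budget, 1
afterwards. The reference schedule's warm-up is 3000 steps (the LossConfig
default); because total step budgets here are much smaller, warm-up is
expressed as an absolute step count and desk-scale runs set it to half the
total budget, preserving the regularise-first regime. Note that although
ε = 0.01 makes the regulariser's *loss* small, Adam's per-parameter scaling
makes its warm-up updates full-sized, which is why the warm-up phase can
restructure the latent space at all. The `ce_only` baseline sets ε = 0 and
warm-up 0, reducing the total loss to L_CE exactly.

Optimisation: Adam (lr 5e-4, betas (0.9, 0.98), eps 1e-8), batch size 4,
one optimiser over encoder and head jointly, no freezing, no learning-rate
schedule. A seeded validation split (default 10% of training utterances,
drawn from training speakers only) provides periodic validation
cross-entropy for monitoring; validation loss is deliberately the CE term
only, since that is the quantity whose convergence matters for the
classifier. Non-finite losses abort with a diagnostic. Training is
bit-reproducible given the seed.

## Evaluation conventions

- **Overall accuracy** is the unweighted mean of per-held-out-speaker
  accuracies (each speaker counts equally regardless of test-set size);
  repeat mean ± SD is taken across independent repeats of the whole LOSO
  pass (sample SD, ddof = 1; a single repeat reports SD 0 with a flag).
- **Macro-F1** is the unweighted mean of the four per-class F1 scores on
  predictions pooled over a repeat's folds; classes absent from both truth
  and prediction are excluded with a logged note rather than scored 0.
- **Confusion matrices** are row-normalised over pooled predictions; empty
  rows remain zero.
- **Speaker probe**: a multinomial logistic model with default
  regularisation on pooled corpus embeddings, stratified 80/20
  within-speaker split, seeded; chance is 1/n_speakers. Pooling (rather
  than per-fold probe training) is a declared choice.
- **d1/d2 diagnostics**: triplets are re-mined from the embedded
  utterances' metadata; d1 is the mean anchor–negative distance, d2 the
  mean anchor–positive distance; the ratio is undefined (flagged None) when
  d2 = 0. Intra/inter-severity mean pairwise distances are estimated from
  seeded random pairs.

## Desk-scale study conditions

The headline comparison (`salr.experiments.run_directional_comparison`, also
driven by `scripts/acceptance.py`) uses the default 15-speaker corpus, an
encoder with 64 hidden units and 32-dim embeddings, 800 optimisation steps
per fold (warm-up 400 in `salr` mode, triplet batch 32), a full 15-fold
LOSO pass per mode, three independent seeded runs, probes on up to 3000
pooled embeddings from the first fold's fitted model, and 2000 sampled
triplets for the distance diagnostics. These sizes were chosen so the whole
comparison completes in minutes on one CPU while leaving the three
directional effects (probe drop, preserved held-out accuracy, d1/d2 → 1)
clearly resolved; they are the package's study conditions, not tuned
per-seed.

## Known limitations

- The factor model is a stand-in; no claim is made that its geometry
  matches a fine-tuned transformer's latent space beyond the qualitative
  confound structure.
- Severity ordinality enters only through the linear v_s scaling; the
  classifier itself is nominal 4-way.
- The probe uses a single linear family (multinomial logistic); nonlinear
  probes could recover more identity information.
- Healthy-control speakers are not modelled: only dysarthric speakers enter
  the folds (controls in the reference protocol served hyperparameter
  selection only).
- Checkpoints store raw parameter arrays with a version tag; no
  cross-version migration is attempted.
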