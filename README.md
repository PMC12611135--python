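# salr — speaker-agnostic latent regularisation for dysarthria severity classification

Dysarthria — impaired control of the speech musculature following stroke,
Parkinson's disease, motor neuron disease and other neurological conditions —
is graded clinically into ordinal severity bands from speech intelligibility
(very low: ≥76% of words intelligible, low: 51–75%, medium: 26–50%, high:
≤25%). Automatic severity classifiers trained on small isolated-word corpora
face a structural confound: **every speaker has exactly one severity**, so a
model can minimise training loss by recognising *who* is speaking and looking
up their label. Such models collapse on unseen speakers, which is exactly the
setting that matters clinically.

This package implements and analyses a multi-task training strategy that
suppresses that shortcut. A trainable encoder produces one latent embedding
per utterance; alongside the 4-class cross-entropy objective, a constrained
triplet-margin regulariser acts on triples of utterances

- anchor `E_AX` — word *A* by speaker *X*,
- negative `E_BX` — word *B* by the **same** speaker *X*,
- positive `E_BY` — word *B* by a **different** speaker *Y* of the **same severity**,

with the hinge

```
L_reg = max(0, d(E_AX, E_BY) − d(E_AX, E_BX) + m),      d = L2 distance, m = 0.05
```

which pushes the same-speaker negative away and pulls the same-severity
positive closer. With a small margin the two distances d1 = d(E_AX, E_BX) and
d2 = d(E_AX, E_BY) become approximately equal, so the latent space organises
by severity and word content rather than by speaker identity. The total loss
is

```
L = ε·L_reg + γ(t)·L_CE,       ε = 0.01
```

where γ(t) is 0 for a warm-up step budget (the encoder is first shaped by the
regulariser alone) and 1 afterwards. Evaluation is leave-one-subject-out
(LOSO): one fold per speaker, training on the other speakers' repeated
common words, testing on the held-out speaker's unique uncommon words — both
the voice and the vocabulary are novel at test time.

Because the audio corpora this protocol comes from are access-restricted, the
package ships a **synthetic corpus generator** that reproduces the protocol's
structure (15 speakers split 5/2/2/6 over the four bands; 3 blocks × (155
common + 100 uncommon) words per speaker) and, crucially, the
speaker–severity confound, via an additive latent factor model with word,
speaker and severity factors and a word-complexity × severity interaction.
Every claim the package makes is measured on that generator; see
`docs/methods.md` for what this does and does not say about real speech.

## Worked example

Train one LOSO fold of the default synthetic corpus with the multi-task
objective and inspect the fitted model:

```python
from salr import GeneratorConfig, generate_corpus, build_loso_folds
from salr.model import SeverityModel
from salr.encoder import EncoderConfig
from salr.train import TrainConfig
from salr.losses import LossConfig

manifest, signals = generate_corpus(GeneratorConfig(seed=42))
fold = build_loso_folds(manifest)[0]          # hold out speaker HI01
model = SeverityModel(
    manifest, signals, fold=fold,
    encoder_config=EncoderConfig(input_dim=64, hidden_dim=64,
                                 embedding_dim=32, head_hidden=32),
    train_config=TrainConfig(mode="salr", total_steps=800, triplet_batch_size=32,
                             seed=7, loss_config=LossConfig(gamma_warmup_steps=400)),
)
res = model.fit()
print(res.summary())
probe = res.probe_speaker_identity(split_seed=7)
print(f"speaker probe accuracy: {probe.accuracy:.3f} (chance {probe.chance_level:.3f})")
diag = res.latent_diagnostics(rng_seed=7)
print(f"d1 = {diag.d1_mean:.3f}, d2 = {diag.d2_mean:.3f}, d1/d2 = {diag.ratio:.3f}")
```

Output:

```
Severity classification model
================================================
mode:              salr
held-out speaker:  HI01
train utterances:  6510
test utterances:   300
steps:             800 (warm-up 400)
final L_CE:        0.0170
final L_reg:       0.3226
final total loss:  0.0202
held-out accuracy: 100.00 % (300 utterances)

speaker probe accuracy: 0.926 (chance 0.067)
d1 = 1.435, d2 = 1.636, d1/d2 = 0.878
```

The 6510 training utterances are 14 subjects × 465 common-word utterances
(3 blocks × 155 words); the 300 test utterances are the held-out speaker's
uncommon words. The probe accuracy measures how well a linear classifier can
recover speaker identity from the embeddings (identity leakage); the d1/d2
ratio is 1 in a perfectly speaker-agnostic geometry.

The same workflow is available from the shell:

```sh
salr synth --seed 1 --out runs/corpus
salr train-eval --corpus runs/corpus --mode both --seed 1 --out runs/exp
salr diagnose --run runs/exp
salr report --run runs/exp
```

`train-eval --mode both` trains the cross-entropy-only baseline and the
regularised model on the same corpus and emits a side-by-side comparison;
`diagnose` adds per-fold probe results, latent distance diagnostics and
embedding CSV exports.

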