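# ddifuse

Multimodal classification of drug–drug interaction (DDI) types.

When two drugs are co-administered, one can alter the other's
pharmacokinetics or pharmacodynamics — "the serum concentration of drug B
can be increased when combined with drug A". These interaction sentences
define **directional** classes over ordered drug pairs, and predicting them
at scale matters wherever polypharmacy is common. `ddifuse` implements a
multimodal pipeline for this multiclass problem, intended for
cheminformatics and drug-safety researchers who work from Python:

- **SSP — structural similarity profile.** Each drug's SMILES becomes an
  extended-connectivity fingerprint (ECFP4 by default); the drug's profile
  is its vector of Tanimoto similarities `|A∩B| / |A∪B|` to all drugs,
  compressed by PCA.
- **PSP — protein similarity profile.** From a weighted protein–protein
  interaction network and each drug's carrier/transporter/enzyme/target
  (CTET) protein set, a random walk with restart
  `p ← (1−r)·W·p + r·p₀` (column-stochastic `W`, restart `r`) yields a
  diffusion score vector per drug; pairwise cosine similarity of these
  vectors, PCA-reduced, is the PSP feature.
- **Text embeddings.** Drug name/description pairs are prepared (name
  prepended when absent from the description) and embedded into 768
  dimensions through a pluggable provider — a deterministic keyword-anchored
  mock for testing, a hashing provider for arbitrary text, or an optional
  pretrained biomedical transformer ([CLS]-token hidden state).
- **Fusion classifier.** Per-pair features are the drug-major concatenation
  of both drugs' modality blocks. The classifier is an MLP with an optional
  square **projection layer** (input_dim → input_dim) that re-weights and
  mixes heterogeneous blocks before compression, then a hidden layer and a
  softmax output over the interaction classes; ReLU and dropout follow each
  linear map. Training is two-stage: Adam + cross-entropy with
  best-validation checkpointing and late-activated early stopping, then
  fine-tuning with a reduce-on-plateau learning-rate schedule (factor 0.1,
  patience 5, floor 1e−6).
- **Evaluation.** Accuracy, macro precision/recall/F1, one-vs-rest macro
  AUROC/AUPR, per-class accuracy, and a misclassification analysis (each
  class's share of all errors, top-k error heatmap).
- **Synthetic data.** A generator plants cluster structure jointly in
  SMILES scaffolds, PPI modules, and description keywords, with pair labels
  a fixed function of the two drugs' clusters plus label noise — so the
  whole pipeline is testable end to end without downloads, including
  ablation and feature-scale degradation experiments.

## Worked example

```bash
python examples/04_end_to_end.py
```

generates the default synthetic study (60 drugs in 4 latent clusters, 1785
ordered pairs over 8 directional classes, 5% label noise), trains the
projection-layer MLP on structural + text features with a stratified
0.64/0.16/0.20 split, and prints:

```
test accuracy    0.9412   (chance would be 0.125; label noise caps the ceiling near 0.95)
macro precision  0.9420
macro recall     0.9414
macro F1         0.9413
macro AUROC      0.9721
macro AUPR       0.9270
```

Accuracy near the noise ceiling means the model recovered the planted
cluster-pair → class map almost perfectly; the macro metrics confirm no
class is sacrificed. `examples/01–03` walk through each modality on tiny
hand-built inputs, and `examples/05` runs the modality ablation and the
projection-layer experiment.

A thin CLI mirrors the pipeline stages for shell use:

```bash
ddifuse simulate --seed 1 --out data/
ddifuse featurize-ssp --drugs data/drugs.tsv --k 30 --out feats/
ddifuse train --data data/ --features ssp,emb --out run/
```

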