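# Methods

## Problem setting

Ordered drug pairs (A, B) are classified into directional interaction
types. Order matters: the sentence templates that define the classes
distinguish the perpetrator from the victim drug, so (A, B) and (B, A) are
distinct records and no symmetrization is applied (an augmentation switch
exists for symmetric classes but is off by default).

## Feature construction

**Structural similarity profile (SSP).** SMILES are canonicalized (sources
disagree on notation; a round-trip through canonical SMILES makes aromatic
and Kekulé forms identical) and hashed into binary extended-connectivity
fingerprints. Defaults: radius 2 (ECFP4) and 2048 bits, both configurable;
radius 3 (ECFP6) changes results only marginally on our data. Binary bits
are used rather than counts. A drug's raw profile is its row of the
all-vs-all Tanimoto matrix; PCA compresses rows to `k` components (200 at
full scale). The 0/0 Tanimoto of two empty fingerprints is defined as 0
with a warning — an empty fingerprint carries no evidence of similarity —
and degenerate molecules are flagged rather than dropped. PCA is fit on
the full drug-by-drug matrix (transductive, matching how similarity
profiles are normally built); a train-only fit is available as the
leakage-safe alternative when inductive evaluation matters.

**Protein similarity profile (PSP).** The PPI network loader drops edges
below a confidence threshold (default 700 on the STRING 0–1000 scale),
collapses duplicate unordered pairs keeping the maximum score, and removes
self-loops, logging counts of each. Edge weights are kept in the
column-stochastic normalization — confidence scores quantify evidence, so
binarizing would discard information. The random walk with restart iterates
`p ← (1−r)·W·p + r·p₀` from the seed until the L1 change falls below 1e−6
(max 1000 iterations), with restart 0.5 by default — the standard setting
in network-propagation work on gene/protein neighborhoods; all three are
configurable. Seeds put uniform mass on the drug's mapped proteins; drugs
whose proteins are all absent from the network get an all-zero profile and
a flag, so downstream code can exclude or impute rather than silently
learning from zeros. The PSP feature is the PCA-reduced cosine-similarity
matrix of diffusion vectors, mirroring the SSP construction; reducing the
raw drugs × proteins diffusion matrix instead is available via
`build_psp(..., mode="raw")`.

**Text embeddings.** Preparation rule: if the drug's name (case-insensitive
exact string) occurs in the description, the description is used as
provided; otherwise the name is prepended ("Name. Description"); an empty
description degenerates to the bare name. The rule is idempotent. Vectors
are 768-dimensional and used at native dimension — compressing them with
PCA is supported but off by default, since dense learned embeddings lose
predictive signal under further compression. Inputs beyond the 512-token
limit are truncated and flagged rather than dropped, preserving drugs at
the cost of tail content. Providers are pluggable: the deterministic mock
(unit keyword direction scaled by 1−η plus η of hash-seeded noise, η = 0.1)
is the test backend; a hashing provider handles arbitrary text without
pretrained weights; a transformer backend using a pretrained biomedical
encoder's [CLS] hidden state is an optional extra requiring the
`transformers` library.

## Pairs, filtering, split

Classes with fewer than `min_count` pairs (default 5 — the smallest count
that can populate all three partitions under stratification) are removed
with their pairs and survivors re-indexed contiguously; the original ids
are retained in the catalog. The 0.64/0.16/0.20 train/validation/test
split is stratified per class with largest-remainder apportionment, which
preserves the ratios exactly up to integer rounding: every class's test
fraction is within 1/class-size of 0.20. Membership is a seeded
within-class shuffle, bit-reproducible for a fixed seed. The split is over
pairs, not drugs, so evaluation is transductive — test pairs contain drugs
seen in training pairs. A drug-disjoint (cold-drug) split is a noted
extension, off by default.

## Classifier and training schedule

The pair vector is the drug-major concatenation of both drugs' modality
blocks (block order is a fixed permutation, so the choice affects file
layout only). No feature standardization is applied before concatenation —
absorbing cross-modal scale mismatch is precisely the projection layer's
job — though a z-scoring flag exists.

Architecture: optional square projection (d → d), then hidden (d → h,
default h = 512), then output logits; ReLU and dropout (default 0.3)
follow each linear map. He-initialized, seeded. Stage 1 trains from
scratch with Adam (lr 1e−3) and cross-entropy for up to 300 epochs;
early stopping monitors validation accuracy with patience 20 but its
counter starts only after epoch 200, so a model that plateaus from epoch
200 stops at 220; the best-validation checkpoint is saved. Stage 2 resumes
from that checkpoint for up to 100 epochs with a reduce-on-plateau
schedule: when validation accuracy fails to improve for 5 consecutive
epochs the learning rate is multiplied by 0.1 and the plateau counter
resets (so a never-improving run decays after epochs 5, 10, 15, …), floored
at 1e−6; early stopping patience 20 applies from the stage's start. Test
metrics come from the stage-2 best checkpoint. Argmax ties break toward
the lowest class id for determinism. The trainer is pure NumPy;
reproducibility is bit-exact on a single device for a fixed seed and
statistical across hardware.

Hyperparameters (hidden width, dropout, learning rate, batch size — default
256) are plain config values; no tuning framework is bundled.

## Evaluation

Macro precision/recall/F1 are unweighted means over classes present in the
test set; classes never predicted contribute precision 0; classes absent
from the test set are excluded from macro averages with a warning rather
than imputed (their one-vs-rest curves are undefined). AUROC uses the
Mann–Whitney convention (ties count ½); AUPR is step-wise
precision–recall integration without interpolation. The misclassification
table reports, per class, its test-set share and its share of all
misclassified samples (the latter summing to 100% whenever errors exist);
the error heatmap restricts the confusion matrix to the top-k classes by
that share, normalizes off-diagonal cells by total errors, and masks the
diagonal.

## Synthetic data: what it emulates and what it does not

The generator plants one latent cluster per drug and realizes it in all
three modalities: SMILES drawn from per-cluster scaffold families
(hard-coded valid cores — substituted benzenes, aliphatic chains, fused
aromatics, piperidines, thiophenes, cyclohexanes — with enumerated
decorations, guaranteeing parseability and a within-cluster Tanimoto
excess over between-cluster of > 0.2); a PPI graph of dense intra-cluster
modules (ring + random edges, so modules stay connected) with sparse
inter-module edges, drug associations sampled from the drug's module; and
templated descriptions carrying a cluster keyword the mock provider maps
to a basis direction. Ordered pair labels are a seeded injective map from
cluster pairs to class ids; a `label_noise` fraction (default 0.05) is
flipped uniformly. Per-modality informativeness (default 0.9) is the
probability a drug's modality reflects its own cluster rather than a
random other one; pair sampling is without replacement within each
cluster-pair cell.

Defaults are 60 drugs, 120 proteins, 4 clusters, 8 classes — sized so the
full pipeline trains in about a minute on one CPU. Desk-scale runs reduce
the PCA dimensions to fit the library (k = 30 for SSP/PSP on 60 drugs;
k ≤ N is a hard PCA constraint) and train stage 1 for 60 epochs, which is
past convergence at this problem size; the full-scale defaults (k = 200/300,
300 + 100 epochs) remain in the configs.

What passing tests show: the pipeline recovers planted multimodal cluster
structure through the real featurizers (RDKit fingerprints, sparse RWR,
PCA) and the real trainer, modality fusion is additive when information is
split, and the projection layer absorbs planted scale mismatches. What
they do not show: performance on real pharmacology. Real DDI data has
heavy class imbalance across ~80 types, molecules far from any template
family, PPI networks three orders of magnitude larger, and text whose
semantics no keyword mock captures. One consequence is measured and worth
stating: because the split is transductive over pairs, per-drug feature
uniqueness alone lets the model recover drug identity — shuffling
descriptions across drugs barely dents end-to-end accuracy even though it
destroys the embedding↔cluster alignment (the tests verify the latter via
a nearest-centroid probe). Chance-level controls therefore use label
permutation, which breaks the label function itself.

## Numerical choices and degenerate inputs

- RWR convergence is L1 with tol 1e−6; iterative results match the dense
  closed form `r(I − (1−r)W)^{-1} p₀` to better than 1e−6 L∞ (verified on
  random connected graphs ≤ 50 nodes).
- PCA uses the full SVD solver for determinism; reductions retaining
  < 95% variance raise a flag (and a warning), never an error — the caller
  decides whether a lossy compression is acceptable.
- Probability rows from the classifier sum to 1 within 1e−6 (stabilized
  softmax); the learning-rate floor snaps within float rounding of the
  decay chain so the floor is hit exactly.
- Degenerate inputs are flagged, not fatal, wherever the record can still
  flow through the pipeline (empty fingerprints, empty seed sets,
  truncated texts); they are errors where silence would corrupt results
  (unparseable SMILES, malformed network rows with their line numbers,
  zero-sum RWR seeds, duplicate drug ids).

## Known limitations

- The transformer embedding backend is untested here (no pretrained
  weights in the test environment); its contract is exercised through the
  provider interface only.
- The misclassification analysis assumes single-label classes; pairs with
  multiple concurrent interaction mechanisms are outside the model.
- Full-scale behavior (thousands of drugs, ~80 classes) is represented by
  configuration defaults, not by measurements in this repository.
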