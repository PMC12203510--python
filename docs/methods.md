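# Methods

`synfuse` predicts the synergy of anti-cancer drug pairs on cell lines from
three drug feature families (chemical structure, protein targets, KEGG-style
pathway tags) and two cell-line omics layers (gene expression, gene
mutation) fused with a protein–protein interaction (PPI) network.  This
note documents the model, its assumptions, the tunable parameters, the
synthetic data generator, and the numerical choices made where the design
was genuinely open.

## Model

### Drug representation

Each drug `i` contributes four feature blocks:

* **Fingerprint** `d_i^mf ∈ {0,1}^1024`: Morgan circular fingerprint,
  radius 3, 1024 bits, computed with RDKit from the drug's SMILES.
* **Similarity** `d_i^sm ∈ [0,1]^N`: Jaccard (intersection-over-union)
  similarity of the drug's fingerprint against a *fixed, ordered reference
  set* of N training drugs.  The reference order is stored with the model,
  so an unseen drug in a cold-start evaluation is embedded against the same
  references the training drugs were.  Jaccard of two all-zero fingerprints
  is defined as 1 (identical empty substructure sets); empty vs non-empty
  is 0, where the raw ratio would be 0/0.
* **Target** `d_i^t ∈ R^1024`: the mean of the protein-language-model
  embedding vectors of the drug's annotated targets.  Running the language
  model is out of scope; a precomputed id → 1024-vector table is an input.
  Drugs with no (mapped) targets get the zero vector rather than being
  excluded, so every drug in a benchmark-style panel stays usable.
* **Pathway** `d_i^p ∈ R^1024`: each pathway tag is represented by the mean
  embedding of its member genes; the drug's block is the mean over its
  tags.  Zero vector for drugs without pathway annotations.

For a pair (i, j) the blocks are zero-padded to a common width `d` and
stacked in the fixed order
`[d_i^mf, d_i^sm, d_i^t, d_i^p, d_j^mf, d_j^sm, d_j^t, d_j^p]`, an 8 × d
token matrix.  Padding is lossless: the original blocks are recovered by
truncation.

### Attention fusion encoder

The token stack passes through a stack of multi-head self-attention blocks:
per-head projections `Q = W_q x`, `K = W_k x`, `V = W_v x` (shared across
tokens), scaled dot-product attention `softmax(QKᵀ/√d_h)V` with `d_h = d/h`
the per-head width, head concatenation through `W_O`, a residual
connection, then layer normalisation (post-norm).  There is no positional
encoding — the encoder is equivariant under token permutation — and no
position-wise feed-forward sublayer (the fusion step is attention only).
The final 8 × d output is flattened row-major to `f_d ∈ R^{8d}`.

Open choices resolved here: transformer depth is not dictated by the
method, default 2 layers (config-exposed; the fixture-scale experiments
use 1); layer norm is applied after the residual (the conventional
"Add & Norm" reading); dropout is applied in the prediction head only,
not inside attention.

### Cell-line representation

Expression is z-scored per gene across cell lines (zero-variance genes map
to zero columns).  Each omics matrix (cells × genes) is multiplied by the
symmetric PPI weight matrix aligned to its own gene list — every gene's
value becomes a network-neighbourhood-weighted combination — and the two
fused blocks are concatenated: `C = [C_mut·P | C_e·P]`.  PPI edges come
from a STRING-style edge list; edges with combined score below 0.7 are
excluded (both the 0–999 and unit score conventions are accepted; weights
are stored on the unit scale).  Genes present in the network but absent
from an omics gene list are dropped; omics genes absent from the network
get zero rows/columns, so dimensions always conform.  Row-normalisation of
the PPI matrix is off by default (raw weights), with an optional
degree-normalisation flag.

An unsupervised autoencoder (mirrored encoder/decoder, ReLU hidden
activations, linear output) is trained once on all cell lines to minimise
mean squared reconstruction error, then frozen; the encoder maps each cell
line to the bottleneck vector `f_c` (768-d at benchmark scale).  Cell-line
embeddings are not fine-tuned with the synergy loss.  One joint
autoencoder is trained on the concatenated fused matrix (not one per omics
layer), and only cell lines present in the synergy dataset participate.

### Prediction head and training

`[f_d, f_c]` feeds a three-layer fully connected network with ReLU, batch
normalisation and dropout between layers; linear output for regression
(MSE loss), sigmoid for classification (binary cross-entropy — the
classification loss is not dictated by the method; BCE is the standard
choice).  Labels come from strict thresholds: Loewe > 30 or ZIP > 0 means
synergistic; a score exactly at the threshold is labelled 0.

Training uses Adam on mini-batches with early stopping: a validation split
(10% of training, drawn by unordered pair key so no combination straddles
the boundary) is monitored and training stops after `patience` epochs
without improvement, restoring the best-validation parameters.

Pair order: training presents each sample in canonical (lexicographically
sorted) pair order; a config flag additionally presents each pair in both
orders (swap augmentation), which enforces the symmetry the score
possesses and measurably improves generalisation to unseen pairs — the
fixture-scale experiments enable it.  At inference the prediction is
symmetrised: `(ŷ(A,B,c) + ŷ(B,A,c))/2`, which is exactly order-invariant.

The whole network (attention blocks and head) runs on a compact NumPy
engine with hand-written backpropagation (dense, batch/layer norm,
dropout, multi-head attention, Adam); gradients are verified against
central finite differences in the test suite to 1e-4 relative error.

### Defaults

| parameter | default | note |
| --- | --- | --- |
| fingerprint radius / bits | 3 / 1024 | Morgan, RDKit |
| token width d | 1024 | ≥ max block width; fixture scale 32 |
| heads h | 8 | must divide d; fixture scale 4 |
| attention layers | 2 | fixture scale 1 |
| bottleneck | 768 | fixture scale 16 |
| head widths | 4096, 1024 | fixture scale 128, 32 |
| dropout | 0.5 | fixture scale 0.1 (tiny model, noise-free target) |
| batch size | 512 | |
| optimiser | Adam, lr 1e-3 | fixture scale 1.5e-3 |
| early-stop patience | 20 epochs | |
| label thresholds | Loewe 30, ZIP 0 | strict `>` |
| PPI score cutoff | 0.7 (700 on the 0–999 scale) | |

### Ablation variants

Named variants map to configuration: `no_target`, `no_pathway`,
`no_target_pathway` zero the corresponding token families at the
featurizer; `no_attention` replaces the encoder with the identity so `f_d`
is the raw flattened combination feature (verified bit-exact);
`no_ppi` skips the network fusion and column-standardises the
concatenated `[mutation | expression]` matrix instead.

### Inference-time feature removal

Named targets/pathways can be removed at inference: the affected drug's
`d^t` / `d^p` token is recomputed as the mean over the remaining
annotations (zero if none remain); all other tokens are untouched, and ids
not annotated to either drug produce a warning and no change.  This
reproduces the interrogation procedure used in case studies (how much does
the prediction drop when a putative mechanism is removed?).

## Evaluation protocols

* **Combination-disjoint k-fold** (default k = 5): distinct unordered pairs
  are shuffled with the run seed and dealt round-robin into k folds; every
  sample follows its pair, so no combination leaks across folds.  Folds
  balance pairs, not records.
* **Leave-one-drug-out**: each drug in turn defines a test fold of all
  combinations containing it (each record is therefore tested exactly
  twice across folds); training excludes every record containing the drug.
* **Leave-one-cell-line-out**: each cell line in turn is the test object;
  folds partition the records.

Metrics: MSE/RMSE, Pearson r, Spearman rho, and the concordance index
(comparable pairs are those with distinct true values; tied predictions
count one half — the standard convention).  Classification: ROC AUC, area
under the precision–recall curve, and accuracy/precision at a 0.5
probability cutoff (the method does not dictate a decision threshold).
Per-fold values are reported with mean and standard deviation; per-fold
averaging (rather than pooling) is the default aggregation, and the pooled
out-of-fold variant is also reported.  A per-cell-line Pearson table
supports tissue-level inspection.

## Synthetic data generator

The generator emulates all six input files with a planted, learnable
synergy signal so every stage is testable offline:

    score(A,B,c) = w_s·z[J(A,B)] + w_t·z[overlap_t(A,B)]
                 + w_p·z[overlap_p(A,B)] + w_c·z[⟨u_c, β⟩] + ε,
    ε ~ N(0, σ²)

where `J` is fingerprint Jaccard similarity, `u_c` is the cell line's
latent expression factor, and `z[·]` standardises each component over its
realised values.  The score is symmetric in (A,B) by construction and the
true components are stored for diagnostics.

Design choices, made once:

* **Overlap in feature space.**  `overlap_t` is the cosine similarity of
  the two drugs' mean target-embedding vectors — exactly the `d^t` blocks
  the model consumes (likewise `overlap_p` for pathways).  This is a smooth
  measure of annotation-set overlap (identical sets give 1, disjoint sets
  of near-orthogonal embeddings give ≈ 0) and guarantees the planted
  signal is a deterministic function of the generated features, which is
  the point of the fixture.  Raw set intersection-over-union is only
  partially identifiable from mean embeddings and would bound recovery
  well below 1 regardless of implementation quality.
* **Anisotropic embeddings.**  Target/gene embedding vectors are drawn
  from a low-rank latent subspace (rank 4 by default, orthonormal basis),
  emulating the strong anisotropy of real protein-language-model
  embeddings.  Isotropic high-dimensional Gaussians make pairwise cosine
  structure statistically unlearnable from a few hundred training pairs.
* **Scaffold families.**  Fingerprints are family-core bits (6 families,
  density 0.15) OR-ed with drug-specific bits (density 0.05), emulating
  the scaffold clustering of real drug panels; within-family Jaccard is
  high, cross-family low.  A single-family mode generates i.i.d. bits at a
  configurable density, and a SMILES-backed mode computes real Morgan
  fingerprints from a built-in list of valid molecules.
* **Cells.**  Expression is a rank-r factor model (r = 3) plus Gaussian
  noise (sd 0.1); mutation is Bernoulli(0.2); the PPI is a symmetric
  random graph (density 0.15) with weights uniform in [0.7, 1), i.e.
  already above the score cutoff.
* **Counts.**  30 drugs × 10 cell lines (4 350 triplets over 435 pairs),
  15-protein target pool with 2–4 targets per drug, 8 pathways of 3–8
  genes with 1–3 per drug.  Signal weights default to (1, 1, 1, 1) and
  σ = 0: the four components contribute equally and the target is
  noise-free, so recovery quality is attributable to the pipeline alone.

What the generator does **not** emulate: real synergy score distributions
(Loewe values in the benchmark literature have heavy tails and replicate
noise), dose–response structure, correlated target/pathway annotations
across related drugs, and tissue structure among cell lines.  Passing the
fixture-scale tests therefore shows the pipeline recovers a signal
expressible in its own feature families — not that it attains any
particular accuracy on real screens.

## Fixture-scale experiment configuration

End-to-end experiments in the tests and the acceptance script run at
reduced width so they complete quickly on one CPU: 32-bit fingerprints,
32-d embeddings (latent rank 4), token width d = 32 with 4 heads and one
attention layer, 16-d cell bottleneck, head widths (128, 32), dropout 0.1,
batch 512, lr 1.5e-3, swap augmentation on, at most 80 epochs with
patience 20.  The autoencoder at this scale uses hidden widths (64, 16)
and 200 full-batch epochs at lr 1e-2.  Benchmark-scale defaults are as in
the table above.

## Numerical notes

* All computation is float64; training is single-threaded and
  deterministic given the seed — repeated runs with an identical config
  produce byte-identical reports.
* Per-fold model seeds are derived as `seed + fold`; the validation split
  and batch order use separate generators seeded from the run seed.
* Batch normalisation keeps running statistics (momentum 0.1) for
  evaluation mode; a batch of size 1 degenerates gracefully (ε = 1e-5).
* Softmax is computed with max-subtraction; BCE uses the logits form.
* Degenerate inputs: empty PPI after thresholding returns an empty network
  (optional identity fallback); zero-variance genes z-score to zero;
  drugs lacking annotations get zero blocks; constant truth vectors make
  correlation metrics undefined and they are reported as missing rather
  than NaN.

## Known limitations

* The NumPy training engine is compact and single-threaded; benchmark-scale
  training (d = 1024, 22 737 triplets) is functional but slow compared to a
  GPU framework, and the package is tuned for method correctness and
  fixture-scale experiments.
* One model per synergy score type; no multi-task training across types.
* No hyperparameter search utilities; configuration is explicit.
* The PPI fusion is a single linear smoothing step, not a graph
  convolution; methods built on GCN cell encoders are related but out of
  scope.
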