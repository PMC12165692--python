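# Methods

This note documents the model, the numerical choices, the synthetic study
conditions, and the known limitations of `cellvec`.

## Preprocessing

The chain is: cell filter → gene filter → CPM-10k + `ln(1+x)` → HVG →
per-gene z-score → per-gene integer min-max to `[0, 10]`.

* **Filtering.** Cells expressing fewer than `min_genes_per_cell` (default
  200) genes are removed first; genes expressed in fewer than
  `min_cells_per_gene` (default 20) of the *surviving* cells second.  The
  cell-before-gene order matters for borderline genes and is fixed.
  Filtering to an empty matrix raises an error naming the offending
  threshold.
* **Normalization.** Each cell is scaled to 10,000 total counts and
  log-transformed with a pseudo-count of one.  TPM/FPKM input is already
  length/depth normalized and passes through unchanged (the `unit` flag on
  the matrix controls this).  Cells with zero total counts are an error,
  not a silent NaN.
* **HVG selection.** The mean-binned normalized-dispersion statistic
  (scanpy's `seurat` flavor) ranks genes; ties are broken by gene id so the
  selection is fully deterministic.  Default `n_top_hvg` = 2000.
* **z-scoring** uses the population standard deviation; zero-variance genes
  become all-zero rows rather than being dropped, keeping gene sets aligned
  across layers.
* **Integer rescaling.** `int(((x − min_g)/(max_g − min_g)) · 10)` with
  truncation toward zero; constant genes map to 0.  The ratio is evaluated
  *before* multiplying by 10: with the factor applied first, floating-point
  rounding can make the per-gene maximum land at 9.999… and truncate to 9,
  violating the invariant that every non-constant gene attains 10 at its
  argmax cell.  The scale `[0, 10]` bounds document lengths: a cell's
  document has at most `10 × n_HVG` tokens.

## Corpus encoding

Gene *g* contributes exactly `E'[g,c]` copies of its sanitized name
(whitespace → `_`, so one gene is always one token) to cell *c*'s document.
Token order is randomized per cell with independent seeded streams keyed by
cell index (or by a content hash in the joint bulk/pseudo-bulk embedding,
so duplicated profiles produce byte-identical documents).  Only the token
*multiset* is informative; the shuffle removes positional bias.  All-zero
cells yield empty documents that are kept, with a warning, to preserve
column alignment.

## PV-DM embedding model

The embedding is a distributed-memory paragraph-vector model written
against numpy with a numba-compiled SGD kernel (single-threaded, hence
bit-reproducible for a fixed seed):

* For each position *t*, the hidden vector is the **mean** of the document
  vector and the context token vectors within ±`window` (default 5).
* The output distribution is a **hierarchical softmax** over a binary
  Huffman tree of the vocabulary (heap ties broken by token id, so the tree
  is deterministic).  Output-node weights start at zero; token and document
  vectors start uniform in `±0.5/dim` from seeded streams.  Negative
  sampling is not implemented — the hierarchical softmax is the normative
  output layer here.
* The learning rate decays linearly from `initial_lr` (0.025) to `min_lr`
  (1e-4) over all (epoch × position) pairs.  The sigmoid argument is
  clamped at ±6, the classic word2vec guard.
* Defaults: `dim` 300, `window` 5, `initial_lr` 0.025.  Epoch counts are
  exposed (`epochs_pretrain` 40, `epochs_finetune` 10, `infer_epochs` 50):
  small corpora need more passes, and no single value suits all data sizes.
  `min_count` defaults to 1 and frequency subsampling is disabled so rare
  marker genes are never dropped.

**Fine-tuning** merges vocabularies by union (never the intersection),
copies pre-existing token vectors, seeds novel tokens from a hash of their
names, rebuilds the Huffman tree on the combined frequencies and
re-estimates its output weights on the target corpus.  Zero-epoch
fine-tuning changes the vocabulary but not a single token vector.  The
input model is never mutated.

**Inference** freezes token and output weights and runs the same update on
the document vector only.  A document's starting vector is keyed by
`(seed, hash(token sequence))`, so identical documents always map to
identical embeddings.  Out-of-vocabulary tokens are ignored (counted in the
log); a document with no usable tokens keeps its deterministic
initialization and triggers a warning.

## Clustering and metrics

Leiden modularity optimization (RBConfiguration partition, seeded, 2
iterations) runs on a cosine kNN graph (`n_neighbors` 15) built directly on
the embeddings — no intermediate PCA, since the embedding already is the
reduced representation and cosine is the geometry the model optimizes.
Edge weights are cosine similarities (floored at 1e-12); the graph is the
symmetrized union of directed kNN edges.  Labels are canonicalized by
descending cluster size with ties broken by the smallest member id, which
makes the labeling independent of row order.  The resolution sweep covers
0.2–2.0 in steps of 0.2.  ARI and NMI compare a clustering with truth
labels; the cell-type silhouette is computed on the embedding (cosine
metric) against the *truth* annotation, measuring embedding-space
separation rather than clustering quality.

## Phenotype algebra

* **Balancing.** Minority groups are oversampled to the majority size by
  convex interpolation between a group member and one of its k (default 5,
  reduced to group size − 1) nearest same-group neighbors.  Balancing runs
  on the normalized HVG matrix *before* pseudo-bulk averaging, so group
  means are not confounded by cell-type proportions.  Groups of size 1
  cannot be interpolated and raise an error suggesting a merge.
* **Pseudo-bulk.** `T` is the mean profile over all (balanced) cells; a
  query's profile is the mean over the union of its groups' cells, making
  `(P_a + P_b)` order-invariant.  Query strings follow a minimal grammar:
  `T`, `T - G`, `T - (G1 + G2 [+ …])`.
* **Joint embedding.** The bulk cohort is restricted to genes shared with
  the target (< 50 shared genes is an error), depth-normalized when it is
  raw counts, concatenated with the pseudo-bulk profiles, z-scored per gene
  across the combined columns (this absorbs scale differences between bulk
  and pseudo-bulk), integer-rescaled, encoded, and inferred through the
  trained model in one pass — inference only, no re-fitting — so all
  vectors share one latent space.
* **ΔE is vector subtraction**, `E(T) − E(P)`, exactly as the removal
  queries are defined.  The cosine similarity of each query's pseudo-bulk
  embedding to the reference embedding is additionally reported as a
  diagnostic column, reconciling the two ways such queries are commonly
  described.
* **Bootstrap protocol.** 50 RSF models (1000 trees each) are fitted on
  80% subsamples of the bulk cohort drawn *without replacement* from
  seed-derived streams; every ΔE is scored by every model.  Queries are
  ranked by ascending median risk (ties by name); survival curves are the
  pointwise mean of the per-model step functions on the union time grid,
  with S(t) = 1 before the first event time — a mean of valid survival
  curves, hence itself monotone in [0, 1].
* **RSF regularization.** `n_estimators` 1000 is fixed by the protocol;
  the package default `min_samples_leaf` is 20 rather than the library's 3.
  The bootstrap cohorts here are ~10²-sample subsamples of noisy
  embeddings; depth-unconstrained survival trees overfit them and triple
  the fitting cost for no ranking benefit.  The value is exposed in
  `RunConfig` for larger cohorts.

## Synthetic data generator

The generator is the package's test bed and defines its study conditions.

* **Single cells**: negative-binomial counts (gamma–Poisson, shared
  dispersion φ = 0.3, variance μ + φμ²), per-cell library sizes log-normal
  around 2000, per-cluster relative profiles log-normal with each cluster's
  disjoint marker block up-shifted by `marker_fold` (default 8).  No
  zero-inflation: NB overdispersion is the minimal realistic model and
  keeps recovery behavior interpretable.
* **Bulk cohorts**: each sample mixes the cluster mean profiles with
  Dirichlet(1) proportions (then NB sampling at a 10⁶ library), so the
  phenotype-proportion → hazard link is exact: hazard
  `λ_i = ln2/500 · exp(hazard_coef · p_i[aggressive])` (days; baseline
  median survival 500 days), exponential event times, independent
  exponential censoring calibrated numerically so the expected censored
  fraction equals `censor_rate`.  The per-sample truth (proportions,
  hazards) is returned for recovery tests.
* What it does **not** emulate: batch effects, doublets, ambient RNA,
  zero-inflation, patient structure.  Passing recovery tests therefore
  shows the machinery is correct and self-consistent, not that it is robust
  to every artifact of real data.

## Study conditions used by the tests and the acceptance script

Scaled to run on one CPU:

* **Cluster recovery**: 3 clusters × 200 cells, 1000 genes, marker fold 8;
  HVG 200, dim 30, 12 training epochs, 8 inference epochs; median Leiden
  ARI over 5 seeds.  Transfer arm: 2000-cell source (3 × 667), 300-cell
  target, 6 pretrain + 8 fine-tune epochs, compared against direct training
  on the 300-cell target.
* **Aggressiveness recovery**: 3 clusters × 80 cells, 600 genes; cohort
  n = 200, hazard coefficient 3, 30% censoring; HVG 150, dim 10; the full
  bootstrap protocol (50 × 1000 trees at 80%).  Replicated end to end from
  simulation through ranking, with a null arm at hazard coefficient 0.
* Embedding dimensions below the 300 default are used throughout these
  studies; the corpora have only a few hundred distinct genes, and compact
  embeddings keep the survival forests well-posed on 10²-sample cohorts.

## Numerical and degenerate-input conventions

* Truncation toward zero in the integer rescale; ratio-before-factor
  evaluation (see above).
* Zero-variance genes: z-score → 0, min-max → 0.
* Zero vectors are rejected by cosine similarity rather than returning 0.
* Survival step functions are extended with S = 1 left of the first knot
  and carried forward right of the last.
* All randomness flows from explicit seeds through `numpy` `SeedSequence`
  streams; a workflow's master seed fans out to per-stage seeds via a CRC32
  of the stage name.  Training and inference are single-threaded by
  construction, so equal seeds give byte-identical outputs.

## Limitations

* PV-DM training is O(total tokens × epochs); documents grow with
  `10 × n_HVG` tokens per cell, so very large HVG panels are costly.
* The RSF scores ΔE vectors that lie outside the convex hull of the bulk
  training embeddings; the ranking relies on risk being monotone along the
  learned hazard direction, which the forest extrapolates piecewise-
  constantly.  Absolute risk values for queries are therefore not
  calibrated — only their ordering is interpreted.
* Aggressiveness rankings are relative to the cohort used for supervision;
  a cohort whose outcome is unrelated to the tumor's composition yields
  unstable rankings (by design — see the null-hazard calibration test).
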