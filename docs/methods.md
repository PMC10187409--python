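# Methods

## Sequence and family representation

A protein language model assigns each residue a *d*-dimensional vector; the
sequence representation is the arithmetic mean over residues ("mean
pooling"). Sequences longer than 5,096 residues are truncated to that
length before embedding — truncation rather than rejection, with the count
logged — matching the input limit of large transformer models. A family is
represented by the centroid (element-wise mean) of its member-sequence
embeddings; the centroid is used consistently for embedding-space analysis
and for family-level prediction.

External embedders run out-of-process and deliver per-sequence vectors
through an HDF5 store (`ids`, `embeddings` datasets plus an `embedder`
attribute); the core never links against a deep-learning runtime. The
built-in `LookupEmbedder` is a deterministic, context-free baseline: one
fixed standard-normal vector per canonical residue letter, drawn under a
recorded seed. In moderate dimension the letter vectors are near-orthogonal,
so pooled vectors separate sequences by residue composition — enough signal
to exercise every downstream stage, while making no claim to transformer
embedding geometry. Ambiguity codes (X, B, Z, U and anything else
non-canonical) map to the zero vector, which preserves dimension and keeps
pooling well defined.

## Classifier

A dense feed-forward network: hidden layers 512 → 256 → 128 with ReLU
activations and 20% inverted dropout during training (inference is
deterministic), softmax output over the ordered category set, categorical
cross-entropy loss, Adam at learning rate 10⁻⁴, mini-batches of 60, exactly
20 epochs (5 for binary cluster classifiers). When the input dimension
exceeds 1,024, a 1,024-wide first hidden layer is prepended. There is no
early stopping, validation split, class weighting or input normalisation;
the epoch budget is the stopping rule. Training shuffles per epoch under
the run seed. Duplicate sequences are kept as separate observations —
source databases are not deduplicated, and training follows the data as
distributed.

The network is implemented directly on numpy (forward/backward passes and
the Adam update are a few dense matrix products at these sizes). That keeps
the whole training state explicit, runs bit-reproducibly from a single
seed, and makes save→load→predict exactly identical to pre-save
prediction (weights stored as float64 npz plus a JSON sidecar with the
category order, input dimension and config). Weight initialisation is
He-normal under the config seed; reproducibility is per-seed, not
cross-implementation.

**Unknown-family pruning.** When the unknown-function category is included
as a training class, families mis-binned as unknown would poison it. A
classifier trained *without* the unknown category first scores every
unknown family; the family score is the maximum category probability of the
mean of its members' probability rows (the lowest-variance family-level
aggregate of per-sequence softmax outputs; per-sequence majority vote and
centroid-based scoring were the alternatives). Families scoring strictly
above 0.5 are removed from training.

## Evaluation

Folds partition *families*, stratified by category: within each category,
families are shuffled under the seed and dealt round-robin, so per-category
fold counts differ by at most one; a category with fewer families than
folds is an error. Sequence-level folding would leak intra-family homology
between train and test. Training uses every member sequence of the training
families; testing scores one uniformly chosen sequence per held-out family
(fixed at split time so the choice is independent of iteration order).

Per category, one-vs-rest curves use that category's softmax probability
column as the score. AUROC is trapezoidal over the ROC curve; the
precision-recall area is the average-precision step sum, because
trapezoidal PRC interpolation is optimistic. F1 = 2·TP / (2·TP + FP + FN)
with TP/FP/FN from argmax class assignment (argmax ties break to the
earliest category in the fixed order). The optimal threshold maximises F1
of the rule "score ≥ t" over all distinct observed scores, with ties broken
toward the larger threshold; the ≥ convention makes the maximum attainable
at an observed point and is used consistently when gating annotation calls.
Headline class averages are macro (unweighted); the support-weighted F1 is
emitted alongside.

## Embedding space

Cosine similarity, dot(u,v)/(‖u‖‖v‖), measures sequence-sequence similarity
within families and family-family similarity between centroids. The
intra-category diagonal of the category-category matrix averages unordered
within-category family pairs, excluding self-pairs (self-similarity of 1
would inflate it) and is undefined (NaN) below two families. Families whose
mean pairwise member similarity exceeds 0.999 — typically all-duplicate
families from undeduplicated sources — are excluded from summary statistics
only, never from other analyses.

Spectral bipartition feeds the similarity matrix directly to spectral
clustering (n = 2, precomputed affinity, seeded): cosine similarities here
are empirically non-negative and already behave as affinities; if any entry
is negative the matrix is mapped [-1, 1] → [0, 1] first, and undefined
diagonals become 1. A constant matrix carries no structure: it is flagged
degenerate and an arbitrary seeded split is returned with a warning, since
tiny inputs hit this legitimately. An exhaustive minimum-normalized-cut
search (n ≤ 20) is provided as an independent reference objective. Random
two-group baselines draw uniformly among splits with both groups non-empty
(group sizes unconstrained — the least-assuming null). 2-D projection of
the embedding (UMAP and the like) is presentation, not computation, and is
left out of the core.

## Annotation

Truth labels from HMM hit tables: per query family, hits with e-value
strictly below 10⁻¹² are sorted ascending (ties by target id, making the
result independent of row order); the best hit's category is assigned,
skipping *all* unknown-function hits while any later qualifying hit has a
known category; all-unknown yields "unknown function"; no qualifying hits
leaves the family unlabeled. Family-level classifier prediction applies the
trained network to the family centroid. A call is accepted when its
probability reaches the predicted category's maximum-F1 threshold; rejected
calls are kept so the accounting stays exhaustive: every family lands in
exactly one of HMM-labeled, newly classifier-annotated, or unannotated.
When an accepted call contradicts an HMM label the conflict is reported and
the HMM label wins in the merged annotation. The expansion percentage is
newly-annotated / HMM-labeled × 100. A length-stratification helper splits
calls at mean member length 100 (≤ goes short), separating e.g. short
excisionase-like from longer integrase-like families inside one category.

## Synthetic fixtures

Embeddings come from a three-level spherical-Gaussian hierarchy: category
means placed on orthonormal directions scaled so pairwise distance equals
`category_separation × sequence_noise_sd`; family means add a spherical
offset of per-coordinate SD `family_spread`; sequences add noise of SD
`sequence_noise_sd`. Orthonormal placement requires `dim ≥ n_categories`
(+2 with block structure); smaller dimensions are an error rather than
silently degrading the planted geometry. With block structure, two
orthogonal block directions carry a `within_correlation` share ρ of each
category direction, so same-block category means have cosine ρ and
between-block cosine 0.

Defaults: 9 categories × 10 families × 10 sequences, *d* = 64, separation
8, noise SD 1, family spread 0.25. The spread is deliberately small
relative to the separation: offsets concentrate at norm ≈ spread·√d in high
dimension, and a spread of 1 would displace held-out families by ~8 — as
far as the categories are apart — making the stated separation meaningless
as a separability statement. 0.25 (offset norm ≈ 2) keeps family identity
visible while held-out families remain recognisably of their category.
`block_config()` is the two-block fixture for the spectral analyses:
blocks of 4+5 categories, ρ = 0.9, separation 12 — blocks far apart,
same-block categories deliberately confusable, which is exactly the regime
where a block-aligned binary split is easy and an arbitrary one is not.
The default (`default_config()`) carries no block structure, so each planted
category is individually recoverable.

Sequence fixtures plant family-correlated residue composition (a sparse
per-category Dirichlet base profile, perturbed per family), so lookup-
embedder pooling yields family-clustered vectors from raw FASTA; a couple
of records exceed the truncation limit by construction. HMM hit fixtures
withhold a category-stratified fraction of families (largest-remainder
quotas, so coverage carries no category bias and every category keeps
labeled families), give the rest a qualifying hit to a reference of the
true category, and give a configurable fraction an unknown-function decoy
at strictly lower e-value, forcing the skip rule; withheld families get
either no hits or hits above the cutoff.

None of this simulates protein evolution, realistic HMM score
distributions, or transformer embedding geometry. Passing tests therefore
demonstrate that the machinery — pooling, training, stratified evaluation,
spectral analysis, truth assignment, threshold gating — recovers planted
structure correctly; they say nothing about how well any particular
language model separates real viral protein functions.

## Problem sizes and determinism

The standard analyses run on the 900-sequence default fixture (seconds per
cross-validation on one CPU); the spectral recovery check repeats over 100
seeded fixtures; the monotonicity check of AUROC versus planted separation
uses a reduced 3-category fixture, the ordering property being scale-free.
All randomness flows through explicit integer seeds (numpy `default_rng`);
per-fold classifier seeds derive deterministically from the run seed. Runs
with identical inputs and seeds produce byte-identical primary outputs;
the CLI records inputs, options and digests in a `run_manifest.json`.

## Known limitations

- The lookup embedder sees composition only; permuted sequences embed
  identically. That is a feature for testing pooling invariances, a
  non-feature for biology.
- Training-order contracts are per-seed: permuting training rows under the
  same seed changes batch composition and hence the fitted weights.
- The spectral degenerate-input path returns an arbitrary split by design;
  callers who need a hard failure should check the warning.
- `percent_increase` is NaN when no family has an HMM label (division by
  zero is not given a conventional value).
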