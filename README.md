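# vpfclass

Functional annotation of viral protein families (VPFs) from pooled
protein-language-model embeddings.

Most proteins in uncultivated viral genomes have no detectable sequence
homology to anything with a known function, so alignment-based annotation
(BLAST, profile HMMs) leaves the large majority of viral protein families
unlabeled. `vpfclass` implements an alignment-free alternative: every
sequence is represented by the mean of its per-residue embedding vectors, a
dense feed-forward network maps that vector to a functional category, and
families that no HMM search can label are annotated wherever the classifier
is confident enough.

## The method

Given a protein sequence with per-residue vectors *v₁ … v_L* (dimension
*d*), its representation is the mean-pooled embedding **e** = (1/L) Σᵢ vᵢ.
A family's representation is the centroid (column mean) of its member
embeddings.

The classifier is a dense network *d* → 512 → 256 → 128 → |categories|
(ReLU hidden layers, 20% dropout in training, softmax output; an extra
1,024-wide first layer when *d* > 1,024), trained with Adam (lr 10⁻⁴),
categorical cross-entropy, batches of 60, for 20 epochs (5 for binary
cluster classifiers).

Evaluation is **family-stratified** five-fold cross-validation: folds
partition families (stratified by category), training uses every member
sequence of the training families, and testing scores a single randomly
chosen sequence per held-out family — so train/test never share a family.
Per category the package reports one-vs-rest ROC/PRC curves, AUROC, AUPRC,
F1 = 2·TP / (2·TP + FP + FN), and the probability threshold maximising F1.

Around the classifier:

- **Embedding space** — cosine similarities at sequence, family and category
  level; the category-category similarity matrix is bipartitioned with
  spectral clustering (n = 2) and compared against random two-group splits.
- **Ground truth from HMM hit tables** — per query family, the category of
  the lowest-e-value hit below 10⁻¹², skipping unknown-function hits while a
  later qualifying hit has a known category.
- **Annotation expansion** — families without a qualifying HMM hit are
  predicted from their centroid and accepted when the probability reaches
  that category's maximum-F1 threshold; the report counts newly annotated
  families per category and the percentage gain.

External protein language models run out-of-process; their per-sequence
vectors enter through an HDF5 embedding store. A deterministic built-in
lookup embedder (one seeded random vector per residue letter, mean-pooled)
and a synthetic fixture generator with planted category/family/block
structure make the whole pipeline self-contained and testable.

## Worked example

`examples/02_crossvalidate.py` generates the default planted fixture
(9 categories × 10 families × 10 sequences, *d* = 64, category separation 8
noise-SD) and cross-validates the classifier:

```
fixture: 90 families, 900 sequences, d=64

macro AUROC 0.999 +/- 0.001, macro AUPRC 0.996 +/- 0.007

fold 0 per-category metrics (one-vs-rest on softmax probabilities):
category  AUROC  AUPRC    F1  thr*
cat01     1.000  1.000  1.00  0.99
cat02     1.000  1.000  1.00  0.94
...
cat09     1.000  1.000  0.67  0.21
```

Macro AUROC/AUPRC are means over categories and folds of the one-vs-rest
areas; `thr*` is the per-category decision threshold later used to gate
annotation calls. The other examples cover embedding + training
(`01_embed_and_train.py`), the spectral two-block analysis
(`03_embedding_space.py`, spectral split AUPRC 1.000 vs 0.805 mean over 10
random splits), and annotation expansion (`04_annotate.py`, 42.9% more
families annotated at 27/27 call precision on the planted fixture).

The same pipeline is available as a CLI:

```sh
vpfclass simulate --seed 5 --out fixture/
vpfclass train --embeddings fixture/embeddings.h5 --families fixture/families.tsv \
    --categories fixture/categories.txt --out model/
vpfclass evaluate --embeddings fixture/embeddings.h5 --families fixture/families.tsv \
    --k 5 --seed 5 --out report/
vpfclass annotate --model model/ --embeddings fixture/embeddings.h5 \
    --families fixture/families.tsv --hmm-hits fixture/hits.tsv \
    --targets fixture/targets.tsv --thresholds report/thresholds.json --out annot/
```

## Layout

- `src/vpfclass/io.py` — domain types; FASTA/TSV/HDF5 readers and writers
- `src/vpfclass/embedding.py` — truncation, mean pooling, lookup embedder
- `src/vpfclass/classifier.py` — the feed-forward network, training,
  unknown-family pruning, persistence
- `src/vpfclass/evaluation.py` — family-stratified CV, curves, F1,
  thresholds, binary task assembly
- `src/vpfclass/embedspace.py` — centroids, cosine similarities, spectral
  bipartition, random baselines
- `src/vpfclass/annotation.py` — HMM truth labels, threshold-gated calls,
  expansion report
- `src/vpfclass/synthetic.py` — planted fixture generators
- `src/vpfclass/cli.py` — the `vpfclass` command
- `docs/methods.md` — model, assumptions, parameter choices, limitations
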