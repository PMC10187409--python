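"""Embed sequences with the built-in lookup embedder and train a classifier.

Builds a small synthetic FASTA fixture whose residue composition tracks the
family, pools per-residue vectors to one embedding per sequence, trains the
feed-forward functional classifier, and prints held-out predictions.
"""

import numpy as np

import vpfclass as v

cfg = v.SyntheticConfig(
    n_categories=3, families_per_category=6, sequences_per_family=5,
    dim=16, seed=0,
)
records, table = v.generate_sequence_fixture(cfg, n_overlength=0)
embeddings = v.embed_sequences(records, v.LookupEmbedder(dim=32, seed=0))
print(f"{len(records)} sequences embedded to d={embeddings.dim} pooled vectors")

# hold out one family per category, train on the rest
held_out = [fams[0] for fams in table.families_by_category().values()]
train_table = table.restrict_to_families(
    [f for f in table.families() if f not in held_out]
)
ids = sorted(train_table.protein_to_family)
labels = [train_table.category_of(train_table.protein_to_family[p]) for p in ids]

clf_cfg = v.ClassifierConfig(seed=0)
clf = v.build_classifier(embeddings.dim, table.category_set, clf_cfg)
v.train(clf, embeddings.rows(ids), labels, clf_cfg)

print("\nheld-out family predictions (family representation = centroid):")
held_table = table.restrict_to_families(held_out)
for fam, (cat, prob) in v.predict_family_categories(
    clf, embeddings, held_table
).items():
    truth = table.category_of(fam)
    mark = "ok " if cat == truth else "MISS"
    print(f"  {fam}: predicted {cat} (p={prob:.2f}), true {truth}  [{mark}]")
print("\nEach line is a family never seen in training; 'p' is the softmax")
print("probability of the winning category from the centroid embedding.")
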