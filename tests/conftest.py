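import numpy as np
import pytest

import vpfclass as v


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast, well-separated fixture for unit tests."""
    return v.SyntheticConfig(
        n_categories=3,
        families_per_category=5,
        sequences_per_family=4,
        dim=8,
        category_separation=8.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_fixture(tiny_config):
    return v.generate_embedding_fixture(tiny_config)


@pytest.fixture(scope="session")
def default_fixture():
    """The standard 9x10x10, d=64, separation-8 fixture."""
    return v.generate_embedding_fixture(v.default_config(seed=1))


@pytest.fixture(scope="session")
def block_fixture():
    """The two-block (4+5) category fixture."""
    cfg = v.block_config(seed=3)
    table, emb = v.generate_embedding_fixture(cfg)
    return cfg, table, emb


@pytest.fixture(scope="session")
def trained_tiny(tiny_fixture):
    """A classifier trained on the whole tiny fixture."""
    table, emb = tiny_fixture
    cfg = v.ClassifierConfig(seed=7)
    clf = v.build_classifier(emb.dim, table.category_set, cfg)
    ids = list(emb.ids)
    labels = [table.category_of(table.protein_to_family[p]) for p in ids]
    v.train(clf, emb.rows(ids), labels, cfg)
    return clf


def brute_force_auroc(scores, labels) -> float:
    """Concordant-pair (rank-sum) AUROC: ties count half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_best_f1(scores, labels):
    """Exhaustive F1 scan over all distinct scores (rule: score >= t)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    best_t, best_f1 = None, -1.0
    for t in sorted(set(scores.tolist()), reverse=True):
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        f1 = 2 * tp / (2 * tp + fp + fn) if (tp + fp + fn) else 0.0
        if f1 > best_f1:
            best_t, best_f1 = t, f1
    return best_t, best_f1
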