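"""Dense feed-forward functional-category classifier.

Architecture: three ReLU hidden layers of widths 512, 256 and 128 with 20%
dropout during training, softmax output over the ordered category set,
categorical cross-entropy loss, Adam at learning rate 1e-4, mini-batches of
60 for 20 epochs (5 for the binary cluster classifiers).  When the embedding
dimension exceeds 1,024 an extra 1,024-wide first hidden layer is prepended.
The network is small enough that it is implemented directly on numpy: the
whole training state is a handful of dense matrices, which keeps runs exactly
reproducible from a single seed and models bit-identical across save/load.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._errors import ValidationError
from .io import CategorySet, EmbeddingMatrix, FamilyTable

__all__ = [
    "ClassifierConfig",
    "Classifier",
    "build_classifier",
    "train",
    "predict_proba",
    "predict_category",
    "family_prediction_scores",
    "prune_unknown_families",
    "save_classifier",
    "load_classifier",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters; the defaults are the reference settings."""

    hidden_dims: tuple[int, ...] = (512, 256, 128)
    dropout_rate: float = 0.2
    n_epochs: int = 20
    learning_rate: float = 1e-4
    batch_size: int = 60
    seed: int = 0
    prepend_1024: bool = True  # add a 1024-wide first hidden layer when d > 1024

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden_dims):
            raise ValidationError("hidden layer widths must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.n_epochs < 1 or self.batch_size < 1:
            raise ValidationError("n_epochs and batch_size must be positive")
        if not self.learning_rate > 0:
            raise ValidationError("learning_rate must be positive")

    @classmethod
    def binary(cls, **kwargs) -> "ClassifierConfig":
        """Settings for the two-class cluster classifiers (5 epochs)."""
        kwargs.setdefault("n_epochs", 5)
        return cls(**kwargs)


@dataclass
class Classifier:
    """Layer weights plus the ordered category list they predict."""

    input_dim: int
    categories: CategorySet
    config: ClassifierConfig
    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)
    trained: bool = False

    @property
    def layer_widths(self) -> list[int]:
        return [w.shape[1] for w in self.weights]


def build_classifier(
    d: int, categories: CategorySet, config: ClassifierConfig | None = None
) -> Classifier:
    """Initialise an untrained network for ``d``-dimensional inputs.

    Hidden widths are ``[1024] + hidden_dims`` when ``d > 1024`` (and the
    config's ``prepend_1024`` rule flag is on), else ``hidden_dims``; weights
    use He-normal initialisation under the config seed.
    """
    if d < 1:
        raise ValidationError(f"input dimension must be >= 1, got {d}")
    if len(categories) < 2:
        raise ValidationError("a classifier needs at least 2 categories")
    config = config or ClassifierConfig()
    hidden = list(config.hidden_dims)
    if config.prepend_1024 and d > 1024:
        hidden = [1024] + hidden
    widths = [d] + hidden + [len(categories)]
    rng = np.random.default_rng(config.seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        weights.append(rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in))
        biases.append(np.zeros(fan_out))
    return Classifier(d, categories, config, weights, biases)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward_train(clf, x, rng):
    """Forward pass with inverted dropout; returns activations and masks."""
    keep = 1.0 - clf.config.dropout_rate
    activations, masks = [x], []
    h = x
    for w, b in zip(clf.weights[:-1], clf.biases[:-1]):
        h = np.maximum(h @ w + b, 0.0)
        if clf.config.dropout_rate > 0:
            mask = (rng.random(h.shape) < keep) / keep
            h = h * mask
        else:
            mask = None
        masks.append(mask)
        activations.append(h)
    probs = _softmax(h @ clf.weights[-1] + clf.biases[-1])
    return activations, masks, probs


def train(
    classifier: Classifier,
    embeddings: np.ndarray | EmbeddingMatrix,
    labels: Sequence[str],
    config: ClassifierConfig | None = None,
) -> Classifier:
    """Fit in place with Adam on categorical cross-entropy; returns the model.

    Runs exactly ``n_epochs`` passes over seeded per-epoch shuffles in
    mini-batches of ``batch_size``.  No validation split and no early
    stopping: the epoch budget is the stopping rule.
    """
    cfg = config or classifier.config
    x = embeddings.values if isinstance(embeddings, EmbeddingMatrix) else np.asarray(embeddings, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != classifier.input_dim:
        raise ValidationError(
            f"embeddings have dimension {x.shape[-1] if x.ndim == 2 else '?'}, "
            f"classifier expects {classifier.input_dim}"
        )
    if len(labels) != x.shape[0]:
        raise ValidationError("need exactly one label per embedding row")
    y = np.array([classifier.categories.index(lab) for lab in labels])
    onehot = np.zeros((len(y), len(classifier.categories)))
    onehot[np.arange(len(y)), y] = 1.0

    rng = np.random.default_rng(cfg.seed)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    params = classifier.weights + classifier.biases
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    step = 0
    n = x.shape[0]
    for _ in range(cfg.n_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x[idx], onehot[idx]
            activations, masks, probs = _forward_train(classifier, xb, rng)
            # softmax + cross-entropy gradient
            delta = (probs - yb) / len(idx)
            grads_w, grads_b = [], []
            for layer in range(len(classifier.weights) - 1, -1, -1):
                grads_w.append(activations[layer].T @ delta)
                grads_b.append(delta.sum(axis=0))
                if layer > 0:
                    delta = delta @ classifier.weights[layer].T
                    if masks[layer - 1] is not None:
                        delta = delta * masks[layer - 1]
                    delta = delta * (activations[layer] > 0)
            grads = list(reversed(grads_w)) + list(reversed(grads_b))
            step += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for i, (p, g) in enumerate(zip(params, grads)):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g * g
                p -= lr_t * m[i] / (np.sqrt(v[i]) + eps)
    classifier.trained = True
    return classifier


def predict_proba(
    classifier: Classifier, embeddings: np.ndarray | EmbeddingMatrix
) -> np.ndarray:
    """Softmax probabilities, one row per input, columns in category order.

    Dropout is inactive: prediction is a deterministic pure function.
    """
    x = embeddings.values if isinstance(embeddings, EmbeddingMatrix) else np.asarray(embeddings, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != classifier.input_dim:
        raise ValidationError(
            f"embeddings have dimension {x.shape[1]}, "
            f"classifier expects {classifier.input_dim}"
        )
    h = x
    for w, b in zip(classifier.weights[:-1], classifier.biases[:-1]):
        h = np.maximum(h @ w + b, 0.0)
    return _softmax(h @ classifier.weights[-1] + classifier.biases[-1])


def predict_category(
    classifier: Classifier, embeddings: np.ndarray | EmbeddingMatrix
) -> list[str]:
    """Highest-probability category per row; ties break to the earliest category."""
    probs = predict_proba(classifier, embeddings)
    return [classifier.categories.names[i] for i in probs.argmax(axis=1)]


def family_prediction_scores(
    classifier: Classifier,
    embeddings: EmbeddingMatrix,
    family_table: FamilyTable,
    families: Sequence[str] | None = None,
) -> dict[str, float]:
    """Family score = max category probability of the mean member-probability row.

    Averaging member probabilities before taking the max is the
    lowest-variance family-level aggregate of per-sequence softmax outputs.
    """
    fams = list(families) if families is not None else family_table.families()
    scores: dict[str, float] = {}
    for fam in fams:
        members = [p for p in family_table.members(fam) if p in embeddings]
        if not members:
            raise ValidationError(f"family {fam!r} has no embedded members")
        probs = predict_proba(classifier, embeddings.rows(members))
        scores[fam] = float(probs.mean(axis=0).max())
    return scores


def prune_unknown_families(
    family_scores: dict[str, float], threshold: float = 0.5
) -> tuple[set[str], set[str]]:
    """Split unknown-function families into (retained, removed) at a score cutoff.

    Families the known-category classifier already recognises with score
    strictly above ``threshold`` are likely mis-binned as unknown and are
    removed from training; the partition is exhaustive and disjoint.
    """
    for fam, s in family_scores.items():
        if not 0.0 <= s <= 1.0:
            raise ValidationError(f"family {fam!r}: score {s} outside [0, 1]")
    removed = {f for f, s in family_scores.items() if s > threshold}
    retained = set(family_scores) - removed
    return retained, removed


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_classifier(classifier: Classifier, directory) -> None:
    """Write weights (npz, float64) plus a JSON sidecar to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, (w, b) in enumerate(zip(classifier.weights, classifier.biases)):
        arrays[f"w{i}"] = w
        arrays[f"b{i}"] = b
    np.savez(directory / "weights.npz", **arrays)
    sidecar = {
        "input_dim": classifier.input_dim,
        "categories": list(classifier.categories.names),
        "unknown_name": classifier.categories.unknown_name,
        "config": asdict(classifier.config),
        "n_layers": len(classifier.weights),
        "trained": classifier.trained,
    }
    (directory / "model.json").write_text(json.dumps(sidecar, indent=2))


def load_classifier(directory) -> Classifier:
    """Reload a saved model; predictions are bit-identical to pre-save."""
    directory = Path(directory)
    sidecar = json.loads((directory / "model.json").read_text())
    cfg_dict = dict(sidecar["config"])
    cfg_dict["hidden_dims"] = tuple(cfg_dict["hidden_dims"])
    config = ClassifierConfig(**cfg_dict)
    categories = CategorySet(tuple(sidecar["categories"]), sidecar["unknown_name"])
    with np.load(directory / "weights.npz") as data:
        weights = [data[f"w{i}"] for i in range(sidecar["n_layers"])]
        biases = [data[f"b{i}"] for i in range(sidecar["n_layers"])]
    return Classifier(
        sidecar["input_dim"], categories, config, weights, biases, sidecar["trained"]
    )
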