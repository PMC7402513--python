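"""Similarity featurization and per-side-effect binary classifiers.

Each drug is represented by its row of the comprehensive similarity matrix:
a D-dimensional vector whose i-th entry is S_com(drug, drug_i) over the full
drug set.  Note this featurization intentionally uses the similarity matrix
over *all* D drugs — including drugs that later land in a test fold — which
mirrors how similarity-vector methods are evaluated in this setting: the
similarity channels derive from chemistry and annotation, not from the
side-effect labels under prediction, so no label information leaks.

Two learners are implemented natively because their contracts (tie-breaking,
seeding, target coding) matter to reproducibility:

* k-nearest neighbours with Euclidean distance, vote-fraction scores and
  deterministic (distance, drug id) tie-breaking;
* an extreme learning machine (ELM): a single hidden layer with random
  uniform [-1, 1] weights, sigmoid activation, and output weights solved by
  least squares against +1/-1 targets.

Support-vector machines and radial-basis-function networks run behind a
pluggable backend registry; default backends (scikit-learn SVC and an exact
Gaussian RBF network) are registered at import.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import Dataset
from ._rng import substream
from .negatives import GoldStandard
from .similarity import SimilarityMatrix

__all__ = [
    "ClassifierSpec",
    "TrainingSet",
    "ELMModel",
    "vectorize",
    "build_training_set",
    "knn_fit_predict",
    "elm_fit",
    "elm_predict",
    "register_backend",
    "backend_fit_predict",
    "fit_predict",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier choice plus hyperparameters.

    Defaults are the tuned operating points for this prediction task:
    KNN k=50; ELM sigmoid activation with 150 hidden units; SVM with an RBF
    kernel and gamma=0.07; RBF network with spread 500.
    """

    kind: str = "knn"
    k: int = 50
    hidden_units: int = 150
    activation: str = "sigmoid"
    kernel: str = "rbf"
    gamma: float = 0.07
    spread: float = 500.0
    seed: int = 0

    def with_seed(self, seed: int) -> "ClassifierSpec":
        return replace(self, seed=seed)


@dataclass
class TrainingSet:
    """Feature vectors for one side-effect's training drugs."""

    side_effect_id: str
    X_pos: np.ndarray
    X_neg: np.ndarray
    pos_ids: list[str]
    neg_ids: list[str]
    balance_mode: str
    n_s: int

    def __post_init__(self):
        if self.balance_mode == "balanced" and len(self.pos_ids) != len(self.neg_ids):
            raise ValueError(
                f"{self.side_effect_id}: balanced set has {len(self.pos_ids)} positives "
                f"vs {len(self.neg_ids)} negatives"
            )

    @property
    def X(self) -> np.ndarray:
        return np.vstack([self.X_pos, self.X_neg])

    @property
    def y(self) -> np.ndarray:
        return np.concatenate([np.ones(len(self.pos_ids)), np.zeros(len(self.neg_ids))])

    @property
    def ids(self) -> list[str]:
        return list(self.pos_ids) + list(self.neg_ids)


def vectorize(drug_id: str, S: SimilarityMatrix) -> np.ndarray:
    """Similarity feature vector: the drug's row of S (self-entry 1)."""
    return S.row(drug_id).copy()


def build_training_set(
    dataset: Dataset,
    side_effect_id: str,
    S: SimilarityMatrix,
    gold: GoldStandard | None,
    balance: str = "balanced",
    seed: int = 0,
) -> TrainingSet:
    """Assemble the positive/negative feature vectors for one side-effect.

    balanced: n_s = min(#labeled, #unlabeled); positives are a seeded uniform
    subsample when the labeled side is larger, and negatives are the first
    n_s entries of the gold-standard ranking (reliable) or draw (random).
    unbalanced: all labeled drugs vs all unlabeled drugs, ignoring ``gold``.
    """
    positives = dataset.positives(side_effect_id)
    candidates = dataset.candidates(side_effect_id)
    if not positives:
        raise ValueError(f"{side_effect_id}: no positive drugs")
    if not candidates:
        raise ValueError(f"{side_effect_id}: no candidate negative drugs")

    if balance == "unbalanced":
        pos_ids, neg_ids = positives, candidates
        n_s = min(len(positives), len(candidates))
    elif balance == "balanced":
        n_s = min(len(positives), len(candidates))
        if len(positives) > n_s:
            rng = substream(seed, "positive-subsample", side_effect_id)
            chosen = rng.choice(len(positives), size=n_s, replace=False)
            pos_ids = [positives[i] for i in sorted(chosen)]
        else:
            pos_ids = positives
        if gold is None:
            raise ValueError("balanced mode requires a GoldStandard negative source")
        if len(gold.negatives) < n_s:
            raise ValueError(
                f"{side_effect_id}: gold standard holds {len(gold.negatives)} negatives, "
                f"need {n_s}"
            )
        neg_ids = list(gold.negatives[:n_s])
    else:
        raise ValueError(f"unknown balance mode {balance!r}")

    X_pos = np.stack([vectorize(d, S) for d in pos_ids])
    X_neg = np.stack([vectorize(d, S) for d in neg_ids])
    return TrainingSet(
        side_effect_id=side_effect_id,
        X_pos=X_pos,
        X_neg=X_neg,
        pos_ids=pos_ids,
        neg_ids=neg_ids,
        balance_mode=balance,
        n_s=n_s,
    )


# ---------------------------------------------------------------------------
# K-nearest neighbours (native)


def knn_fit_predict(
    train: TrainingSet, X_test: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vote-fraction KNN scores and labels for the test vectors.

    Euclidean distance on similarity feature vectors; effective k' =
    min(k, training size); distance ties broken by training drug id; score =
    positive fraction among the k' nearest; label = score >= 0.5.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = train.X
    y = train.y
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    ids = np.array(train.ids)
    k_eff = min(k, X.shape[0])
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    d2 = (
        np.sum(X_test**2, axis=1)[:, None]
        - 2.0 * X_test @ X.T
        + np.sum(X**2, axis=1)[None, :]
    )
    d2 = np.maximum(d2, 0.0)
    id_rank = np.argsort(np.argsort(ids, kind="stable"))  # lexicographic rank per column
    scores = np.empty(X_test.shape[0])
    for i in range(X_test.shape[0]):
        order = np.lexsort((id_rank, np.round(d2[i], 12)))
        scores[i] = y[order[:k_eff]].mean()
    return scores, (scores >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# Extreme learning machine (native)


@dataclass
class ELMModel:
    weights: np.ndarray  # (n_features, hidden_units)
    biases: np.ndarray  # (hidden_units,)
    beta: np.ndarray  # (hidden_units,)
    activation: str = "sigmoid"


def _activate(Z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "sigmoid":
        return 1.0 / (1.0 + np.exp(-Z))
    if activation == "tanh":
        return np.tanh(Z)
    raise ValueError(f"unknown activation {activation!r}")


def elm_fit(
    train: TrainingSet, hidden_units: int = 150, activation: str = "sigmoid", seed: int = 0
) -> ELMModel:
    """Fit an ELM: random hidden layer, least-squares output weights.

    Hidden weights and biases drawn uniformly from [-1, 1] with the given
    seed; targets coded +1 (positive) / -1 (negative); output weights are the
    minimum-norm least-squares solution, so degenerate hidden matrices are
    handled without failure.
    """
    if hidden_units < 1:
        raise ValueError("hidden_units must be >= 1")
    X, y = train.X, train.y
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    rng = substream(seed, "elm-hidden")
    W = rng.uniform(-1.0, 1.0, size=(X.shape[1], hidden_units))
    b = rng.uniform(-1.0, 1.0, size=hidden_units)
    H = _activate(X @ W + b, activation)
    targets = np.where(y > 0, 1.0, -1.0)
    beta, *_ = np.linalg.lstsq(H, targets, rcond=None)
    return ELMModel(weights=W, biases=b, beta=beta, activation=activation)


def elm_predict(model: ELMModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores (raw margin through a sigmoid) and hard labels (margin >= 0)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    H = _activate(X @ model.weights + model.biases, model.activation)
    raw = H @ model.beta
    return 1.0 / (1.0 + np.exp(-raw)), (raw >= 0).astype(int)


# ---------------------------------------------------------------------------
# Pluggable backends (SVM, RBF network)

_BACKENDS: dict = {}


def register_backend(kind: str, fn) -> None:
    """Register ``fn(spec, train, X_test) -> (scores, labels)`` for ``kind``."""
    _BACKENDS[kind] = fn


def backend_fit_predict(
    spec: ClassifierSpec, train: TrainingSet, X_test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Delegate svm/rbf fitting to a registered backend.

    Backends must be deterministic given spec.seed and return scores that
    increase with positive-class confidence.  The native knn/elm paths are
    not routed here.
    """
    if spec.kind in ("knn", "elm"):
        raise ValueError(f"{spec.kind!r} is implemented natively, not via a backend")
    fn = _BACKENDS.get(spec.kind)
    if fn is None:
        raise NotImplementedError(
            f"no backend registered for classifier kind {spec.kind!r}; "
            f"register one with register_backend()"
        )
    return fn(spec, train, np.atleast_2d(np.asarray(X_test, dtype=float)))


def _svm_backend(spec: ClassifierSpec, train: TrainingSet, X_test: np.ndarray):
    from sklearn.svm import SVC

    clf = SVC(kernel=spec.kernel, gamma=spec.gamma, random_state=spec.seed)
    clf.fit(train.X, train.y)
    margin = clf.decision_function(X_test)
    return 1.0 / (1.0 + np.exp(-margin)), (margin >= 0).astype(int)


def _rbf_backend(spec: ClassifierSpec, train: TrainingSet, X_test: np.ndarray):
    """Exact RBF network: one Gaussian unit per training point (radial basis
    exp(-(d/spread)^2)), output weights by least squares on +1/-1 targets."""
    X, y = train.X, train.y
    targets = np.where(y > 0, 1.0, -1.0)

    def design(A: np.ndarray) -> np.ndarray:
        d2 = (
            np.sum(A**2, axis=1)[:, None]
            - 2.0 * A @ X.T
            + np.sum(X**2, axis=1)[None, :]
        )
        return np.exp(-np.maximum(d2, 0.0) / spec.spread**2)

    w, *_ = np.linalg.lstsq(design(X), targets, rcond=None)
    raw = design(X_test) @ w
    return 1.0 / (1.0 + np.exp(-raw)), (raw >= 0).astype(int)


register_backend("svm", _svm_backend)
register_backend("rbf", _rbf_backend)


def fit_predict(
    spec: ClassifierSpec, train: TrainingSet, X_test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Dispatch to the native or backend classifier named by ``spec.kind``."""
    if spec.kind == "knn":
        return knn_fit_predict(train, X_test, k=spec.k)
    if spec.kind == "elm":
        model = elm_fit(
            train, hidden_units=spec.hidden_units, activation=spec.activation, seed=spec.seed
        )
        return elm_predict(model, X_test)
    return backend_fit_predict(spec, train, X_test)
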