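"""End classifiers over combined drug-cell feature vectors, and per-cell drug ranking.

A drug representation (fingerprint or learned embedding) and a cell
representation (expression or learned embedding) are combined — concatenated
drug-block-first by default, or via a Hadamard product when block lengths
match — and fed to a logistic regression, random forest, or dense feed-forward
network that predicts the probability a drug is effective against the cell
line. Per-cell prioritization sorts a drug pool by predicted score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .io import PrioritizationResult
from .nn import MLP, Adam, EarlyStopper, bce_loss, sigmoid

CLASSIFIER_KINDS = ("logistic", "random_forest", "dense_network")


@dataclass
class FeatureAssembly:
    """How drug and cell vectors combine into one classifier input row.

    ``combine='concat'`` emits ``[drug | cell]`` in that fixed order;
    ``'hadamard'`` multiplies elementwise (equal block lengths required).
    Block lengths are recorded so importance attribution can tag each feature
    as drug- or cell-derived.
    """

    drug_repr: str = "embedding"   # {"fingerprint", "embedding"}
    cell_repr: str = "embedding"   # {"expression", "embedding"}
    combine: str = "concat"        # {"concat", "hadamard"}
    drug_block_len: int = 0
    cell_block_len: int = 0

    def __post_init__(self) -> None:
        if self.drug_repr not in ("fingerprint", "embedding"):
            raise ValueError(f"unknown drug_repr {self.drug_repr!r}")
        if self.cell_repr not in ("expression", "embedding"):
            raise ValueError(f"unknown cell_repr {self.cell_repr!r}")
        if self.combine not in ("concat", "hadamard"):
            raise ValueError(f"unknown combine {self.combine!r}")
        if self.combine == "hadamard" and self.drug_block_len != self.cell_block_len:
            raise ValueError("hadamard combination requires equal block lengths")

    @property
    def width(self) -> int:
        if self.combine == "concat":
            return self.drug_block_len + self.cell_block_len
        return self.drug_block_len

    def feature_sources(self) -> list:
        """Per-feature origin tags ('drug' / 'cell'); Hadamard features are 'drug'
        by the drug-block-first convention (each mixes both blocks)."""
        if self.combine == "concat":
            return ["drug"] * self.drug_block_len + ["cell"] * self.cell_block_len
        return ["drug"] * self.drug_block_len


@dataclass
class ClassifierSpec:
    kind: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}, got {self.kind!r}")


def assemble_features(drug_vec, cell_vec, assembly: FeatureAssembly) -> np.ndarray:
    """Combine one drug vector and one cell vector per the assembly."""
    d = np.asarray(drug_vec, dtype=float).ravel()
    c = np.asarray(cell_vec, dtype=float).ravel()
    if len(d) != assembly.drug_block_len:
        raise ValueError(f"drug vector length {len(d)} != declared {assembly.drug_block_len}")
    if len(c) != assembly.cell_block_len:
        raise ValueError(f"cell vector length {len(c)} != declared {assembly.cell_block_len}")
    if assembly.combine == "concat":
        return np.concatenate([d, c])
    return d * c


class _DenseNetClassifier:
    """Feed-forward binary classifier: Adam, dropout, early stopping, LR decay."""

    def __init__(self, hidden_dims=(64, 32), dropout: float = 0.2,
                 learning_rate: float = 1e-3, lr_decay_per_epoch: float = 0.99,
                 max_epochs: int = 100, patience: int = 10, batch_size: int = 128,
                 validation_fraction: float = 0.15, seed: int = 0):
        self.hidden_dims = tuple(hidden_dims)
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.lr_decay_per_epoch = lr_decay_per_epoch
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.seed = seed
        self.net: Optional[MLP] = None
        self.log: list = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_DenseNetClassifier":
        rng = np.random.default_rng(self.seed)
        self.net = MLP([X.shape[1], *self.hidden_dims, 1], activation="relu",
                       dropout=self.dropout, rng=rng)
        opt = Adam(self.net.parameters(), lr=self.learning_rate)
        n = len(X)
        perm = rng.permutation(n)
        n_val = max(1, int(round(self.validation_fraction * n)))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        stopper = EarlyStopper(self.patience)
        for epoch in range(self.max_epochs):
            opt.lr = self.learning_rate * self.lr_decay_per_epoch**epoch
            order = rng.permutation(len(train_idx))
            losses = []
            for start in range(0, len(order), self.batch_size):
                idx = train_idx[order[start:start + self.batch_size]]
                out, cache = self.net.forward(X[idx], training=True, rng=rng)
                p = sigmoid(out[:, 0])
                loss = bce_loss(p, y[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(f"non-finite loss at epoch {epoch}")
                grad = ((p - y[idx]) / len(idx))[:, None]
                gW, gb, _ = self.net.backward(cache, grad)
                opt.step(gW + gb)
                losses.append(loss)
            val_loss = bce_loss(self.predict_proba(X[val_idx]), y[val_idx])
            self.log.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                             "val_loss": float(val_loss), "lr": opt.lr})
            if stopper.update(val_loss, self.net.parameters()):
                break
        if stopper.best_state is not None:
            self.net.set_state(stopper.best_state)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        out, _ = self.net.forward(np.atleast_2d(X), training=False)
        return sigmoid(out[:, 0])


class CDRClassifier:
    """A fitted end classifier exposing calibrated-range scores in [0, 1]."""

    def __init__(self, spec: ClassifierSpec, assembly: Optional[FeatureAssembly] = None):
        self.spec = spec
        self.assembly = assembly
        self.n_features_: Optional[int] = None
        self._impl = None
        self.X_train_: Optional[np.ndarray] = None
        self.y_train_: Optional[np.ndarray] = None

    @property
    def kind(self) -> str:
        return self.spec.kind

    def fit(self, X, y) -> "CDRClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int).ravel()
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        hp = dict(self.spec.hyperparameters)
        if self.spec.kind == "logistic":
            # L2-penalized by default (sklearn's default penalty)
            self._impl = LogisticRegression(
                C=hp.pop("C", 1.0), max_iter=hp.pop("max_iter", 2000),
                class_weight=hp.pop("class_weight", None), **hp).fit(X, y)
        elif self.spec.kind == "random_forest":
            self._impl = RandomForestClassifier(
                n_estimators=hp.pop("n_estimators", 500),
                min_samples_split=hp.pop("min_samples_split", 2),
                class_weight=hp.pop("class_weight", None),
                random_state=self.spec.seed, n_jobs=1, **hp).fit(X, y)
        else:
            self._impl = _DenseNetClassifier(seed=self.spec.seed, **hp).fit(X, y.astype(float))
        self.n_features_ = X.shape[1]
        self.X_train_, self.y_train_ = X, y
        return self

    def predict_scores(self, X) -> np.ndarray:
        """Per-row probability that the drug is effective against the cell line."""
        if self._impl is None:
            raise RuntimeError("classifier is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_:
            raise ValueError(f"feature width {X.shape[1]} != training width {self.n_features_}")
        if self.spec.kind == "dense_network":
            return self._impl.predict_proba(X)
        proba = self._impl.predict_proba(X)
        return proba[:, list(self._impl.classes_).index(1)]


def train_classifier(features, labels, spec: ClassifierSpec,
                     assembly: Optional[FeatureAssembly] = None) -> CDRClassifier:
    """Fit an end classifier on assembled feature rows and 0/1 labels."""
    return CDRClassifier(spec, assembly=assembly).fit(features, labels)


def predict_scores(model: CDRClassifier, features) -> np.ndarray:
    return model.predict_scores(features)


def prioritize(model: CDRClassifier, cell_id: str, cell_vec,
               drug_pool: Mapping[str, np.ndarray],
               assembly: FeatureAssembly) -> PrioritizationResult:
    """Rank every pool drug for one cell line by descending predicted score.

    Exact score ties break by ascending drug id; ranks run 1..n.
    """
    if not drug_pool:
        raise ValueError("drug pool is empty")
    drug_ids = list(drug_pool)
    X = np.vstack([assemble_features(drug_pool[d], cell_vec, assembly) for d in drug_ids])
    scores = model.predict_scores(X)
    order = sorted(range(len(drug_ids)), key=lambda i: (-scores[i], drug_ids[i]))
    ranked = [(drug_ids[i], float(scores[i]), rank)
              for rank, i in enumerate(order, start=1)]
    return PrioritizationResult(cell_id=cell_id, ranked_drugs=ranked)
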