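"""Siamese contrastive pretraining of drug and cell-line encoders.

A single encoder (twin network with shared weights) embeds both members of a
pair; a sigmoid applied to an affine transform of the Euclidean distance
between the two embeddings yields the probability that the pair comes from
different groups (label 1) rather than the same group (label 0). Binary
cross-entropy pulls same-group entities together and pushes different-group
entities apart.

Drugs are grouped by gene targets (default: sharing at least one target puts
two drugs in the same group); cell lines are grouped by cancer type. Only
drugs with at least one reported target enter pretraining.

A raw sigmoid of a nonnegative distance can never emit a probability below
0.5, so by default the distance passes through a learnable positive scale and
offset, sigma(w*d + b), initialized at (1, 0) — the literal formulation — and
freezable via ``distance_scale_learnable=False``.

A symmetric reconstruction autoencoder trained on the same features serves as
the non-contrastive baseline embedder in expressiveness comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np

from .io import DrugProfile, EmbeddingSet
from .nn import MLP, Adam, EarlyStopper, bce_loss, sigmoid


@dataclass
class PairExample:
    """One contrastive training pair; y = 1 means different groups."""

    id_a: str
    id_b: str
    x_a: np.ndarray
    x_b: np.ndarray
    y: int

    def __post_init__(self) -> None:
        if self.y not in (0, 1):
            raise ValueError("pair label must be 0 (same group) or 1 (different)")
        self.x_a = np.asarray(self.x_a, dtype=float)
        self.x_b = np.asarray(self.x_b, dtype=float)
        if self.x_a.shape != self.x_b.shape:
            raise ValueError("pair members must have equal feature lengths")


@dataclass
class EncoderConfig:
    """Architecture of an encoder twin (and of the autoencoder baseline).

    The embedding layer applies ``embedding_activation`` (default sigmoid):
    bounded positive embeddings keep the cosine-based expressiveness metrics
    well-defined — no zero vectors, nonnegative inter-group similarity — while
    leaving the contrastive geometry free to separate groups.
    """

    input_dim: int
    embedding_dim: int
    hidden_dims: tuple = (128, 64)
    dropout_rate: float = 0.2
    activation: str = "relu"
    embedding_activation: str = "sigmoid"
    distance_scale_learnable: bool = True

    def __post_init__(self) -> None:
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        if self.input_dim <= 0 or any(h <= 0 for h in self.hidden_dims):
            raise ValueError("layer dimensions must be positive")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    lr_decay_per_epoch: float = 0.99
    max_epochs: int = 100
    patience: int = 10
    pairs_per_epoch: int = 2048
    batch_size: int = 128
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if not 0 < self.lr_decay_per_epoch <= 1:
            raise ValueError("lr_decay_per_epoch must be in (0, 1]")
        for name in ("learning_rate", "max_epochs", "patience", "pairs_per_epoch", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

def same_drug_group(targets_a: Iterable[str], targets_b: Iterable[str],
                    mode: str = "any_shared", jaccard_threshold: float = 0.5) -> bool:
    """Pairwise drug-grouping relation over gene-target sets.

    ``any_shared``: same group iff the target sets intersect; ``exact``: iff
    equal; ``jaccard``: iff Jaccard similarity >= ``jaccard_threshold``.
    """
    a, b = frozenset(targets_a), frozenset(targets_b)
    if mode == "any_shared":
        return bool(a & b)
    if mode == "exact":
        return a == b
    if mode == "jaccard":
        union = a | b
        return bool(union) and len(a & b) / len(union) >= jaccard_threshold
    raise ValueError(f"unknown drug grouping mode {mode!r}")


def drug_group_key(drugs: Sequence[DrugProfile], mode: str = "any_shared",
                   jaccard_threshold: float = 0.5) -> Dict[str, int]:
    """Partition drugs into groups consistent with :func:`same_drug_group`.

    For the non-transitive modes the partition is the transitive closure
    (connected components of the pairwise relation). Drugs with no reported
    gene target are excluded with a warning, matching the pretraining rule.
    """
    usable = [d for d in drugs if d.gene_targets]
    skipped = len(drugs) - len(usable)
    if skipped:
        warnings.warn(f"{skipped} drug(s) without reported gene targets excluded from grouping")
    parent = list(range(len(usable)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            if same_drug_group(usable[i].gene_targets, usable[j].gene_targets,
                               mode, jaccard_threshold):
                parent[find(i)] = find(j)
    roots = {}
    groups = {}
    for i, d in enumerate(usable):
        r = find(i)
        groups[d.drug_id] = roots.setdefault(r, len(roots))
    return groups


def make_group_pairs(entities: Mapping[str, np.ndarray], groups: Mapping[str, object],
                     n_pairs: int, balance: float = 0.5,
                     seed: int | np.random.Generator = 0) -> list:
    """Sample labeled contrastive pairs from grouped entities.

    ``balance`` is the expected fraction of same-group pairs (y = 0). Pairs
    never repeat an entity with itself; sampling is with replacement and
    deterministic under a fixed seed. Groups of size 1 cannot supply
    same-group pairs and are warned about; a single group overall is an error.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = [i for i in entities if i in groups]
    by_group: Dict[object, list] = {}
    for i in ids:
        by_group.setdefault(groups[i], []).append(i)
    group_keys = sorted(by_group, key=repr)
    if len(group_keys) < 2:
        raise ValueError("need >= 2 groups to form contrastive pairs")
    eligible_same = [g for g in group_keys if len(by_group[g]) >= 2]
    if len(eligible_same) < len(group_keys):
        warnings.warn("singleton group(s) cannot supply same-group pairs; resampling from others")
    if not eligible_same:
        raise ValueError("no group has >= 2 members; cannot sample same-group pairs")

    pairs = []
    for _ in range(n_pairs):
        if rng.random() < balance:
            g = eligible_same[rng.integers(len(eligible_same))]
            ia, ib = rng.choice(len(by_group[g]), size=2, replace=False)
            id_a, id_b = by_group[g][ia], by_group[g][ib]
            y = 0
        else:
            ga, gb = rng.choice(len(group_keys), size=2, replace=False)
            id_a = by_group[group_keys[ga]][rng.integers(len(by_group[group_keys[ga]]))]
            id_b = by_group[group_keys[gb]][rng.integers(len(by_group[group_keys[gb]]))]
            y = 1
        pairs.append(PairExample(id_a, id_b, entities[id_a], entities[id_b], y))
    return pairs


# ---------------------------------------------------------------------------
# Siamese encoder
# ---------------------------------------------------------------------------

class SiameseEncoder:
    """Shared-weight twin encoder with a sigmoid-of-distance pair head."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator | None = None):
        self.config = config
        self.mlp = MLP([config.input_dim, *config.hidden_dims, config.embedding_dim],
                       activation=config.activation, dropout=config.dropout_rate,
                       final_activation=config.embedding_activation, rng=rng)
        # small output projection at init keeps initial pair distances inside
        # the pair head's responsive range (large d saturates the sigmoid and
        # the loss collapses every embedding toward one point)
        self.mlp.weights[-1] *= 0.1
        # w = exp(log_w) keeps the distance scale positive; (w, b) = (1, 0) at init
        self.log_w = np.zeros(1)
        self.offset = np.zeros(1)
        # per-feature standardization fitted on the training entities
        self.feat_mean = np.zeros(config.input_dim)
        self.feat_scale = np.ones(config.input_dim)

    def fit_normalizer(self, X: np.ndarray) -> None:
        self.feat_mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.feat_scale = np.where(sd > 0, sd, 1.0)

    def _normalize(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(np.asarray(x, dtype=float)) - self.feat_mean) / self.feat_scale

    @property
    def distance_scale(self) -> float:
        return float(np.exp(self.log_w[0]))

    def parameters(self):
        params = self.mlp.parameters()
        if self.config.distance_scale_learnable:
            params = params + [self.log_w, self.offset]
        return params

    def get_state(self):
        return ([p.copy() for p in self.mlp.parameters()]
                + [self.log_w.copy(), self.offset.copy(),
                   self.feat_mean.copy(), self.feat_scale.copy()])

    def set_state(self, state):
        self.mlp.set_state(state[:-4])
        self.log_w[...] = state[-4]
        self.offset[...] = state[-3]
        self.feat_mean = state[-2].copy()
        self.feat_scale = state[-1].copy()

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Embed feature rows (inference mode: dropout off)."""
        out, _ = self.mlp.forward(self._normalize(x), training=False)
        return out

    def pair_probability(self, x_a, x_b) -> np.ndarray:
        """P(different groups) = sigma(w * ||e_a - e_b|| + b)."""
        e_a = self.transform(x_a)
        e_b = self.transform(x_b)
        if e_a.shape != e_b.shape:
            raise ValueError("pair members must have equal feature lengths")
        d = np.linalg.norm(e_a - e_b, axis=1)
        return sigmoid(self.distance_scale * d + self.offset[0])

    def save(self, path) -> None:
        arrays = {f"param_{i}": p for i, p in enumerate(self.get_state())}
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path, config: EncoderConfig) -> "SiameseEncoder":
        enc = cls(config)
        data = np.load(path)
        enc.set_state([data[f"param_{i}"] for i in range(len(data.files))])
        return enc


def snn_forward(encoder: SiameseEncoder, x_a, x_b) -> np.ndarray:
    """Probability that a pair of inputs belongs to different groups."""
    return encoder.pair_probability(x_a, x_b)


def _pair_batch_arrays(pairs: Sequence[PairExample]):
    Xa = np.vstack([p.x_a for p in pairs])
    Xb = np.vstack([p.x_b for p in pairs])
    y = np.array([p.y for p in pairs], dtype=float)
    return Xa, Xb, y


def _siamese_batch_step(enc: SiameseEncoder, opt: Adam, Xa, Xb, y,
                        rng: np.random.Generator) -> float:
    e_a, cache_a = enc.mlp.forward(enc._normalize(Xa), training=True, rng=rng)
    e_b, cache_b = enc.mlp.forward(enc._normalize(Xb), training=True, rng=rng)
    diff = e_a - e_b
    d = np.linalg.norm(diff, axis=1)
    w = enc.distance_scale
    u = w * d + enc.offset[0]
    p = sigmoid(u)
    loss = bce_loss(p, y)

    n = len(y)
    dL_du = (p - y) / n
    dL_dd = dL_du * w
    unit = diff / np.maximum(d, 1e-12)[:, None]
    grad_ea = dL_dd[:, None] * unit
    gW_a, gb_a, _ = enc.mlp.backward(cache_a, grad_ea)
    gW_b, gb_b, _ = enc.mlp.backward(cache_b, -grad_ea)
    # twins share weights: accumulate both branches' gradients
    grads = [ga + gb for ga, gb in zip(gW_a, gW_b)] + [ga + gb for ga, gb in zip(gb_a, gb_b)]
    if enc.config.distance_scale_learnable:
        grads = grads + [np.array([np.sum(dL_du * d * w)]), np.array([np.sum(dL_du)])]
    opt.step(grads)
    return loss


def train_encoder(entities: Mapping[str, np.ndarray], groups: Mapping[str, object],
                  enc_cfg: EncoderConfig, train_cfg: TrainConfig):
    """Contrastively pretrain a :class:`SiameseEncoder` on grouped entities.

    Validation pairs are drawn once and frozen; each epoch resamples fresh
    training pairs, steps Adam with per-epoch exponentially decayed learning
    rate, and early-stops on validation BCE with the configured patience. The
    best-validation state is restored before returning. Returns
    ``(encoder, log)`` where ``log`` is a list of per-epoch dicts.
    """
    rng = np.random.default_rng(train_cfg.seed)
    enc = SiameseEncoder(enc_cfg, rng=rng)
    enc.fit_normalizer(np.vstack([np.asarray(v, dtype=float) for v in entities.values()]))
    opt = Adam(enc.parameters(), lr=train_cfg.learning_rate)

    n_val = max(32, int(round(train_cfg.validation_fraction * train_cfg.pairs_per_epoch)))
    val_pairs = make_group_pairs(entities, groups, n_val, seed=rng)
    Xa_v, Xb_v, y_v = _pair_batch_arrays(val_pairs)

    stopper = EarlyStopper(train_cfg.patience)
    log = []
    for epoch in range(train_cfg.max_epochs):
        lr = train_cfg.learning_rate * train_cfg.lr_decay_per_epoch**epoch
        opt.lr = lr
        train_pairs = make_group_pairs(entities, groups, train_cfg.pairs_per_epoch, seed=rng)
        Xa, Xb, y = _pair_batch_arrays(train_pairs)
        epoch_losses = []
        for start in range(0, len(y), train_cfg.batch_size):
            sl = slice(start, start + train_cfg.batch_size)
            loss = _siamese_batch_step(enc, opt, Xa[sl], Xb[sl], y[sl], rng)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            epoch_losses.append(loss)
        val_loss = bce_loss(snn_forward(enc, Xa_v, Xb_v), y_v)
        log.append({"epoch": epoch, "lr": lr,
                    "train_loss": float(np.mean(epoch_losses)),
                    "val_loss": float(val_loss), "seed": train_cfg.seed})
        if stopper.update(val_loss, enc.get_state()):
            break
    if stopper.best_state is not None:
        enc.set_state(stopper.best_state)
    return enc, log


def embed(encoder, entities: Mapping[str, np.ndarray],
          entity_kind: str = "drug") -> EmbeddingSet:
    """Embed entities (insertion order preserved) with dropout disabled."""
    ids = list(entities)
    if not ids:
        raise ValueError("no entities to embed")
    X = np.vstack([np.asarray(entities[i], dtype=float) for i in ids])
    return EmbeddingSet(entity_kind, ids, encoder.transform(X))


# ---------------------------------------------------------------------------
# Autoencoder baseline
# ---------------------------------------------------------------------------

class AutoencoderEmbedder:
    """Symmetric encoder-decoder trained on reconstruction error.

    The non-contrastive baseline: its bottleneck embeddings preserve overall
    feature variance rather than group structure, mirroring pretrained
    autoencoder cell encoders used by prior dose-response predictors. The
    bottleneck applies a continuous tanh code (the convention for
    reconstruction autoencoders — a saturating positive bottleneck would
    binarize the code and change the baseline's character); the
    reconstruction output is linear. Inputs are standardized like the Siamese
    encoder's.
    """

    def __init__(self, config: EncoderConfig, rng: np.random.Generator | None = None,
                 bottleneck_activation: str = "tanh"):
        self.config = config
        self.enc_net = MLP([config.input_dim, *config.hidden_dims, config.embedding_dim],
                           activation=config.activation, dropout=config.dropout_rate,
                           final_activation=bottleneck_activation, rng=rng)
        self.dec_net = MLP([config.embedding_dim, *reversed(config.hidden_dims),
                            config.input_dim],
                           activation=config.activation, dropout=config.dropout_rate,
                           rng=rng)
        self.feat_mean = np.zeros(config.input_dim)
        self.feat_scale = np.ones(config.input_dim)

    def fit_normalizer(self, X: np.ndarray) -> None:
        self.feat_mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.feat_scale = np.where(sd > 0, sd, 1.0)

    def _normalize(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(np.asarray(x, dtype=float)) - self.feat_mean) / self.feat_scale

    def parameters(self):
        return self.enc_net.parameters() + self.dec_net.parameters()

    def transform(self, x: np.ndarray) -> np.ndarray:
        out, _ = self.enc_net.forward(self._normalize(x), training=False)
        return out

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        out, _ = self.dec_net.forward(self.transform(x), training=False)
        return out


def train_autoencoder_baseline(entities: Mapping[str, np.ndarray],
                               enc_cfg: EncoderConfig, train_cfg: TrainConfig,
                               bottleneck_activation: str = "tanh"):
    """Train the reconstruction baseline; same determinism and early-stopping
    contract as :func:`train_encoder`. Returns ``(embedder, log)``."""
    rng = np.random.default_rng(train_cfg.seed)
    ae = AutoencoderEmbedder(enc_cfg, rng=rng,
                             bottleneck_activation=bottleneck_activation)
    opt = Adam(ae.parameters(), lr=train_cfg.learning_rate)

    X_raw = np.vstack([np.asarray(v, dtype=float) for v in entities.values()])
    ae.fit_normalizer(X_raw)
    X = (X_raw - ae.feat_mean) / ae.feat_scale
    n = len(X)
    perm = rng.permutation(n)
    n_val = max(1, int(round(train_cfg.validation_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        raise ValueError("too few entities for the configured validation fraction")

    stopper = EarlyStopper(train_cfg.patience)
    log = []
    for epoch in range(train_cfg.max_epochs):
        opt.lr = train_cfg.learning_rate * train_cfg.lr_decay_per_epoch**epoch
        order = rng.permutation(len(train_idx))
        epoch_losses = []
        for start in range(0, len(order), train_cfg.batch_size):
            batch = X[train_idx[order[start:start + train_cfg.batch_size]]]
            emb, cache_e = ae.enc_net.forward(batch, training=True, rng=rng)
            out, cache_d = ae.dec_net.forward(emb, training=True, rng=rng)
            resid = out - batch
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite reconstruction loss at epoch {epoch}")
            gW_d, gb_d, grad_emb = ae.dec_net.backward(cache_d, 2.0 * resid / resid.size)
            gW_e, gb_e, _ = ae.enc_net.backward(cache_e, grad_emb)
            opt.step(gW_e + gb_e + gW_d + gb_d)
            epoch_losses.append(loss)
        out_val, _ = ae.dec_net.forward(ae.enc_net.forward(X[val_idx], training=False)[0],
                                        training=False)
        val_loss = float(np.mean((out_val - X[val_idx])**2))
        log.append({"epoch": epoch, "lr": opt.lr,
                    "train_loss": float(np.mean(epoch_losses)),
                    "val_loss": val_loss, "seed": train_cfg.seed})
        if stopper.update(val_loss, ae.parameters()):
            break
    if stopper.best_state is not None:
        n_enc = len(ae.enc_net.parameters())
        ae.enc_net.set_state(stopper.best_state[:n_enc])
        ae.dec_net.set_state(stopper.best_state[n_enc:])
    return ae, log
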