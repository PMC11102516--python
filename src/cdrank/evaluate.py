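"""Ranking metrics, embedding expressiveness, feature importance, and model comparison.

Precision@k per cell line is the fraction of a model's top-k prioritized
drugs that are truly highly effective for that cell::

    P_cell@k(i) = |D_i(k) ∩ E_i| / k

with D_i(k) the top-k prioritized drugs and E_i the cell's effective set;
the per-cancer variant mean-pools P_cell@k over each cancer's cell lines.

Embedding expressiveness: intra-group similarity is the mean pairwise cosine
similarity within a group, inter-group similarity the mean cosine of each
member to all non-members, and their ratio is the group's separability
(1.0 means groups are indistinguishable). Reported means weight groups
equally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import CDRClassifier, FeatureAssembly
from .io import EmbeddingSet, PrioritizationResult

SIGNIFICANCE_TIERS = ((0.001, "****"), (0.01, "***"), (0.05, "**"), (0.1, "*"))


# ---------------------------------------------------------------------------
# Ranking metrics
# ---------------------------------------------------------------------------

def precision_at_k_cell(result: PrioritizationResult, effective_set, k: int) -> float:
    """|top-k ∩ effective| / k for one cell line's prioritization."""
    n = len(result.ranked_drugs)
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= pool size ({n}), got {k}")
    top = result.top_k(k)
    return len(set(top) & set(effective_set)) / k


def precision_at_k_cancer(per_cell: Mapping[str, float],
                          cancer_of: Mapping[str, str]) -> Dict[str, float]:
    """Unweighted mean of per-cell precision over each cancer's cell lines."""
    sums: Dict[str, float] = {}
    counts: Dict[str, int] = {}
    for cell, value in per_cell.items():
        if cell not in cancer_of:
            raise ValueError(f"cell '{cell}' has no cancer label")
        cancer = cancer_of[cell]
        sums[cancer] = sums.get(cancer, 0.0) + value
        counts[cancer] = counts.get(cancer, 0) + 1
    return {cancer: sums[cancer] / counts[cancer] for cancer in sums}


@dataclass
class EvalReport:
    """Per-cell and per-cancer precision@k tables plus supporting counts."""

    per_cell: pd.DataFrame          # index cell_id, columns k values
    per_cancer: pd.DataFrame        # index cancer, columns k values
    k_cell: tuple
    k_cancer: tuple
    n_effective: Dict[str, int]     # |E_i| per cell
    cells_per_cancer: Dict[str, int]

    def mean_p_cell(self, k: int) -> float:
        return float(self.per_cell[k].mean())

    def mean_p_cancer(self, k: int) -> float:
        return float(self.per_cancer[k].mean())

    def to_csv(self, cell_path, cancer_path) -> None:
        self.per_cell.to_csv(cell_path)
        self.per_cancer.to_csv(cancer_path)


def evaluate_prioritizations(results: Mapping[str, PrioritizationResult],
                             effective: Mapping[str, set],
                             cancer_of: Mapping[str, str],
                             k_cell: Sequence[int] = (1, 2, 3, 4, 5, 10),
                             k_cancer: Sequence[int] = (1, 2, 3, 4, 5)) -> EvalReport:
    """Score a set of per-cell prioritizations at each requested k."""
    all_k = sorted(set(k_cell) | set(k_cancer))
    rows = {}
    for cell, result in results.items():
        eff = effective.get(cell, set())
        rows[cell] = {k: precision_at_k_cell(result, eff, k) for k in all_k}
    per_cell = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    per_cancer_rows = {}
    for k in all_k:
        for cancer, v in precision_at_k_cancer(per_cell[k].to_dict(), cancer_of).items():
            per_cancer_rows.setdefault(cancer, {})[k] = v
    per_cancer = pd.DataFrame.from_dict(per_cancer_rows, orient="index").sort_index()
    counts: Dict[str, int] = {}
    for cell in rows:
        counts[cancer_of[cell]] = counts.get(cancer_of[cell], 0) + 1
    return EvalReport(
        per_cell=per_cell[list(sorted(set(k_cell)))],
        per_cancer=per_cancer[list(sorted(set(k_cancer)))],
        k_cell=tuple(sorted(set(k_cell))), k_cancer=tuple(sorted(set(k_cancer))),
        n_effective={c: len(effective.get(c, set())) for c in rows},
        cells_per_cancer=counts,
    )


# ---------------------------------------------------------------------------
# Embedding expressiveness
# ---------------------------------------------------------------------------

@dataclass
class SeparabilityReport:
    """Per-group intra/inter cosine similarity and their separability ratio."""

    groups: list
    intra: Dict[str, float]
    inter: Dict[str, float]
    separability: Dict[str, float]
    mean_intra: float
    mean_inter: float
    mean_separability: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": self.groups,
            "intra_similarity": [self.intra.get(g, np.nan) for g in self.groups],
            "inter_similarity": [self.inter.get(g, np.nan) for g in self.groups],
            "separability": [self.separability.get(g, np.nan) for g in self.groups],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def group_similarity(embeddings: EmbeddingSet, groups: Mapping[str, object],
                     max_separability: float = 100.0,
                     inter_floor: float = 1e-9) -> SeparabilityReport:
    """Intra-/inter-group cosine similarity and separability per group.

    Intra averages over unordered distinct within-group pairs (size-1 groups
    are skipped with a warning); inter averages each member's cosine to all
    non-members. Separability = intra / inter, capped at
    ``max_separability`` when |inter| falls below ``inter_floor``. Group means
    weight groups equally and skip undefined entries.
    """
    ids = [i for i in embeddings.ids if i in groups]
    if len({groups[i] for i in ids}) < 2:
        raise ValueError("need >= 2 groups for a separability report")
    idx = [embeddings.ids.index(i) for i in ids]
    V = embeddings.vectors[idx]
    norms = np.linalg.norm(V, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm embedding vector; cosine similarity undefined")
    U = V / norms[:, None]
    C = np.clip(U @ U.T, -1.0, 1.0)  # clamp float artifacts beyond the cosine range
    labels = np.array([repr(groups[i]) for i in ids])
    group_names = sorted(set(labels))

    intra: Dict[str, float] = {}
    inter: Dict[str, float] = {}
    sep: Dict[str, float] = {}
    for g in group_names:
        members = np.flatnonzero(labels == g)
        others = np.flatnonzero(labels != g)
        if len(members) < 2:
            warnings.warn(f"group {g} has a single member; intra similarity undefined")
        else:
            block = C[np.ix_(members, members)]
            iu = np.triu_indices(len(members), k=1)
            intra[g] = float(block[iu].mean())
        inter[g] = float(C[np.ix_(members, others)].mean())
        if g in intra:
            if abs(inter[g]) <= inter_floor:
                warnings.warn(f"group {g} inter similarity ~ 0; separability capped")
                sep[g] = max_separability
            else:
                sep[g] = intra[g] / inter[g]
    return SeparabilityReport(
        groups=group_names, intra=intra, inter=inter, separability=sep,
        mean_intra=float(np.mean(list(intra.values()))) if intra else float("nan"),
        mean_inter=float(np.mean(list(inter.values()))),
        mean_separability=float(np.mean(list(sep.values()))) if sep else float("nan"),
    )


# ---------------------------------------------------------------------------
# Feature importance
# ---------------------------------------------------------------------------

@dataclass
class ImportanceReport:
    """Min-max scaled per-feature importances tagged by drug/cell origin."""

    raw: np.ndarray
    scaled: np.ndarray
    sources: list
    method: str

    def __post_init__(self) -> None:
        if len(self.raw) != len(self.sources):
            raise ValueError("one source tag per feature required")

    def per_source_mean(self) -> Dict[str, float]:
        out: Dict[str, float] = {}
        src = np.array(self.sources)
        for s in sorted(set(self.sources)):
            out[s] = float(self.scaled[src == s].mean())
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature_index": np.arange(len(self.raw)),
            "source": self.sources,
            "raw": self.raw,
            "scaled": self.scaled,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def _permutation_importance(model: CDRClassifier, X: np.ndarray, y: np.ndarray,
                            rng: np.random.Generator) -> np.ndarray:
    """Log-loss increase when one feature column is shuffled (seeded)."""
    from sklearn.metrics import log_loss

    base = log_loss(y, model.predict_scores(X), labels=[0, 1])
    importances = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        Xp = X.copy()
        Xp[:, j] = Xp[rng.permutation(len(X)), j]
        importances[j] = max(0.0, log_loss(y, model.predict_scores(Xp), labels=[0, 1]) - base)
    return importances


def feature_importance(model: CDRClassifier, assembly: FeatureAssembly,
                       X=None, y=None, n_samples: int = 5000, seed: int = 0,
                       coef_stable: Optional[bool] = None) -> ImportanceReport:
    """Per-feature contribution to the fitted end classifier's predictions.

    Random forests report native impurity importances; logistic models the
    coefficient magnitudes (run :func:`coefficient_stability` first — pass
    ``coef_stable=True`` to silence the advisory, ``False`` to refuse); dense
    networks use seeded permutation importance over at most ``n_samples``
    training rows. All importances are min-max scaled to [0, 1] and each
    feature is tagged drug/cell by its assembly block.
    """
    if model._impl is None:
        raise RuntimeError("classifier is not fitted")
    sources = assembly.feature_sources()
    if model.kind == "random_forest":
        raw = np.asarray(model._impl.feature_importances_, dtype=float)
        method = "impurity"
    elif model.kind == "logistic":
        if coef_stable is False:
            raise ValueError("logistic coefficients flagged unstable; importance unreliable")
        if coef_stable is None:
            warnings.warn("verify coefficient_stability before trusting logistic importances")
        raw = np.abs(model._impl.coef_).ravel()
        method = "abs_coefficient"
    else:
        if X is None or y is None:
            X, y = model.X_train_, model.y_train_
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int).ravel()
        rng = np.random.default_rng(seed)
        if len(X) > n_samples:
            idx = rng.choice(len(X), size=n_samples, replace=False)
            X, y = X[idx], y[idx]
        raw = _permutation_importance(model, X, y, rng)
        method = "permutation"
    if len(raw) != len(sources):
        raise ValueError("assembly block lengths do not match model feature width")
    return ImportanceReport(raw=raw, scaled=_minmax(raw), sources=sources, method=method)


def coefficient_stability(coef_matrix, stability_ratio: float = 0.1):
    """Assess cross-fold stability of linear-model coefficients.

    ``coef_matrix`` is folds x features. Returns (mean |coef|, mean per-feature
    variance across folds, stable) where stable means the mean variance is at
    most ``stability_ratio`` times the mean magnitude.
    """
    M = np.asarray(coef_matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need a folds x features matrix with >= 2 folds")
    mean_abs = float(np.abs(M).mean())
    mean_var = float(M.var(axis=0, ddof=0).mean())
    return mean_abs, mean_var, mean_var <= stability_ratio * mean_abs


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def significance_tier(p: float) -> str:
    """Star string for a (corrected) p-value; tightest tier wins."""
    for alpha, stars in SIGNIFICANCE_TIERS:
        if p <= alpha:
            return stars
    return ""


def compare_models(metric_per_fold_a, metric_per_fold_b, n_comparisons: int = 1,
                   welch: bool = False):
    """Two-sample two-tailed t-test with Bonferroni correction.

    Pooled-variance ("independent") by default, Welch optional. Returns
    (t, raw p, corrected p, tier) where tier is the star string at
    alpha <= 0.1/0.05/0.01/0.001. Two zero-variance samples with equal means
    give p = 1 by convention.
    """
    a = np.asarray(metric_per_fold_a, dtype=float)
    b = np.asarray(metric_per_fold_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 folds per model")
    if a.var() == 0 and b.var() == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = np.inf * np.sign(a.mean() - b.mean()), 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(t), float(p)
    corrected = min(1.0, p * n_comparisons)
    return t, p, corrected, significance_tier(corrected)
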