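"""Continuous effective score (CES), label binarization, and the record-filter cascade.

The CES condenses three fitted dose-response parameters into one
effectiveness value::

    CES = log((AUC + LL + IC50) / (2 * AUC * LL * IC50))

where LL is the curve's lower viability limit. All three parameters decrease
as a drug becomes more effective, so CES increases with effectiveness; it is
symmetric in its arguments and strictly decreasing in each. Labels mark the
top decile of CES values as highly effective (label 1).

The filter cascade mirrors secondary-screen curation: drop records with
missing parameters, negative lower limits, or poorly fit curves (R^2 < 0.7);
resolve duplicate screens by preferring the designated high-quality screen id
and otherwise the best fit; then exclude withdrawn drugs and cell lines that
are unannotated, lack expression, or show almost no effective drugs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import CDRPair, CellLineProfile, DoseResponseRecord, DrugProfile

#: arguments at or below this floor are rejected (the score needs log of each)
POSITIVITY_FLOOR = 1e-12


class DomainError(ValueError):
    """A CES argument lies outside the positive domain of the score."""


@dataclass
class BinarizationRule:
    """The fitted rule that maps CES values to 0/1 effectiveness labels.

    ``empirical_quantile`` thresholds at the (default 90th) percentile of the
    observed scores; ``normal_approx`` uses mu + z*sigma with z = 1.28, the
    standard-normal deviate of the same upper decile.
    """

    mu: float
    sigma: float
    threshold: float
    method: str = "empirical_quantile"
    quantile: float = 0.90
    z: float = 1.28

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.method not in ("empirical_quantile", "normal_approx"):
            raise ValueError(f"unknown binarization method {self.method!r}")

    def apply(self, ces_values) -> np.ndarray:
        """Label 1 iff CES >= threshold (closed on the effective side)."""
        return (np.asarray(ces_values, dtype=float) >= self.threshold).astype(np.uint8)


@dataclass
class FilterReport:
    """Per-stage record counts plus a dropped-record log with reasons.

    Counts telescope: the output count of stage i is the input count of
    stage i+1.
    """

    stages: list = field(default_factory=list)  # (name, n_in, n_out)
    dropped: list = field(default_factory=list)  # dicts: stage, reason, ids

    def add_stage(self, name: str, n_in: int, n_out: int) -> None:
        if self.stages and self.stages[-1][2] != n_in:
            raise ValueError("stage counts must telescope")
        self.stages.append((name, n_in, n_out))

    def log_drop(self, stage: str, reason: str, **ids) -> None:
        self.dropped.append({"stage": stage, "reason": reason, **ids})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_in", "n_out"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# CES
# ---------------------------------------------------------------------------

def compute_ces(auc, lower_limit, ic50, base: Optional[float] = None,
                eps: float = POSITIVITY_FLOOR):
    """Continuous effective score of one (or a vector of) dose-response fits.

    Parameters must exceed the positivity floor ``eps``. ``base=None`` uses
    the natural log; pass e.g. 10 for a decimal scale (the score is then
    divided by ln(base)).
    """
    args = {"auc": auc, "lower_limit": lower_limit, "ic50": ic50}
    arrs = {}
    for name, value in args.items():
        arr = np.asarray(value, dtype=float)
        if np.any(~np.isfinite(arr)) or np.any(arr <= eps):
            raise DomainError(f"CES argument '{name}' must be finite and > {eps}")
        arrs[name] = arr
    a, b, c = arrs["auc"], arrs["lower_limit"], arrs["ic50"]
    # log of the ratio, expanded to avoid overflow of the product
    value = np.log(a + b + c) - (np.log(2.0) + np.log(a) + np.log(b) + np.log(c))
    if base is not None:
        value = value / np.log(base)
    return float(value) if np.ndim(value) == 0 else value


def binarize_scores(ces_values, method: str = "empirical_quantile",
                    quantile: float = 0.90, z: float = 1.28):
    """Binarize CES values so the top (1 - quantile) fraction is labeled 1.

    Returns ``(labels, rule)`` where ``rule`` is the fitted
    :class:`BinarizationRule` (mu, sigma and threshold populated from the
    input). ``empirical_quantile`` uses the linear-interpolation quantile;
    ``normal_approx`` uses mu + z*sigma.
    """
    values = np.asarray(ces_values, dtype=float)
    if values.size < 2 or not np.isfinite(values).all():
        raise ValueError("binarize_scores needs >= 2 finite values")
    mu = float(values.mean())
    sigma = float(values.std(ddof=0))
    if method == "empirical_quantile":
        threshold = float(np.quantile(values, quantile))
        if np.ptp(values) == 0:
            warnings.warn("all CES values identical; every pair labeled effective")
    elif method == "normal_approx":
        threshold = mu + z * sigma
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    rule = BinarizationRule(mu=mu, sigma=sigma, threshold=threshold,
                            method=method, quantile=quantile, z=z)
    return rule.apply(values), rule


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

def filter_records(records: Iterable[DoseResponseRecord], r2_min: float = 0.7,
                   eps: float = POSITIVITY_FLOOR):
    """Drop unusable dose-response records, in a fixed stage order.

    Stages: missing AUC/lower-limit/IC50; lower limit < 0; any parameter in
    (0, eps] (the score's log would diverge); R^2 < ``r2_min`` (or missing).
    Returns the retained records and a telescoping :class:`FilterReport`.
    """
    report = FilterReport()
    current = list(records)

    def run_stage(name, keep_fn, reason):
        nonlocal current
        n_in = len(current)
        kept = []
        for rec in current:
            if keep_fn(rec):
                kept.append(rec)
            else:
                report.log_drop(name, reason, drug_id=rec.drug_id,
                                cell_id=rec.cell_id, screen_id=rec.screen_id)
        report.add_stage(name, n_in, len(kept))
        current = kept

    run_stage("missing_values", lambda r: not r.has_missing_values(),
              "missing AUC, lower limit or IC50")
    run_stage("negative_lower_limit", lambda r: r.lower_limit >= 0,
              "fitted lower limit < 0")
    run_stage("nonpositive_parameter",
              lambda r: min(r.auc, r.lower_limit, r.ic50) > eps,
              f"parameter <= positivity floor {eps}")
    run_stage("r2_filter", lambda r: r.r2 is not None and r.r2 >= r2_min,
              f"curve fit R^2 < {r2_min}")
    return current, report


def resolve_duplicates(records: Sequence[DoseResponseRecord],
                       preferred_screen: str = "MTS010") -> list:
    """Keep one record per (drug, cell): the preferred screen if present,
    otherwise the highest-R^2 duplicate; R^2 ties keep the first occurrence."""
    groups: dict = {}
    order = []
    for rec in records:
        key = (rec.drug_id, rec.cell_id)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)

    def best(dups):
        pool = [r for r in dups if r.screen_id == preferred_screen] or dups
        r2s = [(-math.inf if r.r2 is None else r.r2) for r in pool]
        return pool[int(np.argmax(r2s))]  # argmax keeps first on ties

    return [best(groups[key]) for key in order]


def score_records(records: Sequence[DoseResponseRecord],
                  method: str = "empirical_quantile", quantile: float = 0.90,
                  base: Optional[float] = None):
    """Compute CES for filtered records and binarize into :class:`CDRPair` rows."""
    ces = np.array([compute_ces(r.auc, r.lower_limit, r.ic50, base=base) for r in records])
    labels, rule = binarize_scores(ces, method=method, quantile=quantile)
    pairs = [CDRPair(r.drug_id, r.cell_id, float(s), int(l))
             for r, s, l in zip(records, ces, labels)]
    return pairs, rule


def exclude_entities(pairs: Sequence[CDRPair], drugs: Sequence[DrugProfile],
                     cells: Sequence[CellLineProfile],
                     min_effective_frac: float = 0.01):
    """Remove pairs of withdrawn drugs and of disqualified cell lines.

    A cell line is disqualified when its cancer type is unknown, it lacks an
    expression profile, or fewer than ``min_effective_frac`` of its screened
    drugs are labeled effective. The effective-fraction criterion uses the
    labels already attached to ``pairs`` (one-pass semantics: the threshold is
    not recomputed after exclusion).
    """
    report = FilterReport()
    drug_map = {d.drug_id: d for d in drugs}
    cell_map = {c.cell_id: c for c in cells}
    current = list(pairs)

    n_in = len(current)
    kept = []
    for p in current:
        d = drug_map.get(p.drug_id)
        if d is not None and d.withdrawn:
            report.log_drop("withdrawn_drug", "drug previously withdrawn",
                            drug_id=p.drug_id, cell_id=p.cell_id)
        else:
            kept.append(p)
    report.add_stage("withdrawn_drug", n_in, len(kept))
    current = kept

    def cell_ok(cell_id):
        c = cell_map.get(cell_id)
        if c is None or c.expression is None:
            return "expression profile unavailable"
        if not c.cancer_type or c.cancer_type.strip().lower() == "unknown":
            return "cancer type unknown"
        return None

    n_in = len(current)
    kept = []
    for p in current:
        reason = cell_ok(p.cell_id)
        if reason is None:
            kept.append(p)
        else:
            report.log_drop("cell_annotation", reason, drug_id=p.drug_id, cell_id=p.cell_id)
    report.add_stage("cell_annotation", n_in, len(kept))
    current = kept

    eff = {}
    tot = {}
    for p in current:
        tot[p.cell_id] = tot.get(p.cell_id, 0) + 1
        eff[p.cell_id] = eff.get(p.cell_id, 0) + p.label
    bad_cells = {c for c in tot if eff.get(c, 0) / tot[c] < min_effective_frac}
    n_in = len(current)
    kept = []
    for p in current:
        if p.cell_id in bad_cells:
            report.log_drop("low_effective_fraction",
                            f"cell has < {min_effective_frac:.0%} effective drugs",
                            drug_id=p.drug_id, cell_id=p.cell_id)
        else:
            kept.append(p)
    report.add_stage("low_effective_fraction", n_in, len(kept))
    return kept, report
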