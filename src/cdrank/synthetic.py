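"""Synthetic study data: all four input tables with planted group structure.

The generator emulates a secondary-screen setting end to end:

* drugs fall into mechanism-of-action (MOA) classes; all MOA prototype
  fingerprints share one random 256-bit base, and each MOA flips its own
  dedicated ``fp_signal_bits`` bits of it — a subtle planted class signal —
  while each drug is its prototype with ``fp_noise_bits`` further random
  flips;
* cell lines fall into cancer types; every gene carries a shared positive
  baseline (log-expression scale) on top of which each cancer shifts a
  cancer-specific block of panel genes at the ``expr_signal`` scale, and each
  cell adds i.i.d. Gaussian noise;
* a latent sensitivity s = base + match(MOA, cancer) + noise links drug
  classes to cancer classes, and is mapped monotonically onto the three
  dose-response parameters (AUC, lower limit, IC50 all strictly decreasing in
  s) so the continuous effective score is strictly increasing in s;
* quality defects (low-R^2 fits, duplicate screen rows, negative lower
  limits, withdrawn drugs, unannotated cells) are planted at configurable
  rates to exercise the filter cascade.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from . import io as cio
from .io import CellLineProfile, DoseResponseRecord, DrugProfile


@dataclass
class SimConfig:
    """Study conditions for the synthetic tables.

    Defaults plant a clearly detectable but noisy signal: eight MOA classes
    of which four carry a diagonal sensitivity boost of 3 (base -2) against
    the four cancer types, fingerprints within 6 bits of their prototype,
    expression class shifts at four times the within-class noise, and a 10%
    rate of poorly fit curves. With these rates the top-decile effectiveness
    labels concentrate almost entirely inside the matched (MOA, cancer)
    blocks.
    """

    n_drugs: int = 80
    n_moas: int = 8
    targets_per_moa: int = 3
    n_bits: int = 256
    fp_signal_bits: int = 6
    fp_noise_bits: int = 6
    withdrawn_frac: float = 0.05
    n_cells: int = 80
    n_cancers: int = 4
    n_genes: int = 463
    genes_per_cancer: int = 40
    expr_baseline: tuple = (1.0, 8.0)
    expr_signal: float = 1.0
    expr_noise_sd: float = 0.25
    unknown_cancer_count: int = 2
    match_matrix: Optional[np.ndarray] = None  # MOA x cancer sensitivity boost
    match_strength: float = 3.0                # diagonal boost when match_matrix is None
    base_sensitivity: float = -2.0
    sensitivity_noise_sd: float = 0.5
    r2_low_frac: float = 0.1
    duplicate_frac: float = 0.05
    neg_lower_frac: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_drugs", "n_moas", "targets_per_moa", "n_bits",
                     "n_cells", "n_cancers", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("withdrawn_frac", "r2_low_frac", "duplicate_frac", "neg_lower_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fp_noise_bits >= self.n_bits:
            raise ValueError("fp_noise_bits must be smaller than n_bits")
        if self.n_moas * self.fp_signal_bits > self.n_bits:
            raise ValueError("not enough bits for disjoint per-MOA signal bits")
        if self.n_cancers > self.n_cells:
            raise ValueError("cannot have more cancers than cells")

    def resolved_match_matrix(self) -> np.ndarray:
        if self.match_matrix is not None:
            M = np.asarray(self.match_matrix, dtype=float)
            if M.shape != (self.n_moas, self.n_cancers):
                raise ValueError("match_matrix must be n_moas x n_cancers")
            return M
        M = np.zeros((self.n_moas, self.n_cancers))
        for i in range(min(self.n_moas, self.n_cancers)):
            M[i, i] = self.match_strength
        return M

    def gene_panel(self) -> List[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


def _rng_for(cfg: SimConfig, stream: str) -> np.random.Generator:
    # named substreams off the one config seed keep partial reruns reproducible
    offsets = {"drugs": 1, "cells": 2, "dose": 3}
    return np.random.default_rng(cfg.seed * 8 + offsets[stream])


def gen_drugs(cfg: SimConfig) -> List[DrugProfile]:
    """Drugs as MOA-prototype fingerprints with per-drug bit flips.

    Prototypes share one random base fingerprint; MOA m flips its own
    disjoint ``fp_signal_bits`` bits, so any two prototypes differ in exactly
    ``2 * fp_signal_bits`` positions.
    """
    rng = _rng_for(cfg, "drugs")
    base = rng.integers(0, 2, size=cfg.n_bits).astype(np.uint8)
    signal_bits = rng.choice(cfg.n_bits, size=cfg.n_moas * cfg.fp_signal_bits,
                             replace=False)
    prototypes = np.tile(base, (cfg.n_moas, 1))
    for m in range(cfg.n_moas):
        own = signal_bits[m * cfg.fp_signal_bits:(m + 1) * cfg.fp_signal_bits]
        prototypes[m, own] ^= 1
    target_sets = [frozenset(f"TG{m}_{t}" for t in range(cfg.targets_per_moa))
                   for m in range(cfg.n_moas)]
    n_withdrawn = int(round(cfg.withdrawn_frac * cfg.n_drugs))
    withdrawn_ids = set(rng.choice(cfg.n_drugs, size=n_withdrawn, replace=False).tolist())
    drugs = []
    for i in range(cfg.n_drugs):
        m = i % cfg.n_moas
        fp = prototypes[m].copy()
        if cfg.fp_noise_bits:
            flip = rng.choice(cfg.n_bits, size=cfg.fp_noise_bits, replace=False)
            fp[flip] ^= 1
        drugs.append(DrugProfile(
            drug_id=f"D{i:04d}", fingerprint=fp, gene_targets=target_sets[m],
            moa=f"MOA_{m}", withdrawn=i in withdrawn_ids))
    return drugs


def gen_cells(cfg: SimConfig) -> Tuple[List[CellLineProfile], List[str]]:
    """Cell lines as cancer-mean expression plus noise; returns (cells, gene panel)."""
    rng = _rng_for(cfg, "cells")
    panel = cfg.gene_panel()
    baseline = rng.uniform(cfg.expr_baseline[0], cfg.expr_baseline[1], size=cfg.n_genes)
    means = np.tile(baseline, (cfg.n_cancers, 1))
    block = min(cfg.genes_per_cancer, cfg.n_genes // cfg.n_cancers)
    for c in range(cfg.n_cancers):
        genes = slice(c * block, (c + 1) * block)
        means[c, genes] += rng.normal(0.0, cfg.expr_signal, size=block)
    cells = []
    for i in range(cfg.n_cells):
        c = i % cfg.n_cancers
        expr = means[c] + rng.normal(0.0, cfg.expr_noise_sd, size=cfg.n_genes)
        cancer = "Unknown" if i < cfg.unknown_cancer_count else f"Cancer_{c}"
        cells.append(CellLineProfile(cell_id=f"C{i:04d}", cancer_type=cancer, expression=expr))
    return cells, panel


def _moa_index(drug: DrugProfile) -> int:
    return int(drug.moa.split("_")[1])


def _cancer_index(cell: CellLineProfile) -> Optional[int]:
    if cell.cancer_type.startswith("Cancer_"):
        return int(cell.cancer_type.split("_")[1])
    return None


def latent_sensitivity(cfg: SimConfig, moa: int, cancer: Optional[int],
                       noise: float = 0.0) -> float:
    M = cfg.resolved_match_matrix()
    boost = 0.0 if cancer is None else float(M[moa, cancer])
    return cfg.base_sensitivity + boost + noise


def curve_params_from_sensitivity(s: float) -> Tuple[float, float, float]:
    """Monotone map from latent sensitivity to (auc, lower_limit, ic50).

    All three outputs strictly decrease in s, so the effective score strictly
    increases in s. The transforms are fixed so oracle expectations stay
    closed-form: auc = 1/(1+e^s), lower_limit = 0.01 + 0.99/(1+e^s),
    ic50 = e^{-s}.
    """
    logistic = 1.0 / (1.0 + np.exp(s))
    return float(logistic), float(0.01 + 0.99 * logistic), float(np.exp(-s))


def gen_dose_response(drugs: List[DrugProfile], cells: List[CellLineProfile],
                      cfg: SimConfig) -> List[DoseResponseRecord]:
    """One fitted-curve record per drug-cell pair, plus planted defects."""
    rng = _rng_for(cfg, "dose")
    records = []
    for cell in cells:
        cancer = _cancer_index(cell)
        for drug in drugs:
            s = latent_sensitivity(cfg, _moa_index(drug), cancer,
                                   noise=rng.normal(0.0, cfg.sensitivity_noise_sd))
            auc, lower, ic50 = curve_params_from_sensitivity(s)
            if rng.random() < cfg.neg_lower_frac:
                lower = -lower
            r2 = (rng.uniform(0.30, 0.69) if rng.random() < cfg.r2_low_frac
                  else rng.uniform(0.75, 0.99))
            records.append(DoseResponseRecord(drug.drug_id, cell.cell_id,
                                              auc, lower, ic50, r2, "MTS010"))
            if rng.random() < cfg.duplicate_frac:
                # a second, lower-quality screen of the same pair
                s2 = s + rng.normal(0.0, cfg.sensitivity_noise_sd)
                a2, l2, i2 = curve_params_from_sensitivity(s2)
                records.append(DoseResponseRecord(drug.drug_id, cell.cell_id,
                                                  a2, l2, i2,
                                                  rng.uniform(0.70, 0.95), "MTS005"))
    return records


def generate(cfg: SimConfig):
    """Generate all tables: (drugs, cells, gene_panel, dose_response_records)."""
    drugs = gen_drugs(cfg)
    cells, panel = gen_cells(cfg)
    records = gen_dose_response(drugs, cells, cfg)
    return drugs, cells, panel, records


def write_tables(cfg: SimConfig, outdir) -> dict:
    """Generate and write the four CSV inputs plus a manifest; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    drugs, cells, panel, records = generate(cfg)
    paths = {
        "dose_response": outdir / "dose_response.csv",
        "drugs": outdir / "drugs.csv",
        "cells": outdir / "cells.csv",
        "expression": outdir / "expression.csv",
        "gene_panel": outdir / "gene_panel.txt",
        "manifest": outdir / "manifest.json",
    }
    cio.write_dose_response(records, paths["dose_response"])
    cio.write_drug_metadata(drugs, paths["drugs"])
    cio.write_cell_metadata(cells, paths["cells"])
    cio.write_expression(cells, panel, paths["expression"])
    cio.write_gene_panel(panel, paths["gene_panel"])
    cfg_dict = asdict(cfg)
    if cfg_dict.get("match_matrix") is not None:
        cfg_dict["match_matrix"] = np.asarray(cfg_dict["match_matrix"]).tolist()
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump({"config": cfg_dict}, fh, indent=2)
    return {k: str(v) for k, v in paths.items()}
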