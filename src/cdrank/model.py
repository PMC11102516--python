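"""End-to-end prioritization pipeline as a model/results pair.

:class:`DrugResponsePrioritizer` is built from the four input tables (dose
response, drug metadata, cell metadata + expression). ``fit()`` runs the full
pipeline — filter cascade, effective-score labeling, cancer-stratified
splitting, contrastive pretraining of both encoders, end-classifier training
on the cross-validation folds — and returns a
:class:`PrioritizationResults` carrying per-cell drug rankings on the held-out
cells, precision@k tables, embedding-separability reports and a ``summary()``
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from . import classify, contrastive, evaluate, scoring, splits
from .io import CellLineProfile, DrugProfile, PrioritizationResult


@dataclass
class PipelineConfig:
    """Tunable knobs of the full pipeline, with screening-study defaults."""

    r2_min: float = 0.7
    preferred_screen: str = "MTS010"
    binarize_method: str = "empirical_quantile"
    quantile: float = 0.90
    min_effective_frac: float = 0.01
    drug_repr: str = "embedding"        # {"fingerprint", "embedding"}
    cell_repr: str = "embedding"        # {"expression", "embedding"}
    classifier: str = "random_forest"
    classifier_hyperparameters: dict = field(default_factory=dict)
    drug_embedding_dim: int = 64
    cell_embedding_dim: int = 32
    hidden_dims: tuple = (128, 64)
    encoder_epochs: int = 40
    pairs_per_epoch: int = 1024
    test_frac: float = 0.15
    novel_min: int = 15
    k_folds: int = 5
    k_cell: tuple = (1, 2, 3, 4, 5, 10)
    k_cancer: tuple = (1, 2, 3, 4, 5)


class PrioritizationResults:
    """Fitted pipeline state: rankings, metrics, embeddings, diagnostics."""

    def __init__(self, *, config, seed, rule, filter_report, exclusion_report,
                 pairs, split_plan, drug_embeddings, cell_embeddings,
                 drug_separability, cell_separability, classifier,
                 prioritizations, eval_report, prevalence, assembly,
                 encoder_logs):
        self.config = config
        self.seed = seed
        self.rule = rule
        self.filter_report = filter_report
        self.exclusion_report = exclusion_report
        self.pairs = pairs
        self.split_plan = split_plan
        self.drug_embeddings = drug_embeddings
        self.cell_embeddings = cell_embeddings
        self.drug_separability = drug_separability
        self.cell_separability = cell_separability
        self.classifier = classifier
        self.prioritizations: Dict[str, PrioritizationResult] = prioritizations
        self.eval_report = eval_report
        self.prevalence = prevalence
        self.assembly = assembly
        self.encoder_logs = encoder_logs

    def mean_p_cell(self, k: int) -> float:
        return self.eval_report.mean_p_cell(k)

    def mean_p_cancer(self, k: int) -> float:
        return self.eval_report.mean_p_cancer(k)

    def summary(self) -> str:
        lines = [
            "Drug-response prioritization results",
            "=" * 52,
            f"retained pairs:          {len(self.pairs)}",
            f"effective-label rate:    {self.prevalence:.4f}",
            f"CES threshold:           {self.rule.threshold:.4f} ({self.rule.method})",
            f"cells (train/test/novel): "
            f"{len(self.split_plan.training_cells)}/"
            f"{len(self.split_plan.trained_on_test)}/{len(self.split_plan.novel_test)}",
            f"classifier:              {self.config.classifier} "
            f"({self.config.drug_repr} drug x {self.config.cell_repr} cell)",
            "",
            "precision@k on trained-on test cells",
        ]
        for k in self.eval_report.k_cell:
            lines.append(f"  P_cell@{k:<3d} = {self.mean_p_cell(k):.4f}")
        for k in self.eval_report.k_cancer:
            lines.append(f"  P_cancer@{k:<2d} = {self.mean_p_cancer(k):.4f}")
        if self.drug_separability is not None:
            lines.append("")
            lines.append(f"drug embedding separability (by MOA):    "
                         f"{self.drug_separability.mean_separability:.3f}")
        if self.cell_separability is not None:
            lines.append(f"cell embedding separability (by cancer): "
                         f"{self.cell_separability.mean_separability:.3f}")
        return "\n".join(lines)


class DrugResponsePrioritizer:
    """The pipeline model, built from parsed input tables."""

    def __init__(self, records, drugs: Sequence[DrugProfile],
                 cells: Sequence[CellLineProfile],
                 config: Optional[PipelineConfig] = None):
        self.records = list(records)
        self.drugs = list(drugs)
        self.cells = list(cells)
        self.config = config or PipelineConfig()

    @classmethod
    def from_tables(cls, dose_response_path, drug_path, cell_path,
                    expression_path, gene_panel_path,
                    config: Optional[PipelineConfig] = None) -> "DrugResponsePrioritizer":
        from . import io as cio
        records = cio.read_dose_response(dose_response_path)
        drugs = cio.read_drug_metadata(drug_path)
        cancer_of = cio.read_cell_metadata(cell_path)
        panel = cio.read_gene_panel(gene_panel_path)
        cells = cio.read_expression(expression_path, panel)
        for c in cells:
            c.cancer_type = cancer_of.get(c.cell_id, "")
        return cls(records, drugs, cells, config=config)

    # -- pipeline stages -----------------------------------------------------

    def _score_and_filter(self):
        cfg = self.config
        filtered, filter_report = scoring.filter_records(self.records, r2_min=cfg.r2_min)
        deduped = scoring.resolve_duplicates(filtered, preferred_screen=cfg.preferred_screen)
        pairs, rule = scoring.score_records(deduped, method=cfg.binarize_method,
                                            quantile=cfg.quantile)
        pairs, exclusion_report = scoring.exclude_entities(
            pairs, self.drugs, self.cells, min_effective_frac=cfg.min_effective_frac)
        return pairs, rule, filter_report, exclusion_report

    def _train_encoders(self, pairs, split_plan, seed):
        cfg = self.config
        drug_map = {d.drug_id: d for d in self.drugs}
        cell_map = {c.cell_id: c for c in self.cells}
        pair_drugs = sorted({p.drug_id for p in pairs})
        pair_cells = sorted({p.cell_id for p in pairs})

        drug_feats = {d: drug_map[d].fingerprint.astype(float) for d in pair_drugs}
        cell_feats = {c: cell_map[c].expression for c in pair_cells}

        logs = {}
        drug_emb = None
        if cfg.drug_repr == "embedding":
            groups = contrastive.drug_group_key([drug_map[d] for d in pair_drugs])
            enc_cfg = contrastive.EncoderConfig(
                input_dim=len(next(iter(drug_feats.values()))),
                embedding_dim=cfg.drug_embedding_dim, hidden_dims=cfg.hidden_dims)
            tr_cfg = contrastive.TrainConfig(max_epochs=cfg.encoder_epochs,
                                             pairs_per_epoch=cfg.pairs_per_epoch,
                                             seed=seed * 4 + 1)
            enc, logs["drug"] = contrastive.train_encoder(drug_feats, groups, enc_cfg, tr_cfg)
            drug_emb = contrastive.embed(enc, drug_feats, "drug")

        cell_emb = None
        if cfg.cell_repr == "embedding":
            # pretrain the cell encoder on training-compartment cells only,
            # then embed every cell with the frozen encoder
            train_cells = {c: cell_feats[c] for c in pair_cells
                           if c in split_plan.training_cells}
            groups = {c: cell_map[c].cancer_type for c in train_cells}
            enc_cfg = contrastive.EncoderConfig(
                input_dim=len(next(iter(cell_feats.values()))),
                embedding_dim=cfg.cell_embedding_dim, hidden_dims=cfg.hidden_dims)
            tr_cfg = contrastive.TrainConfig(max_epochs=cfg.encoder_epochs,
                                             pairs_per_epoch=cfg.pairs_per_epoch,
                                             seed=seed * 4 + 2)
            enc, logs["cell"] = contrastive.train_encoder(train_cells, groups, enc_cfg, tr_cfg)
            cell_emb = contrastive.embed(enc, cell_feats, "cell")

        drug_vecs = (drug_emb.as_dict() if drug_emb is not None else drug_feats)
        cell_vecs = (cell_emb.as_dict() if cell_emb is not None else cell_feats)
        return drug_vecs, cell_vecs, drug_emb, cell_emb, logs

    def fit(self, seed: int = 0) -> PrioritizationResults:
        cfg = self.config
        pairs, rule, filter_report, exclusion_report = self._score_and_filter()
        prevalence = float(np.mean([p.label for p in pairs]))

        cell_map = {c.cell_id: c for c in self.cells}
        retained_cells = [cell_map[c] for c in sorted({p.cell_id for p in pairs})]
        split_plan = splits.make_split(retained_cells, test_frac=cfg.test_frac,
                                       novel_min=cfg.novel_min, k=cfg.k_folds, seed=seed)

        drug_vecs, cell_vecs, drug_emb, cell_emb, enc_logs = self._train_encoders(
            pairs, split_plan, seed)

        assembly = classify.FeatureAssembly(
            drug_repr=cfg.drug_repr, cell_repr=cfg.cell_repr, combine="concat",
            drug_block_len=len(next(iter(drug_vecs.values()))),
            cell_block_len=len(next(iter(cell_vecs.values()))))

        train_pairs = [p for p in pairs if p.cell_id in split_plan.training_cells]
        X = np.vstack([classify.assemble_features(drug_vecs[p.drug_id],
                                                  cell_vecs[p.cell_id], assembly)
                       for p in train_pairs])
        y = np.array([p.label for p in train_pairs])
        spec = classify.ClassifierSpec(kind=cfg.classifier,
                                       hyperparameters=dict(cfg.classifier_hyperparameters),
                                       seed=seed * 4 + 3)
        model = classify.train_classifier(X, y, spec, assembly=assembly)

        test_cells = sorted(split_plan.trained_on_test)
        prioritizations = {c: classify.prioritize(model, c, cell_vecs[c], drug_vecs, assembly)
                           for c in test_cells}
        effective = {c: set() for c in test_cells}
        for p in pairs:
            if p.label and p.cell_id in effective:
                effective[p.cell_id].add(p.drug_id)
        cancer_of = {c: cell_map[c].cancer_type for c in test_cells}
        k_cell = tuple(k for k in cfg.k_cell if k <= len(drug_vecs))
        k_cancer = tuple(k for k in cfg.k_cancer if k <= len(drug_vecs))
        eval_report = evaluate.evaluate_prioritizations(
            prioritizations, effective, cancer_of, k_cell=k_cell, k_cancer=k_cancer)

        drug_sep = cell_sep = None
        if drug_emb is not None:
            moa_of = {d.drug_id: d.moa for d in self.drugs
                      if d.moa and d.drug_id in drug_emb.ids}
            if len(set(moa_of.values())) >= 2:
                drug_sep = evaluate.group_similarity(drug_emb, moa_of)
        if cell_emb is not None:
            cancer_all = {c.cell_id: c.cancer_type for c in retained_cells}
            if len(set(cancer_all.values())) >= 2:
                cell_sep = evaluate.group_similarity(cell_emb, cancer_all)

        return PrioritizationResults(
            config=cfg, seed=seed, rule=rule, filter_report=filter_report,
            exclusion_report=exclusion_report, pairs=pairs, split_plan=split_plan,
            drug_embeddings=drug_emb, cell_embeddings=cell_emb,
            drug_separability=drug_sep, cell_separability=cell_sep,
            classifier=model, prioritizations=prioritizations,
            eval_report=eval_report, prevalence=prevalence, assembly=assembly,
            encoder_logs=enc_logs)
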