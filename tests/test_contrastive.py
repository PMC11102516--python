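"""Siamese pretraining: grouping, pair sampling, twin forward pass, training."""

import numpy as np
import pytest

from cdrank import contrastive
from cdrank.contrastive import (
    EncoderConfig,
    SiameseEncoder,
    TrainConfig,
    drug_group_key,
    embed,
    make_group_pairs,
    same_drug_group,
    snn_forward,
    train_autoencoder_baseline,
    train_encoder,
)
from cdrank.io import DrugProfile


def _two_cluster_entities(n_per=8, dim=12, gap=4.0, seed=0):
    rng = np.random.default_rng(seed)
    entities, groups = {}, {}
    for g in range(2):
        center = np.full(dim, g * gap)
        for i in range(n_per):
            eid = f"g{g}_{i}"
            entities[eid] = center + rng.normal(scale=0.3, size=dim)
            groups[eid] = g
    return entities, groups


class TestGrouping:
    @pytest.mark.parametrize("a,b,mode,expected", [
        ({"EGFR"}, {"EGFR", "ERBB2"}, "any_shared", True),
        ({"EGFR"}, {"TOP1"}, "any_shared", False),
        ({"EGFR"}, {"TOP1"}, "exact", False),
        ({"EGFR"}, {"EGFR"}, "exact", True),
        ({"EGFR"}, {"EGFR", "ERBB2"}, "exact", False),
        ({"A", "B"}, {"A", "B", "C"}, "jaccard", True),   # 2/3 >= 0.5
        ({"A"}, {"A", "B", "C"}, "jaccard", False),       # 1/3 < 0.5
    ])
    def test_pairwise_relation(self, a, b, mode, expected):
        assert same_drug_group(a, b, mode) is expected

    def test_partition_matches_disjoint_target_sets(self):
        drugs = [DrugProfile(f"d{i}", gene_targets={f"T{i % 3}"}) for i in range(9)]
        groups = drug_group_key(drugs)
        assert len(set(groups.values())) == 3
        assert groups["d0"] == groups["d3"] == groups["d6"]

    def test_untargeted_drugs_excluded_with_warning(self):
        drugs = [DrugProfile("d0", gene_targets={"A"}),
                 DrugProfile("d1", gene_targets={"B"}),
                 DrugProfile("d2")]
        with pytest.warns(UserWarning, match="without reported gene targets"):
            groups = drug_group_key(drugs)
        assert "d2" not in groups


class TestMakeGroupPairs:
    def test_contract_on_two_groups(self):
        entities, groups = _two_cluster_entities(n_per=3)
        pairs = make_group_pairs(entities, groups, 100, balance=0.5, seed=5)
        assert len(pairs) == 100
        assert all(p.id_a != p.id_b for p in pairs)
        same_frac = np.mean([p.y == 0 for p in pairs])
        assert 0.35 < same_frac < 0.65  # binomial noise around 0.5
        for p in pairs:
            assert (groups[p.id_a] == groups[p.id_b]) == (p.y == 0)

    def test_single_group_is_error(self):
        entities = {"a": np.zeros(2), "b": np.ones(2)}
        with pytest.raises(ValueError, match="2 groups"):
            make_group_pairs(entities, {"a": 0, "b": 0}, 10)

    def test_deterministic_under_seed(self):
        entities, groups = _two_cluster_entities()
        p1 = make_group_pairs(entities, groups, 50, seed=9)
        p2 = make_group_pairs(entities, groups, 50, seed=9)
        assert [(p.id_a, p.id_b, p.y) for p in p1] == [(p.id_a, p.id_b, p.y) for p in p2]

    def test_singleton_group_warns_and_resamples(self):
        entities = {"a": np.zeros(2), "b": np.ones(2), "c": np.ones(2) * 2}
        groups = {"a": 0, "b": 0, "c": 1}
        with pytest.warns(UserWarning, match="singleton"):
            pairs = make_group_pairs(entities, groups, 30, seed=1)
        same = [p for p in pairs if p.y == 0]
        assert all({p.id_a, p.id_b} == {"a", "b"} for p in same)


class TestSnnForward:
    def test_identical_inputs_give_half_at_init(self):
        enc = SiameseEncoder(EncoderConfig(input_dim=6, embedding_dim=4),
                             rng=np.random.default_rng(0))
        x = np.ones(6)
        assert snn_forward(enc, x, x)[0] == pytest.approx(0.5)

    def test_output_in_open_unit_interval_and_monotone(self):
        cfg = EncoderConfig(input_dim=6, embedding_dim=4, distance_scale_learnable=False)
        enc = SiameseEncoder(cfg, rng=np.random.default_rng(1))
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 6))
        Y = rng.normal(size=(20, 6))
        p = snn_forward(enc, X, Y)
        assert np.all((p > 0) & (p < 1))
        # with frozen (w, b) = (1, 0), p is strictly increasing in the distance
        d = np.linalg.norm(enc.transform(X) - enc.transform(Y), axis=1)
        order = np.argsort(d)
        assert np.all(np.diff(p[order]) >= 0)
        assert p[order[-1]] > p[order[0]]

    def test_dimension_mismatch_raises(self):
        enc = SiameseEncoder(EncoderConfig(input_dim=6, embedding_dim=4))
        with pytest.raises(ValueError):
            snn_forward(enc, np.ones(5), np.ones(5))

    def test_twins_share_weights_bitwise(self):
        enc = SiameseEncoder(EncoderConfig(input_dim=6, embedding_dim=4),
                             rng=np.random.default_rng(3))
        x = np.random.default_rng(4).normal(size=(3, 6))
        np.testing.assert_array_equal(enc.transform(x), enc.transform(x))


class TestTrainEncoder:
    def _cfgs(self, input_dim, **train_kw):
        enc_cfg = EncoderConfig(input_dim=input_dim, embedding_dim=4,
                                hidden_dims=(16,), dropout_rate=0.1)
        defaults = dict(max_epochs=30, pairs_per_epoch=128, batch_size=32, seed=11)
        defaults.update(train_kw)
        return enc_cfg, TrainConfig(**defaults)

    def test_validation_loss_improves_on_separable_groups(self):
        entities, groups = _two_cluster_entities()
        enc_cfg, tr_cfg = self._cfgs(12)
        _, log = train_encoder(entities, groups, enc_cfg, tr_cfg)
        assert min(l["val_loss"] for l in log) < log[0]["val_loss"]

    def test_early_stopping_restores_best_state(self):
        entities, groups = _two_cluster_entities()
        enc_cfg, tr_cfg = self._cfgs(12, max_epochs=60, patience=3)
        enc, log = train_encoder(entities, groups, enc_cfg, tr_cfg)
        best = min(l["val_loss"] for l in log)
        # recompute validation loss of the returned state on the frozen pairs
        rng = np.random.default_rng(tr_cfg.seed)
        SiameseEncoder(enc_cfg, rng=rng)  # consume init stream as training did
        val_pairs = contrastive.make_group_pairs(
            entities, groups,
            max(32, int(round(tr_cfg.validation_fraction * tr_cfg.pairs_per_epoch))),
            seed=rng)
        Xa = np.vstack([p.x_a for p in val_pairs])
        Xb = np.vstack([p.x_b for p in val_pairs])
        y = np.array([p.y for p in val_pairs], dtype=float)
        from cdrank.nn import bce_loss
        assert bce_loss(snn_forward(enc, Xa, Xb), y) == pytest.approx(best, rel=1e-9)

    def test_same_seed_identical_weights(self):
        entities, groups = _two_cluster_entities()
        enc_cfg, tr_cfg = self._cfgs(12, max_epochs=10)
        e1, _ = train_encoder(entities, groups, enc_cfg, tr_cfg)
        e2, _ = train_encoder(entities, groups, enc_cfg, tr_cfg)
        for a, b in zip(e1.get_state(), e2.get_state()):
            np.testing.assert_array_equal(a, b)

    def test_trained_encoder_contracts_within_group_distances(self):
        entities, groups = _two_cluster_entities(gap=6.0)
        enc_cfg, tr_cfg = self._cfgs(12, max_epochs=40)
        enc, _ = train_encoder(entities, groups, enc_cfg, tr_cfg)
        emb = embed(enc, entities, "drug")
        V = emb.vectors
        ids = emb.ids
        same_d, diff_d = [], []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                d = np.linalg.norm(V[i] - V[j])
                (same_d if groups[ids[i]] == groups[ids[j]] else diff_d).append(d)
        assert np.mean(same_d) < np.mean(diff_d)


class TestEmbed:
    def test_shape_and_duplicate_rows(self):
        enc = SiameseEncoder(EncoderConfig(input_dim=5, embedding_dim=3),
                             rng=np.random.default_rng(0))
        entities = {"a": np.ones(5), "b": np.ones(5), "c": np.zeros(5)}
        emb = embed(enc, entities, "drug")
        assert emb.vectors.shape == (3, 3)
        np.testing.assert_array_equal(emb.vector("a"), emb.vector("b"))

    def test_unseen_entity_embeds(self):
        entities, groups = _two_cluster_entities()
        enc_cfg = EncoderConfig(input_dim=12, embedding_dim=4, hidden_dims=(16,))
        enc, _ = train_encoder(entities, groups, enc_cfg,
                               TrainConfig(max_epochs=5, pairs_per_epoch=64, seed=0))
        novel = np.random.default_rng(99).normal(size=12)
        out = enc.transform(novel)
        assert out.shape == (1, 4) and np.isfinite(out).all()


class TestAutoencoder:
    def test_reconstruction_error_decreases(self):
        entities, _ = _two_cluster_entities(n_per=12)
        enc_cfg = EncoderConfig(input_dim=12, embedding_dim=4, hidden_dims=(16,),
                                dropout_rate=0.0)
        _, log = train_autoencoder_baseline(
            entities, enc_cfg, TrainConfig(max_epochs=40, pairs_per_epoch=64,
                                           batch_size=8, seed=2))
        assert min(l["val_loss"] for l in log) < log[0]["val_loss"]

    def test_same_seed_identical_embeddings(self):
        entities, _ = _two_cluster_entities()
        enc_cfg = EncoderConfig(input_dim=12, embedding_dim=4, hidden_dims=(8,))
        tr = TrainConfig(max_epochs=5, pairs_per_epoch=64, batch_size=8, seed=3)
        a1, _ = train_autoencoder_baseline(entities, enc_cfg, tr)
        a2, _ = train_autoencoder_baseline(entities, enc_cfg, tr)
        X = np.vstack(list(entities.values()))
        np.testing.assert_array_equal(a1.transform(X), a2.transform(X))

    def test_wide_linear_bottleneck_reconstructs_well(self):
        # identity limit: bottleneck as wide as the input, linear activations
        rng = np.random.default_rng(5)
        entities = {f"e{i}": rng.normal(size=6) for i in range(40)}
        enc_cfg = EncoderConfig(input_dim=6, embedding_dim=6, hidden_dims=(12,),
                                dropout_rate=0.0, activation="linear")
        ae, log = train_autoencoder_baseline(
            entities, enc_cfg,
            TrainConfig(max_epochs=400, pairs_per_epoch=64, batch_size=8,
                        learning_rate=1e-2, patience=400, seed=6),
            bottleneck_activation="linear",
        )
        assert min(l["val_loss"] for l in log) < 1e-4  # vs unit input variance
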