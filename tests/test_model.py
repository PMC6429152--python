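"""Architecture census, training-protocol contracts, persistence."""

import numpy as np
import pytest

import rpinet as rp
from rpinet import nn
from rpinet.model import (ModelError, ModuleConfig, PairFeatures,
                          build_cnn_module, build_ensemble_head,
                          build_sae_module, fit_network, pretrain_sae,
                          train_module)


def _dense_out_widths(seq):
    return [l.W.shape[1] for l in seq.layers if isinstance(l, nn.Dense)]


class TestArchitectureCensus:
    def test_cnn_branch_has_three_convs_with_published_filters(self):
        m = build_cnn_module(ModuleConfig(), 340, 399)
        for branch in (m.net.branch_rna, m.net.branch_protein):
            convs = [l for l in branch.layers if isinstance(l, nn.Conv1D)]
            assert [c.W.shape[2] for c in convs] == [45, 64, 45]
            pools = [l for l in branch.layers if isinstance(l, nn.MaxPool1D)]
            assert len(pools) == 2  # pooling between consecutive convolutions

    def test_sae_branch_widths(self):
        m = build_sae_module(ModuleConfig(), 370, 438, use_structure=True)
        for branch in (m.net.branch_rna, m.net.branch_protein):
            assert _dense_out_widths(branch) == [256, 128, 64]

    def test_prediction_head_widths(self):
        m = build_cnn_module(ModuleConfig(), 340, 399)
        assert _dense_out_widths(m.net.head) == [128, 64, 2]

    def test_ensemble_head_is_dense_16_8_2_over_8_inputs(self):
        head = build_ensemble_head(ModuleConfig())
        dense = [l for l in head.layers if isinstance(l, nn.Dense)]
        assert dense[0].W.shape[0] == 8
        assert [d.W.shape[1] for d in dense] == [16, 8, 2]


class TestForwardContracts:
    @pytest.mark.parametrize("builder,dims", [
        (build_cnn_module, (340, 399)),
        (build_sae_module, (370, 438)),
    ])
    def test_softmax_probabilities(self, builder, dims, rng):
        m = builder(ModuleConfig(seed=2), *dims)
        xr = rng.random((5, dims[0]))
        xp = rng.random((5, dims[1]))
        probs = m.predict_proba(xr, xp)
        assert probs.shape == (5, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.isfinite(probs).all() and (probs >= 0).all()

    def test_inference_is_deterministic(self, rng):
        m = build_sae_module(ModuleConfig(seed=3), 340, 399)
        xr, xp = rng.random((4, 340)), rng.random((4, 399))
        np.testing.assert_array_equal(m.predict_proba(xr, xp),
                                      m.predict_proba(xr, xp))

    def test_dimension_mismatch_rejected(self, rng):
        m = build_cnn_module(ModuleConfig(), 340, 399)
        with pytest.raises(ModelError):
            m.predict_proba(rng.random((2, 370)), rng.random((2, 399)))

    def test_untrained_module_is_a_null_model(self, rng):
        # balanced random batches: accuracy should hover near chance
        accs = []
        for seed in range(30):
            m = build_sae_module(ModuleConfig(seed=seed), 50, 60)
            xr, xp = rng.random((40, 50)), rng.random((40, 60))
            labels = np.array([0, 1] * 20)
            probs = m.predict_proba(xr, xp)
            accs.append(((probs[:, 1] >= 0.5).astype(int) == labels).mean())
        # binomial bounds: mean of 30x40 Bernoulli(0.5) draws
        assert 0.4 <= np.mean(accs) <= 0.6


class TestEarlyStopping:
    def _toy(self, rng, n=40, d=6):
        x = rng.standard_normal((n, d)).astype(np.float32)
        labels = rng.integers(0, 2, size=n)
        return x, labels

    def test_zero_lr_stops_after_exactly_patience_epochs(self, rng):
        x, labels = self._toy(rng)
        net = nn.Sequential([nn.Dense(6, 2, np.random.default_rng(0))])
        config = ModuleConfig(adam_lr=0.0, sgd_lr=0.0, patience=1,
                              max_epochs_adam=10, max_epochs_sgd=10,
                              batch_size=16)
        report = fit_network(net, lambda idx: x[idx], len(labels), labels,
                             config, np.random.default_rng(1))
        # epoch 1 improves on -inf; epoch 2 cannot improve -> stop
        assert len(report.accuracies) == 2
        assert report.stopped_early
        assert report.best_epoch == 0
        assert report.optimizer_phases == [("adam", 2)]

    def test_best_checkpoint_restored(self, rng):
        x, labels = self._toy(rng, n=60)
        net = nn.Sequential([nn.Dense(6, 8, np.random.default_rng(2)), nn.ReLU(),
                             nn.Dense(8, 2, np.random.default_rng(3))])
        config = ModuleConfig(adam_lr=0.05, patience=3, max_epochs_adam=8,
                              max_epochs_sgd=2, batch_size=16)
        report = fit_network(net, lambda idx: x[idx], len(labels), labels,
                             config, np.random.default_rng(4))
        assert report.accuracies[report.best_epoch] == max(report.accuracies)
        logits = net.forward(x, training=False)
        acc_now = float((logits.argmax(axis=1) == labels).mean())
        assert acc_now == pytest.approx(report.accuracies[report.best_epoch])

    def test_single_class_training_rejected(self, small_dataset, small_features,
                                            fast_config):
        m = build_sae_module(fast_config, *small_features.dims(False))
        with pytest.raises(ModelError, match="single class"):
            train_module(m, small_dataset.positives, small_features, fast_config)


class TestSAEPretraining:
    def test_reconstruction_error_decreases_per_layer(self, small_features,
                                                      fast_config):
        m = build_sae_module(fast_config, *small_features.dims(False))
        pretrain_sae(m, small_features.entity_matrix("rna", False),
                     small_features.entity_matrix("protein", False))
        assert len(m.pretraining_log) == 2
        for branch_log in m.pretraining_log:
            assert len(branch_log["layers"]) == 3
            for layer_log in branch_log["layers"]:
                assert layer_log["final_mse"] <= layer_log["initial_mse"]

    def test_rank_one_input_reconstructed_nearly_perfectly(self, rng):
        config = ModuleConfig(sae_pretrain_epochs=80, adam_lr=0.01,
                              standardize=False, seed=6)
        m = build_sae_module(config, 20, 25)
        row_r = rng.random(20).astype(np.float32)
        row_p = rng.random(25).astype(np.float32)
        pretrain_sae(m, np.tile(row_r, (50, 1)), np.tile(row_p, (50, 1)))
        first_layer = m.pretraining_log[0]["layers"][0]
        assert first_layer["final_mse"] < 1e-3

    def test_requires_sae_module(self, small_features, fast_config):
        m = build_cnn_module(fast_config, *small_features.dims(False))
        with pytest.raises(ModelError):
            pretrain_sae(m, np.ones((3, 340)), np.ones((3, 399)))


class TestEnsembleAndFreezing:
    def test_head_training_leaves_modules_bit_identical(self, small_dataset,
                                                        small_features,
                                                        fast_config):
        from rpinet.model import EnsembleModel

        modules = []
        for kind, use_structure in [("cnn", False), ("sae", False),
                                    ("cnn", True), ("sae", True)]:
            builder = build_cnn_module if kind == "cnn" else build_sae_module
            m = builder(fast_config, *small_features.dims(use_structure),
                        use_structure=use_structure)
            train_module(m, small_dataset.pairs, small_features, fast_config)
            modules.append(m)
        snapshots = [nn.snapshot_params(m.net) for m in modules]
        head = build_ensemble_head(fast_config)
        ensemble = EnsembleModel(modules, head, fast_config)
        x = ensemble.module_outputs(small_dataset.pairs, small_features)
        labels = np.array([p.label for p in small_dataset.pairs])
        fit_network(head, lambda idx: x[idx], len(labels), labels, fast_config,
                    np.random.default_rng(0))
        for module, snap in zip(modules, snapshots):
            for p, s in zip(nn.snapshot_params(module.net), snap):
                np.testing.assert_array_equal(p, s)

    def test_train_ensemble_end_to_end(self, small_dataset, fast_config):
        model, reports = rp.train_ensemble(small_dataset, fast_config)
        assert set(reports) == {"conjoint-cnn", "conjoint-sae",
                                "conjoint-struct-cnn", "conjoint-struct-sae",
                                "ensemble"}
        features = PairFeatures.from_dataset(small_dataset)
        probs = model.predict_proba(small_dataset.pairs[:7], features)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        # ensembling should not be far below the best single module on train data
        ens_acc = max(reports["ensemble"].accuracies)
        best_single = max(max(reports[name].accuracies)
                          for name in rp.model.MODULE_NAMES)
        assert ens_acc >= best_single - 0.02

    def test_predict_order_and_duplicates(self, small_dataset, fast_config):
        model, _ = rp.train_ensemble(small_dataset, fast_config)
        features = PairFeatures.from_dataset(small_dataset)
        pairs = [small_dataset.pairs[0], small_dataset.pairs[1],
                 small_dataset.pairs[0]]
        scores = rp.predict(model, pairs, features)
        assert scores.shape == (3,)
        assert scores[0] == scores[2]
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_unknown_id_raises_missing_feature(self, small_dataset, fast_config,
                                               small_features):
        from rpinet.model import MissingFeatureError

        model, _ = rp.train_ensemble(small_dataset, fast_config)
        ghost = [rp.InteractionPair("nonexistent", "alsono", 1)]
        with pytest.raises(MissingFeatureError):
            rp.predict(model, ghost, small_features)


@pytest.fixture(scope="module")
def benchmark_split():
    ds = rp.simulate_dataset_with_structures(rp.SyntheticConfig(seed=19))
    folds = rp.stratified_kfold(ds.pairs, k=5, seed=19)
    test_pairs = folds[0]
    train_pairs = [p for fold in folds[1:] for p in fold]
    return PairFeatures.from_dataset(ds), train_pairs, test_pairs


class TestLearnability:
    def test_cnn_fits_planted_rule_training_data(self, small_dataset,
                                                 small_features):
        config = ModuleConfig(max_epochs_adam=6, max_epochs_sgd=1, patience=3,
                              batch_size=32, seed=11)
        m = build_cnn_module(config, *small_features.dims(False))
        _, report = train_module(m, small_dataset.pairs, small_features, config)
        assert max(report.accuracies) >= 0.95

    @pytest.mark.parametrize("builder,use_structure", [
        (build_cnn_module, False), (build_sae_module, True),
    ])
    def test_modules_generalize_to_held_out_pairs(self, builder, use_structure,
                                                  benchmark_split):
        features, train_pairs, test_pairs = benchmark_split
        config = ModuleConfig.quick(seed=19)
        m = builder(config, *features.dims(use_structure),
                    use_structure=use_structure)
        if m.kind == "sae":
            pretrain_sae(m, features.entity_matrix("rna", use_structure),
                         features.entity_matrix("protein", use_structure))
        train_module(m, train_pairs, features, config)
        scores = rp.predict(m, test_pairs, features)
        auc = rp.roc_auc([p.label for p in test_pairs], scores)
        assert auc >= 0.9


class TestPersistence:
    def test_config_file_round_trip(self, tmp_path):
        config = ModuleConfig(conv_kernel=5, dropout_rate=0.3, seed=42,
                              standardize=False)
        path = tmp_path / "config.txt"
        config.to_file(path)
        assert ModuleConfig.from_file(path) == config

    def test_model_directory_round_trip(self, tmp_path, small_dataset,
                                        fast_config):
        model, _ = rp.train_ensemble(small_dataset, fast_config)
        features = PairFeatures.from_dataset(small_dataset)
        before = rp.predict(model, small_dataset.pairs[:11], features)
        rp.save_model(model, tmp_path / "model")
        loaded = rp.load_model(tmp_path / "model")
        after = rp.predict(loaded, small_dataset.pairs[:11], features)
        np.testing.assert_allclose(after, before, atol=1e-6)
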