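"""Architecture, feature preparation, folds, training and ensembling."""

import numpy as np
import pytest

from sskit.core import SS8_STATES, FeatureBundle, ProteinRecord
from sskit.model import (
    ModelConfig,
    TrainConfig,
    build_model,
    ensemble_predict,
    load_checkpoint,
    predict,
    prepare_batch,
    save_checkpoint,
    standardize,
    stratified_folds,
    train_model,
    window_contact_map,
)
from sskit.synthetic import GeneratorConfig, generate_features, generate_truth

TINY = ModelConfig(inputs=("pssm",), depth=1, f_c=8, f_e=8, kernel_size=3, max_len=64)


@pytest.fixture(scope="module")
def tiny_featured_records():
    cfg = GeneratorConfig(n_chains=6, length_min=30, length_max=64,
                          length_mean=48, seed=3)
    return generate_features(generate_truth(cfg), noise=0.1, seed=4)


class TestWindowContactMap:
    def test_hand_enumerated_offsets(self):
        out = window_contact_map(np.ones((3, 3)), w=4)
        # offsets are (-2, -1, +1, +2), self excluded, zero padding at ends
        expected = np.array([
            [0, 0, 1, 1],
            [0, 1, 1, 0],
            [1, 1, 0, 0],
        ], dtype=float)
        np.testing.assert_array_equal(out, expected)

    def test_zero_map_propagates(self):
        np.testing.assert_array_equal(
            window_contact_map(np.zeros((5, 5)), w=4), np.zeros((5, 4))
        )

    def test_values_passed_through_unstandardised(self):
        cmap = np.full((6, 6), 0.37)
        out = window_contact_map(cmap, w=4)
        assert set(np.unique(out)) <= {0.0, 0.37}

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            window_contact_map(np.ones((3, 4)), w=4)


class TestStandardize:
    def test_direct_formula(self):
        b = FeatureBundle(pssm=np.tile([[5.0] * 20, [9.0] * 20], (2, 1)))
        out, stats = standardize([b])
        # mean 7, sd 2 -> values +-1
        np.testing.assert_allclose(sorted(np.unique(out[0].pssm)), [-1.0, 1.0])

    def test_training_columns_become_standard(self):
        rng = np.random.default_rng(0)
        bundles = [FeatureBundle(pssm=rng.normal(3, 2, (40, 20)),
                                 hhm=rng.uniform(0, 1, (40, 30)))
                   for _ in range(5)]
        out, stats = standardize(bundles)
        pssm = np.concatenate([b.pssm for b in out])
        assert np.abs(pssm.mean(axis=0)).max() < 1e-6
        assert np.abs(pssm.std(axis=0) - 1).max() < 1e-6

    def test_validation_uses_training_stats(self):
        rng = np.random.default_rng(1)
        train = [FeatureBundle(pssm=rng.normal(0, 1, (30, 20)))]
        val = [FeatureBundle(pssm=rng.normal(5, 1, (30, 20)))]  # shifted
        _, stats = standardize(train)
        with_train_stats, _ = standardize(val, stats)
        self_standardised, _ = standardize(val)
        assert with_train_stats[0].pssm.mean() > 3  # shift survives
        assert abs(self_standardised[0].pssm.mean()) < 1e-6

    def test_zero_variance_column_centred_with_warning(self):
        b = FeatureBundle(pssm=np.ones((10, 20)))
        with pytest.warns(UserWarning, match="zero-variance"):
            out, _ = standardize([b])
        np.testing.assert_array_equal(out[0].pssm, np.zeros((10, 20)))

    def test_contact_window_untouched(self):
        b = FeatureBundle(pssm=np.random.default_rng(2).normal(size=(10, 20)),
                          contact_window=np.full((10, 4), 0.5))
        out, _ = standardize([b])
        np.testing.assert_array_equal(out[0].contact_window, b.contact_window)


class TestBuildModel:
    def test_dual_row_stochastic_heads(self):
        m = build_model(TINY, seed=0)
        rng = np.random.default_rng(1)
        feats = {"pssm": rng.normal(size=(2, 64, 20))}
        p8, p3 = m.predict_probs(feats)
        assert p8.shape == (2, 64, 8) and p3.shape == (2, 64, 3)
        np.testing.assert_allclose(p8.sum(axis=2), 1.0, atol=1e-9)
        np.testing.assert_allclose(p3.sum(axis=2), 1.0, atol=1e-9)

    def test_attention_adds_parameters(self):
        with_attn = build_model(TINY).param_count
        without = build_model(
            ModelConfig(**{**TINY.__dict__, "attention": False})
        ).param_count
        assert with_attn > without

    def test_seeded_builds_are_identical(self):
        w1 = build_model(TINY, seed=7).get_weights()
        w2 = build_model(TINY, seed=7).get_weights()
        for a, b in zip(w1, w2):
            np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("field,larger", [("f_c", 16), ("f_e", 16), ("depth", 2)])
    def test_parameter_count_grows_with_capacity(self, field, larger):
        base = build_model(TINY).param_count
        grown = build_model(
            ModelConfig(**{**TINY.__dict__, field: larger})
        ).param_count
        assert grown > base

    def test_max_len_must_match_depth(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(inputs=("pssm",), depth=3, max_len=100)

    def test_batch_independence(self, tiny_featured_records):
        m = build_model(TINY, seed=0)
        alone = predict(m, tiny_featured_records[0])
        feats, _, _, _ = prepare_batch(tiny_featured_records[:3], TINY)
        p8, _ = m.predict_probs(feats)
        L = len(tiny_featured_records[0])
        np.testing.assert_allclose(alone.probs8, p8[0, :L], atol=1e-10)


class TestStratifiedFolds:
    def test_balanced_fold_sizes(self, medium_truth):
        split = stratified_folds(medium_truth[:100], k=10, seed=0)
        sizes = [len(split.fold_ids(f)) for f in range(10)]
        assert sum(sizes) == 100
        assert max(sizes) - min(sizes) <= len(set(split.strata.values()))

    def test_determinism(self, medium_truth):
        a = stratified_folds(medium_truth, k=10, seed=5).assignment
        b = stratified_folds(medium_truth, k=10, seed=5).assignment
        assert a == b

    def test_class_frequencies_balanced_across_folds(self, medium_truth):
        split = stratified_folds(medium_truth, k=5, seed=1)
        by_id = {r.id: r for r in medium_truth}
        total = "".join(r.ss8 for r in medium_truth)
        for cls in ("H", "E", "C", "T"):  # the well-populated classes
            global_freq = total.count(cls) / len(total)
            for f in range(5):
                fold = "".join(by_id[cid].ss8 for cid in split.fold_ids(f))
                assert fold.count(cls) / len(fold) == pytest.approx(
                    global_freq, rel=0.2
                )

    def test_too_many_folds_rejected(self, small_truth):
        with pytest.raises(ValueError, match="folds"):
            stratified_folds(small_truth[:5], k=10)

    def test_nine_factor_strata(self, small_truth):
        split = stratified_folds(small_truth, k=4, seed=0)
        assert all(len(bits) == 9 for bits in split.strata.values())


class TestTraining:
    def test_learnability_and_checkpoint_contract(self, tiny_featured_records):
        m = build_model(TINY, seed=0)
        m, hist = train_model(
            m, tiny_featured_records, tiny_featured_records,
            TrainConfig(max_epochs=25, seed=0),
        )
        assert hist.train_loss[-1] < hist.train_loss[0]
        # best checkpoint is the minimum of the recorded validation losses
        assert hist.val_loss[hist.best_epoch] == min(hist.val_loss)

    def test_lr_drops_by_exactly_factor_ten_at_plateaus(self, tiny_featured_records):
        m = build_model(TINY, seed=1)
        cfg = TrainConfig(max_epochs=60, lr_patience=2, stop_patience=8, seed=1)
        m, hist = train_model(m, tiny_featured_records[:2],
                              tiny_featured_records[2:4], cfg)
        lrs = hist.lr
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))  # non-increasing
        drops = {round(a / b) for a, b in zip(lrs, lrs[1:]) if b < a}
        assert drops <= {10}

    def test_empty_training_set_rejected(self, tiny_featured_records):
        with pytest.raises(ValueError, match="empty"):
            train_model(build_model(TINY), [], tiny_featured_records, TrainConfig())


class TestEnsemble:
    def test_single_model_identity(self, tiny_featured_records):
        m = build_model(TINY, seed=0)
        rec = tiny_featured_records[0]
        one = ensemble_predict([m], rec)
        np.testing.assert_allclose(one.probs8, predict(m, rec).probs8, atol=1e-12)

    def test_two_model_mean(self, tiny_featured_records):
        m1, m2 = build_model(TINY, seed=0), build_model(TINY, seed=1)
        rec = tiny_featured_records[0]
        ens = ensemble_predict([m1, m2], rec)
        mean = (predict(m1, rec).probs8 + predict(m2, rec).probs8) / 2
        np.testing.assert_allclose(ens.probs8, mean, atol=1e-12)
        np.testing.assert_allclose(ens.probs8.sum(axis=1), 1.0, atol=1e-9)

    def test_mixed_configs_rejected(self, tiny_featured_records):
        other = ModelConfig(**{**TINY.__dict__, "f_c": 16})
        with pytest.raises(ValueError, match="share"):
            ensemble_predict(
                [build_model(TINY), build_model(other)], tiny_featured_records[0]
            )


class TestCheckpoint:
    def test_round_trip(self, tmp_path, tiny_featured_records):
        m = build_model(TINY, seed=0)
        bundles, stats = standardize([r.features for r in tiny_featured_records])
        save_checkpoint(tmp_path / "m.npz", m, stats)
        back, back_stats = load_checkpoint(tmp_path / "m.npz")
        rec = tiny_featured_records[0]
        np.testing.assert_allclose(
            predict(back, rec).probs8, predict(m, rec).probs8, atol=1e-12
        )
        np.testing.assert_allclose(back_stats.pssm_mean, stats.pssm_mean)
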