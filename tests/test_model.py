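import numpy as np
import pytest

from toponet import nn
from toponet.metrics import auroc
from toponet.model import (LR_GRID, EPOCH_GRID, ModelConfig, NormalizationStats,
                           TRANSFER_CONFIG, TachycardiaOnsetModel,
                           TachycardiaOnsetResults, encode_static)
from toponet.sampling import LabeledSample
from toponet.vitals import StaticProfile


def toy_samples(n=40, T=6, F=5, seed=0, signal=1.5, n_patients=None):
    """Separable two-class sequence set: class shifts the feature means."""
    rng = np.random.default_rng(seed)
    n_patients = n_patients or n
    out = []
    for i in range(n):
        label = i % 2
        out.append(LabeledSample(
            features=rng.normal(label * signal, 1.0, size=(T, F)),
            static_vector=np.concatenate([[60.0], np.zeros(10)]),
            label=label,
            patient_id=f"P{i % n_patients}",
            window_end=120, forecast_range=2))
    return out


class TestStaticEncoding:
    def test_icu_profile_vector(self):
        v = encode_static(StaticProfile(66.0, "male", "emergency", "medical-ICU", True))
        assert v.shape == (11,)
        assert v[0] == 66.0
        assert v[1] == 1.0                       # male indicator
        assert v[2:5].tolist() == [0, 1, 0]      # admission one-hot
        assert v[5:10].sum() == 1.0
        assert v[10] == 1.0

    def test_ward_profile_care_unit_block_zero(self):
        v = encode_static(StaticProfile(61.0, "female", "elective", None, False))
        assert v[5:10].tolist() == [0, 0, 0, 0, 0]
        assert v[1] == 0.0 and v[10] == 0.0

    def test_deterministic(self):
        p = StaticProfile(45.0, "female", "urgent", "coronary", True)
        assert np.array_equal(encode_static(p), encode_static(p))


class TestNetwork:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        params = nn.init_params(input_dim=3, hidden_size=4, seed=1)
        X = rng.normal(size=(2, 5, 3))
        y = np.array([1.0, 0.0])
        _, grads = nn.loss_and_grads(params, X, y)
        eps = 1e-6
        for key in params:
            flat = params[key].reshape(-1)
            for idx in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = nn.loss_and_grads(params, X, y)
                flat[idx] = orig - eps
                lm, _ = nn.loss_and_grads(params, X, y)
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert grads[key].reshape(-1)[idx] == pytest.approx(
                    numeric, rel=1e-4, abs=1e-7), key

    def test_forward_is_pure_and_order_invariant(self):
        params = nn.init_params(4, 3, seed=2)
        X = np.random.default_rng(3).normal(size=(6, 5, 4))
        p1 = nn.forward(params, X)
        p2 = nn.forward(params, X[::-1])[::-1]
        assert p1 == pytest.approx(p2.tolist(), abs=1e-12)
        assert ((p1 > 0) & (p1 < 1)).all()


class TestTraining:
    def test_overfits_separable_toy_set(self):
        samples = toy_samples()
        res = TachycardiaOnsetModel(samples).fit(
            ModelConfig(hidden_size=8, learning_rate=5e-3, epochs=200,
                        batch_size=8, seed=0))
        assert res.history[-1] < 0.05

    def test_same_seed_identical_weights(self):
        samples = toy_samples()
        cfg = ModelConfig(hidden_size=8, epochs=10, seed=3)
        a = TachycardiaOnsetModel(samples).fit(cfg)
        b = TachycardiaOnsetModel(samples).fit(cfg)
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_single_class_errors(self):
        samples = [s for s in toy_samples() if s.label == 1]
        with pytest.raises(ValueError):
            TachycardiaOnsetModel(samples).fit()

    def test_uninformative_features_give_chance_auroc(self):
        aurocs = []
        for seed in (0, 1, 2):
            train = toy_samples(n=80, seed=2 * seed, signal=0.0)
            test = toy_samples(n=120, seed=2 * seed + 1, signal=0.0)
            res = TachycardiaOnsetModel(train).fit(
                ModelConfig(hidden_size=8, epochs=20, seed=seed))
            aurocs.append(auroc(res.predict(test), [s.label for s in test]))
        assert 0.35 <= float(np.median(aurocs)) <= 0.65

    def test_normalization_fitted_on_training_data_only(self):
        samples = toy_samples()
        res = TachycardiaOnsetModel(samples).fit(
            ModelConfig(hidden_size=4, epochs=5, seed=0))
        before = res.norm.seq_mean.copy()
        shifted = toy_samples(seed=99, signal=5.0)
        res.predict(shifted)
        assert np.array_equal(res.norm.seq_mean, before)

    def test_zero_variance_feature_passes_through(self):
        X_seq = np.zeros((4, 3, 2))
        X_seq[:, :, 0] = 7.0  # constant feature
        X_static = np.tile([50.0] + [0.0] * 10, (4, 1))
        norm = NormalizationStats.fit(X_seq, X_static)
        assert norm.seq_std[0] == 1.0


class TestRandomSearch:
    def test_budget_one_returns_single_draw(self):
        samples = toy_samples(n=30, n_patients=10)
        best, trials = TachycardiaOnsetModel(samples).random_search_cv(1, seed=0)
        assert len(trials) == 1
        assert best.learning_rate == trials[0]["learning_rate"]
        assert best.learning_rate in LR_GRID
        assert best.epochs in EPOCH_GRID

    def test_deterministic_trajectory(self):
        samples = toy_samples(n=30, n_patients=10)
        m = TachycardiaOnsetModel(samples)
        _, t1 = m.random_search_cv(3, seed=5)
        _, t2 = m.random_search_cv(3, seed=5)
        assert t1 == t2

    def test_best_is_argmin_of_trials(self):
        samples = toy_samples(n=30, n_patients=10)
        best, trials = TachycardiaOnsetModel(samples).random_search_cv(3, seed=1)
        best_loss = min(t["val_loss"] for t in trials)
        chosen = [t for t in trials if t["learning_rate"] == best.learning_rate
                  and t["epochs"] == best.epochs]
        assert any(t["val_loss"] == best_loss for t in chosen)

    def test_too_few_patients_errors(self):
        samples = toy_samples(n=8, n_patients=3)
        with pytest.raises(ValueError):
            TachycardiaOnsetModel(samples).random_search_cv(1, seed=0)


class TestTransfer:
    def test_default_transfer_recipe(self):
        assert TRANSFER_CONFIG.learning_rate == pytest.approx(2e-4)
        assert TRANSFER_CONFIG.epochs == 18
        assert TRANSFER_CONFIG.batch_size == 32

    def test_zero_epochs_is_identity_on_weights(self):
        res = TachycardiaOnsetModel(toy_samples()).fit(
            ModelConfig(hidden_size=8, epochs=5, seed=0))
        frozen = res.finetune(toy_samples(seed=2),
                              ModelConfig(hidden_size=8, epochs=0, seed=0))
        for k in res.params:
            assert np.array_equal(frozen.params[k], res.params[k])

    def test_nonzero_epochs_move_weights(self):
        res = TachycardiaOnsetModel(toy_samples()).fit(
            ModelConfig(hidden_size=8, epochs=5, seed=0))
        ft = res.finetune(toy_samples(seed=2))
        assert any(not np.array_equal(ft.params[k], res.params[k])
                   for k in res.params)

    def test_finetuning_continues_from_pretrained_weights(self):
        pre = TachycardiaOnsetModel(toy_samples(seed=0)).fit(
            ModelConfig(hidden_size=8, epochs=30, seed=0))
        new = toy_samples(seed=4, n=20)
        ft = pre.finetune(new, ModelConfig(hidden_size=8, epochs=1,
                                           learning_rate=1e-6, seed=0))
        # near-zero learning rate for one epoch: weights barely move
        for k in pre.params:
            assert np.allclose(ft.params[k], pre.params[k], atol=1e-4)

    def test_architecture_mismatch_errors(self):
        pre = TachycardiaOnsetModel(toy_samples(F=5)).fit(
            ModelConfig(hidden_size=4, epochs=5, seed=0))
        with pytest.raises(ValueError):
            TachycardiaOnsetModel(toy_samples(F=7)).fit(
                ModelConfig(hidden_size=4, epochs=5, seed=0),
                warm_start=pre.params)


class TestPersistence:
    def test_bundle_round_trip(self, tmp_path):
        samples = toy_samples()
        res = TachycardiaOnsetModel(samples).fit(
            ModelConfig(hidden_size=8, epochs=5, seed=0))
        res.save(tmp_path / "bundle")
        loaded = TachycardiaOnsetResults.load(tmp_path / "bundle")
        assert loaded.registry_hash == res.registry_hash
        assert loaded.predict(samples) == pytest.approx(
            res.predict(samples).tolist(), abs=1e-15)

    def test_summary_mentions_key_settings(self):
        res = TachycardiaOnsetModel(toy_samples()).fit(
            ModelConfig(hidden_size=8, epochs=5, seed=0))
        text = res.summary()
        assert "hidden size" in text and "seed" in text
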