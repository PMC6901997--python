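"""Loss oracle, initialization, optimization and the transfer protocols."""

import numpy as np
import pytest

from mieeg.epochs import ValidationError
from mieeg.model import build_model
from mieeg.training import (
    LayeredLRPolicy,
    TrainConfig,
    _make_optimizer,
    cross_entropy,
    evaluate,
    fine_tune,
    initialize_weights,
    pretrain_pooled,
    small_sample_protocol,
    train,
)

from .conftest import (make_dataset, small_model_config,
                       small_preproc_config, small_synth_config)


class TestCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        p = np.array([[0.0, 0.0, 1.0]])
        logq = np.log(np.array([[1e-12, 1e-12, 1.0 - 2e-12]]))
        assert cross_entropy(p, logq) < 1e-9

    def test_uniform_four_class_is_ln4(self):
        p = np.eye(4)
        logq = np.full((4, 4), np.log(0.25))
        assert abs(cross_entropy(p, logq) - np.log(4.0)) < 1e-12

    def test_two_class_example(self):
        p = np.array([[1.0, 0.0]])
        logq = np.log(np.array([[0.8, 0.2]]))
        assert abs(cross_entropy(p, logq) - 0.22314355) < 1e-6

    def test_matches_direct_formula_on_random_pairs(self):
        """Agrees with an independent dense evaluation of -sum p_i log q_i."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(2, 6))
            b = int(rng.integers(1, 8))
            labels = rng.integers(0, n, b)
            p = np.zeros((b, n))
            p[np.arange(b), labels] = 1.0
            q = rng.dirichlet(np.ones(n), size=b)
            direct = float(np.mean([-np.log(q[i, labels[i]]) for i in range(b)]))
            assert abs(cross_entropy(p, np.log(q)) - direct) < 1e-6

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            cross_entropy(np.eye(3), np.log(np.full((3, 4), 0.25)))


class TestInitialization:
    def test_paper_scheme_unit_variance(self, tiny_model_config):
        model = initialize_weights(build_model(tiny_model_config, seed=0),
                                   scheme="paper", seed=1)
        # enough weights for a law-of-large-numbers check
        big = small_model_config(n_times=300, n_channels=16, f_t=16)
        model = initialize_weights(build_model(big, seed=0), scheme="paper", seed=1)
        weights = np.concatenate([
            arr.ravel() for name, arr, _ in model.parameters()
            if not name.startswith("bn_") and not name.endswith(".b")
        ])
        assert weights.size >= 10_000
        assert abs(weights.mean()) < 0.05
        assert abs(weights.var() - 1.0) < 0.1

    def test_batchnorm_weights_exactly_one(self, tiny_model_config):
        model = initialize_weights(build_model(tiny_model_config, seed=0),
                                   scheme="paper", seed=2)
        assert (model.bn_temporal.params["gamma"] == 1.0).all()
        assert (model.bn_spatial.params["gamma"] == 1.0).all()
        assert (model.bn_temporal.params["beta"] == 0.0).all()

    def test_seeded_determinism(self, tiny_model_config):
        a = initialize_weights(build_model(tiny_model_config, seed=0), "paper", seed=9)
        b = initialize_weights(build_model(tiny_model_config, seed=1), "paper", seed=9)
        for (_, x, _), (_, y, _) in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(x, y)

    def test_scaled_scheme_shrinks_with_fan_in(self, tiny_model_config):
        model = initialize_weights(build_model(tiny_model_config, seed=0),
                                   scheme="scaled", seed=3)
        w = model.spatial.params["w"]  # fan-in 8 maps x 3 channels
        assert w.std() < 0.5

    def test_unknown_scheme_rejected(self, tiny_model_config):
        with pytest.raises(ValidationError, match="scheme"):
            initialize_weights(build_model(tiny_model_config, seed=0), "xavier", 0)


class TestEvaluate:
    def test_perfect_predictions(self, tiny_model_config):
        # force the model to predict a constant class via the classifier bias
        model = build_model(tiny_model_config, seed=0, scheme="scaled")
        model.classifier.params["w"][:] = 0.0
        model.classifier.params["b"][:] = np.array([10.0, -10.0], dtype=np.float32)
        ds = make_dataset(n_trials=10, n_channels=3, n_times=60)
        ds.labels[:] = 0
        acc, cm = evaluate(model, ds)
        assert acc == 1.0
        assert cm[0, 0] == 10 and cm.sum() == 10

    def test_confusion_matrix_row_sums(self, tiny_model_config):
        model = build_model(tiny_model_config, seed=1)
        ds = make_dataset(n_trials=20, n_channels=3, n_times=60, seed=3)
        acc, cm = evaluate(model, ds)
        np.testing.assert_array_equal(cm.sum(axis=1),
                                      np.bincount(ds.labels, minlength=2))
        assert cm.sum() == 20

    def test_untrained_model_near_chance(self, tiny_model_config):
        """Untrained networks on randomly labelled balanced data sit near
        chance level when averaged over seeds."""
        accs = []
        for seed in range(8):
            model = build_model(tiny_model_config, seed=seed, scheme="scaled")
            ds = make_dataset(n_trials=64, n_channels=3, n_times=60, seed=seed)
            ds.labels = np.tile([0, 1], 32)
            acc, _ = evaluate(model, ds)
            accs.append(acc)
        assert abs(np.mean(accs) - 0.5) < 0.15

    def test_empty_test_set_rejected(self, tiny_model_config):
        model = build_model(tiny_model_config, seed=0)
        ds = make_dataset(n_trials=8, n_channels=3, n_times=60).subset(np.array([], dtype=int))
        with pytest.raises(ValidationError):
            evaluate(model, ds)


class TestLayeredLRPolicy:
    def test_default_factors(self):
        policy = LayeredLRPolicy()
        factors = policy.factors()
        assert factors["feature_extraction"] == pytest.approx(1 / 27)
        assert factors["feature_reduction"] == pytest.approx(1 / 9)
        assert factors["classifier"] == pytest.approx(1 / 3)

    def test_group_learning_rates(self, tiny_model_config):
        """base_lr 1e-3 with the default policy yields per-group rates
        (3.7037e-5, 1.1111e-4, 3.3333e-4)."""
        model = build_model(tiny_model_config, seed=0)
        opt = _make_optimizer(model, TrainConfig(base_lr=1e-3), LayeredLRPolicy())
        rates = [opt.base_lr * g["lr_factor"] for g in opt.groups]
        np.testing.assert_allclose(rates, [3.7037037e-5, 1.1111111e-4, 3.3333333e-4],
                                   rtol=1e-6)

    def test_every_parameter_in_exactly_one_group(self, tiny_model_config):
        model = build_model(tiny_model_config, seed=0)
        opt = _make_optimizer(model, TrainConfig(), LayeredLRPolicy())
        seen = []
        for group in opt.groups:
            for layer in group["layers"]:
                for pname, arr in layer.params.items():
                    seen.append(id(arr))
        expected = [id(arr) for _, arr, _ in model.parameters()]
        assert sorted(seen) == sorted(expected)

    def test_ordering_invariant_enforced(self):
        with pytest.raises(ValidationError):
            LayeredLRPolicy(fe_factor=0.5, fr_factor=0.1, clf_factor=1.0)


def _quick_cfg(**kw):
    defaults = dict(max_epochs=8, seed=0, batch_size=32)
    defaults.update(kw)
    return TrainConfig(**defaults)


@pytest.fixture(scope="module")
def synthetic_splits():
    """Small, fast, well-separated two-class dataset (shared by the
    training tests; read-only)."""
    from mieeg.epochs import split_dataset
    from mieeg.preprocessing import preprocess
    from mieeg.synthetic import generate_dataset

    ds = preprocess(
        generate_dataset(small_synth_config(n_trials_per_class=90, seed=11,
                                            base_mu_amp=9.0, noise_amp=9.0)),
        small_preproc_config())
    return split_dataset(ds, (0.6, 0.2, 0.2), seed=11)


class TestTrain:
    def test_learns_separable_synthetic_data(self, synthetic_splits):
        """Smoke-level learning check: well above chance within a small
        epoch budget (the full-accuracy end-to-end run is an integration
        test)."""
        tr, va, te = synthetic_splits
        model = build_model(small_model_config(tr.n_times), seed=0, scheme="scaled")
        model, hist = train(model, tr, va, _quick_cfg(max_epochs=40))
        df = hist.to_frame()
        assert df.valid_accuracy.max() >= 0.8
        assert df.train_loss.iloc[hist.best_epoch - 1] <= df.train_loss.iloc[0]
        acc, _ = evaluate(model, te)
        assert acc >= 0.6

    def test_identical_seed_identical_history(self, synthetic_splits):
        tr, va, _ = synthetic_splits
        histories = []
        for _ in range(2):
            model = build_model(small_model_config(tr.n_times), seed=3, scheme="scaled")
            _, hist = train(model, tr, va, _quick_cfg(max_epochs=3, seed=5))
            histories.append(hist.to_frame())
        assert histories[0].equals(histories[1])

    def test_empty_training_set_rejected(self, synthetic_splits):
        tr, va, _ = synthetic_splits
        model = build_model(small_model_config(tr.n_times), seed=0)
        with pytest.raises(ValidationError):
            train(model, tr.subset(np.array([], dtype=int)), va, _quick_cfg())


class TestTransfer:
    @pytest.fixture(scope="class")
    def family(self):
        from mieeg.preprocessing import preprocess
        from mieeg.synthetic import SubjectShift, generate_subject_family

        fam = generate_subject_family(
            small_synth_config(n_trials_per_class=60),
            n_subjects=4,
            shift=SubjectShift(amplitude_scale=1.5, frequency_jitter_hz=1.0,
                               channel_group_rotation=2, noise_scale=1.3),
            seed=21,
        )
        return [preprocess(d, small_preproc_config()) for d in fam]

    @pytest.fixture(scope="class")
    def coarse(self, family):
        sources = family[:-1]
        model = build_model(small_model_config(sources[0].n_times), seed=1, scheme="scaled")
        model, _ = pretrain_pooled(sources, model, _quick_cfg(max_epochs=6, seed=1))
        return model

    def test_pooling_counts(self, family):
        from mieeg.epochs import concatenate_datasets
        pooled = concatenate_datasets(family[:3])
        assert pooled.n_trials == sum(d.n_trials for d in family[:3])

    def test_pooling_invariant_to_subject_order(self, family):
        sources = family[:3]
        results = []
        for order in (sources, sources[::-1]):
            model = build_model(small_model_config(sources[0].n_times), seed=2,
                                scheme="scaled")
            model, hist = pretrain_pooled(list(order), model,
                                          _quick_cfg(max_epochs=2, seed=2))
            results.append(hist.to_frame())
        assert results[0].equals(results[1])

    def test_coarse_model_transfers_above_chance(self, coarse, family):
        acc, _ = evaluate(coarse, family[-1])
        assert acc >= 0.55

    def test_fine_tune_does_not_modify_coarse(self, coarse, family):
        from mieeg.epochs import split_dataset
        target = family[-1]
        tr, _, _ = split_dataset(target, (0.7, 0.0, 0.3), seed=0)
        before = coarse.state_dict()
        fine_tune(coarse, tr, family[:-1], LayeredLRPolicy(),
                  _quick_cfg(max_epochs=2, seed=0))
        after = coarse.state_dict()
        for key in before:
            np.testing.assert_array_equal(before[key], after[key])

    def test_mix_ratio_zero_trains_on_target_only(self, coarse, family):
        """With mix_ratio 0 the fine-tuning history reflects exactly the
        target trials (train+valid split of the target set)."""
        from mieeg.epochs import split_dataset
        target = family[-1]
        tr, _, _ = split_dataset(target, (0.5, 0.0, 0.5), seed=0)
        a, _ = fine_tune(coarse, tr, family[:-1], LayeredLRPolicy(),
                         _quick_cfg(max_epochs=2, seed=4), mix_ratio=0.0)
        b, _ = fine_tune(coarse, tr, [], LayeredLRPolicy(),
                         _quick_cfg(max_epochs=2, seed=4), mix_ratio=1.0)
        for key, arr in a.state_dict().items():
            np.testing.assert_array_equal(arr, b.state_dict()[key])

    def test_small_sample_table_structure(self, coarse, family):
        from mieeg.epochs import split_dataset
        target = family[-1]
        tr, _, te = split_dataset(target, (0.7, 0.0, 0.3), seed=0)
        table = small_sample_protocol(
            coarse, tr, te, LayeredLRPolicy(), _quick_cfg(max_epochs=2),
            sample_sizes=(8, 16), seeds=(0, 1),
        )
        assert table.n_samples.tolist() == [8, 16]
        assert ((table.mean_accuracy >= 0) & (table.mean_accuracy <= 1)).all()
        assert (table.n_seeds == 2).all()

    def test_small_sample_full_set_matches_fine_tune(self, coarse, family):
        from mieeg.epochs import split_dataset
        target = family[-1]
        tr, _, te = split_dataset(target, (0.7, 0.0, 0.3), seed=0)
        table = small_sample_protocol(
            coarse, tr, te, LayeredLRPolicy(), _quick_cfg(max_epochs=2),
            sample_sizes=(tr.n_trials,), seeds=(6,), mix_ratio=0.0,
        )
        direct, _ = fine_tune(coarse, tr, [], LayeredLRPolicy(),
                              _quick_cfg(max_epochs=2, seed=6), mix_ratio=0.0)
        acc, _ = evaluate(direct, te)
        assert table.mean_accuracy.iloc[0] == pytest.approx(acc)

    def test_sample_size_exceeding_target_rejected(self, coarse, family):
        from mieeg.epochs import split_dataset
        tr, _, te = split_dataset(family[-1], (0.7, 0.0, 0.3), seed=0)
        with pytest.raises(ValidationError):
            small_sample_protocol(coarse, tr, te, LayeredLRPolicy(),
                                  _quick_cfg(), sample_sizes=(10_000,))
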