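"""Training protocol: splits, loss, early stopping, stage freezing, and
determinism of seeded runs."""

import numpy as np
import pytest

from molpath.model import ModelConfig, build_model, forward
from molpath.synthetic import SynthSpec, make_dataset
from molpath.training import (SplitSpec, TrainConfig, mse_loss, run_trials,
                              should_stop, split_dataset, train_model,
                              train_stage1, train_stage2)


@pytest.fixture(scope="module")
def tiny_composition_records():
    """60 small molecules with a composition target (fast fixture runs)."""
    spec = SynthSpec(n_molecules=60, atoms_range=(3, 6), mode="composition",
                     noise_sd=0.1, seed=5)
    return [(r.graph, r.target) for r in make_dataset(spec)]


def fast_train_config(**kw):
    base = dict(max_epochs=3, seed=2)
    base.update(kw)
    return TrainConfig(**base)


class TestSplitDataset:
    def test_hundred_records_split_80_10_10(self):
        recs = list(range(100))
        tr, va, te = split_dataset(recs, SplitSpec(base_seed=0), 0)
        assert (len(tr), len(va), len(te)) == (80, 10, 10)
        assert sorted(tr + va + te) == recs  # disjoint and exhaustive

    def test_twenty_five_records_remainder_goes_to_test(self):
        tr, va, te = split_dataset(list(range(25)), SplitSpec(base_seed=0), 0)
        assert (len(tr), len(va), len(te)) == (20, 2, 3)

    def test_same_spec_and_trial_reproduce_identical_split(self):
        recs = list(range(40))
        s = SplitSpec(base_seed=7)
        assert split_dataset(recs, s, 3) == split_dataset(recs, s, 3)
        assert split_dataset(recs, s, 3) != split_dataset(recs, s, 4)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(list(range(9)), SplitSpec(), 0)


class TestMseLoss:
    def test_equal_vectors_give_zero(self):
        assert mse_loss([1, 2], [1, 2]) == 0.0

    def test_hand_value(self):
        assert mse_loss([0, 0], [1, -1]) == pytest.approx(1.0)

    def test_quadratic_in_residual_scale(self):
        rng = np.random.default_rng(0)
        p, t = rng.standard_normal(10), rng.standard_normal(10)
        assert mse_loss(t + 2 * (p - t), t) == pytest.approx(4 * mse_loss(p, t))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mse_loss([], [])


class TestShouldStop:
    def test_ten_successive_sub_threshold_improvements_stop(self):
        history = [1.0]
        for _ in range(10):
            history.append(history[-1] - 0.00005)
        assert should_stop(history, patience=10, min_delta=1e-4)

    def test_one_real_improvement_in_window_keeps_going(self):
        history = [1.0] + [1.0 - 0.00005 * k for k in range(1, 10)]
        history.append(history[-1] - 0.01)
        assert not should_stop(history, patience=10, min_delta=1e-4)

    def test_short_history_never_stops(self):
        assert not should_stop([1.0, 0.9], patience=10, min_delta=1e-4)

    def test_zero_min_delta_with_strictly_decreasing_losses_never_fires(self):
        history = list(np.linspace(1.0, 0.5, 50))
        for k in range(10, 50):
            assert not should_stop(history[:k], patience=10, min_delta=0.0)

    def test_plateau_counts_as_no_improvement(self):
        # ten plateau epochs after the last real improvement
        assert should_stop([1.0] + [0.5] * 11, patience=10, min_delta=1e-4)
        # only nine plateau epochs: the improvement is still in the window
        assert not should_stop([1.0] + [0.5] * 10, patience=10, min_delta=1e-4)


class TestStageOne:
    def test_training_reduces_path_loss_on_composition_fixture(
            self, tiny_composition_records):
        tr, va, _ = split_dataset(tiny_composition_records, SplitSpec(base_seed=1), 0)
        model = build_model(ModelConfig(paths=("node",), seed=1))
        logs = train_stage1(model, tr, va, fast_train_config(max_epochs=8))
        assert logs["node"].train_losses[-1] < logs["node"].train_losses[0]

    def test_aggregator_and_final_head_untouched(self, tiny_composition_records):
        tr, va, _ = split_dataset(tiny_composition_records, SplitSpec(base_seed=1), 0)
        model = build_model(ModelConfig(paths=("node", "edge"), seed=1))
        before_agg = {k: t.data.copy() for k, t in model.agg_tensors().items()}
        before_head = model.W_fc.data.copy()
        train_stage1(model, tr, va, fast_train_config())
        for k, t in model.agg_tensors().items():
            np.testing.assert_array_equal(t.data, before_agg[k])
        np.testing.assert_array_equal(model.W_fc.data, before_head)

    def test_same_seed_reproduces_identical_loss_sequences(
            self, tiny_composition_records):
        tr, va, _ = split_dataset(tiny_composition_records, SplitSpec(base_seed=1), 0)
        runs = []
        for _ in range(2):
            model = build_model(ModelConfig(paths=("node",), seed=1))
            runs.append(train_stage1(model, tr, va, fast_train_config()))
        assert runs[0]["node"].train_losses == runs[1]["node"].train_losses
        assert runs[0]["node"].valid_losses == runs[1]["node"].valid_losses


class TestStageTwo:
    def test_path_parameters_bitwise_frozen(self, tiny_composition_records):
        tr, va, _ = split_dataset(tiny_composition_records, SplitSpec(base_seed=1), 0)
        model = build_model(ModelConfig(paths=("node", "edge"), seed=1))
        cfg = fast_train_config()
        train_stage1(model, tr, va, cfg)
        snapshot = {name: t.data.copy()
                    for p in model.config.paths
                    for name, t in model.path_tensors(p).items()}
        train_stage2(model, tr, va, cfg)
        for p in model.config.paths:
            for name, t in model.path_tensors(p).items():
                np.testing.assert_array_equal(t.data, snapshot[name])

    def test_temp_heads_discarded_and_head_trained(self, tiny_composition_records):
        tr, va, _ = split_dataset(tiny_composition_records, SplitSpec(base_seed=1), 0)
        model = build_model(ModelConfig(paths=("node",), seed=1))
        cfg = fast_train_config()
        train_stage1(model, tr, va, cfg)
        assert "node" in model.temp_heads
        before_head = model.W_fc.data.copy()
        log = train_stage2(model, tr, va, cfg)
        assert model.temp_heads == {}
        assert not np.array_equal(model.W_fc.data, before_head)
        assert log.trained_groups == ("aggregator", "head")

    def test_stage2_validation_loss_not_worse_than_start(
            self, tiny_composition_records):
        tr, va, _ = split_dataset(tiny_composition_records, SplitSpec(base_seed=1), 0)
        model = build_model(ModelConfig(paths=("node",), seed=1))
        cfg = fast_train_config(max_epochs=10)
        train_stage1(model, tr, va, cfg)
        log = train_stage2(model, tr, va, cfg)
        assert log.valid_losses[-1] <= log.valid_losses[0]


class TestFullRunDeterminism:
    def test_identical_seeds_give_identical_predictions(
            self, tiny_composition_records):
        tr, va, te = split_dataset(tiny_composition_records, SplitSpec(base_seed=1), 0)
        preds = []
        for _ in range(2):
            model = build_model(ModelConfig(paths=("node", "edge"), seed=3))
            train_model(model, tr, va, fast_train_config())
            preds.append([forward(model, g) for g, _ in te])
        assert preds[0] == preds[1]

    def test_stopping_never_exceeds_max_epochs(self, tiny_composition_records):
        tr, va, _ = split_dataset(tiny_composition_records, SplitSpec(base_seed=1), 0)
        model = build_model(ModelConfig(paths=("node",), seed=1))
        logs = train_model(model, tr, va, fast_train_config(max_epochs=2))
        for log in logs.values():
            assert log.stop_epoch <= 2
            assert len(log.train_losses) <= 2


class TestRunTrials:
    def test_single_trial_mean_equals_that_trial(self, tiny_composition_records):
        results, agg = run_trials(tiny_composition_records,
                                  ModelConfig(paths=("node",), seed=1),
                                  fast_train_config(),
                                  SplitSpec(n_trials=1, base_seed=2))
        assert agg["mean"]["mae"] == results[0].metrics["mae"]
        assert agg["std"]["mae"] == 0.0

    def test_three_trial_mean_is_arithmetic_mean(self, tiny_composition_records):
        results, agg = run_trials(tiny_composition_records,
                                  ModelConfig(paths=("node",), seed=1),
                                  fast_train_config(),
                                  SplitSpec(n_trials=3, base_seed=2))
        assert len(results) == 3
        assert agg["mean"]["mae"] == pytest.approx(
            np.mean([r.metrics["mae"] for r in results]))

    def test_same_base_seed_reproduces_per_trial_metrics(
            self, tiny_composition_records):
        kwargs = dict(model_config=ModelConfig(paths=("node",), seed=1),
                      train_config=fast_train_config(),
                      split_spec=SplitSpec(n_trials=2, base_seed=4))
        r1, _ = run_trials(tiny_composition_records, **kwargs)
        r2, _ = run_trials(tiny_composition_records, **kwargs)
        assert [r.metrics for r in r1] == [r.metrics for r in r2]
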