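"""Early stopping, fold splitting, metrics, run averaging, sweep logic."""

import numpy as np
import pytest

from eegstage import (
    ConfusionSummary,
    CVReport,
    LossParams,
    TrainConfig,
    average_runs,
    build,
    gamma_sweep,
    kappa,
    ninefold_split,
    per_class_accuracy,
    train,
)
from eegstage.training import SweepResult, TrainingDivergedError, mean_loss


@pytest.fixture
def tiny_task(tiny_model_config, rng):
    x = rng.standard_normal((24, 7, 11, 64, 1)).astype(np.float32)
    y = np.arange(24) % 2
    x[y == 1, 3, 5, :, 0] += 1.5
    return x, y


class TestEarlyStopping:
    def test_scripted_costs_stop_at_k_plus_patience(self, tiny_model_config,
                                                    tiny_task):
        """Costs constant after epoch 2 with patience 20 stop training at
        epoch 22 and restore the epoch-2 weights."""
        model = build(tiny_model_config, seed=0)
        costs = {1: 1.0, 2: 0.9}  # epochs >= 2 all see 0.9
        snapshots = {}

        def monitor(m, epoch):
            snapshots[epoch] = m.net.get_weights()
            return costs.get(epoch, 0.9)

        cfg = TrainConfig(max_epochs=100, patience=20, batch_size=8, seed=0)
        history = train(model, tiny_task, config=cfg, monitor_fn=monitor)
        assert history.stopped_epoch == 22
        assert history.best_epoch == 2
        assert history.restored
        for got, want in zip(model.net.get_weights(), snapshots[2]):
            np.testing.assert_array_equal(got, want)

    def test_strictly_decreasing_costs_run_all_epochs(self, tiny_model_config,
                                                      tiny_task):
        model = build(tiny_model_config, seed=0)
        cfg = TrainConfig(max_epochs=30, patience=20, batch_size=8, seed=0)
        history = train(model, tiny_task, config=cfg,
                        monitor_fn=lambda m, e: 1.0 / e)
        assert history.stopped_epoch == 30
        assert history.best_epoch == 30

    def test_restored_weights_hit_minimum_recorded_cost(self,
                                                        tiny_model_config,
                                                        tiny_task, rng):
        # with a validation monitor the recorded cost is a pure function of
        # the end-of-epoch weights, so restoring must reproduce its minimum
        xv = rng.standard_normal((10, 7, 11, 64, 1)).astype(np.float32)
        yv = np.arange(10) % 2
        model = build(tiny_model_config, seed=0)
        cfg = TrainConfig(max_epochs=12, patience=3, batch_size=8, seed=0,
                          monitor="valid")
        history = train(model, tiny_task, valid_data=(xv, yv), config=cfg)
        final = mean_loss(model, xv, yv, cfg.loss)
        assert final == pytest.approx(min(history.costs), rel=1e-5)

    def test_same_seed_same_final_weights(self, tiny_model_config, tiny_task):
        cfg = TrainConfig(max_epochs=3, batch_size=8, seed=7)
        m1 = build(tiny_model_config, seed=1)
        m2 = build(tiny_model_config, seed=1)
        train(m1, tiny_task, config=cfg)
        train(m2, tiny_task, config=cfg)
        for a, b in zip(m1.net.get_weights(), m2.net.get_weights()):
            np.testing.assert_array_equal(a, b)

    def test_divergent_cost_aborts(self, tiny_model_config, tiny_task):
        model = build(tiny_model_config, seed=0)
        cfg = TrainConfig(max_epochs=5, batch_size=8, seed=0)
        with pytest.raises(TrainingDivergedError):
            train(model, tiny_task, config=cfg,
                  monitor_fn=lambda m, e: np.nan)

    def test_empty_data_rejected(self, tiny_model_config):
        model = build(tiny_model_config, seed=0)
        empty = (np.zeros((0, 7, 11, 64, 1), dtype=np.float32),
                 np.zeros(0, dtype=int))
        with pytest.raises(ValueError):
            train(model, empty, config=TrainConfig())


class TestNinefoldSplit:
    def test_90_items_give_nine_folds_of_ten(self):
        splits = ninefold_split(90, seed=0)
        assert len(splits) == 9
        assert all(len(te) == 10 for _, te in splits)

    def test_91_items_sizes_differ_by_at_most_one(self):
        sizes = [len(te) for _, te in ninefold_split(91, seed=0)]
        assert max(sizes) - min(sizes) <= 1

    def test_partition_properties(self):
        splits = ninefold_split(91, seed=3)
        all_test = np.concatenate([te for _, te in splits])
        assert len(all_test) == 91
        assert len(np.unique(all_test)) == 91  # disjoint union = dataset
        for tr, te in splits:
            assert len(np.intersect1d(tr, te)) == 0
            assert len(tr) + len(te) == 91

    def test_too_small_dataset_rejected(self):
        with pytest.raises(ValueError):
            ninefold_split(8, seed=0)

    def test_groups_never_straddle_folds(self):
        groups = np.repeat(np.arange(30), 7)  # 30 trials, 7 crops each
        labels = np.repeat(np.arange(30) % 2, 7)
        splits = ninefold_split(len(groups), seed=0, groups=groups,
                                labels=labels)
        for tr, te in splits:
            assert not set(groups[tr]) & set(groups[te])

    def test_stratified_folds_contain_both_classes(self):
        labels = np.repeat([0, 1], [140, 70])
        splits = ninefold_split(210, seed=0, labels=labels)
        for _, te in splits:
            assert set(labels[te]) == {0, 1}


class TestPerClassAccuracy:
    def test_all_correct(self):
        a1, a2, gap = per_class_accuracy([1, 1, 0, 0], [1, 1, 0, 0])
        assert (a1, a2, gap) == (1.0, 1.0, 0.0)

    def test_known_counts(self):
        y = [1] * 10 + [0] * 10
        pred = [1] * 8 + [0] * 2 + [0] * 3 + [1] * 7
        a1, a2, gap = per_class_accuracy(pred, y)
        assert (a1, a2) == (0.8, 0.3)
        assert gap == pytest.approx(0.5)

    def test_degenerate_predictor(self):
        a1, a2, gap = per_class_accuracy([1, 1, 1, 1], [1, 1, 0, 0])
        assert (a1, a2, gap) == (1.0, 0.0, 1.0)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            per_class_accuracy([1, 1], [1, 1])

    def test_overall_equals_prevalence_weighted_mean(self, rng):
        y = rng.integers(0, 2, size=200)
        pred = rng.integers(0, 2, size=200)
        a1, a2, _ = per_class_accuracy(pred, y)
        w1 = (y == 1).mean()
        overall = (pred == y).mean()
        assert overall == pytest.approx(w1 * a1 + (1 - w1) * a2)


class TestKappa:
    def test_perfect_agreement(self):
        assert kappa(ConfusionSummary(np.array([[50, 0], [0, 50]]))) == 1.0

    def test_worked_example_p0_08_pe_05(self):
        # symmetric table with P0 = 0.8 and Pe = 0.5 gives (0.8-0.5)/0.5 = 0.6
        table = np.array([[40, 10], [10, 40]])
        summary = ConfusionSummary(table)
        assert summary.P0 == pytest.approx(0.8)
        assert summary.Pe == pytest.approx(0.5)
        assert kappa(summary) == pytest.approx(0.6)

    def test_chance_level_predictor_is_zero(self):
        # equal marginals, agreement exactly at chance
        table = np.array([[25, 25], [25, 25]])
        assert kappa(ConfusionSummary(table)) == pytest.approx(0.0)

    def test_matches_sklearn_on_random_tables(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(20):
            y = rng.integers(0, 2, size=300)
            pred = rng.integers(0, 2, size=300)
            ours = kappa(ConfusionSummary.from_predictions(pred, y))
            ref = cohen_kappa_score(y, pred)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_bounded_in_minus_one_one(self, rng):
        for _ in range(50):
            t = rng.integers(0, 50, size=(2, 2))
            if t.sum() == 0 or t.sum(0).max() == t.sum() \
                    or t.sum(1).max() == t.sum():
                continue
            k = kappa(ConfusionSummary(t))
            assert -1.0 - 1e-12 <= k <= 1.0 + 1e-12

    def test_degenerate_single_cell_rejected(self):
        with pytest.raises(ValueError):
            kappa(ConfusionSummary(np.array([[10, 0], [0, 0]])))


def make_report(a1, a2, gamma=None, n_runs=1, folds=3):
    a1 = np.full(folds, a1)
    a2 = np.full(folds, a2)
    return CVReport(a1, a2, (a1 + a2) / 2, np.zeros(folds), gamma=gamma,
                    n_runs=n_runs)


class TestAverageRuns:
    def test_identical_reports_unchanged(self):
        avg = average_runs([make_report(0.8, 0.6)] * 3)
        assert avg.mean_acc_c1 == pytest.approx(0.8)
        assert avg.n_runs == 3

    def test_two_reports_mean(self):
        avg = average_runs([make_report(0.6, 0.4), make_report(0.8, 0.6)])
        assert avg.mean_acc_c1 == pytest.approx(0.7)
        assert avg.mean_acc_c2 == pytest.approx(0.5)

    def test_permutation_invariant(self):
        reports = [make_report(0.5, 0.5), make_report(0.7, 0.3),
                   make_report(0.9, 0.1)]
        a = average_runs(reports)
        b = average_runs(reports[::-1])
        np.testing.assert_allclose(a.acc_c1, b.acc_c1)

    def test_mismatched_structure_rejected(self):
        with pytest.raises(ValueError):
            average_runs([make_report(0.5, 0.5, folds=3),
                          make_report(0.5, 0.5, folds=4)])


class TestGammaSweepLogic:
    def test_small_gap_skips_sweep(self):
        baseline = make_report(0.8, 0.6)  # gap 0.2

        def run_fn(gamma, seed):  # pragma: no cover - must not be called
            raise AssertionError("sweep should not run")

        result = gamma_sweep(run_fn, baseline, grid=[0, 2], trigger_gap=0.3)
        assert not result.swept
        assert result.final is baseline

    def test_large_gap_triggers_and_selects_best(self):
        baseline = make_report(1.0, 0.1)  # gap 0.9
        outcomes = {0.0: (1.0, 0.1), 2.0: (0.9, 0.5), 5.0: (0.6, 0.55)}

        def run_fn(gamma, seed):
            return make_report(*outcomes[gamma], gamma=gamma)

        result = gamma_sweep(run_fn, baseline, grid=[0.0, 2.0, 5.0])
        assert result.swept
        assert result.best_gamma == 2.0  # balanced accuracy 0.7 is best
        assert result.final.mean_acc_c2 == pytest.approx(0.5)

    def test_min_class_criterion(self):
        baseline = make_report(1.0, 0.1)
        outcomes = {2.0: (0.9, 0.5), 5.0: (0.62, 0.58)}

        def run_fn(gamma, seed):
            return make_report(*outcomes[gamma], gamma=gamma)

        result = gamma_sweep(run_fn, baseline, grid=[2.0, 5.0],
                             criterion="min_class_accuracy")
        assert result.best_gamma == 5.0

    def test_runs_per_gamma_averages_repeats(self):
        baseline = make_report(1.0, 0.1)
        calls = []

        def run_fn(gamma, seed):
            calls.append((gamma, seed))
            return make_report(0.9, 0.5, gamma=gamma)

        result = gamma_sweep(run_fn, baseline, grid=[2.0], runs_per_gamma=3)
        assert result.final.n_runs == 3
        assert len(calls) == 3
        assert len({seed for _, seed in calls}) == 3

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            gamma_sweep(lambda g, s: None, make_report(1.0, 0.1), grid=[])
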