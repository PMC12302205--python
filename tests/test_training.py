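import math

import numpy as np
import pytest

from deltasolv.training import (
    EarlyStopper,
    LabeledBatch,
    TrainConfig,
    evaluate,
    predict,
    predict_corrections,
    residual_loss,
    train_ensemble,
    train_member,
)

FAST = dict(patience=5, max_epochs=15, batch_size=100)


class TestResidualLoss:
    def test_exact_correction_zero(self):
        batch = LabeledBatch(y_expt=[1.0, -2.0], y_phys=[0.5, -1.0], y_corr=[0.5, -1.0])
        assert residual_loss(batch) == 0.0

    def test_zero_correction_is_physics_mse(self):
        batch = LabeledBatch(y_expt=[1.0, -2.0], y_phys=[0.0, 0.0], y_corr=[0.0, 0.0])
        assert residual_loss(batch) == pytest.approx((1.0 + 4.0) / 2)

    def test_three_four_gives_twelve_point_five(self):
        batch = LabeledBatch(y_expt=[0.0, 0.0], y_phys=[3.0, 4.0], y_corr=[0.0, 0.0])
        assert residual_loss(batch) == pytest.approx(12.5)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            LabeledBatch(y_expt=[], y_phys=[], y_corr=[])

    def test_loss_equals_rmse_squared(self):
        rng = np.random.default_rng(0)
        y, p, c = rng.normal(size=(3, 20))
        batch = LabeledBatch(y_expt=y, y_phys=p, y_corr=c)
        report = evaluate([str(i) for i in range(20)], y, p + c, p)
        assert residual_loss(batch) == pytest.approx(report.rmse ** 2)


class TestEarlyStopper:
    def test_plateau_stops_after_exactly_patience(self):
        stopper = EarlyStopper(patience=4, min_delta=0.01)
        stops = [stopper.update(e, 1.0) for e in range(10)]
        # epoch 0 sets the best; epochs 1..4 plateau -> stop at epoch 4
        assert stops.index(True) == 4

    def test_improvement_resets_patience(self):
        stopper = EarlyStopper(patience=2, min_delta=0.01)
        series = [1.0, 0.9, 0.95, 0.8, 0.85, 0.84]
        stops = [stopper.update(e, v) for e, v in enumerate(series)]
        assert stops == [False, False, False, False, False, True]
        assert stopper.best_epoch == 3

    def test_sub_min_delta_improvement_does_not_reset_patience(self):
        stopper = EarlyStopper(patience=2, min_delta=0.01)
        stops = [stopper.update(e, v) for e, v in enumerate([1.0, 0.995, 0.991])]
        assert stops == [False, False, True]
        # weights still revert to the strict minimum of the run
        assert stopper.best_epoch == 2
        assert stopper.best == 0.991


class TestTrainMember:
    def test_learnable_residual_improves(self, chem_graphs):
        # residual is a deterministic function of atom counts by fixture
        # construction (y - y_phys = -0.3 everywhere): trivially learnable
        graphs = [g for g in chem_graphs if g.n_nodes >= 2]
        tc = TrainConfig(**FAST, ensemble_size=1, base_seed=0, min_delta=0.0001)
        model, history = train_member("graphconv", graphs, graphs, tc, seed=0)
        assert history.val_rmse[-1] <= history.val_rmse[0]
        assert min(history.val_rmse) == pytest.approx(history.best_val_rmse)

    def test_returned_weights_are_best_epoch(self, chem_graphs):
        graphs = [g for g in chem_graphs if g.n_nodes >= 2]
        tc = TrainConfig(**FAST, ensemble_size=1, base_seed=1)
        model, history = train_member("graphconv", graphs, graphs, tc, seed=1)
        y_phys = np.array([g.y_phys for g in graphs])
        y = np.array([g.y for g in graphs])
        corr = predict_corrections(model, graphs)
        rmse = float(np.sqrt(np.mean((y - y_phys - corr) ** 2)))
        assert rmse == pytest.approx(history.best_val_rmse, abs=1e-9)

    def test_deterministic_given_seed(self, chem_graphs):
        graphs = [g for g in chem_graphs if g.n_nodes >= 2]
        tc = TrainConfig(**FAST, ensemble_size=1, base_seed=2)
        m1, h1 = train_member("graphconv", graphs, graphs, tc, seed=2)
        m2, h2 = train_member("graphconv", graphs, graphs, tc, seed=2)
        assert h1.val_rmse == h2.val_rmse
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k].data, m2.params[k].data)

    def test_empty_partition_raises(self, chem_graphs):
        tc = TrainConfig(**FAST)
        with pytest.raises(ValueError):
            train_member("graphconv", [], chem_graphs, tc, seed=0)

    def test_missing_physics_raises(self, chem_graphs):
        graphs = [g for g in chem_graphs if g.n_nodes >= 2]
        for g in graphs:
            g = g
        import copy

        broken = copy.deepcopy(graphs)
        broken[0].y_phys = None
        tc = TrainConfig(**FAST)
        with pytest.raises(ValueError, match="physics"):
            train_member("graphconv", broken, broken, tc, seed=0)


class TestEnsemble:
    def _tiny_ensemble(self, graphs, size=3, mode="residual"):
        tc = TrainConfig(patience=2, max_epochs=3, batch_size=100,
                         ensemble_size=size, base_seed=10, mode=mode)
        return train_ensemble("graphconv", graphs, graphs, tc)

    def test_member_count_and_distinct_seeds(self, chem_graphs):
        graphs = [g for g in chem_graphs if g.n_nodes >= 2]
        ens = self._tiny_ensemble(graphs, size=3)
        assert len(ens.members) == 3
        assert ens.member_seeds == [10, 11, 12]
        assert len(set(ens.member_seeds)) == 3

    def test_mean_equals_brute_force_average(self, chem_graphs):
        graphs = [g for g in chem_graphs if g.n_nodes >= 2]
        ens = self._tiny_ensemble(graphs, size=3)
        mean = ens.mean_correction(graphs)
        brute = sum(predict_corrections(m, graphs) for m, _ in ens.members) / 3
        np.testing.assert_allclose(mean, brute, atol=1e-12)

    def test_single_member_prediction(self, chem_graphs):
        graphs = [g for g in chem_graphs if g.n_nodes >= 2]
        ens = self._tiny_ensemble(graphs, size=1)
        y_phys = np.array([g.y_phys for g in graphs])
        final = predict(ens, graphs, y_phys)
        member_out = predict_corrections(ens.members[0][0], graphs)
        np.testing.assert_allclose(final, y_phys + member_out)

    def test_opposite_members_cancel(self, chem_graphs):
        graphs = [g for g in chem_graphs if g.n_nodes >= 2][:3]
        ens = self._tiny_ensemble(graphs, size=2)
        m0, m1 = ens.members[0][0], ens.members[1][0]
        # force symmetric outputs: member1 = -member0
        m1.load_state_arrays(m0.state_arrays())
        m1.params["head.W"].data *= -1
        m1.params["head.b"].data *= -1
        y_phys = np.array([g.y_phys for g in graphs])
        final = predict(ens, graphs, y_phys)
        np.testing.assert_allclose(final, y_phys, atol=1e-10)

    def test_ensemble_mean_rmse_not_worse_than_member_mean(self, chem_graphs):
        graphs = [g for g in chem_graphs if g.n_nodes >= 2]
        ens = self._tiny_ensemble(graphs, size=3)
        y = np.array([g.y for g in graphs])
        y_phys = np.array([g.y_phys for g in graphs])
        final = predict(ens, graphs, y_phys)
        ens_rmse = float(np.sqrt(np.mean((y - final) ** 2)))
        member_rmses = [
            float(np.sqrt(np.mean((y - y_phys - predict_corrections(m, graphs)) ** 2)))
            for m, _ in ens.members
        ]
        assert ens_rmse <= np.mean(member_rmses) + 1e-9


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([-1.0, -2.0])
        report = evaluate(["a", "b"], y, y, y + 1.0)
        assert report.rmse == 0.0
        assert report.relative_improvement == 1.0

    def test_zero_corrections(self):
        y = np.array([-1.0, -2.0])
        y_phys = y + 0.5
        report = evaluate(["a", "b"], y, y_phys, y_phys)
        assert report.relative_improvement == 0.0

    def test_three_four_rmse(self):
        report = evaluate(["a", "b"], np.zeros(2), np.array([3.0, 4.0]), np.ones(2))
        assert report.rmse == pytest.approx(math.sqrt(12.5))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            evaluate([], np.array([]), np.array([]), np.array([]))

    def test_relative_improvement_definition(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=10)
        y_phys = y + rng.normal(scale=2.0, size=10)
        final = y + rng.normal(scale=1.0, size=10)
        report = evaluate([str(i) for i in range(10)], y, final, y_phys)
        expected = (report.rmse_physics_alone - report.rmse) / report.rmse_physics_alone
        assert report.relative_improvement == pytest.approx(expected)
        assert report.relative_improvement <= 1.0


class TestTrainConfig:
    def test_defaults(self):
        tc = TrainConfig()
        assert tc.batch_size == 100
        assert tc.learning_rate == 0.001
        assert tc.min_delta == 0.01
        assert tc.ensemble_size == 20

    def test_invalid(self):
        with pytest.raises(ValueError):
            TrainConfig(patience=0)
        with pytest.raises(ValueError):
            TrainConfig(mode="hybrid")
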