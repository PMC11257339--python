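import numpy as np
import pytest

from bfselect.bfs_trainer import (
    TrainerConfig,
    run_init_step,
    run_training_step,
    train_baseline,
    train_bfs,
)
from bfselect.mlp_core import NetworkSpec, init_network, predict
from bfselect.metrics_eval import classification_metrics, pareto_filter, sparsity_score
from bfselect.objectives import cross_entropy, sparse_group_lasso
from bfselect.regions import build_regions


def _std(data):
    return data.standardized()


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            TrainerConfig(init_fraction=0.0)
        with pytest.raises(ValueError):
            TrainerConfig(patience=0)
        with pytest.raises(ValueError):
            TrainerConfig(K_regions=0)
        with pytest.raises(ValueError):
            TrainerConfig(method="adam")


class TestInitStep:
    def test_already_in_region_returns_immediately(self, toy_dataset):
        data = _std(toy_dataset)
        cfg = TrainerConfig(K_regions=1, max_epochs=100, seed=0, hidden_layers=(4,))
        regions = build_regions(1)
        params = init_network(NetworkSpec((2, 4, 2), seed=1))
        before = params.flatten().copy()
        refs, record = run_init_step(params, 1, regions, data, cfg)
        assert record.stop_reason_init == "in_region"
        np.testing.assert_array_equal(params.flatten(), before)
        assert refs[0] > 0 and refs[1] > 0

    def test_epoch_budget_respected(self, toy_dataset):
        data = _std(toy_dataset)
        cfg = TrainerConfig(K_regions=50, max_epochs=50, seed=0, hidden_layers=(4,))
        regions = build_regions(50)
        params = init_network(NetworkSpec((2, 4, 2), seed=1))
        _, record = run_init_step(params, 1, regions, data, cfg)
        init_epochs = sum(1 for p in record.phase if p == "init")
        assert init_epochs <= int(np.ceil(0.2 * 50))

    def test_violation_nonincreasing(self, toy_dataset):
        # out-of-region start: active constraint value must fall monotonically
        # (the line search enforces sufficient decrease)
        data = _std(toy_dataset)
        cfg = TrainerConfig(K_regions=8, max_epochs=200, seed=0, hidden_layers=(4,))
        regions = build_regions(8)
        params = init_network(NetworkSpec((2, 4, 2), seed=2))
        _, record = run_init_step(params, 1, regions, data, cfg)
        # reconstruct the active-constraint value per logged epoch
        vals = []
        for fn, act in zip(record.f_norm, record.active):
            if act:
                from bfselect.regions import constraint_values

                vals.append(constraint_values(fn, regions, 1)[act[0] - 1])
        assert all(b <= a + 1e-6 for a, b in zip(vals, vals[1:]))


class TestTrainingStep:
    def test_stationary_stop_before_max_epochs(self, toy_dataset):
        data = _std(toy_dataset)
        cfg = TrainerConfig(K_regions=1, max_epochs=5000, seed=0, hidden_layers=(4,))
        regions = build_regions(1)
        params = init_network(NetworkSpec((2, 4, 2), seed=3))
        record = run_training_step(params, 1, regions, data, cfg, (0.7, 30.0))
        assert record.stop_reason_train in ("stationary", "patience", "line_search")
        assert len(record.f_raw) < 5000

    def test_norm_refs_constant_within_phase(self, toy_dataset):
        data = _std(toy_dataset)
        cfg = TrainerConfig(K_regions=2, max_epochs=30, seed=0, hidden_layers=(4,))
        regions = build_regions(2)
        params = init_network(NetworkSpec((2, 4, 2), seed=3))
        refs = (0.5, 20.0)
        record = run_training_step(params, 1, regions, data, cfg, refs)
        for fr, fn in zip(record.f_raw, record.f_norm):
            assert fn[0] == pytest.approx(fr[0] / refs[0])
            assert fn[1] == pytest.approx(fr[1] / refs[1])

    def test_rejects_nonpositive_refs(self, toy_dataset):
        data = _std(toy_dataset)
        cfg = TrainerConfig(K_regions=1, max_epochs=10, seed=0, hidden_layers=(4,))
        with pytest.raises(ValueError):
            run_training_step(
                init_network(NetworkSpec((2, 4, 2), seed=0)),
                1, build_regions(1), data, cfg, (0.0, 1.0),
            )


class TestTrainBfs:
    def test_returns_k_networks_with_tagged_records(self, toy_dataset):
        data = _std(toy_dataset)
        cfg = TrainerConfig(K_regions=4, max_epochs=60, seed=0, hidden_layers=(4,))
        out = train_bfs(data, cfg)
        assert len(out) == 4
        for k, (params, record) in enumerate(out, start=1):
            assert record.region == k
            assert set(record.phase) <= {"init", "train"}
            assert record.norm_refs[0] > 0

    def test_bit_reproducible(self, toy_dataset):
        data = _std(toy_dataset)
        cfg = TrainerConfig(K_regions=2, max_epochs=40, seed=9, hidden_layers=(4,))
        a = train_bfs(data, cfg)
        b = train_bfs(data, cfg)
        for (pa, _), (pb, _) in zip(a, b):
            np.testing.assert_array_equal(pa.flatten(), pb.flatten())

    def test_k1_trajectory_bit_matches_mgda_baseline(self, toy_dataset):
        # with a single region covering the quadrant the sector constraints
        # never activate, so the constrained method reduces to plain
        # min-norm biobjective descent, step for step
        data = _std(toy_dataset)
        cfg = TrainerConfig(K_regions=1, max_epochs=40, seed=5, hidden_layers=(4,))
        cfg_m = TrainerConfig(K_regions=1, max_epochs=40, seed=5, hidden_layers=(4,),
                              method="moo_mtl")
        (pb, rb), = train_bfs(data, cfg)
        (pm, rm), = train_baseline(data, cfg_m)
        assert not any(rb.active[i] for i in range(len(rb.active)))
        np.testing.assert_array_equal(pb.flatten(), pm.flatten())
        bfs_train_log = [f for f, ph in zip(rb.f_raw, rb.phase) if ph == "train"]
        assert bfs_train_log == rm.f_raw

    def test_front_has_multiple_distinct_points(self, small_data):
        data = _std(small_data)
        cfg = TrainerConfig(K_regions=10, max_epochs=150, seed=1, hidden_layers=(16,))
        out = train_bfs(data, cfg)
        points = [r.f_raw[-1] for _, r in out]
        front = set(pareto_filter(points))
        assert len(front) >= 2

    def test_sparser_than_l1_baseline(self, small_data):
        data = _std(small_data)
        cfg = TrainerConfig(K_regions=10, max_epochs=150, seed=1, hidden_layers=(16,))
        bfs_s = max(sparsity_score(p) for p, _ in train_bfs(data, cfg))
        cfg_l1 = TrainerConfig(K_regions=10, max_epochs=150, seed=1, hidden_layers=(16,),
                               method="l1")
        l1_s = max(sparsity_score(p) for p, _ in train_baseline(data, cfg_l1))
        assert bfs_s > l1_s


class TestBaselines:
    def test_unknown_method_rejected(self, toy_dataset):
        cfg = TrainerConfig(K_regions=1, max_epochs=10, seed=0, method="bfs")
        with pytest.raises(ValueError):
            train_baseline(_std(toy_dataset), cfg)

    def test_l1_weight_zero_is_vanilla_descent(self, toy_dataset):
        data = _std(toy_dataset)
        cfg = TrainerConfig(K_regions=1, max_epochs=300, seed=0, hidden_layers=(8,),
                            method="l1", scalarization_weight=0.0, patience=50)
        (params, record), = train_baseline(data, cfg)
        losses = [fn[0] for fn in record.f_norm]  # scalarized loss log
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))
        acc = classification_metrics(data.labels_test, predict(params, data.X_test), 2)[0]
        assert acc == 1.0

    def test_sgl_loss_log_consistent(self, toy_dataset):
        data = _std(toy_dataset)
        cfg = TrainerConfig(K_regions=1, max_epochs=30, seed=0, hidden_layers=(4,),
                            method="sgl", scalarization_weight=0.01)
        (_, record), = train_baseline(data, cfg)
        for fr, fn in zip(record.f_raw, record.f_norm):
            # logged scalarized loss equals CE + weight * regularizer
            assert fn[0] == pytest.approx(fr[0] + 0.01 * fr[1], rel=1e-9)

    def test_baseline_population_size_matches_bfs(self, toy_dataset):
        data = _std(toy_dataset)
        for method in ("moo_mtl", "bfs_init_only", "l1", "sgl"):
            cfg = TrainerConfig(K_regions=3, max_epochs=20, seed=0, hidden_layers=(4,),
                                method=method)
            assert len(train_baseline(data, cfg)) == 3

    def test_patience_bounds_epochs_after_stall(self, toy_dataset):
        data = _std(toy_dataset)
        cfg = TrainerConfig(K_regions=1, max_epochs=4000, seed=0, hidden_layers=(4,),
                            method="moo_mtl", patience=5)
        (_, record), = train_baseline(data, cfg)
        assert len(record.f_raw) < 4000
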