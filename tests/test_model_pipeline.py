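"""Split plans, the validator/recorder, and the variability filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mietox import model_pipeline as mp


def ids(n):
    return [f"S{i:05d}" for i in range(n)]


class TestSplitDataset:
    def test_ten_percent_test_allocation(self):
        plan = mp.split_dataset(ids(1000), seed=1)
        assert len(plan.test_ids) == 100
        assert len(plan.dev_ids) == 900

    def test_exact_fold_division(self):
        plan = mp.split_dataset(ids(9), test_fraction=0.0, seed=1)
        assert sorted(len(f) for f in plan.folds) == [3, 3, 3]

    def test_uneven_fold_division(self):
        plan = mp.split_dataset(ids(10), test_fraction=0.0, seed=1)
        assert sorted(len(f) for f in plan.folds) == [3, 3, 4]

    def test_too_few_compounds_rejected(self):
        with pytest.raises(ValueError):
            mp.split_dataset(ids(3))

    @given(n=st.integers(5, 200), seed=st.integers(0, 2**20))
    @settings(max_examples=60, deadline=None)
    def test_partition_invariants(self, n, seed):
        """Test/dev disjoint; folds disjoint, cover dev, sizes within 1."""
        plan = mp.split_dataset(ids(n), seed=seed)  # validated in __post_init__
        assert set(plan.test_ids) | set(plan.dev_ids) == set(ids(n))
        again = mp.split_dataset(ids(n), seed=seed)
        assert again.test_ids == plan.test_ids
        assert again.folds == plan.folds


class TestValidator:
    @pytest.fixture(scope="class")
    def small_problem(self, gaussian_dataset):
        X, y = gaussian_dataset
        plan = mp.split_dataset(list(X.index), seed=5)
        grid = mp.HyperparameterGrid(learning_rates=(0.0, 0.1, 0.3, 0.6), seed=5)
        records = mp.run_validator(X, y, plan, grid)
        return X, y, plan, grid, records

    def test_recorder_completeness(self, small_problem):
        _, _, plan, grid, records = small_problem
        assert len(records) == len(plan.folds) * len(grid.learning_rates)

    def test_zero_learning_rate_is_degenerate(self, small_problem):
        _, _, _, _, records = small_problem
        zero = [r for r in records if r.learning_rate == 0.0]
        assert len(zero) == 3
        assert all(r.degenerate and r.auc == 0.5 for r in zero)

    def test_validation_auc_in_range(self, small_problem):
        _, _, _, _, records = small_problem
        assert all(0.0 <= r.auc <= 1.0 for r in records)

    def test_separable_signal_learned(self, small_problem):
        _, _, _, _, records = small_problem
        by_lr = {}
        for r in records:
            by_lr.setdefault(r.learning_rate, []).append(r.auc)
        best_mean = max(np.mean(v) for lr, v in by_lr.items() if lr > 0)
        assert best_mean >= 0.9

    def test_determinism(self, small_problem):
        X, y, plan, grid, records = small_problem
        again = mp.run_validator(X, y, plan, grid)
        assert [r.auc for r in again] == [r.auc for r in records]

    def test_single_class_training_fold_recorded_not_crashed(self):
        import pandas as pd

        X = pd.DataFrame(
            np.random.default_rng(0).normal(size=(8, 3)), index=ids(8)
        )
        y = pd.Series([1, 0, 0, 0, 0, 0, 0, 0], index=ids(8))
        plan = mp.split_dataset(ids(8), test_fraction=0.0, seed=0)
        records = mp.run_validator(X, y, plan, mp.HyperparameterGrid((0.1,), seed=0))
        assert len(records) == 3
        assert any(r.degenerate for r in records)


def fake_records(aucs_by_lr):
    return [
        mp.ModelRecord(fold=f, learning_rate=lr, model=None, auc=a)
        for lr, aucs in aucs_by_lr.items()
        for f, a in enumerate(aucs)
    ]


class TestFilter:
    def test_high_variability_rate_excluded(self):
        records = fake_records({0.1: [0.90, 0.90, 0.90], 0.2: [0.99, 0.50, 0.50]})
        selected = mp.apply_filter(records, sd_max=0.05)
        assert selected.learning_rate == 0.1
        assert selected.fold_aucs == [0.90, 0.90, 0.90]
        assert not selected.fallback_used

    def test_tie_breaks_toward_lower_learning_rate(self):
        records = fake_records({0.3: [0.9, 0.9, 0.9], 0.1: [0.9, 0.9, 0.9]})
        assert mp.apply_filter(records).learning_rate == 0.1

    def test_tie_breaks_toward_lower_fold(self):
        records = fake_records({0.1: [0.9, 0.9, 0.9]})
        assert mp.apply_filter(records).fold == 0

    def test_all_excluded_falls_back_with_warning(self):
        records = fake_records({0.1: [0.99, 0.5, 0.5], 0.2: [0.9, 0.5, 0.7]})
        with pytest.warns(UserWarning, match="sd_max"):
            selected = mp.apply_filter(records, sd_max=0.01)
        assert selected.fallback_used
        assert selected.learning_rate == 0.2  # smaller across-fold SD

    def test_empty_recorder_rejected(self):
        with pytest.raises(ValueError):
            mp.apply_filter([])

    @given(
        aucs=st.lists(
            st.tuples(*[st.floats(0, 1, allow_nan=False, width=16)] * 3),
            min_size=1,
            max_size=8,
        ),
        sd_lo=st.floats(0, 0.2, allow_nan=False),
        sd_delta=st.floats(0, 0.3, allow_nan=False),
    )
    @settings(max_examples=80, deadline=None)
    def test_filter_monotone_in_sd_max(self, aucs, sd_lo, sd_delta):
        """Raising sd_max never shrinks the survivor set."""
        records = fake_records(
            {round(0.01 * (i + 1), 2): list(a) for i, a in enumerate(aucs)}
        )
        lo = set(mp.filter_survivors(records, sd_lo))
        hi = set(mp.filter_survivors(records, sd_lo + sd_delta))
        assert lo <= hi


class TestTrainTarget:
    def test_selected_model_recovers_signal(self, gaussian_dataset):
        X, y = gaussian_dataset
        grid = mp.HyperparameterGrid(
            learning_rates=tuple(round(0.1 * i, 1) for i in range(1, 11)), seed=5
        )
        bundle = mp.train_target(X, y, aid=720516, criterion=40, seed=5, grid=grid)
        assert bundle.test_metrics.auc >= 0.85
        assert 0 < bundle.selected.cutoff < 1
        assert bundle.selected.learning_rate in grid.learning_rates

    def test_deterministic_end_to_end(self, gaussian_dataset):
        X, y = gaussian_dataset
        grid = mp.HyperparameterGrid(learning_rates=(0.1, 0.3), seed=5)
        a = mp.train_target(X, y, aid=720516, criterion=40, seed=9, grid=grid)
        b = mp.train_target(X, y, aid=720516, criterion=40, seed=9, grid=grid)
        assert a.selected.learning_rate == b.selected.learning_rate
        assert a.selected.cutoff == b.selected.cutoff
        assert a.test_metrics.as_dict() == b.test_metrics.as_dict()

    def test_single_class_target_rejected(self, gaussian_dataset):
        X, y = gaussian_dataset
        with pytest.raises(ValueError, match="single class"):
            mp.train_target(X, y * 0, aid=720516, criterion=40, seed=1)

    def test_bundle_round_trip(self, gaussian_dataset, tmp_path):
        X, y = gaussian_dataset
        grid = mp.HyperparameterGrid(learning_rates=(0.1, 0.3), seed=5)
        bundle = mp.train_target(
            X, y, aid=720516, criterion=40, seed=5, grid=grid, abbreviation="ATAD5_ind"
        )
        where = bundle.save(tmp_path)
        back = mp.TargetBundle.load(where)
        assert back.aid == 720516 and back.criterion == 40
        assert back.selected.cutoff == pytest.approx(bundle.selected.cutoff)
        assert back.schema.names == bundle.schema.names
        probe = X.iloc[:5]
        np.testing.assert_allclose(
            back.selected.model.predict_proba(probe),
            bundle.selected.model.predict_proba(probe),
            rtol=1e-6,
        )
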