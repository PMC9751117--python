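"""Partitioning, stratified sampling, the R² contract, and Monte Carlo CV."""

import numpy as np
import pytest

from seq2exp.errors import SizingError, ValidationError
from seq2exp.experiment import (
    EvalResult,
    PartitionSpec,
    largest_remainder,
    make_partitions,
    mean_r2,
    monte_carlo_cv,
    r_squared,
    stratified_sample,
)
from seq2exp.models import ModelSpec


class TestRSquared:
    def test_perfect_fit(self):
        y = np.array([0.1, 0.5, 0.9])
        assert r_squared(y, y) == pytest.approx(1.0)

    def test_mean_baseline_is_zero(self):
        y = np.array([0.1, 0.5, 0.9])
        assert r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_hand_computed_negative(self):
        # 1 - 8/2 = -3
        assert r_squared([1, 2, 3], [3, 2, 1]) == pytest.approx(-3.0)

    def test_never_above_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y, f = rng.random(10), rng.random(10)
            assert r_squared(y, f) <= 1.0

    def test_constant_measurements_rejected(self):
        with pytest.raises(ValidationError):
            r_squared([1.0, 1.0, 1.0], [1.0, 0.9, 1.1])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            r_squared([1.0, 2.0], [1.0])


class TestLargestRemainder:
    def test_sums_to_total(self):
        alloc = largest_remainder(np.array([3, 3, 4]), 7)
        assert alloc.sum() == 7

    def test_proportionality(self):
        alloc = largest_remainder(np.array([100, 100]), 10)
        assert alloc.tolist() == [5, 5]

    def test_tie_broken_by_index(self):
        alloc = largest_remainder(np.array([1, 1, 1]), 2)
        assert alloc.tolist() == [1, 1, 0]


class TestStratifiedSample:
    def test_full_pool_returned(self, small_partitions):
        pool = small_partitions.splits[1].train_pool
        out = stratified_sample(pool, len(pool), 10, 0)
        assert len(out) == len(pool)

    def test_one_bin_is_simple_random_sample(self, small_partitions):
        pool = small_partitions.splits[1].train_pool
        out = stratified_sample(pool, 50, 1, 0)
        assert len(out) == 50

    def test_oversampling_rejected(self, small_partitions):
        pool = small_partitions.splits[1].train_pool
        with pytest.raises(SizingError):
            stratified_sample(pool, len(pool) + 1, 10, 0)

    def test_bin_proportions_match_source(self, small_library):
        frame = small_library.to_frame()
        series = frame[frame.series_id == 1].reset_index(drop=True)
        n, n_bins = 200, 10
        out = stratified_sample(series, n, n_bins, 7)
        qs = np.quantile(series["fluorescence"], np.linspace(0, 1, n_bins + 1))
        src = np.histogram(series["fluorescence"], bins=qs)[0] / len(series)
        got = np.histogram(out["fluorescence"], bins=qs)[0]
        assert np.all(np.abs(got - src * n) <= 1 + 1e-9)

    def test_deterministic(self, small_partitions):
        pool = small_partitions.splits[1].train_pool
        a = stratified_sample(pool, 60, 10, 13)
        b = stratified_sample(pool, 60, 10, 13)
        assert a["seq_id"].tolist() == b["seq_id"].tolist()


class TestMakePartitions:
    def test_sets_disjoint_and_sized(self, small_library, small_partitions):
        frame = small_library.to_frame()
        for sid, split in small_partitions.splits.items():
            n = (frame.series_id == sid).sum()
            assert len(split.test) == round(0.10 * n)
            ids = [set(split.test.seq_id), set(split.validation.seq_id),
                   set(split.train_pool.seq_id)]
            assert not (ids[0] & ids[1]) and not (ids[0] & ids[2]) and not (ids[1] & ids[2])

    def test_merged_validation_size(self, small_partitions):
        assert len(small_partitions.merged_validation) == 3 * 70

    def test_sizing_error_names_series(self, small_library):
        spec = PartitionSpec(train_pool_size=10_000, validation_per_series=70)
        with pytest.raises(SizingError, match="series 1"):
            make_partitions(small_library, spec)


class TestMonteCarloCv:
    def test_repeat_count_and_mean(self, small_partitions):
        results = monte_carlo_cv(
            ModelSpec("ridge", {"alpha": 1.0}), "biophysical", 1, 100,
            small_partitions, n_repeats=5, rng_seed=1,
        )
        assert len(results) == 5
        assert mean_r2(results) == pytest.approx(np.mean([r.r2 for r in results]))
        for r in results:
            # R² recomputable from the stored measured/predicted vectors
            assert r.r2 == pytest.approx(r_squared(r.y, r.f))

    def test_no_leakage_into_training(self, small_partitions):
        split = small_partitions.splits[1]
        test_ids = set(split.test.seq_id)
        for rep in range(3):
            from seq2exp._rand import STAGE_SAMPLING, derive_rng

            rng = derive_rng(5, STAGE_SAMPLING, 1, rep)
            train = stratified_sample(split.train_pool, 100, 10, rng)
            assert not (set(train.seq_id) & test_ids)

    def test_train_size_exceeding_pool_rejected(self, small_partitions):
        with pytest.raises(SizingError):
            monte_carlo_cv(
                ModelSpec("ridge"), "biophysical", 1, 10_000, small_partitions,
            )


@pytest.mark.parametrize("train_sizes", [(200, 500, 1000, 2000)])
def test_rf_onehot_accuracy_non_decreasing_in_train_size(train_sizes):
    """More training data never hurts the random forest (up to one SE)."""
    from seq2exp.experiment import make_partitions
    from seq2exp.synthetic import LibraryConfig, build_library

    cfg = LibraryConfig(n_series=1, variants_per_series=2800, length=30, master_seed=21)
    lib = build_library(config=cfg)
    parts = make_partitions(
        lib, PartitionSpec(train_pool_size=None, validation_per_series=50, seed=21)
    )
    spec = ModelSpec("random_forest", {"n_estimators": 50})
    means, ses = [], []
    for size in train_sizes:
        results = monte_carlo_cv(spec, "onehot_binary", 1, size, parts,
                                 n_repeats=5, rng_seed=21)
        r2s = [r.r2 for r in results]
        means.append(np.mean(r2s))
        ses.append(np.std(r2s) / np.sqrt(len(r2s)))
    for i in range(1, len(means)):
        assert means[i] >= means[i - 1] - ses[i - 1]
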