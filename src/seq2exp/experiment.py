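"""Data partitioning, stratified sampling and Monte Carlo cross-validation.

The partition scheme mirrors genotype–phenotype benchmarking practice: per
mutational series, a fixed stratified 10% test set is held out first; from
the remainder a per-series validation slice (for hyperparameter selection,
merged across series into one large validation set) and a training pool are
drawn.  Training sets of any size are then stratified-sampled from the pool,
models fitted, and accuracy reported as the coefficient of determination

    R² = 1 − Σ(yᵢ − fᵢ)² / Σ(yᵢ − ȳ)²

on the fixed test set, averaged over repeats with resampled training sets
(Monte Carlo cross-validation).  R² is 1 for a perfect fit, 0 for the
mean-baseline predictor, and negative for models worse than the baseline.

Stratification uses quantile bins on fluorescence with largest-remainder
proportional allocation, so sample phenotype distributions track the source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rand import STAGE_PARTITION, STAGE_SAMPLING, derive_int_seed, derive_rng
from .errors import SizingError, ValidationError
from .synthetic import SequenceRecord, records_to_frame


def as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    if hasattr(records, "to_frame"):
        return records.to_frame()
    if records and isinstance(records[0], SequenceRecord):
        return records_to_frame(records)
    raise ValidationError("records must be a DataFrame, SyntheticLibrary or SequenceRecord list")


def _quantile_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile bin index per value; degenerate edges collapse gracefully."""
    if n_bins <= 1:
        return np.zeros(len(values), dtype=int)
    binned = pd.qcut(values, q=n_bins, labels=False, duplicates="drop")
    return np.asarray(binned, dtype=int)


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation proportional to ``weights`` summing to ``total``.

    Floors the exact quotas and hands the remainder to the largest fractional
    parts; ties broken by lowest index.
    """
    weights = np.asarray(weights, dtype=float)
    quotas = total * weights / weights.sum()
    alloc = np.floor(quotas).astype(int)
    rem = total - alloc.sum()
    if rem > 0:
        frac = quotas - alloc
        order = np.lexsort((np.arange(len(frac)), -frac))
        alloc[order[:rem]] += 1
    return alloc


def stratified_sample(
    records, n: int, n_bins: int = 10, rng_seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Draw ``n`` records preserving the fluorescence distribution.

    Values are split into ``n_bins`` quantile bins and samples drawn per bin
    in proportion to bin occupancy (largest-remainder rounding); within a bin
    the draw is uniform without replacement.
    """
    frame = as_frame(records)
    if n > len(frame):
        raise SizingError(f"requested {n} records from a pool of {len(frame)}")
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else derive_rng(rng_seed, STAGE_SAMPLING)
    )
    if n == len(frame):
        return frame.copy()
    bins = _quantile_bins(frame["fluorescence"].to_numpy(), n_bins)
    uniq, counts = np.unique(bins, return_counts=True)
    alloc = largest_remainder(counts, n)
    take: list[np.ndarray] = []
    positions = np.arange(len(frame))
    for b, m in zip(uniq, alloc):
        pool = positions[bins == b]
        take.append(rng.choice(pool, size=min(m, len(pool)), replace=False))
    idx = np.concatenate(take)
    # top up if any bin was smaller than its allocation
    if len(idx) < n:
        rest = np.setdiff1d(positions, idx)
        idx = np.concatenate([idx, rng.choice(rest, size=n - len(idx), replace=False)])
    return frame.iloc[np.sort(idx)].copy()


@dataclass
class PartitionSpec:
    test_fraction: float = 0.10
    train_pool_size: int | None = 3200
    validation_per_series: int = 400
    n_bins: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValidationError("test_fraction must be in (0,1)")


@dataclass
class SeriesSplit:
    test: pd.DataFrame
    validation: pd.DataFrame
    train_pool: pd.DataFrame


@dataclass
class Partitions:
    splits: dict[int, SeriesSplit]
    spec: PartitionSpec

    @property
    def series_ids(self) -> list[int]:
        return sorted(self.splits)

    @property
    def merged_validation(self) -> pd.DataFrame:
        return pd.concat([self.splits[s].validation for s in self.series_ids], ignore_index=True)

    def manifest(self) -> pd.DataFrame:
        rows = []
        for sid in self.series_ids:
            sp = self.splits[sid]
            for label, frame in (("test", sp.test), ("validation", sp.validation),
                                 ("train_pool", sp.train_pool)):
                for seq_id in frame["seq_id"]:
                    rows.append((seq_id, sid, label))
        return pd.DataFrame(rows, columns=["seq_id", "series_id", "split_label"])


def make_partitions(records, spec: PartitionSpec | None = None) -> Partitions:
    """Per-series stratified test / validation / train-pool split.

    Test is a stratified ``test_fraction`` (rounded) of each series; from the
    remainder a validation slice of ``validation_per_series`` records and a
    training pool of ``train_pool_size`` (or all that is left, when None) are
    drawn.  The three sets are disjoint within each series.
    """
    spec = spec or PartitionSpec()
    frame = as_frame(records)
    splits: dict[int, SeriesSplit] = {}
    for sid, group in frame.groupby("series_id"):
        group = group.reset_index(drop=True)
        n = len(group)
        n_test = round(spec.test_fraction * n)
        pool_need = spec.train_pool_size if spec.train_pool_size is not None else 1
        if n - n_test < spec.validation_per_series + pool_need:
            raise SizingError(
                f"series {sid}: {n} records cannot supply test={n_test}, "
                f"validation={spec.validation_per_series} and a train pool"
            )
        rng = derive_rng(spec.seed, STAGE_PARTITION, int(sid))
        test = stratified_sample(group, n_test, spec.n_bins, rng)
        rest = group.loc[~group["seq_id"].isin(test["seq_id"])]
        val = stratified_sample(rest, spec.validation_per_series, spec.n_bins, rng)
        rest2 = rest.loc[~rest["seq_id"].isin(val["seq_id"])]
        if spec.train_pool_size is None:
            pool = rest2.copy()
        else:
            pool = stratified_sample(rest2, spec.train_pool_size, spec.n_bins, rng)
        splits[int(sid)] = SeriesSplit(
            test.reset_index(drop=True),
            val.reset_index(drop=True),
            pool.reset_index(drop=True),
        )
    return Partitions(splits, spec)


def r_squared(y, f) -> float:
    """Coefficient of determination; may be negative, never above 1."""
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if y.shape != f.shape or y.ndim != 1 or len(y) < 2:
        raise ValidationError("y and f must be equal-length 1-D vectors of length >= 2")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValidationError("R² undefined: constant measurements")
    ss_res = float(((y - f) ** 2).sum())
    return 1.0 - ss_res / ss_tot


@dataclass
class EvalResult:
    model_name: str
    series_id: int
    train_size: int
    repeat_index: int
    r2: float
    y: np.ndarray = field(repr=False)
    f: np.ndarray = field(repr=False)

    @property
    def y_bar(self) -> float:
        return float(np.mean(self.y))


def monte_carlo_cv(
    model_spec,
    encoding_name: str,
    series_id: int,
    train_size: int,
    partitions: Partitions,
    n_repeats: int = 5,
    rng_seed: int = 0,
    k: int = 4,
    biophys_config=None,
    resample_test: bool = False,
) -> list[EvalResult]:
    """Monte Carlo cross-validation for one (model, encoding, series, size) cell.

    Each repeat stratified-samples ``train_size`` records from the series'
    training pool under a fresh derived seed, fits the model, and scores R²
    on the fixed held-out test set.  ``resample_test=True`` switches to a
    sensitivity mode where the test set is re-drawn per repeat from the
    test+pool remainder (the fixed-test protocol is the default).
    """
    from . import models as _models
    from .encoders import encode_train_test

    split = partitions.splits[series_id]
    if train_size > len(split.train_pool):
        raise SizingError(
            f"train_size {train_size} exceeds series {series_id} pool of {len(split.train_pool)}"
        )
    results = []
    for rep in range(n_repeats):
        rng = derive_rng(rng_seed, STAGE_SAMPLING, series_id, rep)
        train = stratified_sample(split.train_pool, train_size, partitions.spec.n_bins, rng)
        if resample_test:
            test = stratified_sample(split.test, len(split.test), partitions.spec.n_bins, rng)
        else:
            test = split.test
        X_train, X_test = encode_train_test(
            encoding_name,
            list(train["sequence"]),
            list(test["sequence"]),
            k=k,
            config=biophys_config,
        )
        seed = derive_int_seed(rng_seed, STAGE_SAMPLING, series_id, rep, 1)
        try:
            handle = _models.fit(model_spec, X_train, train["fluorescence"].to_numpy(), seed)
            f = _models.predict(handle, X_test)
        except Exception as exc:  # annotate with repeat context
            raise type(exc)(f"repeat {rep}: {exc}") from exc
        y = test["fluorescence"].to_numpy()
        results.append(
            EvalResult(
                model_name=getattr(model_spec, "family", str(model_spec)),
                series_id=series_id,
                train_size=train_size,
                repeat_index=rep,
                r2=r_squared(y, f),
                y=y,
                f=f,
            )
        )
    return results


def mean_r2(results: Sequence[EvalResult]) -> float:
    """Arithmetic mean of per-repeat R² values."""
    return float(np.mean([r.r2 for r in results]))
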