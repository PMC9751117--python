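"""Constant-size / increasing-diversity experiments.

The protocol holds the total number of training sequences fixed (default
5800) while aggregating sequences from an increasing number of mutational
series: the first model draws from 2 series, the next from 4, and so on in
steps of 2, with the per-series allocation kept even (floor + remainder to
the first groups).  Some series are excluded from training altogether to
probe generalization.  Every model is evaluated on the held-out test set of
*every* series, giving a model × series R² matrix.

Training-set sequence diversity is quantified by the reciprocal of the
summed counts of the ``top_m`` (default 100) most frequent overlapping
5-mers across all training sequences: flat k-mer usage (diverse sets) gives
a higher score than repetitive usage.

A grouped variant of the protocol emulates promoter-variant screens: many
small variant clusters are first aggregated at random into a few groups
(default 12), and a short schedule of models (default 5, at total size 400)
is run over the groups, evaluated on ~30 held-out sequences per group.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rand import STAGE_SCHEDULE, derive_int_seed, derive_rng
from .errors import SizingError, ValidationError
from .experiment import Partitions, as_frame, mean_r2, r_squared, stratified_sample


def allocate_even(total: int, n_groups: int) -> list[int]:
    """Even integer split: each group gets ⌊total/n⌋, remainder to the first groups."""
    if n_groups < 1:
        raise SizingError("n_groups must be >= 1")
    if total < n_groups:
        raise SizingError(f"cannot give {n_groups} groups at least one of {total}")
    base, rem = divmod(total, n_groups)
    return [base + 1 if i < rem else base for i in range(n_groups)]


@dataclass(frozen=True)
class DiversityScore:
    k: int
    top_m: int
    counts: tuple[int, ...]
    score: float


def diversity_score(sequences: Sequence[str], k: int = 5, top_m: int = 100) -> DiversityScore:
    """1 / (summed counts of the ``top_m`` most frequent overlapping k-mers)."""
    if len(sequences) == 0:
        raise ValidationError("empty sequence set")
    counter: Counter = Counter()
    for s in sequences:
        if len(s) < k:
            raise ValidationError(f"sequence shorter than k={k}")
        for i in range(len(s) - k + 1):
            counter[s[i : i + k]] += 1
    top = tuple(c for _, c in counter.most_common(top_m))
    return DiversityScore(k=k, top_m=top_m, counts=top, score=1.0 / sum(top))


def schedule_series_counts(n_included: int, start: int = 2, step: int = 2) -> list[int]:
    """Series counts along the schedule: start, start+step, ... ≤ n_included."""
    if n_included < start:
        raise SizingError("not enough included series for the schedule start")
    return list(range(start, n_included + 1, step))


@dataclass
class AggregationSchedule:
    """Which series feed each model of the constant-size schedule.

    ``series_order`` is a seeded permutation of all series ids; the last
    ``n_excluded`` ids in it are never used for training.  Model m trains on
    the first ``counts[m]`` ids of the remaining order, with an even
    per-series allocation of ``total_train_size`` sequences.
    """

    series_ids: Sequence[int]
    total_train_size: int = 5800
    step: int = 2
    start: int = 2
    n_excluded: int = 2
    seed: int = 0
    series_order: list[int] = field(init=False)

    def __post_init__(self) -> None:
        ids = list(self.series_ids)
        if len(ids) - self.n_excluded < self.start:
            raise SizingError("too few series for this schedule")
        rng = derive_rng(self.seed, STAGE_SCHEDULE)
        self.series_order = [ids[i] for i in rng.permutation(len(ids))]

    @property
    def excluded_series(self) -> list[int]:
        return sorted(self.series_order[len(self.series_order) - self.n_excluded :])

    @property
    def included_order(self) -> list[int]:
        return self.series_order[: len(self.series_order) - self.n_excluded]

    @property
    def counts(self) -> list[int]:
        return schedule_series_counts(len(self.included_order), self.start, self.step)

    @property
    def n_models(self) -> int:
        return len(self.counts)

    def model_series(self, model_index: int) -> list[int]:
        """Series feeding model ``model_index`` (0-based)."""
        return self.included_order[: self.counts[model_index]]


def build_schedule_datasets(
    partitions: Partitions,
    schedule: AggregationSchedule,
    rng_seed: int = 0,
) -> list[pd.DataFrame]:
    """One training DataFrame per schedule model, drawn from the train pools.

    Each model's total is split evenly over its series (floor + remainder to
    the first series in schedule order) and drawn by stratified sampling from
    each series' training pool; excluded series are never sampled.
    """
    datasets = []
    for m in range(schedule.n_models):
        series = schedule.model_series(m)
        alloc = allocate_even(schedule.total_train_size, len(series))
        parts = []
        for sid, n in zip(series, alloc):
            pool = partitions.splits[sid].train_pool
            if n > len(pool):
                raise SizingError(
                    f"model {m}: series {sid} pool has {len(pool)} < {n} requested"
                )
            rng = derive_rng(rng_seed, STAGE_SCHEDULE, m, sid)
            parts.append(stratified_sample(pool, n, partitions.spec.n_bins, rng))
        datasets.append(pd.concat(parts, ignore_index=True))
    return datasets


@dataclass
class DiversityExperimentResult:
    r2_matrix: pd.DataFrame            # models × series
    diversity: list[DiversityScore]    # per model
    train_manifests: list[pd.DataFrame]
    schedule: AggregationSchedule

    @property
    def mean_r2_per_model(self) -> pd.Series:
        return self.r2_matrix.mean(axis=1)

    def diversity_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.r2_matrix.index,
                "n_series": self.schedule.counts,
                "diversity": [d.score for d in self.diversity],
                "mean_r2": self.mean_r2_per_model.to_numpy(),
            }
        )


def run_diversity_experiment(
    partitions: Partitions,
    schedule: AggregationSchedule,
    model_spec,
    encoding_name: str = "onehot_binary",
    k: int = 4,
    rng_seed: int = 0,
    diversity_k: int = 5,
    diversity_top_m: int = 100,
) -> DiversityExperimentResult:
    """Fit one model per schedule step; score R² on every series' test set."""
    from . import models as _models
    from .encoders import encode

    datasets = build_schedule_datasets(partitions, schedule, rng_seed)
    series_ids = partitions.series_ids
    rows = []
    scores = []
    for m, train in enumerate(datasets):
        scores.append(diversity_score(list(train["sequence"]), diversity_k, diversity_top_m))
        seed = derive_int_seed(rng_seed, STAGE_SCHEDULE, m, 0, 1)
        X_train = encode(encoding_name, list(train["sequence"]), k=k)
        handle = _models.fit(model_spec, X_train, train["fluorescence"].to_numpy(), seed)
        r2_row = {}
        for sid in series_ids:
            test = partitions.splits[sid].test
            X_test = encode(
                encoding_name, list(test["sequence"]), k=k, stats=X_train.stats
            )
            f = _models.predict(handle, X_test)
            r2_row[sid] = r_squared(test["fluorescence"].to_numpy(), f)
        rows.append(r2_row)
    r2_matrix = pd.DataFrame(rows, index=[f"model_{i+1}" for i in range(len(rows))])
    return DiversityExperimentResult(r2_matrix, scores, datasets, schedule)


# ---------------------------------------------------------------------------
# grouped (promoter-screen style) protocol


def group_clusters(
    cluster_ids: Sequence[int], n_groups: int = 12, rng_seed: int = 0
) -> dict[int, int]:
    """Randomly aggregate cluster ids into ``n_groups`` groups (1-based labels).

    Clusters are dealt round-robin over a seeded permutation, so group sizes
    differ by at most one cluster.
    """
    ids = sorted(set(int(c) for c in cluster_ids))
    if n_groups < 1 or n_groups > len(ids):
        raise SizingError(f"cannot form {n_groups} groups from {len(ids)} clusters")
    rng = derive_rng(rng_seed, STAGE_SCHEDULE, 99)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    return {cid: (i % n_groups) + 1 for i, cid in enumerate(perm)}


def run_grouped_experiment(
    library,
    n_groups: int = 12,
    total_train_size: int = 400,
    model_spec=None,
    encoding_name: str = "onehot_binary",
    group_counts: Sequence[int] = (2, 4, 6, 8, 10),
    test_per_group: int = 30,
    n_bins: int = 10,
    rng_seed: int = 0,
) -> DiversityExperimentResult:
    """Constant-size/increasing-diversity protocol over aggregated groups.

    Variant clusters (the library's series ids) are aggregated into
    ``n_groups`` groups; one model per entry of ``group_counts`` is trained
    on ``total_train_size`` sequences split evenly over that many groups and
    evaluated on ~``test_per_group`` held-out sequences from every group.
    """
    from . import models as _models
    from .encoders import encode

    if model_spec is None:
        model_spec = _models.ModelSpec("random_forest")
    frame = as_frame(library)
    mapping = group_clusters(frame["series_id"].tolist(), n_groups, rng_seed)
    frame = frame.assign(group_id=frame["series_id"].map(mapping))

    # per-group held-out test sets and training pools
    tests, pools = {}, {}
    for gid, grp in frame.groupby("group_id"):
        grp = grp.reset_index(drop=True)
        rng = derive_rng(rng_seed, STAGE_SCHEDULE, 100, int(gid))
        n_test = min(test_per_group, max(2, len(grp) // 10))
        test = stratified_sample(grp, n_test, n_bins, rng)
        tests[int(gid)] = test.reset_index(drop=True)
        pools[int(gid)] = grp.loc[~grp["seq_id"].isin(test["seq_id"])].reset_index(drop=True)

    group_ids = sorted(tests)
    rng = derive_rng(rng_seed, STAGE_SCHEDULE, 101)
    order = [group_ids[i] for i in rng.permutation(len(group_ids))]
    rows, scores, manifests = [], [], []
    for m, n_incl in enumerate(group_counts):
        if n_incl > len(order):
            raise SizingError(f"schedule step {n_incl} exceeds {len(order)} groups")
        chosen = order[:n_incl]
        alloc = allocate_even(total_train_size, n_incl)
        parts = []
        for gid, n in zip(chosen, alloc):
            rng_g = derive_rng(rng_seed, STAGE_SCHEDULE, 102, m, gid)
            parts.append(stratified_sample(pools[gid], min(n, len(pools[gid])), n_bins, rng_g))
        train = pd.concat(parts, ignore_index=True)
        manifests.append(train)
        scores.append(diversity_score(list(train["sequence"])))
        seed = derive_int_seed(rng_seed, STAGE_SCHEDULE, 103, m)
        X_train = encode(encoding_name, list(train["sequence"]))
        handle = _models.fit(model_spec, X_train, train["fluorescence"].to_numpy(), seed)
        r2_row = {}
        for gid in group_ids:
            test = tests[gid]
            X_test = encode(encoding_name, list(test["sequence"]), stats=X_train.stats)
            f = _models.predict(handle, X_test)
            r2_row[gid] = r_squared(test["fluorescence"].to_numpy(), f)
        rows.append(r2_row)

    r2_matrix = pd.DataFrame(rows, index=[f"model_{i+1}" for i in range(len(rows))])
    # reuse the schedule container for bookkeeping symmetry
    schedule = AggregationSchedule(
        series_ids=group_ids,
        total_train_size=total_train_size,
        n_excluded=max(0, len(group_ids) - max(group_counts)),
        start=group_counts[0],
        step=(group_counts[1] - group_counts[0]) if len(group_counts) > 1 else 2,
        seed=rng_seed,
    )
    return DiversityExperimentResult(r2_matrix, scores, manifests, schedule)
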