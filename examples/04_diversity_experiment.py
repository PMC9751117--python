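"""Constant-size / increasing-diversity experiment.

Trains one random-forest model per schedule step on a fixed total of
training sequences drawn from an increasing number of mutational series,
then scores every model on every series' held-out test set.  The diversity
of each training set is 1 / (summed counts of its 100 most frequent 5-mers).
"""

from seq2exp.diversity import AggregationSchedule, run_diversity_experiment
from seq2exp.experiment import PartitionSpec, make_partitions
from seq2exp.models import ModelSpec
from seq2exp.synthetic import LibraryConfig, build_library

library = build_library(config=LibraryConfig(
    n_series=6, variants_per_series=700, length=30, master_seed=9))
partitions = make_partitions(library, PartitionSpec(
    train_pool_size=None, validation_per_series=70, seed=9))

schedule = AggregationSchedule(
    series_ids=partitions.series_ids, total_train_size=800,
    start=2, step=1, n_excluded=2, seed=9)
result = run_diversity_experiment(
    partitions, schedule, ModelSpec("random_forest", {"n_estimators": 60}),
    rng_seed=9)

print(f"schedule: {schedule.n_models} models, total 800 sequences each, "
      f"excluded series {schedule.excluded_series}\n")
print(result.diversity_frame().to_string(index=False))
print()
print("R² per (model, series); series absent from training regress poorly:")
print(result.r2_matrix.round(2).to_string())
print()
print("diversity and mean R² rise together as series are added at constant size.")
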