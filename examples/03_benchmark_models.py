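"""Benchmark regressors across encodings with Monte Carlo cross-validation.

Per mutational series the data are split into a fixed stratified 10% test
set, a validation slice and a training pool; each (model, encoding, size)
cell is scored as the mean R² over repeats with resampled training sets.
"""

from seq2exp.experiment import (
    PartitionSpec, make_partitions, mean_r2, monte_carlo_cv,
)
from seq2exp.models import ModelSpec
from seq2exp.synthetic import LibraryConfig, build_library

library = build_library(config=LibraryConfig(
    n_series=2, variants_per_series=900, length=30, master_seed=3))
partitions = make_partitions(library, PartitionSpec(
    train_pool_size=None, validation_per_series=90, seed=3))

models = {
    "ridge": ModelSpec("ridge", {"alpha": 1.0}),
    "random_forest": ModelSpec("random_forest", {"n_estimators": 60}),
    "mlp": ModelSpec("mlp"),
}
print("series 1, train size 400, 3 repeats\n")
print("model          encoding        mean R²")
for mname, spec in models.items():
    for enc in ("onehot_binary", "biophysical"):
        r2 = mean_r2(monte_carlo_cv(spec, enc, 1, 400, partitions,
                                    n_repeats=3, rng_seed=3))
        print(f"{mname:<14} {enc:<15} {r2:>7.3f}")
print()
print("R² = 1 is a perfect fit, 0 matches the mean-baseline predictor.")
print("The synthetic ground truth is a function of the 8 biophysical properties,")
print("so the biophysical encoding shines here; on real screens it usually")
print("trails base-resolution one-hot encodings.")
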