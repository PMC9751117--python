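"""Run configuration and pipeline stages behind the command-line interface.

Each ``cmd_*`` function is a thin, reproducible wrapper over one analysis
stage: it reads a :class:`RunConfig`, derives all randomness from the master
seed, writes tidy CSV/JSON outputs under a seed-stamped directory, and
returns the primary result so the stages are equally usable from Python.
Two runs with identical configuration and seed produce identical outputs
(up to float round-trip through CSV).
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .diversity import (
    AggregationSchedule,
    run_diversity_experiment,
    run_grouped_experiment,
)
from .errors import ConfigurationError
from .experiment import PartitionSpec, make_partitions, monte_carlo_cv
from .models import ModelSpec
from .synthetic import LibraryConfig

logger = logging.getLogger("seq2exp")

#: study-condition presets; "full" matches the screen being emulated
SCALES = {
    "ci": dict(n_series=8, variants_per_series=1200),
    "desk": dict(n_series=14, variants_per_series=3700),
    "full": dict(n_series=56, variants_per_series=4000),
}


@dataclass
class RunConfig:
    """Fully serializable run description; config + code version reproduce a run."""

    master_seed: int = 0
    scale: str = "ci"
    library: dict = field(default_factory=dict)       # LibraryConfig overrides
    partition: dict = field(default_factory=dict)     # PartitionSpec overrides
    benchmark: dict = field(default_factory=dict)
    diversity: dict = field(default_factory=dict)
    grouped: dict = field(default_factory=dict)
    attribute: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ConfigurationError(f"unknown scale {self.scale!r}; pick from {list(SCALES)}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = cls.__dataclass_fields__
        extra = set(data) - set(known)
        if extra:
            raise ConfigurationError(f"unknown config keys: {sorted(extra)}")
        if "master_seed" not in data:
            raise ConfigurationError("config missing required key 'master_seed'")
        return cls(**data)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    def library_config(self) -> LibraryConfig:
        kw = {**SCALES[self.scale], "master_seed": self.master_seed, **self.library}
        return LibraryConfig(**kw)

    def partition_spec(self, library_cfg: LibraryConfig) -> PartitionSpec:
        kw = dict(self.partition)
        kw.setdefault("seed", self.master_seed)
        # default pool: everything left after test + validation
        kw.setdefault("train_pool_size", None)
        n = library_cfg.variants_per_series
        kw.setdefault("validation_per_series", min(400, max(10, n // 10)))
        return PartitionSpec(**kw)


def make_run_dir(outdir, seed: int) -> Path:
    stamp = datetime.now(timezone.utc).strftime("%Y%m%dT%H%M%S")
    path = Path(outdir) / f"{stamp}_seed{seed}"
    path.mkdir(parents=True, exist_ok=True)
    return path


def setup_logging(run_dir: Path | None = None) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if run_dir is not None:
        handlers.append(logging.FileHandler(run_dir / "run.log"))
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


def _build_library(config: RunConfig):
    lib_cfg = config.library_config()
    logger.info(
        "generating library: %d series x %d variants, L=%d, seed=%d",
        lib_cfg.n_series, lib_cfg.variants_per_series, lib_cfg.length, lib_cfg.master_seed,
    )
    return synthetic.build_library(config=lib_cfg)


def cmd_generate(config: RunConfig, run_dir: Path):
    """Generate a library; write CSV, FASTA and a config echo."""
    lib = _build_library(config)
    synthetic.write_csv(lib.records, run_dir / "library.csv")
    synthetic.write_fasta(lib.records, run_dir / "library.fasta")
    (run_dir / "generator_config.json").write_text(lib.config.to_json())
    config.to_json(run_dir / "run_config.json")
    logger.info("wrote %d records to %s", len(lib), run_dir / "library.csv")
    return lib


def _model_specs(entries) -> list[ModelSpec]:
    specs = []
    for e in entries:
        if isinstance(e, str):
            specs.append(ModelSpec(e))
        else:
            specs.append(ModelSpec(e["family"], e.get("hyperparameters", {})))
    return specs


def cmd_benchmark(config: RunConfig, run_dir: Path) -> pd.DataFrame:
    """Encoding × model × train-size grid with Monte Carlo cross-validation."""
    lib = _build_library(config)
    spec = config.partition_spec(lib.config)
    partitions = make_partitions(lib, spec)
    bench = config.benchmark
    encodings = bench.get("encodings", ["onehot_binary", "biophysical"])
    model_specs = _model_specs(bench.get("models", ["ridge", "random_forest"]))
    train_sizes = bench.get("train_sizes", [200, 500])
    series_ids = bench.get("series_ids", partitions.series_ids)
    n_repeats = bench.get("n_repeats", 5)
    rows = []
    for ms in model_specs:
        for enc in encodings:
            for sid in series_ids:
                for size in train_sizes:
                    t0 = time.perf_counter()
                    results = monte_carlo_cv(
                        ms, enc, sid, size, partitions,
                        n_repeats=n_repeats, rng_seed=config.master_seed,
                    )
                    dt = time.perf_counter() - t0
                    for r in results:
                        rows.append(
                            (ms.family, enc, sid, size, r.repeat_index, r.r2)
                        )
                        logger.info(
                            "fit model=%s enc=%s series=%d size=%d repeat=%d "
                            "seed=%d r2=%.4f duration=%.2fs",
                            ms.family, enc, sid, size, r.repeat_index,
                            config.master_seed, r.r2, dt / n_repeats,
                        )
    frame = pd.DataFrame(
        rows, columns=["model", "encoding", "series", "train_size", "repeat", "r2"]
    )
    frame.to_csv(run_dir / "benchmark_results.csv", index=False)
    config.to_json(run_dir / "run_config.json")
    return frame


def cmd_diversity(config: RunConfig, run_dir: Path):
    """Constant-size / increasing-diversity schedule over mutational series."""
    lib = _build_library(config)
    spec = config.partition_spec(lib.config)
    partitions = make_partitions(lib, spec)
    div = config.diversity
    schedule = AggregationSchedule(
        series_ids=partitions.series_ids,
        total_train_size=div.get("total_train_size", 5800),
        step=div.get("step", 2),
        start=div.get("start", 2),
        n_excluded=div.get("n_excluded", 2),
        seed=config.master_seed,
    )
    model = _model_specs([div.get("model", "random_forest")])[0]
    result = run_diversity_experiment(
        partitions, schedule, model,
        encoding_name=div.get("encoding", "onehot_binary"),
        rng_seed=config.master_seed,
    )
    result.r2_matrix.to_csv(run_dir / "diversity_r2_matrix.csv")
    result.diversity_frame().to_csv(run_dir / "diversity_scores.csv", index=False)
    for m, manifest in enumerate(result.train_manifests, start=1):
        manifest[["seq_id", "series_id"]].to_csv(
            run_dir / f"train_manifest_model{m:02d}.csv", index=False
        )
    sidecar = {
        "excluded_series": schedule.excluded_series,
        "series_order": schedule.series_order,
        "diversity": [d.score for d in result.diversity],
    }
    (run_dir / "diversity_sidecar.json").write_text(json.dumps(sidecar, indent=1))
    config.to_json(run_dir / "run_config.json")
    return result


def cmd_grouped_diversity(config: RunConfig, run_dir: Path):
    """Grouped (promoter-screen style) diversity protocol."""
    grp = config.grouped
    lib = synthetic.build_clustered_library(
        n_clusters=grp.get("n_clusters", 199),
        total_variants=grp.get("total_variants", 3929),
        length=grp.get("length", 81),
    )
    result = run_grouped_experiment(
        lib,
        n_groups=grp.get("n_groups", 12),
        total_train_size=grp.get("total_train_size", 400),
        group_counts=tuple(grp.get("group_counts", (2, 4, 6, 8, 10))),
        rng_seed=config.master_seed,
    )
    result.r2_matrix.to_csv(run_dir / "grouped_r2_matrix.csv")
    result.diversity_frame().to_csv(run_dir / "grouped_scores.csv", index=False)
    config.to_json(run_dir / "run_config.json")
    return result


def cmd_attribute(config: RunConfig, run_dir: Path):
    """Train two networks on one series and compare their attribution structure."""
    from . import models as _models
    from .attribution import (
        attribute_set,
        attribution_distance_matrix,
        compare_models,
        hierarchical_order,
    )
    from .encoders import encode
    from .experiment import stratified_sample

    lib = _build_library(config)
    spec = config.partition_spec(lib.config)
    partitions = make_partitions(lib, spec)
    att = config.attribute
    sid = att.get("series_id", partitions.series_ids[0])
    split = partitions.splits[sid]
    train_size = att.get("train_size", min(1000, len(split.train_pool)))
    train = stratified_sample(split.train_pool, train_size, spec.n_bins, config.master_seed)
    X = encode("onehot_binary", list(train["sequence"]))
    y = train["fluorescence"].to_numpy()
    cnn = _models.fit(ModelSpec("cnn"), X, y, config.master_seed)
    mlp = _models.fit(ModelSpec("mlp"), X, y, config.master_seed)

    n_seq = att.get("n_sequences", 30)
    rng = np.random.default_rng(config.master_seed)
    take = rng.choice(len(split.test), size=min(n_seq, len(split.test)), replace=False)
    subset = split.test.iloc[np.sort(take)]

    for name, handle in (("cnn", cnn), ("mlp", mlp)):
        vectors = attribute_set(handle, subset)
        pd.DataFrame(
            [v.scores for v in vectors], index=[v.seq_id for v in vectors]
        ).to_csv(run_dir / f"attribution_scores_{name}.csv")
        dm = attribution_distance_matrix(vectors)
        dm.to_frame().to_csv(run_dir / f"attribution_distances_{name}.csv")
        order = hierarchical_order(dm)
        (run_dir / f"attribution_order_{name}.json").write_text(json.dumps(order))
    comparison = compare_models(cnn, mlp, subset, rng_seed=config.master_seed)
    comparison.curve_a.to_csv(run_dir / "kmeans_curve_cnn.csv", index=False)
    comparison.curve_b.to_csv(run_dir / "kmeans_curve_mlp.csv", index=False)
    (run_dir / "attribution_verdict.json").write_text(
        json.dumps({"series_id": sid, "verdict": comparison.verdict})
    )
    config.to_json(run_dir / "run_config.json")
    return comparison
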