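"""Synthetic genotype–phenotype libraries with mutational-series structure.

Real screens of this kind build a library from a few dozen *seed* sequences
chosen to be mutually distant in Hamming space, then randomize each seed into
a *mutational series* of thousands of local variants, and read out a
normalized fluorescence per variant.  This module emulates that structure
with a known ground-truth sequence→fluorescence map so that every downstream
stage (encodings, partitioning, model benchmarking, diversity experiments)
can be tested without external data.

The ground-truth map is a logistic-linear function of the eight biophysical
properties (see :mod:`seq2exp.biophys`), optionally with a threshold switch
term that creates bimodal phenotype distributions.  Per-series calibration of
the map produces the qualitatively distinct phenotype shapes observed in real
libraries: near-Gaussian, left- and right-skewed, bimodal and uniform.

All randomness flows from one master seed via per-series derived streams, so
any single series is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from . import biophys
from ._rand import (
    STAGE_PHENOTYPE,
    STAGE_SEEDS,
    STAGE_SERIES,
    derive_rng,
)
from .errors import ConfigurationError, ValidationError

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_STOPS = ("TAA", "TAG", "TGA")

SHAPES = ("gaussian", "left_skew", "right_skew", "bimodal", "uniform")


@dataclass(frozen=True)
class SequenceRecord:
    """One library variant."""

    seq_id: str
    series_id: int
    sequence: str
    fluorescence: float

    def __post_init__(self) -> None:
        if not set(self.sequence) <= set(_BASES):
            raise ValidationError(f"{self.seq_id}: non-ACGT sequence")
        if not 0.0 <= self.fluorescence <= 1.0:
            raise ValidationError(f"{self.seq_id}: fluorescence outside [0,1]")


@dataclass(frozen=True)
class SeedSet:
    seeds: tuple[str, ...]
    min_pairwise_hamming: int


@dataclass
class GroundTruthModel:
    """Parametric sequence→fluorescence map over normalized biophysical properties.

    u = weights · φ_norm + offset − switch_depth · 1[φ_norm(switch_property) < switch_threshold]
    fluorescence = clip(link(u) + N(0, noise_sd²), 0, 1)

    ``link`` is the logistic squashing by default; the identity link (clamped)
    gives an exactly linear noise-free map, used for parameter-recovery tests.
    """

    weights: np.ndarray
    offset: float = 0.0
    switch_property: str | None = None
    switch_threshold: float = 0.0
    switch_depth: float = 0.0
    noise_sd: float = 0.0
    shape: str = "gaussian"
    link: str = "logistic"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(biophys.PROPERTY_NAMES),):
            raise ConfigurationError("weights must have one entry per biophysical property")
        if self.switch_depth < 0 or self.noise_sd < 0:
            raise ConfigurationError("switch_depth and noise_sd must be non-negative")
        if self.switch_property is not None and self.switch_property not in biophys.PROPERTY_NAMES:
            raise ConfigurationError(f"unknown switch_property {self.switch_property!r}")
        if self.link not in ("logistic", "identity"):
            raise ConfigurationError(f"unknown link {self.link!r}")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValidationError("Hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def _random_sequences(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=(n, length), dtype=np.int8)


def _to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def design_seeds(
    n_seeds: int, length: int, candidate_pool: int = 200, rng_seed: int = 0
) -> SeedSet:
    """Greedy maximin seed design.

    The first seed is drawn uniformly; each subsequent seed is the candidate
    (among ``candidate_pool`` uniform draws, or all 4^length strings when the
    pool covers them) that maximizes the minimum Hamming distance to the
    seeds already chosen.  Ties go to the first candidate.
    """
    if n_seeds < 1 or length < 1 or candidate_pool < 1:
        raise ValidationError("n_seeds, length and candidate_pool must be >= 1")
    if length <= 16 and n_seeds > 4**length:
        raise ConfigurationError(f"cannot choose {n_seeds} distinct seeds of length {length}")
    rng = derive_rng(rng_seed, STAGE_SEEDS)
    chosen = [_random_sequences(rng, 1, length)[0]]
    exhaustive = length <= 8 and candidate_pool >= 4**length
    if exhaustive:
        grid = np.array(
            np.meshgrid(*([np.arange(4, dtype=np.int8)] * length), indexing="ij")
        ).reshape(length, -1).T
    for _ in range(1, n_seeds):
        cands = grid if exhaustive else _random_sequences(rng, candidate_pool, length)
        mat = np.stack(chosen)  # (m, L)
        # min Hamming distance of each candidate to the chosen set
        dmin = (cands[:, None, :] != mat[None, :, :]).sum(axis=2).min(axis=1)
        chosen.append(cands[int(np.argmax(dmin))].copy())
    seeds = tuple(_to_str(c) for c in chosen)
    if len(seeds) == 1:
        mph = length  # vacuous: no pairs
    else:
        mph = min(
            hamming(seeds[i], seeds[j]) for i in range(len(seeds)) for j in range(i + 1, len(seeds))
        )
    return SeedSet(seeds=seeds, min_pairwise_hamming=mph)


def generate_series(
    seed: str,
    n_variants: int,
    per_position_mutation_prob: float,
    rng_seed: int = 0,
) -> list[str]:
    """Mutate each position of ``seed`` independently with the given probability.

    Substitutions are uniform over the three other bases.
    """
    if not 0.0 <= per_position_mutation_prob <= 1.0:
        raise ValidationError("per_position_mutation_prob must be in [0,1]")
    if not set(seed) <= set(_BASES):
        raise ValidationError("seed contains non-ACGT characters")
    rng = derive_rng(rng_seed, STAGE_SERIES)
    codes = np.array([_CODE[b] for b in seed], dtype=np.int8)
    mask = rng.random((n_variants, codes.size)) < per_position_mutation_prob
    shifts = rng.integers(1, 4, size=(n_variants, codes.size), dtype=np.int8)
    out = np.where(mask, (codes[None, :] + shifts) % 4, codes[None, :])
    return [_to_str(row) for row in out]


def remove_stop_codons(sequence: str) -> str:
    """Repair in-frame stop codons by rewriting their third base to T.

    TAA/TAG → TAT (Tyr), TGA → TGT (Cys).  Used during library assembly so
    that the translated-peptide property (MHI) is defined for every record.
    """
    codons = [sequence[i : i + 3] for i in range(0, len(sequence) - len(sequence) % 3, 3)]
    fixed = [c[:2] + "T" if c in _STOPS else c for c in codons]
    return "".join(fixed) + sequence[len(codons) * 3 :]


def compute_norm_stats(
    sequences: Sequence[str], config: biophys.BiophysConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-property (min, max) over a set of sequences, for min–max normalization."""
    mat = biophys.profile_matrix(sequences, config)
    return mat.min(axis=0), mat.max(axis=0)


def _normalize(mat: np.ndarray, stats: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    lo, hi = stats
    span = np.where(hi > lo, hi - lo, 1.0)
    out = (mat - lo) / span
    out[:, hi <= lo] = 0.0
    return out


def _link(u: np.ndarray, link: str) -> np.ndarray:
    if link == "logistic":
        return 1.0 / (1.0 + np.exp(-u))
    return u


def simulate_phenotypes(
    sequences: Sequence[str],
    model: GroundTruthModel,
    norm_stats: tuple[np.ndarray, np.ndarray],
    rng_seed: int = 0,
    config: biophys.BiophysConfig | None = None,
    profiles: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized ground-truth fluorescence for many sequences."""
    if profiles is None:
        profiles = biophys.profile_matrix(sequences, config)
    phi = _normalize(profiles, norm_stats)
    u = phi @ model.weights + model.offset
    if model.switch_property is not None:
        j = biophys.PROPERTY_NAMES.index(model.switch_property)
        u = u - model.switch_depth * (phi[:, j] < model.switch_threshold)
    y = _link(u, model.link)
    if model.noise_sd > 0:
        rng = derive_rng(rng_seed, STAGE_PHENOTYPE)
        y = y + rng.normal(0.0, model.noise_sd, size=y.shape)
    return np.clip(y, 0.0, 1.0)


def simulate_phenotype(
    sequence: str,
    model: GroundTruthModel,
    norm_stats: tuple[np.ndarray, np.ndarray],
    rng_seed: int = 0,
    config: biophys.BiophysConfig | None = None,
) -> float:
    """Ground-truth fluorescence of a single sequence (deterministic when noise_sd=0)."""
    return float(simulate_phenotypes([sequence], model, norm_stats, rng_seed, config)[0])


# per-shape calibration constants: (gain a, offset b, switch depth d)
# u = a·z + b − d·1[switch], z the standardized linear score within the series
_SHAPE_PARAMS = {
    "gaussian": (0.9, 0.0, 0.0),
    "right_skew": (1.0, -2.0, 0.0),
    "left_skew": (1.0, 2.0, 0.0),
    "bimodal": (0.6, 2.2, 4.4),
    "uniform": (1.7, 0.0, 0.0),
}


def _draw_symmetric_weights(
    rng: np.random.Generator, phi_norm: np.ndarray, n_draws: int = 20
) -> np.ndarray:
    """Draw candidate weight vectors, keep the one with the most symmetric score.

    The discrete biophysical properties (bottleneck position, the integer fold
    scores) can make a single random linear score strongly skewed; choosing
    the most symmetric of a few draws keeps the standardized score near-normal
    so the shape presets transform it predictably.
    """
    best_w, best_skew = None, np.inf
    for _ in range(n_draws):
        w = rng.uniform(-1.0, 1.0, size=phi_norm.shape[1])
        s = phi_norm @ w
        sd = s.std()
        if sd <= 0:
            continue
        z = (s - s.mean()) / sd
        sk = abs(float((z**3).mean()))
        if sk < best_skew:
            best_w, best_skew = w, sk
        if sk < 0.1:
            break
    return best_w if best_w is not None else rng.uniform(-1, 1, phi_norm.shape[1])


def calibrate_series_model(
    base_weights: np.ndarray,
    phi_norm: np.ndarray,
    shape: str,
    noise_sd: float,
    link: str = "logistic",
) -> GroundTruthModel:
    """Fold per-series standardization and a shape preset into a GroundTruthModel.

    The raw linear score s = base_weights·φ is standardized using the series'
    empirical mean and standard deviation, then scaled and shifted by the
    shape preset.  The bimodal preset adds a threshold switch on the property
    with the largest absolute weight, split at its series median.
    """
    if shape not in SHAPES:
        raise ConfigurationError(f"unknown shape {shape!r}")
    s = phi_norm @ base_weights
    mu, sd = float(s.mean()), float(s.std())
    if sd <= 0:
        sd = 1.0
    a, b, d = _SHAPE_PARAMS[shape]
    weights = a * base_weights / sd
    offset = b - a * mu / sd
    switch_property = None
    switch_threshold = 0.0
    if shape == "bimodal":
        # switch on a continuous property whose median split is balanced;
        # discrete properties (btl_p, the integer fold scores) tie at the
        # median and would produce lobes of very unequal mass
        candidates = ("at_content", "cai", "btl_s", "mhi")
        idx = [biophys.PROPERTY_NAMES.index(c) for c in candidates]
        idx.sort(key=lambda j: -abs(base_weights[j]))
        best_j, best_balance = idx[0], 0.0
        for j in idx:
            thr = float(np.median(phi_norm[:, j]))
            frac = float(np.mean(phi_norm[:, j] < thr))
            balance = min(frac, 1.0 - frac)
            if balance >= 0.35:
                best_j, best_balance = j, balance
                break
            if balance > best_balance:
                best_j, best_balance = j, balance
        switch_property = biophys.PROPERTY_NAMES[best_j]
        switch_threshold = float(np.median(phi_norm[:, best_j]))
    return GroundTruthModel(
        weights=weights,
        offset=offset,
        switch_property=switch_property,
        switch_threshold=switch_threshold,
        switch_depth=d,
        noise_sd=noise_sd,
        shape=shape,
        link=link,
    )


@dataclass
class LibraryConfig:
    """Study conditions of the synthetic library.

    Defaults emulate the full-scale screen: 56 series of ~4000 variants with
    96-nt variable regions; ``scaled()`` gives an 8 × 1200 configuration for
    fast continuous-integration runs.
    """

    length: int = 96
    n_series: int = 56
    variants_per_series: int = 4000
    mutation_rate: float = 0.05
    noise_sd: float = 0.02
    shapes: tuple[str, ...] = SHAPES
    candidate_pool: int = 200
    master_seed: int = 0
    link: str = "logistic"
    biophys_config: biophys.BiophysConfig | None = None

    def __post_init__(self) -> None:
        if self.length % 3 != 0:
            raise ConfigurationError("length must be a multiple of 3 (in-frame codons)")
        if self.biophys_config is None:
            self.biophys_config = biophys.BiophysConfig(
                btl_window=min(8, self.length // 3)
            )

    @classmethod
    def scaled(cls, master_seed: int = 0, **kw) -> "LibraryConfig":
        return cls(n_series=8, variants_per_series=1200, master_seed=master_seed, **kw)

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items() if k != "biophys_config"}
        d["shapes"] = list(self.shapes)
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LibraryConfig":
        d = json.loads(text)
        d["shapes"] = tuple(d.get("shapes", SHAPES))
        return cls(**d)


@dataclass
class SyntheticLibrary(Sequence):
    """A generated library: records plus its generating ground truth."""

    records: list[SequenceRecord]
    seed_set: SeedSet
    series_models: dict[int, GroundTruthModel]
    norm_stats: tuple[np.ndarray, np.ndarray]
    config: LibraryConfig

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def records_to_frame(records: Sequence[SequenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "seq_id": [r.seq_id for r in records],
            "series_id": [r.series_id for r in records],
            "sequence": [r.sequence for r in records],
            "fluorescence": [r.fluorescence for r in records],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[SequenceRecord]:
    return [
        SequenceRecord(str(r.seq_id), int(r.series_id), str(r.sequence), float(r.fluorescence))
        for r in frame.itertuples(index=False)
    ]


def build_library(
    n_series: int | None = None,
    variants_per_series: int | None = None,
    config: LibraryConfig | None = None,
) -> SyntheticLibrary:
    """Generate a full library: seeds → series → repaired variants → phenotypes.

    Per-series phenotype shapes cycle through ``config.shapes``.  The library
    is byte-identical across runs for a fixed configuration and master seed.
    """
    config = config or LibraryConfig()
    if n_series is not None or variants_per_series is not None:
        config = replace(
            config,
            n_series=n_series if n_series is not None else config.n_series,
            variants_per_series=(
                variants_per_series
                if variants_per_series is not None
                else config.variants_per_series
            ),
            biophys_config=config.biophys_config,
        )
    seed_set = design_seeds(
        config.n_series, config.length, config.candidate_pool, rng_seed=config.master_seed
    )
    all_seqs: list[list[str]] = []
    for sid in range(1, config.n_series + 1):
        variants = generate_series(
            seed_set.seeds[sid - 1],
            config.variants_per_series,
            config.mutation_rate,
            rng_seed=int(derive_rng(config.master_seed, STAGE_SERIES, sid).integers(2**31)),
        )
        all_seqs.append([remove_stop_codons(v) for v in variants])
    flat = [s for series in all_seqs for s in series]
    profiles = biophys.profile_matrix(flat, config.biophys_config)
    norm_stats = (profiles.min(axis=0), profiles.max(axis=0))
    phi = _normalize(profiles, norm_stats)

    records: list[SequenceRecord] = []
    series_models: dict[int, GroundTruthModel] = {}
    offset = 0
    for sid in range(1, config.n_series + 1):
        n = len(all_seqs[sid - 1])
        phi_series = phi[offset : offset + n]
        rng = derive_rng(config.master_seed, STAGE_PHENOTYPE, sid)
        base_w = _draw_symmetric_weights(rng, phi_series)
        shape = config.shapes[(sid - 1) % len(config.shapes)]
        model = calibrate_series_model(base_w, phi_series, shape, config.noise_sd, config.link)
        series_models[sid] = model
        y = simulate_phenotypes(
            all_seqs[sid - 1],
            model,
            norm_stats,
            rng_seed=int(rng.integers(2**31)),
            config=config.biophys_config,
            profiles=profiles[offset : offset + n],
        )
        for i, (s, f) in enumerate(zip(all_seqs[sid - 1], y), start=1):
            records.append(SequenceRecord(f"s{sid:02d}_v{i:05d}", sid, s, float(f)))
        offset += n
    return SyntheticLibrary(records, seed_set, series_models, norm_stats, config)


def build_linear_series(
    n_variants: int = 2000,
    length: int = 30,
    weights: np.ndarray | None = None,
    offset: float = 0.1,
    mutation_rate: float = 0.08,
    master_seed: int = 0,
) -> SyntheticLibrary:
    """One series with an exactly linear, noise-free ground truth.

    Uses the identity link with non-negative weights summing to 0.8 and
    offset 0.1, so fluorescence = weights·φ_norm + offset lies in [0.1, 0.9]
    and is never clipped: a linear model on the normalized biophysical
    encoding can recover the weights exactly.  Intended for parameter-
    recovery checks.
    """
    config = LibraryConfig(
        length=length, n_series=1, variants_per_series=n_variants,
        mutation_rate=mutation_rate, master_seed=master_seed,
    )
    seed_set = design_seeds(1, length, rng_seed=master_seed)
    variants = [
        remove_stop_codons(v)
        for v in generate_series(
            seed_set.seeds[0], n_variants, mutation_rate, rng_seed=master_seed
        )
    ]
    profiles = biophys.profile_matrix(variants, config.biophys_config)
    norm_stats = (profiles.min(axis=0), profiles.max(axis=0))
    if weights is None:
        rng = derive_rng(master_seed, STAGE_PHENOTYPE, 0)
        weights = rng.uniform(0.2, 1.0, size=len(biophys.PROPERTY_NAMES))
    weights = 0.8 * np.asarray(weights, dtype=float) / np.sum(np.abs(weights))
    model = GroundTruthModel(weights=weights, offset=offset, link="identity", noise_sd=0.0)
    y = simulate_phenotypes(
        variants, model, norm_stats, config=config.biophys_config, profiles=profiles
    )
    records = [
        SequenceRecord(f"s01_v{i:05d}", 1, s, float(f))
        for i, (s, f) in enumerate(zip(variants, y), start=1)
    ]
    return SyntheticLibrary(records, seed_set, {1: model}, norm_stats, config)


# ---------------------------------------------------------------------------
# promoter-screen emulation: many small variant clusters of natural genes

def build_clustered_library(
    n_clusters: int = 199,
    total_variants: int = 3929,
    length: int = 81,
    config: LibraryConfig | None = None,
) -> SyntheticLibrary:
    """Library shaped like a promoter-variant screen: many small clusters.

    ``total_variants`` records are spread over ``n_clusters`` clusters with a
    floor + first-remainder rule (e.g. 3929 over 199 clusters gives ~20
    variants per cluster).  Cluster ids play the role of series ids.
    """
    from .diversity import allocate_even  # local import avoids a cycle

    sizes = allocate_even(total_variants, n_clusters)
    config = config or LibraryConfig(
        length=length, n_series=n_clusters, variants_per_series=max(sizes)
    )
    lib = build_library(config=config)
    # trim each series down to its allocated size, preserving order
    kept: list[SequenceRecord] = []
    by_series: dict[int, list[SequenceRecord]] = {}
    for r in lib.records:
        by_series.setdefault(r.series_id, []).append(r)
    for sid in range(1, n_clusters + 1):
        kept.extend(by_series[sid][: sizes[sid - 1]])
    return SyntheticLibrary(kept, lib.seed_set, lib.series_models, lib.norm_stats, config)


# ---------------------------------------------------------------------------
# I/O

CSV_COLUMNS = ("seq_id", "series_id", "sequence", "fluorescence")


def write_csv(records: Sequence[SequenceRecord] | pd.DataFrame, path) -> None:
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    frame.to_csv(path, index=False, columns=list(CSV_COLUMNS))


def read_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"genotype–phenotype CSV missing columns: {sorted(missing)}")
    return frame[list(CSV_COLUMNS)]


def write_fasta(records: Sequence[SequenceRecord] | pd.DataFrame, path) -> None:
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord as BioRecord
    from Bio.Seq import Seq

    if isinstance(records, pd.DataFrame):
        records = frame_to_records(records)
    bio = [
        BioRecord(Seq(r.sequence), id=r.seq_id, description=str(r.series_id)) for r in records
    ]
    seqio_write(bio, str(path), "fasta")
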