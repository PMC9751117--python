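"""DNA encodings for model training.

Six encodings at three resolutions, with exact dimensional contracts for a
sequence of length L and k-mer size k:

==================  =========  =============
encoding            resolution  n_cols
==================  =========  =============
biophysical         global      8
kmer_counts         subseq      4^k
kmer_ordinal        subseq      L − k + 1
onehot_binary       base        4·L
onehot_ordinal      base        L
mixed               multiple    4·L + 8
==================  =========  =============

Binary one-hot uses channel order A,C,G,T and position-major flattening
(positions outer, channels inner), so a 96-nt sequence flattens to a
384-vector.  Ordinal codes are A→1, C→2, G→3, T→4; ordinal k-mer codes are
the 1-based lexicographic rank among the 4^k possible k-mers.  Biophysical
columns are min–max normalized; the statistics can be fitted on a training
set and re-applied to a test set to avoid leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np

from . import biophys
from .errors import ValidationError

logger = logging.getLogger(__name__)

ENCODING_NAMES = (
    "biophysical",
    "kmer_counts",
    "kmer_ordinal",
    "onehot_binary",
    "onehot_ordinal",
    "mixed",
)

_ORD = {"A": 1, "C": 2, "G": 3, "T": 4}


@dataclass
class EncodedMatrix:
    encoding_name: str
    values: np.ndarray
    L: int
    k: int | None = None
    columns: list[str] | None = None
    stats: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def __post_init__(self) -> None:
        expected = expected_n_cols(self.encoding_name, self.L, self.k)
        if self.values.ndim != 2 or self.values.shape[1] != expected:
            raise ValidationError(
                f"{self.encoding_name}: expected {expected} columns, got {self.values.shape}"
            )


def expected_n_cols(name: str, L: int, k: int | None = None) -> int:
    """The dimension contract of each encoding."""
    if name == "biophysical":
        return 8
    if name == "kmer_counts":
        return 4**k
    if name == "kmer_ordinal":
        return L - k + 1
    if name == "onehot_binary":
        return 4 * L
    if name == "onehot_ordinal":
        return L
    if name == "mixed":
        return 4 * L + 8
    raise ValidationError(f"unknown encoding {name!r}")


def _codes(sequences: Sequence[str], L: int | None) -> tuple[np.ndarray, int]:
    if not sequences:
        raise ValidationError("no sequences to encode")
    lengths = {len(s) for s in sequences}
    if L is None:
        if len(lengths) != 1:
            raise ValidationError("ragged sequence lengths; pass a common L")
        L = lengths.pop()
    elif lengths != {L}:
        raise ValidationError(f"sequences must all have length {L}")
    table = np.full(128, -1, dtype=np.int8)
    for b, i in zip("ACGT", range(4)):
        table[ord(b)] = i
    arr = np.frombuffer("".join(sequences).encode(), dtype=np.uint8).reshape(len(sequences), L)
    codes = table[arr]
    if (codes < 0).any():
        raise ValidationError("sequences contain non-ACGT characters")
    return codes.astype(np.int64), L


def encode_onehot_binary(sequences: Sequence[str], L: int | None = None) -> EncodedMatrix:
    """4-channel indicator per position, flattened position-major to 4·L columns."""
    codes, L = _codes(sequences, L)
    n = codes.shape[0]
    out = np.zeros((n, L, 4))
    np.put_along_axis(out, codes[:, :, None], 1.0, axis=2)
    return EncodedMatrix("onehot_binary", out.reshape(n, 4 * L), L=L)


def encode_onehot_ordinal(sequences: Sequence[str], L: int | None = None) -> EncodedMatrix:
    """Integer code per base: A→1, C→2, G→3, T→4."""
    codes, L = _codes(sequences, L)
    return EncodedMatrix("onehot_ordinal", (codes + 1).astype(float), L=L)


def _kmer_ranks(codes: np.ndarray, k: int) -> np.ndarray:
    """0-based lexicographic rank of the k-mer starting at each position."""
    L = codes.shape[1]
    if k < 1 or k > L:
        raise ValidationError(f"k={k} invalid for length {L}")
    powers = 4 ** np.arange(k - 1, -1, -1)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k, axis=1)
    return windows @ powers  # (n, L-k+1)


def encode_kmer_counts(sequences: Sequence[str], k: int = 4) -> EncodedMatrix:
    """Occurrences of each of the 4^k overlapping k-mers, lexicographic column order."""
    codes, L = _codes(sequences, None)
    ranks = _kmer_ranks(codes, k)
    n = codes.shape[0]
    out = np.zeros((n, 4**k))
    for i in range(n):
        out[i] = np.bincount(ranks[i], minlength=4**k)
    cols = ["".join(p) for p in product("ACGT", repeat=k)]
    return EncodedMatrix("kmer_counts", out, L=L, k=k, columns=cols)


def encode_kmer_ordinal(sequences: Sequence[str], k: int = 4) -> EncodedMatrix:
    """1-based lexicographic rank (1..4^k) of the k-mer at each position."""
    codes, L = _codes(sequences, None)
    ranks = _kmer_ranks(codes, k) + 1
    return EncodedMatrix("kmer_ordinal", ranks.astype(float), L=L, k=k)


def encode_biophysical(
    sequences: Sequence[str],
    config: biophys.BiophysConfig | None = None,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> EncodedMatrix:
    """Eight property columns, min–max normalized to [0,1].

    When ``stats`` (per-column min, max) is given — typically fitted on a
    training set — it is re-applied unchanged; otherwise statistics are
    computed over the encoded set itself and stored on the result.  Degenerate
    columns (max == min) are set to zero with a logged warning.
    """
    mat = biophys.profile_matrix(sequences, config)
    L = len(sequences[0])
    if stats is None:
        stats = (mat.min(axis=0), mat.max(axis=0))
    lo, hi = stats
    degenerate = hi <= lo
    if degenerate.any():
        names = [biophys.PROPERTY_NAMES[i] for i in np.flatnonzero(degenerate)]
        logger.warning("degenerate biophysical columns set to 0: %s", names)
    span = np.where(degenerate, 1.0, hi - lo)
    out = (mat - lo) / span
    out[:, degenerate] = 0.0
    return EncodedMatrix(
        "biophysical", out, L=L, columns=list(biophys.PROPERTY_NAMES), stats=stats
    )


def encode_mixed(
    sequences: Sequence[str],
    L: int | None = None,
    config: biophys.BiophysConfig | None = None,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> EncodedMatrix:
    """Flattened binary one-hot columns followed by the 8 normalized properties."""
    onehot = encode_onehot_binary(sequences, L)
    bio = encode_biophysical(sequences, config, stats)
    values = np.hstack([onehot.values, bio.values])
    return EncodedMatrix("mixed", values, L=onehot.L, stats=bio.stats)


def encode(
    name: str,
    sequences: Sequence[str],
    k: int = 4,
    L: int | None = None,
    config: biophys.BiophysConfig | None = None,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> EncodedMatrix:
    """Dispatch on encoding name."""
    if name == "biophysical":
        return encode_biophysical(sequences, config, stats)
    if name == "kmer_counts":
        return encode_kmer_counts(sequences, k)
    if name == "kmer_ordinal":
        return encode_kmer_ordinal(sequences, k)
    if name == "onehot_binary":
        return encode_onehot_binary(sequences, L)
    if name == "onehot_ordinal":
        return encode_onehot_ordinal(sequences, L)
    if name == "mixed":
        return encode_mixed(sequences, L, config, stats)
    raise ValidationError(f"unknown encoding {name!r}")


def encode_train_test(
    name: str,
    train_sequences: Sequence[str],
    test_sequences: Sequence[str],
    k: int = 4,
    L: int | None = None,
    config: biophys.BiophysConfig | None = None,
) -> tuple[EncodedMatrix, EncodedMatrix]:
    """Encode a train/test pair, fitting normalization statistics on train only."""
    train = encode(name, train_sequences, k=k, L=L, config=config)
    test = encode(name, test_sequences, k=k, L=L, config=config, stats=train.stats)
    return train, test
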