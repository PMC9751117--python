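"""Eight biophysical sequence properties of a protein-coding variable region.

The variable region is treated as an in-frame stretch of codons fused to a
reporter.  The properties are the ones classically used to design
translation-efficiency libraries:

* ``at_content`` — fraction of A/T bases (%AT).
* ``cai`` — codon adaptation index: geometric mean of per-codon relative
  adaptiveness weights ``w``; the default table is an E. coli-like table
  shipped as package data.
* ``btl_p`` / ``btl_s`` — codon-ramp bottleneck position and strength: the
  sliding codon window (default 8 codons) with the lowest geometric-mean
  ``w``; the strength is that minimum, the position the 1-based index of the
  first codon of the first window attaining it.
* ``mhi`` — mean hydrophobicity index of the encoded peptide under the
  Kyte–Doolittle scale.
* ``mfe1``–``mfe3`` — stability scores for three secondary-structure windows
  tiled along the transcript.  These are computed with a Nussinov
  maximum-base-pairing score (−1 per pair, minimum hairpin loop of 3 bases),
  a self-contained stand-in for thermodynamic minimum free energy that keeps
  the score oracle-verifiable; it is *not* a nearest-neighbour MFE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from math import exp, log
from typing import Mapping, Sequence

import numpy as np
from numba import njit
from Bio.Seq import Seq

from .errors import FrameError, ValidationError

_VALID = set("ACGT")

#: order of the eight properties in every vectorised representation
PROPERTY_NAMES = ("at_content", "cai", "btl_p", "btl_s", "mhi", "mfe1", "mfe2", "mfe3")


def _load_json(name: str) -> dict:
    with resources.files("seq2exp.data").joinpath(name).open() as fh:
        return json.load(fh)


def load_codon_weights() -> dict[str, float]:
    """Default codon → relative-adaptiveness table (E. coli-like, max 1 per family)."""
    return _load_json("codon_weights.json")


def load_kd_scale() -> dict[str, float]:
    """Kyte–Doolittle residue hydrophobicity scale."""
    return _load_json("kyte_doolittle.json")


def _check_seq(sequence: str) -> None:
    if not sequence:
        raise ValidationError("empty sequence")
    if not set(sequence) <= _VALID:
        bad = sorted(set(sequence) - _VALID)
        raise ValidationError(f"sequence contains non-ACGT characters: {bad}")


def _codons(sequence: str) -> list[str]:
    if len(sequence) % 3 != 0:
        raise FrameError(f"length {len(sequence)} is not divisible by 3")
    return [sequence[i : i + 3] for i in range(0, len(sequence), 3)]


@dataclass(frozen=True)
class BiophysicalProfile:
    at_content: float
    cai: float
    btl_p: int
    btl_s: float
    mhi: float
    mfe1: float
    mfe2: float
    mfe3: float

    def as_vector(self) -> np.ndarray:
        """The eight values in the documented order (see PROPERTY_NAMES)."""
        return np.array([getattr(self, n) for n in PROPERTY_NAMES], dtype=float)


@dataclass
class BiophysConfig:
    """Parameters of the profile computation.

    ``btl_window`` is in codons; ``mfe_windows`` are 0-based half-open base
    intervals; when None they default to the three half-overlapping windows
    [0, L/2), [L/4, 3L/4), [L/2, L) — for L=96 that is [0,48), [24,72), [48,96).
    """

    codon_weights: Mapping[str, float] = field(default_factory=load_codon_weights)
    hydrophobicity: Mapping[str, float] = field(default_factory=load_kd_scale)
    btl_window: int = 8
    mfe_windows: tuple[tuple[int, int], ...] | None = None

    def windows_for(self, L: int) -> tuple[tuple[int, int], ...]:
        if self.mfe_windows is not None:
            return self.mfe_windows
        h, q = L // 2, L // 4
        return ((0, h), (q, q + h), (L - h, L))


def at_content(sequence: str) -> float:
    """(A count + T count) / length."""
    _check_seq(sequence)
    return (sequence.count("A") + sequence.count("T")) / len(sequence)


def cai(sequence: str, table: Mapping[str, float] | None = None) -> float:
    """Geometric mean of relative-adaptiveness weights over all codons."""
    _check_seq(sequence)
    table = table if table is not None else load_codon_weights()
    total = 0.0
    codons = _codons(sequence)
    for c in codons:
        if c not in table:
            raise ValidationError(f"codon {c!r} absent from weight table")
        total += log(table[c])
    return exp(total / len(codons))


def bottleneck(
    sequence: str, table: Mapping[str, float] | None = None, window: int = 8
) -> tuple[int, float]:
    """Codon-ramp bottleneck (position, strength).

    Strength is the minimum sliding-window geometric mean of codon weights;
    position is the 1-based first codon of the first window attaining it.
    """
    _check_seq(sequence)
    if window < 1:
        raise ValidationError("window must be >= 1")
    table = table if table is not None else load_codon_weights()
    codons = _codons(sequence)
    if window > len(codons):
        raise ValidationError(f"window {window} exceeds codon count {len(codons)}")
    logs = []
    for c in codons:
        if c not in table:
            raise ValidationError(f"codon {c!r} absent from weight table")
        logs.append(log(table[c]))
    best_pos, best_val = 1, float("inf")
    for i in range(len(codons) - window + 1):
        gm = exp(sum(logs[i : i + window]) / window)
        if gm < best_val - 1e-15:
            best_pos, best_val = i + 1, gm
    return best_pos, best_val


def mhi(sequence: str, scale: Mapping[str, float] | None = None) -> float:
    """Mean hydrophobicity of the in-frame translation (frame 1)."""
    _check_seq(sequence)
    if len(sequence) % 3 != 0:
        raise FrameError(f"length {len(sequence)} is not divisible by 3")
    scale = scale if scale is not None else load_kd_scale()
    peptide = str(Seq(sequence).translate())
    if "*" in peptide:
        raise ValidationError("internal stop codon in variable region")
    return float(np.mean([scale[a] for a in peptide]))


# Nussinov maximum base pairing.  Bases coded A=0, C=1, G=2, T(U)=3;
# admissible pairs A-U, G-C and the G-U wobble; hairpin loops of >= 3 bases
# (partners i, j must satisfy j - i > 3).
_PAIRABLE = np.zeros((4, 4), dtype=np.bool_)
for _a, _b in ((0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)):
    _PAIRABLE[_a, _b] = True

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@njit(cache=False)
def _nussinov_pairs(codes: np.ndarray, pairable: np.ndarray) -> int:  # pragma: no cover
    n = codes.size
    N = np.zeros((n, n), dtype=np.int32)
    for span in range(4, n):
        for i in range(n - span):
            j = i + span
            best = N[i + 1, j]
            for k in range(i + 4, j + 1):
                if pairable[codes[i], codes[k]]:
                    left = N[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    right = N[k + 1, j] if k + 1 <= j else 0
                    cand = 1 + left + right
                    if cand > best:
                        best = cand
            N[i, j] = best
    return int(N[0, n - 1])


def fold_score(sequence: str) -> float:
    """Maximum-base-pairing fold score: −(pairs in the optimal structure) ≤ 0."""
    _check_seq(sequence)
    if len(sequence) < 5:
        return 0.0
    codes = np.array([_CODE[b] for b in sequence], dtype=np.int8)
    return -float(_nussinov_pairs(codes, _PAIRABLE))


def mfe_windows(
    sequence: str, windows: Sequence[tuple[int, int]] | None = None
) -> tuple[float, float, float]:
    """Fold score of three windows tiled along the sequence."""
    _check_seq(sequence)
    L = len(sequence)
    if windows is None:
        windows = BiophysConfig().windows_for(L)
    if len(windows) != 3:
        raise ValidationError("exactly 3 windows required")
    scores = []
    for lo, hi in windows:
        if not (0 <= lo < hi <= L):
            raise ValidationError(f"window [{lo},{hi}) out of range for length {L}")
        scores.append(fold_score(sequence[lo:hi]))
    return tuple(scores)  # type: ignore[return-value]


def profile(sequence: str, config: BiophysConfig | None = None) -> BiophysicalProfile:
    """Assemble all eight properties; a pure function of (sequence, config)."""
    config = config or BiophysConfig()
    _check_seq(sequence)
    p, s = bottleneck(sequence, config.codon_weights, config.btl_window)
    m1, m2, m3 = mfe_windows(sequence, config.windows_for(len(sequence)))
    return BiophysicalProfile(
        at_content=at_content(sequence),
        cai=cai(sequence, config.codon_weights),
        btl_p=p,
        btl_s=s,
        mhi=mhi(sequence, config.hydrophobicity),
        mfe1=m1,
        mfe2=m2,
        mfe3=m3,
    )


def profile_matrix(sequences: Sequence[str], config: BiophysConfig | None = None) -> np.ndarray:
    """Stack profiles of many sequences into an (n, 8) array."""
    config = config or BiophysConfig()
    return np.array([profile(s, config).as_vector() for s in sequences])
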