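"""Attribution analysis: how trained networks discriminate input sequences.

Per-nucleotide attribution scores are computed against a *blank* reference
(the all-zeros one-hot matrix) with a reference-based multiplier backprop —
the rescale rule — which for dense ReLU networks makes the per-unit
contributions sum exactly to f(x) − f(reference).  For linear models the
scores are the exact per-position contributions w·x.  Per-position scores
sum the four channel contributions.

Pairwise cosine distances between attribution vectors quantify how similarly
a model treats two sequences; the distance matrix can be ordered by
hierarchical clustering for display, and its cluster structure summarized by
k-means score curves (mean within-cluster sum of squares over random
restarts).  Lower curves indicate a model that clusters its inputs more
heavily, i.e. discriminates them at a coarser granularity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.linear_model import Ridge

from ._rand import STAGE_KMEANS, derive_int_seed
from .encoders import encode_onehot_binary
from .errors import CapabilityError, ValidationError
from .experiment import r_squared  # noqa: F401  (re-exported convenience)
from .models import FittedModel
from .nn import Network


@dataclass
class AttributionVector:
    seq_id: str
    scores: np.ndarray  # length L, per-position (channel-summed)
    reference: str = "blank (all-zeros one-hot)"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError(f"{self.seq_id}: non-finite attribution scores")


@dataclass
class DistanceMatrix:
    ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
            raise ValidationError("distance matrix must be symmetric with zero diagonal")
        self.D = D

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.ids, columns=self.ids)


def attribute(
    handle: FittedModel, sequence: str, seq_id: str | None = None
) -> AttributionVector:
    """Per-position attribution of one sequence under a fitted model.

    Supports the network families (gradient access via the in-package
    engine) and ridge (closed-form linear contributions).  Tree and kernel
    models have no gradient surface and raise :class:`CapabilityError`.
    """
    onehot = encode_onehot_binary([sequence])
    x = onehot.values  # (1, 4L)
    L = onehot.L
    if isinstance(handle.backend, Network):
        if handle.spec.family == "cnn":
            xs = x.reshape(1, L, 4)
            contrib = handle.backend.deeplift(xs, np.zeros_like(xs)).reshape(1, L, 4)
        else:
            contrib = handle.backend.deeplift(x, np.zeros_like(x)).reshape(1, L, 4)
        scores = contrib.sum(axis=2)[0]
    elif isinstance(handle.backend, Ridge):
        w = handle.backend.coef_.reshape(-1)
        if w.size != 4 * L:
            raise CapabilityError(
                "linear attribution requires a model fitted on binary one-hot input"
            )
        scores = (w * x[0]).reshape(L, 4).sum(axis=1)
    else:
        raise CapabilityError(
            f"model family {handle.spec.family!r} exposes no gradients for attribution"
        )
    return AttributionVector(seq_id=seq_id or sequence[:12], scores=scores)


def attribute_set(handle: FittedModel, records) -> list[AttributionVector]:
    """Attribution vectors for a test-set DataFrame (seq_id, sequence columns)."""
    from .experiment import as_frame

    frame = as_frame(records)
    return [attribute(handle, s, i) for i, s in zip(frame["seq_id"], frame["sequence"])]


def attribution_distance_matrix(vectors: Sequence[AttributionVector]) -> DistanceMatrix:
    """Pairwise cosine distances 1 − cos(vᵢ, vⱼ) between attribution vectors."""
    if len(vectors) < 2:
        raise ValidationError("need at least 2 attribution vectors")
    mat = np.stack([v.scores for v in vectors])
    norms = np.linalg.norm(mat, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValidationError(
            f"all-zero attribution vector for {vectors[zero[0]].seq_id!r}"
        )
    unit = mat / norms[:, None]
    D = 1.0 - unit @ unit.T
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(ids=[v.seq_id for v in vectors], D=D)


def hierarchical_order(dm: DistanceMatrix, method: str = "average") -> list[str]:
    """Leaf order of an agglomerative dendrogram over the distance matrix."""
    Z = linkage(squareform(dm.D, checks=False), method=method)
    return [dm.ids[i] for i in leaves_list(Z)]


def kmeans_score_curve(
    dm: DistanceMatrix,
    k_values: Sequence[int] = tuple(range(2, 16)),
    n_inits: int = 20,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Mean k-means score (within-cluster sum of squares) per k.

    Rows of the distance matrix are treated as feature vectors; for each k
    the algorithm is restarted ``n_inits`` times from seeded random
    initializations and the per-run scores averaged.  Lower curves indicate
    heavier clustering.  Returns columns (k, mean_score, sd).
    """
    n = len(dm.ids)
    rows = []
    for k in k_values:
        if k > n:
            raise ValidationError(f"k={k} exceeds {n} items")
        scores = []
        for i in range(n_inits):
            seed = derive_int_seed(rng_seed, STAGE_KMEANS, k, i)
            km = KMeans(n_clusters=k, init="random", n_init=1, random_state=seed)
            km.fit(dm.D)
            scores.append(km.inertia_)
        rows.append(
            (k, float(np.mean(scores)), float(np.std(scores)), float(np.min(scores)))
        )
    return pd.DataFrame(rows, columns=["k", "mean_score", "sd", "min_score"])


@dataclass
class ModelComparison:
    curve_a: pd.DataFrame
    curve_b: pd.DataFrame
    verdict: str  # "model_a_lower" | "model_b_lower" | "mixed"


def compare_models(
    handle_a: FittedModel,
    handle_b: FittedModel,
    records,
    k_values: Sequence[int] = tuple(range(2, 16)),
    n_inits: int = 20,
    rng_seed: int = 0,
) -> ModelComparison:
    """Attribution → distances → k-means curves for two models on one test set."""
    va = attribute_set(handle_a, records)
    vb = attribute_set(handle_b, records)
    ca = kmeans_score_curve(attribution_distance_matrix(va), k_values, n_inits, rng_seed)
    cb = kmeans_score_curve(attribution_distance_matrix(vb), k_values, n_inits, rng_seed)
    a_lower = (ca["mean_score"] <= cb["mean_score"]).all()
    b_lower = (cb["mean_score"] <= ca["mean_score"]).all()
    if a_lower and not b_lower:
        verdict = "model_a_lower"
    elif b_lower and not a_lower:
        verdict = "model_b_lower"
    else:
        verdict = "mixed"
    return ModelComparison(curve_a=ca, curve_b=cb, verdict=verdict)
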