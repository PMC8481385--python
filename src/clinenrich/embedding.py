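"""Pairwise distances, 2D embedding, and the planar metric.

Sample similarity is computed on the digitized matrix with one of three
pairwise measures (Euclidean, cosine, Jaccard — the latter two converted
to dissimilarities), embedded into 2D with UMAP (default) or t-SNE, and
from then on every neighborhood query uses the plain Euclidean distance

    d(i, j) = sqrt((x_i - x_j)^2 + (y_i - y_j)^2)

between embedded coordinates: the embedding is assumed to have absorbed
the high-dimensional similarity structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .preprocess import DigitizedMatrix

METRICS = ("euclidean", "cosine", "jaccard")
EMBED_METHODS = ("umap", "tsne")
MIN_EMBED_SAMPLES = 4


@dataclass
class Embedding2D:
    """Per-sample (x, y) coordinates."""

    sample_ids: list[str]
    coords: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError("embedding coordinates must be n x 2")
        if len(self.sample_ids) != len(self.coords):
            raise ValidationError("embedding IDs and coordinates differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample IDs in embedding")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("embedding coordinates must be finite")
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    def xy(self, sample_id: str) -> tuple[float, float]:
        i = self._index[sample_id]
        return float(self.coords[i, 0]), float(self.coords[i, 1])

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._index

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative pairwise distances with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValidationError("distance matrix shape does not match sample IDs")
        if not np.all(np.isfinite(v)):
            raise ValidationError("distance matrix has non-finite entries")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise ValidationError("distance matrix has negative entries")
        self.values = np.clip(v, 0.0, None)


def euclid2d(p: Sequence[float], q: Sequence[float]) -> float:
    """Planar Euclidean distance between two embedded points."""
    px, py = float(p[0]), float(p[1])
    qx, qy = float(q[0]), float(q[1])
    if not all(math.isfinite(v) for v in (px, py, qx, qy)):
        raise ValidationError("euclid2d requires finite coordinates")
    return math.hypot(px - qx, py - qy)


def pairwise_distance(matrix: DigitizedMatrix, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise distances between digitized sample rows.

    ``euclidean`` is the straight L2 distance.  ``cosine`` is
    1 - cosine similarity; an all-zero row is defined to be at distance
    1 from everything except itself.  ``jaccard`` is 1 - |A & B|/|A | B|
    over the set bits of indicator columns and requires a fully binary
    matrix (z-scored columns are rejected by name); two all-zero rows
    are at distance 0.
    """
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; choose from {METRICS}")
    X = np.asarray(matrix.values, dtype=float)
    if X.size == 0:
        raise ValidationError("empty digitized matrix")
    n = X.shape[0]

    if metric == "euclidean":
        sq = np.sum(X * X, axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
        D = np.sqrt(np.clip(d2, 0.0, None))
    elif metric == "cosine":
        norms = np.linalg.norm(X, axis=1)
        zero = norms == 0
        safe = np.where(zero, 1.0, norms)
        U = X / safe[:, None]
        D = 1.0 - U @ U.T
        D[zero, :] = 1.0
        D[:, zero] = 1.0
    else:  # jaccard
        binary_ok = np.isin(X, (0.0, 1.0)).all(axis=0)
        if not binary_ok.all():
            bad = [matrix.column_names[j] for j in np.flatnonzero(~binary_ok)]
            raise ValidationError(
                f"jaccard requires binary indicator columns only; offending columns: {bad}"
            )
        B = X.astype(bool)
        inter = B.astype(float) @ B.T.astype(float)
        counts = B.sum(axis=1).astype(float)
        union = counts[:, None] + counts[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            D = 1.0 - np.where(union > 0, inter / union, 1.0)
        # two all-zero rows share an empty set: distance 0
        D[union == 0] = 0.0
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return DistanceMatrix(list(matrix.sample_ids), D)


def _tsne_params(n: int, seed: int) -> dict:
    return {
        "n_components": 2,
        "perplexity": min(30.0, (n - 1) / 3.0),
        "init": "random",
        "random_state": seed,
        "metric": "precomputed",
    }


def _umap_params(n: int, seed: int) -> dict:
    return {
        "n_components": 2,
        "n_neighbors": min(15, n - 1),
        "min_dist": 0.1,
        "random_state": seed,
        "metric": "precomputed",
    }


def embed(dist: DistanceMatrix, method: str = "umap", seed: int = 0) -> Embedding2D:
    """Embed a pairwise distance matrix into 2D.

    Hyperparameters are the library defaults (neighborhood sizes capped
    for small n) and are recorded on the returned embedding's ``params``
    so a run log can reproduce the call.  A fixed seed gives identical
    coordinates across runs on the same machine and library versions.
    """
    if method not in EMBED_METHODS:
        raise ValidationError(f"unknown embedding method {method!r}; choose from {EMBED_METHODS}")
    n = len(dist.sample_ids)
    if n < MIN_EMBED_SAMPLES:
        raise ValidationError(
            f"{method} embedding requires at least {MIN_EMBED_SAMPLES} samples, got {n}"
        )
    if method == "tsne":
        from sklearn.manifold import TSNE

        params = _tsne_params(n, seed)
        coords = TSNE(**params).fit_transform(dist.values)
    else:
        import warnings

        from umap import UMAP

        params = _umap_params(n, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords = UMAP(**params).fit_transform(dist.values)
    return Embedding2D(list(dist.sample_ids), np.asarray(coords, dtype=float),
                       params={"method": method, **params})
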