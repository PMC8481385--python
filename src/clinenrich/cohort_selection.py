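"""Subcohort selection: manual ID lists, density clusters, radius queries.

The subcohort s is the sample set whose clinical attributes are tested
for enrichment against the full population S.  Three selection routes
are supported, mirroring how an analyst works with a 2D sample map:

* ``select_manual`` — an explicit list of sample IDs;
* ``cluster_embedding`` + ``select_cluster`` — density-based (DBSCAN)
  clustering of the 2D embedding, then picking one cluster;
* ``select_radius`` — all samples within a closed disc of radius r
  around a chosen sample ("similarity area").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .clinotype_io import ClinotypeTable
from .embedding import Embedding2D, euclid2d
from .errors import SelectionError

DEFAULT_MIN_SAMPLES = 5


@dataclass
class Subcohort:
    """A selected sample set with provenance."""

    member_ids: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.member_ids) == 0:
            raise SelectionError("subcohort is empty")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise SelectionError("subcohort has duplicate member IDs")

    def __len__(self) -> int:
        return len(self.member_ids)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in set(self.member_ids)


@dataclass
class ClusterAssignment:
    """Per-sample integer cluster labels; -1 marks noise."""

    sample_ids: list[str]
    labels: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.sample_ids):
            raise SelectionError("cluster labels and sample IDs differ in length")

    @property
    def cluster_labels(self) -> list[int]:
        """Sorted distinct non-noise labels."""
        return sorted(int(c) for c in np.unique(self.labels) if c != -1)

    def members(self, label: int) -> list[str]:
        return [s for s, c in zip(self.sample_ids, self.labels) if c == label]


def select_manual(ids: Sequence[str], population: ClinotypeTable) -> Subcohort:
    """Subcohort from an explicit ID list; unknown IDs are rejected."""
    if len(ids) == 0:
        raise SelectionError("manual selection: empty ID list")
    known = set(population.sample_ids)
    unknown = [i for i in ids if i not in known]
    if unknown:
        raise SelectionError(f"unknown sample IDs: {sorted(set(unknown))}")
    seen: dict[str, None] = dict.fromkeys(ids)
    return Subcohort(tuple(seen), provenance={"mode": "manual", "n_listed": len(ids)})


def auto_eps(emb: Embedding2D, min_samples: int) -> float:
    """Choose DBSCAN eps from the elbow of the sorted k-distance curve.

    k = min_samples; the elbow is the point of maximum discrete second
    difference of the ascending k-th nearest-neighbor distances.
    """
    n = len(emb)
    k = min(min_samples, n - 1)
    if k < 1:
        raise SelectionError("auto eps needs at least 2 samples")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb.coords)
    dists = np.sort(nn.kneighbors(emb.coords)[0][:, -1])
    if len(dists) < 3:
        eps = float(dists[-1])
    else:
        second = dists[2:] - 2.0 * dists[1:-1] + dists[:-2]
        eps = float(dists[int(np.argmax(second)) + 1])
    if eps <= 0:
        eps = float(dists[-1]) or 1e-12
    return eps


def cluster_embedding(
    emb: Embedding2D,
    eps: float | str = "auto",
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> ClusterAssignment:
    """Density-based clustering of the 2D embedding (DBSCAN, Euclidean).

    ``eps="auto"`` uses the k-distance-elbow heuristic of
    :func:`auto_eps`.  All points landing in noise is reported as an
    empty cluster list, not an error.  Deterministic given its inputs.
    """
    n = len(emb)
    if min_samples < 1:
        raise SelectionError("min_samples must be positive")
    if n < min_samples:
        raise SelectionError(f"min_samples={min_samples} exceeds the {n} available samples")
    if eps == "auto":
        eps_value = auto_eps(emb, min_samples)
    else:
        eps_value = float(eps)
        if eps_value <= 0:
            raise SelectionError("eps must be positive")
    labels = DBSCAN(eps=eps_value, min_samples=min_samples).fit_predict(emb.coords)
    return ClusterAssignment(
        list(emb.sample_ids),
        labels,
        params={"eps": eps_value, "min_samples": min_samples, "eps_mode": eps},
    )


def select_cluster(assign: ClusterAssignment, label: int) -> Subcohort:
    """Subcohort = all members of one (non-noise) cluster."""
    if label == -1:
        raise SelectionError("noise (label -1) is not a cluster")
    members = assign.members(label)
    if not members:
        raise SelectionError(
            f"cluster label {label} not present; available: {assign.cluster_labels}"
        )
    return Subcohort(
        tuple(members), provenance={"mode": "cluster", "label": int(label), **assign.params}
    )


def select_radius(emb: Embedding2D, center_id: str, r: float) -> Subcohort:
    """Closed-disc neighborhood: members with d(center, j) <= r.

    The boundary is included and the center always belongs to its own
    subcohort (distance 0).
    """
    if center_id not in emb:
        raise SelectionError(f"unknown center sample ID {center_id!r}")
    r = float(r)
    if r <= 0:
        raise SelectionError("radius must be positive")
    center = emb.xy(center_id)
    members = tuple(
        s for s, xy in zip(emb.sample_ids, emb.coords) if euclid2d(center, xy) <= r
    )
    return Subcohort(members, provenance={"mode": "radius", "center_id": center_id, "r": r})
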