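"""Digitization, z-scoring and discretization of clinical attributes.

Categorical attributes are one-hot "digitized": an attribute X with
levels (low, normal, high) becomes three binary indicators is_X_low,
is_X_normal, is_X_high, so a patient valued "high" is represented as
(0, 0, 1).  Numerical attributes are z-scored.  For enrichment testing,
numerical attributes can additionally be discretized into categorical
bins at explicit cutpoints (e.g. survival <300 vs >=300 days) or at
cutpoints derived from a clustering of the samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .clinotype_io import (
    CATEGORICAL,
    NUMERICAL,
    AttributeSpec,
    ClinotypeTable,
)
from .errors import ValidationError


def _fmt(x: float) -> str:
    """Compact numeric formatting for bin labels (300.0 -> '300')."""
    return f"{x:g}"


@dataclass(frozen=True)
class DiscretizationRule:
    """Cutpoints turning one numerical attribute into categorical bins.

    Bins are half-open, upper-closed at each cutpoint: [-inf, c1),
    [c1, c2), ..., [c_last, inf) — a value exactly at a cutpoint falls
    in the upper bin, so cutpoint 300 yields "<300" and ">=300".
    """

    attribute: str
    cutpoints: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.cutpoints) == 0:
            raise ValidationError(f"rule for {self.attribute!r}: no cutpoints")
        cp = np.asarray(self.cutpoints, dtype=float)
        if not np.all(np.isfinite(cp)):
            raise ValidationError(f"rule for {self.attribute!r}: non-finite cutpoint")
        if not np.all(np.diff(cp) > 0):
            raise ValidationError(
                f"rule for {self.attribute!r}: cutpoints must be strictly ascending"
            )

    @property
    def labels(self) -> tuple[str, ...]:
        """Generated bin labels, one more than there are cutpoints."""
        cp = [_fmt(c) for c in self.cutpoints]
        if len(cp) == 1:
            return (f"<{cp[0]}", f">={cp[0]}")
        mids = tuple(f"[{a},{b})" for a, b in zip(cp[:-1], cp[1:]))
        return (f"<{cp[0]}", *mids, f">={cp[-1]}")

    @property
    def derived_name(self) -> str:
        return f"Discrete_{self.attribute}"

    def to_json(self) -> str:
        return json.dumps({"attribute": self.attribute, "cutpoints": list(self.cutpoints)})

    @classmethod
    def from_json(cls, text: str) -> "DiscretizationRule":
        obj = json.loads(text)
        return cls(obj["attribute"], tuple(float(c) for c in obj["cutpoints"]))


@dataclass
class DigitizedMatrix:
    """Dense numeric matrix after one-hot digitization and z-scoring.

    ``column_specs`` records, per column, the source attribute and the
    level it indicates (None for z-scored numerical columns).
    """

    sample_ids: list[str]
    column_specs: list[tuple[str, str | None]]
    values: np.ndarray

    @property
    def column_names(self) -> list[str]:
        return [
            name if level is None else f"is_{name}_{level}"
            for name, level in self.column_specs
        ]

    @property
    def is_binary(self) -> np.ndarray:
        """Boolean per column: True for indicator (0/1) columns."""
        return np.array([level is not None for _, level in self.column_specs])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.column_names)


def zscore(values: Sequence[float] | np.ndarray, name: str = "<anonymous>") -> np.ndarray:
    """Standardize a vector with population (n-denominator) sigma.

    Mean and sigma are computed over non-missing entries; missing
    entries map to 0 (the standardized mean), and a constant column maps
    to all zeros.  An all-missing column is a hard error.
    """
    x = np.asarray(values, dtype=float)
    mask = np.isfinite(x)
    if not mask.any():
        raise ValidationError(f"attribute {name!r} has no non-missing values to z-score")
    mu = x[mask].mean()
    sigma = x[mask].std(ddof=0)
    out = np.zeros_like(x, dtype=float)
    if sigma > 0:
        out[mask] = (x[mask] - mu) / sigma
    return out


def digitize(table: ClinotypeTable) -> DigitizedMatrix:
    """One-hot encode categorical attributes and z-score numerical ones.

    A missing categorical cell yields an all-zero indicator block; a
    missing numerical cell becomes 0 after z-scoring (mean imputation in
    standardized space).  Indicator columns appear in level order.
    """
    blocks: list[np.ndarray] = []
    specs: list[tuple[str, str | None]] = []
    for attr in table.attributes:
        col = table.column(attr.name)
        if attr.kind == CATEGORICAL:
            for level in attr.levels or ():
                blocks.append((col == level).to_numpy(dtype=float))
                specs.append((attr.name, level))
        else:
            blocks.append(zscore(col.to_numpy(dtype=float), name=attr.name))
            specs.append((attr.name, None))
    values = np.column_stack(blocks) if blocks else np.empty((table.n_samples, 0))
    return DigitizedMatrix(table.sample_ids, specs, values)


def discretize(table: ClinotypeTable, rule: DiscretizationRule) -> ClinotypeTable:
    """Append the categorical binning of a numerical attribute.

    The original numerical attribute is retained; the new attribute is
    named ``Discrete_<attr>`` with ``origin="discretized"``.  Missing
    values stay missing.
    """
    attr = table.attribute(rule.attribute)
    if attr.kind != NUMERICAL:
        raise ValidationError(f"attribute {rule.attribute!r} is not numerical")
    x = table.column(rule.attribute).to_numpy(dtype=float)
    cp = np.asarray(rule.cutpoints, dtype=float)
    labels = rule.labels
    idx = np.searchsorted(cp, x, side="right")  # cutpoint value -> upper bin
    binned = pd.Series(
        [labels[i] if np.isfinite(v) else np.nan for v, i in zip(x, idx)],
        index=table.data.index,
        dtype=object,
    )
    spec = AttributeSpec(rule.derived_name, CATEGORICAL, labels, origin="discretized")
    return table.with_attribute(spec, binned)


def cluster_derived_cutpoints(
    values: Sequence[float] | np.ndarray,
    cluster_labels: Sequence[int] | np.ndarray,
    attribute: str = "<anonymous>",
) -> DiscretizationRule:
    """Derive cutpoints from a clustering of the samples.

    Clusters are ordered by their mean of the attribute (missing values
    dropped; noise label -1 ignored) and one cutpoint is placed at the
    midpoint between each adjacent pair of means.
    """
    x = np.asarray(values, dtype=float)
    lab = np.asarray(cluster_labels)
    if x.shape != lab.shape:
        raise ValidationError("values and cluster labels are not aligned")
    means = []
    for c in np.unique(lab):
        if c == -1:
            continue
        vals = x[(lab == c) & np.isfinite(x)]
        if len(vals):
            means.append(vals.mean())
    if len(means) < 2:
        raise ValidationError(f"attribute {attribute!r}: no threshold derivable from a single cluster")
    means = np.sort(np.asarray(means))
    if np.any(np.diff(means) == 0):
        raise ValidationError(
            f"attribute {attribute!r}: adjacent clusters have equal means (degenerate midpoint)"
        )
    cutpoints = tuple((means[:-1] + means[1:]) / 2.0)
    return DiscretizationRule(attribute, cutpoints)
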