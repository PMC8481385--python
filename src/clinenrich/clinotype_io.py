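"""Clinical-metadata ("clinotype") tables and the files they live in.

A clinotype table is a rectangular grid of samples (rows) by clinical
attributes (columns): age group, gender, treatment status, survival days
and so on.  Each attribute is either *categorical* (a finite set of
labels) or *numerical* (finite reals); any cell may be missing.  The
table is the population S against which subcohort enrichment is judged,
and the attribute set C is what gets tested.

This module reads and validates such tables from delimited text, reads
user-supplied 2D embeddings, and writes enrichment reports as TSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import InputFormatError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .embedding import Embedding2D
    from .enrichment import EnrichmentResults

CATEGORICAL = "categorical"
NUMERICAL = "numerical"

#: Tokens recognised (case-insensitively) as missing values on read.
#: No imputation is performed anywhere; recognition only.
MISSING_TOKENS = frozenset({"", "na", "nan", "null"})

#: Exact column set of the enrichment report TSV.
REPORT_COLUMNS = (
    "attribute",
    "level",
    "test",
    "k",
    "n",
    "K",
    "N",
    "statistic",
    "p_value",
    "p_adjusted",
    "enriched_flag",
)


def _is_missing_token(cell: str) -> bool:
    return cell.strip().lower() in MISSING_TOKENS


def _parse_float(cell: str) -> float | None:
    """Parse a cell as a finite real; None if it is not one."""
    try:
        v = float(cell)
    except ValueError:
        return None
    return v if math.isfinite(v) else None


@dataclass(frozen=True)
class AttributeSpec:
    """Type descriptor for one clinical attribute.

    Parameters
    ----------
    name : str
        Column name.
    kind : {"categorical", "numerical"}
    levels : tuple of str, optional
        Ordered label set; required for (and only for) categorical
        attributes.
    origin : {"raw", "discretized"}
        Whether the attribute came from the input table or was derived
        by discretizing a numerical attribute.
    """

    name: str
    kind: str
    levels: tuple[str, ...] | None = None
    origin: str = "raw"

    def __post_init__(self) -> None:
        if self.kind not in (CATEGORICAL, NUMERICAL):
            raise ValidationError(f"attribute {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == CATEGORICAL:
            if not self.levels:
                raise ValidationError(f"categorical attribute {self.name!r} has no levels")
            if len(set(self.levels)) != len(self.levels):
                raise ValidationError(f"attribute {self.name!r}: duplicate levels")
        elif self.levels is not None:
            raise ValidationError(f"numerical attribute {self.name!r} must not carry levels")


@dataclass
class ClinotypeTable:
    """Samples x typed clinical attributes, with missing-value support.

    ``data`` is indexed by sample ID; categorical columns hold strings
    (NaN for missing), numerical columns hold float64 (NaN for missing).
    """

    data: pd.DataFrame
    attributes: list[AttributeSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- construction ------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        id_column: str | None = None,
        type_overrides: Mapping[str, str] | None = None,
    ) -> "ClinotypeTable":
        """Build a table from a raw (string-ish) DataFrame.

        Attribute kinds are inferred per column: if every non-missing
        cell parses as a finite real the column is numerical, otherwise
        categorical with levels taken from the sorted distinct labels.
        ``type_overrides`` maps attribute name to an explicit kind.
        """
        overrides = dict(type_overrides or {})
        if id_column is not None:
            if id_column not in df.columns:
                raise InputFormatError(f"id column {id_column!r} not found in table")
            df = df.set_index(df[id_column].astype(str)).drop(columns=[id_column])
        ids = df.index.astype(str)
        dup = ids[ids.duplicated()].unique().tolist()
        if dup:
            raise ValidationError(f"duplicate sample IDs: {sorted(dup)}")
        if df.shape[1] == 0:
            raise ValidationError("table has zero attributes")

        for name in overrides:
            if name not in df.columns:
                raise ValidationError(f"type override for unknown attribute {name!r}")
            if overrides[name] not in (CATEGORICAL, NUMERICAL):
                raise ValidationError(f"type override for {name!r}: bad kind {overrides[name]!r}")

        cols: dict[str, pd.Series] = {}
        specs: list[AttributeSpec] = []
        for name in df.columns:
            raw = df[name].astype(object).where(df[name].notna(), "").astype(str)
            missing = raw.map(_is_missing_token)
            parsed = raw.map(_parse_float)
            all_numeric = bool((missing | parsed.notna()).all())
            kind = overrides.get(name, NUMERICAL if all_numeric else CATEGORICAL)
            if kind == NUMERICAL:
                if not all_numeric:
                    bad = raw[~missing & parsed.isna()].iloc[0]
                    raise ValidationError(
                        f"attribute {name!r} declared numerical but has non-numeric cell {bad!r}"
                    )
                col = parsed.astype(float).where(~missing, np.nan)
                specs.append(AttributeSpec(name, NUMERICAL))
            else:
                col = raw.where(~missing, np.nan)
                levels = tuple(sorted(col.dropna().unique()))
                if not levels:
                    raise ValidationError(f"categorical attribute {name!r} is entirely missing")
                specs.append(AttributeSpec(name, CATEGORICAL, levels))
            cols[name] = col
        out = pd.DataFrame(cols, index=pd.Index(ids, name="sample_id"))
        return cls(out, specs)

    # -- basic protocol ----------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def attribute(self, name: str) -> AttributeSpec:
        for spec in self.attributes:
            if spec.name == name:
                return spec
        raise KeyError(name)

    def column(self, name: str) -> pd.Series:
        return self.data[name]

    def with_attribute(self, spec: AttributeSpec, values: pd.Series) -> "ClinotypeTable":
        """Return a new table with one attribute appended."""
        if spec.name in self.data.columns:
            raise ValidationError(f"attribute {spec.name!r} already present")
        data = self.data.copy()
        data[spec.name] = values.reindex(data.index)
        return ClinotypeTable(data, [*self.attributes, spec])

    def validate(self) -> None:
        ids = self.data.index
        if len(ids) == 0:
            raise ValidationError("table has no samples")
        dup = ids[ids.duplicated()].unique().tolist()
        if dup:
            raise ValidationError(f"duplicate sample IDs: {sorted(dup)}")
        names = [s.name for s in self.attributes]
        if list(self.data.columns) != names:
            raise ValidationError("attribute specs do not match table columns")
        for spec in self.attributes:
            col = self.data[spec.name]
            if spec.kind == NUMERICAL:
                vals = pd.to_numeric(col, errors="raise")
                if np.isinf(vals.to_numpy(dtype=float, na_value=np.nan)).any():
                    raise ValidationError(f"attribute {spec.name!r} has non-finite values")
            else:
                observed = set(col.dropna().astype(str))
                extra = observed - set(spec.levels or ())
                if extra:
                    raise ValidationError(
                        f"attribute {spec.name!r} has labels outside its level set: {sorted(extra)}"
                    )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        ncat = sum(1 for s in self.attributes if s.kind == CATEGORICAL)
        return (
            f"<ClinotypeTable {self.n_samples} samples, "
            f"{ncat} categorical + {len(self.attributes) - ncat} numerical attributes>"
        )


# ---------------------------------------------------------------------------
# file readers / writers
# ---------------------------------------------------------------------------


def _sep_for(path: str | Path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_clinotype_table(
    path: str | Path,
    id_column: str = "sample_id",
    type_overrides: Mapping[str, str] | None = None,
) -> ClinotypeTable:
    """Read a CSV/TSV clinical-metadata table.

    The delimiter is chosen from the extension (``.tsv``/``.tab``/
    ``.txt`` = tab, anything else comma).  Empty strings and the tokens
    ``NA``, ``NaN``, ``null`` (case-insensitive) are treated as missing.
    Attribute kinds are inferred by parseability unless overridden.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    return ClinotypeTable.from_dataframe(df, id_column=id_column, type_overrides=type_overrides)


def write_clinotype_table(table: ClinotypeTable, path: str | Path) -> None:
    """Write a table back to CSV/TSV; missing cells become empty strings.

    Numerical cells are written with repr-precision so a read round-trip
    restores the same float64 values.
    """
    out = table.data.copy()
    for spec in table.attributes:
        if spec.kind == NUMERICAL:
            out[spec.name] = out[spec.name].map(
                lambda v: "" if pd.isna(v) else repr(float(v))
            )
    out = out.fillna("")
    out.insert(0, "sample_id", table.sample_ids)
    out.to_csv(path, sep=_sep_for(path), index=False)


def read_embedding_file(path: str | Path, id_column: str = "sample_id") -> "Embedding2D":
    """Read a user-supplied 2D embedding (columns: ID, x, y).

    Coordinate columns are matched case-insensitively to ``x`` and
    ``y``.  Non-numeric coordinates are a hard error citing the data row
    number (1-based, excluding the header).
    """
    from .embedding import Embedding2D

    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    colmap = {c.lower(): c for c in df.columns}
    if id_column not in df.columns:
        raise InputFormatError(f"id column {id_column!r} not found in embedding file")
    for axis in ("x", "y"):
        if axis not in colmap:
            raise InputFormatError(f"embedding file lacks a {axis!r} column")
    if len(df) == 0:
        raise InputFormatError("embedding file has no samples")

    ids = df[id_column].astype(str)
    dup = ids[ids.duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"duplicate sample IDs in embedding file: {sorted(dup)}")

    coords = np.empty((len(df), 2), dtype=float)
    for j, axis in enumerate(("x", "y")):
        for i, cell in enumerate(df[colmap[axis]]):
            v = _parse_float(cell)
            if v is None:
                raise InputFormatError(
                    f"non-numeric {axis} coordinate {cell!r} on row {i + 1}"
                )
            coords[i, j] = v
    return Embedding2D(list(ids), coords)


def write_embedding_file(emb: "Embedding2D", path: str | Path) -> None:
    """Write an embedding in the same dialect :func:`read_embedding_file` reads."""
    df = pd.DataFrame(
        {"sample_id": emb.sample_ids, "x": emb.coords[:, 0], "y": emb.coords[:, 1]}
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_subcohort_file(path: str | Path) -> list[str]:
    """Read a one-ID-per-line subcohort file; ``#`` lines are comments."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line)
    if not ids:
        raise InputFormatError(f"subcohort file {path} contains no sample IDs")
    return ids


def write_subcohort_file(ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in ids))


def report_frame(results: Sequence) -> pd.DataFrame:
    """Assemble enrichment results into the report DataFrame.

    Rows are sorted by ascending adjusted p (untestable rows, which have
    no p, sort last), ties broken by attribute name then level.
    """
    rows = [
        {
            "attribute": r.attribute,
            "level": "" if r.level is None else r.level,
            "test": r.test,
            "k": r.k,
            "n": r.n,
            "K": r.K,
            "N": r.N,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "p_adjusted": r.p_adjusted,
            "enriched_flag": bool(r.enriched_flag),
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    if len(df):
        df = df.sort_values(
            ["p_adjusted", "attribute", "level"], na_position="last", kind="mergesort"
        ).reset_index(drop=True)
    return df


def write_enrichment_report(report: "EnrichmentResults", path: str | Path) -> None:
    """Write an enrichment report as TSV with the fixed column set."""
    if report is None:
        raise ValidationError("report is null")
    report_frame(report.results).to_csv(path, sep="\t", index=False)
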