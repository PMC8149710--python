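"""Region tables: the central data model.

A :class:`RegionTable` holds an ordered set of genomic intervals (0-based,
half-open — the BED convention) together with an arbitrary number of typed
metadata columns, a per-row set of tags, and stable integer row ids.  Every
other stage of the toolkit (signal quantification, annotation, embedding,
recipes) reads and writes this object.

Rows are never deleted by analysis operations: filters produce
:class:`Selection` objects, tags mark subsets, and :func:`clone_subset`
materialises an independent copy when a genuinely new dataset is wanted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from . import expr as _expr

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "RegionTable",
    "Selection",
    "FilterPredicate",
    "ProjectSchemaError",
    "load_regions",
    "write_table",
    "write_bed",
    "derive_column",
    "delete_column",
    "apply_filter",
    "tag_rows",
    "clone_subset",
    "summarize_column",
    "save_project",
    "load_project",
]

PROTECTED_COLUMNS = ("chrom", "start", "end", "strand")

PROJECT_SCHEMA_VERSION = 1

_NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signalValue", "neg_log10_p", "neg_log10_q", "summit_offset",
]


class ProjectSchemaError(ValueError):
    """Project JSON is missing, truncated, or of an unsupported version."""


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - ., got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Selection:
    """A set of row ids plus the provenance expression that produced it."""

    row_ids: frozenset[int]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.row_ids)


@dataclass(frozen=True)
class FilterPredicate:
    """One conjunct of a filter.

    ``kind`` is one of ``numeric_range`` (closed interval ``[lo, hi]`` on a
    numeric column; missing values never match), ``category_in`` (membership
    in a value set), ``tag_has_any`` / ``tag_has_all`` (tag-set tests; the
    ``column`` field is ignored for tag predicates).
    """

    kind: Literal["numeric_range", "category_in", "tag_has_any", "tag_has_all"]
    column: str = ""
    lo: float = float("-inf")
    hi: float = float("inf")
    values: frozenset = frozenset()

    def describe(self) -> str:
        if self.kind == "numeric_range":
            return f"{self.column} in [{self.lo}, {self.hi}]"
        if self.kind == "category_in":
            return f"{self.column} in {sorted(map(str, self.values))}"
        return f"{self.kind}({sorted(map(str, self.values))})"

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind}
        if self.kind == "numeric_range":
            d.update(column=self.column, lo=float(self.lo), hi=float(self.hi))
        elif self.kind == "category_in":
            d.update(column=self.column, values=sorted(map(str, self.values)))
        else:
            d.update(values=sorted(map(str, self.values)))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FilterPredicate":
        kind = d["kind"]
        if kind == "numeric_range":
            return cls(kind=kind, column=d["column"], lo=float(d["lo"]), hi=float(d["hi"]))
        if kind == "category_in":
            return cls(kind=kind, column=d["column"], values=frozenset(d["values"]))
        if kind in ("tag_has_any", "tag_has_all"):
            return cls(kind=kind, values=frozenset(d["values"]))
        raise ValueError(f"unknown predicate kind {kind!r}")


class RegionTable:
    """Genomic intervals with metadata columns, tags, and stable row ids.

    Internally a pandas DataFrame indexed by row id with the reserved
    columns ``chrom``, ``start``, ``end``, ``strand`` first, followed by
    metadata columns.  ``tags`` is a parallel Series of per-row sets.
    Missing values are NaN (numeric) or NaN/None (categorical/text).
    """

    def __init__(
        self,
        df: pd.DataFrame,
        tags: pd.Series | None = None,
        genome: str | None = None,
        meta: dict | None = None,
    ):
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        if "strand" not in df.columns:
            df = df.assign(strand=".")
        order = list(PROTECTED_COLUMNS) + [c for c in df.columns if c not in PROTECTED_COLUMNS]
        self.df = df[order]
        if not self.df.index.is_unique:
            raise ValueError("row ids must be unique")
        if tags is None:
            tags = pd.Series([set() for _ in range(len(df))], index=df.index, dtype=object)
        self.tags = tags
        self.genome = genome
        self.meta = dict(meta or {})

    # -- basic introspection -------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def row_ids(self) -> list[int]:
        return list(self.df.index)

    @property
    def metadata_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in PROTECTED_COLUMNS]

    def has_column(self, name: str) -> bool:
        return name in self.df.columns

    def is_numeric(self, name: str) -> bool:
        return pd.api.types.is_numeric_dtype(self.df[name])

    def interval(self, row_id: int) -> GenomicInterval:
        row = self.df.loc[row_id]
        return GenomicInterval(str(row["chrom"]), int(row["start"]), int(row["end"]),
                               str(row["strand"]))

    def intervals(self) -> Iterable[tuple[int, GenomicInterval]]:
        for row_id, row in self.df.iterrows():
            yield int(row_id), GenomicInterval(
                str(row["chrom"]), int(row["start"]), int(row["end"]), str(row["strand"])
            )

    def numeric(self, name: str) -> np.ndarray:
        """Column as a float array (missing -> NaN); errors on non-numeric."""
        if not self.has_column(name):
            raise KeyError(f"no column named {name!r}")
        if not self.is_numeric(name):
            raise TypeError(f"column {name!r} is not numeric")
        return self.df[name].to_numpy(dtype=float)

    def copy(self) -> "RegionTable":
        return RegionTable(
            self.df.copy(),
            self.tags.map(set).copy(),
            self.genome,
            dict(self.meta),
        )


# ---------------------------------------------------------------------------
# I/O


def _parse_tag_cell(cell: object) -> set[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return set()
    return {t for t in str(cell).split(",") if t}


def _coerce_metadata(s: pd.Series) -> pd.Series:
    """Type a metadata column: numeric when at least half its non-empty
    cells parse as numbers (bad cells in a numeric column become missing),
    text otherwise."""
    as_str = s.astype("string")
    nonempty = as_str.notna() & (as_str.str.strip() != "")
    if nonempty.sum() == 0:
        return pd.Series(np.nan, index=s.index)
    if as_str[nonempty].isin(["True", "False"]).all():
        vals = [None if not ne else v == "True" for v, ne in zip(as_str, nonempty)]
        return pd.Series(pd.array(vals, dtype="boolean"), index=s.index)
    def to_float(v: object) -> float:
        try:
            return float(str(v).strip())  # correctly-rounded parse, unlike the csv fast path
        except ValueError:
            return np.nan

    numeric = pd.Series(
        [to_float(v) if ne else np.nan for v, ne in zip(as_str, nonempty)], index=s.index
    )
    frac = numeric[nonempty].notna().mean()
    if frac >= 0.5:
        if not numeric.isna().any() and (numeric % 1 == 0).all():
            return numeric.astype(np.int64)
        return numeric
    return pd.Series(
        [str(v) if ne else np.nan for v, ne in zip(as_str, nonempty)],
        index=s.index,
        dtype=object,
    )


def load_regions(
    path: str | Path,
    dialect: Literal["tsv", "csv", "bed", "narrowPeak"] = "tsv",
    one_based: bool = False,
) -> RegionTable:
    """Load a region table from disk.

    ``tsv``/``csv`` files carry a header whose first three columns are the
    genomic location (chrom, start, end); additional columns become typed
    metadata.  ``bed`` (BED3/BED6) and ``narrowPeak`` are headerless with
    their standard column layouts; narrowPeak exposes columns 7–10 as
    ``signalValue``, ``neg_log10_p``, ``neg_log10_q`` and ``summit_offset``.

    Coordinates are stored 0-based half-open; pass ``one_based=True`` for
    tsv/csv files whose start coordinates are 1-based.  Rows with a
    malformed location (non-integer coordinate, empty chrom, or
    ``start >= end`` after conversion) are dropped with a warning; the
    number dropped is recorded as ``meta['rejected_rows']``.
    A metadata column named ``tags`` is interpreted as comma-joined tag
    sets (the serialization used by :func:`write_table`).
    """
    path = Path(path)
    if dialect in ("bed", "narrowPeak"):
        raw = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#",
                          skip_blank_lines=True)
        if dialect == "narrowPeak":
            if raw.shape[1] < 10:
                raise ValueError("narrowPeak requires 10 columns")
            raw = raw.iloc[:, :10]
            raw.columns = _NARROWPEAK_COLUMNS
        else:
            names = ["chrom", "start", "end", "name", "score", "strand"][: raw.shape[1]]
            raw.columns = names
        one_based = False  # BED-family formats are natively 0-based half-open
    else:
        sep = "\t" if dialect == "tsv" else ","
        raw = pd.read_csv(path, sep=sep, header=0, dtype=str, skip_blank_lines=True)
        if raw.shape[1] < 3:
            raise ValueError("need at least three columns (chrom, start, end)")
        raw = raw.rename(columns=dict(zip(raw.columns[:3], ("chrom", "start", "end"))))

    chrom = raw["chrom"].astype("string").fillna("")
    start = pd.to_numeric(raw["start"], errors="coerce")
    end = pd.to_numeric(raw["end"], errors="coerce")
    integral = (
        start.notna() & end.notna() & (start % 1 == 0) & (end % 1 == 0)
    )
    if one_based:
        start = start - 1
    ok = integral & (chrom.str.len() > 0) & (start >= 0) & (start < end)
    rejected = int((~ok).sum())
    if rejected:
        logger.warning("rejected %d malformed row(s) while loading %s", rejected, path)

    kept = raw.loc[ok].reset_index(drop=True)
    df = pd.DataFrame({
        "chrom": kept["chrom"].astype(str),
        "start": start[ok].to_numpy(dtype=np.int64),
        "end": end[ok].to_numpy(dtype=np.int64),
    })
    if "strand" in kept.columns:
        strand = kept["strand"].astype("string").fillna(".")
        df["strand"] = strand.where(strand.isin(["+", "-", "."]), ".").astype(str)
    else:
        df["strand"] = "."

    tags = None
    meta_cols = [c for c in kept.columns if c not in ("chrom", "start", "end", "strand")]
    for col in meta_cols:
        if col == "tags":
            tags = kept[col].map(_parse_tag_cell)
            continue
        df[col] = _coerce_metadata(kept[col])

    df.index = pd.RangeIndex(1, len(df) + 1)
    if tags is not None:
        tags.index = df.index
    table = RegionTable(df, tags=tags, meta={"rejected_rows": rejected, "source": str(path)})
    return table


def _format_value(v: object) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return "" if np.isnan(v) else repr(float(v))
    if v is pd.NA:
        return ""
    return str(v)


def write_table(table: RegionTable, path: str | Path, format: Literal["tsv", "csv"] = "tsv") -> Path:
    """Write the table as TSV/CSV with a header.

    Columns appear as chrom, start, end, strand, metadata..., tags (tags
    comma-joined, sorted).  Floats are written with ``repr`` so a
    write/load/write cycle is byte-identical.
    """
    path = Path(path)
    sep = "\t" if format == "tsv" else ","
    cols = list(PROTECTED_COLUMNS) + table.metadata_columns
    with open(path, "w") as fh:
        fh.write(sep.join(cols + ["tags"]) + "\n")
        for row_id in table.df.index:
            row = table.df.loc[row_id]
            fields = [_format_value(row[c]) for c in cols]
            fields.append(",".join(sorted(table.tags.loc[row_id])))
            fh.write(sep.join(fields) + "\n")
    return path


def write_bed(table: RegionTable, path: str | Path, selection: Selection | None = None) -> Path:
    """Write BED6 (name = row id, score = 0) for the selection, in table order."""
    path = Path(path)
    ids = None if selection is None else selection.row_ids
    with open(path, "w") as fh:
        for row_id in table.df.index:
            if ids is not None and row_id not in ids:
                continue
            row = table.df.loc[row_id]
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\t{row_id}\t0\t{row['strand']}\n"
            )
    return path


# ---------------------------------------------------------------------------
# Column operations


def derive_column(table: RegionTable, name: str, expression: str) -> RegionTable:
    """Append a numeric column computed by an arithmetic expression.

    The expression may reference existing numeric columns; see
    :mod:`regionkit.expr` for the grammar.  Rows whose evaluation divides
    by zero or takes a log of a non-positive value get the missing marker.
    Errors (syntax, unknown column) occur before any mutation.
    """
    names = _expr.expression_names(expression)
    env = {}
    for n in names:
        if not table.has_column(n):
            raise _expr.ExpressionError(f"unknown column(s): {n}")
        if not table.is_numeric(n):
            raise _expr.ExpressionError(f"column {n!r} is not numeric")
        env[n] = table.numeric(n)
    if name in PROTECTED_COLUMNS:
        raise ValueError(f"cannot overwrite reserved column {name!r}")
    values = _expr.evaluate(expression, env)
    if values.shape[0] != len(table):
        values = np.full(len(table), float(values[0]) if values.size else np.nan)
    table.df[name] = values
    return table


def delete_column(table: RegionTable, name: str) -> RegionTable:
    """Remove a metadata column; the location columns are protected."""
    if name in ("chrom", "start", "end", "strand"):
        raise ValueError(f"column {name!r} is protected and cannot be deleted")
    if not table.has_column(name):
        raise KeyError(f"no column named {name!r}")
    table.df = table.df.drop(columns=[name])
    return table


# ---------------------------------------------------------------------------
# Filtering, tagging, cloning


def _predicate_mask(table: RegionTable, pred: FilterPredicate) -> np.ndarray:
    if pred.kind == "numeric_range":
        x = table.numeric(pred.column)
        with np.errstate(invalid="ignore"):
            return np.isfinite(x) & (x >= pred.lo) & (x <= pred.hi)
    if pred.kind == "category_in":
        if not table.has_column(pred.column):
            raise KeyError(f"no column named {pred.column!r}")
        col = table.df[pred.column]
        return col.isin(list(pred.values)).to_numpy()
    if pred.kind == "tag_has_any":
        return np.array([bool(t & pred.values) for t in table.tags], dtype=bool)
    if pred.kind == "tag_has_all":
        return np.array([pred.values <= t for t in table.tags], dtype=bool)
    raise ValueError(f"unknown predicate kind {pred.kind!r}")


def apply_filter(table: RegionTable, predicates: Sequence[FilterPredicate]) -> Selection:
    """Rows satisfying the conjunction of all predicates.

    An empty predicate list selects every row.  Rows with a missing value
    in a numerically filtered column are excluded.  The table is never
    mutated.
    """
    mask = np.ones(len(table), dtype=bool)
    for pred in predicates:
        mask &= _predicate_mask(table, pred)
    ids = frozenset(int(i) for i in np.asarray(table.df.index)[mask])
    provenance = " AND ".join(p.describe() for p in predicates) or "all"
    return Selection(ids, provenance)


def tag_rows(table: RegionTable, selection: Selection, tag: str) -> RegionTable:
    """Add ``tag`` to each selected row's tag set (idempotent)."""
    if not tag or "," in tag:
        raise ValueError("tag must be non-empty and must not contain commas")
    for row_id in selection.row_ids:
        table.tags.loc[row_id].add(tag)
    return table


def clone_subset(table: RegionTable, selection: Selection | None = None) -> RegionTable:
    """Independent copy of the selected rows with fresh row ids 1..k.

    Row order follows the parent table; all columns and tags are copied.
    Mutating the clone never changes the parent.
    """
    if selection is None:
        keep = list(table.df.index)
    else:
        keep = [i for i in table.df.index if i in selection.row_ids]
    df = table.df.loc[keep].copy()
    tags = table.tags.loc[keep].map(set)
    df.index = pd.RangeIndex(1, len(df) + 1)
    tags.index = df.index
    return RegionTable(df, tags=tags, genome=table.genome, meta=dict(table.meta))


# ---------------------------------------------------------------------------
# Summaries


def summarize_column(
    table: RegionTable,
    column: str,
    selection: Selection | None = None,
    bins: int | Literal["auto"] = "auto",
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram (bin edges, counts) of a numeric column over a selection.

    Equal-width bins span [min, max] of the non-missing values.  ``auto``
    uses the Freedman–Diaconis rule, falling back to 10 bins when the IQR
    is zero.  A constant column collapses to a single bin.  All-missing
    input yields an empty histogram.
    """
    x = table.numeric(column)
    if selection is not None:
        mask = np.isin(np.asarray(table.df.index), list(selection.row_ids))
        x = x[mask]
    x = x[np.isfinite(x)]
    if x.size == 0:
        return np.array([]), np.array([], dtype=int)
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        return np.array([lo, hi]), np.array([x.size])
    if bins == "auto":
        q75, q25 = np.percentile(x, [75, 25])
        iqr = q75 - q25
        if iqr <= 0:
            nbins = 10
        else:
            width = 2 * iqr / x.size ** (1 / 3)
            nbins = max(1, int(np.ceil((hi - lo) / width)))
    else:
        nbins = int(bins)
    counts, edges = np.histogram(x, bins=nbins, range=(lo, hi))
    return edges, counts


# ---------------------------------------------------------------------------
# Project persistence


def save_project(
    path: str | Path,
    table_path: str | Path,
    filters: dict[str, Sequence[FilterPredicate]] | None = None,
    derived_columns: dict[str, str] | None = None,
    tag_vocabulary: Iterable[str] | None = None,
    embeddings: Sequence[dict] | None = None,
    genome: str | None = None,
) -> Path:
    """Serialize project state (filters, derived-column expressions, tag
    vocabulary, embedding configs, and the table file reference) as JSON."""
    doc = {
        "schema_version": PROJECT_SCHEMA_VERSION,
        "table_path": str(table_path),
        "genome": genome,
        "filters": {
            name: [p.to_dict() for p in preds] for name, preds in (filters or {}).items()
        },
        "derived_columns": dict(derived_columns or {}),
        "tag_vocabulary": sorted(set(tag_vocabulary or [])),
        "embeddings": list(embeddings or []),
    }
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def load_project(path: str | Path) -> dict:
    """Load a project JSON; filters come back as FilterPredicate lists.

    Raises :class:`ProjectSchemaError` on truncated files or a schema
    version this code does not understand; no partial state is returned.
    """
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, OSError) as exc:
        raise ProjectSchemaError(f"unreadable project file {path}: {exc}") from exc
    version = doc.get("schema_version")
    if version != PROJECT_SCHEMA_VERSION:
        raise ProjectSchemaError(
            f"unsupported schema_version {version!r} (expected {PROJECT_SCHEMA_VERSION})"
        )
    doc["filters"] = {
        name: [FilterPredicate.from_dict(d) for d in preds]
        for name, preds in doc.get("filters", {}).items()
    }
    return doc
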