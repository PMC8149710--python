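"""Nearest-TSS annotation and region-set intersection.

Replaces the external interval tooling a pipeline would normally shell out
to with two deterministic, pinned-convention operations:

* nearest transcription start site (TSS) per region, with an explicit
  distance convention (below) and tie-breaks, and
* intersection of a region table with another region set, either flagging
  or counting overlaps or importing metadata from the dominant
  overlapping record.

Distance convention for a TSS at base ``t`` and a region ``[s, e)`` with
slop ``k``: distance 0 when ``s - k <= t < e + k``; otherwise ``s - t``
when ``t < s`` and ``t - (e - 1)`` when ``t >= e``.  A TSS at the first
base past the region therefore has distance 1.  Regions are treated as
unstranded (peaks); only the TSS strand determines where the TSS sits on
its transcript.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .regions import RegionTable

__all__ = [
    "TssRecord",
    "load_tss",
    "annotate_nearest_tss",
    "intersect",
]


@dataclass(frozen=True, order=True)
class TssRecord:
    """A transcription start site: 0-based position plus transcript identity."""

    chrom: str
    pos: int
    strand: str
    refseq_id: str
    gene_name: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("TSS position must be >= 0")
        if not self.refseq_id:
            raise ValueError("refseq_id must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


def load_tss(path: str | Path, format: Literal["bed6", "refseq_tsv"] = "bed6") -> list[TssRecord]:
    """Read TSS records from a transcript table.

    The TSS is the transcript start for ``+`` strand transcripts and
    ``end - 1`` for ``-`` strand (0-based half-open input).  ``bed6`` is a
    headerless BED6 file (name = transcript accession); ``refseq_tsv`` is a
    headered TSV with columns chrom, txStart, txEnd, strand, name, name2.
    Records come back sorted by (chrom, pos, refseq_id).
    """
    path = Path(path)
    if format == "bed6":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 6:
            raise ValueError("BED6 requires six columns (strand is mandatory)")
        df = df.iloc[:, :6]
        df.columns = ["chrom", "txStart", "txEnd", "name", "score", "strand"]
        df["name2"] = df["name"]
    else:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
        required = {"chrom", "txStart", "txEnd", "strand", "name"}
        if not required <= set(df.columns):
            raise ValueError(f"refseq_tsv requires columns {sorted(required)}")
        if "name2" not in df.columns:
            df["name2"] = df["name"]
    if df["strand"].isna().any() or not df["strand"].isin(["+", "-"]).all():
        raise ValueError("every transcript needs a + or - strand")
    records = []
    for row in df.itertuples(index=False):
        start, end = int(row.txStart), int(row.txEnd)
        pos = start if row.strand == "+" else end - 1
        records.append(TssRecord(str(row.chrom), pos, str(row.strand), str(row.name), str(row.name2)))
    records.sort(key=lambda r: (r.chrom, r.pos, r.refseq_id))
    return records


def _tss_index(tss_list: Sequence[TssRecord]) -> dict[str, tuple[np.ndarray, list[TssRecord]]]:
    by_chrom: dict[str, list[TssRecord]] = {}
    for rec in tss_list:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    out = {}
    for chrom, recs in by_chrom.items():
        recs.sort(key=lambda r: (r.pos, r.refseq_id))
        out[chrom] = (np.array([r.pos for r in recs], dtype=np.int64), recs)
    return out


def _nearest_for_region(
    pos: np.ndarray, recs: list[TssRecord], start: int, end: int, slop: int
) -> tuple[int, TssRecord]:
    """(distance, record) under the pinned convention and tie-breaks."""
    lo = int(np.searchsorted(pos, start - slop, side="left"))
    hi = int(np.searchsorted(pos, end + slop, side="left"))
    if hi > lo:  # overlap within the slopped window: smallest pos wins,
        return 0, recs[lo]  # equal positions already sorted by refseq_id
    left_d = right_d = None
    left_rec = right_rec = None
    if lo > 0:
        t = int(pos[lo - 1])
        left_d = start - t
        first = int(np.searchsorted(pos, t, side="left"))
        left_rec = recs[first]
    if hi < len(pos):
        t = int(pos[hi])
        right_d = t - (end - 1)
        right_rec = recs[hi]
    if left_d is None:
        return right_d, right_rec  # type: ignore[return-value]
    if right_d is None or left_d <= right_d:  # tie -> smaller pos (left)
        return left_d, left_rec  # type: ignore[return-value]
    return right_d, right_rec


def annotate_nearest_tss(
    table: RegionTable, tss_list: Sequence[TssRecord], slop: int = 0
) -> RegionTable:
    """Annotate each region with its nearest TSS.

    Adds ``tss_distance`` (bp, 0 on overlap), ``tss_refseq_id``,
    ``tss_gene_name`` and ``tss_overlap``.  Ties go to the smallest TSS
    position, then the lexicographically smallest accession.  Regions on a
    chromosome with no TSS get missing values in all four columns.
    """
    if slop < 0:
        raise ValueError("slop must be >= 0")
    index = _tss_index(tss_list)
    if not any(str(c) in index for c in table.df["chrom"].unique()):
        raise ValueError("no chromosome in the table has any TSS")
    n = len(table)
    distance = np.full(n, np.nan)
    refseq = np.full(n, None, dtype=object)
    gene = np.full(n, None, dtype=object)
    overlap = np.full(n, None, dtype=object)
    chroms = table.df["chrom"].to_numpy()
    starts = table.df["start"].to_numpy()
    ends = table.df["end"].to_numpy()
    for i in range(n):
        entry = index.get(str(chroms[i]))
        if entry is None:
            continue
        pos, recs = entry
        d, rec = _nearest_for_region(pos, recs, int(starts[i]), int(ends[i]), slop)
        distance[i] = d
        refseq[i] = rec.refseq_id
        gene[i] = rec.gene_name
        overlap[i] = d == 0
    table.df["tss_distance"] = pd.array(
        [None if np.isnan(d) else int(d) for d in distance], dtype="Int64"
    )
    table.df["tss_refseq_id"] = refseq
    table.df["tss_gene_name"] = gene
    table.df["tss_overlap"] = pd.array(overlap, dtype="boolean")
    return table


def _as_interval_rows(other) -> list[tuple[str, int, int, dict]]:
    """Normalise the 'other' region set to (chrom, start, end, metadata) rows."""
    if isinstance(other, RegionTable):
        meta_cols = other.metadata_columns
        rows = []
        for rid in other.df.index:
            row = other.df.loc[rid]
            rows.append(
                (str(row["chrom"]), int(row["start"]), int(row["end"]),
                 {c: row[c] for c in meta_cols})
            )
        return rows
    rows = []
    for item in other:
        chrom, start, end = item[0], int(item[1]), int(item[2])
        meta = dict(item[3]) if len(item) > 3 else {}
        rows.append((str(chrom), start, end, meta))
    return rows


def intersect(
    table: RegionTable,
    other,
    mode: Literal["flag", "count", "import"] = "flag",
    column: str = "overlap",
    import_columns: Sequence[str] | None = None,
    multi_rule: Literal["first", "max_overlap"] = "max_overlap",
) -> RegionTable:
    """Intersect the table's regions with another region set.

    ``flag`` adds a boolean column (any overlap of >= 1 bp, half-open
    semantics: touching intervals do not overlap); ``count`` adds the
    number of overlapping records; ``import`` copies ``import_columns``
    from the overlapping record chosen by ``multi_rule`` (``max_overlap``
    = largest bp overlap, ties by smallest start; ``first`` = smallest
    (start, end) record).  ``other`` may be a RegionTable or an iterable
    of (chrom, start, end[, metadata dict]) rows.
    """
    if import_columns and mode != "import":
        raise ValueError("import_columns only make sense with mode='import'")
    if mode == "import" and not import_columns:
        raise ValueError("mode='import' requires import_columns")
    rows = _as_interval_rows(other)
    if mode == "import":
        for col in import_columns:  # type: ignore[union-attr]
            if not all(col in meta for _, _, _, meta in rows):
                raise KeyError(f"import column {col!r} absent from the other region set")
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, meta in rows:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, (start, end, meta))

    n = len(table)
    chroms = table.df["chrom"].to_numpy()
    starts = table.df["start"].to_numpy()
    ends = table.df["end"].to_numpy()
    if mode == "flag":
        out = np.zeros(n, dtype=bool)
    elif mode == "count":
        out = np.zeros(n, dtype=np.int64)
    else:
        out = {c: np.full(n, None, dtype=object) for c in import_columns}  # type: ignore[union-attr]

    for i in range(n):
        tree = trees.get(str(chroms[i]))
        hits = tree.overlap(int(starts[i]), int(ends[i])) if tree is not None else set()
        if mode == "flag":
            out[i] = bool(hits)
        elif mode == "count":
            out[i] = len(hits)
        elif hits:
            if multi_rule == "first":
                best = min(hits, key=lambda h: (h.data[0], h.data[1]))
            else:
                s, e = int(starts[i]), int(ends[i])
                best = min(
                    hits,
                    key=lambda h: (-(min(e, h.data[1]) - max(s, h.data[0])), h.data[0]),
                )
            for c in import_columns:  # type: ignore[union-attr]
                out[c][i] = best.data[2][c]

    if mode in ("flag", "count"):
        table.df[column] = out
    else:
        for c in import_columns:  # type: ignore[union-attr]
            table.df[f"{column}_{c}" if column else c] = out[c]
    return table
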