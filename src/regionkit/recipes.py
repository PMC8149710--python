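"""Case-study pipelines: peak QC, element classification, differential binding.

Three composable recipes mirror the standard interactive workflows on a
peak table:

* :func:`peak_qc` — split peaks into strong/weak by a −log10 q-value
  threshold and summarise the weak fraction (false-positive triage of a
  peak caller's output).
* :func:`classify_elements` — tag putative enhancers and promoters by the
  log2 H3K4me1:H3K4me3 signal ratio and summarise per-class TSS overlap
  and mean H3K27ac/CTCF signal.
* :func:`differential_binding` — per-factor log2 fold-change columns
  between condition pairs, a blacklist overlap flag, and counts in
  user-given fold-change windows (e.g. the gained/lost split).

Recipes never drop rows — they tag and summarise, leaving filtering to
the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import annotate as _annotate
from . import regions as _regions
from .regions import FilterPredicate, RegionTable, Selection

__all__ = [
    "PeakQcSummary",
    "ClassSummary",
    "DiffBindSummary",
    "peak_qc",
    "classify_elements",
    "differential_binding",
]

DEFAULT_Q_THRESHOLD = 10.0
DEFAULT_RATIO_HI = 1.0
DEFAULT_RATIO_LO = -1.0
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class PeakQcSummary:
    n_total: int
    threshold: float
    n_below: int
    n_at_or_above: int
    n_missing: int

    @property
    def frac_below(self) -> float:
        return self.n_below / self.n_total if self.n_total else 0.0

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "threshold": self.threshold,
            "n_below": self.n_below,
            "n_at_or_above": self.n_at_or_above,
            "n_missing": self.n_missing,
            "frac_below": self.frac_below,
        }


@dataclass
class ClassSummary:
    classes: dict[str, dict] = field(default_factory=dict)
    # per class: count, tss_overlap_fraction, mean_<mark> entries

    def to_dict(self) -> dict:
        return {"classes": self.classes}


@dataclass
class DiffBindSummary:
    factors: dict[str, dict] = field(default_factory=dict)
    blacklist_fraction_selection: float | None = None
    blacklist_fraction_global: float = 0.0

    def to_dict(self) -> dict:
        return {
            "factors": self.factors,
            "blacklist_fraction_selection": self.blacklist_fraction_selection,
            "blacklist_fraction_global": self.blacklist_fraction_global,
        }


def peak_qc(
    table: RegionTable,
    q_column: str = "neg_log10_q",
    threshold: float = DEFAULT_Q_THRESHOLD,
) -> tuple[RegionTable, PeakQcSummary]:
    """Tag peaks below the q threshold "weak_peak", the rest "strong_peak".

    Rows with a missing q value receive neither tag and are counted
    separately.  The partition over non-missing rows is exhaustive and
    exclusive.
    """
    q = table.numeric(q_column)
    finite = np.isfinite(q)
    ids = np.asarray(table.df.index)
    below = Selection(frozenset(map(int, ids[finite & (q < threshold)])),
                      f"{q_column} < {threshold}")
    above = Selection(frozenset(map(int, ids[finite & (q >= threshold)])),
                      f"{q_column} >= {threshold}")
    _regions.tag_rows(table, below, "weak_peak")
    _regions.tag_rows(table, above, "strong_peak")
    summary = PeakQcSummary(
        n_total=int(finite.sum()),
        threshold=float(threshold),
        n_below=len(below),
        n_at_or_above=len(above),
        n_missing=int((~finite).sum()),
    )
    return table, summary


def classify_elements(
    table: RegionTable,
    me1_col: str,
    me3_col: str,
    k27_col: str | None = None,
    ctcf_col: str | None = None,
    tss_overlap_col: str | None = "tss_overlap",
    ratio_hi: float = DEFAULT_RATIO_HI,
    ratio_lo: float = DEFAULT_RATIO_LO,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ratio_column: str = "me1_me3_l2fc",
) -> tuple[RegionTable, ClassSummary]:
    """Classify regions as enhancer / promoter / unclassified by mark ratio.

    Derives ``r = log2((me1 + p) / (me3 + p))`` and tags rows with
    ``r >= ratio_hi`` as "enhancer" (H3K4me1-dominated), ``r <= ratio_lo``
    as "promoter", and everything else "unclassified".  The summary gives,
    per class, the count, the TSS-overlap fraction, and the mean of the
    optional H3K27ac / CTCF columns — the tabular counterpart of the usual
    pie-chart and colouring read-outs.  Tags are a pure function of the
    ratio column, so re-running is idempotent.
    """
    if not ratio_lo < ratio_hi:
        raise ValueError("require ratio_lo < ratio_hi")
    _regions.derive_column(
        table, ratio_column, f"l2fc({me1_col}, {me3_col}, {pseudocount})"
    )
    r = table.numeric(ratio_column)
    ids = np.asarray(table.df.index)
    finite = np.isfinite(r)
    sel = {
        "enhancer": finite & (r >= ratio_hi),
        "promoter": finite & (r <= ratio_lo),
        "unclassified": finite & (r > ratio_lo) & (r < ratio_hi),
    }
    for tag, mask in sel.items():
        _regions.tag_rows(table, Selection(frozenset(map(int, ids[mask]))), tag)

    summary = ClassSummary()
    for tag, mask in sel.items():
        entry: dict = {"count": int(mask.sum())}
        if tss_overlap_col and table.has_column(tss_overlap_col):
            ov = table.df[tss_overlap_col][mask]
            entry["tss_overlap_fraction"] = float(ov.fillna(False).mean()) if len(ov) else math.nan
        for label, col in (("H3K27ac", k27_col), ("CTCF", ctcf_col)):
            if col is not None:
                x = table.numeric(col)[mask]
                entry[f"mean_{label}"] = float(np.nanmean(x)) if len(x) else math.nan
        summary.classes[tag] = entry
    return table, summary


def differential_binding(
    table: RegionTable,
    pairs: Sequence[tuple[str, str, str]],
    blacklist=None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    windows: Sequence[tuple[float, float]] = ((-math.inf, 0.0), (0.0, math.inf)),
    selection: Selection | None = None,
    blacklist_column: str = "blacklisted",
) -> tuple[RegionTable, DiffBindSummary]:
    """Per-factor log2 fold changes plus blacklist flagging.

    ``pairs`` lists (name, wt_column, mut_column); each yields a column
    ``l2fc_<name>`` = log2((mut + p)/(wt + p)) computed through the same
    derived-column path as interactive column arithmetic.  ``blacklist``
    (a RegionTable or (chrom, start, end) rows) adds a boolean
    ``blacklisted`` column via overlap flagging.  The summary counts rows
    per fold-change window ``[lo, hi)`` per factor and reports the
    blacklisted fraction globally and within ``selection`` if given.
    """
    if not pairs:
        raise ValueError("at least one (name, wt, mut) pair is required")
    summary = DiffBindSummary()
    for name, wt_col, mut_col in pairs:
        col = f"l2fc_{name}"
        _regions.derive_column(table, col, f"l2fc({mut_col}, {wt_col}, {pseudocount})")
        x = table.numeric(col)
        window_counts = {}
        for lo, hi in windows:
            mask = np.isfinite(x) & (x >= lo) & (x < hi)
            window_counts[f"[{lo}, {hi})"] = int(mask.sum())
        summary.factors[name] = {"column": col, "window_counts": window_counts}

    if blacklist is not None:
        _annotate.intersect(table, blacklist, mode="flag", column=blacklist_column)
        flags = table.df[blacklist_column].to_numpy(dtype=bool)
        summary.blacklist_fraction_global = float(flags.mean()) if len(flags) else 0.0
        if selection is not None:
            mask = np.isin(np.asarray(table.df.index), list(selection.row_ids))
            sel_flags = flags[mask]
            summary.blacklist_fraction_selection = (
                float(sel_flags.mean()) if len(sel_flags) else math.nan
            )
    return table, summary
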