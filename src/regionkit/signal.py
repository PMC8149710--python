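"""Per-region signal quantification over bigWig-style step functions.

A genome-wide coverage track is modelled as a step function: disjoint,
sorted (start, end, value) intervals per chromosome in 0-based half-open
coordinates.  Two implementations share one interface: :class:`StepSignal`
holds the intervals in memory (used by the fixture generator and as the
oracle-friendly test double) and :class:`BigWigSignal` reads a real bigWig
file through pyBigWig.

For each region three statistics are computed:

* ``area`` — the per-base sum of the signal over the region (signal·bp),
* ``max``  — the maximum step value overlapping the region,
* ``mean`` — ``area / (end - start)``.

Area is an exact sum over the step function, so it is additive across
adjacent regions and directly checkable against a per-base brute force.
Bases with no data count as signal 0 (set ``missing_as_zero=False`` on
:func:`quantify` to mark fully data-free regions as missing instead).
"""

from __future__ import annotations

import logging
from typing import Iterable, Protocol, Sequence

import numpy as np

from .regions import GenomicInterval, RegionTable

logger = logging.getLogger(__name__)

__all__ = ["SignalTrack", "StepSignal", "BigWigSignal", "read_signal", "quantify"]

STAT_NAMES = ("area", "max", "mean")


class SignalTrack(Protocol):
    """Anything that can serve interval queries against a step function."""

    def fetch(self, chrom: str, start: int, end: int) -> list[tuple[int, int, float]]:
        """Intervals overlapping [start, end), clipped, sorted, disjoint."""
        ...

    def chroms(self) -> dict[str, int]:
        ...


class StepSignal:
    """In-memory step function: per chromosome, sorted disjoint intervals."""

    def __init__(self, intervals: dict[str, Sequence[tuple[int, int, float]]],
                 chrom_sizes: dict[str, int] | None = None):
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._sizes = dict(chrom_sizes or {})
        for chrom, ivs in intervals.items():
            if len(ivs) == 0:
                self._data[chrom] = (np.array([], dtype=np.int64),) * 2 + (np.array([]),)
                continue
            arr = sorted(ivs)
            starts = np.array([s for s, _, _ in arr], dtype=np.int64)
            ends = np.array([e for _, e, _ in arr], dtype=np.int64)
            values = np.array([v for _, _, v in arr], dtype=float)
            if np.any(starts >= ends):
                raise ValueError(f"empty interval on {chrom}")
            if np.any(ends[:-1] > starts[1:]):
                raise ValueError(f"overlapping intervals on {chrom}")
            if not np.all(np.isfinite(values)):
                raise ValueError(f"non-finite signal value on {chrom}")
            self._data[chrom] = (starts, ends, values)
            self._sizes.setdefault(chrom, int(ends[-1]))

    def chroms(self) -> dict[str, int]:
        return dict(self._sizes)

    def fetch(self, chrom: str, start: int, end: int) -> list[tuple[int, int, float]]:
        if chrom not in self._data:
            return []
        starts, ends, values = self._data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        out = []
        for i in range(lo, hi):
            s = max(int(starts[i]), start)
            e = min(int(ends[i]), end)
            if s < e:
                out.append((s, e, float(values[i])))
        return out


class BigWigSignal:
    """Step-function view of an on-disk bigWig file."""

    def __init__(self, path: str):
        import pyBigWig

        self.path = str(path)
        self._bw = pyBigWig.open(self.path)
        self._warned: set[str] = set()

    def chroms(self) -> dict[str, int]:
        return dict(self._bw.chroms())

    def fetch(self, chrom: str, start: int, end: int) -> list[tuple[int, int, float]]:
        if chrom not in self._bw.chroms():
            if chrom not in self._warned:
                logger.warning("chromosome %s absent from %s", chrom, self.path)
                self._warned.add(chrom)
            return []
        raw = self._bw.intervals(chrom, start, end)
        if not raw:
            return []
        return [(max(s, start), min(e, end), float(v)) for s, e, v in raw if max(s, start) < min(e, end)]

    def close(self) -> None:
        self._bw.close()

    def __enter__(self) -> "BigWigSignal":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def read_signal(track: SignalTrack, interval: GenomicInterval) -> list[tuple[int, int, float]]:
    """Step intervals of ``track`` overlapping ``interval``, clipped to it.

    Bases with no recorded data are simply absent from the result; a
    chromosome missing from the track yields an empty list.
    """
    return track.fetch(interval.chrom, interval.start, interval.end)


def _region_stats(track: SignalTrack, chrom: str, start: int, end: int) -> tuple[float, float, float, bool]:
    pieces = track.fetch(chrom, start, end)
    if not pieces:
        return 0.0, 0.0, 0.0, False
    area = float(sum((e - s) * v for s, e, v in pieces))
    mx = float(max(v for _, _, v in pieces))
    covered = sum(e - s for s, e, _ in pieces)
    if covered < end - start:
        mx = max(mx, 0.0)  # uncovered bases contribute value 0
    return area, mx, area / (end - start), True


def quantify(
    track: SignalTrack,
    table: RegionTable,
    stats: Iterable[str] = STAT_NAMES,
    prefix: str = "signal",
    overwrite: bool = False,
    missing_as_zero: bool = True,
) -> RegionTable:
    """Add one numeric column per requested statistic, named ``<prefix>_<stat>``.

    Regions with no overlapping data get area/max/mean 0 (or missing when
    ``missing_as_zero=False``).  Raises on a column-name collision unless
    ``overwrite`` is set.
    """
    stats = tuple(stats)
    unknown = set(stats) - set(STAT_NAMES)
    if unknown:
        raise ValueError(f"unknown statistic(s): {sorted(unknown)}")
    if len(table) == 0:
        raise ValueError("cannot quantify an empty table")
    colnames = {s: f"{prefix}_{s}" for s in stats}
    for col in colnames.values():
        if table.has_column(col) and not overwrite:
            raise ValueError(f"column {col!r} already exists (pass overwrite=True)")

    chrom_arr = table.df["chrom"].to_numpy()
    start_arr = table.df["start"].to_numpy()
    end_arr = table.df["end"].to_numpy()
    out = {s: np.empty(len(table)) for s in stats}
    for i in range(len(table)):
        area, mx, mean, has_data = _region_stats(
            track, str(chrom_arr[i]), int(start_arr[i]), int(end_arr[i])
        )
        if not has_data and not missing_as_zero:
            area = mx = mean = np.nan
        vals = {"area": area, "max": mx, "mean": mean}
        for s in stats:
            out[s][i] = vals[s]
    for s in stats:
        table.df[colnames[s]] = out[s]
    return table
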