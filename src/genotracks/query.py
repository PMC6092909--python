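"""Interval indexing, overlap queries, region-binning summarization and
overlapping-point grouping.

The index is a per-chromosome sorted-start array augmented with a
running maximum of interval ends, giving sublinear lower/upper bounds
for half-open overlap queries without an external interval-tree
dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import ColumnTable, GenomicRange

__all__ = [
    "RangeIndex",
    "BinnedTable",
    "PointGroup",
    "build_index",
    "overlap_query",
    "summarize",
    "group_overlapping_points",
    "DEFAULT_N_BINS",
    "SUMMARY_STATS",
]

DEFAULT_N_BINS = 2000
SUMMARY_STATS = ("mean", "min", "max", "sum", "count", "wmean")


class RangeIndex:
    """Per-chromosome overlap index over a ColumnTable's rows.

    Query results are exactly the rows whose ``[start, end)`` intersects
    the query range, sorted ascending by ``(start, end, row index)``.
    """

    def __init__(self, table: ColumnTable) -> None:
        self.table = table
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        chroms = np.asarray(table.chrom, dtype=object)
        for c in sorted(set(chroms.tolist())):
            rows = np.nonzero(chroms == c)[0]
            starts = table.start[rows]
            ends = table.end[rows]
            # stable sort by (start, end, original index)
            order = np.lexsort((rows, ends, starts))
            starts, ends, rows = starts[order], ends[order], rows[order]
            cummax_end = np.maximum.accumulate(ends)
            self._by_chrom[c] = (starts, ends, rows, cummax_end)

    def query(self, region: GenomicRange) -> np.ndarray:
        """Row indices overlapping ``region`` (half-open semantics)."""
        entry = self._by_chrom.get(region.chrom)
        if entry is None or region.end <= region.start:
            return np.empty(0, dtype=np.int64)
        starts, ends, rows, cummax_end = entry
        # rows with start >= region.end cannot overlap
        hi = int(np.searchsorted(starts, region.end, side="left"))
        # rows before the first index where cummax_end > region.start
        # all have end <= region.start and cannot overlap
        lo = int(np.searchsorted(cummax_end, region.start, side="right"))
        if lo >= hi:
            return np.empty(0, dtype=np.int64)
        sel = ends[lo:hi] > region.start
        return rows[lo:hi][sel].astype(np.int64)


def build_index(table: ColumnTable) -> RangeIndex:
    """Build an overlap index over all rows (idempotent on same table)."""
    return RangeIndex(table)


def overlap_query(index: RangeIndex, region: GenomicRange) -> np.ndarray:
    """Rows of the indexed table intersecting ``region``.

    ``[0,10)`` and ``[10,20)`` do NOT overlap.  Unknown chromosomes
    yield an empty result rather than an error.
    """
    return index.query(region)


@dataclass
class BinnedTable:
    """Fixed-bin summary of a region: contiguous bins tiling
    ``[region.start, region.end)`` with one value and count per column
    per bin.  Value is NaN exactly where count is 0."""

    region: GenomicRange
    n_bins: int
    bin_starts: np.ndarray
    bin_ends: np.ndarray
    values: dict[str, np.ndarray] = field(default_factory=dict)
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def to_payload(self) -> dict:
        """Columnar-JSON-style payload for the wire."""
        return {
            "chr": [self.region.chrom] * self.n_bins,
            "start": [int(s) for s in self.bin_starts],
            "end": [int(e) for e in self.bin_ends],
            "values": {
                name: [None if np.isnan(v) else float(v) for v in col]
                for name, col in self.values.items()
            },
            "counts": {
                name: [int(c) for c in col] for name, col in self.counts.items()
            },
        }


def _bin_edges(region: GenomicRange, n_bins: int) -> np.ndarray:
    """n_bins+1 integer edges exactly tiling [start, end).

    Edge b = start + floor(b * span / n_bins): exact integer arithmetic,
    the last bin absorbs the remainder.
    """
    span = region.end - region.start
    b = np.arange(n_bins + 1, dtype=np.int64)
    return region.start + (b * span) // n_bins


def summarize(
    table: ColumnTable,
    region: GenomicRange,
    n_bins: int = DEFAULT_N_BINS,
    stat: str = "mean",
) -> BinnedTable:
    """Bin ``region`` into ``n_bins`` intervals and summarize each value
    column per bin.

    A row contributes its full value once to every bin its span
    intersects (no length weighting); ``stat="wmean"`` is the optional
    overlap-length-weighted variant.  Empty bins get NaN and count 0.
    """
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    if stat not in SUMMARY_STATS:
        raise ValueError(f"unknown stat {stat!r}; choose from {SUMMARY_STATS}")
    if region.end <= region.start:
        raise ValueError(f"region {region} has non-positive span")

    edges = _bin_edges(region, n_bins)
    bin_starts, bin_ends = edges[:-1], edges[1:]

    idx = build_index(table)
    rows = overlap_query(idx, region)

    values: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    if rows.size == 0:
        for name in table.values:
            counts[name] = np.zeros(n_bins, dtype=np.int64)
            values[name] = np.full(n_bins, np.nan)
        return BinnedTable(region, n_bins, bin_starts, bin_ends, values, counts)

    # clip each row to the region, find first/last intersected bin
    s = np.maximum(table.start[rows], region.start)
    e = np.minimum(table.end[rows], region.end)
    # zero-length rows (start == end) anchor at their position
    first = np.searchsorted(edges, s, side="right") - 1
    last_pos = np.maximum(e - 1, s)  # last base covered (or anchor)
    last = np.searchsorted(edges, last_pos, side="right") - 1
    first = np.clip(first, 0, n_bins - 1)
    last = np.clip(last, 0, n_bins - 1)

    single = first == last
    multi_rows = np.nonzero(~single)[0]

    for name, col in table.values.items():
        vals = col[rows]
        cnt = np.zeros(n_bins, dtype=np.int64)
        ssum = np.zeros(n_bins, dtype=np.float64)
        smin = np.full(n_bins, np.inf)
        smax = np.full(n_bins, -np.inf)
        wsum = np.zeros(n_bins, dtype=np.float64)
        wtot = np.zeros(n_bins, dtype=np.float64)

        def _accumulate(bins: np.ndarray, v: np.ndarray, w: np.ndarray) -> None:
            ok = ~np.isnan(v)
            bins, v, w = bins[ok], v[ok], w[ok]
            np.add.at(cnt, bins, 1)
            np.add.at(ssum, bins, v)
            np.minimum.at(smin, bins, v)
            np.maximum.at(smax, bins, v)
            np.add.at(wsum, bins, v * w)
            np.add.at(wtot, bins, w)

        # rows confined to a single bin: fully vectorized
        _accumulate(
            first[single],
            vals[single],
            (e[single] - s[single]).astype(np.float64),
        )
        # rows spanning bin boundaries: loop (rare for point-like data)
        for i in multi_rows:
            brange = np.arange(first[i], last[i] + 1)
            ov = (
                np.minimum(e[i], bin_ends[brange])
                - np.maximum(s[i], bin_starts[brange])
            ).astype(np.float64)
            _accumulate(brange, np.full(brange.size, vals[i]), ov)

        empty = cnt == 0
        if stat == "mean":
            out = np.divide(ssum, cnt, out=np.full(n_bins, np.nan), where=~empty)
        elif stat == "sum":
            out = np.where(empty, np.nan, ssum)
        elif stat == "min":
            out = np.where(empty, np.nan, smin)
        elif stat == "max":
            out = np.where(empty, np.nan, smax)
        elif stat == "count":
            # NaN in empty bins keeps the null-iff-count-0 invariant;
            # the counts mapping still carries explicit zeros.
            out = np.where(empty, np.nan, cnt.astype(np.float64))
        else:  # wmean
            out = np.divide(
                wsum, wtot, out=np.full(n_bins, np.nan),
                where=(~empty) & (wtot > 0),
            )
        values[name] = out
        counts[name] = cnt

    return BinnedTable(region, n_bins, bin_starts, bin_ends, values, counts)


@dataclass(frozen=True)
class PointGroup:
    """Rows collapsing to one visual object at a pixel column."""

    pixel_x: int
    rows: tuple
    values: Mapping[str, float]


def group_overlapping_points(
    table: ColumnTable,
    region: GenomicRange,
    plot_width_px: int,
) -> list[PointGroup]:
    """Group in-region rows that land on the same pixel column.

    pixel_x = floor((midpoint - region.start) / span * width), clamped
    to [0, width-1]; the representative value per column is the group
    mean (NaN-skipping).  Groups come back sorted by pixel_x.
    """
    if plot_width_px < 1:
        raise ValueError(f"plot_width_px must be >= 1, got {plot_width_px}")
    rows = overlap_query(build_index(table), region)
    if rows.size == 0:
        return []
    mid = (table.start[rows] + table.end[rows]) / 2.0
    span = region.end - region.start
    px = np.floor((mid - region.start) / span * plot_width_px).astype(np.int64)
    px = np.clip(px, 0, plot_width_px - 1)

    groups: list[PointGroup] = []
    for p in np.unique(px):
        members = rows[px == p]
        rep = {}
        for name, col in table.values.items():
            vals = col[members]
            rep[name] = (
                float(np.nan) if np.all(np.isnan(vals)) else float(np.nanmean(vals))
            )
        groups.append(PointGroup(int(p), tuple(int(m) for m in members), rep))
    return groups
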