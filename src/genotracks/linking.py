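"""Linked brushing across charts and genome navigation arithmetic.

A brush event carries a genomic region; resolution walks every chart's
object map and highlights a visual object iff any member row's range
overlaps the event region (half-open, same chromosome only).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

from .core import ColumnTable, GenomicRange, ValidationError
from .query import group_overlapping_points

__all__ = [
    "BrushEvent",
    "VisualObject",
    "ObjectMap",
    "build_object_map",
    "resolve_brush",
    "navigate",
    "NAV_ACTIONS",
]

NAV_ACTIONS = ("pan_left", "pan_right", "zoom_in", "zoom_out")

TRACK_CHART_TYPES = ("genes_track", "line_track", "blocks_track")
PLOT_CHART_TYPES = ("scatter_plot", "heatmap_plot")


@dataclass(frozen=True)
class BrushEvent:
    """A highlight of ``region`` originating from one chart."""

    source_chart_id: str
    region: GenomicRange

    def to_json(self) -> str:
        return json.dumps(
            {
                "source_chart_id": self.source_chart_id,
                "region": {
                    "chr": self.region.chrom,
                    "start": self.region.start,
                    "end": self.region.end,
                },
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "BrushEvent":
        obj = json.loads(text)
        r = obj["region"]
        return cls(
            source_chart_id=obj["source_chart_id"],
            region=GenomicRange(r["chr"], r["start"], r["end"]),
        )


@dataclass(frozen=True)
class VisualObject:
    """One drawable object and the table rows (with their ranges) it
    represents."""

    object_id: str
    rows: tuple
    ranges: tuple  # GenomicRange per member row


@dataclass
class ObjectMap:
    """chart_id -> visual objects; member sets within a chart are
    disjoint and object ids unique."""

    entries: dict[str, list[VisualObject]] = field(default_factory=dict)

    def add_chart(self, chart_id: str, objects: list[VisualObject]) -> None:
        ids = [o.object_id for o in objects]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"chart {chart_id}: duplicate visual object ids")
        seen: set[int] = set()
        for o in objects:
            for r in o.rows:
                if r in seen:
                    raise ValidationError(
                        f"chart {chart_id}: row {r} in multiple visual objects"
                    )
                seen.add(r)
        self.entries[chart_id] = objects


def build_object_map(
    chart,
    table: ColumnTable,
    region: GenomicRange,
    width_px: int,
) -> list[VisualObject]:
    """Visual objects for one chart over ``region``.

    Track charts get one object per in-region row; feature plots get
    one object per pixel group from :func:`group_overlapping_points`,
    each carrying its member rows' ranges.
    """
    from .query import build_index, overlap_query  # local to avoid cycle noise

    chart_type = chart.chart_type
    chart_id = chart.chart_id
    if chart_type in TRACK_CHART_TYPES:
        rows = overlap_query(build_index(table), region)
        return [
            VisualObject(
                object_id=f"{chart_id}-row{int(i)}",
                rows=(int(i),),
                ranges=(table.row_range(int(i)),),
            )
            for i in rows
        ]
    if chart_type in PLOT_CHART_TYPES:
        groups = group_overlapping_points(table, region, width_px)
        return [
            VisualObject(
                object_id=f"{chart_id}-px{g.pixel_x}",
                rows=g.rows,
                ranges=tuple(table.row_range(r) for r in g.rows),
            )
            for g in groups
        ]
    raise ValueError(f"unknown chart type {chart_type!r}")


def resolve_brush(
    event: BrushEvent,
    maps: ObjectMap,
    tables: Mapping[str, ColumnTable] | None = None,
) -> dict[str, list[str]]:
    """Highlighted visual-object ids per chart.

    An object is highlighted iff any member row's range overlaps the
    event region (half-open).  The source chart is included; charts
    whose data lie on other chromosomes get empty lists.  The result
    does not depend on which chart fired the event.
    """
    out: dict[str, list[str]] = {}
    for chart_id, objects in maps.entries.items():
        hits = [
            o.object_id
            for o in objects
            if any(r.overlaps(event.region) for r in o.ranges)
        ]
        out[chart_id] = hits
    return out


def navigate(
    region: GenomicRange,
    action: str,
    step_fraction: float = 0.2,
    zoom_factor: float = 2.0,
    seq_length: int | None = None,
) -> GenomicRange:
    """Pan/zoom arithmetic for a navigation region.

    Pans shift by ``step_fraction * span``, clamped at 0 and (when
    known) the chromosome length.  Zooms scale the span about the
    midpoint by ``zoom_factor`` (out) or its inverse (in); the span
    never drops below 1 base.
    """
    if action not in NAV_ACTIONS:
        raise ValueError(f"unknown action {action!r}; choose from {NAV_ACTIONS}")
    span = region.span
    if action in ("pan_left", "pan_right"):
        step = int(round(span * step_fraction))
        delta = -step if action == "pan_left" else step
        start = region.start + delta
        end = region.end + delta
        if start < 0:
            start, end = 0, span
        if seq_length is not None and end > seq_length:
            end = seq_length
            start = max(0, end - span)
        return GenomicRange(region.chrom, start, end)

    new_span = span / zoom_factor if action == "zoom_in" else span * zoom_factor
    new_span = max(1, int(round(new_span)))
    center = (region.start + region.end) / 2.0
    start = int(round(center - new_span / 2.0))
    if start < 0:
        start = 0
    end = start + new_span
    if seq_length is not None and end > seq_length:
        end = seq_length
        start = max(0, end - new_span)
    return GenomicRange(region.chrom, start, end)
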