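"""Grid layout assignment and deterministic static SVG rendering of the
five chart types.

Rendering is a pure function: identical inputs produce byte-identical
SVG.  Every drawable visual object carries a stable ``id`` and
``class="visual-object"`` so linked-brushing targets can be located in
the output; the object set matches :func:`linking.build_object_map`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import ColumnTable, GeneModel, GenomicRange, SeqInfo, ValidationError
from .query import BinnedTable, group_overlapping_points
from .transforms import Dendrogram

__all__ = [
    "CHART_TYPES",
    "TRACK_TYPES",
    "PLOT_TYPES",
    "ChartSpec",
    "GridPlacement",
    "layout_assign",
    "render_chart",
    "render_ideogram",
    "DEFAULT_PALETTE",
]

TRACK_TYPES = ("genes_track", "line_track", "blocks_track")
PLOT_TYPES = ("scatter_plot", "heatmap_plot")
CHART_TYPES = TRACK_TYPES + PLOT_TYPES

# fixed categorical palette keyed by measurement order
DEFAULT_PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)

MARGIN = 30  # px on each side of the data area
TRACK_SPAN = None  # tracks span all columns (filled from total at layout time)
PLOT_SPAN = 2


@dataclass(frozen=True)
class ChartSpec:
    """Declarative chart description, decoupled from its data."""

    chart_id: str
    chart_type: str
    measurement_ids: tuple = ()
    settings: Mapping = field(default_factory=dict)
    region_bound: GenomicRange | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurement_ids", tuple(self.measurement_ids))
        if self.chart_type not in CHART_TYPES:
            raise ValidationError(f"unknown chart type {self.chart_type!r}")
        if self.chart_type in ("line_track", "blocks_track", "scatter_plot") and \
                len(self.measurement_ids) < 1:
            raise ValidationError(
                f"chart {self.chart_id}: {self.chart_type} needs >= 1 measurement"
            )
        if self.chart_type == "heatmap_plot" and len(self.measurement_ids) < 2:
            raise ValidationError(
                f"chart {self.chart_id}: heatmap needs >= 2 measurements for clustering"
            )

    @property
    def is_track(self) -> bool:
        return self.chart_type in TRACK_TYPES


@dataclass(frozen=True)
class GridPlacement:
    chart_id: str
    row: int
    col_start: int
    col_span: int


def layout_assign(
    charts: Sequence[ChartSpec], total_columns: int = 6
) -> list[GridPlacement]:
    """Assign charts to the grid.

    Tracks span all ``total_columns`` columns; plots span 2.  Charts
    pack left-to-right, top-to-bottom in input order; anything that
    does not fit on the current row starts a new one.
    """
    ids = [c.chart_id for c in charts]
    if len(set(ids)) != len(ids):
        raise ValidationError("chart ids must be unique")
    placements: list[GridPlacement] = []
    row, col = 0, 0
    for chart in charts:
        span = total_columns if chart.is_track else PLOT_SPAN
        if col > 0 and col + span > total_columns:
            row, col = row + 1, 0
        placements.append(GridPlacement(chart.chart_id, row, col, span))
        col += span
        if col >= total_columns:
            row, col = row + 1, 0
    return placements


# ---------------------------------------------------------------------------
# SVG helpers

def _f(x: float) -> str:
    """Fixed 2-decimal formatting keeps output byte-stable."""
    return f"{x:.2f}".rstrip("0").rstrip(".")


def _svg_open(width: int, height: int) -> list[str]:
    return [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
    ]


def _axes(width: int, height: int) -> list[str]:
    x0, y0 = MARGIN, height - MARGIN
    x1, y1 = width - MARGIN, MARGIN
    return [
        f'<line class="axis" x1="{x0}" y1="{y0}" x2="{x1}" y2="{y0}" '
        'stroke="#333" stroke-width="1"/>',
        f'<line class="axis" x1="{x0}" y1="{y0}" x2="{x0}" y2="{y1}" '
        'stroke="#333" stroke-width="1"/>',
    ]


def _x_scale(region: GenomicRange, width: int):
    inner = width - 2 * MARGIN
    span = region.end - region.start

    def to_px(pos: float) -> float:
        return MARGIN + (pos - region.start) / span * inner

    return to_px


def _value_bounds(arrays: Sequence[np.ndarray]) -> tuple[float, float]:
    finite = np.concatenate([a[np.isfinite(a)] for a in arrays]) if arrays else np.array([])
    if finite.size == 0:
        return 0.0, 1.0
    lo, hi = float(finite.min()), float(finite.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    return lo, hi


def _y_scale(lo: float, hi: float, height: int):
    inner = height - 2 * MARGIN

    def to_px(v: float) -> float:
        return height - MARGIN - (v - lo) / (hi - lo) * inner

    return to_px


# ---------------------------------------------------------------------------
# Chart renderers

def render_chart(
    chart: ChartSpec,
    data,
    region: GenomicRange,
    width_px: int = 800,
    height_px: int = 400,
    dendrogram: Dendrogram | None = None,
) -> str:
    """Render one chart to SVG text.

    ``data`` must match the chart type: ColumnTable for blocks/scatter/
    heatmap, BinnedTable or ColumnTable for line tracks, a GeneModel
    sequence for genes tracks.  A heatmap additionally accepts a
    Dendrogram to order and annotate its rows.
    """
    ct = chart.chart_type
    if ct == "line_track":
        if isinstance(data, BinnedTable):
            return _render_line_binned(chart, data, region, width_px, height_px)
        if isinstance(data, ColumnTable):
            return _render_line_table(chart, data, region, width_px, height_px)
        raise TypeError(f"line_track needs BinnedTable or ColumnTable, got {type(data).__name__}")
    if ct == "blocks_track":
        if not isinstance(data, ColumnTable):
            raise TypeError(f"blocks_track needs ColumnTable, got {type(data).__name__}")
        return _render_blocks(chart, data, region, width_px, height_px)
    if ct == "genes_track":
        if not (isinstance(data, Sequence) and all(isinstance(g, GeneModel) for g in data)):
            raise TypeError("genes_track needs a sequence of GeneModel")
        return _render_genes(chart, data, region, width_px, height_px)
    if ct == "scatter_plot":
        if not isinstance(data, ColumnTable):
            raise TypeError(f"scatter_plot needs ColumnTable, got {type(data).__name__}")
        return _render_scatter(chart, data, region, width_px, height_px)
    if ct == "heatmap_plot":
        if not isinstance(data, ColumnTable):
            raise TypeError(f"heatmap_plot needs ColumnTable, got {type(data).__name__}")
        return _render_heatmap(chart, data, region, width_px, height_px, dendrogram)
    raise ValueError(f"unknown chart type {ct!r}")


def _in_region_rows(table: ColumnTable, region: GenomicRange) -> np.ndarray:
    from .query import build_index, overlap_query

    return overlap_query(build_index(table), region)


def _render_line_binned(
    chart: ChartSpec, binned: BinnedTable, region: GenomicRange,
    width: int, height: int,
) -> str:
    parts = _svg_open(width, height)
    parts += _axes(width, height)
    xs = _x_scale(region, width)
    cols = [binned.values[m] for m in chart.measurement_ids if m in binned.values] \
        or list(binned.values.values())
    lo, hi = _value_bounds(cols)
    ys = _y_scale(lo, hi, height)
    mids = (binned.bin_starts + binned.bin_ends) / 2.0
    names = [m for m in chart.measurement_ids if m in binned.values] \
        or list(binned.values.keys())
    for ci, name in enumerate(names):
        col = binned.values[name]
        color = DEFAULT_PALETTE[ci % len(DEFAULT_PALETTE)]
        # null bins break the polyline into segments
        segments: list[list[tuple[float, float]]] = []
        current: list[tuple[float, float]] = []
        for b in range(binned.n_bins):
            if np.isnan(col[b]):
                if current:
                    segments.append(current)
                    current = []
            else:
                current.append((xs(mids[b]), ys(col[b])))
        if current:
            segments.append(current)
        for si, seg in enumerate(segments):
            pts = " ".join(f"{_f(x)},{_f(y)}" for x, y in seg)
            parts.append(
                f'<polyline id="{chart.chart_id}-{name}-seg{si}" '
                f'class="line-segment" fill="none" stroke="{color}" '
                f'stroke-width="1.5" points="{pts}"/>'
            )
        for b in range(binned.n_bins):
            if not np.isnan(col[b]):
                parts.append(
                    f'<circle id="{chart.chart_id}-{name}-bin{b}" '
                    f'class="visual-object" data-bin="{b}" '
                    f'cx="{_f(xs(mids[b]))}" cy="{_f(ys(col[b]))}" '
                    f'r="1.5" fill="{color}"/>'
                )
    parts.append("</svg>")
    return "\n".join(parts)


def _render_line_table(
    chart: ChartSpec, table: ColumnTable, region: GenomicRange,
    width: int, height: int,
) -> str:
    parts = _svg_open(width, height)
    parts += _axes(width, height)
    xs = _x_scale(region, width)
    rows = _in_region_rows(table, region)
    names = [m for m in chart.measurement_ids if m in table.values] \
        or table.column_names()
    cols = [table.values[n][rows] for n in names] if rows.size else []
    lo, hi = _value_bounds(cols)
    ys = _y_scale(lo, hi, height)
    mids = (table.start[rows] + table.end[rows]) / 2.0 if rows.size else np.array([])
    for ci, name in enumerate(names):
        color = DEFAULT_PALETTE[ci % len(DEFAULT_PALETTE)]
        col = table.values[name]
        pts = []
        for k, i in enumerate(rows):
            v = col[i]
            if not np.isnan(v):
                pts.append(f"{_f(xs(mids[k]))},{_f(ys(v))}")
        if pts:
            parts.append(
                f'<polyline id="{chart.chart_id}-{name}-line" '
                f'class="line-segment" fill="none" stroke="{color}" '
                f'stroke-width="1.5" points="{" ".join(pts)}"/>'
            )
        for k, i in enumerate(rows):
            v = col[i]
            cy = _f(ys(v)) if not np.isnan(v) else _f(height - MARGIN)
            parts.append(
                f'<circle id="{chart.chart_id}-row{int(i)}-{name}" '
                f'class="visual-object" data-row="{int(i)}" '
                f'cx="{_f(xs(mids[k]))}" cy="{cy}" r="1.5" fill="{color}"/>'
            )
    parts.append("</svg>")
    return "\n".join(parts)


def _render_blocks(
    chart: ChartSpec, table: ColumnTable, region: GenomicRange,
    width: int, height: int,
) -> str:
    parts = _svg_open(width, height)
    parts += _axes(width, height)
    xs = _x_scale(region, width)
    rows = _in_region_rows(table, region)
    y0 = MARGIN + 10
    block_h = max(4, (height - 2 * MARGIN - 20))
    color = DEFAULT_PALETTE[0]
    for i in rows:
        x_left = xs(max(int(table.start[i]), region.start))
        x_right = xs(min(int(table.end[i]), region.end))
        w = max(1.0, x_right - x_left)
        parts.append(
            f'<rect id="{chart.chart_id}-row{int(i)}" class="visual-object" '
            f'data-row="{int(i)}" x="{_f(x_left)}" y="{y0}" '
            f'width="{_f(w)}" height="{block_h}" fill="{color}" '
            'fill-opacity="0.7"/>'
        )
    parts.append("</svg>")
    return "\n".join(parts)


def _render_genes(
    chart: ChartSpec, genes: Sequence[GeneModel], region: GenomicRange,
    width: int, height: int,
) -> str:
    parts = _svg_open(width, height)
    parts += _axes(width, height)
    xs = _x_scale(region, width)
    mid_y = height / 2.0
    hits = [g for g in genes if g.range.overlaps(region)]
    for gi, g in enumerate(hits):
        x_left = xs(max(g.range.start, region.start))
        x_right = xs(min(g.range.end, region.end))
        body = [
            f'<line x1="{_f(x_left)}" y1="{_f(mid_y)}" x2="{_f(x_right)}" '
            f'y2="{_f(mid_y)}" stroke="#555" stroke-width="1"/>'
        ]
        # strand arrow: small chevron at the transcription end
        if g.strand == "+":
            ax = x_right
            body.append(
                f'<path class="strand-arrow" d="M {_f(ax)} {_f(mid_y)} '
                f'l -6 -4 l 0 8 z" fill="#555"/>'
            )
        elif g.strand == "-":
            ax = x_left
            body.append(
                f'<path class="strand-arrow" d="M {_f(ax)} {_f(mid_y)} '
                f'l 6 -4 l 0 8 z" fill="#555"/>'
            )
        for es, ee in zip(g.exon_starts, g.exon_ends):
            if ee <= region.start or es >= region.end:
                continue
            ex_l = xs(max(es, region.start))
            ex_r = xs(min(ee, region.end))
            body.append(
                f'<rect class="exon" x="{_f(ex_l)}" y="{_f(mid_y - 6)}" '
                f'width="{_f(max(1.0, ex_r - ex_l))}" height="12" '
                f'fill="#2ca02c"/>'
            )
        body.append(
            f'<text x="{_f(x_left)}" y="{_f(mid_y - 10)}" font-size="9" '
            f'fill="#333">{g.gene_name}</text>'
        )
        parts.append(
            f'<g id="{chart.chart_id}-gene{gi}" class="visual-object" '
            f'data-gene="{g.gene_name}">' + "".join(body) + "</g>"
        )
    parts.append("</svg>")
    return "\n".join(parts)


def _render_scatter(
    chart: ChartSpec, table: ColumnTable, region: GenomicRange,
    width: int, height: int,
) -> str:
    parts = _svg_open(width, height)
    parts += _axes(width, height)
    inner_width = width - 2 * MARGIN
    names = [m for m in chart.measurement_ids if m in table.values] \
        or table.column_names()
    yname = names[0] if names else None
    if chart.settings.get("group_points", True) is False:
        # legacy ungrouped mode: every in-region row drawn individually
        return _render_scatter_ungrouped(
            chart, table, region, width, height, yname, parts
        )
    groups = group_overlapping_points(table, region, inner_width)
    vals = [np.array([g.values[yname] for g in groups])] if (groups and yname) else []
    lo, hi = _value_bounds(vals)
    ys = _y_scale(lo, hi, height)
    r = float(chart.settings.get("point_size", 3))
    color = DEFAULT_PALETTE[0]
    for g in groups:
        v = g.values.get(yname, np.nan) if yname else np.nan
        cy = _f(ys(v)) if not np.isnan(v) else _f(height - MARGIN)
        parts.append(
            f'<circle id="{chart.chart_id}-px{g.pixel_x}" class="visual-object" '
            f'data-members="{len(g.rows)}" cx="{MARGIN + g.pixel_x}" '
            f'cy="{cy}" r="{_f(r)}" fill="{color}" fill-opacity="0.8"/>'
        )
    parts.append("</svg>")
    return "\n".join(parts)


def _render_scatter_ungrouped(
    chart: ChartSpec, table: ColumnTable, region: GenomicRange,
    width: int, height: int, yname: str | None, parts: list[str],
) -> str:
    xs = _x_scale(region, width)
    rows = _in_region_rows(table, region)
    col = table.values[yname] if yname else None
    vals = [col[rows]] if (col is not None and rows.size) else []
    lo, hi = _value_bounds(vals)
    ys = _y_scale(lo, hi, height)
    r = float(chart.settings.get("point_size", 3))
    color = DEFAULT_PALETTE[0]
    mids = (table.start[rows] + table.end[rows]) / 2.0 if rows.size else []
    for k, i in enumerate(rows):
        v = col[i] if col is not None else np.nan
        cy = _f(ys(v)) if not np.isnan(v) else _f(height - MARGIN)
        parts.append(
            f'<circle id="{chart.chart_id}-row{int(i)}" class="visual-object" '
            f'cx="{_f(xs(mids[k]))}" cy="{cy}" r="{_f(r)}" '
            f'fill="{color}" fill-opacity="0.8"/>'
        )
    parts.append("</svg>")
    return "\n".join(parts)


def _render_heatmap(
    chart: ChartSpec, table: ColumnTable, region: GenomicRange,
    width: int, height: int, dendrogram: Dendrogram | None,
) -> str:
    parts = _svg_open(width, height)
    inner_width = width - 2 * MARGIN
    dendro_w = 80 if dendrogram is not None else 0
    grid_x0 = MARGIN + dendro_w
    grid_w = inner_width - dendro_w
    groups = group_overlapping_points(table, region, max(1, grid_w))
    names = [m for m in chart.measurement_ids if m in table.values] \
        or table.column_names()
    if dendrogram is not None:
        order = [n for n in dendrogram.leaf_order if n in names]
        order += [n for n in names if n not in order]
        names = order
    n_rows = len(names)
    row_h = (height - 2 * MARGIN) / max(1, n_rows)
    all_vals = np.array(
        [g.values[n] for g in groups for n in names if n in g.values]
    ) if groups else np.array([])
    finite = all_vals[np.isfinite(all_vals)] if all_vals.size else np.array([])
    lo, hi = (float(finite.min()), float(finite.max())) if finite.size else (0.0, 1.0)
    if lo == hi:
        hi = lo + 1.0
    cell_w = grid_w / max(1, len(groups))
    for ci, g in enumerate(sorted(groups, key=lambda g: g.pixel_x)):
        cells = []
        for ri, name in enumerate(names):
            v = g.values.get(name, np.nan)
            fill = _heat_color(v, lo, hi)
            cells.append(
                f'<rect x="{_f(grid_x0 + ci * cell_w)}" '
                f'y="{_f(MARGIN + ri * row_h)}" width="{_f(cell_w)}" '
                f'height="{_f(row_h)}" fill="{fill}"/>'
            )
        parts.append(
            f'<g id="{chart.chart_id}-px{g.pixel_x}" class="visual-object" '
            f'data-members="{len(g.rows)}">' + "".join(cells) + "</g>"
        )
    for ri, name in enumerate(names):
        parts.append(
            f'<text x="{width - MARGIN + 2}" '
            f'y="{_f(MARGIN + (ri + 0.6) * row_h)}" font-size="9" '
            f'fill="#333">{name}</text>'
        )
    if dendrogram is not None:
        parts += _render_dendrogram(
            dendrogram, names, x0=MARGIN, x1=grid_x0 - 4,
            y0=MARGIN, row_h=row_h,
        )
    parts.append("</svg>")
    return "\n".join(parts)


def _heat_color(v: float, lo: float, hi: float) -> str:
    """White-to-blue ramp; NaN cells are light grey."""
    if not np.isfinite(v):
        return "#dddddd"
    t = (v - lo) / (hi - lo)
    t = min(1.0, max(0.0, t))
    r = int(round(255 * (1 - t)))
    g = int(round(255 * (1 - t * 0.7)))
    return f"#{r:02x}{g:02x}ff"


def _render_dendrogram(
    dendro: Dendrogram, leaf_names: Sequence[str],
    x0: float, x1: float, y0: float, row_h: float,
) -> list[str]:
    max_h = dendro.root.height or 1.0
    leaf_y = {name: y0 + (i + 0.5) * row_h for i, name in enumerate(leaf_names)}

    def hx(h: float) -> float:  # height 0 at x1 (leaves), max at x0
        return x1 - (h / max_h) * (x1 - x0)

    lines: list[str] = []

    def rec(node) -> float:
        if node.is_leaf:
            return leaf_y.get(node.id, y0)
        child_y = []
        for c in node.children:
            cy = rec(c)
            lines.append(
                f'<line class="dendro" x1="{_f(hx(node.height))}" '
                f'y1="{_f(cy)}" x2="{_f(hx(c.height))}" y2="{_f(cy)}" '
                'stroke="#888" stroke-width="1"/>'
            )
            child_y.append(cy)
        lines.append(
            f'<line class="dendro" x1="{_f(hx(node.height))}" '
            f'y1="{_f(min(child_y))}" x2="{_f(hx(node.height))}" '
            f'y2="{_f(max(child_y))}" stroke="#888" stroke-width="1"/>'
        )
        return sum(child_y) / len(child_y)

    rec(dendro.root)
    return lines


def render_ideogram(
    chrom: SeqInfo,
    highlight: GenomicRange,
    width_px: int = 600,
    height_px: int = 24,
) -> str:
    """Chromosome bar with a proportional highlight rectangle."""
    if highlight.chrom != chrom.chrom or highlight.start < 0 \
            or highlight.end > chrom.length:
        raise ValidationError(
            f"highlight {highlight} outside chromosome "
            f"{chrom.chrom}:0-{chrom.length}"
        )
    parts = _svg_open(width_px, height_px)
    parts.append(
        f'<rect class="chrom-bar" x="0" y="4" width="{width_px}" '
        f'height="{height_px - 8}" rx="4" fill="#cccccc"/>'
    )
    x = highlight.start / chrom.length * width_px
    w = max(1.0, highlight.span / chrom.length * width_px)
    parts.append(
        f'<rect class="highlight" x="{_f(x)}" y="2" width="{_f(w)}" '
        f'height="{height_px - 4}" fill="#ffd700" fill-opacity="0.85"/>'
    )
    parts.append("</svg>")
    return "\n".join(parts)
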