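"""JSON request/response data provider, an HTTP front end for it, and
standalone-HTML export.

The provider answers columnar-JSON data requests (measurements,
seqinfos, rows, values, region summaries, gene search) from in-memory
datasources loaded from flat files.  Charts never query data
themselves: a workspace session groups charts by their backing table
and issues one query per table per region change, and collapsed
navigation sessions issue none.
"""

from __future__ import annotations

import json
import logging
import threading
import time
from collections import Counter
from dataclasses import dataclass, field
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path
from typing import Mapping, Sequence

from .core import ColumnTable, GenomicRange, Measurement, SeqInfo, ValidationError
from .io import (
    Datasource,
    get_reader,
    to_json_columnar,
)
from .linking import navigate
from .query import DEFAULT_N_BINS, build_index, overlap_query, summarize
from .render import ChartSpec, layout_assign, render_chart

__all__ = [
    "ACTIONS",
    "DataRequest",
    "DataResponse",
    "DataProvider",
    "handle_request",
    "serve",
    "run_server",
    "export_standalone_html",
    "WorkspaceSession",
    "load_sources_config",
]

logger = logging.getLogger("genotracks.provider")

ACTIONS = (
    "get_measurements",
    "get_seqinfos",
    "get_rows",
    "get_values",
    "get_summary",
    "search_genes",
)


@dataclass(frozen=True)
class DataRequest:
    request_id: int
    action: str
    params: Mapping = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"request_id": self.request_id, "action": self.action,
             "params": dict(self.params)},
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "DataRequest":
        obj = json.loads(text)
        return cls(
            request_id=int(obj["request_id"]),
            action=str(obj["action"]),
            params=obj.get("params", {}),
        )


@dataclass(frozen=True)
class DataResponse:
    request_id: int
    success: bool
    payload: object = None
    error: str | None = None

    def to_json(self) -> str:
        return json.dumps(
            {"request_id": self.request_id, "success": self.success,
             "payload": self.payload, "error": self.error},
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "DataResponse":
        obj = json.loads(text)
        return cls(
            request_id=int(obj["request_id"]),
            success=bool(obj["success"]),
            payload=obj.get("payload"),
            error=obj.get("error"),
        )


def _parse_region(params: Mapping) -> GenomicRange:
    try:
        if "region" in params and isinstance(params["region"], str):
            return GenomicRange.parse(params["region"])
        return GenomicRange(
            str(params["chr"]), int(params["start"]), int(params["end"])
        )
    except (KeyError, TypeError, ValueError, ValidationError) as exc:
        raise ValidationError(f"malformed region parameters: {exc}") from exc


class DataProvider:
    """Stateless request handler over a set of datasources.

    Keeps per-action call counters so tests can assert the
    data/plot-separation contract (charts never trigger their own
    queries).
    """

    def __init__(self, sources: Sequence[Datasource]):
        self.sources: dict[str, Datasource] = {}
        for s in sources:
            if s.id in self.sources:
                raise ValidationError(f"duplicate datasource id {s.id!r}")
            self.sources[s.id] = s
        self.query_counts: Counter = Counter()

    # -- action implementations ------------------------------------------

    def _source(self, params: Mapping) -> Datasource:
        ds_id = params.get("datasource")
        if ds_id not in self.sources:
            raise KeyError(f"unknown datasource {ds_id!r}")
        return self.sources[ds_id]

    def _table(self, source: Datasource, params: Mapping) -> tuple[ColumnTable, list[str]]:
        """Resolve the table (and the wanted columns) for a request."""
        m_ids = params.get("measurements")
        if m_ids:
            tables = {id(source.table_for_measurement(m)): source.table_for_measurement(m)
                      for m in m_ids}
            if len(tables) > 1:
                raise ValidationError(
                    "measurements span multiple tables; query them separately"
                )
            return next(iter(tables.values())), list(m_ids)
        kind = params.get("table")
        if kind is not None:
            if kind not in source.tables:
                raise KeyError(f"unknown table {kind!r} in datasource {source.id}")
            t = source.tables[kind]
            return t, t.column_names()
        # default: the first table
        t = next(iter(source.tables.values()))
        return t, t.column_names()

    def handle(self, request: DataRequest) -> DataResponse:
        t0 = time.perf_counter()
        try:
            payload = self._dispatch(request)
            resp = DataResponse(request.request_id, True, payload)
        except Exception as exc:  # protocol errors become success=false
            resp = DataResponse(request.request_id, False, None, str(exc))
        logger.info(
            "action=%s request_id=%d success=%s elapsed_ms=%.2f",
            request.action, request.request_id, resp.success,
            (time.perf_counter() - t0) * 1e3,
        )
        return resp

    def _dispatch(self, request: DataRequest):
        action, params = request.action, request.params
        if action not in ACTIONS:
            raise ValueError(f"unknown action {action!r}")
        self.query_counts[action] += 1

        if action == "get_measurements":
            out = []
            for s in self.sources.values():
                out.extend(m.to_dict() for m in s.measurements)
            return out

        if action == "get_seqinfos":
            out = []
            for s in self.sources.values():
                out.extend(
                    {"chr": si.chrom, "length": si.length} for si in s.seqinfo
                )
            return out

        source = self._source(params)

        if action == "search_genes":
            q = str(params.get("q", "")).lower()
            max_results = int(params.get("max_results", 10))
            hits = [
                {
                    "gene_name": g.gene_name,
                    "chr": g.range.chrom,
                    "start": g.range.start,
                    "end": g.range.end,
                    "strand": g.strand,
                }
                for g in source.genes
                if g.gene_name.lower().startswith(q)
            ]
            return hits[:max_results]

        table, columns = self._table(source, params)
        region = _parse_region(params)

        if action in ("get_rows", "get_values"):
            rows = overlap_query(build_index(table), region)
            from .core import subset_rows

            sub = subset_rows(table, rows)
            payload = json.loads(to_json_columnar(sub))
            if action == "get_values":
                payload["values"] = {
                    k: v for k, v in payload["values"].items() if k in columns
                }
            return payload

        # get_summary
        n_bins = int(params.get("n_bins", DEFAULT_N_BINS))
        stat = str(params.get("stat", "mean"))
        binned = summarize(table, region, n_bins=n_bins, stat=stat)
        payload = binned.to_payload()
        payload["values"] = {
            k: v for k, v in payload["values"].items() if k in columns
        }
        payload["counts"] = {
            k: v for k, v in payload["counts"].items() if k in columns
        }
        return payload


def handle_request(request: DataRequest, sources: Sequence[Datasource]) -> DataResponse:
    """One-shot functional entry point (builds a throwaway provider)."""
    return DataProvider(sources).handle(request)


# ---------------------------------------------------------------------------
# HTTP front end (stdlib; the handler is stateless so threads are safe)

def _make_handler(provider: DataProvider):
    class Handler(BaseHTTPRequestHandler):
        def do_POST(self):  # noqa: N802 (stdlib naming)
            length = int(self.headers.get("Content-Length", 0))
            body = self.rfile.read(length)
            try:
                request = DataRequest.from_json(body.decode("utf-8"))
            except (ValueError, KeyError, UnicodeDecodeError) as exc:
                self._send(400, json.dumps(
                    {"success": False, "error": f"malformed request: {exc}"}))
                return
            response = provider.handle(request)
            self._send(200, response.to_json())

        def _send(self, status: int, body: str) -> None:
            data = body.encode("utf-8")
            self.send_response(status)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(data)))
            self.end_headers()
            self.wfile.write(data)

        def log_message(self, fmt, *args):  # route to logging, not stderr
            logger.debug("http " + fmt, *args)

    return Handler


def run_server(
    provider: DataProvider, host: str = "127.0.0.1", port: int = 8000
) -> tuple[ThreadingHTTPServer, threading.Thread]:
    """Start the provider in a daemon thread; caller owns shutdown()."""
    server = ThreadingHTTPServer((host, port), _make_handler(provider))
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    return server, thread


def serve(sources: Sequence[Datasource], host: str = "127.0.0.1", port: int = 8000) -> None:
    """Blocking variant of :func:`run_server` for the CLI."""
    provider = DataProvider(sources)
    server = ThreadingHTTPServer((host, port), _make_handler(provider))
    logger.info("serving on %s:%d", host, port)
    try:
        server.serve_forever()
    finally:
        server.server_close()


# ---------------------------------------------------------------------------
# Workspace session: data/plot separation and collapsed-navigation rules

class WorkspaceSession:
    """Charts bound to one navigation region, fetching through a shared
    provider.

    Data queries are issued per backing table, not per chart: charts
    sharing a measurement table share one query per region change.
    Collapsed sessions issue no data queries at all.
    """

    def __init__(
        self,
        provider: DataProvider,
        datasource_id: str,
        charts: Sequence[ChartSpec],
        region: GenomicRange,
        collapsed: bool = False,
    ):
        self.provider = provider
        self.datasource_id = datasource_id
        self.charts = list(charts)
        self.region = region
        self.collapsed = collapsed
        self.data: dict[str, dict] = {}  # table kind -> columnar payload
        self.fetch_log: list[tuple[str, str]] = []  # (table kind, region)
        self.refresh()

    def _tables_needed(self) -> list[str]:
        source = self.provider.sources[self.datasource_id]
        kinds: list[str] = []
        for chart in self.charts:
            for m in chart.measurement_ids:
                for kind, table in source.tables.items():
                    if m in table.values and kind not in kinds:
                        kinds.append(kind)
        return kinds

    def refresh(self) -> None:
        if self.collapsed:
            return
        for kind in self._tables_needed():
            req = DataRequest(
                request_id=len(self.fetch_log) + 1,
                action="get_rows",
                params={
                    "datasource": self.datasource_id,
                    "table": kind,
                    "chr": self.region.chrom,
                    "start": self.region.start,
                    "end": self.region.end,
                },
            )
            resp = self.provider.handle(req)
            if not resp.success:
                raise RuntimeError(f"data request failed: {resp.error}")
            self.data[kind] = resp.payload
            self.fetch_log.append((kind, str(self.region)))

    def navigate(self, action: str, **kwargs) -> GenomicRange:
        self.region = navigate(self.region, action, **kwargs)
        self.refresh()
        return self.region

    def set_collapsed(self, collapsed: bool) -> None:
        was = self.collapsed
        self.collapsed = collapsed
        if was and not collapsed:
            self.refresh()


# ---------------------------------------------------------------------------
# Standalone HTML export (offline mode)

_HTML_TEMPLATE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8"/>
<title>genotracks workspace</title>
<style>
body {{ font-family: sans-serif; margin: 1em; }}
.grid {{ display: grid; grid-template-columns: repeat({ncols}, 1fr); gap: 8px; }}
.chart {{ border: 1px solid #ddd; padding: 4px; }}
.chart svg {{ width: 100%; height: auto; }}
</style>
</head>
<body>
<h1>Workspace: {region}</h1>
<div class="grid">
{cells}
</div>
</body>
</html>
"""


def export_standalone_html(
    charts: Sequence[ChartSpec],
    sources: Sequence[Datasource],
    region: GenomicRange,
    out_path,
    width_px: int = 800,
    total_columns: int = 6,
) -> str:
    """Render every chart and write one self-contained HTML page.

    Each chart cell embeds its SVG plus the columnar JSON it was
    rendered from (``<script type="application/json">``), so the page
    needs no network access.  Output is deterministic.  Raises before
    writing anything if a chart's measurements cannot be resolved.
    """
    by_id = {s.id: s for s in sources}

    def resolve(chart: ChartSpec):
        for s in by_id.values():
            if chart.chart_type == "genes_track":
                if s.genes:
                    return s, None
                continue
            try:
                return s, s.table_for_measurement(chart.measurement_ids[0])
            except KeyError:
                continue
        raise ValidationError(
            f"chart {chart.chart_id}: measurements "
            f"{list(chart.measurement_ids)} not resolvable in any datasource"
        )

    resolved = [resolve(c) for c in charts]  # fail fast, before writing

    placements = {p.chart_id: p for p in layout_assign(charts, total_columns)}
    cells = []
    for chart, (source, table) in zip(charts, resolved):
        if chart.chart_type == "genes_track":
            data = source.genes
            embedded = json.dumps(
                [
                    {
                        "gene_name": g.gene_name,
                        "chr": g.range.chrom,
                        "start": g.range.start,
                        "end": g.range.end,
                        "strand": g.strand,
                        "exon_starts": list(g.exon_starts),
                        "exon_ends": list(g.exon_ends),
                    }
                    for g in data
                ],
                sort_keys=True,
            )
        else:
            from .core import subset_rows

            rows = overlap_query(build_index(table), region)
            sub = subset_rows(table, rows)
            data = sub
            embedded = to_json_columnar(sub)
        height = 200 if chart.is_track else 300
        svg = render_chart(chart, data, region, width_px, height)
        p = placements[chart.chart_id]
        cells.append(
            f'<div class="chart" id="cell-{chart.chart_id}" '
            f'style="grid-row: {p.row + 1}; '
            f'grid-column: {p.col_start + 1} / span {p.col_span};">\n'
            f'<script type="application/json" id="data-{chart.chart_id}">'
            f"{embedded}</script>\n{svg}\n</div>"
        )

    html = _HTML_TEMPLATE.format(
        ncols=total_columns, region=str(region), cells="\n".join(cells)
    )
    Path(out_path).write_text(html, encoding="utf-8")
    return html


# ---------------------------------------------------------------------------
# Config loading

def load_sources_config(config_path) -> list[Datasource]:
    """Load datasources from a YAML/JSON config (see fixtures'
    sources.yaml for the shape)."""
    import yaml

    path = Path(config_path)
    cfg = yaml.safe_load(path.read_text())
    sources = []
    for entry in cfg.get("datasources", []):
        ds_id = entry["id"]
        tables: dict[str, ColumnTable] = {}
        genes = []
        measurements = []
        chrom_lengths: dict[str, int] = {}
        declared = int(entry.get("chrom_length", 0))
        for f in entry.get("files", []):
            fpath = path.parent / f["path"]
            reader = get_reader(f["format"])
            if f["format"] == "gff3":
                genes = reader(str(fpath))
                for g in genes:
                    chrom_lengths[g.range.chrom] = max(
                        chrom_lengths.get(g.range.chrom, 0), g.range.end
                    )
                continue
            if f["format"] == "bedgraph":
                table = reader(str(fpath), f.get("column", "score"))
            else:
                table = reader(str(fpath))
            kind = f.get("kind", f["format"])
            tables[kind] = table
            m_kind = "feature" if f["format"] == "feature_matrix" else "track"
            for col in table.column_names():
                measurements.append(
                    Measurement(col, col, ds_id, m_kind)
                )
            for i in range(table.row_count):
                c = str(table.chrom[i])
                chrom_lengths[c] = max(chrom_lengths.get(c, 0), int(table.end[i]))
        seqinfo = [
            SeqInfo(c, max(declared, ln)) for c, ln in sorted(chrom_lengths.items())
        ]
        sources.append(
            Datasource(id=ds_id, tables=tables, genes=genes,
                       seqinfo=seqinfo, measurements=measurements)
        )
    return sources
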