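# genotracks

A server-side genomic track/plot toolkit: a columnar genomic data
model, interval overlap queries, region-binning summarization,
measurement aggregation and hierarchical clustering with dendrograms,
linked-brushing resolution across charts, six-column grid layout,
deterministic static SVG rendering of five chart types, a JSON data
provider over HTTP, and standalone-HTML export with embedded data.

## Package layout

| module | contents |
|---|---|
| `genotracks.core` | `GenomicRange`, `ColumnTable`, `Measurement`, `GeneModel`, `SeqInfo`; table construction/subsetting. Coordinates are 0-based half-open everywhere. |
| `genotracks.io` | BED, GFF3 (converted from 1-based closed on read), bedGraph and feature-matrix readers/writers; the columnar JSON wire format (`chr`/`start`/`end`/`values`, see `docs/columnar-json.schema.json`); `Datasource`; pluggable reader registry. |
| `genotracks.query` | per-chromosome overlap index, `overlap_query`, `summarize` (default 2000 bins; mean/min/max/sum/count plus a length-weighted `wmean`), `group_overlapping_points`. |
| `genotracks.transforms` | `aggregate_columns` (mean/min/max/sum/median, null-skipping), `pairwise_distances` (euclidean, manhattan, 1−Pearson), `hierarchical_cluster` (single/complete/average linkage, deterministic tie-breaking, Newick + JSON tree output). |
| `genotracks.linking` | `BrushEvent`, `ObjectMap`, `build_object_map`, `resolve_brush` (half-open overlap, chromosome-strict), `navigate` (pan/zoom with clamping). |
| `genotracks.render` | `ChartSpec`, `layout_assign` (six columns; tracks span six, plots span two), `render_chart` (genes/line/blocks tracks, scatter, heatmap with dendrogram), `render_ideogram`. Byte-deterministic SVG. |
| `genotracks.service` | `DataProvider` / `handle_request` (get_measurements, get_seqinfos, get_rows, get_values, get_summary, search_genes), stdlib HTTP server, `WorkspaceSession` (one query per table per region change; collapsed sessions query nothing), `export_standalone_html`. |
| `genotracks.fixtures` | seeded generators for genomes, gene models, random-walk signal, non-overlapping peaks and group-shifted expression matrices; byte-deterministic per seed. |

## CLI

```sh
genotracks make-fixtures --seed 42 --out fixtures/
genotracks summarize --input fixtures/signal.bedgraph --column signal \
    --region chr1:0-10000000 --bins 2000 --stat mean --out bins.json
genotracks render --chart scatter_plot --input data.json \
    --region chr1:0-1000000 --width 800 --out chart.svg
genotracks serve --config fixtures/sources.yaml --port 8000
genotracks export-html --workspace workspace.json \
    --config fixtures/sources.yaml --out page.html
```

The server accepts POST requests with a JSON body
`{"request_id": 1, "action": "get_summary", "params": {...}}` and
echoes `request_id` in every response.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (bin-count
contract, layout contract, oracle-equivalence suites against
brute-force references, payload/object reduction under summarization,
round trips, clustering reference checks, brushing, determinism).

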