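"""Readers and writers for BED, GFF3, bedGraph, feature matrices and the
columnar JSON wire format.

The wire format uses the key ``"chr"`` while the internal field is
``chrom``; the (de)serializers own that mapping.  Parse errors carry
1-based line numbers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence, TextIO

import numpy as np

from .core import (
    ColumnTable,
    GeneModel,
    GenomicRange,
    Measurement,
    SeqInfo,
    ValidationError,
    make_column_table,
)

__all__ = [
    "Datasource",
    "ParseError",
    "SchemaError",
    "read_bed",
    "write_bed",
    "read_gff3",
    "write_gff3",
    "read_bedgraph",
    "write_bedgraph",
    "read_feature_matrix",
    "write_feature_matrix",
    "to_json_columnar",
    "from_json_columnar",
    "register_reader",
    "get_reader",
]


class ParseError(ValueError):
    """File-format parse failure, with a 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SchemaError(ValueError):
    """Columnar-JSON payload violates the schema."""


def _open_text(source) -> tuple[TextIO, bool]:
    """Return (stream, should_close) for a path or text stream."""
    if hasattr(source, "read"):
        return source, False
    return open(source, "r", encoding="utf-8"), True


def _iter_data_lines(stream: TextIO) -> Iterable[tuple[int, str]]:
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith("#"):
            continue
        if line.startswith(("track", "browser")):
            continue
        yield lineno, line


# ---------------------------------------------------------------------------
# BED

def read_bed(source) -> ColumnTable:
    """Read BED3+ into a ColumnTable (coordinates stay 0-based half-open).

    Column 4 (name), if present, becomes ``row_names``; column 5 (score)
    becomes the value column ``"score"``.  Columns beyond 5 are ignored.
    """
    stream, close = _open_text(source)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    names: list[str] = []
    scores: list[float] = []
    have_names = have_scores = False
    try:
        for lineno, line in _iter_data_lines(stream):
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"expected >=3 BED columns, got {len(fields)}", lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"non-integer coordinates {fields[1]!r}/{fields[2]!r}", lineno
                ) from None
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            if len(fields) >= 4:
                have_names = True
                names.append(fields[3])
            else:
                names.append("")
            if len(fields) >= 5:
                have_scores = True
                try:
                    scores.append(float(fields[4]))
                except ValueError:
                    raise ParseError(f"non-numeric score {fields[4]!r}", lineno) from None
            else:
                scores.append(math.nan)
    finally:
        if close:
            stream.close()
    return make_column_table(
        chroms,
        starts,
        ends,
        values={"score": scores} if have_scores else {},
        row_names=names if have_names else None,
    )


def write_bed(table: ColumnTable, dest) -> None:
    """Write a ColumnTable as BED (3, 4 or 5 columns depending on content)."""
    stream, close = (dest, False) if hasattr(dest, "write") else (
        open(dest, "w", encoding="utf-8"), True)
    score = table.values.get("score")
    try:
        for i in range(table.row_count):
            cols = [str(table.chrom[i]), str(int(table.start[i])), str(int(table.end[i]))]
            if table.row_names is not None or score is not None:
                name = table.row_names[i] if table.row_names is not None else "."
                cols.append(name)
            if score is not None:
                cols.append(_fmt_number(score[i]))
            stream.write("\t".join(cols) + "\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# bedGraph

def read_bedgraph(source, column_name: str = "score") -> ColumnTable:
    """Read 4-column bedGraph; the value column is named ``column_name``."""
    stream, close = _open_text(source)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    vals: list[float] = []
    try:
        for lineno, line in _iter_data_lines(stream):
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"expected 4 bedGraph columns, got {len(fields)}", lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"non-integer coordinates {fields[1]!r}/{fields[2]!r}", lineno
                ) from None
            try:
                value = float(fields[3])
            except ValueError:
                raise ParseError(f"non-numeric value {fields[3]!r}", lineno) from None
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            vals.append(value)
    finally:
        if close:
            stream.close()
    return make_column_table(chroms, starts, ends, {column_name: vals})


def write_bedgraph(table: ColumnTable, dest, column_name: str | None = None) -> None:
    if column_name is None:
        if len(table.values) != 1:
            raise ValueError("column_name required when table has multiple value columns")
        column_name = next(iter(table.values))
    col = table.values[column_name]
    stream, close = (dest, False) if hasattr(dest, "write") else (
        open(dest, "w", encoding="utf-8"), True)
    try:
        for i in range(table.row_count):
            stream.write(
                f"{table.chrom[i]}\t{int(table.start[i])}\t{int(table.end[i])}\t"
                f"{_fmt_number(col[i])}\n"
            )
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(source) -> list[GeneModel]:
    """Read GFF3 gene/exon features into GeneModel objects.

    GFF3 is 1-based closed; coordinates are converted to 0-based
    half-open (start-1, end).  Exons are attached via their ``Parent``
    attribute and sorted by start.
    """
    stream, close = _open_text(source)
    genes: dict[str, dict] = {}
    exons: list[tuple[str, int, int, int]] = []  # (parent, start, end, lineno)
    try:
        for lineno, line in _iter_data_lines(stream):
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"expected 9 GFF3 columns, got {len(fields)}", lineno)
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"non-integer coordinates {start_s!r}/{end_s!r}", lineno
                ) from None
            start, end = start1 - 1, end1  # to 0-based half-open
            attrs = _parse_gff_attributes(attrs_s)
            if ftype == "gene":
                gene_id = attrs.get("ID")
                if gene_id is None:
                    raise ParseError("gene feature without ID attribute", lineno)
                genes[gene_id] = {
                    "name": attrs.get("Name", gene_id),
                    "range": GenomicRange(chrom, start, end),
                    "strand": strand if strand in "+-" else ".",
                    "exons": [],
                }
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise ParseError("exon feature without Parent attribute", lineno)
                exons.append((parent, start, end, lineno))
    finally:
        if close:
            stream.close()

    for parent, start, end, lineno in exons:
        if parent not in genes:
            raise ParseError(f"exon Parent {parent!r} not a known gene", lineno)
        g = genes[parent]
        if start < g["range"].start or end > g["range"].end:
            raise ValidationError(
                f"gene {g['name']}: exon [{start},{end}) outside gene span "
                f"[{g['range'].start},{g['range'].end})"
            )
        g["exons"].append((start, end))

    models = []
    for g in genes.values():
        g["exons"].sort()
        models.append(
            GeneModel(
                gene_name=g["name"],
                range=g["range"],
                strand=g["strand"],
                exon_starts=tuple(s for s, _ in g["exons"]),
                exon_ends=tuple(e for _, e in g["exons"]),
            )
        )
    return models


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition("=")
        out[key.strip()] = value.strip()
    return out


def write_gff3(genes: Sequence[GeneModel], dest, source: str = "genotracks") -> None:
    """Write GeneModels as GFF3 (converting back to 1-based closed)."""
    stream, close = (dest, False) if hasattr(dest, "write") else (
        open(dest, "w", encoding="utf-8"), True)
    try:
        stream.write("##gff-version 3\n")
        for k, g in enumerate(genes):
            gid = f"gene{k}"
            r = g.range
            stream.write(
                f"{r.chrom}\t{source}\tgene\t{r.start + 1}\t{r.end}\t.\t"
                f"{g.strand}\t.\tID={gid};Name={g.gene_name}\n"
            )
            for s, e in zip(g.exon_starts, g.exon_ends):
                stream.write(
                    f"{r.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\tParent={gid}\n"
                )
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# Feature matrix (artifact-defined TSV dialect)

_MATRIX_FIXED = ("chrom", "start", "end", "feature_name")


def read_feature_matrix(source) -> ColumnTable:
    """Read a tab-delimited feature-by-sample matrix.

    Header: ``chrom  start  end  feature_name  <sample>...``.  One
    numeric column per sample; ``NA`` or empty cells become nulls.
    Feature names land in ``row_names``.
    """
    stream, close = _open_text(source)
    try:
        header_line = stream.readline().rstrip("\n").rstrip("\r")
        header = header_line.split("\t")
        if tuple(header[:4]) != _MATRIX_FIXED:
            raise ParseError(
                f"header must start with {_MATRIX_FIXED}, got {tuple(header[:4])}", 1
            )
        samples = header[4:]
        if len(set(samples)) != len(samples):
            dupes = sorted({s for s in samples if samples.count(s) > 1})
            raise ParseError(f"duplicate sample names: {dupes}", 1)
        chroms: list[str] = []
        starts: list[int] = []
        ends: list[int] = []
        names: list[str] = []
        cols: dict[str, list[float]] = {s: [] for s in samples}
        for lineno, raw in enumerate(stream, start=2):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4 + len(samples):
                raise ParseError(
                    f"expected {4 + len(samples)} columns, got {len(fields)}", lineno
                )
            try:
                starts.append(int(fields[1]))
                ends.append(int(fields[2]))
            except ValueError:
                raise ParseError(
                    f"non-integer coordinates {fields[1]!r}/{fields[2]!r}", lineno
                ) from None
            chroms.append(fields[0])
            names.append(fields[3])
            for s, cell in zip(samples, fields[4:]):
                if cell in ("NA", "", "null", "NaN"):
                    cols[s].append(math.nan)
                else:
                    try:
                        cols[s].append(float(cell))
                    except ValueError:
                        raise ParseError(
                            f"non-numeric value {cell!r} in column {s!r}", lineno
                        ) from None
    finally:
        if close:
            stream.close()
    return make_column_table(chroms, starts, ends, cols, row_names=names)


def write_feature_matrix(table: ColumnTable, dest) -> None:
    stream, close = (dest, False) if hasattr(dest, "write") else (
        open(dest, "w", encoding="utf-8"), True)
    samples = table.column_names()
    try:
        stream.write("\t".join(_MATRIX_FIXED + tuple(samples)) + "\n")
        for i in range(table.row_count):
            name = table.row_names[i] if table.row_names is not None else f"feature{i}"
            cells = [str(table.chrom[i]), str(int(table.start[i])),
                     str(int(table.end[i])), name]
            for s in samples:
                v = table.values[s][i]
                cells.append("NA" if math.isnan(v) else _fmt_number(v))
            stream.write("\t".join(cells) + "\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# Columnar JSON wire format

_REQUIRED_KEYS = ("chr", "start", "end")


def to_json_columnar(table: ColumnTable, *, indent: int | None = None) -> str:
    """Serialize to the columnar wire format.

    Keys: ``chr``, ``start``, ``end``, ``values`` (name -> array).
    NaN values become JSON ``null``; numbers keep full precision.  A
    ``feature_names`` key is emitted when the table has row names.
    """
    payload: dict = {
        "chr": [str(c) for c in table.chrom],
        "start": [int(s) for s in table.start],
        "end": [int(e) for e in table.end],
        "values": {
            name: [None if math.isnan(v) else float(v) for v in col]
            for name, col in table.values.items()
        },
    }
    if table.row_names is not None:
        payload["feature_names"] = list(table.row_names)
    return json.dumps(payload, indent=indent, sort_keys=True)


def from_json_columnar(text: str | Mapping) -> ColumnTable:
    """Parse the columnar wire format back into a validated ColumnTable."""
    obj = json.loads(text) if isinstance(text, str) else text
    if not isinstance(obj, Mapping):
        raise SchemaError("payload must be a JSON object")
    for key in _REQUIRED_KEYS:
        if key not in obj:
            raise SchemaError(f"missing required key {key!r}")
    values = obj.get("values", {})
    if not isinstance(values, Mapping):
        raise SchemaError("'values' must be an object mapping name -> array")
    return make_column_table(
        chrom=obj["chr"],
        start=obj["start"],
        end=obj["end"],
        values={str(k): v for k, v in values.items()},
        row_names=obj.get("feature_names"),
    )


def _fmt_number(v: float) -> str:
    """Render a number compactly: integral floats without the .0 tail."""
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    f = float(v)
    if f.is_integer():
        return str(int(f))
    return repr(f)


# ---------------------------------------------------------------------------
# Datasource and the pluggable reader registry

_READERS: dict[str, Callable] = {}


def register_reader(format_name: str, fn: Callable) -> None:
    """Register a custom parser under a format name (plugin hook)."""
    _READERS[format_name] = fn


def get_reader(format_name: str) -> Callable:
    try:
        return _READERS[format_name]
    except KeyError:
        raise KeyError(
            f"unknown format {format_name!r}; known: {sorted(_READERS)}"
        ) from None


register_reader("bed", read_bed)
register_reader("bedgraph", read_bedgraph)
register_reader("gff3", read_gff3)
register_reader("feature_matrix", read_feature_matrix)
register_reader("json", from_json_columnar)


@dataclass
class Datasource:
    """A named bundle of tables, gene models and measurement metadata
    served by the data provider."""

    id: str
    tables: dict[str, ColumnTable] = field(default_factory=dict)  # kind -> table
    genes: list[GeneModel] = field(default_factory=list)
    seqinfo: list[SeqInfo] = field(default_factory=list)
    measurements: list[Measurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        chrom_set = {s.chrom for s in self.seqinfo}
        for kind, table in self.tables.items():
            for c in set(table.chrom):
                if c not in chrom_set:
                    raise ValidationError(
                        f"datasource {self.id}: chromosome {c!r} in table "
                        f"{kind!r} missing from seqinfo"
                    )
        for m in self.measurements:
            owners = [
                kind for kind, t in self.tables.items() if m.id in t.values
            ]
            if len(owners) != 1:
                raise ValidationError(
                    f"datasource {self.id}: measurement {m.id!r} found in "
                    f"{len(owners)} tables (expected exactly 1)"
                )

    def table_for_measurement(self, measurement_id: str) -> ColumnTable:
        for table in self.tables.values():
            if measurement_id in table.values:
                return table
        raise KeyError(f"measurement {measurement_id!r} not in datasource {self.id}")
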