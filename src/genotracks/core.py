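"""Core domain types: genomic ranges, columnar tables, measurements.

All coordinates are 0-based half-open ``[start, end)``.  Adjacent
intervals share a boundary and do not overlap; interval length is
``end - start``.  Formats using other conventions (GFF3) are converted
on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicRange",
    "ColumnTable",
    "Measurement",
    "GeneModel",
    "SeqInfo",
    "ValidationError",
    "make_column_table",
    "subset_rows",
]


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


@dataclass(frozen=True, order=True)
class GenomicRange:
    """A chromosome span, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"end ({self.end}) must be >= start ({self.start})"
            )

    @property
    def span(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRange") -> bool:
        """Half-open overlap: [0,10) and [10,20) do NOT overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicRange") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    @classmethod
    def parse(cls, text: str) -> "GenomicRange":
        """Parse ``chr1:0-1000`` notation (0-based half-open)."""
        m = _REGION_RE.match(text.strip())
        if m is None:
            raise ValidationError(f"cannot parse region {text!r}")
        return cls(m.group(1), int(m.group(2)), int(m.group(3)))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class SeqInfo:
    """Chromosome name and length in bases."""

    chrom: str
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(
                f"chromosome length must be positive, got {self.length}"
            )

    @property
    def range(self) -> GenomicRange:
        return GenomicRange(self.chrom, 0, self.length)


@dataclass(frozen=True)
class Measurement:
    """Metadata for one queryable value column.

    ``kind`` is ``"track"`` for positional signal and ``"feature"`` for
    per-feature quantities (expression-like data).
    """

    id: str
    name: str
    datasource_id: str
    kind: str  # "track" | "feature"
    value_min: float | None = None
    value_max: float | None = None
    annotation: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("track", "feature"):
            raise ValidationError(f"unknown measurement kind {self.kind!r}")
        if (
            self.value_min is not None
            and self.value_max is not None
            and self.value_min > self.value_max
        ):
            raise ValidationError(
                f"value_min ({self.value_min}) > value_max ({self.value_max})"
            )

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "name": self.name,
            "datasource_id": self.datasource_id,
            "kind": self.kind,
            "value_min": self.value_min,
            "value_max": self.value_max,
            "annotation": dict(self.annotation),
        }


@dataclass(frozen=True)
class GeneModel:
    """A gene span with strand and sorted non-overlapping exons."""

    gene_name: str
    range: GenomicRange
    strand: str = "."
    exon_starts: tuple = ()
    exon_ends: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "exon_starts", tuple(self.exon_starts))
        object.__setattr__(self, "exon_ends", tuple(self.exon_ends))
        if self.strand not in ("+", "-", "."):
            raise ValidationError(
                f"gene {self.gene_name}: bad strand {self.strand!r}"
            )
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValidationError(
                f"gene {self.gene_name}: exon start/end arrays differ in length"
            )
        prev_end = None
        for s, e in zip(self.exon_starts, self.exon_ends):
            if s < self.range.start or e > self.range.end:
                raise ValidationError(
                    f"gene {self.gene_name}: exon [{s},{e}) outside gene span"
                )
            if s >= e:
                raise ValidationError(
                    f"gene {self.gene_name}: empty exon [{s},{e})"
                )
            if prev_end is not None and s < prev_end:
                raise ValidationError(
                    f"gene {self.gene_name}: exons unsorted or overlapping"
                )
            prev_end = e

    @property
    def n_exons(self) -> int:
        return len(self.exon_starts)


class ColumnTable:
    """Columnar genomic data: parallel coordinate arrays plus named
    numeric value columns.

    Missing values are NaN internally and serialize as JSON ``null``.
    Row order is insertion order and is preserved by construction and
    subsetting; query operations sort their own output.

    An optional ``row_names`` array carries a per-row string label
    (e.g. feature names for expression matrices).
    """

    def __init__(
        self,
        chrom: Sequence[str],
        start: Sequence[int],
        end: Sequence[int],
        values: Mapping[str, Sequence[float]] | None = None,
        row_names: Sequence[str] | None = None,
    ) -> None:
        self.chrom = np.asarray(chrom, dtype=object)
        self.start = np.asarray(start, dtype=np.int64)
        self.end = np.asarray(end, dtype=np.int64)
        self.values: dict[str, np.ndarray] = {}
        for name, col in (values or {}).items():
            arr = np.array(
                [np.nan if v is None else float(v) for v in col],
                dtype=np.float64,
            )
            self.values[name] = arr
        self.row_names = None if row_names is None else list(row_names)
        self.validate()

    @property
    def row_count(self) -> int:
        return len(self.start)

    def __len__(self) -> int:
        return self.row_count

    def validate(self) -> None:
        """Check the shared ColumnTable invariants; raise ValidationError."""
        n = len(self.start)
        if len(self.chrom) != n:
            raise ValidationError(
                f"column 'chrom': length {len(self.chrom)} != {n}"
            )
        if len(self.end) != n:
            raise ValidationError(f"column 'end': length {len(self.end)} != {n}")
        for name, col in self.values.items():
            if not name:
                raise ValidationError("value column with empty name")
            if len(col) != n:
                raise ValidationError(
                    f"column {name!r}: length {len(col)} != {n}"
                )
        if self.row_names is not None and len(self.row_names) != n:
            raise ValidationError(
                f"column 'row_names': length {len(self.row_names)} != {n}"
            )
        bad = np.nonzero(self.start > self.end)[0]
        if bad.size:
            i = int(bad[0])
            raise ValidationError(
                f"row {i}: start {self.start[i]} > end {self.end[i]}"
            )
        if np.any(self.start < 0):
            i = int(np.nonzero(self.start < 0)[0][0])
            raise ValidationError(f"row {i}: negative start {self.start[i]}")

    def column_names(self) -> list[str]:
        return list(self.values.keys())

    def row_range(self, i: int) -> GenomicRange:
        return GenomicRange(str(self.chrom[i]), int(self.start[i]), int(self.end[i]))

    def equals(self, other: "ColumnTable") -> bool:
        if self.row_count != other.row_count:
            return False
        if list(self.chrom) != list(other.chrom):
            return False
        if not (
            np.array_equal(self.start, other.start)
            and np.array_equal(self.end, other.end)
        ):
            return False
        if set(self.values) != set(other.values):
            return False
        for name, col in self.values.items():
            if not np.array_equal(col, other.values[name], equal_nan=True):
                return False
        return self.row_names == other.row_names

    def __repr__(self) -> str:
        cols = ",".join(self.values)
        return f"ColumnTable({self.row_count} rows, values=[{cols}])"


def make_column_table(
    chrom: Sequence[str],
    start: Sequence[int],
    end: Sequence[int],
    values: Mapping[str, Sequence[float]] | None = None,
    row_names: Sequence[str] | None = None,
) -> ColumnTable:
    """Build and validate a :class:`ColumnTable`; row order is preserved."""
    return ColumnTable(chrom, start, end, values, row_names)


def subset_rows(table: ColumnTable, row_ids: Iterable[int]) -> ColumnTable:
    """Select rows in the order given by ``row_ids``.

    Value columns are subset in lockstep.  Out-of-range indices raise
    IndexError.
    """
    idx = np.asarray(list(row_ids), dtype=np.int64)
    n = table.row_count
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        bad = idx[(idx < 0) | (idx >= n)][0]
        raise IndexError(f"row index {bad} out of range [0, {n})")
    return ColumnTable(
        chrom=table.chrom[idx] if idx.size else [],
        start=table.start[idx],
        end=table.end[idx],
        values={name: col[idx] for name, col in table.values.items()},
        row_names=(
            None
            if table.row_names is None
            else [table.row_names[i] for i in idx]
        ),
    )
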