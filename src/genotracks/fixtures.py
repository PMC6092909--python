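"""Deterministic synthetic-data generators: genomes, gene models,
signal tracks, peak blocks and expression matrices with known ground
truth.

Every generator is a pure function of :class:`FixtureConfig`; the same
seed yields byte-identical files.  Signal values come from a bounded
random walk (not white noise) so line tracks and summarization show
visible structure.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .core import ColumnTable, GeneModel, GenomicRange, Measurement, SeqInfo, make_column_table
from .io import (
    Datasource,
    write_bed,
    write_bedgraph,
    write_feature_matrix,
    write_gff3,
)

__all__ = [
    "FixtureConfig",
    "make_genome",
    "make_signal_track",
    "make_peaks",
    "make_genes",
    "make_expression",
    "make_datasource",
    "write_fixture_files",
]


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 42
    n_chroms: int = 1
    chrom_length: int = 10_000_000
    n_genes: int = 50
    signal_step: int = 1000
    n_peaks: int = 100
    n_features: int = 200
    n_samples: int = 10
    group_effect: float = 2.0

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_length", "n_genes", "signal_step",
                     "n_peaks", "n_features", "n_samples"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _chrom_names(n: int) -> list[str]:
    """chr1..chr22, then chrX, chrY, then numeric continuation."""
    names = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
    if n <= len(names):
        return names[:n]
    return names + [f"chr{i}" for i in range(25, n + 1)]


def _rng(config: FixtureConfig, stream: int) -> np.random.Generator:
    # independent deterministic stream per generator/chromosome
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _chrom_stream(chrom: str, base: int) -> int:
    return base * 1000 + sum(ord(c) for c in chrom)


def make_genome(config: FixtureConfig) -> list[SeqInfo]:
    """``n_chroms`` chromosomes of ``chrom_length`` bases each."""
    return [SeqInfo(name, config.chrom_length) for name in _chrom_names(config.n_chroms)]


def make_signal_track(config: FixtureConfig, chrom: str) -> tuple[str, ColumnTable]:
    """Tiled fixed-step bedGraph signal from a bounded random walk.

    Returns the file text and the ground-truth table; they agree
    exactly (values are rounded to 4 decimals before both are built).
    """
    rng = _rng(config, _chrom_stream(chrom, 1))
    length = config.chrom_length
    step = min(config.signal_step, length) if config.signal_step > 0 else length
    starts = np.arange(0, length, step, dtype=np.int64)
    ends = np.minimum(starts + step, length)
    n = len(starts)
    steps = rng.uniform(-1.0, 1.0, size=n)
    walk = np.empty(n)
    v = 0.0
    for i in range(n):
        v = float(np.clip(v + steps[i], -5.0, 5.0))
        walk[i] = v
    walk = np.round(walk, 4)
    table = make_column_table([chrom] * n, starts, ends, {"signal": walk})
    buf = io.StringIO()
    write_bedgraph(table, buf, "signal")
    return buf.getvalue(), table


def make_peaks(config: FixtureConfig, chrom: str) -> tuple[str, ColumnTable]:
    """``n_peaks`` sorted, pairwise non-overlapping scored intervals as
    BED5 text plus the ground-truth table."""
    rng = _rng(config, _chrom_stream(chrom, 2))
    n = config.n_peaks
    if n == 0:
        table = make_column_table([], [], [], {"score": []}, row_names=[])
        return "", table
    # 2n+ distinct sorted cut points; alternate segments become peaks,
    # which guarantees non-overlap with at least 1-base gaps
    cuts = np.sort(rng.choice(config.chrom_length, size=2 * n + 1, replace=False))
    starts = cuts[0:2 * n:2]
    ends = cuts[1:2 * n + 1:2]
    ends = np.maximum(ends, starts + 1)
    scores = rng.integers(0, 1001, size=n)
    names = [f"peak{i}" for i in range(n)]
    table = make_column_table(
        [chrom] * n, starts, ends, {"score": scores.astype(float)}, row_names=names
    )
    buf = io.StringIO()
    write_bed(table, buf)
    return buf.getvalue(), table


def make_genes(config: FixtureConfig, chrom: str) -> tuple[str, list[GeneModel]]:
    """``n_genes`` gene models with 2-8 sorted non-overlapping exons,
    as GFF3 text plus the parsed ground truth."""
    rng = _rng(config, _chrom_stream(chrom, 3))
    n = config.n_genes
    genes: list[GeneModel] = []
    if n > 0:
        slot = config.chrom_length // n
        for i in range(n):
            slot_start = i * slot
            gene_len = int(rng.integers(max(2, slot // 10), max(3, slot // 2)))
            gene_start = slot_start + int(rng.integers(0, max(1, slot - gene_len)))
            gene_end = gene_start + gene_len
            n_exons = int(rng.integers(2, 9))
            cuts = np.sort(
                rng.choice(
                    np.arange(gene_start, gene_end),
                    size=min(2 * n_exons, gene_len),
                    replace=False,
                )
            )
            ex_starts = cuts[0::2][: len(cuts) // 2]
            ex_ends = np.maximum(cuts[1::2][: len(cuts) // 2], ex_starts + 1)
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_name=f"GENE{i}",
                    range=GenomicRange(chrom, gene_start, gene_end),
                    strand=strand,
                    exon_starts=tuple(int(s) for s in ex_starts),
                    exon_ends=tuple(int(e) for e in ex_ends),
                )
            )
    buf = io.StringIO()
    write_gff3(genes, buf)
    return buf.getvalue(), genes


def make_expression(
    config: FixtureConfig, chrom: str | None = None
) -> tuple[str, ColumnTable, dict]:
    """Feature-by-sample expression matrix with a known group effect.

    Samples split into a ``normal`` half and a ``tumor`` half shifted by
    ``group_effect``.  Features sit at gene locations when gene models
    exist, otherwise evenly spaced.  Returns (TSV text, ground-truth
    table, truth dict with group labels and the true effect).
    """
    if chrom is None:
        chrom = _chrom_names(max(1, config.n_chroms))[0]
    rng = _rng(config, _chrom_stream(chrom, 4))
    n_feat, n_samp = config.n_features, config.n_samples
    n_normal = n_samp // 2
    samples = [f"normal_{i + 1}" for i in range(n_normal)] + [
        f"tumor_{i + 1}" for i in range(n_samp - n_normal)
    ]
    groups = {s: ("normal" if s.startswith("normal") else "tumor") for s in samples}

    _, genes = make_genes(replace(config, n_genes=max(config.n_genes, 1)), chrom)
    starts, ends, names = [], [], []
    for i in range(n_feat):
        if genes:
            g = genes[i % len(genes)]
            starts.append(g.range.start)
            ends.append(g.range.end)
        else:
            w = max(1, config.chrom_length // max(1, n_feat))
            starts.append(i * w)
            ends.append(min((i + 1) * w, config.chrom_length))
        names.append(f"feature{i}")

    base = rng.normal(5.0, 1.0, size=n_feat)
    cols: dict[str, np.ndarray] = {}
    for s in samples:
        noise = rng.normal(0.0, 1.0, size=n_feat)
        shift = config.group_effect if groups[s] == "tumor" else 0.0
        cols[s] = np.round(base + noise + shift, 4)
    table = make_column_table([chrom] * n_feat, starts, ends, cols, row_names=names)
    buf = io.StringIO()
    write_feature_matrix(table, buf)
    truth = {"groups": groups, "effect": config.group_effect, "samples": samples}
    return buf.getvalue(), table, truth


def make_datasource(config: FixtureConfig, datasource_id: str = "fixture") -> Datasource:
    """Assemble a full in-memory Datasource from all generators.

    Track tables (signal, peaks) cover the first chromosome; the
    expression table provides feature-kind measurements.
    """
    seqinfo = make_genome(config)
    chrom = seqinfo[0].chrom if seqinfo else "chr1"
    if not seqinfo:
        seqinfo = [SeqInfo(chrom, config.chrom_length)]
    _, signal = make_signal_track(config, chrom)
    _, peaks = make_peaks(config, chrom)
    _, genes = make_genes(config, chrom)
    _, expr, _truth = make_expression(config, chrom)

    measurements = [
        Measurement("signal", "Signal", datasource_id, "track",
                    float(np.nanmin(signal.values["signal"])) if len(signal) else None,
                    float(np.nanmax(signal.values["signal"])) if len(signal) else None),
        Measurement("score", "Peak score", datasource_id, "track", 0.0, 1000.0),
    ] + [
        Measurement(s, s.replace("_", " "), datasource_id, "feature")
        for s in expr.column_names()
    ]
    return Datasource(
        id=datasource_id,
        tables={"signal": signal, "peaks": peaks, "expression": expr},
        genes=genes,
        seqinfo=seqinfo,
        measurements=measurements,
    )


def write_fixture_files(config: FixtureConfig, out_dir) -> dict[str, str]:
    """Write BED, bedGraph, GFF3 and TSV fixtures plus a sources.yaml;
    returns {logical name: path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seqinfo = make_genome(config)
    chrom = seqinfo[0].chrom if seqinfo else "chr1"
    signal_text, _ = make_signal_track(config, chrom)
    peaks_text, _ = make_peaks(config, chrom)
    genes_text, _ = make_genes(config, chrom)
    expr_text, _, _ = make_expression(config, chrom)

    paths = {}
    for name, text in [
        ("signal.bedgraph", signal_text),
        ("peaks.bed", peaks_text),
        ("genes.gff3", genes_text),
        ("expression.tsv", expr_text),
    ]:
        (out / name).write_text(text)
        paths[name] = str(out / name)

    yaml_lines = [
        "datasources:",
        "  - id: fixture",
        f"    chrom_length: {config.chrom_length}",
        "    files:",
        "      - {kind: signal, format: bedgraph, path: signal.bedgraph, column: signal}",
        "      - {kind: peaks, format: bed, path: peaks.bed}",
        "      - {kind: genes, format: gff3, path: genes.gff3}",
        "      - {kind: expression, format: feature_matrix, path: expression.tsv}",
    ]
    (out / "sources.yaml").write_text("\n".join(yaml_lines) + "\n")
    paths["sources.yaml"] = str(out / "sources.yaml")
    return paths
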