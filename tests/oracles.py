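"""Independent brute-force reference implementations used as oracles.

Everything here is deliberately naive (pure-Python loops, direct
definitions) and shares no code with the package's query/cluster/brush
paths.
"""

from __future__ import annotations

import numpy as np


def brute_overlap(table, region) -> list[int]:
    """Linear scan for half-open overlap, sorted by (start, end, index)."""
    hits = []
    for i in range(table.row_count):
        if (
            str(table.chrom[i]) == region.chrom
            and int(table.start[i]) < region.end
            and region.start < int(table.end[i])
        ):
            hits.append(i)
    hits.sort(key=lambda i: (int(table.start[i]), int(table.end[i]), i))
    return hits


def brute_bin_edges(region, n_bins: int) -> list[tuple[int, int]]:
    span = region.end - region.start
    edges = [region.start + (b * span) // n_bins for b in range(n_bins + 1)]
    return list(zip(edges[:-1], edges[1:]))


def brute_summarize(table, region, n_bins: int, stat: str, column: str):
    """Per-bin group statistic by double loop over rows and bins.

    Returns (values, counts) lists with None for empty bins.  Rows are
    clipped to the region; a row contributes once to every bin its
    clipped span intersects.
    """
    bins = brute_bin_edges(region, n_bins)
    groups: list[list[float]] = [[] for _ in bins]
    col = table.values[column]
    for i in brute_overlap(table, region):
        s = max(int(table.start[i]), region.start)
        e = min(int(table.end[i]), region.end)
        v = float(col[i])
        if np.isnan(v):
            continue
        for b, (bs, be) in enumerate(bins):
            if s < be and bs < e:
                groups[b].append(v)
    values, counts = [], []
    for g in groups:
        counts.append(len(g))
        if not g:
            values.append(None)
        elif stat == "mean":
            values.append(sum(g) / len(g))
        elif stat == "min":
            values.append(min(g))
        elif stat == "max":
            values.append(max(g))
        elif stat == "sum":
            values.append(sum(g))
        elif stat == "count":
            values.append(float(len(g)))
        else:
            raise ValueError(stat)
    return values, counts


def naive_cluster_heights(d: np.ndarray, linkage: str, labels=None) -> list[float]:
    """Naive O(n^3) agglomeration recomputing every cluster distance
    from the original matrix; returns merge heights in merge order.

    Uses the same lexicographic tie-break contract as the package
    (smallest sorted label-tuple pair wins among equal distances).
    """
    n = d.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    clusters = {(labels[i],): [i] for i in range(n)}
    heights = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for a in range(len(keys)):
            for b in range(a + 1, len(keys)):
                ka, kb = keys[a], keys[b]
                pair_ds = [
                    float(d[i, j]) for i in clusters[ka] for j in clusters[kb]
                ]
                if linkage == "single":
                    dist = min(pair_ds)
                elif linkage == "complete":
                    dist = max(pair_ds)
                elif linkage == "average":
                    dist = sum(pair_ds) / len(pair_ds)
                else:
                    raise ValueError(linkage)
                cand = (dist, ka, kb)
                if best is None or cand < best:
                    best = cand
        dist, ka, kb = best
        members = clusters.pop(ka) + clusters.pop(kb)
        clusters[tuple(sorted(ka + kb))] = members
        heights.append(dist)
    return heights


def mst_edge_weights(d: np.ndarray) -> list[float]:
    """Prim's algorithm; returns the n-1 MST edge weights sorted
    ascending (single-linkage merge heights coincide with these)."""
    n = d.shape[0]
    in_tree = [0]
    out = set(range(1, n))
    weights = []
    while out:
        best = None
        for i in in_tree:
            for j in out:
                if best is None or d[i, j] < best[0]:
                    best = (float(d[i, j]), j)
        weights.append(best[0])
        in_tree.append(best[1])
        out.remove(best[1])
    return sorted(weights)


def brute_resolve_brush(event, object_map) -> dict[str, list[str]]:
    """Membership scan: object highlighted iff some member range
    overlaps the event region (half-open, same chromosome)."""
    out = {}
    for chart_id, objects in object_map.entries.items():
        hits = []
        for obj in objects:
            for r in obj.ranges:
                if (
                    r.chrom == event.region.chrom
                    and r.start < event.region.end
                    and event.region.start < r.end
                ):
                    hits.append(obj.object_id)
                    break
        out[chart_id] = hits
    return out
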