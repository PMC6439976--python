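"""Genomic interval arithmetic on plain numpy arrays.

Coordinates are 0-based half-open throughout (BED convention).  Interval
sets live either in parallel ``starts``/``ends`` arrays (one chromosome)
or in pandas frames with ``chrom``/``start``/``end`` columns.  The merge
primitive is single-linkage with an explicit gap parameter: ``max_gap=-1``
requires a strict >=1 bp overlap (book-ended intervals stay separate),
``max_gap=0`` additionally joins book-ended intervals, and positive values
implement ROSE-style stitching.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

INTERVAL_COLS = ["chrom", "start", "end"]


def merge_intervals(
    starts: np.ndarray, ends: np.ndarray, max_gap: int = -1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge intervals on one chromosome.

    Returns ``(merged_starts, merged_ends, cluster)`` where ``cluster[i]``
    is the merged-interval index of input interval ``i``.  Two intervals
    join when ``next.start - running_end <= max_gap``; merging is
    transitive.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy(), empty.copy()
    order = np.lexsort((ends, starts))
    s, e = starts[order], ends[order]
    run_end = np.maximum.accumulate(e)
    new = np.empty(s.size, dtype=bool)
    new[0] = True
    new[1:] = s[1:] - run_end[:-1] > max_gap
    cid = np.cumsum(new) - 1
    first = np.flatnonzero(new)
    merged_starts = s[first]
    merged_ends = np.maximum.reduceat(e, first)
    cluster = np.empty_like(cid)
    cluster[order] = cid
    return merged_starts, merged_ends, cluster


def merge_frame(df: pd.DataFrame, max_gap: int = -1) -> tuple[pd.DataFrame, pd.Series]:
    """Merge a multi-chromosome interval frame.

    Returns the merged frame (sorted by chrom, start) and a Series mapping
    each input row (by position) to its merged-row index.
    """
    if df.empty:
        merged = pd.DataFrame(columns=INTERVAL_COLS)
        return merged, pd.Series(dtype=np.int64)
    out_chrom, out_start, out_end = [], [], []
    cluster = np.empty(len(df), dtype=np.int64)
    offset = 0
    pos = np.arange(len(df))
    chroms = df["chrom"].to_numpy()
    for chrom in sorted(pd.unique(chroms)):
        mask = chroms == chrom
        ms, me, cl = merge_intervals(
            df["start"].to_numpy()[mask], df["end"].to_numpy()[mask], max_gap
        )
        cluster[pos[mask]] = cl + offset
        offset += ms.size
        out_chrom.extend([chrom] * ms.size)
        out_start.append(ms)
        out_end.append(me)
    merged = pd.DataFrame(
        {
            "chrom": out_chrom,
            "start": np.concatenate(out_start),
            "end": np.concatenate(out_end),
        }
    )
    return merged, pd.Series(cluster)


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: does any subject interval overlap it (>=1 bp)?"""
    result = np.zeros(len(query), dtype=bool)
    if query.empty or subject.empty:
        return result
    pos = np.arange(len(query))
    qchroms = query["chrom"].to_numpy()
    for chrom, sub in subject.groupby("chrom"):
        mask = qchroms == chrom
        if not mask.any():
            continue
        order = np.argsort(sub["start"].to_numpy(), kind="stable")
        s_start = sub["start"].to_numpy()[order]
        s_end = sub["end"].to_numpy()[order]
        run_end = np.maximum.accumulate(s_end)
        q_start = query["start"].to_numpy()[mask]
        q_end = query["end"].to_numpy()[mask]
        # candidate subjects start before the query ends
        n_before = np.searchsorted(s_start, q_end, side="left")
        hit = np.zeros(q_start.size, dtype=bool)
        nz = n_before > 0
        hit[nz] = run_end[n_before[nz] - 1] > q_start[nz]
        result[pos[mask]] = hit
    return result


class GenomeCoords:
    """Flatten a multi-chromosome genome onto one global coordinate axis."""

    def __init__(self, chrom_sizes: dict[str, int]):
        self.chrom_sizes = dict(chrom_sizes)
        self.chroms = list(self.chrom_sizes)
        sizes = np.array([self.chrom_sizes[c] for c in self.chroms], dtype=np.int64)
        self.sizes = sizes
        self.offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        self.total_bp = int(sizes.sum())
        self._index = {c: i for i, c in enumerate(self.chroms)}

    def flatten(self, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Global (start, end) arrays for an interval frame."""
        if df.empty:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        missing = set(df["chrom"]) - set(self._index)
        if missing:
            raise ValueError(f"chromosomes absent from size table: {sorted(missing)}")
        idx = df["chrom"].map(self._index).to_numpy()
        off = self.offsets[idx]
        return df["start"].to_numpy() + off, df["end"].to_numpy() + off


class CoverageIndex:
    """Prefix-sum index over a merged, sorted interval set on the global axis.

    ``covered_before(x)`` is the number of covered bases in [0, x); the
    intersection of a query [s, e) with the set is then F(e) - F(s),
    vectorized over queries.
    """

    def __init__(self, starts: np.ndarray, ends: np.ndarray):
        order = np.argsort(starts, kind="stable")
        self.starts = np.asarray(starts, dtype=np.int64)[order]
        self.ends = np.asarray(ends, dtype=np.int64)[order]
        lengths = self.ends - self.starts
        self.cum = np.concatenate([[0], np.cumsum(lengths)])
        self.total = int(self.cum[-1])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, coords: GenomeCoords) -> "CoverageIndex":
        merged, _ = merge_frame(df, max_gap=-1)
        gs, ge = coords.flatten(merged)
        return cls(gs, ge)

    def covered_before(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.int64)
        j = np.searchsorted(self.starts, x, side="right")
        res = self.cum[j].astype(np.int64)
        nz = j > 0
        jm = j[nz] - 1
        overshoot = np.clip(self.ends[jm] - x[nz], 0, self.ends[jm] - self.starts[jm])
        res[nz] -= overshoot
        return res

    def intersect_bp(self, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Covered bases within each query interval (global coordinates)."""
        return self.covered_before(ends) - self.covered_before(starts)


def intersection_bp(a: pd.DataFrame, b: pd.DataFrame, coords: GenomeCoords) -> int:
    """Total base pairs shared by two interval frames."""
    if a.empty or b.empty:
        return 0
    merged_a, _ = merge_frame(a, max_gap=-1)
    ga_s, ga_e = coords.flatten(merged_a)
    idx = CoverageIndex.from_frame(b, coords)
    return int(idx.intersect_bp(ga_s, ga_e).sum())


def total_bp(df: pd.DataFrame) -> int:
    """Total covered base pairs of a frame after internal merging."""
    merged, _ = merge_frame(df, max_gap=-1)
    if merged.empty:
        return 0
    return int((merged["end"] - merged["start"]).sum())
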