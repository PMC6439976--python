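"""Chromatin-loop strength quantification and recovery classification.

Contact matrices (dense, symmetric, one per chromosome and time point)
are balanced with the Knight-Ruiz diagonal scaling, depth-normalized so
every time point carries the same short-range (<= 100 kb) total as the
untreated matrix, and loop strength is read out as the mean over the
anchor-bin block.  The recovery rate of a loop at time t is
strength(t) / strength(untreated); per time point, the top 10% of rates
are "fast" loops, the bottom 10% "slow", the rest "moderate".

Loops whose strengths do not increase strictly across the recovery time
points, whose observed/expected enrichment falls below the threshold, or
whose anchors hit a user-supplied exclusion set (e.g. karyotype-artifact
regions) are filtered out before classification.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import intervals

DEFAULT_BIN_SIZE = 25_000
DEFAULT_OE_MIN = 4.5
UNTREATED = "untreated"


def kr_balance(
    matrix: np.ndarray, tol: float = 1e-6, max_iter: int = 5000
) -> np.ndarray:
    """Knight-Ruiz balancing: symmetric diagonal scaling D M D.

    All non-empty rows of the result have equal row sums (set to 1) to a
    relative tolerance of ``tol``; empty rows pass through as zeros.
    Raises on non-convergence, reporting the residual.
    """
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(a, a.T, rtol=1e-8, atol=1e-12):
        raise ValueError("matrix must be symmetric")
    if np.any(a < 0) or not np.all(np.isfinite(a)):
        raise ValueError("matrix must be finite and non-negative")
    nonempty = a.sum(axis=1) > 0
    b = a[np.ix_(nonempty, nonempty)]
    n = b.shape[0]
    out = np.zeros_like(a)
    if n == 0:
        return out
    x = 1.0 / np.sqrt(np.maximum(b.sum(axis=1), 1e-300))
    residual = np.inf
    for _ in range(max_iter):
        r = x * (b @ x)
        residual = float(np.abs(r - 1.0).max())
        if residual <= tol:
            break
        # damped multiplicative update toward unit row sums
        x = x * np.power(np.maximum(r, 1e-300), -0.5)
    else:
        raise RuntimeError(
            f"KR balancing did not converge in {max_iter} iterations "
            f"(max relative row-sum residual {residual:.3e})"
        )
    balanced = b * np.outer(x, x)
    out[np.ix_(nonempty, nonempty)] = balanced
    return out


def short_range_total(matrix: np.ndarray, bin_size: int, short_range_bp: int) -> float:
    n = matrix.shape[0]
    i, j = np.indices((n, n))
    mask = np.abs(i - j) * bin_size <= short_range_bp
    return float(matrix[mask].sum())


def depth_normalize(
    matrices: dict[str, np.ndarray],
    bin_size: int = DEFAULT_BIN_SIZE,
    short_range_bp: int = 100_000,
    reference: str = UNTREATED,
) -> dict[str, np.ndarray]:
    """Rescale each matrix so its short-range total matches the reference.

    Short-range interactions (within ``short_range_bp``) are insensitive
    to cohesin loss, so equalizing them corrects for sequencing-depth
    differences between time points.
    """
    if reference not in matrices:
        raise KeyError(f"reference matrix {reference!r} missing")
    shapes = {m.shape for m in matrices.values()}
    if len(shapes) > 1:
        raise ValueError("matrices must share bin grid")
    ref_total = short_range_total(matrices[reference], bin_size, short_range_bp)
    out = {}
    for label, m in matrices.items():
        total = short_range_total(m, bin_size, short_range_bp)
        if total <= 0:
            raise ValueError(f"matrix {label!r} has zero short-range total")
        out[label] = m * (ref_total / total)
    return out


def _anchor_bins(anchor: tuple[int, int], bin_size: int, pad_bins: int, n_bins: int):
    start, end = anchor
    b0 = start // bin_size - pad_bins
    b1 = (end - 1) // bin_size + pad_bins
    if b0 < 0 or b1 >= n_bins:
        raise IndexError(f"anchor {anchor} (pad {pad_bins}) outside matrix of {n_bins} bins")
    return b0, b1 + 1


def loop_strength(
    matrix: np.ndarray,
    anchor1: tuple[int, int],
    anchor2: tuple[int, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    pad_bins: int = 0,
) -> float:
    """Mean matrix value over the anchor1-bins x anchor2-bins block."""
    n = matrix.shape[0]
    r0, r1 = _anchor_bins(anchor1, bin_size, pad_bins, n)
    c0, c1 = _anchor_bins(anchor2, bin_size, pad_bins, n)
    return float(matrix[r0:r1, c0:c1].mean())


def quantify_loops_from_matrices(
    loops: pd.DataFrame,
    matrices: dict[str, dict[str, np.ndarray]],
    timepoints: list[str],
    bin_size: int = DEFAULT_BIN_SIZE,
    pad_bins: int = 0,
) -> pd.DataFrame:
    """Add strength_<tp> columns read from per-chromosome matrices."""
    out = loops.copy()
    for tp in timepoints:
        col = np.empty(len(out))
        for i, row in enumerate(out.itertuples(index=False)):
            m = matrices[row.chrom1][tp]
            col[i] = loop_strength(
                m, (row.start1, row.end1), (row.start2, row.end2), bin_size, pad_bins
            )
        out[f"strength_{tp}"] = col
    return out


def recovery_timepoint_cols(loops: pd.DataFrame) -> list[str]:
    """strength_t<minutes> columns in time order (untreated/degraded excluded)."""
    cols = [c for c in loops.columns if c.startswith("strength_t")]
    return sorted(cols, key=lambda c: int(c.removeprefix("strength_t")))


def filter_loops(
    loops: pd.DataFrame,
    oe_min: float = DEFAULT_OE_MIN,
    exclusion: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """O/E threshold, anchor exclusion, and strict-monotonicity filters.

    The monotonicity filter requires the strength sequence over the
    recovery time points (untreated excluded) to be strictly increasing.
    """
    keep = np.ones(len(loops), dtype=bool)
    if "oe" in loops.columns:
        keep &= loops["oe"].to_numpy(float) >= oe_min
    if exclusion is not None and not exclusion.empty:
        a1 = loops.rename(columns={"chrom1": "chrom", "start1": "start", "end1": "end"})
        a2 = loops.rename(columns={"chrom2": "chrom", "start2": "start", "end2": "end"})
        keep &= ~intervals.overlaps_any(a1[["chrom", "start", "end"]], exclusion)
        keep &= ~intervals.overlaps_any(a2[["chrom", "start", "end"]], exclusion)
    cols = recovery_timepoint_cols(loops)
    if len(cols) >= 2:
        series = loops[cols].to_numpy(float)
        keep &= np.all(np.diff(series, axis=1) > 0, axis=1)
    return loops.loc[keep].reset_index(drop=True)


def classify_recovery(
    loops: pd.DataFrame,
    timepoint: str,
    fast_pct: float = 10,
    slow_pct: float = 10,
) -> pd.DataFrame:
    """Label loops fast/moderate/slow at one time point by recovery rate.

    rate = strength(t) / strength(untreated); fast = the ceil(fast_pct% N)
    largest rates, slow = the ceil(slow_pct% N) smallest; rate ties are
    broken by genomic order so labels are deterministic and exclusive.
    """
    n = len(loops)
    if n < 10:
        raise ValueError(f"need >= 10 loops to classify, got {n}")
    untreated = loops[f"strength_{UNTREATED}"].to_numpy(float)
    if np.any(untreated <= 0):
        raise ValueError("untreated strength must be positive for recovery rates")
    rate = loops[f"strength_{timepoint}"].to_numpy(float) / untreated
    out = loops.copy()
    out[f"rate_{timepoint}"] = rate
    order = out.assign(_rate=rate).sort_values(
        ["_rate", "chrom1", "start1", "start2"], kind="mergesort"
    ).index
    k_fast = math.ceil(fast_pct / 100.0 * n)
    k_slow = math.ceil(slow_pct / 100.0 * n)
    if k_fast + k_slow > n:
        raise ValueError("fast and slow classes would overlap")
    labels = pd.Series("moderate", index=out.index)
    labels[order[:k_slow]] = "slow"
    labels[order[n - k_fast:]] = "fast"
    out[f"class_{timepoint}"] = labels
    return out
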