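"""Per-sample super-enhancer calling.

ROSE-style procedure on pre-called H3K27ac peaks: drop peaks that fall
entirely inside a promoter-proximal exclusion zone around any TSS, stitch
the remaining peaks within a fixed genomic distance, rank the stitched
regions by background-subtracted signal, and cut the ranked curve where
its min-max-scaled tangent slope first exceeds 1.  Regions above the
cutoff are the sample's super-enhancers; any that touch a blacklist
region are discarded.

Peaks are pandas frames with columns ``chrom, start, end, h3k27ac_rpm,
input_rpm``; signal is reads-per-million, background subtraction is
floored at zero (negative enhancer activity is meaningless).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import intervals

logger = logging.getLogger(__name__)

DEFAULT_STITCH_BP = 12_500
DEFAULT_TSS_ZONE_BP = 2_500

REGION_COLS = ["chrom", "start", "end", "n_peaks", "signal"]
SE_COLS = ["chrom", "start", "end", "signal", "rank", "sample"]


def exclude_tss_zones(
    peaks: pd.DataFrame, tss_table: pd.DataFrame, zone_bp: int = DEFAULT_TSS_ZONE_BP
) -> pd.DataFrame:
    """Remove peaks fully contained in [TSS - zone_bp, TSS + zone_bp).

    A peak [s, e) is contained in the zone of a TSS at t iff
    t - zone_bp <= s and e <= t + zone_bp, i.e. iff some TSS lies in
    [e - zone_bp, s + zone_bp].  Peaks that merely overlap a zone are kept.
    """
    if peaks.empty or tss_table is None or tss_table.empty:
        return peaks.reset_index(drop=True)
    keep = np.ones(len(peaks), dtype=bool)
    pos = np.arange(len(peaks))
    peak_chroms = set(peaks["chrom"])
    for chrom, sub in tss_table.groupby("chrom"):
        if chrom not in peak_chroms:
            logger.warning("TSS table chromosome %s absent from peaks; ignored", chrom)
            continue
        tss = np.sort(sub["pos"].to_numpy())
        mask = (peaks["chrom"] == chrom).to_numpy()
        lo = peaks["end"].to_numpy()[mask] - zone_bp
        hi = peaks["start"].to_numpy()[mask] + zone_bp
        has_tss = np.searchsorted(tss, lo, side="left") < np.searchsorted(
            tss, hi, side="right"
        )
        keep[pos[mask]] &= ~has_tss
    return peaks.loc[keep].reset_index(drop=True)


def peak_signal(peaks: pd.DataFrame) -> np.ndarray:
    """Background-subtracted per-peak signal, floored at zero."""
    return np.maximum(
        0.0, peaks["h3k27ac_rpm"].to_numpy(float) - peaks["input_rpm"].to_numpy(float)
    )


def stitch_peaks(peaks: pd.DataFrame, stitch_bp: int = DEFAULT_STITCH_BP) -> pd.DataFrame:
    """Transitively merge peaks whose gap is <= stitch_bp.

    Region signal is the sum of background-subtracted member signals.
    Input need not be sorted; overlapping peaks always merge.
    """
    if peaks.empty:
        return pd.DataFrame(columns=REGION_COLS)
    merged, cluster = intervals.merge_frame(peaks, max_gap=stitch_bp)
    sig = peak_signal(peaks)
    n_clusters = len(merged)
    signal = np.zeros(n_clusters)
    counts = np.zeros(n_clusters, dtype=np.int64)
    np.add.at(signal, cluster.to_numpy(), sig)
    np.add.at(counts, cluster.to_numpy(), 1)
    merged = merged.copy()
    merged["n_peaks"] = counts
    merged["signal"] = signal
    return merged[REGION_COLS]


def rose_cutoff(signals, slope_tol: float = 1e-9) -> float:
    """Signal cutoff at the tangent-slope-1 point of the ranked curve.

    Signals are sorted ascending and both axes min-max scaled to [0, 1];
    the cutoff is the (unscaled) signal at the first index whose forward
    first-difference slope strictly exceeds 1.  A flat curve (or one whose
    slope never exceeds 1, e.g. an exactly linear ramp) returns +inf so
    that no region is called.
    """
    s = np.sort(np.asarray(signals, dtype=float))
    n = s.size
    if n < 2:
        return np.inf
    rng = s[-1] - s[0]
    if rng <= 0:
        return np.inf
    y = (s - s[0]) / rng
    slopes = np.diff(y) * (n - 1)
    above = np.flatnonzero(slopes > 1.0 + slope_tol)
    if above.size == 0:
        return np.inf
    return float(s[above[0]])


def call_sample(
    peaks: pd.DataFrame,
    tss_table: pd.DataFrame | None = None,
    blacklist: pd.DataFrame | None = None,
    stitch_bp: int = DEFAULT_STITCH_BP,
    tss_zone_bp: int = DEFAULT_TSS_ZONE_BP,
    sample: str = "",
) -> pd.DataFrame:
    """Full per-sample call: TSS exclusion -> stitch -> cutoff -> blacklist.

    Returns super-enhancers ranked 1 = strongest; signal ties are broken
    by genomic position for determinism.
    """
    if peaks.empty:
        logger.info("sample %s: empty peak list", sample)
        return pd.DataFrame(columns=SE_COLS)
    kept = exclude_tss_zones(peaks, tss_table, tss_zone_bp) if tss_table is not None else peaks
    regions = stitch_peaks(kept, stitch_bp)
    if regions.empty:
        return pd.DataFrame(columns=SE_COLS)
    cutoff = rose_cutoff(regions["signal"].to_numpy())
    ses = regions.loc[regions["signal"] > cutoff].copy()
    if blacklist is not None and not blacklist.empty and not ses.empty:
        ses = ses.loc[~intervals.overlaps_any(ses, blacklist)]
    if ses.empty:
        return pd.DataFrame(columns=SE_COLS)
    ses = ses.sort_values(
        ["signal", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    ses["rank"] = np.arange(1, len(ses) + 1)
    ses["sample"] = sample
    return ses[SE_COLS]
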