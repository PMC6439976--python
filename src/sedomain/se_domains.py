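"""Cross-sample super-enhancer domains and their activity matrix.

A super-enhancer domain is the union envelope of any-overlap-linked
super-enhancers across all samples.  Book-ended intervals (touching in
half-open coordinates) do NOT merge.  Domain activity per sample is the
mean per-base H3K27ac RPM over the domain minus the mean input RPM,
floored at zero; mean (not summed) signal keeps domains of different
lengths comparable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import intervals

DOMAIN_COLS = ["domain_id", "chrom", "start", "end", "called_count", "samples"]


def merge_super_enhancers(se_by_sample: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Transitive single-linkage merge of per-sample SEs into domains.

    ``called_count`` is the number of samples contributing at least one SE
    to the domain.  Empty input yields an empty frame.
    """
    frames = []
    for sample, df in se_by_sample.items():
        if df is None or df.empty:
            continue
        sub = df[["chrom", "start", "end"]].copy()
        sub["sample"] = sample
        frames.append(sub)
    if not frames:
        return pd.DataFrame(columns=DOMAIN_COLS)
    all_se = pd.concat(frames, ignore_index=True)
    merged, cluster = intervals.merge_frame(all_se, max_gap=-1)
    all_se["cluster"] = cluster.to_numpy()
    contrib = all_se.groupby("cluster")["sample"].agg(lambda s: sorted(set(s)))
    merged = merged.copy()
    merged["called_count"] = [len(contrib[i]) for i in range(len(merged))]
    merged["samples"] = [",".join(contrib[i]) for i in range(len(merged))]
    merged = merged.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    merged.insert(0, "domain_id", [f"SED{i:05d}" for i in range(len(merged))])
    return merged[DOMAIN_COLS]


class SignalTrack:
    """Piecewise-constant coverage track; uncovered bases count as zero."""

    def __init__(self, bedgraph: pd.DataFrame):
        self._chrom = {}
        if bedgraph is None or bedgraph.empty:
            return
        for chrom, sub in bedgraph.groupby("chrom"):
            order = np.argsort(sub["start"].to_numpy(), kind="stable")
            self._chrom[chrom] = (
                sub["start"].to_numpy()[order].astype(np.int64),
                sub["end"].to_numpy()[order].astype(np.int64),
                sub["value"].to_numpy()[order].astype(float),
            )

    def mean_over(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Per-base mean value over each interval (missing coverage = 0)."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if chrom not in self._chrom:
            raise ValueError(f"track has no data for chromosome {chrom!r}")
        ts, te, tv = self._chrom[chrom]
        # prefix integral of value*length at segment boundaries
        seg_int = np.concatenate([[0.0], np.cumsum(tv * (te - ts))])

        def integral_before(x):
            j = np.searchsorted(ts, x, side="right")
            res = seg_int[j].copy()
            nz = j > 0
            jm = j[nz] - 1
            overshoot = np.clip(te[jm] - x[nz], 0, te[jm] - ts[jm])
            res[nz] -= overshoot * tv[jm]
            return res

        total = integral_before(ends) - integral_before(starts)
        lengths = (ends - starts).astype(float)
        return total / np.where(lengths > 0, lengths, 1.0)


def quantify_domain_activity(
    domains: pd.DataFrame,
    signal_tracks: dict[str, pd.DataFrame | SignalTrack],
    input_tracks: dict[str, pd.DataFrame | SignalTrack],
) -> pd.DataFrame:
    """Activity matrix (domains x samples) of background-subtracted RPM.

    activity[d, s] = max(0, mean H3K27ac over domain d - mean input),
    both means per-base over the domain interval.
    """
    samples = list(signal_tracks)
    out = np.zeros((len(domains), len(samples)))
    chroms = domains["chrom"].to_numpy()
    for j, sample in enumerate(samples):
        sig = signal_tracks[sample]
        inp = input_tracks[sample]
        if not isinstance(sig, SignalTrack):
            sig = SignalTrack(sig)
        if not isinstance(inp, SignalTrack):
            inp = SignalTrack(inp)
        for chrom in pd.unique(chroms):
            mask = chroms == chrom
            s = domains["start"].to_numpy()[mask]
            e = domains["end"].to_numpy()[mask]
            out[mask, j] = np.maximum(
                0.0, sig.mean_over(chrom, s, e) - inp.mean_over(chrom, s, e)
            )
    return pd.DataFrame(out, index=domains["domain_id"].to_numpy(), columns=samples)
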