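"""Evolutionary conservation and tolerance (CDTS-like) scores over domains.

Windowed tracks (e.g. phastCons summarized in fixed windows, CDTS at
base or window resolution) are mapped onto domains by window midpoint:
a window contributes to the one domain containing its midpoint, and the
domain score is the unweighted mean over contributing windows.  Class
distributions are compared pairwise and against a length-matched random
control with two-sample KS tests.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def map_track_to_domains(track: pd.DataFrame, domains: pd.DataFrame) -> pd.Series:
    """Mean track value per domain over windows with midpoint inside.

    Domains with no overlapping window midpoint get NaN (logged).
    """
    result = np.full(len(domains), np.nan)
    dom_chroms = domains["chrom"].to_numpy()
    pos = np.arange(len(domains))
    for chrom, sub in track.groupby("chrom"):
        mask = dom_chroms == chrom
        if not mask.any():
            continue
        mids = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(np.int64)
        order = np.argsort(mids, kind="stable")
        mids = mids[order]
        vals = sub["value"].to_numpy(float)[order]
        cum = np.concatenate([[0.0], np.cumsum(vals)])
        lo = np.searchsorted(mids, domains["start"].to_numpy()[mask], side="left")
        hi = np.searchsorted(mids, domains["end"].to_numpy()[mask], side="left")
        counts = hi - lo
        sums = cum[hi] - cum[lo]
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        result[pos[mask]] = means
    n_missing = int(np.isnan(result).sum())
    if n_missing:
        logger.info("%d domains without any overlapping window midpoint", n_missing)
    return pd.Series(result, index=domains["domain_id"].to_numpy(), name="mean_value")


def random_control_intervals(
    domains: pd.DataFrame, chrom_sizes: dict[str, int], rng: np.random.Generator
) -> pd.DataFrame:
    """Length-matched intervals placed uniformly at random in the genome."""
    from .enrichment import shuffle_intervals

    placed = shuffle_intervals(
        (domains["end"] - domains["start"]).to_numpy(np.int64), chrom_sizes, 1, rng
    )[0]
    placed = placed.copy()
    placed["domain_id"] = [f"RAND{i:05d}" for i in range(len(placed))]
    return placed[["domain_id", "chrom", "start", "end"]]


def compare_classes(
    values: pd.Series, class_labels: pd.Series, control_values: pd.Series | None = None
) -> pd.DataFrame:
    """Pairwise two-sample KS tests between class score distributions.

    ``values`` indexed by domain id, ``class_labels`` likewise.  An
    optional control distribution is compared against every class under
    the label "random".  Classes with < 2 finite values are skipped.
    """
    groups = {}
    df = pd.DataFrame({"value": values, "class": class_labels})
    for cls, g in df.groupby("class"):
        vals = g["value"].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            logger.warning("class %s has < 2 finite values; skipped", cls)
            continue
        groups[cls] = vals
    if control_values is not None:
        ctrl = np.asarray(control_values, dtype=float)
        ctrl = ctrl[np.isfinite(ctrl)]
        if ctrl.size >= 2:
            groups["random"] = ctrl
    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ks = stats.ks_2samp(groups[a], groups[b])
            rows.append(
                (a, b, groups[a].mean(), groups[b].mean(), ks.statistic, ks.pvalue)
            )
    return pd.DataFrame(
        rows, columns=["class_a", "class_b", "mean_a", "mean_b", "ks_stat", "p_value"]
    )
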