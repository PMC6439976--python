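"""Tau tissue-specificity score and domain classification.

Tau for an activity vector x over n samples is

    tau = sum_i (1 - x_i / max(x)) / (n - 1)

which ranges from 0 (uniform activity across all samples) to 1 (activity
confined to a single sample).  Domains are classified by tau percentile:
the lowest-tau 20% are "common"; domains called in exactly one sample
whose tau is in the top 20% are "unique"; everything else is
"non_unique".  Percentiles are realized as order statistics (k smallest /
largest with k = ceil(pct/100 * N)) so that class sizes are exact counts,
with tau ties broken by genomic position.  A domain satisfying both rules
is labeled common (low tau contradicts genuine uniqueness).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASS_COMMON = "common"
CLASS_NON_UNIQUE = "non_unique"
CLASS_UNIQUE = "unique"
CLASS_EXCLUDED = "excluded"


def tau_score(x) -> float:
    """Tau of a non-negative vector; NaN for an all-zero vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau requires a 1-D vector with n >= 2")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("tau requires finite non-negative inputs")
    m = x.max()
    if m == 0:
        return float("nan")
    xhat = x / m
    return float((1.0 - xhat).sum() / (x.size - 1))


def tau_scores(activity: pd.DataFrame) -> pd.Series:
    """Row-wise tau of an activity matrix (rows = domains)."""
    values = activity.to_numpy(float)
    m = values.max(axis=1)
    n = values.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = (1.0 - values / m[:, None]).sum(axis=1) / (n - 1)
    tau[m == 0] = np.nan
    n_zero = int((m == 0).sum())
    if n_zero:
        logger.info("%d domains with all-zero activity excluded from tau", n_zero)
    return pd.Series(tau, index=activity.index, name="tau")


def classify_domains(
    profiles: pd.DataFrame, low_pct: float = 20, high_pct: float = 80
) -> pd.DataFrame:
    """Label domains common / non_unique / unique by tau order statistics.

    ``profiles`` needs columns tau, called_count, chrom, start.  Rows with
    non-finite tau get the label "excluded" and do not count toward N.
    """
    out = profiles.copy()
    finite = np.isfinite(out["tau"].to_numpy(float))
    n = int(finite.sum())
    if n < 5:
        raise ValueError(f"need >= 5 domains with finite tau, got {n}")
    sub = out.loc[finite]
    order = sub.sort_values(["tau", "chrom", "start"], kind="mergesort").index
    k_common = math.ceil(low_pct / 100.0 * n)
    k_top = math.ceil((1.0 - high_pct / 100.0) * n)
    common_idx = set(order[:k_common])
    top_idx = set(order[n - k_top:])
    labels = []
    for idx in out.index:
        if not finite[out.index.get_loc(idx)]:
            labels.append(CLASS_EXCLUDED)
        elif idx in common_idx:
            labels.append(CLASS_COMMON)
        elif idx in top_idx and out.at[idx, "called_count"] == 1:
            labels.append(CLASS_UNIQUE)
        else:
            labels.append(CLASS_NON_UNIQUE)
    out["class"] = labels
    return out
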