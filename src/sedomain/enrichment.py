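"""Super-enhancer-domain enrichment in loop anchors and loop domains.

The "fraction" of a domain class in a query region set is the class's
base-pair density inside the regions divided by its genome-wide density,
so a value of 1 means no enrichment.  The random expectation of the
fraction is estimated by placing length-preserved, mutually
non-overlapping shuffles of the class intervals uniformly across the
genome (chromosome assignment is free); its mean tends to 1.  Enrichment
is observed fraction / shuffle-mean fraction, with an add-one empirical
p-value over the shuffle distribution.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import CoverageIndex, GenomeCoords, merge_frame, total_bp

logger = logging.getLogger(__name__)

DEFAULT_PAD_BP = 5_000
DEFAULT_N_SHUFFLES = 10_000


def fraction(
    regions: pd.DataFrame, class_domains: pd.DataFrame, chrom_sizes: dict[str, int]
) -> float:
    """Observed/expected base-pair density of a domain class in regions."""
    coords = GenomeCoords(chrom_sizes)
    region_bp = total_bp(regions)
    if region_bp == 0:
        raise ValueError("query region set has zero length")
    class_bp = total_bp(class_domains)
    if class_bp == 0:
        raise ValueError("domain class has zero genomic extent")
    idx = CoverageIndex.from_frame(class_domains, coords)
    merged_regions, _ = merge_frame(regions, max_gap=-1)
    gs, ge = coords.flatten(merged_regions)
    covered = int(idx.intersect_bp(gs, ge).sum())
    density = covered / region_bp
    expected_density = class_bp / coords.total_bp
    return density / expected_density


def _shuffle_starts_global(
    lengths: np.ndarray,
    coords: GenomeCoords,
    n_shuffles: int,
    rng: np.random.Generator,
    max_rounds: int = 500,
) -> np.ndarray:
    """(n_shuffles, n_domains) global start positions, non-overlapping per row.

    Each interval keeps its length, may move to any chromosome (chosen
    with probability proportional to the room it has there), and is
    placed uniformly in that chromosome.  Overlapping placements within a
    shuffle are iteratively re-drawn.
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    n_dom = lengths.size
    if lengths.sum() > 0.9 * coords.total_bp:
        raise ValueError(
            "shuffled intervals occupy > 90% of the genome; placement infeasible"
        )
    room = coords.sizes[None, :] - lengths[:, None]  # (n_dom, n_chrom)
    if np.any((room <= 0).all(axis=1)):
        raise ValueError("an interval is longer than every chromosome")
    probs = np.clip(room, 0, None).astype(float)
    cdf = np.cumsum(probs / probs.sum(axis=1, keepdims=True), axis=1)

    def draw(row_dom_idx: np.ndarray) -> np.ndarray:
        u = rng.random(row_dom_idx.size)
        chrom_idx = (u[:, None] > cdf[row_dom_idx]).sum(axis=1)
        span = coords.sizes[chrom_idx] - lengths[row_dom_idx]
        pos = (rng.random(row_dom_idx.size) * (span + 1)).astype(np.int64)
        return coords.offsets[chrom_idx] + pos

    dom_idx_full = np.tile(np.arange(n_dom), n_shuffles)
    starts = draw(dom_idx_full).reshape(n_shuffles, n_dom)
    len_row = np.broadcast_to(lengths, starts.shape)
    for _ in range(max_rounds):
        order = np.argsort(starts, axis=1, kind="stable")
        s_sorted = np.take_along_axis(starts, order, axis=1)
        e_sorted = s_sorted + np.take_along_axis(len_row, order, axis=1)
        bad_sorted = np.zeros(starts.shape, dtype=bool)
        bad_sorted[:, 1:] = s_sorted[:, 1:] < np.maximum.accumulate(e_sorted, axis=1)[:, :-1]
        if not bad_sorted.any():
            return starts
        bad = np.zeros_like(bad_sorted)
        np.put_along_axis(bad, order, bad_sorted, axis=1)
        rows, doms = np.nonzero(bad)
        starts[rows, doms] = draw(doms)
    raise RuntimeError(f"could not resolve shuffle overlaps in {max_rounds} rounds")


def shuffle_intervals(
    lengths: np.ndarray,
    chrom_sizes: dict[str, int],
    n_shuffles: int,
    rng: np.random.Generator,
) -> list[pd.DataFrame]:
    """Length-preserving random interval sets as chrom/start/end frames."""
    coords = GenomeCoords(chrom_sizes)
    starts = _shuffle_starts_global(np.asarray(lengths, np.int64), coords, n_shuffles, rng)
    boundaries = np.concatenate([coords.offsets, [coords.total_bp]])
    out = []
    for row in starts:
        chrom_idx = np.searchsorted(boundaries, row, side="right") - 1
        local = row - coords.offsets[chrom_idx]
        out.append(
            pd.DataFrame(
                {
                    "chrom": [coords.chroms[i] for i in chrom_idx],
                    "start": local,
                    "end": local + np.asarray(lengths, np.int64),
                }
            )
        )
    return out


def shuffle_null(
    class_domains: pd.DataFrame,
    chrom_sizes: dict[str, int],
    regions: pd.DataFrame,
    n: int = DEFAULT_N_SHUFFLES,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Null distribution of the fraction under random domain placement."""
    if rng is None:
        rng = np.random.default_rng()
    coords = GenomeCoords(chrom_sizes)
    merged_class, _ = merge_frame(class_domains, max_gap=-1)
    lengths = (merged_class["end"] - merged_class["start"]).to_numpy(np.int64)
    if lengths.size == 0:
        raise ValueError("domain class has zero genomic extent")
    region_idx = CoverageIndex.from_frame(regions, coords)
    if region_idx.total == 0:
        raise ValueError("query region set has zero length")
    starts = _shuffle_starts_global(lengths, coords, n, rng)
    ends = starts + lengths[None, :]
    covered = (
        region_idx.covered_before(ends.ravel()) - region_idx.covered_before(starts.ravel())
    ).reshape(n, lengths.size).sum(axis=1)
    density = covered / region_idx.total
    expected_density = lengths.sum() / coords.total_bp
    return density / expected_density


def empirical_p(observed: float, null_values: np.ndarray) -> float:
    """Add-one empirical p-value: (1 + #{null >= observed}) / (1 + n)."""
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("empty null distribution")
    return float((1 + (null_values >= observed).sum()) / (1 + null_values.size))


def padded_anchor_regions(
    loops: pd.DataFrame, pad_bp: int, chrom_sizes: dict[str, int]
) -> pd.DataFrame:
    """Both anchors of every loop, padded and clipped to chromosome bounds."""
    rows = []
    for side in ("1", "2"):
        sub = loops[[f"chrom{side}", f"start{side}", f"end{side}"]].copy()
        sub.columns = ["chrom", "start", "end"]
        rows.append(sub)
    df = pd.concat(rows, ignore_index=True)
    df["start"] = np.maximum(0, df["start"] - pad_bp)
    df["end"] = np.minimum(df["chrom"].map(chrom_sizes).to_numpy(), df["end"] + pad_bp)
    return df


def loop_domain_regions(loops: pd.DataFrame, pad_bp: int) -> pd.DataFrame:
    """Interval between the two (padded) anchors of each loop.

    The padded anchors themselves are excluded so anchor and loop-domain
    enrichments are measured on disjoint territory.
    """
    start = loops["end1"].to_numpy() + pad_bp
    end = loops["start2"].to_numpy() - pad_bp
    keep = start < end
    return pd.DataFrame(
        {"chrom": loops["chrom1"].to_numpy()[keep], "start": start[keep], "end": end[keep]}
    )


def _per_loop_fractions(
    loops: pd.DataFrame,
    region_kind: str,
    pad_bp: int,
    class_idx: CoverageIndex,
    expected_density: float,
    coords: GenomeCoords,
    chrom_sizes: dict[str, int],
) -> np.ndarray:
    values = np.full(len(loops), np.nan)
    for i in range(len(loops)):
        one = loops.iloc[[i]]
        if region_kind == "anchors":
            regions = padded_anchor_regions(one, pad_bp, chrom_sizes)
        else:
            regions = loop_domain_regions(one, pad_bp)
        if regions.empty:
            continue
        merged, _ = merge_frame(regions, max_gap=-1)
        gs, ge = coords.flatten(merged)
        bp = int((merged["end"] - merged["start"]).sum())
        if bp == 0:
            continue
        covered = int(class_idx.intersect_bp(gs, ge).sum())
        values[i] = (covered / bp) / expected_density
    return values


def enrichment_timecourse(
    classified_domains: pd.DataFrame,
    loops: pd.DataFrame,
    chrom_sizes: dict[str, int],
    timepoints: list[str],
    pad_bp: int = DEFAULT_PAD_BP,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    rng: np.random.Generator | None = None,
    se_classes: tuple[str, ...] = ("common", "non_unique", "unique"),
    loop_classes: tuple[str, ...] = ("fast", "moderate", "slow"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pooled EnrichmentResult table and per-loop fraction values.

    For every (se_class, loop_class, region_kind, time point): the pooled
    observed fraction over the group's regions, the shuffle-null mean,
    enrichment = observed / null mean, and the empirical p-value.  The
    per-loop frame carries one fraction per loop for t-test comparisons.
    """
    if rng is None:
        rng = np.random.default_rng()
    coords = GenomeCoords(chrom_sizes)
    results = []
    per_loop_rows = []
    class_sets = {}
    for se_class in se_classes:
        dom = classified_domains.loc[classified_domains["class"] == se_class]
        bp = total_bp(dom[["chrom", "start", "end"]]) if not dom.empty else 0
        if bp == 0:
            logger.warning("SE class %s has zero genomic extent; skipped", se_class)
            continue
        class_sets[se_class] = (
            dom[["chrom", "start", "end"]],
            CoverageIndex.from_frame(dom[["chrom", "start", "end"]], coords),
            bp / coords.total_bp,
        )
    for tp in timepoints:
        class_col = f"class_{tp}"
        if class_col not in loops.columns:
            raise KeyError(f"loops are not classified at time point {tp}")
        for loop_class in loop_classes:
            group = loops.loc[loops[class_col] == loop_class]
            if group.empty:
                logger.warning("no %s loops at %s; omitted", loop_class, tp)
                continue
            for region_kind in ("anchors", "loop_domains"):
                if region_kind == "anchors":
                    regions = padded_anchor_regions(group, pad_bp, chrom_sizes)
                else:
                    regions = loop_domain_regions(group, pad_bp)
                if regions.empty or total_bp(regions) == 0:
                    logger.warning(
                        "empty %s region set for %s loops at %s", region_kind, loop_class, tp
                    )
                    continue
                for se_class, (dom_iv, class_idx, exp_density) in class_sets.items():
                    observed = fraction(regions, dom_iv, chrom_sizes)
                    nulls = shuffle_null(dom_iv, chrom_sizes, regions, n_shuffles, rng)
                    null_mean = float(nulls.mean())
                    results.append(
                        {
                            "se_class": se_class,
                            "loop_class": loop_class,
                            "region_kind": region_kind,
                            "timepoint": tp,
                            "n_loops": len(group),
                            "observed_fraction": observed,
                            "expected_fraction_mean": null_mean,
                            "enrichment": observed / null_mean,
                            "empirical_p": empirical_p(observed, nulls),
                            "n_shuffles": n_shuffles,
                        }
                    )
                    vals = _per_loop_fractions(
                        group, region_kind, pad_bp, class_idx, exp_density, coords, chrom_sizes
                    )
                    for (_, loop_row), v in zip(group.iterrows(), vals):
                        per_loop_rows.append(
                            {
                                "loop_id": loop_row.get("name", ""),
                                "se_class": se_class,
                                "loop_class": loop_class,
                                "region_kind": region_kind,
                                "timepoint": tp,
                                "fraction": v,
                            }
                        )
    return pd.DataFrame(results), pd.DataFrame(per_loop_rows)


def enrichment_ttests(per_loop: pd.DataFrame) -> pd.DataFrame:
    """Two-sample t-tests on per-loop fractions.

    Compares (a) fast vs slow loops within each (se_class, region_kind,
    timepoint) and (b) for fast loops, the earliest time point vs each
    later one within (se_class, region_kind).
    """
    rows = []
    finite = per_loop.loc[np.isfinite(per_loop["fraction"])]

    def run(label, a, b, key):
        if len(a) >= 2 and len(b) >= 2:
            t = stats.ttest_ind(a, b)
            rows.append(
                {**key, "comparison": label, "mean_a": np.mean(a), "mean_b": np.mean(b),
                 "t_stat": t.statistic, "p_value": t.pvalue}
            )

    for (se, kind, tp), g in finite.groupby(["se_class", "region_kind", "timepoint"]):
        fast = g.loc[g["loop_class"] == "fast", "fraction"].to_numpy()
        slow = g.loc[g["loop_class"] == "slow", "fraction"].to_numpy()
        run("fast_vs_slow", fast, slow,
            {"se_class": se, "region_kind": kind, "timepoint": tp})
    fast_only = finite.loc[finite["loop_class"] == "fast"]
    for (se, kind), g in fast_only.groupby(["se_class", "region_kind"]):
        tps = sorted(g["timepoint"].unique(), key=lambda t: int(t.lstrip("t")))
        if len(tps) < 2:
            continue
        first = g.loc[g["timepoint"] == tps[0], "fraction"].to_numpy()
        for later in tps[1:]:
            run(f"{tps[0]}_vs_{later}",
                first, g.loc[g["timepoint"] == later, "fraction"].to_numpy(),
                {"se_class": se, "region_kind": kind, "timepoint": later})
    return pd.DataFrame(rows)
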