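"""Putative target genes of super-enhancer domains and their expression.

The target of a domain is the gene whose TSS is closest to the domain
midpoint (or the 3 closest, for the extended definition).  Domain
activity is then correlated with target RPKM across the samples shared
between the ChIP and expression panels, class r-distributions are
compared, housekeeping-gene enrichment among targets is scored with a
hypergeometric test, and the tau specificity of target expression is
summarized per class.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .specificity import tau_score

logger = logging.getLogger(__name__)

LINK_COLS = ["domain_id", "gene_id", "gene_rank", "distance"]


def assign_targets(domains: pd.DataFrame, genes: pd.DataFrame, k: int = 1) -> pd.DataFrame:
    """k genes with TSS nearest the domain midpoint, per domain.

    Midpoint = floor((start + end) / 2).  Distance ties are broken by the
    smaller TSS coordinate, then lexicographic gene id.  Domains on a
    chromosome without genes yield no link (logged).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    links = []
    gene_by_chrom = dict(tuple(genes.groupby("chrom")))
    for row in domains.itertuples(index=False):
        sub = gene_by_chrom.get(row.chrom)
        if sub is None or sub.empty:
            logger.warning("domain %s: no gene on chromosome %s", row.domain_id, row.chrom)
            continue
        mid = (row.start + row.end) // 2
        dist = np.abs(sub["pos"].to_numpy() - mid)
        order = sorted(
            range(len(sub)),
            key=lambda i: (dist[i], sub["pos"].iat[i], sub["gene_id"].iat[i]),
        )[:k]
        for rank, i in enumerate(order, start=1):
            links.append(
                (row.domain_id, sub["gene_id"].iat[i], rank, int(dist[i]))
            )
    return pd.DataFrame(links, columns=LINK_COLS)


def correlate_activity_expression(
    classified: pd.DataFrame,
    links: pd.DataFrame,
    activity: pd.DataFrame,
    rpkm: pd.DataFrame,
    shared_samples: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r between log2(activity+1) and target RPKM per domain.

    Domains called in none of the shared samples are excluded, as are
    domains or targets with zero variance across the shared panel.
    Returns (per_domain, per_class) where per_class holds a one-sample
    t-test of r against 0 and pairwise two-sample KS tests between
    class r-distributions.
    """
    if len(shared_samples) < 3:
        raise ValueError("need >= 3 shared samples for correlation")
    class_of = dict(zip(classified["domain_id"], classified["class"]))
    called_in = {
        d: set(s.split(",")) if isinstance(s, str) and s else set()
        for d, s in zip(classified["domain_id"], classified["samples"])
    }
    rows = []
    n_excluded = 0
    primary = links.loc[links["gene_rank"] == 1]
    for dom, gene in zip(primary["domain_id"], primary["gene_id"]):
        if dom not in activity.index or gene not in rpkm.index:
            continue
        if not (called_in.get(dom, set()) & set(shared_samples)):
            n_excluded += 1
            continue
        a = np.log2(activity.loc[dom, shared_samples].to_numpy(float) + 1.0)
        e = rpkm.loc[gene, shared_samples].to_numpy(float)
        if a.std() == 0 or e.std() == 0:
            n_excluded += 1
            continue
        r = float(stats.pearsonr(a, e).statistic)
        rows.append((dom, gene, class_of.get(dom, "NA"), r))
    if n_excluded:
        logger.info("correlation: %d domains excluded (uncalled or zero variance)", n_excluded)
    per_domain = pd.DataFrame(rows, columns=["domain_id", "gene_id", "class", "pearson_r"])
    stat_rows = []
    groups = {c: g["pearson_r"].to_numpy() for c, g in per_domain.groupby("class")}
    for cls, vals in groups.items():
        if vals.size >= 2:
            t = stats.ttest_1samp(vals, 0.0)
            stat_rows.append(("t_vs_zero", cls, "", vals.mean(), t.statistic, t.pvalue))
    names = sorted(groups)
    for i, a_cls in enumerate(names):
        for b_cls in names[i + 1:]:
            if groups[a_cls].size >= 2 and groups[b_cls].size >= 2:
                ks = stats.ks_2samp(groups[a_cls], groups[b_cls])
                stat_rows.append(
                    ("ks_pair", a_cls, b_cls, np.nan, ks.statistic, ks.pvalue)
                )
    per_class = pd.DataFrame(
        stat_rows, columns=["test", "class_a", "class_b", "mean_r", "statistic", "p_value"]
    )
    return per_domain, per_class


def housekeeping_overlap(
    links: pd.DataFrame,
    classified: pd.DataFrame,
    housekeeping: set[str],
    all_genes: set[str],
) -> pd.DataFrame:
    """Housekeeping-gene counts and hypergeometric enrichment per class.

    The universe is the full gene table; the test asks whether a class's
    target set over-samples housekeeping genes relative to that universe.
    """
    housekeeping = set(housekeeping)
    if housekeeping and not (housekeeping & all_genes):
        raise ValueError("housekeeping list shares no ids with the gene table")
    class_of = dict(zip(classified["domain_id"], classified["class"]))
    primary = links.loc[links["gene_rank"] == 1].copy()
    primary["class"] = primary["domain_id"].map(class_of)
    hk_in_universe = housekeeping & all_genes
    m_universe = len(all_genes)
    rows = []
    for cls, g in primary.groupby("class"):
        targets = set(g["gene_id"]) & all_genes
        n_t = len(targets)
        n_hk = len(targets & hk_in_universe)
        if not housekeeping or n_t == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(n_hk - 1, m_universe, len(hk_in_universe), n_t))
        frac_hk = n_hk / n_t if n_t else 0.0
        rows.append((cls, n_t, n_hk, frac_hk, 1.0 - frac_hk, p))
    return pd.DataFrame(
        rows,
        columns=["class", "n_targets", "n_housekeeping", "frac_hk", "frac_non_hk", "p_hypergeom"],
    )


def expression_tau(
    links: pd.DataFrame, classified: pd.DataFrame, rpkm: pd.DataFrame
) -> pd.DataFrame:
    """Tau of each primary target gene's RPKM vector, grouped by class.

    Genes with all-zero expression are skipped.
    """
    class_of = dict(zip(classified["domain_id"], classified["class"]))
    primary = links.loc[links["gene_rank"] == 1]
    rows = []
    for dom, gene in zip(primary["domain_id"], primary["gene_id"]):
        if gene not in rpkm.index:
            continue
        x = rpkm.loc[gene].to_numpy(float)
        if x.max() == 0:
            continue
        rows.append((class_of.get(dom, "NA"), gene, tau_score(x)))
    return pd.DataFrame(rows, columns=["class", "gene_id", "tau"])
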