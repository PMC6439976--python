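"""End-to-end orchestration: call -> merge -> classify -> downstream stages.

One :class:`PipelineConfig` names every input file and parameter; one
seed drives all stochastic stages (shuffle nulls, random controls).
Stage outputs are plain TSV/BED so any stage can be rerun on its own,
and a JSON manifest records the seed, parameters and a parameter hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    conservation,
    enrichment,
    io,
    loop_recovery,
    se_calling,
    se_domains,
    specificity,
    target_expression,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run.

    ``expression_samples`` is the subset of samples shared between the
    ChIP panel and the expression matrix (the paper-style 24-sample
    analogue); it defaults to whatever columns the RPKM matrix carries.
    """

    outdir: str = "results"
    chrom_sizes: str = ""
    peaks: dict[str, str] = field(default_factory=dict)
    signal_tracks: dict[str, str] = field(default_factory=dict)
    input_tracks: dict[str, str] = field(default_factory=dict)
    tss: str = ""
    blacklist: str = ""
    rpkm: str = ""
    housekeeping: str = ""
    conservation: str = ""
    cdts: str = ""
    loops: str = ""
    loop_exclusion: str = ""
    timepoints: list[str] = field(default_factory=lambda: ["t20", "t40", "t60", "t180"])
    expression_samples: list[str] = field(default_factory=list)
    stitch_bp: int = 12_500
    tss_zone_bp: int = 2_500
    low_pct: float = 20.0
    high_pct: float = 80.0
    target_k: int = 1
    bin_size: int = 25_000
    oe_min: float = 4.5
    fast_pct: float = 10.0
    slow_pct: float = 10.0
    pad_bp: int = 5_000
    n_shuffles: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    @classmethod
    def from_bundle(cls, bundle: dict, outdir, **overrides) -> "PipelineConfig":
        """Build a config from a synthetic-dataset bundle."""
        cfg = cls(
            outdir=str(outdir),
            chrom_sizes=str(bundle["chrom_sizes"]),
            peaks={s: str(p) for s, p in bundle["peaks"].items()},
            signal_tracks={s: str(p) for s, p in bundle["signal_tracks"].items()},
            input_tracks={s: str(p) for s, p in bundle["input_tracks"].items()},
            tss=str(bundle["tss"]),
            blacklist=str(bundle["blacklist"]),
            rpkm=str(bundle["rpkm"]),
            housekeeping=str(bundle["housekeeping"]),
            conservation=str(bundle["conservation"]),
            cdts=str(bundle["cdts"]),
            loops=str(bundle["loops"]),
            loop_exclusion=str(bundle["loop_exclusion"]),
            timepoints=list(bundle["timepoints"]),
            expression_samples=list(bundle["expression_samples"]),
        )
        for key, value in overrides.items():
            setattr(cfg, key, value)
        return cfg


def validate_config(config: PipelineConfig) -> list[str]:
    """Empty list iff the configuration is runnable."""
    issues = []
    if config.low_pct >= config.high_pct:
        issues.append("low_pct must be < high_pct")
    for name in ("stitch_bp", "tss_zone_bp", "bin_size", "pad_bp", "n_shuffles"):
        if getattr(config, name) < 0:
            issues.append(f"{name} must be non-negative")
    if not (0 < config.fast_pct <= 50 and 0 < config.slow_pct <= 50):
        issues.append("fast_pct and slow_pct must be in (0, 50]")
    if config.target_k < 1:
        issues.append("target_k must be >= 1")
    if config.oe_min < 0:
        issues.append("oe_min must be non-negative")
    if not config.chrom_sizes:
        issues.append("chrom_sizes path is required")
    elif not Path(config.chrom_sizes).exists():
        issues.append(f"chrom_sizes file missing: {config.chrom_sizes}")
    if not config.peaks:
        issues.append("at least one sample peak file is required")
    for sample, path in config.peaks.items():
        if not Path(path).exists():
            issues.append(f"peaks file missing for {sample}: {path}")
    for label in ("tss", "blacklist", "rpkm", "housekeeping", "conservation",
                  "cdts", "loops", "loop_exclusion"):
        path = getattr(config, label)
        if path and not Path(path).exists():
            issues.append(f"{label} file missing: {path}")
    return issues


def _param_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; return the result frames plus a manifest.

    Stages with missing optional inputs (expression, conservation, loops)
    are skipped with a warning; a failure in a running stage aborts with
    the stage name.
    """
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid pipeline configuration: " + "; ".join(issues))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    results: dict = {}
    stage = "setup"
    try:
        chrom_sizes = io.read_chrom_sizes(config.chrom_sizes)
        tss = io.read_tss_table(config.tss) if config.tss else None
        blacklist = io.read_bed(config.blacklist) if config.blacklist else None

        stage = "call-se"
        se_by_sample = {}
        for sample, path in config.peaks.items():
            peaks = io.read_peaks(path)
            se_by_sample[sample] = se_calling.call_sample(
                peaks, tss, blacklist, config.stitch_bp, config.tss_zone_bp, sample
            )
            io.write_table(se_by_sample[sample], outdir / "se" / f"{sample}.se.tsv")
        results["super_enhancers"] = se_by_sample

        stage = "merge-domains"
        domains = se_domains.merge_super_enhancers(se_by_sample)
        io.write_table(domains, outdir / "domains.tsv")
        results["domains"] = domains

        sigs = {s: io.read_bedgraph(p) for s, p in config.signal_tracks.items()}
        inps = {s: io.read_bedgraph(p) for s, p in config.input_tracks.items()}
        activity = se_domains.quantify_domain_activity(domains, sigs, inps)
        io.write_table(activity.reset_index(names="domain_id"), outdir / "activity.tsv")
        results["activity"] = activity

        stage = "classify"
        profiles = domains.copy()
        profiles["tau"] = specificity.tau_scores(activity).to_numpy()
        classified = specificity.classify_domains(
            profiles, config.low_pct, config.high_pct
        )
        io.write_table(classified, outdir / "domains_classified.tsv")
        results["classified"] = classified

        stage = "targets"
        if config.rpkm:
            genes = io.read_tss_table(config.tss)
            links = target_expression.assign_targets(classified, genes, config.target_k)
            io.write_table(links, outdir / "target_links.tsv")
            rpkm = io.read_table(config.rpkm).set_index("gene_id")
            shared = config.expression_samples or [
                c for c in rpkm.columns if c in activity.columns
            ]
            per_domain, per_class = target_expression.correlate_activity_expression(
                classified, links, activity, rpkm, shared
            )
            io.write_table(per_domain, outdir / "target_correlation.tsv")
            io.write_table(per_class, outdir / "target_correlation_tests.tsv")
            expr_tau = target_expression.expression_tau(links, classified, rpkm)
            io.write_table(expr_tau, outdir / "target_expression_tau.tsv")
            results.update(links=links, target_correlation=per_domain,
                           target_tests=per_class, expression_tau=expr_tau)
            if config.housekeeping:
                hk = io.read_gene_list(config.housekeeping)
                hk_table = target_expression.housekeeping_overlap(
                    links, classified, hk, set(genes["gene_id"])
                )
                io.write_table(hk_table, outdir / "housekeeping_enrichment.tsv")
                results["housekeeping"] = hk_table
            class_of = dict(zip(classified["domain_id"], classified["class"]))
            for cls in ("common", "non_unique", "unique"):
                ids = sorted(
                    set(links.loc[links["domain_id"].map(class_of) == cls, "gene_id"])
                )
                io.write_gene_list(ids, outdir / f"target_genes.{cls}.txt")
        else:
            logger.warning("no expression matrix configured; targets stage skipped")

        stage = "conservation"
        if config.conservation or config.cdts:
            scores = pd.DataFrame(index=classified["domain_id"].to_numpy())
            control = conservation.random_control_intervals(
                classified, chrom_sizes, rng
            )
            ks_frames = []
            for label, path in (("cons", config.conservation), ("cdts", config.cdts)):
                if not path:
                    continue
                track = io.read_bedgraph(path)
                scores[f"{label}_mean"] = conservation.map_track_to_domains(
                    track, classified
                ).to_numpy()
                ctrl_vals = conservation.map_track_to_domains(track, control)
                ks = conservation.compare_classes(
                    pd.Series(scores[f"{label}_mean"].to_numpy(),
                              index=classified["domain_id"]),
                    pd.Series(classified["class"].to_numpy(),
                              index=classified["domain_id"]),
                    ctrl_vals,
                )
                ks.insert(0, "track", label)
                ks_frames.append(ks)
            io.write_table(scores.reset_index(names="domain_id"),
                           outdir / "domain_scores.tsv")
            if ks_frames:
                ks_all = pd.concat(ks_frames, ignore_index=True)
                io.write_table(ks_all, outdir / "score_class_tests.tsv")
                results["score_tests"] = ks_all
            results["domain_scores"] = scores
        else:
            logger.warning("no conservation/CDTS track configured; stage skipped")

        stage = "loops"
        loops_classified = None
        if config.loops:
            loops = io.read_loops(config.loops)
            exclusion = (
                io.read_bed(config.loop_exclusion) if config.loop_exclusion else None
            )
            loops = loop_recovery.filter_loops(loops, config.oe_min, exclusion)
            for tp in config.timepoints:
                loops = loop_recovery.classify_recovery(
                    loops, tp, config.fast_pct, config.slow_pct
                )
            io.write_table(loops, outdir / "loops_classified.tsv")
            loops_classified = loops
            results["loops"] = loops
        else:
            logger.warning("no loop list configured; loop stages skipped")

        stage = "enrich"
        if loops_classified is not None:
            table, per_loop = enrichment.enrichment_timecourse(
                classified, loops_classified, chrom_sizes, config.timepoints,
                config.pad_bp, config.n_shuffles, rng,
            )
            ttests = enrichment.enrichment_ttests(per_loop)
            io.write_table(table, outdir / "enrichment.tsv")
            io.write_table(per_loop, outdir / "enrichment_per_loop.tsv")
            io.write_table(ttests, outdir / "enrichment_ttests.tsv")
            results.update(enrichment=table, per_loop=per_loop, enrichment_ttests=ttests)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameter_hash": _param_hash(config),
        "parameters": {k: v for k, v in asdict(config).items()
                       if not isinstance(v, dict)},
        "stages_run": sorted(results.keys()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results
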