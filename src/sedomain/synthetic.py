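"""Synthetic multi-sample epigenome with planted ground truth.

Generates every input the pipeline consumes — per-sample H3K27ac peak and
coverage files, a TSS table and RPKM matrix, conservation and tolerance
tracks, a chromatin-loop list with per-time-point strengths, blacklist
and exclusion files — with the statistical structure the analysis
assumes, so the whole pipeline runs with no download and planted labels
can be checked by parameter-recovery tests.

The signal model: each planted domain is active in a class-determined set
of samples (common: all samples; unique: exactly one; non_unique: a few).
Active H3K27ac level is Gamma-distributed around a mean activity on top
of a flat background; the input track carries background only, so
background subtraction recovers the planted activity.  Loop strengths
follow a saturating recovery curve s(t) = S0 * A * (1 - exp(-t / tau))
with a small time constant for fast loops, which makes the strict
monotonicity filter pass for every planted loop; the amplitude A varies
slightly per loop so late-time recovery ranks mix classes, as real
recovery time courses do.  Fast-loop anchors preferentially land in
planted common domains; slow-loop anchors mildly prefer unique domains.

All randomness flows through one seeded generator: the same config gives
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io

MIN_DOMAIN_GAP_BP = 50_000
PEAK_LEN_BP = 1_500
PEAK_STEP_BP = 2_500
CONS_WINDOW_BP = 500
RECOVERY_MINUTES = (20, 40, 60, 180)

CLASSES = ("common", "non_unique", "unique")

CONS_MEANS = {"background": 0.08, "unique": 0.15, "non_unique": 0.25, "common": 0.50}
CDTS_MEANS = {"background": 0.0, "unique": -0.3, "non_unique": -0.8, "common": -2.0}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults mirror the analyzed design.

    30 samples, ~200 planted domains with a 20/60/20 common/non-unique/
    unique mix (matching the observed 20.0/61.8/18.2% class split), mean
    domain length 30 kb (observed mean 32 kb), 2 chromosomes of 10 Mb,
    and 5 Hi-C time points (untreated + 20/40/60/180 min of cohesin
    recovery) at 25 kb resolution.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 10_000_000
    n_samples: int = 30
    n_planted_domains: int = 200
    class_mix: tuple[float, float, float] = (0.2, 0.6, 0.2)
    domain_length_mean_bp: int = 30_000
    domain_length_disp: float = 0.2
    active_rpm: float = 8.0
    background_rpm: float = 1.0
    noise_disp: float = 0.25
    n_genes: int = 400
    expression_coupling: float = 0.8
    n_expression_samples: int = 24
    n_loops: int = 100
    n_timepoints: int = 5
    fast_loop_common_bias: float = 0.9
    slow_loop_unique_bias: float = 0.6
    bin_size_bp: int = 25_000
    write_matrices: bool = False

    def __post_init__(self):
        if min(self.n_chromosomes, self.chrom_length_bp, self.n_samples,
               self.n_planted_domains, self.domain_length_mean_bp, self.n_genes,
               self.n_loops) <= 0:
            raise ValueError("all sizes must be positive")
        if len(self.class_mix) != 3 or any(p < 0 or p > 1 for p in self.class_mix):
            raise ValueError("class_mix must be three proportions in [0, 1]")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if self.n_timepoints < 2:
            raise ValueError("need at least untreated plus one recovery time point")
        if self.n_expression_samples > self.n_samples:
            raise ValueError("expression sample subset exceeds n_samples")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length_bp for i in range(self.n_chromosomes)}

    @property
    def samples(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]

    @property
    def expression_samples(self) -> list[str]:
        return self.samples[: self.n_expression_samples]

    @property
    def recovery_times(self) -> list[int]:
        times = list(RECOVERY_MINUTES)
        while len(times) < self.n_timepoints - 1:
            times.append(times[-1] * 2)
        return times[: self.n_timepoints - 1]

    @property
    def timepoint_labels(self) -> list[str]:
        return [f"t{t}" for t in self.recovery_times]


@dataclass
class GroundTruth:
    """Planted labels: domain classes, loop recovery classes, gene coupling."""

    domains: pd.DataFrame = field(default_factory=pd.DataFrame)
    loops: pd.DataFrame = field(default_factory=pd.DataFrame)
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)

    DOMAIN_COLS = ["domain_id", "chrom", "start", "end", "class", "n_active",
                   "active_samples", "target_gene"]
    LOOP_COLS = ["name", "chrom1", "start1", "end1", "chrom2", "start2", "end2",
                 "class", "tau_min", "s0", "amplitude"]
    GENE_COLS = ["gene_id", "domain_id", "class", "housekeeping"]


def _truth_sibling(path: Path, suffix: str) -> Path:
    return path.with_name(path.stem + suffix + path.suffix)


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Planted-domain TSV at ``path``; loops and genes in sibling files."""
    path = Path(path)
    dom = truth.domains if not truth.domains.empty else pd.DataFrame(
        columns=GroundTruth.DOMAIN_COLS)
    io.write_table(dom, path)
    loops = truth.loops if not truth.loops.empty else pd.DataFrame(
        columns=GroundTruth.LOOP_COLS)
    io.write_table(loops, _truth_sibling(path, ".loops"))
    genes = truth.genes if not truth.genes.empty else pd.DataFrame(
        columns=GroundTruth.GENE_COLS)
    io.write_table(genes, _truth_sibling(path, ".genes"))


def read_ground_truth(path) -> GroundTruth:
    path = Path(path)
    return GroundTruth(
        domains=io.read_table(path),
        loops=io.read_table(_truth_sibling(path, ".loops")),
        genes=io.read_table(_truth_sibling(path, ".genes")),
    )


def _largest_remainder_counts(n: int, proportions) -> list[int]:
    raw = np.asarray(proportions, float) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts.tolist()


def _place_intervals(cfg: SyntheticConfig, rng: np.random.Generator, n_total: int):
    """Non-overlapping intervals with >= MIN_DOMAIN_GAP_BP spacing.

    Returns (frame of chrom/start/end, list of gap intervals per chrom).
    """
    sigma = cfg.domain_length_disp
    mu = np.log(cfg.domain_length_mean_bp) - sigma**2 / 2
    lengths = np.clip(
        rng.lognormal(mu, sigma, n_total).astype(np.int64),
        max(10_000, 4 * PEAK_STEP_BP),
        4 * cfg.domain_length_mean_bp,
    )
    chroms = list(cfg.chrom_sizes)
    per_chrom = [n_total // len(chroms)] * len(chroms)
    for i in range(n_total - sum(per_chrom)):
        per_chrom[i] += 1
    rows = []
    gaps = []
    idx = 0
    for chrom, m in zip(chroms, per_chrom):
        size = cfg.chrom_sizes[chrom]
        ls = lengths[idx: idx + m]
        idx += m
        required = int(ls.sum()) + (m + 1) * MIN_DOMAIN_GAP_BP
        if required > size:
            raise ValueError(
                f"planted domains exceed genome capacity on {chrom}: "
                f"need {required} bp, have {size} bp"
            )
        slack = size - required
        u = rng.random(m + 1)
        extra = np.floor(slack * u / u.sum()).astype(np.int64)
        pos = 0
        for k in range(m):
            gap = MIN_DOMAIN_GAP_BP + int(extra[k])
            gaps.append((chrom, pos, pos + gap))
            pos += gap
            rows.append((chrom, pos, pos + int(ls[k])))
            pos += int(ls[k])
        gaps.append((chrom, pos, size))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]), gaps


def _active_sets(cfg: SyntheticConfig, rng: np.random.Generator, labels: list[str]):
    """Per-domain boolean activity over samples, honoring the class contract."""
    n_s = cfg.n_samples
    active = np.zeros((len(labels), n_s), dtype=bool)
    unique_rotation = rng.permutation(n_s)
    u_i = 0
    for j, lab in enumerate(labels):
        if lab == "common":
            active[j, :] = True
        elif lab == "unique":
            active[j, unique_rotation[u_i % n_s]] = True
            u_i += 1
        else:
            k = int(rng.integers(2, min(11, n_s)))
            active[j, rng.choice(n_s, size=k, replace=False)] = True
    return active


def generate_dataset(config: SyntheticConfig, outdir) -> tuple[dict, GroundTruth]:
    """Write the full input bundle; return file paths and ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    (outdir / "tracks").mkdir(exist_ok=True)

    chrom_sizes = cfg.chrom_sizes
    samples = cfg.samples

    # ---- planted domains (+2 blacklist decoys) -------------------------
    n_decoys = 2
    placed, gaps = _place_intervals(cfg, rng, cfg.n_planted_domains + n_decoys)
    decoy_rows = rng.choice(len(placed), size=n_decoys, replace=False)
    is_decoy = np.zeros(len(placed), dtype=bool)
    is_decoy[decoy_rows] = True
    domains = placed.loc[~is_decoy].reset_index(drop=True)
    decoys = placed.loc[is_decoy].reset_index(drop=True)

    counts = _largest_remainder_counts(cfg.n_planted_domains, cfg.class_mix)
    labels = np.repeat(CLASSES, counts)
    labels = labels[rng.permutation(len(labels))].tolist()

    active = _active_sets(cfg, rng, labels)
    shape = 1.0 / cfg.noise_disp**2
    scale = cfg.active_rpm * cfg.noise_disp**2
    levels = np.where(active, rng.gamma(shape, scale, active.shape), 0.0)

    # ---- peaks and coverage tracks per sample --------------------------
    noise_loci = []
    for chrom, gs, ge in gaps:
        if ge - gs >= 40_000:
            mid = (gs + ge) // 2
            noise_loci.append((chrom, mid - PEAK_LEN_BP // 2, mid + PEAK_LEN_BP // 2))
    noise_loci = noise_loci[:60]

    bg = cfg.background_rpm
    peak_paths, sig_paths, inp_paths = {}, {}, {}
    all_active = pd.concat([domains, decoys], ignore_index=True)
    domain_levels = np.vstack([levels, np.full((n_decoys, cfg.n_samples), cfg.active_rpm)])
    for s_i, sample in enumerate(samples):
        rows = []
        for d_i, row in enumerate(all_active.itertuples(index=False)):
            lev = domain_levels[d_i, s_i]
            if lev <= 0:
                continue
            for p_start in range(row.start, row.end - PEAK_LEN_BP + 1, PEAK_STEP_BP):
                h3 = bg + lev * max(0.0, 1.0 + rng.normal(0, 0.1))
                inp = bg * max(0.0, 1.0 + rng.normal(0, 0.05))
                rows.append((row.chrom, p_start, p_start + PEAK_LEN_BP, h3, inp))
        for chrom, ns, ne in noise_loci:
            h3 = bg * (1.0 + abs(rng.normal(0, 0.2)))
            rows.append((chrom, ns, ne, h3, bg))
        peaks = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "h3k27ac_rpm", "input_rpm"]
        ).sort_values(["chrom", "start"], kind="mergesort")
        path = outdir / "peaks" / f"{sample}.peaks.bed"
        io.write_peaks(peaks.reset_index(drop=True), path)
        peak_paths[sample] = path

        # piecewise-flat signal: background everywhere, planted level on domains
        seg_rows = []
        for chrom, size in chrom_sizes.items():
            sub = all_active.loc[all_active["chrom"] == chrom]
            pos = 0
            for d_i, row in zip(sub.index, sub.itertuples(index=False)):
                if row.start > pos:
                    seg_rows.append((chrom, pos, row.start, bg))
                seg_rows.append((chrom, row.start, row.end, bg + domain_levels[d_i, s_i]))
                pos = row.end
            if pos < size:
                seg_rows.append((chrom, pos, size, bg))
        sig = pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "value"])
        inp = pd.DataFrame(
            [(c, 0, n, bg) for c, n in chrom_sizes.items()],
            columns=["chrom", "start", "end", "value"],
        )
        sp = outdir / "tracks" / f"{sample}.h3k27ac.bedgraph"
        ip = outdir / "tracks" / f"{sample}.input.bedgraph"
        io.write_bedgraph(sig, sp)
        io.write_bedgraph(inp, ip)
        sig_paths[sample], inp_paths[sample] = sp, ip

    io.write_bed(decoys, outdir / "blacklist.bed")
    io.write_chrom_sizes(chrom_sizes, outdir / "chrom.sizes")

    # ---- genes: one target per planted domain + background fillers -----
    gene_rows = []
    for j, row in enumerate(domains.itertuples(index=False)):
        tss = row.end + 3000
        if tss >= chrom_sizes[row.chrom] - 1000:
            tss = row.start - 3000
        gene_rows.append((row.chrom, tss, f"G{j:04d}", "+", f"PLD{j:04d}", labels[j]))
    n_fill = max(0, cfg.n_genes - len(gene_rows))
    fill_space = [
        (chrom, gs + 6000, ge - 6000) for chrom, gs, ge in gaps if ge - gs > 20_000
    ]
    space_len = np.array([e - s for _, s, e in fill_space], dtype=np.int64)
    cum = np.cumsum(space_len)
    for f in range(n_fill):
        g = int(rng.integers(0, cum[-1]))
        seg = int(np.searchsorted(cum, g, side="right"))
        chrom, s, _ = fill_space[seg]
        offset = g - (cum[seg - 1] if seg else 0)
        gene_rows.append((chrom, s + offset, f"F{f:04d}", "+", "", "background"))
    genes = pd.DataFrame(
        gene_rows, columns=["chrom", "pos", "gene_id", "strand", "domain_id", "class"]
    )
    io.write_table(genes[["chrom", "pos", "gene_id", "strand"]], outdir / "tss.tsv")

    # ---- expression matrix over the shared sample subset ---------------
    expr_samples = cfg.expression_samples
    expr_idx = [samples.index(s) for s in expr_samples]
    rpkm = np.zeros((len(genes), len(expr_samples)))
    coupling = cfg.expression_coupling
    for g_i in range(len(genes)):
        cls = genes["class"].iat[g_i]
        if cls == "background":
            rpkm[g_i] = rng.gamma(2.0, 1.5, len(expr_samples))
        else:
            j = int(genes["domain_id"].iat[g_i].removeprefix("PLD"))
            act = levels[j, expr_idx]
            if cls == "common":
                rpkm[g_i] = np.maximum(
                    0.0,
                    6.0 + rng.normal(0, 1.0, len(expr_samples)) + 0.3 * coupling * act,
                )
            else:
                rpkm[g_i] = 0.8 * coupling * act + np.abs(
                    rng.normal(0, 0.3, len(expr_samples))
                )
    rpkm_df = pd.DataFrame(
        np.round(rpkm, 4), index=genes["gene_id"], columns=expr_samples
    )
    rpkm_df.index.name = "gene_id"
    io.write_table(rpkm_df.reset_index(), outdir / "rpkm.tsv")

    hk_prob = np.where(genes["class"] == "common", 0.2,
                       np.where(genes["class"] == "background", 0.05, 0.03))
    hk_flag = rng.random(len(genes)) < hk_prob
    io.write_gene_list(genes.loc[hk_flag, "gene_id"].tolist(), outdir / "housekeeping.txt")

    # ---- conservation and tolerance tracks ------------------------------
    label_of_domain = dict(zip(range(len(domains)), labels))
    for name, means, sd, clip in (
        ("conservation", CONS_MEANS, 0.05, (0.0, 1.0)),
        ("cdts", CDTS_MEANS, 0.3, (None, None)),
    ):
        rows = []
        for chrom, size in chrom_sizes.items():
            n_w = size // CONS_WINDOW_BP
            starts = np.arange(n_w, dtype=np.int64) * CONS_WINDOW_BP
            mids = starts + CONS_WINDOW_BP // 2
            sub = domains.loc[domains["chrom"] == chrom]
            base = np.full(n_w, means["background"])
            d_starts = sub["start"].to_numpy()
            d_ends = sub["end"].to_numpy()
            pos_in = np.searchsorted(d_starts, mids, side="right") - 1
            inside = (pos_in >= 0) & (mids < d_ends[np.clip(pos_in, 0, None)])
            for w in np.flatnonzero(inside):
                base[w] = means[label_of_domain[sub.index[pos_in[w]]]]
            vals = base + rng.normal(0, sd, n_w)
            if clip[0] is not None:
                vals = np.clip(vals, *clip)
            rows.append(pd.DataFrame({
                "chrom": chrom, "start": starts, "end": starts + CONS_WINDOW_BP,
                "value": np.round(vals, 4),
            }))
        io.write_bedgraph(pd.concat(rows, ignore_index=True), outdir / f"{name}.bedgraph")

    # ---- loops -----------------------------------------------------------
    truth_loops, loops_df, exclusion = _generate_loops(cfg, rng, domains, labels)
    io.write_loops(loops_df, outdir / "loops.bedpe")
    io.write_bed(exclusion, outdir / "loop_exclusion.bed")

    truth = GroundTruth(
        domains=pd.DataFrame({
            "domain_id": [f"PLD{j:04d}" for j in range(len(domains))],
            "chrom": domains["chrom"],
            "start": domains["start"],
            "end": domains["end"],
            "class": labels,
            "n_active": active.sum(axis=1),
            "active_samples": [
                ",".join(samples[i] for i in np.flatnonzero(active[j]))
                for j in range(len(domains))
            ],
            "target_gene": [f"G{j:04d}" for j in range(len(domains))],
        }),
        loops=truth_loops,
        genes=pd.DataFrame({
            "gene_id": genes["gene_id"],
            "domain_id": genes["domain_id"].replace("", "."),
            "class": genes["class"],
            "housekeeping": hk_flag.astype(int),
        }),
    )
    write_ground_truth(truth, outdir / "ground_truth.tsv")

    bundle = {
        "outdir": outdir,
        "chrom_sizes": outdir / "chrom.sizes",
        "peaks": peak_paths,
        "signal_tracks": sig_paths,
        "input_tracks": inp_paths,
        "tss": outdir / "tss.tsv",
        "rpkm": outdir / "rpkm.tsv",
        "housekeeping": outdir / "housekeeping.txt",
        "conservation": outdir / "conservation.bedgraph",
        "cdts": outdir / "cdts.bedgraph",
        "loops": outdir / "loops.bedpe",
        "blacklist": outdir / "blacklist.bed",
        "loop_exclusion": outdir / "loop_exclusion.bed",
        "ground_truth": outdir / "ground_truth.tsv",
        "samples": samples,
        "expression_samples": expr_samples,
        "timepoints": cfg.timepoint_labels,
    }
    if cfg.write_matrices:
        mat_dir = outdir / "matrices"
        mat_dir.mkdir(exist_ok=True)
        matrices = generate_contact_matrices(cfg, rng, truth_loops)
        for chrom, by_tp in matrices.items():
            for label, m in by_tp.items():
                io.write_matrix_tsv(m, mat_dir / f"{chrom}.{label}.tsv")
        bundle["matrices"] = mat_dir
    return bundle, truth


def _generate_loops(cfg: SyntheticConfig, rng: np.random.Generator,
                    domains: pd.DataFrame, labels: list[str]):
    """Planted fast/moderate/slow loops plus filter-exercise decoys."""
    bs = cfg.bin_size_bp
    n_fast = max(1, int(np.ceil(0.1 * cfg.n_loops)))
    n_slow = max(1, int(np.ceil(0.1 * cfg.n_loops)))
    n_mod = cfg.n_loops - n_fast - n_slow
    classes = ["fast"] * n_fast + ["slow"] * n_slow + ["moderate"] * n_mod
    chroms = list(cfg.chrom_sizes)
    common_by_chrom = {
        c: domains.loc[(domains["chrom"] == c)
                       & (np.asarray(labels) == "common")].reset_index(drop=True)
        for c in chroms
    }
    unique_by_chrom = {
        c: domains.loc[(domains["chrom"] == c)
                       & (np.asarray(labels) == "unique")].reset_index(drop=True)
        for c in chroms
    }
    tau_ranges = {"fast": (5, 15), "moderate": (40, 90), "slow": (250, 400)}
    rows, truth_rows = [], []

    def random_bin(chrom):
        n_bins = cfg.chrom_sizes[chrom] // bs
        return int(rng.integers(4, n_bins - 4))

    def domain_bin(dom_row):
        return ((dom_row.start + dom_row.end) // 2) // bs

    for i, cls in enumerate(classes):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        anchor_pool = None
        if cls == "fast" and rng.random() < cfg.fast_loop_common_bias:
            anchor_pool = common_by_chrom[chrom]
        elif cls == "slow" and rng.random() < cfg.slow_loop_unique_bias:
            anchor_pool = unique_by_chrom[chrom]
        if anchor_pool is not None and len(anchor_pool):
            pick = anchor_pool.iloc[int(rng.integers(0, len(anchor_pool)))]
            b1 = int(domain_bin(pick))
        else:
            b1 = random_bin(chrom)
        delta = int(rng.integers(12, 80))
        n_bins = cfg.chrom_sizes[chrom] // bs
        b2 = b1 + delta
        if b2 >= n_bins - 4:
            b1, b2 = b1 - delta, b1
        tau = float(rng.uniform(*tau_ranges[cls]))
        s0 = float(rng.uniform(8, 15))
        amp = float(rng.uniform(0.9, 1.15))
        strengths = {
            "untreated": s0,
            "degraded": 0.05 * s0,
            **{f"t{t}": s0 * amp * (1.0 - np.exp(-t / tau)) for t in cfg.recovery_times},
        }
        name = f"L{i:04d}"
        rows.append((chrom, b1 * bs, (b1 + 1) * bs, chrom, b2 * bs, (b2 + 1) * bs,
                     name, float(rng.uniform(5, 12)), strengths))
        truth_rows.append((name, chrom, b1 * bs, (b1 + 1) * bs, chrom, b2 * bs,
                           (b2 + 1) * bs, cls, tau, s0, amp))

    # decoys: sub-threshold O/E, non-monotone recovery, excluded anchor
    exclusion_rows = []
    for d in range(16):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        b1 = random_bin(chrom)
        b2 = min(b1 + int(rng.integers(12, 80)), cfg.chrom_sizes[chrom] // bs - 2)
        tau = float(rng.uniform(20, 200))
        s0 = float(rng.uniform(8, 15))
        strengths = {
            "untreated": s0,
            "degraded": 0.05 * s0,
            **{f"t{t}": s0 * (1.0 - np.exp(-t / tau)) for t in cfg.recovery_times},
        }
        if d < 8:
            kind, oe = "decoy_oe", float(rng.uniform(1.0, 4.4))
        elif d < 15:
            kind, oe = "decoy_nonmono", float(rng.uniform(5, 12))
            tps = cfg.timepoint_labels
            a, b = tps[0], tps[1]
            strengths[a], strengths[b] = strengths[b], strengths[a]
        else:
            kind, oe = "decoy_excluded", float(rng.uniform(5, 12))
            exclusion_rows.append((chrom, b1 * bs, (b1 + 1) * bs))
        name = f"D{d:04d}"
        rows.append((chrom, b1 * bs, (b1 + 1) * bs, chrom, b2 * bs, (b2 + 1) * bs,
                     name, oe, strengths))
        truth_rows.append((name, chrom, b1 * bs, (b1 + 1) * bs, chrom, b2 * bs,
                           (b2 + 1) * bs, kind, tau, s0, 1.0))

    labels_tp = ["untreated", "degraded"] + cfg.timepoint_labels
    loop_records = []
    for chrom1, s1, e1, chrom2, s2, e2, name, oe, strengths in rows:
        rec = {"chrom1": chrom1, "start1": s1, "end1": e1, "chrom2": chrom2,
               "start2": s2, "end2": e2, "name": name, "oe": round(oe, 4)}
        for tp in labels_tp:
            rec[f"strength_{tp}"] = round(strengths[tp], 6)
        loop_records.append(rec)
    loops_df = pd.DataFrame(loop_records)
    truth_loops = pd.DataFrame(truth_rows, columns=GroundTruth.LOOP_COLS)
    exclusion = pd.DataFrame(exclusion_rows, columns=["chrom", "start", "end"])
    return truth_loops, loops_df, exclusion


def generate_contact_matrices(
    cfg: SyntheticConfig, rng: np.random.Generator, truth_loops: pd.DataFrame
) -> dict[str, dict[str, np.ndarray]]:
    """Dense symmetric matrices per chromosome and time point.

    Smooth distance-decay background times a per-time-point depth factor,
    plus the planted loop strength at each loop's anchor-bin pixel.  Loop
    texture beyond the loop pixel is deliberately not modeled.
    """
    bs = cfg.bin_size_bp
    labels = ["untreated", "degraded"] + cfg.timepoint_labels
    depth = {lab: float(rng.uniform(0.6, 1.7)) for lab in labels}
    out = {}
    for chrom, size in cfg.chrom_sizes.items():
        n = size // bs
        i, j = np.indices((n, n))
        background = 5.0 / (1.0 + np.abs(i - j))
        out[chrom] = {}
        sub = truth_loops.loc[truth_loops["chrom1"] == chrom]
        for lab in labels:
            m = background.copy()
            for row in sub.itertuples(index=False):
                b1, b2 = row.start1 // bs, row.start2 // bs
                if lab == "untreated":
                    s = row.s0
                elif lab == "degraded":
                    s = 0.05 * row.s0
                else:
                    t = int(lab.lstrip("t"))
                    s = row.s0 * row.amplitude * (1.0 - np.exp(-t / row.tau_min))
                m[b1, b2] += s
                m[b2, b1] += s
            out[chrom][lab] = m * depth[lab]
    return out
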