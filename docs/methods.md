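# Methods

## Pipeline model

The pipeline treats peak-level ChIP-seq summaries as its input boundary:
per-sample H3K27ac peaks (BED6+2 with H3K27ac and input RPM columns) and
per-base coverage tracks (bedGraph). Upstream alignment and peak calling
are assumed done. All coordinates are 0-based half-open throughout.

### Super-enhancer calling

Per sample: (1) peaks **fully contained** in [TSS − z, TSS + z) for any
TSS are removed (z = 2,500 bp by default; peaks that merely overlap a
zone are kept — clipping would change stitching distances); (2)
remaining peaks are transitively stitched when the gap to the previous
peak is ≤ 12,500 bp; (3) stitched-region signal is Σ max(0, H3K27ac −
input) over member peaks — background subtraction is floored at zero
because negative enhancer activity is meaningless; (4) regions are
sorted ascending by signal, both rank and signal axes are min–max scaled
to [0, 1], and the cutoff is the unscaled signal at the first index
whose forward first-difference slope exceeds 1. The slope comparison
uses a 1e-9 tolerance so an exactly linear ramp — slope 1 in exact
arithmetic, ±1 ulp in floats — deterministically calls nothing. Regions
strictly above the cutoff are super-enhancers; any overlap (≥ 1 bp) with
a blacklist interval discards the region. Signal ties in the final
ranking break by genomic position, so output is deterministic.

The slope estimator is declared, not inherited: pointwise first
differences of the scaled curve rather than a fitted tangent. On ≤ 20
regions the called set is verified against an exhaustive
candidate-threshold scan in the test suite.

### Domains and activity

Super-enhancers from all samples are single-linkage merged on any
overlap; book-ended intervals (touching in half-open coordinates) stay
separate. A domain's `called_count` is the number of contributing
samples. Activity per (domain, sample) is mean per-base H3K27ac RPM over
the domain minus mean input RPM, floored at 0. **Mean**, not summed,
RPM is used so domains of different lengths are comparable; log2(x+1)
transforms are applied downstream where needed, never stored.

### Tau and classification

τ = Σ(1 − x̂ᵢ)/(n − 1) on linear (not log) background-subtracted RPM; an
all-zero vector has no defined τ and the domain is excluded (labeled
`excluded`, not counted in N). Percentile classes are order statistics:
`common` = the ⌈0.2·N⌉ smallest τ, candidate-`unique` = the ⌈0.2·N⌉
largest; `unique` additionally requires `called_count == 1`. τ ties
break by genomic order. A domain qualifying for both takes `common`:
a low τ (broad activity) contradicts genuine uniqueness, which matches
the observed behavior of single-sample calls that barely miss the
calling threshold elsewhere.

### Target genes and expression

The target of a domain is the gene whose TSS is nearest the domain
midpoint ⌊(start+end)/2⌋ (k = 3 supported); distance ties prefer the
smaller TSS coordinate, then lexicographic gene id. Pearson r is
computed between log2(activity + 1) and **linear** RPKM over the shared
sample panel — the transform is applied to the ChIP activity only, which
is how the two quantities are ordered in the source procedure; domains
called in none of the shared samples, and zero-variance vectors, are
excluded. Per class: one-sample t-test of r against 0; pairwise
class differences by two-sample KS. Housekeeping enrichment uses a
hypergeometric test against the full gene-table universe (the upstream
method states significance without naming a test; hypergeometric is the
standard choice for set overlap).

### Conservation / tolerance tracks

Windowed scores map to the domain containing the **window midpoint**;
the domain score is the unweighted mean over contributing windows. The
midpoint rule is unambiguous for small windows against multi-kb domains
and avoids fractional weighting; refining windows into equal-valued
halves provably changes nothing (tested). The random control is a
length-matched shuffle of the domain set scored identically,
regenerated from the pipeline seed.

### Hi-C processing and loop recovery

Knight–Ruiz balancing is implemented as the symmetric fixed point
x ← x·(1/rowsum)^½ on the non-empty submatrix, iterated until all
non-empty row sums equal 1 within 1e-6 relative tolerance (error on
non-convergence, residual reported); empty rows pass through as zeros.
Depth normalization rescales each time point so its total contact count
within 100 kb matches the untreated matrix — short-range contacts are
insensitive to cohesin loss, so they serve as an internal depth anchor.
Loop strength is the mean over the anchor-bin × anchor-bin block
(pad 0 bins by default; the enrichment stage pads anchors by 5 kb
separately). Filters: O/E ≥ 4.5; anchors clear of the user-supplied
exclusion set; strength strictly increasing across the recovery time
points (untreated excluded from the monotonicity test). Recovery rate is
strength(t)/strength(untreated); per time point the ⌈0.1·N⌉ largest
rates are `fast`, the smallest `slow`, ties broken by genomic order.
Classification uses anchor-pixel strength; loop-body intervals are used
only as enrichment queries. The pipeline reads strengths from BEDPE
columns when present; the matrix pathway (KR → depth → block mean) is
exercised separately and produces the same fast > moderate > slow
ordering on the synthetic matrices.

### Enrichment

"Density" is base-pair coverage fraction, not domain count: with that
choice the expected fraction under length-preserving random placement is
exactly 1 in the infinite limit, which anchors the null. Shuffles are
genome-wide (an interval may change chromosome, chosen with probability
proportional to the room it has there), length-preserving, and mutually
non-overlapping within a shuffle (iterative redraw of colliding
intervals, vectorized over all 10,000 shuffles). Placement is uniform
over valid start positions; with interval lengths ≪ chromosome lengths
the residual edge bias is well below Monte-Carlo noise at n = 10,000.
Empirical p = (1 + #{null ≥ obs})/(1 + n), never zero. Loop-domain
regions are [anchor1.start, anchor2.end) minus the padded anchors, so
anchor and loop-domain enrichments are measured on disjoint territory.
Fractions are computed both pooled per group (one enrichment +
empirical p per cell of the time course) and per loop (for two-sample
t-tests between loop classes and across time points).

## Synthetic data: what it emulates and what it does not

The generator plants the exact structure the analysis assumes, with
defaults chosen to mirror the analyzed study design:

| parameter | default | rationale |
|---|---|---|
| samples | 30 | size of the analyzed cell/tissue panel |
| planted domains | 200 | desk-scale cohort, ~65 active regions/sample |
| class mix | 0.2 / 0.6 / 0.2 | observed 20.0 / 61.8 / 18.2% class split |
| domain length | lognormal, mean 30 kb | observed mean domain length ≈ 32 kb |
| genome | 2 × 10 Mb | smallest genome where shuffle nulls are well-behaved |
| active / background RPM | 8 / 1 | strong-enhancer contrast; Gamma CV 0.25 |
| expression panel | 24 of 30 samples | shared ChIP/RNA panel analogue |
| loops | 100 (+16 decoys) | 10 fast / 10 slow / 80 moderate planted |
| recovery | s(t) = S0·A·(1 − e^(−t/τ)) | τ: fast 5–15, moderate 40–90, slow 250–400 min; A ~ U(0.9, 1.15) |
| fast-loop common bias | 0.9 | fast anchors land in planted common domains |

Class activity contract: common domains are active in **all** samples,
unique in exactly one, non-unique in 2–10. Activity tracks are
piecewise-flat (background + planted level), so the quantified activity
equals the planted level exactly and the τ separation between classes is
governed by the Gamma noise, not by track estimation error. Target genes
sit 3 kb outside their domain (so TSS exclusion does not erode planted
peaks); common-domain targets are uniformly highly expressed with weak
activity coupling, unique/non-unique targets are expressed where their
domain is active — giving the weaker-correlation-for-common and
higher-target-τ-for-unique patterns. Housekeeping flags are planted at
20% among common targets vs 3–5% elsewhere. Conservation / CDTS windows
(500 bp) draw from class-shifted normals (common most conserved, most
variation-depleted). Decoy content exercises every filter: two
blacklisted strong loci, sub-threshold O/E loops, non-monotone loops,
and one loop in the anchor-exclusion set. The exponential recovery
model guarantees planted loops pass the strict monotonicity filter; the
amplitude jitter A makes late-time recovery ranks mix classes, so the
fast-class enrichment decays over the time course instead of being
frozen.

Deliberately **not** modeled: read-level data, realistic peak shapes,
Hi-C matrix texture beyond the loop pixel, inter-domain correlation
structure, batch effects, and mappability artifacts. Passing
parameter-recovery tests therefore demonstrates correctness of the
pipeline's logic under its own model assumptions — not robustness to
the noise structure of real ChIP-seq or Hi-C.

## Numerical choices and degenerate inputs

- Flat ROSE curve (all signals equal) → +inf cutoff, zero calls.
- All-zero activity → τ undefined → domain excluded, logged.
- Zero-variance expression or activity vectors → correlation undefined,
  excluded, excluded count logged.
- Empty housekeeping list → fraction 0, p = 1; non-empty list with no
  id overlap with the gene table → error (namespace mismatch).
- Shuffle placement refuses sets occupying > 90% of the genome and
  errors after 500 redraw rounds (unreachable at default occupancy).
- KR balancing errors on asymmetric/negative input and on
  non-convergence, reporting the residual.
- Determinism: one `numpy.random.Generator` seeded from the pipeline
  seed drives all stochastic stages; repeated runs are byte-identical,
  and changing only the seed changes only shuffle-dependent outputs.

## Problem sizes

The default validation runs use the 30-sample / 200-domain / 100-loop
synthetic study with 2,000 shuffles per null inside the test suite and
10,000 shuffles in the reference calibration script — sizes chosen so a
full end-to-end run completes in well under a minute on one core while
keeping Monte-Carlo error far below every tested margin.

## Known limitations

- `.hic`/`.cool` containers and bigWig tracks are not parsed; inputs
  are plain-text matrices and bedGraphs.
- Loop detection (HiCCUPS-style) and peak calling are out of scope;
  loops and peaks are inputs.
- GO enrichment is exported as per-class gene lists for external tools;
  no GO statistics are computed in-package.
- The shuffle null does not exclude user-supplied gap regions from
  placement targets other than via the provided exclusion machinery for
  loops; genome gaps (assembly N-runs) are assumed absent, as in the
  synthetic genome.
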