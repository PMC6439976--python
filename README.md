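# sedomain

Super-enhancers — clusters of enhancers with exceptionally high H3K27ac
signal — are usually described as drivers of cell-type-specific gene
programs. When super-enhancers called across many cell and tissue types
are merged into **super-enhancer domains**, however, a sizeable class
turns out to be active almost everywhere. `sedomain` is a pipeline for
finding and characterizing that class: it calls super-enhancers per
sample, merges them across samples, scores each domain's tissue
specificity, and asks where each specificity class sits relative to 3D
chromatin loops that re-form at different speeds after cohesin is
degraded and restored.

It is aimed at regulatory-genomics analysts working from peak-level
ChIP-seq summaries, expression matrices, and loop lists — every input is
a plain-text table, and a built-in synthetic-data generator with planted
ground truth lets the entire pipeline run and be validated without any
external download.

## The statistics at the core

**Per-sample super-enhancer calling (ROSE-style).** Peaks fully inside a
±2,500 bp window around any TSS are removed, the rest are stitched when
separated by ≤ 12,500 bp, and stitched regions are ranked by
background-subtracted signal Σ max(0, H3K27ac − input). Both axes of the
ranked curve are min–max scaled to [0, 1]; the cutoff is the signal at
the first point where the curve's slope exceeds 1, and regions above it
are super-enhancers (regions touching a blacklist interval are
discarded).

**Tau specificity.** For a domain with activity x₁…xₙ over n samples,

    τ = Σᵢ (1 − x̂ᵢ) / (n − 1),   x̂ᵢ = xᵢ / maxᵢ(xᵢ)

so τ = 0 means uniform activity and τ = 1 means single-sample activity.
Domains in the lowest 20% of τ are **common**; domains called in exactly
one sample with τ in the top 20% are **unique**; the rest are
**non_unique**. Percentiles are order statistics (k = ⌈0.2·N⌉), so class
sizes are exact counts.

**Loop-recovery enrichment.** Loops (O/E ≥ 4.5, strictly increasing
strength over the recovery time course) are classified at each time
point by recovery rate strength(t)/strength(untreated): top 10% fast,
bottom 10% slow. The *fraction* of a domain class in a region set
(anchors padded by 5 kb, or the interval between anchors) is its
base-pair density there divided by its genome-wide density; *enrichment*
divides the observed fraction by its mean over 10,000 length-preserving
random shuffles, with an add-one empirical p-value.

## Worked example

```python
from sedomain import SyntheticConfig, PipelineConfig, generate_dataset, run_all

bundle, truth = generate_dataset(SyntheticConfig(seed=1), "demo_inputs")
cfg = PipelineConfig.from_bundle(bundle, "demo_out", n_shuffles=1000, seed=1)
results = run_all(cfg)

print(results["classified"]["class"].value_counts().to_dict())
print(results["enrichment"].query(
    "timepoint == 't20' and loop_class == 'fast' and region_kind == 'anchors'"
)[["se_class", "observed_fraction", "enrichment", "empirical_p"]])
```

Output:

```
{'non_unique': 120, 'common': 40, 'unique': 40}
     se_class  observed_fraction  enrichment  empirical_p
0      common           5.768421    5.902499     0.000999
1  non_unique           0.453658    0.457612     0.931069
2      unique           0.489448    0.510353     0.755245
```

The 200 planted domains are recovered with their planted class mix
(40/120/40). At 20 min of cohesin recovery, fast-loop anchors carry
almost 6× the genome-expected density of common domains (empirical
p ≈ 0.001), while unique domains show no enrichment — the planted
association between constitutively active domains and fast-recovering
loops, recovered end to end from the raw per-sample peak files.

The same stages are available from the shell
(`sedomain simulate|call-se|merge-domains|classify|loops|enrich|run-all`).

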