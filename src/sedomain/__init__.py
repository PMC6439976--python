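"""Super-enhancer domain classification and 3D-loop-recovery enrichment.

Calls super-enhancers per sample from H3K27ac peak signal, merges them
into cross-sample domains, scores each domain's tissue specificity with
tau and labels it common / non-unique / unique, then measures how each
class distributes over fast- and slow-recovering chromatin loops after
cohesin restoration, against a length-preserving shuffle null.
"""

from .se_calling import call_sample, exclude_tss_zones, rose_cutoff, stitch_peaks
from .se_domains import merge_super_enhancers, quantify_domain_activity
from .specificity import classify_domains, tau_score, tau_scores
from .target_expression import assign_targets
from .conservation import compare_classes, map_track_to_domains
from .loop_recovery import (
    classify_recovery,
    depth_normalize,
    filter_loops,
    kr_balance,
    loop_strength,
)
from .enrichment import empirical_p, enrichment_timecourse, fraction, shuffle_null
from .synthetic import (
    GroundTruth,
    SyntheticConfig,
    generate_dataset,
    read_ground_truth,
    write_ground_truth,
)
from .pipeline import PipelineConfig, run_all, validate_config

__version__ = "0.1.0"

__all__ = [
    "call_sample", "exclude_tss_zones", "rose_cutoff", "stitch_peaks",
    "merge_super_enhancers", "quantify_domain_activity",
    "classify_domains", "tau_score", "tau_scores",
    "assign_targets", "compare_classes", "map_track_to_domains",
    "classify_recovery", "depth_normalize", "filter_loops", "kr_balance",
    "loop_strength",
    "empirical_p", "enrichment_timecourse", "fraction", "shuffle_null",
    "GroundTruth", "SyntheticConfig", "generate_dataset",
    "read_ground_truth", "write_ground_truth",
    "PipelineConfig", "run_all", "validate_config",
]
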