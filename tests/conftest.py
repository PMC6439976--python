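import numpy as np
import pytest

from sedomain import PipelineConfig, SyntheticConfig, generate_dataset, run_all


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """Default synthetic study: 30 samples, 200 planted domains, 100 loops."""
    cfg = SyntheticConfig(seed=1)
    outdir = tmp_path_factory.mktemp("synth_default")
    bundle, truth = generate_dataset(cfg, outdir)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def pipeline_results(default_dataset, tmp_path_factory):
    """Full pipeline run on the default synthetic dataset."""
    _, bundle, truth = default_dataset
    out = tmp_path_factory.mktemp("pipeline_default")
    pcfg = PipelineConfig.from_bundle(bundle, out, n_shuffles=2000, seed=1)
    return run_all(pcfg), truth


def match_planted_classes(truth_domains, classified):
    """Fraction of planted domains per class recovered with the planted label.

    A planted domain matches the called domain covering >= 50% of its
    length (if any); returns {class: recovery fraction}.
    """
    rec = {}
    for _, p in truth_domains.iterrows():
        sub = classified.loc[classified["chrom"] == p["chrom"]]
        if sub.empty:
            rec.setdefault(p["class"], []).append(False)
            continue
        overlap = np.minimum(sub["end"], p["end"]) - np.maximum(sub["start"], p["start"])
        best = overlap.max()
        called = (
            sub.loc[overlap.idxmax(), "class"]
            if best >= 0.5 * (p["end"] - p["start"])
            else "missing"
        )
        rec.setdefault(p["class"], []).append(called == p["class"])
    return {cls: float(np.mean(v)) for cls, v in rec.items()}
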