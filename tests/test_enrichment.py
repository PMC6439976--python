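import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sedomain.enrichment import (
    empirical_p,
    fraction,
    loop_domain_regions,
    padded_anchor_regions,
    shuffle_intervals,
    shuffle_null,
)

SIZES = {"chr1": 1_000_000, "chr2": 1_000_000}


def iv(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestFraction:
    def test_arithmetic_example(self):
        # class covers 10% of a 1 Mb genome; regions are 20% covered
        one_chrom = {"chr1": 1_000_000}
        domains = iv([("chr1", i * 10_000, i * 10_000 + 1000) for i in range(100)])
        regions = iv([("chr1", i * 10_000, i * 10_000 + 5000) for i in range(40)])
        assert fraction(regions, domains, one_chrom) == pytest.approx(2.0)

    def test_whole_genome_class_gives_one(self):
        domains = iv([("chr1", 0, 1_000_000), ("chr2", 0, 1_000_000)])
        regions = iv([("chr1", 100, 5000)])
        assert fraction(regions, domains, SIZES) == pytest.approx(1.0)

    def test_no_overlap_gives_zero(self):
        domains = iv([("chr1", 0, 1000)])
        regions = iv([("chr2", 0, 1000)])
        assert fraction(regions, domains, SIZES) == 0.0

    def test_invariant_to_splitting_regions(self):
        domains = iv([("chr1", 2000, 9000)])
        whole = iv([("chr1", 0, 10_000)])
        split = iv([("chr1", 0, 3000), ("chr1", 3000, 7500), ("chr1", 7500, 10_000)])
        assert fraction(whole, domains, SIZES) == pytest.approx(
            fraction(split, domains, SIZES)
        )

    def test_union_of_all_classes_over_whole_genome_is_one(self):
        rng = np.random.default_rng(23)
        starts = np.sort(rng.choice(900_000, 30, replace=False))
        domains = iv([("chr1", int(s), int(s) + 100) for s in starts])
        genome = iv([("chr1", 0, 1_000_000), ("chr2", 0, 1_000_000)])
        assert fraction(genome, domains, SIZES) == pytest.approx(1.0)

    def test_zero_length_region_set_raises(self):
        with pytest.raises(ValueError, match="zero length"):
            fraction(iv([]), iv([("chr1", 0, 10)]), SIZES)


class TestShuffleNull:
    def test_same_seed_identical_distribution(self):
        domains = iv([("chr1", i * 20_000, i * 20_000 + 2000) for i in range(20)])
        regions = iv([("chr2", i * 30_000, i * 30_000 + 5000) for i in range(10)])
        a = shuffle_null(domains, SIZES, regions, 50, np.random.default_rng(5))
        b = shuffle_null(domains, SIZES, regions, 50, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_single_shuffle_finite(self):
        domains = iv([("chr1", 0, 5000)])
        regions = iv([("chr1", 100_000, 200_000)])
        vals = shuffle_null(domains, SIZES, regions, 1, np.random.default_rng(1))
        assert vals.shape == (1,) and np.isfinite(vals[0])

    def test_placements_preserve_lengths_and_avoid_overlap(self):
        rng = np.random.default_rng(31)
        lengths = rng.integers(1000, 20_000, 25)
        frames = shuffle_intervals(lengths, SIZES, 5, rng)
        for df in frames:
            assert sorted((df["end"] - df["start"]).tolist()) == sorted(lengths.tolist())
            for _, sub in df.groupby("chrom"):
                s = sub.sort_values("start")
                assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()
                assert (s["start"] >= 0).all()
                assert (s["end"] <= SIZES[s["chrom"].iloc[0]]).all()

    def test_overfull_genome_rejected(self):
        domains = iv([("chr1", 0, 950_000), ("chr2", 0, 950_000)])
        with pytest.raises(ValueError, match="90%"):
            shuffle_null(domains, SIZES, iv([("chr1", 0, 1000)]), 2,
                         np.random.default_rng(0))


class TestEmpiricalP:
    def test_observed_below_all_nulls(self):
        assert empirical_p(0.0, np.ones(100)) == pytest.approx(101 / 101)

    def test_observed_above_all_nulls_is_add_one_minimum(self):
        nulls = np.zeros(10_000)
        assert empirical_p(5.0, nulls) == pytest.approx(1 / 10_001)

    def test_observed_at_median_is_about_half(self):
        nulls = np.arange(1001, dtype=float)
        assert empirical_p(500.0, nulls) == pytest.approx(0.5, abs=2e-3)


class TestRegionConstruction:
    def test_padded_anchors_clip_to_chromosome(self):
        loops = pd.DataFrame(
            {"chrom1": ["chr1"], "start1": [2000], "end1": [27_000],
             "chrom2": ["chr1"], "start2": [990_000], "end2": [1_000_000]}
        )
        regions = padded_anchor_regions(loops, 5000, SIZES)
        assert regions["start"].min() == 0
        assert regions["end"].max() == 1_000_000

    def test_loop_domain_excludes_padded_anchors(self):
        loops = pd.DataFrame(
            {"chrom1": ["chr1"], "start1": [100_000], "end1": [125_000],
             "chrom2": ["chr1"], "start2": [500_000], "end2": [525_000]}
        )
        region = loop_domain_regions(loops, 5000)
        assert region.iloc[0]["start"] == 130_000
        assert region.iloc[0]["end"] == 495_000

    def test_degenerate_loop_domain_dropped(self):
        loops = pd.DataFrame(
            {"chrom1": ["chr1"], "start1": [100_000], "end1": [125_000],
             "chrom2": ["chr1"], "start2": [130_000], "end2": [155_000]}
        )
        assert loop_domain_regions(loops, 5000).empty


def test_empirical_p_uniform_under_null_placement():
    """When the domain class itself is placed at random, the empirical
    p-values over replicate datasets are approximately uniform."""
    rng = np.random.default_rng(41)
    sizes = {"chr1": 2_000_000, "chr2": 2_000_000}
    regions = iv(
        [("chr1", i * 60_000, i * 60_000 + 8000) for i in range(30)]
        + [("chr2", i * 60_000, i * 60_000 + 8000) for i in range(30)]
    )
    lengths = np.full(15, 6000)
    pvals = []
    for _ in range(200):
        observed_set = shuffle_intervals(lengths, sizes, 1, rng)[0]
        obs = fraction(regions, observed_set, sizes)
        nulls = shuffle_null(observed_set, sizes, regions, 300, rng)
        pvals.append(empirical_p(obs, nulls))
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01
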