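import numpy as np
import pandas as pd
import pytest

from sedomain.loop_recovery import (
    classify_recovery,
    depth_normalize,
    filter_loops,
    kr_balance,
    loop_strength,
    quantify_loops_from_matrices,
)


def random_symmetric(n, rng):
    a = rng.uniform(0.1, 5.0, (n, n))
    return (a + a.T) / 2


class TestKRBalance:
    def test_identity_pattern_unchanged_up_to_scale(self):
        m = np.diag([3.0, 3.0, 3.0])
        b = kr_balance(m)
        ratio = b[b > 0] / m[m > 0]
        assert np.allclose(ratio, ratio[0])

    def test_2x2_closed_form_equal_row_sums(self):
        b = kr_balance(np.array([[2.0, 1.0], [1.0, 2.0]]))
        assert b.sum(axis=0) == pytest.approx(b.sum(axis=1))
        assert np.ptp(b.sum(axis=1)) < 1e-6

    def test_random_50x50_row_sums_within_tolerance(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            b = kr_balance(random_symmetric(50, rng))
            rs = b.sum(axis=1)
            assert np.abs(rs / rs.mean() - 1).max() < 1e-6

    def test_empty_rows_pass_through_as_zeros(self):
        m = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 0.0]])
        b = kr_balance(m)
        assert (b[2] == 0).all() and (b[:, 2] == 0).all()
        rs = b.sum(axis=1)[:2]
        assert np.ptp(rs) < 1e-6

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            kr_balance(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestDepthNormalize:
    def test_triple_depth_recovers_original(self):
        rng = np.random.default_rng(3)
        m = random_symmetric(20, rng)
        out = depth_normalize({"untreated": m, "t20": 3 * m}, bin_size=1, short_range_bp=5)
        assert np.allclose(out["t20"], m)

    def test_reference_scalar_is_one(self):
        m = random_symmetric(10, np.random.default_rng(4))
        out = depth_normalize({"untreated": m}, bin_size=1, short_range_bp=3)
        assert np.allclose(out["untreated"], m)

    def test_planted_ratio_two_equalizes_short_range_totals(self):
        from sedomain.loop_recovery import short_range_total

        rng = np.random.default_rng(5)
        m = random_symmetric(30, rng)
        out = depth_normalize(
            {"untreated": m, "t20": 2 * m}, bin_size=25_000, short_range_bp=100_000
        )
        a = short_range_total(out["untreated"], 25_000, 100_000)
        b = short_range_total(out["t20"], 25_000, 100_000)
        assert a == pytest.approx(b)

    def test_zero_short_range_total_raises(self):
        z = np.zeros((5, 5))
        with pytest.raises(ValueError, match="short-range"):
            depth_normalize({"untreated": z}, bin_size=1, short_range_bp=2)


class TestLoopStrength:
    def test_uniform_matrix_returns_constant(self):
        m = np.full((10, 10), 2.5)
        assert loop_strength(m, (0, 25_000), (100_000, 125_000)) == 2.5

    def test_single_hot_pixel_pad_zero(self):
        m = np.zeros((10, 10))
        m[1, 5] = 7.0
        assert loop_strength(m, (25_000, 50_000), (125_000, 150_000)) == 7.0

    def test_pad_one_gives_block_mean(self):
        m = np.zeros((10, 10))
        m[1:4, 4:7] = np.arange(9).reshape(3, 3)
        got = loop_strength(m, (50_000, 75_000), (125_000, 150_000), pad_bins=1)
        assert got == pytest.approx(np.arange(9).mean())

    def test_out_of_range_anchor_raises(self):
        with pytest.raises(IndexError):
            loop_strength(np.zeros((4, 4)), (0, 25_000), (200_000, 225_000))


def loop_frame(strengths, oe=10.0):
    rows = []
    for i, seq in enumerate(strengths):
        rec = {
            "chrom1": "chr1", "start1": 100_000 * (i + 1), "end1": 100_000 * (i + 1) + 25_000,
            "chrom2": "chr1", "start2": 100_000 * (i + 1) + 500_000,
            "end2": 100_000 * (i + 1) + 525_000,
            "name": f"L{i}", "oe": oe, "strength_untreated": seq[0],
        }
        for tp, v in zip(("t20", "t40", "t60", "t180"), seq[1:]):
            rec[f"strength_{tp}"] = v
        rows.append(rec)
    return pd.DataFrame(rows)


class TestFilterAndClassify:
    def test_monotone_kept_nonmonotone_dropped(self):
        loops = loop_frame([(5, 1, 2, 3, 4), (5, 1, 3, 2, 4)])
        out = filter_loops(loops)
        assert out["name"].tolist() == ["L0"]

    def test_oe_below_threshold_dropped(self):
        loops = loop_frame([(5, 1, 2, 3, 4)], oe=4.4)
        assert filter_loops(loops).empty
        assert len(filter_loops(loop_frame([(5, 1, 2, 3, 4)], oe=4.5))) == 1

    def test_excluded_anchor_dropped(self):
        loops = loop_frame([(5, 1, 2, 3, 4)])
        excl = pd.DataFrame({"chrom": ["chr1"], "start": [110_000], "end": [112_000]})
        assert filter_loops(loops, exclusion=excl).empty

    def test_hundred_distinct_rates_split_10_10_80(self):
        rng = np.random.default_rng(19)
        seqs = []
        for r in rng.permutation(np.linspace(0.1, 0.9, 100)):
            seqs.append((1.0, r * 0.4, r * 0.6, r * 0.8, r))
        loops = classify_recovery(loop_frame(seqs), "t180")
        counts = loops["class_t180"].value_counts()
        assert counts["fast"] == 10 and counts["slow"] == 10 and counts["moderate"] == 80
        # fast loops have the highest rates
        assert loops.loc[loops["class_t180"] == "fast", "rate_t180"].min() > \
            loops.loc[loops["class_t180"] == "moderate", "rate_t180"].max()

    def test_recovery_rate_one_when_strength_equals_untreated(self):
        seqs = [(2.0, 0.5, 1.0, 1.5, 2.0)] + [
            (1.0, 0.1 * i, 0.2 * i, 0.3 * i, 0.4 * i) for i in range(1, 10)
        ]
        loops = classify_recovery(loop_frame(seqs), "t180")
        assert loops["rate_t180"].iloc[0] == pytest.approx(1.0)

    def test_all_equal_rates_tie_break_fills_extreme_classes(self):
        seqs = [(1.0, 0.2, 0.4, 0.6, 0.8)] * 25
        loops = classify_recovery(loop_frame(seqs), "t20")
        counts = loops["class_t20"].value_counts()
        assert counts["fast"] == 3 and counts["slow"] == 3  # ceil(0.1 * 25)

    def test_fewer_than_ten_loops_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            classify_recovery(loop_frame([(1.0, 0.1, 0.2, 0.3, 0.4)]), "t20")


class TestMatrixPathway:
    def test_planted_fast_loops_rank_above_slow_from_matrices(self, default_dataset):
        """Strengths read from KR-balanced, depth-normalized matrices
        reproduce the planted fast > moderate > slow recovery ordering."""
        from sedomain.synthetic import generate_contact_matrices

        cfg, _, truth = default_dataset
        rng = np.random.default_rng(99)
        matrices = generate_contact_matrices(cfg, rng, truth.loops)
        labels = ["untreated", "t20"]
        processed = {}
        for chrom, by_tp in matrices.items():
            balanced = {tp: kr_balance(m, tol=1e-6) for tp, m in by_tp.items() if tp in labels}
            processed[chrom] = depth_normalize(
                balanced, cfg.bin_size_bp, 100_000, "untreated"
            )
        planted = truth.loops.loc[truth.loops["class"].isin(["fast", "moderate", "slow"])]
        q = quantify_loops_from_matrices(planted, processed, labels, cfg.bin_size_bp)
        rate = q["strength_t20"] / q["strength_untreated"]
        by_class = rate.groupby(planted["class"].to_numpy()).median()
        assert by_class["fast"] > by_class["moderate"] > by_class["slow"]
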