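import numpy as np
import pandas as pd
import pytest

from sedomain.target_expression import (
    assign_targets,
    correlate_activity_expression,
    expression_tau,
    housekeeping_overlap,
)


def gene_table(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "gene_id", "strand"])


def domain_table(rows):
    return pd.DataFrame(rows, columns=["domain_id", "chrom", "start", "end"])


class TestAssignTargets:
    def test_single_gene_on_chromosome(self):
        links = assign_targets(
            domain_table([("d0", "chr1", 0, 1000)]),
            gene_table([("chr1", 50_000, "gA", "+")]),
        )
        assert links["gene_id"].tolist() == ["gA"]

    def test_exact_distance_tie_prefers_smaller_coordinate(self):
        links = assign_targets(
            domain_table([("d0", "chr1", 900, 1100)]),  # midpoint 1000
            gene_table([("chr1", 1100, "gB", "+"), ("chr1", 900, "gA", "+")]),
        )
        assert links["gene_id"].iloc[0] == "gA"

    def test_k3_matches_brute_force_sort(self):
        rng = np.random.default_rng(12)
        for seed in range(30):
            r = np.random.default_rng(seed)
            genes = gene_table(
                [("chr1", int(p), f"g{i}", "+") for i, p in enumerate(r.integers(0, 100_000, 9))]
            )
            dom = domain_table([("d0", "chr1", int(r.integers(0, 90_000)), 0)])
            dom["end"] = dom["start"] + 5000
            mid = (dom["start"].iloc[0] + dom["end"].iloc[0]) // 2
            expected = sorted(
                genes.itertuples(index=False),
                key=lambda g: (abs(g.pos - mid), g.pos, g.gene_id),
            )[:3]
            links = assign_targets(dom, genes, k=3)
            assert links["gene_id"].tolist() == [g.gene_id for g in expected]

    def test_no_gene_on_chromosome_logged_and_empty(self, caplog):
        with caplog.at_level("WARNING"):
            links = assign_targets(
                domain_table([("d0", "chr2", 0, 1000)]),
                gene_table([("chr1", 100, "gA", "+")]),
            )
        assert links.empty


def classified_frame():
    return pd.DataFrame(
        {
            "domain_id": ["d0", "d1"],
            "chrom": "chr1",
            "start": [0, 10_000],
            "end": [1000, 11_000],
            "samples": ["s1,s2,s3,s4", "s1,s2,s3,s4"],
            "class": ["common", "unique"],
        }
    )


class TestCorrelation:
    def test_proportional_expression_gives_r_one(self):
        shared = ["s1", "s2", "s3", "s4"]
        activity = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [4.0, 1.0, 2.0, 3.0]], index=["d0", "d1"], columns=shared
        )
        rpkm = pd.DataFrame(
            [np.log2(np.array([1, 2, 3, 4]) + 1.0) * 5,
             np.log2(np.array([4, 1, 2, 3]) + 1.0) * 2],
            index=["gA", "gB"], columns=shared,
        )
        links = pd.DataFrame(
            {"domain_id": ["d0", "d1"], "gene_id": ["gA", "gB"], "gene_rank": 1, "distance": 0}
        )
        per_domain, _ = correlate_activity_expression(
            classified_frame(), links, activity, rpkm, shared
        )
        assert per_domain["pearson_r"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_constant_expression_vector_excluded(self):
        shared = ["s1", "s2", "s3", "s4"]
        activity = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["d0"], columns=shared)
        rpkm = pd.DataFrame([[5.0, 5.0, 5.0, 5.0]], index=["gA"], columns=shared)
        links = pd.DataFrame(
            {"domain_id": ["d0"], "gene_id": ["gA"], "gene_rank": [1], "distance": [0]}
        )
        per_domain, _ = correlate_activity_expression(
            classified_frame().iloc[:1], links, activity, rpkm, shared
        )
        assert per_domain.empty

    def test_r_invariant_under_joint_sample_permutation(self):
        rng = np.random.default_rng(21)
        shared = [f"s{i}" for i in range(1, 9)]
        cl = classified_frame().iloc[:1].assign(samples=",".join(shared))
        act = pd.DataFrame(rng.gamma(2, 2, (1, 8)), index=["d0"], columns=shared)
        rpkm = pd.DataFrame(rng.gamma(2, 2, (1, 8)), index=["gA"], columns=shared)
        links = pd.DataFrame(
            {"domain_id": ["d0"], "gene_id": ["gA"], "gene_rank": [1], "distance": [0]}
        )
        base, _ = correlate_activity_expression(cl, links, act, rpkm, shared)
        perm = list(rng.permutation(shared))
        permuted, _ = correlate_activity_expression(
            cl, links, act[perm], rpkm[perm], perm
        )
        assert permuted["pearson_r"].iloc[0] == pytest.approx(base["pearson_r"].iloc[0])
        assert abs(base["pearson_r"].iloc[0]) <= 1.0


class TestHousekeeping:
    def links(self):
        return pd.DataFrame(
            {"domain_id": ["d0", "d1"], "gene_id": ["gA", "gB"], "gene_rank": 1, "distance": 0}
        )

    def test_all_genes_housekeeping_gives_fraction_one(self):
        table = housekeeping_overlap(
            self.links(), classified_frame(), {"gA", "gB"}, {"gA", "gB"}
        )
        assert (table["frac_hk"] == 1.0).all()

    def test_empty_list_gives_zero_fraction_and_p_one(self):
        table = housekeeping_overlap(self.links(), classified_frame(), set(), {"gA", "gB"})
        assert (table["frac_hk"] == 0.0).all()
        assert (table["p_hypergeom"] == 1.0).all()

    def test_namespace_mismatch_raises(self):
        with pytest.raises(ValueError, match="no ids"):
            housekeeping_overlap(
                self.links(), classified_frame(), {"ENSG000001"}, {"gA", "gB"}
            )


class TestExpressionTau:
    def test_one_sample_gene_tau_one_and_uniform_tau_zero(self):
        rpkm = pd.DataFrame(
            [[0.0, 0.0, 9.0, 0.0], [3.0, 3.0, 3.0, 3.0]],
            index=["gA", "gB"], columns=["s1", "s2", "s3", "s4"],
        )
        links = pd.DataFrame(
            {"domain_id": ["d0", "d1"], "gene_id": ["gA", "gB"], "gene_rank": 1, "distance": 0}
        )
        out = expression_tau(links, classified_frame(), rpkm)
        tau = dict(zip(out["gene_id"], out["tau"]))
        assert tau["gA"] == 1.0 and tau["gB"] == 0.0

    def test_all_zero_gene_skipped(self):
        rpkm = pd.DataFrame([[0.0, 0.0]], index=["gA"], columns=["s1", "s2"])
        links = pd.DataFrame(
            {"domain_id": ["d0"], "gene_id": ["gA"], "gene_rank": [1], "distance": [0]}
        )
        assert expression_tau(links, classified_frame(), rpkm).empty


class TestOnSyntheticPanel:
    def test_common_targets_correlate_less_than_unique(self, pipeline_results):
        """Common-domain targets are near-ubiquitously expressed, so their
        activity-expression coupling is weaker than unique-domain targets."""
        results, _ = pipeline_results
        per_domain = results["target_correlation"]
        means = per_domain.groupby("class")["pearson_r"].mean()
        assert means["common"] < means["unique"]

    def test_unique_targets_more_specific_than_common(self, pipeline_results):
        results, _ = pipeline_results
        tau = results["expression_tau"]
        med = tau.groupby("class")["tau"].median()
        assert med["unique"] > med["common"]

    def test_housekeeping_enriched_in_common_targets(self, pipeline_results):
        results, _ = pipeline_results
        hk = results["housekeeping"].set_index("class")
        assert hk.loc["common", "frac_hk"] > hk.loc["unique", "frac_hk"]
        assert hk.loc["common", "p_hypergeom"] < 0.05
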