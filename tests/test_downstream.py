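"""Downstream statistics against brute-force combinatorial oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from kinsig.downstream import (
    adjust_fdr,
    bin_switch_times,
    compare_groups_ranksum,
    completion_time,
    contour_enrichment,
    enhancer_gene_means,
    hypergeom_enrichment,
    length_ts_correlation,
    mirna_target_enrichment,
    odds_ratio,
    travelling_ratio,
    window_counts,
)


def hypergeom_upper_tail_oracle(n_bg, n_set, n_cat, a):
    """P(X >= a) by direct combinatorial summation."""
    total = math.comb(n_bg, n_cat)
    return sum(
        math.comb(n_set, k) * math.comb(n_bg - n_set, n_cat - k)
        for k in range(a, min(n_set, n_cat) + 1)
    ) / total


def make_sets(n_bg, n_set, n_cat, a):
    bg = [f"g{i}" for i in range(n_bg)]
    cat = bg[:n_cat]
    # a set members inside the category, the rest outside
    members = cat[:a] + bg[n_cat : n_cat + (n_set - a)]
    return cat, members, bg


class TestHypergeom:
    def test_printed_example(self):
        cat, members, bg = make_sets(20, 5, 10, 4)
        res = hypergeom_enrichment(cat, members, bg)
        assert res.p_value == pytest.approx(0.1517, abs=5e-5)
        assert (res.a, res.b, res.c, res.d) == (4, 6, 1, 9)
        assert res.background_size == 20

    def test_zero_overlap_p_is_one(self):
        cat, members, bg = make_sets(20, 5, 10, 0)
        assert hypergeom_enrichment(cat, members, bg).p_value == pytest.approx(1.0)

    def test_category_equals_background(self):
        bg = [f"g{i}" for i in range(12)]
        res = hypergeom_enrichment(bg, bg[:4], bg)
        assert res.p_value == pytest.approx(1.0)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(["a"], ["a"], [])

    def test_matches_enumeration_for_small_universes(self):
        """Exact agreement with combinatorial summation, universes <= 30."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            n_bg = int(rng.integers(5, 31))
            n_cat = int(rng.integers(1, n_bg + 1))
            n_set = int(rng.integers(1, n_bg + 1))
            a_max = min(n_cat, n_set)
            a_min = max(0, n_cat + n_set - n_bg)
            a = int(rng.integers(a_min, a_max + 1))
            cat, members, bg = make_sets(n_bg, n_set, n_cat, a)
            got = hypergeom_enrichment(cat, members, bg).p_value
            want = hypergeom_upper_tail_oracle(n_bg, n_set, n_cat, a)
            assert got == pytest.approx(want, abs=1e-10)


class TestOddsRatio:
    def test_arithmetic(self):
        assert odds_ratio(4, 6, 16, 74) == pytest.approx(296 / 96)
        assert odds_ratio(3, 3, 3, 3) == 1.0
        assert odds_ratio(0, 5, 5, 5) == 0.0

    def test_zero_denominator_flagged(self):
        assert odds_ratio(4, 0, 16, 74) == math.inf
        assert math.isnan(odds_ratio(0, 0, 5, 5))
        # Haldane-corrected value remains computable
        assert np.isfinite(odds_ratio(4.5, 0.5, 16.5, 74.5))

    def test_planted_two_fold_enrichment_recovered(self):
        """Median 2x2 odds ratio over 100 seeds near the planted value."""
        r_in, r_out, n = 0.30, 0.15, 500
        planted = (r_in / (1 - r_in)) / (r_out / (1 - r_out))
        ors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            in_cat = rng.random(n // 2) < r_in
            out_cat = rng.random(n // 2) < r_out
            a, b = in_cat.sum(), (~in_cat).sum()
            c, d = out_cat.sum(), (~out_cat).sum()
            ors.append(odds_ratio(a, b, c, d))
        assert np.median(ors) == pytest.approx(planted, rel=0.15)


class TestFDR:
    def test_bh_by_hand(self):
        assert adjust_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert adjust_fdr([0.2]) == pytest.approx([0.2])
        assert adjust_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])


def assignments_frame(ts_values, gene_ids, category="early_peak"):
    return pd.DataFrame(
        {
            "cluster_id": [f"c{i}" for i in range(len(ts_values))],
            "gene_id": gene_ids,
            "category": category,
            "ts_or_th_mean": ts_values,
        }
    )


class TestSwitchTimeBinning:
    def test_bins_and_percentages(self):
        ts = [75.0, 62.0, 80.0, 10.0, 20.0, 95.0]
        genes = ["g0", "g1", "g2", "g3", "g4", "g5"]
        table = assignments_frame(ts, genes)
        out = bin_switch_times(table, {"g0", "g3"}, bin_width=30.0)
        row_60_90 = out[out["bin_start"] == 60.0].iloc[0]
        assert row_60_90["n_clusters"] == 3  # 75, 62, 80
        assert row_60_90["percent"] == pytest.approx(100.0 / 3)
        row_0_30 = out[out["bin_start"] == 0.0].iloc[0]
        assert row_0_30["percent"] == pytest.approx(50.0)
        # [30, 60) empty -> NA
        assert np.isnan(out[out["bin_start"] == 30.0].iloc[0]["percent"])
        assert out.attrs["overall_percent"] == pytest.approx(100 * 2 / 6)

    def test_boundary_goes_to_upper_bin(self):
        table = assignments_frame([30.0], ["g0"])
        out = bin_switch_times(table, set(), bin_width=30.0)
        assert out[out["bin_start"] == 30.0].iloc[0]["n_clusters"] == 1


class TestCompletionTime:
    def test_printed_example(self):
        assert completion_time(110.0, 36_000.0, 60.0) == pytest.approx(120.0)

    def test_zero_length_and_rate_proportionality(self):
        assert completion_time(42.0, 0.0) == pytest.approx(42.0)
        base = completion_time(0.0, 36_000.0, 60.0)
        assert completion_time(0.0, 36_000.0, 120.0) == pytest.approx(base / 2)


class TestContourEnrichment:
    def make_inputs(self):
        # 12 early-peak genes; short genes finish inside the 90-min contour
        ts = [30.0] * 6 + [200.0] * 6
        genes = [f"g{i}" for i in range(12)]
        table = assignments_frame(ts, genes)
        features = pd.DataFrame({"gene_id": genes, "gene_length": [36_000] * 12})
        return table, features

    def test_engineered_partition_matches_oracle(self):
        table, features = self.make_inputs()
        # completion times: 40 min (inside 90) vs 210 min; set = 4 inside + 1 outside
        gene_set = {"g0", "g1", "g2", "g3", "g6"}
        res = contour_enrichment(table, features, 90.0, gene_set)
        assert (res.a, res.a + res.b) == (4, 6)
        want = hypergeom_upper_tail_oracle(12, 5, 6, 4)
        assert res.p_value == pytest.approx(want, abs=1e-10)

    def test_set_absent_inside(self):
        table, features = self.make_inputs()
        res = contour_enrichment(table, features, 90.0, {"g6", "g7"})
        assert res.a == 0
        assert res.p_value == pytest.approx(1.0)

    def test_infinite_contour_all_inside(self):
        table, features = self.make_inputs()
        res = contour_enrichment(table, features, math.inf, {"g0", "g6"})
        assert res.b == 10
        assert res.p_value == pytest.approx(1.0)


class TestLengthTsCorrelation:
    def run(self, lengths, ts):
        genes = [f"g{i}" for i in range(len(ts))]
        table = assignments_frame(ts, genes)
        features = pd.DataFrame({"gene_id": genes, "gene_length": lengths})
        return length_ts_correlation(table, features)

    def test_collinear(self):
        r, _ = self.run([1.0, 2.0, 3.0, 4.0], [10.0, 20.0, 30.0, 40.0])
        assert r == pytest.approx(1.0)
        r, _ = self.run([1.0, 2.0, 3.0, 4.0], [40.0, 30.0, 20.0, 10.0])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        r, _ = self.run([1.0, 2.0, 3.0], [1.0, 3.0, 2.0])
        assert r == pytest.approx(0.5)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            self.run([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])


class TestTravellingRatio:
    def test_printed_example(self):
        records = pd.DataFrame(
            {
                "gene_id": ["g"] * 3,
                "exon_index": [1, 2, 3],
                "covered_bp": [50, 300, 300],
                "read_depth": [100, 150, 150],
            }
        )
        ratios, excluded = travelling_ratio(records)
        assert ratios["g"] == pytest.approx(4.0)
        assert excluded == []

    def test_uniform_density_is_one(self):
        records = pd.DataFrame(
            {
                "gene_id": ["g"] * 2,
                "exon_index": [1, 2],
                "covered_bp": [100, 400],
                "read_depth": [10, 40],
            }
        )
        ratios, _ = travelling_ratio(records)
        assert ratios["g"] == pytest.approx(1.0)

    def test_zero_body_coverage_excluded(self):
        records = pd.DataFrame(
            {
                "gene_id": ["g"],
                "exon_index": [1],
                "covered_bp": [100],
                "read_depth": [10],
            }
        )
        ratios, excluded = travelling_ratio(records)
        assert len(ratios) == 0
        assert "gene body" in excluded[0]

    def test_invariant_to_splitting_exon_records(self):
        whole = pd.DataFrame(
            {
                "gene_id": ["g"] * 2,
                "exon_index": [1, 2],
                "covered_bp": [60, 600],
                "read_depth": [90, 300],
            }
        )
        split = pd.DataFrame(
            {
                "gene_id": ["g"] * 4,
                "exon_index": [1, 2, 3, 4],
                "covered_bp": [60, 200, 250, 150],
                "read_depth": [90, 100, 125, 75],
            }
        )
        r1, _ = travelling_ratio(whole)
        r2, _ = travelling_ratio(split)
        assert r1["g"] == pytest.approx(r2["g"])


class TestRankSum:
    def test_exact_extreme(self):
        assert compare_groups_ranksum([1, 2, 3], [4, 5, 6], "less") == pytest.approx(0.05)

    def test_identical_groups_two_sided(self):
        assert compare_groups_ranksum([1, 2, 3], [1, 2, 3]) >= 0.5

    def test_swap_mirrors_one_sided(self):
        a, b = [1.0, 4.0, 2.5], [3.0, 5.0, 6.0]
        assert compare_groups_ranksum(a, b, "less") == pytest.approx(
            compare_groups_ranksum(b, a, "greater")
        )

    def test_exact_branch_matches_full_permutation(self):
        """Exact p equals enumeration of all group relabelings, n <= 10."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            n1, n2 = int(rng.integers(2, 5)), int(rng.integers(2, 6))
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free ranks
            a, b = pooled[:n1], pooled[n1:]
            got = compare_groups_ranksum(a, b, "less")
            # oracle: P(rank-sum of group A <= observed) over all splits
            obs = a.sum()
            sums = [
                sum(comb)
                for comb in itertools.combinations(pooled, n1)
            ]
            want = np.mean([s <= obs + 1e-9 for s in sums])
            assert got == pytest.approx(want, abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups_ranksum([], [1.0])


class TestWindowCounts:
    def clusters(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1"],
                "start": [1000],
                "end": [1200],
                "name": ["c1"],
                "score": [0],
                "strand": ["+"],
            }
        )

    def test_half_open_boundaries(self):
        reads = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr1"],
                "start": [1190, 1200, 990],
                "end": [1210, 1220, 1000],
            }
        )
        counts = window_counts(self.clusters(), reads, 200)
        # window is [1000, 1200): read [1190,1210) overlaps, [1200,1220) and
        # [990,1000) do not
        assert counts["c1"] == 1

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(2)
        clusters = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], 20),
                "start": rng.integers(0, 5000, 20),
                "name": [f"c{i}" for i in range(20)],
                "score": 0,
                "strand": "+",
            }
        )
        clusters["end"] = clusters["start"] + rng.integers(50, 400, 20)
        reads = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], 200),
                "start": rng.integers(0, 5400, 200),
            }
        )
        reads["end"] = reads["start"] + rng.integers(20, 60, 200)
        counts = window_counts(clusters, reads, 200)
        for _, row in clusters.iterrows():
            mid = (row["start"] + row["end"]) // 2
            lo, hi = max(mid - 100, 0), mid + 100
            window_bases = set(range(lo, hi))
            n = sum(
                1
                for _, r in reads[reads["chrom"] == row["chrom"]].iterrows()
                if window_bases & set(range(r["start"], r["end"]))
            )
            assert counts[row["name"]] == n

    def test_window_clipped_at_zero(self):
        clusters = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [40], "name": ["c"], "score": [0], "strand": ["+"]}
        )
        reads = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]})
        assert window_counts(clusters, reads, 200)["c"] == 1


class TestEnhancerMeans:
    def test_averaging(self):
        expr = pd.Series({"e1": 2.0, "e2": 4.0, "e3": 6.0, "e4": 9.0})
        links = pd.DataFrame(
            {"enhancer_id": ["e1", "e2", "e3", "e4"], "gene_id": ["g1", "g1", "g1", "g2"]}
        )
        means = enhancer_gene_means(expr, links)
        assert means["g1"] == pytest.approx(4.0)
        assert means["g2"] == pytest.approx(9.0)
        assert "g3" not in means.index  # unlinked gene -> NA on reindex

    def test_missing_enhancer_value_rejected(self):
        with pytest.raises(KeyError):
            enhancer_gene_means(
                pd.Series({"e1": 2.0}), pd.DataFrame({"enhancer_id": ["e2"], "gene_id": ["g"]})
            )


class TestMirnaTargets:
    def test_exact_oracle_on_2x2(self):
        early = [f"e{i}" for i in range(10)]
        ref = [f"r{i}" for i in range(90)]
        targets = pd.DataFrame(
            {"mirna_id": "mir-1", "gene_id": early[:4] + ref[:16]}
        )
        results, log = mirna_target_enrichment(["mir-1"], targets, early, ref)
        assert log == []
        (res,) = results
        want = hypergeom_upper_tail_oracle(100, 20, 10, 4)
        assert res.p_value == pytest.approx(want, abs=1e-10)
        assert res.q_value == pytest.approx(res.p_value)

    def test_absent_and_targetless_mirnas_skipped(self):
        targets = pd.DataFrame({"mirna_id": ["mir-1"], "gene_id": ["not_in_universe"]})
        results, log = mirna_target_enrichment(
            ["mir-1", "mir-2"], targets, ["e1"], ["r1"]
        )
        assert results == []
        assert len(log) == 2

    def test_all_genes_targeted_p_one(self):
        early, ref = ["e1", "e2"], ["r1", "r2"]
        targets = pd.DataFrame({"mirna_id": "mir-1", "gene_id": early + ref})
        results, _ = mirna_target_enrichment(["mir-1"], targets, early, ref)
        assert results[0].p_value == pytest.approx(1.0)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            mirna_target_enrichment([], pd.DataFrame(columns=["mirna_id", "gene_id"]), ["g"], ["g"])
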