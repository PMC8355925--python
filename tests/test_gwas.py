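"""Catalog filtering, clumping, matching, tag expansion, enrichment."""

import numpy as np
import pandas as pd
import pytest

from epitrain.gwas import (
    BlockLd,
    MatchingWindows,
    PairwiseLd,
    block_overlap,
    dedup_controls,
    enrichment_test,
    expand_tags,
    filter_catalog,
    ld_clump,
    match_controls,
    match_controls_all,
    _block_overlap_flags,
)
from epitrain.intervals import GenomicInterval
from epitrain.simulate import SimulationConfig, simulate_snp_panel, synthetic_enhancer_set


def snp_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "p_assoc", "trait", "maf",
                 "gene_density", "dist_nearest_gene", "ld_buddies"],
    )


class TestFilterCatalog:
    def base(self):
        return snp_frame(
            [
                ("rs1", "chr1", 100, 4e-8, "t1", 0.2, 1.0, 1000, 2),
                ("rs2", "chr1", 200, 6e-8, "t1", 0.2, 1.0, 1000, 2),
                ("rs3", "chr1", 300, 1e-9, "t2", 0.2, 1.0, 1000, 2),
                ("rs3", "chr1", 300, 1e-12, "t2", 0.2, 1.0, 1000, 2),
            ]
        )

    def test_strict_threshold(self):
        out = filter_catalog(self.base())
        assert "rs1" in set(out["snp_id"])  # 4e-8 < 5e-8 kept
        assert "rs2" not in set(out["snp_id"])  # 6e-8 dropped

    def test_duplicates_collapse_to_smallest_p(self):
        out = filter_catalog(self.base())
        rs3 = out[out["snp_id"] == "rs3"]
        assert len(rs3) == 1
        assert rs3["p_assoc"].iloc[0] == 1e-12

    def test_haplotypes_and_missing_positions_dropped(self):
        df = self.base()
        df["is_haplotype"] = [False, False, True, True]
        df2 = snp_frame([("rs9", "chr1", None, 1e-10, "t3", 0.2, 1.0, 1000, 2)])
        out = filter_catalog(pd.concat([df, df2], ignore_index=True))
        assert set(out["snp_id"]) == {"rs1"}


class TestLdClump:
    def test_hand_run_of_greedy_rule(self):
        # A (1e-10) absorbs B (r2 0.6); C independent at r2 < 0.5
        snps = snp_frame(
            [
                ("A", "chr1", 100, 1e-10, "t", 0.2, 1, 1000, 1),
                ("B", "chr1", 200, 1e-9, "t", 0.2, 1, 1000, 1),
                ("C", "chr1", 300, 1e-8, "t", 0.2, 1, 1000, 0),
            ]
        )
        ld = PairwiseLd(
            {frozenset(("A", "B")): 0.6, frozenset(("A", "C")): 0.1,
             frozenset(("B", "C")): 0.1},
            ["A", "B", "C"],
        )
        out = ld_clump(snps, ld)
        assert list(out["snp_id"]) == ["A", "C"]

    def test_independent_snps_unchanged(self):
        snps = snp_frame(
            [(f"s{i}", "chr1", 100 * i, 1e-9, "t", 0.2, 1, 1000, 0) for i in range(1, 5)]
        )
        ld = PairwiseLd({}, list(snps["snp_id"]))
        out = ld_clump(snps, ld)
        assert sorted(out["snp_id"]) == sorted(snps["snp_id"])

    def test_single_snp(self):
        snps = snp_frame([("only", "chr1", 5, 1e-9, "t", 0.2, 1, 1000, 0)])
        ld = PairwiseLd({}, ["only"])
        assert list(ld_clump(snps, ld)["snp_id"]) == ["only"]

    def test_missing_snp_named_in_error(self):
        snps = snp_frame([("ghost", "chr1", 5, 1e-9, "t", 0.2, 1, 1000, 0)])
        ld = PairwiseLd({}, ["other"])
        with pytest.raises(KeyError, match="ghost"):
            ld_clump(snps, ld)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        snps = snp_frame(
            [(f"s{i}", "chr1", int(rng.integers(1, 10_000)),
              float(10 ** -rng.uniform(8, 20)), "t", 0.2, 1, 1000, 0)
             for i in range(10)]
        )
        ids = list(snps["snp_id"])
        pairs = {
            frozenset((a, b)): float(rng.uniform(0, 1))
            for i, a in enumerate(ids) for b in ids[i + 1:]
        }
        ld = PairwiseLd(pairs, ids)
        ref = ld_clump(snps, ld)
        for _ in range(5):
            shuffled = snps.sample(frac=1.0, random_state=int(rng.integers(1e6)))
            got = ld_clump(shuffled.reset_index(drop=True), ld)
            pd.testing.assert_frame_equal(
                got.reset_index(drop=True), ref.reset_index(drop=True)
            )


class TestMatchControls:
    def pool(self):
        rows = [
            ("c1", "chr1", 10, 0.5, "", 0.34, 1.0, 10_000, 4),
            ("c2", "chr1", 20, 0.5, "", 0.36, 1.0, 10_000, 4),
            ("c3", "chr1", 30, 0.5, "", 0.30, 1.4, 12_000, 5),
        ]
        return snp_frame(rows)

    def index_row(self):
        return snp_frame([("idx", "chr1", 99, 1e-9, "t", 0.30, 1.0, 10_000, 4)]).iloc[0]

    def test_window_eligibility(self):
        out, shortfall = match_controls(self.index_row(), self.pool(), k=2, rng=0)
        got = set(out["snp_id"])
        assert "c2" not in got  # |0.36 - 0.30| > 0.05
        assert got <= {"c1", "c3"} and not shortfall

    def test_shortfall_flagged(self):
        pool = self.pool().iloc[[0]]
        out, shortfall = match_controls(self.index_row(), pool, k=2, rng=0)
        assert list(out["snp_id"]) == ["c1"] and shortfall

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            match_controls(self.index_row(), self.pool().iloc[0:0], k=2, rng=0)

    def test_all_matched_controls_inside_windows(self):
        # generator guarantee, checked through the matching route itself
        cfg = SimulationConfig(seed=5, n_snps=1500, n_blocks=480)
        enh = synthetic_enhancer_set(200, np.random.default_rng(0))
        _, panel, _, _ = simulate_snp_panel(cfg, enh, np.random.default_rng(1))
        leads = panel[panel["role"] == "case_lead"]
        pool = panel[panel["role"] == "pool_lead"]
        matched = match_controls_all(leads, pool, k=2, seed=0)
        assert not matched["shortfall"].any()
        w = MatchingWindows()
        lead_of = leads.set_index("snp_id")
        for row in matched.itertuples():
            idx = lead_of.loc[row.index_snp_id]
            assert abs(row.maf - idx.maf) <= w.maf_abs + 1e-12
            assert 0.5 * idx.gene_density <= row.gene_density <= 1.5 * idx.gene_density
            assert 0.5 * idx.dist_nearest_gene <= row.dist_nearest_gene <= 1.5 * idx.dist_nearest_gene
            assert 0.5 * idx.ld_buddies <= row.ld_buddies <= 1.5 * idx.ld_buddies


class TestDedupControls:
    def test_per_category_dedup(self):
        df = pd.DataFrame(
            {
                "snp_id": ["c1", "c1", "c1"],
                "category": ["cardio", "cardio", "renal"],
                "index_pos": [200, 100, 50],
            }
        )
        out = dedup_controls(df)
        # kept once per category, first by index position
        assert len(out) == 2
        kept = out[out["category"] == "cardio"]
        assert kept["index_pos"].iloc[0] == 100

    def test_no_duplicates_identity(self):
        df = pd.DataFrame(
            {"snp_id": ["a", "b"], "category": ["x", "x"], "index_pos": [1, 2]}
        )
        assert len(dedup_controls(df)) == 2


class TestExpandTagsAndOverlap:
    def ld(self):
        return BlockLd(
            {"lead": "b1", "perfect": "b1", "near": "b1", "far": "b2"},
            {"lead": 1.0, "perfect": 1.0, "near": 0.99, "far": 1.0},
        )

    def test_perfect_proxy_included_near_miss_excluded(self):
        universe = ["lead", "perfect", "near", "far"]
        tags = expand_tags("lead", self.ld(), universe, r2_threshold=1.0)
        assert tags == {"lead", "perfect"}

    def test_no_partners_singleton(self):
        ld = BlockLd({"solo": "b"}, {"solo": 1.0})
        assert expand_tags("solo", ld, ["solo"]) == {"solo"}

    def test_block_overlap_any_tag_counts_once(self):
        enh = [GenomicInterval("chr1", 100, 200)]
        tags = pd.DataFrame(
            {
                "snp_id": ["lead", "t1", "t2", "t3"],
                "chrom": ["chr1"] * 4,
                "pos": [50, 120, 150, 180],  # three tags inside one enhancer
            }
        )
        lead = tags.iloc[0]
        assert block_overlap(lead, tags, enh) == 1  # one overlap, not three
        outside = tags.assign(pos=[50, 60, 70, 80])
        assert block_overlap(outside.iloc[0], outside, enh) == 0

    def test_block_overlap_monotone_in_enhancers(self):
        rng = np.random.default_rng(3)
        tags = pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(5)],
                "chrom": ["chr1"] * 5,
                "pos": rng.integers(0, 1000, 5),
            }
        )
        enh = [GenomicInterval("chr1", 10, 50)]
        more = enh + [GenomicInterval("chr1", 400, 900)]
        before = block_overlap(tags.iloc[0], tags, enh)
        after = block_overlap(tags.iloc[0], tags, more)
        assert after >= before


class TestEnrichmentTest:
    def test_equal_rates_or_one(self):
        cases = np.r_[np.ones(10), np.zeros(90)]
        controls = np.r_[np.ones(20), np.zeros(180)]
        res = enrichment_test(cases, controls)
        assert res.or_estimate == pytest.approx(1.0, abs=1e-9)

    def test_cross_product_oracle(self):
        cases = np.r_[np.ones(5), np.zeros(5)]
        controls = np.r_[np.ones(2), np.zeros(8)]
        res = enrichment_test(cases, controls)
        assert res.or_estimate == pytest.approx((5 * 8) / (5 * 2), rel=1e-6)

    def test_matches_closed_form_to_six_digits(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            a, b = rng.integers(1, 50, 2)
            n1, n0 = a + rng.integers(1, 200), b + rng.integers(1, 200)
            cases = np.r_[np.ones(a), np.zeros(n1 - a)]
            controls = np.r_[np.ones(b), np.zeros(n0 - b)]
            res = enrichment_test(cases, controls)
            closed = (a * (n0 - b)) / ((n1 - a) * b)
            assert res.or_estimate == pytest.approx(closed, rel=1e-6)
            se = np.sqrt(1 / a + 1 / b + 1 / (n1 - a) + 1 / (n0 - b))
            assert res.ci_high / res.or_estimate == pytest.approx(np.exp(1.96 * se), rel=1e-4)

    def test_swap_inverts_or_keeps_p(self):
        cases = np.r_[np.ones(12), np.zeros(88)]
        controls = np.r_[np.ones(5), np.zeros(95)]
        fwd = enrichment_test(cases, controls)
        rev = enrichment_test(controls, cases)
        assert rev.or_estimate == pytest.approx(1 / fwd.or_estimate, rel=1e-9)
        assert rev.p == pytest.approx(fwd.p, rel=1e-6)

    def test_zero_margin_degenerate(self):
        res = enrichment_test(np.zeros(10), np.r_[np.ones(2), np.zeros(8)])
        assert res.degenerate and np.isnan(res.or_estimate)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test(np.array([]), np.array([1]))


class TestBlockLd:
    def test_invariants(self):
        ld = BlockLd({"a": "b1", "b": "b1", "c": "b2"}, {"a": 1.0, "b": 0.7, "c": 1.0})
        assert ld.r2("a", "b") == ld.r2("b", "a") == 0.7
        assert ld.r2("a", "a") == 1.0
        assert ld.r2("a", "c") == 0.0
        with pytest.raises(KeyError, match="zzz"):
            ld.r2("a", "zzz")

    def test_vectorized_flags_match_per_lead_route(self):
        # the fast path inside run_enrichment must agree with the
        # expand_tags + block_overlap reference semantics
        cfg = SimulationConfig(seed=9, n_snps=600, n_blocks=200)
        enh = synthetic_enhancer_set(100, np.random.default_rng(2))
        _, panel, ld, _ = simulate_snp_panel(cfg, enh, np.random.default_rng(3))
        leads = panel[panel["role"].isin(["case_lead", "pool_lead"])].head(80)
        fast = _block_overlap_flags(leads, panel, enh, ld)
        uni = panel.drop_duplicates(subset=["snp_id"]).set_index("snp_id", drop=False)
        slow = []
        for row in leads.itertuples():
            tags = expand_tags(row.snp_id, ld, list(uni.index))
            slow.append(block_overlap(row, uni.loc[sorted(tags)], enh))
        assert np.array_equal(fast, np.array(slow))
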