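"""The synthetic-data generator: determinism, planted structure, and
self-consistency of the SNP panel."""

import numpy as np
import pandas as pd
import pytest

from epitrain.gwas import read_snp_table
from epitrain.intervals import GenomicInterval
from epitrain.links import EnhancerGeneLink
from epitrain.simulate import (
    SimulationConfig,
    simulate_chip,
    simulate_rna,
    simulate_snp_panel,
    simulate_study,
    synthetic_enhancer_set,
    write_study,
)


class TestConfig:
    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(frac_regulated=1.5)

    def test_dual_mark_floor(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_regions=10, frac_dual_mark=0.01)

    def test_planted_or_positive(self):
        with pytest.raises(ValueError):
            SimulationConfig(planted_category_or={"cancer": -1.0})


class TestDeterminism:
    def test_same_seed_identical_outputs(self, tiny_config):
        a = simulate_study(tiny_config)
        b = simulate_study(tiny_config)
        assert np.array_equal(a.chip_counts.counts, b.chip_counts.counts)
        assert np.array_equal(a.rna_counts.counts, b.rna_counts.counts)
        pd.testing.assert_frame_equal(a.panel, b.panel)
        pd.testing.assert_frame_equal(a.region_truth, b.region_truth)
        assert a.links == b.links
        assert a.k27_peaks == b.k27_peaks

    def test_different_seed_differs(self, tiny_config):
        a = simulate_study(tiny_config)
        cfg2 = SimulationConfig(**{**tiny_config.__dict__, "seed": 99})
        b = simulate_study(cfg2)
        assert not np.array_equal(a.chip_counts.counts, b.chip_counts.counts)


class TestChipSimulation:
    def test_null_config_has_no_regulated_regions(self):
        cfg = SimulationConfig(seed=1, n_regions=200, frac_regulated=0.0)
        rng = np.random.default_rng(0)
        _, _, _, truth, _ = simulate_chip(cfg, rng)
        assert (truth["planted_logfc"] == 0).all()

    def test_exact_regulated_count_by_rounding(self):
        cfg = SimulationConfig(seed=1, n_regions=1250, frac_dual_mark=0.8, frac_regulated=0.1)
        rng = np.random.default_rng(0)
        _, _, _, truth, _ = simulate_chip(cfg, rng)
        assert truth["dual"].sum() == 1000
        assert (truth["planted_logfc"] != 0).sum() == 100

    def test_planted_magnitudes_at_least_mean(self):
        cfg = SimulationConfig(seed=2, n_regions=400)
        rng = np.random.default_rng(1)
        _, _, _, truth, _ = simulate_chip(cfg, rng)
        mags = truth.loc[truth["planted_logfc"] != 0, "planted_logfc"].abs()
        assert (mags >= cfg.effect_logfc_mean).all()

    def test_peak_jitter_within_ten_percent(self):
        cfg = SimulationConfig(seed=3, n_regions=100)
        rng = np.random.default_rng(2)
        k27, _, _, truth, _ = simulate_chip(cfg, rng)
        widths = (truth["end"] - truth["start"]).to_numpy()
        for sample in k27:
            ds = np.abs(np.array([p.start for p in sample]) - truth["start"].to_numpy())
            de = np.abs(np.array([p.end for p in sample]) - truth["end"].to_numpy())
            assert np.all(ds <= 0.1 * widths + 1)
            assert np.all(de <= 0.1 * widths + 1)

    def test_nb_marginal_mean_matches_analytic(self):
        # 10^4 draws at fixed mean: sample mean within 2%
        rng = np.random.default_rng(4)
        mu = 250.0
        r = 1 / 0.1
        draws = rng.negative_binomial(r, r / (r + mu), size=20_000)
        assert abs(draws.mean() - mu) / mu < 0.02


class TestRnaCoupling:
    def region_truth(self, logfc):
        return pd.DataFrame(
            {
                "region_id": ["r0"],
                "chrom": ["chr1"],
                "start": [1000],
                "end": [2000],
                "dual": [True],
                "planted_logfc": [logfc],
            }
        )

    def genes(self, n=1):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "chrom": ["chr1"] * n,
                "tss": np.arange(n) * 1000 + 5000,
            }
        )

    def test_single_link_weighted_mean(self):
        # one gene, one enhancer at lnFC 1.0, coupling 0.5, no noise
        cfg = SimulationConfig(seed=0, n_participants=2, coupling=0.5, gene_noise_sd=0.0)
        links = [EnhancerGeneLink(GenomicInterval("chr1", 1000, 2000, name="r0"), "g0", 0.8, 4000)]
        _, truth = simulate_rna(
            cfg, self.region_truth(1.0), links, self.genes(1),
            np.random.default_rng(0), np.zeros(2),
        )
        assert truth["planted_logfc"].iloc[0] == pytest.approx(0.5)

    def test_zero_coupling_decouples(self):
        # with coupling 0 the gene truth is pure noise, uncorrelated with
        # the enhancer truth transmitted through links
        cfg = SimulationConfig(
            seed=0, n_regions=600, n_genes=600, coupling=0.0, gene_noise_sd=0.3
        )
        study = simulate_study(cfg)
        assert (study.gene_truth["coupled_logfc"] == 0).all()
        coupled_ref = simulate_study(
            SimulationConfig(**{**cfg.__dict__, "coupling": 1.0})
        )
        linked = coupled_ref.gene_truth["n_links"] > 0
        r = np.corrcoef(
            coupled_ref.gene_truth.loc[linked, "coupled_logfc"],
            study.gene_truth.loc[linked, "planted_logfc"],
        )[0, 1]
        assert abs(r) < 0.1

    def test_full_coupling_monotone(self):
        # coupling 1, no noise, single-link genes: gene truth equals enhancer truth
        cfg = SimulationConfig(seed=0, n_participants=2, coupling=1.0, gene_noise_sd=0.0)
        rt = pd.DataFrame(
            {
                "region_id": ["r0", "r1", "r2"],
                "chrom": ["chr1"] * 3,
                "start": [0, 5000, 10_000],
                "end": [1000, 6000, 11_000],
                "dual": [True] * 3,
                "planted_logfc": [1.5, -2.0, 0.3],
            }
        )
        links = [
            EnhancerGeneLink(GenomicInterval("chr1", 0, 1000, name="r0"), "g0", 0.5, 100),
            EnhancerGeneLink(GenomicInterval("chr1", 5000, 6000, name="r1"), "g1", 0.5, 100),
            EnhancerGeneLink(GenomicInterval("chr1", 10_000, 11_000, name="r2"), "g2", 0.5, 100),
        ]
        _, truth = simulate_rna(cfg, rt, links, self.genes(3), np.random.default_rng(0), np.zeros(2))
        assert np.allclose(truth["planted_logfc"], [1.5, -2.0, 0.3])


@pytest.fixture(scope="module")
def panel():
    cfg = SimulationConfig(seed=7, n_snps=2000, n_blocks=640)
    enh = synthetic_enhancer_set(300, np.random.default_rng(0))
    return simulate_snp_panel(cfg, enh, np.random.default_rng(1))


class TestSnpPanel:
    def test_ld_buddies_match_block_bookkeeping(self, panel):
        _, p, ld, _ = panel
        sizes = p.groupby("block_id")["snp_id"].size()
        for row in p.sample(200, random_state=0).itertuples():
            assert row.ld_buddies == sizes[row.block_id] - 1

    def test_every_snp_block_in_ld(self, panel):
        _, p, ld, _ = panel
        assert all(s in ld for s in p["snp_id"])

    def test_catalog_contains_filter_work(self, panel):
        snp_table, p, _, _ = panel
        assert snp_table["is_haplotype"].any()
        dup = snp_table[~snp_table["is_haplotype"]].duplicated(subset=["snp_id", "trait"])
        assert dup.any()

    def test_category_map_covers_all_traits(self, panel):
        _, p, _, cmap = panel
        traits = set(p.loc[p["category"] != "control", "trait"])
        assert traits <= set(cmap["trait"])
        assert (cmap["category"].isin(
            set(p["category"]) - {"control"}
        )).all()

    def test_null_planted_or_realized_near_one(self):
        # planted OR 1.0 everywhere: realized case/control overlap odds agree
        cfg = SimulationConfig(
            seed=13, n_snps=50_000, n_blocks=16_000,
            planted_category_or={},
        )
        enh = synthetic_enhancer_set(500, np.random.default_rng(5))
        _, p, _, _ = simulate_snp_panel(cfg, enh, np.random.default_rng(6))
        from epitrain.intervals import positions_in
        inside = positions_in(p["chrom"].to_numpy(), p["pos"].to_numpy(), enh)
        block_hit = pd.Series(inside).groupby(p["block_id"].to_numpy()).any()
        lead_blocks = p[p["role"] == "case_lead"]["block_id"]
        pool_blocks = p[p["role"] == "pool_lead"]["block_id"]
        case_rate = block_hit[lead_blocks].mean()
        pool_rate = block_hit[pool_blocks].mean()
        orr = (case_rate / (1 - case_rate)) / (pool_rate / (1 - pool_rate))
        assert 0.75 < orr < 1.3


class TestWriteStudy:
    def test_files_written_and_positions_one_based_on_disk(self, tiny_config, tmp_path):
        study = simulate_study(tiny_config)
        write_study(study, tmp_path)
        for name in (
            "chip_counts.tsv", "chip_design.tsv", "rna_counts.tsv", "rna_design.tsv",
            "links.tsv", "snps.tsv", "ld_blocks.tsv", "category_map.tsv",
            "truth_regions.tsv", "truth_genes.tsv",
        ):
            assert (tmp_path / name).exists(), name
        on_disk = pd.read_csv(tmp_path / "snps.tsv", sep="\t")
        reread = read_snp_table(tmp_path / "snps.tsv")
        assert (on_disk["pos"].to_numpy() == reread["pos"].to_numpy() + 1).all()
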