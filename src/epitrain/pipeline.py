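"""End-to-end orchestration: simulate -> enhancers -> differential ->
links -> GWAS enrichment, with deterministic file output.

Every stage is a thin call into the corresponding module; the pipeline
owns only the glue (mapping recovered consensus peaks back to count-table
regions, wiring up/down sets into the link and enrichment stages, and
writing the result tables).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import chip, gwas, links as links_mod, rna
from .intervals import GenomicInterval, overlap_join, write_bed
from .simulate import (
    SimulationConfig,
    SyntheticStudy,
    simulate_snp_panel,
    simulate_study,
    synthetic_enhancer_set,
)

logger = logging.getLogger(__name__)

FDR_THRESHOLD = 0.1


@dataclass
class PipelineResult:
    study: SyntheticStudy
    enhancers: list[GenomicInterval]  # consensus coordinates, named by region
    chip_results: pd.DataFrame
    up: set[str]
    down: set[str]
    nonregulated: set[str]
    rna_results: pd.DataFrame
    link_stats: tuple[float, float, float]
    groups: pd.DataFrame
    ecdf_tests: pd.DataFrame
    concordance_r: float
    concordance_n: int
    concordant_pairs: list[tuple[str, str]]
    secreted: pd.DataFrame
    enrichment: pd.DataFrame
    mds_rna: pd.DataFrame


def _name_by_region(
    consensus: list[GenomicInterval], region_truth: pd.DataFrame
) -> list[GenomicInterval]:
    """Attach count-table region ids to recovered consensus peaks.

    Counts were summarized on the generating regions, so each consensus
    peak inherits the id of the (unique) region it overlaps; peaks
    touching no region (or several) are dropped with a log entry.
    """
    region_ivs = [
        GenomicInterval(r.chrom, r.start, r.end, name=r.region_id)
        for r in region_truth.itertuples()
    ]
    hits = overlap_join(consensus, region_ivs)
    named = []
    for iv, h in zip(consensus, hits):
        if len(h) == 1:
            named.append(
                GenomicInterval(iv.chrom, iv.start, iv.end, name=region_ivs[h[0]].name)
            )
        else:
            logger.warning(
                "consensus peak %s:%d-%d overlaps %d count regions; dropped",
                iv.chrom, iv.start, iv.end, len(h),
            )
    return named


def run_pipeline(cfg: SimulationConfig, outdir: str | Path | None = None) -> PipelineResult:
    study = simulate_study(cfg)
    rng_root = np.random.SeedSequence(cfg.seed ^ 0x5EED)
    match_seed = int(rng_root.generate_state(1)[0] % (2**31))

    # --- enhancer identification ---------------------------------------
    k27_cons = chip.consensus_peaks(study.k27_peaks)
    k4_cons = chip.consensus_peaks(study.k4_peaks)
    enhancer_cons = chip.identify_enhancers(k27_cons, k4_cons)
    enhancers = _name_by_region(enhancer_cons, study.region_truth)
    logger.info("identified %d dual-mark enhancers", len(enhancers))

    # --- differential H3K27ac ------------------------------------------
    enhancer_ids = [iv.name for iv in enhancers]
    chip_sub = study.chip_counts.subset_features(enhancer_ids)
    chip_res = chip.differential_activity(chip_sub)
    up, down = chip.classify_regulated(chip_res, fdr=FDR_THRESHOLD)
    n_reg = len(up) + len(down)
    nonreg = chip.select_nonregulated(chip_res, n_reg) if n_reg else set()

    # --- RNA -------------------------------------------------------------
    rna_res = rna.differential_expression(study.rna_counts)
    reg_genes = set(
        rna_res.loc[rna_res["q"] < FDR_THRESHOLD, "feature_id"]
    )
    universe = set(rna_res.loc[rna_res["p"].notna(), "feature_id"])
    secreted_rows = []
    for label, annot in (
        ("uniprot", study.secreted_uniprot),
        ("exocarta", study.secreted_exocarta),
    ):
        tab = rna.secreted_enrichment(reg_genes & universe, universe, annot)
        secreted_rows.append(
            dict(
                annotation=label,
                regulated_annotated=int(tab.table[0, 0]),
                regulated_total=int(tab.table[0].sum()),
                other_annotated=int(tab.table[1, 0]),
                other_total=int(tab.table[1].sum()),
                chi2=tab.chi2,
                p=tab.p,
            )
        )
    secreted = pd.DataFrame(secreted_rows)
    mds_rna = rna.mds_embedding(study.rna_counts)

    # --- enhancer-gene links --------------------------------------------
    attached = links_mod.attach_links(enhancers, study.links)
    link_stats = links_mod.link_statistics(attached)
    groups = links_mod.promoter_groups(universe, attached, up, down)
    lnfc = rna_res.set_index("feature_id")["logFC"]
    ecdf_rows = []
    none_vals = lnfc.reindex(groups.loc[groups["group"] == "None", "gene_id"]).dropna().to_numpy()
    for grp in ("Up", "Down", "Both"):
        vals = lnfc.reindex(groups.loc[groups["group"] == grp, "gene_id"]).dropna().to_numpy()
        if len(vals) == 0 or len(none_vals) == 0:
            continue
        d, p, direction = links_mod.ecdf_shift(vals, none_vals)
        ecdf_rows.append(
            dict(group=grp, reference="None", n_group=len(vals),
                 n_reference=len(none_vals), ks_D=d, p=p, direction=direction)
        )
    ecdf_tests = pd.DataFrame(ecdf_rows)
    conc_r, conc_n, conc_pairs = links_mod.activity_expression_concordance(
        chip_res, rna_res, attached, fdr=FDR_THRESHOLD
    )

    # --- GWAS enrichment -------------------------------------------------
    filtered = gwas.filter_catalog(study.snp_table)
    clumped = gwas.ld_clump(filtered, study.ld)
    cat_of = dict(zip(study.category_map["trait"], study.category_map["category"]))
    clumped = clumped.assign(category=clumped["trait"].map(cat_of))
    pool = study.panel[study.panel["role"] == "pool_lead"]
    matched = gwas.match_controls_all(
        clumped, pool, k=cfg.control_ratio, seed=match_seed
    )
    controls = gwas.dedup_controls(matched)
    reg_ivs = [iv for iv in enhancers if iv.name in (up | down)]
    nonreg_ivs = [iv for iv in enhancers if iv.name in nonreg]
    results = gwas.run_enrichment(
        clumped, controls, reg_ivs, study.ld, study.panel, enhancer_set="regulated"
    )
    if nonreg_ivs:
        results += gwas.run_enrichment(
            clumped, controls, nonreg_ivs, study.ld, study.panel,
            enhancer_set="nonregulated",
        )
    enrichment = gwas.enrichment_frame(results)

    result = PipelineResult(
        study=study,
        enhancers=enhancers,
        chip_results=chip_res,
        up=up,
        down=down,
        nonregulated=nonreg,
        rna_results=rna_res,
        link_stats=link_stats,
        groups=groups,
        ecdf_tests=ecdf_tests,
        concordance_r=conc_r,
        concordance_n=conc_n,
        concordant_pairs=conc_pairs,
        secreted=secreted,
        enrichment=enrichment,
        mds_rna=mds_rna,
    )
    if outdir is not None:
        write_results(result, outdir)
    return result


def run_snp_study(cfg: SimulationConfig, n_enhancers: int = 7018) -> pd.DataFrame:
    """SNP-enrichment study without the ChIP/RNA stages.

    Generates a standalone enhancer set and SNP panel, then runs the full
    catalog -> clump -> match -> dedup -> tag-expand -> overlap ->
    logistic-regression chain and returns the enrichment table.  Used for
    calibration and recovery studies where only the variant arm matters.
    """
    root = np.random.SeedSequence(cfg.seed)
    s_enh, s_panel, s_match = root.spawn(3)
    rng_enh = np.random.default_rng(s_enh)
    rng_panel = np.random.default_rng(s_panel)
    match_seed = int(s_match.generate_state(1)[0] % (2**31))
    enhancers = synthetic_enhancer_set(n_enhancers, rng_enh)
    snp_table, panel, ld, cat_map = simulate_snp_panel(cfg, enhancers, rng_panel)
    filtered = gwas.filter_catalog(snp_table)
    clumped = gwas.ld_clump(filtered, ld)
    cat_of = dict(zip(cat_map["trait"], cat_map["category"]))
    clumped = clumped.assign(category=clumped["trait"].map(cat_of))
    pool = panel[panel["role"] == "pool_lead"]
    matched = gwas.match_controls_all(clumped, pool, k=cfg.control_ratio, seed=match_seed)
    controls = gwas.dedup_controls(matched)
    results = gwas.run_enrichment(clumped, controls, enhancers, ld, panel)
    return gwas.enrichment_frame(results)


def write_results(res: PipelineResult, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_bed(out / "enhancers.bed", res.enhancers)
    for label, ids in (("up", res.up), ("down", res.down), ("nonregulated", res.nonregulated)):
        ivs = [iv for iv in res.enhancers if iv.name in ids]
        write_bed(out / f"enhancers_{label}.bed", ivs)
    res.chip_results.to_csv(out / "differential_chip.tsv", sep="\t", index=False)
    res.rna_results.to_csv(out / "differential_rna.tsv", sep="\t", index=False)
    res.secreted.to_csv(out / "secreted_enrichment.tsv", sep="\t", index=False)
    res.mds_rna.to_csv(out / "mds_rna.tsv", sep="\t")
    res.groups.to_csv(out / "promoter_groups.tsv", sep="\t", index=False)
    res.ecdf_tests.to_csv(out / "ecdf_tests.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "mean_enhancers_per_gene": [res.link_stats[0]],
            "mean_genes_per_enhancer": [res.link_stats[1]],
            "mean_distance_bp": [res.link_stats[2]],
            "concordance_r": [res.concordance_r],
            "n_pairs": [res.concordance_n],
            "n_concordant_significant": [len(res.concordant_pairs)],
        }
    ).to_csv(out / "link_summary.tsv", sep="\t", index=False)
    pd.DataFrame(res.concordant_pairs, columns=["enhancer_id", "gene_id"]).to_csv(
        out / "concordant_pairs.tsv", sep="\t", index=False
    )
    res.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
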