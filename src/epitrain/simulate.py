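"""Seeded generator for every input the pipeline consumes.

The generator emulates the study design: 8 participants sampled before and
after an endurance-training block, two histone marks (H3K4me1 marking
enhancer regions, H3K27ac marking the active subset), gene-level RNA
counts coupled to enhancer activity through scored enhancer-gene links, a
GWAS-catalog-like SNP table over 19 trait categories with LD-block
structure and matching covariates, and a block-model LD reference.

Structure of the synthetic genome: four chromosomes carrying consensus
regions ~10 kb apart (widths 0.8-3 kb).  A configurable fraction of
regions carries both marks (dual-mark regions are the enhancer
candidates); a fraction of those carries a planted training effect on
H3K27ac whose sign split mirrors the predominance of deacetylation after
training.  Counts are negative binomial with lognormal region abundances,
per-participant log-scale effects shared between the ChIP and RNA
simulations of the same participant, and library-size offsets.

SNP panel: each GWAS lead owns an LD block with Poisson-distributed tag
SNPs; tags are perfect proxies (R^2 = 1) with probability one half,
otherwise R^2 in [0.5, 1).  For every lead, ``control_ratio + 1`` control
pool leads are created with covariates drawn inside the matching windows,
guaranteeing matchability.  Block-level enhancer overlap is Bernoulli: the
control odds are ``baseline_overlap`` and each category's case odds are
that times the planted odds ratio, so the planted OR is the estimand the
enrichment stage should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import CountMatrix
from .intervals import GenomicInterval, positions_in, write_bed
from .links import EnhancerGeneLink, write_links
from .gwas import BlockLd, write_snp_table

CATEGORIES = (
    "anthropometric", "autoimmune", "bone_mineral_density", "cancer",
    "cardiovascular", "cognitive", "coagulation",
    "inflammatory_bowel_disease", "inflammatory_response", "lipid_levels",
    "lung", "diabetes_glucose", "neuropsychiatric", "obesity",
    "ophthalmological", "oxygen_carriers", "renal", "female_reproductive",
    "other",
)

N_CHROMS = 4
REGION_SPACING = 10_000

# secreted-factor annotation rates (baseline vs among planted-regulated genes)
UNIPROT_RATES = (0.15, 0.28)
EXOCARTA_RATES = (0.30, 0.45)


def default_planted_or() -> dict[str, float]:
    """Planted per-category odds ratios: the five categories reported as
    enriched carry the printed combined effect size; the rest are null."""
    ors = {c: 1.0 for c in CATEGORIES}
    for c in ("coagulation", "cognitive", "cardiovascular", "renal", "inflammatory_response"):
        ors[c] = 1.44
    return ors


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic data generator."""

    seed: int = 0
    n_participants: int = 8
    n_regions: int = 2000
    n_genes: int = 2000
    frac_dual_mark: float = 0.8
    frac_regulated: float = 0.1
    frac_up_among_regulated: float = 0.21  # most regulated enhancers lose acetylation
    effect_logfc_mean: float = 1.5
    effect_logfc_sd: float = 0.25
    nb_dispersion: float = 0.1
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    n_snps: int = 20_000
    n_blocks: int = 6000
    n_categories: int = 19
    planted_category_or: dict[str, float] = field(default_factory=default_planted_or)
    control_ratio: int = 2
    coupling: float = 0.8  # enhancer-to-gene fold-change transmission
    gene_noise_sd: float = 0.1
    baseline_overlap: float = 0.018  # control-SNP in-enhancer probability
    participant_sd: float = 0.3

    def __post_init__(self) -> None:
        for name in ("frac_dual_mark", "frac_regulated", "frac_up_among_regulated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if any(v <= 0 for v in self.planted_category_or.values()):
            raise ValueError("planted odds ratios must be > 0")
        if round(self.frac_dual_mark * self.n_regions) < 1:
            raise ValueError("frac_dual_mark * n_regions must be >= 1")
        if self.n_categories > len(CATEGORIES):
            raise ValueError(f"n_categories must be <= {len(CATEGORIES)}")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "library_size_range" in d:
            d["library_size_range"] = tuple(d["library_size_range"])
        return cls(**d)


@dataclass
class SyntheticStudy:
    """Everything the pipeline consumes, plus the planted truth."""

    config: SimulationConfig
    k27_peaks: list[list[GenomicInterval]]
    k4_peaks: list[list[GenomicInterval]]
    chip_counts: CountMatrix
    rna_counts: CountMatrix
    region_truth: pd.DataFrame  # region_id, chrom, start, end, dual, planted_logfc
    gene_truth: pd.DataFrame  # gene_id, chrom, tss, planted_logfc, n_links
    links: list[EnhancerGeneLink]
    snp_table: pd.DataFrame  # catalog-style, includes haplotype/duplicate rows
    panel: pd.DataFrame  # unique SNPs with covariates and block structure
    ld: BlockLd
    category_map: pd.DataFrame  # trait -> category
    secreted_uniprot: set[str]
    secreted_exocarta: set[str]
    participant_effects: np.ndarray


# ---------------------------------------------------------------------------
# ChIP simulation


def _sample_labels(n_participants: int) -> tuple[list[str], pd.DataFrame]:
    ids, rows = [], []
    for i in range(1, n_participants + 1):
        for training, tag in ((0, "pre"), (1, "post")):
            sid = f"P{i}_{tag}"
            ids.append(sid)
            rows.append((sid, f"P{i}", training))
    design = pd.DataFrame(rows, columns=["sample_id", "participant", "training"])
    return ids, design.set_index("sample_id")


def _make_regions(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_regions
    per_chrom = np.full(N_CHROMS, n // N_CHROMS)
    per_chrom[: n % N_CHROMS] += 1
    rows = []
    i = 0
    for c, n_c in enumerate(per_chrom, start=1):
        offsets = rng.integers(1000, 6000, n_c)
        widths = rng.integers(800, 3001, n_c)
        starts = np.arange(n_c) * REGION_SPACING + offsets
        for s, w in zip(starts, widths):
            rows.append((f"region_{i:05d}", f"chr{c}", int(s), int(s + w)))
            i += 1
    return pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end"])


def _plant_effects(cfg: SimulationConfig, regions: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    n = len(regions)
    n_dual = round(cfg.frac_dual_mark * n)
    dual_idx = np.sort(rng.choice(n, size=n_dual, replace=False))
    dual = np.zeros(n, dtype=bool)
    dual[dual_idx] = True
    n_reg = round(cfg.frac_regulated * n_dual)
    reg_idx = np.sort(rng.choice(dual_idx, size=n_reg, replace=False))
    n_up = round(cfg.frac_up_among_regulated * n_reg)
    signs = np.concatenate([np.ones(n_up), -np.ones(n_reg - n_up)])
    rng.shuffle(signs)
    # magnitudes never fall below the configured mean: mean + half-normal spread
    mags = cfg.effect_logfc_mean + np.abs(rng.normal(0.0, cfg.effect_logfc_sd, n_reg))
    logfc = np.zeros(n)
    logfc[reg_idx] = signs * mags
    out = regions.copy()
    out["dual"] = dual
    out["planted_logfc"] = logfc
    return out


def _jitter_peaks(
    truth: pd.DataFrame, n_samples: int, rng: np.random.Generator
) -> list[list[GenomicInterval]]:
    """Per-sample peak lists: consensus edges jittered by <=10% of width."""
    starts = truth["start"].to_numpy()
    ends = truth["end"].to_numpy()
    widths = ends - starts
    chroms = truth["chrom"].to_numpy()
    out = []
    for _ in range(n_samples):
        ds = np.rint(rng.uniform(-0.1, 0.1, len(truth)) * widths).astype(int)
        de = np.rint(rng.uniform(-0.1, 0.1, len(truth)) * widths).astype(int)
        s = np.maximum(starts + ds, 0)
        e = np.maximum(ends + de, s + 1)
        out.append([GenomicInterval(c, int(a), int(b)) for c, a, b in zip(chroms, s, e)])
    return out


def _nb_counts(
    mu: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu))


def simulate_chip(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    participant_effects: np.ndarray | None = None,
) -> tuple[list[list[GenomicInterval]], list[list[GenomicInterval]], CountMatrix, pd.DataFrame, np.ndarray]:
    """Per-sample peak lists for both marks, region counts, and the truth.

    Returns (k27_peaks, k4_peaks, chip_counts, region_truth,
    participant_effects).
    """
    regions = _make_regions(cfg, rng)
    truth = _plant_effects(cfg, regions, rng)
    sample_ids, design = _sample_labels(cfg.n_participants)
    n_samples = len(sample_ids)

    k27_peaks = _jitter_peaks(truth, n_samples, rng)

    # H3K4me1: covers every dual region (slightly extended), plus gap peaks
    dual = truth[truth["dual"]]
    ext_lo = rng.integers(100, 501, len(dual))
    ext_hi = rng.integers(100, 501, len(dual))
    k4_truth_rows = [
        (c, max(int(s - lo), 0), int(e + hi))
        for c, s, e, lo, hi in zip(dual["chrom"], dual["start"], dual["end"], ext_lo, ext_hi)
    ]
    # K4-only peaks in inter-region gaps (never touching an H3K27ac region)
    n_extra = round(0.3 * cfg.n_regions)
    gaps = []
    t = truth.reset_index(drop=True)
    for i in range(len(t) - 1):
        if t.loc[i, "chrom"] == t.loc[i + 1, "chrom"]:
            gaps.append((t.loc[i, "chrom"], t.loc[i, "end"], t.loc[i + 1, "start"]))
    pick = rng.choice(len(gaps), size=min(n_extra, len(gaps)), replace=False)
    for j in np.sort(pick):
        chrom, lo, hi = gaps[j]
        mid = (lo + hi) // 2
        half = int(rng.integers(300, 601))
        k4_truth_rows.append((chrom, mid - half, mid + half))
    k4_truth = pd.DataFrame(k4_truth_rows, columns=["chrom", "start", "end"])
    k4_peaks = _jitter_peaks(k4_truth, n_samples, rng)

    if participant_effects is None:
        participant_effects = rng.normal(0.0, cfg.participant_sd, cfg.n_participants)
    weights = rng.lognormal(0.0, 1.0, cfg.n_regions)
    weights /= weights.sum()
    lo, hi = cfg.library_size_range
    libs = rng.integers(lo, hi + 1, n_samples)
    part_idx = np.array([int(p[1:]) - 1 for p in design["participant"]])
    training = design["training"].to_numpy()
    logfc = truth["planted_logfc"].to_numpy()
    mu = (
        weights[:, None]
        * libs[None, :]
        * np.exp(participant_effects[part_idx][None, :] + training[None, :] * logfc[:, None])
    )
    counts = _nb_counts(mu, cfg.nb_dispersion, rng)
    design = design.copy()
    design["library_size"] = libs
    cm = CountMatrix(list(truth["region_id"]), sample_ids, counts, design)
    return k27_peaks, k4_peaks, cm, truth, participant_effects


# ---------------------------------------------------------------------------
# Genes, links, RNA


def _make_genes(cfg: SimulationConfig, region_truth: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    spans = region_truth.groupby("chrom")["end"].max() + 20_000
    chroms = list(spans.index)
    weights = spans.to_numpy(dtype=float)
    weights /= weights.sum()
    per_chrom = rng.multinomial(cfg.n_genes, weights)
    rows = []
    i = 0
    for chrom, n_c in zip(chroms, per_chrom):
        tss = np.sort(rng.integers(0, int(spans[chrom]), n_c))
        for p in tss:
            rows.append((f"gene_{i:05d}", chrom, int(p)))
            i += 1
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss"])


def simulate_links(
    cfg: SimulationConfig,
    region_truth: pd.DataFrame,
    genes: pd.DataFrame,
    rng: np.random.Generator,
) -> list[EnhancerGeneLink]:
    """Scored links from each dual-mark region to 1-5 nearby genes.

    The link-side geometry is the region shifted by up to 20% of its width
    (guaranteeing a single-base overlap with the region it came from), as
    produced by lifting externally mapped enhancer coordinates.
    """
    links: list[EnhancerGeneLink] = []
    by_chrom = {c: g.reset_index(drop=True) for c, g in genes.groupby("chrom")}
    for row in region_truth[region_truth["dual"]].itertuples():
        g = by_chrom.get(row.chrom)
        if g is None or len(g) == 0:
            continue
        mid = (row.start + row.end) // 2
        width = row.end - row.start
        dist_all = np.abs(g["tss"].to_numpy() - mid)
        nearest = np.argsort(dist_all, kind="stable")[:8]
        n_links = min(1 + rng.poisson(1.3), 5, len(nearest))
        chosen = rng.choice(nearest, size=n_links, replace=False)
        shift = int(np.rint(rng.uniform(-0.2, 0.2) * width))
        geom = GenomicInterval(row.chrom, row.start + shift, row.end + shift, name=row.region_id)
        for j in np.sort(chosen):
            links.append(
                EnhancerGeneLink(
                    interval=geom,
                    gene_id=str(g.loc[j, "gene_id"]),
                    score=float(np.round(rng.uniform(0.2, 1.0), 4)),
                    distance=int(dist_all[j]),
                )
            )
    return links


def simulate_rna(
    cfg: SimulationConfig,
    region_truth: pd.DataFrame,
    links: list[EnhancerGeneLink],
    genes: pd.DataFrame,
    rng: np.random.Generator,
    participant_effects: np.ndarray,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Gene counts whose planted fold change follows linked enhancers.

    A gene's planted lnFC is ``coupling`` times the interaction-score-
    weighted mean of its linked enhancers' planted lnFC, plus independent
    Gaussian noise; unlinked genes get noise only.
    """
    region_fc = dict(zip(region_truth["region_id"], region_truth["planted_logfc"]))
    num: dict[str, float] = {}
    den: dict[str, float] = {}
    n_links_of: dict[str, int] = {}
    for l in links:
        enh_id = l.interval.name
        if enh_id not in region_fc:
            raise ValueError(f"link references unknown region {enh_id!r}")
        num[l.gene_id] = num.get(l.gene_id, 0.0) + l.score * region_fc[enh_id]
        den[l.gene_id] = den.get(l.gene_id, 0.0) + l.score
        n_links_of[l.gene_id] = n_links_of.get(l.gene_id, 0) + 1
    noise = rng.normal(0.0, cfg.gene_noise_sd, len(genes))
    planted = np.array(
        [
            cfg.coupling * (num[g] / den[g]) if g in den else 0.0
            for g in genes["gene_id"]
        ]
    )
    gene_fc = planted + noise

    sample_ids, design = _sample_labels(cfg.n_participants)
    n_samples = len(sample_ids)
    weights = rng.lognormal(0.0, 1.0, len(genes))
    weights /= weights.sum()
    lo, hi = cfg.library_size_range
    libs = rng.integers(lo, hi + 1, n_samples)
    part_idx = np.array([int(p[1:]) - 1 for p in design["participant"]])
    training = design["training"].to_numpy()
    mu = (
        weights[:, None]
        * libs[None, :]
        * np.exp(participant_effects[part_idx][None, :] + training[None, :] * gene_fc[:, None])
    )
    counts = _nb_counts(mu, cfg.nb_dispersion, rng)
    design = design.copy()
    design["library_size"] = libs
    cm = CountMatrix(list(genes["gene_id"]), sample_ids, counts, design)
    truth = genes.copy()
    truth["planted_logfc"] = gene_fc
    truth["coupled_logfc"] = planted
    truth["n_links"] = [n_links_of.get(g, 0) for g in genes["gene_id"]]
    return cm, truth


def simulate_annotations(
    gene_truth: pd.DataFrame, rng: np.random.Generator
) -> tuple[set[str], set[str]]:
    """Synthetic secreted-factor annotation sets (UniProt- and ExoCarta-like)
    enriched among planted-regulated genes."""
    regulated = (np.abs(gene_truth["coupled_logfc"].to_numpy()) > 0).astype(int)
    out = []
    for base, enriched in (UNIPROT_RATES, EXOCARTA_RATES):
        prob = np.where(regulated == 1, enriched, base)
        mask = rng.random(len(gene_truth)) < prob
        out.append(set(gene_truth.loc[mask, "gene_id"]))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# SNP panel


def simulate_snp_panel(
    cfg: SimulationConfig,
    enhancers: list[GenomicInterval],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, BlockLd, pd.DataFrame]:
    """(catalog-style snp_table, unique panel, LD reference, category map).

    The snp_table includes a few haplotype-flagged and duplicated records
    so the catalog filter has work to do; the panel holds each SNP once.
    """
    if not enhancers:
        raise ValueError("enhancer list must be nonempty")
    cats = list(CATEGORIES[: cfg.n_categories])
    n_cases = cfg.n_blocks // (cfg.control_ratio + 2)
    if n_cases < 1:
        raise ValueError("n_blocks too small for the requested control_ratio")
    n_pool_per = cfg.control_ratio + 1
    n_pool = n_cases * n_pool_per
    lam = max(cfg.n_snps / cfg.n_blocks - 1.0, 0.2)

    case_tags = rng.poisson(lam, n_cases)
    pool_tags = np.repeat(case_tags, n_pool_per)
    case_cat_idx = rng.integers(0, len(cats), n_cases)
    case_cat = np.array(cats, dtype=object)[case_cat_idx]
    case_trait = np.array(
        [f"trait_{c}_{t}" for c, t in zip(case_cat, rng.integers(1, 4, n_cases))],
        dtype=object,
    )
    case_maf = rng.uniform(0.1, 0.45, n_cases)
    case_gd = rng.uniform(0.2, 3.0, n_cases)
    case_dist = rng.integers(2_000, 500_000, n_cases)
    case_p = 10.0 ** (-rng.uniform(8.2, 25.0, n_cases))

    # pool-lead covariates perturbed inside the matching windows
    rep = np.repeat
    pool_maf = np.clip(rep(case_maf, n_pool_per) + rng.uniform(-0.045, 0.045, n_pool), 0.01, 0.5)
    pool_gd = rep(case_gd, n_pool_per) * rng.uniform(0.55, 1.45, n_pool)
    pool_dist = np.maximum(
        (rep(case_dist, n_pool_per) * rng.uniform(0.55, 1.45, n_pool)).astype(int), 1
    )
    pool_p = rng.uniform(0.05, 1.0, n_pool)

    # block-level enhancer overlap
    p0 = cfg.baseline_overlap
    or_map = {c: cfg.planted_category_or.get(c, 1.0) for c in cats}
    odds = np.array([or_map[c] for c in case_cat]) * p0 / (1.0 - p0)
    case_overlap = rng.random(n_cases) < odds / (1.0 + odds)
    pool_overlap = rng.random(n_pool) < p0

    # member tables ------------------------------------------------------
    def build_members(n_leads, tags, overlap, prefix, id_offset):
        n_members = int(n_leads + tags.sum())
        block_idx = np.repeat(np.arange(n_leads), tags + 1)
        is_lead = np.zeros(n_members, dtype=bool)
        is_lead[np.concatenate([[0], np.cumsum(tags + 1)[:-1]])] = True
        tier = np.where(
            rng.random(n_members) < 0.5, 1.0, np.round(rng.uniform(0.5, 0.99, n_members), 3)
        )
        tier[is_lead] = 1.0
        # the overlapping member must be a perfect proxy of the lead
        overlap_member = np.full(n_members, False)
        member_of_block = np.flatnonzero(is_lead)
        for b in np.flatnonzero(overlap[:n_leads]):
            lo = member_of_block[b]
            hi = lo + tags[b] + 1
            perfect = np.flatnonzero(tier[lo:hi] >= 1.0) + lo
            if rng.random() < 0.6 or len(perfect) == 1:
                overlap_member[lo] = True
            else:
                overlap_member[int(rng.choice(perfect[1:]))] = True
        ids = np.array([f"{prefix}{id_offset + j:07d}" for j in range(n_members)], dtype=object)
        blocks = np.array([f"blk_{prefix}{b:06d}" for b in block_idx], dtype=object)
        return block_idx, is_lead, tier, overlap_member, ids, blocks

    cb_idx, c_lead, c_tier, c_ovm, c_ids, c_blocks = build_members(
        n_cases, case_tags, case_overlap, "rs", 0
    )
    pb_idx, p_lead, p_tier, p_ovm, p_ids, p_blocks = build_members(
        n_pool, pool_tags, pool_overlap, "ct", 0
    )

    # positions ----------------------------------------------------------
    enh_chrom = np.array([e.chrom for e in enhancers], dtype=object)
    enh_start = np.array([e.start for e in enhancers])
    enh_end = np.array([e.end for e in enhancers])
    chrom_max: dict[str, int] = {}
    for e in enhancers:
        chrom_max[e.chrom] = max(chrom_max.get(e.chrom, 0), e.end)
    chrom_names = np.array(sorted(chrom_max), dtype=object)
    chrom_lens = np.array([chrom_max[c] + 50_000 for c in chrom_names])
    chrom_w = chrom_lens / chrom_lens.sum()

    def place(block_idx, overlap_member, n_leads, overlap):
        n_members = len(block_idx)
        # one center per block
        which_chrom = rng.choice(len(chrom_names), size=n_leads, p=chrom_w)
        centers = rng.integers(1, chrom_lens[which_chrom])
        block_chrom = chrom_names[which_chrom]
        # overlap blocks: center at a position inside a random enhancer
        for b in np.flatnonzero(overlap):
            j = int(rng.integers(0, len(enhancers)))
            pos_in = int(rng.integers(enh_start[j], enh_end[j]))
            centers[b] = pos_in
            block_chrom[b] = enh_chrom[j]
        pos = centers[block_idx] + rng.integers(-25_000, 25_001, n_members)
        chroms = block_chrom[block_idx]
        pos[overlap_member] = centers[block_idx[overlap_member]]
        # every non-designated member must sit outside all enhancers
        need_out = ~overlap_member
        for _ in range(60):
            bad = need_out & positions_in(chroms, np.maximum(pos, 1), enhancers)
            if not bad.any():
                break
            pos[bad] = centers[block_idx[bad]] + rng.integers(-25_000, 25_001, int(bad.sum()))
        pos = np.maximum(pos, 1)
        return chroms, pos

    c_chrom, c_pos = place(cb_idx, c_ovm, n_cases, case_overlap)
    p_chrom, p_pos = place(pb_idx, p_ovm, n_pool, pool_overlap)

    # member-level attributes inherited from the block's lead
    def expand_lead(attr, block_idx):
        return np.asarray(attr)[block_idx]

    c_buddies = case_tags[cb_idx]  # LD buddies at R^2 = 0.5: block size - 1
    p_buddies = pool_tags[pb_idx]

    # tag association p-values: some tags are themselves catalog hits
    c_p = np.empty(len(cb_idx))
    c_p[c_lead] = case_p
    tag_mask = ~c_lead
    lead_p_of = case_p[cb_idx]
    strong_tag = tag_mask & (rng.random(len(cb_idx)) < 0.35)
    c_p[strong_tag] = np.minimum(lead_p_of[strong_tag] * 10 ** rng.uniform(0.5, 3.0, int(strong_tag.sum())), 1.0)
    weak_tag = tag_mask & ~strong_tag
    c_p[weak_tag] = rng.uniform(1e-6, 1.0, int(weak_tag.sum()))
    p_p = np.empty(len(pb_idx))
    p_p[p_lead] = pool_p
    p_p[~p_lead] = rng.uniform(0.05, 1.0, int((~p_lead).sum()))

    case_df = pd.DataFrame(
        {
            "snp_id": c_ids,
            "chrom": c_chrom,
            "pos": c_pos.astype(np.int64),
            "p_assoc": c_p,
            "trait": expand_lead(case_trait, cb_idx),
            "category": expand_lead(case_cat, cb_idx),
            "maf": expand_lead(case_maf, cb_idx) + rng.uniform(-0.01, 0.01, len(cb_idx)),
            "gene_density": expand_lead(case_gd, cb_idx),
            "dist_nearest_gene": expand_lead(case_dist, cb_idx),
            "ld_buddies": c_buddies,
            "block_id": c_blocks,
            "r2_tier": c_tier,
            "role": np.where(c_lead, "case_lead", "case_tag"),
            "is_haplotype": False,
        }
    )
    # leads keep their exact covariates (matching happens on leads)
    case_df.loc[c_lead, "maf"] = case_maf
    pool_df = pd.DataFrame(
        {
            "snp_id": p_ids,
            "chrom": p_chrom,
            "pos": p_pos.astype(np.int64),
            "p_assoc": p_p,
            "trait": "",
            "category": "control",
            "maf": np.clip(expand_lead(pool_maf, pb_idx), 0.01, 0.5),
            "gene_density": expand_lead(pool_gd, pb_idx),
            "dist_nearest_gene": expand_lead(pool_dist, pb_idx),
            "ld_buddies": p_buddies,
            "block_id": p_blocks,
            "r2_tier": p_tier,
            "role": np.where(p_lead, "pool_lead", "pool_tag"),
            "is_haplotype": False,
        }
    )
    pool_df.loc[p_lead, "maf"] = pool_maf
    panel = pd.concat([case_df, pool_df], ignore_index=True)

    # verify guaranteed matchability: each case lead's own n_pool_per pool
    # leads were drawn inside its windows; check the construction held
    pm = pool_maf.reshape(n_cases, n_pool_per)
    pg = pool_gd.reshape(n_cases, n_pool_per)
    pdst = pool_dist.reshape(n_cases, n_pool_per)
    ok = (
        (np.abs(pm - case_maf[:, None]) <= 0.05)
        & (pg >= 0.5 * case_gd[:, None]) & (pg <= 1.5 * case_gd[:, None])
        & (pdst >= 0.5 * case_dist[:, None]) & (pdst <= 1.5 * case_dist[:, None])
    )
    if (ok.sum(axis=1) < cfg.control_ratio).any():
        raise RuntimeError(
            "matchability violated: some case lead has fewer than "
            f"{cfg.control_ratio} in-window pool leads"
        )

    ld = BlockLd.from_frame(panel[["snp_id", "block_id", "r2_tier"]])

    # catalog-style table with artefacts to exercise the filter
    extras = []
    n_hap = max(3, n_cases // 200)
    for j in range(n_hap):
        extras.append(
            dict(
                snp_id=f"hap{j:04d}", chrom="chr1", pos=int(rng.integers(1, 10_000)),
                p_assoc=float(10.0 ** (-rng.uniform(9, 15))),
                trait=str(case_trait[j % n_cases]), category=str(case_cat[j % n_cases]),
                maf=0.2, gene_density=1.0, dist_nearest_gene=10_000,
                ld_buddies=0, block_id="", r2_tier=1.0, role="haplotype",
                is_haplotype=True,
            )
        )
    dup_leads = np.flatnonzero(c_lead)[rng.random(n_cases) < 0.01]
    dup_rows = case_df.iloc[dup_leads].copy()
    dup_rows["p_assoc"] = np.minimum(dup_rows["p_assoc"] * 10 ** rng.uniform(0.2, 1.0, len(dup_rows)), 4e-8)
    snp_table = pd.concat([panel, pd.DataFrame(extras), dup_rows], ignore_index=True)

    traits = sorted(set(case_trait))
    category_map = pd.DataFrame(
        {"trait": traits, "category": [t.split("_", 1)[1].rsplit("_", 1)[0] for t in traits]}
    )
    return snp_table, panel, ld, category_map


def synthetic_enhancer_set(
    n: int, rng: np.random.Generator, spacing: int = 30_000
) -> list[GenomicInterval]:
    """A standalone enhancer interval set for SNP-enrichment studies that
    do not need the ChIP stages (widths 1.5-2.5 kb, spread over four
    chromosomes)."""
    per_chrom = np.full(N_CHROMS, n // N_CHROMS)
    per_chrom[: n % N_CHROMS] += 1
    out = []
    i = 0
    for c, n_c in enumerate(per_chrom, start=1):
        offsets = rng.integers(1_000, spacing // 2, n_c)
        widths = rng.integers(1_500, 2_501, n_c)
        for j in range(n_c):
            s = int(j * spacing + offsets[j])
            out.append(GenomicInterval(f"chr{c}", s, s + int(widths[j]), name=f"enh_{i:05d}"))
            i += 1
    return out


# ---------------------------------------------------------------------------
# Whole study


def simulate_study(cfg: SimulationConfig) -> SyntheticStudy:
    """Generate every pipeline input from one seed; fully deterministic."""
    root = np.random.SeedSequence(cfg.seed)
    rng_chip, rng_genes, rng_links, rng_rna, rng_annot, rng_snp = (
        np.random.default_rng(s) for s in root.spawn(6)
    )
    k27, k4, chip_counts, region_truth, part_fx = simulate_chip(cfg, rng_chip)
    genes = _make_genes(cfg, region_truth, rng_genes)
    links = simulate_links(cfg, region_truth, genes, rng_links)
    rna_counts, gene_truth = simulate_rna(cfg, region_truth, links, genes, rng_rna, part_fx)
    uniprot, exocarta = simulate_annotations(gene_truth, rng_annot)
    regulated = region_truth[region_truth["planted_logfc"] != 0]
    enhancer_ivs = [
        GenomicInterval(r.chrom, r.start, r.end, name=r.region_id)
        for r in regulated.itertuples()
    ]
    snp_table, panel, ld, category_map = simulate_snp_panel(cfg, enhancer_ivs, rng_snp)
    return SyntheticStudy(
        config=cfg,
        k27_peaks=k27,
        k4_peaks=k4,
        chip_counts=chip_counts,
        rna_counts=rna_counts,
        region_truth=region_truth,
        gene_truth=gene_truth,
        links=links,
        snp_table=snp_table,
        panel=panel,
        ld=ld,
        category_map=category_map,
        secreted_uniprot=uniprot,
        secreted_exocarta=exocarta,
        participant_effects=part_fx,
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write the study as the plain-text fixture directory the CLI reads."""
    out = Path(outdir)
    for mark, peaks in (("k27", study.k27_peaks), ("k4", study.k4_peaks)):
        d = out / f"{mark}_peaks"
        d.mkdir(parents=True, exist_ok=True)
        for sid, ivs in zip(study.chip_counts.sample_ids, peaks):
            write_bed(d / f"{sid}.bed", ivs)
    study.chip_counts.to_tsv(out / "chip_counts.tsv", out / "chip_design.tsv")
    study.rna_counts.to_tsv(out / "rna_counts.tsv", out / "rna_design.tsv")
    write_links(out / "links.tsv", study.links)
    write_snp_table(out / "snps.tsv", study.snp_table)
    study.ld.to_frame().to_csv(out / "ld_blocks.tsv", sep="\t", index=False)
    study.category_map.to_csv(out / "category_map.tsv", sep="\t", index=False)
    study.region_truth.to_csv(out / "truth_regions.tsv", sep="\t", index=False)
    study.gene_truth.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    for name, ids in (
        ("secreted_uniprot.txt", study.secreted_uniprot),
        ("secreted_exocarta.txt", study.secreted_exocarta),
    ):
        (out / name).write_text("".join(f"{g}\n" for g in sorted(ids)))
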