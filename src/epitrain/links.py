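"""Scored enhancer-gene links: attachment, summary statistics, promoter
grouping, ECDF comparisons, and activity-expression concordance.

Links are externally scored enhancer->gene assignments (EpiMap-style): a
genomic interval on the enhancer side, a target gene, an interaction
score, and the enhancer-midpoint-to-TSS distance.  A single-base overlap
between an identified enhancer and a link's interval suffices to connect
the enhancer to the linked gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp, pearsonr, spearmanr

from .intervals import GenomicInterval, overlap_join

GROUPS = ("None", "Up", "Down", "Both")


@dataclass(frozen=True)
class EnhancerGeneLink:
    interval: GenomicInterval  # link-side geometry
    gene_id: str
    score: float
    distance: int  # |enhancer midpoint - TSS| in bp

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("link score must be finite")
        if self.distance < 0:
            raise ValueError("link distance must be >= 0")


def read_links(path: str | Path) -> list[EnhancerGeneLink]:
    """Read a link table TSV: chrom, start, end, gene_id, score, distance."""
    df = pd.read_csv(path, sep="\t")
    return [
        EnhancerGeneLink(
            GenomicInterval(r.chrom, int(r.start), int(r.end)),
            str(r.gene_id),
            float(r.score),
            int(r.distance),
        )
        for r in df.itertuples()
    ]


def write_links(path: str | Path, links: Sequence[EnhancerGeneLink]) -> None:
    pd.DataFrame(
        {
            "chrom": [l.interval.chrom for l in links],
            "start": [l.interval.start for l in links],
            "end": [l.interval.end for l in links],
            "gene_id": [l.gene_id for l in links],
            "score": [l.score for l in links],
            "distance": [l.distance for l in links],
        }
    ).to_csv(path, sep="\t", index=False)


def attach_links(
    enhancers: Sequence[GenomicInterval], links: Sequence[EnhancerGeneLink]
) -> dict[str, list[EnhancerGeneLink]]:
    """Map each enhancer (by id) to every link overlapping it by >=1 base.

    Enhancers with no overlapping link map to an empty list.  Duplicate
    (enhancer, gene) links are all retained; deduplication happens in the
    statistics, not here.
    """
    geoms = [l.interval for l in links]
    hits = overlap_join(list(enhancers), geoms)
    return {e.id: [links[j] for j in h] for e, h in zip(enhancers, hits)}


def link_statistics(
    attached: Mapping[str, Sequence[EnhancerGeneLink]]
) -> tuple[float, float, float]:
    """(mean enhancers per linked gene, mean genes per linked enhancer,
    mean link distance in bp), counting each distinct (enhancer, gene)
    pair once (the highest-scoring duplicate wins)."""
    pairs: dict[tuple[str, str], EnhancerGeneLink] = {}
    for enh_id, lks in attached.items():
        for l in lks:
            key = (enh_id, l.gene_id)
            if key not in pairs or l.score > pairs[key].score:
                pairs[key] = l
    if not pairs:
        raise ValueError("no enhancer has any attached link")
    per_gene: dict[str, int] = {}
    per_enh: dict[str, int] = {}
    for (enh_id, gene_id) in pairs:
        per_gene[gene_id] = per_gene.get(gene_id, 0) + 1
        per_enh[enh_id] = per_enh.get(enh_id, 0) + 1
    mean_enh_per_gene = float(np.mean(list(per_gene.values())))
    mean_gene_per_enh = float(np.mean(list(per_enh.values())))
    mean_dist = float(np.mean([l.distance for l in pairs.values()]))
    return mean_enh_per_gene, mean_gene_per_enh, mean_dist


def strongest_gene(links: Sequence[EnhancerGeneLink]) -> str | None:
    """Gene of the maximum-score link; ties break to the smallest gene id."""
    if not links:
        return None
    top = max(l.score for l in links)
    return min(l.gene_id for l in links if l.score == top)


def promoter_groups(
    genes: set[str],
    attached: Mapping[str, Sequence[EnhancerGeneLink]],
    up: set[str],
    down: set[str],
) -> pd.DataFrame:
    """Classify each linked gene by the regulation of its enhancers.

    "Both": linked to >=1 up- and >=1 down-regulated enhancer; "Up"/"Down":
    >=1 of one kind and none of the other (unregulated co-links do not
    demote, matching the at-least-one rule); "None": linked only to
    unregulated enhancers.  Genes with no links are excluded.
    """
    if up & down:
        raise ValueError(f"up and down sets overlap: {sorted(up & down)[:5]}")
    has_up: dict[str, bool] = {}
    has_down: dict[str, bool] = {}
    linked: set[str] = set()
    for enh_id, lks in attached.items():
        for l in lks:
            g = l.gene_id
            if g not in genes:
                continue
            linked.add(g)
            if enh_id in up:
                has_up[g] = True
            elif enh_id in down:
                has_down[g] = True
    rows = []
    for g in sorted(linked):
        u, d = has_up.get(g, False), has_down.get(g, False)
        group = "Both" if (u and d) else "Up" if u else "Down" if d else "None"
        rows.append((g, group))
    return pd.DataFrame(rows, columns=["gene_id", "group"])


def ecdf_shift(
    group_values: np.ndarray, reference_values: np.ndarray
) -> tuple[float, float, int]:
    """Two-sample KS comparison of lnFC distributions.

    Returns (D, asymptotic p, direction) where direction is the sign of
    median(group) - median(reference).
    """
    g = np.asarray(group_values, dtype=float)
    r = np.asarray(reference_values, dtype=float)
    if g.size == 0 or r.size == 0:
        raise ValueError("both vectors must be nonempty")
    res = ks_2samp(g, r, method="asymp")
    direction = int(np.sign(np.median(g) - np.median(r)))
    return float(res.statistic), float(res.pvalue), direction


def activity_expression_concordance(
    enh_results: pd.DataFrame,
    gene_results: pd.DataFrame,
    attached: Mapping[str, Sequence[EnhancerGeneLink]],
    mode: str = "strongest",
    method: str = "pearson",
    fdr: float = 0.1,
) -> tuple[float, int, list[tuple[str, str]]]:
    """Correlate enhancer-activity and linked-gene-expression fold changes.

    ``mode="strongest"`` reduces each enhancer to its highest-interaction-
    score gene; ``mode="all"`` uses every distinct (enhancer, gene) pair.
    Returns (r, n_pairs, concordant_significant) where the concordant list
    holds pairs with both q < fdr and the same logFC sign.  r is NaN when
    fewer than 3 pairs are available.
    """
    if mode not in ("strongest", "all"):
        raise ValueError("mode must be 'strongest' or 'all'")
    enh = enh_results.set_index("feature_id")
    gene = gene_results.set_index("feature_id")
    pairs: list[tuple[str, str]] = []
    for enh_id, lks in attached.items():
        if not lks or enh_id not in enh.index:
            continue
        if mode == "strongest":
            g = strongest_gene(lks)
            cand = [g] if g is not None else []
        else:
            cand = sorted({l.gene_id for l in lks})
        for g in cand:
            if g in gene.index and np.isfinite(gene.loc[g, "p"]):
                pairs.append((enh_id, g))
    xs = np.array([enh.loc[e, "logFC"] for e, _ in pairs], dtype=float)
    ys = np.array([gene.loc[g, "logFC"] for _, g in pairs], dtype=float)
    if len(pairs) < 3:
        r = float("nan")
    elif method == "spearman":
        r = float(spearmanr(xs, ys).statistic)
    else:
        r = float(pearsonr(xs, ys).statistic)
    concordant = [
        (e, g)
        for (e, g), x, y in zip(pairs, xs, ys)
        if enh.loc[e, "q"] < fdr and gene.loc[g, "q"] < fdr and np.sign(x) == np.sign(y) != 0
    ]
    return r, len(pairs), concordant
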