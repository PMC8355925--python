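"""Consensus peaks, dual-mark enhancer identification, and the paired
differential H3K27ac test.

Enhancers are operationalized as H3K27ac consensus peaks that share at
least one base with an H3K4me1 consensus peak: H3K4me1 marks enhancer
regions, H3K27ac marks the active subset, and the H3K27ac peak is the
enhancer unit whose activity change after training is tested.

The consensus rule is a deterministic coverage criterion: a base belongs
to the consensus if at least ``min_support`` of the per-sample peak sets
cover it (default: half the samples, rounded up).  This replaces
reproducibility pipelines built on pseudo-replicates with a rule that is
order-independent and exactly testable.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .counts import CountMatrix
from .glm import nb_lrt
from .intervals import GenomicInterval, overlap_join
from .stats import adjust_pvalues


def consensus_peaks(
    per_sample_peaks: Sequence[Sequence[GenomicInterval]],
    min_support: int | None = None,
) -> list[GenomicInterval]:
    """Maximal runs of bases covered by >= min_support samples.

    Coverage is counted per sample (a base covered by two peaks of the same
    sample counts once).  Returns intervals sorted by (chrom, start).
    """
    n_samples = len(per_sample_peaks)
    if n_samples < 2:
        raise ValueError("need at least 2 samples to form a consensus")
    if min_support is None:
        min_support = math.ceil(n_samples / 2)
    if min_support < 1:
        raise ValueError(f"min_support must be >= 1, got {min_support}")
    if min_support > n_samples:
        raise ValueError(
            f"min_support {min_support} exceeds the number of samples {n_samples}"
        )

    # breakpoint sweep: +1 at each per-sample covered-region start, -1 at end
    events: dict[str, list[tuple[int, int]]] = {}
    for peaks in per_sample_peaks:
        seen: dict[str, list[tuple[int, int]]] = {}
        for iv in peaks:
            seen.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, spans in seen.items():
            # merge within-sample so each sample contributes coverage 0/1
            spans.sort()
            merged = []
            cs, ce = spans[0]
            for s, e in spans[1:]:
                if s <= ce:
                    ce = max(ce, e)
                else:
                    merged.append((cs, ce))
                    cs, ce = s, e
            merged.append((cs, ce))
            ev = events.setdefault(chrom, [])
            for s, e in merged:
                ev.append((s, +1))
                ev.append((e, -1))

    out: list[GenomicInterval] = []
    for chrom in sorted(events):
        ev = sorted(events[chrom])
        coverage = 0
        run_start: int | None = None
        prev_pos: int | None = None
        for pos, delta in ev:
            if prev_pos is not None and pos > prev_pos:
                if coverage >= min_support and run_start is None:
                    run_start = prev_pos
                elif coverage < min_support and run_start is not None:
                    out.append(GenomicInterval(chrom, run_start, prev_pos))
                    run_start = None
            coverage += delta
            prev_pos = pos
        if run_start is not None and prev_pos is not None and prev_pos > run_start:
            out.append(GenomicInterval(chrom, run_start, prev_pos))
    return out


def identify_enhancers(
    k27_consensus: Sequence[GenomicInterval],
    k4_consensus: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """H3K27ac consensus peaks overlapping >=1 H3K4me1 peak by >=1 base.

    Coordinates are returned unchanged; the H3K27ac peak is the enhancer.
    """
    hits = overlap_join(list(k27_consensus), list(k4_consensus))
    return [iv for iv, h in zip(k27_consensus, hits) if h]


def differential_activity(
    counts: CountMatrix, adjust: str = "BH"
) -> pd.DataFrame:
    """Per-region paired NB test of the training effect on H3K27ac counts.

    Fits log mu = log(library_size) + participant + training per region,
    tests training = 0 by likelihood ratio, and BH-adjusts across tested
    regions.  All-zero regions are reported with NaN p and q.
    Columns: feature_id, logFC (natural log), se, p, q, mean_cpm, dispersion.
    """
    res = nb_lrt(counts)
    tested = res["p"].notna()
    q = np.full(len(res), np.nan)
    if tested.any():
        q[tested.to_numpy()] = adjust_pvalues(res.loc[tested, "p"].to_numpy(), adjust).q
    res["q"] = q
    return res


def classify_regulated(
    results: pd.DataFrame, fdr: float = 0.1
) -> tuple[set[str], set[str]]:
    """Split tested features into up- (q<fdr, logFC>0) and down-regulated sets."""
    sig = results["q"] < fdr
    up = set(results.loc[sig & (results["logFC"] > 0), "feature_id"])
    down = set(results.loc[sig & (results["logFC"] < 0), "feature_id"])
    return up, down


def select_nonregulated(results: pd.DataFrame, n: int) -> set[str]:
    """The n features least affected by training: largest q, then largest p,
    then lexicographically smallest id.  Mirrors the contrast set built by
    ranking all enhancers by FDR and taking the top of the ranking."""
    tested = results[results["q"].notna()]
    if n > len(tested):
        raise ValueError(f"requested {n} features but only {len(tested)} were tested")
    ranked = tested.sort_values(
        by=["q", "p", "feature_id"], ascending=[False, False, True], kind="stable"
    )
    return set(ranked["feature_id"].head(n))
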