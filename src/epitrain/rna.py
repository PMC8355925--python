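"""Paired differential expression, secreted-factor enrichment, and the
MDS sample-structure diagnostic.

The differential test compares, per gene, a model with only participant
effects (~participant) against one adding the training indicator
(~participant + training) by a negative-binomial likelihood-ratio test;
the reported fold change is the Wald (fitted-coefficient) estimate of the
training effect.  Adjustment defaults to Benjamini-Hochberg with a
Bonferroni option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .counts import CountMatrix
from .glm import nb_lrt
from .stats import adjust_pvalues


def differential_expression(counts: CountMatrix, adjust: str = "BH") -> pd.DataFrame:
    """Per-gene paired NB LRT of the training effect.

    Columns: feature_id, logFC (natural-log Wald estimate), se, p, q,
    mean_cpm, dispersion.  Raises for unpaired designs, listing the
    offending participant ids.  Samples flagged as outliers must be
    dropped by the caller before testing.
    """
    counts.require_paired()
    res = nb_lrt(counts)
    tested = res["p"].notna()
    q = np.full(len(res), np.nan)
    if tested.any():
        q[tested.to_numpy()] = adjust_pvalues(res.loc[tested, "p"].to_numpy(), adjust).q
    res["q"] = q
    return res


@dataclass(frozen=True)
class EnrichmentTable:
    """2x2 contingency result for an annotation against a regulated set."""

    table: np.ndarray  # rows: regulated / not; cols: annotated / not
    chi2: float
    p: float
    low_expected: bool  # true when any expected cell < 1


def secreted_enrichment(
    regulated: set[str], universe: set[str], annotation: set[str]
) -> EnrichmentTable:
    """Pearson chi-square (1 df, no continuity correction) for whether the
    annotation (e.g. UniProt-secreted or ExoCarta ids) is overrepresented
    among regulated genes relative to the rest of the expressed universe.

    The annotation set is intersected with the universe first.
    """
    if not regulated <= universe:
        raise ValueError("regulated gene set must be a subset of the universe")
    annot = annotation & universe
    n_reg = len(regulated)
    n_other = len(universe) - n_reg
    a = len(regulated & annot)
    c = len(annot) - a
    table = np.array([[a, n_reg - a], [c, n_other - c]], dtype=float)
    stat, p, _, expected = chi2_contingency(table, correction=False)
    return EnrichmentTable(table=table, chi2=float(stat), p=float(p), low_expected=bool((expected < 1).any()))


def mds_embedding(counts: CountMatrix, dims: int = 2, top: int = 500) -> pd.DataFrame:
    """Classical MDS of samples after removing participant effects.

    Log2-CPM with prior count 0.5 is computed, each participant's mean
    profile is subtracted (the paired analogue of batch removal), and the
    distance between two samples is the root-mean-square of the ``top``
    largest absolute per-gene log differences (leading-logFC distance).
    Classical (Torgerson) MDS of that matrix gives the coordinates.
    """
    if counts.n_samples < 3:
        raise ValueError("MDS needs at least 3 samples")
    if dims >= counts.n_samples:
        raise ValueError(f"dims must be < n_samples ({counts.n_samples})")
    lib = counts.design["library_size"].to_numpy(dtype=float)
    logcpm = np.log2((counts.counts + 0.5) / (lib[None, :] + 1.0) * 1e6)
    centered = logcpm.copy()
    for _, idx in counts.design.groupby("participant").indices.items():
        centered[:, idx] -= centered[:, idx].mean(axis=1, keepdims=True)
    n = counts.n_samples
    top = min(top, counts.n_features)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(centered[:, i] - centered[:, j])
            lead = np.partition(diff, counts.n_features - top)[-top:]
            d[i, j] = d[j, i] = np.sqrt(np.mean(lead**2))
    # Torgerson double centering
    d2 = d**2
    jmat = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * jmat @ d2 @ jmat
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))[None, :]
    # deterministic sign: largest-magnitude loading positive per axis
    for k in range(coords.shape[1]):
        pivot = np.argmax(np.abs(coords[:, k]))
        if coords[pivot, k] < 0:
            coords[:, k] = -coords[:, k]
    out = pd.DataFrame(
        coords, index=counts.sample_ids, columns=[f"dim{k + 1}" for k in range(dims)]
    )
    out.index.name = "sample_id"
    return out
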