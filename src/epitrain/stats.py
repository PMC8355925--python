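"""Multiple-testing adjustment shared by all feature-level tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

METHODS = ("BH", "Bonferroni")


@dataclass(frozen=True)
class AdjustedPValues:
    """Raw and adjusted p-values with the adjustment method used."""

    p: np.ndarray
    q: np.ndarray
    method: str


def adjust_pvalues(p, method: str = "BH") -> AdjustedPValues:
    """Benjamini-Hochberg step-up or Bonferroni adjustment.

    BH: ``q_i = min_{j: p_j >= p_i} m * p_j / rank_j`` capped at 1, which is
    the usual "sort, scale by m/rank, cumulative-min from the largest"
    recipe and is invariant to the input ordering.
    Bonferroni: ``q_i = min(1, m * p_i)``.

    Raises ``ValueError`` for p outside [0, 1] (NaN included: callers mask
    untested features before adjusting).
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if p.size == 0:
        return AdjustedPValues(p=p, q=p.copy(), method=method)
    if not np.all((p >= 0) & (p <= 1)):
        raise ValueError("all p-values must lie in [0, 1]")
    m = p.size
    if method == "Bonferroni":
        q = np.minimum(p * m, 1.0)
    else:
        order = np.argsort(p, kind="stable")
        scaled = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
        q = np.empty(m)
        q[order] = q_sorted
    return AdjustedPValues(p=p, q=q, method=method)
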