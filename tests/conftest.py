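"""Shared fixtures: paired-design count matrices and small studies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from epitrain.counts import CountMatrix
from epitrain.simulate import SimulationConfig


def paired_design(n_participants: int, library_sizes=None) -> tuple[list[str], pd.DataFrame]:
    """Sample ids and design frame for a pre/post paired study."""
    ids, rows = [], []
    for i in range(1, n_participants + 1):
        for training, tag in ((0, "pre"), (1, "post")):
            sid = f"P{i}_{tag}"
            ids.append(sid)
            rows.append((sid, f"P{i}", training))
    design = pd.DataFrame(rows, columns=["sample_id", "participant", "training"])
    design = design.set_index("sample_id")
    if library_sizes is None:
        library_sizes = np.full(len(ids), 1_000_000)
    design["library_size"] = library_sizes
    return ids, design


def make_counts(counts: np.ndarray, n_participants: int, library_sizes=None) -> CountMatrix:
    ids, design = paired_design(n_participants, library_sizes)
    features = [f"f{i:04d}" for i in range(counts.shape[0])]
    return CountMatrix(features, ids, counts, design)


def simulate_null_counts(seed: int, n_features: int, n_participants: int = 8,
                         dispersion: float = 0.1) -> CountMatrix:
    """NB counts with participant effects but no training effect."""
    rng = np.random.default_rng(seed)
    ids, design = paired_design(n_participants)
    libs = rng.integers(800_000, 1_200_001, len(ids))
    design["library_size"] = libs
    w = rng.lognormal(0, 1, n_features)
    w /= w.sum()
    pe = rng.normal(0, 0.3, n_participants)
    pidx = np.repeat(np.arange(n_participants), 2)
    mu = w[:, None] * libs[None, :] * np.exp(pe[pidx][None, :])
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    return CountMatrix([f"f{i:04d}" for i in range(n_features)], ids, counts, design)


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """A small study used by smoke tests across modules."""
    return SimulationConfig(
        seed=11, n_regions=160, n_genes=150, n_snps=1500, n_blocks=480
    )
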