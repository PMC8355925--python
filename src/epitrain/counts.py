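"""Count-matrix container for the paired pre/post training design.

Both the H3K27ac region counts and the gene-level RNA counts are
features x samples matrices of non-negative integers with a per-sample
design: participant id, training status (0 untrained / 1 trained) and
library size (total sequencing depth, used as a log offset; it need not
equal the column sum because reads fall outside counted features too).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DESIGN_COLUMNS = ("participant", "training", "library_size")


@dataclass
class CountMatrix:
    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_features, n_samples) non-negative integers
    design: pd.DataFrame  # indexed by sample_id, columns DESIGN_COLUMNS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        missing = [c for c in DESIGN_COLUMNS if c not in self.design.columns]
        if missing:
            raise ValueError(f"design is missing columns: {missing}")
        if list(self.design.index) != list(self.sample_ids):
            self.design = self.design.loc[self.sample_ids]
        bad = set(self.design["training"]) - {0, 1}
        if bad:
            raise ValueError(f"training must be 0/1, found {sorted(bad)}")
        if np.any(self.design["library_size"].to_numpy() <= 0):
            raise ValueError("library sizes must be positive")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def require_paired(self) -> None:
        """Raise if any participant lacks a pre- or post-training sample."""
        states = self.design.groupby("participant")["training"].agg(lambda s: set(s))
        offenders = sorted(states.index[states != {0, 1}])
        if offenders:
            raise ValueError(
                "unpaired participants (need training 0 and 1): "
                + ", ".join(map(str, offenders))
            )

    def cpm(self) -> np.ndarray:
        """Counts per million, using design library sizes."""
        lib = self.design["library_size"].to_numpy(dtype=float)
        return self.counts / lib[None, :] * 1e6

    def subset_features(self, keep: list[str]) -> "CountMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in keep if f not in idx]
        if missing:
            raise KeyError(f"unknown feature ids: {missing[:5]}")
        rows = [idx[f] for f in keep]
        return CountMatrix(list(keep), list(self.sample_ids), self.counts[rows], self.design.copy())

    def to_tsv(self, counts_path: str | Path, design_path: str | Path) -> None:
        df = pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)
        df.index.name = "feature_id"
        df.to_csv(counts_path, sep="\t")
        out = self.design.copy()
        out.index.name = "sample_id"
        out.to_csv(design_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, design_path: str | Path) -> "CountMatrix":
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t", index_col=0)
        counts = df.to_numpy()
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError(f"{counts_path}: counts must be integers")
            counts = counts.astype(np.int64)
        return cls(list(df.index), list(df.columns), counts, design)
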