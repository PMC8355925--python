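"""Genomic interval primitives and BED I/O.

Every coordinate inside the package is 0-based, half-open (the BED
convention): an interval [start, end) covers ``end - start`` bases.
External 1-based inclusive spans (browser-style ``chr13:59341171-59343427``,
GWAS-catalog positions) must be converted at the parser boundary, never
downstream.  Strand is ignored throughout; the overlap rule used by the
pipeline (a single shared base suffices) is strand-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name; must be nonempty.
    start, end : int
        0-based half-open coordinates with ``0 <= start < end``.
    name : str, optional
        Feature identifier (BED column 4).
    score : float, optional
        Feature score (BED column 5).
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a nonempty string")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "start must be strictly less than end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def id(self) -> str:
        """Name if set, else a coordinate string."""
        return self.name if self.name is not None else f"{self.chrom}:{self.start}-{self.end}"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff ``a`` and ``b`` share at least one base.

    Half-open semantics: abutting intervals ([100,200) vs [200,300)) do not
    overlap; intervals on different chromosomes never overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3/BED5 file into a list of intervals, preserving file order.

    Raises a :class:`ValueError` naming the offending line number on a
    malformed line or inverted coordinates.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                score = float(fields[4])
            try:
                out.append(GenomicInterval(chrom, start, end, name=name, score=score))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    """Write intervals as BED.

    Emits 3 columns when no interval carries a name or score (so a BED3
    round-trip is byte-identical), otherwise 4 or 5 columns with ``.``
    placeholders.
    """
    ivs = list(intervals)
    has_name = any(iv.name is not None for iv in ivs)
    has_score = any(iv.score is not None for iv in ivs)
    with open(path, "w") as fh:
        for iv in ivs:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if has_name or has_score:
                fields.append(iv.name if iv.name is not None else ".")
            if has_score:
                fields.append(format(iv.score, "g") if iv.score is not None else ".")
            fh.write("\t".join(fields) + "\n")


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: merged, sorted by (chrom, start); names dropped."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def overlap_join(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> list[list[int]]:
    """For each query interval, indices of subject intervals sharing >=1 base."""
    trees: dict[str, IntervalTree] = {}
    for j, iv in enumerate(subject):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)
    hits: list[list[int]] = []
    for q in query:
        tree = trees.get(q.chrom)
        if tree is None:
            hits.append([])
        else:
            hits.append(sorted(h.data for h in tree.overlap(q.start, q.end)))
    return hits


def positions_in(
    chroms: np.ndarray, pos: np.ndarray, intervals: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean mask: does each 0-based position fall inside any interval?

    A position ``p`` is inside ``[start, end)`` iff ``start <= p < end``.
    Intervals are merged per chromosome first, so the test is a pair of
    searchsorted lookups regardless of overlaps in the input.
    """
    chroms = np.asarray(chroms)
    pos = np.asarray(pos)
    merged = merge_intervals(list(intervals)) if len(intervals) else []
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, ([], []))  # type: ignore[arg-type]
    starts_tmp: dict[str, list[int]] = {}
    ends_tmp: dict[str, list[int]] = {}
    for iv in merged:
        starts_tmp.setdefault(iv.chrom, []).append(iv.start)
        ends_tmp.setdefault(iv.chrom, []).append(iv.end)
    inside = np.zeros(pos.shape[0], dtype=bool)
    for chrom, starts in starts_tmp.items():
        mask = chroms == chrom
        if not mask.any():
            continue
        s = np.asarray(starts)
        e = np.asarray(ends_tmp[chrom])
        idx = np.searchsorted(s, pos[mask], side="right") - 1
        ok = idx >= 0
        hit = np.zeros(ok.shape, dtype=bool)
        hit[ok] = pos[mask][ok] < e[idx[ok]]
        inside[mask] = hit
    return inside
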