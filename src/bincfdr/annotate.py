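"""SNP-vs-BED overlap: turn an annotation track into a binary covariate.

Coordinate conventions: SNP positions are 1-based (GWAS summary-statistic
convention); BED intervals are 0-based half-open ``[start, end)``.  The
conversion happens only here.  Annotations are strand-agnostic and overlap is
by union — overlapping intervals are allowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from intervaltree import IntervalTree

__all__ = ["AnnotationTrack", "annotate_with_bed"]


@dataclass
class AnnotationTrack:
    """A set of genomic intervals (BED convention) indexed per chromosome."""

    trees: dict = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple]) -> "AnnotationTrack":
        """Build from (chrom, start, end) triples; start < end required."""
        trees: dict = {}
        for chrom, start, end in intervals:
            start, end = int(start), int(end)
            if start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}: start >= end")
            trees.setdefault(str(chrom), IntervalTree()).addi(start, end)
        return cls(trees=trees)

    @classmethod
    def from_bed(cls, path) -> "AnnotationTrack":
        """Parse a BED3(+) file; malformed lines raise with their line number."""
        intervals = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: expected >= 3 tab-separated BED columns"
                    )
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: non-integer BED coordinates"
                    ) from exc
                if start >= end:
                    raise ValueError(f"{path}:{lineno}: start >= end")
                intervals.append((parts[0], start, end))
        return cls.from_intervals(intervals)

    def __len__(self) -> int:
        return sum(len(t) for t in self.trees.values())


def annotate_with_bed(
    chrom: np.ndarray, pos: np.ndarray, track: AnnotationTrack
) -> np.ndarray:
    """Binary overlap vector: 1 iff the SNP's 0-based coordinate lies in the track.

    ``pos`` is 1-based; a SNP at 1-based position P overlaps interval
    [start, end) iff start <= P-1 < end.
    """
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    if chrom.shape != pos.shape:
        raise ValueError("chrom and pos must have the same length")
    q = np.zeros(pos.size, dtype=np.int8)
    for i in range(pos.size):
        tree = track.trees.get(str(chrom[i]))
        if tree is not None and tree.overlaps_point(int(pos[i]) - 1):
            q[i] = 1
    return q
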