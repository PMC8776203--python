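"""BED interval I/O and peak-gene colocalization within a TAD-scale window.

Coordinates are BED convention throughout: 0-based, half-open [start, end).
Colocalization anchors each gene at its TSS-equivalent interval edge (start
on the + strand, end-1 on the -), finds the nearest peak edge on the same
chromosome and flags genes whose nearest peak lies within a configurable
window — default 1 Mb, half the canonical 2 Mb upper bound on the size of a
topologically associated domain, the genomic unit bounding enhancer-promoter
regulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_WINDOW_BP = 1_000_000


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval (BED semantics)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def anchor(self) -> int:
        """TSS-equivalent position: start on +/unstranded, last base on -."""
        return self.start if self.strand in ("+", ".") else self.end - 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6; invalid coordinates raise with the offending line number."""
    out: list[GenomicInterval] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ValueError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            out.append(
                GenomicInterval(
                    chrom=fields[0],
                    start=start,
                    end=end,
                    name=fields[3] if len(fields) > 3 else ".",
                    score=float(fields[4]) if len(fields) > 4 else 0.0,
                    strand=fields[5] if len(fields) > 5 else "+",
                )
            )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED6 (lossless round-trip with :func:`read_bed`)."""
    with open(path, "w", encoding="utf-8") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


def _signed_distance(anchor: int, start: int, end: int) -> int:
    """Signed anchor-to-nearest-edge distance; 0 when the anchor lies in the peak."""
    if anchor < start:
        return start - anchor
    if anchor > end - 1:
        return (end - 1) - anchor
    return 0


def colocalize(
    genes: Sequence[GenomicInterval],
    peaks: Sequence[GenomicInterval],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """Nearest peak per gene (same chromosome) with a within-window flag.

    The sweep sorts each chromosome's peaks once and uses binary search plus
    a running maximum of peak ends, so overlapping peaks are handled; genes
    on chromosomes without peaks get an empty ``nearest_peak`` and a null
    distance.  The signed distance is positive for a peak downstream of the
    anchor (in reference orientation), negative upstream, zero for overlap.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[GenomicInterval]]] = {}
    for chrom in {p.chrom for p in peaks}:
        ps = sorted((p for p in peaks if p.chrom == chrom), key=lambda p: (p.start, p.end))
        starts = np.array([p.start for p in ps])
        ends = np.array([p.end for p in ps])
        by_chrom[chrom] = (starts, ends, ps)
    rows = []
    for g in genes:
        a = g.anchor
        entry = by_chrom.get(g.chrom)
        nearest: GenomicInterval | None = None
        if entry is not None:
            starts, ends, ps = entry
            j = int(np.searchsorted(starts, a, side="right"))
            candidates: list[int] = []
            if j < len(ps):
                candidates.append(j)  # nearest peak starting at/after the anchor
            if j > 0:
                # best peak starting before the anchor: the one reaching furthest right
                left = int(np.argmax(ends[:j]))
                candidates.append(left)
            best = min(candidates, key=lambda i: abs(_signed_distance(a, starts[i], ends[i])))
            nearest = ps[best]
        if nearest is None:
            rows.append(
                {"gene": g.name, "nearest_peak": "", "distance_bp": np.nan, "within_window": False}
            )
        else:
            d = _signed_distance(a, nearest.start, nearest.end)
            rows.append(
                {
                    "gene": g.name,
                    "nearest_peak": nearest.name,
                    "distance_bp": float(d),
                    "within_window": abs(d) <= window_bp,
                }
            )
    return pd.DataFrame(rows, columns=["gene", "nearest_peak", "distance_bp", "within_window"])


def count_region_peaks(region: GenomicInterval, peaks: Iterable[GenomicInterval]) -> int:
    """Number of peaks overlapping the region (half-open overlap)."""
    return sum(1 for p in peaks if region.overlaps(p))
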