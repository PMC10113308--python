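"""Genomic intervals and the overlap/flank/distance engine.

All internal coordinates are 0-based half-open ``[start, end)``. GFF3 input
(1-based inclusive) is converted at the I/O boundary. Overlap requires at
least one shared base under half-open semantics, so ``(0, 100)`` and
``(100, 200)`` do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval, sortable by (chrom, start, end)."""

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance(self, other: "GenomicInterval") -> int | None:
        """Gap between nearest ends; 0 if overlapping; None across chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


@dataclass(frozen=True)
class GeneModel:
    """Gene with strand-aware 1-kbp promoter and exon/intron structure."""

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()
    promoter_bp: int = 1000

    def __post_init__(self) -> None:
        for ex in self.exons:
            if ex.chrom != self.interval.chrom or ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"exon {ex} outside gene {self.gene_id} span")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def promoter(self) -> GenomicInterval | None:
        """1 kbp upstream of the strand-aware gene start, clipped at 0.

        Returns None when the gene starts at the chromosome edge and the
        promoter would be empty (minus-strand clipping is the caller's
        concern: chromosome length is unknown here, so the downstream flank
        of minus-strand genes is emitted unclipped on the right).
        """
        iv = self.interval
        if iv.strand == "-":
            return GenomicInterval(iv.chrom, iv.end, iv.end + self.promoter_bp, iv.strand)
        start = max(0, iv.start - self.promoter_bp)
        if start == iv.start:
            return None
        return GenomicInterval(iv.chrom, start, iv.start, iv.strand)

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        if len(self.exons) < 2:
            return ()
        exs = sorted(self.exons, key=lambda e: e.start)
        out = []
        for a, b in zip(exs, exs[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(a.chrom, a.end, b.start, self.interval.strand))
        return tuple(out)


def _by_chrom(intervals: Sequence[GenomicInterval]) -> dict[str, list[tuple[int, GenomicInterval]]]:
    d: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for i, iv in enumerate(intervals):
        d.setdefault(iv.chrom, []).append((i, iv))
    return d


def intersect(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """All overlapping pairs (>=1 shared bp), sorted deterministically.

    Sweep per chromosome: b sorted by start, numpy mask on ends. Output is
    sorted by (a, b) interval order.
    """
    pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
    bmap = _by_chrom(b)
    for chrom, alist in _by_chrom(a).items():
        blist = bmap.get(chrom)
        if not blist:
            continue
        bsorted = sorted((iv for _, iv in blist), key=lambda iv: (iv.start, iv.end))
        bstarts = np.array([iv.start for iv in bsorted])
        bends = np.array([iv.end for iv in bsorted])
        for _, av in alist:
            hi = int(np.searchsorted(bstarts, av.end, side="left"))
            if hi == 0:
                continue
            mask = bends[:hi] > av.start
            pairs.extend((av, bsorted[j]) for j in np.nonzero(mask)[0])
    pairs.sort(key=lambda p: (p[0].chrom, p[0].start, p[0].end, p[1].start, p[1].end))
    return pairs


def overlaps_any(
    query: Sequence[GenomicInterval], targets: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean vector: does query[i] overlap any target interval."""
    out = np.zeros(len(query), dtype=bool)
    tmap = _by_chrom(targets)
    for chrom, qlist in _by_chrom(query).items():
        tlist = tmap.get(chrom)
        if not tlist:
            continue
        tsorted = sorted((iv for _, iv in tlist), key=lambda iv: iv.start)
        tstarts = np.array([iv.start for iv in tsorted])
        tends = np.array([iv.end for iv in tsorted])
        # running maximum of ends lets a single binary search suffice
        tmax = np.maximum.accumulate(tends)
        for i, qv in qlist:
            hi = int(np.searchsorted(tstarts, qv.end, side="left"))
            out[i] = hi > 0 and tmax[hi - 1] > qv.start
    return out


def flanks(
    gene: GenomicInterval,
    distance_bp: int = 5000,
    chrom_length: int | None = None,
) -> list[GenomicInterval]:
    """Upstream and downstream flanks, clipped at chromosome bounds.

    Flanks exclude the gene body; an empty flank (gene at an edge) is
    omitted rather than raising.
    """
    if distance_bp <= 0:
        raise ValueError("distance_bp must be positive")
    out = []
    up_start = max(0, gene.start - distance_bp)
    if up_start < gene.start:
        out.append(GenomicInterval(gene.chrom, up_start, gene.start))
    down_end = gene.end + distance_bp
    if chrom_length is not None:
        down_end = min(down_end, chrom_length)
    if down_end > gene.end:
        out.append(GenomicInterval(gene.chrom, gene.end, down_end))
    return out


def nearest_gene_distance(
    regions: Sequence[GenomicInterval], genes: Sequence[GeneModel]
) -> list[tuple[int | None, str | None]]:
    """Distance to the closest gene per region (0 if overlapping).

    Ties are broken toward the lexicographically smaller gene ID. Regions on
    chromosomes without genes get (None, None).
    """
    gmap: dict[str, list[GeneModel]] = {}
    for g in genes:
        gmap.setdefault(g.interval.chrom, []).append(g)
    out: list[tuple[int | None, str | None]] = []
    for r in regions:
        best: tuple[int, str] | None = None
        for g in gmap.get(r.chrom, []):
            d = r.distance(g.interval)
            assert d is not None
            if best is None or d < best[0] or (d == best[0] and g.gene_id < best[1]):
                best = (d, g.gene_id)
        out.append(best if best is not None else (None, None))
    return out


def merge_adjacent(
    intervals: Iterable[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals separated by <= max_gap bp (0 merges touching ones)."""
    ivs = sorted(intervals)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and iv.chrom == merged[-1].chrom and iv.start - merged[-1].end <= max_gap:
            last = merged.pop()
            merged.append(GenomicInterval(last.chrom, last.start, max(last.end, iv.end)))
        else:
            merged.append(iv)
    return merged
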