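"""Closest transcription-start-site search and distance histograms.

One TSS entry per transcript: ``tx_start`` on the plus strand, ``tx_end - 1``
on the minus strand.  Entries are kept per chromosome in a sorted array and
the nearest one is found by binary search, ignoring strand for the distance.
Distances are signed genomically (query - TSS); on an exact tie the TSS with
the smaller coordinate wins, so results are deterministic.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .gene_model import Transcript

__all__ = [
    "TssEntry",
    "TssArray",
    "DistanceHistogram",
    "closest_tss",
    "tss_histogram",
]


@dataclass(frozen=True)
class TssEntry:
    pos: int
    transcript_id: str
    gene: str
    strand: str


class TssArray:
    """Per-chromosome ascending-sorted TSS positions with binary search."""

    def __init__(self) -> None:
        self._entries: dict[str, list[TssEntry]] = {}
        self._positions: dict[str, list[int]] = {}

    @classmethod
    def from_transcripts(cls, transcripts: Iterable[Transcript]) -> "TssArray":
        arr = cls()
        for t in transcripts:
            arr._entries.setdefault(t.chrom, []).append(
                TssEntry(t.tss(), t.id, t.gene, t.strand)
            )
        for chrom, entries in arr._entries.items():
            entries.sort(key=lambda e: (e.pos, e.transcript_id))
            arr._positions[chrom] = [e.pos for e in entries]
        return arr

    def __len__(self) -> int:
        return sum(len(v) for v in self._entries.values())

    def entries(self, chrom: str) -> Sequence[TssEntry]:
        return self._entries.get(chrom, ())

    def closest(self, chrom: str, pos: int) -> Optional[tuple[TssEntry, int]]:
        """(nearest entry, signed distance pos - tss) or None for an
        unknown chromosome / empty array."""
        positions = self._positions.get(chrom)
        if not positions:
            return None
        entries = self._entries[chrom]
        i = bisect_left(positions, pos)
        # candidates: nearest position left of pos, nearest at/right of pos;
        # within a run of identical positions the first entry (smallest
        # transcript id) represents the run
        best: Optional[TssEntry] = None
        if i > 0:
            best = entries[bisect_left(positions, positions[i - 1])]
        if i < len(entries):
            right = entries[i]
            # strictly smaller |distance| wins; ties keep the smaller tss_pos
            if best is None or abs(right.pos - pos) < abs(pos - best.pos):
                best = right
        assert best is not None
        return best, pos - best.pos


def closest_tss(pos: int, chrom: str, array: TssArray) -> Optional[tuple[TssEntry, int]]:
    return array.closest(chrom, pos)


@dataclass
class DistanceHistogram:
    """Signed-distance histogram with symmetric bins around zero.

    Bin k (for -n_bins <= k < n_bins) covers [k*bin_size, (k+1)*bin_size);
    distances with |d| >= bin_size*n_bins land in the under/overflow bins.
    """

    bin_size: int
    n_bins: int
    counts: list[int]  # length 2*n_bins, bin k at counts[k + n_bins]
    underflow: int = 0
    overflow: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts) + self.underflow + self.overflow

    def bin_edges(self, i: int) -> tuple[int, int]:
        k = i - self.n_bins
        return k * self.bin_size, (k + 1) * self.bin_size

    def to_lines(self) -> list[str]:
        lines = ["bin_start\tbin_end\tcount"]
        lines.append(f"<{-self.bin_size * self.n_bins}\t.\t{self.underflow}")
        for i, c in enumerate(self.counts):
            lo, hi = self.bin_edges(i)
            lines.append(f"{lo}\t{hi}\t{c}")
        lines.append(f">={self.bin_size * self.n_bins}\t.\t{self.overflow}")
        return lines


def tss_histogram(distances: Iterable[int], bin_size: int, n_bins: int) -> DistanceHistogram:
    if bin_size <= 0 or n_bins <= 0:
        raise ValueError("bin_size and n_bins must be positive")
    counts = [0] * (2 * n_bins)
    under = over = 0
    for d in distances:
        k = d // bin_size  # floor division keeps the half-open convention
        if k < -n_bins:
            under += 1
        elif k >= n_bins:
            over += 1
        else:
            counts[k + n_bins] += 1
    return DistanceHistogram(bin_size, n_bins, counts, under, over)
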