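"""Transcript models, generic genomic features and the reference genome.

All coordinates are 0-based half-open throughout the package, matching the
genePred/BED convention; PSL target coordinates already follow it and pass
through unchanged.  Query files on disk use 1-based positions and are
converted at the I/O boundary (see :mod:`segannot.native`).

Parsers never abort on a malformed row: the row is rejected with a logged
warning and parsing continues, because the intended inputs are large,
occasionally messy annotation tables.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from Bio.Seq import Seq
from Bio.Seq import reverse_complement as _bio_revcomp

log = logging.getLogger(__name__)

__all__ = [
    "Transcript",
    "GenericFeature",
    "Genome",
    "parse_genepred",
    "parse_bed",
    "parse_psl",
    "to_genepred_lines",
    "to_bed_lines",
    "to_psl_lines",
    "introns",
    "coding_sequence",
    "translate",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse-complement of a nucleotide string over {A,C,G,T,N}."""
    return _bio_revcomp(seq)


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass(eq=False)
class Transcript:
    """One splicing isoform of a gene.

    ``cds_start == cds_end`` signals a non-coding transcript.  Exons are
    ascending, disjoint, and tile ``[tx_start, tx_end)`` together with the
    introns between them.
    """

    id: str
    gene: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.id}: tx_start must be < tx_end")
        if not self.exons:
            raise ValueError(f"{self.id}: transcript needs at least one exon")
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"{self.id}: exon ({s},{e}) outside transcript span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.id}: exons unsorted or overlapping")
            prev_end = e
        if self.exons[0][0] != self.tx_start or self.exons[-1][1] != self.tx_end:
            raise ValueError(f"{self.id}: first/last exon must touch transcript bounds")
        if self.cds_start > self.cds_end:
            raise ValueError(f"{self.id}: cds_start must be <= cds_end")
        if self.is_coding:
            if not (self.tx_start <= self.cds_start and self.cds_end <= self.tx_end):
                raise ValueError(f"{self.id}: CDS outside transcript span")
            if not self._on_exon(self.cds_start) or not self._on_exon(self.cds_end):
                raise ValueError(f"{self.id}: CDS bounds must lie on exons")

    def _on_exon(self, pos: int) -> bool:
        # inside an exon or exactly at an exon boundary
        return any(s <= pos <= e for s, e in self.exons)

    # generic feature protocol used by the interval index
    @property
    def start(self) -> int:
        return self.tx_start

    @property
    def end(self) -> int:
        return self.tx_end

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end

    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, in ascending genomic order."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    def exon_ordinal(self, genomic_index: int) -> int:
        """1-based, strand-aware exon number (exon 1 is 5'-most)."""
        if self.strand == "+":
            return genomic_index + 1
        return len(self.exons) - genomic_index

    def intron_ordinal(self, genomic_index: int) -> int:
        if self.strand == "+":
            return genomic_index + 1
        return (len(self.exons) - 1) - genomic_index

    def tss(self) -> int:
        """Transcription start site: 5'-most transcribed base on the strand."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


@dataclass(eq=False)
class GenericFeature:
    """A strand-optional interval from BED or PSL, with optional sub-blocks."""

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    blocks: Optional[tuple[tuple[int, int], ...]] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"{self.id}: strand must be '+', '-' or '.'")
        if not self.start < self.end:
            raise ValueError(f"{self.id}: start must be < end")
        if self.blocks is not None:
            self.blocks = tuple((int(s), int(e)) for s, e in self.blocks)
            prev = None
            for s, e in self.blocks:
                if not (self.start <= s < e <= self.end):
                    raise ValueError(f"{self.id}: block ({s},{e}) outside feature span")
                if prev is not None and s < prev:
                    raise ValueError(f"{self.id}: blocks unsorted or overlapping")
                prev = e


class Genome:
    """chrom -> uppercase nucleotide sequence over {A,C,G,T,N}.

    Backed either by an in-memory mapping or by a FASTA file opened lazily
    through pyfaidx (per-chromosome access, wrapped or unwrapped records).
    """

    def __init__(self, seqs: Optional[Mapping[str, str]] = None):
        self._seqs: dict[str, str] = {c: s.upper() for c, s in (seqs or {}).items()}
        self._fasta = None

    @classmethod
    def from_fasta(cls, path: str) -> "Genome":
        import pyfaidx

        g = cls()
        g._fasta = pyfaidx.Fasta(str(path), sequence_always_upper=True)
        return g

    def __contains__(self, chrom: str) -> bool:
        if chrom in self._seqs:
            return True
        return self._fasta is not None and chrom in self._fasta

    def chroms(self) -> list[str]:
        names = list(self._seqs)
        if self._fasta is not None:
            names.extend(k for k in self._fasta.keys() if k not in self._seqs)
        return names

    def length(self, chrom: str) -> int:
        if chrom in self._seqs:
            return len(self._seqs[chrom])
        if self._fasta is not None and chrom in self._fasta:
            return len(self._fasta[chrom])
        raise KeyError(chrom)

    def sequence(self, chrom: str) -> str:
        """Full chromosome sequence (cached once read from FASTA)."""
        if chrom not in self._seqs:
            if self._fasta is None or chrom not in self._fasta:
                raise KeyError(chrom)
            self._seqs[chrom] = str(self._fasta[chrom][:]).upper()
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        n = self.length(chrom)
        if start < 0 or end > n or start > end:
            raise ValueError(
                f"fetch({chrom},{start},{end}) outside sequence of length {n}"
            )
        return self.sequence(chrom)[start:end]


# ---------------------------------------------------------------------------
# parsers


def _int_list(field: str) -> list[int]:
    return [int(x) for x in field.rstrip(",").split(",") if x != ""]


def parse_genepred(lines: Iterable[str]) -> list[Transcript]:
    """Parse UCSC genePred rows (with or without a leading bin column).

    The layout is auto-detected per row from the position of the strand
    column.  The gene symbol comes from the name2 column when the extended
    layout carries one, otherwise the transcript id is used.
    """
    out: list[Transcript] = []
    rejected = 0
    for lineno, raw in enumerate(lines, 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        try:
            out.append(_genepred_row(line.split("\t")))
        except (ValueError, IndexError) as exc:
            rejected += 1
            log.warning("genePred line %d rejected: %s", lineno, exc)
    if rejected:
        log.warning("genePred: %d row(s) rejected", rejected)
    return out


def _genepred_row(f: list[str]) -> Transcript:
    if len(f) >= 10 and f[2] in ("+", "-"):
        pass
    elif len(f) >= 11 and f[3] in ("+", "-"):
        f = f[1:]  # leading bin column
    else:
        raise ValueError("unrecognized genePred column layout")
    name, chrom, strand = f[0], f[1], f[2]
    tx_start, tx_end, cds_start, cds_end, exon_count = (int(x) for x in f[3:8])
    starts, ends = _int_list(f[8]), _int_list(f[9])
    if not (len(starts) == len(ends) == exon_count):
        raise ValueError(
            f"{name}: exonCount {exon_count} != list lengths {len(starts)}/{len(ends)}"
        )
    gene = name
    if len(f) >= 12 and f[11]:
        gene = f[11]  # genePredExt: score at 10, name2 at 11
    elif len(f) == 11 and f[10] and not f[10].lstrip("-").isdigit():
        gene = f[10]
    return Transcript(
        id=name,
        gene=gene,
        chrom=chrom,
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        cds_start=cds_start,
        cds_end=cds_end,
        exons=tuple(zip(starts, ends)),
    )


def to_genepred_lines(transcripts: Iterable[Transcript]) -> list[str]:
    """Serialize transcripts as 12-column extended genePred (score + name2)."""
    lines = []
    for t in transcripts:
        starts = "".join(f"{s}," for s, _ in t.exons)
        ends = "".join(f"{e}," for _, e in t.exons)
        lines.append(
            "\t".join(
                [
                    t.id,
                    t.chrom,
                    t.strand,
                    str(t.tx_start),
                    str(t.tx_end),
                    str(t.cds_start),
                    str(t.cds_end),
                    str(len(t.exons)),
                    starts,
                    ends,
                    "0",
                    t.gene,
                ]
            )
        )
    return lines


_BED_SKIP = re.compile(r"^(track\b|browser\b|#)")


def parse_bed(lines: Iterable[str]) -> list[GenericFeature]:
    """Parse BED3-BED12; track/browser/comment lines are skipped."""
    out: list[GenericFeature] = []
    rejected = 0
    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or _BED_SKIP.match(line):
            continue
        f = line.split()
        try:
            out.append(_bed_row(f))
        except (ValueError, IndexError) as exc:
            rejected += 1
            log.warning("BED line %d rejected: %s", lineno, exc)
    if rejected:
        log.warning("BED: %d row(s) rejected", rejected)
    return out


def _bed_row(f: list[str]) -> GenericFeature:
    chrom, start, end = f[0], int(f[1]), int(f[2])
    if start >= end:
        raise ValueError(f"chromStart {start} >= chromEnd {end}")
    name = f[3] if len(f) > 3 else f"{chrom}:{start}-{end}"
    strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
    blocks = None
    if len(f) >= 12:
        count = int(f[9])
        sizes, offsets = _int_list(f[10]), _int_list(f[11])
        if not (len(sizes) == len(offsets) == count):
            raise ValueError(f"{name}: blockCount mismatch")
        blocks = tuple((start + o, start + o + sz) for o, sz in zip(offsets, sizes))
    return GenericFeature(id=name, chrom=chrom, strand=strand, start=start, end=end, blocks=blocks)


def to_bed_lines(features: Iterable[GenericFeature]) -> list[str]:
    """BED6 for block-less features, BED12 otherwise."""
    lines = []
    for f in features:
        base = [f.chrom, str(f.start), str(f.end), f.id, "0", f.strand]
        if f.blocks is None:
            lines.append("\t".join(base))
        else:
            sizes = "".join(f"{e - s}," for s, e in f.blocks)
            offsets = "".join(f"{s - f.start}," for s, _ in f.blocks)
            lines.append(
                "\t".join(
                    base
                    + [str(f.start), str(f.end), "0", str(len(f.blocks)), sizes, offsets]
                )
            )
    return lines


def parse_psl(lines: Iterable[str]) -> list[GenericFeature]:
    """Parse 21-column PSL (optional header); target-side coordinates used.

    When the strand field has two characters the target character (second)
    is taken.  Minus-target coordinates are assumed already forward-mapped,
    as produced by common spliced aligners.
    """
    out: list[GenericFeature] = []
    rejected = 0
    for lineno, raw in enumerate(lines, 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        f = line.split("\t")
        if len(f) < 21 or not f[0].lstrip("-").isdigit():
            continue  # header / separator lines
        try:
            out.append(_psl_row(f))
        except (ValueError, IndexError) as exc:
            rejected += 1
            log.warning("PSL line %d rejected: %s", lineno, exc)
    if rejected:
        log.warning("PSL: %d row(s) rejected", rejected)
    return out


def _psl_row(f: list[str]) -> GenericFeature:
    strand_field = f[8]
    strand = strand_field[-1] if strand_field and strand_field[-1] in "+-" else "."
    qname, tname = f[9], f[13]
    t_start, t_end, block_count = int(f[15]), int(f[16]), int(f[17])
    sizes, t_starts = _int_list(f[18]), _int_list(f[20])
    if not (len(sizes) == len(t_starts) == block_count):
        raise ValueError(f"{qname}: blockCount mismatch")
    blocks = tuple((ts, ts + sz) for ts, sz in zip(t_starts, sizes))
    return GenericFeature(id=qname, chrom=tname, strand=strand, start=t_start, end=t_end, blocks=blocks)


def to_psl_lines(features: Iterable[GenericFeature]) -> list[str]:
    lines = []
    for f in features:
        blocks = f.blocks or ((f.start, f.end),)
        sizes = [e - s for s, e in blocks]
        q_size = sum(sizes)
        q_starts, acc = [], 0
        for sz in sizes:
            q_starts.append(acc)
            acc += sz
        strand = f.strand if f.strand in "+-" else "+"
        lines.append(
            "\t".join(
                str(x)
                for x in [
                    q_size, 0, 0, 0, 0, 0, 0, 0,
                    strand,
                    f.id, q_size, 0, q_size,
                    f.chrom, f.end, f.start, f.end,
                    len(blocks),
                    "".join(f"{sz}," for sz in sizes),
                    "".join(f"{qs}," for qs in q_starts),
                    "".join(f"{s}," for s, _ in blocks),
                ]
            )
        )
    return lines


# ---------------------------------------------------------------------------
# sequence-level operations


def introns(t: Transcript) -> tuple[tuple[int, int], ...]:
    return t.introns()


def coding_sequence(t: Transcript, genome: Genome) -> str:
    """Spliced CDS of a coding transcript, 5'->3' on the transcript strand."""
    if not t.is_coding:
        raise ValueError(f"{t.id} is non-coding (cds_start == cds_end)")
    if t.chrom not in genome:
        raise KeyError(f"chromosome {t.chrom!r} absent from genome")
    parts = []
    for s, e in t.exons:
        lo, hi = max(s, t.cds_start), min(e, t.cds_end)
        if lo < hi:
            parts.append(genome.fetch(t.chrom, lo, hi))
    cds = "".join(parts)
    if t.strand == "-":
        cds = reverse_complement(cds)
    return cds


def translate(cds: str) -> str:
    """Standard-genetic-code translation from offset 0.

    The stop is rendered '*' and translation halts at the first stop; a
    trailing partial codon is ignored; any codon containing N yields 'X'.
    """
    if len(cds) < 3:
        raise ValueError("need at least one full codon")
    trimmed = cds[: len(cds) // 3 * 3]
    aa = str(Seq(trimmed).translate())
    stop = aa.find("*")
    return aa[: stop + 1] if stop != -1 else aa
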