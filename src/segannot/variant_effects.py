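"""Consequence calling for SNVs, indels and translocations.

SNVs inside the CDS are resolved at the codon level: the variant's offset in
the spliced CDS is computed (strand-corrected), the affected codon is
substituted, and both codons are translated.  The full mutated protein is
produced by translating the substituted spliced CDS up to the first stop.

Indels are applied in spliced-CDS space: a deletion removes the
CDS-overlapping bases, an insertion lands at the spliced offset of its
genomic insertion point.  A net CDS length change that is not a multiple of
three is a frameshift.  Insertions are anchored *before* their 0-based
position, so an insertion at an exon's start coordinate falls in the
preceding intron while one at the exon's end coordinate extends the exon.

Translocation breakpoints are annotated like coordinates; when the retained
sides of two coding transcripts are compatible (one keeps its CDS 5' prefix,
the other its 3' suffix) a putative fusion protein is emitted by
concatenating the two spliced-CDS pieces and translating, the 3' piece read
in the frame implied by the 5' piece's length.

The splice-site rule is positional only: an intronic base at offset 1 or 2
from either junction is SPLICE_SITE; no attempt is made to predict altered
splice patterns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from .gene_model import (
    Genome,
    Transcript,
    coding_sequence,
    complement_base,
    reverse_complement,
    translate,
)
from .interval_index import IntervalIndex

log = logging.getLogger(__name__)

__all__ = [
    "Snv",
    "Indel",
    "Translocation",
    "ConsequenceCategory",
    "Consequence",
    "SnpCatalog",
    "snv_consequence",
    "indel_consequence",
    "translocation_annotation",
    "rank_consequences",
    "known_snp_lookup",
    "annotate_snvs",
    "annotate_indels",
    "annotate_translocations",
    "TranslocationResult",
    "VariantAnnotationResult",
    "SPLICE_WINDOW",
]

SPLICE_WINDOW = 2  # intronic bases adjacent to each junction called SPLICE_SITE
_BASES = frozenset("ACGT")


class ConsequenceCategory(str, Enum):
    NONSENSE = "NONSENSE"
    NONSYNONYMOUS = "NONSYNONYMOUS"
    SYNONYMOUS = "SYNONYMOUS"
    SPLICE_SITE = "SPLICE_SITE"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    NONCODING_EXON = "NONCODING_EXON"
    INTRON = "INTRON"
    UPSTREAM = "UPSTREAM"
    DOWNSTREAM = "DOWNSTREAM"
    FRAMESHIFT = "FRAMESHIFT"
    INFRAME_INDEL = "INFRAME_INDEL"
    INTERGENIC = "INTERGENIC"


# Highest impact first.  NONSENSE is split out above NONSYNONYMOUS as an
# extension; pass collapse_nonsense=True to fold it back for coarser tallies.
CONSEQUENCE_PRIORITY: dict[ConsequenceCategory, int] = {
    ConsequenceCategory.NONSENSE: 0,
    ConsequenceCategory.FRAMESHIFT: 1,
    ConsequenceCategory.NONSYNONYMOUS: 2,
    ConsequenceCategory.INFRAME_INDEL: 3,
    ConsequenceCategory.SYNONYMOUS: 4,
    ConsequenceCategory.SPLICE_SITE: 5,
    ConsequenceCategory.UTR5: 6,
    ConsequenceCategory.UTR3: 7,
    ConsequenceCategory.NONCODING_EXON: 8,
    ConsequenceCategory.INTRON: 9,
    ConsequenceCategory.UPSTREAM: 10,
    ConsequenceCategory.DOWNSTREAM: 11,
    ConsequenceCategory.INTERGENIC: 99,
}


@dataclass
class Snv:
    id: str
    chrom: str
    pos: int  # 0-based internal
    ref: str
    alt: str

    def __post_init__(self) -> None:
        self.ref, self.alt = self.ref.upper(), self.alt.upper()
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"{self.id}: alleles must be single A/C/G/T bases")
        if self.ref == self.alt:
            raise ValueError(f"{self.id}: ref and alt alleles are identical")


@dataclass
class Indel:
    id: str
    chrom: str
    pos: int  # DEL: first deleted base; INS: bases inserted before this position
    kind: str  # "INS" | "DEL"
    sequence: Optional[str] = None
    del_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("INS", "DEL"):
            raise ValueError(f"{self.id}: kind must be INS or DEL")
        if self.kind == "INS":
            if not self.sequence:
                raise ValueError(f"{self.id}: insertion needs a non-empty sequence")
            self.sequence = self.sequence.upper()
            if not set(self.sequence) <= _BASES:
                raise ValueError(f"{self.id}: inserted sequence must be A/C/G/T")
        else:
            if not self.del_length or self.del_length < 1:
                raise ValueError(f"{self.id}: deletion needs del_length >= 1")

    @property
    def span(self) -> tuple[int, int]:
        if self.kind == "DEL":
            return self.pos, self.pos + self.del_length
        return self.pos, self.pos + 1


@dataclass
class Translocation:
    id: str
    chrom_a: str
    pos_a: int
    side_a: str  # "5": genomic left of the breakpoint retained; "3": right
    chrom_b: str
    pos_b: int
    side_b: str

    def __post_init__(self) -> None:
        for side in (self.side_a, self.side_b):
            if side not in ("5", "3"):
                raise ValueError(f"{self.id}: side must be '5' or '3'")
        if (self.chrom_a, self.pos_a) == (self.chrom_b, self.pos_b):
            raise ValueError(f"{self.id}: breakpoints must be distinct positions")


@dataclass
class Consequence:
    query_id: str
    transcript_id: str
    gene: str
    category: ConsequenceCategory
    aa_change: Optional[tuple[str, int, str]] = None  # (ref_aa, 1-based pos, alt_aa)
    mutated_protein: Optional[str] = None
    known_id: Optional[str] = None
    ref_mismatch: bool = False
    distance: int = 0
    splice_flag: bool = False  # indel additionally touches a splice window

    @property
    def rank(self) -> int:
        return CONSEQUENCE_PRIORITY[self.category]

    def sort_key(self) -> tuple:
        return (self.rank, self.gene, self.transcript_id)

    @property
    def aa_change_str(self) -> str:
        if self.aa_change is None:
            return ""
        ref_aa, pos, alt_aa = self.aa_change
        return f"{ref_aa}{pos}{alt_aa}"


# ---------------------------------------------------------------------------
# CDS geometry helpers


def _cds_info(t: Transcript, genome: Genome) -> tuple[str, tuple[tuple[int, int], ...]]:
    """(spliced CDS string, ascending exon-CDS genomic segments), cached."""
    cached = getattr(t, "_segannot_cds", None)
    if cached is not None and cached[0] is genome:
        return cached[1], cached[2]
    cds = coding_sequence(t, genome)
    segs = tuple(
        (max(s, t.cds_start), min(e, t.cds_end))
        for s, e in t.exons
        if max(s, t.cds_start) < min(e, t.cds_end)
    )
    t._segannot_cds = (genome, cds, segs)
    return cds, segs


def _plus_offset(segs: Sequence[tuple[int, int]], pos: int) -> Optional[int]:
    """Offset of genomic pos within the CDS counted on the + strand."""
    acc = 0
    for s, e in segs:
        if pos >= e:
            acc += e - s
        elif pos >= s:
            return acc + (pos - s)
        else:
            return None
    return None


def _count_before(segs: Sequence[tuple[int, int]], pos: int) -> int:
    """Number of CDS bases at genomic coordinates < pos."""
    return sum(max(0, min(pos, e) - s) for s, e in segs)


def _splice_positions(t: Transcript) -> set[int]:
    out: set[int] = set()
    for s, e in t.introns():
        out.update(range(s, min(s + SPLICE_WINDOW, e)))
        out.update(range(max(e - SPLICE_WINDOW, s), e))
    return out


def _location_category(
    pos: int, t: Transcript, range_bp: int
) -> Optional[tuple[ConsequenceCategory, int]]:
    """Non-CDS placement of a single base: (category, distance) or None."""
    if t.tx_start <= pos < t.tx_end:
        in_exon = any(s <= pos < e for s, e in t.exons)
        if in_exon:
            if not t.is_coding:
                return ConsequenceCategory.NONCODING_EXON, 0
            if pos < t.cds_start:
                cat = ConsequenceCategory.UTR5 if t.strand == "+" else ConsequenceCategory.UTR3
            elif pos >= t.cds_end:
                cat = ConsequenceCategory.UTR3 if t.strand == "+" else ConsequenceCategory.UTR5
            else:
                return None  # CDS base; caller handles codon-level logic
            return cat, 0
        if pos in _splice_positions(t):
            return ConsequenceCategory.SPLICE_SITE, 0
        return ConsequenceCategory.INTRON, 0
    if pos < t.tx_start:
        dist = t.tx_start - pos
        if dist <= range_bp:
            cat = (
                ConsequenceCategory.UPSTREAM
                if t.strand == "+"
                else ConsequenceCategory.DOWNSTREAM
            )
            return cat, dist
        return None
    dist = pos - t.tx_end + 1
    if dist <= range_bp:
        cat = (
            ConsequenceCategory.DOWNSTREAM
            if t.strand == "+"
            else ConsequenceCategory.UPSTREAM
        )
        return cat, dist
    return None


def _strip_stop(protein: str) -> str:
    return protein[:-1] if protein.endswith("*") else protein


def _is_cds_base(t: Transcript, p: int) -> bool:
    return (
        t.is_coding
        and t.cds_start <= p < t.cds_end
        and any(s <= p < e for s, e in t.exons)
    )


# ---------------------------------------------------------------------------
# SNVs


def snv_consequence(
    snv: Snv,
    t: Transcript,
    genome: Genome,
    range_bp: int = 10_000,
    collapse_nonsense: bool = False,
) -> Optional[Consequence]:
    """Consequence of one SNV on one transcript, or None when out of range.

    A ref allele that disagrees with the genome is flagged but the call
    proceeds using the genome base as the reference.
    """
    if snv.chrom not in genome:
        raise KeyError(f"chromosome {snv.chrom!r} absent from genome")
    genome_base = genome.fetch(snv.chrom, snv.pos, snv.pos + 1)
    mismatch = genome_base != snv.ref

    in_cds = (
        t.is_coding
        and t.cds_start <= snv.pos < t.cds_end
        and any(s <= snv.pos < e for s, e in t.exons)
    )
    if in_cds:
        cds, segs = _cds_info(t, genome)
        plus_off = _plus_offset(segs, snv.pos)
        off = plus_off if t.strand == "+" else len(cds) - 1 - plus_off
        alt = snv.alt if t.strand == "+" else complement_base(snv.alt)
        codon_i, within = divmod(off, 3)
        ref_codon = cds[3 * codon_i : 3 * codon_i + 3]
        if len(ref_codon) < 3:
            # CDS length not a multiple of 3 and the hit lands in the stub
            return _fallback_noncodon(snv, t, range_bp, mismatch)
        alt_codon = ref_codon[:within] + alt + ref_codon[within + 1 :]
        ref_aa = translate(ref_codon)
        alt_aa = translate(alt_codon)
        if alt_aa == ref_aa:
            cat = ConsequenceCategory.SYNONYMOUS
        elif alt_aa == "*":
            cat = (
                ConsequenceCategory.NONSYNONYMOUS
                if collapse_nonsense
                else ConsequenceCategory.NONSENSE
            )
        else:
            cat = ConsequenceCategory.NONSYNONYMOUS
        mutant_cds = cds[:off] + alt + cds[off + 1 :]
        protein = _strip_stop(translate(mutant_cds)) if len(mutant_cds) >= 3 else None
        return Consequence(
            snv.id, t.id, t.gene, cat,
            aa_change=(ref_aa, codon_i + 1, alt_aa),
            mutated_protein=protein,
            ref_mismatch=mismatch,
        )
    return _fallback_noncodon(snv, t, range_bp, mismatch)


def _fallback_noncodon(
    snv: Snv, t: Transcript, range_bp: int, mismatch: bool
) -> Optional[Consequence]:
    loc = _location_category(snv.pos, t, range_bp)
    if loc is None:
        return None
    cat, dist = loc
    return Consequence(snv.id, t.id, t.gene, cat, distance=dist, ref_mismatch=mismatch)


def rank_consequences(records: Sequence[Consequence]) -> list[Consequence]:
    """Order records by decreasing protein impact; deterministic tie-break."""
    return sorted(records, key=Consequence.sort_key)


# ---------------------------------------------------------------------------
# indels


def indel_consequence(
    indel: Indel,
    t: Transcript,
    genome: Genome,
    range_bp: int = 10_000,
) -> Optional[Consequence]:
    """Consequence of a small insertion or deletion on one transcript."""
    if indel.chrom not in genome:
        raise KeyError(f"chromosome {indel.chrom!r} absent from genome")
    splice = _splice_positions(t)
    if t.is_coding:
        cds, segs = _cds_info(t, genome)
        if indel.kind == "DEL":
            d_start, d_end = indel.span
            plus_offsets = [
                _plus_offset(segs, p)
                for p in range(max(d_start, t.cds_start), min(d_end, t.cds_end))
            ]
            hit = [o for o in plus_offsets if o is not None]
            if hit:
                if t.strand == "-":
                    hit = [len(cds) - 1 - o for o in hit]
                drop = set(hit)
                mutant = "".join(c for i, c in enumerate(cds) if i not in drop)
                delta = -len(drop)
                touches_splice = any(d_start <= p < d_end for p in splice)
                return _cds_indel_record(indel, t, mutant, delta, touches_splice)
        else:
            pos = indel.pos
            in_cds_point = any(s < pos <= e for s, e in segs)
            if in_cds_point:
                k_plus = _count_before(segs, pos)
                if t.strand == "+":
                    off, ins = k_plus, indel.sequence
                else:
                    off, ins = len(cds) - k_plus, reverse_complement(indel.sequence)
                mutant = cds[:off] + ins + cds[off:]
                delta = len(indel.sequence)
                near = min(
                    (abs(pos - b) for s, e in t.introns() for b in (s, e)),
                    default=10**9,
                )
                return _cds_indel_record(indel, t, mutant, delta, near <= SPLICE_WINDOW)
    # Non-CDS placement: best single-base location across the edited span.
    # An insertion sits between two bases; when it is flush against the CDS
    # edge (no protein change) the non-CDS flanking base is classified.
    if indel.kind == "INS":
        candidates = [
            p for p in (indel.pos, indel.pos - 1)
            if p >= 0 and not _is_cds_base(t, p)
        ]
    else:
        candidates = list(range(*indel.span))
    best: Optional[tuple[ConsequenceCategory, int]] = None
    for p in candidates:
        loc = _location_category(p, t, range_bp)
        if loc is not None and (
            best is None or CONSEQUENCE_PRIORITY[loc[0]] < CONSEQUENCE_PRIORITY[best[0]]
        ):
            best = loc
    if best is None:
        return None
    cat, dist = best
    return Consequence(indel.id, t.id, t.gene, cat, distance=dist)


def _cds_indel_record(
    indel: Indel, t: Transcript, mutant_cds: str, delta: int, splice_flag: bool
) -> Consequence:
    cat = (
        ConsequenceCategory.INFRAME_INDEL
        if delta % 3 == 0
        else ConsequenceCategory.FRAMESHIFT
    )
    protein = _strip_stop(translate(mutant_cds)) if len(mutant_cds) >= 3 else None
    return Consequence(
        indel.id, t.id, t.gene, cat, mutated_protein=protein, splice_flag=splice_flag
    )


# ---------------------------------------------------------------------------
# translocations


@dataclass
class TranslocationResult:
    query_id: str
    records_a: list  # AnnotationRecord per overlapping transcript, ranked
    records_b: list
    fusion_protein: Optional[str] = None
    fusion_partners: Optional[tuple[str, str]] = None  # (5' transcript, 3' transcript)


def _retained_cds_counts(
    t: Transcript, genome: Genome, pos: int, genomic_side: str
) -> tuple[int, int]:
    """(prefix_len, suffix_len): CDS bases retained at the transcript's
    5' start and 3' end respectively, given the retained genomic side
    ('5' keeps coordinates <= pos, '3' keeps coordinates >= pos).  One of
    the two is always 0."""
    cds, segs = _cds_info(t, genome)
    n = len(cds)
    le = sum(max(0, min(pos + 1, e) - s) for s, e in segs)  # CDS bases <= pos
    lt = _count_before(segs, pos)                           # CDS bases <  pos
    if genomic_side == "5":
        return (le, 0) if t.strand == "+" else (0, le)
    return (0, n - lt) if t.strand == "+" else (n - lt, 0)


def translocation_annotation(
    tr: Translocation,
    index: IntervalIndex,
    genome: Optional[Genome],
    range_bp: int = 10_000,
) -> TranslocationResult:
    """Annotate both breakpoints; emit a putative fusion protein when the
    retained sides of two coding transcripts are compatible.

    Each breakpoint is classified exactly like a coordinate query (EXON,
    INTRON, UPSTREAM, DOWNSTREAM records per overlapping transcript)."""
    from .annotator import AnnotationRecord, classify_coordinate

    sides = []
    for chrom, pos, side in (
        (tr.chrom_a, tr.pos_a, tr.side_a),
        (tr.chrom_b, tr.pos_b, tr.side_b),
    ):
        hits = [h for h in index.range_query(chrom, max(0, pos - range_bp), pos + range_bp + 1)
                if isinstance(h, Transcript)]
        records = []
        for t in hits:
            rec = classify_coordinate(pos, t, range_bp, query_id=tr.id)
            if rec is not None:
                records.append(rec)
        records.sort(key=AnnotationRecord.sort_key)
        sides.append((chrom, pos, side, hits, records))

    fusion = partners = None
    if genome is not None:
        candidates = []
        for (ca, pa, sa, hits_a, _), (cb, pb, sb, hits_b, _) in (
            (sides[0], sides[1]),
            (sides[1], sides[0]),
        ):
            five = _cds_partners(hits_a, genome, pa, sa, want="prefix")
            three = _cds_partners(hits_b, genome, pb, sb, want="suffix")
            if five and three:
                candidates.append((five[0], three[0]))
        if candidates:
            (t5, k5), (t3, k3) = candidates[0]
            cds5, _ = _cds_info(t5, genome)
            cds3, _ = _cds_info(t3, genome)
            fusion_cds = cds5[:k5] + cds3[len(cds3) - k3 :]
            if len(fusion_cds) >= 3:
                fusion = _strip_stop(translate(fusion_cds))
                partners = (t5.id, t3.id)
    return TranslocationResult(
        tr.id, sides[0][4], sides[1][4], fusion_protein=fusion, fusion_partners=partners
    )


def _cds_partners(
    hits: Sequence[Transcript], genome: Genome, pos: int, side: str, want: str
) -> list[tuple[Transcript, int]]:
    out = []
    for t in sorted(hits, key=lambda t: (t.gene, t.id)):
        if not t.is_coding:
            continue
        if not (t.tx_start <= pos < t.tx_end):
            continue
        prefix, suffix = _retained_cds_counts(t, genome, pos, side)
        k = prefix if want == "prefix" else suffix
        cds, _ = _cds_info(t, genome)
        if 0 < k < len(cds):
            out.append((t, k))
    return out


# ---------------------------------------------------------------------------
# known-SNP catalog


class SnpCatalog:
    """Position-keyed table of known SNVs: chrom, 1-based pos, ref, alt, id.

    Alleles are assumed normalized to the + strand; lookups also accept the
    complemented allele pair to tolerate catalogs recorded on the other
    orientation.  Strand is otherwise ignored.
    """

    def __init__(self) -> None:
        self._by_pos: dict[tuple[str, int], list[tuple[str, str, str]]] = {}

    @classmethod
    def from_lines(cls, lines: Iterable[str]) -> "SnpCatalog":
        cat = cls()
        rejected = 0
        for lineno, raw in enumerate(lines, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                chrom, pos, ref, alt, sid = f[0], int(f[1]) - 1, f[2].upper(), f[3].upper(), f[4]
            except (ValueError, IndexError) as exc:
                rejected += 1
                log.warning("SNP catalog line %d rejected: %s", lineno, exc)
                continue
            cat._by_pos.setdefault((chrom, pos), []).append((ref, alt, sid))
        if rejected:
            log.warning("SNP catalog: %d row(s) rejected", rejected)
        return cat

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_pos.values())

    def entries(self) -> Iterable[tuple[str, int, str, str, str]]:
        for (chrom, pos), lst in self._by_pos.items():
            for ref, alt, sid in lst:
                yield chrom, pos, ref, alt, sid

    def lookup(self, snv: Snv) -> Optional[str]:
        for ref, alt, sid in self._by_pos.get((snv.chrom, snv.pos), ()):
            if (snv.ref, snv.alt) == (ref, alt):
                return sid
            if (snv.ref, snv.alt) == (complement_base(ref), complement_base(alt)):
                return sid
        return None


def known_snp_lookup(snv: Snv, catalog: SnpCatalog) -> Optional[str]:
    return catalog.lookup(snv)


# ---------------------------------------------------------------------------
# drivers


@dataclass
class VariantAnnotationResult:
    all_records: list[Consequence]
    per_gene_best: list[Consequence]
    overall_best: list[Consequence]
    tally: Optional["Tally"]


def _drive(
    variants,
    index: IntervalIndex,
    classify,
    with_tally: bool,
) -> VariantAnnotationResult:
    from .annotator import Tally

    all_records: list[Consequence] = []
    per_gene_best: list[Consequence] = []
    overall_best: list[Consequence] = []
    tally = Tally() if with_tally else None
    for v in variants:
        span = v.span if isinstance(v, Indel) else (v.pos, v.pos + 1)
        records = classify(v, span)
        if not records:
            if tally is not None:
                tally.add(ConsequenceCategory.INTERGENIC)
            continue
        records = rank_consequences(records)
        all_records.extend(records)
        by_gene: dict[str, list[Consequence]] = {}
        for rec in records:
            by_gene.setdefault(rec.gene, []).append(rec)
        gene_best = sorted(
            (min(recs, key=Consequence.sort_key) for recs in by_gene.values()),
            key=Consequence.sort_key,
        )
        per_gene_best.extend(gene_best)
        best = gene_best[0]
        overall_best.append(best)
        if tally is not None:
            tally.add(best.category)
    return VariantAnnotationResult(all_records, per_gene_best, overall_best, tally)


def annotate_snvs(
    snvs: Iterable[Snv],
    index: IntervalIndex,
    genome: Genome,
    range_bp: int = 10_000,
    catalog: Optional[SnpCatalog] = None,
    collapse_nonsense: bool = False,
) -> VariantAnnotationResult:
    """Annotate SNVs against indexed transcripts; tally by best record."""

    def classify(snv: Snv, span):
        qs, qe = max(0, span[0] - range_bp), span[1] + range_bp
        known = catalog.lookup(snv) if catalog is not None else None
        out = []
        for hit in index.range_query(snv.chrom, qs, qe):
            if not isinstance(hit, Transcript):
                continue
            rec = snv_consequence(snv, hit, genome, range_bp, collapse_nonsense)
            if rec is not None:
                rec.known_id = known
                out.append(rec)
        return out

    return _drive(snvs, index, classify, with_tally=True)


def annotate_indels(
    indels: Iterable[Indel],
    index: IntervalIndex,
    genome: Genome,
    range_bp: int = 10_000,
) -> VariantAnnotationResult:
    """Annotate indels.  No tally is produced for this mode."""

    def classify(indel: Indel, span):
        qs, qe = max(0, span[0] - range_bp), span[1] + range_bp
        out = []
        for hit in index.range_query(indel.chrom, qs, qe):
            if not isinstance(hit, Transcript):
                continue
            rec = indel_consequence(indel, hit, genome, range_bp)
            if rec is not None:
                out.append(rec)
        return out

    return _drive(indels, index, classify, with_tally=False)


def annotate_translocations(
    translocations: Iterable[Translocation],
    index: IntervalIndex,
    genome: Optional[Genome],
    range_bp: int = 10_000,
) -> list[TranslocationResult]:
    """Annotate translocation breakpoint pairs.  No tally for this mode."""
    return [
        translocation_annotation(tr, index, genome, range_bp) for tr in translocations
    ]
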