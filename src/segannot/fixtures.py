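"""Deterministic synthetic genomes, gene sets, queries and naive oracles.

The generator builds a random genome and a set of multi-isoform genes with
known structure, so every other module can be exercised without downloading
anything.  Coding genes are constructed by *painting* a well-formed CDS
(ATG start, no internal stop, terminal stop) onto the genome at the CDS
positions, so translations are well-formed by construction.  Isoforms of a
gene share the exons that carry the CDS and differ in their non-core exons,
which keeps the painted codons consistent across isoforms while still
producing exon/intron disagreements between isoforms.

Genes are placed without overlap and separated by intergenic gaps; this
deliberately omits features of real annotation such as overlapping genes,
nested genes and pseudogene clutter.

The ``naive_*`` functions are independent O(n) oracles: linear scans and
full-string mutant rebuilds that share no code with the segment-tree index
or the codon-level consequence caller (including a hand-written codon
table), used to validate those paths on random data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .gene_model import Genome, Transcript
from .variant_effects import ConsequenceCategory, Indel, Snv

__all__ = [
    "FixtureSpec",
    "Fixture",
    "make_fixture",
    "random_features",
    "naive_overlap",
    "naive_stab",
    "NaiveIntervalStore",
    "naive_snv_consequence",
    "naive_indel_consequence",
    "naive_closest_tss",
    "STANDARD_CODE",
]

# Hand-enumerated standard genetic code; the oracle's own translation table.
_AA = (
    "FFLLSSSSYY**CC*W"  # TTT..TGG
    "LLLLPPPPHHQQRRRR"  # CTT..CGG
    "IIIMTTTTNNKKSSRR"  # ATT..AGG
    "VVVVAAAADDEEGGGG"  # GTT..GGG
)
_ORDER = "TCAG"
STANDARD_CODE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_ORDER)
    for j, b in enumerate(_ORDER)
    for k, c in enumerate(_ORDER)
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_NON_STOP_CODONS = sorted(c for c in STANDARD_CODE if STANDARD_CODE[c] != "*")


def _naive_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _naive_translate(cds: str) -> str:
    """Oracle translation: first-stop truncation, N-codons as X."""
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        aa = STANDARD_CODE.get(codon, "X")
        out.append(aa)
        if aa == "*":
            break
    return "".join(out)


# ---------------------------------------------------------------------------
# the generator


@dataclass
class FixtureSpec:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 200_000
    n_genes: int = 24
    isoforms_per_gene: tuple[int, int] = (1, 3)
    exons_per_transcript: tuple[int, int] = (1, 5)
    exon_length: tuple[int, int] = (30, 200)
    intron_length: tuple[int, int] = (60, 1_200)
    intergenic_gap: tuple[int, int] = (1_000, 8_000)
    fraction_coding: float = 0.8


@dataclass
class Fixture:
    spec: FixtureSpec
    genome: Genome
    transcripts: list[Transcript]
    genes: dict[str, list[Transcript]]

    @property
    def chroms(self) -> list[str]:
        return self.genome.chroms()

    # --- query samplers ----------------------------------------------------

    def _rng(self, salt: int) -> np.random.Generator:
        return np.random.default_rng((self.spec.seed, salt))

    def random_positions(self, n: int, salt: int = 1) -> list[tuple[str, int]]:
        """Positions mixing uniform draws with draws inside transcripts."""
        rng = self._rng(salt)
        out = []
        spans = [(t.chrom, t.tx_start, t.tx_end) for t in self.transcripts]
        for _ in range(n):
            if spans and rng.random() < 0.5:
                chrom, s, e = spans[rng.integers(len(spans))]
                out.append((chrom, int(rng.integers(max(0, s - 50), e + 50))))
            else:
                chrom = self.chroms[rng.integers(len(self.chroms))]
                out.append((chrom, int(rng.integers(0, self.genome.length(chrom)))))
        return out

    def random_snvs(self, n: int, salt: int = 2) -> list[Snv]:
        rng = self._rng(salt)
        out = []
        positions = self.random_positions(n, salt=salt + 1000)
        for i, (chrom, pos) in enumerate(positions):
            pos = min(pos, self.genome.length(chrom) - 1)
            ref = self.genome.fetch(chrom, pos, pos + 1)
            if ref not in "ACGT":
                ref = "A"
            alt = rng.choice([b for b in "ACGT" if b != ref])
            out.append(Snv(f"snv{i}", chrom, pos, ref, str(alt)))
        return out

    def random_indels(self, n: int, salt: int = 3, max_len: int = 12) -> list[Indel]:
        rng = self._rng(salt)
        out = []
        positions = self.random_positions(n, salt=salt + 1000)
        for i, (chrom, pos) in enumerate(positions):
            length = int(rng.integers(1, max_len + 1))
            pos = min(pos, self.genome.length(chrom) - length - 1)
            pos = max(pos, 1)
            if rng.random() < 0.5:
                seq = "".join(rng.choice(list("ACGT"), size=length))
                out.append(Indel(f"ins{i}", chrom, pos, "INS", sequence=seq))
            else:
                out.append(Indel(f"del{i}", chrom, pos, "DEL", del_length=length))
        return out

    def random_intervals(self, n: int, salt: int = 4, max_len: int = 1_500) -> list[tuple[str, int, int]]:
        rng = self._rng(salt)
        out = []
        for chrom, pos in self.random_positions(n, salt=salt + 1000):
            length = int(rng.integers(1, max_len))
            end = min(pos + length, self.genome.length(chrom))
            pos = max(0, min(pos, end - 1))
            out.append((chrom, pos, end))
        return out


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Generate a genome and gene set; identical spec -> identical fixture."""
    rng = np.random.default_rng(spec.seed)
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    seqs = {
        c: "".join(rng.choice(list("ACGT"), size=spec.chrom_length))
        for c in chrom_names
    }
    transcripts: list[Transcript] = []
    genes: dict[str, list[Transcript]] = {}
    cursor = {c: 0 for c in chrom_names}
    for g in range(spec.n_genes):
        chrom = chrom_names[g % spec.n_chroms]
        gap = int(rng.integers(*spec.intergenic_gap))
        start = cursor[chrom] + gap
        gene_name = f"GENE{g}"
        strand = "+" if rng.random() < 0.5 else "-"
        coding = rng.random() < spec.fraction_coding

        # exon template shared by all isoforms of the gene
        n_exons = int(rng.integers(spec.exons_per_transcript[0], spec.exons_per_transcript[1] + 1))
        exons = []
        pos = start
        for i in range(n_exons):
            length = int(rng.integers(*spec.exon_length))
            exons.append((pos, pos + length))
            pos += length
            if i < n_exons - 1:
                pos += int(rng.integers(*spec.intron_length))
        if pos >= spec.chrom_length:
            raise ValueError(
                f"fixture infeasible: gene {gene_name} ends at {pos}, "
                f"chromosome length is {spec.chrom_length}"
            )
        cursor[chrom] = pos

        cds_start = cds_end = exons[0][0]
        if coding:
            cds_start, cds_end = _choose_cds(rng, exons)
            _paint_cds(rng, seqs, chrom, exons, cds_start, cds_end, strand)

        core = [
            i for i, (s, e) in enumerate(exons)
            if coding and s < cds_end and cds_start < e
        ]
        lo_core = min(core) if core else None
        hi_core = max(core) if core else None

        n_iso = int(rng.integers(spec.isoforms_per_gene[0], spec.isoforms_per_gene[1] + 1))
        made: set[tuple] = set()
        for k in range(n_iso):
            keep = []
            for i in range(n_exons):
                is_core = lo_core is not None and lo_core <= i <= hi_core
                if is_core or k == 0 or rng.random() < 0.75:
                    keep.append(i)
            if not keep:
                keep = [0]
            # merge adjacency gaps are kept as introns; isoforms differ by
            # which non-core exons they include
            iso_exons = tuple(exons[i] for i in keep)
            if iso_exons in made:
                continue
            made.add(iso_exons)
            tx_start, tx_end = iso_exons[0][0], iso_exons[-1][1]
            t = Transcript(
                id=f"{gene_name}.iso{k}",
                gene=gene_name,
                chrom=chrom,
                strand=strand,
                tx_start=tx_start,
                tx_end=tx_end,
                cds_start=cds_start if coding else tx_start,
                cds_end=cds_end if coding else tx_start,
                exons=iso_exons,
            )
            transcripts.append(t)
            genes.setdefault(gene_name, []).append(t)
    genome = Genome(seqs)
    return Fixture(spec=spec, genome=genome, transcripts=transcripts, genes=genes)


def _choose_cds(rng: np.random.Generator, exons: Sequence[tuple[int, int]]) -> tuple[int, int]:
    """CDS bounds on the exon template: length a multiple of 3, >= 9 bp."""
    flat = [p for s, e in exons for p in range(s, e)]
    total = len(flat)
    n_codons = int(rng.integers(3, max(4, total // 3)))
    length = min(3 * n_codons, total - total % 3)
    length = max(9, length - length % 3)
    max_start = total - length
    a = int(rng.integers(0, max_start + 1)) if max_start > 0 else 0
    return flat[a], flat[a + length - 1] + 1


def _paint_cds(
    rng: np.random.Generator,
    seqs: dict[str, str],
    chrom: str,
    exons: Sequence[tuple[int, int]],
    cds_start: int,
    cds_end: int,
    strand: str,
) -> None:
    positions = [
        p for s, e in exons for p in range(max(s, cds_start), min(e, cds_end))
    ]
    n_codons = len(positions) // 3
    body = "".join(rng.choice(_NON_STOP_CODONS, size=n_codons - 2))
    stop = str(rng.choice(["TAA", "TAG", "TGA"]))
    cds = "ATG" + body + stop
    genomic = cds if strand == "+" else _naive_revcomp(cds)
    seq = list(seqs[chrom])
    for p, b in zip(positions, genomic):
        seq[p] = b
    seqs[chrom] = "".join(seq)


def random_features(rng: np.random.Generator, n: int, chrom: str = "chr1",
                    span: int = 5_000_000, max_len: int = 200_000):
    """Random block-less features for index stress tests (shared endpoints
    occur naturally through coordinate collisions at small spans)."""
    from .gene_model import GenericFeature

    out = []
    for i in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(
            GenericFeature(
                id=f"f{i}", chrom=chrom, strand=".", start=start, end=start + length
            )
        )
    return out


# ---------------------------------------------------------------------------
# naive oracles (independent of the indexed / codon-level code paths)


def naive_overlap(features, chrom: str, start: int, end: int):
    """O(n) scan for features overlapping [start, end)."""
    hits = [f for f in features if f.chrom == chrom and f.start < end and start < f.end]
    hits.sort(key=lambda f: (f.start, f.end, f.id))
    return hits


def naive_stab(features, chrom: str, pos: int):
    return naive_overlap(features, chrom, pos, pos + 1)


class NaiveIntervalStore:
    """Vectorized linear-scan oracle over one feature list."""

    def __init__(self, features):
        self.features = list(features)
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list]] = {}
        grouped: dict[str, list] = {}
        for f in self.features:
            grouped.setdefault(f.chrom, []).append(f)
        for chrom, feats in grouped.items():
            starts = np.array([f.start for f in feats], dtype=np.int64)
            ends = np.array([f.end for f in feats], dtype=np.int64)
            self.by_chrom[chrom] = (starts, ends, feats)

    def n_comparisons(self, chrom: str) -> int:
        entry = self.by_chrom.get(chrom)
        return 0 if entry is None else len(entry[2])

    def query(self, chrom: str, start: int, end: int):
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, feats = entry
        mask = (starts < end) & (ends > start)
        hits = [feats[i] for i in np.nonzero(mask)[0]]
        hits.sort(key=lambda f: (f.start, f.end, f.id))
        return hits

    def stab(self, chrom: str, pos: int):
        return self.query(chrom, pos, pos + 1)


def _naive_extract_cds(t: Transcript, chrom_seq: str) -> str:
    parts = []
    for s, e in t.exons:
        lo, hi = max(s, t.cds_start), min(e, t.cds_end)
        if lo < hi:
            parts.append(chrom_seq[lo:hi])
    cds = "".join(parts)
    return cds if t.strand == "+" else _naive_revcomp(cds)


def naive_snv_consequence(
    snv: Snv, t: Transcript, genome: Genome, range_bp: int = 10_000,
) -> Optional[tuple]:
    """Full-rebuild oracle for one SNV on one transcript.

    Returns (category, aa_change or None, mutated_protein or None) computed
    by substituting the base in the whole chromosome string, re-extracting
    the spliced CDS and translating with the oracle's own codon table.
    """
    chrom_seq = genome.sequence(snv.chrom)
    pos = snv.pos
    in_exon = any(s <= pos < e for s, e in t.exons)
    in_cds = t.is_coding and t.cds_start <= pos < t.cds_end and in_exon
    if in_cds:
        mutant_seq = chrom_seq[:pos] + snv.alt + chrom_seq[pos + 1 :]
        ref_cds = _naive_extract_cds(t, chrom_seq)
        mut_cds = _naive_extract_cds(t, mutant_seq)
        ref_prot_full = _naive_protein_full(ref_cds)
        mut_prot_full = _naive_protein_full(mut_cds)
        diff = [i for i, (a, b) in enumerate(zip(ref_prot_full, mut_prot_full)) if a != b]
        if not diff:
            # same residue at the changed codon
            changed = next(
                i // 3 for i in range(len(ref_cds)) if ref_cds[i] != mut_cds[i]
            )
            aa = ref_prot_full[changed]
            category = ConsequenceCategory.SYNONYMOUS
            aa_change = (aa, changed + 1, aa)
        else:
            i = diff[0]
            ref_aa, alt_aa = ref_prot_full[i], mut_prot_full[i]
            category = (
                ConsequenceCategory.NONSENSE
                if alt_aa == "*"
                else ConsequenceCategory.NONSYNONYMOUS
            )
            aa_change = (ref_aa, i + 1, alt_aa)
        protein = _truncate_at_stop(mut_prot_full)
        return category, aa_change, protein
    loc = _naive_location(pos, t, range_bp)
    if loc is None:
        return None
    return loc, None, None


def _naive_protein_full(cds: str) -> str:
    """Translate every codon without stopping (for residue comparison)."""
    return "".join(
        STANDARD_CODE.get(cds[i : i + 3], "X")
        for i in range(0, len(cds) - len(cds) % 3, 3)
    )


def _truncate_at_stop(protein_full: str) -> str:
    i = protein_full.find("*")
    return protein_full[:i] if i != -1 else protein_full


def _naive_location(pos: int, t: Transcript, range_bp: int):
    if t.tx_start <= pos < t.tx_end:
        if any(s <= pos < e for s, e in t.exons):
            if not t.is_coding:
                return ConsequenceCategory.NONCODING_EXON
            if pos < t.cds_start:
                return (
                    ConsequenceCategory.UTR5
                    if t.strand == "+"
                    else ConsequenceCategory.UTR3
                )
            return (
                ConsequenceCategory.UTR3
                if t.strand == "+"
                else ConsequenceCategory.UTR5
            )
        for i in range(len(t.exons) - 1):
            s, e = t.exons[i][1], t.exons[i + 1][0]
            if s <= pos < e:
                off5, off3 = pos - s + 1, e - pos
                if off5 <= 2 or off3 <= 2:
                    return ConsequenceCategory.SPLICE_SITE
                return ConsequenceCategory.INTRON
        raise AssertionError("unreachable for well-formed transcripts")
    if pos < t.tx_start and t.tx_start - pos <= range_bp:
        return (
            ConsequenceCategory.UPSTREAM
            if t.strand == "+"
            else ConsequenceCategory.DOWNSTREAM
        )
    if pos >= t.tx_end and pos - t.tx_end + 1 <= range_bp:
        return (
            ConsequenceCategory.DOWNSTREAM
            if t.strand == "+"
            else ConsequenceCategory.UPSTREAM
        )
    return None


def naive_indel_consequence(
    indel: Indel, t: Transcript, genome: Genome, range_bp: int = 10_000,
) -> Optional[tuple]:
    """Full-rebuild oracle: apply the edit to the chromosome string, shift
    all transcript coordinates across the edit, re-extract and translate.

    Returns (category, mutated_protein or None).
    """
    chrom_seq = genome.sequence(indel.chrom)
    if indel.kind == "INS":
        p, L = indel.pos, len(indel.sequence)
        mutant_seq = chrom_seq[:p] + indel.sequence + chrom_seq[p:]

        def shift(b: int) -> int:
            return b + L if b >= p else b

    else:
        p, L = indel.pos, indel.del_length
        mutant_seq = chrom_seq[:p] + chrom_seq[p + L :]

        def shift(b: int) -> int:
            if b <= p:
                return b
            return b - L if b >= p + L else p

    new_exons = []
    for s, e in t.exons:
        ns, ne = shift(s), shift(e)
        if ns < ne:
            new_exons.append((ns, ne))
    ncs, nce = shift(t.cds_start), shift(t.cds_end)
    if t.is_coding:
        old_cds = _naive_extract_cds(t, chrom_seq)
        parts = []
        for s, e in new_exons:
            lo, hi = max(s, ncs), min(e, nce)
            if lo < hi:
                parts.append(mutant_seq[lo:hi])
        new_cds = "".join(parts)
        if t.strand == "-":
            new_cds = _naive_revcomp(new_cds)
        delta = len(new_cds) - len(old_cds)
        if delta != 0:
            category = (
                ConsequenceCategory.INFRAME_INDEL
                if delta % 3 == 0
                else ConsequenceCategory.FRAMESHIFT
            )
            protein = (
                _truncate_at_stop(_naive_protein_full(new_cds))
                if len(new_cds) >= 3
                else None
            )
            return category, protein
    # no CDS change: location category over the edited bases.  An insertion
    # sits between two bases; classify whichever flanking base is not CDS
    # (an insertion flush against the CDS edge does not alter the protein).
    from .variant_effects import CONSEQUENCE_PRIORITY

    def is_cds_base(p: int) -> bool:
        return (
            t.is_coding
            and t.cds_start <= p < t.cds_end
            and any(s <= p < e for s, e in t.exons)
        )

    if indel.kind == "INS":
        candidates = [p for p in (indel.pos, indel.pos - 1) if p >= 0 and not is_cds_base(p)]
    else:
        candidates = list(range(*indel.span))
    best = None
    for pos in candidates:
        loc = _naive_location(pos, t, range_bp)
        if loc is not None:
            if best is None or CONSEQUENCE_PRIORITY[loc] < CONSEQUENCE_PRIORITY[best]:
                best = loc
    if best is None:
        return None
    return best, None


def naive_closest_tss(transcripts: Iterable[Transcript], chrom: str, pos: int):
    """Linear-scan oracle: (transcript id, signed distance) or None."""
    best = None
    for t in transcripts:
        if t.chrom != chrom:
            continue
        tss = t.tss()
        key = (abs(pos - tss), tss, t.id)
        if best is None or key < best[0]:
            best = (key, t.id, pos - tss)
    if best is None:
        return None
    return best[1], best[2]
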