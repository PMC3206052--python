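"""Native tab-separated query formats and converters from common dialects.

One dialect per annotation mode, 1-based positions in files (converted to
the package's internal 0-based half-open convention at this boundary):

- coordinates:    ``id  chrom  pos``
- intervals:      ``id  chrom  start  end``        (inclusive in files)
- SNVs:           ``id  chrom  pos  ref  alt``
- indels:         ``id  chrom  pos  INS|DEL  seq|length``
- translocations: ``id  chromA  posA  sideA  chromB  posB  sideB``

For insertions ``pos`` is the 1-based base before which the sequence is
inserted; for deletions it is the first deleted base.  Sides are ``5`` or
``3``: the genomic side of the breakpoint retained in the derivative
chromosome.

Converters accept BED (to coordinates or intervals), VCF 4.x (to SNVs and
indels, splitting multi-allelic records) and a generic caller TSV with
``chrom  pos  ref  alt`` columns.  Per-row failures are logged and counted,
never fatal.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

from .annotator import CoordinateQuery, IntervalQuery
from .gene_model import parse_bed
from .variant_effects import Indel, Snv, Translocation

log = logging.getLogger(__name__)

__all__ = [
    "read_coordinates",
    "write_coordinates",
    "read_intervals",
    "write_intervals",
    "read_snvs",
    "write_snvs",
    "read_indels",
    "write_indels",
    "read_translocations",
    "write_translocations",
    "read_table",
    "bed_to_coordinates",
    "bed_to_intervals",
    "vcf_to_native",
    "caller_tsv_to_snvs",
]


def _rows(lines: Iterable[str], what: str):
    for lineno, raw in enumerate(lines, 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        yield lineno, line.split("\t")


def _parse(lines, what, builder):
    out, rejected = [], 0
    for lineno, f in _rows(lines, what):
        try:
            out.append(builder(f))
        except (ValueError, IndexError) as exc:
            rejected += 1
            log.warning("%s line %d rejected: %s", what, lineno, exc)
    if rejected:
        log.warning("%s: %d row(s) rejected", what, rejected)
    return out


def read_coordinates(lines: Iterable[str]) -> list[CoordinateQuery]:
    return _parse(
        lines, "coordinates", lambda f: CoordinateQuery(f[0], f[1], int(f[2]) - 1)
    )


def write_coordinates(queries: Iterable[CoordinateQuery]) -> list[str]:
    return [f"{q.id}\t{q.chrom}\t{q.pos + 1}" for q in queries]


def read_intervals(lines: Iterable[str]) -> list[IntervalQuery]:
    def build(f):
        start, end = int(f[2]) - 1, int(f[3])
        if start >= end:
            raise ValueError(f"{f[0]}: empty interval")
        return IntervalQuery(f[0], f[1], start, end)

    return _parse(lines, "intervals", build)


def write_intervals(queries: Iterable[IntervalQuery]) -> list[str]:
    return [f"{q.id}\t{q.chrom}\t{q.start + 1}\t{q.end}" for q in queries]


def read_snvs(lines: Iterable[str]) -> list[Snv]:
    return _parse(
        lines, "SNVs", lambda f: Snv(f[0], f[1], int(f[2]) - 1, f[3], f[4])
    )


def write_snvs(snvs: Iterable[Snv]) -> list[str]:
    return [f"{v.id}\t{v.chrom}\t{v.pos + 1}\t{v.ref}\t{v.alt}" for v in snvs]


def read_indels(lines: Iterable[str]) -> list[Indel]:
    def build(f):
        qid, chrom, pos, kind, payload = f[0], f[1], int(f[2]) - 1, f[3].upper(), f[4]
        if kind == "INS":
            return Indel(qid, chrom, pos, "INS", sequence=payload)
        if kind == "DEL":
            return Indel(qid, chrom, pos, "DEL", del_length=int(payload))
        raise ValueError(f"{qid}: unknown indel kind {kind!r}")

    return _parse(lines, "indels", build)


def write_indels(indels: Iterable[Indel]) -> list[str]:
    out = []
    for v in indels:
        payload = v.sequence if v.kind == "INS" else str(v.del_length)
        out.append(f"{v.id}\t{v.chrom}\t{v.pos + 1}\t{v.kind}\t{payload}")
    return out


def _norm_side(side: str) -> str:
    side = side.strip().rstrip("'′")
    if side not in ("5", "3"):
        raise ValueError(f"breakpoint side must be 5 or 3, got {side!r}")
    return side


def read_translocations(lines: Iterable[str]) -> list[Translocation]:
    return _parse(
        lines,
        "translocations",
        lambda f: Translocation(
            f[0],
            f[1], int(f[2]) - 1, _norm_side(f[3]),
            f[4], int(f[5]) - 1, _norm_side(f[6]),
        ),
    )


def write_translocations(trs: Iterable[Translocation]) -> list[str]:
    return [
        f"{t.id}\t{t.chrom_a}\t{t.pos_a + 1}\t{t.side_a}"
        f"\t{t.chrom_b}\t{t.pos_b + 1}\t{t.side_b}"
        for t in trs
    ]


def read_table(lines: Iterable[str]) -> tuple[list[str], list[list[str]]]:
    """Re-read one of the package's own TSV outputs: (header, rows)."""
    header: list[str] = []
    rows: list[list[str]] = []
    for raw in lines:
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            continue
        if not header:
            header = line.split("\t")
        else:
            rows.append(line.split("\t"))
    return header, rows


# ---------------------------------------------------------------------------
# converters


def bed_to_coordinates(lines: Iterable[str]) -> list[str]:
    """BED rows to native coordinates (the feature's start base, 1-based)."""
    return [
        f"{f.id}\t{f.chrom}\t{f.start + 1}" for f in parse_bed(lines)
    ]


def bed_to_intervals(lines: Iterable[str]) -> list[str]:
    return [
        f"{f.id}\t{f.chrom}\t{f.start + 1}\t{f.end}" for f in parse_bed(lines)
    ]


def vcf_to_native(path: str) -> tuple[list[str], list[str], int]:
    """VCF 4.x to native SNV and indel rows: (snv_lines, indel_lines, n_skipped).

    SNVs are 1 bp ref -> 1 bp alt.  Anchored indels follow the VCF padding
    convention (``REF=A ALT=AT`` inserts T after the anchor base); complex
    substitutions are skipped and counted.
    """
    import pysam

    snv_lines: list[str] = []
    indel_lines: list[str] = []
    skipped = 0
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            base_id = rec.id or f"{rec.chrom}_{rec.pos}"
            for k, alt in enumerate(rec.alts or ()):
                vid = base_id if len(rec.alts) == 1 else f"{base_id}_{k + 1}"
                ref = rec.ref.upper()
                alt = str(alt).upper()
                if len(ref) == 1 and len(alt) == 1 and ref != alt and alt in "ACGT":
                    snv_lines.append(f"{vid}\t{rec.chrom}\t{rec.pos}\t{ref}\t{alt}")
                elif len(alt) == 1 and len(ref) > 1 and ref[0] == alt:
                    # deletion: first deleted base follows the anchor
                    indel_lines.append(
                        f"{vid}\t{rec.chrom}\t{rec.pos + 1}\tDEL\t{len(ref) - 1}"
                    )
                elif len(ref) == 1 and len(alt) > 1 and alt[0] == ref:
                    # insertion after the anchor base
                    indel_lines.append(
                        f"{vid}\t{rec.chrom}\t{rec.pos + 1}\tINS\t{alt[1:]}"
                    )
                else:
                    skipped += 1
                    log.warning("VCF record %s: unsupported allele pair %s>%s", vid, ref, alt)
    return snv_lines, indel_lines, skipped


def caller_tsv_to_snvs(lines: Iterable[str]) -> list[str]:
    """Generic SNV-caller TSV (``chrom pos ref alt`` with optional leading id
    column and optional header) to native SNV rows."""
    out, rejected = [], 0
    for lineno, f in _rows(lines, "caller TSV"):
        if lineno == 1 and not any(x.isdigit() for x in f):
            continue  # header
        try:
            if len(f) >= 5:
                vid, chrom, pos, ref, alt = f[0], f[1], int(f[2]), f[3], f[4]
            else:
                chrom, pos, ref, alt = f[0], int(f[1]), f[2], f[3]
                vid = f"{chrom}_{pos}"
            Snv(vid, chrom, pos - 1, ref, alt)  # validation only
            out.append(f"{vid}\t{chrom}\t{pos}\t{ref.upper()}\t{alt.upper()}")
        except (ValueError, IndexError) as exc:
            rejected += 1
            log.warning("caller TSV line %d rejected: %s", lineno, exc)
    if rejected:
        log.warning("caller TSV: %d row(s) rejected", rejected)
    return out
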