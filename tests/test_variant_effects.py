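import pytest

from conftest import simple_transcript
from segannot.annotator import LocusCategory, classify_coordinate
from segannot.fixtures import (
    FixtureSpec,
    make_fixture,
    naive_indel_consequence,
    naive_snv_consequence,
)
from segannot.gene_model import Genome, Transcript, coding_sequence, reverse_complement, translate
from segannot.interval_index import build_index
from segannot.variant_effects import (
    ConsequenceCategory,
    Indel,
    SnpCatalog,
    Snv,
    Translocation,
    annotate_indels,
    annotate_snvs,
    indel_consequence,
    known_snp_lookup,
    rank_consequences,
    snv_consequence,
    translocation_annotation,
)


def one_exon_gene(seq="ATGAAATGA", strand="+", offset=0, tid="t1", gene="G1",
                  chrom="chr1"):
    n = len(seq)
    return simple_transcript(
        tid=tid, gene=gene, chrom=chrom, strand=strand,
        exons=((offset, offset + n),), cds=(offset, offset + n),
    )


class TestSnvConsequence:
    def test_missense_k2r_with_truncated_protein(self, tiny_genome):
        t = one_exon_gene()
        snv = Snv("s", "chr1", 4, "A", "G")  # codon 2 AAA -> AGA
        rec = snv_consequence(snv, t, tiny_genome)
        assert rec.category is ConsequenceCategory.NONSYNONYMOUS
        assert rec.aa_change == ("K", 2, "R") and rec.aa_change_str == "K2R"
        assert rec.mutated_protein == "MR"

    def test_synonymous_keeps_reference_protein(self, tiny_genome):
        t = one_exon_gene()
        snv = Snv("s", "chr1", 5, "A", "G")  # AAA -> AAG, both K
        rec = snv_consequence(snv, t, tiny_genome)
        assert rec.category is ConsequenceCategory.SYNONYMOUS
        ref_protein = translate(coding_sequence(t, tiny_genome)).rstrip("*")
        assert rec.mutated_protein == ref_protein

    def test_stop_gain_is_nonsense_unless_collapsed(self):
        genome = Genome({"chr1": "ATGTACAAATGA"})
        t = one_exon_gene("ATGTACAAATGA")
        snv = Snv("s", "chr1", 5, "C", "G")  # TAC -> TAG stop
        rec = snv_consequence(snv, t, genome)
        assert rec.category is ConsequenceCategory.NONSENSE
        assert rec.aa_change == ("Y", 2, "*") and rec.mutated_protein == "M"
        rec2 = snv_consequence(snv, t, genome, collapse_nonsense=True)
        assert rec2.category is ConsequenceCategory.NONSYNONYMOUS

    def test_minus_strand_mirror_gives_same_call(self):
        # mirror the plus-strand gene: reverse-complement genome and coordinates
        seq = "ATGAAACCCTGA"
        genome_plus = Genome({"chr1": seq})
        t_plus = one_exon_gene(seq)
        snv_plus = Snv("s", "chr1", 4, "A", "G")
        genome_minus = Genome({"chr1": reverse_complement(seq)})
        t_minus = one_exon_gene(seq, strand="-")
        n = len(seq)
        snv_minus = Snv(
            "s", "chr1", n - 1 - snv_plus.pos,
            reverse_complement(snv_plus.ref), reverse_complement(snv_plus.alt),
        )
        a = snv_consequence(snv_plus, t_plus, genome_plus)
        b = snv_consequence(snv_minus, t_minus, genome_minus)
        assert (a.category, a.aa_change, a.mutated_protein) == (
            b.category, b.aa_change, b.mutated_protein
        )

    def test_utr_sides_are_strand_aware(self):
        genome = Genome({"chr1": "TT" + "ATGAAATGA" + "CC"})
        plus = simple_transcript(exons=((0, 13),), cds=(2, 11))
        assert snv_consequence(Snv("a", "chr1", 0, "T", "A"), plus, genome).category \
            is ConsequenceCategory.UTR5
        assert snv_consequence(Snv("b", "chr1", 12, "C", "A"), plus, genome).category \
            is ConsequenceCategory.UTR3
        minus = simple_transcript(strand="-", exons=((0, 13),), cds=(2, 11))
        assert snv_consequence(Snv("c", "chr1", 0, "T", "A"), minus, genome).category \
            is ConsequenceCategory.UTR3

    def test_noncoding_transcript_exon(self, tiny_genome):
        t = simple_transcript(exons=((0, 9),), cds=(0, 0))
        rec = snv_consequence(Snv("s", "chr1", 4, "A", "G"), t, tiny_genome)
        assert rec.category is ConsequenceCategory.NONCODING_EXON
        assert rec.mutated_protein is None

    def test_ref_mismatch_flagged_but_annotated(self, tiny_genome):
        t = one_exon_gene()
        rec = snv_consequence(Snv("s", "chr1", 4, "C", "G"), t, tiny_genome)
        assert rec.ref_mismatch
        assert rec.category is ConsequenceCategory.NONSYNONYMOUS

    def test_missing_chromosome_errors(self, tiny_genome):
        t = one_exon_gene(chrom="chr9")
        with pytest.raises(KeyError):
            snv_consequence(Snv("s", "chr9", 4, "A", "G"), t, tiny_genome)


class TestSpliceWindow:
    @pytest.fixture()
    def spliced(self):
        # exon1 (0,30) intron (30,90) exon2 (90,120); CDS off (non-coding)
        t = simple_transcript(exons=((0, 30), (90, 120)), cds=(0, 0))
        genome = Genome({"chr1": "A" * 120})
        return t, genome

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (30, ConsequenceCategory.SPLICE_SITE),  # donor +1
            (31, ConsequenceCategory.SPLICE_SITE),  # donor +2
            (32, ConsequenceCategory.INTRON),       # donor +3
            (89, ConsequenceCategory.SPLICE_SITE),  # acceptor -1
            (88, ConsequenceCategory.SPLICE_SITE),  # acceptor -2
            (87, ConsequenceCategory.INTRON),       # acceptor -3
            (29, ConsequenceCategory.NONCODING_EXON),  # last exonic base
        ],
    )
    def test_two_bp_rule(self, spliced, pos, expected):
        t, genome = spliced
        rec = snv_consequence(Snv("s", "chr1", pos, "A", "G"), t, genome)
        assert rec.category is expected

    def test_exhaustive_over_fixture_junctions(self, fixture):
        for t in fixture.transcripts:
            for intron_start, intron_end in t.introns():
                for off in range(min(6, intron_end - intron_start)):
                    for pos in (intron_start + off, intron_end - 1 - off):
                        base = fixture.genome.fetch(t.chrom, pos, pos + 1)
                        alt = "A" if base != "A" else "C"
                        rec = snv_consequence(Snv("s", t.chrom, pos, base, alt),
                                              t, fixture.genome)
                        dist5 = pos - intron_start + 1
                        dist3 = intron_end - pos
                        if min(dist5, dist3) <= 2:
                            assert rec.category is ConsequenceCategory.SPLICE_SITE
                        else:
                            assert rec.category is ConsequenceCategory.INTRON


class TestRanking:
    def test_documented_order(self):
        from segannot.variant_effects import CONSEQUENCE_PRIORITY as P

        chain = [
            ConsequenceCategory.NONSENSE,
            ConsequenceCategory.NONSYNONYMOUS,
            ConsequenceCategory.SYNONYMOUS,
            ConsequenceCategory.SPLICE_SITE,
            ConsequenceCategory.UTR5,
            ConsequenceCategory.UTR3,
            ConsequenceCategory.NONCODING_EXON,
            ConsequenceCategory.INTRON,
            ConsequenceCategory.UPSTREAM,
            ConsequenceCategory.DOWNSTREAM,
        ]
        assert [P[c] for c in chain] == sorted(P[c] for c in chain)

    def test_synonymous_outranks_intron_and_permutation_invariance(self, rng):
        from segannot.variant_effects import Consequence

        records = [
            Consequence("q", f"t{i}", f"g{i}", cat)
            for i, cat in enumerate(
                [
                    ConsequenceCategory.INTRON,
                    ConsequenceCategory.SYNONYMOUS,
                    ConsequenceCategory.DOWNSTREAM,
                    ConsequenceCategory.NONSYNONYMOUS,
                    ConsequenceCategory.UTR5,
                ]
            )
        ]
        reference = rank_consequences(records)
        assert reference[0].category is ConsequenceCategory.NONSYNONYMOUS
        assert [r.category for r in reference][:2] == [
            ConsequenceCategory.NONSYNONYMOUS,
            ConsequenceCategory.SYNONYMOUS,
        ]
        for _ in range(10):
            perm = [records[i] for i in rng.permutation(len(records))]
            assert rank_consequences(perm) == reference

    def test_single_record(self):
        from segannot.variant_effects import Consequence

        rec = Consequence("q", "t", "g", ConsequenceCategory.INTRON)
        assert rank_consequences([rec]) == [rec]


class TestIndelConsequence:
    def test_inframe_codon_deletion(self, tiny_genome):
        t = one_exon_gene()
        indel = Indel("d", "chr1", 3, "DEL", del_length=3)  # drop codon 2
        rec = indel_consequence(indel, t, tiny_genome)
        assert rec.category is ConsequenceCategory.INFRAME_INDEL
        assert rec.mutated_protein == "M"

    def test_single_base_insertion_frameshifts(self, tiny_genome):
        t = one_exon_gene()
        indel = Indel("i", "chr1", 2, "INS", sequence="G")
        rec = indel_consequence(indel, t, tiny_genome)
        assert rec.category is ConsequenceCategory.FRAMESHIFT

    def test_deletion_of_whole_cds_gives_no_protein(self, tiny_genome):
        t = one_exon_gene()
        indel = Indel("d", "chr1", 0, "DEL", del_length=9)
        rec = indel_consequence(indel, t, tiny_genome)
        assert rec.category is ConsequenceCategory.INFRAME_INDEL
        assert rec.mutated_protein is None

    def test_random_indels_match_full_rebuild_oracle(self, fixture):
        index = build_index(fixture.transcripts)
        checked = 0
        for indel in fixture.random_indels(600):
            s, e = indel.span
            for t in index.range_query(indel.chrom, max(0, s - 10_000), e + 10_000):
                impl = indel_consequence(indel, t, fixture.genome)
                oracle = naive_indel_consequence(indel, t, fixture.genome)
                got = None if impl is None else (impl.category, impl.mutated_protein)
                assert got == oracle, (indel, t.id)
                checked += 1
        assert checked > 500


class TestSnvOracleEquivalence:
    @pytest.mark.parametrize("seed", [21, 22])
    def test_random_snvs_match_full_rebuild_oracle(self, seed):
        fx = make_fixture(FixtureSpec(seed=seed))
        index = build_index(fx.transcripts)
        checked = 0
        for snv in fx.random_snvs(1_200):
            for t in index.range_query(
                snv.chrom, max(0, snv.pos - 10_000), snv.pos + 10_001
            ):
                impl = snv_consequence(snv, t, fx.genome)
                oracle = naive_snv_consequence(snv, t, fx.genome)
                got = (
                    None
                    if impl is None
                    else (impl.category, impl.aa_change, impl.mutated_protein)
                )
                assert got == oracle, (snv, t.id)
                checked += 1
        assert checked > 1_000


class TestTranslocation:
    def fusion_setup(self):
        # two plus-strand single-exon genes with distinct codons
        g = Genome({"chr1": "ATGAAACCCTGA" + "T" * 8 + "ATGGGGTTTTGA"})
        t1 = one_exon_gene("ATGAAACCCTGA", tid="t1", gene="GA")
        t2 = simple_transcript(
            tid="t2", gene="GB", exons=((20, 32),), cds=(20, 32)
        )
        return g, t1, t2

    def test_intergenic_breakpoints_have_no_records_or_protein(self, fixture):
        index = build_index(fixture.transcripts)
        tr = Translocation("x", "chrNo", 5, "5", "chrNo", 500, "3")
        res = translocation_annotation(tr, index, fixture.genome, range_bp=0)
        assert res.records_a == [] and res.records_b == []
        assert res.fusion_protein is None

    def test_fusion_at_codon_boundaries(self):
        g, t1, t2 = self.fusion_setup()
        index = build_index([t1, t2])
        # keep codons 1-2 of t1 (coords <= 5), codons 2-4 of t2 (coords >= 23)
        tr = Translocation("f", "chr1", 5, "5", "chr1", 23, "3")
        res = translocation_annotation(tr, index, g)
        assert res.fusion_partners == ("t1", "t2")
        # hand-built halves: MK + GF then stop
        assert res.fusion_protein == "MKGF"

    def test_breakpoints_match_coordinate_classification(self, fixture):
        index = build_index(fixture.transcripts)
        positions = fixture.random_positions(100, salt=77)
        for i in range(0, len(positions) - 1, 2):
            (ca, pa), (cb, pb) = positions[i], positions[i + 1]
            if (ca, pa) == (cb, pb):
                continue
            tr = Translocation(f"tr{i}", ca, pa, "5", cb, pb, "3")
            res = translocation_annotation(tr, index, fixture.genome)
            for pos, chrom, records in ((pa, ca, res.records_a), (pb, cb, res.records_b)):
                expected = []
                for t in fixture.transcripts:
                    if t.chrom != chrom:
                        continue
                    rec = classify_coordinate(pos, t, 10_000, query_id=tr.id)
                    if rec is not None:
                        expected.append(rec)
                expected.sort(key=lambda r: r.sort_key())
                assert [vars(r) for r in records] == [vars(r) for r in expected]


class TestKnownSnpLookup:
    CATALOG = [
        "chr1\t101\tA\tG\trs1",
        "chr1\t201\tC\tT\trs2",
        "chr2\t51\tT\tA\trs3",
    ]

    def test_hit_and_allele_mismatch(self):
        cat = SnpCatalog.from_lines(self.CATALOG)
        assert known_snp_lookup(Snv("a", "chr1", 100, "A", "G"), cat) == "rs1"
        assert known_snp_lookup(Snv("b", "chr1", 100, "A", "C"), cat) is None
        # complemented orientation accepted
        assert known_snp_lookup(Snv("c", "chr1", 100, "T", "C"), cat) == "rs1"

    def test_random_lookups_match_linear_scan(self, rng):
        entries = []
        for i in range(200):
            pos = int(rng.integers(1, 1_000))
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            entries.append(f"chr1\t{pos}\t{ref}\t{alt}\trs{i}")
        cat = SnpCatalog.from_lines(entries)
        from segannot.gene_model import complement_base

        for _ in range(500):
            pos = int(rng.integers(0, 1_000))
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            snv = Snv("q", "chr1", pos, str(ref), str(alt))
            expected = None
            for chrom, cpos, cref, calt, sid in cat.entries():
                if (chrom, cpos) != ("chr1", pos):
                    continue
                if (snv.ref, snv.alt) == (cref, calt) or (
                    snv.ref, snv.alt
                ) == (complement_base(cref), complement_base(calt)):
                    expected = sid
                    break
            assert cat.lookup(snv) == expected


class TestDrivers:
    def test_snv_mode_tally_conserves_and_ranks(self, fixture):
        index = build_index(fixture.transcripts)
        snvs = fixture.random_snvs(300)
        result = annotate_snvs(snvs, index, fixture.genome)
        assert result.tally.total == len(snvs)
        for rec_prev, rec in zip(result.all_records, result.all_records[1:]):
            if rec_prev.query_id == rec.query_id:
                assert rec_prev.rank <= rec.rank

    def test_indel_mode_has_no_tally(self, fixture):
        index = build_index(fixture.transcripts)
        result = annotate_indels(fixture.random_indels(50), index, fixture.genome)
        assert result.tally is None
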