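import pytest

from conftest import simple_transcript
from segannot.annotator import (
    AnnotationRecord,
    CoordinateQuery,
    IntervalQuery,
    LocusCategory,
    annotate,
    classify_coordinate,
    classify_interval,
)
from segannot.gene_model import Transcript
from segannot.interval_index import build_index


THREE_EXON_MINUS = simple_transcript(
    strand="-", exons=((100, 200), (300, 400), (500, 600)), cds=(100, 100)
)


def naive_annotate(queries, transcripts, range_bp, mode):
    """Oracle: classify every query against every transcript by linear scan."""
    from segannot.annotator import AnnotationResult, Tally, _best

    all_records, per_gene_best, overall_best = [], [], []
    tally = Tally()
    for q in queries:
        records = []
        for t in transcripts:
            if t.chrom != q.chrom:
                continue
            if mode == "coordinates":
                rec = classify_coordinate(q.pos, t, range_bp, query_id=q.id)
            else:
                rec = classify_interval(q.start, q.end, t, range_bp, query_id=q.id)
            if rec is not None:
                records.append(rec)
        if not records:
            tally.add(LocusCategory.INTERGENIC)
            continue
        records.sort(key=AnnotationRecord.sort_key)
        all_records.extend(records)
        by_gene = {}
        for rec in records:
            by_gene.setdefault(rec.gene, []).append(rec)
        gene_best = sorted(
            (_best(v) for v in by_gene.values()), key=AnnotationRecord.sort_key
        )
        per_gene_best.extend(gene_best)
        overall_best.append(gene_best[0])
        tally.add(gene_best[0].category)
    return AnnotationResult(all_records, per_gene_best, overall_best, tally)


class TestClassifyCoordinate:
    def test_minus_strand_exon_ordinal(self):
        # genomically middle exon is exon 2 regardless of strand here,
        # but the genomically last exon is exon 1 on the minus strand
        rec = classify_coordinate(350, THREE_EXON_MINUS)
        assert rec.category is LocusCategory.EXON and rec.exon_index == 2
        rec = classify_coordinate(550, THREE_EXON_MINUS)
        assert rec.exon_index == 1
        rec = classify_coordinate(250, THREE_EXON_MINUS)
        assert rec.category is LocusCategory.INTRON and rec.intron_index == 2

    def test_upstream_boundary_distance_one(self):
        t = simple_transcript()
        rec = classify_coordinate(t.tx_start - 1, t, range_bp=10_000)
        assert rec.category is LocusCategory.UPSTREAM and rec.distance == 1
        rec = classify_coordinate(t.tx_end, t, range_bp=10_000)
        assert rec.category is LocusCategory.DOWNSTREAM and rec.distance == 1

    def test_out_of_range_returns_none(self):
        t = simple_transcript()
        assert classify_coordinate(t.tx_start - 11, t, range_bp=10) is None

    def test_random_positions_match_per_base_oracle(self, fixture, rng):
        transcripts = fixture.transcripts
        for _ in range(3_000):
            t = transcripts[rng.integers(len(transcripts))]
            pos = int(rng.integers(max(0, t.tx_start - 200), t.tx_end + 200))
            rec = classify_coordinate(pos, t, range_bp=100)
            # direct region membership
            in_exon = any(s <= pos < e for s, e in t.exons)
            in_intron = any(s <= pos < e for s, e in t.introns())
            if in_exon:
                assert rec.category is LocusCategory.EXON
            elif in_intron:
                assert rec.category is LocusCategory.INTRON
            elif pos < t.tx_start:
                expect = LocusCategory.UPSTREAM if t.strand == "+" else LocusCategory.DOWNSTREAM
                if t.tx_start - pos <= 100:
                    assert rec.category is expect
                else:
                    assert rec is None
            else:
                expect = LocusCategory.DOWNSTREAM if t.strand == "+" else LocusCategory.UPSTREAM
                if pos - t.tx_end + 1 <= 100:
                    assert rec.category is expect
                else:
                    assert rec is None


class TestClassifyInterval:
    def test_interval_equal_to_exon(self):
        t = simple_transcript()
        rec = classify_interval(100, 200, t)
        assert rec.category is LocusCategory.CONTAINED_IN_EXON
        assert rec.exon_index == 1

    def test_minimal_junction_straddle(self):
        t = simple_transcript()
        rec = classify_interval(199, 201, t)
        assert rec.category is LocusCategory.SPANS_EXON_INTRON

    def test_crossing_gene_boundary(self):
        t = simple_transcript()
        rec = classify_interval(50, 150, t)
        assert rec.category is LocusCategory.OVERLAPS_GENE_BOUNDARY

    def test_empty_interval_errors(self):
        with pytest.raises(ValueError):
            classify_interval(10, 10, simple_transcript())

    def test_randomized_intervals_match_per_base_combination(self, fixture, rng):
        transcripts = fixture.transcripts
        for _ in range(2_000):
            t = transcripts[rng.integers(len(transcripts))]
            start = int(rng.integers(max(0, t.tx_start - 100), t.tx_end + 100))
            end = start + int(rng.integers(1, 500))
            rec = classify_interval(start, end, t, range_bp=50)
            # oracle: combine per-base membership over the covered bases
            bases = range(start, end)
            any_exon = any(
                s <= p < e for p in bases for s, e in t.exons
            )
            any_intron = any(
                s <= p < e for p in bases for s, e in t.introns()
            )
            overlaps = start < t.tx_end and t.tx_start < end
            if overlaps and (start < t.tx_start or end > t.tx_end):
                assert rec.category is LocusCategory.OVERLAPS_GENE_BOUNDARY
            elif any_exon and any_intron:
                assert rec.category is LocusCategory.SPANS_EXON_INTRON
            elif any_exon:
                assert rec.category is LocusCategory.CONTAINED_IN_EXON
            elif any_intron:
                assert rec.category is LocusCategory.CONTAINED_IN_INTRON
            elif rec is not None:
                assert rec.category in (LocusCategory.UPSTREAM, LocusCategory.DOWNSTREAM)


class TestAnnotate:
    def make_isoform_pair(self):
        """Same gene: position 350 is exonic in iso_a, intronic in iso_b."""
        iso_a = Transcript(
            id="iso_a", gene="G", chrom="chr1", strand="+",
            tx_start=100, tx_end=600, cds_start=100, cds_end=100,
            exons=((100, 400), (500, 600)),
        )
        iso_b = Transcript(
            id="iso_b", gene="G", chrom="chr1", strand="+",
            tx_start=100, tx_end=600, cds_start=100, cds_end=100,
            exons=((100, 200), (500, 600)),
        )
        return iso_a, iso_b

    def test_exon_record_beats_intron_record_per_gene(self):
        iso_a, iso_b = self.make_isoform_pair()
        index = build_index([iso_a, iso_b])
        result = annotate([CoordinateQuery("q1", "chr1", 350)], index)
        assert len(result.per_gene_best) == 1
        best = result.per_gene_best[0]
        assert best.transcript_id == "iso_a"
        assert best.category is LocusCategory.EXON
        # both isoforms still present in the full record file
        assert {r.transcript_id for r in result.all_records} == {"iso_a", "iso_b"}

    def test_gene_free_chromosome_is_intergenic(self, fixture):
        index = build_index(fixture.transcripts)
        result = annotate([CoordinateQuery("q", "chrEmpty", 5)], index)
        assert result.tally.counts == {"INTERGENIC": 1}
        assert result.all_records == []

    def test_tally_conserves_query_count(self, fixture):
        index = build_index(fixture.transcripts)
        queries = [
            CoordinateQuery(f"q{i}", chrom, pos)
            for i, (chrom, pos) in enumerate(fixture.random_positions(500))
        ]
        result = annotate(queries, index)
        assert result.tally.total == len(queries)
        assert len(result.overall_best) + result.tally.counts.get("INTERGENIC", 0) == len(queries)

    def test_interval_tally_conserves(self, fixture):
        index = build_index(fixture.transcripts)
        queries = [
            IntervalQuery(f"i{i}", chrom, s, e)
            for i, (chrom, s, e) in enumerate(fixture.random_intervals(300))
        ]
        result = annotate(queries, index, mode="intervals")
        assert result.tally.total == len(queries)

    def test_larger_range_never_loses_gene_contact(self, fixture):
        index = build_index(fixture.transcripts)
        queries = [
            CoordinateQuery(f"q{i}", chrom, pos)
            for i, (chrom, pos) in enumerate(fixture.random_positions(300))
        ]
        small = annotate(queries, index, range_bp=500)
        large = annotate(queries, index, range_bp=20_000)
        assert large.tally.counts.get("INTERGENIC", 0) <= small.tally.counts.get(
            "INTERGENIC", 0
        )

    @pytest.mark.parametrize("mode", ["coordinates", "intervals"])
    def test_full_annotate_equals_naive_scan(self, fixture, rng, mode):
        index = build_index(fixture.transcripts, bin_size=50_000, tree_threshold=0)
        if mode == "coordinates":
            queries = [
                CoordinateQuery(f"q{i}", chrom, pos)
                for i, (chrom, pos) in enumerate(fixture.random_positions(400))
            ]
        else:
            queries = [
                IntervalQuery(f"i{i}", chrom, s, e)
                for i, (chrom, s, e) in enumerate(fixture.random_intervals(400))
            ]
        got = annotate(queries, index, range_bp=2_000, mode=mode)
        expected = naive_annotate(queries, fixture.transcripts, 2_000, mode)
        assert [vars(r) for r in got.all_records] == [vars(r) for r in expected.all_records]
        assert [vars(r) for r in got.overall_best] == [vars(r) for r in expected.overall_best]
        assert got.tally.counts == expected.tally.counts
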