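# segannot

Segment-tree-indexed annotation of genomic coordinates, intervals, SNVs,
indels and translocations against transcript models.

Resequencing and other NGS studies routinely produce millions of mapped
positions and called variants that must be placed relative to known genes:
which reads fall in exons or introns, which SNVs change the encoded
protein, how far a peak lies from the nearest transcription start site.
`segannot` answers these questions without a database server.  Transcript
models (UCSC genePred dialect, or custom BED/PSL features) are loaded into
a binned, serializable index whose dense bins hold **segment trees** —
balanced binary trees built over the sorted unique endpoints of the
features, in which every stored interval decomposes into O(log n) canonical
nodes.  A stabbing query for a coordinate walks one root-to-leaf path; a
range query descends to the node where the query endpoints separate and
harvests the flanking subtrees (the classic *vsplit* strategy), so each
query touches a small fraction of the stored features.

On top of the index sit five annotation modes:

1. **coordinates** — exon/intron/upstream/downstream calls with strand-aware
   exon and intron ordinals, within a configurable range (default 10 kb);
2. **intervals** — contained-in-exon / spans-exon-intron / contained-in-
   intron / overlaps-gene-boundary refinements for short intervals;
3. **snv** — codon-level consequence calls (synonymous, non-synonymous,
   stop-gain, UTR, splice-site within 2 bp of a junction, intron,
   up/downstream), amino-acid changes such as `K2R`, the full mutated
   protein sequence, and optional known-SNP catalog lookup;
4. **tss** — closest transcription start site regardless of strand, by
   binary search in a sorted TSS array, with a signed-distance histogram;
5. **indel / translocation** — frameshift vs in-frame calls from the spliced
   CDS length change, mutated proteins, and putative fusion proteins for
   breakpoint pairs with compatible retained sides.

Every mode writes three record files — all transcripts, the most relevant
transcript per gene, and the most relevant transcript overall (an exonic
hit in one isoform outranks an intronic hit in another) — plus, for modes
1–3, a tally of queries per category that always sums to the number of
inputs.  A deterministic synthetic-data generator (`segannot simulate`)
produces genomes, gene sets and query files so the whole tool can be
exercised offline.

## Worked example

```sh
segannot simulate --seed 5 --out-dir sim
segannot index build --genes sim/genes.genepred --out genes.idx
# -> indexed 32 features -> genes.idx
segannot annotate --mode snv --index genes.idx --queries sim/snvs.tsv \
    --genome sim/genome.fa --proteins --out-prefix out/snv
```

`out/snv.best.tsv` holds the most relevant call per SNV, e.g.

```
query_id  transcript   gene    category       exon intron distance aa_change known_id ref_mismatch
snv94     GENE1.iso0   GENE1   SYNONYMOUS     .    .      0        A35A      .        0
snv113    GENE13.iso0  GENE13  NONSYNONYMOUS  .    .      0        R14I      .        0
```

`snv113` lands in the coding sequence of `GENE13.iso0` and replaces
arginine 14 with isoleucine; `snv94` changes codon 35 without changing the
alanine it encodes.  `out/snv.tally.tsv` summarizes all 200 inputs
(counts sum to 200):

```
category        count
DOWNSTREAM      2
INTERGENIC      56
INTRON          58
NONCODING_EXON  8
NONSYNONYMOUS   3
SPLICE_SITE     1
SYNONYMOUS      2
UPSTREAM        49
UTR3            11
UTR5            10
# total 200
```

and `out/snv.proteins.fa` contains the full mutated proteins, e.g. the
R14I variant of GENE13 (`...MRVKRDPLSVAQAIVVTVYTT...`), ready for
proteomics workflows.

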