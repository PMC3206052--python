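# Methods

## The index

Features are assigned to fixed-width genomic bins (default 1 Mbp,
configurable; `None`/`inf` disables binning).  A feature spanning k bins is
registered in all k, and query results are deduplicated by feature
identity and sorted by `(start, end, id)` so output order never depends on
insertion order or bin layout.  Within a bin, storage switches from a
plain array to a segment tree when the feature count exceeds
`tree_threshold` (default 64).  Both defaults are package choices: the
binning mirrors the window sizes commonly used for genome-browser tables,
and 64 is roughly where a tree walk starts beating a linear scan of a
Python list; neither affects results, only speed, and the test grid
includes the degenerate settings (threshold 0 = always tree, ∞ = never).

The segment tree is built over the elementary intervals between the sorted
unique endpoints of the bin's features (endpoints clipped to the bin; the
feature objects themselves are stored unclipped).  Leaves are the
elementary intervals; internal nodes span the concatenation of their
children; each stored interval is decomposed into the canonical nodes it
fully covers, so it appears in O(log n) payloads.  A stabbing query
collects payloads along the single root-to-leaf path whose node intervals
contain the position.  A range query uses the vsplit strategy: payloads are
collected while both query endpoints lie in the same child; at the split
node the two flanking root-to-leaf paths are walked, harvesting every
right subtree while walking the left boundary and every left subtree while
walking the right boundary.  All coordinates are half-open, which makes
endpoint membership unambiguous: a feature ending at `pos` does not
contain `pos`.

Range queries are capped at 100 Mbp; wider requests raise an error rather
than silently scanning a chromosome.

**Serialization.** The on-disk index is a versioned JSON-lines container:
a header (magic string, format version, build parameters, provenance), one
line per feature, and an end marker carrying the expected feature count.
Trees are rebuilt on load — building takes seconds at genome-annotation
scale, so structural serialization of the tree would add complexity and a
second code path for no benefit.  A missing end marker, wrong count,
incomplete final line, bad magic or unknown version all raise
`IndexFormatError`; the loader never silently misreads.

## Classification

A coordinate inside a transcript is EXON or INTRON with a 1-based,
strand-aware ordinal (exon 1 is the 5′-most exon on the transcript
strand).  Outside the transcript it is UPSTREAM or DOWNSTREAM — defined by
the transcript's strand, not the query's — when within `range_bp`
(default 10,000 bp) of the boundary, with the distance measured to the
nearest transcript edge (the base immediately left of `tx_start` is at
distance 1).  Intervals refine this: OVERLAPS_GENE_BOUNDARY when crossing
`tx_start`/`tx_end`, otherwise SPANS_EXON_INTRON, CONTAINED_IN_EXON or
CONTAINED_IN_INTRON; intervals longer than 2 kb are processed with a
warning.

Records for one query are clustered by gene symbol (genePred `name2` when
present, else the transcript id — the natural clustering key the format
provides).  Priority, highest first: exon > spans-exon-intron >
overlaps-boundary > intron > upstream > downstream; ties are broken by
smaller distance, then gene name, then transcript id.  Only the extremes
of this order are externally constrained (exonic hits must outrank
everything, downstream ranks last); the middle is a package choice made
total so that the per-gene and overall "most relevant transcript" files
are deterministic.  The tally counts one category per query, taken from
its overall-best record (a per-record tally would not conserve the query
count across multi-gene hits); queries with no record count as INTERGENIC.

## Consequence calling

For an SNV in the CDS, the spliced-CDS offset of the position is computed
from the exon/CDS intersection segments (mirrored for minus-strand
transcripts, with the allele complemented), the affected codon is
substituted and both codons translated: same residue → SYNONYMOUS, stop →
NONSENSE, else NONSYNONYMOUS.  NONSENSE as a category above NONSYNONYMOUS
is an extension; `collapse_nonsense=True` folds it back for coarser
tallies.  The full mutated protein is the translation of the substituted
spliced CDS up to the first stop (terminal `*` stripped).  Translation
uses the standard genetic code only; codons containing N yield `X`;
trailing partial codons are ignored; start-codon-destroying SNVs are
reported from the raw translated string without rescanning for a
downstream ATG.  A ref allele disagreeing with the genome is flagged but
annotated using the genome base; exonic non-CDS positions become
UTR5/UTR3 by strand-aware side (NONCODING_EXON for CDS-less transcripts,
including dbEST-style alignments, which therefore never receive
amino-acid calls); intronic positions within 2 bp of either junction are
SPLICE_SITE — a purely positional rule; no splice-pattern prediction is
attempted.

Consequence ranking, highest impact first: NONSENSE > FRAMESHIFT >
NONSYNONYMOUS > INFRAME_INDEL > SYNONYMOUS > SPLICE_SITE > UTR5 > UTR3 >
NONCODING_EXON > INTRON > UPSTREAM > DOWNSTREAM.

**Indels.** Edits are applied in spliced-CDS space: a deletion removes the
CDS-overlapping bases (contiguous there even when the deletion spans an
intron); an insertion lands at the spliced offset of its genomic insertion
point, reverse-complemented on minus-strand transcripts.  The convention —
an insertion at 0-based `pos` lands *before* `pos`; coordinates ≥ `pos`
shift right — means an insertion at an exon's start coordinate is
intronic while one at its end coordinate extends the exon.  Net CDS length
change mod 3 ≠ 0 → FRAMESHIFT, else INFRAME_INDEL; a deletion removing the
whole CDS keeps the frame category but reports no protein.  Edits touching
a splice window are additionally flagged in a secondary field without
changing the primary category.  Non-CDS placements fall back to the
single-base location categories, taking the highest-priority category over
the edited bases (for an insertion flush against the CDS edge, the non-CDS
flanking base — such an insertion does not change the protein).

**Translocations.** Each breakpoint is classified exactly like a
coordinate query.  A breakpoint's side (`5` = genomic coordinates ≤ pos
retained, `3` = ≥ pos retained) determines which part of an overlapping
transcript's CDS survives.  When one breakpoint retains a coding
transcript's CDS prefix (in transcript orientation) and the other a CDS
suffix, a putative fusion protein is emitted: the prefix and suffix
spliced-CDS pieces are concatenated and translated to the first stop, the
3′ piece read in whatever frame the 5′ piece's length implies.  This
composition rule is a package decision; breakpoints without compatible
coding contexts produce records but no protein.

**Known-SNP lookup.** The catalog is a position-keyed table of
(chrom, 1-based pos, ref, alt, id), assumed normalized to the + strand; a
query matches when position and allele pair agree directly or after
complementing both alleles.  Strand is otherwise ignored.

## Closest TSS

One entry per transcript: `tx_start` on +, `tx_end − 1` on −.  Entries are
sorted per chromosome and queried by binary search; isoforms sharing a TSS
are all kept, and the entry with the smallest transcript id represents a
run of identical positions.  Distance is signed genomically
(query − TSS), not strand-relative, and strand is ignored when choosing
the nearest; on an exact tie the smaller coordinate wins.  Both
conventions are package decisions, stated here because output signs and
tie winners depend on them.  The histogram uses symmetric half-open bins
`[k·b, (k+1)·b)` around zero with under/overflow bins; by the half-open
rule the single value −b·n lands in the lowest regular bin while +b·n
overflows.  Counts always sum to the number of queries.

## Synthetic data and what it does (not) show

The generator builds uniform-random genomes and genes with known
structure: per gene an exon template, an optional CDS chosen on the
spliced template (length a multiple of 3, ≥ 3 codons), and 1–3 isoforms
that share the CDS-bearing "core" exons but differ in non-core exons.
Coding sequences are painted onto the genome — ATG, non-stop codons, one
stop — so every coding transcript translates to `M…*` by construction and
protein-level assertions are exact.  Defaults: 2 chromosomes × 200 kb,
24 genes, 80% coding, exons 30–200 bp, introns 60–1,200 bp, intergenic
gaps 1–8 kb — sized so that a gene-dense but resolvable landscape fits in
memory-light tests.  Identical seeds give identical fixtures, including
query samples.

Deliberately not modeled: overlapping and nested genes, realistic base
composition, N runs, selenocysteine/readthrough, multi-transcript CDS
variation within a gene, and chromosome-scale feature counts.  Passing
tests therefore demonstrate algorithmic correctness of indexing,
classification and protein reconstruction — not robustness to every
pathology of real annotation databases.  Overlap-heavy stress for the
index uses a separate uniform random-interval generator where features
collide freely.

The naive oracles are kept independent of the main code paths: index
queries are checked against vectorized linear scans; consequence calls
against a full rebuild that mutates the chromosome string, shifts
coordinates across the edit, re-extracts the CDS and translates with a
hand-enumerated codon table; TSS results against an exhaustive scan.

## Problem sizes

The standard verification runs use 20 index fixtures (up to 5,000 features
each; 10,000 stabbing plus 10,000 range queries per fixture, with the
array-only degenerate configurations exercised at up to 1,000 features),
10,000 SNVs and 2,000 indels against the rebuild oracle, exhaustive
splice-window sweeps over every fixture junction, and 10,000 TSS queries
plus engineered ties.  Operation counting uses 2,000 stabs at 500 and
5,000 features to show the per-query work of the tree is a small, slowly
growing fraction of a linear scan.

## Known limitations

- genePred dialect only for transcript models (no GTF/GFF); PSL
  minus-target coordinates are taken as already forward-mapped.
- CDS lengths that are not a multiple of 3 are tolerated but the trailing
  stub codon is not given amino-acid calls.
- The 11-column genePred variant is ambiguous between score and name2; a
  non-numeric 11th column is read as the gene symbol.
- Indexes store features, not trees; loading re-derives the structure, so
  two indexes built from the same features always answer identically but
  load time grows with feature count.
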