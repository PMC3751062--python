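# Methods

`holotx` re-creates, at desk scale, the computational workflow used to
characterise a coral holobiont transcriptome: paired-end cDNA reads are
assembled de novo across several k-mer sizes, the best assemblies are
combined and merged, open reading frames are extracted and annotated by
homology against a distant reference proteome, expressed isoforms are
grouped into homologous protein-family clusters, symbiont-derived
sequences are partitioned out, and per-transcript expression is quantified
as RPKM.  This note records the models, the parameters that matter, the
numerical choices, and what the synthetic data do and do not emulate.

## Assembly

**Model.** A strand-merged unitig assembler over a de Bruijn graph: nodes
are canonical k-mers (the lexicographic minimum of a k-mer and its reverse
complement) with an occurrence-count floor, edges are observed (k+1)-mers,
and contigs are maximal non-branching paths, emitted once per canonical
orientation in lexicographic order.  k must be odd so no k-mer is its own
reverse complement.  There is no tip clipping or bubble popping: on the
intended inputs (error-free or low-error reads) the count floor
(`min_kmer_count`, default 1; the pipeline default is 2) removes
sequencing-error nodes, and anything the floor misses surfaces as short
unitigs that the downstream length filter drops.

**Multi-k selection.** Weakly expressed transcripts assemble best at small
k, strongly expressed ones at large k, so the pipeline sweeps several k
values (default 29–45 for 75 bp reads), ranks the per-k assemblies by N50
and keeps the top three.  N50 ties prefer the larger k (deterministic, and
larger k resolves longer repeats).  Among the kept assemblies, the one
with the longest median contig length contributes *all* of its contigs;
the others lose contigs shorter than 150 bp.  The asymmetry preserves
short bridging material from exactly one assembly while removing bulk
fragment noise.

Nx is defined as the largest length L such that contigs of length ≥ L sum
to at least x% of the total assembly length; the implementation compares
`100·cumsum ≥ x·total` in integer arithmetic so boundary cases are exact.

**Overlap merge.** The combined pool is merged by a greedy
overlap-layout-consensus step: ungapped suffix–prefix overlaps (both
orientations) of at least `min_overlap = 40` bases at
`min_identity = 0.90` are merged best-overlap-first (most matching bases,
ties broken deterministically by working-set index); contained and
duplicate contigs are absorbed.  Candidate offsets come from shared
16-mers, so only plausible placements are scored.  In a pairwise merge the
consensus base in the overlap is taken from the longer sequence — with two
sequences there is no majority, and this rule is deterministic.  Indels
inside overlaps are not modelled; the substitution-only read simulator and
unitig inputs make gapped overlap handling unnecessary.

## ORF extraction

All six reading frames are scanned for maximal stop-free codon runs
between stop codons, with sequence ends also acting as boundaries
(assembled transcripts are frequently truncated, so partial ORFs at contig
edges are real signal).  Intervals are stop-exclusive; a run is kept when
its nucleotide span is strictly greater than `min_nt = 150`.  Codons
containing ambiguity codes translate to `X` and never terminate a run
(conservative: an `N` might or might not be part of a stop).  Every
reported ORF carries its frame, strand, 1-based forward-contig
coordinates, peptide, and the cDNA span that translates to the peptide.

## Homology search and E-values

Alignment is optimal Smith–Waterman under affine gaps (gap of length g
costs `open + g·extend`), delegated to Biopython's `PairwiseAligner`;
the test-suite checks it against an independent exhaustive
dynamic-programming oracle.  Significance uses the Karlin–Altschul
formula

    E = K · m · n · exp(−λ · S)

with the standard gapped protein constants (BLOSUM62, open 11, extend 1,
λ = 0.267, K = 0.041) and a blastn-like nucleotide scheme (match +1,
mismatch −2, open 5, extend 2, λ = 1.28, K = 0.46).  m is the query
length, n the total residue count of the database, both used raw: edge
corrections would shift every E-value by a similar factor and none of the
pipeline's decisions depend on absolute calibration against any external
tool.  These E-values are therefore *internally* consistent but not
interchangeable with NCBI BLAST output.

Searches report every pair with E below the threshold, sorted per query by
ascending E (ties: higher score, then lexicographic subject id); the same
tie-break defines best hits.  Translated search six-frame-translates the
nucleotide query, splits frames at stops, and searches fragments of ≥15
residues in protein mode, keeping the best frame per subject (m is taken
as query length in codons).  An optional shared-word prefilter
(`seed_filter_word`) skips pairs with no exact word in common; it is off
by default and verified in tests to reproduce the full-DP hit table on
realistic inputs.

The annotation threshold is E ≤ 2e-30, with a relaxed 2e-10 tier used only
by the family screen.  One-directional best hits (ORF → reference) drive
annotation; a strict reciprocal-best-hit filter is available
(`reciprocal_best_hits`) but off by default, since isoforms of one gene
necessarily share their reference best hit and would be discarded by
strict reciprocity.

**Completeness.** The fraction of the reference proteome with at least one
hit at E ≤ 2e-30 whose aligned span covers at least 80% of the reference
protein's length (boundary inclusive).  It is a coverage census of the
reference, not of the assembly, so it is monotone under added hits.

## Clustering and annotation transfer

The pre-clustering graph has ORF ids and reference ids as nodes and edge
weight `min(−log10 E, 200)` (E = 0 maps to the cap; duplicate pairs keep
the best E).  Markov clustering alternates expansion (matrix squaring) and
inflation (entrywise power r = 2.5 with column renormalisation), with
self-loops set per node to its maximum incident weight, pruning of entries
below 1e-5 (renormalising afterwards), and convergence declared when the
maximum absolute entry change between inflation steps drops below 1e-8
(cap 200 iterations; non-convergence returns the current interpretation
with a warning).  Clusters are the connected components of the attractor
matrix's support.  Column sums are tracked every iteration; the worst
deviation from 1 is reported and stays at machine precision.  The matrices
are dense NumPy arrays — graphs at this scale have at most a few hundred
nodes, where dense expansion is faster than sparse bookkeeping.

Clusters inherit the union of their reference members' GO/KOG/InterPro
labels; the cluster gene name comes from the reference member with the
best (lowest-E) supporting hit from the cluster's ORFs.  GO category
membership is read from the annotation table itself (terms are
`category:term` tokens), not from an ontology download.  Because Markov
clustering can in principle merge several reference proteins into one
cluster, a complementary per-reference grouping (`group_by_reference`)
is provided: one group per matched reference protein, the reading under
which cluster counts equal matched-reference counts.

The family screen reports, for clusters containing any of a given set of
reference ids (e.g. the fluorescent-protein entries of a reference
proteome), the ORF members qualifying at 2e-30 and, in a second tier
flagged `relaxed`, those qualifying only at 2e-10.

## Symbiont partition

Holobiont assemblies mix host transcripts with transcripts of the algal
endosymbiont, and the symbiont's conserved genes are similar enough to the
host-side reference to pass annotation.  The separating cutoff is
calibrated from a reciprocal nucleotide search between the host-side
reference and the symbiont transcriptome: the geometric mean
(10^mean(log10 E)) of the pooled cross-hit E-values.  The geometric mean
is the only stable reading of an "average E-value" — the arithmetic mean
(available behind a flag) is dominated by its largest member and can never
produce a value like 1e-80 from a spread of magnitudes.  Zero E-values are
excluded from the log-mean with a warning.  When calibration is skipped
(the pipeline default) the operating cutoff is 1e-80.

A cDNA region is labelled symbiont iff its best nucleotide hit against the
symbiont database has E ≤ cutoff; best-hit-only classification keeps the
rule monotone in the cutoff.  The partition is binary and exhaustive, and
symbiont percentages are reported against both the annotated-region set
and the total contig count.  As a cross-check, every host-labelled region
is six-frame-translated and searched against the reference proteome; the
best subject must match the one found by the original peptide search.

## Quantification

Reads are mapped to annotated cDNA regions by seed-and-verify:
`max_mismatch + 1` exact 31-mer seeds spread evenly across the read anchor
candidate ungapped full-length placements on either strand, the placement
with the fewest mismatches (≤ 2) wins, and reads tied between different
transcripts are discarded as ambiguous.  Only uniquely mapped reads are
counted — the convention the RPKM definition assumes — and mates are
mapped independently as single-end reads.  Seed spreading is a heuristic:
mismatches falling in every seed window leave a read unmapped, which at
the default error rates affects a negligible fraction of reads.

    RPKM = 1e9 · C / (N · L)

with C reads on the transcript, N total uniquely mapped reads, L
transcript length in bp.  Expression summaries (min/mean/max reads and
RPKM) cover transcripts with at least one mapped read; any stronger
reporting floor is a display filter, not part of quantification.

## Synthetic data

The generator builds a study with known ground truth:

- a reference proteome of `n_families` gene families (default 12), each
  drawn from a random ancestor with paralogs at 10% within-family
  divergence — within-family identity ~80%, between-family ~5% (random
  20-letter background);
- host transcripts (default 36): 5'UTR + in-frame stop + CDS + stop +
  3'UTR, the CDS back-translated (uniform-random synonymous codons) from a
  reference protein mutated at 5% per residue; 10% carry random N-terminal
  extensions of 20–60 residues, emulating long 5'-extended isoforms;
- a symbiont pool (default 8) derived from the same ancestral proteins at
  50% divergence — so weak cross-taxon similarity exists, which is what
  makes cutoff calibration meaningful — with each expressed symbiont
  transcript a pool member plus 1% nucleotide noise;
- log-normal relative abundances (σ = 1) and 75 bp read pairs (default
  4000 pairs ≈ 25× coverage) from uniform fragment positions
  (insert 200 ± 30 bp) with substitution errors at 0.5% per base.

All randomness flows from one integer seed through
`numpy.random.default_rng`; identical seeds give byte-identical files.

**What the generator does not emulate,** and hence what passing tests do
not show about real data: indels and quality-score structure in reads;
codon bias (back-translation is uniform, which makes nucleotide identity
between related CDSs lower than in real genomes); strand-specific
libraries and PCR duplicates; UTR/intergenic repeats; and real cross-taxon
similarity profiles, which are dominated by a handful of ultra-conserved
genes rather than a uniform divergence level.  One structural consequence
of the uniform fragment model: terminal transcript bases are covered with
probability below 1 at any finite depth (only a fragment starting at base
0 covers base 0), so complete-tiling properties hold for the transcript
interior and assembly recovery is scored at 95% length coverage rather
than 100%.

## Problem sizes

Tests and the acceptance script run everything at desk scale, chosen so
the whole suite completes in well under a minute of compute per stage:
500 random pairs for the alignment oracle, 1,000 length multisets for the
N-statistic oracle, 200 random contigs for the ORF oracle; 20 transcripts
at 30× error-free coverage for assembly recovery; 10 families × 2 paralogs
× 2 expressed isoforms for cluster recovery; the default 44-transcript
holobiont for annotation, partitioning and expression recovery; and a
16-host/4-symbiont configuration for the end-to-end determinism check.
The clustering fixture expresses each reference protein as two isoform
transcripts because the object under study is the isoform cluster; with a
single ORF per reference protein, Markov clustering at r = 2.5 legitimately
splits a family's complete-bipartite subgraph into per-reference pairs —
the same ambiguity that makes cluster counts track matched-reference
counts.

## Known limitations

- No paired-end scaffolding: mates constrain nothing beyond their own
  placements.
- E-values are internally consistent, not calibrated to NCBI BLAST.
- The merge step's ungapped overlap model cannot bridge indel
  disagreements between contigs.
- Markov clustering is dense; inputs with many thousands of nodes would
  need a sparse implementation.
- Expression recovery compares RPKM ranks against molar abundances; the
  effective-length/length ratio varies across transcripts, so rank
  agreement is high but not exact even at infinite depth.
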