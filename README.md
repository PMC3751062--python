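# holotx

Holobiont transcriptome characterisation at desk scale: de novo multi-k
assembly, homology clustering of expressed isoforms, symbiont partitioning
and expression quantification, with a ground-truth synthetic-data
generator so every stage is testable without real sequencing data.

## Who this is for

Sequencing a coral (or any host plus endosymbiont) yields a *holobiont*
library: host and symbiont transcripts mixed, no genome to map against,
and only a distantly related reference proteome for annotation.  `holotx`
implements the standard workflow for that situation as a single tested
Python package:

1. **Assembly** — unitig de Bruijn assembly across several k-mer sizes
   (small k recovers weakly expressed transcripts, large k the strongly
   expressed ones), selection of the top three assemblies by N50, a
   150 bp length filter that spares the longest-median assembly, and a
   greedy overlap-consensus merge of the combined pool.
2. **ORFs** — six-frame stop-to-stop open reading frames longer than
   150 bp, with the cDNA region backing each ORF.
3. **Annotation** — Smith–Waterman search of ORF peptides against a
   reference proteome with Karlin–Altschul statistics,
   `E = K·m·n·e^(−λS)`, thresholded at E ≤ 2e-30.
4. **Clustering** — Markov clustering (inflation r = 2.5) of the
   ORF/reference similarity graph into homologous isoform clusters, with
   GO/KOG/InterPro annotation transfer and a gene-family screen
   (primary tier 2e-30, relaxed tier 2e-10).
5. **Completeness** — the fraction of the reference proteome covered
   ≥ 80% of its length by qualifying hits.
6. **Symbiont partition** — an E-value cutoff calibrated as the geometric
   mean of reciprocal cross-taxon nucleotide hits (operating default
   1e-80); regions whose best symbiont hit beats the cutoff are labelled
   symbiont-derived, and host labels are confirmed by translated search.
7. **Quantification** — unique-mapper read counting and
   `RPKM = 1e9·C/(N·L)` per annotated cDNA region.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Run the whole pipeline on a simulated holobiont (12 reference gene
families, 36 host + 8 symbiont transcripts, 4,000 read pairs of 75 bp at
0.5% error):

```sh
holotx pipeline --seed 1 --out-dir run
```

which writes every intermediate (per-k FASTA, merged contigs, ORF
peptides, hit table, clusters, partition, expression table, ground-truth
tables) under `run/` and prints the stage report:

```
"assembly_per_k": { "29": {"n_contigs": 346, "n50": 151, ...}, ... }
"merged":        { "n_contigs": 169, "n50": 245 }
"orfs":          { "n_orfs": 133 }
"search":        { "n_hits": 53, "n_annotated_orfs": 30 }
"clusters":      { "n_clusters": 14, "n_annotated_clusters": 14 }
"completeness":  { "percent": 83.33 }
"partition":     { "threshold": 1e-80, "n_symbiont": 0, "n_host": 30, ... }
"translated_confirmation": { "agreement": 1.0 }
"quantify":      { "n_mapped": 2420, "summary": { "reads_min": 10,
                   "reads_mean": 80.7, "reads_max": 244, ... } }
```

Reading the numbers: the k = 29 assembly wins the N50 ranking (weakly
expressed transcripts dominate at this depth), merging lifts N50 from 151
to 245 and collapses 429 pooled contigs to 169; 30 of 133 ORFs annotate
against the reference at 2e-30 and group into 14 isoform clusters, all of
which receive a transferred gene name; 83% of the reference proteome is
covered at ≥ 80% length; no annotated region beats the 1e-80 symbiont
cutoff in this run (the symbiont transcripts were too weakly expressed to
assemble), every host label is confirmed by translated search, and mapped
read counts per annotated region range from 10 to 244.

The same stages are available individually (`holotx simulate`, `assemble`,
`nstats`, `orfs`, `search`, `cluster`, `completeness`, `partition`,
`quantify`), and as library functions for programmatic use:

```python
from holotx import simulate, orffinder, homology

truth, m1, m2 = simulate.simulate_holobiont(seed=1)
orfs = [o for t in truth.transcripts for o in orffinder.find_orfs(t)]
hits = homology.search(orffinder.orf_peptides(orfs),
                       truth.reference_proteome, evalue_max=2e-30)
```

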