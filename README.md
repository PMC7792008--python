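# hybridec

Hybrid error correction of noisy long reads (ONT-class, ~10% mixed errors)
using accurate short reads (Illumina-class paired-end) indexed in a
compacted, colored de Bruijn graph.  The corrector preserves heterozygous
variation: candidate SNP sites are marked on the graph with IUPAC ambiguity
codes and the raw read's allele is restored after path selection, so
correction does not collapse a diploid sample onto one haplotype.

## Who this is for

Anyone polishing kb-scale noisy reads with short accurate reads from the
same sample before assembly or variant calling, and anyone who wants a
readable, tested reference implementation of color-guided graph traversal
for hybrid correction.  Everything runs from Python; a `hybridec` CLI wraps
the library.

## Method

Two correction passes over a de Bruijn graph of the short-read set S:

1. **Index.** A compacted graph G₂ is built from the k₂-mers of S (k-mers
   seen once are discarded as sequencing errors); a short-k graph G₁ is
   derived from the k₁-mers of G₂'s unitigs (k₂ ≥ 2·k₁).  G₁'s unitig
   k-mers are *colored* with the read pairs that contain them, and
   positions where two graph k-mers differ by exactly one substitution are
   annotated with the IUPAC code of the two bases (candidate SNPs).
2. **Anchor.** Each long read k-mer is classified **solid** (exact unitig
   match), **near-solid** (one substitution or indel away), or **weak**.
   Runs of solid k-mers delimit the *non-solid regions* to correct; unique
   near-solid matches (UNSMs) inside a region serve as traversal waypoints.
3. **Traverse.** For each region a single corrective path is grown
   greedily, stage by stage (`P_max` unitigs per stage), keeping the
   extension with the highest conflated probability

   &nbsp;&nbsp;&nbsp;&nbsp;s_P = s_c·s_q / (s_c·s_q + (1−s_c)(1−s_q)),

   where s_q is infix-alignment sequence similarity to the raw region and
   s_c the fraction of the locally collected color set C the path carries
   (union over anchors within B bases, Eq.-style; per-side intersections in
   pass 2).  A color floor T_C = ⌊D·min|C_u|⌋ prunes poorly supported
   unitigs.  Dead ends leave a literal *gap* carrying the raw bases.
4. **Reconcile and restore.** Regions failing forward are retried backward;
   two incomplete paths are merged through global alignment to the raw
   region.  Finally, IUPAC-annotated positions on the chosen path are
   overwritten with the raw read's base when compatible — the SNP-aware,
   haplotype-preserving step.
5. **Pass 2** repeats anchoring/correction on G₂ (k₂-mers, long solid
   regions of at least B > k₂ bases) with colors taken from the pass-1
   corrected long reads themselves.

An optional reference-guided mode consumes SAM/PAF alignments, groups
reads into 5-Mbp bins, rescues unmapped short reads supported by the bin's
long reads (insertions absent from the reference), corrects bins
independently, and corrects ambiguously mapped reads last against
everything.

## Worked example

```sh
hybridec simulate --length 20000 --srs-cov 15 --lrs-cov 3 \
    --lrs-len-mean 2000 --seed 5 --out-dir sim
hybridec correct --srs sim/short_reads.fastq --lrs sim/long_reads.fastq \
    --out corrected.fasta --pass both
hybridec evaluate --reads corrected.fasta --truth-dir sim
```

which prints (exact numbers for this seed):

```json
{
  "n_reads": 31,
  "mean_error_rate": 0.00021295568232409194,
  "median_error_rate": 0.0,
  "skipped": 0,
  "het_retention": 0.9125
}
```

The simulated long reads start at ~10% error; after both passes the mean
truth-based error rate is ~0.02% (a ~450-fold reduction) and 91% of the
heterozygous SNP sites covered by a read still carry that read's haplotype
allele.  `hybridec index` exports the colored graph as GFA1 with a
candidate-SNP sidecar TSV; `hybridec bin-correct` runs the
reference-guided mode from a SAM or PAF file.

The library surface mirrors the pipeline: `graph_core` (build/color/
annotate/query), `anchoring`, `pathsearch`, `correction`, `pipeline`,
`simdata` (seeded diploid benchmark generator), `evaluate`, `cli_io`.
See `docs/methods.md` for the model, parameter defaults and limitations.

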