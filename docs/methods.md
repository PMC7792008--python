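# Methods

## Model and data structures

The corrector treats accurate short reads as a sample of the underlying
(diploid) genome and indexes them in a **compacted, colored de Bruijn
graph**.  Vertices of the underlying graph are canonical k-mers (the
lexicographic minimum of a k-mer and its reverse complement); maximal
non-branching paths are stored as single **unitigs**.  k is required to be
odd so no k-mer equals its own reverse complement, and at most 31 so a
k-mer packs into one 64-bit word — the whole anchoring layer is vectorised
over numpy arrays of packed k-mers (windows, reverse complements,
canonicalisation, edit-distance-1 neighbour enumeration, batched index
lookups through a sorted key array).

Three per-unitig tracks carry the evidence used during correction:

* **coverage** — the multiplicity of each k-mer in the input reads;
* **colors** — per k-mer *position*, the set of source-unit identifiers
  (short-read pairs in pass 1, corrected long reads in pass 2) containing
  that k-mer.  Colors are stored per position rather than per unitig so
  that color lookups at a match are not inflated by compaction.
* **candidate-SNP annotations** — IUPAC symbols at positions where two
  graph k-mers differ by exactly one substitution, found by probing the
  3k substitution neighbours of every k-mer against the index (O(3k·|G|)
  lookups instead of an all-pairs scan).  Multiple alternates at one
  position merge into the covering symbol; a hit between a k-mer and a
  reverse-complement occurrence annotates both sides symmetrically because
  every unitig enumerates its own neighbours in its stored orientation.

Two k-mer lengths are used: G₂ is built from the k₂-mers of the short
reads with a multiplicity filter (`min_count=2`; k-mers seen once are
treated as sequencing errors), and G₁ from the k₁-mers of G₂'s unitigs —
short k-mers anchor noisy reads well, long k-mers give contiguous unitigs,
and deriving G₁ from G₂ inherits the error filter.

## Anchoring

Every read window is classified solid / near-solid / weak.  Near-solid
candidates are the window's substitution neighbours, its single-base
deletions (with the next read base shifted in; generated only when that
base exists), and its strictly interior single-base insertions (with the
last window base dropped).  Insertions at window offset 0 are deliberately
not generated: such candidates merely re-anchor the previous read position
and, in practice, mass-produce spurious two-hit ambiguities that destroy
genuine unique matches.  Uniqueness is judged per graph *vertex*: a
candidate and its reverse complement resolve to the same stored k-mer and
count as one hit; a window with two or more distinct hit vertices yields
no waypoint (anchoring a read on the wrong allele is worse than not
anchoring).  A solid window contributes no near-solid matches.

Non-solid regions span successive non-adjacent solid matches, including
the flanking solid k-mers, so region length is l = p_t − p_s + k; head and
tail regions lack one anchor.  With the error-rate upper bound F, the
corrected sequence must lie in [⌈l/(1+F)⌉, ⌊l·(1+F)⌋].

## Guided traversal

One candidate path per region is grown greedily between waypoints (source
anchor → UNSMs in read order → target anchor), each leg with base budget
(Δread + k)·(1+F).  A stage enumerates all simple extensions of the
current path — up to `P_max` unitigs (pass 1) or until ≥ B appended bases
(pass 2, which makes stage scores length-comparable when unitig lengths
vary) — discards extensions containing a k-mer carrying fewer than
T_C = ⌊D·min|C_u|⌋ colors of the locally collected color set C, scores the
survivors, and commits only the argmax of

    s_P = s_c·s_q / (s_c·s_q + (1−s_c)·(1−s_q))

with s_q = 1 − (infix edit distance of the candidate to the raw region,
normalised by candidate length; edlib) and s_c = |C_p ∩ C| / |C|.
Numerical details that the formula alone does not fix:

* 0/0 (both factors degenerate) is defined as 0;
* an empty C gives s_c = 1 — absent evidence is not negative evidence;
* s_c = 1 makes the conflation saturate at 1 for any s_q > 0, so ties on
  s_P are broken by s_q, then by the lexicographically smallest extension
  (fully deterministic, seed-free);
* within one stage a (unitig, strand) pair is never revisited, but
  revisits across stages are allowed up to the base budget — short
  tandem-repeat cycles stay traversable without infinite loops.

C is the union of per-k-mer color sets over all solid matches and UNSMs
within B bases of the region (pass 1).  Pass 2 instead intersects colors
on each side of the region and unions the two sides — corrected long reads
are long enough that intersection removes erroneous colors without
emptying the set.  Legs that dead-end (graph tip, color-floor exhaustion,
budget) contribute a literal gap holding the raw read bases, and the walk
reseeds at the next waypoint (trimming re-emitted bases when waypoint
k-mers overlap in read coordinates).  Head/tail regions extend open-ended
to the length bound and are trimmed where a prefix-anchored alignment of
the raw remainder scores best.

## Reconciliation, SNP restoration, splicing

A complete path wins outright (forward preferred on ties).  Two incomplete
paths are merged by aligning each globally (edlib NW) to the raw region
and walking both alignments over raw coordinates, taking whichever
direction is graph-derived (non-gap) at each position — forward on ties —
and falling back to the raw base where neither covers.  After selection,
the path is aligned globally to the raw region; at every match/mismatch
column whose path base carries an IUPAC annotation (complemented when the
path traverses the unitig in reverse), the raw base overwrites the path
base if it belongs to the symbol's set.  A site that already agreed is
*strongly compatible* and licenses restoring annotated bases of the same
unitig inside the adjacent insertion runs, using the raw base at the
unitig-implied offset (the contiguous-run + offset-delta interpretation is
this package's concretisation; the alignment guard skips restoration when
the corrected/raw length ratio leaves [1/(1+F), 1+F]).  Region corrections
replace exactly the raw interval [p_s, p_t + k); adjacent regions sharing
a single-k-mer solid run overlap by k bases and the overlap is trimmed
from the later region.  Bases inside solid regions are never modified.

## Parameter defaults

| parameter | default | meaning / rationale |
|---|---|---|
| k₁ | 15 | anchoring k-mer length; odd, unique at desk scale (≤ ~10 Mbp) |
| k₂ | 31 | long k-mer length; k₂ ≥ 2·k₁, the engine's 64-bit packing caps k at 31 |
| min_count | 2 | k-mers seen once in the short reads are treated as errors |
| F | 0.4 | long-read error-rate upper bound; loose enough to admit true paths through locally error-dense stretches |
| B (pass 1) | 1000 b | color window spans a read pair plus insert gap |
| B (pass 2) | 2·k₂ | corrected reads anchor densely; a short window saves time; also the minimum solid-region length (must exceed k₂) |
| P_max | 4 | unitigs per greedy stage |
| D | 0.2 | color-floor factor |
| bin size | 5 Mbp | reference-guided binning granularity |
| MAPQ | 30 | below this a long read is ambiguous |

The k₁/k₂ defaults are this package's choice for its 64-bit k-mer engine
and desk-scale genomes; all are configurable (`RunConfig` validates
k₂ ≥ 2·k₁ and odd k).  Tests use k₁ = 9–15, k₂ = 19–31.

## Reference-guided mode

Mapping is an input (SAM via pysam, or 12-column PAF), never invoked.
Long reads bin by primary-alignment start (MAPQ < 30 or unmapped →
ambiguous bin); short-read pairs follow the first mapped mate; fully
unmapped pairs form S_u.  Per bin, k₁ graphs are built from the bin's
short reads (G_S) and long reads (G_L, initially inflated by erroneous
k-mers); lowest-mean-coverage unitig strata of G_L are removed while
|G_L| > 1.1·|G_S|, but never below |G_S| itself — with clean long reads
G_L can be a single unitig and unguarded removal would empty it.  An
unmapped pair joins the bin when > 50% of its k₁-mers occur in the cleaned
G_L but not in G_S (long-read-supported sequence absent from the mapped
short reads, e.g. an insertion).  Bins share no mutable state; output
merges in input read order; the ambiguous bin is corrected last against
all short reads with pass-2 colors augmented by the already corrected
reads.

## Synthetic benchmark generator

`simdata` emulates the input regime at desk scale: hap1 is iid uniform
ACGT; hap2 applies Poisson-spaced heterozygous SNPs and 1–5 bp indels
(sites closer than 63 bp are suppressed by default so truth evaluation is
unambiguous; disable with `min_spacing=0`).  Short reads are 2×151 bp
pairs from ~400 bp fragments with substitution errors only; long-read
lengths are log-normal truncated to [1 kb, 4× mean] with uniform-position
substitution/insertion/deletion errors — at most one event per template
base.  Not modelled: homopolymer-biased ONT errors, base-quality
structure, chimeras, adapter sequence, GC bias.  Passing tests on this
generator therefore demonstrate the correction logic under the stated
error regime, not performance on any particular instrument's error
profile.  Everything is reproducible from (parameters, seed), and truth
files (haplotype FASTA, VCF 4.2, provenance TSV) round-trip.

The evaluator defines a read's error rate as the edit distance to the
exact haplotype substring it was simulated from (end-free on the read
side), divided by the truth length — a truth-based re-specification, not
an alignment-to-reference estimate, so absolute numbers are comparable to
reference-based reports only in spirit.  Haplotype preservation is the
fraction of (read, covered het SNP site) pairs whose corrected base equals
the read's true allele, over sites the read aligns across.

## Problem sizes used by the shipped checks

The end-to-end benchmark uses a 100-kb diploid genome (SNPs 10⁻³, indels
2·10⁻⁴), 40× 2×151 bp short reads at 0.2% error and 20× long reads of
mean 8 kb at 10% mixed error; the idempotence check draws 1,000 error-free
reads from a 50-kb genome; oracle equivalence runs on 100 random 500-bp
genomes and on bubble graphs under 50 unitigs.  On these sizes the raw
~9.6% mean error rate drops to ~1% after pass 1 and ~0.015% after pass 2
with het retention ≈ 0.94 (the shipped tests assert the documented
thresholds: ≤ raw/3, pass 2 ≤ pass 1, retention ≥ 0.90).

## Known limitations

* k ≤ 31 end to end; human-scale k₂ = 63 contiguity is out of reach of
  the packed engine.
* The traversal is greedy by design; it can commit to a wrong branch that
  a global search would avoid — the backward pass, merging and SNP
  restoration exist precisely to blunt that failure mode.
* At small k on small genomes, spurious solid/near-solid matches (random
  k-mer collisions, distance-1 lookalikes) can bound regions with false
  anchors or seed false waypoints; the budget checks and gap mechanism
  keep the output safe (raw bases are preserved) but such regions are not
  corrected.  At the default k₁ = 15 on ≤ 10 Mbp data this is rare.
* Correction is single-process; the per-read and per-bin units are
  independent by contract (bin order cannot change the output), so
  process-level parallelism is safe but not built in.
* `prune_low_color_kmers` drops SNP annotations (prune before annotating).
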