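"""Two-pass correction orchestration and reference-guided binning.

Pass 1 builds a long-k graph (k2) from the short reads, derives a short-k
graph (k1) from its unitigs, colors it with short-read pairs and corrects
every long read independently.  Pass 2 rebuilds the k2 graph, colors it
with the pass-1 corrected long reads themselves — by then largely accurate
and far longer than any short read — anchors with k2-mers, demands solid
regions of at least B bases, and guides traversal with per-side color
intersections instead of unions.

The optional reference-guided mode consumes alignments (SAM or PAF; this
package never invokes a mapper), groups reads into 5-Mbp reference bins,
rescues unmapped short reads that belong in a bin (e.g. over large
insertions absent from the reference), corrects each bin independently and
finally corrects ambiguously mapped long reads against everything.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from ._kmers import canonical_u64, seq_to_codes, split_acgt, windows_u64
from .correction import PassConfig, correct_read
from .graph_core import (
    CCDBG,
    annotate_candidate_snps,
    build_graph,
    build_subgraph_from_unitigs,
    color_graph,
)
from .pathsearch import TraversalParams

logger = logging.getLogger(__name__)

DEFAULT_K1 = 15
DEFAULT_K2 = 31
DEFAULT_BIN_SIZE = 5_000_000
DEFAULT_MAPQ_MIN = 30


def pass1_config(k1: int = DEFAULT_K1, B: int = 1000) -> PassConfig:
    return PassConfig(
        pass_id=1, k=k1, color_mode="pair_union",
        min_solid_region=k1, B=B, frontier_mode="unitig_count",
    )


def pass2_config(k2: int = DEFAULT_K2, B: int | None = None) -> PassConfig:
    if B is None:
        B = 2 * k2
    if B <= k2:
        raise ValueError("pass-2 B must exceed k2")
    return PassConfig(
        pass_id=2, k=k2, color_mode="side_intersection",
        min_solid_region=B, B=B, frontier_mode="base_length",
    )


def _drop_duplicate_pairs(srs_pairs):
    seen = set()
    out = []
    for pid, m1, m2 in srs_pairs:
        key = (m1, m2)
        if key in seen:
            continue
        seen.add(key)
        out.append((pid, m1, m2))
    return out


def build_pass1_graph(srs_pairs, k1: int, k2: int, min_count: int = 2) -> CCDBG:
    """The pass-1 index: G2 from k2-mers of the short reads (singletons
    dropped), G1 from the k1-mers of G2's unitigs, colored per read pair
    and annotated with candidate SNPs."""
    seqs = [s for _pid, m1, m2 in srs_pairs for s in (m1, m2)]
    g2 = build_graph(seqs, k2, min_count)
    g1 = build_subgraph_from_unitigs(g2, k1)
    color_graph(g1, ((i + 1, (m1, m2)) for i, (_pid, m1, m2) in enumerate(srs_pairs)))
    annotate_candidate_snps(g1)
    return g1


def run_pass1(
    srs_pairs,
    lrs,
    k1: int = DEFAULT_K1,
    k2: int = DEFAULT_K2,
    min_count: int = 2,
    params: TraversalParams | None = None,
    remove_duplicate_pairs: bool = False,
):
    """First correction pass.  ``srs_pairs`` is ``[(pair id, mate1, mate2)]``,
    ``lrs`` is ``[(read id, sequence)]``; returns corrected ``(id, seq)``
    in input order plus per-read stats."""
    if params is None:
        params = TraversalParams(frontier_mode="unitig_count")
    cfg = pass1_config(k1, params.B)
    if not lrs:
        return [], {}
    if not srs_pairs:
        logger.warning("no short reads: long reads returned uncorrected")
        return list(lrs), {rid: {"flag": "no_srs"} for rid, _ in lrs}
    if remove_duplicate_pairs:
        srs_pairs = _drop_duplicate_pairs(srs_pairs)
    graph = build_pass1_graph(srs_pairs, k1, k2, min_count)
    out = []
    stats = {}
    for rid, seq in lrs:
        corrected, st = correct_read(seq, graph, params, cfg)
        out.append((rid, corrected))
        stats[rid] = st
    return out, stats


def run_pass2(
    srs_pairs,
    corrected_lrs,
    k2: int = DEFAULT_K2,
    min_count: int = 2,
    params: TraversalParams | None = None,
    helper_lrs=(),
):
    """Second correction pass over pass-1 output.

    The k2 graph is colored with the corrected long reads themselves (one
    color per read; no similar-read removal — corrected reads are not
    expected to be alike).  ``helper_lrs`` are additional already-corrected
    reads that contribute colors but are not corrected here (used by the
    binned mode for the ambiguous bin).
    """
    cfg = pass2_config(k2)
    if params is None:
        params = TraversalParams(B=cfg.B, frontier_mode="base_length")
    else:
        params = replace(params, B=cfg.B, frontier_mode="base_length")
    if not corrected_lrs:
        return [], {}
    if not srs_pairs:
        logger.warning("no short reads: long reads returned unchanged")
        return list(corrected_lrs), {rid: {"flag": "no_srs"} for rid, _ in corrected_lrs}
    seqs = [s for _pid, m1, m2 in srs_pairs for s in (m1, m2)]
    graph = build_graph(seqs, k2, min_count)
    units = [(i + 1, seq) for i, (_rid, seq) in enumerate(list(corrected_lrs) + list(helper_lrs))]
    color_graph(graph, units)
    annotate_candidate_snps(graph)
    out = []
    stats = {}
    for rid, seq in corrected_lrs:
        corrected, st = correct_read(seq, graph, params, cfg)
        out.append((rid, corrected))
        stats[rid] = st
    return out, stats


def run_both_passes(srs_pairs, lrs, k1=DEFAULT_K1, k2=DEFAULT_K2, min_count=2,
                    params: TraversalParams | None = None):
    p1, s1 = run_pass1(srs_pairs, lrs, k1, k2, min_count, params)
    p2, s2 = run_pass2(srs_pairs, p1, k2, min_count, params)
    return p2, {"pass1": s1, "pass2": s2}


# ---------------------------------------------------------------- binning


@dataclass
class Bin:
    """Reads assigned to one reference interval (or the ambiguous bin)."""

    ref: str | None
    start: int
    end: int
    srs_ids: set = field(default_factory=set)
    lrs_ids: set = field(default_factory=set)
    ambiguous: bool = False


def bin_reads(
    lr_alignments,
    sr_alignments,
    bin_size: int = DEFAULT_BIN_SIZE,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    ref_lengths: dict | None = None,
):
    """Assign reads to fixed-size reference bins from primary alignments.

    Long reads with MAPQ < ``mapq_min`` or unmapped go to the ambiguous
    bin.  Short-read pairs follow either mate's primary alignment (the
    first mapped one); pairs with both mates unmapped are returned
    separately as the unmapped set S_u.  Returns ``(bins, ambiguous_bin,
    srs_unmapped_ids)``.
    """
    bins: dict[tuple[str, int], Bin] = {}
    ambiguous = Bin(None, 0, 0, ambiguous=True)
    lr_unmapped = set()

    def get_bin(ref, pos):
        b0 = (pos // bin_size) * bin_size
        key = (ref, b0)
        if key not in bins:
            end = b0 + bin_size
            if ref_lengths and ref in ref_lengths:
                end = min(end, ref_lengths[ref])
            bins[key] = Bin(ref, b0, end)
        return bins[key]

    for rec in lr_alignments:
        if rec.secondary or rec.supplementary:
            continue
        if rec.unmapped or rec.mapq < mapq_min:
            ambiguous.lrs_ids.add(rec.read_id)
            lr_unmapped.add(rec.read_id)
        else:
            get_bin(rec.ref, rec.pos).lrs_ids.add(rec.read_id)

    sr_primary: dict[str, tuple] = {}
    for rec in sr_alignments:
        if rec.secondary or rec.supplementary:
            continue
        cur = sr_primary.get(rec.read_id)
        if cur is None or (cur[0] and not rec.unmapped):
            sr_primary[rec.read_id] = (rec.unmapped, rec.ref, rec.pos)
    srs_unmapped = set()
    for rid, (unmapped, ref, pos) in sr_primary.items():
        if unmapped:
            srs_unmapped.add(rid)
        else:
            get_bin(ref, pos).srs_ids.add(rid)

    ordered = [bins[k] for k in sorted(bins)]
    return ordered, ambiguous, srs_unmapped


def recover_unmapped(
    bin_: Bin,
    srs_seqs: dict[str, tuple[str, str]],
    lrs_seqs: dict[str, str],
    srs_unmapped_ids,
    k1: int = DEFAULT_K1,
    size_ratio: float = 1.1,
    kmer_fraction: float = 0.5,
):
    """Add unmapped short-read pairs that likely belong in this bin.

    A k1 graph G_S is built from the bin's short reads and G_L from its
    long reads (k-mers seen twice or more).  G_L initially contains many
    erroneous long-read k-mers, so its lowest-mean-coverage unitig strata
    are removed until |G_L| <= ``size_ratio``*|G_S|.  An unmapped pair is
    recovered when more than ``kmer_fraction`` of its k1-mers occur in the
    cleaned G_L but not in G_S — the signature of sequence supported by the
    long reads yet absent from the mapped short reads (e.g. an insertion).
    """
    if bin_.ambiguous:
        raise ValueError("recovery applies to non-ambiguous bins only")
    sr_seqs = [s for rid in bin_.srs_ids for s in srs_seqs[rid]]
    lr_seqs = [lrs_seqs[rid] for rid in bin_.lrs_ids]
    if not sr_seqs or not lr_seqs:
        return bin_
    g_s = build_graph(sr_seqs, k1, 2)
    g_l = build_graph(lr_seqs, k1, 2)
    if g_s.n_kmers == 0 or g_l.n_kmers == 0:
        return bin_
    strata = sorted(
        g_l.unitigs.values(),
        key=lambda u: sum(u.kmer_coverage) / len(u.kmer_coverage),
    )
    keep = {u.id for u in g_l.unitigs.values()}
    sizes = {u.id: u.n_kmers for u in g_l.unitigs.values()}
    total = g_l.n_kmers
    i = 0
    while total > size_ratio * g_s.n_kmers and i < len(strata):
        mean_cov = sum(strata[i].kmer_coverage) / strata[i].n_kmers
        j = i
        stratum_size = 0
        while j < len(strata) and sum(strata[j].kmer_coverage) / strata[j].n_kmers <= mean_cov:
            stratum_size += sizes[strata[j].id]
            j += 1
        if total - stratum_size < g_s.n_kmers:
            break  # removing this stratum would undershoot |G_S|
        for u in strata[i:j]:
            keep.discard(u.id)
        total -= stratum_size
        i = j
    gl_kmers = set()
    for uid in keep:
        u = g_l.unitigs[uid]
        canon, _ = canonical_u64(windows_u64(seq_to_codes(u.sequence), k1), k1)
        gl_kmers.update(int(v) for v in canon)
    gs_kmers = g_s.kmer_set()

    for rid in sorted(srs_unmapped_ids):
        n_total = 0
        n_evidence = 0
        for seq in srs_seqs[rid]:
            for _, seg in split_acgt(seq):
                if len(seg) < k1:
                    continue
                canon, _ = canonical_u64(windows_u64(seq_to_codes(seg), k1), k1)
                for v in canon:
                    n_total += 1
                    iv = int(v)
                    if iv in gl_kmers and iv not in gs_kmers:
                        n_evidence += 1
        if n_total and n_evidence > kmer_fraction * n_total:
            bin_.srs_ids.add(rid)
    return bin_


def run_binned(
    srs_pairs,
    lrs,
    lr_alignments,
    sr_alignments,
    k1: int = DEFAULT_K1,
    k2: int = DEFAULT_K2,
    min_count: int = 2,
    params: TraversalParams | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    recover: bool = True,
):
    """Reference-guided correction: bin, recover, correct bins independently.

    Bins share no mutable state, so their processing order cannot affect
    the result; output is merged in input long-read order.  The ambiguous
    bin is corrected last against all short reads, with pass-2 coloring
    assisted by the already corrected non-ambiguous long reads.
    """
    srs_by_id = {pid: (m1, m2) for pid, m1, m2 in srs_pairs}
    lrs_by_id = dict(lrs)
    bins, ambiguous, srs_unmapped = bin_reads(
        lr_alignments, sr_alignments, bin_size, mapq_min
    )
    known = set(lrs_by_id)
    assigned = set()
    for b in bins:
        assigned |= b.lrs_ids
    assigned |= ambiguous.lrs_ids
    for rid in known - assigned:  # reads without any alignment record
        ambiguous.lrs_ids.add(rid)

    corrected: dict[str, str] = {}
    helper: list[tuple[str, str]] = []
    for b in bins:
        if recover and srs_unmapped:
            recover_unmapped(b, srs_by_id, lrs_by_id, srs_unmapped, k1)
        bin_srs = [(pid, *srs_by_id[pid]) for pid in sorted(b.srs_ids)]
        bin_lrs = [(rid, lrs_by_id[rid]) for rid in sorted(b.lrs_ids) if rid in lrs_by_id]
        if not bin_lrs:
            continue
        out, _ = run_both_passes(bin_srs, bin_lrs, k1, k2, min_count, params)
        for rid, seq in out:
            corrected[rid] = seq
        helper.extend(out)

    amb_lrs = [(rid, lrs_by_id[rid]) for rid in sorted(ambiguous.lrs_ids) if rid in lrs_by_id]
    if amb_lrs:
        p1, _ = run_pass1(srs_pairs, amb_lrs, k1, k2, min_count, params)
        p2, _ = run_pass2(srs_pairs, p1, k2, min_count, params, helper_lrs=helper)
        for rid, seq in p2:
            corrected[rid] = seq

    return [(rid, corrected.get(rid, seq)) for rid, seq in lrs]
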