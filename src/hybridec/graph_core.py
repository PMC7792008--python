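"""Compacted, colored de Bruijn graph of short accurate reads.

The graph is the index against which noisy long reads are corrected.  It is
built in three steps:

1. ``build_graph`` counts canonical k-mers of the input reads, drops those
   below a multiplicity threshold (k-mers seen once are almost always
   sequencing errors), and compacts the surviving k-mer set into unitigs —
   maximal non-branching paths of the underlying bidirected de Bruijn graph.
2. ``color_graph`` attaches *colors* to unitig k-mers: each color identifies
   one source unit (a short-read pair in the first correction pass, a single
   corrected long read in the second).  Colors highlight k-mer paths that
   co-occur in a real molecule and later guide graph traversal.
3. ``annotate_candidate_snps`` marks unitig positions where two graph k-mers
   differ by exactly one substitution — a cheap stand-in for bubble calling
   that flags candidate heterozygous SNP sites with IUPAC ambiguity symbols.

Colors are stored per k-mer position rather than per unitig so that color
lookups during traversal are position-accurate after compaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._kmers import (
    BASES,
    canon_int,
    canonical_u64,
    decode_u64,
    encode_u64,
    rc_int,
    revcomp_str,
    seq_to_codes,
    split_acgt,
    windows_u64,
)

logger = logging.getLogger(__name__)

# IUPAC ambiguity codes for base sets (candidate-SNP annotation).
IUPAC_FROM_SET = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("AC"): "M",
    frozenset("GT"): "K",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("ACG"): "V",
    frozenset("ACT"): "H",
    frozenset("AGT"): "D",
    frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}
SET_FROM_IUPAC = {sym: s for s, sym in IUPAC_FROM_SET.items()}


def canonicalize(seq: str) -> str:
    """Canonical form of a k-mer: the lexicographic min of seq and its
    reverse complement.  Rejects non-ACGT input."""
    if not seq:
        raise ValueError("empty k-mer")
    seq_to_codes(seq)  # validation
    rc = revcomp_str(seq)
    return seq if seq <= rc else rc


@dataclass
class Unitig:
    """A maximal non-branching path, stored as one sequence.

    ``kmer_coverage``, ``kmer_colors`` are indexed by k-mer start offset in
    the stored (forward) orientation; ``snp_annotations`` maps 0-based
    sequence offsets to IUPAC symbols whose base set always contains the
    base stored at that offset.
    """

    id: int
    sequence: str
    kmer_coverage: list[int]
    kmer_colors: list[set[int]]
    snp_annotations: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.kmer_coverage)
        if len(self.kmer_colors) != n:
            raise ValueError("coverage/color track length mismatch")

    @property
    def n_kmers(self) -> int:
        return len(self.kmer_coverage)

    def oriented_sequence(self, strand: str) -> str:
        return self.sequence if strand == "+" else revcomp_str(self.sequence)


class CCDBG:
    """Compacted (optionally colored) de Bruijn graph.

    Every retained canonical k-mer occurs at exactly one ``(unitig, offset)``
    up to orientation; ``lookup`` resolves a k-mer to that location.
    Adjacency between unitigs is implied by (k-1)-base overlaps and answered
    by ``successors``.
    """

    def __init__(self, k: int):
        if k % 2 == 0 or k < 3:
            raise ValueError("k must be odd and >= 3")
        self.k = k
        self.unitigs: dict[int, Unitig] = {}
        # canonical k-mer value -> (unitig id, kmer offset, stored-forward?)
        self._index: dict[int, tuple[int, int, bool]] = {}
        # sorted-array twin of _index for batch lookups
        self._keys: np.ndarray = np.empty(0, dtype=np.uint64)
        self._uid: np.ndarray = np.empty(0, dtype=np.int64)
        self._off: np.ndarray = np.empty(0, dtype=np.int64)
        self._fwd: np.ndarray = np.empty(0, dtype=bool)
        self._color_union_cache: dict[int, frozenset[int]] = {}

    # ------------------------------------------------------------------ build

    def _register_unitig(self, seq: str, coverage: list[int], colors: list[set[int]]):
        uid = len(self.unitigs)
        self.unitigs[uid] = Unitig(uid, seq, coverage, colors)
        return uid

    def _build_index(self):
        keys, uids, offs, fwds = [], [], [], []
        for uid, u in self.unitigs.items():
            w = windows_u64(seq_to_codes(u.sequence), self.k)
            canon, fwd = canonical_u64(w, self.k)
            keys.append(canon)
            uids.append(np.full(canon.size, uid, dtype=np.int64))
            offs.append(np.arange(canon.size, dtype=np.int64))
            fwds.append(fwd)
        if keys:
            keys = np.concatenate(keys)
            uids = np.concatenate(uids)
            offs = np.concatenate(offs)
            fwds = np.concatenate(fwds)
        else:
            keys = np.empty(0, dtype=np.uint64)
            uids = offs = np.empty(0, dtype=np.int64)
            fwds = np.empty(0, dtype=bool)
        order = np.argsort(keys, kind="stable")
        keys = keys[order]
        if keys.size and (keys[1:] == keys[:-1]).any():
            dup = keys[1:][keys[1:] == keys[:-1]][0]
            raise ValueError(
                f"k-mer {decode_u64(int(dup), self.k)} occurs at more than one unitig position"
            )
        self._keys = keys
        self._uid = uids[order]
        self._off = offs[order]
        self._fwd = fwds[order]
        self._index = {
            int(kv): (int(u), int(o), bool(f))
            for kv, u, o, f in zip(keys, self._uid, self._off, self._fwd)
        }
        self._color_union_cache.clear()

    # ---------------------------------------------------------------- queries

    @property
    def n_kmers(self) -> int:
        return self._keys.size

    @property
    def n_unitigs(self) -> int:
        return len(self.unitigs)

    def lookup_value(self, canon_val: int):
        return self._index.get(int(canon_val))

    def lookup_batch(self, canon_vals: np.ndarray):
        """Vectorised membership + location lookup for canonical values.

        Returns ``(hit, uid, off, fwd)`` arrays aligned with the input;
        entries of the location arrays are undefined where ``hit`` is False.
        """
        canon_vals = np.asarray(canon_vals, dtype=np.uint64)
        if self._keys.size == 0:
            z = np.zeros(canon_vals.size, dtype=np.int64)
            return np.zeros(canon_vals.size, dtype=bool), z, z, z.astype(bool)
        pos = np.searchsorted(self._keys, canon_vals)
        pos_c = np.minimum(pos, self._keys.size - 1)
        hit = self._keys[pos_c] == canon_vals
        return hit, self._uid[pos_c], self._off[pos_c], self._fwd[pos_c]

    def successors(self, uid: int, strand: str):
        """Unitigs reachable from the (uid, strand) end over a (k-1)-overlap.

        Returns ``(next_uid, next_strand, entry_kmer_offset)`` triples where
        ``entry_kmer_offset`` is the offset (in the *oriented* k-mer
        coordinates of the next unitig) of the first shared k-mer.  In a
        properly compacted graph the entry offset is always 0.
        """
        u = self.unitigs[uid]
        oseq = u.oriented_sequence(strand)
        suffix = oseq[-(self.k - 1):]
        out = []
        for a in BASES:
            q = suffix + a
            qv = encode_u64(q)
            hit = self.lookup_value(canon_int(qv, self.k))
            if hit is None:
                continue
            uid2, off2, fwd2 = hit
            q_is_canon = qv <= rc_int(qv, self.k)
            strand2 = "+" if (q_is_canon == fwd2) else "-"
            n2 = self.unitigs[uid2].n_kmers
            entry = off2 if strand2 == "+" else n2 - 1 - off2
            out.append((uid2, strand2, entry))
        return out

    def colors_at(self, uid: int, off: int) -> set[int]:
        return self.unitigs[uid].kmer_colors[off]

    def unitig_color_union(self, uid: int) -> frozenset[int]:
        cached = self._color_union_cache.get(uid)
        if cached is None:
            acc: set[int] = set()
            for s in self.unitigs[uid].kmer_colors:
                acc |= s
            cached = frozenset(acc)
            self._color_union_cache[uid] = cached
        return cached

    # ------------------------------------------------------------- validation

    def _assert_maximal(self):
        """No two adjacent unitigs could be merged without a branch."""
        for uid, u in self.unitigs.items():
            for strand in "+-":
                succ = self.successors(uid, strand)
                if len(succ) != 1:
                    continue
                uid2, strand2, entry = succ[0]
                if uid2 == uid or entry != 0:
                    continue  # self-loop / cycle or non-compacted parent
                back = self.successors(uid2, "-" if strand2 == "+" else "+")
                if len(back) == 1:
                    raise AssertionError(
                        f"unitigs {uid} and {uid2} are mergeable; compaction not maximal"
                    )

    def validate(self):
        """Structural invariants: track lengths, index uniqueness, maximality."""
        for u in self.unitigs.values():
            n = len(u.sequence) - self.k + 1
            assert u.n_kmers == n and len(u.kmer_colors) == n
            for off, sym in u.snp_annotations.items():
                assert 0 <= off < len(u.sequence)
                assert u.sequence[off] in SET_FROM_IUPAC[sym]
        assert len(self._index) == self._keys.size
        self._assert_maximal()

    # ---------------------------------------------------------------- export

    def kmer_set(self) -> set[int]:
        return {int(v) for v in self._keys}


def _succ_values(val: int, k: int, kset) -> list[int]:
    m = (1 << (2 * k)) - 1
    base = (val << 2) & m
    return [base | b for b in range(4) if canon_int(base | b, k) in kset]


def _pred_values(val: int, k: int, kset) -> list[int]:
    suf = val >> 2
    return [
        (b << (2 * (k - 1))) | suf
        for b in range(4)
        if canon_int((b << (2 * (k - 1))) | suf, k) in kset
    ]


def _compact_from_kmers(
    kset: set[int],
    k: int,
    counts: dict[int, int],
    colors: dict[int, set[int]] | None = None,
) -> CCDBG:
    """Compact a canonical k-mer set into maximal non-branching unitigs.

    Walks the bidirected de Bruijn graph implied by ``kset``: from each seed
    k-mer the chain is extended while the current vertex has a unique
    successor whose predecessor is also unique.  Cycles are broken at the
    seed k-mer.
    """
    g = CCDBG(k)
    visited: set[int] = set()
    for seed in sorted(kset):
        if seed in visited:
            continue
        chain = [seed]
        chain_canons = {seed}
        # forward extension
        cur = seed
        while True:
            ss = _succ_values(cur, k, kset)
            if len(ss) != 1:
                break
            nxt = ss[0]
            cn = canon_int(nxt, k)
            if cn in chain_canons or cn in visited:
                break
            if len(_pred_values(nxt, k, kset)) != 1:
                break
            chain.append(nxt)
            chain_canons.add(cn)
            cur = nxt
        # backward extension
        cur = seed
        while True:
            pp = _pred_values(cur, k, kset)
            if len(pp) != 1:
                break
            prv = pp[0]
            cn = canon_int(prv, k)
            if cn in chain_canons or cn in visited:
                break
            if len(_succ_values(prv, k, kset)) != 1:
                break
            chain.insert(0, prv)
            chain_canons.add(cn)
            cur = prv
        visited |= chain_canons
        seq = decode_u64(chain[0], k) + "".join(
            BASES[v & 3] for v in chain[1:]
        )
        canons = [canon_int(v, k) for v in chain]
        cov = [counts.get(c, 0) for c in canons]
        cols = [set(colors.get(c, ())) if colors else set() for c in canons]
        g._register_unitig(seq, cov, cols)
    g._build_index()
    return g


def build_graph(reads, k: int, min_count: int = 1) -> CCDBG:
    """Count canonical k-mers of ``reads``, keep those with multiplicity >=
    ``min_count`` and compact them into unitigs.

    ``reads`` is an iterable of DNA strings; non-ACGT symbols split a read
    into separate k-merisation segments.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    chunks = []
    for read in reads:
        for _, seg in split_acgt(read):
            if len(seg) >= k:
                w = windows_u64(seq_to_codes(seg), k)
                canon, _ = canonical_u64(w, k)
                chunks.append(canon)
    if chunks:
        allk = np.concatenate(chunks)
        uniq, cnt = np.unique(allk, return_counts=True)
        keep = cnt >= min_count
        uniq, cnt = uniq[keep], cnt[keep]
    else:
        uniq = np.empty(0, dtype=np.uint64)
        cnt = np.empty(0, dtype=np.int64)
    if uniq.size == 0:
        logger.warning("no k-mer survives the multiplicity filter; graph is empty")
        g = CCDBG(k)
        g._build_index()
        return g
    counts = {int(v): int(c) for v, c in zip(uniq, cnt)}
    g = _compact_from_kmers(set(counts), k, counts)
    g._assert_maximal()
    return g


def build_subgraph_from_unitigs(parent: CCDBG, k_small: int) -> CCDBG:
    """Graph of all ``k_small``-mers occurring in the parent's unitigs.

    The parent's multiplicity filter has already been applied, so every
    k_small-mer of a parent unitig is kept (min_count = 1).
    """
    if k_small >= parent.k:
        raise ValueError("k_small must be < parent.k")
    return build_graph([u.sequence for u in parent.unitigs.values()], k_small, 1)


def from_unitig_sequences(seqs, k: int) -> CCDBG:
    """Build a graph whose unitigs are exactly the given sequences.

    Used for worked examples and fixtures where the unitig decomposition is
    prescribed; k-mers must not repeat across the given sequences.  No
    maximality requirement is imposed.
    """
    g = CCDBG(k)
    for seq in seqs:
        n = len(seq) - k + 1
        if n < 1:
            raise ValueError(f"unitig {seq!r} shorter than k")
        g._register_unitig(seq, [0] * n, [set() for _ in range(n)])
    g._build_index()
    return g


def color_graph(graph: CCDBG, units) -> CCDBG:
    """Color the graph with source units.

    ``units`` is an iterable of ``(color_id, sequences)`` where sequences is
    one DNA string (a long read) or a pair of strings (a short-read pair).
    The unit's color id is added to the color set of every graph k-mer the
    unit contains, at that k-mer's position.  Color ids must be unique.
    """
    k = graph.k
    seen: set[int] = set()
    for color_id, seqs in units:
        if color_id in seen:
            raise ValueError(f"color id {color_id} used twice")
        seen.add(color_id)
        if isinstance(seqs, str):
            seqs = (seqs,)
        for seq in seqs:
            for _, seg in split_acgt(seq):
                if len(seg) < k:
                    continue
                canon, _ = canonical_u64(windows_u64(seq_to_codes(seg), k), k)
                hit, uid, off, _f = graph.lookup_batch(canon)
                for j in np.flatnonzero(hit):
                    graph.unitigs[int(uid[j])].kmer_colors[int(off[j])].add(color_id)
    graph._color_union_cache.clear()
    return graph


def prune_low_color_kmers(graph: CCDBG, min_colors: int) -> CCDBG:
    """Drop k-mers carrying fewer than ``min_colors`` colors and re-compact.

    Unitigs are implicitly split/trimmed by rebuilding the graph from the
    retained k-mer set; coverage and color tracks are carried over, SNP
    annotations are not (annotate after pruning).
    """
    if min_colors <= 0:
        return graph
    counts: dict[int, int] = {}
    colors: dict[int, set[int]] = {}
    k = graph.k
    for u in graph.unitigs.values():
        w = windows_u64(seq_to_codes(u.sequence), k)
        canon, _ = canonical_u64(w, k)
        for off, cv in enumerate(canon):
            if len(u.kmer_colors[off]) >= min_colors:
                counts[int(cv)] = u.kmer_coverage[off]
                colors[int(cv)] = u.kmer_colors[off]
    if not counts:
        logger.warning("all k-mers below the color threshold; graph is empty")
        g = CCDBG(k)
        g._build_index()
        return g
    g = _compact_from_kmers(set(counts), k, counts, colors)
    return g


def _merge_annotation(unitig: Unitig, off: int, bases: set[str]):
    prev = unitig.snp_annotations.get(off)
    if prev is not None:
        bases = bases | SET_FROM_IUPAC[prev]
    unitig.snp_annotations[off] = IUPAC_FROM_SET[frozenset(bases)]


def annotate_candidate_snps(graph: CCDBG) -> CCDBG:
    """Mark candidate SNP positions on unitigs with IUPAC symbols.

    For every graph k-mer, the 3k substitution neighbours are looked up in
    the index; each hit marks the substituted position on *this* unitig with
    the symbol covering the two observed bases.  Iterating every unitig makes
    the annotation symmetric, and annotating in each unitig's stored strand
    keeps offsets orientation-correct.  Multiple alternates at one position
    merge into the covering IUPAC symbol.
    """
    k = graph.k
    two = np.uint64(2)
    for uid, u in list(graph.unitigs.items()):
        codes = seq_to_codes(u.sequence)
        w = windows_u64(codes, k)
        if w.size == 0:
            continue
        for i in range(k):
            shift = np.uint64(2 * (k - 1 - i))
            own = codes[i : i + w.size]
            for d in (1, 2, 3):
                cand = w ^ (np.uint64(d) << shift)
                canon, _ = canonical_u64(cand, k)
                hit, _hu, _ho, _hf = graph.lookup_batch(canon)
                for j in np.flatnonzero(hit):
                    p = int(j)
                    b_own = BASES[int(own[p])]
                    b_alt = BASES[int(own[p]) ^ d]
                    _merge_annotation(u, p + i, {b_own, b_alt})
    return graph


def lookup(graph: CCDBG, kmer: str):
    """Exact canonical lookup of one k-mer.

    Returns ``(unitig id, offset, strand)`` where strand is '+' when the
    k-mer as given matches the unitig slice forward, or None if absent.
    """
    if len(kmer) != graph.k:
        raise ValueError(f"k-mer length {len(kmer)} != graph k {graph.k}")
    v = encode_u64(kmer)
    hit = graph.lookup_value(canon_int(v, graph.k))
    if hit is None:
        return None
    uid, off, fwd = hit
    is_canon = v <= rc_int(v, graph.k)
    strand = "+" if (is_canon == fwd) else "-"
    return uid, off, strand
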