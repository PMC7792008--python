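"""Independent string-based oracles for cross-checking the package.

The oracles deliberately avoid the package's packed-integer machinery: they
work on plain strings so that agreement with the implementation is a real
cross-check, not a tautology.
"""

from __future__ import annotations

import random


COMP = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(COMP)[::-1]


def canon(s: str) -> str:
    r = rc(s)
    return s if s <= r else r


def naive_kmer_counts(reads, k):
    counts = {}
    for read in reads:
        for i in range(len(read) - k + 1):
            w = read[i : i + k]
            if any(c not in "ACGT" for c in w):
                continue
            c = canon(w)
            counts[c] = counts.get(c, 0) + 1
    return counts


def naive_kmer_set(reads, k, min_count=1):
    return {c for c, n in naive_kmer_counts(reads, k).items() if n >= min_count}


def naive_compaction(kset, k):
    """Greedy string-based compaction of a canonical k-mer set.

    Returns the set of canonical unitig sequences (min of sequence and its
    reverse complement), computed independently of the package.
    """

    def succs(s):
        return [s[1:] + a for a in "ACGT" if canon(s[1:] + a) in kset]

    def preds(s):
        return [a + s[:-1] for a in "ACGT" if canon(a + s[:-1]) in kset]

    visited = set()
    unitigs = set()
    for seed in sorted(kset):
        if seed in visited:
            continue
        chain = [seed]
        chain_set = {seed}
        cur = seed
        while True:
            ss = succs(cur)
            if len(ss) != 1:
                break
            nxt = ss[0]
            cn = canon(nxt)
            if cn in chain_set or cn in visited or len(preds(nxt)) != 1:
                break
            chain.append(nxt)
            chain_set.add(cn)
            cur = nxt
        cur = seed
        while True:
            pp = preds(cur)
            if len(pp) != 1:
                break
            prv = pp[0]
            cn = canon(prv)
            if cn in chain_set or cn in visited or len(succs(prv)) != 1:
                break
            chain.insert(0, prv)
            chain_set.add(cn)
            cur = prv
        visited |= chain_set
        seq = chain[0] + "".join(x[-1] for x in chain[1:])
        unitigs.add(canon(seq))
    return unitigs


def decompact(graph):
    """Canonical k-mer set implied by a graph's unitigs (with multiplicity check)."""
    k = graph.k
    seen = []
    for u in graph.unitigs.values():
        for i in range(len(u.sequence) - k + 1):
            seen.append(canon(u.sequence[i : i + k]))
    assert len(seen) == len(set(seen)), "duplicate k-mers across unitigs"
    return set(seen)


def enumerate_paths(graph, start, goal, max_len, require_min=0):
    """Exhaustive bounded-length path sequences from one anchor k-mer to another.

    Anchors are (unitig id, strand, forward k-mer offset) as used by the
    greedy search; sequences include both anchor k-mers.  Works directly on
    oriented unitig strings via DFS; only usable on tiny graphs.
    """
    k = graph.k
    results = set()

    def oriented(uid, strand):
        u = graph.unitigs[uid]
        return u.sequence if strand == "+" else rc(u.sequence)

    def okoff(uid, off, strand):
        n = graph.unitigs[uid].n_kmers
        return off if strand == "+" else n - 1 - off

    s_uid, s_strand, s_off = start
    g_uid, g_strand, g_off = goal

    def dfs(uid, strand, kpos, seq):
        O = oriented(uid, strand)
        n = graph.unitigs[uid].n_kmers
        if uid == g_uid and strand == g_strand:
            t_ko = okoff(uid, g_off, strand)
            if t_ko >= kpos:
                cand = seq + O[kpos + k - 1 : t_ko + k]
                if require_min <= len(cand) <= max_len:
                    results.add(cand)
                # a longer route may revisit; continue exploring too
        ext = seq + O[kpos + k - 1 :]
        if len(ext) > max_len:
            return
        for uid2, strand2, entry in graph.successors(uid, strand):
            dfs(uid2, strand2, entry, ext)

    O0 = oriented(s_uid, s_strand)
    ko0 = okoff(s_uid, s_off, s_strand)
    dfs(s_uid, s_strand, ko0, O0[ko0 : ko0 + k - 1])
    return results


def mutate(seq, pos, rng=None):
    """Substitute the base at pos deterministically (next base in ACGT)."""
    alt = "ACGT"[("ACGT".index(seq[pos]) + 1) % 4]
    return seq[:pos] + alt + seq[pos + 1 :]




def pick_weak_mutation(genome, graph, read_start, read_end, lo, hi):
    """First position in [lo, hi) whose substitution leaves every overlapping
    window weak (absent from the graph), so the error is actually correctable
    and the flanking anchors are genuine."""
    from hybridec.graph_core import lookup

    k = graph.k
    for p in range(lo, hi):
        read = mutate(genome[read_start:read_end], p)
        windows = [
            read[i : i + k]
            for i in range(max(0, p - k + 1), min(len(read) - k + 1, p + 1))
        ]
        if all(lookup(graph, w) is None for w in windows):
            return p, read
    raise AssertionError("no clean mutation site in range")
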