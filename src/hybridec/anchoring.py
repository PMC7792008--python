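"""Anchoring long reads on the graph.

Each k-mer window of a long read is classified against the graph:

* **solid** — exact match with a unitig slice;
* **near-solid** — match after exactly one substitution or indel;
* **weak** — neither.

Maximal runs of solid positions form *solid regions*; the stretches between
them (bounded by the flanking solid k-mers) are the *non-solid regions* to
correct.  Near-solid matches that are the only hit at their read position
(UNSMs) are kept as traversal waypoints inside non-solid regions; ambiguous
near-solid positions are discarded so the read is never anchored on the
wrong allele of a SNP or indel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._kmers import canonical_u64, seq_to_codes, split_acgt, windows_u64
from .graph_core import CCDBG

_EDIT_NAMES = ("substitution", "deletion", "insertion")


@dataclass(frozen=True)
class Match:
    """One anchoring of a read k-mer onto a unitig position.

    ``unitig_pos`` is the k-mer offset in the unitig's stored (forward)
    orientation; ``strand`` is '+' when the read k-mer (after the edit, for
    near-solid matches) equals the unitig slice forward.
    """

    read_pos: int
    unitig: int
    unitig_pos: int
    strand: str
    kind: str  # 'solid' | 'near_solid'
    edit: str  # 'none' | 'substitution' | 'insertion' | 'deletion'


@dataclass
class NonSolidRegion:
    """A stretch of a read between two solid anchors (either may be absent).

    ``length`` is measured from the source k-mer start to the target k-mer
    end; ``l_min``/``l_max`` bound the acceptable corrected length under the
    error-rate upper bound F.
    """

    source: Match | None
    target: Match | None
    start: int
    length: int
    l_min: int
    l_max: int
    unsms: list[Match] = field(default_factory=list)


def _edit1_candidates(codes: np.ndarray, k: int, windows: np.ndarray, miss: np.ndarray):
    """Packed k-mer candidates at edit distance 1 from the windows at ``miss``.

    Returns concatenated ``(values, positions, edit_codes)`` where edit code
    0/1/2 = substitution/deletion/insertion.  Deletion candidates drop one
    window base and append the next read base, so they exist only where that
    base is available; insertion candidates insert one base and drop the last
    window base.  Positions are window starts regardless of edit type.
    """
    n = windows.size
    W = windows[miss]
    m = miss.astype(np.int64)
    vals, pos, edits = [], [], []
    two = np.uint64(2)

    # substitutions: flip the base at window offset i to each alternative
    for i in range(k):
        shift = np.uint64(2 * (k - 1 - i))
        for d in (1, 2, 3):
            vals.append(W ^ (np.uint64(d) << shift))
            pos.append(m)
            edits.append(np.zeros(m.size, dtype=np.int8))

    # deletions: remove window base j, shift in the next read base
    has_next = m + k < codes.size
    if has_next.any():
        mh = m[has_next]
        Wh = W[has_next]
        nb = codes[mh + k].astype(np.uint64)
        for j in range(k):
            high = Wh >> np.uint64(2 * (k - j))
            low = Wh & np.uint64((1 << (2 * (k - 1 - j))) - 1)
            cand = (high << np.uint64(2 * (k - j))) | (low << two) | nb
            vals.append(cand)
            pos.append(mh)
            edits.append(np.ones(mh.size, dtype=np.int8))

    # insertions: insert base a before window offset j (strictly inside the
    # window; inserting before offset 0 would merely re-anchor the previous
    # position), drop the last base
    for j in range(1, k):
        high = W >> np.uint64(2 * (k - j))
        low = (W >> two) & np.uint64((1 << (2 * (k - 1 - j))) - 1)
        for a in range(4):
            cand = (
                (high << np.uint64(2 * (k - j)))
                | (np.uint64(a) << np.uint64(2 * (k - 1 - j)))
                | low
            )
            vals.append(cand)
            pos.append(m)
            edits.append(np.full(m.size, 2, dtype=np.int8))

    return (
        np.concatenate(vals) if vals else np.empty(0, dtype=np.uint64),
        np.concatenate(pos) if pos else np.empty(0, dtype=np.int64),
        np.concatenate(edits) if edits else np.empty(0, dtype=np.int8),
    )


def classify_kmers(read: str, graph: CCDBG):
    """Classify every read k-mer; return ``(solid, near_solid)`` match lists.

    The near-solid list contains only *unique* near-solid matches (exactly
    one distinct graph hit at that read position); positions with a solid
    match contribute no near-solid candidates.  Both lists are sorted by
    read position.
    """
    k = graph.k
    solid: list[Match] = []
    near: list[Match] = []
    if len(read) < k:
        return solid, near
    for seg_off, seg in split_acgt(read):
        if len(seg) < k:
            continue
        codes = seq_to_codes(seg)
        W = windows_u64(codes, k)
        canon, fwd = canonical_u64(W, k)
        hit, uid, off, ifwd = graph.lookup_batch(canon)
        for j in np.flatnonzero(hit):
            strand = "+" if bool(fwd[j]) == bool(ifwd[j]) else "-"
            solid.append(
                Match(seg_off + int(j), int(uid[j]), int(off[j]), strand, "solid", "none")
            )
        miss = np.flatnonzero(~hit)
        if miss.size == 0 or graph.n_kmers == 0:
            continue
        cvals, cpos, cedit = _edit1_candidates(codes, k, W, miss)
        ccanon, cfwd = canonical_u64(cvals, k)
        chit, cuid, coff, cifwd = graph.lookup_batch(ccanon)
        hits = np.flatnonzero(chit)
        if hits.size == 0:
            continue
        # uniqueness is judged per graph vertex: a candidate and its reverse
        # complement resolve to the same stored k-mer and count as one match.
        # order hits by (position, vertex, edit priority) so duplicates
        # collapse onto the lowest edit code
        order = hits[np.lexsort((cedit[hits], ccanon[hits], cpos[hits]))]
        i = 0
        while i < order.size:
            p = cpos[order[i]]
            jend = i
            distinct = []
            while jend < order.size and cpos[order[jend]] == p:
                idx = order[jend]
                if not distinct or ccanon[idx] != ccanon[distinct[-1]]:
                    distinct.append(idx)
                jend += 1
            if len(distinct) == 1:
                idx = distinct[0]
                strand = "+" if bool(cfwd[idx]) == bool(cifwd[idx]) else "-"
                near.append(
                    Match(
                        seg_off + int(p),
                        int(cuid[idx]),
                        int(coff[idx]),
                        strand,
                        "near_solid",
                        _EDIT_NAMES[int(cedit[idx])],
                    )
                )
            i = jend
    solid.sort(key=lambda mt: mt.read_pos)
    near.sort(key=lambda mt: mt.read_pos)
    return solid, near


def filter_solid_runs(solid: list[Match], k: int, min_bases: int) -> list[Match]:
    """Keep only solid matches belonging to runs spanning >= ``min_bases``.

    A run of consecutive solid positions p..q spans q - p + k bases.  The
    second correction pass demands long solid regions for reliable anchoring
    and treats shorter runs as region interior.
    """
    if not solid or min_bases <= k:
        return list(solid)
    out: list[Match] = []
    run: list[Match] = []
    for mt in solid:
        if run and mt.read_pos != run[-1].read_pos + 1:
            if run[-1].read_pos - run[0].read_pos + k >= min_bases:
                out.extend(run)
            run = []
        run.append(mt)
    if run and run[-1].read_pos - run[0].read_pos + k >= min_bases:
        out.extend(run)
    return out


def _region(source, target, start, length, k, F, near_solid, read_len):
    l_min = math.ceil(length / (1 + F))
    l_max = math.floor(length * (1 + F))
    lo = source.read_pos + k if source else 0
    hi = target.read_pos - k if target else read_len - k
    unsms = [mt for mt in near_solid if lo <= mt.read_pos <= hi]
    return NonSolidRegion(source, target, start, length, l_min, l_max, unsms)


def delimit_regions(
    solid: list[Match],
    near_solid: list[Match],
    read_len: int,
    k: int,
    F: float,
) -> list[NonSolidRegion]:
    """Delimit the non-solid regions of a read from its sorted solid matches.

    One region per pair of successive solid matches that are not adjacent,
    plus head/tail regions when the read starts or ends non-solid; a single
    full-read region when there is no solid match at all.  Each region
    collects the unique near-solid matches lying strictly inside it.
    """
    regions: list[NonSolidRegion] = []
    if not solid:
        regions.append(_region(None, None, 0, read_len, k, F, near_solid, read_len))
        return regions
    first = solid[0]
    if first.read_pos > 0:
        regions.append(
            _region(None, first, 0, first.read_pos + k, k, F, near_solid, read_len)
        )
    for prev, nxt in zip(solid, solid[1:]):
        if nxt.read_pos != prev.read_pos + 1:
            regions.append(
                _region(
                    prev,
                    nxt,
                    prev.read_pos,
                    nxt.read_pos - prev.read_pos + k,
                    k,
                    F,
                    near_solid,
                    read_len,
                )
            )
    last = solid[-1]
    if last.read_pos + k < read_len:
        regions.append(
            _region(last, None, last.read_pos, read_len - last.read_pos, k, F, near_solid, read_len)
        )
    return regions
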