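"""Guided graph traversal: extracting one corrective path per non-solid region.

The search is deliberately greedy.  From the source anchor the path is grown
in *stages*: each stage enumerates every simple extension of the current
path up to ``P_max`` unitigs (first pass) or until at least ``B`` appended
bases (second pass), scores the survivors, and commits only the best one.

Two signals score an extension:

* ``s_q`` — sequence similarity of the candidate path to the raw region,
  from an infix edit-distance alignment (gaps at region ends unpenalised);
* ``s_c`` — color similarity: the fraction of the locally collected color
  set C that the path's unitig k-mers carry.  C is the union of k-mer color
  sets over solid anchors and unique near-solid matches within B bases of
  the region (first pass), or a per-side intersection (second pass).

The two probabilities are conflated into

    s_P = s_c * s_q / (s_c * s_q + (1 - s_c) * (1 - s_q)).

A local color floor T_C = floor(D * min |C_u|) over the same window prunes
extensions through k-mers carried by fewer than T_C colors of C.  When the
search dead-ends (graph tip, floor exhaustion, length budget), the path is
completed with a literal *gap* — the uncorrected read subsequence — and
resumes from the next waypoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from ._kmers import revcomp_str
from .anchoring import Match, NonSolidRegion
from .graph_core import CCDBG


@dataclass
class TraversalParams:
    """Tunables of the guided traversal.

    F    error-rate upper bound of the long reads (length slack of paths);
    B    color-collection buffer around a region, bases (pass 2 also uses it
         as the frontier length and minimum solid-region length);
    P_max unitigs enumerated per greedy stage (first pass frontier);
    D    color-floor factor in [0, 1];
    frontier_mode 'unitig_count' (pass 1) or 'base_length' (pass 2).
    """

    F: float = 0.4
    B: int = 1000
    P_max: int = 4
    D: float = 0.2
    frontier_mode: str = "unitig_count"

    def __post_init__(self):
        if self.F <= 0 or self.P_max < 1 or not 0 <= self.D <= 1:
            raise ValueError("invalid traversal parameters")
        if self.frontier_mode not in ("unitig_count", "base_length"):
            raise ValueError(f"unknown frontier mode {self.frontier_mode!r}")


@dataclass
class GraphPath:
    """An oriented unitig walk, possibly interrupted by literal gap segments.

    ``origin[i]`` records where ``sequence[i]`` came from: ``(unitig id,
    forward sequence offset, strand)`` for bases emitted from a unitig, or
    None for bases carried over from the uncorrected read (gaps).
    ``colors`` is the union of color sets over the path's unitig k-mers
    (C_p).  After mirroring, element k-mer offsets remain in the pre-mirror
    orientation; sequence and origin are authoritative.
    """

    elements: list = field(default_factory=list)
    sequence: str = ""
    origin: list = field(default_factory=list)
    colors: set = field(default_factory=set)
    s_c: float = 0.0
    s_q: float = 0.0
    s_P: float = 0.0
    complete: bool = False

    @property
    def has_gap(self) -> bool:
        return any(e[0] == "gap" for e in self.elements)


def path_probability(s_c: float, s_q: float) -> float:
    """Conflation of the color and sequence matching probabilities."""
    num = s_c * s_q
    den = num + (1.0 - s_c) * (1.0 - s_q)
    if den == 0.0:
        return 0.0
    return num / den


def _window_matches(solid, near_solid, region: NonSolidRegion, B: int):
    lo = region.source.read_pos - B if region.source else None
    hi = region.target.read_pos + B if region.target else None
    for mt in list(solid) + list(near_solid):
        if (lo is None or mt.read_pos >= lo) and (hi is None or mt.read_pos <= hi):
            yield mt


def collect_color_union(solid, near_solid, region: NonSolidRegion, B: int, graph: CCDBG):
    """Union of k-mer color sets over all matches within B bases of the region."""
    C: set[int] = set()
    for mt in _window_matches(solid, near_solid, region, B):
        C |= graph.colors_at(mt.unitig, mt.unitig_pos)
    return C


def color_floor(solid, near_solid, region: NonSolidRegion, B: int, D: float, graph: CCDBG):
    """Local minimum color count T_C = floor(D * min |C_u|) over the window."""
    sizes = [
        len(graph.colors_at(mt.unitig, mt.unitig_pos))
        for mt in _window_matches(solid, near_solid, region, B)
    ]
    if not sizes:
        return 0
    return int(D * min(sizes))


def side_intersection_colors(solid, region: NonSolidRegion, B: int, graph: CCDBG):
    """Second-pass color set: per-side intersections, then their union.

    C^s intersects the color sets of solid matches within B bases left of the
    region's source anchor, C^t within B bases right of the target anchor;
    intersecting removes erroneous colors that do not belong to the locus.
    A side with no solid match contributes nothing.
    """

    def _intersect(lo, hi):
        acc = None
        for mt in solid:
            if lo <= mt.read_pos <= hi:
                cs = graph.colors_at(mt.unitig, mt.unitig_pos)
                acc = set(cs) if acc is None else acc & cs
        return acc or set()

    C: set[int] = set()
    if region.source is not None:
        C |= _intersect(region.source.read_pos - B, region.source.read_pos)
    if region.target is not None:
        C |= _intersect(region.target.read_pos, region.target.read_pos + B)
    return C


def _okoff(n_kmers: int, off: int, strand: str) -> int:
    return off if strand == "+" else n_kmers - 1 - off

_fwd_off = _okoff  # the mapping is its own inverse


def score_path(path: GraphPath, C, region_subseq: str) -> GraphPath:
    """Fill in s_c, s_q, s_P for a path against a region.

    s_c counts the fraction of C carried by the path's unitig k-mers (1 when
    C is empty: absent evidence is not negative evidence); s_q is one minus
    the normalised infix edit distance of the path sequence to the region.
    """
    if not path.sequence:
        raise ValueError("cannot score an empty path")
    if not C:
        path.s_c = 1.0
    else:
        path.s_c = len(path.colors & set(C)) / len(C)
    d = edlib.align(path.sequence, region_subseq, mode="HW")["editDistance"]
    path.s_q = max(0.0, 1.0 - d / max(1, len(path.sequence)))
    path.s_P = path_probability(path.s_c, path.s_q)
    return path


class _Walk:
    """Incremental assembly of an oriented unitig walk."""

    def __init__(self, graph: CCDBG):
        self.graph = graph
        self.k = graph.k
        self.elements: list = []
        self.seq: list[str] = []
        self.origin: list = []
        self.colors: set[int] = set()
        self.total = 0

    def _emit(self, uid, strand, ob_from, ob_to):
        """Emit oriented bases [ob_from, ob_to) of (uid, strand)."""
        u = self.graph.unitigs[uid]
        O = u.oriented_sequence(strand)
        self.seq.append(O[ob_from:ob_to])
        L = len(O)
        for ob in range(ob_from, ob_to):
            f = ob if strand == "+" else L - 1 - ob
            self.origin.append((uid, f, strand))
        self.total += ob_to - ob_from

    def start_kmer(self, uid, strand, ko, skip: int = 0):
        """Seed the walk with a k-mer; ``skip`` suppresses its first bases
        (used when resuming at a waypoint whose k-mer overlaps the bases
        already emitted in read coordinates)."""
        self.elements.append(["unitig", uid, strand, ko, ko])
        self._emit(uid, strand, ko + skip, ko + self.k)
        self._absorb_colors(uid, strand, ko, ko)

    def _absorb_colors(self, uid, strand, ka, kb):
        u = self.graph.unitigs[uid]
        n = u.n_kmers
        if kb - ka + 1 >= n:
            self.colors |= self.graph.unitig_color_union(uid)
        else:
            for j in range(ka, kb + 1):
                self.colors |= u.kmer_colors[_fwd_off(n, j, strand)]

    def advance(self, kb):
        """Advance the last unitig element to k-mer offset kb (oriented)."""
        e = self.elements[-1]
        assert e[0] == "unitig"
        _tag, uid, strand, ka, cur = e
        if kb <= cur:
            return
        self._emit(uid, strand, cur + self.k, kb + self.k)
        self._absorb_colors(uid, strand, cur + 1, kb)
        e[4] = kb

    def jump(self, uid, strand, entry, exit_k):
        """Enter a successor unitig at k-mer ``entry`` and consume to ``exit_k``."""
        self.elements.append(["unitig", uid, strand, entry, entry])
        self._emit(uid, strand, entry + self.k - 1, entry + self.k)
        self._absorb_colors(uid, strand, entry, entry)
        self.advance(exit_k)

    def add_gap(self, seq: str):
        if seq:
            self.elements.append(["gap", seq])
            self.seq.append(seq)
            self.origin.extend([None] * len(seq))
            self.total += len(seq)

    def sequence(self) -> str:
        return "".join(self.seq)

    def to_path(self, complete: bool) -> GraphPath:
        return GraphPath(
            elements=[tuple(e) for e in self.elements],
            sequence=self.sequence(),
            origin=list(self.origin),
            colors=set(self.colors),
            complete=complete,
        )


def _slice_floor_ok(graph, uid, strand, ka, kb, C, T_C, memo):
    """Does every k-mer of the oriented slice carry >= T_C colors of C?"""
    if T_C <= 0 or not C:
        return True
    u = graph.unitigs[uid]
    n = u.n_kmers
    if kb - ka + 1 >= n:
        key = uid
        got = memo.get(key)
        if got is None:
            got = min(len(s & C) for s in u.kmer_colors)
            memo[key] = got
        return got >= T_C
    for j in range(ka, kb + 1):
        if len(u.kmer_colors[_fwd_off(n, j, strand)] & C) < T_C:
            return False
    return True


def _enumerate_stage(graph, cur_uid, cur_strand, base_total, max_bases, to, params, C, T_C, memo):
    """All simple stage extensions from the end of (cur_uid, cur_strand).

    Each candidate is ``(jumps, seq, colors, complete, terminal)`` where
    jumps = [(uid, strand, entry, exit_k)], seq is the appended sequence and
    terminal marks candidates that must not be extended further (target
    reached or base budget exhausted).
    """
    k = graph.k
    out = []

    def slice_seq(uid, strand, entry, exit_k):
        O = graph.unitigs[uid].oriented_sequence(strand)
        return O[entry + k - 1 : exit_k + k]

    def rec(uid, strand, depth, added, visited, jumps, seq_parts, colors):
        succs = graph.successors(uid, strand)
        extended = False
        for u2, s2, e2 in succs:
            if (u2, s2) in visited:
                continue
            un2 = graph.unitigs[u2]
            n2 = un2.n_kmers
            exit_k = n2 - 1
            complete = False
            if to is not None and to[0] == u2 and to[1] == s2:
                t_ko = _okoff(n2, to[2], s2)
                if t_ko >= e2:
                    exit_k = t_ko
                    complete = True
            add = 1 + (exit_k - e2)
            allowed = max_bases - base_total - added
            if allowed <= 0:
                continue
            terminal = False
            if add > allowed:
                exit_k = e2 + allowed - 1
                add = allowed
                complete = False
                terminal = True
            if not _slice_floor_ok(graph, u2, s2, e2, exit_k, C, T_C, memo):
                continue
            extended = True
            seq_add = slice_seq(u2, s2, e2, exit_k)
            jumps2 = jumps + [(u2, s2, e2, exit_k)]
            parts2 = seq_parts + [seq_add]
            colors2 = colors | (
                graph.unitig_color_union(u2)
                if exit_k - e2 + 1 >= n2
                else set().union(
                    *(un2.kmer_colors[_fwd_off(n2, j, s2)] for j in range(e2, exit_k + 1))
                )
            )
            frontier_full = (
                depth + 1 >= params.P_max
                if params.frontier_mode == "unitig_count"
                else added + add >= params.B
            )
            if complete or terminal or frontier_full:
                out.append((jumps2, "".join(parts2), colors2, complete, complete or terminal))
            else:
                rec(u2, s2, depth + 1, added + add, visited | {(u2, s2)}, jumps2, parts2, colors2)
        if not extended and jumps:
            # tip of the graph: the partial stage is itself a candidate
            out.append((jumps, "".join(seq_parts), colors, False, True))

    rec(cur_uid, cur_strand, 0, 0, {(cur_uid, cur_strand)}, [], [], set())
    return out


def greedy_bfs_extend(
    graph: CCDBG,
    from_anchor,
    to_anchor,
    max_bases: int,
    C,
    T_C: int,
    region_subseq: str,
    params: TraversalParams,
    floor_memo: dict | None = None,
) -> GraphPath:
    """Greedy staged search from one anchor k-mer toward another.

    Anchors are ``(unitig id, strand, forward k-mer offset)``; the returned
    path starts with the source k-mer and, when complete, ends with the
    target k-mer.  ``to_anchor=None`` extends open-endedly until the base
    budget or a dead end (head/tail regions); the caller trims the result.
    """
    uid, strand, off = from_anchor
    if uid not in graph.unitigs:
        raise ValueError(f"unitig {uid} not in graph")
    if floor_memo is None:
        floor_memo = {}
    Cset = set(C) if C else set()
    walk = _Walk(graph)
    n0 = graph.unitigs[uid].n_kmers
    ko = _okoff(n0, off, strand)
    walk.start_kmer(uid, strand, ko)
    cur_uid, cur_strand = uid, strand

    while True:
        u = graph.unitigs[cur_uid]
        n = u.n_kmers
        cur_k = walk.elements[-1][4]
        # direct completion within the current unitig
        if to_anchor is not None and to_anchor[0] == cur_uid and to_anchor[1] == cur_strand:
            t_ko = _okoff(n, to_anchor[2], cur_strand)
            if t_ko >= cur_k and walk.total + (t_ko - cur_k) <= max_bases:
                walk.advance(t_ko)
                return walk.to_path(complete=True)
        # consume the remainder of the current unitig
        room = max_bases - walk.total
        if n - 1 > cur_k:
            step = min(n - 1 - cur_k, room)
            walk.advance(cur_k + step)
            if step < n - 1 - cur_k:
                return walk.to_path(complete=False)  # budget exhausted mid-unitig
        if walk.total >= max_bases:
            return walk.to_path(complete=False)
        cands = _enumerate_stage(
            graph, cur_uid, cur_strand, walk.total, max_bases,
            to_anchor, params, Cset, T_C, floor_memo,
        )
        if not cands:
            return walk.to_path(complete=False)  # tip or color-floor exhaustion
        cur_seq = walk.sequence()
        best = None
        for jumps, seq_add, colors, complete, terminal in cands:
            full = cur_seq + seq_add
            s_c = 1.0 if not Cset else len((walk.colors | colors) & Cset) / len(Cset)
            d = edlib.align(full, region_subseq, mode="HW")["editDistance"]
            s_q = max(0.0, 1.0 - d / max(1, len(full)))
            s_P = path_probability(s_c, s_q)
            # the conflation saturates at s_c = 1 (e.g. empty C), so ties on
            # s_P fall back to raw sequence similarity, then to the
            # lexicographically smallest extension for determinism
            key = (-s_P, -s_q, seq_add)
            if best is None or key < best[0]:
                best = (key, jumps, complete, terminal)
        _key, jumps, complete, terminal = best
        for u2, s2, e2, x2 in jumps:
            walk.jump(u2, s2, e2, x2)
        if complete:
            return walk.to_path(complete=True)
        if terminal:
            return walk.to_path(complete=False)
        cur_uid, cur_strand = jumps[-1][0], jumps[-1][1]


def _anchor(mt: Match):
    return (mt.unitig, mt.strand, mt.unitig_pos)


def _mirror_match(mt: Match, read_len: int, k: int) -> Match:
    return Match(
        read_len - k - mt.read_pos,
        mt.unitig,
        mt.unitig_pos,
        "-" if mt.strand == "+" else "+",
        mt.kind,
        mt.edit,
    )


def _mirror_region(region: NonSolidRegion, read_len: int, k: int) -> NonSolidRegion:
    src = _mirror_match(region.target, read_len, k) if region.target else None
    tgt = _mirror_match(region.source, read_len, k) if region.source else None
    unsms = sorted(
        (_mirror_match(m, read_len, k) for m in region.unsms), key=lambda m: m.read_pos
    )
    return NonSolidRegion(
        src,
        tgt,
        read_len - (region.start + region.length),
        region.length,
        region.l_min,
        region.l_max,
        unsms,
    )


def _mirror_path(path: GraphPath) -> GraphPath:
    seq = revcomp_str(path.sequence)
    origin = []
    for o in reversed(path.origin):
        if o is None:
            origin.append(None)
        else:
            uid, f, s = o
            origin.append((uid, f, "-" if s == "+" else "+"))
    elements = []
    for e in reversed(path.elements):
        if e[0] == "gap":
            elements.append(("gap", revcomp_str(e[1])))
        else:
            _tag, uid, strand, ka, kb = e
            elements.append(("unitig", uid, "-" if strand == "+" else "+", ka, kb))
    return GraphPath(
        elements, seq, origin, set(path.colors),
        path.s_c, path.s_q, path.s_P, path.complete,
    )


def find_region_path(
    graph: CCDBG,
    region: NonSolidRegion,
    read: str,
    solid,
    near_solid,
    params: TraversalParams,
    direction: str = "forward",
    color_set=None,
    t_c: int | None = None,
) -> GraphPath | None:
    """Extract one candidate corrective path for a non-solid region.

    Chains greedy searches across the region's waypoints (source anchor,
    UNSMs in read order, target anchor); failed legs contribute literal gap
    segments.  ``direction='backward'`` runs the same search on the
    reverse complement and un-mirrors the result.  Head regions (no source)
    are only correctable backward, tail regions (no target) only forward;
    the inapplicable direction returns None, as does a region with no anchor
    at all.
    """
    if region.source is None and region.target is None:
        return None
    k = graph.k
    if direction == "backward":
        if region.source is None:
            mreg = _mirror_region(region, len(read), k)
            mpath = _forward_region_path(
                graph, mreg, revcomp_str(read), params, color_set, t_c,
                solid, near_solid, mirrored=True,
            )
            return _mirror_path(mpath) if mpath else None
        if region.target is None:
            return None
        mreg = _mirror_region(region, len(read), k)
        mpath = _forward_region_path(
            graph, mreg, revcomp_str(read), params, color_set, t_c,
            solid, near_solid, mirrored=True,
        )
        return _mirror_path(mpath) if mpath else None
    if region.source is None:
        return None
    return _forward_region_path(
        graph, region, read, params, color_set, t_c, solid, near_solid, mirrored=False
    )


def _forward_region_path(
    graph, region, read, params, color_set, t_c, solid, near_solid, mirrored
):
    """Forward chaining; ``region`` must have a source anchor.

    When ``mirrored`` is True the region/read are already reverse
    complemented and the original match lists are only used for color
    collection (colors are orientation-free).
    """
    k = graph.k
    F = params.F
    if color_set is None:
        # color windows are computed on the original-orientation lists; the
        # color sets themselves carry no orientation
        C = collect_color_union(solid, near_solid, _unmirror(region, len(read), k, mirrored), params.B, graph)
    else:
        C = set(color_set)
    if t_c is None:
        T_C = color_floor(solid, near_solid, _unmirror(region, len(read), k, mirrored), params.B, params.D, graph)
    else:
        T_C = t_c
    memo: dict = {}

    waypoints = [region.source] + list(region.unsms)
    if region.target is not None:
        waypoints.append(region.target)

    out = _Walk(graph)
    prev = waypoints[0]
    n0 = graph.unitigs[prev.unitig].n_kmers
    out.start_kmer(prev.unitig, prev.strand, _okoff(n0, prev.unitig_pos, prev.strand))
    any_gap = False

    for wp in waypoints[1:]:
        budget = int((wp.read_pos - prev.read_pos + k) * (1 + F))
        leg = greedy_bfs_extend(
            graph,
            _anchor(prev),
            _anchor(wp),
            budget,
            C,
            T_C,
            read[prev.read_pos : wp.read_pos + k],
            params,
            memo,
        )
        if leg.complete:
            _append_leg(out, leg)
        else:
            any_gap = True
            gap_from = prev.read_pos + k
            overlap = max(0, gap_from - wp.read_pos)
            out.add_gap(read[gap_from : wp.read_pos])
            n2 = graph.unitigs[wp.unitig].n_kmers
            out.start_kmer(
                wp.unitig, wp.strand, _okoff(n2, wp.unitig_pos, wp.strand), skip=overlap
            )
        prev = wp

    if region.target is None:
        # open-ended tail: extend to the length bound, then trim by aligning
        # the raw remainder (prefix-anchored, free end gap in the extension)
        raw_rest = read[prev.read_pos : region.start + region.length]
        budget = max(region.l_max - out.total + k, int(len(raw_rest) * (1 + F)))
        ext = greedy_bfs_extend(
            graph, _anchor(prev), None, budget, C, T_C, raw_rest, params, memo
        )
        elements, t_complete = _trim_open_end(ext, raw_rest, k)
        if elements:
            # first element continues the anchor k-mer already on the walk
            out.advance(elements[0][4])
            _replay_elements(out, elements[1:])
        total = out.total
        complete = (not any_gap) and t_complete and region.l_min <= total <= region.l_max
        return out.to_path(complete)

    complete = not any_gap and region.l_min <= out.total <= region.l_max
    return out.to_path(complete)


def _unmirror(region, read_len, k, mirrored):
    return _mirror_region(region, read_len, k) if mirrored else region


def _append_leg(walk: _Walk, leg: GraphPath):
    """Append a complete leg to the walk.

    Every leg starts with the previous waypoint's anchor k-mer, which the
    walk has already emitted as the end of its last unitig element, so the
    leg's first element merely advances that element; subsequent elements
    are replayed as jumps.  Legs produced by the greedy search contain no
    gap elements.
    """
    first = leg.elements[0]
    assert first[0] == "unitig"
    walk.advance(first[4])
    _replay_elements(walk, leg.elements[1:])


def _replay_elements(walk: _Walk, elements):
    for e in elements:
        if e[0] == "gap":
            walk.add_gap(e[1])
        else:
            _tag, uid, strand, ka, kb = e
            walk.jump(uid, strand, ka, kb)


def _trim_open_end(ext: GraphPath, raw_rest: str, k: int):
    """Trim an open-ended extension where it best matches the raw remainder.

    Prefix-anchored alignment of the raw remainder against the extension:
    the best-scoring end location in the extension becomes the cut point.
    Returns the surviving elements beyond the anchor k-mer (for replay onto
    the accumulated walk) and whether the extension is usable.
    """
    if not ext.sequence or len(ext.sequence) < k:
        return [], False
    end = len(ext.sequence)
    if len(ext.sequence) > k and raw_rest:
        res = edlib.align(raw_rest, ext.sequence, mode="SHW", task="locations")
        locs = res.get("locations") or []
        if locs:
            end = max(k, min(locs[0][1] + 1, len(ext.sequence)))
    elements = []
    pos = 0
    for i, e in enumerate(ext.elements):
        _tag, uid, strand, ka, kb = e
        span = (kb - ka) + (k if i == 0 else 1)
        avail = end - pos
        if avail <= 0:
            break
        if span > avail:
            elements.append(("unitig", uid, strand, ka, kb - (span - avail)))
            break
        elements.append(tuple(e))
        pos += span
    if not elements:
        return [], False
    return elements, True
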