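"""From candidate paths to corrected read sequence.

Each non-solid region is corrected forward; if that yields no complete
path, also backward.  Incomplete paths from both directions are merged by
globally aligning each to the raw region and, column by column, taking the
direction that actually corrected (is non-gap at) that position.  Finally,
candidate-SNP sites on the chosen path are restored from the raw read: a
corrected base whose unitig position carries an IUPAC annotation is
overwritten with the raw base whenever the raw base belongs to the symbol's
base set, so the traversal cannot silently switch the read to the wrong
allele.  Corrected regions are spliced back between the untouched solid
regions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import edlib

from .anchoring import NonSolidRegion, classify_kmers, delimit_regions, filter_solid_runs
from .graph_core import CCDBG, SET_FROM_IUPAC
from .pathsearch import GraphPath, TraversalParams, find_region_path, side_intersection_colors

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class RegionCorrection:
    """The corrected sequence chosen for one non-solid region.

    ``origin`` parallels ``sequence`` (see GraphPath); ``snp_sites`` lists
    the annotated candidate-SNP positions on the corrected sequence as
    ``(offset, IUPAC symbol, unitig id)``, with the symbol expressed in read
    orientation.
    """

    region: NonSolidRegion
    sequence: str
    source_direction: str  # 'forward' | 'backward' | 'merged' | 'uncorrected'
    complete: bool
    origin: list = field(default_factory=list)
    snp_sites: list = field(default_factory=list)


def _oriented_symbol_set(symbol: str, strand: str) -> frozenset:
    bases = SET_FROM_IUPAC[symbol]
    if strand == "-":
        bases = frozenset(_COMP[b] for b in bases)
    return bases


def _collect_snp_sites(sequence, origin, graph: CCDBG):
    from .graph_core import IUPAC_FROM_SET

    sites = []
    for i, o in enumerate(origin):
        if o is None:
            continue
        uid, f, strand = o
        sym = graph.unitigs[uid].snp_annotations.get(f)
        if sym is None:
            continue
        sites.append((i, IUPAC_FROM_SET[_oriented_symbol_set(sym, strand)], uid))
    return sites


def _cigar_columns(cigar: str):
    for num, op in _CIGAR_RE.findall(cigar):
        for _ in range(int(num)):
            yield op


def _alignment_profile(seq: str, origin, raw: str):
    """Global alignment of a correction against the raw region.

    Returns ``(segments, covered)``: ``segments[p]`` is the list of
    ``(base, origin)`` aligned onto raw position p (insertions attach to the
    preceding raw position, leading insertions to p = -1 via index 0 of a
    prefix list), ``covered[p]`` is True when the aligned material at p came
    from the graph rather than a gap segment.
    """
    res = edlib.align(seq, raw, mode="NW", task="path")
    segments: list[list] = [[] for _ in raw]
    prefix: list = []
    covered = [False] * len(raw)
    p = -1  # raw cursor
    q = 0  # corrected cursor
    for op in _cigar_columns(res["cigar"]):
        if op in "=XM":
            p += 1
            segments[p].append((seq[q], origin[q]))
            covered[p] = origin[q] is not None
            q += 1
        elif op == "I":
            tgt = segments[p] if p >= 0 else prefix
            tgt.append((seq[q], origin[q]))
            q += 1
        else:  # D: raw base absent from the correction
            p += 1
            covered[p] = p > 0 and covered[p - 1]
    return prefix, segments, covered


def reconcile_directions(
    fwd: GraphPath | None,
    bwd: GraphPath | None,
    region_subseq: str,
    region: NonSolidRegion | None = None,
) -> RegionCorrection:
    """Choose or merge the forward and backward candidate corrections.

    A complete path wins outright (forward on ties).  Two incomplete paths
    are merged by walking their global alignments to the raw region in
    parallel, taking at each raw position the direction whose aligned
    material is graph-derived there; positions covered by neither keep the
    raw base.  With no path at all the region stays uncorrected.
    """
    if fwd is None and bwd is None:
        return RegionCorrection(region, region_subseq, "uncorrected", False)
    if fwd is not None and (bwd is None or fwd.complete or not bwd.complete):
        if fwd.complete or bwd is None:
            return RegionCorrection(region, fwd.sequence, "forward", fwd.complete, list(fwd.origin))
    if bwd is not None and bwd.complete:
        return RegionCorrection(region, bwd.sequence, "backward", True, list(bwd.origin))
    if fwd is None:
        return RegionCorrection(region, bwd.sequence, "backward", bwd.complete, list(bwd.origin))
    # both present, both incomplete: merge
    fpre, fseg, fcov = _alignment_profile(fwd.sequence, fwd.origin, region_subseq)
    bpre, bseg, bcov = _alignment_profile(bwd.sequence, bwd.origin, region_subseq)
    out_seq: list[str] = []
    out_origin: list = []
    for base, o in (fpre or bpre):
        out_seq.append(base)
        out_origin.append(o)
    for p in range(len(region_subseq)):
        if fcov[p]:
            chosen = fseg[p]
        elif bcov[p]:
            chosen = bseg[p]
        else:
            chosen = [(region_subseq[p], None)]
        for base, o in chosen:
            out_seq.append(base)
            out_origin.append(o)
    return RegionCorrection(region, "".join(out_seq), "merged", False, out_origin)


def restore_snps(
    region_subseq: str,
    correction: RegionCorrection,
    graph: CCDBG,
    F: float = 0.4,
) -> RegionCorrection:
    """Restore candidate-SNP alleles of the raw read onto the correction.

    The corrected sequence is globally aligned to the raw region.  At every
    match/mismatch column whose corrected base carries an IUPAC candidate-SNP
    annotation, the raw base overwrites the corrected one if it belongs to
    the symbol's base set.  A site where both bases already agreed is
    *strongly compatible*: the traversal chose the right subpath there, so
    annotated bases of the same unitig inside the insertion run adjacent to
    that site are also restored, using the raw base at the unitig-implied
    offset.
    """
    if correction.source_direction == "uncorrected" or not correction.sequence:
        correction.snp_sites = []
        return correction
    ratio = len(correction.sequence) / max(1, len(region_subseq))
    if not (1.0 / (1.0 + F) <= ratio <= 1.0 + F):
        logger.debug("correction/raw length ratio %.2f outside bounds; SNP restore skipped", ratio)
        correction.snp_sites = _collect_snp_sites(correction.sequence, correction.origin, graph)
        return correction

    seq = list(correction.sequence)
    origin = correction.origin
    res = edlib.align(correction.sequence, region_subseq, mode="NW", task="path")
    cols = list(_cigar_columns(res["cigar"]))

    # map alignment columns to (raw p, corrected q)
    col_info = []  # (op, p, q)
    p = q = 0
    for op in cols:
        if op in "=XM":
            col_info.append((op, p, q))
            p += 1
            q += 1
        elif op == "I":
            col_info.append((op, None, q))
            q += 1
        else:
            col_info.append((op, p, None))
            p += 1

    strong: list[tuple[int, int, int]] = []  # (column index, p, q)
    for ci, (op, p, q) in enumerate(col_info):
        if op not in "=XM" or origin[q] is None:
            continue
        uid, f, strand = origin[q]
        sym = graph.unitigs[uid].snp_annotations.get(f)
        if sym is None:
            continue
        allowed = _oriented_symbol_set(sym, strand)
        raw_base = region_subseq[p]
        if raw_base not in allowed:
            continue
        if seq[q] == raw_base:
            strong.append((ci, p, q))
        else:
            seq[q] = raw_base

    # strongly compatible sites license restoring annotated bases inside the
    # insertion runs adjacent to them
    for ci, p, q in strong:
        uid, f, strand = origin[q]
        for step in (-1, 1):
            cj = ci + step
            while 0 <= cj < len(col_info) and col_info[cj][0] == "I":
                qj = col_info[cj][2]
                oj = origin[qj]
                if oj is not None and oj[0] == uid:
                    _uid, fj, sj = oj
                    sym = graph.unitigs[uid].snp_annotations.get(fj)
                    if sym is not None:
                        delta = fj - f if strand == "+" else f - fj
                        praw = p + delta
                        if 0 <= praw < len(region_subseq):
                            allowed = _oriented_symbol_set(sym, sj)
                            if region_subseq[praw] in allowed:
                                seq[qj] = region_subseq[praw]
                cj += step

    correction.sequence = "".join(seq)
    correction.snp_sites = _collect_snp_sites(correction.sequence, origin, graph)
    return correction


@dataclass
class PassConfig:
    """Configuration distinguishing the two correction passes."""

    pass_id: int = 1
    k: int = 15
    color_mode: str = "pair_union"  # or 'side_intersection'
    min_solid_region: int = 15
    B: int = 1000
    frontier_mode: str = "unitig_count"

    def __post_init__(self):
        if self.pass_id not in (1, 2):
            raise ValueError("pass_id must be 1 or 2")
        if self.color_mode not in ("pair_union", "side_intersection"):
            raise ValueError(f"unknown color mode {self.color_mode!r}")


def correct_read(
    read: str,
    graph: CCDBG,
    params: TraversalParams,
    pass_cfg: PassConfig | None = None,
):
    """Correct one long read against the graph; returns ``(sequence, stats)``.

    Classify k-mers, delimit non-solid regions, extract a path per region
    (forward, then backward when the forward path is absent or incomplete),
    reconcile, restore candidate SNPs, and splice the region corrections
    between the untouched solid regions.  Reads without any solid anchor are
    returned unchanged and flagged.
    """
    if pass_cfg is None:
        pass_cfg = PassConfig(k=graph.k, min_solid_region=graph.k, B=params.B,
                              frontier_mode=params.frontier_mode)
    k = graph.k
    stats = {"regions": 0, "complete": 0, "merged": 0, "uncorrected": 0, "flag": None}
    if len(read) < k:
        stats["flag"] = "too_short"
        return read, stats
    solid, near = classify_kmers(read, graph)
    solid = filter_solid_runs(solid, k, pass_cfg.min_solid_region)
    if not solid:
        stats["flag"] = "no_anchor"
        return read, stats
    regions = delimit_regions(solid, near, len(read), k, params.F)
    stats["regions"] = len(regions)

    corrections: list[RegionCorrection] = []
    for region in regions:
        start_raw = region.start
        end_raw = region.start + region.length
        raw = read[start_raw:end_raw]
        kwargs = {}
        if pass_cfg.color_mode == "side_intersection":
            kwargs["color_set"] = side_intersection_colors(solid, region, pass_cfg.B, graph)
        fwd = find_region_path(graph, region, read, solid, near, params, "forward", **kwargs)
        bwd = None
        if fwd is None or not fwd.complete:
            bwd = find_region_path(graph, region, read, solid, near, params, "backward", **kwargs)
        corr = reconcile_directions(fwd, bwd, raw, region)
        corr = restore_snps(raw, corr, graph, params.F)
        if corr.complete:
            stats["complete"] += 1
        elif corr.source_direction == "merged":
            stats["merged"] += 1
        elif corr.source_direction == "uncorrected":
            stats["uncorrected"] += 1
        corrections.append(corr)

    # splice: region corrections replace raw interval [start, start+length);
    # adjacent regions sharing a single-k-mer solid anchor overlap by k bases
    out: list[str] = []
    cursor = 0
    for corr in corrections:
        start_raw = corr.region.start
        end_raw = corr.region.start + corr.region.length
        if start_raw > cursor:
            out.append(read[cursor:start_raw])
            overlap = 0
        else:
            overlap = cursor - start_raw
        out.append(corr.sequence[overlap:])
        cursor = end_raw
    out.append(read[cursor:])
    return "".join(out), stats
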