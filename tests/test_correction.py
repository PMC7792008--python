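"""Direction reconciliation, SNP restoration and whole-read correction."""

import random

import edlib
import pytest

from hybridec.correction import (
    PassConfig,
    RegionCorrection,
    correct_read,
    reconcile_directions,
    restore_snps,
)
from hybridec.graph_core import annotate_candidate_snps, build_graph, from_unitig_sequences
from hybridec.pathsearch import GraphPath, TraversalParams

from _oracles import mutate, pick_weak_mutation, rc


def _path(seq, complete, origin=None, elements=None):
    return GraphPath(
        elements=elements or [("unitig", 0, "+", 0, 0)],
        sequence=seq,
        origin=origin if origin is not None else [(0, i, "+") for i in range(len(seq))],
        complete=complete,
    )


class TestReconcile:
    def test_complete_forward_wins(self):
        fwd = _path("ACGTACGT", True)
        bwd = _path("ACGTAAAA", False)
        rc_ = reconcile_directions(fwd, bwd, "ACGTACGT")
        assert rc_.source_direction == "forward" and rc_.complete

    def test_complete_backward_beats_incomplete_forward(self):
        fwd = _path("ACGTAAAA", False)
        bwd = _path("ACGTACGT", True)
        rc_ = reconcile_directions(fwd, bwd, "ACGTACGT")
        assert rc_.source_direction == "backward" and rc_.complete

    def test_both_absent_is_uncorrected(self):
        rc_ = reconcile_directions(None, None, "ACGT")
        assert rc_.source_direction == "uncorrected" and not rc_.complete
        assert rc_.sequence == "ACGT"

    def test_half_coverage_merge_recovers_truth(self):
        # truth differs from the raw region by two substitutions; the forward
        # path corrected only the left half (then gap), the backward path
        # only the right half
        truth = "ACGTTGCAACGTTGCAACGT"
        raw = mutate(mutate(truth, 4), 15)
        half = len(truth) // 2
        fwd = GraphPath(
            elements=[("unitig", 0, "+", 0, 0), ("gap", raw[half:])],
            sequence=truth[:half] + raw[half:],
            origin=[(0, i, "+") for i in range(half)] + [None] * (len(raw) - half),
            complete=False,
        )
        bwd = GraphPath(
            elements=[("gap", raw[:half]), ("unitig", 1, "+", 0, 0)],
            sequence=raw[:half] + truth[half:],
            origin=[None] * half + [(1, i, "+") for i in range(len(truth) - half)],
            complete=False,
        )
        merged = reconcile_directions(fwd, bwd, raw)
        assert merged.source_direction == "merged"
        assert merged.sequence == truth


class TestRestoreSnps:
    def _graph_with_annotation(self):
        # unitig with an R (A/G) annotation at offset 3
        g = from_unitig_sequences(["CCTGACC"], 3)
        g.unitigs[0].snp_annotations[3] = "R"
        return g

    def test_compatible_raw_base_overwrites(self):
        g = self._graph_with_annotation()
        corr = RegionCorrection(
            None, "CCTGACC", "forward", True,
            origin=[(0, i, "+") for i in range(7)],
        )
        # raw read carries the other allele A at the annotated G position
        out = restore_snps("CCTAACC", corr, g)
        assert out.sequence == "CCTAACC"

    def test_incompatible_raw_base_left_alone(self):
        g = self._graph_with_annotation()
        corr = RegionCorrection(
            None, "CCTGACC", "forward", True,
            origin=[(0, i, "+") for i in range(7)],
        )
        out = restore_snps("CCTCACC", corr, g)  # C not in {A, G}
        assert out.sequence == "CCTGACC"

    def test_reverse_strand_annotation_is_complemented(self):
        g = self._graph_with_annotation()
        # path traversed the unitig in '-' orientation: base at offset 3 is
        # emitted as C (complement of G), allowed raw alleles become {T, C}
        seq = rc("CCTGACC")
        corr = RegionCorrection(
            None, seq, "forward", True,
            origin=[(0, 6 - i, "-") for i in range(7)],
        )
        raw = seq[:3] + "T" + seq[4:]
        out = restore_snps(raw, corr, g)
        assert out.sequence == raw

    def test_strongly_compatible_site_restores_adjacent_insertion(self):
        # corrected sequence has a two-base insertion relative to the raw
        # region right after a strongly compatible annotated site; the
        # second inserted base is annotated and the raw read carries the
        # alternate allele at the unitig-implied offset
        g = from_unitig_sequences(["CCTGAACC"], 3)
        g.unitigs[0].snp_annotations[3] = "R"  # G, strongly compatible site
        g.unitigs[0].snp_annotations[4] = "Y"  # C/T at the inserted base
        corr = RegionCorrection(
            None, "CCTGCACC"[:8], "forward", True,
            origin=[(0, i, "+") for i in range(8)],
        )
        corr.sequence = "CCTGAACC"
        raw = "CCTGTCC"  # G matches (strong); raw T at the +1 offset; A deleted
        out = restore_snps(raw, corr, g, F=0.4)
        # the annotated inserted base (offset 4, Y) is overwritten with raw T
        assert out.sequence[3] == "G"
        assert out.sequence[4] == "T"

    def test_snp_sites_reported(self):
        g = self._graph_with_annotation()
        corr = RegionCorrection(
            None, "CCTGACC", "forward", True,
            origin=[(0, i, "+") for i in range(7)],
        )
        out = restore_snps("CCTGACC", corr, g)
        assert out.snp_sites == [(3, "R", 0)]


@pytest.fixture(scope="module")
def genome_graph():
    rng = random.Random(17)
    genome = "".join(rng.choice("ACGT") for _ in range(4000))
    return genome, build_graph([genome], 11, 1)


class TestCorrectRead:

    def test_error_free_read_is_unchanged(self, genome_graph):
        genome, g = genome_graph
        read = genome[500:1500]
        out, stats = correct_read(read, g, TraversalParams())
        assert out == read
        assert stats["regions"] == 0

    def test_single_substitution_restored_to_truth(self, genome_graph):
        genome, g = genome_graph
        _p, read = pick_weak_mutation(genome, g, 500, 1500, 400, 450)
        out, stats = correct_read(read, g, TraversalParams())
        assert out == genome[500:1500]

    def test_read_over_coverage_gap_keeps_raw_bases(self):
        from hybridec.anchoring import classify_kmers, delimit_regions

        rng = random.Random(18)
        genome = "".join(rng.choice("ACGT") for _ in range(3000))
        # pick a hole whose interior raises no distance-1 waypoints, so the
        # whole uncovered stretch must be carried through as one gap
        for hole in range(1100, 2000, 20):
            g = build_graph([genome[:hole], genome[hole + 80 :]], 11, 1)
            read = genome[1000:2000]
            solid, near = classify_kmers(read, g)
            regions = delimit_regions(solid, near, len(read), 11, 0.4)
            big = [r for r in regions if r.length > 60]
            if len(big) == 1 and not big[0].unsms:
                break
        else:
            raise AssertionError("no waypoint-free hole found")
        out, _stats = correct_read(read, g, TraversalParams())
        assert genome[hole : hole + 80] in out

    def test_solid_regions_never_modified(self, genome_graph):
        genome, g = genome_graph
        rng = random.Random(19)
        read = list(genome[200:1800])
        for _ in range(15):
            read[rng.randrange(len(read))] = rng.choice("ACGT")
        read = "".join(read)
        from hybridec.anchoring import classify_kmers

        solid, _ = classify_kmers(read, g)
        out, _stats = correct_read(read, g, TraversalParams())
        # long interior solid runs must appear verbatim in the output
        runs = []
        cur = [solid[0]]
        for m in solid[1:]:
            if m.read_pos == cur[-1].read_pos + 1:
                cur.append(m)
            else:
                runs.append(cur)
                cur = [m]
        runs.append(cur)
        for run in runs:
            if len(run) > 30:
                s = read[run[0].read_pos : run[-1].read_pos + g.k]
                assert s in out

    def test_too_short_read_flagged(self, genome_graph):
        _genome, g = genome_graph
        out, stats = correct_read("ACGT", g, TraversalParams())
        assert out == "ACGT" and stats["flag"] == "too_short"

    def test_read_without_anchor_flagged(self, genome_graph):
        _genome, g = genome_graph
        read = "AT" * 40
        out, stats = correct_read(read, g, TraversalParams())
        assert out == read and stats["flag"] == "no_anchor"

    def test_mixed_errors_reduced(self, genome_graph):
        genome, g = genome_graph
        rng = random.Random(20)
        read = list(genome[100:2100])
        for _ in range(40):
            i = rng.randrange(len(read))
            op = rng.choice("sid")
            if op == "s":
                read[i] = rng.choice("ACGT")
            elif op == "i":
                read[i] = read[i] + rng.choice("ACGT")
            else:
                read[i] = ""
        read = "".join(read)
        out, _stats = correct_read(read, g, TraversalParams())
        truth = genome[100:2100]
        d_raw = edlib.align(read, truth)["editDistance"]
        d_corr = edlib.align(out, truth)["editDistance"]
        assert d_corr < d_raw / 3
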