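"""Scoring corrected reads against simulated truth.

The error rate of a read is its edit distance to the exact substring of the
haplotype it was drawn from, divided by the truth length; the alignment is
end-free on the read side so trimmed read ends are not charged.  This is a
truth-based re-specification of the usual alignment-to-reference error
estimate and is only comparable in spirit to reference-based numbers.

Haplotype preservation is measured directly: over all (read, heterozygous
SNP site) pairs where the read aligns across the site, the fraction whose
corrected base equals the allele of the read's haplotype of origin.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass

import edlib

from ._kmers import revcomp_str
from .simdata import DiploidTruth

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class ErrorReport:
    per_read: list[tuple[str, int, int, float]]  # (id, distance, truth len, rate)
    mean_rate: float
    median_rate: float
    skipped: int = 0

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("read_id\tedit_distance\ttruth_length\terror_rate\n")
            for rid, d, L, rate in self.per_read:
                fh.write(f"{rid}\t{d}\t{L}\t{rate:.6f}\n")

    def summary(self) -> dict:
        return {
            "n_reads": len(self.per_read),
            "mean_error_rate": self.mean_rate,
            "median_error_rate": self.median_rate,
            "skipped": self.skipped,
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def _oriented_truth(truth: DiploidTruth, rid: str) -> str | None:
    prov = truth.read_provenance.get(rid)
    if prov is None:
        return None
    return prov.true_seq if prov.strand == "+" else revcomp_str(prov.true_seq)


def error_rate(reads, truth: DiploidTruth) -> ErrorReport:
    """Per-read truth-based error rates plus mean/median aggregates.

    ``reads`` is an iterable of ``(read id, sequence)``.  Reads without
    provenance are skipped with a warning and counted.
    """
    per_read = []
    skipped = 0
    for rid, seq in reads:
        t = _oriented_truth(truth, rid)
        if t is None:
            logger.warning("read %s has no provenance; skipped", rid)
            skipped += 1
            continue
        d = edlib.align(seq, t, mode="HW")["editDistance"]
        per_read.append((rid, d, len(t), d / len(t)))
    rates = sorted(r for *_x, r in per_read)
    n = len(rates)
    mean = sum(rates) / n if n else 0.0
    median = (rates[n // 2] if n % 2 else (rates[n // 2 - 1] + rates[n // 2]) / 2) if n else 0.0
    return ErrorReport(per_read, mean, median, skipped)


def het_retention(reads, truth: DiploidTruth) -> float | None:
    """Fraction of covered heterozygous SNP sites carrying the true allele.

    For each read, the corrected sequence is globally aligned to the true
    subsequence; every het site inside the aligned span contributes one
    observation.  Returns None when no site is covered.
    """
    sites = truth.snp_sites()
    if not sites:
        raise ValueError("truth contains no SNP")
    hits = 0
    seen = 0
    for rid, seq in reads:
        prov = truth.read_provenance.get(rid)
        if prov is None:
            continue
        hap_positions = []
        for p1, p2, ref, alt in sites:
            pos = p1 if prov.haplotype == 1 else p2
            allele = ref if prov.haplotype == 1 else alt
            off = pos - prov.start
            if 0 <= off < len(prov.true_seq):
                hap_positions.append((off, allele))
        if not hap_positions:
            continue
        t = prov.true_seq
        q = seq if prov.strand == "+" else revcomp_str(seq)
        res = edlib.align(q, t, mode="NW", task="path")
        # map truth offsets to read offsets through the alignment
        tmap: dict[int, int | None] = {}
        p = q_i = 0
        for num, op in _CIGAR_RE.findall(res["cigar"]):
            num = int(num)
            if op in "=XM":
                for _ in range(num):
                    tmap[p] = q_i
                    p += 1
                    q_i += 1
            elif op == "I":
                q_i += num
            else:  # deletion in read
                for _ in range(num):
                    tmap[p] = None
                    p += 1
        for off, allele in hap_positions:
            qoff = tmap.get(off)
            if qoff is None:
                continue  # read does not align across the site: excluded
            seen += 1
            if q[qoff] == allele:
                hits += 1
    if seen == 0:
        return None
    return hits / seen
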