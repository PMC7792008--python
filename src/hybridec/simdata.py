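"""Seeded synthetic diploid data with full truth tracking.

Emulates the input regime of hybrid correction at desk scale: a diploid
genome pair differing by heterozygous SNPs and short indels, accurate
Illumina-like paired short reads (~151 bp, substitution errors only) and
noisy ONT-like long reads (kb-scale, mixed substitution/insertion/deletion
errors at ~10%).  Everything is reproducible from ``(parameters, seed)``,
and per-read provenance (haplotype, start, strand) lets the evaluator score
corrections against the exact molecule of origin.

Deliberate simplifications relative to real data: error positions are
uniform (no homopolymer bias), long-read lengths are log-normal truncated
to [1 kb, 4x mean], and there are no chimeric or adapter artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._kmers import BASES, codes_to_seq, revcomp_str, seq_to_codes

_MAX_RATE = 0.05


@dataclass
class Variant:
    pos: int  # 0-based position on hap1 (VCF-style anchor for indels)
    kind: str  # 'SNP' | 'insertion' | 'deletion'
    ref: str
    alt: str


@dataclass
class ReadProvenance:
    haplotype: int  # 1 or 2
    start: int  # 0-based start on the haplotype
    strand: str  # '+' | '-'
    true_seq: str  # forward-strand substring of the haplotype


@dataclass
class DiploidTruth:
    hap1: str
    hap2: str
    variants: list[Variant]
    read_provenance: dict[str, ReadProvenance] = field(default_factory=dict)

    def snp_sites(self):
        """Heterozygous SNP sites as ``(hap1 pos, hap2 pos, ref, alt)``."""
        out = []
        shift = 0
        for v in sorted(self.variants, key=lambda v: v.pos):
            if v.kind == "SNP":
                out.append((v.pos, v.pos + shift, v.ref, v.alt))
            elif v.kind == "insertion":
                shift += len(v.alt) - len(v.ref)
            else:
                shift += len(v.alt) - len(v.ref)
        return out

    def haplotype(self, which: int) -> str:
        return self.hap1 if which == 1 else self.hap2


def _random_seq(rng, length: int) -> str:
    return codes_to_seq(rng.integers(0, 4, size=length))


def simulate_diploid(
    length: int,
    snp_rate: float,
    indel_rate: float,
    seed: int,
    min_spacing: int | None = None,
    k2: int = 63,
) -> DiploidTruth:
    """Simulate a diploid genome: hap1 uniform iid, hap2 by applying variants.

    Variant sites are Poisson-spaced along hap1 at rate snp_rate+indel_rate.
    By default sites closer than ``min_spacing`` (k2 bases) to the previous
    one are suppressed so truth evaluation stays unambiguous; pass
    ``min_spacing=0`` to disable.  Indels are 1-5 bp with geometric lengths.
    """
    for r in (snp_rate, indel_rate):
        if not 0 <= r <= _MAX_RATE:
            raise ValueError(f"variant rate {r} outside [0, {_MAX_RATE}]")
    if length < 10 * k2:
        raise ValueError(f"genome length must be >= 10*k2 = {10 * k2}")
    if min_spacing is None:
        min_spacing = k2
    rng = np.random.default_rng(seed)
    hap1 = _random_seq(rng, length)
    total = snp_rate + indel_rate
    variants: list[Variant] = []
    if total > 0:
        pos = 0
        p_snp = snp_rate / total
        while True:
            gap = rng.geometric(total)
            pos += max(gap, min_spacing if variants else gap)
            if pos >= length - 1:
                break
            if rng.random() < p_snp:
                ref = hap1[pos]
                alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
                variants.append(Variant(pos, "SNP", ref, alt))
            else:
                ln = min(int(rng.geometric(0.5)), 5)
                if rng.random() < 0.5:
                    variants.append(
                        Variant(pos, "insertion", hap1[pos], hap1[pos] + _random_seq(rng, ln))
                    )
                else:
                    if pos + 1 + ln >= length:
                        continue
                    variants.append(
                        Variant(pos, "deletion", hap1[pos : pos + 1 + ln], hap1[pos])
                    )
    hap2 = apply_variants(hap1, variants)
    return DiploidTruth(hap1, hap2, variants)


def apply_variants(hap1: str, variants) -> str:
    parts = []
    cur = 0
    for v in sorted(variants, key=lambda v: v.pos):
        parts.append(hap1[cur : v.pos])
        parts.append(v.alt)
        cur = v.pos + len(v.ref)
    parts.append(hap1[cur:])
    return "".join(parts)


def _apply_substitutions(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    codes = seq_to_codes(seq).astype(np.int64)
    hits = rng.random(codes.size) < rate
    if hits.any():
        codes[hits] = (codes[hits] + rng.integers(1, 4, size=int(hits.sum()))) % 4
    return codes_to_seq(codes)


def _apply_mixed_errors(seq: str, sub: float, ins: float, dele: float, rng) -> str:
    """Apply substitution/insertion/deletion errors at per-base rates.

    Per template base at most one event fires (drawn from one uniform), so
    the requested rates are per-base event probabilities.
    """
    codes = seq_to_codes(seq).astype(np.int64)
    n = codes.size
    r = rng.random(n)
    subs = r < sub
    dels = (r >= sub) & (r < sub + dele)
    inss = (r >= sub + dele) & (r < sub + dele + ins)
    codes = (codes + np.where(subs, rng.integers(1, 4, size=n), 0)) % 4
    ins_base = rng.integers(0, 4, size=n)
    reps = np.where(dels, 0, 1) + np.where(inss & ~dels, 1, 0)
    idx = np.repeat(np.arange(n), reps)
    out = codes[idx]
    dup = np.zeros(idx.size, dtype=bool)
    dup[1:] = idx[1:] == idx[:-1]  # second copy of a base = the inserted one
    out[dup] = ins_base[idx[dup]]
    return codes_to_seq(out)


@dataclass
class SimulatedReads:
    srs_pairs: list[tuple[str, str, str]]  # (pair id, mate1, mate2)
    lrs: list[tuple[str, str]]  # (read id, sequence)


def simulate_reads(
    truth: DiploidTruth,
    srs_cov: float,
    srs_len: int = 151,
    insert_mean: int = 400,
    srs_err: float = 0.002,
    lrs_cov: float = 20.0,
    lrs_len_mean: int = 8000,
    lrs_err: tuple[float, float, float] = (0.04, 0.03, 0.03),
    seed: int = 0,
) -> SimulatedReads:
    """Draw paired short reads and noisy long reads from both haplotypes.

    Reads are sampled uniformly over haplotypes, positions and strands.
    Short-read errors are substitutions at ``srs_err``; long reads mix
    substitutions, insertions and deletions at ``lrs_err``.  Provenance is
    recorded on ``truth.read_provenance``.
    """
    if srs_cov <= 0 or lrs_cov <= 0:
        raise ValueError("coverages must be > 0")
    rng = np.random.default_rng(seed)
    G = len(truth.hap1)
    haps = (truth.hap1, truth.hap2)
    if srs_len > min(len(h) for h in haps) or lrs_len_mean > min(len(h) for h in haps):
        raise ValueError("read length exceeds genome length")

    srs_pairs = []
    n_pairs = int(np.ceil(srs_cov * G / (2 * srs_len)))
    frag_sd = max(10, insert_mean // 10)
    for i in range(n_pairs):
        h = int(rng.integers(1, 3))
        hap = haps[h - 1]
        frag_len = int(np.clip(rng.normal(insert_mean, frag_sd), srs_len, len(hap)))
        start = int(rng.integers(0, len(hap) - frag_len + 1))
        frag = hap[start : start + frag_len]
        if rng.random() < 0.5:
            frag = revcomp_str(frag)
        m1 = _apply_substitutions(frag[:srs_len], srs_err, rng)
        m2 = _apply_substitutions(revcomp_str(frag[-srs_len:]), srs_err, rng)
        srs_pairs.append((f"sr{i}", m1, m2))

    lrs = []
    sigma = 0.5
    mu = np.log(lrs_len_mean) - sigma**2 / 2
    total = 0
    target = lrs_cov * G
    i = 0
    while total < target:
        h = int(rng.integers(1, 3))
        hap = haps[h - 1]
        L = int(np.clip(rng.lognormal(mu, sigma), 1000, 4 * lrs_len_mean))
        L = min(L, len(hap))
        start = int(rng.integers(0, len(hap) - L + 1))
        true_sub = hap[start : start + L]
        strand = "+" if rng.random() < 0.5 else "-"
        template = true_sub if strand == "+" else revcomp_str(true_sub)
        read = _apply_mixed_errors(template, *lrs_err, rng)
        rid = f"lr{i}"
        truth.read_provenance[rid] = ReadProvenance(h, start, strand, true_sub)
        lrs.append((rid, read))
        total += L
        i += 1
    return SimulatedReads(srs_pairs, lrs)


# ------------------------------------------------------------- truth files


def write_truth(truth: DiploidTruth, out_dir):
    """Write haplotypes (FASTA), variants (VCF 4.2) and provenance (TSV)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    out = Path(out_dir)
    SeqIO.write(
        [
            SeqRecord(Seq(truth.hap1), id="hap1", description=""),
            SeqRecord(Seq(truth.hap2), id="hap2", description=""),
        ],
        str(out / "haplotypes.fasta"),
        "fasta",
    )
    with open(out / "variants.vcf", "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=hap1,length={len(truth.hap1)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(truth.variants, key=lambda v: v.pos):
            fh.write(f"hap1\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\n")
    with open(out / "provenance.tsv", "w") as fh:
        fh.write("read_id\thaplotype\tstart\tstrand\ttrue_length\n")
        for rid, p in truth.read_provenance.items():
            fh.write(f"{rid}\t{p.haplotype}\t{p.start}\t{p.strand}\t{len(p.true_seq)}\n")


def load_truth(out_dir) -> DiploidTruth:
    """Reload a truth directory written by ``write_truth``."""
    import pysam
    from Bio import SeqIO

    out = Path(out_dir)
    seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(out / "haplotypes.fasta"), "fasta")}
    variants = []
    with pysam.VariantFile(str(out / "variants.vcf")) as vf:
        for rec in vf:
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) == len(alt) == 1:
                kind = "SNP"
            elif len(alt) > len(ref):
                kind = "insertion"
            else:
                kind = "deletion"
            variants.append(Variant(rec.pos - 1, kind, ref, alt))
    truth = DiploidTruth(seqs["hap1"], seqs["hap2"], variants)
    prov_path = out / "provenance.tsv"
    if prov_path.exists():
        with open(prov_path) as fh:
            next(fh)
            for line in fh:
                rid, hap, start, strand, tlen = line.rstrip("\n").split("\t")
                hap_i, start_i, tlen_i = int(hap), int(start), int(tlen)
                hseq = truth.haplotype(hap_i)
                truth.read_provenance[rid] = ReadProvenance(
                    hap_i, start_i, strand, hseq[start_i : start_i + tlen_i]
                )
    return truth
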