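"""Synthetic genomes, planted integrations, junction reads and barcode reads.

Every downstream stage of the toolkit is testable against the ground truth
produced here: bacterial genome pairs differing by a planted integrant with a
target-site duplication, donor-genome junction read pairs with soft-clipped
crossovers (emitted both as FASTQ and as truth-derived SAM alignments against
the composite donor+genome reference), and barcode amplicon reads with
per-base quality scores.  All output is deterministic under a fixed seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from ._seq import BASES, common_prefix_len, common_suffix_len, revcomp

DEFAULT_WINDOW = 50
BASELINE_Q = 37  # high fixed baseline quality; degraded per-base by seed


# ---------------------------------------------------------------------------
# Genomes and planted integrations
# ---------------------------------------------------------------------------

def make_genome(length: int, gc_fraction: float = 0.5, seed: int = 0) -> str:
    """Random nucleotide sequence of ``length`` bases at the given GC content."""
    if length < 1:
        raise ValueError("length must be a positive integer")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    bases = rng.choice(list(BASES), size=length, p=[at, gc, gc, at])
    return "".join(bases)


@dataclass
class SyntheticTruth:
    """Ground truth for one planted integration."""

    genome_id: str
    insertion_position: int   # canonical-leftmost site on the pre-integration genome
    duplication: str
    element: str
    true_attB: str
    true_attP: str
    core: str
    seed: int
    pre_genome: str = ""
    post_genome: str = ""


def _canonical_leftmost(pre: str, post: str) -> tuple[int, int, str]:
    """Leftmost-canonical (site, duplication_len, element) for a planted pair.

    Closed-form arithmetic from the common prefix/suffix of the pair; this is
    the same canonicalization the boundary decomposition reports, so planted
    truths compare exactly, but it is computed independently of that module.
    """
    ins_len = len(post) - len(pre)
    cp = common_prefix_len(pre, post)
    cs = common_suffix_len(pre, post)
    site = len(pre) - cs
    if site < 0:
        site = 0
    dlen = min(cp - site, ins_len)
    if dlen < 0:
        dlen = 0
    element = post[site + dlen : site + ins_len]
    return site, dlen, element


def plant_integration(genome: str, element: str, position: int,
                      duplication_len: int = 0, core: str = "TT",
                      seed: int = 0, window: int = DEFAULT_WINDOW,
                      genome_id: str = "synthetic") -> tuple[str, SyntheticTruth]:
    """Insert ``element`` into ``genome`` with a target-site duplication.

    The post-integration genome is ``genome[:p] + D + element + D +
    genome[p+|D|:]`` with ``D = genome[p:p+duplication_len]``.  The requested
    core dinucleotide is written into the pre-integration genome at the
    duplication midpoint (or, for duplications shorter than 2 bp, across the
    insertion junction and the element termini) so that the core is genuinely
    shared between the planted attB and attP.  Truth attB/attP windows are
    centered on the duplication midpoint after leftmost canonicalization.
    """
    if len(core) != 2 or any(b not in BASES for b in core):
        raise ValueError("core must be a 2-mer over ACGT")
    if not element:
        raise ValueError("element must be non-empty")
    if position < 0 or position + duplication_len > len(genome):
        raise ValueError("position out of range for the requested duplication")

    g = list(genome)
    e = list(element)
    if duplication_len >= 2:
        mid = position + duplication_len // 2
        g[mid - 1], g[mid] = core[0], core[1]
    else:
        # Plant the core across the junction and mirror it on the element
        # termini so attB and attP share it.
        if position == 0 or position == len(genome):
            raise ValueError("zero-duplication planting requires interior position")
        g[position - 1], g[position] = core[0], core[1]
        e[-1], e[0] = core[0], core[1]
    pre = "".join(g)
    element = "".join(e)

    dup = pre[position : position + duplication_len]
    post = pre[:position] + dup + element + dup + pre[position + duplication_len :]

    site, dlen, canon_element = _canonical_leftmost(pre, post)
    attb_mid = site + dlen // 2
    start = attb_mid - window // 2
    true_attB = pre[max(0, start) : max(0, start) + window]
    wrap = canon_element + pre[site : site + dlen] + canon_element
    attp_mid = len(canon_element) + dlen // 2
    pstart = attp_mid - window // 2
    true_attP = wrap[pstart : pstart + window]

    truth = SyntheticTruth(
        genome_id=genome_id,
        insertion_position=site,
        duplication=pre[site : site + dlen],
        element=canon_element,
        true_attB=true_attB,
        true_attP=true_attP,
        core=core,
        seed=seed,
        pre_genome=pre,
        post_genome=post,
    )
    return post, truth


# ---------------------------------------------------------------------------
# Junction-read simulation
# ---------------------------------------------------------------------------

@dataclass
class DonorDesign:
    """Donor amplicon carrying an attD attachment site and a priming site."""

    sequence: str
    primer: str
    primer_start: int
    attd_interval: tuple[int, int]   # half-open, donor coordinates
    core_offset: int                 # core start within the attD


def build_donor(attD: str, core_offset: int, seed: int = 0,
                primer_len: int = 25, spacer_len: int = 10,
                upstream: int = 40, downstream: int = 60) -> DonorDesign:
    """Assemble a donor sequence: filler + primer + spacer + attD + filler."""
    if not 0 <= core_offset <= len(attD) - 2:
        raise ValueError("core_offset out of range for the attD")
    rng = np.random.default_rng(seed)

    def rand(n: int) -> str:
        return "".join(rng.choice(list(BASES), size=n))

    up = rand(upstream)
    primer = rand(primer_len)
    spacer = rand(spacer_len)
    down = rand(downstream)
    seq = up + primer + spacer + attD + down
    return DonorDesign(
        sequence=seq,
        primer=primer,
        primer_start=len(up),
        attd_interval=(len(up) + primer_len + spacer_len,
                       len(up) + primer_len + spacer_len + len(attD)),
        core_offset=core_offset,
    )


@dataclass
class PlantedSite:
    chrom: str
    position: int     # 0-based core start on the genome
    strand: str       # '+' or '-'
    n_fragments: int = 0


@dataclass
class SimulatedRead:
    name: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass
class JunctionSimulation:
    reads: list[SimulatedRead]
    sam_text: str
    sites: list[PlantedSite]
    donor: DonorDesign
    genome: str
    chrom: str = "chr1"


def _apply_errors(seq: str, qual: list[int], error_rate: float,
                  rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    out = list(seq)
    n_err = rng.binomial(len(seq), error_rate)
    for pos in rng.choice(len(seq), size=n_err, replace=False):
        out[pos] = BASES[(BASES.index(out[pos]) + rng.integers(1, 4)) % 4]
        qual[pos] = int(rng.integers(8, 20))
    return "".join(out)


def _qual_string(length: int, rng: np.random.Generator) -> list[int]:
    # Fixed high baseline with seeded per-base degradation.
    quals = np.full(length, BASELINE_Q, dtype=int)
    degrade = rng.random(length) < 0.02
    quals[degrade] = rng.integers(20, BASELINE_Q, size=int(degrade.sum()))
    return quals.tolist()


def _phred(quals: list[int]) -> str:
    return "".join(chr(q + 33) for q in quals)


def simulate_junction_reads(post_genome: str, donor: DonorDesign,
                            primer: str | None = None, n_reads: int = 2000,
                            error_rate: float = 0.001, seed: int = 0,
                            sites: list[PlantedSite] | None = None,
                            n_sites: int = 20, read_len: int = 150,
                            duplicate_fraction: float = 0.08,
                            chrom: str = "chr1") -> JunctionSimulation:
    """Simulate paired junction-sequencing reads over planted integration sites.

    Read 1 begins at the donor primer, runs through the donor up to the attD
    core and crosses over into the genome at a planted site; read 2 is fully
    genomic.  Alignments against the composite donor+genome reference are
    emitted as SAM with the donor part of read 1 soft-clipped, the way an
    aligner would place these reads.  A fraction of fragments is re-emitted
    as positional PCR duplicates.
    """
    primer = primer if primer is not None else donor.primer
    if primer not in donor.sequence:
        raise ValueError("primer is not a substring of the donor")
    rng = np.random.default_rng(seed)
    genome = post_genome

    attd_lo, attd_hi = donor.attd_interval
    core_don = attd_lo + donor.core_offset          # donor coord of core start
    primer_start = donor.sequence.index(primer)
    clip_template = donor.sequence[primer_start:core_don]
    clip_len = len(clip_template)
    if clip_len >= read_len - 30:
        raise ValueError("read length too short for the donor clip")

    if sites is None:
        # Rejection-sample positions separated by > 2 kb so loci are
        # unambiguous at the 500 bp merge scale.
        margin = 1000
        positions: list[int] = []
        attempts = 0
        while len(positions) < n_sites:
            attempts += 1
            if attempts > 100 * n_sites:
                raise ValueError("genome too short for the requested site count")
            p = int(rng.integers(margin, len(genome) - margin))
            if all(abs(p - q) > 2000 for q in positions):
                positions.append(p)
        sites = [
            PlantedSite(chrom=chrom, position=p,
                        strand="+" if rng.random() < 0.5 else "-")
            for p in sorted(positions)
        ]
    sites = [PlantedSite(s.chrom, s.position, s.strand, 0) for s in sites]

    reads: list[SimulatedRead] = []
    sam = io.StringIO()
    sam.write("@HD\tVN:1.6\tSO:unsorted\n")
    sam.write(f"@SQ\tSN:donor\tLN:{len(donor.sequence)}\n")
    sam.write(f"@SQ\tSN:{chrom}\tLN:{len(genome)}\n")
    records: list[tuple[int, str]] = []  # (sort position, sam line block)

    glen = read_len - clip_len
    fragments: list[tuple[int, int, int]] = []  # (site index, frag_len, copy)
    n_unique = max(0, int(round(n_reads * (1.0 - duplicate_fraction))))
    for _ in range(n_unique):
        fragments.append((int(rng.integers(0, len(sites))),
                          int(rng.integers(glen + 60, 600)), 0))
    while len(fragments) < n_reads and n_unique:
        src = fragments[int(rng.integers(0, n_unique))]
        fragments.append((src[0], src[1], 1))

    for idx, (si, frag_len, copy) in enumerate(fragments):
        site = sites[si]
        if copy == 0:
            site.n_fragments += 1
        c = site.position
        name = f"jx{idx:06d}"
        if site.strand == "+":
            gpart = genome[c : c + glen]
            mate = revcomp(genome[c + frag_len - read_len : c + frag_len])
            r1_pos, r1_cigar, r1_rev = c, f"{clip_len}S{glen}M", False
            r2_pos, r2_rev = c + frag_len - read_len, True
            tlen = frag_len
        else:
            gpart = revcomp(genome[c + 2 - glen : c + 2])
            mate = genome[c + 2 - frag_len : c + 2 - frag_len + read_len]
            r1_pos, r1_cigar, r1_rev = c + 2 - glen, f"{glen}M{clip_len}S", True
            r2_pos, r2_rev = c + 2 - frag_len, False
            tlen = -frag_len
        seq1 = clip_template + gpart
        q1 = _qual_string(read_len, rng)
        q2 = _qual_string(read_len, rng)
        seq1 = _apply_errors(seq1, q1, error_rate, rng)
        seq2 = _apply_errors(mate, q2, error_rate, rng)
        reads.append(SimulatedRead(name, seq1, _phred(q1), seq2, _phred(q2)))

        # SAM stores sequences in reference orientation.
        s1 = revcomp(seq1) if r1_rev else seq1
        p1 = _phred(q1[::-1] if r1_rev else q1)
        s2 = revcomp(seq2) if r2_rev else seq2
        p2 = _phred(q2[::-1] if r2_rev else q2)
        flag1 = 0x1 | 0x2 | 0x40 | (0x10 if r1_rev else 0) | (0x20 if not r1_rev else 0)
        flag2 = 0x1 | 0x2 | 0x80 | (0x10 if r2_rev else 0) | (0x20 if not r2_rev else 0)
        line1 = (f"{name}\t{flag1}\t{chrom}\t{r1_pos + 1}\t60\t{r1_cigar}\t="
                 f"\t{r2_pos + 1}\t{tlen}\t{s1}\t{p1}")
        line2 = (f"{name}\t{flag2}\t{chrom}\t{r2_pos + 1}\t60\t{read_len}M\t="
                 f"\t{r1_pos + 1}\t{-tlen}\t{s2}\t{p2}")
        records.append((min(r1_pos, r2_pos), line1 + "\n" + line2 + "\n"))

    for _, block in sorted(records, key=lambda t: t[0]):
        sam.write(block)
    return JunctionSimulation(reads=reads, sam_text=sam.getvalue(),
                              sites=sites, donor=donor, genome=genome,
                              chrom=chrom)


# ---------------------------------------------------------------------------
# Barcode amplicon reads
# ---------------------------------------------------------------------------

def simulate_barcode_reads(depth: float = 20.0, k: int = 6,
                           barcode_offset: int = 20, read_len: int = 40,
                           seed: int = 0,
                           low_quality_fraction: float = 0.05) -> list[tuple[str, str, str]]:
    """Amplicon reads carrying a random k-mer barcode at a fixed offset.

    Samples ``round(depth * 4**k)`` reads with uniformly drawn barcodes; a
    fraction of reads is emitted with degraded quality so the Q30 filters are
    exercised.  Returns (name, sequence, phred33-quality) tuples.
    """
    rng = np.random.default_rng(seed)
    n_reads = int(round(depth * 4 ** k))
    flank5 = "".join(rng.choice(list(BASES), size=barcode_offset))
    flank3 = "".join(rng.choice(list(BASES), size=read_len - barcode_offset - k))
    out = []
    for i in range(n_reads):
        bc = "".join(rng.choice(list(BASES), size=k))
        seq = flank5 + bc + flank3
        quals = _qual_string(read_len, rng)
        if rng.random() < low_quality_fraction:
            # Degrade either the whole read or the barcode region.
            if rng.random() < 0.5:
                quals = [int(q) for q in rng.integers(10, 29, size=read_len)]
            else:
                pos = barcode_offset + int(rng.integers(0, k))
                quals[pos] = int(rng.integers(2, 29))
        out.append((f"bc{i:07d}", seq, _phred(quals)))
    return out


# ---------------------------------------------------------------------------
# FASTA/FASTQ writers (byte-stable under fixed seeds)
# ---------------------------------------------------------------------------

def write_fasta(path: str, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fastq_pair(prefix: str, reads: list[SimulatedRead]) -> tuple[str, str]:
    p1, p2 = f"{prefix}_R1.fastq", f"{prefix}_R2.fastq"
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for r in reads:
            f1.write(f"@{r.name}/1\n{r.seq1}\n+\n{r.qual1}\n")
            f2.write(f"@{r.name}/2\n{r.seq2}\n+\n{r.qual2}\n")
    return p1, p2
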