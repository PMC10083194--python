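"""Call genomic integration sites from donor-genome junction sequencing.

One-sided junction sequencing primes inside the integrated donor and reads
across the crossover into the genome.  After alignment to a composite
donor+genome reference (donor contig named ``donor``), the genomic portion
of each junction read is aligned and the donor portion soft-clipped; the
soft clip carries the primer, the donor attachment site (attD) up to the
crossover, and nothing else.  The pipeline filters reads, builds a
per-anchor consensus of the clipped ends, gates each candidate against the
attD sequence (shared 9-mer, 80% alignment identity, crossover within 15 bp
of the predicted dinucleotide core), merges nearby calls into loci, and
quantifies each locus as a share of unique reads (or UMIs).
"""

from __future__ import annotations

import io
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np
import pysam
from scipy.stats import fisher_exact

from ._seq import make_local_aligner, revcomp
from .motif import NucleotideMotif, align_on_core, build_motif

MIN_MAPQ = 30
MAX_INSERT = 1500
KMER = 9
MIN_IDENTITY = 0.80
MAX_CORE_DISTANCE = 15
MERGE_DISTANCE = 500

# Local alignment of the clip consensus to the attD subsequence.
_CLIP_ALIGNER = make_local_aligner(match=2.0, mismatch=2.0,
                                   gap_open=4.0, gap_extend=1.0)


@dataclass
class SiteConfig:
    """Donor-side geometry needed to interpret junction reads."""

    donor_seq: str
    primer: str
    attd_interval: tuple[int, int]    # half-open donor coordinates of the attD
    core_offset: int                  # core start within the attD

    @property
    def primer_start(self) -> int:
        pos = self.donor_seq.find(self.primer)
        if pos < 0:
            raise ValueError("primer not found in donor sequence")
        return pos

    @property
    def attd_subsequence(self) -> str:
        """Donor sequence from the primer to 25 bp after the attD end."""
        lo, hi = self.attd_interval
        return self.donor_seq[self.primer_start : min(len(self.donor_seq), hi + 25)]

    @property
    def core_in_subsequence(self) -> int:
        """Core start in attd_subsequence coordinates."""
        return self.attd_interval[0] + self.core_offset - self.primer_start


@dataclass
class JunctionReadRecord:
    read_id: str
    chrom: str
    anchor: int                  # junction-proximal genomic position (core-adjacent)
    strand: str                  # '+' or '-'
    clip_seq: str                # donor-side soft clip, read orientation (primer first)
    mapq: int
    insert_size: int
    maps_to_donor: bool
    maps_to_genome: bool
    begins_at_primer: bool
    attd_intact: str             # "intact" / "disrupted" / "undeterminable"
    duplicate: bool = False
    umi: Optional[str] = None


@dataclass
class IntegrationSite:
    chrom: str
    position: int                # 0-based core start
    orientation: str
    support: int                 # unique reads
    umi_support: Optional[int] = None


@dataclass
class IntegrationLocus:
    chrom: str
    start: int
    end: int                     # half-open
    sites: list[IntegrationSite]
    unique_reads: int
    umis: Optional[int]
    percent_of_total: float


def _edlib_contains(needle: str, haystack: str, max_fraction: float = 0.1) -> bool:
    if len(haystack) < len(needle):
        return False
    res = edlib.align(needle, haystack, mode="HW", task="distance")
    return res["editDistance"] <= max_fraction * len(needle)


def _classify_attd(read_seq: str, clip_seq: str, config: SiteConfig) -> str:
    """Is the full pre-integration attD present in this read?"""
    attd = config.donor_seq[slice(*config.attd_interval)]
    if _edlib_contains(attd, read_seq):
        return "intact"
    # The read begins at the primer; it could have contained the attD only
    # if it is long enough to reach past the attD end.
    span_needed = config.attd_interval[1] - config.primer_start
    if len(read_seq) < span_needed:
        return "undeterminable"
    return "disrupted"


def filter_reads(alignments: str | Iterable[pysam.AlignedSegment],
                 config: SiteConfig,
                 min_mapq: int = MIN_MAPQ,
                 max_insert: int = MAX_INSERT,
                 umi_tag: str = "RX") -> list[JunctionReadRecord]:
    """Select junction reads that inform integration-site calling.

    Keeps primary genomic alignments of first-in-pair reads that carry a
    donor-derived soft clip beginning at the primer, do not contain an
    intact attD, have mapping quality >= 30 and insert size <= 1,500 bp.
    PCR duplicates are collapsed positionally on (chrom, anchor, strand,
    mate position), or per UMI when the donor carries one.  Idempotent.
    """
    tmp_path = None
    if isinstance(alignments, str):
        if alignments.lstrip().startswith("@"):
            # Raw SAM text; htslib needs a real file handle.
            import tempfile
            tmp = tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False)
            tmp.write(alignments)
            tmp.close()
            tmp_path = tmp.name
            path = tmp_path
        else:
            path = alignments
        segments: Iterable[pysam.AlignedSegment] = pysam.AlignmentFile(path, "r")
    else:
        segments = alignments
    records: list[JunctionReadRecord] = []
    for seg in segments:
        if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
            continue
        if not seg.is_read1:
            continue
        chrom = seg.reference_name
        if chrom == "donor":
            # Donor-only read: never spans a junction.
            continue
        if seg.mapping_quality < min_mapq:
            continue
        insert = abs(seg.template_length)
        if insert > max_insert:
            continue
        cigar = seg.cigartuples or []
        seq = seg.query_sequence or ""
        if seg.is_reverse:
            # Reference-orientation record; read orientation = revcomp.
            read_seq = revcomp(seq)
            clip_len = cigar[-1][1] if cigar and cigar[-1][0] == 4 else 0
            clip = revcomp(seq[len(seq) - clip_len :]) if clip_len else ""
            anchor = seg.reference_end
            strand = "-"
        else:
            read_seq = seq
            clip_len = cigar[0][1] if cigar and cigar[0][0] == 4 else 0
            clip = seq[:clip_len]
            anchor = seg.reference_start
            strand = "+"
        if not clip:
            continue
        begins_at_primer = _edlib_contains(
            config.primer, clip[: len(config.primer) + 3], max_fraction=0.15)
        maps_to_donor = _edlib_contains(clip, config.donor_seq, max_fraction=0.15)
        attd_state = _classify_attd(read_seq, clip, config)
        if not (maps_to_donor and begins_at_primer):
            continue
        if attd_state == "intact":
            continue
        umi = seg.get_tag(umi_tag) if seg.has_tag(umi_tag) else None
        records.append(JunctionReadRecord(
            read_id=seg.query_name, chrom=chrom, anchor=anchor, strand=strand,
            clip_seq=clip, mapq=seg.mapping_quality, insert_size=insert,
            maps_to_donor=True, maps_to_genome=True,
            begins_at_primer=True, attd_intact=attd_state, umi=umi,
        ))
    if tmp_path is not None:
        import os
        os.unlink(tmp_path)
    # Duplicate collapse: positional, or per UMI when present.
    seen: set = set()
    kept: list[JunctionReadRecord] = []
    for rec in records:
        key = ((rec.chrom, rec.anchor, rec.strand, rec.umi) if rec.umi
               else (rec.chrom, rec.anchor, rec.strand, rec.insert_size))
        if key in seen:
            rec.duplicate = True
            continue
        seen.add(key)
        kept.append(rec)
    return kept


def consensus_clips(records: Sequence[JunctionReadRecord],
                    config: SiteConfig,
                    min_support: int = 1) -> dict[tuple[str, int, str], str]:
    """Per-anchor consensus of the donor-side clipped ends.

    Clips are aligned at their junction-proximal end (they all begin at the
    primer); the consensus takes the per-position majority base, with ties
    written as N, and is trimmed to begin at the primer site.
    """
    groups: dict[tuple[str, int, str], list[str]] = defaultdict(list)
    for rec in records:
        groups[(rec.chrom, rec.anchor, rec.strand)].append(rec.clip_seq)
    out: dict[tuple[str, int, str], str] = {}
    for key, clips in groups.items():
        if len(clips) < min_support:
            continue
        width = max(len(c) for c in clips)
        cons = []
        for pos in range(width):
            counter = Counter(c[pos] for c in clips if pos < len(c))
            top = counter.most_common()
            if len(top) > 1 and top[0][1] == top[1][1]:
                cons.append("N")
            else:
                cons.append(top[0][0])
        consensus = "".join(cons)
        # Trim to begin at the primer site.
        idx = consensus.find(config.primer)
        if idx < 0:
            res = edlib.align(config.primer, consensus, mode="HW", task="locations")
            if res["editDistance"] <= 0.15 * len(config.primer) and res["locations"]:
                idx = res["locations"][0][0]
            else:
                idx = 0
        out[key] = consensus[idx:]
    return out


@dataclass
class SiteRejection:
    chrom: str
    anchor: int
    strand: str
    reason: str


def _alignment_identities(consensus: str, attd_sub: str) -> tuple[float, float, int]:
    """(full identity, contiguous identity, crossover position in attD_sub)."""
    aln = _CLIP_ALIGNER.align(consensus, attd_sub)[0]
    counts = aln.counts()
    cols = counts.identities + counts.mismatches + counts.gaps
    full = counts.identities / cols if cols else 0.0
    # Contiguous alignment: the longest gap-free, unambiguous block.
    best_len = best_ident = 0
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        block_q = consensus[qs:qe]
        block_t = attd_sub[ts:te]
        run_len = run_match = 0
        cur_len = cur_match = 0
        for a, b in zip(block_q, block_t):
            if a == "N" or b == "N":
                if cur_len > run_len:
                    run_len, run_match = cur_len, cur_match
                cur_len = cur_match = 0
                continue
            cur_len += 1
            cur_match += a == b
        if cur_len > run_len:
            run_len, run_match = cur_len, cur_match
        if run_len > best_len:
            best_len, best_ident = run_len, run_match
    contiguous = best_ident / best_len if best_len else 0.0
    crossover = int(aln.aligned[1][-1][1])   # attD_sub coordinate where it ends
    return full, contiguous, crossover


def call_sites(consensus: Mapping[tuple[str, int, str], str],
               config: SiteConfig,
               support: Mapping[tuple[str, int, str], int] | None = None,
               min_identity: float = MIN_IDENTITY,
               max_core_distance: int = MAX_CORE_DISTANCE,
               ) -> tuple[list[IntegrationSite], list[SiteRejection]]:
    """Gate per-anchor consensus sequences into integration-site calls.

    A candidate must share a 9-mer with the attD subsequence (primer to
    25 bp after the attD end), align to it at >= 80% identity in either the
    full local alignment or the longest contiguous (gap-free, unambiguous)
    block, and place the crossover within 15 bp of the predicted
    dinucleotide core.  The genomic core position is the junction-proximal
    anchor ('+' anchor directly; '-' anchor minus the core length).
    """
    attd_sub = config.attd_subsequence
    kmers = {attd_sub[i : i + KMER] for i in range(len(attd_sub) - KMER + 1)}
    core_pos = config.core_in_subsequence
    sites: list[IntegrationSite] = []
    rejections: list[SiteRejection] = []
    for (chrom, anchor, strand), cons in consensus.items():
        if not cons:
            rejections.append(SiteRejection(chrom, anchor, strand, "empty consensus"))
            continue
        shared = any(cons[i : i + KMER] in kmers
                     for i in range(len(cons) - KMER + 1))
        if not shared:
            rejections.append(SiteRejection(chrom, anchor, strand, "no shared 9-mer"))
            continue
        full, contiguous, crossover = _alignment_identities(cons, attd_sub)
        if full < min_identity and contiguous < min_identity:
            rejections.append(SiteRejection(
                chrom, anchor, strand,
                f"identity below threshold (full={full:.2f}, "
                f"contiguous={contiguous:.2f})"))
            continue
        if abs(crossover - core_pos) > max_core_distance:
            rejections.append(SiteRejection(
                chrom, anchor, strand,
                f"crossover {abs(crossover - core_pos)} bp from core"))
            continue
        position = anchor if strand == "+" else anchor - 2
        n = support.get((chrom, anchor, strand), 1) if support else 1
        sites.append(IntegrationSite(chrom=chrom, position=position,
                                     orientation=strand, support=n))
    sites.sort(key=lambda s: (s.chrom, s.position))
    return sites, rejections


def merge_loci(sites: Sequence[IntegrationSite],
               merge_distance: int = MERGE_DISTANCE) -> list[IntegrationLocus]:
    """Single-linkage merge of integration sites into loci.

    Sites within ``merge_distance`` of each other on the same chromosome
    are merged regardless of orientation; each locus reports its unique
    read (and UMI, when available) support and its percentage of the total.
    """
    ordered = sorted(sites, key=lambda s: (s.chrom, s.position))
    loci: list[list[IntegrationSite]] = []
    for site in ordered:
        if (loci and loci[-1][0].chrom == site.chrom
                and site.position - loci[-1][-1].position <= merge_distance):
            loci[-1].append(site)
        else:
            loci.append([site])
    total_reads = sum(s.support for s in sites)
    total_umis = sum(s.umi_support or 0 for s in sites)
    use_umis = total_umis > 0
    out = []
    for members in loci:
        reads = sum(s.support for s in members)
        umis = sum(s.umi_support or 0 for s in members) if use_umis else None
        weight = umis if use_umis else reads
        denom = total_umis if use_umis else total_reads
        out.append(IntegrationLocus(
            chrom=members[0].chrom,
            start=members[0].position,
            end=members[-1].position + 2,
            sites=list(members),
            unique_reads=reads,
            umis=umis,
            percent_of_total=100.0 * weight / denom if denom else 0.0,
        ))
    return out


def locus_motif(loci: Sequence[IntegrationLocus], genome: Mapping[str, str],
                flank_bp: int = 20, top_n: int | None = None,
                pseudocount: float = 0.01) -> NucleotideMotif:
    """Target-site motif from the genomic sequence around called cores.

    Per locus the best-supported site is chosen; its core-centered window
    (core plus ``flank_bp`` on each side) is extracted on the strand of the
    integration.  Optionally restricted to the ``top_n`` best-supported
    loci.  Windows exceeding chromosome bounds are skipped with a warning.
    """
    ranked = sorted(loci, key=lambda l: -l.unique_reads)
    if top_n is not None:
        ranked = ranked[:top_n]
    windows = []
    for locus in ranked:
        site = max(locus.sites, key=lambda s: s.support)
        chrom_seq = genome[site.chrom]
        lo = site.position - flank_bp
        hi = site.position + 2 + flank_bp
        if lo < 0 or hi > len(chrom_seq):
            import warnings
            warnings.warn(f"window for site {site.chrom}:{site.position} "
                          "exceeds chromosome bounds; skipped")
            continue
        window = chrom_seq[lo:hi]
        if site.orientation == "-":
            window = revcomp(window)
        windows.append(window)
    if not windows:
        raise ValueError("no usable site windows")
    aligned = align_on_core(windows, [flank_bp] * len(windows))
    return build_motif(aligned, pseudocount=pseudocount)


def accessibility_enrichment(sites: Sequence[IntegrationSite],
                             peaks: Mapping[str, Sequence[tuple[int, int]]],
                             seed: int = 0,
                             background_per_site: int = 2,
                             background_span: int = 100_000,
                             ) -> tuple[float, float]:
    """Enrichment of integration sites in accessibility peaks.

    Background positions are drawn uniformly within ``background_span`` of
    each true site (``background_per_site`` per site, seeded).  Returns the
    odds ratio (inf sentinel when the background column is empty) and the
    two-sided Fisher exact p-value of the 2x2 in-peak table.  Sites on
    chromosomes absent from the peak set count as out-of-peak.
    """
    if not sites:
        raise ValueError("at least one integration site is required")
    rng = np.random.default_rng(seed)
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivals in peaks.items():
        arr = sorted(ivals)
        starts = np.array([a for a, _ in arr])
        ends = np.array([b for _, b in arr])
        merged[chrom] = (starts, ends)

    def in_peak(chrom: str, pos: int) -> bool:
        if chrom not in merged:
            return False
        starts, ends = merged[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < ends[i]

    site_hits = sum(in_peak(s.chrom, s.position) for s in sites)
    bg_hits = 0
    n_bg = 0
    for s in sites:
        offsets = rng.integers(-background_span, background_span + 1,
                               size=background_per_site)
        for off in offsets:
            bg_hits += in_peak(s.chrom, max(0, s.position + int(off)))
            n_bg += 1
    table = [[site_hits, len(sites) - site_hits],
             [bg_hits, n_bg - bg_hits]]
    _, p = fisher_exact(table, alternative="two-sided")
    if table[0][1] == 0 and table[1][0] == 0:
        odds = float("inf") if site_hits else 1.0
    elif table[1][0] == 0 or table[0][1] == 0:
        odds = float("inf") if site_hits and table[1][0] == 0 else (
            table[0][0] * table[1][1] / max(1, table[0][1] * table[1][0]))
    else:
        odds = (table[0][0] * table[1][1]) / (table[0][1] * table[1][0])
    return float(odds), float(p)


# ---------------------------------------------------------------------------
# End-to-end convenience pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    records: list[JunctionReadRecord]
    sites: list[IntegrationSite]
    loci: list[IntegrationLocus]
    rejections: list[SiteRejection]


def map_integration_sites(sam: str, config: SiteConfig,
                          min_support: int = 1) -> PipelineResult:
    """Filter -> consensus -> call -> merge, from SAM text to loci."""
    records = filter_reads(sam, config)
    support = Counter((r.chrom, r.anchor, r.strand) for r in records)
    consensus = consensus_clips(records, config, min_support=min_support)
    sites, rejections = call_sites(consensus, config, support=support)
    loci = merge_loci(sites)
    return PipelineResult(records=records, sites=sites, loci=loci,
                          rejections=rejections)
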