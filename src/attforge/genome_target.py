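"""Search attachment sites against a target genome and assign attA/attD/attH.

A recombinase whose native attB or attP closely matches a sequence in a
target genome (for example human) can integrate there directly.  Attachment
sites (20-200 bp) are searched with a seed-and-extend local alignment
(exact-match words, windowed affine-gap extension) and hits are assessed
with a Karlin-Altschul expectation value; hits with E below the threshold
(strictly) are reported on both strands.  The attachment site with the best
genomic hit is renamed attA (acceptor), its cognate site attD (donor), and
the genomic span of the hit attH (the predicted target site).

Precomputed hits in BLAST tabular (outfmt 6) columns can be ingested
instead, so an external search engine may be substituted bit-compatibly.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, log
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy.optimize import brentq

from ._seq import make_local_aligner, revcomp

WORD_SIZE = 11
MATCH, MISMATCH = 2.0, 3.0
GAP_OPEN, GAP_EXTEND = 5.0, 2.0
KA_K = 0.3   # Karlin-Altschul K; order-of-magnitude constant for this scheme


def _lambda_for_scheme(match: float = MATCH, mismatch: float = MISMATCH) -> float:
    """Ungapped Karlin-Altschul lambda for uniform base composition."""
    def expectation(lam: float) -> float:
        return 0.25 * exp(lam * match) + 0.75 * exp(-lam * mismatch) - 1.0
    return brentq(expectation, 1e-6, 5.0)


_LAMBDA = _lambda_for_scheme()


@dataclass
class GenomeHit:
    att_id: str
    site_kind: str               # "attB" or "attP"
    chrom: str
    start: int                   # 0-based half-open on the target
    end: int
    strand: str                  # '+' or '-'
    alignment_length: int
    identity: float              # fraction of identical columns
    bit_score: float
    e_value: float


def _evalue(score: float, query_len: int, db_len: int) -> tuple[float, float]:
    bits = (_LAMBDA * score - log(KA_K)) / log(2.0)
    e = KA_K * query_len * db_len * exp(-_LAMBDA * score)
    return bits, e


def _extend_seeds(query: str, target: str, chrom: str, strand: str,
                  att_id: str, site_kind: str, db_len: int,
                  index: Mapping[str, list[int]],
                  e_threshold: float) -> list[GenomeHit]:
    qlen = len(query)
    diagonals: set[int] = set()
    for off in range(qlen - WORD_SIZE + 1):
        for pos in index.get(query[off : off + WORD_SIZE], ()):
            diagonals.add(pos - off)
    # Collapse nearby diagonals into bands so each region is extended once.
    bands: list[int] = []
    for diag in sorted(diagonals):
        if not bands or diag - bands[-1] > qlen:
            bands.append(diag)
    aligner = make_local_aligner(MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND)
    hits: list[GenomeHit] = []
    for diag in bands:
        lo = max(0, diag - qlen)
        hi = min(len(target), diag + 2 * qlen)
        window = target[lo:hi]
        if len(window) < WORD_SIZE:
            continue
        aln = aligner.align(query, window)[0]
        score = aln.score
        bits, e = _evalue(score, qlen, db_len)
        if e >= e_threshold:
            continue
        tstart = int(aln.aligned[1][0][0]) + lo
        tend = int(aln.aligned[1][-1][1]) + lo
        counts = aln.counts()
        length = counts.identities + counts.mismatches + counts.gaps
        if strand == "-":
            tstart, tend = len(target) - tend, len(target) - tstart
        hits.append(GenomeHit(
            att_id=att_id, site_kind=site_kind, chrom=chrom,
            start=tstart, end=tend, strand=strand,
            alignment_length=int(length),
            identity=counts.identities / length if length else 0.0,
            bit_score=bits, e_value=e,
        ))
    return hits


def search_sites(att_sites: Mapping[str, tuple[str, str]] | Iterable[tuple[str, str, str]],
                 target_genome: Mapping[str, str],
                 e_threshold: float = 1e-3) -> list[GenomeHit]:
    """Local-alignment search of attachment sites against a genome.

    ``att_sites`` maps an attachment-site id to (site_kind, sequence) with
    site_kind "attB" or "attP" (or an iterable of (id, kind, seq) triples);
    ``target_genome`` maps chromosome names to sequences.  Hits on both
    strands with E-value strictly below ``e_threshold`` are returned sorted
    ascending by E-value.
    """
    if isinstance(att_sites, Mapping):
        triples = [(sid, kind, seq) for sid, (kind, seq) in att_sites.items()]
    else:
        triples = list(att_sites)
    if not target_genome or all(len(s) == 0 for s in target_genome.values()):
        raise ValueError("target genome is empty")
    for _, _, seq in triples:
        if not 20 <= len(seq) <= 200:
            raise ValueError("attachment sites must be 20-200 bp")
    db_len = sum(len(s) for s in target_genome.values())
    hits: list[GenomeHit] = []
    for chrom, seq in target_genome.items():
        index = _index_of(seq)
        rc = revcomp(seq)
        rc_index = _index_of(rc)
        for att_id, kind, site in triples:
            hits.extend(_extend_seeds(site, seq, chrom, "+", att_id, kind,
                                      db_len, index, e_threshold))
            # Minus strand: search the site against the reverse complement
            # and report coordinates back on the forward strand.
            hits.extend(_extend_seeds(site, rc, chrom, "-", att_id, kind,
                                      db_len, rc_index, e_threshold))
    hits.sort(key=lambda h: (h.e_value, -h.bit_score, h.chrom, h.start))
    return hits


def _index_of(seq: str) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for pos in range(len(seq) - WORD_SIZE + 1):
        index.setdefault(seq[pos : pos + WORD_SIZE], []).append(pos)
    return index


@dataclass
class RoleAssignment:
    attA: str                    # acceptor sequence (best genomic match)
    attA_kind: str               # which site became the acceptor
    attD: str                    # donor (cognate) sequence
    attH: str                    # predicted genomic target sequence
    attH_chrom: str
    attH_interval: tuple[int, int]
    attH_strand: str
    best_hit: GenomeHit


def assign_roles(attB: str, attP: str, hits: list[GenomeHit],
                 target_genome: Mapping[str, str]) -> Optional[RoleAssignment]:
    """Assign acceptor/donor/target roles from the best genomic hit.

    The attachment site producing the lowest-E-value hit becomes attA; the
    cognate site becomes attD; the hit's genomic span is attH.  Ties on
    E-value are broken by higher bit score, then attB is preferred.
    Returns None when there are no hits (not genome-targeting).
    """
    if not hits:
        return None
    ranked = sorted(hits, key=lambda h: (h.e_value, -h.bit_score,
                                         0 if h.site_kind == "attB" else 1))
    best = ranked[0]
    att_a, att_d = (attB, attP) if best.site_kind == "attB" else (attP, attB)
    chrom_seq = target_genome[best.chrom]
    att_h = chrom_seq[best.start : best.end]
    if best.strand == "-":
        att_h = revcomp(att_h)
    return RoleAssignment(attA=att_a, attA_kind=best.site_kind, attD=att_d,
                          attH=att_h, attH_chrom=best.chrom,
                          attH_interval=(best.start, best.end),
                          attH_strand=best.strand, best_hit=best)


def parse_blast_tabular(lines: Iterable[str],
                        site_kinds: Mapping[str, str]) -> list[GenomeHit]:
    """Ingest hits in BLAST outfmt 6 columns.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  ``site_kinds`` maps query ids to
    "attB"/"attP".  Subject coordinates are converted to 0-based half-open
    with strand inferred from their order.
    """
    hits = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        sstart, send = int(f[8]), int(f[9])
        strand = "+" if send >= sstart else "-"
        lo, hi = (sstart - 1, send) if strand == "+" else (send - 1, sstart)
        hits.append(GenomeHit(
            att_id=f[0], site_kind=site_kinds.get(f[0], "attB"), chrom=f[1],
            start=lo, end=hi, strand=strand, alignment_length=int(f[3]),
            identity=float(f[2]) / 100.0, bit_score=float(f[11]),
            e_value=float(f[10]),
        ))
    hits.sort(key=lambda h: (h.e_value, -h.bit_score, h.chrom, h.start))
    return hits
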