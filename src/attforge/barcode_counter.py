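"""Amplicon barcode counting with quality gating and pooled-reporter ratios.

Donor amplicons carry a randomized k-mer barcode (k = 6 gives the 4,096
possible 6xN barcodes); reads are kept when the mean quality over the whole
read and the minimum quality over the barcode region are both at least
Q30, and literal matches in the barcode region to the complete 4^k universe
are tallied.  A barcode with 0 or 1 counts is a dropout.  Pooled-reporter
experiments are summarized as a depth-normalized log2(ON:OFF) ratio per
element.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping

import numpy as np

from ._seq import BASES


def barcode_universe(k: int) -> list[str]:
    """All 4^k DNA barcodes in lexicographic order."""
    return ["".join(p) for p in product(BASES, repeat=k)]


@dataclass
class BarcodeTally:
    k: int
    counts: dict[str, int]                 # complete universe, 4^k entries
    kept: int = 0
    discarded: dict[str, int] = field(default_factory=dict)

    @property
    def dropouts(self) -> set[str]:
        """Barcodes with only 0 or 1 counts."""
        return {bc for bc, n in self.counts.items() if n <= 1}

    @property
    def dropout_fraction(self) -> float:
        return len(self.dropouts) / len(self.counts)


def count_barcodes(reads: Iterable[tuple[str, str, str]],
                   barcode_offset: int, k: int = 6,
                   q_mean_min: float = 30.0, q_barcode_min: int = 30,
                   phred_offset: int = 33) -> BarcodeTally:
    """Tally exact barcode matches from quality-gated reads.

    ``reads`` yields (name, sequence, quality-string) tuples.  A read is
    discarded when it is too short to contain the barcode region, its mean
    quality over all positions is below ``q_mean_min``, its minimum quality
    over the k-bp barcode region is below ``q_barcode_min``, or the barcode
    region is not one of the 4^k literal barcodes (no mismatch rescue).
    """
    counts = {bc: 0 for bc in barcode_universe(k)}
    discarded = {"too_short": 0, "mean_quality": 0, "barcode_quality": 0,
                 "not_a_barcode": 0}
    kept = 0
    for _, seq, qual in reads:
        if len(seq) < barcode_offset + k or len(qual) < barcode_offset + k:
            discarded["too_short"] += 1
            continue
        quals = np.frombuffer(qual.encode(), dtype=np.uint8).astype(int) - phred_offset
        if quals.mean() < q_mean_min:
            discarded["mean_quality"] += 1
            continue
        bc_quals = quals[barcode_offset : barcode_offset + k]
        if bc_quals.min() < q_barcode_min:
            discarded["barcode_quality"] += 1
            continue
        bc = seq[barcode_offset : barcode_offset + k].upper()
        if bc not in counts:
            discarded["not_a_barcode"] += 1
            continue
        counts[bc] += 1
        kept += 1
    return BarcodeTally(k=k, counts=counts, kept=kept, discarded=discarded)


def read_fastq(path: str) -> Iterable[tuple[str, str, str]]:
    """Minimal FASTQ reader yielding (name, sequence, quality)."""
    with open(path) as fh:
        while True:
            header = fh.readline().strip()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            yield header[1:], seq, qual


def reporter_log_ratio(bound_counts: Mapping[str, float],
                       unbound_counts: Mapping[str, float],
                       pseudocount: float = 1.0) -> dict[str, float]:
    """Depth-normalized log2(ON:OFF) per element.

    Counts in each sample are converted to counts-per-million before the
    ratio, so uniform depth changes leave the ratios unchanged.
    """
    if set(bound_counts) != set(unbound_counts):
        raise ValueError("bound and unbound samples must share one element universe")
    total_b = sum(bound_counts.values())
    total_u = sum(unbound_counts.values())
    if total_b <= 0 or total_u <= 0:
        raise ValueError("zero total depth in a sample")
    out = {}
    for elem in bound_counts:
        cpm_b = 1e6 * bound_counts[elem] / total_b
        cpm_u = 1e6 * unbound_counts[elem] / total_u
        out[elem] = float(np.log2((cpm_b + pseudocount) / (cpm_u + pseudocount)))
    return out
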