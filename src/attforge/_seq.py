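"""Small shared sequence utilities used across modules."""

from __future__ import annotations

from Bio.Align import PairwiseAligner

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def common_suffix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def make_global_aligner(match: float = 1.0, mismatch: float = 0.0,
                        gap_open: float = 10.0, gap_extend: float = 1.0) -> PairwiseAligner:
    """Global aligner with unit match score and affine gaps (open 10, extend 1).

    This is the identity scheme used for greedy sequence clustering and for
    the attB-vs-attB comparisons; all parameters are overridable.
    """
    aln = PairwiseAligner()
    aln.mode = "global"
    aln.match_score = match
    aln.mismatch_score = -abs(mismatch) if mismatch else 0.0
    aln.open_gap_score = -abs(gap_open)
    aln.extend_gap_score = -abs(gap_extend)
    return aln


def make_local_aligner(match: float, mismatch: float,
                       gap_open: float, gap_extend: float) -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.mode = "local"
    aln.match_score = match
    aln.mismatch_score = -abs(mismatch)
    aln.open_gap_score = -abs(gap_open)
    aln.extend_gap_score = -abs(gap_extend)
    return aln


def alignment_identity(aligner: PairwiseAligner, a: str, b: str) -> float:
    """Fraction of identical columns over the alignment length.

    Returns 0.0 for a pair with an empty alignment.
    """
    if not a or not b:
        return 0.0
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    length = alignment.length
    if length == 0:
        return 0.0
    return counts.identities / length


def percent_identity(a: str, b: str) -> float:
    """Global identity (unit-match affine-gap scheme) as a fraction in [0, 1]."""
    return alignment_identity(make_global_aligner(), a, b)
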