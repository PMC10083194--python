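"""Reconstruct attachment sites from an insertion call.

The bacterial attachment site attB and the element attachment site attP are
rebuilt from the decomposed insertion locus as

    attB = B1 + D + B2        attP = P2 + D + P1

(concatenation), then trimmed to a fixed window (default 50 bp) centered on
the attachment-site center -- the stretch of sequence homologous between attB
and attP, which contains the dinucleotide crossover core.  The flanks used for
attB are those of the post-integration chromosome, which most closely
represent the original attB immediately before integration; on the assembled
pairs handled here these equal the pre-integration flanks outside the
duplication.
"""

from __future__ import annotations

from dataclasses import dataclass

from .boundary_finder import InsertionCall

DEFAULT_WINDOW = 50


@dataclass
class AttachmentSitePair:
    attB: str
    attP: str
    center: str
    core: str                 # 2-mer at the center midpoint
    core_offset_attB: int     # offset of the core within attB
    core_offset_attP: int
    orientation: str = "forward"
    truncated: bool = False   # True when a flank was too short for the window


@dataclass
class RecombinedSites:
    attL: str
    attR: str


def _window_around(seq: str, mid: int, window: int) -> tuple[str, bool]:
    """Window of ``window`` bases of ``seq`` centered on position ``mid``."""
    start = mid - window // 2
    end = start + window
    truncated = start < 0 or end > len(seq)
    return seq[max(0, start) : min(len(seq), end)], truncated


def reconstruct_sites(call: InsertionCall, window: int = DEFAULT_WINDOW) -> AttachmentSitePair:
    """Reconstruct the attB/attP pair for one insertion call.

    Windows are centered on the midpoint of the target-site duplication
    (the attachment-site center always contains the duplication; with an
    empty duplication the junction point itself is used).  A pair whose
    flanks are too short for the full window is returned truncated and
    flagged rather than rejected.
    """
    dlen = call.duplication_len
    # attB on the reference/post-integration flank coordinates:
    ref_locus = call.b1_flank + call.duplication + call.b2_flank
    attb_mid = len(call.b1_flank) + dlen // 2
    attB, trunc_b = _window_around(ref_locus, attb_mid, window)
    # attP wraps the element termini around the duplication: P2 + D + P1.
    wrap = call.element + call.duplication + call.element
    attp_mid = len(call.element) + dlen // 2
    attP, trunc_p = _window_around(wrap, attp_mid, window)
    # The homologous center necessarily contains the duplication, whose
    # window position is known here; extend the exact match outward from it
    # rather than searching for a window-wide common substring (which a
    # chance off-center repeat could win for short duplications).
    d_start = window // 2 - dlen // 2
    lo, hi = d_start, d_start + dlen
    while lo > 0 and lo - 1 < len(attB) and lo - 1 < len(attP) \
            and attB[lo - 1] == attP[lo - 1]:
        lo -= 1
    while hi < min(len(attB), len(attP)) and attB[hi] == attP[hi]:
        hi += 1
    center = attB[lo:hi]
    core_off = d_start + (max(dlen, 2) - 2 + 1) // 2 - (0 if dlen >= 2 else 1)
    core = attB[core_off : core_off + 2]
    return AttachmentSitePair(
        attB=attB,
        attP=attP,
        center=center,
        core=core,
        core_offset_attB=core_off,
        core_offset_attP=core_off,
        truncated=trunc_b or trunc_p,
    )


def _longest_common_substrings(a: str, b: str) -> list[tuple[int, int, int]]:
    """All maximal-length common substrings as (length, offset_a, offset_b)."""
    best = 0
    hits: list[tuple[int, int, int]] = []
    # Dynamic programming over suffix match lengths; sequences here are
    # attachment-site windows (~50 bp), so quadratic time is immaterial.
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
                    hits = [(best, i - best, j - best)]
                elif cur[j] == best:
                    hits.append((best, i - best, j - best))
        prev = cur
    return hits if best >= 2 else []


def find_center(attB: str, attP: str) -> tuple[str, str, int, int]:
    """Locate the attachment-site center shared by attB and attP.

    The center is the longest common substring of the two sites; ties are
    broken by the proximity of the substring midpoint to the sequence
    midpoints, then leftmost.  Returns (center, core, offset_in_attB,
    offset_in_attP) where the core is the central 2-mer of the center.

    Raises ValueError when the two sites share no 2-mer (incompatible pair).
    """
    if len(attB) < 2 or len(attP) < 2:
        raise ValueError("attachment sites must be at least 2 bp")
    hits = _longest_common_substrings(attB, attP)
    if not hits:
        raise ValueError("attB and attP share no common substring of length >= 2")

    def tie_key(hit: tuple[int, int, int]) -> tuple[float, int, int]:
        length, ia, ip = hit
        mid_a = ia + length / 2
        mid_p = ip + length / 2
        dist = abs(mid_a - len(attB) / 2) + abs(mid_p - len(attP) / 2)
        return (dist, ia, ip)

    length, off_b, off_p = min(hits, key=tie_key)
    center = attB[off_b : off_b + length]
    core_off = (length - 2 + 1) // 2
    core = center[core_off : core_off + 2]
    return center, core, off_b, off_p


def derive_attL_attR(pair: AttachmentSitePair) -> RecombinedSites:
    """Post-integration junction sites formed by crossover at the core.

    attL carries the attB left arm joined to the attP right arm through the
    core, and attR the converse; applying the same crossover to (attL, attR)
    regenerates the original pair.
    """
    cb = pair.core_offset_attB
    cp = pair.core_offset_attP
    if pair.attB[cb : cb + 2] != pair.core or pair.attP[cp : cp + 2] != pair.core:
        raise ValueError("core offsets do not point at the core dinucleotide")
    attL = pair.attB[:cb] + pair.core + pair.attP[cp + 2 :]
    attR = pair.attP[:cp] + pair.core + pair.attB[cb + 2 :]
    return RecombinedSites(attL=attL, attR=attR)
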