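"""Locate mobile-element insertions by direct comparison of genome pairs.

Given an assembled reference genome (without an integrant) and a query genome
(carrying one or more integrants), each insertion locus is decomposed as

    query     = B1 + D + P1 + (interior of E) + P2 + D + B2
    reference = B1 + D + B2

where ``D`` is the target-site duplication created upon insertion (possibly
empty) and ``E`` the integrated element, whose terminal segments ``P1``/``P2``
are retained for reporting.  When microhomology between the element termini
and the flanks makes the breakpoint ambiguous, the reported site position is
canonicalized to the leftmost valid placement.

Detection anchors on exact-match seed k-mers on both flanks and extends
outward; this replaces read-based boundary inference, which is unnecessary
when assembled pre/post-integration pairs are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

TERMINAL_LEN = 100  # length of the P1/P2 terminal segments kept on each call


@dataclass
class InsertionCall:
    """One insertion of a query genome relative to a reference genome."""

    reference_id: str
    query_id: str
    site_position: int          # 0-based offset on the reference
    b1_flank: str
    duplication: str
    p1_terminal: str
    element: str
    p2_terminal: str
    b2_flank: str
    element_interval: tuple[int, int] = field(default=(0, 0))  # on query, half-open

    def __post_init__(self) -> None:
        lo, hi = self.element_interval
        if hi - lo != len(self.element):
            raise ValueError("element_interval length must equal element length")

    @property
    def duplication_len(self) -> int:
        return len(self.duplication)

    def splice_out(self, query: str) -> str:
        """Remove this insertion from the query, restoring the reference locus."""
        lo, hi = self.element_interval
        # One duplication copy precedes the element on the query.
        return query[: lo - len(self.duplication)] + query[hi:]


def _decompose(reference: str, query: str, ref_id: str, query_id: str,
               i: int, j: int, jq: int) -> tuple[InsertionCall, int]:
    """Build an InsertionCall for the insertion detected at scan state (i, j).

    ``i``/``j`` are the first divergent positions on reference/query and
    ``jq`` the query offset where the reference re-anchors.  Returns the call
    and the query position at which scanning resumes.
    """
    ins_len = jq - j
    # Leftmost canonicalization: slide the breakpoint left through any
    # microhomology between the upstream flank and the tail of the insert.
    m = 0
    limit = min(i, ins_len)
    while m < limit and reference[i - 1 - m] == query[jq - 1 - m]:
        m += 1
    site = i - m
    dlen = m
    dup = reference[site : site + dlen]
    q_site = j - m                        # query offset of the first D copy
    element = query[q_site + dlen : q_site + ins_len]
    elem_lo = q_site + dlen
    t = min(TERMINAL_LEN, len(element))
    call = InsertionCall(
        reference_id=ref_id,
        query_id=query_id,
        site_position=site,
        b1_flank=reference[:site],
        duplication=dup,
        p1_terminal=element[:t],
        element=element,
        p2_terminal=element[-t:] if t else "",
        b2_flank=reference[site + dlen :],
        element_interval=(elem_lo, elem_lo + len(element)),
    )
    return call, jq


def find_insertion(reference: str, query: str, min_flank: int = 21,
                   max_element_len: int = 200_000,
                   reference_id: str = "reference",
                   query_id: str = "query") -> list[InsertionCall]:
    """Find insertions present in ``query`` but absent from ``reference``.

    ``min_flank`` is the exact-match seed anchor length used to re-anchor the
    scan downstream of an insertion; flanks shorter than this cannot be
    re-anchored.  Elements longer than ``max_element_len`` are still reported
    (length policy is applied downstream by quality control).  Returns calls
    sorted by ``site_position``; an identical pair yields an empty list.
    """
    if not reference or not query:
        raise ValueError("both sequences must be non-empty")
    if min_flank < 8:
        raise ValueError("min_flank must be at least the seed anchor length (8)")
    k = min_flank
    calls: list[InsertionCall] = []
    i = j = 0
    n_ref, n_query = len(reference), len(query)
    while i < n_ref:
        if j < n_query and reference[i] == query[j]:
            i += 1
            j += 1
            continue
        if j >= n_query:
            raise ValueError(
                "query is missing reference sequence (deletion), which this "
                "comparison does not model"
            )
        anchor = reference[i : i + k]
        if len(anchor) < k:
            # Too close to the reference end to re-anchor: treat the entire
            # remaining divergence as unanchorable unless the reference tail
            # matches the query tail exactly.
            if reference[i:] == query[n_query - (n_ref - i):]:
                jq = n_query - (n_ref - i)
            else:
                raise ValueError("could not re-anchor near the reference end")
        else:
            jq = query.find(anchor, j + 1)
            if jq == -1:
                raise ValueError(
                    f"no downstream anchor for reference position {i}; the "
                    "pair differs by more than insertions"
                )
        call, j = _decompose(reference, query, reference_id, query_id, i, j, jq)
        calls.append(call)
    if j < n_query:
        # Trailing insertion at the reference end.
        call, j = _decompose(reference, query, reference_id, query_id,
                             n_ref, j, n_query)
        calls.append(call)
    for a, b in zip(calls, calls[1:]):
        if a.site_position + a.duplication_len > b.site_position:
            raise ValueError(
                f"overlapping insertion calls at reference positions "
                f"{a.site_position} and {b.site_position}"
            )
    return calls


# ---------------------------------------------------------------------------
# Average nucleotide identity
# ---------------------------------------------------------------------------

_ANI_SEED_K = 15


def _seed_index(genome: str, k: int) -> dict[str, int]:
    """First-occurrence index of every k-mer in the genome."""
    index: dict[str, int] = {}
    for pos in range(len(genome) - k + 1):
        kmer = genome[pos : pos + k]
        if kmer not in index:
            index[kmer] = pos
    return index


def _best_fragment_identity(fragment: str, genome: str,
                            index: dict[str, int], k: int) -> float | None:
    """Identity of the best seeded match of the fragment in the genome."""
    candidates: set[int] = set()
    for off in range(0, len(fragment) - k + 1, 7):
        pos = index.get(fragment[off : off + k])
        if pos is not None:
            candidates.add(pos - off)
            if len(candidates) >= 4:
                break
    best: float | None = None
    for diag in candidates:
        lo = max(0, diag - 30)
        hi = min(len(genome), diag + len(fragment) + 30)
        res = edlib.align(fragment, genome[lo:hi], mode="HW", task="distance")
        ident = 1.0 - res["editDistance"] / len(fragment)
        if best is None or ident > best:
            best = ident
    return best


def measure_ani(genome_a: str, genome_b: str, fragment_len: int = 500) -> float:
    """Fragment-level average nucleotide identity between two genomes.

    Each genome is chopped into non-overlapping fragments that are matched to
    the other genome by exact seed k-mers and scored with an edit-distance
    alignment; the mean best-match identity over both directions is returned
    as a percentage.  Fragments with no seed match are excluded; NaN is
    returned when nothing matches (unrelated genomes).
    """
    if len(genome_a) < fragment_len or len(genome_b) < fragment_len:
        raise ValueError("both genomes must be at least fragment_len long")

    def one_direction(src: str, dst: str) -> list[float]:
        index = _seed_index(dst, _ANI_SEED_K)
        idents = []
        for start in range(0, len(src) - fragment_len + 1, fragment_len):
            frag = src[start : start + fragment_len]
            ident = _best_fragment_identity(frag, dst, index, _ANI_SEED_K)
            if ident is not None:
                idents.append(ident)
        return idents

    idents = one_direction(genome_a, genome_b) + one_direction(genome_b, genome_a)
    if not idents:
        return float("nan")
    return 100.0 * float(np.mean(idents))
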