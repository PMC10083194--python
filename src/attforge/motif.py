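"""Target-site motifs: core dinucleotides, core-anchored alignments,
position-frequency matrices, database-derived post-hoc motifs, log-odds
scanning and ROC evaluation.

The attachment sites recombined by one enzyme share a short crossover core;
candidate core dinucleotides in a multiple alignment of attB sites are
ranked by a score that weights nucleotide conservation and proximity to the
attB center equally.  Sites are then re-aligned purely by stacking on the
predicted core (no alignment algorithm), giving a position-frequency motif.
For a query recombinase without enough native sites, a post-hoc motif is
accumulated from the attB sites of its nearest relatives in a database.
Motifs are scanned over sequences as summed log-odds versus a background,
and prediction quality is summarized as the area under the ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import BASES, make_global_aligner, revcomp

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
GAP = "-"


# ---------------------------------------------------------------------------
# Core scoring and core-anchored alignment
# ---------------------------------------------------------------------------

@dataclass
class CoreAnchoredAlignment:
    rows: list[str]                  # equal width, gap-padded
    core_col: int                    # column index of the first core base
    ids: list[str] = field(default_factory=list)

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def score_core_dinucleotides(rows: Sequence[str]) -> list[tuple[tuple[int, int], float]]:
    """Rank adjacent column pairs of an alignment as candidate crossover cores.

    For each pair: conservation = mean modal-base frequency of the two
    columns (gaps excluded); distance = |pair midpoint - alignment midpoint|
    normalized by the half width; score = 0.5 * conservation +
    0.5 * (1 - distance).  Pairs containing an all-gap column are skipped.
    Ranked descending; ties favor the pair nearer the center, then leftmost.
    """
    if len(rows) < 2:
        raise ValueError("need at least two aligned sequences")
    width = len(rows[0])
    if width < 2 or any(len(r) != width for r in rows):
        raise ValueError("rows must be equal width >= 2")

    def modal_freq(col: int) -> float | None:
        counts = np.zeros(4)
        for row in rows:
            idx = _BASE_INDEX.get(row[col].upper())
            if idx is not None:
                counts[idx] += 1
        total = counts.sum()
        return None if total == 0 else counts.max() / total

    modal = [modal_freq(c) for c in range(width)]
    scored = []
    for col in range(width - 1):
        if modal[col] is None or modal[col + 1] is None:
            continue
        conservation = 0.5 * (modal[col] + modal[col + 1])
        distance = abs((col + 1) - width / 2) / (width / 2)
        score = 0.5 * conservation + 0.5 * (1.0 - distance)
        scored.append(((col, col + 1), score, distance))
    scored.sort(key=lambda t: (-t[1], t[2], t[0][0]))
    return [(pair, score) for pair, score, _ in scored]


def align_on_core(attBs: Sequence[str], core_offsets: Sequence[int],
                  ids: Sequence[str] | None = None) -> CoreAnchoredAlignment:
    """Stack sequences so their core dinucleotides share a column.

    No internal gaps are introduced; flanks are padded with the gap symbol.
    Width = max left extent + 2 + max right extent.
    """
    if len(attBs) != len(core_offsets):
        raise ValueError("one core offset per sequence is required")
    for seq, off in zip(attBs, core_offsets):
        if not 0 <= off <= len(seq) - 2:
            raise ValueError(f"core offset {off} out of bounds for length {len(seq)}")
    left = max(core_offsets)
    right = max(len(s) - off - 2 for s, off in zip(attBs, core_offsets))
    rows = [
        GAP * (left - off) + seq + GAP * (right - (len(seq) - off - 2))
        for seq, off in zip(attBs, core_offsets)
    ]
    return CoreAnchoredAlignment(rows=rows, core_col=left,
                                 ids=list(ids) if ids else [])


# ---------------------------------------------------------------------------
# Position-frequency motifs
# ---------------------------------------------------------------------------

@dataclass
class NucleotideMotif:
    frequencies: np.ndarray          # (width, 4) rows summing to 1
    core_col: int
    pseudocount: float
    background: np.ndarray           # (4,)
    uniform_columns: list[int] = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.frequencies.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.frequencies.argmax(axis=1))


def build_motif(alignment: CoreAnchoredAlignment | Sequence[str],
                pseudocount: float = 0.01,
                background: Sequence[float] | None = None,
                gaps: str = "exclude") -> NucleotideMotif:
    """Column base frequencies of an alignment, pseudocount-smoothed.

    ``gaps="exclude"`` computes frequencies over non-gap characters only;
    ``gaps="uniform"`` lets every gap contribute equally weighted
    frequencies (0.25 to each base).  A column with no informative
    characters falls back to uniform frequencies and is flagged.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if isinstance(alignment, CoreAnchoredAlignment):
        rows, core_col = alignment.rows, alignment.core_col
    else:
        rows, core_col = list(alignment), max(0, (len(alignment[0]) - 2) // 2)
    if not rows:
        raise ValueError("alignment must contain at least one row")
    width = len(rows[0])
    bg = (np.full(4, 0.25) if background is None
          else np.asarray(background, dtype=float))
    freqs = np.zeros((width, 4))
    uniform_cols = []
    for col in range(width):
        counts = np.zeros(4)
        n_gap = 0
        for row in rows:
            idx = _BASE_INDEX.get(row[col].upper())
            if idx is None:
                n_gap += 1
            else:
                counts[idx] += 1
        if gaps == "uniform":
            counts = counts + n_gap / 4.0
        if counts.sum() == 0:
            freqs[col] = 0.25
            uniform_cols.append(col)
        else:
            smoothed = counts + pseudocount
            freqs[col] = smoothed / smoothed.sum()
    return NucleotideMotif(frequencies=freqs, core_col=core_col,
                           pseudocount=pseudocount, background=bg,
                           uniform_columns=uniform_cols)


# ---------------------------------------------------------------------------
# Internal progressive multiple alignment
# ---------------------------------------------------------------------------
# Used by build_posthoc_motif so no external alignment binary is required;
# any function with the same (sequences -> aligned rows) contract can be
# substituted.  Scoring: match 1, mismatch -1, gap -2, UPGMA guide tree.

_MSA_MATCH, _MSA_MISMATCH, _MSA_GAP = 1.0, -1.0, -2.0


def _profile(rows: list[str]) -> np.ndarray:
    """(width, 5) frequency profile over A,C,G,T,gap."""
    width = len(rows[0])
    prof = np.zeros((width, 5))
    for row in rows:
        for col, ch in enumerate(row):
            prof[col, _BASE_INDEX.get(ch.upper(), 4)] += 1
    return prof / len(rows)


def _align_profiles(rows_a: list[str], rows_b: list[str]) -> list[str]:
    pa, pb = _profile(rows_a), _profile(rows_b)
    wa, wb = pa.shape[0], pb.shape[0]
    # Expected substitution score between columns (gap frequencies score 0).
    ident = pa[:, :4] @ pb[:, :4].T
    occ = np.outer(pa[:, :4].sum(1), pb[:, :4].sum(1))
    sub = _MSA_MATCH * ident + _MSA_MISMATCH * (occ - ident)
    score = np.zeros((wa + 1, wb + 1))
    move = np.zeros((wa + 1, wb + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    score[1:, 0] = np.arange(1, wa + 1) * _MSA_GAP
    score[0, 1:] = np.arange(1, wb + 1) * _MSA_GAP
    move[1:, 0] = 1
    move[0, 1:] = 2
    for i in range(1, wa + 1):
        diag = score[i - 1, :-1] + sub[i - 1]
        up = score[i - 1, 1:] + _MSA_GAP
        row = score[i]
        for j in range(1, wb + 1):
            left = row[j - 1] + _MSA_GAP
            best = diag[j - 1]
            mv = 0
            if up[j - 1] > best:
                best, mv = up[j - 1], 1
            if left > best:
                best, mv = left, 2
            row[j] = best
            move[i, j] = mv
    # Traceback
    out_a = [""] * len(rows_a)
    out_b = [""] * len(rows_b)
    i, j = wa, wb
    cols_a: list[int | None] = []
    cols_b: list[int | None] = []
    while i > 0 or j > 0:
        mv = move[i, j]
        if mv == 0:
            i, j = i - 1, j - 1
            cols_a.append(i)
            cols_b.append(j)
        elif mv == 1:
            i -= 1
            cols_a.append(i)
            cols_b.append(None)
        else:
            j -= 1
            cols_a.append(None)
            cols_b.append(j)
    cols_a.reverse()
    cols_b.reverse()
    for r, row in enumerate(rows_a):
        out_a[r] = "".join(GAP if c is None else row[c] for c in cols_a)
    for r, row in enumerate(rows_b):
        out_b[r] = "".join(GAP if c is None else row[c] for c in cols_b)
    return out_a + out_b


def _kmer_identity(a: str, b: str, k: int = 4) -> float:
    """Cheap k-mer containment identity used for guide-tree distances."""
    if len(a) < k or len(b) < k:
        return float(a == b)
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    denom = min(len(ka), len(kb))
    return len(ka & kb) / denom if denom else 0.0


def progressive_msa(seqs: Sequence[str]) -> list[str]:
    """Progressive multiple alignment along a UPGMA guide tree."""
    n = len(seqs)
    if n == 0:
        return []
    if n == 1:
        return [seqs[0]]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - _kmer_identity(seqs[i], seqs[j])
            dist[i, j] = dist[j, i] = d
    # UPGMA agglomeration; each active node carries its aligned rows.
    nodes: dict[int, list[str]] = {i: [seqs[i]] for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(nodes) > 1:
        (i, j), _ = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        merged = _align_profiles(nodes[i], nodes[j])
        for k in list(nodes):
            if k in (i, j):
                continue
            dik = d[tuple(sorted((i, k)))]
            djk = d[tuple(sorted((j, k)))]
            dnew = (dik * sizes[i] + djk * sizes[j]) / (sizes[i] + sizes[j])
            d[(k, next_id)] = dnew
        for key in [key for key in d if i in key or j in key]:
            del d[key]
        sizes[next_id] = sizes.pop(i) + sizes.pop(j)
        del nodes[i], nodes[j]
        nodes[next_id] = merged
        next_id += 1
    return nodes.popitem()[1]


# ---------------------------------------------------------------------------
# Post-hoc database-derived motifs
# ---------------------------------------------------------------------------

@dataclass
class LsrRecord:
    lsr_id: str
    protein: str
    attB: str


_PROT_ALIGNER = make_global_aligner()


def _identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    aln = _PROT_ALIGNER.align(a, b)[0]
    return aln.counts().identities / aln.length if aln.length else 0.0


def build_posthoc_motif(query_protein: str, query_attB: str,
                        database: Sequence[LsrRecord], n_sites: int = 20,
                        min_lsr_identity: float = 0.30,
                        max_attb_identity: float = 0.95,
                        window_nt: int = 60,
                        max_gap_fraction: float = 0.5,
                        pseudocount: float = 0.01) -> NucleotideMotif:
    """Build a target-site motif for a query enzyme from database relatives.

    Relatives at >= 30% amino-acid identity to the query are visited in
    order of decreasing identity (ties by id); each relative's attB is added
    only if it is 95% identical or less to every attB already selected,
    until ``n_sites`` sites are accumulated or the database is exhausted.
    Each attB is oriented by the strand with the higher global-alignment
    score to the query's own attB.  The selected sites are multiply aligned,
    the middle ``window_nt`` columns are extracted after dropping columns
    with over 50% gaps, and column frequencies are mapped back onto the
    query attB coordinates; gap characters contribute equally weighted
    frequencies, and unmapped query positions get uniform frequencies.
    """
    if not database:
        raise ValueError("database must be non-empty")
    if not query_attB:
        raise ValueError("query must have its own attB")
    ranked = sorted(
        ((rec, _identity(query_protein, rec.protein)) for rec in database),
        key=lambda t: (-t[1], t[0].lsr_id),
    )
    relatives = [(rec, ident) for rec, ident in ranked if ident >= min_lsr_identity]

    nt_aligner = make_global_aligner(match=1.0, mismatch=1.0,
                                     gap_open=2.0, gap_extend=2.0)

    def nt_identity(a: str, b: str) -> float:
        aln = nt_aligner.align(a, b)[0]
        return aln.counts().identities / aln.length if aln.length else 0.0

    def orient(seq: str) -> str:
        fwd = nt_aligner.align(seq, query_attB)[0].score
        rev = nt_aligner.align(revcomp(seq), query_attB)[0].score
        return seq if fwd >= rev else revcomp(seq)

    selected = [query_attB]
    warned = not relatives
    for rec, _ in relatives:
        if len(selected) >= n_sites:
            break
        cand = orient(rec.attB)
        if all(nt_identity(cand, prev) <= max_attb_identity for prev in selected):
            selected.append(cand)

    msa = progressive_msa(selected)
    query_row = msa[0]
    width = len(query_row)
    n_rows = len(msa)
    keep = [
        col for col in range(width)
        if sum(row[col] == GAP for row in msa) / n_rows <= max_gap_fraction
    ]
    if len(keep) > window_nt:
        start = (len(keep) - window_nt) // 2
        keep = keep[start : start + window_nt]

    freqs = np.full((len(query_attB), 4), 0.25)
    uniform_cols = list(range(len(query_attB)))
    # Map alignment columns to query attB coordinates through the query row.
    col_to_qpos: dict[int, int] = {}
    qpos = 0
    for col in range(width):
        if query_row[col] != GAP:
            col_to_qpos[col] = qpos
            qpos += 1
    for col in keep:
        if col not in col_to_qpos:
            continue
        counts = np.zeros(4)
        for row in msa:
            idx = _BASE_INDEX.get(row[col].upper())
            if idx is None:
                counts += 0.25
            else:
                counts[idx] += 1
        smoothed = counts + pseudocount
        pos = col_to_qpos[col]
        freqs[pos] = smoothed / smoothed.sum()
        uniform_cols.remove(pos)

    motif = NucleotideMotif(frequencies=freqs,
                            core_col=max(0, (len(query_attB) - 2) // 2),
                            pseudocount=pseudocount,
                            background=np.full(4, 0.25),
                            uniform_columns=uniform_cols)
    if warned:
        import warnings
        warnings.warn("no database relative at the identity threshold; "
                      "motif built from the query attB alone")
    return motif


# ---------------------------------------------------------------------------
# Scanning and ROC
# ---------------------------------------------------------------------------

def scan_motif(motif: NucleotideMotif, sequences: Iterable[str],
               background: Sequence[float] | None = None,
               both_strands: bool = True) -> np.ndarray:
    """Best log-odds motif score per sequence.

    Every window on both strands is scored as the sum over positions of
    log2(f_i(base) / bg(base)); non-ACGT characters contribute the
    background frequency (zero log-odds).  The per-sequence score is the
    maximum over windows and strands.
    """
    bg = motif.background if background is None else np.asarray(background, float)
    logodds = np.log2(motif.frequencies / bg)          # (width, 4)
    width = motif.width
    scores = []
    for seq in sequences:
        seq = seq.upper()
        if len(seq) < width:
            raise ValueError("sequence shorter than the motif width")
        best = -np.inf
        strands = (seq, revcomp(seq)) if both_strands else (seq,)
        for strand in strands:
            idx = np.fromiter(
                (_BASE_INDEX.get(ch, -1) for ch in strand), dtype=np.int64,
                count=len(strand),
            )
            for start in range(len(strand) - width + 1):
                window = idx[start : start + width]
                valid = window >= 0
                s = logodds[np.nonzero(valid)[0], window[valid]].sum()
                if s > best:
                    best = s
        scores.append(best)
    return np.asarray(scores)


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_auc(positive_scores: Sequence[float],
            negative_scores: Sequence[float]) -> RocResult:
    """ROC curve and area from two score samples.

    Sweeps thresholds over the union of observed scores; at each threshold
    the true-positive and false-positive rates are the fractions of scores
    at or above it.  The area is the trapezoidal integral, which credits
    tied scores 0.5 (equal to the Mann-Whitney U statistic normalized by
    n_pos * n_neg).
    """
    pos = np.asarray(positive_scores, float)
    neg = np.asarray(negative_scores, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score classes must be non-empty")
    thresholds = np.concatenate(([np.inf], np.unique(np.concatenate((pos, neg)))[::-1]))
    tpr = np.array([(pos >= t).mean() for t in thresholds])
    fpr = np.array([(neg >= t).mean() for t in thresholds])
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


# ---------------------------------------------------------------------------
# MEME minimal-format serialization
# ---------------------------------------------------------------------------

def write_meme(motif: NucleotideMotif, name: str, path: str,
               n_sites: int = 20) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*motif.background))
        fh.write(f"MOTIF {name}\n")
        fh.write(f"letter-probability matrix: alength= 4 w= {motif.width} "
                 f"nsites= {n_sites} E= 0\n")
        for row in motif.frequencies:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
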