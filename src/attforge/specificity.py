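"""Cluster recombinases and target genes and classify target-site specificity.

Recombinases are greedily clustered at 90% and 50% amino-acid identity and
the bacterial genes they disrupt at 50% identity.  Site-specific recombinase
clusters are those whose integrations all fall in a single target-gene
cluster that is independently targeted by at least three recombinase
clusters; clusters whose 90%-identity members hit many distinct gene
clusters are binned (2, 3, >3 targets) and called multi-targeting at ">3",
with each 50% cluster inheriting the highest bin among its 90% members.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

from ._seq import alignment_identity, make_global_aligner

BIN_ORDER = ("1", "2", "3", ">3")


@dataclass
class SequenceCluster:
    threshold: float
    representative_id: str
    member_ids: list[str] = field(default_factory=list)


def cluster_sequences(seqs: Mapping[str, str] | Sequence[tuple[str, str]],
                      threshold: float,
                      match: float = 1.0, gap_open: float = 10.0,
                      gap_extend: float = 1.0) -> list[SequenceCluster]:
    """Greedy centroid clustering at a fractional identity threshold.

    Sequences are processed in order of decreasing length (ties broken
    lexicographically by id); each joins the first existing centroid it
    matches at >= threshold identity (matches over alignment columns under
    global alignment with unit match score and affine gaps), else founds a
    new cluster.  Deterministic by construction.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    items = list(seqs.items()) if isinstance(seqs, Mapping) else list(seqs)
    if not items:
        return []
    aligner = make_global_aligner(match=match, gap_open=gap_open, gap_extend=gap_extend)
    items.sort(key=lambda kv: (-len(kv[1]), kv[0]))
    clusters: list[SequenceCluster] = []
    centroids: list[str] = []
    for sid, seq in items:
        placed = False
        for cluster, centroid in zip(clusters, centroids):
            if alignment_identity(aligner, seq, centroid) >= threshold:
                cluster.member_ids.append(sid)
                placed = True
                break
        if not placed:
            clusters.append(SequenceCluster(threshold=threshold,
                                            representative_id=sid,
                                            member_ids=[sid]))
            centroids.append(seq)
    return clusters


@dataclass
class SpecificityCall:
    lsr_cluster_id: Hashable       # 50%-identity cluster
    n_target_clusters: int
    bin: str                       # one of "1", "2", "3", ">3"
    label: str                     # site-specific / multi-targeting / unclassified


def _bin_for(n: int) -> str:
    if n <= 0:
        raise ValueError("target count must be positive")
    return str(n) if n <= 3 else ">3"


def classify_site_specific(
        lsr_to_target: Iterable[tuple[Hashable, Hashable]]) -> set[Hashable]:
    """Recombinase clusters predicted to target a single conserved site.

    Edges are (recombinase 50%-cluster, target-gene 50%-cluster) pairs,
    deduplicated.  Target clusters hit by fewer than three recombinase
    clusters are discarded; among the surviving edges, a recombinase cluster
    is site-specific when its edges cover exactly one target cluster.
    """
    edges = set(lsr_to_target)
    targets_by_lsr: dict[Hashable, set] = defaultdict(set)
    lsrs_by_target: dict[Hashable, set] = defaultdict(set)
    for lsr, tgt in edges:
        targets_by_lsr[lsr].add(tgt)
        lsrs_by_target[tgt].add(lsr)
    surviving_targets = {t for t, ls in lsrs_by_target.items() if len(ls) >= 3}
    result = set()
    for lsr, tgts in targets_by_lsr.items():
        # Single-targeting means the cluster's entire edge set covers one
        # gene cluster (which must itself be independently supported); this
        # keeps site-specific and multi-targeting labels mutually exclusive.
        if len(tgts) == 1 and tgts <= surviving_targets:
            result.add(lsr)
    return result


def classify_multi_targeting(
        lsr90_to_target: Iterable[tuple[Hashable, Hashable]],
        lsr90_to_lsr50: Mapping[Hashable, Hashable]) -> list[SpecificityCall]:
    """Bin recombinase clusters by the number of distinct gene clusters hit.

    Counts distinct target-gene clusters per 90%-identity cluster, removes
    clusters targeting a single gene cluster from multi-targeting
    consideration, bins the remainder (2, 3, >3), and assigns each
    50%-identity cluster the highest bin among its member 90% clusters.
    ">3" is fully multi-targeting.
    """
    edges = set(lsr90_to_target)
    targets_by_90: dict[Hashable, set] = defaultdict(set)
    for lsr90, tgt in edges:
        if lsr90 not in lsr90_to_lsr50:
            raise KeyError(f"90% cluster {lsr90!r} has no 50% cluster assignment")
        targets_by_90[lsr90].add(tgt)
    best_bin_by_50: dict[Hashable, int] = {}
    count_by_50: dict[Hashable, int] = {}
    for lsr90, tgts in targets_by_90.items():
        n = len(tgts)
        if n <= 1:
            continue  # single-target 90% clusters leave multi-targeting consideration
        bin_idx = BIN_ORDER.index(_bin_for(n))
        parent = lsr90_to_lsr50[lsr90]
        if bin_idx > best_bin_by_50.get(parent, -1):
            best_bin_by_50[parent] = bin_idx
            count_by_50[parent] = n
        elif bin_idx == best_bin_by_50.get(parent) and n > count_by_50[parent]:
            count_by_50[parent] = n
    calls = []
    for parent in sorted(best_bin_by_50, key=repr):
        bin_label = BIN_ORDER[best_bin_by_50[parent]]
        calls.append(SpecificityCall(
            lsr_cluster_id=parent,
            n_target_clusters=count_by_50[parent],
            bin=bin_label,
            label="multi-targeting" if bin_label == ">3" else "unclassified",
        ))
    return calls


def select_motif_eligible(
        attB_sets: Mapping[Hashable, Sequence[tuple[Hashable, str]]],
        min_sites: int = 10) -> dict[Hashable, list[str]]:
    """Choose candidates with enough distinct attB evidence for motif building.

    ``attB_sets`` maps a candidate (ortholog or cluster) to (target-gene
    cluster, attB sequence) pairs.  Candidates qualify with more than
    ``min_sites`` unique attB sequences or more than ``min_sites`` distinct
    target-gene clusters; for each qualifying candidate one attB per target
    gene cluster is forwarded (first seen, to avoid redundancy).
    """
    eligible: dict[Hashable, list[str]] = {}
    for cand, pairs in attB_sets.items():
        unique_attbs = {seq for _, seq in pairs}
        target_clusters = {t for t, _ in pairs}
        if len(unique_attbs) > min_sites or len(target_clusters) > min_sites:
            per_cluster: dict[Hashable, str] = {}
            for tgt, seq in pairs:
                per_cluster.setdefault(tgt, seq)
            eligible[cand] = list(per_cluster.values())
    return eligible
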