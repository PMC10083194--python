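"""Domain/term enrichment among target genes and anti-phage proximity tests.

Genes disrupted by recombinase integration are compared with background
genes drawn from the same contigs: each annotation feature occurring in at
least five different target genes is tested with a two-sided Fisher exact
test and the p-values are adjusted by Benjamini-Hochberg FDR.  Proximity to
anti-phage defense genes is compared between target and background genes
with a Wilcoxon rank-sum test (exact for small samples).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Set

import numpy as np
from scipy.stats import fisher_exact, mannwhitneyu, norm

MIN_TARGET_GENES = 5


@dataclass
class EnrichmentRow:
    feature: str
    target_count: int
    background_count: int
    n_target: int
    n_background: int
    odds_ratio: float
    p: float
    fdr: float | None = None
    tested: bool = True
    reason: str = ""


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up FDR adjustment (the p.adjust 'fdr' method)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    # Enforce monotonicity from the largest p downward.
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out


def feature_enrichment(target_features: Mapping[str, Set[str]],
                       background_features: Mapping[str, Set[str]],
                       min_target_genes: int = MIN_TARGET_GENES,
                       ) -> list[EnrichmentRow]:
    """Per-feature Fisher enrichment of target genes over background genes.

    ``target_features``/``background_features`` map gene ids to their
    annotation feature sets.  Features present in fewer than
    ``min_target_genes`` target genes are reported untested.  Adjusted
    p-values are Benjamini-Hochberg over the tested features.
    """
    if not background_features:
        raise ValueError("background gene set is empty")
    n_t = len(target_features)
    n_b = len(background_features)
    all_features = sorted(
        set().union(*target_features.values(), *background_features.values())
        if (target_features or background_features) else set()
    )
    rows: list[EnrichmentRow] = []
    for feat in all_features:
        t = sum(feat in fs for fs in target_features.values())
        b = sum(feat in fs for fs in background_features.values())
        if t < min_target_genes:
            rows.append(EnrichmentRow(
                feature=feat, target_count=t, background_count=b,
                n_target=n_t, n_background=n_b, odds_ratio=float("nan"),
                p=float("nan"), tested=False,
                reason=f"present in {t} < {min_target_genes} target genes"))
            continue
        table = [[t, n_t - t], [b, n_b - b]]
        odds, p = fisher_exact(table, alternative="two-sided")
        rows.append(EnrichmentRow(
            feature=feat, target_count=t, background_count=b,
            n_target=n_t, n_background=n_b,
            odds_ratio=float(odds), p=float(p)))
    tested = [r for r in rows if r.tested]
    if tested:
        fdrs = benjamini_hochberg([r.p for r in tested])
        for row, fdr in zip(tested, fdrs):
            row.fdr = float(fdr)
    return rows


def antiphage_proximity_test(target_distances: Sequence[float],
                             background_distances: Sequence[float],
                             exact_max_n: int = 25) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of distances to the nearest defense gene.

    Returns (rank-sum statistic of the target sample, two-sided p).  The
    exact null distribution is used for combined sample sizes up to
    ``exact_max_n``; larger samples use the normal approximation with
    continuity correction.  Degenerate all-tied input returns p = 1.
    """
    x = np.asarray(target_distances, dtype=float)
    y = np.asarray(background_distances, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate((x, y))
    ranks = _rankdata(combined)
    w = float(ranks[: x.size].sum())       # rank-sum statistic of the targets
    if np.all(combined == combined[0]):
        return w, 1.0
    if x.size + y.size <= exact_max_n and len(np.unique(combined)) == combined.size:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method,
                       use_continuity=True)
    return w, float(res.pvalue)


def _rankdata(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties shared."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size, dtype=float)
    i = 0
    sorted_vals = values[order]
    while i < values.size:
        j = i
        while j + 1 < values.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks
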