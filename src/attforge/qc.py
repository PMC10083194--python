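"""Candidate quality control and mobile-element category voting.

Eight filters gate a recombinase candidate: same-species genome comparison
(ANI >= 95%), attachment-site center length (centers above 20 bp are
rejected), ambiguous-nucleotide content of the attachment sites (<= 5%),
protein length (400-650 aa inclusive), presence of at least one of the three
canonical serine-recombinase Pfam domains, ambiguous-amino-acid content
(<= 5%), element length (< 200 kb), and distance of the recombinase gene
from its predicted attachment site (<= 500 nt).  "More than X removed"
thresholds are strict (exactly X passes) and "between A and B" is inclusive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .attsite import AttachmentSitePair

LSR_DOMAINS = frozenset({"Resolvase", "Recombinase", "Zn_ribbon_recom"})

DEFAULT_THRESHOLDS = {
    "min_ani_percent": 95.0,
    "max_center_len": 20,
    "max_ambiguous_nt_fraction": 0.05,
    "min_protein_len": 400,
    "max_protein_len": 650,
    "required_domains": LSR_DOMAINS,
    "max_ambiguous_aa_fraction": 0.05,
    "max_element_len": 200_000,     # strict: an element of exactly 200 kb fails
    "max_distance_to_site": 500,
}


@dataclass
class LsrCandidate:
    lsr_id: str
    protein_seq: Optional[str] = None
    pfam_domains: Optional[set[str]] = None
    distance_to_site: Optional[int] = None
    element_length: Optional[int] = None
    ani_percent: Optional[float] = None
    att_pair: Optional[AttachmentSitePair] = None
    ambiguous_nt_fraction: Optional[float] = None
    ambiguous_aa_fraction: Optional[float] = None


@dataclass
class FilterVerdict:
    name: str
    passed: bool
    value: object = None
    indeterminate: bool = False


@dataclass
class QcReport:
    verdicts: list[FilterVerdict] = field(default_factory=list)

    @property
    def overall_pass(self) -> bool:
        return all(v.passed for v in self.verdicts)

    def verdict(self, name: str) -> FilterVerdict:
        for v in self.verdicts:
            if v.name == name:
                return v
        raise KeyError(name)


def apply_filters(candidate: LsrCandidate, config: dict | None = None) -> QcReport:
    """Evaluate every quality-control filter for one candidate.

    A missing field marks that filter indeterminate (failed) rather than
    raising, so partial candidate tables can be screened.  Thresholds are
    read from ``config`` with the published defaults.
    """
    cfg = dict(DEFAULT_THRESHOLDS)
    if config:
        cfg.update(config)
    report = QcReport()

    def check(name: str, value, predicate) -> None:
        if value is None:
            report.verdicts.append(FilterVerdict(name, False, None, indeterminate=True))
        else:
            report.verdicts.append(FilterVerdict(name, bool(predicate(value)), value))

    check("ani", candidate.ani_percent, lambda v: v >= cfg["min_ani_percent"])
    center_len = len(candidate.att_pair.center) if candidate.att_pair else None
    check("center_length", center_len, lambda v: v <= cfg["max_center_len"])
    check("ambiguous_nt", candidate.ambiguous_nt_fraction,
          lambda v: v <= cfg["max_ambiguous_nt_fraction"])
    protein_len = len(candidate.protein_seq) if candidate.protein_seq else None
    check("protein_length", protein_len,
          lambda v: cfg["min_protein_len"] <= v <= cfg["max_protein_len"])
    check("pfam_domain", candidate.pfam_domains,
          lambda v: bool(set(v) & set(cfg["required_domains"])))
    check("ambiguous_aa", candidate.ambiguous_aa_fraction,
          lambda v: v <= cfg["max_ambiguous_aa_fraction"])
    check("element_length", candidate.element_length,
          lambda v: v < cfg["max_element_len"])
    check("distance_to_site", candidate.distance_to_site,
          lambda v: v <= cfg["max_distance_to_site"])
    return report


MGE_CATEGORIES = ("dsDNA Phage", "ICE/IME", "Plasmid", "Other replicon")


def vote_mge_category(annotations: Iterable[str]) -> str:
    """Plurality vote over per-tool mobile-element annotations.

    Ties are resolved in the fixed priority order dsDNA Phage, ICE/IME,
    Plasmid, Other replicon; an empty annotation set yields "Other".
    """
    counts = Counter(annotations)
    unknown = set(counts) - set(MGE_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown MGE annotation labels: {sorted(unknown)}")
    if not counts:
        return "Other"
    best = max(counts.values())
    for category in MGE_CATEGORIES:
        if counts.get(category, 0) == best:
            return category
    raise AssertionError("unreachable")
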