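"""Per-protein enrichment of strongly predicted SAVs and localization folds.

Two questions: (1) which proteins concentrate strongly predicted effect
SAVs — at least ``min_count`` SAVs of a frequency class with at least (or
more than) ``min_fraction`` of them scored above ``score_threshold``; and
(2) whether such protein subsets are over- or under-represented in
sub-cellular localization categories relative to a background set of
SAV-bearing proteins (fold = observed fraction / expected fraction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

from .variant_model import (
    FrequencyClass,
    ProteinRecord,
    SAV,
    ScoredSAV,
    VariantModelError,
)


class EnrichmentError(VariantModelError):
    pass


@dataclass(frozen=True)
class EnrichmentFilterSpec:
    """Filter for proteins enriched in strongly predicted SAVs.

    ``frequency_class`` restricts which SAVs count ("any" uses all);
    ``fraction_strict`` selects > vs >= for the fraction comparison — the
    count comparison is always >= ``min_count``.
    """

    frequency_class: Union[FrequencyClass, str] = "any"
    min_count: int = 2
    score_threshold: float = 50.0
    min_fraction: float = 0.5
    fraction_strict: bool = True
    method: str = "SNAP2"

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise EnrichmentError(f"min_count must be >= 1, got {self.min_count}")
        if not 0.0 <= self.min_fraction <= 1.0:
            raise EnrichmentError(
                f"min_fraction {self.min_fraction} outside [0, 1]"
            )


def filter_enriched_proteins(
    scored_savs: Iterable[ScoredSAV], spec: EnrichmentFilterSpec
) -> list[str]:
    """Protein ids with >= min_count class-matching SAVs of which the
    fraction scored above ``score_threshold`` meets ``min_fraction``
    (strictly, when ``fraction_strict``).  Deterministic sorted order;
    invariant under input reordering."""
    counts: dict[str, int] = {}
    strong: dict[str, int] = {}
    for ssav in scored_savs:
        if spec.frequency_class != "any":
            if ssav.sav.frequency_class != spec.frequency_class:
                continue
        score = float(ssav.score(spec.method))
        pid = ssav.sav.protein_id
        counts[pid] = counts.get(pid, 0) + 1
        if score > spec.score_threshold:
            strong[pid] = strong.get(pid, 0) + 1
    out = []
    for pid, n in counts.items():
        if n < spec.min_count:
            continue
        frac = strong.get(pid, 0) / n
        ok = frac > spec.min_fraction if spec.fraction_strict else frac >= spec.min_fraction
        if ok:
            out.append(pid)
    return sorted(out)


def coverage_filter(
    savs: Iterable[SAV],
    proteins: Mapping[str, ProteinRecord],
    min_coverage: float,
) -> list[str]:
    """Proteins whose distinct SAV positions cover at least
    ``min_coverage`` of their residues (distinct positions / length)."""
    if not 0.0 <= min_coverage <= 1.0:
        raise EnrichmentError(f"min_coverage {min_coverage} outside [0, 1]")
    positions: dict[str, set[int]] = {}
    for sav in savs:
        positions.setdefault(sav.protein_id, set()).add(sav.position)
    out = []
    for pid, pos in positions.items():
        protein = proteins.get(pid)
        if protein is None:
            continue
        if len(pos) / len(protein) >= min_coverage:
            out.append(pid)
    return sorted(out)


@dataclass(frozen=True)
class LocalizationEnrichment:
    """Observed vs expected fraction of a localization category and their
    ratio.  ``fold`` is inf (flagged, not a crash) when the category is
    present in the subset but absent from the background."""

    category: str
    observed: float
    expected: float
    fold: float

    @property
    def infinite(self) -> bool:
        return math.isinf(self.fold)


def localization_fold(
    member_labels: Mapping[str, str],
    subset: Sequence[str],
    background: Sequence[str],
    groups: Optional[Mapping[str, Sequence[str]]] = None,
) -> list[LocalizationEnrichment]:
    """Per-category over/under-representation of ``subset`` relative to
    ``background``.

    ``groups`` optionally unions raw labels into composite categories
    (e.g. {"secreted+membrane": ["secreted", "membrane"]}); when given,
    only the composite categories are reported.  Categories absent from
    the subset are reported with observed 0.
    """
    if not background:
        raise EnrichmentError("background protein set is empty")
    for pid in list(subset) + list(background):
        if pid not in member_labels:
            raise EnrichmentError(f"protein {pid!r} has no localization label")

    def fractions(ids: Sequence[str], members: Sequence[str]) -> float:
        member_set = set(members)
        return sum(1 for p in ids if member_labels[p] in member_set) / len(ids)

    if groups is None:
        categories = sorted({member_labels[p] for p in background}
                            | {member_labels[p] for p in subset})
        groups = {c: [c] for c in categories}

    out = []
    for category in sorted(groups):
        members = groups[category]
        expected = fractions(background, members)
        observed = fractions(subset, members) if subset else 0.0
        if expected > 0:
            fold = observed / expected
        else:
            fold = math.inf if observed > 0 else 0.0
        out.append(LocalizationEnrichment(category, observed, expected, fold))
    return out
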