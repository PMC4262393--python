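"""Rule-based severity classification of a disease from its characteristics.

A disease's untreated characteristic profile is first reduced to the
characteristics that count: traits below the penetrance threshold (default
25%, inclusive) are dropped, as are the two severity modifiers
(availability of treatment, variable expressivity) and the single Tier-4
characteristic (reduced fertility), none of which inform untreated
severity.  The remaining traits are bucketed by tier and classified by a
fixed rule cascade:

    R1  Profound  if more than one Tier 1 characteristic
    R2  Severe    if exactly one Tier 1 characteristic
    R3  Severe    if >=1 Tier 2 characteristic and >=4 Tier 2+3 in total
                  (one qualifying Tier 2 item plus at least three others)
    R4  Moderate  if any Tier 2 or Tier 3 characteristic remains
    R5  Mild      otherwise

Every rule evaluated is recorded in the result's rule trace, so the reason
a disease landed in a bin is always reportable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .core_model import (
    LABEL_TO_ORDINAL,
    DiseaseProfile,
    RuleOutcome,
    SeverityClass,
    TierMap,
    load_packaged_tier_map,
)

__all__ = [
    "ClassifierConfig",
    "EffectiveTraitSet",
    "PanelSummary",
    "effective_characteristics",
    "classify",
    "classify_panel",
]

logger = logging.getLogger(__name__)

EXCLUSION_REASONS = ("below_penetrance", "modifier", "tier4")


@dataclass(frozen=True)
class ClassifierConfig:
    """Classifier parameters.

    penetrance_threshold: minimum fraction of affected individuals showing
        a characteristic for it to count (default 0.25).
    threshold_inclusive: whether exactly-at-threshold penetrance passes
        ("at least 25%" reading, default) or a strictly-greater reading.
    tier_map: packaged or derived characteristic tier assignment.
    r3_others_tier3_only: documented variant of the Severe rule R3 in which
        the three additional characteristics must be Tier 3 specifically
        rather than Tier 2 or 3.
    """

    tier_map: TierMap = field(default_factory=load_packaged_tier_map)
    penetrance_threshold: float = 0.25
    threshold_inclusive: bool = True
    r3_others_tier3_only: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.penetrance_threshold <= 1.0):
            raise ValueError("penetrance_threshold must be in [0, 1]")


@dataclass(frozen=True)
class EffectiveTraitSet:
    """A profile's traits bucketed by tier after filtering.

    ``excluded`` maps characteristic id -> exclusion reason; the three tier
    sets and the excluded set partition the (deduplicated) profile traits.
    """

    tier1: frozenset
    tier2: frozenset
    tier3: frozenset
    excluded: Mapping[str, str]


@dataclass(frozen=True)
class PanelSummary:
    """Severity-bin composition of a screening panel."""

    counts: Mapping[str, int]
    fractions: Mapping[str, float]
    n: int


def _passes_penetrance(pen: Optional[float], config: ClassifierConfig) -> bool:
    if pen is None:  # presence-only profiles are classified as-is
        return True
    if config.threshold_inclusive:
        return pen >= config.penetrance_threshold
    return pen > config.penetrance_threshold


def effective_characteristics(
    profile: DiseaseProfile, config: ClassifierConfig
) -> EffectiveTraitSet:
    """Apply the penetrance filter and modifier/Tier-4 exclusions."""
    tiers: dict[int, set] = {1: set(), 2: set(), 3: set()}
    excluded: dict[str, str] = {}
    for trait in profile.traits:
        cid = trait.characteristic_id
        if cid in excluded or any(cid in s for s in tiers.values()):
            continue  # duplicate trait ids are idempotent
        if not _passes_penetrance(trait.penetrance, config):
            excluded[cid] = "below_penetrance"
            continue
        tier = config.tier_map.classification_tier(cid)
        if tier is None:
            excluded[cid] = "modifier"
            logger.warning(
                "profile %s: modifier characteristic %r ignored for classification",
                profile.disease_id,
                cid,
            )
            continue
        if tier == 4:
            excluded[cid] = "tier4"
            continue
        if tier not in tiers:
            raise KeyError(
                f"characteristic {cid!r} has unusable tier {tier} in tier map"
            )
        tiers[tier].add(cid)
    return EffectiveTraitSet(
        tier1=frozenset(tiers[1]),
        tier2=frozenset(tiers[2]),
        tier3=frozenset(tiers[3]),
        excluded=excluded,
    )


def classify(profile: DiseaseProfile, config: Optional[ClassifierConfig] = None) -> SeverityClass:
    """Classify one disease; rules R1-R5 are evaluated in strict precedence."""
    if config is None:
        config = ClassifierConfig()
    eff = effective_characteristics(profile, config)
    n1, n2, n3 = len(eff.tier1), len(eff.tier2), len(eff.tier3)
    trace: list[RuleOutcome] = []

    r1 = n1 >= 2
    trace.append(RuleOutcome("R1", r1, f"tier1={n1} (Profound needs >=2)"))
    if r1:
        return _result("Profound", trace)

    r2 = n1 == 1
    trace.append(RuleOutcome("R2", r2, f"tier1={n1} (Severe needs exactly 1)"))
    if r2:
        return _result("Severe", trace)

    others = n3 if config.r3_others_tier3_only else n2 + n3 - 1
    r3 = n2 >= 1 and others >= 3
    trace.append(
        RuleOutcome(
            "R3", r3, f"tier2={n2}, tier3={n3} (Severe needs a Tier 2 item + 3 others)"
        )
    )
    if r3:
        return _result("Severe", trace)

    r4 = n2 + n3 >= 1
    trace.append(RuleOutcome("R4", r4, f"tier2+tier3={n2 + n3} (Moderate needs >=1)"))
    if r4:
        return _result("Moderate", trace)

    trace.append(RuleOutcome("R5", True, "no qualifying characteristics (Mild)"))
    return _result("Mild", trace)


def _result(label: str, trace: Sequence[RuleOutcome]) -> SeverityClass:
    return SeverityClass(
        label=label, ordinal=LABEL_TO_ORDINAL[label], rule_trace=tuple(trace)
    )


def classify_panel(
    profiles: Iterable[DiseaseProfile],
    config: Optional[ClassifierConfig] = None,
) -> tuple[dict[str, SeverityClass], PanelSummary]:
    """Classify every disease on a panel and summarize bin composition."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("classify_panel needs at least one profile")
    results = {p.disease_id: classify(p, config) for p in profiles}
    counts = {lab: 0 for lab in LABEL_TO_ORDINAL}
    for res in results.values():
        counts[res.label] += 1
    n = len(results)
    fractions = {lab: c / n for lab, c in counts.items()}
    return results, PanelSummary(counts=counts, fractions=fractions, n=n)
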