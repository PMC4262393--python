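"""Domain types and packaged reference data for disease-severity classification.

The package operationalizes a survey-derived severity model for expanded
carrier screening: 192 health-care professionals rated the importance of 15
clinical characteristics of genetic disease on a 1-10 scale and rated the
untreated severity of 15 recessive diseases on an ordinal Mild < Moderate <
Severe < Profound scale.  The rating summaries, the characteristic tier
assignments, the disease severity groups, and each disease's characteristic
profile ship with the package as versioned CSV resources loaded here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Optional

import pandas as pd

__all__ = [
    "Characteristic",
    "RatingSummary",
    "TierMap",
    "Trait",
    "DiseaseProfile",
    "SeverityClass",
    "RuleOutcome",
    "ReferenceDisease",
    "UnknownCharacteristicError",
    "ProfileValidationError",
    "SEVERITY_LABELS",
    "LABEL_TO_ORDINAL",
    "ORDINAL_TO_LABEL",
    "SET_RESPONDENTS",
    "TOTAL_RESPONDENTS",
    "PENETRANCE_COUNTS",
    "load_default_characteristics",
    "load_characteristic_summaries",
    "load_packaged_tier_map",
    "load_reference_diseases",
    "load_disease_summaries",
    "validate_profile",
]

# Ordinal severity scale.  The mapping is fixed: 1 = Mild, 2 = Moderate,
# 3 = Severe, 4 = Profound; it is never configurable.
SEVERITY_LABELS: tuple[str, ...] = ("Mild", "Moderate", "Severe", "Profound")
LABEL_TO_ORDINAL: dict[str, int] = {lab: i + 1 for i, lab in enumerate(SEVERITY_LABELS)}
ORDINAL_TO_LABEL: dict[int, str] = {v: k for k, v in LABEL_TO_ORDINAL.items()}

# Respondents per disease survey set.  Each respondent rated all 15
# characteristics plus one randomly assigned set of five diseases.
SET_RESPONDENTS: dict[str, int] = {"A": 52, "B": 46, "C": 94}
TOTAL_RESPONDENTS: int = sum(SET_RESPONDENTS.values())

# Invitation counts are recorded as annotations only: the survey report
# gives both figures in different places and the package does not resolve
# the one-person discrepancy.
INVITED_ANNOTATIONS: tuple[int, int] = (3184, 3185)

# Observed distribution of answers to "what fraction of affected individuals
# must show a characteristic for it to count toward severity".  The survey
# offered >25%/>50%/>75%/100%; ">0%" additionally appears in the responses.
PENETRANCE_COUNTS: dict[str, int] = {
    ">0%": 17,
    ">25%": 75,
    ">50%": 63,
    ">75%": 36,
    "100%": 1,
}


class UnknownCharacteristicError(ValueError):
    """A profile refers to a characteristic outside the controlled vocabulary."""


class ProfileValidationError(ValueError):
    """A disease profile is structurally invalid (e.g. empty name)."""


@dataclass(frozen=True)
class Characteristic:
    """One of the 15 rated clinical characteristics.

    ``category`` separates true features of untreated disease progression
    (``core``) from the two severity *modifiers* (availability of treatment,
    variable expressivity) that are rated but never used to classify.
    ``lifespan_flag`` marks the three shortened-life-span items.
    """

    id: str
    name: str
    category: str  # "core" | "modifier"
    lifespan_flag: bool = False

    def __post_init__(self) -> None:
        if self.category not in ("core", "modifier"):
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class RatingSummary:
    """Summary statistics of ratings for one item (characteristic or disease)."""

    item_id: str
    mean: float
    median: float
    min: float
    max: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (self.min <= self.median <= self.max):
            raise ValueError(f"{self.item_id}: min <= median <= max violated")
        if not (self.min <= self.mean <= self.max):
            raise ValueError(f"{self.item_id}: min <= mean <= max violated")


@dataclass(frozen=True)
class TierMap:
    """Assignment of characteristics to importance tiers 1 (highest) .. k.

    Modifiers carry the tier they co-cluster with (availability of treatment
    sits at the top of Tier 2, variable expressivity at the bottom of
    Tier 3) but are listed in ``modifiers`` and are never treated as tiered
    characteristics during classification.
    """

    assignment: Mapping[str, int]
    modifiers: frozenset = frozenset()
    provenance: str = "packaged"  # "packaged" | "derived"
    cluster_means: Optional[Mapping[int, float]] = None

    def tier_of(self, characteristic_id: str) -> int:
        """Co-clustered tier of a characteristic (modifiers included)."""
        return self.assignment[characteristic_id]

    def classification_tier(self, characteristic_id: str) -> Optional[int]:
        """Tier used for classification; ``None`` for modifiers."""
        if characteristic_id in self.modifiers:
            return None
        return self.assignment[characteristic_id]


@dataclass(frozen=True)
class Trait:
    """A characteristic present in a disease's untreated course.

    ``penetrance`` is the fraction of affected individuals showing the
    characteristic, or ``None`` when unspecified.  Unspecified penetrance is
    treated as passing the penetrance filter, since the reference profiles
    record presence only.
    """

    characteristic_id: str
    penetrance: Optional[float] = None

    def __post_init__(self) -> None:
        if self.penetrance is not None and not (0.0 <= self.penetrance <= 1.0):
            raise ValueError(
                f"penetrance {self.penetrance} for {self.characteristic_id} "
                "outside [0, 1]"
            )


@dataclass(frozen=True)
class DiseaseProfile:
    """A disease plus the set of characteristics of its untreated course."""

    disease_id: str
    name: str
    traits: tuple[Trait, ...] = ()

    @property
    def trait_ids(self) -> frozenset:
        return frozenset(t.characteristic_id for t in self.traits)

    def penetrance_of(self, characteristic_id: str) -> Optional[float]:
        for t in self.traits:
            if t.characteristic_id == characteristic_id:
                return t.penetrance
        raise KeyError(characteristic_id)


@dataclass(frozen=True)
class RuleOutcome:
    rule_id: str
    fired: bool
    detail: str = ""


@dataclass(frozen=True)
class SeverityClass:
    """Classification outcome with the ordered trace of rules evaluated."""

    label: str
    ordinal: int
    rule_trace: tuple[RuleOutcome, ...]

    def __post_init__(self) -> None:
        if LABEL_TO_ORDINAL.get(self.label) != self.ordinal:
            raise ValueError(f"label {self.label!r} / ordinal {self.ordinal} mismatch")
        if not self.rule_trace:
            raise ValueError("rule_trace must be non-empty")

    @property
    def deciding_rule(self) -> str:
        for r in self.rule_trace:
            if r.fired:
                return r.rule_id
        raise AssertionError("no rule fired")


@dataclass(frozen=True)
class ReferenceDisease:
    """One of the 15 surveyed reference diseases with its survey outcome."""

    profile: DiseaseProfile
    summary: RatingSummary
    survey_group: str  # "Profound" | "Severe" | "Moderate"
    survey_set: str  # "A" | "B" | "C"
    acmg_acog: bool
    assessed_nbs: bool
    included_nbs: bool


# ---------------------------------------------------------------------------
# Packaged fixture loading


def _read_resource(name: str) -> pd.DataFrame:
    ref = resources.files("sevtier.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def _as_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    return str(x).strip().lower() in ("true", "1", "x", "yes")


def load_default_characteristics() -> list[Characteristic]:
    """The controlled vocabulary of 15 rated characteristics."""
    df = _read_resource("characteristics.csv")
    return [
        Characteristic(
            id=row.id,
            name=row.name,
            category=row.category,
            lifespan_flag=_as_bool(row.lifespan_flag),
        )
        for row in df.itertuples(index=False)
    ]


def load_characteristic_summaries() -> dict[str, RatingSummary]:
    """Published importance-rating summaries (1-10 scale) per characteristic."""
    df = _read_resource("characteristics.csv")
    return {
        row.id: RatingSummary(
            item_id=row.id,
            mean=float(row.mean),
            median=float(row.median),
            min=float(row.min),
            max=float(row.max),
            n=int(row.n),
        )
        for row in df.itertuples(index=False)
    }


def load_packaged_tier_map() -> TierMap:
    """The published tier assignment (Tier 1: 3, Tier 2: 3, Tier 3: 6, Tier 4: 1)."""
    df = _read_resource("characteristics.csv")
    assignment = {row.id: int(row.tier) for row in df.itertuples(index=False)}
    modifiers = frozenset(
        row.id for row in df.itertuples(index=False) if row.category == "modifier"
    )
    return TierMap(assignment=assignment, modifiers=modifiers, provenance="packaged")


def load_reference_diseases() -> list[ReferenceDisease]:
    """The 15 surveyed diseases with profiles, rating summaries and flags."""
    diseases = _read_resource("diseases.csv")
    profiles = _read_resource("profiles.csv")
    traits_by_disease: dict[str, list[Trait]] = {}
    for row in profiles.itertuples(index=False):
        traits_by_disease.setdefault(row.disease_id, []).append(
            Trait(characteristic_id=row.characteristic_id)
        )
    out = []
    for row in diseases.itertuples(index=False):
        profile = DiseaseProfile(
            disease_id=row.disease_id,
            name=row.name,
            traits=tuple(traits_by_disease.get(row.disease_id, ())),
        )
        summary = RatingSummary(
            item_id=row.disease_id,
            mean=float(row.mean),
            median=float(row.median),
            min=float(row.min),
            max=float(row.max),
            n=SET_RESPONDENTS[row.survey_set],
        )
        out.append(
            ReferenceDisease(
                profile=profile,
                summary=summary,
                survey_group=row.group,
                survey_set=row.survey_set,
                acmg_acog=_as_bool(row.acmg_acog),
                assessed_nbs=_as_bool(row.assessed_nbs),
                included_nbs=_as_bool(row.included_nbs),
            )
        )
    return out


def load_disease_summaries() -> dict[str, RatingSummary]:
    """Severity-rating summaries (1-4 scale) per reference disease."""
    return {d.profile.disease_id: d.summary for d in load_reference_diseases()}


# ---------------------------------------------------------------------------
# Profile validation


def validate_profile(
    profile: DiseaseProfile,
    vocabulary: Optional[Iterable[Characteristic]] = None,
) -> DiseaseProfile:
    """Validate a user-supplied disease profile against the vocabulary.

    Unknown characteristic ids raise :class:`UnknownCharacteristicError`;
    an empty disease name raises :class:`ProfileValidationError`.  Duplicate
    traits are collapsed (first occurrence kept) and more than one lifespan
    characteristic is flagged, both with warnings rather than errors.
    """
    if not profile.name or not profile.name.strip():
        raise ProfileValidationError(
            f"disease {profile.disease_id!r} has an empty name"
        )
    vocab = list(vocabulary) if vocabulary is not None else load_default_characteristics()
    known = {c.id for c in vocab}
    lifespan_ids = {c.id for c in vocab if c.lifespan_flag}

    unknown = [t.characteristic_id for t in profile.traits if t.characteristic_id not in known]
    if unknown:
        raise UnknownCharacteristicError(
            f"unknown characteristic(s) in profile {profile.disease_id!r}: "
            + ", ".join(sorted(set(unknown)))
        )

    seen: dict[str, Trait] = {}
    dupes = []
    for t in profile.traits:
        if t.characteristic_id in seen:
            dupes.append(t.characteristic_id)
        else:
            seen[t.characteristic_id] = t
    if dupes:
        warnings.warn(
            f"profile {profile.disease_id!r}: duplicate trait(s) collapsed: "
            + ", ".join(sorted(set(dupes))),
            stacklevel=2,
        )

    n_lifespan = sum(1 for cid in seen if cid in lifespan_ids)
    if n_lifespan > 1:
        warnings.warn(
            f"profile {profile.disease_id!r}: {n_lifespan} lifespan characteristics "
            "listed; reference profiles carry at most one",
            stacklevel=2,
        )

    if len(seen) == len(profile.traits):
        return profile
    return replace(profile, traits=tuple(seen.values()))
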