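"""Synthetic respondent-level survey data with controllable structure.

No respondent-level ratings are published for the reference survey — only
per-item summaries — so testing aggregation, clustering and evaluation
end-to-end requires simulated questionnaires.  Ratings are drawn from a
normal distribution centred on the item's target mean, rounded to the
nearest integer and truncated to the scale bounds.  Truncation pulls the
realized mean slightly toward mid-scale for targets near the bounds; that
bias is documented and bounded empirically rather than corrected, which
keeps the generator trivial to reason about.

Randomness is reproducible: one master seed, with an independent substream
per item derived by stable hashing of the item id, so adding or removing
an item never perturbs another item's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core_model import TierMap, load_characteristic_summaries, load_packaged_tier_map
from .survey_aggregation import RatingRecord, aggregate_ratings
from .tier_clustering import derive_tiers

__all__ = [
    "ItemSpec",
    "GeneratorSpec",
    "simulate_ratings",
    "simulate_disease_votes",
    "RecoveryResult",
    "recovery_experiment",
]

SCALE_IMPORTANCE = (1, 10)
SCALE_SEVERITY = (1, 4)


@dataclass(frozen=True)
class ItemSpec:
    item_id: str
    target_mean: float
    spread: float  # standard deviation of the latent normal, >= 0

    def __post_init__(self) -> None:
        if self.spread < 0:
            raise ValueError(f"{self.item_id}: spread must be >= 0")


@dataclass(frozen=True)
class GeneratorSpec:
    """Specification of one simulated survey component."""

    items: tuple[ItemSpec, ...]
    n_respondents: int
    seed: int
    scale: tuple[int, int] = SCALE_IMPORTANCE

    def __post_init__(self) -> None:
        lo, hi = self.scale
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")
        for item in self.items:
            if not (lo <= item.target_mean <= hi):
                raise ValueError(
                    f"{item.item_id}: target mean {item.target_mean} outside "
                    f"scale [{lo}, {hi}]"
                )


def _item_rng(seed: int, item_id: str) -> np.random.Generator:
    # Stable per-item substream: master seed spawned with a CRC of the id.
    return np.random.default_rng([seed, zlib.crc32(item_id.encode("utf-8"))])


def simulate_ratings(spec: GeneratorSpec) -> list[RatingRecord]:
    """Draw integer ratings for every (respondent, item) pair.

    spread 0 degenerates to every rating equalling round(target_mean).
    Identical specs (same seed included) produce identical record lists.
    """
    lo, hi = spec.scale
    width = len(str(spec.n_respondents))
    columns: dict[str, np.ndarray] = {}
    for item in spec.items:
        if item.spread == 0:
            vals = np.full(spec.n_respondents, round(item.target_mean))
        else:
            rng = _item_rng(spec.seed, item.item_id)
            draws = rng.normal(item.target_mean, item.spread, size=spec.n_respondents)
            vals = np.clip(np.rint(draws), lo, hi)
        columns[item.item_id] = vals.astype(int)
    records = []
    for j in range(spec.n_respondents):
        rid = f"r{j + 1:0{width}d}"
        for item in spec.items:
            records.append(RatingRecord(rid, item.item_id, int(columns[item.item_id][j])))
    return records


def simulate_disease_votes(spec: GeneratorSpec) -> list[RatingRecord]:
    """Simulate ordinal severity votes; the spec must use the 1-4 scale."""
    if spec.scale != SCALE_SEVERITY:
        raise ValueError("disease votes use the 1-4 severity scale")
    return simulate_ratings(spec)


@dataclass(frozen=True)
class RecoveryResult:
    """Outcome of a tier-recovery experiment across seeds."""

    fraction: float
    outcomes: tuple[bool, ...]
    n_respondents: int
    spread: float

    @property
    def n_seeds(self) -> int:
        return len(self.outcomes)


def recovery_experiment(
    n_respondents: int,
    spread: float,
    n_seeds: int,
    base_seed: int,
    reference: Optional[TierMap] = None,
) -> RecoveryResult:
    """How often does tier derivation from simulated surveys recover the
    packaged tier map?

    Each seed simulates a full survey (all 15 characteristics at their
    published mean ratings as generative targets), aggregates it, derives
    tiers at k = 4, and compares the complete assignment — including the
    tier each modifier co-clusters with — against the packaged map.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    if reference is None:
        reference = load_packaged_tier_map()
    targets = load_characteristic_summaries()
    items = tuple(
        ItemSpec(item_id=i, target_mean=s.mean, spread=spread)
        for i, s in targets.items()
    )
    outcomes = []
    for s in range(n_seeds):
        spec = GeneratorSpec(
            items=items,
            n_respondents=n_respondents,
            seed=base_seed + s,
            scale=SCALE_IMPORTANCE,
        )
        summaries = aggregate_ratings(simulate_ratings(spec))
        derived = derive_tiers(summaries, k=4, modifiers=reference.modifiers)
        outcomes.append(dict(derived.assignment) == dict(reference.assignment))
    return RecoveryResult(
        fraction=sum(outcomes) / n_seeds,
        outcomes=tuple(outcomes),
        n_respondents=n_respondents,
        spread=spread,
    )
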