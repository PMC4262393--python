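"""Agreement between algorithmic severity classes and survey-derived groups,
and bootstrap assessment of tier stability under respondent resampling."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .core_model import LABEL_TO_ORDINAL, SEVERITY_LABELS, SeverityClass
from .survey_aggregation import RatingRecord, aggregate_ratings
from .tier_clustering import derive_tiers

__all__ = ["ConcordanceReport", "concordance", "bootstrap_tier_stability"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConcordanceReport:
    """Confusion matrix (predicted x reference, ordinal-indexed) and accuracy."""

    confusion: pd.DataFrame
    accuracy: float
    mismatches: tuple[tuple[str, str, str], ...]  # (disease, predicted, reference)

    @property
    def n(self) -> int:
        return int(self.confusion.to_numpy().sum())


def _label_of(x: Union[SeverityClass, str]) -> str:
    label = x.label if isinstance(x, SeverityClass) else str(x)
    if label not in LABEL_TO_ORDINAL:
        raise ValueError(f"unknown severity label {label!r}")
    return label


def concordance(
    predicted: Mapping[str, Union[SeverityClass, str]],
    reference: Mapping[str, str],
) -> ConcordanceReport:
    """Exact agreement between predicted classes and reference group labels.

    Both maps must cover the same diseases; accuracy is the confusion-matrix
    trace over the total, and mismatches are listed sorted by disease id.
    """
    if set(predicted) != set(reference):
        diff = sorted(set(predicted) ^ set(reference))
        raise ValueError(f"disease key sets differ; symmetric difference: {diff}")
    mat = np.zeros((4, 4), dtype=int)
    mismatches = []
    for disease in sorted(predicted):
        p = _label_of(predicted[disease])
        r = _label_of(reference[disease])
        mat[LABEL_TO_ORDINAL[p] - 1, LABEL_TO_ORDINAL[r] - 1] += 1
        if p != r:
            mismatches.append((disease, p, r))
    confusion = pd.DataFrame(mat, index=list(SEVERITY_LABELS), columns=list(SEVERITY_LABELS))
    confusion.index.name = "predicted"
    confusion.columns.name = "reference"
    accuracy = float(np.trace(mat) / mat.sum())
    return ConcordanceReport(
        confusion=confusion, accuracy=accuracy, mismatches=tuple(mismatches)
    )


def bootstrap_tier_stability(
    records: Iterable[RatingRecord],
    k: int = 4,
    B: int = 200,
    seed: int = 0,
    modifiers: frozenset = frozenset(),
) -> pd.DataFrame:
    """Tier-assignment frequency per characteristic over B bootstrap resamples.

    The resampling unit is the respondent (each questionnaire is resampled
    whole).  Respondents are sorted canonically before resampling so output
    depends only on data content and seed.  A degenerate resample where all
    item means coincide is assigned the single-cluster solution (everything
    Tier 1) with a logged notice.

    Returns a DataFrame indexed by characteristic id with one column per
    tier 1..k; rows sum to 1.
    """
    records = list(records)
    by_resp: dict[str, list[RatingRecord]] = {}
    for r in records:
        by_resp.setdefault(r.respondent_id, []).append(r)
    respondents = sorted(by_resp)
    if len(respondents) < 2:
        raise ValueError("bootstrap requires at least 2 respondents")
    if B < 1:
        raise ValueError("B must be >= 1")
    items = sorted({r.item_id for r in records})
    freq = pd.DataFrame(
        0.0, index=items, columns=[f"tier{t}" for t in range(1, k + 1)]
    )
    rng = np.random.default_rng(seed)
    for _ in range(B):
        draw = rng.integers(0, len(respondents), size=len(respondents))
        resampled = [rec for j in draw for rec in by_resp[respondents[j]]]
        summaries = aggregate_ratings(resampled)
        means = {i: s.mean for i, s in summaries.items()}
        if len(set(means.values())) == 1:
            logger.info("degenerate bootstrap replicate: all item means equal")
            assignment = {i: 1 for i in means}
        else:
            assignment = derive_tiers(summaries, k=k, modifiers=modifiers).assignment
        for item, tier in assignment.items():
            freq.loc[item, f"tier{tier}"] += 1.0
    freq /= B
    freq.index.name = "characteristic"
    return freq
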