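"""Aggregation of respondent-level survey ratings into summary statistics.

Characteristic importance is rated 1-10 (1 = least important); disease
severity votes arrive as ordinal labels and are encoded 1-4 (Mild=1 ...
Profound=4) before averaging.  Aggregation is item-wise: respondents who
skipped some items still contribute to the items they rated.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import LABEL_TO_ORDINAL, RatingSummary

__all__ = [
    "RatingRecord",
    "PenetranceResponse",
    "PENETRANCE_OPTIONS",
    "encode_severity_label",
    "aggregate_ratings",
    "penetrance_distribution",
    "read_ratings_csv",
    "write_ratings_csv",
    "read_penetrance_csv",
    "write_summary_csv",
]

# Closed set of answers to the penetrance question, in ascending order of
# the threshold they express.  The survey offered the last four; ">0%"
# additionally occurs in the collected responses.
PENETRANCE_OPTIONS: tuple[str, ...] = (">0%", ">25%", ">50%", ">75%", "100%")


@dataclass(frozen=True)
class RatingRecord:
    """A single rating of one item by one respondent."""

    respondent_id: str
    item_id: str
    value: int


@dataclass(frozen=True)
class PenetranceResponse:
    respondent_id: str
    option: str

    def __post_init__(self) -> None:
        if self.option not in PENETRANCE_OPTIONS:
            raise ValueError(
                f"unknown penetrance option {self.option!r}; "
                f"expected one of {PENETRANCE_OPTIONS}"
            )


def encode_severity_label(label: str) -> int:
    """Encode an ordinal severity label as its integer 1-4 (Mild=1, Profound=4)."""
    norm = label.strip().capitalize()
    try:
        return LABEL_TO_ORDINAL[norm]
    except KeyError:
        raise ValueError(f"unknown severity label {label!r}") from None


def aggregate_ratings(
    records: Iterable[RatingRecord],
    items: Optional[Sequence[str]] = None,
) -> dict[str, RatingSummary]:
    """Per-item mean/median/min/max/n across respondents.

    Medians of even-sized samples use the midpoint of the two central
    values.  If ``items`` is given, every requested item must have at least
    one record.
    """
    by_item: dict[str, list[float]] = {}
    for r in records:
        by_item.setdefault(r.item_id, []).append(float(r.value))
    if items is not None:
        missing = [i for i in items if i not in by_item]
        if missing:
            raise ValueError(f"no ratings for item(s): {', '.join(missing)}")
        wanted = list(items)
    else:
        wanted = list(by_item)
    out = {}
    for item in wanted:
        vals = np.asarray(by_item[item])
        out[item] = RatingSummary(
            item_id=item,
            mean=float(vals.mean()),
            median=float(np.median(vals)),
            min=float(vals.min()),
            max=float(vals.max()),
            n=int(vals.size),
        )
    return out


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def penetrance_distribution(
    responses: Iterable[PenetranceResponse],
) -> pd.DataFrame:
    """Count and percentage of respondents per penetrance option.

    Percentages are 100 * count / total rounded half-up to one decimal.
    The modal option(s) are flagged in the ``mode`` column.  Options with no
    responses are included with count 0 to keep the table shape stable.
    """
    responses = list(responses)
    if not responses:
        raise ValueError("no penetrance responses")
    total = len(responses)
    counts = {opt: 0 for opt in PENETRANCE_OPTIONS}
    for r in responses:
        counts[r.option] += 1
    peak = max(counts.values())
    df = pd.DataFrame(
        {
            "option": list(PENETRANCE_OPTIONS),
            "count": [counts[o] for o in PENETRANCE_OPTIONS],
        }
    )
    df["percent"] = [_round_half_up(100.0 * c / total) for c in df["count"]]
    df["mode"] = df["count"] == peak
    return df


# ---------------------------------------------------------------------------
# CSV interfaces.  Ratings: respondent_id,item_id,value.  Penetrance:
# respondent_id,option.  Summaries: item,mean,median,min,max,n.


def read_ratings_csv(path: str | Path) -> list[RatingRecord]:
    df = pd.read_csv(path, dtype={"respondent_id": str, "item_id": str})
    required = {"respondent_id", "item_id", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"ratings CSV must have columns {sorted(required)}")
    return [
        RatingRecord(r.respondent_id, r.item_id, int(r.value))
        for r in df.itertuples(index=False)
    ]


def write_ratings_csv(records: Sequence[RatingRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "respondent_id": [r.respondent_id for r in records],
            "item_id": [r.item_id for r in records],
            "value": [r.value for r in records],
        }
    ).to_csv(path, index=False)


def read_penetrance_csv(path: str | Path) -> list[PenetranceResponse]:
    df = pd.read_csv(path, dtype=str)
    required = {"respondent_id", "option"}
    if not required.issubset(df.columns):
        raise ValueError(f"penetrance CSV must have columns {sorted(required)}")
    return [PenetranceResponse(r.respondent_id, r.option) for r in df.itertuples(index=False)]


def write_summary_csv(
    summaries: Mapping[str, RatingSummary], path: str | Path
) -> None:
    rows = [
        {
            "item": s.item_id,
            "mean": s.mean,
            "median": s.median,
            "min": s.min,
            "max": s.max,
            "n": s.n,
        }
        for s in summaries.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_summary_csv(path: str | Path) -> dict[str, RatingSummary]:
    df = pd.read_csv(path, dtype={"item": str})
    return {
        r.item: RatingSummary(
            item_id=r.item,
            mean=float(r.mean),
            median=float(r.median),
            min=float(r.min),
            max=float(r.max),
            n=int(r.n),
        )
        for r in df.itertuples(index=False)
    }
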