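"""Ward minimum-variance hierarchical clustering of one-dimensional ratings.

Characteristics and diseases are grouped on their mean ratings alone, so
the clustering problem is one-dimensional.  The agglomeration is written
out explicitly rather than delegated: at every step the two clusters whose
merger produces the smallest increase in total within-cluster sum of
squares are joined,

    dESS(A, B) = |A| |B| / (|A| + |B|) * (mean_A - mean_B)^2.

Ties are broken deterministically by the lowest input-order index present
in either candidate cluster, then by the other cluster's lowest index, so
repeated runs are bit-reproducible.

Cutting the merge history at k clusters yields characteristic Tiers
(k = 4, Tier 1 = highest mean) or disease severity groups (k = 3, labels
Profound > Severe > Moderate taken from the top of the severity ladder).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .core_model import RatingSummary, TierMap

__all__ = [
    "MergeStep",
    "ClusterCut",
    "ward_linkage",
    "cut",
    "derive_tiers",
    "derive_severity_groups",
    "cost_gap_report",
]

SEVERITY_LADDER: tuple[str, ...] = ("Profound", "Severe", "Moderate", "Mild")


@dataclass(frozen=True)
class MergeStep:
    """One agglomeration step: the two clusters joined and its dESS cost."""

    step_index: int
    left: frozenset
    right: frozenset
    cost: float

    @property
    def merged(self) -> frozenset:
        return self.left | self.right


@dataclass(frozen=True)
class ClusterCut:
    """A partition into k clusters with per-cluster means.

    ``assignment`` maps item id -> cluster index; clusters are indexed in
    descending order of their mean value (cluster 0 has the highest mean).
    """

    k: int
    assignment: Mapping[str, int]
    cluster_means: tuple[float, ...]

    def members(self, cluster_index: int) -> frozenset:
        return frozenset(i for i, c in self.assignment.items() if c == cluster_index)


def ward_linkage(values: Mapping[str, float]) -> list[MergeStep]:
    """Full greedy Ward agglomeration of a 1-D value map; n-1 merge steps."""
    ids = list(values)
    if len(ids) < 2:
        raise ValueError("ward_linkage requires at least 2 items")
    vals = [float(values[i]) for i in ids]
    if not np.all(np.isfinite(vals)):
        raise ValueError("values must be finite")
    order = {item: idx for idx, item in enumerate(ids)}

    # Active clusters as (member frozenset, sum, count); means derived.
    clusters: list[tuple[frozenset, float, int]] = [
        (frozenset([i]), v, 1) for i, v in zip(ids, vals)
    ]
    steps: list[MergeStep] = []
    for step in range(len(ids) - 1):
        best = None
        for a in range(len(clusters)):
            ma, sa, na = clusters[a][1] / clusters[a][2], clusters[a][1], clusters[a][2]
            for b in range(a + 1, len(clusters)):
                mb, nb = clusters[b][1] / clusters[b][2], clusters[b][2]
                cost = na * nb / (na + nb) * (ma - mb) ** 2
                lo_a = min(order[i] for i in clusters[a][0])
                lo_b = min(order[i] for i in clusters[b][0])
                key = (cost, min(lo_a, lo_b), max(lo_a, lo_b))
                if best is None or key < best[0]:
                    best = (key, a, b)
        assert best is not None
        _, a, b = best
        (mem_a, sum_a, n_a), (mem_b, sum_b, n_b) = clusters[a], clusters[b]
        steps.append(
            MergeStep(
                step_index=step,
                left=mem_a,
                right=mem_b,
                cost=float(best[0][0]),
            )
        )
        merged = (mem_a | mem_b, sum_a + sum_b, n_a + n_b)
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return steps


def cut(
    merges: Sequence[MergeStep],
    k: int,
    values: Optional[Mapping[str, float]] = None,
) -> ClusterCut:
    """Partition into k clusters by replaying all but the last k-1 merges.

    ``values`` (the clustered value map) is needed to order clusters by
    mean; without it clusters are ordered by their lowest merge step.
    """
    n = len(merges) + 1
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range [1, {n}]")
    all_ids = set()
    for m in merges:
        all_ids |= m.left | m.right
    parts: list[set] = [{i} for i in sorted(all_ids)]
    for m in merges[: n - k]:
        left = next(p for p in parts if p >= m.left)
        right = next(p for p in parts if p >= m.right)
        parts.remove(left)
        parts.remove(right)
        parts.append(left | right)
    if values is not None:
        means = [float(np.mean([values[i] for i in p])) for p in parts]
    else:
        means = [float(-min(sorted(all_ids).index(i) for i in p)) for p in parts]
    rank = np.argsort(means)[::-1]
    assignment: dict[str, int] = {}
    ordered_means = []
    for new_idx, old_idx in enumerate(rank):
        ordered_means.append(means[old_idx])
        for item in parts[old_idx]:
            assignment[item] = new_idx
    return ClusterCut(k=k, assignment=assignment, cluster_means=tuple(ordered_means))


def derive_tiers(
    summaries: Mapping[str, RatingSummary],
    k: int = 4,
    modifiers: frozenset = frozenset(),
    include_modifiers: bool = True,
) -> TierMap:
    """Cluster characteristic mean ratings into importance Tiers 1..k.

    All 15 items, modifiers included, enter the clustering by default; the
    modifiers are merely marked so the classifier can ignore them later.
    With ``include_modifiers=False`` the modifiers are left out entirely
    (both readings give identical core-characteristic tiers on the
    reference ratings).
    """
    values = {
        item: s.mean
        for item, s in summaries.items()
        if include_modifiers or item not in modifiers
    }
    if len(values) < k:
        raise ValueError(f"need at least k={k} items, got {len(values)}")
    cut_k = cut(ward_linkage(values), k, values)
    assignment = {item: c + 1 for item, c in cut_k.assignment.items()}
    cluster_means = {c + 1: m for c, m in enumerate(cut_k.cluster_means)}
    return TierMap(
        assignment=assignment,
        modifiers=frozenset(m for m in modifiers if m in values),
        provenance="derived",
        cluster_means=cluster_means,
    )


def derive_severity_groups(
    summaries: Mapping[str, RatingSummary],
    k: int = 3,
) -> dict[str, str]:
    """Cluster disease mean severity ratings into k ordinal groups.

    Labels are taken from the top of the Profound > Severe > Moderate >
    Mild ladder in descending cluster-mean order; with k = 3 the lowest
    cluster is Moderate (no surveyed disease rated low enough for Mild).
    """
    if not (1 <= k <= len(SEVERITY_LADDER)):
        raise ValueError(f"k={k} outside [1, {len(SEVERITY_LADDER)}]")
    values = {item: s.mean for item, s in summaries.items()}
    if len(values) < k:
        raise ValueError(f"need at least k={k} diseases, got {len(values)}")
    cut_k = cut(ward_linkage(values), k, values)
    return {item: SEVERITY_LADDER[c] for item, c in cut_k.assignment.items()}


def cost_gap_report(merges: Sequence[MergeStep]) -> list[dict]:
    """Diagnostic: merge costs and the k each step's undoing would produce.

    The largest cost late in the agglomeration suggests a natural number of
    clusters; this is reported only, never used to choose k.
    """
    n = len(merges) + 1
    return [
        {"step": m.step_index, "k_after_undo": n - m.step_index, "cost": m.cost}
        for m in merges
    ]
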