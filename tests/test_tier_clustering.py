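"""Ward clustering: merge costs, cuts, tier and severity-group derivation."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage

from sevtier import cut, derive_severity_groups, derive_tiers, ward_linkage


def brute_force_first_merge(values):
    """Oracle: evaluate dESS for every candidate pair directly."""
    best = None
    for a, b in itertools.combinations(values, 2):
        cost = 0.5 * (values[a] - values[b]) ** 2  # singletons: 1*1/2
        if best is None or cost < best[1]:
            best = (frozenset([a, b]), cost)
    return best


class TestWardLinkage:
    def test_first_merge_matches_brute_force(self):
        values = {"a": 1.0, "b": 2.0, "c": 10.0}
        expected_pair, expected_cost = brute_force_first_merge(values)
        steps = ward_linkage(values)
        assert steps[0].merged == expected_pair == {"a", "b"}
        assert steps[0].cost == pytest.approx(expected_cost) == pytest.approx(0.5)

    def test_two_equal_items_merge_at_zero_cost(self):
        steps = ward_linkage({"a": 5.0, "b": 5.0})
        assert len(steps) == 1
        assert steps[0].cost == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_total_cost_telescopes_to_tss(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 10, size=10)
        values = {f"i{j}": v for j, v in enumerate(vals)}
        steps = ward_linkage(values)
        tss = float(((vals - vals.mean()) ** 2).sum())
        assert sum(s.cost for s in steps) == pytest.approx(tss)

    def test_fewer_than_two_items_rejected(self):
        with pytest.raises(ValueError):
            ward_linkage({"a": 1.0})

    def test_deterministic_under_ties(self):
        values = {"a": 1.0, "b": 3.0, "c": 5.0}  # (a,b) and (b,c) tie at 2.0
        steps1 = ward_linkage(values)
        steps2 = ward_linkage(values)
        assert steps1 == steps2
        assert steps1[0].merged == {"a", "b"}  # lowest input index wins


class TestCut:
    def test_extreme_cuts(self, characteristic_summaries):
        values = {i: s.mean for i, s in characteristic_summaries.items()}
        merges = ward_linkage(values)
        singles = cut(merges, 15, values)
        assert all(len(singles.members(c)) == 1 for c in range(15))
        whole = cut(merges, 1, values)
        assert whole.members(0) == frozenset(values)

    def test_k_out_of_range(self):
        merges = ward_linkage({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError):
            cut(merges, 0)
        with pytest.raises(ValueError):
            cut(merges, 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_clusters_are_contiguous_intervals_on_reference_style_data(self, seed):
        # 1-D Ward at any k on these data yields contiguous blocks of the
        # sorted values; verified on random vectors shaped like the ratings.
        rng = np.random.default_rng(seed)
        vals = np.sort(rng.uniform(1, 10, size=15))[::-1]
        values = {f"i{j}": float(v) for j, v in enumerate(vals)}
        merges = ward_linkage(values)
        for k in (3, 4):
            cu = cut(merges, k, values)
            for c in range(k):
                member_vals = sorted(values[i] for i in cu.members(c))
                others = [values[i] for i in values if i not in cu.members(c)]
                assert not any(member_vals[0] < o < member_vals[-1] for o in others)


class TestOracleEquivalence:
    def test_partitions_match_reference_ward_at_all_k(self):
        # Independent reference: scipy's Lance-Williams Ward linkage.
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(2, 9))
            vals = rng.uniform(0, 10, size=n)
            while len(set(vals.tolist())) < n:
                vals = rng.uniform(0, 10, size=n)
            ids = [f"i{j}" for j in range(n)]
            values = dict(zip(ids, vals.tolist()))
            merges = ward_linkage(values)
            Z = linkage(vals.reshape(-1, 1), method="ward")
            for k in range(1, n + 1):
                mine = cut(merges, k, values)
                ref_labels = fcluster(Z, t=k, criterion="maxclust")
                mine_part = {
                    frozenset(mine.members(c)) for c in range(k)
                }
                ref_part = {
                    frozenset(ids[j] for j in range(n) if ref_labels[j] == lab)
                    for lab in set(ref_labels)
                }
                assert mine_part == ref_part


class TestDeriveTiers:
    def test_reference_ratings_recover_published_tiers(
        self, characteristic_summaries, packaged_tier_map
    ):
        derived = derive_tiers(
            characteristic_summaries, k=4, modifiers=packaged_tier_map.modifiers
        )
        assert derived.provenance == "derived"
        assert dict(derived.assignment) == dict(packaged_tier_map.assignment)

    def test_tier1_and_tier4_memberships(self, characteristic_summaries, packaged_tier_map):
        derived = derive_tiers(
            characteristic_summaries, k=4, modifiers=packaged_tier_map.modifiers
        )
        tier1 = {i for i, t in derived.assignment.items() if t == 1}
        tier4 = {i for i, t in derived.assignment.items() if t == 4}
        assert tier1 == {"le_infancy", "le_childhood_adolescence", "intellectual_disability"}
        assert tier4 == {"reduced_fertility"}

    def test_modifiers_cocluster_as_published(self, characteristic_summaries, packaged_tier_map):
        derived = derive_tiers(
            characteristic_summaries, k=4, modifiers=packaged_tier_map.modifiers
        )
        assert derived.assignment["availability_of_treatment"] == 2
        assert derived.assignment["variable_expressivity"] == 3
        assert derived.classification_tier("availability_of_treatment") is None

    def test_excluding_modifiers_gives_same_core_tiers(
        self, characteristic_summaries, packaged_tier_map
    ):
        with_mods = derive_tiers(
            characteristic_summaries, k=4, modifiers=packaged_tier_map.modifiers
        )
        without = derive_tiers(
            characteristic_summaries,
            k=4,
            modifiers=packaged_tier_map.modifiers,
            include_modifiers=False,
        )
        for cid in without.assignment:
            assert without.assignment[cid] == with_mods.assignment[cid]

    def test_tier_mean_bands(self, characteristic_summaries, packaged_tier_map):
        # Tier means sit in the described bands: >9, around 8, 6-7, below 6.
        derived = derive_tiers(
            characteristic_summaries, k=4, modifiers=packaged_tier_map.modifiers
        )
        means = {i: characteristic_summaries[i].mean for i in derived.assignment}
        for cid, tier in derived.assignment.items():
            if tier == 1:
                assert means[cid] > 9
            elif tier == 2:
                assert 7.71 <= means[cid] <= 8.07
            elif tier == 3:
                assert 6.14 <= means[cid] <= 6.98
            else:
                assert means[cid] < 6

    def test_too_few_items_rejected(self, characteristic_summaries):
        two = dict(list(characteristic_summaries.items())[:2])
        with pytest.raises(ValueError):
            derive_tiers(two, k=4)


class TestDeriveSeverityGroups:
    def test_reference_ratings_recover_published_groups(
        self, disease_summaries, survey_groups
    ):
        assert derive_severity_groups(disease_summaries, k=3) == survey_groups

    def test_moderate_group_membership(self, disease_summaries):
        groups = derive_severity_groups(disease_summaries, k=3)
        moderate = {d for d, g in groups.items() if g == "Moderate"}
        assert moderate == {"gjb2_deafness", "a1at_deficiency"}

    def test_profound_block_and_usher(self, disease_summaries):
        groups = derive_severity_groups(disease_summaries, k=3)
        profound = {d for d, g in groups.items() if g == "Profound"}
        assert profound == {"canavan", "slos", "citrullinemia_1", "pompe", "galactosemia"}
        assert groups["usher_1f"] == "Severe"

    def test_two_diseases_higher_mean_higher_label(self):
        from sevtier.core_model import RatingSummary

        summaries = {
            "hi": RatingSummary("hi", 4.0, 4, 4, 4, 5),
            "lo": RatingSummary("lo", 1.0, 1, 1, 1, 5),
        }
        groups = derive_severity_groups(summaries, k=2)
        assert groups == {"hi": "Profound", "lo": "Severe"}
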