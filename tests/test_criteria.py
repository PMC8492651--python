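import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenocriteria.criteria import (
    MAX_AGE_MONTHS,
    CriteriaDefinition,
    ParticipantProfile,
    TermGroup,
    age_first_met,
    existing_criteria_definition,
    get_criteria,
    group_satisfied,
    meets_criteria,
    proposed_criteria_definition,
    read_cohort,
    score_proposed,
    write_cohort,
)

MAJOR_TERMS = ["HP:0010603", "HP:0010610", "HP:0005462", "HP:0002671"]
MINOR_TERMS = [  # one representative per minor group
    "HP:0002885",
    "HP:0000256",
    "HP:0000175",
    "HP:0010442",
    "HP:0000925",
    "HP:0000518",
]


def profile(*features, fh=False, mdx=False, pid="p"):
    return ParticipantProfile(
        id=pid,
        features=tuple(features),
        family_history_first_degree=fh,
        molecular_diagnosis=mdx,
    )


class TestDefinitions:
    def test_existing_major_slots(self):
        defn = existing_criteria_definition()
        assert defn.n_major_slots == 5  # 4 coded groups + family history
        assert len(defn.tiers[0].groups) == 4

    def test_existing_minor_groups(self):
        assert len(existing_criteria_definition().tiers[1].groups) == 6

    def test_existing_variants(self):
        assert existing_criteria_definition("methods").sufficient_combinations == (
            (2, 1),
            (1, 3),
        )
        assert existing_criteria_definition("table").sufficient_combinations == (
            (2, 0),
            (1, 2),
        )
        with pytest.raises(ValueError):
            existing_criteria_definition("consensus")

    def test_proposed_tier_shape(self):
        defn = proposed_criteria_definition()
        assert [len(t.groups) for t in defn.tiers] == [6, 3, 7]
        assert [t.weight for t in defn.tiers] == [3, 2, 1]
        assert defn.threshold == 6
        assert defn.family_history_role == "standalone_trigger"

    def test_all_coded_ids_canonical(self):
        for defn in (existing_criteria_definition(), proposed_criteria_definition()):
            for t in defn.all_terms():
                assert len(t.split(":")[1]) == 7

    def test_all_coded_ids_in_mini_ontology(self, mini_ont):
        for defn in (existing_criteria_definition(), proposed_criteria_definition()):
            for t in defn.all_terms():
                assert t in mini_ont

    def test_duplicate_group_rejected(self):
        g = TermGroup(terms=frozenset({"HP:0000256"}))
        from phenocriteria.criteria import Tier

        with pytest.raises(ValueError, match="duplicate"):
            CriteriaDefinition(
                name="dup",
                kind="points",
                tiers=(Tier("a", (g,), 1), Tier("b", (g,), 2)),
                family_history_role="standalone_trigger",
                threshold=3,
            )

    def test_json_roundtrip(self, tmp_path):
        defn = proposed_criteria_definition()
        path = tmp_path / "criteria.json"
        defn.to_json(path)
        assert CriteriaDefinition.from_json(path) == defn
        assert get_criteria(str(path)) == defn

    def test_get_criteria_names(self):
        assert get_criteria("existing").name == "existing-methods"
        assert get_criteria("existing-table").name == "existing-table"
        assert get_criteria("proposed").kind == "points"
        with pytest.raises(ValueError):
            get_criteria("nonexistent")


class TestGroupSatisfied:
    gu_group = TermGroup(terms=frozenset({"HP:0000107", "HP:0000104"}), label="gu")

    def test_direct_member_at_age(self, mini_ont):
        p = profile(("HP:0000104", 0))
        assert group_satisfied(p, self.gu_group, mini_ont, 0)

    def test_unknown_onset_counts_only_age_free(self, mini_ont):
        p = profile(("HP:0000104", None))
        assert group_satisfied(p, self.gu_group, mini_ont, "any")
        assert not group_satisfied(p, self.gu_group, mini_ont, 60)

    def test_descendant_matches_group(self, mini_ont):
        macro = TermGroup(terms=frozenset({"HP:0000256"}))
        p = profile(("HP:0004482", 2))  # descendant of macrocephaly
        assert group_satisfied(p, macro, mini_ont, 2)
        assert not group_satisfied(p, macro, mini_ont, 1)

    def test_onset_after_age_excluded(self, mini_ont):
        p = profile(("HP:0000104", 24))
        assert not group_satisfied(p, self.gu_group, mini_ont, 23)
        assert group_satisfied(p, self.gu_group, mini_ont, 24)


class TestScoreProposed:
    def test_two_cardinal_features(self, mini_ont):
        p = profile(("HP:0010603", 100), ("HP:0010610", 80))
        assert score_proposed(p, mini_ont, "any") == 6

    def test_three_suggestive_features(self, mini_ont):
        p = profile(("HP:0002885", 10), ("HP:0000256", 1), ("HP:0000925", 0))
        assert score_proposed(p, mini_ont, "any") == 6

    def test_one_of_each_tier(self, mini_ont):
        p = profile(("HP:0010603", 100), ("HP:0000256", 1), ("HP:0000486", 12))
        assert score_proposed(p, mini_ont, "any") == 6

    def test_group_counts_once(self, mini_ont):
        # two distinct cleft terms still score a single possible point
        p = profile(("HP:0000175", 0), ("HP:0410030", 0))
        assert score_proposed(p, mini_ont, "any") == 1

    def test_age_resolved(self, mini_ont):
        p = profile(("HP:0010603", 100), ("HP:0010610", 80))
        assert score_proposed(p, mini_ont, 79) == 0
        assert score_proposed(p, mini_ont, 80) == 3
        assert score_proposed(p, mini_ont, 100) == 6

    def test_requires_points_kind(self, mini_ont):
        with pytest.raises(ValueError):
            score_proposed(profile(), mini_ont, "any", existing_criteria_definition())

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_adding_feature_never_decreases_score(self, mini_ont, data):
        pool = MAJOR_TERMS + MINOR_TERMS + ["HP:0000486", "HP:0000365", "HP:0000098"]
        base_terms = data.draw(st.lists(st.sampled_from(pool), max_size=5))
        extra = data.draw(st.sampled_from(pool))
        base = profile(*[(t, 10) for t in base_terms])
        bigger = profile(*([(t, 10) for t in base_terms] + [(extra, 10)]))
        assert score_proposed(bigger, mini_ont, "any") >= score_proposed(
            base, mini_ont, "any"
        )

    def test_duplicate_features_idempotent(self, mini_ont):
        p1 = profile(("HP:0010603", 50))
        p2 = profile(("HP:0010603", 50), ("HP:0010603", 50))
        for age in ("any", 50, 216):
            assert score_proposed(p1, mini_ont, age) == score_proposed(p2, mini_ont, age)


class TestMeetsCriteria:
    def test_methods_rule(self, mini_ont):
        defn = existing_criteria_definition("methods")
        two_maj_one_min = profile(
            ("HP:0010603", 1), ("HP:0002671", 1), ("HP:0000256", 1)
        )
        one_maj_three_min = profile(
            ("HP:0010603", 1), ("HP:0000256", 1), ("HP:0000175", 1), ("HP:0000925", 1)
        )
        one_maj_two_min = profile(("HP:0010603", 1), ("HP:0000256", 1), ("HP:0000175", 1))
        assert meets_criteria(two_maj_one_min, defn, mini_ont, "any", False, False)
        assert meets_criteria(one_maj_three_min, defn, mini_ont, "any", False, False)
        assert not meets_criteria(one_maj_two_min, defn, mini_ont, "any", False, False)

    def test_table_variant_rule(self, mini_ont):
        defn = existing_criteria_definition("table")
        one_maj_two_min = profile(("HP:0010603", 1), ("HP:0000256", 1), ("HP:0000175", 1))
        two_maj = profile(("HP:0010603", 1), ("HP:0002671", 1))
        one_maj_mdx = profile(("HP:0010603", 1), mdx=True)
        assert meets_criteria(one_maj_two_min, defn, mini_ont, "any", False, False)
        assert meets_criteria(two_maj, defn, mini_ont, "any", False, False)
        assert meets_criteria(one_maj_mdx, defn, mini_ont, "any", False, True)
        assert not meets_criteria(one_maj_mdx, defn, mini_ont, "any", False, False)

    def test_family_history_counts_as_major(self, mini_ont):
        defn = existing_criteria_definition("methods")
        # 1 coded major + FH major + 1 minor -> meets (2, 1)
        p = profile(("HP:0010603", 1), ("HP:0000256", 1), fh=True)
        assert meets_criteria(p, defn, mini_ont, "any", True, False)
        assert not meets_criteria(p, defn, mini_ont, "any", False, False)

    def test_family_history_standalone_trigger(self, mini_ont):
        defn = proposed_criteria_definition()
        p = profile(fh=True)
        assert meets_criteria(p, defn, mini_ont, "any", True, False)
        assert not meets_criteria(p, defn, mini_ont, "any", False, False)

    def test_points_threshold(self, mini_ont):
        defn = proposed_criteria_definition()
        five_points = profile(("HP:0010603", 1), ("HP:0000256", 1))  # 3 + 2
        six_points = profile(("HP:0010603", 1), ("HP:0010610", 1))  # 3 + 3
        assert not meets_criteria(five_points, defn, mini_ont, "any", False, False)
        assert meets_criteria(six_points, defn, mini_ont, "any", False, False)

    def test_age_monotone(self, mini_ont):
        rng = np.random.default_rng(17)
        pool = MAJOR_TERMS + MINOR_TERMS
        for defn in (existing_criteria_definition(), proposed_criteria_definition()):
            for _ in range(20):
                feats = [
                    (t, int(rng.integers(0, 217)))
                    for t in rng.choice(pool, size=4, replace=False)
                ]
                p = profile(*feats, fh=bool(rng.random() < 0.3))
                prev = False
                for age in range(0, 217, 9):
                    now = meets_criteria(p, defn, mini_ont, age, True, False)
                    assert now or not prev  # once true, stays true
                    prev = now


class TestAgeFirstMet:
    def test_max_of_required_onsets(self, mini_ont):
        defn = proposed_criteria_definition()
        p = profile(("HP:0010603", 24), ("HP:0010610", 60))
        assert age_first_met(p, defn, mini_ont, False, False) == 60

    def test_family_history_from_birth(self, mini_ont):
        p = profile(fh=True)
        assert age_first_met(p, proposed_criteria_definition(), mini_ont, True, False) == 0

    def test_never_met_returns_none(self, mini_ont):
        p = profile(("HP:0000365", 12))
        assert age_first_met(p, proposed_criteria_definition(), mini_ont, False, False) is None

    def test_agrees_with_monthly_brute_force(self, mini_ont):
        rng = np.random.default_rng(31)
        pool = MAJOR_TERMS + MINOR_TERMS + ["HP:0000486", "HP:0000365", "HP:0000098"]
        defns = (
            existing_criteria_definition("methods"),
            existing_criteria_definition("table"),
            proposed_criteria_definition(),
        )
        for _ in range(25):
            n_feat = int(rng.integers(0, 6))
            feats = [
                (t, None if rng.random() < 0.2 else int(rng.integers(0, 230)))
                for t in rng.choice(pool, size=n_feat, replace=False)
            ]
            p = profile(
                *feats,
                fh=bool(rng.random() < 0.3),
                mdx=bool(rng.random() < 0.3),
            )
            for defn in defns:
                for use_fh, use_mol in ((True, True), (False, False), (True, False)):
                    oracle = next(
                        (
                            m
                            for m in range(MAX_AGE_MONTHS + 1)
                            if meets_criteria(p, defn, mini_ont, m, use_fh, use_mol)
                        ),
                        None,
                    )
                    assert age_first_met(p, defn, mini_ont, use_fh, use_mol) == oracle


class TestCohortIO:
    def test_roundtrip(self, tmp_path):
        cohort = [
            profile(("HP:0010603", 24), ("HP:0000256", None), fh=True, pid="p1"),
            profile(pid="p2", mdx=True),
            profile(("HP:0000365", 0), pid="p3"),
        ]
        path = tmp_path / "cohort.tsv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        assert back == cohort

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("participant_id\thpo_id\np1\tHP:0000256\n", encoding="utf-8")
        with pytest.raises(ValueError, match="missing required column"):
            read_cohort(path)
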