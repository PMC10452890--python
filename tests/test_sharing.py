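"""Familial sharing classification against brute-force set algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskcluster.sharing import (
    SharingClass,
    classify_sharing,
    count_by_class,
    classify_records,
    is_exclusive_and_shared,
    presence_map,
    write_sharing_tsv,
)

GROUPS = {"HRLS": {"h1", "h2", "h3"},
          "IRLS": {"i1", "i2", "i3", "i4"},
          "LRLS": {"l1", "l2", "l3", "l4", "l5", "l6"}}
ROSTER = sorted(s for m in GROUPS.values() for s in m)


def _presence(carriers):
    return {s: s in carriers for s in ROSTER}


class TestClassification:
    def test_present_everywhere_is_shared_all_and_within_each_group(self):
        classes = classify_sharing(_presence(set(ROSTER)), GROUPS)
        assert SharingClass("shared_all_samples") in classes
        for g in GROUPS:
            assert SharingClass("shared_within_group", g) in classes

    def test_shared_within_two_groups_only(self):
        carriers = GROUPS["HRLS"] | GROUPS["IRLS"]
        classes = classify_sharing(_presence(carriers), GROUPS)
        assert classes == {SharingClass("shared_within_group", "HRLS"),
                           SharingClass("shared_within_group", "IRLS")}

    def test_single_carrier_is_exclusive(self):
        classes = classify_sharing(_presence({"l3"}), GROUPS)
        assert classes == {SharingClass("exclusive_to_group", "LRLS")}

    def test_full_group_is_both_shared_and_exclusive(self):
        classes = classify_sharing(_presence(GROUPS["LRLS"]), GROUPS)
        assert classes == {SharingClass("shared_within_group", "LRLS"),
                           SharingClass("exclusive_to_group", "LRLS")}
        assert is_exclusive_and_shared(_presence(GROUPS["LRLS"]), GROUPS, "LRLS")
        assert not is_exclusive_and_shared(_presence({"l1"}), GROUPS, "LRLS")

    def test_absent_everywhere_is_other_not_dropped(self):
        assert classify_sharing(_presence(set()), GROUPS) == {SharingClass("other")}

    def test_empty_roster_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            classify_sharing({}, {"HRLS": set(), "IRLS": set(), "LRLS": set()})

    def test_uncovered_subject_is_error(self):
        with pytest.raises(ValueError, match="undefined"):
            classify_sharing({"h1": True}, GROUPS)


class TestInvariants:
    def test_shared_all_implies_within_every_group_randomized(self):
        rng = np.random.default_rng(11)
        for _ in range(500):
            carriers = {s for s in ROSTER if rng.random() < 0.5}
            classes = classify_sharing(_presence(carriers), GROUPS)
            if SharingClass("shared_all_samples") in classes:
                for g in GROUPS:
                    assert SharingClass("shared_within_group", g) in classes
            # exclusivity to g excludes within-h for any other h
            for c in classes:
                if c.kind == "exclusive_to_group":
                    assert not any(
                        d.kind == "shared_within_group" and d.group != c.group
                        for d in classes)

    @settings(derandomize=True, max_examples=300)
    @given(st.frozensets(st.sampled_from(ROSTER)))
    def test_every_carrier_set_classified_consistently(self, carriers):
        """For any carrier subset: the class set is nonempty, mutually
        consistent, and a superset pattern never loses a within-group
        class it already implies."""
        classes = classify_sharing(_presence(set(carriers)), GROUPS)
        assert classes
        kinds = {c.kind for c in classes}
        if "shared_all_samples" in kinds:
            assert {c.group for c in classes if c.kind == "shared_within_group"} \
                == set(GROUPS)
        if kinds == {"other"}:
            assert not any(m <= set(carriers) for m in GROUPS.values())
        # adding a carrier preserves every within-group class
        if len(carriers) < len(ROSTER):
            extra = next(s for s in ROSTER if s not in carriers)
            grown = classify_sharing(_presence(set(carriers) | {extra}), GROUPS)
            assert {c for c in classes if c.kind == "shared_within_group"} <= grown

    def test_brute_force_subset_evaluation(self):
        """Direct set-algebra re-derivation on random presence vectors."""
        rng = np.random.default_rng(5)
        for _ in range(2000):
            carriers = {s for s in ROSTER if rng.random() < rng.uniform(0.05, 0.95)}
            classes = classify_sharing(_presence(carriers), GROUPS)
            expected = set()
            if carriers == set(ROSTER):
                expected.add(SharingClass("shared_all_samples"))
            for g, members in GROUPS.items():
                if members <= carriers:
                    expected.add(SharingClass("shared_within_group", g))
                if carriers and carriers <= members:
                    expected.add(SharingClass("exclusive_to_group", g))
            if not expected:
                expected.add(SharingClass("other"))
            assert classes == expected


class TestCounting:
    def test_multiplicity_convention(self):
        # two variants shared everywhere + one HRLS-exclusive
        sharing = {
            "v1": classify_sharing(_presence(set(ROSTER)), GROUPS),
            "v2": classify_sharing(_presence(set(ROSTER)), GROUPS),
            "v3": classify_sharing(_presence({"h1"}), GROUPS),
        }
        counts = count_by_class(sharing)
        assert counts.shared_all == 2
        assert counts.shared_within_total == 6  # 2 variants x 3 groups
        assert counts.exclusive["HRLS"] == 1
        assert counts.shared_within_total >= counts.shared_all * len(GROUPS)

    def test_study_coding_occurrences(self, table3):
        """The published per-group shared coding tallies (HRLS 37, LRLS 15)."""
        coding = [r for r, row in zip(table3.records, table3.expected)
                  if row["track"] == "coding"]
        sharing = classify_records(coding, table3.subject_order, table3.groups)
        counts = count_by_class(sharing)
        assert counts.shared_within["HRLS"] == 37
        assert counts.shared_within["LRLS"] == 15

    def test_output_tsv_stable(self, tmp_path):
        sharing = {"v1": classify_sharing(_presence({"h1"}), GROUPS)}
        out = tmp_path / "sharing.tsv"
        write_sharing_tsv(sharing, out)
        assert "exclusive_to_group(HRLS)" in out.read_text()


class TestPresenceMap:
    def test_length_mismatch_rejected(self, cohort):
        rec = cohort.small_records[0]
        with pytest.raises(ValueError, match="length"):
            presence_map(rec, cohort.subject_order[:-1])
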