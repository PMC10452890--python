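"""Small-variant prioritization cascade: boundaries, oracles, invariants."""

from itertools import product

import numpy as np
import pytest

from riskcluster.sharing import SharingClass, classify_records
from riskcluster.small_variants import (
    CascadeTrace,
    SmallVariantThresholds,
    filter_af,
    filter_cadd,
    filter_deleterious_consensus,
    filter_regulome,
    first_failing_stage,
    run_cascade,
    stratify_region,
    tabulate_regions,
)
from riskcluster.variants import (
    DELETERIOUS,
    MISSING,
    PREDICTOR_TOOLS,
    REGION_CLASSES,
    TOLERATED,
    SmallVariantRecord,
)

T = SmallVariantThresholds()


def _rec(**kw):
    base = dict(chrom="1", pos=1, ref="A", alt="T")
    base.update(kw)
    return SmallVariantRecord(**base)


class TestAFFilter:
    def test_rare_with_one_panel_missing_kept(self):
        # a retained study variant: panel AF 0.0054, other panel unseen
        rec = _rec(af_1000g=0.0054, af_exac_nontcga=None)
        assert filter_af([rec]) == [rec]

    def test_common_removed(self):
        assert filter_af([_rec(af_1000g=0.5)]) == []

    def test_boundary_af_fails_strict(self):
        assert filter_af([_rec(af_1000g=0.01)]) == []

    def test_either_panel_common_removes(self):
        assert filter_af([_rec(af_1000g=0.001, af_exac_nontcga=0.02)]) == []

    def test_both_missing_passes_as_novel(self):
        assert len(filter_af([_rec()])) == 1


class TestCADDFilter:
    @pytest.mark.parametrize("cadd,kept", [(10.0, False), (25.3, True),
                                           (None, False), (9.99, False),
                                           (10.01, True)])
    def test_strict_threshold_and_missing(self, cadd, kept):
        assert bool(filter_cadd([_rec(cadd_phred=cadd)])) == kept


class TestRegionStratification:
    def test_exonic_is_coding(self):
        coding, noncoding = stratify_region([_rec(region="exonic")])
        assert len(coding) == 1 and not noncoding

    def test_intronic_is_noncoding(self):
        coding, noncoding = stratify_region([_rec(region="intronic")])
        assert len(noncoding) == 1 and not coding

    def test_partition_over_random_labels(self):
        rng = np.random.default_rng(3)
        recs = [_rec(pos=i, region=REGION_CLASSES[rng.integers(len(REGION_CLASSES))])
                for i in range(200)]
        coding, noncoding = stratify_region(recs)
        assert len(coding) + len(noncoding) == len(recs)
        assert {id(r) for r in coding} | {id(r) for r in noncoding} == {id(r) for r in recs}


class TestConsensusFilter:
    def test_exhaustive_call_combinations_match_enumeration(self):
        """All 3^4 predictor call combinations against direct counting."""
        for calls in product((DELETERIOUS, TOLERATED, MISSING), repeat=4):
            rec = _rec(predictors=dict(zip(PREDICTOR_TOOLS, calls)))
            expected = sum(c == DELETERIOUS for c in calls) >= 3
            assert bool(filter_deleterious_consensus([rec])) is expected

    def test_quorum_parameter_respected(self):
        rec = _rec(predictors=dict(zip(PREDICTOR_TOOLS,
                                       (DELETERIOUS, DELETERIOUS, MISSING, MISSING))))
        assert not filter_deleterious_consensus([rec])
        loose = SmallVariantThresholds(predictor_quorum=2)
        assert filter_deleterious_consensus([rec], loose)


class TestRegulomeGate:
    @pytest.mark.parametrize("rank,kept", [(2, True), (3, True), (4, False),
                                           (None, False)])
    def test_strict_threshold(self, rank, kept):
        assert bool(filter_regulome([_rec(regulomedb=rank)])) == kept

    def test_four_of_fourteen_lrls_exclusives_survive(self):
        """Mirrors the study's 14 group-exclusive noncoding variants of
        which 4 carried a regulatory-evidence rank below 4."""
        ranks = [1, 2, 2, 3] + [4, 5, 6, 7, 4, 5, 6, 7, 5, 6]
        recs = [_rec(pos=i, region="intronic", regulomedb=r)
                for i, r in enumerate(ranks, 1)]
        assert len(filter_regulome(recs)) == 4


class TestCascadeProperties:
    def test_monotone_counts_and_conservation(self, cohort):
        result = run_cascade(cohort.small_records)
        counts = [n for _, n in result.trace.as_rows()]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        # stage trace refuses non-monotone updates
        trace = CascadeTrace()
        trace.record("a", 5)
        with pytest.raises(AssertionError):
            trace.record("b", 6)

    def test_order_invariance(self, cohort):
        records = cohort.small_records
        result = run_cascade(records)
        shuffled = list(records)[::-1]
        result2 = run_cascade(shuffled)
        assert {r.variant_id for r in result.coding} == {r.variant_id for r in result2.coding}
        assert {r.variant_id for r in result.noncoding} == {r.variant_id for r in result2.noncoding}
        assert result.trace.as_rows()[-1] == result2.trace.as_rows()[-1]

    def test_equals_single_pass_brute_force(self, cohort):
        """Pipeline output equals one brute-force predicate sweep."""
        records = cohort.small_records
        result = run_cascade(records)
        survivors = {r.variant_id for r in result.coding + result.noncoding}
        brute = set()
        for r in records:
            af_ok = (r.af_1000g is None or r.af_1000g < 0.01) and \
                (r.af_exac_nontcga is None or r.af_exac_nontcga < 0.01)
            cadd_ok = r.cadd_phred is not None and r.cadd_phred > 10
            votes = sum(c == DELETERIOUS for c in r.predictors.values())
            if af_ok and cadd_ok and votes >= 3:
                brute.add(r.variant_id)
        assert survivors == brute

    def test_planted_first_failures_recovered(self, cohort):
        truth = {t.variant_id: t.first_failure for t in cohort.truth
                 if t.track == "small"}
        for rec in cohort.small_records:
            assert first_failing_stage(rec) == truth[rec.variant_id]


class TestRegionTabulation:
    def test_empty_input_gives_zero_table(self):
        table = tabulate_regions([], {})
        assert all(v == 0 for row in table.values() for v in row.values())

    def test_group_shared_intergenic_counted(self, study_pedigree):
        from riskcluster.pedigree import groups_map, sequenced_order

        order = sequenced_order(study_pedigree)
        groups = groups_map(study_pedigree)
        hrls = groups["HRLS"]
        recs = [_rec(pos=i, region="intergenic",
                     presence=tuple(s in hrls for s in order))
                for i in range(10)]
        sharing = classify_records(recs, order, groups)
        table = tabulate_regions(recs, sharing)
        assert table["Intergenic"]["within_group"] == 10
        assert table["Intergenic"]["all_subjects"] == 0

    def test_matches_brute_force_cross_tab(self, cohort):
        from riskcluster.pedigree import RISK_GROUPS
        from riskcluster.small_variants import NONCODING_REGION_ROWS

        order = cohort.subject_order
        groups = {g: set(m) for g, m in cohort.groups.items()}
        noncoding = [r for r in cohort.small_records if r.region != "exonic"]
        sharing = classify_records(noncoding, order, groups)
        table = tabulate_regions(noncoding, sharing)
        region_to_row = dict(NONCODING_REGION_ROWS)
        for row in set(region_to_row.values()):
            all_n = wg_n = 0
            for r in noncoding:
                if region_to_row[r.region] != row:
                    continue
                carriers = {s for s, p in zip(order, r.presence) if p}
                if carriers == set(order):
                    all_n += 1
                elif any(groups[g] and groups[g] <= carriers for g in RISK_GROUPS):
                    wg_n += 1
            assert table[row]["all_subjects"] == all_n
            assert table[row]["within_group"] == wg_n
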