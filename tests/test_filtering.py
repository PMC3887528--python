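"""Hard filters, high-confidence set construction and the exclusion cascade."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popld.filtering import (
    CASCADE_STAGES,
    FilterLedger,
    HardFilterThresholds,
    build_high_confidence_set,
    cascade_filter,
    hard_filter,
    ledger_report,
    minor_allele_carriers,
)
from tests.conftest import make_record

PASSING = {
    "QUAL": 100.0,
    "QD": 20.0,
    "MQ": 50.0,
    "FS": 10.0,
    "HaplotypeScore": 5.0,
    "MQRankSum": 0.0,
    "ReadPosRankSum": 0.0,
    "DP": 200,
}


def rec_with(ann_overrides=None, **kwargs):
    ann = dict(PASSING)
    if ann_overrides:
        ann.update(ann_overrides)
    return make_record(annotations=ann, **kwargs)


class TestHardFilter:
    def test_low_qd_fails_with_reason(self):
        ok, reasons = hard_filter(rec_with({"QD": 1.5}), HardFilterThresholds())
        assert not ok and reasons == ["QD"]

    @pytest.mark.parametrize(
        "tag,value,should_fail",
        [
            ("QD", 2.0, False),  # strict: fails only below 2.0
            ("QD", 1.999, True),
            ("MQ", 40.0, False),  # MQ = 40 exactly passes
            ("MQ", 39.9, True),
            ("FS", 60.0, False),  # fails only above 60
            ("FS", 60.1, True),
            ("HaplotypeScore", 13.0, False),
            ("HaplotypeScore", 13.1, True),
            ("MQRankSum", -12.5, False),
            ("MQRankSum", -12.6, True),
            ("ReadPosRankSum", -8.0, False),
            ("ReadPosRankSum", -8.1, True),
        ],
    )
    def test_strict_inequality_boundaries(self, tag, value, should_fail):
        ok, reasons = hard_filter(rec_with({tag: value}), HardFilterThresholds())
        assert ok != should_fail
        if should_fail:
            assert reasons == [tag]

    def test_all_tags_absent_passes(self):
        ok, reasons = hard_filter(make_record(annotations={}), HardFilterThresholds())
        assert ok and reasons == []

    def test_every_violated_tag_listed(self):
        ok, reasons = hard_filter(
            rec_with({"QD": 0.5, "FS": 99.0, "MQ": 10.0}), HardFilterThresholds()
        )
        assert not ok and set(reasons) == {"QD", "FS", "MQ"}

    def test_non_numeric_value_raises_naming_tag(self):
        rec = make_record(annotations={"QD": "high"})
        with pytest.raises(TypeError, match="QD"):
            hard_filter(rec, HardFilterThresholds())


class TestHighConfidenceSet:
    def test_qual_and_depth_just_above_30_retained(self):
        rec = rec_with({"QUAL": 31.0, "DP": 31})
        assert build_high_confidence_set([rec]) == {rec.key}

    def test_qual_exactly_30_excluded(self):
        assert build_high_confidence_set([rec_with({"QUAL": 30.0})]) == set()
        assert build_high_confidence_set([rec_with({"DP": 30})]) == set()

    def test_indel_excluded_by_allele_length(self):
        assert build_high_confidence_set([rec_with(ref="A", alts=("AT",))]) == set()
        assert build_high_confidence_set([rec_with(ref="AT", alts=("A",))]) == set()

    def test_multiallelic_excluded(self):
        assert build_high_confidence_set([rec_with(alts=("T", "G"))]) == set()


def passing_cascade_record(pos=100, dosages=None):
    """A site that sails through the whole cascade for 12 samples."""
    if dosages is None:
        dosages = (1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0)  # 5 alt carriers
    return rec_with(pos=pos, dosages=dosages)


def run_cascade(records, hc=None, **kwargs):
    n = len(records[0].genotypes)
    if hc is None:
        hc = {r.key for r in records if len(r.alts) == 1}
    return cascade_filter(records, hc, n_samples=n, **kwargs)


class TestCascade:
    def test_clean_record_retained(self):
        retained, ledger = run_cascade([passing_cascade_record()])
        assert len(retained) == 1 and ledger.total_excluded == 0

    def test_missing_in_one_sample_charged_to_rule_one(self):
        rec = rec_with(pos=100, dosages=tuple([1] * 5 + [0] * 7), missing=(3,))
        _, ledger = run_cascade([rec])
        stages = dict((n, e) for n, _, e in ledger.stages)
        assert stages["not_called_in_all"] == 1

    def test_not_in_reference_set_charged_to_rule_two(self):
        rec = passing_cascade_record()
        retained, ledger = cascade_filter([rec], hc=set(), n_samples=12)
        assert not retained
        assert dict((n, e) for n, _, e in ledger.stages)["not_in_high_confidence"] == 1

    def test_reference_match_requires_identical_alleles(self):
        rec = passing_cascade_record()
        wrong_alt = {(rec.chrom, rec.pos, rec.ref, "G")}
        retained, _ = cascade_filter([rec], wrong_alt, n_samples=12)
        assert not retained

    @pytest.mark.parametrize("carriers,kept", [(4, False), (5, True)])
    def test_minor_carrier_boundary(self, carriers, kept):
        dosages = tuple([1] * carriers + [0] * (12 - carriers))
        retained, ledger = run_cascade([rec_with(pos=100, dosages=dosages)])
        assert bool(retained) == kept
        if not kept:
            assert dict((n, e) for n, _, e in ledger.stages)["minor_carriers"] == 1

    def test_two_nonreference_alleles_charged_to_rule_four(self):
        # genotypes use only alleles 1 and 2: biallelic within the sample
        # but for two non-reference alleles
        genotypes = [(1, 1)] * 6 + [(1, 2)] * 6
        rec = make_record(alts=("T", "G"), dosages=(0,) * 12, annotations=dict(PASSING))
        rec.genotypes = genotypes
        _, ledger = run_cascade([rec])
        assert dict((n, e) for n, _, e in ledger.stages)["multiallelic"] == 1

    def test_low_qual_charged_to_hard_filter_with_threshold_four(self):
        rec = rec_with(pos=100, dosages=tuple([1] * 5 + [0] * 7), ann_overrides={"QUAL": 3.9})
        _, ledger = run_cascade([rec])
        assert dict((n, e) for n, _, e in ledger.stages)["hard_filter"] == 1
        rec2 = rec_with(pos=100, dosages=tuple([1] * 5 + [0] * 7), ann_overrides={"QUAL": 4.5})
        retained, _ = run_cascade([rec2])
        assert retained

    def test_depth_not_filtered_in_low_coverage_tier(self):
        rec = rec_with(pos=100, dosages=tuple([1] * 5 + [0] * 7), ann_overrides={"DP": 1})
        retained, _ = run_cascade([rec])
        assert retained

    def test_first_failing_stage_charged_only_once(self):
        # fails hard filter AND has a missing call AND few carriers
        rec = rec_with(
            pos=100, dosages=tuple([1] + [0] * 11), missing=(5,), ann_overrides={"QD": 0.1}
        )
        _, ledger = run_cascade([rec])
        stages = dict((n, e) for n, _, e in ledger.stages)
        assert stages["hard_filter"] == 1
        assert sum(stages.values()) == 1

    def test_sample_count_mismatch_rejected(self):
        rec = passing_cascade_record()
        with pytest.raises(ValueError, match="genotypes"):
            cascade_filter([rec], {rec.key}, n_samples=99)

    def test_idempotent_on_retained_set(self):
        rng = np.random.default_rng(42)
        records = []
        for pos in range(100, 400, 10):
            dosages = tuple(rng.integers(0, 3, size=12))
            records.append(rec_with(pos=pos, dosages=dosages))
        retained, _ = run_cascade(records)
        again, ledger = run_cascade(retained) if retained else ([], None)
        assert len(again) == len(retained)
        assert ledger.total_excluded == 0

    @settings(deadline=None, max_examples=100)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_conservation_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n_samples = int(rng.integers(4, 16))
        records = []
        hc = set()
        for k, pos in enumerate(range(50, 50 + 20 * int(rng.integers(3, 30)), 20)):
            ann = dict(PASSING)
            if rng.random() < 0.3:
                ann["QD"] = float(rng.uniform(0, 4))
            if rng.random() < 0.2:
                ann["QUAL"] = float(rng.uniform(0, 10))
            missing = tuple(
                int(i) for i in rng.choice(n_samples, size=rng.integers(0, 3), replace=False)
            ) if rng.random() < 0.4 else ()
            alts = ("T", "G") if rng.random() < 0.1 else ("T",)
            dosages = tuple(rng.integers(0, 3, size=n_samples))
            rec = make_record(pos=pos, alts=alts, dosages=dosages, missing=missing, annotations=ann)
            records.append(rec)
            if len(alts) == 1 and rng.random() < 0.8:
                hc.add(rec.key)
        retained, ledger = cascade_filter(records, hc, n_samples=n_samples)
        ledger.check_conservation()
        assert ledger.total_in == len(records)
        assert ledger.retained + ledger.total_excluded == len(records)
        assert ledger.retained == len(retained)
        assert [n for n, _, _ in ledger.stages] == list(CASCADE_STAGES)


class TestMinorAlleleCarriers:
    def test_alt_minor(self):
        rec = make_record(dosages=(1, 1, 0, 0, 0, 0))
        assert minor_allele_carriers(rec) == (2, 6)

    def test_ref_minor(self):
        rec = make_record(dosages=(2, 2, 2, 2, 1, 2))
        assert minor_allele_carriers(rec) == (1, 6)

    def test_tie_reports_smaller_first(self):
        rec = make_record(dosages=(2, 2, 0, 0))
        assert minor_allele_carriers(rec) == (2, 2)


class TestLedger:
    def test_report_arithmetic(self):
        ledger = FilterLedger()
        ledger.add_stage("A", 100, 10)
        ledger.add_stage("B", 90, 5)
        ledger.retained = 85
        report = ledger_report(ledger)
        assert "85" in report.splitlines()[-1]

    def test_empty_stream_gives_zero_ledger(self):
        retained, ledger = cascade_filter([], set(), n_samples=0)
        assert retained == [] and ledger.total_in == 0
        ledger.check_conservation()

    def test_report_refuses_broken_conservation(self):
        ledger = FilterLedger()
        ledger.add_stage("A", 100, 10)
        ledger.add_stage("B", 95, 5)  # should be 90
        ledger.retained = 85
        with pytest.raises(ValueError, match="ledger"):
            ledger_report(ledger)
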