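"""Control-reference assembly, Filter-1/Filter-2 and color annotation."""

import itertools

import numpy as np
import pytest

import turbofilter as tf
from turbofilter.enrichment import DetectionCategory, EnrichmentRecord


def record(
    pid,
    fc,
    adj_p,
    n_bait=3,
    n_ctrl=3,
    r_bait=3,
    r_ctrl=3,
    est=False,
):
    if n_bait == 0 and n_ctrl == 0:
        cat = DetectionCategory.NEITHER
    elif n_bait > 0 and n_ctrl > 0:
        cat = DetectionCategory.BOTH
    elif n_bait == r_bait and n_ctrl == 0:
        cat = DetectionCategory.BAIT_ONLY
    elif n_ctrl == r_ctrl and n_bait == 0:
        cat = DetectionCategory.CONTROL_ONLY
    else:
        cat = DetectionCategory.PARTIAL
    return EnrichmentRecord(
        protein_id=pid,
        bait_mean=1000.0 if n_bait else None,
        control_mean=(1000.0 / fc) if (fc and n_ctrl) else None,
        n_detected_bait=n_bait,
        n_detected_control=n_ctrl,
        n_bait_runs=r_bait,
        n_control_runs=r_ctrl,
        fold_change=fc,
        log2_fc=None if fc is None else float(np.log2(fc)),
        p_value=adj_p,
        adj_p=adj_p,
        fc_is_estimate=est,
        detection_category=cat,
    )


class TestBuildControlReference:
    def test_enriched_in_both_averages_fold_changes(self):
        ref = tf.build_control_reference(
            [[record("ALDO-2", 120.0, 0.001)], [record("ALDO-2", 144.0, 0.001)]]
        )
        entry = ref.get("ALDO-2")
        assert entry.category == "enriched_both"
        assert entry.control_fc == pytest.approx(132.0)

    def test_single_experiment_enrichment_with_absent_other_control(self):
        a = [record("X", 3.0, 0.01)]
        b = [record("X", None, None, n_bait=3, n_ctrl=0)]  # absent from N2 of b
        ref = tf.build_control_reference([a, b])
        entry = ref.get("X")
        assert entry.category == "enriched_single_a"
        assert entry.control_fc == pytest.approx(3.0)

    def test_control_only_category(self):
        contrasts = [
            [record("G", None, None, n_bait=3, n_ctrl=0)],
            [record("G", None, None, n_bait=3, n_ctrl=0)],
        ]
        entry = tf.build_control_reference(contrasts).get("G")
        assert entry.category == "control_only"
        assert entry.control_fc is None

    def test_not_significant_everywhere_is_excluded(self):
        ref = tf.build_control_reference(
            [[record("W", 1.5, 0.01)], [record("W", 1.4, 0.01)]]
        )
        assert ref.get("W") is None

    def test_zero_contrasts_error(self):
        with pytest.raises(tf.DataError):
            tf.build_control_reference([])


class TestFilter1:
    def test_enriched_fully_detected_retained(self):
        assert tf.filter1([record("EEA-1", 17.0, 0.01)]) == {"EEA-1"}

    def test_below_twofold_excluded(self):
        assert tf.filter1([record("X", 1.95, 0.015)]) == set()

    def test_partial_bait_detection_excluded(self):
        assert tf.filter1([record("X", 4.0, 0.01, n_bait=2)]) == set()

    def test_bait_only_retained_without_p(self):
        assert tf.filter1([record("X", None, None, n_bait=3, n_ctrl=0)]) == {"X"}

    def test_rule_enumeration_over_detection_counts(self):
        """Every (detection count, FC, p) combination against the written rule."""
        for n_bait, fc, p in itertools.product(
            range(4), [None, 1.5, 2.0, 8.0], [None, 0.01, 0.2]
        ):
            if (fc is None) != (p is None):
                continue
            n_ctrl = 3 if fc is not None else 0
            rec = record("X", fc, p, n_bait=n_bait, n_ctrl=n_ctrl)
            got = tf.filter1([rec])
            expect = (
                fc is not None and fc >= 2 and p is not None and p <= 0.05 and n_bait == 3
            ) or (n_bait == 3 and n_ctrl == 0)
            assert (got == {"X"}) == expect, (n_bait, fc, p)


class TestAnnotateColors:
    def build(self, control_fc_by_pid, complex_members=None, bait_fcs=None):
        contrasts = [
            [record(p, fc, 0.001) for p, fc in control_fc_by_pid.items()],
            [record(p, fc, 0.001) for p, fc in control_fc_by_pid.items()],
        ]
        ref = tf.build_control_reference(contrasts)
        pids = set(control_fc_by_pid) | (set(bait_fcs) if bait_fcs else set())
        records = {
            p: record(p, (bait_fcs or {}).get(p, 4.0), 0.01) for p in pids
        }
        ann = tf.annotate(pids, records, ref, complex_members)
        return ann

    def test_color_breakpoints(self):
        ann = self.build({"R": 132.0, "O": 7.0, "Y": 4.0, "EDGE10": 10.0, "EDGE5": 5.0})
        assert ann["R"].color == "red"
        assert ann["O"].color == "orange"
        assert ann["Y"].color == "yellow"
        assert ann["EDGE10"].color == "orange"  # boundary to lower-severity bucket
        assert ann["EDGE5"].color == "yellow"

    def test_absent_from_reference_is_white(self):
        ann = self.build({}, bait_fcs={"W": 9.0})
        assert ann["W"].color == "white"

    def test_complex_member_is_green_even_when_in_reference(self, caplog):
        members = tf.ReferenceSet("complex", frozenset({"NEKL-3"}))
        import logging

        with caplog.at_level(logging.WARNING):
            ann = self.build({"NEKL-3": 6.0}, complex_members=members)
        assert ann["NEKL-3"].color == "green"
        assert any("complex member" in r.message for r in caplog.records)

    def test_every_protein_gets_exactly_one_color(self):
        ann = self.build({"A": 3.0, "B": 20.0}, bait_fcs={"C": 5.0})
        colors = {"red", "orange", "yellow", "gray", "white", "green"}
        for a in ann.values():
            assert a.color in colors


class TestBaitControlRatio:
    def test_enriched_over_control_retained(self):
        ratio = tf.bait_control_ratio(17.0, 2.2)
        assert ratio == pytest.approx(7.7, rel=0.02)
        assert ratio >= 1.5  # retained at the default cutoff

    def test_comparable_to_control_removed(self):
        ratio = tf.bait_control_ratio(3.6, 4.0)
        assert ratio == pytest.approx(0.9)
        assert ratio < 1.5

    def test_equal_fold_changes_give_one(self):
        assert tf.bait_control_ratio(7.3, 7.3) == 1.0


def annotate_and_filter(bait_fc_by_pid, control_fc_by_pid, **kwargs):
    contrasts = [
        [record(p, fc, 0.001) for p, fc in control_fc_by_pid.items()],
        [record(p, fc, 0.001) for p, fc in control_fc_by_pid.items()],
    ]
    ref = tf.build_control_reference(contrasts)
    records = {p: record(p, fc, 0.01) for p, fc in bait_fc_by_pid.items()}
    f1 = tf.filter1(records.values())
    ann = tf.annotate(f1, records, ref, **kwargs)
    return f1, ann, tf.filter2(ann, f1)


class TestFilter2:
    def test_high_control_fc_removed_regardless_of_bait_fc(self):
        _, _, kept = annotate_and_filter({"ALDO-2": 50.0}, {"ALDO-2": 132.0})
        assert kept == set()

    def test_yellow_with_good_ratio_retained(self):
        _, ann, kept = annotate_and_filter({"EEA-1": 17.0}, {"EEA-1": 2.2})
        assert ann["EEA-1"].color == "yellow"
        assert kept == {"EEA-1"}

    def test_yellow_with_poor_ratio_removed(self):
        _, ann, kept = annotate_and_filter({"MDT-6": 3.6}, {"MDT-6": 4.0})
        assert ann["MDT-6"].color == "yellow"
        assert ann["MDT-6"].bait_control_ratio == pytest.approx(0.9)
        assert kept == set()

    def test_gray_and_white_and_green_retained(self):
        members = tf.ReferenceSet("complex", frozenset({"GRN"}))
        contrasts = [
            [record("GRY", None, None, n_bait=3, n_ctrl=0)],
            [record("GRY", None, None, n_bait=3, n_ctrl=0)],
        ]
        ref = tf.build_control_reference(contrasts)
        records = {p: record(p, 9.0, 0.01) for p in ("GRY", "WHT", "GRN")}
        f1 = tf.filter1(records.values())
        ann = tf.annotate(f1, records, ref, members)
        assert {ann[p].color for p in f1} == {"gray", "white", "green"}
        assert tf.filter2(ann, f1) == f1

    def test_missing_annotation_errors(self):
        with pytest.raises(tf.DataError, match="no annotation"):
            tf.filter2({}, {"X"})

    def test_filter2_subset_of_filter1(self):
        rng = np.random.default_rng(17)
        bait = {f"P{i}": float(rng.lognormal(1, 1) + 1) for i in range(40)}
        ctrl = {f"P{i}": float(rng.lognormal(1, 1) + 1) for i in range(0, 40, 2)}
        f1, _, f2 = annotate_and_filter(bait, ctrl)
        assert f2 <= f1 <= set(bait)

    def test_monotone_in_thresholds(self):
        """Raising remove_above_control_fc or lowering ratio_cut never
        shrinks the retained set."""
        rng = np.random.default_rng(23)
        bait = {f"P{i}": float(rng.lognormal(1.5, 1) + 1) for i in range(60)}
        ctrl = {f"P{i}": float(rng.lognormal(1.5, 1) + 1) for i in range(60)}
        contrasts = [
            [record(p, fc, 0.001) for p, fc in ctrl.items()],
            [record(p, fc, 0.001) for p, fc in ctrl.items()],
        ]
        ref = tf.build_control_reference(contrasts)
        records = {p: record(p, fc, 0.01) for p, fc in bait.items()}
        f1 = tf.filter1(records.values())

        def kept(remove_above, ratio_cut):
            ann = tf.annotate(
                f1, records, ref, ratio_cut=ratio_cut, remove_above_control_fc=remove_above
            )
            return tf.filter2(ann, f1)

        for lo, hi in [(5.0, 10.0), (2.0, 5.0), (10.0, 50.0)]:
            assert kept(lo, 1.5) <= kept(hi, 1.5)
        for hi_r, lo_r in [(2.0, 1.5), (1.5, 1.0), (1.0, 0.5)]:
            assert kept(5.0, hi_r) <= kept(5.0, lo_r)

    def test_planted_classes_perfectly_separated(self):
        """True interactors (bait FC >= 8, control FC < 2) all retained;
        promiscuous targets (control FC > 5) all removed."""
        true_pos = {f"T{i}": 8.0 + i for i in range(10)}
        promiscuous = {f"N{i}": 6.0 + i for i in range(10)}
        bait = dict(true_pos) | {p: 10.0 for p in promiscuous}
        f1, _, f2 = annotate_and_filter(bait, promiscuous)
        assert set(true_pos) <= f2
        assert f2 & set(promiscuous) == set()


class TestCrossBaitOverlap:
    def test_identical_sets_single_region(self):
        rows = tf.cross_bait_overlap({"a": {"X", "Y"}, "b": {"X", "Y"}})
        assert len(rows) == 1
        assert rows[0]["members"] == frozenset({"a", "b"})
        assert rows[0]["count"] == 2

    def test_disjoint_sets_no_shared_region(self):
        rows = tf.cross_bait_overlap({"a": {"X"}, "b": {"Y"}})
        assert all(len(r["members"]) == 1 for r in rows)

    def test_three_sets_match_enumeration(self):
        rng = np.random.default_rng(31)
        universe = [f"P{i}" for i in range(100)]
        sets = {
            name: set(rng.choice(universe, 40, replace=False)) for name in "abc"
        }
        rows = {r["members"]: r["count"] for r in tf.cross_bait_overlap(sets)}
        for size in (1, 2, 3):
            for combo in itertools.combinations("abc", size):
                expected = sum(
                    1
                    for p in universe
                    if {n for n in "abc" if p in sets[n]} == set(combo)
                )
                assert rows.get(frozenset(combo), 0) == expected
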