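"""Up %, TurboID %, Carboxylase %, Epidermal %, replicate agreement."""

import itertools

import numpy as np
import pytest

import turbofilter as tf
from conftest import make_matrix
from turbofilter.enrichment import DetectionCategory, EnrichmentRecord


def record(pid, fc, adj_p, est=False):
    return EnrichmentRecord(
        protein_id=pid,
        bait_mean=100.0,
        control_mean=None if fc is None else 100.0 / fc,
        n_detected_bait=3,
        n_detected_control=0 if est else 3,
        n_bait_runs=3,
        n_control_runs=3,
        fold_change=fc,
        log2_fc=None if fc is None else float(np.log2(fc)),
        p_value=adj_p,
        adj_p=adj_p,
        fc_is_estimate=est,
        detection_category=DetectionCategory.BAIT_ONLY if est else DetectionCategory.BOTH,
    )


class TestUpDown:
    def test_just_below_twofold_is_excluded(self):
        up, down = tf.up_down_counts([record("A", 1.95, 0.015)])
        assert (up, down) == (0, 0)

    def test_boundary_values_are_inclusive(self):
        up, down = tf.up_down_counts([record("A", 2.0, 0.05), record("B", 0.5, 0.05)])
        assert (up, down) == (1, 1)

    def test_estimated_fc_records_are_excluded(self):
        recs = [record("A", 8.0, None, est=True), record("B", 8.0, 0.01)]
        recs[0].adj_p = None
        assert tf.up_down_counts(recs) == (1, 0)

    def test_counts_match_exhaustive_filter(self):
        rng = np.random.default_rng(9)
        recs = []
        for i in range(50):
            fc = float(rng.lognormal(0, 1.5))
            p = float(rng.random())
            recs.append(record(f"P{i}", fc, p))
        up, down = tf.up_down_counts(recs)
        assert up == sum(1 for r in recs if r.fold_change >= 2 and r.adj_p <= 0.05)
        assert down == sum(1 for r in recs if r.fold_change <= 0.5 and r.adj_p <= 0.05)


class TestPercentages:
    @pytest.mark.parametrize("up,down,expected", [(94, 6, 94.0), (27, 73, 27.0)])
    def test_up_percent(self, up, down, expected):
        assert tf.up_percent(up, down) == pytest.approx(expected)

    def test_zero_denominator_undefined(self):
        assert tf.up_percent(0, 0) is None
        assert tf.turboid_percent(0, 0) is None

    def test_up_percent_complement(self):
        for a, b in [(94, 6), (1, 99), (50, 50)]:
            assert tf.up_percent(a, b) + tf.up_percent(b, a) == pytest.approx(100.0)

    @pytest.mark.parametrize("to,n2,expected", [(80, 20, 80.0), (0, 5, 0.0)])
    def test_turboid_percent(self, to, n2, expected):
        assert tf.turboid_percent(to, n2) == pytest.approx(expected)


class TestCarboxylasePercent:
    def test_all_intensity_in_carboxylases(self, carboxylase_ref):
        m = make_matrix({"PYC-1": {"r1": 50.0, "r2": 50.0}})
        assert tf.carboxylase_percent(m, ["r1", "r2"], carboxylase_ref) == 100.0

    def test_quarter_share(self, carboxylase_ref):
        m = make_matrix({"PYC-1": {"r1": 25.0}, "OTHER": {"r1": 75.0}})
        assert tf.carboxylase_percent(m, ["r1"], carboxylase_ref) == pytest.approx(25.0)

    def test_pooled_equals_per_run_mean_only_for_equal_totals(self, carboxylase_ref):
        """The pooled-sum convention matches the mean of per-run ratios iff
        per-run totals agree; verified against a per-run brute force."""
        m = make_matrix(
            {"PYC-1": {"r1": 10.0, "r2": 40.0}, "OTHER": {"r1": 90.0, "r2": 160.0}}
        )
        pooled = tf.carboxylase_percent(m, ["r1", "r2"], carboxylase_ref)
        per_run = np.mean([100 * 10 / 100, 100 * 40 / 200])  # unequal totals 100 vs 200
        assert pooled == pytest.approx(100 * 50 / 300)
        assert pooled != pytest.approx(per_run)
        # equal per-run totals: the two conventions coincide
        eq = make_matrix({"PYC-1": {"r1": 20.0, "r2": 30.0}, "OTHER": {"r1": 80.0, "r2": 70.0}})
        pooled_eq = tf.carboxylase_percent(eq, ["r1", "r2"], carboxylase_ref)
        assert pooled_eq == pytest.approx(np.mean([20.0, 30.0]))

    def test_undetected_proteins_do_not_change_share(self, carboxylase_ref):
        m1 = make_matrix({"PYC-1": {"r1": 25.0}, "OTHER": {"r1": 75.0}})
        m2 = make_matrix(
            {"PYC-1": {"r1": 25.0}, "OTHER": {"r1": 75.0}, "GHOST": {"r1": np.nan}, "PAD": {"r1": np.nan}}
        )
        assert tf.carboxylase_percent(m1, ["r1"], carboxylase_ref) == tf.carboxylase_percent(
            m2, ["r1"], carboxylase_ref
        )

    def test_increasing_carboxylase_intensity_increases_share(self, carboxylase_ref):
        shares = []
        for boost in (1.0, 2.0, 4.0):
            m = make_matrix({"PYC-1": {"r1": 25.0 * boost}, "OTHER": {"r1": 75.0}})
            shares.append(tf.carboxylase_percent(m, ["r1"], carboxylase_ref))
        assert shares == sorted(shares) and shares[0] < shares[-1]

    def test_zero_total_errors(self, carboxylase_ref):
        m = make_matrix({"A": {"r1": np.nan}, "B": {"r1": np.nan}})
        with pytest.raises(tf.DataError, match="zero"):
            tf.carboxylase_percent(m, ["r1"], carboxylase_ref)


class TestEpidermalPercent:
    def test_subset_and_disjoint(self):
        ref = tf.ReferenceSet("epi", frozenset({"A", "B", "C"}))
        assert tf.epidermal_percent({"A", "B"}, ref) == 100.0
        assert tf.epidermal_percent({"X", "Y"}, ref) == 0.0

    def test_matches_brute_force_intersection(self):
        rng = np.random.default_rng(4)
        universe = [f"P{i}" for i in range(200)]
        ref_ids = frozenset(rng.choice(universe, 80, replace=False))
        ref = tf.ReferenceSet("epi", ref_ids)
        candidates = set(rng.choice(universe, 40, replace=False))
        expected = 100 * len(candidates & set(ref_ids)) / 40
        assert tf.epidermal_percent(candidates, ref) == pytest.approx(expected)


class TestReplicateOverlap:
    def test_identical_runs_full_overlap(self):
        m = make_matrix({"A": {"r1": 1.0, "r2": 1.0}, "B": {"r1": 2.0, "r2": 2.0}})
        s = tf.replicate_overlap(m, ["r1", "r2"])
        assert s.all_runs_fraction == 1.0
        assert s.n_union == 2

    def test_disjoint_runs_no_full_region(self):
        m = make_matrix({"A": {"r1": 1.0, "r2": np.nan}, "B": {"r1": np.nan, "r2": 2.0}})
        s = tf.replicate_overlap(m, ["r1", "r2"])
        assert s.all_runs_fraction == 0.0

    def test_three_run_regions_match_enumeration(self):
        rng = np.random.default_rng(12)
        runs = ["r1", "r2", "r3"]
        values = {}
        detect = {}
        for i in range(60):
            pid = f"P{i}"
            pattern = tuple(bool(b) for b in rng.integers(0, 2, 3))
            detect[pid] = pattern
            values[pid] = {
                r: (float(rng.lognormal(5, 1)) if on else np.nan)
                for r, on in zip(runs, pattern)
            }
        m = make_matrix(values)
        s = tf.replicate_overlap(m, runs)
        for subset_size in (1, 2, 3):
            for combo in itertools.combinations(runs, subset_size):
                expected = sum(
                    1
                    for pid, pat in detect.items()
                    if {r for r, on in zip(runs, pat) if on} == set(combo)
                )
                got = s.region_counts.get(frozenset(combo), 0)
                assert got == expected
        assert sum(s.region_counts.values()) == s.n_union


class TestReplicateR2:
    def test_proportional_runs_give_r2_one(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(8, 2, 50)
        m = make_matrix({f"P{i}": {"a": float(v), "b": float(2 * v)} for i, v in enumerate(vals)})
        assert tf.replicate_r2(m, "a", "b") == pytest.approx(1.0)

    def test_independent_runs_give_r2_near_zero(self):
        rng = np.random.default_rng(2)
        m = make_matrix(
            {
                f"P{i}": {"a": float(rng.lognormal(8, 2)), "b": float(rng.lognormal(8, 2))}
                for i in range(2000)
            }
        )
        assert tf.replicate_r2(m, "a", "b") < 0.05

    def test_symmetric_and_ignores_non_codetected(self):
        rng = np.random.default_rng(3)
        values = {
            f"P{i}": {"a": float(rng.lognormal(8, 1)), "b": float(rng.lognormal(8, 1))}
            for i in range(30)
        }
        m1 = make_matrix(values)
        r_ab = tf.replicate_r2(m1, "a", "b")
        assert r_ab == tf.replicate_r2(m1, "b", "a")
        values["EXTRA"] = {"a": 123.0, "b": np.nan}
        m2 = make_matrix(values)
        assert tf.replicate_r2(m2, "a", "b") == pytest.approx(r_ab)

    def test_too_few_shared_proteins_undefined(self):
        m = make_matrix({"A": {"a": 1.0, "b": 2.0}, "B": {"a": 1.0, "b": np.nan}})
        assert tf.replicate_r2(m, "a", "b") is None


class TestMetricCorrelation:
    def reports(self, xs, ys):
        return [
            tf.QCReport("S", f"Exp{i}", up_percent=x, carboxylase_percent=y)
            for i, (x, y) in enumerate(zip(xs, ys))
        ]

    def test_identity_relation(self):
        reps = self.reports([10, 20, 30, 40, 50], [10, 20, 30, 40, 50])
        r2, slope, p = tf.metric_correlation(reps, "up_percent", "carboxylase_percent")
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_constant_x_undefined(self):
        reps = self.reports([5, 5, 5, 5], [1, 2, 3, 4])
        assert tf.metric_correlation(reps, "up_percent", "carboxylase_percent") is None

    def test_permutation_destroys_linked_correlation(self):
        rng = np.random.default_rng(8)
        xs = np.linspace(10, 90, 24)
        ys = xs + rng.normal(0, 2, 24)
        linked = tf.metric_correlation(
            self.reports(xs, ys), "up_percent", "carboxylase_percent"
        )
        shuffled = tf.metric_correlation(
            self.reports(xs, rng.permutation(ys)), "up_percent", "carboxylase_percent"
        )
        assert linked[0] > 0.9
        assert shuffled[0] < 0.3
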