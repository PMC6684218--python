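"""Contingency counting, PRR arithmetic, negative controls and calibration."""

import math
from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adrsignal.stats import (
    ContingencyCounts,
    PairRecord,
    aggregate_counts,
    build_negative_controls,
    calibrate_threshold,
    compute_prr,
    flag_signals,
    KnownAssociationTable,
)


def _rec(drug, group, user, post="p0", day=1):
    return PairRecord(drug, group, user, post, date(2014, 1, day))


class TestAggregateCounts:
    def test_same_user_same_pair_counts_once(self):
        target = [_rec("d1", "rash", "u1", f"p{i}", day=i + 1) for i in range(3)]
        counts = aggregate_counts(target, [_rec("d2", "rash", "u9")])
        assert counts["rash"].n_dr == 1
        assert counts["rash"].n_d == 1

    def test_counts_equal_bruteforce_set_cardinalities(self):
        # 12 records across 3 drugs; d1 is the target
        rows = [
            ("d1", "rash", "u1"), ("d1", "rash", "u2"), ("d1", "acne", "u1"),
            ("d1", "other", "u3"), ("d2", "rash", "u4"), ("d2", "rash", "u1"),
            ("d2", "acne", "u5"), ("d3", "rash", "u6"), ("d3", "other", "u4"),
            ("d3", "acne", "u5"), ("d2", "other", "u7"), ("d1", "acne", "u2"),
        ]
        records = [_rec(d, g, u, f"p{i}") for i, (d, g, u) in enumerate(rows)]
        target = [r for r in records if r.drug_id == "d1"]
        comparison = [r for r in records if r.drug_id != "d1"]
        counts = aggregate_counts(target, comparison)
        # independent oracle: explicit set cardinalities
        assert counts["rash"].n_dr == len({"u1", "u2"})
        assert counts["rash"].n_d == len({"u1", "u2", "u3"})
        assert counts["rash"].n_notd_r == len({"u4", "u1", "u6"})
        assert counts["rash"].n_notd == len({"u1", "u4", "u5", "u6", "u7"})
        assert counts["acne"].n_dr == 2
        assert counts["acne"].n_notd_r == 1

    def test_no_comparison_records_gives_zero_comparators(self):
        counts = aggregate_counts([_rec("d1", "rash", "u1")], [])
        assert counts["rash"].n_notd_r == 0
        assert counts["rash"].n_notd == 0

    def test_target_drug_in_comparison_rejected(self):
        with pytest.raises(ValueError, match="comparison"):
            aggregate_counts([_rec("d1", "rash", "u1")], [_rec("d1", "rash", "u2")])


class TestComputePrr:
    def test_symmetric_table_is_one(self):
        assert compute_prr(ContingencyCounts(10, 100, 10, 100)) == 1.0

    def test_printed_formula_hand_case(self):
        # (20/50) / (30/300) = 0.4 / 0.1
        assert compute_prr(ContingencyCounts(20, 50, 30, 300)) == 4.0

    def test_zero_comparator_gives_infinity(self):
        assert compute_prr(ContingencyCounts(5, 50, 0, 300)) == math.inf

    def test_zero_target_reports_gives_zero(self):
        assert compute_prr(ContingencyCounts(0, 50, 10, 300)) == 0.0

    def test_undefined_denominators_raise(self):
        with pytest.raises(ZeroDivisionError):
            compute_prr(ContingencyCounts(0, 0, 10, 300))
        with pytest.raises(ZeroDivisionError):
            compute_prr(ContingencyCounts(5, 50, 0, 0))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyCounts(10, 5, 0, 0)  # n_dr > n_d
        with pytest.raises(ValueError):
            ContingencyCounts(1, 2, 5, 3)  # n_notd_r > n_notd

    def test_haldane_correction_tames_infinity(self):
        prr = compute_prr(ContingencyCounts(5, 50, 0, 300), correction=0.5)
        assert math.isfinite(prr) and prr > 1

    def test_matches_direct_arithmetic_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n_d = int(rng.integers(1, 1000))
            n_dr = int(rng.integers(0, n_d + 1))
            n_notd = int(rng.integers(1, 5000))
            n_notd_r = int(rng.integers(0, n_notd + 1))
            got = compute_prr(ContingencyCounts(n_dr, n_d, n_notd_r, n_notd))
            if n_dr == 0:
                assert got == 0.0
            elif n_notd_r == 0:
                assert got == math.inf
            else:
                want = (n_dr / n_d) / (n_notd_r / n_notd)
                assert abs(got - want) <= 1e-12 * want

    @given(
        n_d=st.integers(1, 10_000),
        n_notd=st.integers(1, 10_000),
        data=st.data(),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_ndr(self, n_d, n_notd, data):
        """Adding a reporting user for the pair strictly increases PRR."""
        n_dr = data.draw(st.integers(0, n_d - 1))
        n_notd_r = data.draw(st.integers(1, n_notd))
        lo = compute_prr(ContingencyCounts(n_dr, n_d, n_notd_r, n_notd))
        hi = compute_prr(ContingencyCounts(n_dr + 1, n_d, n_notd_r, n_notd))
        assert hi > lo


class TestNegativeControls:
    def test_full_grid_cardinality(self):
        drugs = [f"c{i:02d}" for i in range(27)]
        groups = [f"g{i}" for i in range(8)]
        out = build_negative_controls(drugs, groups)
        assert out.n_candidates == 216
        assert out.n_after_known == 216
        assert out.n_final == 216

    def test_known_pairs_removed(self):
        known = KnownAssociationTable({("d1", "g1", "adr")})
        out = build_negative_controls(["d1", "d2"], ["g1", "g2"], known)
        assert out.n_candidates == 4
        assert out.n_final == 3
        assert ("d1", "g1") not in out.pairs

    def test_manual_exclusions_and_reasons(self):
        out = build_negative_controls(
            ["d1", "d2"], ["g1"], None, [("d1", "g1", "coprescription")]
        )
        assert out.pairs == [("d2", "g1")]
        with pytest.raises(ValueError, match="reason"):
            build_negative_controls(["d1"], ["g1"], None, [("d1", "g1", "whim")])

    def test_exclusion_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="not a candidate"):
            build_negative_controls(["d1"], ["g1"], None, [("dX", "g1", "syndromic")])

    def test_everything_excluded_warns_and_returns_empty(self):
        drugs, groups = ["d1", "d2", "d3"], ["g1", "g2", "g3"]
        exclusions = [(d, g, "syndromic") for d in drugs for g in groups]
        with pytest.warns(UserWarning, match="empty"):
            out = build_negative_controls(drugs, groups, None, exclusions)
        assert out.n_final == 0


class TestCalibration:
    def test_linear_interpolation_definition(self):
        values = [i / 100 for i in range(1, 101)]
        assert calibrate_threshold(values, percentile=95) == pytest.approx(0.9505)

    def test_constant_values_give_that_constant(self):
        assert calibrate_threshold([0.7] * 20) == 0.7

    def test_too_few_finite_values_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            calibrate_threshold([0.1, 0.2, 0.3, 0.4])

    def test_infinite_values_excluded_with_warning(self):
        values = [i / 100 for i in range(1, 101)] + [math.inf]
        with pytest.warns(UserWarning, match="non-finite"):
            got = calibrate_threshold(values, percentile=95)
        assert got == pytest.approx(0.9505)

    def test_threshold_bounds_control_mass(self):
        rng = np.random.default_rng(3)
        values = rng.lognormal(mean=-1.0, sigma=0.8, size=400).tolist()
        thr = calibrate_threshold(values, percentile=95)
        assert sum(v <= thr for v in values) / len(values) >= 0.95


class TestFlagging:
    def test_discovered_signal_is_flagged(self):
        # PRR 1.90 with calibrated threshold 0.82 and the PRR>1 rule
        counts = ContingencyCounts(23, 242, 50, 1000)
        assert compute_prr(counts) == pytest.approx(1.9, abs=0.005)
        [res] = flag_signals([("erlotinib", "hypohidrosis", counts)], threshold=0.82)
        assert res.flagged and res.flagged_fixed

    def test_boundary_is_strict(self):
        counts = ContingencyCounts(10, 100, 10, 100)  # PRR exactly 1.0
        [res] = flag_signals([("d", "g", counts)], threshold=0.82)
        assert not res.flagged and not res.flagged_fixed

    def test_below_threshold_not_flagged(self):
        counts = ContingencyCounts(5, 100, 10, 100)  # PRR 0.5
        [res] = flag_signals([("d", "g", counts)], threshold=0.82)
        assert not res.flagged

    def test_calibrated_threshold_above_fixed_rule_dominates(self):
        counts = ContingencyCounts(12, 100, 10, 100)  # PRR 1.2
        [res] = flag_signals([("d", "g", counts)], threshold=1.5)
        assert res.flagged_fixed and not res.flagged

    def test_infinite_threshold_rejected(self):
        with pytest.raises(ValueError):
            flag_signals([], threshold=math.inf)
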