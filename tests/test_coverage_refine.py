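"""Coverage purification: median filter, inverse-profile split, z-score loop.

The z-score purifier is checked against a naive oracle written with plain
Python arithmetic that literally recomputes full z-vectors after every
single removal.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from binrefine.coverage_refine import (
    median_outlier_filter,
    split_inverse_profiles,
    zscore_purify,
)
from conftest import make_bin, make_coverage, random_coverage_fixture


# ---------------------------------------------------------------------------
# Independent oracles (plain Python, no numpy)
# ---------------------------------------------------------------------------

def naive_z(values):
    n = len(values)
    if n < 2:
        return [0.0] * n
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    if var == 0.0:
        return [0.0] * n
    sd = math.sqrt(var)
    return [(v - mean) / sd for v in values]


def naive_purify(depths, start=4.0, end=2.0, step=1.0, min_members=4):
    """Literal re-derivation: full z recomputation after each removal."""
    cur = sorted(depths)
    removed = []
    cutoffs = []
    c = start
    while c > end:
        cutoffs.append(c)
        c -= step
    cutoffs.append(end)
    early = False
    for c in cutoffs:
        if early:
            break
        while True:
            za = naive_z([depths[s][0] for s in cur])
            zb = naive_z([depths[s][1] for s in cur])
            deltas = [abs(a - b) for a, b in zip(za, zb)]
            worst = max(deltas)
            if worst <= c:
                break
            if len(cur) - 1 < min_members:
                early = True
                break
            idx = min(i for i, d in enumerate(deltas) if d == worst)
            removed.append(cur.pop(idx))
    return cur, removed, early


def brute_force_median_removed(depths, factor=3.0):
    datasets = range(len(next(iter(depths.values()))))
    removed = set()
    for d in datasets:
        col = sorted(v[d] for v in depths.values())
        n = len(col)
        med = col[n // 2] if n % 2 else (col[n // 2 - 1] + col[n // 2]) / 2
        if med == 0:
            continue
        for sid, v in depths.items():
            if v[d] > factor * med:
                removed.add(sid)
    return removed


# ---------------------------------------------------------------------------
# Median-outlier filter
# ---------------------------------------------------------------------------

class TestMedianOutlierFilter:
    def test_threefold_median_rule_on_simple_bin(self):
        depths = {"s1": (10.0,), "s2": (10.0,), "s3": (10.0,), "s4": (100.0,)}
        b = make_bin(depths)
        cov = make_coverage(depths, datasets=("A",))
        res = median_outlier_filter(b, cov)
        assert res.medians == {"A": 10.0}
        assert res.removed == {"s4"} and len(res.kept) == 3

    def test_uniform_coverage_removes_nothing(self):
        depths = {f"s{i}": (7.0, 7.0) for i in range(6)}
        res = median_outlier_filter(make_bin(depths), make_coverage(depths))
        assert not res.removed

    def test_over_threshold_in_one_dataset_suffices(self):
        # hand-enumerated 6-scaffold fixture: s5 exceeds 3x median only in B
        depths = {
            "s0": (10.0, 20.0), "s1": (11.0, 21.0), "s2": (9.0, 19.0),
            "s3": (10.0, 22.0), "s4": (12.0, 18.0), "s5": (10.0, 70.0),
        }
        res = median_outlier_filter(make_bin(depths), make_coverage(depths))
        assert res.removed == {"s5"}
        assert res.removed == brute_force_median_removed(depths)

    def test_zero_median_dataset_skipped_with_flag(self):
        depths = {"s1": (0.0, 10.0), "s2": (0.0, 10.0), "s3": (5.0, 10.0)}
        res = median_outlier_filter(make_bin(depths), make_coverage(depths))
        assert res.skipped_datasets == ["A"]
        assert not res.removed      # s3 must NOT be removed on the zero-median axis

    def test_and_semantics_require_all_datasets(self):
        depths = {"s0": (10.0, 10.0), "s1": (10.0, 10.0), "s2": (10.0, 10.0),
                  "s3": (40.0, 10.0), "s4": (40.0, 40.0)}
        res = median_outlier_filter(make_bin(depths), make_coverage(depths),
                                    require_all=True)
        assert res.removed == {"s4"}

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(4, 60))
            depths = {f"s{i:03d}": (float(rng.uniform(0, 40)),
                                    float(rng.uniform(0, 40)))
                      for i in range(n)}
            res = median_outlier_filter(make_bin(depths), make_coverage(depths))
            assert res.removed == brute_force_median_removed(depths)
            assert res.kept.members | res.removed == set(depths)
            assert not res.kept.members & res.removed


# ---------------------------------------------------------------------------
# Inverse-profile split
# ---------------------------------------------------------------------------

class TestSplitInverseProfiles:
    def test_flat_ratio_profile_does_not_split(self):
        depths = {f"s{i:02d}": (10.0 + i * 0.01, 10.0 + i * 0.01)
                  for i in range(20)}
        res = split_inverse_profiles(make_bin(depths), make_coverage(depths),
                                     "A", "B")
        assert not res.was_split
        assert len(res.sub_bins) == 1
        assert res.sub_bins[0].members == set(depths)

    def test_opposite_profiles_split_into_two_sub_bins(self):
        # 10 members at log2 ratio ~ +3 and 10 at ~ -3: gap ~ 6 >= 2
        depths = {}
        for i in range(10):
            depths[f"a{i:02d}"] = (80.0 + i, 10.0)     # high in A
            depths[f"b{i:02d}"] = (10.0, 80.0 + i)     # high in B
        res = split_inverse_profiles(make_bin(depths), make_coverage(depths),
                                     "A", "B")
        assert res.was_split
        assert res.split_statistic >= 2.0
        sides = sorted(res.sub_bins, key=lambda b: b.bin_id)
        assert sides[0].members == {f"a{i:02d}" for i in range(10)}
        assert sides[1].members == {f"b{i:02d}" for i in range(10)}
        # partition property
        union = set().union(*(b.members for b in res.sub_bins))
        assert union == set(depths)

    def test_large_gap_same_sign_does_not_split(self):
        # ratios ~ +1 and ~ +4: wide gap, but both sides high in A
        depths = {}
        for i in range(10):
            depths[f"a{i:02d}"] = (20.0 + i, 10.0)     # r ~ +1
            depths[f"b{i:02d}"] = (160.0 + i, 10.0)    # r ~ +4
        res = split_inverse_profiles(make_bin(depths), make_coverage(depths),
                                     "A", "B")
        assert not res.was_split
        assert res.reason == "same_sign_profiles"

    def test_small_bin_refuses_to_split_with_reason(self):
        depths = {f"s{i}": (80.0, 10.0) if i < 4 else (10.0, 80.0)
                  for i in range(8)}
        res = split_inverse_profiles(make_bin(depths), make_coverage(depths),
                                     "A", "B", min_side=5)
        assert not res.was_split and res.reason == "too_few_members"

    def test_narrow_gap_does_not_split(self):
        depths = {}
        for i in range(10):
            depths[f"a{i:02d}"] = (18.0, 10.0)
            depths[f"b{i:02d}"] = (10.0, 18.0)
        res = split_inverse_profiles(make_bin(depths), make_coverage(depths),
                                     "A", "B", min_gap_log2=2.0)
        assert not res.was_split and res.reason == "gap_below_threshold"


# ---------------------------------------------------------------------------
# Z-score purification
# ---------------------------------------------------------------------------

class TestZscorePurify:
    def test_identical_profiles_remove_nothing(self):
        depths = {f"s{i:02d}": (10.0 + i, 10.0 + i) for i in range(20)}
        res = zscore_purify(make_bin(depths), make_coverage(depths), "A", "B")
        assert not res.removed
        assert res.kept.members == set(depths)

    def test_single_planted_outlier_removed(self):
        depths = {f"s{i:02d}": (10.0, 10.0) for i in range(20)}
        depths["zz"] = (100.0, 10.0)
        res = zscore_purify(make_bin(depths), make_coverage(depths), "A", "B")
        assert res.removed == ["zz"]
        assert len(res.kept) == 20

    def test_matches_naive_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(10, 80))
            depths = {f"s{i:03d}": (float(rng.uniform(0, 50)),
                                    float(rng.uniform(0, 50)))
                      for i in range(n)}
            res = zscore_purify(make_bin(depths), make_coverage(depths), "A", "B")
            kept_o, removed_o, early_o = naive_purify(depths)
            assert res.removed == removed_o
            assert res.kept.sorted_members() == kept_o
            assert res.early_stopped == early_o

    def test_zero_variance_dataset_drives_no_removals(self):
        depths = {f"s{i}": (5.0, float(i)) for i in range(10)}
        # dataset A is constant: z_A all zero, flagged; removals only via B,
        # but z_B alone cannot exceed |z_A - z_B| thresholds beyond its spread
        res = zscore_purify(make_bin(depths), make_coverage(depths), "A", "B")
        assert res.zero_variance_seen

    def test_min_members_guard_stops_early_with_flag(self):
        depths = {"s1": (1.0, 50.0), "s2": (50.0, 1.0), "s3": (1.0, 40.0),
                  "s4": (40.0, 1.0), "s5": (25.0, 25.0)}
        res = zscore_purify(make_bin(depths), make_coverage(depths), "A", "B",
                            min_members=4)
        assert len(res.kept) >= 4
        if res.removed:
            assert res.early_stopped

    def test_bin_below_min_members_is_error(self):
        depths = {"s1": (1.0, 2.0), "s2": (2.0, 1.0)}
        with pytest.raises(ValueError, match="min_members"):
            zscore_purify(make_bin(depths), make_coverage(depths), "A", "B")

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(17)
        bin_, cov = random_coverage_fixture(rng, 60)
        res1 = zscore_purify(bin_, cov, "A", "B")
        res2 = zscore_purify(res1.kept, cov, "A", "B")
        assert not res2.removed

    def test_lower_end_cutoff_never_keeps_more(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            bin_, cov = random_coverage_fixture(rng, 50)
            kept3 = zscore_purify(bin_, cov, "A", "B", end_cutoff=3.0).kept.members
            kept2 = zscore_purify(bin_, cov, "A", "B", end_cutoff=2.0).kept.members
            assert kept2 <= kept3

    def test_order_invariance_ties_broken_by_id(self):
        # two identical offenders: the lexicographically smaller is removed first
        depths = {f"s{i:02d}": (10.0, 10.0) for i in range(10)}
        depths["x2"] = (60.0, 10.0)
        depths["x1"] = (60.0, 10.0)
        res = zscore_purify(make_bin(depths), make_coverage(depths), "A", "B")
        assert res.removed[:2] == ["x1", "x2"]

    def test_batch_mode_satisfies_same_termination_contract(self):
        rng = np.random.default_rng(31)
        bin_, cov = random_coverage_fixture(rng, 60)
        res = zscore_purify(bin_, cov, "A", "B", batch=True)
        st = res.final_state
        assert all(abs(za - zb) <= 2.0 + 1e-9 for za, zb in st.z.values())

    def test_trace_rows_match_removals(self):
        depths = {f"s{i:02d}": (10.0, 10.0) for i in range(15)}
        depths["zz"] = (90.0, 10.0)
        res = zscore_purify(make_bin(depths), make_coverage(depths), "A", "B")
        removals = [r for r in res.trace if r.action == "remove"]
        assert [r.scaffold_id for r in removals] == res.removed
        assert all(r.stage == "zscore_purify" for r in removals)
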