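"""Rating cleanup, permutation stratification and summary statistics."""

from datetime import datetime, timedelta
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from placebo_rct import (
    assign_periods, dedupe_ratings, exclude_outliers, magnitude_of_response,
    permutation_response_test, pill_effect_size, response_rate_chi2, stratify,
)
from placebo_rct.ema import PERIODS, RatingSeries, _pooled_t

T0 = datetime(2024, 1, 8, 8, 0)


def _mins(m):
    return T0 + timedelta(minutes=m)


def exhaustive_permutation_p(x, y):
    """Independent oracle: enumerate all label partitions of the pooled data."""
    pooled = np.array(list(x) + list(y), dtype=float)
    nx = len(x)
    t_obs = _pooled_t(pooled[:nx], pooled[nx:])
    count = total = 0
    for idx in combinations(range(len(pooled)), nx):
        a = pooled[list(idx)]
        b = np.delete(pooled, list(idx))
        if abs(_pooled_t(a, b)) >= abs(t_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestDedupe:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            # within 30 min: only the later survives
            ([(_mins(0), 6.0), (_mins(25), 5.0)], [(_mins(25), 5.0)]),
            # 31 min apart: both kept
            ([(_mins(0), 6.0), (_mins(31), 5.0)], [(_mins(0), 6.0), (_mins(31), 5.0)]),
            # chained run 0/20/40: pairwise-close chain collapses to its last entry
            ([(_mins(0), 6.0), (_mins(20), 5.0), (_mins(40), 4.0)], [(_mins(40), 4.0)]),
            ([], []),
        ],
    )
    def test_thirty_minute_rule(self, raw, expected):
        out = dedupe_ratings(raw)
        got = [(ts, v) for ts, v in zip(out.entries["timestamp"], out.entries["vas"])]
        assert got == expected

    def test_matches_sequential_scan_oracle(self, rng):
        # oracle: scan in time order, keep entry unless within 30 min of the
        # previous kept candidate, in which case it replaces it
        times = np.cumsum(rng.integers(1, 90, size=60))
        raw = [(_mins(int(t)), float(v)) for t, v in
               zip(times, rng.uniform(0, 10, size=60))]
        kept = []
        for ts, v in raw:
            if kept and (ts - kept[-1][0]).total_seconds() < 1800:
                kept[-1] = (ts, v)
            else:
                kept.append((ts, v))
        out = dedupe_ratings(raw)
        assert list(out.entries["vas"]) == [v for _, v in kept]
        gaps = out.entries["timestamp"].diff().dropna().dt.total_seconds()
        assert (gaps >= 1800).all()


class TestAssignPeriods:
    def test_half_open_intervals_and_drops(self, visit_dates):
        import pandas as pd

        entries = pd.DataFrame(
            {
                "timestamp": [
                    visit_dates[0] - timedelta(hours=1),  # before V1: dropped
                    visit_dates[0],  # exactly V1 -> BL
                    visit_dates[1],  # exactly V2 -> T1 (later period)
                    visit_dates[2] + timedelta(days=3),  # W1
                    visit_dates[5],  # at V6: dropped
                ],
                "vas": [5.0] * 5,
            }
        )
        out = assign_periods(RatingSeries("s", entries), visit_dates)
        assert list(out.entries["period"]) == ["BL", "T1", "W1"]

    def test_all_before_first_visit_empty(self, visit_dates):
        import pandas as pd

        entries = pd.DataFrame(
            {"timestamp": [visit_dates[0] - timedelta(days=2)], "vas": [4.0]}
        )
        out = assign_periods(RatingSeries("s", entries), visit_dates)
        assert len(out) == 0

    def test_two_per_day_compliance_gives_28_baseline_entries(self, visit_dates):
        import pandas as pd

        stamps = [visit_dates[0] + timedelta(days=d, hours=h)
                  for d in range(14) for h in (1, 13)]
        out = assign_periods(
            RatingSeries("s", pd.DataFrame({"timestamp": stamps, "vas": 5.0})),
            visit_dates,
        )
        assert (out.entries["period"] == "BL").sum() == 28

    def test_too_few_visits_rejected(self):
        import pandas as pd

        series = RatingSeries("s", pd.DataFrame({"timestamp": [T0], "vas": [5.0]}))
        with pytest.raises(ValueError):
            assign_periods(series, [T0])


class TestPermutationTest:
    def test_agrees_with_exhaustive_enumeration(self):
        cases = [
            ([7, 7, 8, 7], [3, 3, 2, 3]),
            ([5, 6, 7, 5, 6], [5, 6, 6, 5]),
            ([2, 4, 3, 5, 4, 3], [3, 4, 2, 5, 3, 4]),
        ]
        for x, y in cases:
            p_exact = exhaustive_permutation_p(x, y)
            _, p_mc = permutation_response_test(x, y, n_perm=20_000, seed=11)
            assert p_mc == pytest.approx(p_exact, abs=0.01)

    def test_strong_separation_example(self):
        # exact two-sided p for this split is 2/70
        assert exhaustive_permutation_p([7, 7, 8, 7], [3, 3, 2, 3]) == pytest.approx(2 / 70)
        _, p = permutation_response_test([7, 7, 8, 7], [3, 3, 2, 3], n_perm=10_000, seed=0)
        assert p < 0.05

    def test_identical_constant_groups(self):
        t, p = permutation_response_test([5, 5, 5], [5, 5, 5], seed=0)
        assert t == 0.0 and p == 1.0

    def test_swap_symmetry(self):
        x, y = [6, 7, 5, 6, 8], [4, 3, 5, 4]
        t1, p1 = permutation_response_test(x, y, n_perm=5000, seed=3)
        t2, p2 = permutation_response_test(y, x, n_perm=5000, seed=3)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2, abs=0.02)

    def test_seed_reproducibility(self):
        x, y = [6, 7, 5, 6], [5, 4, 6, 5]
        assert permutation_response_test(x, y, seed=9) == permutation_response_test(
            x, y, seed=9
        )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        x=st.lists(st.floats(0, 10, allow_nan=False), min_size=2, max_size=8),
        y=st.lists(st.floats(0, 10, allow_nan=False), min_size=2, max_size=8),
    )
    def test_p_always_a_probability(self, x, y):
        _, p = permutation_response_test(x, y, n_perm=200, seed=1)
        assert 0.0 < p <= 1.0


class TestStratify:
    def test_significant_increase_is_not_response(self):
        base = [3.0, 3.1, 2.9, 3.0, 3.2, 2.8] * 4
        worse = [7.0, 7.1, 6.9, 7.0, 7.2, 6.8] * 4
        res = stratify(base, worse, worse, n_perm=2000, seed=5)
        assert res.p_t1 < 0.05  # difference is real...
        assert res.label == "NonResponder"  # ...but in the wrong direction

    def test_both_periods_null_is_nonresponder(self, rng):
        base = rng.normal(6, 1, 30)
        res = stratify(base, rng.normal(6, 1, 28), rng.normal(6, 1, 28),
                       n_perm=2000, seed=5)
        assert res.label == "NonResponder"

    def test_planted_responder_detected(self, rng):
        base = rng.normal(6.1, 1, 28)
        treat = rng.normal(6.1 * 0.67, 1, 28)  # 33% analgesia
        res = stratify(base, treat, treat, n_perm=2000, seed=5)
        assert res.label == "Responder"

    def test_missing_period_recorded_absent(self, rng):
        base = rng.normal(6, 1, 20)
        res = stratify(base, None, rng.normal(4, 1, 20), n_perm=1000, seed=2)
        assert np.isnan(res.p_t1) and res.p_t2 < 0.05
        assert res.label == "Responder"


class TestSummaries:
    def test_magnitude_and_percent(self):
        s = magnitude_of_response([6.0] * 10, [4.0] * 8, [4.5] * 8)
        assert s.magnitude_units == pytest.approx(2.0)
        assert s.pct_analgesia == pytest.approx(100 * 2 / 6)
        assert s.period_of_max == "T1"

    def test_t2_stronger(self):
        s = magnitude_of_response([6.0] * 4, [5.0] * 4, [3.0] * 4)
        assert s.period_of_max == "T2"

    def test_no_change(self):
        s = magnitude_of_response([5.0] * 4, [5.0] * 4, None)
        assert s.magnitude_units == 0.0 and s.pct_analgesia == 0.0

    def test_empty_baseline_errors(self):
        with pytest.raises(ValueError):
            magnitude_of_response([], [4.0], [4.0])

    def test_effect_size_formula(self):
        # (2-1)/sd([2,2,1,1]) with sample sd
        es = pill_effect_size([2, 2], [1, 1])
        assert es == pytest.approx(1 / np.std([2, 2, 1, 1], ddof=1))
        assert es == pytest.approx(1.732, abs=0.001)

    def test_effect_size_invariances(self, rng):
        a, b = rng.normal(30, 8, 24), rng.normal(5, 8, 20)
        assert pill_effect_size(a, a[:20]) == pytest.approx(
            (a.mean() - a[:20].mean()) / np.concatenate([a, a[:20]]).std(ddof=1)
        )
        es = pill_effect_size(a, b)
        assert pill_effect_size(3 * a, 3 * b) == pytest.approx(es)
        with pytest.raises(ValueError):
            pill_effect_size([1, 1], [1, 1])


class TestChi2:
    def test_printed_response_rates(self):
        chi2, p = response_rate_chi2(24, 43, 4, 20)
        assert chi2 == pytest.approx(7.09, abs=0.01)
        assert p == pytest.approx(0.008, abs=0.001)

    def test_equal_proportions_zero(self):
        chi2, _ = response_rate_chi2(10, 20, 5, 10)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_textbook_formula(self):
        # direct Pearson formula on the 2x2 table 10/20 vs 5/20
        a, b, c, d = 10, 10, 5, 15
        n = a + b + c + d
        expected = (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
        chi2, _ = response_rate_chi2(10, 20, 5, 20)
        assert chi2 == pytest.approx(expected)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            response_rate_chi2(0, 20, 0, 20)


class TestOutliers:
    def test_single_extreme_value_excluded(self):
        vals = [0.0] * 20 + [100.0]
        mask = exclude_outliers(vals)
        # oracle: one-pass mean/sd computed directly
        x = np.array(vals)
        expected = np.abs(x - x.mean()) <= 3 * x.std(ddof=1)
        assert (mask == expected).all()
        assert not mask[-1] and mask[:-1].all()

    def test_all_equal_all_kept(self):
        assert exclude_outliers([4.0, 4.0, 4.0]).all()

    def test_large_k_keeps_everything(self, rng):
        assert exclude_outliers(rng.normal(size=50), k=1e9).all()
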