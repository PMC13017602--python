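"""Efficiency frontier identification against brute-force oracles and the
published 34-strategy outcome table."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import crc_screen_sim as cs
from crc_screen_sim.frontier import find_frontier, frontier_value_at, hull_value


def brute_force_efficient(x, y):
    """O(n^3) oracle: a point is efficient iff no convex combination of two
    other points (or a single point) attains >= QALYs at <= colonoscopies,
    beating it; equivalently it lies on the upper-left hull."""
    n = x.size
    eff = np.ones(n, dtype=bool)
    for i in range(n):
        # dominated by a single point?
        for j in range(n):
            if j != i and x[j] <= x[i] and y[j] >= y[i] and (x[j] < x[i] or y[j] > y[i]):
                eff[i] = False
        # strictly below a chord between two points spanning it?
        for j in range(n):
            for k in range(n):
                if x[j] < x[i] < x[k]:
                    t = (x[i] - x[j]) / (x[k] - x[j])
                    y_chord = y[j] + t * (y[k] - y[j])
                    if y_chord > y[i] + 1e-9:
                        eff[i] = False
    return eff


def test_table2_reproduces_published_efficiency_labels(table2):
    """The strict upper-left hull of the 34 published points reproduces the
    published Yes/No efficiency column exactly (23 efficient, 11 not), and
    agrees with the brute-force oracle."""
    x = table2["colonoscopies_per_1000"].to_numpy(dtype=float)
    y = table2["qalys_gained_per_1000"].to_numpy(dtype=float)
    published = (table2["efficient"] == "yes").to_numpy()
    fr = find_frontier(x, y, tolerance=0.0)
    assert published.sum() == 23 and (~published).sum() == 11
    assert np.array_equal(fr.on_hull, published)
    assert np.array_equal(brute_force_efficient(x, y), published)


def test_table2_borderline_point_is_excluded(table2):
    """The 50%_74 point sits just below the chord between its neighbours and
    is therefore not efficient despite being non-dominated."""
    t = table2.set_index("label")
    fr_row = t.loc["50%_74"]
    x40, y40 = t.loc["40%_74", ["colonoscopies_per_1000", "qalys_gained_per_1000"]]
    x60, y60 = t.loc["60%_74", ["colonoscopies_per_1000", "qalys_gained_per_1000"]]
    slope_l = (fr_row["qalys_gained_per_1000"] - y40) / (fr_row["colonoscopies_per_1000"] - x40)
    slope_r = (y60 - fr_row["qalys_gained_per_1000"]) / (x60 - fr_row["colonoscopies_per_1000"])
    assert slope_l < slope_r  # convexity violated -> off the hull


def test_table2_tie_in_colonoscopies(table2):
    """Two strategies at 1654 colonoscopies: only the higher-QALY one is a
    hull candidate, the other is dominated."""
    x = table2["colonoscopies_per_1000"].to_numpy(dtype=float)
    y = table2["qalys_gained_per_1000"].to_numpy(dtype=float)
    fr = find_frontier(x, y, tolerance=0.0)
    tie = np.flatnonzero(x == 1654)
    assert tie.size == 2
    hi, lo = (tie[0], tie[1]) if y[tie[0]] > y[tie[1]] else (tie[1], tie[0])
    assert fr.on_hull[hi] and not fr.on_hull[lo]
    assert fr.dominated[lo] and not fr.dominated[hi]


def test_collinear_points_all_on_hull():
    fr = find_frontier([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], tolerance=0.0)
    assert fr.on_hull.all()
    assert not fr.dominated.any()


def test_simple_dominance():
    fr = find_frontier([1.0, 2.0], [2.0, 1.0], tolerance=0.0)
    assert list(fr.dominated) == [False, True]
    assert list(fr.on_hull) == [True, False]


def test_interpolation(table2):
    x = table2["colonoscopies_per_1000"].to_numpy(dtype=float)
    y = table2["qalys_gained_per_1000"].to_numpy(dtype=float)
    fr = find_frontier(x, y)
    # at a vertex the hull passes through the vertex
    assert frontier_value_at(fr, fr.hull_x[3]) == pytest.approx(fr.hull_y[3])
    # midway between two vertices the hull is the midpoint of their QALYs
    mid = (fr.hull_x[2] + fr.hull_x[3]) / 2
    assert frontier_value_at(fr, mid) == pytest.approx((fr.hull_y[2] + fr.hull_y[3]) / 2)
    # at budget 1373 the interpolated frontier beats the published 50%_74 point
    assert frontier_value_at(fr, 1373.0) > 167.69
    with pytest.raises(ValueError):
        frontier_value_at(fr, fr.hull_x[0] - 1.0)


def test_compare_to_reference_published_claims(table2):
    t2 = table2
    cmp1 = cs.compare_to_reference(t2, "age_54", "COL_only")
    assert cmp1 == {"qalys_pct": 6.7, "colonoscopies_pct": -3.9}
    cmp2 = cs.compare_to_reference(t2, "60%_54:64:74", "50/50")
    assert cmp2["qalys_pct"] == 10.0
    cmp3 = cs.compare_to_reference(t2, "80%_64:74", "COL_only")
    assert cmp3["colonoscopies_pct"] == -35.7
    cmp4 = cs.compare_to_reference(t2, "60%_74", "50/50")
    assert cmp4["colonoscopies_pct"] == -30.7
    same = cs.compare_to_reference(t2, "age_54", "age_54")
    assert same == {"qalys_pct": 0.0, "colonoscopies_pct": 0.0}
    with pytest.raises(KeyError):
        cs.compare_to_reference(t2, "nonexistent", "COL_only")


@settings(max_examples=60, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50)), min_size=1, max_size=25),
       st.randoms(use_true_random=False))
def test_frontier_invariant_to_order_and_duplicates(points, rnd):
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    fr = find_frontier(x, y, tolerance=0.0)
    perm = list(range(len(points)))
    rnd.shuffle(perm)
    fr_p = find_frontier(x[perm], y[perm], tolerance=0.0)
    assert np.array_equal(fr.on_hull[perm], fr_p.on_hull)
    assert np.array_equal(fr.dominated[perm], fr_p.dominated)
    # duplicating every point changes nothing
    fr_d = find_frontier(np.concatenate([x, x]), np.concatenate([y, y]), tolerance=0.0)
    assert np.array_equal(fr_d.on_hull[: x.size], fr.on_hull)
    # hull implies near-efficient and non-dominated
    assert not (fr.on_hull & fr.dominated).any()
    assert (fr.near_efficient | ~fr.on_hull).all()
    # every non-hull point is strictly below the hull (oracle agreement)
    oracle = brute_force_efficient(x, y)
    assert np.array_equal(fr.on_hull, oracle)
    # non-dominated points off the hull are strictly beatable by a convex
    # combination; dominated ones are at least weakly below the hull
    strictly = ~fr.on_hull & ~fr.dominated
    if strictly.any():
        interp = hull_value(fr.hull_x, fr.hull_y, x[strictly])
        assert (interp > y[strictly] + 1e-12).all()
    interp_all = hull_value(fr.hull_x, fr.hull_y, x)
    assert (interp_all >= y - 1e-9).all()


@settings(max_examples=30, deadline=None)
@given(st.lists(st.tuples(st.floats(0, 100, allow_nan=False), st.floats(0, 100, allow_nan=False)),
                min_size=1, max_size=15),
       st.floats(0, 5), st.floats(0, 5))
def test_near_efficiency_monotone_in_tolerance(points, tol_a, tol_extra):
    x = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points])
    small = find_frontier(x, y, tolerance=tol_a)
    large = find_frontier(x, y, tolerance=tol_a + tol_extra)
    assert (large.near_efficient | ~small.near_efficient).all()
    assert small.near_efficient.sum() <= large.near_efficient.sum()


def test_hull_slopes_strictly_decreasing(table2):
    fr = find_frontier(table2["colonoscopies_per_1000"].to_numpy(dtype=float),
                       table2["qalys_gained_per_1000"].to_numpy(dtype=float))
    slopes = np.diff(fr.hull_y) / np.diff(fr.hull_x)
    assert (np.diff(slopes) < 1e-12).all()
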