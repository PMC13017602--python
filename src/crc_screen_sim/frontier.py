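"""Efficiency-frontier analysis of strategy outcomes.

Each strategy is a point in (colonoscopies per 1000, QALYs gained per 1000)
space.  The efficiency frontier is the upper-left concave hull: the piecewise
linear curve of maximal QALYs attainable at a given colonoscopy budget, with
non-increasing marginal returns.  A strategy is *dominated* if another needs
no more colonoscopies and gains at least as many QALYs (one strictly);
*on the hull* if it is a hull vertex (collinear frontier points included);
and *near-efficient* if it falls within a vertical tolerance below the
interpolated hull (default 0.125 QALYs per 1000 = 1.5 quality-adjusted
months per 1000 individuals).

A packaged fixture (``data/table2.csv``) carries the 34 published strategy
points used by the comparison helpers and the test-suite oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .outcomes import percent_change

__all__ = [
    "FrontierResult",
    "find_frontier",
    "frontier_value_at",
    "compare_to_reference",
    "load_table2",
    "NEAR_EFFICIENCY_TOLERANCE",
]

#: 1.5 quality-adjusted months on the per-1000 QALY axis
NEAR_EFFICIENCY_TOLERANCE = 1.5 / 12.0

_COLLINEAR_EPS = 1e-9


@dataclass
class FrontierResult:
    colonoscopies: np.ndarray
    qalys: np.ndarray
    dominated: np.ndarray       # bool per strategy
    on_hull: np.ndarray         # bool: vertex of (or collinear on) the hull
    near_efficient: np.ndarray  # within `tolerance` below the hull
    hull_x: np.ndarray          # hull vertex budgets, increasing
    hull_y: np.ndarray          # hull vertex QALYs, increasing
    tolerance: float

    def to_frame(self, labels=None) -> pd.DataFrame:
        df = pd.DataFrame({
            "colonoscopies_per_1000": self.colonoscopies,
            "qalys_gained_per_1000": self.qalys,
            "dominated": self.dominated,
            "on_hull": self.on_hull,
            "near_efficient": self.near_efficient,
        })
        if labels is not None:
            df.insert(0, "label", list(labels))
        return df


def _upper_left_hull(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vertices of the upper-left concave hull (collinear vertices retained)."""
    order = np.lexsort((-y, x))
    xs, ys = x[order], y[order]
    # per distinct budget keep only the best point
    keep = np.ones(xs.size, dtype=bool)
    keep[1:] = xs[1:] != xs[:-1]
    xs, ys = xs[keep], ys[keep]
    stack: list[tuple[float, float]] = []
    for px, py in zip(xs, ys):
        if stack and py <= stack[-1][1]:
            continue  # not above the current hull end: dominated, never a vertex
        while len(stack) >= 2:
            (x0, y0), (x1, y1) = stack[-2], stack[-1]
            cross = (x1 - x0) * (py - y0) - (y1 - y0) * (px - x0)
            if cross > _COLLINEAR_EPS * max(1.0, abs(px - x0) + abs(py - y0)):
                stack.pop()  # middle point lies strictly below the chord
            else:
                break
        stack.append((float(px), float(py)))
    hx = np.array([p[0] for p in stack])
    hy = np.array([p[1] for p in stack])
    return hx, hy


def hull_value(hull_x: np.ndarray, hull_y: np.ndarray, budget) -> np.ndarray:
    """Interpolated hull QALYs at ``budget`` (constant beyond the last vertex)."""
    b = np.asarray(budget, dtype=float)
    return np.interp(b, hull_x, hull_y)


def find_frontier(colonoscopies, qalys, tolerance: float = NEAR_EFFICIENCY_TOLERANCE) -> FrontierResult:
    """Identify dominated, efficient (hull) and near-efficient strategies.

    Invariant to input ordering and duplicated points.  Points beyond the
    last hull vertex are judged against that vertex's QALY level.
    """
    x = np.asarray(colonoscopies, dtype=float)
    y = np.asarray(qalys, dtype=float)
    if x.size == 0:
        raise ValueError("at least one strategy point is required")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("strategy points must be finite")

    hx, hy = _upper_left_hull(x, y)
    interp = hull_value(hx, hy, x)
    dist = interp - y
    near = dist <= tolerance + 1e-12

    # dominance: another point with <= colonoscopies, >= QALYs, one strict
    dominated = np.zeros(x.size, dtype=bool)
    order = np.lexsort((-y, x))
    best_y = -np.inf  # best QALYs among strictly cheaper budgets
    i = 0
    xs, ys = x[order], y[order]
    while i < xs.size:
        j = i
        while j < xs.size and xs[j] == xs[i]:
            j += 1
        block = order[i:j]
        top = ys[i]  # max QALYs at this budget (sorted desc within budget)
        for k, idx in enumerate(block):
            yy = y[idx]
            dominated[idx] = (yy <= best_y) or (yy < top)
        best_y = max(best_y, top)
        i = j
    # a hull point lies at vertical distance 0 and is never dominated (this
    # keeps collinear frontier points in, but excludes flat-tail duplicates)
    on_hull = (dist <= _COLLINEAR_EPS * np.maximum(1.0, np.abs(interp))) & ~dominated
    return FrontierResult(
        colonoscopies=x, qalys=y, dominated=dominated, on_hull=on_hull,
        near_efficient=near, hull_x=hx, hull_y=hy, tolerance=float(tolerance),
    )


def frontier_value_at(fr: FrontierResult, budget: float) -> float:
    """QALYs attainable on the frontier at a colonoscopy ``budget`` per 1000."""
    if budget < fr.hull_x[0]:
        raise ValueError(
            f"budget {budget} is below the cheapest frontier strategy ({fr.hull_x[0]})"
        )
    return float(hull_value(fr.hull_x, fr.hull_y, budget))


def compare_to_reference(outcomes: pd.DataFrame, strategy_label: str,
                         reference_label: str) -> dict:
    """Percent change in QALYs gained and colonoscopy demand of one strategy
    versus a reference, from an outcome table with columns
    ``label``, ``colonoscopies_per_1000``, ``qalys_gained_per_1000``."""
    tbl = outcomes.set_index("label")
    for lbl in (strategy_label, reference_label):
        if lbl not in tbl.index:
            raise KeyError(f"strategy {lbl!r} not present in the outcome table")
    srow, rrow = tbl.loc[strategy_label], tbl.loc[reference_label]
    return {
        "qalys_pct": percent_change(float(srow["qalys_gained_per_1000"]),
                                    float(rrow["qalys_gained_per_1000"])),
        "colonoscopies_pct": percent_change(float(srow["colonoscopies_per_1000"]),
                                            float(rrow["colonoscopies_per_1000"])),
    }


def load_table2() -> pd.DataFrame:
    """The packaged 34-strategy published outcome table."""
    path = Path(str(resources.files("crc_screen_sim").joinpath("data/table2.csv")))
    return pd.read_csv(path)
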