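"""Segmented (piecewise) linear regression with an R²-selected cut.

The procedure quantifies a threshold seen on a smoothed scatter without
any spline machinery: ordinary least-squares lines are fitted to the data
below every candidate cut on a 1 ng/mL grid (default 15–40 ng/mL), the cut
maximizing the lower-segment R² is selected, a second line is fitted to
the remaining points, and the threshold is reported as the intersection of
the two lines. The two segments are fitted independently — they need not
meet — and the intersection restores a continuous description.

An optional second search over a higher candidate window looks for an
upper threshold; its result always carries a reliability flag, since
near-parallel segments push the intersection far outside the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentFit",
    "Intersection",
    "PiecewiseResult",
    "grid_search_cut",
    "fit_lower_segment",
    "fit_upper_segment",
    "intersect_lines",
    "piecewise_analysis",
]


@dataclass
class SegmentFit:
    """An OLS line on a restricted 25(OH)D range."""

    x_range: tuple[float, float]
    slope: float
    intercept: float
    slope_ci95: tuple[float, float]
    slope_p: float
    r_squared: float
    n_points: int

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def _ols_segment(x: np.ndarray, y: np.ndarray) -> SegmentFit:
    if len(x) < 3:
        raise ValueError("segment needs at least 3 points")
    res = stats.linregress(x, y)
    dof = len(x) - 2
    tcrit = stats.t.ppf(0.975, dof)
    return SegmentFit(
        x_range=(float(x.min()), float(x.max())),
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_ci95=(
            float(res.slope - tcrit * res.stderr),
            float(res.slope + tcrit * res.stderr),
        ),
        slope_p=float(res.pvalue),
        r_squared=float(res.rvalue**2),
        n_points=len(x),
    )


@dataclass
class Intersection:
    x: float
    y: float
    reliable: bool
    slope_difference: float
    reason: str = ""
    y_ci95: tuple[float, float] | None = None


@dataclass
class PiecewiseResult:
    cut: float
    lower_fit: SegmentFit
    upper_fit: SegmentFit
    intersection: Intersection
    r2_profile: pd.DataFrame
    second_threshold: "PiecewiseResult | None" = None
    second_reliable: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def intersection_x(self) -> float:
        return self.intersection.x

    @property
    def intersection_y(self) -> float:
        return self.intersection.y

    def to_dict(self) -> dict:
        d = {
            "cut": self.cut,
            "lower": vars(self.lower_fit) | {},
            "upper": vars(self.upper_fit) | {},
            "intersection_x": self.intersection.x,
            "intersection_y": self.intersection.y,
            "intersection_reliable": self.intersection.reliable,
            "intersection_y_ci95": self.intersection.y_ci95,
            "notes": self.notes,
        }
        if self.second_threshold is not None:
            d["second_cut"] = self.second_threshold.cut
            d["second_intersection_x"] = self.second_threshold.intersection.x
            d["second_reliable"] = self.second_reliable
        return d


_R2_TIE_TOL = 1e-9


def grid_search_cut(
    x, y, lo: float = 15.0, hi: float = 40.0, step: float = 1.0
) -> tuple[pd.DataFrame, float]:
    """R² profile of lower-segment fits over candidate cuts.

    For each candidate c in [lo, hi] (inclusive, ``step`` spacing) an OLS
    line is fitted to the points with x <= c and its R² recorded; the cut
    with maximal R² is selected, ties broken toward the largest cut (which
    maximizes the data entering the lower segment). Candidates capturing
    fewer than 3 points are skipped with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    cuts = np.arange(lo, hi + step / 2, step)
    logger.info("grid_search_cut: %d candidate cuts in [%g, %g]", len(cuts), lo, hi)
    rows = []
    for c in cuts:
        sel = x <= c
        if sel.sum() < 3 or np.ptp(x[sel]) == 0:
            logger.warning("cut %g captures <3 usable points; skipped", c)
            continue
        fit = _ols_segment(x[sel], y[sel])
        rows.append({"cut": float(c), "r_squared": fit.r_squared, "n_points": fit.n_points})
    if not rows:
        raise ValueError("no candidate cut captured at least 3 points")
    profile = pd.DataFrame(rows)
    best_r2 = profile["r_squared"].max()
    tied = profile.loc[profile["r_squared"] >= best_r2 - _R2_TIE_TOL, "cut"]
    selected = float(tied.max())
    return profile, selected


def fit_lower_segment(x, y, cut: float) -> SegmentFit:
    """OLS on the points with x <= cut."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sel = np.isfinite(x) & np.isfinite(y) & (x <= cut)
    if sel.sum() < 3:
        raise ValueError(f"fewer than 3 points at or below cut {cut}")
    return _ols_segment(x[sel], y[sel])


def fit_upper_segment(x, y, cut: float) -> SegmentFit:
    """OLS on the points with x > cut (the near-plateau region)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sel = np.isfinite(x) & np.isfinite(y) & (x > cut)
    if sel.sum() < 3:
        raise ValueError(f"fewer than 3 points above cut {cut}")
    return _ols_segment(x[sel], y[sel])


def intersect_lines(
    lower: SegmentFit, upper: SegmentFit, parallel_tol: float = 1e-8
) -> Intersection:
    """Intersection of two fitted lines, flagged when near-parallel.

    Solves a1 + b1 x = a2 + b2 x. When the slope difference is within
    ``parallel_tol`` (relative to the slope magnitudes) the intersection is
    unreliable — the abscissa diverges — and is returned flagged rather
    than raising.
    """
    db = lower.slope - upper.slope
    scale = max(1.0, abs(lower.slope), abs(upper.slope))
    if abs(db) <= parallel_tol * scale:
        return Intersection(
            x=float("nan"),
            y=float("nan"),
            reliable=False,
            slope_difference=db,
            reason="segments are near-parallel; intersection abscissa diverges",
        )
    xi = (upper.intercept - lower.intercept) / db
    yi = lower.intercept + lower.slope * xi
    return Intersection(x=float(xi), y=float(yi), reliable=True, slope_difference=db)


def _bootstrap_intersection_ci(
    x: np.ndarray,
    y: np.ndarray,
    cut: float,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, float] | None:
    """Percentile bootstrap CI for the intersection ordinate.

    Patients are resampled with replacement; both segments are refitted at
    the fixed selected cut and the intersection recomputed per resample.
    """
    rng = np.random.default_rng(seed)
    n = len(x)
    ys = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        lo_sel = xb <= cut
        hi_sel = ~lo_sel
        if lo_sel.sum() < 3 or hi_sel.sum() < 3:
            continue
        if np.ptp(xb[lo_sel]) == 0 or np.ptp(xb[hi_sel]) == 0:
            continue
        inter = intersect_lines(
            _ols_segment(xb[lo_sel], yb[lo_sel]), _ols_segment(xb[hi_sel], yb[hi_sel])
        )
        if inter.reliable:
            ys.append(inter.y)
    if len(ys) < max(50, n_boot // 10):
        return None
    lo_q, hi_q = np.percentile(ys, [2.5, 97.5])
    return (float(lo_q), float(hi_q))


def _second_threshold_search(
    x: np.ndarray,
    y: np.ndarray,
    first_cut: float,
    window: tuple[float, float],
    step: float,
) -> tuple["PiecewiseResult | None", bool]:
    """Search for an upper threshold above the plateau region.

    For each candidate c in the window, a line is fitted to the points with
    x >= c and the candidate maximizing R² wins; the middle (plateau)
    segment between the first cut and the selected candidate provides the
    other line. The intersection is reliable only when the steep segment's
    slope is significant and the abscissa lies inside the observed range.
    """
    lo_w, hi_w = window
    cands = np.arange(lo_w, hi_w + step / 2, step)
    rows = []
    for c in cands:
        sel = x >= c
        if sel.sum() < 3 or np.ptp(x[sel]) == 0:
            continue
        fit = _ols_segment(x[sel], y[sel])
        rows.append({"cut": float(c), "r_squared": fit.r_squared, "n_points": fit.n_points})
    if not rows:
        return None, False
    profile = pd.DataFrame(rows)
    best_r2 = profile["r_squared"].max()
    tied = profile.loc[profile["r_squared"] >= best_r2 - _R2_TIE_TOL, "cut"]
    c2 = float(tied.min())  # smallest tied candidate maximizes upper-segment data
    upper_sel = x >= c2
    mid_sel = (x > first_cut) & (x < c2)
    if mid_sel.sum() < 3 or np.ptp(x[mid_sel]) == 0:
        return None, False
    upper = _ols_segment(x[upper_sel], y[upper_sel])
    middle = _ols_segment(x[mid_sel], y[mid_sel])
    inter = intersect_lines(middle, upper)
    reliable = bool(
        inter.reliable
        and upper.slope_p < 0.05
        and x.min() <= inter.x <= x.max()
    )
    result = PiecewiseResult(
        cut=c2,
        lower_fit=middle,
        upper_fit=upper,
        intersection=inter,
        r2_profile=profile,
    )
    return result, reliable


def piecewise_analysis(
    x,
    y,
    lo: float = 15.0,
    hi: float = 40.0,
    step: float = 1.0,
    second_window: tuple[float, float] | None = (40.0, 70.0),
    n_boot: int = 1000,
    seed: int | None = None,
) -> PiecewiseResult:
    """Full segmented-regression recipe for one biomarker.

    Composes the R² grid search, the two independent segment fits, the
    intersection point with a bootstrap CI on its ordinate, and the
    optional upper-threshold search (always flagged for reliability).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    profile, cut = grid_search_cut(x, y, lo=lo, hi=hi, step=step)
    lower = fit_lower_segment(x, y, cut)
    upper = fit_upper_segment(x, y, cut)
    inter = intersect_lines(lower, upper)
    notes = []
    if inter.reliable:
        if not (x.min() <= inter.x <= x.max()):
            inter.reliable = False
            inter.reason = "intersection outside the observed 25(OH)D range"
            notes.append(inter.reason)
        else:
            inter.y_ci95 = _bootstrap_intersection_ci(x, y, cut, n_boot=n_boot, seed=seed)
    else:
        notes.append(inter.reason)
    second, second_ok = (None, False)
    if second_window is not None:
        second, second_ok = _second_threshold_search(x, y, cut, second_window, step)
        if second is not None and not second_ok:
            notes.append(
                "second-threshold search did not yield a reliable intersection"
            )
    return PiecewiseResult(
        cut=cut,
        lower_fit=lower,
        upper_fit=upper,
        intersection=inter,
        r2_profile=profile,
        second_threshold=second,
        second_reliable=second_ok,
        notes=notes,
    )
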