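"""LOWESS screening of biomarker vs 25(OH)D scatter.

Locally weighted scatterplot smoothing is the visual first stage of the
threshold analysis: a tricube-weighted local linear fit through the
nearest ``bandwidth * n`` points at each evaluation abscissa, optionally
robustified by bisquare reweighting iterations. It is used qualitatively —
to judge whether the scatter can be approximated by straight-line
segments — so no confidence bands are produced.

The numerical engine is ``statsmodels.nonparametric.lowess`` (tricube
kernel, local degree 1, bisquare robustness), exposed behind this module's
interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess


class DegenerateInputError(ValueError):
    pass


@dataclass
class SmoothCurve:
    """A smoothed curve evaluated on a strictly increasing grid."""

    grid_x: np.ndarray
    fitted_y: np.ndarray
    bandwidth: float

    def __post_init__(self):
        if len(self.grid_x) != len(self.fitted_y):
            raise ValueError("grid_x and fitted_y must have equal length")
        if np.any(np.diff(self.grid_x) <= 0):
            raise ValueError("grid_x must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"grid_x": self.grid_x, "fitted_y": self.fitted_y})


def lowess_fit(
    x,
    y,
    bandwidth: float = 0.8,
    robust_iterations: int = 0,
    grid: np.ndarray | int | None = None,
) -> SmoothCurve:
    """Tricube-weighted local linear smooth of y on x.

    ``bandwidth`` is the fraction of the data entering each local fit
    (default 0.8, the conventional default). By default the curve is
    evaluated at the sorted, deduplicated observed x values; pass an
    integer ``grid`` for a uniform grid of that size (useful for plotting)
    or an explicit array of abscissae.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have the same length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise DegenerateInputError("need at least 3 finite observations")
    if np.ptp(x) == 0:
        raise DegenerateInputError("all x values identical")
    if not 0 < bandwidth <= 1:
        raise ValueError("bandwidth must be in (0, 1]")
    if robust_iterations < 0:
        raise ValueError("robust_iterations must be >= 0")

    if grid is None:
        xvals = np.unique(x)
    elif np.isscalar(grid):
        xvals = np.linspace(x.min(), x.max(), int(grid))
    else:
        xvals = np.asarray(grid, dtype=float)
    # keep at least three neighbours in every local fit so a local line is
    # always determined at arbitrary evaluation abscissae
    frac = max(bandwidth, min(1.0, 3.001 / len(x)))
    fitted = _sm_lowess(
        y, x, frac=frac, it=robust_iterations, xvals=xvals, is_sorted=False
    )
    return SmoothCurve(grid_x=xvals, fitted_y=np.asarray(fitted), bandwidth=bandwidth)


def extrapolation_flags(curve: SmoothCurve, y) -> np.ndarray:
    """Flag fitted values outside [min(y) - range, max(y) + range].

    Local linear fits may overshoot the data range slightly; values beyond
    a full data range are a sign of a degenerate local neighbourhood.
    """
    y = np.asarray(y, dtype=float)
    lo, hi = np.nanmin(y), np.nanmax(y)
    span = hi - lo
    return (curve.fitted_y < lo - span) | (curve.fitted_y > hi + span)


def plot_smooth(x, y, curve: SmoothCurve, path, xlabel="25(OH)D (ng/mL)", ylabel=""):
    """Scatter plus smoothed line, written to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(x, y, s=8, alpha=0.4, color="steelblue")
    ax.plot(curve.grid_x, curve.fitted_y, color="firebrick", lw=2)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
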