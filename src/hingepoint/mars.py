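"""Univariate multivariate-adaptive-regression-splines (MARS) engine.

Fits continuous piecewise-linear models built from mirrored hinge bases
max(0, x - t) and max(0, t - x):

* a greedy forward pass adds the mirrored hinge pair whose knot most
  reduces the residual sum of squares, refitting all coefficients by
  ordinary least squares at every step;
* a backward pass deletes terms one at a time (the deletion that least
  increases the RSS), yielding one candidate model per size, each scored
  by generalized cross-validation (GCV);
* model size is selected by k-fold cross-validation repeated many times
  with reshuffled folds, minimizing mean held-out RSS, then the selected
  size is refitted on all data.

The single predictor here is serum 25(OH)D and the response a biomarker
(calcium or PTH), but nothing in the engine is specific to those units.
Candidate knots are all distinct observed x values except the extremes
(an endpoint knot makes one half of the mirrored pair identically zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "HingeBasis",
    "MarsModel",
    "CvSelection",
    "DegenerateInputError",
    "forward_pass",
    "gcv_score",
    "backward_prune",
    "fit_mars",
    "extract_thresholds",
    "primary_hinge",
    "ThresholdSummary",
    "SegmentInfo",
]


class DegenerateInputError(ValueError):
    """Raised for inputs on which no hinge model can be fitted."""


@dataclass(frozen=True)
class HingeBasis:
    """A single hinge basis function.

    direction ``"+"`` is max(0, x - knot); ``"-"`` is max(0, knot - x).
    """

    knot: float
    direction: str

    def __post_init__(self):
        if self.direction not in ("+", "-"):
            raise ValueError("direction must be '+' or '-'")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.direction == "+":
            return np.maximum(0.0, x - self.knot)
        return np.maximum(0.0, self.knot - x)


def _design(x: np.ndarray, bases: list[HingeBasis]) -> np.ndarray:
    cols = [np.ones_like(x)] + [b.evaluate(x) for b in bases]
    return np.column_stack(cols)


def _lstsq(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


@dataclass
class MarsModel:
    """A fitted hinge-regression model.

    ``terms`` pairs each hinge basis with its coefficient. ``hinges`` are
    the sorted distinct knots, ``segment_slopes`` the implied derivative on
    each of the ``len(hinges) + 1`` segments.
    """

    intercept: float
    terms: list[tuple[HingeBasis, float]]
    r_squared: float
    x_range: tuple[float, float]
    y_range: tuple[float, float]

    @property
    def hinges(self) -> list[float]:
        return sorted({b.knot for b, _ in self.terms})

    @property
    def segment_slopes(self) -> list[float]:
        """Derivative of the fitted function on each inter-hinge segment."""
        hinges = self.hinges
        edges = [-np.inf] + hinges + [np.inf]
        slopes = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            s = 0.0
            for basis, coef in self.terms:
                if basis.direction == "+" and basis.knot <= lo:
                    s += coef
                elif basis.direction == "-" and basis.knot >= hi:
                    s -= coef
            slopes.append(s)
        return slopes

    def predict(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.full(x.shape, self.intercept)
        for basis, coef in self.terms:
            y += coef * basis.evaluate(x)
        return y

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "terms": [
                {"direction": b.direction, "knot": b.knot, "coefficient": c}
                for b, c in self.terms
            ],
            "r_squared": self.r_squared,
            "hinges": self.hinges,
            "segment_slopes": self.segment_slopes,
        }


@dataclass
class CvSelection:
    """Cross-validation table behind the selected model size."""

    candidate_sizes: list[int]
    mean_cv_rss: list[float]
    selected_size: int
    k_folds: int = 10
    repetitions: int = 100

    def to_dict(self) -> dict:
        return {
            "candidate_sizes": self.candidate_sizes,
            "mean_cv_rss": self.mean_cv_rss,
            "selected_size": self.selected_size,
            "k_folds": self.k_folds,
            "repetitions": self.repetitions,
        }


def _candidate_knots(x: np.ndarray) -> np.ndarray:
    knots = np.unique(x)
    return knots[1:-1]  # endpoint knots give a zero column in one direction


def forward_pass(
    x: np.ndarray,
    y: np.ndarray,
    max_terms: int = 6,
    rel_tol: float = 1e-8,
    _validate: bool = True,
) -> list[HingeBasis]:
    """Greedy forward knot search; returns the accepted bases in order.

    At every step, for each candidate knot t the mirrored pair
    (max(0, x-t), max(0, t-x)) is appended to the current design and all
    coefficients are refitted by least squares; the knot with the smallest
    resulting RSS wins (ties broken toward the smallest knot). The pass
    stops at ``max_terms`` basis terms or when the relative RSS improvement
    falls below ``rel_tol`` of the total sum of squares.

    The knot scan is vectorized over candidates through stacked
    normal-equation solves with a small ridge for numerical safety; the
    accepted model is refitted exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if _validate:
        if len(x) != len(y):
            raise ValueError("x and y must have the same length")
        if len(x) < 10:
            raise DegenerateInputError("need at least 10 observations")
    if max_terms < 2:
        raise ValueError("max_terms must be >= 2")
    knots = _candidate_knots(x)
    if len(knots) == 0:
        raise DegenerateInputError("fewer than 3 distinct x values")

    n = len(x)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        return []  # constant response: no hinge can improve the intercept fit
    # hinge columns for every candidate knot, shape (n, K)
    Hp = np.maximum(0.0, x[:, None] - knots[None, :])
    Hm = np.maximum(0.0, knots[None, :] - x[:, None])
    hp2 = np.einsum("ij,ij->j", Hp, Hp)
    hm2 = np.einsum("ij,ij->j", Hm, Hm)
    hphm = np.einsum("ij,ij->j", Hp, Hm)
    hpy = Hp.T @ y
    hmy = Hm.T @ y
    yty = float(y @ y)

    bases: list[HingeBasis] = []
    B = _design(x, bases)
    coef, rss = _lstsq(B, y)
    while len(bases) + 2 <= max_terms and len(bases) + 3 < n:
        m = B.shape[1]
        K = len(knots)
        G = B.T @ B
        c = B.T @ y
        BtHp = B.T @ Hp  # (m, K)
        BtHm = B.T @ Hm
        A = np.empty((K, m + 2, m + 2))
        A[:, :m, :m] = G
        A[:, :m, m] = BtHp.T
        A[:, m, :m] = BtHp.T
        A[:, :m, m + 1] = BtHm.T
        A[:, m + 1, :m] = BtHm.T
        A[:, m, m] = hp2
        A[:, m + 1, m + 1] = hm2
        A[:, m, m + 1] = hphm
        A[:, m + 1, m] = hphm
        b = np.empty((K, m + 2))
        b[:, :m] = c
        b[:, m] = hpy
        b[:, m + 1] = hmy
        # ridge keeps near-singular candidates (e.g. knots adjacent to an
        # endpoint) finite during the scan; the winner is refitted exactly
        ridge = 1e-10 * np.trace(G) / m
        A[:, np.arange(m + 2), np.arange(m + 2)] += ridge
        try:
            sol = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover - ridge should prevent
            sol = np.stack([np.linalg.lstsq(A[k], b[k], rcond=None)[0] for k in range(K)])
        cand_rss = yty - np.einsum("kj,kj->k", sol, b)
        best = int(np.argmin(cand_rss))  # argmin -> first -> smallest knot on ties
        trial = bases + [HingeBasis(float(knots[best]), "+"), HingeBasis(float(knots[best]), "-")]
        Bt = _design(x, trial)
        coef_t, rss_t = _lstsq(Bt, y)
        if rss - rss_t <= rel_tol * tss:
            break
        bases, B, coef, rss = trial, Bt, coef_t, rss_t
    if not bases and np.ptp(x) == 0:
        raise DegenerateInputError("all x values identical")
    return bases


def gcv_score(
    rss: float, n: int, n_terms: int, n_knots: int, penalty_per_knot: float = 2.0
) -> float:
    """Generalized cross-validation score rss / (n * (1 - C/n)^2).

    The effective parameter count C = n_terms + penalty_per_knot * n_knots
    charges each basis coefficient once plus a per-knot penalty for the
    selected knot locations. Models with C >= n are inadmissible and score
    +inf rather than raising.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    c_m = n_terms + penalty_per_knot * n_knots
    if c_m >= n:
        return float("inf")
    return rss / (n * (1.0 - c_m / n) ** 2)


@dataclass
class _PrunedModel:
    bases: list[HingeBasis]
    coef: np.ndarray  # intercept first
    rss: float
    gcv: float


def backward_prune(
    bases: list[HingeBasis],
    x: np.ndarray,
    y: np.ndarray,
    penalty_per_knot: float = 2.0,
) -> list[_PrunedModel]:
    """Nested deletion sequence from the full model down to intercept-only.

    Each step removes the single term whose deletion least increases the
    RSS. Returns one model per size, largest first, each carrying its GCV
    score (coefficient count includes the intercept).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    current = list(bases)
    sequence: list[_PrunedModel] = []
    coef, rss = _lstsq(_design(x, current), y)
    while True:
        n_knots = len({b.knot for b in current})
        sequence.append(
            _PrunedModel(
                list(current),
                coef,
                rss,
                gcv_score(rss, n, len(current) + 1, n_knots, penalty_per_knot),
            )
        )
        if not current:
            break
        best_rss, best_idx, best_coef = np.inf, -1, None
        for i in range(len(current)):
            trial = current[:i] + current[i + 1 :]
            coef_t, rss_t = _lstsq(_design(x, trial), y)
            if rss_t < best_rss:
                best_rss, best_idx, best_coef = rss_t, i, coef_t
        current = current[:best_idx] + current[best_idx + 1 :]
        coef, rss = best_coef, best_rss
    return sequence


def _best_single_basis(x: np.ndarray, y: np.ndarray) -> _PrunedModel:
    """Exact RSS-optimal one-term hinge model (either direction, any knot)."""
    best = None
    for knot in _candidate_knots(x):
        for direction in ("+", "-"):
            basis = HingeBasis(float(knot), direction)
            coef, rss = _lstsq(_design(x, [basis]), y)
            if best is None or rss < best.rss - 1e-12:
                best = _PrunedModel([basis], coef, rss,
                                    gcv_score(rss, len(x), 2, 1))
    return best


def _model_of_size(sequence: list[_PrunedModel], size: int) -> _PrunedModel:
    # sequence is largest-first with one model per size
    sizes = [len(m.bases) for m in sequence]
    if size >= sizes[0]:
        return sequence[0]
    return sequence[sizes[0] - size]


def fit_mars(
    x,
    y,
    k_folds: int = 10,
    repetitions: int = 100,
    max_terms: int = 6,
    penalty_per_knot: float = 2.0,
    seed: int | None = None,
) -> tuple[MarsModel, CvSelection]:
    """Fit a hinge model with repeated k-fold model-size selection.

    Each repetition reshuffles the data into ``k_folds`` folds; for every
    fold a forward + backward pass on the training part yields one model
    per size, and the held-out RSS is recorded per size. The size with the
    smallest mean held-out RSS (ties toward the smaller size) is refitted
    on all data. Deterministic given ``seed``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 2 * k_folds:
        raise DegenerateInputError(
            f"n={n} is too small for {k_folds}-fold validation; lower k_folds"
        )
    rng = np.random.default_rng(seed)
    sizes = np.arange(max_terms + 1)
    rss_sum = np.zeros(max_terms + 1)
    rss_count = np.zeros(max_terms + 1)
    for _ in range(repetitions):
        perm = rng.permutation(n)
        for fold in np.array_split(perm, k_folds):
            train = np.setdiff1d(perm, fold, assume_unique=True)
            xt, yt = x[train], y[train]
            try:
                fwd = forward_pass(xt, yt, max_terms=max_terms, _validate=False)
            except DegenerateInputError:
                continue
            seq = backward_prune(fwd, xt, yt, penalty_per_knot)
            xv, yv = x[fold], y[fold]
            for s in sizes:
                m = _model_of_size(seq, int(s))
                pred = _design(xv, m.bases) @ m.coef
                rss_sum[s] += float(np.sum((yv - pred) ** 2))
                rss_count[s] += 1
    mean_cv = rss_sum / np.maximum(rss_count, 1)
    selected = int(np.argmin(mean_cv))  # first minimum -> smaller size on ties
    selection = CvSelection(
        candidate_sizes=list(map(int, sizes)),
        mean_cv_rss=list(map(float, mean_cv)),
        selected_size=selected,
        k_folds=k_folds,
        repetitions=repetitions,
    )
    # refit the selected size on all data with a search dedicated to that
    # size: the knots of a small final model are then optimal for that size
    # instead of being inherited from the over-grown forward expansion
    if selected == 1:
        final = _best_single_basis(x, y)
    else:
        cap = selected + (selected % 2) if selected > 0 else 2
        fwd = forward_pass(x, y, max_terms=max(cap, 2))
        seq = backward_prune(fwd, x, y, penalty_per_knot)
        final = _model_of_size(seq, selected)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - final.rss / tss if tss > 0 else 0.0
    model = MarsModel(
        intercept=float(final.coef[0]),
        terms=[(b, float(c)) for b, c in zip(final.bases, final.coef[1:])],
        r_squared=r2,
        x_range=(float(x.min()), float(x.max())),
        y_range=(float(y.min()), float(y.max())),
    )
    logger.debug(
        "fit_mars: n=%d selected size %d (cv rss %.4g), r2=%.4f, hinges=%s",
        n, selected, mean_cv[selected], r2, model.hinges,
    )
    return model, selection


@dataclass
class SegmentInfo:
    """One linear segment of a fitted hinge model."""

    x_lo: float
    x_hi: float
    slope: float
    level: float  # fitted value at the segment midpoint (clipped to data range)
    is_plateau: bool


@dataclass
class ThresholdSummary:
    hinges: list[float]
    segments: list[SegmentInfo] = field(default_factory=list)

    @property
    def plateau_segments(self) -> list[SegmentInfo]:
        return [s for s in self.segments if s.is_plateau]

    def plateau_level(self, above: float | None = None) -> float | None:
        """Fitted level of the plateau, the widest segment classified flat.

        Restricted to segments ending above ``above`` when given. Falls
        back to the flattest qualifying segment when none is classified as
        a plateau, and None when there is no qualifying segment at all.
        """
        cands = self.plateau_segments
        if above is not None:
            cands = [s for s in cands if s.x_hi > above]
        if cands:
            widest = max(cands, key=lambda s: s.x_hi - s.x_lo)
            return widest.level
        flat = self.flattest_segment(above=above)
        return flat.level if flat is not None else None

    def flattest_segment(self, above: float | None = None) -> SegmentInfo | None:
        cands = self.segments
        if above is not None:
            cands = [s for s in cands if s.x_hi > above]
        if not cands:
            return None
        return min(cands, key=lambda s: abs(s.slope))


def primary_hinge(model: MarsModel) -> tuple[float, float] | None:
    """The threshold knot: where the fitted response flattens.

    Returns (knot, slope_below) for the hinge with the largest drop in
    absolute slope from its left to its right segment — the steep-to-flat
    transition read as the biomarker's sufficiency threshold — or None for
    an intercept-only model.
    """
    hinges = model.hinges
    if not hinges:
        return None
    slopes = model.segment_slopes
    drops = [abs(slopes[i]) - abs(slopes[i + 1]) for i in range(len(hinges))]
    i = int(np.argmax(drops))
    return hinges[i], slopes[i]


def extract_thresholds(
    model: MarsModel, slope_epsilon: float | None = None
) -> ThresholdSummary:
    """Hinge locations with per-segment slopes and plateau levels.

    A segment is classified as a plateau when its |slope| is below
    ``slope_epsilon``. By default the threshold is 0.1 in normalized units,
    i.e. 0.1 * (training y-range / training x-range): flat to within the
    sampling noise of a segment slope rather than numerically zero.
    """
    hinges = model.hinges
    x_lo, x_hi = model.x_range
    if slope_epsilon is None:
        y_span = model.y_range[1] - model.y_range[0]
        x_span = x_hi - x_lo if x_hi > x_lo else 1.0
        slope_epsilon = 0.1 * y_span / x_span
    edges = [x_lo] + [h for h in hinges if x_lo < h < x_hi] + [x_hi]
    slopes = model.segment_slopes
    segments = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (lo + hi)
        # segment index in the unclipped slope list
        idx = int(np.searchsorted(hinges, mid, side="left"))
        slope = slopes[idx]
        segments.append(
            SegmentInfo(
                x_lo=lo,
                x_hi=hi,
                slope=slope,
                level=float(model.predict(mid)[0]),
                is_plateau=abs(slope) < slope_epsilon,
            )
        )
    return ThresholdSummary(hinges=hinges, segments=segments)
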