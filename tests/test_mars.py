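"""Hinge-regression engine: oracle equivalence, recovery, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hingepoint.mars import (
    DegenerateInputError,
    HingeBasis,
    MarsModel,
    _design,
    backward_prune,
    extract_thresholds,
    fit_mars,
    forward_pass,
    gcv_score,
    primary_hinge,
)


def brute_force_best_pair_rss(x, y, bases):
    """Independent exhaustive scan: min RSS over all candidate knots when a
    mirrored hinge pair is added to the given basis set."""
    knots = np.unique(x)[1:-1]
    best = np.inf
    best_knot = None
    for t in knots:
        trial = bases + [HingeBasis(float(t), "+"), HingeBasis(float(t), "-")]
        X = _design(x, trial)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ coef) ** 2))
        if rss < best - 1e-12:
            best, best_knot = rss, float(t)
    return best, best_knot


class TestForwardPass:
    def test_realizable_single_hinge_recovered_exactly(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 20, 50)
        x[7] = 10.0  # make the generating knot a candidate
        y = 2.0 * np.maximum(0, x - 10.0) + 1.0
        bases = forward_pass(x, y, max_terms=4)
        assert bases[0].knot == 10.0
        X = _design(x, bases[:2])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert float(np.sum((y - X @ coef) ** 2)) == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("trial_seed", range(6))
    def test_each_step_matches_exhaustive_knot_scan(self, trial_seed):
        rng = np.random.default_rng(trial_seed)
        n = 35
        x = rng.uniform(0, 10, n)
        y = np.maximum(0, x - 3) - 2 * np.maximum(0, x - 7) + rng.normal(0, 0.3, n)
        accepted = forward_pass(x, y, max_terms=4)
        # replay the greedy steps, checking each accepted pair against the oracle
        for step in range(0, len(accepted), 2):
            current = list(accepted[:step])
            _, oracle_knot = brute_force_best_pair_rss(x, y, current)
            assert accepted[step].knot == oracle_knot

    def test_constant_response_accepts_no_terms(self):
        x = np.linspace(0, 10, 20)
        assert forward_pass(x, np.full(20, 2.0)) == []

    def test_pure_line_fitted_exactly_after_one_pair(self):
        # a line is realizable with a mirrored pair at any knot
        x = np.linspace(0, 10, 25)
        y = 3.0 * x
        bases = forward_pass(x, y, max_terms=2)
        X = _design(x, bases)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert float(np.sum((y - X @ coef) ** 2)) == pytest.approx(0.0, abs=1e-16)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            forward_pass(np.full(20, 1.0), np.arange(20.0))
        with pytest.raises(DegenerateInputError):
            forward_pass(np.arange(5.0), np.arange(5.0))


class TestGcvScore:
    def test_zero_rss_scores_zero(self):
        assert gcv_score(0.0, 100, 3, 1) == 0.0

    def test_saturated_model_is_inadmissible(self):
        assert gcv_score(1.0, 10, 8, 1, penalty_per_knot=2.0) == np.inf

    def test_strictly_increasing_in_model_size_at_fixed_rss(self):
        scores = [gcv_score(5.0, 200, m, m // 2) for m in range(1, 20)]
        assert all(b > a for a, b in zip(scores, scores[1:]))


class TestBackwardPrune:
    def test_single_term_sequence_length(self):
        x = np.linspace(0, 10, 30)
        y = np.maximum(0, x - 4)
        seq = backward_prune([HingeBasis(4.0, "+")], x, y)
        assert [len(m.bases) for m in seq] == [1, 0]

    def test_noiseless_single_kink_has_zero_rss_at_true_size(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 40)
        x[0] = 3.0
        y = 1.5 * np.maximum(0, x - 3.0) + 0.25
        fwd = forward_pass(x, y, max_terms=6)
        seq = backward_prune(fwd, x, y)
        by_size = {len(m.bases): m for m in seq}
        assert by_size[2].rss == pytest.approx(0.0, abs=1e-18)
        assert by_size[0].rss == pytest.approx(float(np.sum((y - y.mean()) ** 2)))

    def test_noiseless_two_kink_near_interpolation(self):
        # greedy knot placement compromises between kinks, so recovery is
        # near-exact (tiny residual relative to the signal), not exact
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 40)
        x[0], x[1] = 3.0, 7.0
        y = 1.5 * np.maximum(0, x - 3.0) - 0.5 * np.maximum(0, 7.0 - x)
        fwd = forward_pass(x, y, max_terms=6)
        seq = backward_prune(fwd, x, y)
        tss = float(np.sum((y - y.mean()) ** 2))
        assert min(m.rss for m in seq if len(m.bases) >= 4) / tss < 1e-4

    def test_each_deletion_step_is_locally_optimal(self):
        # every pruning step removes the term whose deletion increases the
        # RSS least, verified against exhaustive single-term deletion
        rng = np.random.default_rng(8)
        n = 30
        x = rng.uniform(0, 10, n)
        y = np.maximum(0, x - 5) + rng.normal(0, 0.2, n)
        fwd = forward_pass(x, y, max_terms=6)
        seq = backward_prune(fwd, x, y)
        for model, smaller in zip(seq[:-1], seq[1:]):
            best = np.inf
            for i in range(len(model.bases)):
                trial = model.bases[:i] + model.bases[i + 1 :]
                X = _design(x, trial)
                coef, *_ = np.linalg.lstsq(X, y, rcond=None)
                best = min(best, float(np.sum((y - X @ coef) ** 2)))
            assert smaller.rss == pytest.approx(best, rel=1e-9, abs=1e-12)


class TestFitMars:
    def test_noiseless_hinge_recovered(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 40, 80)
        x[10] = 20.0
        y = -1.0 * np.maximum(0, 20.0 - x) + 5.0
        model, cv = fit_mars(x, y, repetitions=3, seed=1)
        assert model.hinges == [20.0]
        assert model.r_squared == pytest.approx(1.0)

    def test_pth_defaults_hinge_recovered(self, default_spec):
        from hingepoint import datagen

        df = datagen.simulate_cohort(default_spec, seed=14)
        model, _ = fit_mars(df["x25ohd_y1"], df["pth_y1"], repetitions=20, seed=2)
        knot, slope = primary_hinge(model)
        assert knot == pytest.approx(29.0, abs=8.0)  # single-cohort scatter
        assert slope < 0

    def test_too_few_observations_message_names_k_folds(self):
        with pytest.raises(DegenerateInputError, match="k_folds"):
            fit_mars(np.arange(12.0), np.arange(12.0), k_folds=10)

    def test_deterministic_given_seed(self, cohort):
        x, y = cohort["x25ohd_y1"], cohort["calcium_y1"]
        m1, cv1 = fit_mars(x, y, repetitions=3, seed=77)
        m2, cv2 = fit_mars(x, y, repetitions=3, seed=77)
        assert m1.to_dict() == m2.to_dict()
        assert cv1.mean_cv_rss == cv2.mean_cv_rss

    def test_repetition_stability_on_low_noise_data(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 40, 120)
        y = -1.0 * np.maximum(0, 20.0 - x) + 5.0 + rng.normal(0, 0.05, 120)
        _, cv1 = fit_mars(x, y, repetitions=1, seed=3)
        _, cv25 = fit_mars(x, y, repetitions=25, seed=3)
        assert cv1.selected_size == cv25.selected_size


class TestModelGeometry:
    @pytest.fixture()
    def two_hinge_model(self):
        terms = [
            (HingeBasis(17.0, "+"), 1.2),
            (HingeBasis(17.0, "-"), -0.5),
            (HingeBasis(47.0, "+"), -0.8),
        ]
        return MarsModel(
            intercept=2.0, terms=terms, r_squared=1.0, x_range=(0, 60), y_range=(0, 60)
        )

    def test_segment_slopes_match_symbolic_derivative(self, two_hinge_model):
        # d/dx: below 17: -(-0.5) = 0.5; 17-47: 1.2; above 47: 1.2 - 0.8
        assert two_hinge_model.segment_slopes == pytest.approx([0.5, 1.2, 0.4])
        assert two_hinge_model.hinges == [17.0, 47.0]

    def test_predict_continuous_and_piecewise_linear(self, two_hinge_model):
        grid = np.linspace(0, 60, 6001)
        y = two_hinge_model.predict(grid)
        d2 = np.diff(y, 2)
        # curvature only at the hinges
        bendy = grid[1:-1][np.abs(d2) > 1e-9]
        assert set(np.round(bendy, 1)).issubset({17.0, 47.0})
        assert np.max(np.abs(np.diff(y))) < 0.05  # no jumps on a fine grid

    def test_extract_thresholds_orders_hinges_and_flags_plateau(self):
        terms = [(HingeBasis(29.0, "-"), 0.96)]  # falling then flat
        model = MarsModel(0.0, terms, 0.9, x_range=(4, 90), y_range=(0, 80))
        summary = extract_thresholds(model)
        assert summary.hinges == [29.0]
        flat = [s for s in summary.segments if s.is_plateau]
        assert len(flat) == 1 and flat[0].x_lo == 29.0

    def test_intercept_only_model_has_no_hinges(self):
        model = MarsModel(5.0, [], 0.0, (0, 1), (0, 1))
        assert extract_thresholds(model).hinges == []
        assert primary_hinge(model) is None

    @given(st.integers(0, 200))
    @settings(max_examples=40)
    def test_forward_r2_never_decreases(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        x = rng.uniform(0, 10, n)
        y = np.sin(x) + rng.normal(0, 0.2, n)
        bases = forward_pass(x, y, max_terms=6)
        rss_prev = np.inf
        for k in range(0, len(bases) + 1, 2):
            X = _design(x, bases[:k])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((y - X @ coef) ** 2))
            assert rss <= rss_prev + 1e-9
            rss_prev = rss
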