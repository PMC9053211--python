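import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from evmced import (
    auc,
    bootstrap_auc_ci,
    partial_auc,
    roc_curve,
    sensitivity_specificity,
    threshold_at_specificity,
    wilson_ci,
)


def pair_count_auc(scores, labels):
    """Brute-force oracle: P(case score > control score) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    cases = scores[np.asarray(labels) == 1]
    ctrls = scores[np.asarray(labels) == 0]
    wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in ctrls)
    return wins / (cases.size * ctrls.size)


class TestRocCurve:
    def test_perfect_separation_passes_through_corner(self):
        roc = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert any(f == 0 and t == 1 for f, t in zip(roc.fpr, roc.tpr))
        assert auc(roc) == 1.0

    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        roc = roc_curve(rng.normal(size=40), rng.integers(0, 2, 40) | np.r_[1, np.zeros(39, int)])
        assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
        assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)

    def test_uninformative_scores_give_chance_auc(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            scores = rng.normal(size=10000)
            labels = rng.integers(0, 2, 10000)
            assert abs(auc(roc_curve(scores, labels)) - 0.5) < 0.02

    def test_sign_reversal_flips_auc(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        a = auc(roc_curve(scores, labels))
        assert auc(roc_curve(-scores, labels)) == pytest.approx(1.0 - a, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([1.0, 2.0], [1, 1])


class TestAuc:
    def test_separated_toy(self):
        assert auc(roc_curve([3, 4, 1, 2], [1, 1, 0, 0])) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auc(roc_curve([5.0] * 6, [1, 1, 1, 0, 0, 0])) == pytest.approx(0.5)

    def test_matches_pair_counting_oracle_with_ties(self):
        rng = np.random.default_rng(7)
        scores = rng.integers(0, 5, 30).astype(float)  # heavy ties
        labels = np.r_[np.ones(12, int), np.zeros(18, int)]
        assert auc(roc_curve(scores, labels)) == pytest.approx(
            pair_count_auc(scores, labels), abs=1e-12
        )

    @settings(max_examples=200, derandomize=True)
    @given(st.data())
    def test_auc_equals_oracle_property(self, data):
        n = data.draw(st.integers(2, 50))
        n_pos = data.draw(st.integers(1, n - 1))
        scores = np.array(
            data.draw(
                st.lists(
                    st.integers(-5, 5) | st.floats(-10, 10, allow_nan=False),
                    min_size=n,
                    max_size=n,
                )
            ),
            dtype=float,
        )
        labels = np.r_[np.ones(n_pos, int), np.zeros(n - n_pos, int)]
        a = auc(roc_curve(scores, labels))
        assert a == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)
        assert a == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestPartialAuc:
    def test_chance_diagonal_band_area(self):
        roc = roc_curve([5.0] * 6, [1, 1, 1, 0, 0, 0])  # ties -> diagonal
        assert partial_auc(roc, 0.75, 1.00) == pytest.approx(0.25**2 / 2, abs=1e-15)

    def test_perfect_classifier_band_area(self):
        roc = roc_curve([1, 2, 9, 10], [0, 0, 1, 1])
        assert partial_auc(roc, 0.75, 1.00) == pytest.approx(0.25)

    def test_full_band_equals_auc(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50) | np.r_[1, np.zeros(49, int)]
        roc = roc_curve(scores, labels)
        assert partial_auc(roc, 0.0, 1.0) == pytest.approx(auc(roc), abs=1e-12)

    def test_additive_over_adjoining_bands(self):
        rng = np.random.default_rng(2)
        scores = rng.integers(0, 6, 80).astype(float)
        labels = np.r_[np.ones(30, int), np.zeros(50, int)]
        roc = roc_curve(scores, labels)
        whole = partial_auc(roc, 0.75, 1.0)
        parts = partial_auc(roc, 0.75, 0.9) + partial_auc(roc, 0.9, 1.0)
        assert parts == pytest.approx(whole, abs=1e-12)

    def test_matches_fine_grid_integration_oracle(self):
        """Random piecewise-linear curves with distinct breakpoints integrate
        identically by trapezoid over the union of breakpoints and band edges."""
        from evmced.roc import RocCurve

        rng = np.random.default_rng(5)
        for _ in range(20):
            k = 20
            fpr = np.r_[0.0, np.sort(rng.uniform(size=k - 2)), 1.0]
            tpr = np.r_[0.0, np.sort(rng.uniform(size=k - 2)), 1.0]
            curve = RocCurve(fpr=fpr, tpr=tpr, thresholds=np.zeros(k), n_pos=5, n_neg=5)
            lo, hi = sorted(rng.uniform(size=2))
            if hi - lo < 1e-6:
                continue
            f_lo, f_hi = 1 - hi, 1 - lo
            grid = np.unique(np.clip(np.r_[fpr, f_lo, f_hi], f_lo, f_hi))
            vals = np.interp(grid, fpr, tpr)
            oracle = np.trapezoid(vals, grid)
            assert partial_auc(curve, lo, hi) == pytest.approx(oracle, abs=1e-9)

    def test_invalid_band_rejected(self):
        roc = roc_curve([1, 2], [0, 1])
        with pytest.raises(ValueError, match="band"):
            partial_auc(roc, 0.9, 0.8)


class TestThresholdAtSpecificity:
    def test_three_controls_forced_example(self):
        thr = threshold_at_specificity([0.1, 0.2, 0.3], 0.99)
        assert thr == 0.3
        sens, _ = sensitivity_specificity([0.31, 0.3], [1, 1], thr)
        assert sens == 0.5  # 0.31 positive, 0.30 negative (tie -> negative)

    def test_61_controls_all_called_negative(self):
        rng = np.random.default_rng(0)
        controls = rng.normal(size=61)
        thr = threshold_at_specificity(controls, 0.99)
        assert (controls > thr).sum() == 0
        assert thr == controls.max()

    def test_200_controls_two_exceed(self):
        rng = np.random.default_rng(1)
        controls = rng.normal(size=200)  # distinct values a.s.
        thr = threshold_at_specificity(controls, 0.99)
        assert (controls > thr).sum() == 2

    def test_brute_force_minimality(self):
        """Achieves the target on its own input; no smaller candidate does."""
        rng = np.random.default_rng(2)
        for n, target in [(10, 0.9), (61, 0.99), (200, 0.99), (37, 0.8)]:
            controls = rng.normal(size=n)
            thr = threshold_at_specificity(controls, target)
            assert np.mean(controls <= thr) >= target
            smaller = controls[controls < thr]
            for cand in smaller:
                assert np.mean(controls <= cand) < target

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            threshold_at_specificity([], 0.99)


class TestWilsonCI:
    def test_boundary_all_successes_hits_one(self):
        ci = wilson_ci(20, 20, 0.95)
        assert ci.upper == 1.0
        assert ci.lower < 1.0

    def test_interval_brackets_estimate(self):
        ci = wilson_ci(7, 30, 0.95)
        assert ci.lower <= 7 / 30 <= ci.upper

    def test_width_shrinks_with_n_at_fixed_rate(self):
        widths = []
        for n in (10, 20, 40, 80, 160):
            k = int(0.3 * n)
            ci = wilson_ci(k, n, 0.95)
            widths.append(ci.upper - ci.lower)
        assert all(b < a for a, b in zip(widths, widths[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            wilson_ci(1, 0)
        with pytest.raises(ValueError):
            wilson_ci(5, 4)


class TestBootstrapAucCI:
    def test_perfect_separation_gives_point_interval_at_one(self):
        scores = np.r_[np.zeros(20), np.ones(20)]
        labels = np.r_[np.zeros(20, int), np.ones(20, int)]
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = bootstrap_auc_ci(scores, labels, B=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_same_seed_reproduces_interval(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=100) + np.r_[np.ones(40), np.zeros(60)]
        labels = np.r_[np.ones(40, int), np.zeros(60, int)]
        a = bootstrap_auc_ci(scores, labels, B=500, seed=11)
        b = bootstrap_auc_ci(scores, labels, B=500, seed=11)
        assert a == b

    def test_interval_brackets_observed_auc_on_moderate_data(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=200) + np.r_[np.full(80, 1.2), np.zeros(120)]
        labels = np.r_[np.ones(80, int), np.zeros(120, int)]
        lo, hi = bootstrap_auc_ci(scores, labels, B=1000, seed=3)
        observed = auc(roc_curve(scores, labels))
        assert lo < observed < hi
        assert 0.0 < hi - lo < 0.2
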