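import hashlib

import numpy as np
import pytest
from scipy.optimize import minimize

from saccdecode.mvpa import (
    MvpaConfig,
    SampleSet,
    accuracy_vs_size,
    feature_counts,
    loro_accuracy,
    mean_center,
    select_topk,
    train_linear_svm,
)


def svm_qp_reference(X, y_num, C):
    """Independent dual-QP oracle: max sum(a) - 1/2 a'Qa, 0<=a<=C, y'a=0."""
    X = np.asarray(X, float)
    y = np.asarray(y_num, float)
    n = X.shape[0]
    Q = (y[:, None] * y[None, :]) * (X @ X.T)

    def obj(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - np.ones(n)

    cons = {"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}
    res = minimize(
        obj, np.full(n, C / 2), jac=grad, bounds=[(0, C)] * n, constraints=[cons],
        method="SLSQP", options={"maxiter": 2000, "ftol": 1e-14},
    )
    a = res.x
    w = (a * y) @ X
    # b from the KKT conditions. Free SVs pin b exactly; when every SV sits at
    # a bound, b is any value in the feasible interval and libsvm returns its
    # midpoint, so the oracle does the same.
    margins = X @ w
    lo, hi = -np.inf, np.inf
    for i in range(n):
        at_zero = a[i] <= 1e-6 * C
        at_c = a[i] >= C * (1 - 1e-6)
        target = y[i] - margins[i]  # b value putting i exactly on the margin
        if not at_zero and not at_c:  # free SV: equality
            lo, hi = max(lo, target), min(hi, target)
        elif (y[i] > 0 and at_zero) or (y[i] < 0 and at_c):
            lo = max(lo, target)  # y (w.x + b) >= 1 from below
        else:
            hi = min(hi, target)
    b = float((lo + hi) / 2)
    return w, b


def _samples(rng, n_runs=4, per_run=6, p=8, sep=3.0):
    # class signal is a zero-spatial-mean pattern so it survives mean-centering
    pattern = np.resize([1.0, -1.0], p)
    X, y, runs = [], [], []
    for r in range(n_runs):
        for i in range(per_run):
            label = "small" if i % 2 == 0 else "large"
            mu = (-sep / 2 if label == "small" else sep / 2) * pattern
            X.append(rng.normal(mu, 1.0))
            y.append(label)
            runs.append(r)
    return SampleSet(X=np.array(X), y=np.array(y), runs=np.array(runs))


class TestMeanCenter:
    def test_per_voxel_run_zero_means(self, rng):
        ss = mean_center(_samples(rng), "per_voxel_run")
        for r in np.unique(ss.runs):
            np.testing.assert_allclose(ss.X[ss.runs == r].mean(axis=0), 0.0, atol=1e-10)

    def test_per_sample_spatial_zero_means(self, rng):
        ss = mean_center(_samples(rng), "per_sample_spatial")
        np.testing.assert_allclose(ss.X.mean(axis=1), 0.0, atol=1e-10)

    def test_run_constant_offset_invariance(self, rng):
        ss = _samples(rng)
        shifted = SampleSet(X=ss.X.copy(), y=ss.y, runs=ss.runs)
        shifted.X[shifted.runs == 1] += 57.0  # additive constant on one run
        a = mean_center(ss, "both")
        b = mean_center(shifted, "both")
        np.testing.assert_allclose(a.X, b.X, atol=1e-9)

    def test_unknown_mode(self, rng):
        with pytest.raises(ValueError):
            mean_center(_samples(rng), "zscore")


class TestLinearSvm:
    def test_two_point_problem(self):
        # closed form: alpha = (0.5, 0.5), w = 1, b = 0
        m = train_linear_svm(np.array([[-1.0], [1.0]]), np.array(["small", "large"]))
        assert m.w[0] == pytest.approx(1.0, abs=1e-6)
        assert m.b == pytest.approx(0.0, abs=1e-6)
        assert m.predict(np.array([[0.5]]))[0] == "large"

    def test_separable_zero_training_error(self, rng):
        X = np.vstack([rng.normal(-4, 0.5, (10, 3)), rng.normal(4, 0.5, (10, 3))])
        y = np.array(["small"] * 10 + ["large"] * 10)
        m = train_linear_svm(X, y)
        assert np.all(m.predict(X) == y)

    def test_label_swap_antisymmetry(self, rng):
        X = rng.normal(size=(12, 4))
        y = np.array(["small", "large"] * 6)
        y_swapped = np.where(y == "small", "large", "small")
        m1 = train_linear_svm(X, y)
        m2 = train_linear_svm(X, y_swapped)
        assert np.abs(m1.w + m2.w).max() < 1e-5
        assert abs(m1.b + m2.b) < 1e-5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_linear_svm(np.zeros((3, 2)), np.array(["small"] * 3))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_qp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 10)
        X = rng.normal(size=(n, 3))
        y = np.array(["small", "large"] * n)[:n]
        if len(set(y)) < 2:
            y[0] = "small" if y[1] == "large" else "large"
        m = train_linear_svm(X, y, c=1.0)
        y_num = np.where(y == "large", 1.0, -1.0)
        w_ref, b_ref = svm_qp_reference(X, y_num, 1.0)
        np.testing.assert_allclose(m.decision_function(X), X @ w_ref + b_ref, atol=1e-4)

    def test_deterministic(self, rng):
        X = rng.normal(size=(30, 6))
        y = np.array(["small", "large"] * 15)
        m1, m2 = train_linear_svm(X, y), train_linear_svm(X, y)
        np.testing.assert_array_equal(m1.w, m2.w)
        assert m1.b == m2.b


class TestSelectTopk:
    def test_full_size_identity(self):
        loc = np.array([[3.0, 1.0, 2.0]])
        np.testing.assert_array_equal(select_topk(loc, 3), [0, 1, 2])

    def test_exact_count(self, rng):
        loc = rng.normal(size=(4, 300))
        assert select_topk(loc, 200).size == 200

    def test_ties_broken_by_canonical_order(self):
        loc = np.array([[1.0, 1.0, 1.0, 1.0]])
        np.testing.assert_array_equal(select_topk(loc, 2), [0, 1])

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            select_topk(np.ones((1, 5)), 6)

    def test_mean_over_runs(self):
        loc = np.array([[0.0, 10.0], [10.0, 0.0], [0.0, 1.0]])
        np.testing.assert_array_equal(select_topk(loc, 1), [1])


class TestLoroAccuracy:
    def test_fold_structure_default_design(self):
        """Default design: 12 small + 12 large samples per run; 4-run training
        folds hold 96 samples."""
        rng = np.random.default_rng(0)
        X, y, runs = [], [], []
        for r in range(5):
            for cond in ("small", "large"):
                for _ in range(12):
                    X.append(rng.normal(size=6))
                    y.append(cond)
                    runs.append(r)
        ss = SampleSet(X=np.array(X), y=np.array(y), runs=np.array(runs))
        run_ids = np.unique(ss.runs)
        for test_run in run_ids:
            train = ss.runs != test_run
            assert train.sum() == 96
            for cond in ("small", "large"):
                for r in run_ids[run_ids != test_run]:
                    assert np.sum((ss.runs == r) & (ss.y == cond)) == 12
        acc = loro_accuracy(ss)
        assert 0.0 <= acc <= 100.0

    def test_strong_signal_perfect(self, rng):
        ss = _samples(rng, sep=20.0)
        assert loro_accuracy(ss) == 100.0

    def test_single_run_rejected(self, rng):
        ss = _samples(rng, n_runs=1)
        with pytest.raises(ValueError):
            loro_accuracy(ss)

    def test_permuted_labels_near_chance(self):
        """Monte-Carlo null: grand mean within 3 SE of 50% over 50 seeds."""
        accs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            ss = _samples(rng, n_runs=3, per_run=8, sep=4.0)
            for r in np.unique(ss.runs):
                sel = np.flatnonzero(ss.runs == r)
                ss.y[sel] = ss.y[sel][rng.permutation(sel.size)]
            accs.append(loro_accuracy(ss))
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 50.0) <= 3 * se

    def test_no_peeking_test_run_untouched(self, rng):
        ss = _samples(rng)
        test_bytes = ss.X[ss.runs == 0].tobytes()
        digest_before = hashlib.sha256(test_bytes).hexdigest()
        loro_accuracy(ss)
        digest_after = hashlib.sha256(ss.X[ss.runs == 0].tobytes()).hexdigest()
        assert digest_before == digest_after

    def test_deterministic(self, rng):
        ss = _samples(rng)
        assert loro_accuracy(ss) == loro_accuracy(ss)


class TestFeatureCounts:
    def test_sef_grid(self):
        assert feature_counts(564) == [200, 300, 400, 500, 564]

    def test_parietal_grid_caps_at_900(self):
        assert feature_counts(1043) == [200, 300, 400, 500, 600, 700, 800, 900]

    def test_small_roi(self):
        assert feature_counts(100) == [100]

    def test_exact_900(self):
        assert feature_counts(900) == [200, 300, 400, 500, 600, 700, 800, 900]


class TestAccuracyVsSize:
    def _informative_samples(self, rng, p=60, informative=10, sep=2.0):
        X, y, runs = [], [], []
        for r in range(3):
            for i in range(12):
                label = "small" if i % 2 == 0 else "large"
                x = rng.normal(0, 1.0, size=p)
                x[:informative] += -sep / 2 if label == "small" else sep / 2
                X.append(x)
                y.append(label)
                runs.append(r)
        return SampleSet(X=np.array(X), y=np.array(y), runs=np.array(runs))

    def test_counts_and_range(self, rng):
        ss = self._informative_samples(rng)
        loc = {r: np.abs(rng.normal(size=(ss.n_features,))) for r in range(3)}
        cfg = MvpaConfig(feature_min=10, feature_step=20, feature_cap=60)
        table = accuracy_vs_size(ss, loc, cfg)
        assert list(table["n_features"]) == [10, 30, 50, 60]
        assert table["accuracy_pct"].between(0, 100).all()

    def test_selection_uses_training_runs_only(self, rng):
        """A pathological test-run localizer must not change the fold's subset."""
        ss = self._informative_samples(rng)
        loc_a = {r: np.arange(ss.n_features, dtype=float) for r in range(3)}
        loc_b = {r: v.copy() for r, v in loc_a.items()}
        loc_b[0] = -loc_b[0]  # flip only run 0's map
        # the fold testing run 0 selects on runs 1 and 2 -> identical subsets
        train_a = np.vstack([loc_a[1], loc_a[2]])
        train_b = np.vstack([loc_b[1], loc_b[2]])
        np.testing.assert_array_equal(select_topk(train_a, 10), select_topk(train_b, 10))

    def test_monotone_signal_full_not_much_worse_than_small(self):
        """Accuracy at full size >= accuracy at the smallest count - 5%,
        averaged over seeds."""
        full_accs, small_accs = [], []
        cfg = MvpaConfig(feature_min=10, feature_step=100, feature_cap=60)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ss = self._informative_samples(rng, sep=1.5)
            loc = {r: rng.normal(size=(ss.n_features,)) for r in range(3)}
            table = accuracy_vs_size(ss, loc, cfg)
            small_accs.append(table["accuracy_pct"].iloc[0])
            full_accs.append(table["accuracy_pct"].iloc[-1])
        assert np.mean(full_accs) >= np.mean(small_accs) - 5.0
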