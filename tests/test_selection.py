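"""Two-step feature selection: correlations, filters, CV scoring, wrapper."""

import itertools

import numpy as np
import pytest
from sklearn.model_selection import KFold

from discon.models import make_estimator
from discon.selection import (
    cv_feature_target_correlation,
    cv_pairwise_correlation,
    relevance_redundancy_filter,
    repeated_cv_mse,
    wrapper_best_first,
    select_features,
)


@pytest.fixture(scope="module")
def ridge_estimator():
    return make_estimator("ridge", {"lambda": 1e-6})


class TestTargetCorrelation:
    def test_self_and_negated_correlation(self):
        rng = np.random.default_rng(0)
        y = rng.random(50)
        X = np.column_stack([y, -y])
        pcc, _ = cv_feature_target_correlation(X, y, ["same", "neg"], seed=0)
        assert pcc["same"] == pytest.approx(1.0)
        assert pcc["neg"] == pytest.approx(1.0)

    def test_independent_noise_below_relevance_cutoff(self):
        rng = np.random.default_rng(1)
        y = rng.random(200)
        X = rng.standard_normal((200, 5))
        pcc, _ = cv_feature_target_correlation(X, y, [f"n{i}" for i in range(5)], seed=0)
        # a 200-sample null |PCC| concentrates well below the 0.2 cutoff
        assert all(v < 0.2 for v in pcc.values())

    def test_constant_feature_flagged_zero(self):
        y = np.linspace(0, 1, 30)
        X = np.column_stack([np.ones(30), y])
        pcc, flags = cv_feature_target_correlation(X, y, ["const", "lin"], seed=0)
        assert pcc["const"] == 0.0
        assert any("const" in f for f in flags)


class TestFilters:
    def _tables(self, pcc_values, pairwise):
        ids = sorted(pcc_values)
        idx = {f: j for j, f in enumerate(ids)}
        P = np.eye(len(ids))
        for (a, b), v in pairwise.items():
            P[idx[a], idx[b]] = P[idx[b], idx[a]] = v
        return pcc_values, P, ids

    def test_relevance_boundary(self):
        pcc, P, ids = self._tables({"a": 0.19, "b": 0.21}, {})
        relevant, kept, _ = relevance_redundancy_filter(pcc, P, ids)
        assert relevant == ["b"] and kept == ["b"]

    def test_redundancy_keeps_higher_target_pcc(self):
        pcc, P, ids = self._tables({"a": 0.5, "b": 0.4}, {("a", "b"): 1.0})
        _, kept, rejections = relevance_redundancy_filter(pcc, P, ids)
        assert kept == ["a"]
        assert rejections == {"b": "a"}

    def test_orthogonal_survivors_ordered_by_target_pcc(self):
        pcc, P, ids = self._tables({"a": 0.3, "b": 0.5, "c": 0.4}, {})
        _, kept, _ = relevance_redundancy_filter(pcc, P, ids)
        assert kept == ["b", "c", "a"]

    def test_identity_at_degenerate_thresholds(self):
        pcc, P, ids = self._tables({"a": 0.01, "b": 0.9}, {("a", "b"): 0.99})
        relevant, kept, _ = relevance_redundancy_filter(pcc, P, ids, t_rel=0.0, t_red=1.0)
        assert set(kept) == {"a", "b"}

    def test_column_permutation_stability(self):
        rng = np.random.default_rng(3)
        y = rng.random(60)
        X = np.column_stack([y + rng.normal(0, s, 60) for s in (0.1, 0.2, 0.4, 1.0)])
        ids = ["f0", "f1", "f2", "f3"]

        def survivors(perm):
            Xp = X[:, perm]
            idsp = [ids[j] for j in perm]
            pcc, _ = cv_feature_target_correlation(Xp, y, idsp, seed=0)
            P = cv_pairwise_correlation(Xp, idsp, seed=0)
            _, kept, _ = relevance_redundancy_filter(pcc, P, idsp, t_red=0.95)
            return kept

        base = survivors([0, 1, 2, 3])
        for perm in ([3, 2, 1, 0], [1, 3, 0, 2]):
            assert survivors(perm) == base


class TestRepeatedCV:
    def test_deterministic_given_seed(self, ridge_estimator):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 3))
        y = X @ [1.0, -0.5, 0.2] + rng.normal(0, 0.1, 40)
        out1 = repeated_cv_mse(X, y, [0, 1, 2], ridge_estimator, seed=9)
        out2 = repeated_cv_mse(X, y, [0, 1, 2], ridge_estimator, seed=9)
        assert out1 == out2

    def test_noiseless_linear_stops_after_two_repetitions(self, ridge_estimator):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((50, 2))
        y = X @ [2.0, -1.0]
        mse, reps = repeated_cv_mse(X, y, [0, 1], ridge_estimator, seed=0)
        assert mse < 1e-8
        assert reps == 2  # CoV of two ~zero MSEs is below the limit

    def test_intercept_only_matches_closed_form(self, ridge_estimator):
        # CV MSE of the training-fold mean is ~ sigma^2 * (1 + 1/fold_size)
        rng = np.random.default_rng(6)
        sigma = 0.3
        y = rng.normal(0.5, sigma, 500)
        X = np.zeros((500, 1))
        mse, _ = repeated_cv_mse(X, y, [], ridge_estimator, seed=0)
        expected = sigma**2 * (1 + 1 / 400)
        assert mse == pytest.approx(expected, rel=0.15)

    def test_cov_stopping_rule_matches_independent_recomputation(self, ridge_estimator):
        """The repetition count equals what the CoV<0.02 rule dictates when the
        per-repetition MSEs are recomputed independently."""
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 2))
        y = X @ [0.5, 0.1] + rng.normal(0, 0.5, 30)
        for seed in range(4):
            mse, reps = repeated_cv_mse(X, y, [0, 1], ridge_estimator, seed=seed)
            # independent re-run of each repetition with the same fold seeds
            rep_mses = []
            for rep in range(5):
                errors = np.empty(len(y))
                kf = KFold(n_splits=5, shuffle=True, random_state=seed * 1000 + rep)
                for tr, te in kf.split(np.arange(len(y))):
                    from sklearn.base import clone
                    est = clone(ridge_estimator).fit(X[tr], y[tr])
                    errors[te] = est.predict(X[te]) - y[te]
                rep_mses.append(np.mean(errors**2))
                if len(rep_mses) >= 2:
                    cov = np.std(rep_mses) / np.mean(rep_mses)
                    if cov < 0.02:
                        break
            assert reps == len(rep_mses)
            assert mse == pytest.approx(np.mean(rep_mses))


def exhaustive_subset_oracle(X, y, candidates, estimator, seed=0):
    """Score every feature subset with the same repeated-CV MSE."""
    scores = {}
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(range(len(candidates)), r):
            mse, _ = repeated_cv_mse(X, y, list(subset), estimator, seed=seed)
            scores[subset] = mse
    return scores


class TestWrapperSearch:
    def _linear_data(self, n=60, seed=8):
        rng = np.random.default_rng(seed)
        f1 = rng.standard_normal(n)
        f2 = rng.standard_normal(n)
        noise = rng.standard_normal(n)
        X = np.column_stack([f1, f2, noise])
        y = 2.0 * f1 - f2
        return X, y

    def test_forward_selects_true_support_and_matches_oracle(self, ridge_estimator):
        X, y = self._linear_data()
        ids = ["f1", "f2", "noise"]
        trace = wrapper_best_first(X, y, ids, ids, ridge_estimator, seed=0)
        assert sorted(trace.selected) == ["f1", "f2"]
        scores = exhaustive_subset_oracle(X, y, ids, ridge_estimator, seed=0)
        best_subset = min(scores, key=scores.get)
        assert sorted(ids[j] for j in best_subset) == ["f1", "f2"]
        assert trace.final_mse == pytest.approx(scores[best_subset], abs=1e-8)

    def test_backward_matches_forward_mse(self, ridge_estimator):
        X, y = self._linear_data()
        ids = ["f1", "f2", "noise"]
        fwd = wrapper_best_first(X, y, ids, ids, ridge_estimator, direction="forward", seed=0)
        bwd = wrapper_best_first(X, y, ids, ids, ridge_estimator, direction="backward", seed=0)
        assert bwd.final_mse == pytest.approx(fwd.final_mse, abs=1e-6)
        # backward keeps the informative pair (it may retain a harmless extra:
        # removals are only accepted on strict improvement)
        assert {"f1", "f2"} <= set(bwd.selected)

    def test_accepted_mse_non_increasing(self, ridge_estimator):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((80, 6))
        y = X[:, 0] * 0.5 + X[:, 1] * 0.3 + rng.normal(0, 0.2, 80)
        ids = [f"f{j}" for j in range(6)]
        trace = wrapper_best_first(X, y, ids, ids, ridge_estimator, seed=1)
        accepted = [s["mse"] for s in trace.steps
                    if s.get("accepted") or s["action"] == "init"]
        assert all(b <= a + 1e-12 for a, b in zip(accepted, accepted[1:]))

    def test_zero_candidates(self, ridge_estimator):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((30, 2))
        y = rng.random(30)
        trace = wrapper_best_first(X, y, [], ["a", "b"], ridge_estimator, seed=0)
        assert trace.selected == []
        assert trace.final_mse == pytest.approx(np.var(y), rel=0.5)  # intercept-only scale


class TestFullSelection:
    def test_informative_feature_recovery(self, ridge_estimator):
        # 5 informative + 50 noise features, n = 300, noise SD 0.05
        rng = np.random.default_rng(42)
        n = 300
        X = rng.standard_normal((n, 55))
        w = np.array([0.3, 0.3, 0.25, 0.25, 0.2])
        y = X[:, :5] @ w + rng.normal(0, 0.05, n)
        ids = [f"inf{j}" for j in range(5)] + [f"noise{j}" for j in range(50)]
        trace = select_features(X, y, ids, ridge_estimator, seed=42)
        informative_kept = [f for f in trace.selected if f.startswith("inf")]
        assert len(informative_kept) >= 4
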