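"""Two-step feature selection: correlation filters, then a wrapper search.

Step 1 (coarse, correlation-based):
  * relevance — keep features whose cross-validated average absolute Pearson
    correlation with the disorder content is at least ``t_rel`` (default 0.2);
  * redundancy — walk the survivors in decreasing target-|PCC| order, keeping
    a feature only if its average absolute pairwise correlation with every
    already-kept feature stays below ``t_red`` (default 0.9).

Step 2 (wrapper): a greedy single-scan best-first search (forward from the
empty set or backward from the full set) that accepts a move only when it
strictly lowers the repeated cross-validated MSE of the estimator.  Cross
validation is 5-fold, re-randomized up to 5 times, stopping early once the
coefficient of variation of the per-repetition MSEs drops below 0.02.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.dummy import DummyRegressor
from sklearn.model_selection import KFold

DEFAULT_T_REL = 0.2
DEFAULT_T_RED = 0.9
DEFAULT_FOLDS = 5
DEFAULT_MAX_REP = 5
DEFAULT_COV_LIMIT = 0.02
#: a wrapper move must beat the incumbent MSE by more than this
MSE_IMPROVEMENT_TOL = 1e-6


@dataclass
class SelectionTrace:
    """Audit log of the two-step selection."""

    target_pcc: dict[str, float] = field(default_factory=dict)
    relevance_survivors: list[str] = field(default_factory=list)
    redundancy_survivors: list[str] = field(default_factory=list)
    redundancy_rejections: dict[str, str] = field(default_factory=dict)  # removed -> blocker
    direction: str = "forward"
    steps: list[dict] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    final_mse: Optional[float] = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "target_pcc": self.target_pcc,
            "relevance_survivors": self.relevance_survivors,
            "redundancy_survivors": self.redundancy_survivors,
            "redundancy_rejections": self.redundancy_rejections,
            "direction": self.direction,
            "steps": self.steps,
            "selected": self.selected,
            "final_mse": self.final_mse,
            "flags": self.flags,
        }


def _fold_indices(n: int, folds: int, seed: int):
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n)))


def _safe_pcc_columns(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|PCC| of each column of X with y; constant columns (or constant y) -> 0."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = Xc.std(axis=0)
    sy = yc.std()
    if sy == 0:
        return np.zeros(X.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).mean(axis=0) / (sx * sy)
    r[sx == 0] = 0.0
    return np.abs(r)


def cv_feature_target_correlation(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: Sequence[str],
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> tuple[dict[str, float], list[str]]:
    """Average absolute Pearson correlation of each feature with the target.

    Each of the ``folds`` cross-validation training folds contributes one
    |PCC| per feature; the fold values are averaged.  Constant features (and
    folds with zero target variance) contribute 0 and are flagged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    flags: list[str] = []
    acc = np.zeros(X.shape[1])
    for train_idx, _ in _fold_indices(len(y), folds, seed):
        if y[train_idx].std() == 0:
            flags.append("zero-variance target in a training fold")
            continue
        acc += _safe_pcc_columns(X[train_idx], y[train_idx])
    avg = acc / folds
    for j, fid in enumerate(feature_ids):
        if X[:, j].std() == 0:
            flags.append(f"constant feature '{fid}'")
    return {fid: float(avg[j]) for j, fid in enumerate(feature_ids)}, flags


def cv_pairwise_correlation(
    X: np.ndarray,
    feature_ids: Sequence[str],
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> np.ndarray:
    """Average (over training folds) absolute pairwise |PCC| matrix."""
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    acc = np.zeros((p, p))
    for train_idx, _ in _fold_indices(X.shape[0], folds, seed):
        sub = X[train_idx]
        sd = sub.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(sub, rowvar=False)
        c = np.atleast_2d(c)
        c[~np.isfinite(c)] = 0.0
        # constant columns correlate with nothing
        c[sd == 0, :] = 0.0
        c[:, sd == 0] = 0.0
        acc += np.abs(c)
    np.fill_diagonal(acc, folds)
    return acc / folds


def _ranked(feature_ids: Sequence[str], target_pcc: dict[str, float]) -> list[str]:
    """Decreasing target-|PCC|, ties broken lexicographically by id."""
    return sorted(feature_ids, key=lambda f: (-target_pcc[f], f))


def relevance_redundancy_filter(
    target_pcc: dict[str, float],
    pairwise: np.ndarray,
    feature_ids: Sequence[str],
    t_rel: float = DEFAULT_T_REL,
    t_red: float = DEFAULT_T_RED,
) -> tuple[list[str], list[str], dict[str, str]]:
    """Apply the relevance and redundancy filters.

    Returns (relevance survivors, redundancy survivors, rejections), where
    rejections maps each redundancy-removed feature to the already-kept
    feature that blocked it.  Survivor lists are ordered by decreasing
    target-|PCC| (ties by id), so the output is independent of input column
    order.
    """
    index = {f: j for j, f in enumerate(feature_ids)}
    relevant = [f for f in feature_ids if target_pcc[f] >= t_rel]
    relevant = _ranked(relevant, target_pcc)

    kept: list[str] = []
    rejections: dict[str, str] = {}
    for f in relevant:
        blocker = None
        for g in kept:
            if pairwise[index[f], index[g]] >= t_red:
                blocker = g
                break
        if blocker is None:
            kept.append(f)
        else:
            rejections[f] = blocker
    return relevant, kept, rejections


def repeated_cv_mse(
    X: np.ndarray,
    y: np.ndarray,
    feature_idx: Sequence[int],
    estimator,
    folds: int = DEFAULT_FOLDS,
    max_rep: int = DEFAULT_MAX_REP,
    cov_limit: float = DEFAULT_COV_LIMIT,
    seed: int = 0,
) -> tuple[float, int]:
    """Mean 5-fold CV MSE over re-randomized repetitions with CoV early stop.

    Each repetition re-randomizes the fold assignment; after at least two
    repetitions, the loop stops as soon as the coefficient of variation
    (SD / mean) of the per-repetition MSEs falls below ``cov_limit``,
    otherwise it runs to ``max_rep``.  An empty feature subset is scored with
    an intercept-only model (training-fold mean).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    feature_idx = list(feature_idx)
    sub = X[:, feature_idx] if feature_idx else np.empty((len(y), 0))
    model = estimator if feature_idx else DummyRegressor(strategy="mean")

    rep_mses: list[float] = []
    for rep in range(max_rep):
        errors = np.empty(len(y))
        for train_idx, test_idx in _fold_indices(len(y), folds, seed * 1000 + rep):
            est = clone(model)
            est.fit(sub[train_idx], y[train_idx])
            errors[test_idx] = est.predict(sub[test_idx]) - y[test_idx]
        rep_mses.append(float(np.mean(errors**2)))
        if len(rep_mses) >= 2:
            mean = float(np.mean(rep_mses))
            # an essentially-zero MSE is deterministic: its relative spread is
            # float noise, not genuine fold-to-fold variation
            cov = float(np.std(rep_mses) / mean) if mean > 1e-12 else 0.0
            if cov < cov_limit:
                break
    return float(np.mean(rep_mses)), len(rep_mses)


def wrapper_best_first(
    X: np.ndarray,
    y: np.ndarray,
    candidate_ids: Sequence[str],
    feature_ids: Sequence[str],
    estimator,
    target_pcc: Optional[dict[str, float]] = None,
    direction: str = "forward",
    seed: int = 0,
    folds: int = DEFAULT_FOLDS,
    max_rep: int = DEFAULT_MAX_REP,
    cov_limit: float = DEFAULT_COV_LIMIT,
    confirmation_pass: bool = True,
) -> SelectionTrace:
    """Greedy single-scan wrapper search over candidate features.

    Forward: starting from the empty set, scan candidates in decreasing
    target-|PCC| order and accept each addition that lowers the incumbent
    repeated-CV MSE by more than :data:`MSE_IMPROVEMENT_TOL`.  Backward:
    start from the full candidate set and scan for removals that lower the
    MSE.  After the first scan, one confirmation pass re-scans the remaining
    moves and the search stops at the first pass with no acceptance.
    """
    if direction not in ("forward", "backward"):
        raise ValueError(f"unknown search direction '{direction}'")
    index = {f: j for j, f in enumerate(feature_ids)}
    if target_pcc is None:
        target_pcc = {f: _safe_pcc_columns(
            np.asarray(X, dtype=float)[:, [index[f]]], np.asarray(y, dtype=float))[0]
            for f in candidate_ids}
    order = _ranked(candidate_ids, target_pcc)

    trace = SelectionTrace(direction=direction,
                           target_pcc={f: float(target_pcc[f]) for f in order})

    def score(subset: list[str]) -> tuple[float, int]:
        return repeated_cv_mse(X, y, [index[f] for f in subset], estimator,
                               folds=folds, max_rep=max_rep,
                               cov_limit=cov_limit, seed=seed)

    current = [] if direction == "forward" else list(order)
    incumbent, reps = score(current)
    trace.steps.append({"step": 0, "feature": None, "action": "init",
                        "mse": incumbent, "repetitions": reps})

    max_passes = 2 if confirmation_pass else 1
    step = 0
    for _pass in range(max_passes):
        accepted_any = False
        for f in order:
            in_set = f in current
            if direction == "forward" and in_set:
                continue
            if direction == "backward" and not in_set:
                continue
            trial = current + [f] if direction == "forward" else [g for g in current if g != f]
            mse, reps = score(trial)
            step += 1
            accepted = mse < incumbent - MSE_IMPROVEMENT_TOL
            trace.steps.append({
                "step": step,
                "feature": f,
                "action": ("add" if direction == "forward" else "remove"),
                "mse": mse,
                "repetitions": reps,
                "accepted": bool(accepted),
            })
            if accepted:
                current = trial
                incumbent = mse
                accepted_any = True
        if not accepted_any:
            break

    trace.selected = _ranked(current, target_pcc)
    trace.final_mse = incumbent
    return trace


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: Sequence[str],
    estimator,
    t_rel: float = DEFAULT_T_REL,
    t_red: float = DEFAULT_T_RED,
    direction: str = "forward",
    seed: int = 0,
    folds: int = DEFAULT_FOLDS,
) -> SelectionTrace:
    """Run the complete two-step selection and return its trace."""
    target_pcc, flags = cv_feature_target_correlation(X, y, feature_ids, folds=folds, seed=seed)
    pairwise = cv_pairwise_correlation(X, feature_ids, folds=folds, seed=seed)
    relevant, survivors, rejections = relevance_redundancy_filter(
        target_pcc, pairwise, feature_ids, t_rel=t_rel, t_red=t_red)
    trace = wrapper_best_first(X, y, survivors, feature_ids, estimator,
                               target_pcc=target_pcc, direction=direction, seed=seed,
                               folds=folds)
    trace.target_pcc = {f: float(v) for f, v in target_pcc.items()}
    trace.relevance_survivors = relevant
    trace.redundancy_survivors = survivors
    trace.redundancy_rejections = rejections
    trace.flags.extend(flags)
    return trace
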