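"""Content regression models: ridge regression and epsilon-SVR.

Ridge is the deployed model; SVR (polynomial, RBF, and the Pearson VII
universal kernel, PUK) is available for the alternative configurations of the
model-design protocol.  Features are standardized to mean 0 / SD 1 inside the
model; the standardization constants are stored and applied at prediction
time.  Raw regression output is clamped to [0, 1], the codomain of a
disorder-content estimate.

Hyperparameter grids (all searched by repeated cross-validated MSE):

=========  =====================================================
estimator  grid
=========  =====================================================
ridge      lambda = 10^w, w in {-11, -9, -7, -5, -3, -1, 1, 2}
svr_poly   degree in {1, 2} x C = 2^x, x = -8..2   (22 points)
svr_rbf    gamma = 2^y, y = -11..2 x C = 2^x, x = -3..6  (140)
svr_puk    omega = 2^z, z = -4..1 x C = 2^x, x = -4..5   (60)
=========  =====================================================
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Ridge
from sklearn.svm import SVR

from discon.selection import repeated_cv_mse

ESTIMATOR_KINDS = ("ridge", "svr_poly", "svr_rbf", "svr_puk")

RIDGE_LAMBDA_GRID = tuple(10.0**w for w in (-11, -9, -7, -5, -3, -1, 1, 2))
POLY_GRID = tuple({"degree": d, "C": 2.0**x} for d in (1, 2) for x in range(-8, 3))
RBF_GRID = tuple({"gamma": 2.0**y, "C": 2.0**x} for y in range(-11, 3) for x in range(-3, 7))
PUK_GRID = tuple({"omega": 2.0**z, "C": 2.0**x} for z in range(-4, 2) for x in range(-4, 6))

SVR_EPSILON = 0.001
PUK_SIGMA = 1.0


def puk_kernel(U: np.ndarray, V: np.ndarray, omega: float, sigma: float = PUK_SIGMA) -> np.ndarray:
    """Pearson VII universal kernel.

    K(u, v) = 1 / [1 + (2 ||u - v|| sqrt(2^(1/omega) - 1) / sigma)^2]^omega
    """
    U = np.atleast_2d(np.asarray(U, dtype=float))
    V = np.atleast_2d(np.asarray(V, dtype=float))
    d2 = (
        (U**2).sum(axis=1)[:, None]
        + (V**2).sum(axis=1)[None, :]
        - 2.0 * U @ V.T
    )
    d = np.sqrt(np.maximum(d2, 0.0))
    scale = 2.0 * np.sqrt(2.0 ** (1.0 / omega) - 1.0) / sigma
    return (1.0 + (scale * d) ** 2) ** (-omega)


class _Standardizer:
    def __init__(self, mean: np.ndarray, sd: np.ndarray):
        self.mean = np.asarray(mean, dtype=float)
        self.sd = np.asarray(sd, dtype=float)

    @classmethod
    def fit(cls, X: np.ndarray) -> "_Standardizer":
        sd = X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        return cls(X.mean(axis=0), sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


@dataclass
class ContentModel:
    """A fitted disorder-content regressor with its preprocessing constants."""

    kind: str
    hyperparams: dict
    feature_ids: list[str]
    fingerprint: Optional[str]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    # ridge representation
    coef: Optional[np.ndarray] = None
    intercept: Optional[float] = None
    # SVR representation
    support_vectors: Optional[np.ndarray] = None
    dual_coef: Optional[np.ndarray] = None
    extra: dict = field(default_factory=dict)

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_ids):
            raise ValueError(
                f"expected {len(self.feature_ids)} features, got {X.shape[1]}"
            )
        Z = (X - self.scaler_mean) / self.scaler_sd
        if self.kind == "ridge":
            return Z @ self.coef + self.intercept
        K = self._kernel(Z, self.support_vectors)
        return K @ self.dual_coef + self.intercept

    def _kernel(self, Z: np.ndarray, SV: np.ndarray) -> np.ndarray:
        hp = self.hyperparams
        if self.kind == "svr_poly":
            return (Z @ SV.T) ** hp["degree"]
        if self.kind == "svr_rbf":
            d2 = ((Z**2).sum(axis=1)[:, None] + (SV**2).sum(axis=1)[None, :]
                  - 2.0 * Z @ SV.T)
            return np.exp(-hp["gamma"] * np.maximum(d2, 0.0))
        if self.kind == "svr_puk":
            return puk_kernel(Z, SV, hp["omega"], hp.get("sigma", PUK_SIGMA))
        raise ValueError(f"unknown model kind '{self.kind}'")

    def to_json(self, path=None) -> str:
        doc = {
            "kind": self.kind,
            "hyperparams": self.hyperparams,
            "feature_ids": self.feature_ids,
            "fingerprint": self.fingerprint,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "coef": None if self.coef is None else self.coef.tolist(),
            "intercept": self.intercept,
            "support_vectors": (None if self.support_vectors is None
                                else self.support_vectors.tolist()),
            "dual_coef": None if self.dual_coef is None else self.dual_coef.tolist(),
            "extra": self.extra,
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ContentModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(
            kind=doc["kind"],
            hyperparams=doc["hyperparams"],
            feature_ids=doc["feature_ids"],
            fingerprint=doc["fingerprint"],
            scaler_mean=np.asarray(doc["scaler_mean"], dtype=float),
            scaler_sd=np.asarray(doc["scaler_sd"], dtype=float),
            coef=None if doc["coef"] is None else np.asarray(doc["coef"], dtype=float),
            intercept=doc["intercept"],
            support_vectors=(None if doc["support_vectors"] is None
                             else np.asarray(doc["support_vectors"], dtype=float)),
            dual_coef=(None if doc["dual_coef"] is None
                       else np.asarray(doc["dual_coef"], dtype=float)),
            extra=doc.get("extra", {}),
        )


def fit_ridge(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    feature_ids: Optional[Sequence[str]] = None,
    fingerprint: Optional[str] = None,
) -> ContentModel:
    """Fit ridge regression minimizing ||y - X b - b0||^2 + lambda ||b||^2.

    Features are standardized internally; the intercept is unpenalized.
    """
    if lam < 0:
        raise ValueError(f"ridge lambda must be non-negative, got {lam}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[1] == 0:  # intercept-only degenerate model
        return ContentModel(
            kind="ridge", hyperparams={"lambda": float(lam)},
            feature_ids=[], fingerprint=fingerprint,
            scaler_mean=np.empty(0), scaler_sd=np.empty(0),
            coef=np.empty(0), intercept=float(np.mean(y)))
    scaler = _Standardizer.fit(X)
    Z = scaler.transform(X)
    est = Ridge(alpha=lam, fit_intercept=True, solver="cholesky")
    est.fit(Z, y)
    return ContentModel(
        kind="ridge",
        hyperparams={"lambda": float(lam)},
        feature_ids=list(feature_ids) if feature_ids is not None else [
            f"f{j}" for j in range(X.shape[1])],
        fingerprint=fingerprint,
        scaler_mean=scaler.mean,
        scaler_sd=scaler.sd,
        coef=np.asarray(est.coef_, dtype=float),
        intercept=float(est.intercept_),
    )


def fit_svr(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str,
    params: dict,
    feature_ids: Optional[Sequence[str]] = None,
    fingerprint: Optional[str] = None,
) -> ContentModel:
    """Fit epsilon-SVR with a polynomial, RBF or PUK kernel."""
    kind = kernel if kernel.startswith("svr_") else f"svr_{kernel}"
    if kind not in ("svr_poly", "svr_rbf", "svr_puk"):
        raise ValueError(f"unknown SVR kernel '{kernel}'")
    C = float(params["C"])
    if C <= 0:
        raise ValueError(f"C must be positive, got {C}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    scaler = _Standardizer.fit(X)
    Z = scaler.transform(X)

    hyper = {"C": C}
    if kind == "svr_poly":
        degree = int(params["degree"])
        est = SVR(kernel="poly", degree=degree, gamma=1.0, coef0=0.0,
                  C=C, epsilon=SVR_EPSILON)
        hyper["degree"] = degree
    elif kind == "svr_rbf":
        gamma = float(params["gamma"])
        est = SVR(kernel="rbf", gamma=gamma, C=C, epsilon=SVR_EPSILON)
        hyper["gamma"] = gamma
    else:
        omega = float(params["omega"])
        sigma = float(params.get("sigma", PUK_SIGMA))
        est = SVR(kernel=lambda A, B: puk_kernel(A, B, omega, sigma),
                  C=C, epsilon=SVR_EPSILON)
        hyper["omega"] = omega
        hyper["sigma"] = sigma
    est.fit(Z, y)
    if hasattr(est, "support_"):
        sv = Z[est.support_]
    else:  # pragma: no cover
        sv = est.support_vectors_
    return ContentModel(
        kind=kind,
        hyperparams=hyper,
        feature_ids=list(feature_ids) if feature_ids is not None else [
            f"f{j}" for j in range(X.shape[1])],
        fingerprint=fingerprint,
        scaler_mean=scaler.mean,
        scaler_sd=scaler.sd,
        support_vectors=sv,
        dual_coef=np.asarray(est.dual_coef_, dtype=float).ravel(),
        intercept=float(est.intercept_[0]),
    )


class _SkEstimator(BaseEstimator, RegressorMixin):
    """sklearn-compatible wrapper used during cross-validated scoring."""

    def __init__(self, kind: str = "ridge", params: Optional[dict] = None):
        self.kind = kind
        self.params = params if params is not None else {}

    def fit(self, X, y):
        if self.kind == "ridge":
            self.model_ = fit_ridge(X, y, self.params.get("lambda", 1.0))
        else:
            self.model_ = fit_svr(X, y, self.kind, self.params)
        return self

    def predict(self, X):
        return self.model_.predict_raw(X)


def make_estimator(kind: str, params: dict) -> _SkEstimator:
    """Cloneable estimator for :func:`discon.selection.repeated_cv_mse`."""
    if kind not in ESTIMATOR_KINDS:
        raise ValueError(f"unknown estimator kind '{kind}'")
    return _SkEstimator(kind=kind, params=dict(params))


def enumerate_grid(kind: str) -> list[dict]:
    """The hyperparameter grid for one estimator kind."""
    if kind == "ridge":
        return [{"lambda": lam} for lam in RIDGE_LAMBDA_GRID]
    if kind == "svr_poly":
        return [dict(p) for p in POLY_GRID]
    if kind == "svr_rbf":
        return [dict(p) for p in RBF_GRID]
    if kind == "svr_puk":
        return [dict(p) for p in PUK_GRID]
    raise ValueError(f"unknown estimator kind '{kind}'")


def _complexity_key(kind: str, params: dict) -> tuple:
    # tie-break toward the simpler model: smaller C first, then the smaller
    # secondary parameter (lambda / gamma / omega / degree)
    if kind == "ridge":
        return (params["lambda"],)
    secondary = params.get("degree", params.get("gamma", params.get("omega", 0.0)))
    return (params["C"], secondary)


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    kind: str,
    seed: int = 0,
    folds: int = 5,
    max_rep: int = 5,
    cov_limit: float = 0.02,
) -> tuple[dict, list[dict]]:
    """Exhaustive grid search scored by repeated cross-validated MSE.

    Returns the winning hyperparameters and the full table of
    ``{params, mse, repetitions}`` rows.  Ties on MSE go to the lower
    complexity point (smaller C, then smaller lambda / gamma / omega).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    table = []
    for params in enumerate_grid(kind):
        est = make_estimator(kind, params)
        mse, reps = repeated_cv_mse(
            X, y, list(range(X.shape[1])), est,
            folds=folds, max_rep=max_rep, cov_limit=cov_limit, seed=seed)
        table.append({"params": params, "mse": mse, "repetitions": reps})
    best = min(table, key=lambda row: (row["mse"], _complexity_key(kind, row["params"])))
    return dict(best["params"]), table


def predict_content(model: ContentModel, X: np.ndarray, fingerprint: Optional[str] = None) -> np.ndarray:
    """Predict disorder content, clamped to [0, 1].

    When ``fingerprint`` is given it must match the catalog fingerprint the
    model was trained with.
    """
    if fingerprint is not None and model.fingerprint is not None \
            and fingerprint != model.fingerprint:
        raise ValueError(
            f"feature-catalog fingerprint mismatch: model has "
            f"{model.fingerprint}, input has {fingerprint}"
        )
    return np.clip(model.predict_raw(X), 0.0, 1.0)
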