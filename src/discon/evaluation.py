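"""Evaluation of content and residue-level disorder predictions.

Content predictions (one real value per chain) are scored with MSE, MAE and
the Pearson correlation coefficient, plus an over-/under-prediction
decomposition.  Residue-level binary predictions are scored with accuracy and
the Matthews correlation coefficient (MCC := 0 when every residue is put in
one class), and real-valued propensities with the rank-statistic AUC.
Method comparisons use Shapiro-Wilk normality checks followed by a paired
t-test (with a flagged sign-rank fallback when normality is rejected) and a
subset-resampling comparison of Pearson correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats


@dataclass
class EvaluationReport:
    """Per-chain errors plus summary metrics for one content predictor."""

    predicted: np.ndarray
    native: np.ndarray
    mse: float = 0.0
    mae: float = 0.0
    pcc: Optional[float] = None
    over_under: dict = field(default_factory=dict)
    residue: dict = field(default_factory=dict)
    significance: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mse": self.mse,
            "mae": self.mae,
            "pcc": self.pcc,
            "over_under": self.over_under,
            "residue": self.residue,
            "significance": self.significance,
            "flags": self.flags,
        }


def content_metrics(predicted, native) -> tuple[float, float, Optional[float]]:
    """(MSE, MAE, PCC) of predicted vs native per-chain disorder content.

    PCC uses sample standard deviations and is ``None`` (flagged missing, not
    0) when either side has zero variance.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(native, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("predicted and native must be equal-length 1-D arrays")
    err = x - y
    mse = float(np.mean(err**2))
    mae = float(np.mean(np.abs(err)))
    if len(x) < 2 or x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        return mse, mae, None
    cov = float(np.cov(x, y, ddof=1)[0, 1])
    return mse, mae, cov / (x.std(ddof=1) * y.std(ddof=1))


def confusion_counts(predicted, reference) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with disordered = positive class."""
    p = np.asarray(predicted).astype(bool)
    r = np.asarray(reference).astype(bool)
    if p.shape != r.shape:
        raise ValueError("prediction and reference lengths differ")
    tp = int((p & r).sum())
    fp = int((p & ~r).sum())
    tn = int((~p & ~r).sum())
    fn = int((~p & r).sum())
    return tp, fp, tn, fn


def mcc_from_counts(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when the denominator vanishes."""
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def auc_score(propensities, reference) -> Optional[float]:
    """Rank-statistic AUC with average-rank tie handling.

    ``None`` when the reference contains a single class.
    """
    s = np.asarray(propensities, dtype=float)
    r = np.asarray(reference).astype(bool)
    n_pos = int(r.sum())
    n_neg = len(r) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = stats.rankdata(s)
    return float((ranks[r].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def residue_metrics(predicted, reference, propensities=None) -> tuple[float, float, Optional[float]]:
    """(MCC, accuracy, AUC) for per-residue binary disorder predictions.

    AUC is computed from ``propensities`` when supplied and the reference has
    both classes; otherwise it is ``None``.
    """
    tp, fp, tn, fn = confusion_counts(predicted, reference)
    total = tp + fp + tn + fn
    acc = (tp + tn) / total if total else 0.0
    mcc = mcc_from_counts(tp, fp, tn, fn)
    auc = auc_score(propensities, reference) if propensities is not None else None
    return mcc, acc, auc


def over_under_analysis(predicted, native) -> dict:
    """Decompose content errors into over- and under-predicted chains.

    Returns the fractions of chains with predicted > native, < native and
    == native, plus the MAE within the over- and under-predicted subsets
    (``None`` when a subset is empty).
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(native, dtype=float)
    n = len(x)
    over = x > y
    under = x < y
    exact = ~over & ~under
    out = {
        "over_fraction": float(over.sum()) / n,
        "under_fraction": float(under.sum()) / n,
        "exact_fraction": float(exact.sum()) / n,
        "mae_over": float(np.abs(x[over] - y[over]).mean()) if over.any() else None,
        "mae_under": float(np.abs(x[under] - y[under]).mean()) if under.any() else None,
    }
    return out


def _significance_code(p: float, alphas=(0.05, 0.01)) -> str:
    if p < alphas[1]:
        return "++"
    if p < alphas[0]:
        return "+"
    return "="


def significance_compare(
    errors_a,
    errors_b,
    predictions_a=None,
    predictions_b=None,
    native=None,
    alphas=(0.05, 0.01),
    seed: int = 0,
    n_subsets: int = 200,
    subset_size: int = 100,
) -> dict:
    """Paired significance comparison of two methods' per-chain errors.

    Shapiro-Wilk is run on the paired differences; the paired t-test is used
    when normality holds at 0.05, otherwise a Wilcoxon sign-rank fallback is
    applied and flagged.  When paired predictions and native contents are
    supplied, Pearson correlations are additionally compared over
    ``n_subsets`` random subsets of ``subset_size`` chains (drawn without
    replacement within a subset, with replacement across subsets) and the
    per-subset PCC pairs are paired-t-tested.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need paired error vectors of length >= 3")
    diff = a - b
    out: dict = {"n": len(a), "flags": []}
    if np.allclose(diff, 0):
        out.update({"normality_p": None, "test": "degenerate", "p_value": 1.0, "code": "="})
    else:
        sw_stat, sw_p = stats.shapiro(diff)
        out["normality_p"] = float(sw_p)
        if sw_p >= 0.05:
            t_stat, p = stats.ttest_rel(a, b)
            out["test"] = "paired_t"
        else:
            t_stat, p = stats.wilcoxon(a, b)
            out["test"] = "wilcoxon_signrank"
            out["flags"].append("normality rejected; sign-rank fallback used")
        out["p_value"] = float(p)
        out["code"] = _significance_code(float(p), alphas)

    if predictions_a is not None and predictions_b is not None and native is not None:
        pa = np.asarray(predictions_a, dtype=float)
        pb = np.asarray(predictions_b, dtype=float)
        y = np.asarray(native, dtype=float)
        rng = np.random.default_rng(seed)
        size = min(subset_size, len(y))
        pccs_a, pccs_b = [], []
        for _ in range(n_subsets):
            idx = rng.choice(len(y), size=size, replace=False)
            _, _, ra = content_metrics(pa[idx], y[idx])
            _, _, rb = content_metrics(pb[idx], y[idx])
            if ra is not None and rb is not None:
                pccs_a.append(ra)
                pccs_b.append(rb)
        if len(pccs_a) >= 3 and not np.allclose(pccs_a, pccs_b):
            t_stat, p = stats.ttest_rel(pccs_a, pccs_b)
            out["pcc_comparison"] = {
                "n_subsets": len(pccs_a),
                "mean_pcc_a": float(np.mean(pccs_a)),
                "mean_pcc_b": float(np.mean(pccs_b)),
                "p_value": float(p),
                "code": _significance_code(float(p), alphas),
            }
        else:
            out["pcc_comparison"] = {"n_subsets": len(pccs_a), "p_value": 1.0, "code": "="}
    return out


def evaluate_content(predicted, native) -> EvaluationReport:
    """Full content-level report: metrics plus over/under decomposition."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(native, dtype=float)
    mse, mae, pcc = content_metrics(x, y)
    rep = EvaluationReport(predicted=x, native=y, mse=mse, mae=mae, pcc=pcc,
                           over_under=over_under_analysis(x, y))
    if pcc is None:
        rep.flags.append("PCC undefined (zero variance)")
    return rep
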