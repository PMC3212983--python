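"""End-to-end training pipeline: extraction, selection, grid search, fitting.

This glues the stages together the way the deployed predictor is built:
extract the default feature catalog, run the two-step selection with a
grid-parameterized estimator (parameterized on a representative per-family
subset, re-parameterized once on the selected subset), and fit the final
model on all training chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from discon.features import FeatureCatalog, build_default_catalog, extract_matrix
from discon.models import ContentModel, fit_ridge, fit_svr, grid_search, make_estimator, predict_content
from discon.selection import (
    SelectionTrace,
    cv_feature_target_correlation,
    cv_pairwise_correlation,
    relevance_redundancy_filter,
    wrapper_best_first,
)


@dataclass
class TrainedPipeline:
    model: ContentModel
    catalog: FeatureCatalog
    trace: SelectionTrace
    grid_table: list = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)

    def predict_records(self, records) -> tuple[list[str], np.ndarray]:
        ids, X, _ = extract_matrix(records, self.catalog)
        cols = [self.feature_ids.index(f) for f in self.model.feature_ids]
        return ids, predict_content(self.model, X[:, cols],
                                    fingerprint=self.catalog.fingerprint)


def representative_subset(feature_ids: Sequence[str], families: dict[str, str],
                          target_pcc: dict[str, float]) -> list[str]:
    """One feature per family: the one with the highest target |PCC|."""
    best: dict[str, str] = {}
    for f in sorted(feature_ids):  # lexicographic scan; strict > keeps the first id on ties
        fam = families[f]
        if fam not in best or target_pcc[f] > target_pcc[best[fam]]:
            best[fam] = f
    return sorted(best.values())


def train_pipeline(
    records,
    estimator_kind: str = "ridge",
    direction: str = "forward",
    catalog: Optional[FeatureCatalog] = None,
    t_rel: float = 0.2,
    t_red: float = 0.9,
    seed: int = 0,
    folds: int = 5,
) -> TrainedPipeline:
    """Train the content predictor from annotated records.

    Steps: feature extraction; cross-validated relevance/redundancy filters;
    grid parameterization on a representative per-family subset; wrapper
    best-first search; one post-selection re-parameterization; final fit on
    the full training set.
    """
    if catalog is None:
        catalog = build_default_catalog()
    ids, X, _ = extract_matrix(records, catalog)
    y = np.array([r.content for r in records], dtype=float)
    if np.isnan(y).any():
        raise ValueError("every training record needs a disorder content")
    feature_ids = list(catalog.ids)
    families = {d.id: d.family for d in catalog}

    target_pcc, flags = cv_feature_target_correlation(X, y, feature_ids, folds=folds, seed=seed)
    pairwise = cv_pairwise_correlation(X, feature_ids, folds=folds, seed=seed)
    relevant, survivors, rejections = relevance_redundancy_filter(
        target_pcc, pairwise, feature_ids, t_rel=t_rel, t_red=t_red)

    index = {f: j for j, f in enumerate(feature_ids)}
    rep = representative_subset(survivors, families, target_pcc) or survivors[:1]
    rep_cols = [index[f] for f in rep]
    params, _ = grid_search(X[:, rep_cols], y, estimator_kind, seed=seed, folds=folds)

    trace = wrapper_best_first(
        X, y, survivors, feature_ids, make_estimator(estimator_kind, params),
        target_pcc=target_pcc, direction=direction, seed=seed, folds=folds)
    trace.target_pcc = {f: float(v) for f, v in target_pcc.items()}
    trace.relevance_survivors = relevant
    trace.redundancy_survivors = survivors
    trace.redundancy_rejections = rejections
    trace.flags.extend(flags)

    selected = trace.selected
    if selected:
        sel_cols = [index[f] for f in selected]
        final_params, grid_table = grid_search(X[:, sel_cols], y, estimator_kind,
                                               seed=seed, folds=folds)
    else:
        sel_cols = []
        final_params, grid_table = params, []

    Xsel = X[:, sel_cols] if sel_cols else np.zeros((len(y), 0))
    if estimator_kind == "ridge":
        model = fit_ridge(Xsel, y, final_params["lambda"], feature_ids=selected,
                          fingerprint=catalog.fingerprint)
    else:
        model = fit_svr(Xsel, y, estimator_kind, final_params, feature_ids=selected,
                        fingerprint=catalog.fingerprint)
    return TrainedPipeline(model=model, catalog=catalog, trace=trace,
                           grid_table=grid_table, feature_ids=feature_ids)
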