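"""Stacked generalization over baseline probability columns.

Baselines are ranked by their out-of-fold AUC; the meta-classifier — plain
logistic regression by default,

    log(P / (1 - P)) = beta_0 + beta_1 X_1 + ... + beta_n X_n,

with X_i the i-th baseline's predicted probability — is fitted on the
strictly out-of-fold probability matrix, so no sample's meta-feature was
produced by a model that saw that sample. Meta-level cross-validated
metrics reuse the same fold plan, keeping every layer leakage-free.

A probability of exactly the threshold (default 0.5) calls a site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from . import metrics
from .models import BaselineModel, FoldPlan

META_FAMILIES = ("LR", "LGBM", "XGB", "RF", "SVM", "KNN", "NB")


class StackingError(RuntimeError):
    pass


def _make_meta_estimator(meta_family: str, seed: int):
    # LR is deliberately near-unregularized: the meta-model is plain
    # logistic regression over probability columns.
    if meta_family == "LR":
        return LogisticRegression(C=1e6, max_iter=5000)
    if meta_family == "LGBM":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            n_estimators=100, random_state=seed, n_jobs=1, verbose=-1,
            min_child_samples=5,
        )
    if meta_family == "XGB":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=100, random_state=seed, n_jobs=1,
            eval_metric="logloss", verbosity=0,
        )
    if meta_family == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if meta_family == "SVM":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if meta_family == "KNN":
        return KNeighborsClassifier(n_neighbors=5, n_jobs=1)
    if meta_family == "NB":
        return GaussianNB()
    raise StackingError(f"unknown meta family {meta_family!r}")


def rank_baselines(models: Sequence[BaselineModel]) -> list[str]:
    """Keys in descending OOF AUC; ties broken by MCC at 0.5, then key."""
    return [
        m.key
        for m in sorted(models, key=lambda m: (-m.cv_auc, -m.cv_mcc, m.key))
    ]


def oof_matrix(
    models: Sequence[BaselineModel], selected_keys: Sequence[str]
) -> np.ndarray:
    """Samples x selected-baselines OOF probability matrix, column-aligned."""
    by_key = {m.key: m for m in models}
    cols = []
    for key in selected_keys:
        if key not in by_key:
            raise StackingError(f"no baseline for selected key {key!r}")
        cols.append(by_key[key].oof_probs)
    return np.column_stack(cols)


@dataclass
class MetaModel:
    """Fitted meta-classifier over selected baseline probability columns."""

    selected_keys: tuple[str, ...]
    meta_family: str = "LR"
    threshold: float = 0.5
    estimator: object = None
    beta0: Optional[float] = None
    betas: Optional[np.ndarray] = None
    cv_metrics: dict[str, float] = field(default_factory=dict)
    cv_probs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise StackingError("threshold must lie in (0, 1)")

    def predict_proba(self, prob_matrix: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(prob_matrix)[:, 1]


def fit_meta(
    X_oof: np.ndarray,
    labels: Sequence[int],
    selected_keys: Sequence[str],
    meta_family: str = "LR",
    plan: Optional[FoldPlan] = None,
    threshold: float = 0.5,
    seed: int = 0,
) -> MetaModel:
    """Fit the meta-classifier on out-of-fold probabilities.

    If a fold plan is given, meta-level CV metrics are computed with the
    same folds (fit on the other folds' rows, score the held-out fold),
    stored in ``cv_metrics`` / ``cv_probs``.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise StackingError("labels are single-class; cannot fit meta-model")
    X_oof = np.asarray(X_oof, dtype=float)
    if X_oof.min() < 0.0 or X_oof.max() > 1.0:
        raise StackingError("meta-features must be probabilities in [0, 1]")
    if X_oof.shape[1] != len(selected_keys):
        raise StackingError("column count does not match selected_keys")

    model = MetaModel(tuple(selected_keys), meta_family, threshold)
    est = _make_meta_estimator(meta_family, seed)
    est.fit(X_oof, y)
    model.estimator = est
    if meta_family == "LR":
        model.beta0 = float(est.intercept_[0])
        model.betas = est.coef_[0].copy()

    if plan is not None:
        probs = np.full(y.size, np.nan)
        for fold in range(plan.n_folds):
            tr, va = plan.train_indices(fold), plan.val_indices(fold)
            fold_est = _make_meta_estimator(meta_family, seed)
            fold_est.fit(X_oof[tr], y[tr])
            probs[va] = fold_est.predict_proba(X_oof[va])[:, 1]
        model.cv_probs = probs
        model.cv_metrics = metrics.evaluate_scores(y, probs, threshold)
    return model


def top_n_sweep(
    models: Sequence[BaselineModel],
    labels: Sequence[int],
    plan: FoldPlan,
    n_list: Sequence[int | str] = (
        1, 2, 4, 8, 12, 16, 20, 30, 40, 50, 60, 70, 80, 90,
        100, 110, 120, 130, 140, "all",
    ),
    meta_family: str = "LR",
    seed: int = 0,
) -> dict[int, MetaModel]:
    """One meta-model per top-N baseline subset (the stacking-size curve)."""
    ranking = rank_baselines(models)
    out: dict[int, MetaModel] = {}
    for n in n_list:
        n_eff = len(ranking) if n == "all" else int(n)
        if n_eff > len(ranking):
            raise StackingError(f"top-N={n_eff} exceeds {len(ranking)} models")
        keys = ranking[:n_eff]
        out[n_eff] = fit_meta(
            oof_matrix(models, keys), labels, keys, meta_family, plan, seed=seed
        )
    return out


def predict_meta(
    seqs: Sequence[str],
    baselines: Sequence[BaselineModel],
    meta: MetaModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and site calls for new sequences.

    Baseline probabilities come from the final models refitted on the full
    training data (with full-training-data encoder profiles). The storage
    order of non-selected baselines is irrelevant.
    """
    by_key = {m.key: m for m in baselines}
    cols = []
    for key in meta.selected_keys:
        if key not in by_key:
            raise StackingError(f"missing baseline for selected key {key!r}")
        cols.append(by_key[key].predict_proba_seqs(seqs))
    probs = meta.predict_proba(np.column_stack(cols))
    labels = (probs >= meta.threshold).astype(int)
    return probs, labels
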