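"""Baseline (classifier family x encoder) models under stratified k-fold CV.

Each baseline pairs one of 8 classifier families {RF, SVM, XGB, LGBM, CBC,
NB, KNN, LR} with one feature encoding, and is trained under a shared
stratified 5-fold plan. The out-of-fold (OOF) probability column — each
sample scored by the fold-model that never saw it — is the baseline's
meta-feature for stacking, and its OOF AUC is the ranking statistic.

Fit-dependent encoders (BPB, NPPS, W2V) are refitted inside every training
fold, so no held-out sample ever influences its own features. Small
hyperparameter grids are scored by the same OOF AUC; the winning candidate's
OOF column is kept and a final model is refitted on all training data for
test-time use.

The CBC (gradient-boosted trees with ordered/histogram boosting) slot is
backed by scikit-learn's histogram gradient boosting.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import metrics
from .encoders import EncoderSpec, get_encoder
from .seqio import RnaRecord

FAMILIES = ("RF", "SVM", "XGB", "LGBM", "CBC", "NB", "KNN", "LR")

# LightGBM's sklearn wrapper records feature names at fit time and sklearn
# then warns on plain-array predict input; the arrays are identical
warnings.filterwarnings(
    "ignore", message="X does not have valid feature names"
)

#: Hyperparameter grids per family. Kept deliberately small; candidates are
#: scored by out-of-fold AUC inside the training folds.
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "RF": [
        {"n_estimators": n, "max_depth": d}
        for n in (100, 300)
        for d in (None, 6)
    ],
    "SVM": [{"C": c, "gamma": "scale"} for c in (1.0, 10.0)],
    "XGB": [{"learning_rate": 0.1, "n_estimators": n} for n in (100, 300)],
    "LGBM": [{"learning_rate": 0.1, "n_estimators": n} for n in (100, 300)],
    "CBC": [{"learning_rate": 0.1, "max_iter": n} for n in (100, 300)],
    "NB": [{}],
    "KNN": [{"n_neighbors": k} for k in (5, 15)],
    "LR": [{"C": 1.0}],
}


class ModelError(RuntimeError):
    pass


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family with its hyperparameter grid and seed."""

    family: str
    grid: tuple[dict, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ModelError(f"unknown family {self.family!r}; must be one of {FAMILIES}")
        if not self.grid:
            object.__setattr__(
                self, "grid", tuple(dict(g) for g in DEFAULT_GRIDS[self.family])
            )


def make_estimator(family: str, params: dict, seed: int):
    """Instantiate one sklearn-API estimator emitting class probabilities.

    Scale-sensitive families (SVM, KNN, LR) are wrapped with a standardizer.
    """
    if family == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "SVM":
        return make_pipeline(
            StandardScaler(),
            SVC(kernel="rbf", probability=True, random_state=seed, **params),
        )
    if family == "XGB":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            verbosity=0,
            **params,
        )
    if family == "LGBM":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            random_state=seed, n_jobs=1, verbose=-1, min_child_samples=5, **params
        )
    if family == "CBC":
        return HistGradientBoostingClassifier(random_state=seed, **params)
    if family == "NB":
        return GaussianNB(**params)
    if family == "KNN":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_jobs=1, **params))
    if family == "LR":
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, **params)
        )
    raise ModelError(f"unknown family {family!r}")


@dataclass(frozen=True)
class FoldPlan:
    """Stratified partition of training samples into folds."""

    n_folds: int
    assignments: np.ndarray  # sample index -> fold id
    stratified: bool
    seed: int

    @property
    def n_samples(self) -> int:
        return self.assignments.size

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)

    def val_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)


def make_folds(labels: Sequence[int], n_folds: int = 5, seed: int = 0) -> FoldPlan:
    """Deterministic stratified fold assignment."""
    y = np.asarray(labels)
    if n_folds < 2:
        raise ModelError("n_folds must be >= 2")
    for cls in (0, 1):
        if np.sum(y == cls) < n_folds:
            raise ModelError(
                f"class {cls} has fewer than n_folds={n_folds} samples"
            )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignments = np.empty(y.size, dtype=int)
    for fold, (_, val_idx) in enumerate(skf.split(np.zeros((y.size, 1)), y)):
        assignments[val_idx] = fold
    return FoldPlan(n_folds, assignments, True, seed)


@dataclass
class BaselineModel:
    """One (family x encoder) pair with its out-of-fold probability column."""

    key: str
    family: str
    encoder_id: str
    params: dict
    oof_probs: np.ndarray
    cv_auc: float
    fold_of: np.ndarray  # fold that produced each sample's OOF probability
    final_estimator: object
    final_profile: object = None  # full-training-data encoder state
    cv_mcc: float = field(default=0.0)

    def predict_proba_seqs(self, seqs: Sequence[str]) -> np.ndarray:
        enc = get_encoder(self.encoder_id)
        X = encode_matrix(seqs, enc, self.final_profile)
        return self.final_estimator.predict_proba(X)[:, 1]


def baseline_seed(global_seed: int, key: str) -> int:
    """Stable per-baseline seed below 2**31."""
    return (global_seed * 7919 + zlib.crc32(key.encode())) % (2**31 - 1)


def encode_matrix(
    seqs: Sequence[str], enc: EncoderSpec, state=None
) -> np.ndarray:
    rows = []
    for i, s in enumerate(seqs):
        fv = enc.transform(s, state) if enc.requires_fit else enc.transform(s)
        if not np.all(np.isfinite(fv.values)):
            raise ModelError(f"non-finite features from {enc.id} for sample {i}")
        rows.append(fv.values)
    return np.vstack(rows)


def _fit_encoder_fold(
    enc: EncoderSpec, seqs: list[str], y: np.ndarray, idx: np.ndarray, seed: int
):
    """Fit a fold-local profile for a fit-dependent encoder."""
    train_seqs = [seqs[i] for i in idx]
    train_y = y[idx]
    pos = [s for s, lab in zip(train_seqs, train_y) if lab == 1]
    neg = [s for s, lab in zip(train_seqs, train_y) if lab == 0]
    return enc.fit(pos_train=pos, neg_train=neg, corpus=train_seqs, seed=seed)


def fit_baseline(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    plan: FoldPlan,
    key: str = "",
) -> BaselineModel:
    """Fit one baseline on a precomputed (stateless-encoder) feature matrix."""
    provider = _StaticFolds(X)
    return _fit_baseline_core(provider, y, spec, plan, key, encoder_id="", X_full=X)


class _StaticFolds:
    """Fold feature provider over one precomputed matrix."""

    def __init__(self, X: np.ndarray):
        if not np.all(np.isfinite(X)):
            raise ModelError("non-finite entries in feature matrix")
        self.X = X

    def fold_features(self, plan: FoldPlan, fold: int):
        tr, va = plan.train_indices(fold), plan.val_indices(fold)
        return self.X[tr], self.X[va]


class _RefitFolds:
    """Fold feature provider that refits a fit-dependent encoder per fold."""

    def __init__(self, enc: EncoderSpec, seqs: list[str], y: np.ndarray, seed: int):
        self.enc, self.seqs, self.y, self.seed = enc, seqs, y, seed
        self._cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def fold_features(self, plan: FoldPlan, fold: int):
        if fold not in self._cache:
            tr, va = plan.train_indices(fold), plan.val_indices(fold)
            profile = _fit_encoder_fold(self.enc, self.seqs, self.y, tr, self.seed)
            X_tr = encode_matrix([self.seqs[i] for i in tr], self.enc, profile)
            X_va = encode_matrix([self.seqs[i] for i in va], self.enc, profile)
            self._cache[fold] = (X_tr, X_va)
        return self._cache[fold]


def _fit_baseline_core(
    provider, y, spec, plan, key, encoder_id, X_full=None, final_profile=None
) -> BaselineModel:
    y = np.asarray(y)
    best = None  # (cv_auc, -grid_index, params, oof)
    for gi, params in enumerate(spec.grid):
        oof = np.full(y.size, np.nan)
        for fold in range(plan.n_folds):
            X_tr, X_va = provider.fold_features(plan, fold)
            est = make_estimator(spec.family, params, spec.seed)
            est.fit(X_tr, y[plan.train_indices(fold)])
            oof[plan.val_indices(fold)] = est.predict_proba(X_va)[:, 1]
        auc = metrics.roc_auc(y, oof)
        cand = (auc, -gi, params, oof)
        if best is None or cand[:2] > best[:2]:
            best = cand
    auc, _, params, oof = best
    np.clip(oof, 0.0, 1.0, out=oof)

    final = make_estimator(spec.family, params, spec.seed)
    final.fit(X_full, y)
    mcc = metrics.summary(metrics.confusion(y, oof))["MCC"]
    return BaselineModel(
        key=key,
        family=spec.family,
        encoder_id=encoder_id,
        params=dict(params),
        oof_probs=oof,
        cv_auc=float(auc),
        fold_of=plan.assignments.copy(),
        final_estimator=final,
        final_profile=final_profile,
        cv_mcc=float(mcc),
    )


def fit_encoder_baseline(
    records: Sequence[RnaRecord],
    enc: EncoderSpec,
    spec: ClassifierSpec,
    plan: FoldPlan,
    global_seed: int = 0,
) -> BaselineModel:
    """Fit one baseline from raw records, handling per-fold encoder refits."""
    seqs = [r.seq for r in records]
    y = np.asarray([r.label for r in records])
    if any(lab is None for lab in y):
        raise ModelError("all records must be labelled")
    key = f"{spec.family}_{enc.id}"
    seed = baseline_seed(global_seed, key)
    spec = ClassifierSpec(spec.family, spec.grid, seed)

    if enc.requires_fit:
        provider = _RefitFolds(enc, seqs, y, seed)
        full_profile = _fit_encoder_fold(enc, seqs, y, np.arange(len(seqs)), seed)
        X_full = encode_matrix(seqs, enc, full_profile)
        return _fit_baseline_core(
            provider, y, spec, plan, key, enc.id, X_full, full_profile
        )
    X = encode_matrix(seqs, enc)
    model = _fit_baseline_core(_StaticFolds(X), y, spec, plan, key, enc.id, X)
    return model


def build_all_baselines(
    records: Sequence[RnaRecord],
    plan: FoldPlan,
    families: Sequence[str] = FAMILIES,
    encoder_ids: Optional[Sequence[str]] = None,
    seed: int = 0,
    progress: Optional[callable] = None,
) -> list[BaselineModel]:
    """Cross product of families x encoders (8 x 18 = 144 by default)."""
    from .encoders import encoder_registry

    encoders = (
        [get_encoder(e) for e in encoder_ids]
        if encoder_ids is not None
        else encoder_registry()
    )
    models: list[BaselineModel] = []
    for enc in encoders:
        for fam in families:
            spec = ClassifierSpec(fam)
            try:
                model = fit_encoder_baseline(records, enc, spec, plan, seed)
            except Exception as exc:  # annotate with the failing model key
                raise ModelError(f"baseline {fam}_{enc.id} failed: {exc}") from exc
            models.append(model)
            if progress is not None:
                progress(model.key, model.cv_auc)
    keys = [m.key for m in models]
    if len(set(keys)) != len(keys):
        raise ModelError("duplicate baseline keys")
    return models
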