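"""Model/Results interface over the full stacking pipeline.

:class:`MetaStackModel` holds the training data and the census
configuration (which classifier families, which encoders, fold count,
stacking depth); :meth:`MetaStackModel.fit` trains every baseline under the
shared fold plan, ranks them by out-of-fold AUC, fits the logistic
meta-classifier on the out-of-fold probability matrix, and returns a
:class:`MetaStackResults` carrying the ranking table, the meta
coefficients, cross-validated diagnostics, ``summary()`` and ``predict()``.

``run_pipeline`` is the batch entry point used by the command line:
synthesize or load data, fit, and write the artifact set (model bundle,
ranking CSV, metrics JSON, predictions CSV, run manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd

from . import metrics, seqio
from .encoders import encoder_registry, get_encoder
from .models import (
    FAMILIES,
    FoldPlan,
    build_all_baselines,
    make_folds,
)
from .seqio import RnaRecord
from .simulate import MotifSpec, generate, train_test_split
from .stacking import (
    MetaModel,
    fit_meta,
    oof_matrix,
    predict_meta,
    rank_baselines,
    top_n_sweep,
)

logger = logging.getLogger(__name__)

_ALL_ENCODER_IDS = tuple(e.id for e in encoder_registry())


class MetaStackModel:
    """Stacked Nm-site predictor specification bound to training data.

    Parameters
    ----------
    records : labelled training windows (``label`` set on every record).
    families : classifier families to include (default: all 8).
    encoders : encoder ids to include (default: all 18).
    n_folds : stratified CV folds shared by every layer (default 5).
    top_n : how many ranked baselines feed the meta-classifier
        (int or "all").
    meta_family : meta-learner family (default "LR", plain logistic).
    threshold : site-call probability cutoff (a score equal to the
        threshold calls a site).
    seed : master seed; every baseline derives its own seed from it.
    """

    def __init__(
        self,
        records: Sequence[RnaRecord],
        families: Sequence[str] = FAMILIES,
        encoders: Sequence[str] = _ALL_ENCODER_IDS,
        n_folds: int = 5,
        top_n: int | str = "all",
        meta_family: str = "LR",
        threshold: float = 0.5,
        seed: int = 0,
    ):
        for fam in families:
            if fam not in FAMILIES:
                raise ValueError(f"unknown family {fam!r}")
        for enc in encoders:
            get_encoder(enc)  # raises KeyError on unknown id
        labels = [r.label for r in records]
        if any(lab is None for lab in labels):
            raise ValueError("every training record needs a 0/1 label")
        self.records = list(records)
        self.labels = np.asarray(labels)
        self.families = tuple(families)
        self.encoders = tuple(encoders)
        self.n_folds = n_folds
        self.top_n = top_n
        self.meta_family = meta_family
        self.threshold = threshold
        self.seed = seed

    @classmethod
    def from_fasta(
        cls,
        positive_fasta: str | Path,
        negative_fasta: str | Path,
        expected_length: int = 41,
        **kwargs,
    ) -> "MetaStackModel":
        pos = seqio.read_fasta(positive_fasta, expected_length, label=1)
        neg = seqio.read_fasta(negative_fasta, expected_length, label=0)
        return cls(pos + neg, **kwargs)

    def fit(self, progress=None) -> "MetaStackResults":
        plan = make_folds(self.labels, self.n_folds, self.seed)
        baselines = build_all_baselines(
            self.records,
            plan,
            families=self.families,
            encoder_ids=self.encoders,
            seed=self.seed,
            progress=progress,
        )
        ranking = rank_baselines(baselines)
        n_sel = len(ranking) if self.top_n == "all" else int(self.top_n)
        selected = ranking[:n_sel]
        meta = fit_meta(
            oof_matrix(baselines, selected),
            self.labels,
            selected,
            self.meta_family,
            plan,
            self.threshold,
            self.seed,
        )
        return MetaStackResults(self, plan, baselines, ranking, meta)


class MetaStackResults:
    """Fitted census + meta-classifier with diagnostics."""

    def __init__(
        self,
        model: MetaStackModel,
        plan: FoldPlan,
        baselines,
        ranking: list[str],
        meta: MetaModel,
    ):
        self.model = model
        self.plan = plan
        self.baselines = baselines
        self.ranking = ranking
        self.meta = meta

    # -- diagnostics -------------------------------------------------------

    def ranking_table(self) -> pd.DataFrame:
        by_key = {m.key: m for m in self.baselines}
        rows = [
            {
                "rank": i + 1,
                "key": key,
                "cv_auc": by_key[key].cv_auc,
                "cv_mcc": by_key[key].cv_mcc,
            }
            for i, key in enumerate(self.ranking)
        ]
        return pd.DataFrame(rows)

    @property
    def cv_metrics(self) -> dict[str, float]:
        """Meta-level cross-validated SEN/SPE/PRE/ACC/MCC/AUC/AUPRC."""
        return dict(self.meta.cv_metrics)

    @property
    def best_baseline_auc(self) -> float:
        return max(m.cv_auc for m in self.baselines)

    def coefficients(self) -> Optional[pd.DataFrame]:
        """Logistic meta-coefficients (None for non-LR meta-learners)."""
        if self.meta.betas is None:
            return None
        return pd.DataFrame(
            {"key": self.meta.selected_keys, "beta": self.meta.betas}
        )

    def summary(self) -> str:
        lines = [
            "Stacked Nm-site predictor",
            "=" * 60,
            f"training samples: {len(self.model.records)} "
            f"({int(self.model.labels.sum())} positive)",
            f"census: {len(self.model.families)} families x "
            f"{len(self.model.encoders)} encoders = {len(self.baselines)} baselines",
            f"folds: {self.plan.n_folds}  seed: {self.model.seed}  "
            f"meta: {self.meta.meta_family} over top "
            f"{len(self.meta.selected_keys)} baselines",
            "",
            "top baselines by out-of-fold AUC:",
        ]
        for row in self.ranking_table().head(5).itertuples():
            lines.append(f"  {row.rank:3d}  {row.key:<16s} AUC={row.cv_auc:.4f}")
        lines.append("")
        lines.append("meta-classifier cross-validated performance:")
        for name, value in self.cv_metrics.items():
            lines.append(f"  {name:<6s} {value:.4f}")
        if self.meta.beta0 is not None:
            lines.append("")
            lines.append(f"meta intercept beta0 = {self.meta.beta0:+.4f}")
            coef = self.coefficients()
            top = coef.reindex(coef.beta.abs().sort_values(ascending=False).index)
            for row in top.head(5).itertuples():
                lines.append(f"  beta[{row.key}] = {row.beta:+.4f}")
        return "\n".join(lines)

    # -- prediction --------------------------------------------------------

    def predict(
        self, data: Sequence[RnaRecord] | Sequence[str]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Probabilities and 0/1 site calls for new windows."""
        seqs = [r.seq if isinstance(r, RnaRecord) else r for r in data]
        return predict_meta(seqs, self.baselines, self.meta)

    def sweep(self, n_list=None, seed: Optional[int] = None) -> pd.DataFrame:
        """Top-N stacking-size curve: meta CV metrics per subset size."""
        kwargs = {} if n_list is None else {"n_list": n_list}
        swept = top_n_sweep(
            self.baselines,
            self.model.labels,
            self.plan,
            meta_family=self.meta.meta_family,
            seed=self.model.seed if seed is None else seed,
            **kwargs,
        )
        rows = [
            {"n": n, "cv_auc": m.cv_metrics["AUC"], "cv_mcc": m.cv_metrics["MCC"],
             "cv_acc": m.cv_metrics["ACC"]}
            for n, m in sorted(swept.items())
        ]
        return pd.DataFrame(rows)

    # -- persistence -------------------------------------------------------

    def save(self, bundle_dir: str | Path) -> None:
        """Serialize to a directory: manifest JSON + per-model blobs."""
        bundle = Path(bundle_dir)
        bundle.mkdir(parents=True, exist_ok=True)
        manifest = {
            "version": 1,
            "seed": self.model.seed,
            "n_folds": self.plan.n_folds,
            "families": list(self.model.families),
            "encoders": list(self.model.encoders),
            "threshold": self.meta.threshold,
            "meta_family": self.meta.meta_family,
            "selected_keys": list(self.meta.selected_keys),
            "ranking": self.ranking,
            "cv_auc": {m.key: m.cv_auc for m in self.baselines},
        }
        (bundle / "manifest.json").write_text(json.dumps(manifest, indent=1))
        joblib.dump(
            {"baselines": self.baselines, "meta": self.meta, "plan": self.plan},
            bundle / "models.joblib",
        )

    @staticmethod
    def load(bundle_dir: str | Path, model: Optional[MetaStackModel] = None):
        bundle = Path(bundle_dir)
        manifest = json.loads((bundle / "manifest.json").read_text())
        blob = joblib.load(bundle / "models.joblib")
        results = MetaStackResults.__new__(MetaStackResults)
        results.model = model
        results.plan = blob["plan"]
        results.baselines = blob["baselines"]
        results.ranking = manifest["ranking"]
        results.meta = blob["meta"]
        return results


# ---------------------------------------------------------------------------
# batch pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Declarative configuration for one end-to-end run."""

    seed: int = 0
    folds: int = 5
    families: tuple[str, ...] = FAMILIES
    encoders: tuple[str, ...] = _ALL_ENCODER_IDS
    top_n: int | str = "all"
    meta_family: str = "LR"
    threshold: float = 0.5
    # synthetic-data parameters (used when no FASTA inputs are given)
    n_pos: int = 500
    n_neg: int = 500
    length: int = 41
    enrich_prob: float = 0.7
    test_fraction: float = 0.3
    # optional real inputs
    positive_fasta: Optional[str] = None
    negative_fasta: Optional[str] = None
    outdir: str = "nmstack_run"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute simulate/load -> train -> predict -> evaluate, writing artifacts.

    Returns a mapping of artifact names to paths. Re-running with an
    identical config reproduces every deterministic output.
    """
    for fam in config.families:
        if fam not in FAMILIES:
            raise ValueError(f"unknown family {fam!r}")
    for enc in config.encoders:
        get_encoder(enc)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.positive_fasta and config.negative_fasta:
        train_records = (
            seqio.read_fasta(config.positive_fasta, config.length, label=1)
            + seqio.read_fasta(config.negative_fasta, config.length, label=0)
        )
        test_records: list[RnaRecord] = []
    else:
        spec = MotifSpec(enrich_prob=config.enrich_prob)
        dataset = generate(
            config.n_pos, config.n_neg, config.length, spec, config.seed
        )
        train_records, test_records = train_test_split(
            dataset, config.test_fraction, config.seed
        )

    model = MetaStackModel(
        train_records,
        families=config.families,
        encoders=config.encoders,
        n_folds=config.folds,
        top_n=config.top_n,
        meta_family=config.meta_family,
        threshold=config.threshold,
        seed=config.seed,
    )
    results = model.fit(
        progress=lambda key, auc: logger.info("baseline %s cv_auc=%.4f", key, auc)
    )

    bundle_dir = outdir / "model_bundle"
    results.save(bundle_dir)
    ranking_path = outdir / "ranking.csv"
    results.ranking_table().to_csv(ranking_path, index=False, float_format="%.6f")

    metrics_obj = {"cv": results.cv_metrics}
    predictions_path = outdir / "predictions.csv"
    if test_records:
        probs, labels = results.predict(test_records)
        seqio.write_predictions(test_records, probs, labels, predictions_path)
        true = [r.label for r in test_records]
        metrics_obj["test"] = metrics.evaluate_scores(
            true, probs, config.threshold
        )
    else:
        probs, labels = results.predict(train_records)
        seqio.write_predictions(train_records, probs, labels, predictions_path)
    metrics_path = outdir / "metrics.json"
    metrics_path.write_text(json.dumps(metrics_obj, indent=1, sort_keys=True))

    manifest_path = outdir / "run_manifest.json"
    manifest_path.write_text(
        json.dumps(
            {"config": asdict(config), "config_hash": config.config_hash(),
             "n_train": len(train_records), "n_test": len(test_records)},
            indent=1, sort_keys=True, default=str,
        )
    )
    return {
        "bundle": str(bundle_dir),
        "ranking": str(ranking_path),
        "metrics": str(metrics_path),
        "predictions": str(predictions_path),
        "manifest": str(manifest_path),
    }
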