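"""Scar-based HRD classifier (HRDsig): labels, training, threshold, calls.

Training labels come from called allelic status, not latent truth:
biallelic BRCA1/2 samples are positives, HRR-wildtype samples (all 14
basket genes wildtype) are negatives, and everything else (other biallelic
HRR genes, monoallelic or unknown alterations) is excluded from training.
The model is a gradient-boosted tree ensemble (XGBoost) over the scar
feature vector; scores are out-of-fold cross-validated for every labelled
sample so threshold selection never sees in-fold scores.

The decision threshold is chosen on held-out negative scores at a target
specificity (default 95%); a prevalence-matching mode (calibrating the
positive-call rate to an expected population prevalence) is provided as an
alternative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
import xgboost as xgb
from xgboost import XGBClassifier

from .features import FEATURE_NAMES
from .zygosity import SampleHrrClass

DEFAULT_HYPERPARAMS = {
    "n_estimators": 200,
    "max_depth": 3,
    "learning_rate": 0.1,
    "subsample": 0.8,
    "colsample_bytree": 0.8,
    "reg_lambda": 1.0,
    # single-threaded training keeps reruns byte-identical
    "n_jobs": 1,
    "tree_method": "exact",
}


class TrainingError(ValueError):
    pass


@dataclass(frozen=True)
class TrainingLabel:
    sample_id: str
    label: str  # positive | negative | excluded
    reason: str  # biallelic-BRCA1/2 | HRRwt | other


@dataclass(frozen=True)
class HrdsigResult:
    sample_id: str
    score: float
    call: str  # positive | negative
    threshold_used: float


def build_training_labels(
    sample_classes: list[SampleHrrClass],
) -> list[TrainingLabel]:
    """Exhaustive, mutually exclusive label partition.

    positive <=> biallelic BRCA1 or BRCA2; negative <=> HRR-wildtype;
    everything else excluded.
    """
    labels = []
    for sc in sample_classes:
        if "BRCA1" in sc.biallelic_genes or "BRCA2" in sc.biallelic_genes:
            labels.append(TrainingLabel(sc.sample_id, "positive", "biallelic-BRCA1/2"))
        elif sc.is_hrr_wildtype:
            labels.append(TrainingLabel(sc.sample_id, "negative", "HRRwt"))
        else:
            labels.append(TrainingLabel(sc.sample_id, "excluded", "other"))
    return labels


def labels_frame(labels: list[TrainingLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.sample_id, l.label, l.reason) for l in labels],
        columns=["sample", "label", "reason"],
    )


def select_threshold(
    heldout_negative_scores: np.ndarray, target_specificity: float = 0.95
) -> float:
    """Smallest score achieving >= target specificity on held-out negatives.

    Specificity at threshold t is the fraction of negative scores strictly
    below t (calls are positive when score >= t).  If no observed score
    attains the target (e.g. all scores tied), the threshold is nudged just
    above the maximum.
    """
    scores = np.sort(np.asarray(heldout_negative_scores, dtype=float))
    m = len(scores)
    if m == 0:
        raise TrainingError("empty held-out negative score set")
    if not 0.0 <= target_specificity <= 1.0:
        raise TrainingError("target specificity must be in [0, 1]")
    if target_specificity == 0.0:
        return float(scores[0])
    k = int(np.ceil(target_specificity * m))
    for t in np.unique(scores):
        if np.searchsorted(scores, t, side="left") >= k:
            return float(t)
    return float(np.nextafter(scores[-1], np.inf))


class HrdsigClassifier:
    """Gradient-boosted HRD classifier over scar features.

    Parameters
    ----------
    features
        Feature matrix indexed by sample id with :data:`FEATURE_NAMES`
        columns (extra columns ignored, order normalised).
    labels
        Training labels from :func:`build_training_labels`.
    """

    def __init__(self, features: pd.DataFrame, labels: list[TrainingLabel] | pd.DataFrame):
        missing = [c for c in FEATURE_NAMES if c not in features.columns]
        if missing:
            raise TrainingError(f"feature matrix missing columns: {missing}")
        self.features = features[FEATURE_NAMES].copy()
        self.labels = (
            labels if isinstance(labels, pd.DataFrame) else labels_frame(labels)
        ).set_index("sample")

    @classmethod
    def from_cohort(cls, features: pd.DataFrame, sample_classes: list[SampleHrrClass]):
        return cls(features, build_training_labels(sample_classes))

    def fit(
        self,
        seed: int = 0,
        hyperparams: dict | None = None,
        n_folds: int = 5,
        min_class_size: int = 20,
    ) -> "HrdsigClassifierResults":
        """Train with stratified out-of-fold cross-validation.

        Excluded samples never enter any training fold.  Returns a results
        object carrying the refit ensemble, out-of-fold scores, the
        cross-validated AUROC and (not yet selected) decision threshold.
        """
        hp = {**DEFAULT_HYPERPARAMS, **(hyperparams or {})}
        lab = self.labels.reindex(self.features.index)
        train_mask = lab["label"].isin(["positive", "negative"]).fillna(False)
        X = self.features.loc[train_mask].to_numpy(dtype=float)
        y = (lab.loc[train_mask, "label"] == "positive").to_numpy(dtype=int)
        ids = self.features.index[train_mask]
        n_pos, n_neg = int(y.sum()), int((1 - y).sum())
        if n_pos < min_class_size or n_neg < min_class_size:
            raise TrainingError(
                f"need >= {min_class_size} samples per class, got "
                f"{n_pos} positive / {n_neg} negative"
            )

        oof = np.full(len(y), np.nan)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for fold_train, fold_test in skf.split(X, y):
            clf = XGBClassifier(random_state=seed, verbosity=0, **hp)
            clf.fit(X[fold_train], y[fold_train])
            oof[fold_test] = clf.predict_proba(X[fold_test])[:, 1]
        assert not np.isnan(oof).any()
        auroc = float(roc_auc_score(y, oof))

        final = XGBClassifier(random_state=seed, verbosity=0, **hp)
        final.fit(X, y)
        oof_scores = pd.Series(oof, index=ids, name="oof_score")
        return HrdsigClassifierResults(
            model=final.get_booster(),
            feature_names=list(FEATURE_NAMES),
            oof_scores=oof_scores,
            oof_labels=pd.Series(y, index=ids, name="label"),
            auroc=auroc,
            hyperparams=hp,
            seed=seed,
            n_folds=n_folds,
        )


@dataclass
class HrdsigClassifierResults:
    """Fitted HRDsig bundle: ensemble, out-of-fold diagnostics, threshold."""

    model: xgb.Booster
    feature_names: list[str]
    oof_scores: pd.Series
    oof_labels: pd.Series
    auroc: float
    hyperparams: dict
    seed: int
    n_folds: int
    threshold: float | None = None
    threshold_mode: str | None = None

    def select_threshold(
        self,
        target_specificity: float = 0.95,
        heldout_negative_scores: np.ndarray | None = None,
    ) -> float:
        """Fix the decision threshold at a target specificity on held-out
        negatives (default: the out-of-fold scores of negative samples)."""
        if heldout_negative_scores is None:
            heldout_negative_scores = self.oof_scores[self.oof_labels == 0].to_numpy()
        self.threshold = select_threshold(heldout_negative_scores, target_specificity)
        self.threshold_mode = f"specificity>={target_specificity}"
        return self.threshold

    def select_threshold_by_prevalence(
        self, cohort_scores: np.ndarray, target_prevalence: float
    ) -> float:
        """Alternative mode: calibrate the positive-call rate to an expected
        population prevalence."""
        scores = np.asarray(cohort_scores, dtype=float)
        if len(scores) == 0:
            raise TrainingError("empty cohort score set")
        self.threshold = float(np.quantile(scores, 1.0 - target_prevalence))
        self.threshold_mode = f"prevalence~{target_prevalence}"
        return self.threshold

    def score(self, features: pd.DataFrame) -> pd.Series:
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise TrainingError(f"missing feature columns: {missing}")
        if len(features) == 0:
            return pd.Series([], dtype=float, index=features.index, name="score")
        X = features[self.feature_names].to_numpy(dtype=float)
        return pd.Series(
            self.model.inplace_predict(X), index=features.index, name="score"
        )

    def predict(self, features: pd.DataFrame) -> pd.DataFrame:
        """HRDsig calls: positive iff score >= threshold (boundary inclusive)."""
        if self.threshold is None:
            raise TrainingError("select a threshold before predicting")
        scores = self.score(features)
        calls = np.where(scores >= self.threshold, "positive", "negative")
        return pd.DataFrame(
            {
                "sample": scores.index,
                "score": scores.to_numpy(),
                "call": calls,
                "threshold_used": self.threshold,
            }
        ).reset_index(drop=True)

    def predict_results(self, features: pd.DataFrame) -> list[HrdsigResult]:
        df = self.predict(features)
        return [
            HrdsigResult(r.sample, float(r.score), r.call, float(r.threshold_used))
            for r in df.itertuples()
        ]

    def summary(self) -> str:
        y = self.oof_labels
        lines = [
            "HRDsig classifier (gradient-boosted trees over scar features)",
            f"  training samples: {len(y)} "
            f"({int(y.sum())} biallelic-BRCA1/2 positives, "
            f"{int((1 - y).sum())} HRRwt negatives)",
            f"  {self.n_folds}-fold out-of-fold AUROC: {self.auroc:.3f}",
            f"  hyperparameters: {self.hyperparams}",
        ]
        if self.threshold is not None:
            lines.append(
                f"  threshold: {self.threshold:.4f} ({self.threshold_mode})"
            )
        return "\n".join(lines)

    # --- serialization: xgboost JSON + metadata sidecar -------------------

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.model.save_model(str(path))
        meta = {
            "feature_names": self.feature_names,
            "auroc": self.auroc,
            "hyperparams": self.hyperparams,
            "seed": self.seed,
            "n_folds": self.n_folds,
            "threshold": self.threshold,
            "threshold_mode": self.threshold_mode,
            "oof_scores": {str(k): float(v) for k, v in self.oof_scores.items()},
            "oof_labels": {str(k): int(v) for k, v in self.oof_labels.items()},
        }
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "HrdsigClassifierResults":
        model = xgb.Booster()
        model.load_model(str(path))
        meta = json.loads(Path(str(path) + ".meta.json").read_text())
        oof_scores = pd.Series(meta["oof_scores"], name="oof_score")
        oof_labels = pd.Series(meta["oof_labels"], name="label")
        return cls(
            model=model,
            feature_names=meta["feature_names"],
            oof_scores=oof_scores,
            oof_labels=oof_labels,
            auroc=meta["auroc"],
            hyperparams=meta["hyperparams"],
            seed=meta["seed"],
            n_folds=meta["n_folds"],
            threshold=meta["threshold"],
            threshold_mode=meta["threshold_mode"],
        )
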