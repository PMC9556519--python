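"""Label amplification: extend expert labels via calibrated ensembles.

Expert QC labels exist only for a small gold-standard subset.  To
amplify them to the full cohort we train gradient-boosted binary
classifiers on community ratings ("f" mode), automated data-quality
metrics ("q" mode), or both ("q+f"), under repeated stratified K-fold
cross-validation with a per-fold hyperparameter search.  The fold
models are then combined into a voting ensemble whose members are
weighted by their out-of-sample ROC-AUC; the ensemble's weighted mean
pass-probability is the amplified QC score.

Global feature importance is reported as the mean absolute Shapley
value per feature, estimated by permutation sampling against a
background sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterSampler, RepeatedStratifiedKFold
from xgboost import XGBClassifier

from hybridqc.synthetic import METRIC_COLUMNS

__all__ = [
    "FeatureMatrix",
    "CalibrationEnsemble",
    "build_feature_matrix",
    "fit_calibration",
    "ensemble_predict",
    "shapley_importance",
    "default_learner_factory",
    "DEFAULT_SEARCH_SPACE",
]

MODES = ("q", "f", "q+f")

#: Randomized-search space for the gradient-boosted base learner.
DEFAULT_SEARCH_SPACE = {
    "max_depth": [2, 3, 4, 6],
    "learning_rate": [0.05, 0.1, 0.3],
    "n_estimators": [50, 100, 200],
    "subsample": [0.7, 1.0],
    "colsample_bytree": [0.7, 1.0],
}


@dataclass
class FeatureMatrix:
    """Participant-indexed feature table with recorded provenance.

    ``provenance`` maps each column to ``"metric"`` or ``"rater"``.
    Missing values are permitted in rater columns (a rater who never
    saw a participant).
    """

    data: pd.DataFrame
    mode: str
    provenance: dict[str, str]

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)


def build_feature_matrix(
    metrics: pd.DataFrame | None = None,
    community: pd.DataFrame | None = None,
    mode: str = "q+f",
) -> FeatureMatrix:
    """Assemble the calibration feature matrix for a given mode.

    Parameters
    ----------
    metrics : DataFrame, optional
        31-column automated metrics table with ``participant_id``
        (required for modes "q" and "q+f").
    community : DataFrame, optional
        Long-form community ratings (participant_id, rater_id, view,
        rating) (required for modes "f" and "q+f").  Each rater
        becomes one column holding that rater's mean rating per
        participant, missing where unrated -- so the downstream model
        can weight raters individually.
    mode : {"q", "f", "q+f"}
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    needs_metrics = mode in ("q", "q+f")
    needs_community = mode in ("f", "q+f")
    if needs_metrics and metrics is None:
        raise ValueError(f"mode {mode!r} requires a metrics table")
    if needs_community and community is None:
        raise ValueError(f"mode {mode!r} requires community ratings")

    pieces: list[pd.DataFrame] = []
    provenance: dict[str, str] = {}
    if needs_metrics:
        missing = [c for c in METRIC_COLUMNS if c not in metrics.columns]
        if missing:
            raise ValueError(f"metrics table missing columns: {missing}")
        piece = metrics.set_index("participant_id")[METRIC_COLUMNS]
        pieces.append(piece)
        provenance.update({c: "metric" for c in METRIC_COLUMNS})
    if needs_community:
        piece = (
            community.groupby(["participant_id", "rater_id"])["rating"]
            .mean()
            .unstack("rater_id")
        )
        pieces.append(piece)
        provenance.update({c: "rater" for c in piece.columns})

    data = pd.concat(pieces, axis=1, join="outer") if len(pieces) > 1 else pieces[0]
    return FeatureMatrix(data=data, mode=mode, provenance=provenance)


def default_learner_factory(params: dict, seed: int) -> XGBClassifier:
    """Gradient-boosted tree binary classifier (handles missing values)."""
    model = XGBClassifier(
        **params,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
    )
    # xgboost's (de)serializer still expects the legacy sklearn
    # estimator-type tag that new scikit-learn mixins no longer set.
    model._estimator_type = "classifier"
    return model


@dataclass
class CalibrationEnsemble:
    """Cross-validation-born voting ensemble of calibrated classifiers.

    Each member carries the ROC-AUC it achieved on its held-out fold;
    predictions are the weight-normalized average of member
    pass-probabilities.
    """

    members: list = field(default_factory=list)
    weights: list[float] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)
    mode: str = ""
    config: dict = field(default_factory=dict)
    oof_predictions: pd.DataFrame | None = None
    cv_auc_mean: float = float("nan")
    cv_auc_sd: float = float("nan")

    def __post_init__(self):
        if self.weights and not all(0.0 <= w <= 1.0 for w in self.weights):
            raise ValueError("member weights must lie in [0, 1]")

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, member in enumerate(self.members):
            member.save_model(directory / f"member_{i:02d}.ubj")
        meta = {
            "weights": self.weights,
            "feature_names": self.feature_names,
            "mode": self.mode,
            "config": self.config,
            "cv_auc_mean": self.cv_auc_mean,
            "cv_auc_sd": self.cv_auc_sd,
        }
        (directory / "ensemble.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "CalibrationEnsemble":
        directory = Path(directory)
        meta = json.loads((directory / "ensemble.json").read_text())
        members = []
        for path in sorted(directory.glob("member_*.ubj")):
            model = XGBClassifier()
            # the legacy estimator-type tag must exist before load_model
            model._estimator_type = "classifier"
            model.load_model(path)
            members.append(model)
        return cls(
            members=members,
            weights=meta["weights"],
            feature_names=meta["feature_names"],
            mode=meta["mode"],
            config=meta["config"],
            cv_auc_mean=meta["cv_auc_mean"],
            cv_auc_sd=meta["cv_auc_sd"],
        )


def _tune_on_fold(
    x_train: np.ndarray,
    y_train: np.ndarray,
    search_budget: int,
    seed: int,
    learner_factory,
    search_space,
) -> dict:
    """Small randomized hyperparameter search scored by inner 2-fold AUC."""
    if search_budget <= 1:
        return {}
    sampler = ParameterSampler(
        search_space, n_iter=search_budget, random_state=seed
    )
    inner = RepeatedStratifiedKFold(n_splits=2, n_repeats=1, random_state=seed)
    best_params, best_score = {}, -np.inf
    for params in sampler:
        scores = []
        for tr, va in inner.split(x_train, y_train):
            model = learner_factory(params, seed)
            model.fit(x_train[tr], y_train[tr])
            scores.append(
                roc_auc_score(y_train[va], model.predict_proba(x_train[va])[:, 1])
            )
        score = float(np.mean(scores))
        if score > best_score:
            best_params, best_score = params, score
    return best_params


def fit_calibration(
    features: FeatureMatrix,
    targets: pd.Series | np.ndarray,
    n_splits: int = 3,
    n_repeats: int = 2,
    search_budget: int = 8,
    seed: int = 0,
    learner_factory=default_learner_factory,
    search_space=None,
) -> CalibrationEnsemble:
    """Fit the AUC-weighted voting ensemble by repeated stratified CV.

    One base classifier is trained per (split x repeat) -- 6 members
    with the default 3 splits x 2 repeats -- each tuned on its training
    fold by randomized search and weighted by its held-out-fold
    ROC-AUC.  Out-of-fold predictions are retained so cross-validated
    performance can be recomputed independently.

    Raises if a fold loses a class (stratification failure is
    surfaced, not silently re-split).
    """
    if search_space is None:
        search_space = DEFAULT_SEARCH_SPACE
    x = features.data.to_numpy(dtype=float)
    if isinstance(targets, pd.Series):
        targets = targets.reindex(features.data.index)
        if targets.isna().any():
            raise ValueError("targets not aligned to feature matrix index")
        y = targets.to_numpy()
    else:
        y = np.asarray(targets)
        if y.shape[0] != len(features):
            raise ValueError("targets misaligned with features")
    y = y.astype(int)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need >= 2 examples per class")

    cv = RepeatedStratifiedKFold(
        n_splits=n_splits, n_repeats=n_repeats, random_state=seed
    )
    members, weights = [], []
    oof_rows = []
    fold_aucs = []
    for fold, (tr, te) in enumerate(cv.split(x, y)):
        if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
            raise ValueError(f"fold {fold}: a class is absent after stratification")
        params = _tune_on_fold(
            x[tr], y[tr], search_budget, seed + fold, learner_factory, search_space
        )
        model = learner_factory(params, seed + fold)
        model.fit(x[tr], y[tr])
        proba = model.predict_proba(x[te])[:, 1]
        auc = float(roc_auc_score(y[te], proba))
        members.append(model)
        weights.append(auc)
        fold_aucs.append(auc)
        oof_rows.append(
            pd.DataFrame(
                {
                    "participant_id": features.data.index[te],
                    "fold": fold,
                    "y_true": y[te],
                    "y_proba": proba,
                }
            )
        )

    return CalibrationEnsemble(
        members=members,
        weights=[float(np.clip(w, 0.0, 1.0)) for w in weights],
        feature_names=features.columns,
        mode=features.mode,
        config={
            "n_splits": n_splits,
            "n_repeats": n_repeats,
            "search_budget": search_budget,
            "seed": seed,
        },
        oof_predictions=pd.concat(oof_rows, ignore_index=True),
        cv_auc_mean=float(np.mean(fold_aucs)),
        cv_auc_sd=float(np.std(fold_aucs, ddof=1)),
    )


def ensemble_predict(
    ensemble: CalibrationEnsemble,
    features: FeatureMatrix | pd.DataFrame,
) -> pd.Series:
    """Weighted-average pass-probability of all ensemble members.

    p = sum_m w_m p_m / sum_m w_m, guaranteed in [0, 1].
    """
    data = features.data if isinstance(features, FeatureMatrix) else features
    extra = [c for c in data.columns if c not in ensemble.feature_names]
    missing = [c for c in ensemble.feature_names if c not in data.columns]
    if extra or missing:
        raise ValueError(
            f"feature schema mismatch: missing={missing}, unexpected={extra}"
        )
    x = data[ensemble.feature_names].to_numpy(dtype=float)
    w = np.asarray(ensemble.weights, dtype=float)
    probs = np.stack(
        [m.predict_proba(x)[:, 1] for m in ensemble.members], axis=0
    )
    combined = (w[:, None] * probs).sum(axis=0) / w.sum()
    return pd.Series(np.clip(combined, 0.0, 1.0), index=data.index, name="qc_score")


def _predict_fn(model) -> callable:
    if isinstance(model, CalibrationEnsemble):
        w = np.asarray(model.weights, dtype=float)

        def fn(x):
            probs = np.stack(
                [m.predict_proba(x)[:, 1] for m in model.members], axis=0
            )
            return (w[:, None] * probs).sum(axis=0) / w.sum()

        return fn
    if hasattr(model, "predict_proba"):
        if not hasattr(model, "classes_"):
            raise ValueError("model appears unfitted (no classes_)")
        return lambda x: model.predict_proba(x)[:, 1]
    raise TypeError("model must be a CalibrationEnsemble or fitted classifier")


def shapley_importance(
    model,
    features: FeatureMatrix | pd.DataFrame,
    n_samples: int = 32,
    n_background: int = 64,
    n_explain: int | None = None,
    seed: int = 0,
) -> pd.Series:
    """Global feature importance: mean |Shapley value|, sorted descending.

    For each explained prediction, a feature's Shapley value is its
    average marginal contribution over ``n_samples`` random feature
    orderings, where the value of a coalition S is the model output
    with features in S fixed to the explained row and the rest drawn
    from a background sample (expectation over ``n_background`` rows).
    The estimator converges to the exact Shapley value as ``n_samples``
    grows; constant, never-split-on features get importance 0.
    """
    fn = _predict_fn(model)
    data = features.data if isinstance(features, FeatureMatrix) else features
    x = data.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    n, d = x.shape
    bg = x[rng.choice(n, size=min(n_background, n), replace=False)]
    explain_idx = (
        np.arange(n)
        if n_explain is None or n_explain >= n
        else rng.choice(n, size=n_explain, replace=False)
    )

    total_abs = np.zeros(d)
    n_bg = bg.shape[0]
    for i in explain_idx:
        xi = x[i]
        phi = np.zeros(d)
        for _ in range(n_samples):
            order = rng.permutation(d)
            # Walk the permutation, swapping in xi's features one at a
            # time on top of the background rows.
            current = bg.copy()
            prev = fn(current).mean()
            # Batch: build all d coalition matrices then predict once.
            stacked = np.empty((d, n_bg, d), dtype=float)
            for pos, j in enumerate(order):
                current[:, j] = xi[j]
                stacked[pos] = current
            values = fn(stacked.reshape(d * n_bg, d)).reshape(d, n_bg).mean(axis=1)
            contrib = np.diff(np.concatenate([[prev], values]))
            phi[order] += contrib
        phi /= n_samples
        total_abs += np.abs(phi)

    importance = pd.Series(
        total_abs / len(explain_idx), index=data.columns, name="mean_abs_shapley"
    )
    return importance.sort_values(ascending=False)
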