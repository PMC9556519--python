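"""Scoring metrics and the leave-site-out generalization protocol.

QC classifiers trained on some scanning sites are evaluated on data
from sites they never saw, to probe whether quality signatures
transfer across scanners.  The default experiment plan holds out each
3T site combination in turn: CBIC+CUNY vs RU, CBIC vs RU+CUNY,
RU+CUNY vs CBIC, and RU vs CBIC+CUNY.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sklearn.metrics as skm

from hybridqc.amplify import FeatureMatrix, ensemble_predict, fit_calibration

__all__ = [
    "roc_auc",
    "balanced_accuracy",
    "accuracy",
    "SiteGeneralizationPlan",
    "default_site_plan",
    "run_site_generalization",
]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    return labels


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve.

    Equals the probability that a random positive outscores a random
    negative, with ties counted half (Mann-Whitney convention), and is
    invariant under strictly monotone transforms of the scores.
    """
    labels = _check_binary(labels)
    return float(skm.roc_auc_score(labels, np.asarray(scores, dtype=float)))


def balanced_accuracy(labels, predictions) -> float:
    """Mean of sensitivity and specificity for binary predictions."""
    labels = _check_binary(labels)
    return float(skm.balanced_accuracy_score(labels, np.asarray(predictions)))


def accuracy(labels, predictions) -> float:
    return float(skm.accuracy_score(np.asarray(labels), np.asarray(predictions)))


@dataclass(frozen=True)
class SiteExperiment:
    train_sites: tuple[str, ...]
    eval_sites: tuple[str, ...]

    def validate(self) -> None:
        overlap = set(self.train_sites) & set(self.eval_sites)
        if overlap:
            raise ValueError(f"train/eval sites overlap: {sorted(overlap)}")

    @property
    def name(self) -> str:
        return (
            f"train: {' + '.join(self.train_sites)}, "
            f"test: {' + '.join(self.eval_sites)}"
        )


@dataclass
class SiteGeneralizationPlan:
    """List of leave-site-out experiments for one model family."""

    experiments: list[SiteExperiment]
    model_family: str = "metrics-calibration"
    n_replicates: int = 20
    seeds: list[int] | None = None

    def __post_init__(self):
        if self.model_family not in ("cnn", "metrics-calibration"):
            raise ValueError("model_family must be 'cnn' or 'metrics-calibration'")
        for experiment in self.experiments:
            experiment.validate()
        if self.seeds is None:
            self.seeds = list(range(self.n_replicates))


def default_site_plan(
    model_family: str = "metrics-calibration",
    n_replicates: int | None = None,
) -> SiteGeneralizationPlan:
    """The four canonical 3T leave-site-out splits.

    Replicate counts default to 8 for the CNN family and 20 for the
    metrics-calibration family.
    """
    experiments = [
        SiteExperiment(("CBIC", "CUNY"), ("RU",)),
        SiteExperiment(("CBIC",), ("RU", "CUNY")),
        SiteExperiment(("RU", "CUNY"), ("CBIC",)),
        SiteExperiment(("RU",), ("CBIC", "CUNY")),
    ]
    if n_replicates is None:
        n_replicates = 8 if model_family == "cnn" else 20
    return SiteGeneralizationPlan(
        experiments=experiments,
        model_family=model_family,
        n_replicates=n_replicates,
    )


def _eval_scores(labels, scores, threshold=0.5):
    predictions = (np.asarray(scores) >= threshold).astype(int)
    return {
        "accuracy": accuracy(labels, predictions),
        "balanced_accuracy": balanced_accuracy(labels, predictions),
        "roc_auc": roc_auc(labels, scores),
    }


def run_site_generalization(
    plan: SiteGeneralizationPlan,
    data: dict,
    search_budget: int = 4,
    cnn_train_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Execute a leave-site-out plan and summarize metrics per experiment.

    Parameters
    ----------
    plan : SiteGeneralizationPlan
    data : dict
        Data bundle.  Required for both families: ``site`` (Series of
        site per participant, indexed by participant_id).  For the
        metrics-calibration family: ``features`` (FeatureMatrix) and
        ``expert_labels`` (binary Series).  For the cnn family:
        ``volumes`` (N x C x D x H x W), ``amplified_labels`` (the
        calibration-ensemble scores used as training targets), and
        optionally ``expert_labels`` for the report-set decomposition.
    search_budget : int
        Hyperparameter search budget per calibration fold.

    Returns
    -------
    pandas.DataFrame
        One row per (experiment, evaluation set): columns ``model``,
        ``split``, ``eval_on``, mean and sd of accuracy, balanced
        accuracy and ROC-AUC over replicates, ``n_eval``.
    """
    site = data["site"]
    rows = []
    for experiment in plan.experiments:
        for s in experiment.train_sites + experiment.eval_sites:
            if s not in set(site):
                raise ValueError(f"site {s!r} not present in data")
        train_mask = site.isin(experiment.train_sites)
        eval_mask = site.isin(experiment.eval_sites)

        replicate_metrics: dict[str, list[dict]] = {}
        for seed in plan.seeds:
            if plan.model_family == "metrics-calibration":
                features = data["features"]
                labels = data["expert_labels"]
                _check_binary(labels[eval_mask])
                train_features = FeatureMatrix(
                    data=features.data.loc[train_mask],
                    mode=features.mode,
                    provenance=features.provenance,
                )
                ensemble = fit_calibration(
                    train_features,
                    labels.loc[train_mask],
                    search_budget=search_budget,
                    seed=seed,
                )
                scores = ensemble_predict(
                    ensemble,
                    FeatureMatrix(
                        data=features.data.loc[eval_mask],
                        mode=features.mode,
                        provenance=features.provenance,
                    ),
                )
                replicate_metrics.setdefault("test", []).append(
                    _eval_scores(labels.loc[eval_mask], scores)
                )
            else:
                from hybridqc.deep_qc import (
                    QCNetworkSpec,
                    build_qc_cnn,
                    train_qc_cnn,
                )

                volumes = data["volumes"]
                amplified = np.asarray(data["amplified_labels"], dtype=float)
                kwargs = dict(max_epochs=5, batch_size=8)
                kwargs.update(cnn_train_kwargs or {})
                spec = QCNetworkSpec(
                    with_metrics=False,
                    n_imaging_channels=volumes.shape[1],
                    input_shape=tuple(volumes.shape[2:]),
                )
                model = build_qc_cnn(spec, seed=seed)
                tmask = train_mask.to_numpy()
                emask = eval_mask.to_numpy()
                train_qc_cnn(
                    model, volumes[tmask], amplified[tmask], seed=seed, **kwargs
                )
                scores = model.predict_proba(volumes[emask])
                eval_sets = {"test": (amplified[emask] >= 0.5).astype(int)}
                if "expert_labels" in data and data["expert_labels"] is not None:
                    expert = data["expert_labels"]
                    has_expert = expert.notna() & eval_mask
                    if has_expert.any():
                        report_scores = model.predict_proba(
                            volumes[has_expert.to_numpy()]
                        )
                        replicate_metrics.setdefault("report", []).append(
                            _eval_scores(
                                expert[has_expert].astype(int), report_scores
                            )
                        )
                replicate_metrics.setdefault("test", []).append(
                    _eval_scores(eval_sets["test"], scores)
                )

        for eval_on, entries in replicate_metrics.items():
            frame = pd.DataFrame(entries)
            row = {
                "model": plan.model_family,
                "split": experiment.name,
                "eval_on": eval_on,
                "n_eval": int(eval_mask.sum()),
            }
            for metric in ("accuracy", "balanced_accuracy", "roc_auc"):
                row[f"{metric}_mean"] = float(frame[metric].mean())
                row[f"{metric}_sd"] = (
                    float(frame[metric].std(ddof=1)) if len(frame) > 1 else 0.0
                )
            rows.append(row)
    return pd.DataFrame(rows)
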