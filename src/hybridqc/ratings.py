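"""Expert-rating aggregation and inter-rater reliability.

Experts rate each scan on a 5-level ordinal scale: -2 (definitely
fail), -1 (probably fail), 0 (not sure), 1 (probably pass), 2
(definitely pass).  The released QC score is the mean rating rescaled
to [0, 1]; 0.2-wide bands recover the verbal categories, and 0.5 is
the pass threshold.

Reliability is quantified two ways: pairwise Cohen's kappa with
quadratic weights (each pair of coders), and the two-way mixed,
consistency intraclass correlations ICC3 (single coder) and ICC3k
(mean of k coders).  A calibration model's [0, 1] scores can be
entered as an additional coder.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from hybridqc.synthetic import RATING_LEVELS

__all__ = [
    "CATEGORIES",
    "aggregate_expert",
    "cohen_kappa_quadratic",
    "pairwise_kappa_matrix",
    "icc",
    "model_as_coder",
    "discretize_scores",
]

#: Verbal categories of the rating scale, by 0.2-wide bands of the
#: scaled [0, 1] score (left-inclusive; 1.0 belongs to the last band).
CATEGORIES = [
    "definitely fail",
    "probably fail",
    "not sure",
    "probably pass",
    "definitely pass",
]


def score_category(scaled: float) -> str:
    """Map a scaled [0, 1] score to its verbal category."""
    idx = min(int(scaled / 0.2), 4)
    return CATEGORIES[idx]


def aggregate_expert(ratings: pd.DataFrame) -> pd.DataFrame:
    """Aggregate an experts-wide rating table to released QC scores.

    Parameters
    ----------
    ratings : pandas.DataFrame
        Participants x raters, entries in {-2, ..., 2} or NaN.

    Returns
    -------
    pandas.DataFrame
        Indexed like ``ratings`` with columns ``mean_raw`` (mean over
        non-missing raters, in [-2, 2]), ``scaled``
        (= (mean_raw + 2) / 4), ``binary`` (1 iff scaled >= 0.5) and
        ``category``.  Participants with zero ratings keep a row with
        all fields missing rather than being dropped.
    """
    values = ratings.to_numpy(dtype=float)
    bad = ~(np.isnan(values) | np.isin(values, RATING_LEVELS))
    if bad.any():
        raise ValueError("ratings must be in {-2, -1, 0, 1, 2} or missing")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        mean_raw = np.nanmean(values, axis=1)
    scaled = (mean_raw + 2.0) / 4.0
    binary = np.where(np.isnan(scaled), np.nan, (scaled >= 0.5).astype(float))
    category = [
        None if np.isnan(s) else score_category(s) for s in scaled
    ]
    return pd.DataFrame(
        {
            "mean_raw": mean_raw,
            "scaled": scaled,
            "binary": binary,
            "category": category,
        },
        index=ratings.index,
    )


def cohen_kappa_quadratic(r1, r2, levels=RATING_LEVELS) -> float:
    """Quadratic-weighted Cohen's kappa between two coders.

    Pairs where either coder is missing are dropped first.  Weights use
    the full fixed scale (``levels``) even if some levels are
    unobserved in the sample: the scale belongs to the instrument, not
    to the sample.

    Returns NaN (with a warning) when chance disagreement is zero,
    i.e. both coders are constant and identical -- kappa is undefined
    there.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if r1.shape != r2.shape:
        raise ValueError("rating vectors must have equal length")
    keep = ~(np.isnan(r1) | np.isnan(r2))
    r1, r2 = r1[keep], r2[keep]
    if r1.size < 2:
        raise ValueError("need >= 2 pairwise-complete ratings")

    if np.unique(np.concatenate([r1, r2])).size == 1:
        warnings.warn(
            "kappa undefined: both coders constant and identical",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return float(
        cohen_kappa_score(r1, r2, labels=list(levels), weights="quadratic")
    )


def discretize_scores(scores, levels=RATING_LEVELS) -> np.ndarray:
    """Place continuous [0, 1] scores onto the ordinal rating scale.

    Uses the same 0.2-wide bands that define the verbal categories, so
    a model's probabilities can sit in a kappa matrix next to experts.
    """
    scores = np.asarray(scores, dtype=float)
    if np.nanmin(scores) < 0 or np.nanmax(scores) > 1:
        raise ValueError("scores must lie in [0, 1]")
    idx = np.minimum((scores / 0.2).astype(int), 4)
    return np.asarray(levels)[idx].astype(float)


def pairwise_kappa_matrix(
    ratings: pd.DataFrame,
    extra_coders: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Symmetric matrix of pairwise quadratic-weighted kappas.

    Parameters
    ----------
    ratings : pandas.DataFrame
        Participants x raters on the ordinal scale.
    extra_coders : dict, optional
        Name -> [0, 1] score vector aligned to ``ratings``; scores are
        discretized to the rating scale before comparison.

    Undefined cells (constant identical coders) propagate as NaN.
    """
    columns = {c: ratings[c].to_numpy(dtype=float) for c in ratings.columns}
    if extra_coders:
        for name, scores in extra_coders.items():
            if len(scores) != len(ratings):
                raise ValueError(f"extra coder {name!r} misaligned")
            columns[name] = discretize_scores(scores)
    names = list(columns)
    if len(names) < 2:
        raise ValueError("need >= 2 coders")

    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                k = cohen_kappa_quadratic(columns[a], columns[b])
                out.loc[a, b] = out.loc[b, a] = k
    return out


def icc(
    ratings: pd.DataFrame,
    variant: str = "ICC3k",
    ci_level: float = 0.95,
) -> dict:
    """Two-way mixed, consistency intraclass correlation.

    ICC3 = (MS_R - MS_E) / (MS_R + (k - 1) MS_E) judges a single
    coder; ICC3k = (MS_R - MS_E) / MS_R judges the mean of the k fixed
    coders.  MS_R is the between-participant and MS_E the residual mean
    square of the two-way ANOVA.  Confidence intervals are the
    Shrout-Fleiss F-distribution bounds.

    Parameters
    ----------
    ratings : pandas.DataFrame
        Participants x coders; rows with any missing entry are dropped
        (listwise-complete).
    variant : {"ICC3", "ICC3k"}

    Returns
    -------
    dict
        ``estimate``, ``ci`` (tuple), ``df1``, ``df2``, ``pval``,
        ``n_participants``, ``n_raters``.
    """
    if variant not in ("ICC3", "ICC3k"):
        raise ValueError("variant must be 'ICC3' or 'ICC3k'")
    complete = ratings.dropna(axis=0, how="any")
    if complete.shape[1] < 2 or complete.shape[0] < 2:
        raise ValueError("need >= 2 coders and >= 2 complete participants")

    values = complete.to_numpy(dtype=float)
    degenerate = np.isclose(values.mean(axis=1).var(), 0.0)
    if degenerate:
        warnings.warn(
            "zero between-participant variance; ICC estimate degenerate",
            RuntimeWarning,
            stacklevel=2,
        )

    n, k = values.shape
    grand = values.mean()
    ms_rows = k * ((values.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    ms_cols = n * ((values.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    ss_total = ((values - grand) ** 2).sum()
    # SS decomposition: total = rows + cols + error.
    ss_error = ss_total - (n - 1) * ms_rows - (k - 1) * ms_cols
    df_error = (n - 1) * (k - 1)
    ms_error = ss_error / df_error

    if degenerate or ms_rows <= 0:
        estimate = 0.0
        f_obs = 0.0
    else:
        f_obs = ms_rows / ms_error if ms_error > 0 else np.inf
        if variant == "ICC3":
            estimate = (ms_rows - ms_error) / (ms_rows + (k - 1) * ms_error)
        else:
            estimate = (ms_rows - ms_error) / ms_rows

    # Shrout-Fleiss F-distribution confidence bounds.
    alpha = 1.0 - ci_level
    df1, df2 = n - 1, df_error
    f_crit_low = stats.f.ppf(1 - alpha / 2, df1, df2)
    f_crit_up = stats.f.ppf(1 - alpha / 2, df2, df1)
    f_low = f_obs / f_crit_low
    f_up = f_obs * f_crit_up
    with np.errstate(divide="ignore", invalid="ignore"):
        if variant == "ICC3":
            ci = ((f_low - 1) / (f_low + k - 1), (f_up - 1) / (f_up + k - 1))
        else:
            ci = (
                1 - 1 / f_low if f_low > 0 else -np.inf,
                1 - 1 / f_up if f_up > 0 else -np.inf,
            )
    ci = tuple(c if np.isfinite(c) else -np.inf for c in ci)
    pval = float(stats.f.sf(f_obs, df1, df2)) if np.isfinite(f_obs) else 0.0
    return {
        "estimate": float(estimate),
        "ci": (float(ci[0]), float(ci[1])),
        "df1": df1,
        "df2": df2,
        "pval": pval,
        "n_participants": n,
        "n_raters": k,
    }


def model_as_coder(
    probabilities: pd.Series | np.ndarray,
    experts: pd.DataFrame,
    model_name: str = "model",
) -> pd.DataFrame:
    """Append a model's [0, 1] scores to scaled expert ratings.

    Expert ratings are rescaled to [0, 1] via (r + 2) / 4 so every
    column shares the model's scale; the result feeds directly into
    ``icc(..., "ICC3")``, treating the model as one more coder whose
    reliability should generalize to participants it rates alone.
    Model scores stay continuous (no re-discretization).
    """
    if isinstance(probabilities, pd.Series):
        if not probabilities.index.equals(experts.index):
            missing = probabilities.index.symmetric_difference(experts.index)
            raise ValueError(
                f"participant sets misaligned ({len(missing)} mismatched ids)"
            )
        probs = probabilities.to_numpy(dtype=float)
    else:
        probs = np.asarray(probabilities, dtype=float)
        if probs.shape[0] != len(experts):
            raise ValueError("probabilities misaligned with expert table")
    if np.nanmin(probs) < 0 or np.nanmax(probs) > 1:
        raise ValueError("probabilities must lie in [0, 1]")

    scaled = (experts.astype(float) + 2.0) / 4.0
    out = scaled.copy()
    out[model_name] = probs
    return out
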