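"""Integrated-gradients attribution for the deep QC model.

Integrated gradients attribute the model's pass probability to input
voxels by accumulating input gradients along the straight path from a
baseline image (all-zeros, "black") to the input:

    IG_i(x) = (x_i - b_i) * (1/m) * sum_k dF/dx_i |_{b + a_k (x - b)}

with interpolation coefficients a_k evaluated at midpoints
(k - 1/2)/m, which roughly halves the completeness-axiom gap relative
to an endpoint Riemann rule at equal step count.  Positive attribution
is evidence toward passing QC, negative toward failing.  The
completeness gap |sum IG - (F(x) - F(b))| is recorded alongside each
map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hybridqc.deep_qc import QCModel

__all__ = [
    "AttributionMap",
    "integrated_gradients",
    "confusion_examples",
    "display_mask",
]


@dataclass
class AttributionMap:
    """Signed per-voxel attribution with its bookkeeping.

    ``values`` matches the model-input shape (channels first);
    ``metric_values`` holds the attribution of the metrics vector for
    metrics-augmented models.  Positive = evidence for passing.
    """

    values: np.ndarray
    metric_values: np.ndarray | None
    m_steps: int
    baseline: str
    output_at_input: float
    output_at_baseline: float
    completeness_gap: float


def integrated_gradients(
    model: QCModel,
    x: np.ndarray,
    metrics: np.ndarray | None = None,
    baseline: np.ndarray | None = None,
    baseline_metrics: np.ndarray | None = None,
    m_steps: int = 128,
    batch_size: int = 16,
) -> AttributionMap:
    """Integrated-gradients attribution of the sigmoid QC output.

    Parameters
    ----------
    model : QCModel
    x : ndarray
        One input volume, shape (channels, D, H, W).
    metrics : ndarray, optional
        Metrics vector (n_metrics,) for metrics-augmented models; the
        black baseline zeroes this channel too.
    baseline : ndarray, optional
        Defaults to all-zeros of the same shape as ``x``.
    m_steps : int
        Number of midpoint Riemann steps.
    """
    x = np.asarray(x, dtype=np.float32)
    if baseline is None:
        baseline = np.zeros_like(x)
    if baseline.shape != x.shape:
        raise ValueError("baseline must have the same shape as x")
    with_metrics = model.spec.with_metrics
    if with_metrics:
        if metrics is None:
            raise ValueError("metrics-augmented model needs a metrics vector")
        metrics = np.asarray(metrics, dtype=np.float32)
        if baseline_metrics is None:
            baseline_metrics = np.zeros_like(metrics)

    alphas = (np.arange(1, m_steps + 1) - 0.5) / m_steps
    grad_sum = np.zeros_like(x, dtype=np.float64)
    mgrad_sum = (
        np.zeros_like(metrics, dtype=np.float64) if with_metrics else None
    )
    for start in range(0, m_steps, batch_size):
        a = alphas[start : start + batch_size]
        interp = baseline[None] + a[:, None, None, None, None] * (x - baseline)[None]
        m_interp = None
        if with_metrics:
            m_interp = baseline_metrics[None] + a[:, None] * (
                metrics - baseline_metrics
            )[None]
        try:
            g, gm = model.input_gradient(interp, m_interp)
        except FloatingPointError as err:
            raise FloatingPointError(
                f"non-finite gradient in interpolation steps {start}.."
                f"{start + len(a) - 1}"
            ) from err
        grad_sum += g.sum(axis=0)
        if with_metrics:
            mgrad_sum += gm.sum(axis=0)

    attr = (x - baseline) * (grad_sum / m_steps)
    metric_attr = None
    if with_metrics:
        metric_attr = (metrics - baseline_metrics) * (mgrad_sum / m_steps)

    f_x = float(model.predict_proba(x[None], metrics[None] if with_metrics else None)[0])
    f_b = float(
        model.predict_proba(
            baseline[None], baseline_metrics[None] if with_metrics else None
        )[0]
    )
    total = attr.sum() + (metric_attr.sum() if metric_attr is not None else 0.0)
    gap = float(abs(total - (f_x - f_b)))
    return AttributionMap(
        values=attr.astype(np.float64),
        metric_values=metric_attr,
        m_steps=m_steps,
        baseline="zeros" if not np.any(baseline) else "custom",
        output_at_input=f_x,
        output_at_baseline=f_b,
        completeness_gap=gap,
    )


def confusion_examples(
    scores: pd.Series,
    labels: pd.Series | np.ndarray,
    threshold: float = 0.5,
) -> dict[str, str | None]:
    """One deterministic exemplar participant per confusion class.

    Picks the highest-confidence member of each class (score farthest
    from the threshold), breaking ties by participant id.  Empty
    classes map to None rather than being fabricated.
    """
    scores = pd.Series(scores)
    labels = pd.Series(np.asarray(labels), index=scores.index)
    if labels.nunique() < 2:
        raise ValueError("both classes must be present in labels")
    predicted = (scores >= threshold).astype(int)

    classes = {
        "TP": (labels == 1) & (predicted == 1),
        "TN": (labels == 0) & (predicted == 0),
        "FP": (labels == 0) & (predicted == 1),
        "FN": (labels == 1) & (predicted == 0),
    }
    out: dict[str, str | None] = {}
    for name, mask in classes.items():
        members = scores[mask]
        if members.empty:
            out[name] = None
            continue
        confidence = (members - threshold).abs()
        best = confidence.max()
        out[name] = sorted(confidence[confidence == best].index)[0]
    return out


def display_mask(
    attr: AttributionMap | np.ndarray,
    keep_fraction_threshold: float = 0.98,
) -> np.ndarray:
    """Mask of voxels whose |attribution| exceeds the display threshold.

    True where |a| > keep_fraction_threshold * max |a| over the map --
    the convention used to render weak attributions transparent.  An
    all-zero map yields an empty mask.
    """
    values = attr.values if isinstance(attr, AttributionMap) else np.asarray(attr)
    if not np.all(np.isfinite(values)):
        raise ValueError("attribution map must be finite")
    peak = np.abs(values).max()
    if peak == 0:
        return np.zeros_like(values, dtype=bool)
    return np.abs(values) > keep_fraction_threshold * peak
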