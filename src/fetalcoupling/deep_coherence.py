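"""Grad-CAM attention over the trained CNN: the "deep coherence" signal.

Grad-CAM weights each channel of the final convolutional activation by the
spatial mean of the gradient of the target class's pre-softmax score with
respect to that activation, sums the weighted channels, rectifies, and
normalizes by the maximum.  Because the classifier head is linear in the
final (post-ReLU) activation, that gradient is exactly the corresponding
row of the head weights reshaped onto the (channel, time) grid -- the
finite-difference oracle in the tests confirms this.

The per-minute "deep coherence" scalar of a record is the mean of each
segment's attention map after rescaling all maps in the record by the
record-wide maximum raw (pre-normalization) value, which makes minutes
mutually comparable.  Attribution targets the predicted class by default
(ground-truth-class attribution is available via the ``target_class``
argument of :func:`gradcam`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from fetalcoupling.beat_series import EncodedSegment, SegmentPair
from fetalcoupling.coupling_label import CouplingRatio
from fetalcoupling.deepmodel import CLASS_ORDER, CouplingClassifier, Prediction

__all__ = [
    "AttentionMap",
    "DeepCoherenceSeries",
    "gradcam",
    "deep_coherence_series",
    "rmse",
    "heatmap_export",
]


@dataclass(frozen=True)
class AttentionMap:
    """Grad-CAM attention over the input sample grid of one segment."""

    values: np.ndarray  # length L, in [0, 1]
    target_class: CouplingRatio
    raw_max: float  # pre-normalization maximum (for cross-segment scaling)
    segment_ref: tuple | None = None


@dataclass(frozen=True)
class DeepCoherenceSeries:
    """Per-minute coupling-strength scalars across a record's segments."""

    values: np.ndarray  # in [0, 1]
    normalization: str = "record_max"


def gradcam(
    model: CouplingClassifier, seg: EncodedSegment, target_class: CouplingRatio
) -> AttentionMap:
    """Grad-CAM attention map of one encoded segment for a target class.

    Channel weights ``alpha_c`` are the spatial means of
    ``d score(target) / d A_c`` at the final conv activation A; the map is
    ``relu(sum_c alpha_c A_c)`` normalized by its maximum (all zeros when
    the maximum is 0, so degenerate models yield zero maps, never NaN).
    """
    if not model.trained:
        raise RuntimeError("Grad-CAM requires a trained model")
    if target_class not in CLASS_ORDER:
        raise ValueError(f"target_class must be one of {[str(c) for c in CLASS_ORDER]}")
    c = CLASS_ORDER.index(target_class)
    x = seg.grid[None].astype(model.config.dtype)
    A = model.conv_activation(x, training=False)[0]  # (f2, L)
    f2, L = A.shape
    # head is linear in A: d score_c / d A = head weight column c on the grid
    grad = model.head.params["w"][:, c].reshape(f2, L)
    alpha = grad.mean(axis=1)  # (f2,)
    cam = np.maximum((alpha[:, None] * A).sum(axis=0), 0.0).astype(np.float64)
    raw_max = float(cam.max())
    values = cam / raw_max if raw_max > 0 else np.zeros_like(cam)
    ref = None
    if seg.segment is not None:
        ref = (seg.segment.subject_id, seg.segment.segment_index)
    return AttentionMap(values=values, target_class=target_class, raw_max=raw_max, segment_ref=ref)


def gradcam_alpha(model: CouplingClassifier, seg: EncodedSegment, target_class: CouplingRatio) -> np.ndarray:
    """The Grad-CAM channel weights alpha_c alone (oracle-testable)."""
    c = CLASS_ORDER.index(target_class)
    f2 = model.config.filters[1]
    return model.head.params["w"][:, c].reshape(f2, model.config.L).mean(axis=1)


def deep_coherence_series(
    model: CouplingClassifier,
    segments: list[EncodedSegment],
    predictions: list[Prediction],
) -> DeepCoherenceSeries:
    """Per-minute deep-coherence scalars for an ordered record.

    Runs Grad-CAM for each segment's *predicted* class, rescales every map
    by the record-wide maximum raw value, and takes each rescaled map's
    mean as that minute's coupling strength (in [0, 1]).
    """
    if len(segments) != len(predictions):
        raise ValueError("need one prediction per segment")
    if not segments:
        return DeepCoherenceSeries(values=np.empty(0))
    maps = [gradcam(model, seg, pred.predicted) for seg, pred in zip(segments, predictions)]
    record_max = max(m.raw_max for m in maps)
    if record_max == 0:
        return DeepCoherenceSeries(values=np.zeros(len(maps)))
    scalars = np.array([m.values.mean() * (m.raw_max / record_max) for m in maps])
    return DeepCoherenceSeries(values=scalars)


def rmse(series_a: np.ndarray, series_b: np.ndarray) -> float:
    """Root mean square error between two equal-length series."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.size < 1:
        raise ValueError(f"series must have equal nonzero length, got {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def attention_spread(amap: AttentionMap, threshold: float = 0.5) -> float:
    """Fraction of samples with attention above threshold (heatmap width)."""
    return float((amap.values > threshold).mean())


def heatmap_export(
    amap: AttentionMap, seg: SegmentPair, out_path: str | os.PathLike
) -> str:
    """Write the attention heatmap figure (+ raw map CSV alongside).

    The attention is drawn as a color strip over the segment's time axis
    with maternal/fetal R-peak rasters as tick marks (this artifact holds
    beat times, not waveforms).  The raw map goes to ``<out>.csv``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_path = os.fspath(out_path)
    L = amap.values.size
    t0, t1 = seg.window_start, seg.window_start + seg.window_length
    fig, ax = plt.subplots(figsize=(10, 2.2))
    ax.imshow(
        amap.values[None, :],
        aspect="auto",
        cmap="jet",
        vmin=0.0,
        vmax=1.0,
        extent=(t0, t1, -0.1, 1.1),
    )
    for t in seg.maternal.times:
        ax.plot([t, t], [0.55, 1.05], color="black", lw=0.8)
    for t in seg.fetal.times:
        ax.plot([t, t], [-0.05, 0.45], color="white", lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_yticks([0.2, 0.8], ["fetal", "maternal"])
    ax.set_title(f"Grad-CAM attention, target [{amap.target_class}]")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    csv_path = out_path + ".csv"
    pd.DataFrame(
        {"sample_index": np.arange(L), "attention": amap.values}
    ).to_csv(csv_path, index=False)
    return csv_path
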