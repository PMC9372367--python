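"""Phase-occurrence counting and ground-truth coupling-ratio labeling.

The prevalence of a candidate coupling ratio m:n in a segment is measured
by sliding a window of m consecutive maternal beats (``[R_i, R_{i+m})``,
advancing one maternal beat at a time) over the segment and counting the
fetal beats inside each window.  The prevalence of ratio (m, n) is the
percentage of m-beat windows containing exactly n fetal beats, normalized
within the window class m -- prevalences of different ratios therefore need
not sum to 100.  The ground-truth label of a segment is the supported ratio
([1:2], [2:3] or [3:5]) with the highest prevalence.
"""

from __future__ import annotations

import os
import warnings
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from fetalcoupling.beat_series import SegmentPair

__all__ = [
    "CouplingRatio",
    "CouplingAssessment",
    "OTHER",
    "SUPPORTED_RATIOS",
    "count_fetal_per_window",
    "prevalence",
    "assign_label",
    "filter_supported",
    "write_labels_csv",
]


@dataclass(frozen=True, order=True)
class CouplingRatio:
    """m maternal beats coupled to n fetal beats per cycle group."""

    m: int
    n: int

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValueError(f"ratio components must be >= 1, got {self.m}:{self.n}")

    def __str__(self) -> str:
        return f"{self.m}:{self.n}"


#: The three coupling scenarios used as classification labels.
SUPPORTED_RATIOS = (CouplingRatio(1, 2), CouplingRatio(2, 3), CouplingRatio(3, 5))

#: Sentinel label for segments where no supported ratio occurs.
OTHER = None


@dataclass(frozen=True)
class CouplingAssessment:
    """Prevalence percentages per candidate ratio and the assigned label."""

    prevalence: dict  # CouplingRatio -> percentage in [0, 100]
    window_counts: dict  # m -> Counter of fetal-beat counts per window
    label: CouplingRatio | None = OTHER
    margin: float | None = None  # percentage-point gap between top two


class CountingError(ValueError):
    """Too few maternal beats for the requested window class."""


def count_fetal_per_window(seg: SegmentPair, m: int) -> tuple[Counter, int]:
    """Histogram of fetal-beat counts over all m-maternal-beat windows.

    Windows are ``[R_i, R_{i+m})`` for ``i = 0 .. n_maternal - m - 1``
    (advancing by one maternal beat; overlapping for m > 1).  A fetal beat
    coincident with the closing maternal beat belongs to the next window.

    Returns
    -------
    (histogram, n_windows)
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    mat = seg.maternal.times
    if len(mat) < m + 1:
        raise CountingError(
            f"{seg.subject_id} segment {seg.segment_index}: need >= {m + 1} maternal "
            f"beats for m={m} windows, have {len(mat)}"
        )
    fet = seg.fetal.times
    # cumulative fetal count strictly before each maternal beat
    pos = np.searchsorted(fet, mat, side="left")
    counts = pos[m:] - pos[:-m]
    return Counter(counts.tolist()), int(counts.size)


def prevalence(seg: SegmentPair) -> CouplingAssessment:
    """Prevalence (%) of each observed coupling ratio in a segment.

    For ratio (m, n): ``100 * #(m-beat windows with exactly n fetal beats)
    / #(m-beat windows)``.  Computed for the three supported ratios and for
    every other observed (m, count) pair with m in {1, 2, 3}.  The label is
    left unset; use :func:`assign_label`.
    """
    prev: dict[CouplingRatio, float] = {}
    window_counts: dict[int, Counter] = {}
    for m in (1, 2, 3):
        hist, n_windows = count_fetal_per_window(seg, m)
        window_counts[m] = hist
        for n_fetal, occ in hist.items():
            if n_fetal >= 1:
                prev[CouplingRatio(m, n_fetal)] = 100.0 * occ / n_windows
    for ratio in SUPPORTED_RATIOS:
        prev.setdefault(ratio, 0.0)
    return CouplingAssessment(prevalence=prev, window_counts=window_counts)


def assign_label(assessment: CouplingAssessment) -> CouplingAssessment:
    """Assign the ground-truth label: argmax prevalence among supported ratios.

    Ties break toward the ratio with smaller m (logged); if all three
    supported prevalences are zero the label is :data:`OTHER`.
    """
    vals = [(r, assessment.prevalence.get(r, 0.0)) for r in SUPPORTED_RATIOS]
    ranked = sorted(vals, key=lambda rv: (-rv[1], rv[0].m))
    (best, best_p), (_, second_p) = ranked[0], ranked[1]
    if best_p == 0.0:
        return replace(assessment, label=OTHER, margin=None)
    if best_p == second_p:
        warnings.warn(
            f"prevalence tie at {best_p:.1f}% broken toward smaller m ({best})", stacklevel=2
        )
    return replace(assessment, label=best, margin=best_p - second_p)


def label_segment(seg: SegmentPair) -> CouplingAssessment:
    """Convenience: prevalence + label in one call."""
    return assign_label(prevalence(seg))


def filter_supported(
    labeled: list[tuple[SegmentPair, CouplingAssessment]],
) -> tuple[list[tuple[SegmentPair, CouplingAssessment]], float | None]:
    """Drop segments labeled OTHER; report the retention fraction.

    Retention is None for empty input; an all-OTHER input warns.
    """
    if not labeled:
        return [], None
    kept = [(s, a) for s, a in labeled if a.label is not OTHER]
    if not kept:
        warnings.warn("all segments labeled OTHER; nothing retained", stacklevel=2)
    return kept, len(kept) / len(labeled)


def write_labels_csv(
    labeled: list[tuple[SegmentPair, CouplingAssessment]], path: str | os.PathLike
) -> pd.DataFrame:
    """Write the labels CSV (one row per segment) and return the frame."""
    rows = []
    for seg, a in labeled:
        rows.append(
            {
                "subject_id": seg.subject_id,
                "segment_index": seg.segment_index,
                "label": str(a.label) if a.label is not OTHER else "other",
                "prev_1_2": a.prevalence.get(CouplingRatio(1, 2), 0.0),
                "prev_2_3": a.prevalence.get(CouplingRatio(2, 3), 0.0),
                "prev_3_5": a.prevalence.get(CouplingRatio(3, 5), 0.0),
                "margin": a.margin,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["subject_id", "segment_index", "label", "prev_1_2", "prev_2_3", "prev_3_5", "margin"],
    )
    df.to_csv(path, index=False)
    return df
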