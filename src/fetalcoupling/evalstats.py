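"""Evaluation statistics: confusion metrics, OVR ROC, agreement, trends.

Classification performance over the three coupling classes is summarized
by the 3x3 confusion matrix (rows = truth), per-class sensitivity
(TP/truth count) and precision (TP/predicted count), overall accuracy
(trace/total), and one-vs-rest AUROC with a stratified-bootstrap 95% CI.
Agreement between two per-minute coupling signals (e.g. deep coherence vs
the phase coherence index) uses Bland-Altman analysis; coupling-vs-
gestational-age trends use ordinary least squares with Pearson R, the
two-sided t-test p-value on the slope, and a 95% mean-prediction band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

__all__ = [
    "MetricsReport",
    "AgreementReport",
    "TrendFit",
    "confusion_metrics",
    "roc_auc_ovr",
    "bland_altman",
    "trend_vs_gestation",
]


@dataclass
class MetricsReport:
    confusion: np.ndarray  # (3, 3), rows = truth
    sensitivity: np.ndarray  # per class
    precision: np.ndarray  # per class
    precision_defined: np.ndarray  # False where no predictions for the class
    accuracy: float
    auroc: np.ndarray | None = None  # per class, NaN where undefined
    auroc_ci: np.ndarray | None = None  # (3, 2) lower/upper

    def summary(self, class_names=("1:2", "2:3", "3:5")) -> str:
        lines = ["confusion (rows = truth):"]
        for name, row in zip(class_names, self.confusion):
            lines.append(f"  {name}: {row.tolist()}")
        for i, name in enumerate(class_names):
            prec = f"{100 * self.precision[i]:.1f}%" if self.precision_defined[i] else "undefined"
            auc = ""
            if self.auroc is not None and np.isfinite(self.auroc[i]):
                auc = f", AUROC {self.auroc[i]:.3f} [{self.auroc_ci[i, 0]:.3f}, {self.auroc_ci[i, 1]:.3f}]"
            lines.append(f"  [{name}] sensitivity {100 * self.sensitivity[i]:.1f}%, precision {prec}{auc}")
        lines.append(f"  overall accuracy {100 * self.accuracy:.1f}%")
        return "\n".join(lines)


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman agreement between two paired series (a - b)."""

    mean_diff: float
    sd_diff: float
    loa_lower: float  # mean - 1.96 sd
    loa_upper: float  # mean + 1.96 sd
    slope: float  # difference-vs-average OLS
    intercept: float
    n: int


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of a coupling value against gestational age (weeks)."""

    slope: float  # per week
    intercept: float
    r: float  # Pearson correlation
    p: float  # two-sided, t statistic with n-2 df
    n: int
    # 95% mean-prediction band: center x, residual SE, t critical value, Sxx
    band: tuple = field(default=())

    def band_at(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Lower/upper 95% CI of the fitted mean at gestational ages x."""
        xbar, s_err, tcrit, sxx = self.band
        x = np.asarray(x, dtype=float)
        half = tcrit * s_err * np.sqrt(1.0 / self.n + (x - xbar) ** 2 / sxx)
        yhat = self.intercept + self.slope * x
        return yhat - half, yhat + half


def confusion_metrics(truth, predicted) -> MetricsReport:
    """Confusion matrix with per-class sensitivity/precision and accuracy.

    Labels are class indices 0..2 or :class:`CouplingRatio` objects.
    Precision of a never-predicted class is reported as 0 and flagged.
    """
    t = _as_class_indices(truth)
    p = _as_class_indices(predicted)
    if t.shape != p.shape or t.size < 1:
        raise ValueError("truth and predicted must have equal nonzero length")
    cm = _sk_confusion(t, p, labels=[0, 1, 2])
    truth_counts = cm.sum(axis=1)
    pred_counts = cm.sum(axis=0)
    tp = np.diag(cm)
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(truth_counts > 0, tp / np.maximum(truth_counts, 1), 0.0)
        prec = np.where(pred_counts > 0, tp / np.maximum(pred_counts, 1), 0.0)
    return MetricsReport(
        confusion=cm,
        sensitivity=sens,
        precision=prec,
        precision_defined=pred_counts > 0,
        accuracy=float(tp.sum() / cm.sum()),
    )


def _as_class_indices(labels) -> np.ndarray:
    arr = []
    for lb in labels:
        if isinstance(lb, (int, np.integer)):
            arr.append(int(lb))
        else:  # CouplingRatio-like
            arr.append({(1, 2): 0, (2, 3): 1, (3, 5): 2}[(lb.m, lb.n)])
    return np.asarray(arr, dtype=np.int64)


def roc_auc_ovr(
    truth,
    probabilities: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """One-vs-rest AUROC per class with stratified-bootstrap 95% CI.

    AUROC uses the rank (Mann-Whitney) statistic with ties averaged; the
    CI is the 2.5/97.5 percentile interval over ``n_boot`` resamples drawn
    within the positive and negative groups separately.  A class with no
    positives or no negatives gets NaN entries.
    """
    y = _as_class_indices(truth)
    P = np.asarray(probabilities, dtype=float)
    if P.ndim != 2 or P.shape[0] != y.size or P.shape[1] != 3:
        raise ValueError(f"probabilities must be (n, 3), got {P.shape}")
    rng = np.random.default_rng(seed)
    auroc = np.full(3, np.nan)
    ci = np.full((3, 2), np.nan)
    for c in range(3):
        pos = P[y == c, c]
        neg = P[y != c, c]
        if pos.size == 0 or neg.size == 0:
            warnings.warn(f"class {c}: no positives or no negatives; AUROC absent", stacklevel=2)
            continue
        auroc[c] = roc_auc_score((y == c).astype(int), P[:, c])
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bp = pos[rng.integers(0, pos.size, pos.size)]
            bn = neg[rng.integers(0, neg.size, neg.size)]
            labels = np.concatenate([np.ones(pos.size, int), np.zeros(neg.size, int)])
            boots[b] = roc_auc_score(labels, np.concatenate([bp, bn]))
        ci[c] = np.percentile(boots, [2.5, 97.5])
    return auroc, ci


def bland_altman(series_a, series_b) -> AgreementReport:
    """Bland-Altman agreement: differences a - b vs averages (a + b)/2."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("series must have equal length >= 3")
    diff = a - b
    avg = (a + b) / 2.0
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    if np.ptp(avg) > 0:
        slope, intercept = np.polyfit(avg, diff, 1)
    else:
        slope, intercept = 0.0, mean_diff
    return AgreementReport(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_lower=mean_diff - 1.96 * sd_diff,
        loa_upper=mean_diff + 1.96 * sd_diff,
        slope=float(slope),
        intercept=float(intercept),
        n=int(a.size),
    )


def trend_vs_gestation(values, weeks) -> TrendFit:
    """OLS fit of per-segment coupling values against gestational age.

    Returns slope/intercept, Pearson R, the two-sided p-value from the
    slope t statistic (n - 2 df) and the parameters of the 95% CI band of
    the fitted mean.  Segments are treated as independent observations.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weeks, dtype=float)
    if v.shape != w.shape or v.size < 3:
        raise ValueError("values and weeks must have equal length >= 3")
    if np.ptp(w) == 0:
        raise ValueError("gestational ages are constant; trend undefined")
    fit = stats.linregress(w, v)
    n = v.size
    resid = v - (fit.intercept + fit.slope * w)
    s_err = float(np.sqrt((resid**2).sum() / (n - 2)))
    tcrit = float(stats.t.ppf(0.975, n - 2))
    sxx = float(((w - w.mean()) ** 2).sum())
    return TrendFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        n=n,
        band=(float(w.mean()), s_err, tcrit, sxx),
    )
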