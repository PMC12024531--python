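"""Diagnostic evaluation: confusion-matrix metrics, ROC/AUC, Wilson score
intervals, size-stratified model-vs-reader comparison, and brute-force
reconstruction of confusion matrices from printed summary percentages.

GIST is the positive class everywhere (``POSITIVE_LABEL``).  Metrics with a
zero denominator are reported as ``None`` — an explicit undefined marker —
never silently 0 or 1, because small size strata make this reachable.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import ConfigError, DataError

__all__ = [
    "POSITIVE_LABEL",
    "ConfusionSummary",
    "MetricSet",
    "ROCCurve",
    "StratifiedReport",
    "confusion_from_predictions",
    "metrics_from_confusion",
    "roc_auc",
    "wilson_interval",
    "stratified_compare",
    "reconstruct_confusion",
]

POSITIVE_LABEL = "GIST"
SIZE_CUTOFF_MM = 20.0


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ConfigError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Proportion metrics in [0, 1]; ``None`` marks an undefined (0/0) value.
    ``ci`` maps metric name -> Wilson (low, high) for the defined metrics."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    ppv: float | None
    npv: float | None
    f1: float | None
    ci: dict[str, tuple[float, float]] | None = None

    def as_percent_dict(self) -> dict[str, float | None]:
        return {
            k: (None if v is None else 100.0 * v)
            for k, v in [
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("accuracy", self.accuracy),
                ("ppv", self.ppv),
                ("npv", self.npv),
                ("f1", self.f1),
            ]
        }


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class StratifiedReport:
    """strata -> reader -> MetricSet; empty strata are marked None."""

    strata: dict[str, dict[str, MetricSet | None]]
    counts: dict[str, int]


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def confusion_from_predictions(truth: np.ndarray, predicted: np.ndarray) -> ConfusionSummary:
    """Both arguments are binary arrays with 1 = GIST (positive)."""
    truth = np.asarray(truth).astype(int)
    predicted = np.asarray(predicted).astype(int)
    return ConfusionSummary(
        tp=int(((truth == 1) & (predicted == 1)).sum()),
        fp=int(((truth == 0) & (predicted == 1)).sum()),
        tn=int(((truth == 0) & (predicted == 0)).sum()),
        fn=int(((truth == 1) & (predicted == 0)).sum()),
    )


def metrics_from_confusion(c: ConfusionSummary, level: float = 0.95,
                           with_ci: bool = True) -> MetricSet:
    if c.total == 0:
        raise ConfigError("cannot compute metrics of an all-zero confusion matrix")
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    acc = _ratio(c.tp + c.tn, c.total)
    ppv = _ratio(c.tp, c.tp + c.fp)
    npv = _ratio(c.tn, c.tn + c.fn)
    f1 = None
    if ppv is not None and sens is not None and (ppv + sens) > 0:
        f1 = 2 * ppv * sens / (ppv + sens)
    ci = None
    if with_ci:
        ci = {}
        for name, num, den in [
            ("sensitivity", c.tp, c.tp + c.fn),
            ("specificity", c.tn, c.tn + c.fp),
            ("accuracy", c.tp + c.tn, c.total),
            ("ppv", c.tp, c.tp + c.fp),
            ("npv", c.tn, c.tn + c.fn),
        ]:
            if den > 0:
                ci[name] = wilson_interval(num, den, level)
    return MetricSet(sensitivity=sens, specificity=spec, accuracy=acc, ppv=ppv,
                     npv=npv, f1=f1, ci=ci)


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve by threshold sweep and AUC by the trapezoidal rule.

    Tied scores are handled by the sweep itself, which is equivalent to the
    rank statistic with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(set(labels.tolist())) < 2:
        raise DataError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc)


def wilson_interval(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, clipped to [0, 1]."""
    if n <= 0:
        raise ConfigError("n must be positive")
    if not 0 <= successes <= n:
        raise ConfigError("successes must lie in [0, n]")
    from scipy.stats import norm

    z = float(norm.ppf(0.5 + level / 2.0))
    p = successes / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (float(np.clip(center - half, 0, 1)), float(np.clip(center + half, 0, 1)))


def stratified_compare(
    truth,
    lesion_sizes_mm,
    model_predictions=None,
    reader_predictions=None,
    cutoff_mm: float = SIZE_CUTOFF_MM,
) -> StratifiedReport:
    """Per-stratum (< cutoff vs >= cutoff) metrics for each prediction source.

    ``truth`` and predictions are binary arrays (1 = GIST).  Records with a
    missing lesion size are a data error listing the offending indices.
    """
    truth = np.asarray(truth).astype(int)
    sizes = np.asarray(lesion_sizes_mm, dtype=float)
    bad = np.where(~np.isfinite(sizes))[0]
    if len(bad):
        raise DataError(f"records with missing lesion size: {bad.tolist()}")
    sources = {}
    if model_predictions is not None:
        sources["model"] = np.asarray(model_predictions).astype(int)
    if reader_predictions is not None:
        sources["endoscopist"] = np.asarray(reader_predictions).astype(int)
    if not sources:
        raise DataError("at least one prediction source is required")

    strata_masks = {"lt20mm": sizes < cutoff_mm, "ge20mm": sizes >= cutoff_mm}
    strata: dict[str, dict[str, MetricSet | None]] = {}
    counts: dict[str, int] = {}
    for name, mask in strata_masks.items():
        counts[name] = int(mask.sum())
        per_reader: dict[str, MetricSet | None] = {}
        for reader, preds in sources.items():
            if counts[name] == 0:
                per_reader[reader] = None  # empty stratum, not zero-filled
            else:
                per_reader[reader] = metrics_from_confusion(
                    confusion_from_predictions(truth[mask], preds[mask])
                )
        strata[name] = per_reader
    return StratifiedReport(strata=strata, counts=counts)


def _round_half_up_percent(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(100.0 * x)).quantize(q, rounding=ROUND_HALF_UP))


def reconstruct_confusion(
    printed_percent: dict[str, float],
    n_pos: int,
    n_neg: int,
    decimals: int = 1,
) -> tuple[list[ConfusionSummary], dict]:
    """Exhaustively enumerate (tp, tn) grids consistent with printed metrics.

    ``printed_percent`` maps metric names (sensitivity, specificity, accuracy,
    ppv, npv) to the printed percentages.  A candidate matches when each of
    its recomputed metrics rounds (half-up, ``decimals`` places) to the
    printed value.  Returns every fully consistent matrix plus a mismatch
    report: for each (tp, tn) candidate that matches all but one metric, which
    metric disagreed and by how much.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ConfigError("n_pos and n_neg must be positive")
    known = {k: float(v) for k, v in printed_percent.items() if v is not None}
    consistent: list[ConfusionSummary] = []
    near_misses = []
    for tp in range(n_pos + 1):
        for tn in range(n_neg + 1):
            c = ConfusionSummary(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)
            m = metrics_from_confusion(c, with_ci=False).as_percent_dict()
            mismatches = {}
            for name, target in known.items():
                got = m.get(name)
                if got is None or _round_half_up_percent(got / 100.0, decimals) != target:
                    mismatches[name] = None if got is None else round(got, 3)
            if not mismatches:
                consistent.append(c)
            elif len(mismatches) == 1:
                near_misses.append({"tp": tp, "tn": tn, "mismatch": mismatches})
    report = {
        "n_consistent": len(consistent),
        "near_misses": near_misses,
        "metrics_checked": sorted(known),
    }
    return consistent, report
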