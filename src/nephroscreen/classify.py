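"""Binary nephrotoxicity calls, confusion matrices and cell-source ranking.

An in vitro determination is positive when the EC50 POD is strictly below
the 300 µM classification threshold; a censored POD (no EC50 within the
tested range) is negative.  In vivo, high- and intermediate-risk compounds
are positives and low-risk compounds negatives; Gentamicin and Streptomycin
are excluded from scoring.  Per-cell-source confusion matrices yield
sensitivity, specificity, accuracy and the Matthews correlation coefficient

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

which is the ranking statistic: it summarises all four cells and is robust
to the 8:2 class imbalance of the panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

from ._censored import CensoredValue, as_censored
from .datasets import EXCLUDED_DRUGS

__all__ = [
    "ConfusionMatrix",
    "PerformanceMetrics",
    "classify_in_vitro",
    "build_confusion_matrix",
    "compute_metrics",
    "rank_cell_sources",
    "percent",
]

#: In vitro positivity threshold on the EC50 POD, µM (strict less-than).
CLASSIFICATION_THRESHOLD_UM = 300.0


def classify_in_vitro(
    ec50_pod: float | CensoredValue,
    threshold: float = CLASSIFICATION_THRESHOLD_UM,
) -> str:
    """'positive' when the EC50 POD is strictly below the threshold.

    Censored PODs (EC50 not reached within the tested range) are negative,
    as is an EC50 exactly at the threshold.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    pod = as_censored(ec50_pod)
    if pod.censored:
        return "negative"
    return "positive" if pod.value < threshold else "negative"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def positives(self) -> int:
        """Number of in vivo positives scored."""
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        """Number of in vivo negatives scored."""
        return self.fp + self.tn


def _as_label(label: str) -> str:
    if label in ("positive", "negative"):
        return label
    if label in ("High", "Intermediate"):
        return "positive"
    if label == "Low":
        return "negative"
    raise ValueError(f"unrecognised in vivo label {label!r}")


def build_confusion_matrix(
    calls: Mapping[str, str],
    labels: Mapping[str, str],
    exclusions: Iterable[str] = EXCLUDED_DRUGS,
) -> ConfusionMatrix:
    """Tally per-drug in vitro calls against in vivo labels.

    ``labels`` accepts either 'positive'/'negative' or the risk classes
    High/Intermediate (→ positive) and Low (→ negative).  Excluded drugs
    contribute to no cell; every non-excluded called drug must have a label.
    """
    excl = set(exclusions)
    tp = fn = fp = tn = 0
    for drug, call in calls.items():
        if drug in excl:
            continue
        if drug not in labels:
            raise KeyError(f"drug {drug!r} has an in vitro call but no in vivo label")
        if call not in ("positive", "negative"):
            raise ValueError(f"invalid in vitro call {call!r} for {drug!r}")
        label = _as_label(labels[drug])
        if label == "positive":
            tp += call == "positive"
            fn += call == "negative"
        else:
            fp += call == "positive"
            tn += call == "negative"
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def percent(fraction: float) -> int:
    """Round a fraction to an integer percent, halves up (0.625 → 63)."""
    return int(Decimal(fraction * 100).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PerformanceMetrics:
    """Sensitivity, specificity, accuracy and MCC for one cell source.

    A rate whose denominator is zero (e.g. sensitivity with no positives
    scored) is NaN — undefined, deliberately not coerced to 0.  MCC with a
    zero marginal is defined as 0 by convention.
    """

    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float

    def display_percent(self, metric: str) -> int:
        """Integer percent (half-up rounding) for a rate metric."""
        value = getattr(self, metric)
        if math.isnan(value):
            raise ValueError(f"{metric} is undefined for this matrix")
        return percent(value)


def compute_metrics(cm: ConfusionMatrix) -> PerformanceMetrics:
    """Derive the four ranking statistics from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    sens = cm.tp / cm.positives if cm.positives else math.nan
    spec = cm.tn / cm.negatives if cm.negatives else math.nan
    acc = (cm.tp + cm.tn) / cm.total
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    mcc = 0.0 if denom == 0 else (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)
    return PerformanceMetrics(sensitivity=sens, specificity=spec, accuracy=acc, mcc=mcc)


def rank_cell_sources(
    metrics: Mapping[str, PerformanceMetrics],
) -> list[tuple[str, PerformanceMetrics]]:
    """Order cell sources by predictive power.

    Descending MCC; ties broken by accuracy, then sensitivity (NaN sorts
    last), then cell-source name for a stable, reproducible order.
    """
    if not metrics:
        raise ValueError("no cell sources to rank")

    def key(item: tuple[str, PerformanceMetrics]):
        name, m = item
        sens = -math.inf if math.isnan(m.sensitivity) else m.sensitivity
        return (-m.mcc, -m.accuracy, -sens, name)

    return sorted(metrics.items(), key=key)
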