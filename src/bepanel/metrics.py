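"""Confusion-count bookkeeping and the binary-classification metric suite.

Every downstream stage of the pipeline — per-gene thresholding, the
exhaustive classifier search, repeated-run stability summaries and the
ablation curves — reports its performance through the nine metrics defined
here: accuracy, precision (PPV), recall (sensitivity), specificity, NPV,
FPR, F1, Matthews correlation coefficient (MCC) and Cohen's kappa.

Counts are real-valued, not integers: averaging confusion matrices over
repeated runs produces fractional mean counts, and the metric suite is well
defined on them (every metric is a ratio of count sums, invariant under
positive scaling).  Undefined ratios (zero denominators) are reported as
``nan`` rather than silently coerced to 0; the single conventional
exception is the MCC, which is set to 0 when its denominator vanishes and
flagged via :attr:`MetricSuite.mcc_degenerate`.

The positive class is always the disease / progression class (low-grade
dysplasia in the diagnostic setting, progressed Barrett's esophagus in the
prognostic setting), so recall tracks detection of the lesions that matter
clinically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

from .exceptions import DataError

#: Canonical metric order used by every report writer.
METRIC_NAMES = (
    "accuracy",
    "precision",
    "recall",
    "specificity",
    "npv",
    "fpr",
    "f1",
    "mcc",
    "kappa",
)


@dataclass(frozen=True)
class ConfusionCounts:
    """Aggregated binary-classification outcomes.

    Fields may be fractional: the mean confusion matrix over repeated
    cross-validation runs is a valid input to :func:`compute_metrics`.
    """

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise DataError(
                    f"confusion count {f.name}={v!r} must be finite and >= 0"
                )

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )

    def scaled(self, c: float) -> "ConfusionCounts":
        if c <= 0:
            raise DataError("scale factor must be positive")
        return ConfusionCounts(self.tp * c, self.fp * c, self.tn * c, self.fn * c)


@dataclass(frozen=True)
class MetricSuite:
    """The nine performance metrics derived from one confusion matrix.

    Ratio metrics live in [0, 1]; ``mcc`` and ``kappa`` in [-1, 1].
    ``nan`` marks a ratio whose denominator was zero. ``mcc_degenerate``
    is True when the MCC denominator was zero and the conventional value
    0.0 was substituted.
    """

    accuracy: float
    precision: float
    recall: float
    specificity: float
    npv: float
    fpr: float
    f1: float
    mcc: float
    kappa: float
    mcc_degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def __getitem__(self, name: str) -> float:
        if name not in METRIC_NAMES:
            raise KeyError(name)
        return getattr(self, name)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def compute_metrics(cc: ConfusionCounts) -> MetricSuite:
    """Derive the full metric suite from a confusion matrix.

    Parameters
    ----------
    cc
        Confusion counts with ``cc.total > 0``. Fractional (mean) counts
        are accepted.

    Returns
    -------
    MetricSuite
        All nine metrics at full floating-point precision. Report writers
        round half-even to 3 decimals; internal consumers never round.

    Raises
    ------
    DataError
        If all four counts are zero ("empty confusion matrix").
    """
    tp, fp, tn, fn = cc.tp, cc.fp, cc.tn, cc.fn
    n = cc.total
    if n <= 0:
        raise DataError("empty confusion matrix")

    accuracy = (tp + tn) / n
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    npv = _ratio(tn, tn + fn)
    fpr = _ratio(fp, fp + tn)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn)

    mcc_den_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc_degenerate = mcc_den_sq == 0
    mcc = 0.0 if mcc_degenerate else (tp * tn - fp * fn) / math.sqrt(mcc_den_sq)

    p_o = accuracy
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = math.nan if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)

    return MetricSuite(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        specificity=specificity,
        npv=npv,
        fpr=fpr,
        f1=f1,
        mcc=mcc,
        kappa=kappa,
        mcc_degenerate=mcc_degenerate,
    )


def round3(x: float) -> float:
    """Half-even rounding to 3 decimals, used only for report output."""
    return x if math.isnan(x) else round(x, 3)
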