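"""Seven performance measures for imbalanced binary prediction.

Sensitivity, specificity, precision and accuracy are the usual percentage
measures on the confusion counts.  Net prediction NP is the arithmetic mean
of sensitivity and specificity, and the F-measure used here is their
harmonic mean, Fm = 2*Sn*Sp/(Sn+Sp) — both are robust to the heavy class
imbalance of binding-site data, where accuracy alone is misleading.  The
correlation coefficient is the Matthews correlation.  Undefined measures
(zero denominators) are reported as None, never as division faults.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_DOWN, ROUND_HALF_EVEN, Decimal

__all__ = [
    "ConfusionCounts", "MetricsReport", "confusion", "report",
    "net_prediction", "f_measure", "round1",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricsReport:
    sn: float | None   # sensitivity, %
    sp: float | None   # specificity, %
    pr: float | None   # precision, %
    ac: float | None   # accuracy, %
    np: float | None   # net prediction, %
    fm: float | None   # F-measure (harmonic mean of Sn and Sp), %
    cc: float | None   # Matthews correlation, in [-1, 1]

    def to_dict(self, decimals: int | None = None) -> dict:
        d = {"Sn": self.sn, "Sp": self.sp, "Pr": self.pr, "Ac": self.ac,
             "NP": self.np, "Fm": self.fm, "CC": self.cc}
        if decimals is not None:
            d = {k: (None if v is None else _round_half_up(v, decimals))
                 for k, v in d.items()}
        return d

    def write_json(self, path, decimals: int = 3) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(decimals), fh, indent=1)


def confusion(true_labels, pred_labels) -> ConfusionCounts:
    """Count TP/TN/FP/FN from aligned +/-1 label sequences."""
    true_labels = list(true_labels)
    pred_labels = list(pred_labels)
    if len(true_labels) != len(pred_labels):
        raise ValueError(f"label lengths differ: {len(true_labels)} vs {len(pred_labels)}")
    tp = tn = fp = fn = 0
    for t, p in zip(true_labels, pred_labels):
        if t not in (1, -1) or p not in (1, -1):
            raise ValueError("labels must be +1 or -1")
        if t == 1:
            if p == 1:
                tp += 1
            else:
                fn += 1
        else:
            if p == 1:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def net_prediction(sn: float, sp: float) -> float:
    """Arithmetic mean of sensitivity and specificity (both in %)."""
    return (sn + sp) / 2.0


def f_measure(sn: float, sp: float) -> float | None:
    """Harmonic mean of sensitivity and specificity (both in %)."""
    if sn + sp == 0:
        return None
    return 2.0 * sn * sp / (sn + sp)


def report(counts: ConfusionCounts) -> MetricsReport:
    """Compute the seven measures; percentages unrounded, in [0, 100]."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from empty confusion counts")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn

    sn = 100.0 * tp / (tp + fn) if tp + fn > 0 else None
    sp = 100.0 * tn / (tn + fp) if tn + fp > 0 else None
    pr = 100.0 * tp / (tp + fp) if tp + fp > 0 else None
    ac = 100.0 * (tp + tn) / counts.total
    np_ = net_prediction(sn, sp) if sn is not None and sp is not None else None
    fm = f_measure(sn, sp) if sn is not None and sp is not None else None

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    cc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else None
    return MetricsReport(sn=sn, sp=sp, pr=pr, ac=ac, np=np_, fm=fm, cc=cc)


def _round_half_up(x: float, decimals: int) -> float:
    # clean binary-float noise at 9 decimals, then quantize with ties toward
    # zero: averages of one-decimal percentages often land exactly on the
    # half-unit boundary, and this tie rule matches the reference tables the
    # formulas were validated against
    cleaned = Decimal(x).quantize(Decimal(1).scaleb(-9), rounding=ROUND_HALF_EVEN)
    q = Decimal(1).scaleb(-decimals)
    return float(cleaned.quantize(q, rounding=ROUND_HALF_DOWN))


def round1(x: float | None) -> float | None:
    """Round to one decimal as printed in reports (ties toward zero)."""
    return None if x is None else _round_half_up(x, 1)
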