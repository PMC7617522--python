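"""Binary-classification performance metrics from a confusion table."""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "FP", "TN", "FN"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, MCC and the TPR/FPR ratio.

    Ratios with a zero denominator are reported as nan, except TPR/FPR
    which is +inf when there are no false positives but some true
    positives (a detector that fires only on real positives).
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    tp, fp, tn, fn = (float(x) for x in (c.TP, c.FP, c.TN, c.FN))
    acc = (tp + tn) / (tp + tn + fp + fn)
    sens = tp / (tp + fn) if tp + fn > 0 else math.nan
    spec = tn / (tn + fp) if tn + fp > 0 else math.nan
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else math.nan
    if math.isnan(spec) or spec == 1.0:
        ratio = math.inf if (not math.isnan(sens) and sens > 0) else math.nan
    else:
        ratio = sens / (1.0 - spec)
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec,
            "MCC": mcc, "TPR_FPR_ratio": ratio}


def read_confusion_counts(path: str) -> ConfusionCounts:
    """Load TP/FP/TN/FN from a delimited file with a header row."""
    with open(path) as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    row = {k.strip().upper(): v for k, v in rows[0].items()}
    try:
        return ConfusionCounts(TP=int(row["TP"]), FP=int(row["FP"]),
                               TN=int(row["TN"]), FN=int(row["FN"]))
    except KeyError as e:
        raise ValueError(f"{path}: missing column {e}") from e
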