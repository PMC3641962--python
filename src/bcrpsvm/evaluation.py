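"""Confusion counts, performance metrics and classification overlap.

Four metrics summarize a binary prediction (positive = substrate):

    ACC = 100 · (TP + TN) / (TP + TN + FP + FN)
    SE  = 100 · TP / (TP + FN)          (substrate accuracy)
    SP  = 100 · TN / (FP + TN)          (non-substrate accuracy)
    MCC = (TP·TN − FP·FN) / √((TP+FN)(TP+FP)(TN+FP)(TN+FN))

A zero denominator yields an explicit ``None`` marker, never a silent 0;
a coercion option maps undefined MCC to 0 for callers that want the other
common convention. Display rounding is 1 decimal for the percentage
metrics and 3 decimals for MCC; raw values are always retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .chem_io import NON_SUBSTRATE, SUBSTRATE


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise EvaluationError("confusion counts must be non-negative")
        if self.total < 1:
            raise EvaluationError("confusion counts must cover at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class PerformanceReport:
    counts: ConfusionCounts
    acc: float
    se: float | None
    sp: float | None
    mcc: float | None

    def rounded(self) -> dict[str, float | None]:
        """Display precision: percents to 1 decimal, MCC to 3 decimals."""
        rnd = lambda v, d: None if v is None else round(v, d)
        return {
            "ACC": rnd(self.acc, 1),
            "SE": rnd(self.se, 1),
            "SP": rnd(self.sp, 1),
            "MCC": rnd(self.mcc, 3),
        }


def confusion(
    truth: Sequence[str], pred: Sequence[str], positive: str = SUBSTRATE
) -> ConfusionCounts:
    if len(truth) != len(pred):
        raise EvaluationError(f"length mismatch: {len(truth)} vs {len(pred)}")
    if len(truth) == 0:
        raise EvaluationError("empty label vectors")
    vocab = {SUBSTRATE, NON_SUBSTRATE}
    bad = (set(truth) | set(pred)) - vocab
    if bad:
        raise EvaluationError(f"labels outside binary vocabulary: {sorted(bad)}")
    tp = fn = tn = fp = 0
    for t, p in zip(truth, pred):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


def performance(c: ConfusionCounts, coerce_undefined_mcc: bool = False) -> PerformanceReport:
    acc = 100.0 * (c.tp + c.tn) / c.total
    se = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    sp = 100.0 * c.tn / (c.fp + c.tn) if (c.fp + c.tn) else None
    denom = (c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom == 0:
        mcc = 0.0 if coerce_undefined_mcc else None
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return PerformanceReport(counts=c, acc=acc, se=se, sp=sp, mcc=mcc)


def evaluate(
    truth: Sequence[str], pred: Sequence[str], positive: str = SUBSTRATE
) -> PerformanceReport:
    return performance(confusion(truth, pred, positive=positive))


def classification_overlap(pred_a: Sequence[str], pred_b: Sequence[str]) -> float:
    """Percentage of compounds identically predicted by two models."""
    if len(pred_a) != len(pred_b):
        raise EvaluationError(f"length mismatch: {len(pred_a)} vs {len(pred_b)}")
    if len(pred_a) == 0:
        raise EvaluationError("empty prediction vectors")
    same = sum(a == b for a, b in zip(pred_a, pred_b))
    return 100.0 * same / len(pred_a)


def performance_table_text(reports: Mapping[str, PerformanceReport]) -> str:
    """Delimited text mirroring the Category/TP/FN/TN/FP/ACC/SE/SP/MCC layout."""
    lines = ["Category\tTP\tFN\tTN\tFP\tACC\tSE\tSP\tMCC"]
    for cat, rep in reports.items():
        r = rep.rounded()
        fmt = lambda v, d: "NA" if v is None else f"{v:.{d}f}"
        c = rep.counts
        lines.append(
            f"{cat}\t{c.tp}\t{c.fn}\t{c.tn}\t{c.fp}\t"
            f"{fmt(r['ACC'], 1)}\t{fmt(r['SE'], 1)}\t{fmt(r['SP'], 1)}\t{fmt(r['MCC'], 3)}"
        )
    return "\n".join(lines) + "\n"
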