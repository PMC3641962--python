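"""F-score ranking, correlation pruning and greedy forward selection.

The per-feature F-score is the fselect.py definition used with libsvm:

    F = [(x̄⁺ − x̄)² + (x̄⁻ − x̄)²] / (s²⁺ + s²⁻)

with x̄ the pooled mean and s²± the within-class sample variances
(divisor n − 1). A larger F means a more discriminative feature. Features
are then pruned so that no retained pair has |Pearson r| at or above the
threshold (default 0.9), keeping the higher-scored member of each
correlated pair, and finally added one at a time in rank order until the
validation accuracy first strictly decreases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix
from .chem_io import SUBSTRATE


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureScore:
    name: str
    f_score: float  # >= 0, math.inf for perfect zero-variance separators


@dataclass
class SelectionTrace:
    """Audit record of one selection pass."""

    candidates: list[str] = field(default_factory=list)
    pruned_pairs: list[tuple[str, str, float]] = field(default_factory=list)  # kept, dropped, r
    accuracies: list[float] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    flagged: bool = False  # first feature already below baseline

    def to_text(self) -> str:
        lines = ["step\tfeature\taccuracy"]
        for k, (feat, acc) in enumerate(zip(self.candidates, self.accuracies), start=1):
            lines.append(f"{k}\t{feat}\t{acc!r}")
        lines.append("selected: " + ",".join(self.selected))
        for kept, dropped, r in self.pruned_pairs:
            lines.append(f"pruned: kept={kept} dropped={dropped} r={r!r}")
        return "\n".join(lines) + "\n"


def f_score(pos: Sequence[float], neg: Sequence[float]) -> float:
    """F-score of one feature from its positive- and negative-class values.

    Returns ``math.inf`` when both within-class variances are zero but the
    class means differ (a perfect separator), and 0 when the means agree.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise SelectionError("need at least 2 observations per class")
    pooled = np.concatenate([pos, neg]).mean()
    num = (pos.mean() - pooled) ** 2 + (neg.mean() - pooled) ** 2
    den = pos.var(ddof=1) + neg.var(ddof=1)
    if den == 0:
        return math.inf if num > 0 else 0.0
    return float(num / den)


def rank_features(dm: DescriptorMatrix, labels: pd.Series | dict) -> list[FeatureScore]:
    """All features scored and sorted by descending F, name-ordered on ties."""
    labels = pd.Series(labels).loc[dm.ids]
    mask = (labels == SUBSTRATE).to_numpy()
    if mask.all() or not mask.any():
        raise SelectionError("both classes must be present")
    values = dm.values
    scores = [
        FeatureScore(name, f_score(values[mask, k], values[~mask, k]))
        for k, name in enumerate(dm.descriptor_names)
    ]
    return sorted(scores, key=lambda s: (-s.f_score, s.name))


def prune_correlated(
    dm: DescriptorMatrix,
    scores: Sequence[FeatureScore],
    r_threshold: float = 0.9,
) -> tuple[list[str], SelectionTrace]:
    """Greedy pass in descending F-score, keeping the higher-scored member
    of every pair with |Pearson r| >= threshold.

    After pruning, every retained pair has |r| strictly below the
    threshold. Deterministic: ties in F are broken by name.
    """
    by_name = {s.name: s for s in scores}
    missing = [c for c in dm.descriptor_names if c not in by_name]
    if missing:
        raise SelectionError(f"scores missing for columns: {missing}")
    values = dm.frame
    sd = values.to_numpy().std(axis=0, ddof=1)
    flat = [c for c, s in zip(dm.descriptor_names, sd) if s == 0]
    if flat:
        raise SelectionError(
            f"zero-variance columns reached pruning (filtering contract violated): {flat}"
        )
    # standardize once; |r| between columns = |dot|/(n-1)
    z = (values - values.mean()) / values.std(ddof=1)
    n = len(values)
    order = sorted(
        dm.descriptor_names, key=lambda c: (-by_name[c].f_score, c)
    )
    retained: list[str] = []
    trace = SelectionTrace(candidates=list(order))
    for cand in order:
        drop_against = None
        for kept in retained:
            r = float(abs((z[cand] * z[kept]).sum()) / (n - 1))
            if r >= r_threshold:
                drop_against = (kept, r)
                break
        if drop_against is None:
            retained.append(cand)
        else:
            trace.pruned_pairs.append((drop_against[0], cand, drop_against[1]))
    trace.selected = list(retained)
    return retained, trace


def greedy_forward_selection(
    dm: DescriptorMatrix | None,
    labels: pd.Series | dict | None,
    ranked: Sequence[str],
    evaluate: Callable[[list[str]], float],
    baseline: float | None = None,
    max_features: int | None = None,
) -> SelectionTrace:
    """Add features in rank order until validation accuracy first strictly
    decreases; return the set before the decrease (minimum size 1).

    ``baseline`` (e.g. the majority-class accuracy) only matters for the
    first step: if the first feature alone already scores below it, that
    single feature is still selected and the trace is flagged. ``dm`` and
    ``labels`` are accepted for interface symmetry; evaluation happens
    entirely inside the callback.
    """
    if not ranked:
        raise SelectionError("ranked feature list is empty")
    if max_features is not None:
        ranked = list(ranked)[:max_features]
    trace = SelectionTrace(candidates=list(ranked))
    selected: list[str] = []
    prev: float | None = baseline
    for feat in ranked:
        acc = evaluate(selected + [feat])
        trace.accuracies.append(acc)
        if prev is not None and acc < prev:
            if not selected:  # boundary: never return an empty model
                selected = [feat]
                trace.flagged = True
            break
        selected.append(feat)
        prev = acc
    trace.selected = list(selected)
    return trace
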