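"""Descriptor elimination and feature scaling.

Two elimination rules are applied before modelling: descriptors with more
than 80% exact-zero values are dropped, and descriptors whose sample
standard deviation relative to their range falls below 3% (including
constants) are dropped. Scaling is per-column min–max to [−1, 1], fitted on
training rows only and applied without clipping to test/external rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix


class PreprocessError(ValueError):
    pass


@dataclass
class FilterReport:
    removed_by_sparsity: list[str] = field(default_factory=list)
    removed_by_low_variation: list[str] = field(default_factory=list)
    zero_fraction_threshold: float = 0.8
    rel_sd_threshold: float = 0.03

    @property
    def removed(self) -> list[str]:
        return self.removed_by_sparsity + self.removed_by_low_variation

    def to_text(self) -> str:
        lines = [
            f"zero_fraction_threshold: {self.zero_fraction_threshold}",
            f"rel_sd_threshold: {self.rel_sd_threshold}",
            "removed_by_sparsity: " + ",".join(self.removed_by_sparsity),
            "removed_by_low_variation: " + ",".join(self.removed_by_low_variation),
        ]
        return "\n".join(lines) + "\n"


def filter_sparse(
    dm: DescriptorMatrix, zero_fraction: float = 0.8, atol: float = 0.0
) -> tuple[DescriptorMatrix, FilterReport]:
    """Drop columns whose fraction of zeros is strictly greater than the threshold.

    Zero means exact 0.0 by default (descriptor exports emit literal
    zeros); pass ``atol`` for an |x| <= atol variant.
    """
    if not 0 < zero_fraction < 1:
        raise PreprocessError("zero_fraction must be in (0, 1)")
    values = dm.values
    frac = (np.abs(values) <= atol).mean(axis=0) if atol > 0 else (values == 0.0).mean(axis=0)
    removed = [c for c, f in zip(dm.descriptor_names, frac) if f > zero_fraction]
    report = FilterReport(removed_by_sparsity=removed, zero_fraction_threshold=zero_fraction)
    kept = [c for c in dm.descriptor_names if c not in set(removed)]
    if not kept:
        raise PreprocessError("sparsity filter removed every descriptor")
    return dm.select_columns(kept), report


def filter_low_variation(
    dm: DescriptorMatrix, rel_sd: float = 0.03
) -> tuple[DescriptorMatrix, FilterReport]:
    """Drop near-constant columns: sample SD / range < threshold.

    The ratio is unit-free; constant columns (range 0) are always dropped.
    """
    values = dm.values
    sd = values.std(axis=0, ddof=1)
    rng = values.max(axis=0) - values.min(axis=0)
    removed = []
    for c, s, r in zip(dm.descriptor_names, sd, rng):
        if r == 0 or s / r < rel_sd:
            removed.append(c)
    report = FilterReport(removed_by_low_variation=removed, rel_sd_threshold=rel_sd)
    kept = [c for c in dm.descriptor_names if c not in set(removed)]
    if not kept:
        raise PreprocessError("low-variation filter removed every descriptor")
    return dm.select_columns(kept), report


def filter_descriptors(
    dm: DescriptorMatrix, zero_fraction: float = 0.8, rel_sd: float = 0.03
) -> tuple[DescriptorMatrix, FilterReport]:
    """Both elimination rules in the fixed order: sparsity, then variation."""
    dm1, rep1 = filter_sparse(dm, zero_fraction)
    dm2, rep2 = filter_low_variation(dm1, rel_sd)
    return dm2, FilterReport(
        removed_by_sparsity=rep1.removed_by_sparsity,
        removed_by_low_variation=rep2.removed_by_low_variation,
        zero_fraction_threshold=zero_fraction,
        rel_sd_threshold=rel_sd,
    )


@dataclass
class ScalingParams:
    """Per-column affine map onto [−1, 1], fitted on training rows only."""

    columns: list[str]
    mins: np.ndarray
    maxs: np.ndarray
    fitted_on: str = ""

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if np.any(self.maxs <= self.mins):
            bad = [c for c, lo, hi in zip(self.columns, self.mins, self.maxs) if hi <= lo]
            raise PreprocessError(f"zero scale (constant training column): {bad}")

    def to_text(self) -> str:
        lines = [f"fitted_on: {self.fitted_on}"]
        for c, lo, hi in zip(self.columns, self.mins, self.maxs):
            lines.append(f"{c}\t{lo!r}\t{hi!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ScalingParams":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        fitted_on = lines[0].split(":", 1)[1].strip()
        cols, mins, maxs = [], [], []
        for ln in lines[1:]:
            c, lo, hi = ln.split("\t")
            cols.append(c)
            mins.append(float(lo))
            maxs.append(float(hi))
        return cls(cols, np.array(mins), np.array(maxs), fitted_on)


def fit_scaling(dm: DescriptorMatrix, rows: Sequence[str], fitted_on: str = "train") -> ScalingParams:
    sub = dm.select_rows(list(rows))
    return ScalingParams(
        columns=dm.descriptor_names,
        mins=sub.values.min(axis=0),
        maxs=sub.values.max(axis=0),
        fitted_on=fitted_on,
    )


def apply_scaling(dm: DescriptorMatrix, sp: ScalingParams) -> DescriptorMatrix:
    """Affine map to [−1, 1] on the fitted range; values outside the training
    range map outside the interval (no clipping)."""
    missing = [c for c in dm.descriptor_names if c not in set(sp.columns)]
    if missing:
        raise PreprocessError(f"columns not covered by scaling params: {missing}")
    order = dm.descriptor_names
    idx = [sp.columns.index(c) for c in order]
    lo, hi = sp.mins[idx], sp.maxs[idx]
    scaled = 2.0 * (dm.frame[order] - lo) / (hi - lo) - 1.0
    return DescriptorMatrix(scaled, dm.provenance)


def invert_scaling(dm: DescriptorMatrix, sp: ScalingParams) -> DescriptorMatrix:
    idx = [sp.columns.index(c) for c in dm.descriptor_names]
    lo, hi = sp.mins[idx], sp.maxs[idx]
    raw = (dm.frame + 1.0) / 2.0 * (hi - lo) + lo
    return DescriptorMatrix(raw, dm.provenance)
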