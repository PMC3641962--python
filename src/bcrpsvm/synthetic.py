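"""Synthetic descriptor datasets and toy molecules with known ground truth.

The descriptor generator emulates the statistical structure the pipeline
assumes: a two-class compound table with a handful of informative
descriptors (class means shifted by δ within-class standard deviations),
many class-independent noise descriptors, near-duplicate correlated
columns, zero-inflated columns that the sparsity filter should remove, and
an optional borderline fraction of compounds drawn from the midpoint
mixture of the two classes — compounds whose descriptor profiles are too
similar to separate, creating irreducible error by construction while
keeping their true class label.

Defaults mirror the study conditions of the substrate data set this
pipeline targets: 164 substrates vs 99 non-substrates, with 223 compounds
for modelling and 40 (25/15) held out as the external validation set.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import cos, radians, sin

import numpy as np
import pandas as pd

from .chem_io import (
    NON_SUBSTRATE,
    SUBSTRATE,
    CompoundSet,
    LabeledCompound,
    Molecule,
)
from .descriptors import DescriptorMatrix
from .masses import atomic_mass


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic two-class descriptor matrix."""

    n_pos: int = 164
    n_neg: int = 99
    n_informative: int = 5
    n_noise: int = 95
    delta: float = 3.0  # class-mean shift in within-class SD units
    n_correlated_duplicates: int = 0
    n_zero_inflated: int = 0
    zero_fraction: float = 0.9
    borderline_fraction: float = 0.0
    heavy_tails: bool = False  # Student-t(3) draws to stress the scaler
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pos, self.n_neg) < 1:
            raise SyntheticError("both classes need at least one compound")
        if self.n_informative + self.n_noise < 1:
            raise SyntheticError("need at least one feature")
        if self.delta < 0:
            raise SyntheticError("delta must be >= 0")
        if self.n_correlated_duplicates > self.n_informative:
            raise SyntheticError("cannot duplicate more columns than exist")
        if not 0 <= self.borderline_fraction < 1:
            raise SyntheticError("borderline fraction must be in [0, 1)")
        if not 0 < self.zero_fraction < 1:
            raise SyntheticError("zero fraction must be in (0, 1)")


def make_descriptor_dataset(
    spec: SyntheticSpec,
) -> tuple[DescriptorMatrix, pd.Series, list[str]]:
    """Generate (matrix, labels, informative feature names).

    Informative columns are unit-variance draws with the positive-class
    mean shifted by δ; borderline compounds draw their informative values
    from the midpoint N(δ/2, 1) regardless of class. Duplicate columns are
    informative columns plus N(0, 0.03) jitter (sample |r| > 0.99).
    Zero-inflated columns carry an exact planted count of zeros. Fully
    deterministic for a given spec.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    labels = pd.Series(
        [SUBSTRATE] * spec.n_pos + [NON_SUBSTRATE] * spec.n_neg,
        index=[f"c{k + 1:04d}" for k in range(n)],
    )
    is_pos = (labels == SUBSTRATE).to_numpy()

    def draw(size):
        if spec.heavy_tails:
            t = rng.standard_t(3, size=size)
            return t / np.sqrt(3.0)  # unit variance
        return rng.standard_normal(size)

    n_border = int(round(spec.borderline_fraction * n))
    border_idx = rng.choice(n, size=n_border, replace=False) if n_border else np.array([], int)
    border_mask = np.zeros(n, dtype=bool)
    border_mask[border_idx] = True

    cols: dict[str, np.ndarray] = {}
    informative: list[str] = []
    for k in range(spec.n_informative):
        shift = np.where(is_pos, spec.delta, 0.0)
        shift = np.where(border_mask, spec.delta / 2.0, shift)
        name = f"inf_{k + 1:02d}"
        cols[name] = draw(n) + shift
        informative.append(name)
    # Jitter at 12% of the column's spread keeps |r| ≈ 0.993 at any class
    # separation, while making a duplicate a strictly noisier copy: its
    # within-class variance penalty dominates the sampling noise of its
    # F-score, so pruning reliably drops the copy, never the original.
    for k in range(spec.n_correlated_duplicates):
        src = cols[informative[k]]
        cols[f"dup_{k + 1:02d}"] = src + 0.12 * src.std() * rng.standard_normal(n)
    for k in range(spec.n_noise):
        cols[f"noise_{k + 1:02d}"] = draw(n)
    n_zero = int(round(spec.zero_fraction * n))
    for k in range(spec.n_zero_inflated):
        col = draw(n)
        zero_at = rng.choice(n, size=n_zero, replace=False)
        col[zero_at] = 0.0
        cols[f"zero_{k + 1:02d}"] = col

    frame = pd.DataFrame(cols, index=labels.index)
    return DescriptorMatrix(frame, "computed"), labels, informative


def make_split_fixture(
    n_total: int = 263,
    n_external: int = 40,
    labels: pd.Series | None = None,
    n_external_pos: int = 25,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive (modelling, external) id sets.

    With the default class sizes this reproduces the study layout: 223
    modelling compounds (139/84) and a 40-compound external set (25/15).
    If ``labels`` is given the external set is drawn stratified with
    ``n_external_pos`` positives; otherwise a plain seeded draw is used.
    """
    if n_external >= n_total:
        raise SyntheticError("external set must be smaller than the total")
    rng = np.random.default_rng(seed)
    if labels is None:
        ids = [f"c{k + 1:04d}" for k in range(n_total)]
        ext = sorted(rng.choice(n_total, size=n_external, replace=False).tolist())
        ext_ids = [ids[i] for i in ext]
    else:
        if len(labels) != n_total:
            raise SyntheticError("labels length must equal n_total")
        ids = [str(i) for i in labels.index]
        pos_ids = [i for i in ids if labels[i] == SUBSTRATE]
        neg_ids = [i for i in ids if labels[i] != SUBSTRATE]
        n_ext_neg = n_external - n_external_pos
        if n_external_pos > len(pos_ids) or n_ext_neg > len(neg_ids):
            raise SyntheticError("requested external class counts exceed availability")
        ext_ids = sorted(
            list(rng.choice(pos_ids, size=n_external_pos, replace=False))
            + list(rng.choice(neg_ids, size=n_ext_neg, replace=False))
        )
    ext_set = set(ext_ids)
    modelling = [i for i in ids if i not in ext_set]
    return modelling, ext_ids


# ---------------------------------------------------------------------------
# toy molecules with exact, versioned coordinates


def _mol(name: str, atoms: list[tuple[str, tuple[float, float, float]]],
         bonds: list[tuple[int, int, int]]) -> Molecule:
    symbols = tuple(s for s, _ in atoms)
    return Molecule(
        symbols=symbols,
        masses=np.array([atomic_mass(s) for s in symbols]),
        coords=np.array([xyz for _, xyz in atoms]),
        bonds=tuple(bonds),
        name=name,
    )


def _methane() -> Molecule:
    # ideal tetrahedron, C–H 1.09 Å
    a = 1.09 / np.sqrt(3.0)
    return _mol(
        "methane",
        [("C", (0.0, 0.0, 0.0)), ("H", (a, a, a)), ("H", (a, -a, -a)),
         ("H", (-a, a, -a)), ("H", (-a, -a, a))],
        [(0, 1, 1), (0, 2, 1), (0, 3, 1), (0, 4, 1)],
    )


def _water() -> Molecule:
    # ideal bent geometry: O–H 0.9572 Å, H–O–H 104.52°
    r, half = 0.9572, radians(104.52) / 2.0
    return _mol(
        "water",
        [("O", (0.0, 0.0, 0.0)),
         ("H", (r * sin(half), r * cos(half), 0.0)),
         ("H", (-r * sin(half), r * cos(half), 0.0))],
        [(0, 1, 1), (0, 2, 1)],
    )


def _ethane() -> Molecule:
    # staggered ethane, C–C 1.54 Å, C–H 1.09 Å
    cc, ch = 1.54, 1.09
    theta = radians(111.2)
    atoms: list[tuple[str, tuple[float, float, float]]] = [
        ("C", (0.0, 0.0, 0.0)), ("C", (0.0, 0.0, cc))]
    bonds = [(0, 1, 1)]
    rz = ch * cos(np.pi - theta)
    rxy = ch * sin(np.pi - theta)
    for k in range(3):  # H on C1
        phi = radians(120.0 * k)
        atoms.append(("H", (rxy * cos(phi), rxy * sin(phi), -rz)))
        bonds.append((0, len(atoms) - 1, 1))
    for k in range(3):  # staggered H on C2
        phi = radians(120.0 * k + 60.0)
        atoms.append(("H", (rxy * cos(phi), rxy * sin(phi), cc + rz)))
        bonds.append((1, len(atoms) - 1, 1))
    return _mol("ethane", atoms, bonds)


def _benzene() -> Molecule:
    # planar hexagon, C–C 1.39 Å, C–H 1.09 Å; aromatic ring bonds
    atoms = []
    bonds = []
    for k in range(6):
        phi = radians(60.0 * k)
        atoms.append(("C", (1.39 * cos(phi), 1.39 * sin(phi), 0.0)))
    for k in range(6):
        phi = radians(60.0 * k)
        atoms.append(("H", ((1.39 + 1.09) * cos(phi), (1.39 + 1.09) * sin(phi), 0.0)))
        bonds.append((k, 6 + k, 1))
    for k in range(6):
        bonds.append((k, (k + 1) % 6, 4))
    return _mol("benzene", atoms, bonds)


def _carbon_dioxide() -> Molecule:
    return _mol(
        "carbon-dioxide",
        [("O", (0.0, 0.0, -1.16)), ("C", (0.0, 0.0, 0.0)), ("O", (0.0, 0.0, 1.16))],
        [(0, 1, 2), (1, 2, 2)],
    )


def _acetone() -> Molecule:
    # branched at the carbonyl carbon; 10 atoms
    atoms = [
        ("C", (0.0, 0.0, 0.0)),       # carbonyl C
        ("O", (0.0, 1.22, 0.0)),
        ("C", (1.29, -0.75, 0.0)),    # methyl C
        ("C", (-1.29, -0.75, 0.0)),   # methyl C
        ("H", (1.20, -1.55, 0.74)),
        ("H", (2.12, -0.10, 0.25)),
        ("H", (1.48, -1.18, -0.99)),
        ("H", (-1.20, -1.55, -0.74)),
        ("H", (-2.12, -0.10, -0.25)),
        ("H", (-1.48, -1.18, 0.99)),
    ]
    bonds = [(0, 1, 2), (0, 2, 1), (0, 3, 1),
             (2, 4, 1), (2, 5, 1), (2, 6, 1),
             (3, 7, 1), (3, 8, 1), (3, 9, 1)]
    return _mol("acetone", atoms, bonds)


def _isobutylene() -> Molecule:
    # 2-methylpropene: branched alkene, 12 atoms
    atoms = [
        ("C", (0.0, 0.0, 0.0)),      # =C<
        ("C", (0.0, 1.33, 0.0)),     # =CH2
        ("C", (1.28, -0.77, 0.05)),  # methyl
        ("C", (-1.28, -0.77, -0.05)),
        ("H", (0.92, 1.90, -0.03)),
        ("H", (-0.92, 1.90, 0.03)),
        ("H", (1.19, -1.62, 0.75)),
        ("H", (2.11, -0.14, 0.39)),
        ("H", (1.55, -1.17, -0.94)),
        ("H", (-1.19, -1.62, -0.75)),
        ("H", (-2.11, -0.14, -0.39)),
        ("H", (-1.55, -1.17, 0.94)),
    ]
    bonds = [(0, 1, 2), (0, 2, 1), (0, 3, 1), (1, 4, 1), (1, 5, 1),
             (2, 6, 1), (2, 7, 1), (2, 8, 1), (3, 9, 1), (3, 10, 1), (3, 11, 1)]
    return _mol("isobutylene", atoms, bonds)


def toy_molecules() -> CompoundSet:
    """Fixed, versioned toy structures with exact coordinates.

    Methane (ideal tetrahedron), water (ideal bent), staggered ethane,
    planar benzene, linear CO2, and two branched 10–12-atom molecules
    (acetone, isobutylene). Class labels are arbitrary tags so the set can
    drive the full pipeline in tests.
    """
    mols = [_methane(), _water(), _ethane(), _benzene(),
            _carbon_dioxide(), _acetone(), _isobutylene()]
    compounds = [
        LabeledCompound(
            id=f"toy{k + 1:02d}",
            name=m.name,
            structure=m,
            label=SUBSTRATE if k % 2 == 0 else NON_SUBSTRATE,
        )
        for k, m in enumerate(mols)
    ]
    return CompoundSet(compounds, provenance="versioned in-repo toy fixtures")
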