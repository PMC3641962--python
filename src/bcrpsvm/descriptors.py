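"""Molecular descriptors and the descriptor matrix.

Implements the five descriptors used by the final substrate-prediction
model, following the standard descriptor-handbook definitions:

* **AAC** — mean information index on atomic composition: the Shannon
  entropy (base 2) of the molecule's element-count distribution, hydrogens
  included.
* **SPH** — spherosity: ``3·λ3 / (λ1 + λ2 + λ3)`` from the eigenvalues of
  the covariance of atom-centred coordinates; 0 for planar/linear shapes,
  1 for spherically isotropic ones.
* **Mor17m / Mor25m** — 3D-MoRSE signals, the electron-diffraction-style
  pair sum ``Σ_{i<j} w_i w_j sin(s·r_ij)/(s·r_ij)`` at scattering parameter
  ``s``, mass-weighted. Signal number k corresponds to ``s = k − 1`` Å⁻¹
  on the conventional Mor01..Mor32 grid, so Mor17m uses s = 16 and Mor25m
  uses s = 24.
* **R2m** — GETAWAY R autocorrelation of lag 2, mass-weighted: atomic
  leverages from the molecular influence matrix ``H = M (MᵀM)⁻¹ Mᵀ``
  (M = centred coordinates) combined with geometric distances and summed
  over atom pairs at topological distance 2.

Mass weights are carbon-scaled (``w_i = m_i / m_C``), the convention of the
descriptor literature. These definitions are faithful to the published
handbook formulas but are **not** guaranteed to match any specific
commercial descriptor package bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_io import (
    CompoundSet,
    MissingCoordinatesError,
    Molecule,
    interatomic_distances,
    topological_distances,
)
from .masses import CARBON_MASS


class DescriptorError(ValueError):
    """Descriptor computation or table-assembly failure."""


class DegenerateGeometryError(DescriptorError):
    """Geometry makes the descriptor undefined (e.g. all atoms coincident)."""


# ---------------------------------------------------------------------------
# weighting


@dataclass(frozen=True)
class WeightingScheme:
    """Atomic weighting for pairwise descriptors.

    ``unit`` gives every atom weight 1; ``mass`` uses the atomic mass
    divided by the mass of carbon (so carbon has weight 1).
    """

    kind: str = "unit"

    def __post_init__(self) -> None:
        if self.kind not in ("unit", "mass"):
            raise DescriptorError(f"unknown weighting scheme {self.kind!r}")

    def weights(self, m: Molecule) -> np.ndarray:
        if self.kind == "unit":
            return np.ones(m.n_atoms)
        return m.masses / CARBON_MASS


UNIT = WeightingScheme("unit")
MASS = WeightingScheme("mass")


# ---------------------------------------------------------------------------
# the five native descriptors


def aac(m: Molecule) -> float:
    """Mean information index on atomic composition, in bits.

    Shannon entropy of the element-count distribution over all atoms
    (hydrogens included): ``−Σ_g (n_g/n) log2(n_g/n)``.
    """
    _, counts = np.unique(np.asarray(m.symbols), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _coord_cov_eigvals(m: Molecule) -> np.ndarray:
    if m.coords is None:
        raise MissingCoordinatesError(f"molecule {m.name!r} is 2D-only")
    centred = m.coords - m.coords.mean(axis=0)
    cov = centred.T @ centred / m.n_atoms
    vals = np.linalg.eigvalsh(cov)[::-1]  # descending
    return np.clip(vals, 0.0, None)


def spherosity(m: Molecule) -> float:
    """Shape index 3·λ3/(λ1+λ2+λ3) of the coordinate covariance, in [0, 1]."""
    if m.n_atoms < 2:
        raise DescriptorError("spherosity needs at least 2 atoms")
    vals = _coord_cov_eigvals(m)
    total = vals.sum()
    if total <= 0:
        raise DegenerateGeometryError("all atoms coincide; spherosity undefined")
    return float(3.0 * vals[2] / total)


def morse_signal(m: Molecule, s: float, w: WeightingScheme = UNIT) -> float:
    """3D-MoRSE signal at scattering parameter ``s`` (Å⁻¹).

    ``Σ_{i<j} w_i w_j sin(s r_ij)/(s r_ij)`` with the summand defined as
    ``w_i w_j`` when ``s·r_ij = 0``.
    """
    if s < 0:
        raise DescriptorError("scattering parameter must be non-negative")
    if m.n_atoms < 2:
        return 0.0
    r = interatomic_distances(m)
    iu = np.triu_indices(m.n_atoms, k=1)
    x = s * r[iu]
    with np.errstate(invalid="ignore"):
        sinc = np.where(x == 0, 1.0, np.sin(x) / np.where(x == 0, 1.0, x))
    wt = w.weights(m)
    return float((wt[iu[0]] * wt[iu[1]] * sinc).sum())


def leverages(m: Molecule) -> np.ndarray:
    """Diagonal of the molecular influence matrix H = M(MᵀM)⁻¹Mᵀ.

    M is the atom-centred coordinate matrix. For planar or linear
    geometries MᵀM is rank-deficient and the Moore–Penrose pseudo-inverse
    is used.
    """
    if m.coords is None:
        raise MissingCoordinatesError(f"molecule {m.name!r} is 2D-only")
    centred = m.coords - m.coords.mean(axis=0)
    h = centred @ np.linalg.pinv(centred.T @ centred) @ centred.T
    return np.clip(np.diag(h), 0.0, None)


def getaway_r_autocorrelation(m: Molecule, lag: int, w: WeightingScheme = UNIT) -> float:
    """GETAWAY R autocorrelation at a topological lag.

    ``R_lag = Σ_{i<j, d_topo(i,j)=lag} √(h_i h_j)/r_ij · w_i w_j`` with
    leverages h from the molecular influence matrix. Non-negative for
    positive weights; 0 when no atom pair sits at the given lag.
    """
    if lag < 1:
        raise DescriptorError("lag must be >= 1")
    if m.n_atoms < lag + 1:
        raise DescriptorError(f"need at least {lag + 1} atoms for lag {lag}")
    h = leverages(m)
    r = interatomic_distances(m)
    d = topological_distances(m)
    wt = w.weights(m)
    i, j = np.where(np.triu(d == lag, k=1))
    if i.size == 0:
        return 0.0
    return float((np.sqrt(h[i] * h[j]) / r[i, j] * wt[i] * wt[j]).sum())


#: registry of the natively computed descriptors, named as in the final model
NATIVE_DESCRIPTORS: dict[str, Callable[[Molecule], float]] = {
    "AAC": aac,
    "SPH": spherosity,
    "Mor17m": lambda m: morse_signal(m, 16.0, MASS),
    "Mor25m": lambda m: morse_signal(m, 24.0, MASS),
    "R2m": lambda m: getaway_r_autocorrelation(m, 2, MASS),
}

FINAL_MODEL_DESCRIPTORS = ("AAC", "SPH", "Mor17m", "Mor25m", "R2m")


# ---------------------------------------------------------------------------
# the descriptor matrix


class DescriptorMatrix:
    """Compounds × named descriptors, the pipeline's central table.

    A thin wrapper over a float DataFrame that enforces unique row ids and
    column names, finiteness, and tracks per-column provenance
    (``computed`` vs ``ingested``).
    """

    def __init__(self, frame: pd.DataFrame, provenance: str | Mapping[str, str] = "computed"):
        frame = frame.astype(float)
        if frame.index.has_duplicates:
            raise DescriptorError("duplicate compound ids")
        if frame.columns.has_duplicates:
            dupes = sorted(set(frame.columns[frame.columns.duplicated()]))
            raise DescriptorError(f"duplicate descriptor names: {dupes}")
        if not np.all(np.isfinite(frame.to_numpy())):
            bad = [
                (str(i), str(c))
                for i, c in zip(*np.where(~np.isfinite(frame.to_numpy())))
            ][:5]
            raise DescriptorError(f"non-finite descriptor values at (row, col) {bad}")
        self.frame = frame
        if isinstance(provenance, str):
            self.provenance = {c: provenance for c in frame.columns}
        else:
            self.provenance = dict(provenance)

    # -- views -------------------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.frame.index]

    @property
    def descriptor_names(self) -> list[str]:
        return [str(c) for c in self.frame.columns]

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def select_columns(self, names: Sequence[str]) -> "DescriptorMatrix":
        missing = [n for n in names if n not in self.frame.columns]
        if missing:
            raise DescriptorError(f"missing descriptor columns: {missing}")
        return DescriptorMatrix(
            self.frame[list(names)], {n: self.provenance.get(n, "computed") for n in names}
        )

    def select_rows(self, ids: Sequence[str]) -> "DescriptorMatrix":
        missing = [i for i in ids if i not in self.frame.index]
        if missing:
            raise DescriptorError(f"missing compound ids: {missing}")
        return DescriptorMatrix(self.frame.loc[list(ids)], self.provenance)

    # -- serialization -----------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write the table plus a plain-text provenance sidecar."""
        path = Path(path)
        self.frame.to_csv(path, index_label="id")
        sidecar = path.with_suffix(path.suffix + ".provenance.txt")
        with open(sidecar, "w") as fh:
            for col in self.descriptor_names:
                fh.write(f"{col}: {self.provenance.get(col, 'computed')}\n")


def compute_descriptor_matrix(
    cs: CompoundSet,
    descriptors: Sequence[str] = FINAL_MODEL_DESCRIPTORS,
    on_error: str = "abort",
) -> DescriptorMatrix:
    """Compute native descriptors for every compound in a set.

    ``on_error='abort'`` raises on the first per-compound failure (naming
    the compound); ``'drop'`` removes the failing row and records it in the
    matrix provenance under the pseudo-column ``__dropped__``.
    """
    if on_error not in ("abort", "drop"):
        raise DescriptorError("on_error must be 'abort' or 'drop'")
    unknown = [d for d in descriptors if d not in NATIVE_DESCRIPTORS]
    if unknown:
        raise DescriptorError(f"unknown native descriptors: {unknown}")
    rows, ids, dropped = [], [], []
    for comp in cs:
        mol = comp.structure
        if not isinstance(mol, Molecule):
            raise DescriptorError(
                f"compound {comp.id!r}: structure must be materialized as a Molecule"
            )
        try:
            rows.append([NATIVE_DESCRIPTORS[d](mol) for d in descriptors])
            ids.append(comp.id)
        except (DescriptorError, MissingCoordinatesError) as exc:
            if on_error == "abort":
                raise DescriptorError(f"compound {comp.id!r}: {exc}") from exc
            dropped.append(comp.id)
    frame = pd.DataFrame(rows, index=ids, columns=list(descriptors))
    dm = DescriptorMatrix(frame, "computed")
    if dropped:
        dm.provenance["__dropped__"] = ",".join(dropped)
    return dm


def load_descriptor_table(path: str | Path, missing: str = "abort") -> DescriptorMatrix:
    """Ingest a delimited descriptor table (first column = compound id).

    ``missing`` controls non-numeric/empty cells: ``abort`` (default,
    listing the offending cells), ``drop-row`` or ``drop-column`` (removals
    recorded in provenance).
    """
    if missing not in ("abort", "drop-row", "drop-column"):
        raise DescriptorError("missing policy must be abort, drop-row or drop-column")
    # check the raw header first: pandas silently renames duplicate columns
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    sep = "\t" if "\t" in header else ","
    names = [t.strip() for t in header.split(sep)][1:]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise DescriptorError(f"duplicate descriptor names in table: {dupes}")
    raw = pd.read_csv(path, sep=None, engine="python", index_col=0)
    raw.index = raw.index.astype(str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    prov: dict[str, str] = {c: "ingested" for c in numeric.columns}
    if bad.to_numpy().any():
        cells = [
            (str(numeric.index[i]), str(numeric.columns[j]))
            for i, j in zip(*np.where(bad.to_numpy()))
        ]
        if missing == "abort":
            raise DescriptorError(f"non-numeric cells: {cells[:10]}")
        if missing == "drop-row":
            drop = sorted({r for r, _ in cells})
            numeric = numeric.drop(index=drop)
            prov["__dropped_rows__"] = ",".join(drop)
        else:
            drop = sorted({c for _, c in cells})
            numeric = numeric.drop(columns=drop)
            for c in drop:
                prov.pop(c, None)
            prov["__dropped_columns__"] = ",".join(drop)
    return DescriptorMatrix(numeric, prov)
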