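"""Molecular structure and label I/O.

This module exposes a deliberately small molecule model — element symbols,
pinned atomic masses, 3D coordinates in Å and an integer-order bond list —
which is all the descriptor engine needs. Parsing and writing of the
standard formats (V2000 SDF, SMILES) is delegated to RDKit; the results are
converted into :class:`Molecule` so that everything downstream is plain
numpy.

Structures read from SMILES carry no coordinates and are flagged as
2D-only; 3D descriptors refuse such molecules rather than silently
embedding a geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import cdist

from .masses import atomic_mass

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

#: canonical class labels
SUBSTRATE = "substrate"
NON_SUBSTRATE = "non-substrate"

#: accepted spellings in label tables (lower-cased before lookup)
LABEL_ALIASES: dict[str, str] = {
    "substrate": SUBSTRATE,
    "s": SUBSTRATE,
    "1": SUBSTRATE,
    "pos": SUBSTRATE,
    "positive": SUBSTRATE,
    "yes": SUBSTRATE,
    "non-substrate": NON_SUBSTRATE,
    "nonsubstrate": NON_SUBSTRATE,
    "non_substrate": NON_SUBSTRATE,
    "non substrate": NON_SUBSTRATE,
    "n": NON_SUBSTRATE,
    "0": NON_SUBSTRATE,
    "-1": NON_SUBSTRATE,
    "neg": NON_SUBSTRATE,
    "negative": NON_SUBSTRATE,
    "no": NON_SUBSTRATE,
}

_BOND_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: 4,
}


class ChemIOError(ValueError):
    """Base class for structure/label ingestion errors."""


class SdfRecordError(ChemIOError):
    """A malformed molblock; carries the zero-based record index."""

    def __init__(self, index: int, message: str = "malformed molblock"):
        self.index = index
        super().__init__(f"SDF record {index}: {message}")


class DisconnectedMoleculeError(ChemIOError):
    """Bond graph has more than one covalent fragment.

    Raised by operations that require a connected graph; callers that want
    the salt-stripping behaviour should pass the structure through
    :func:`largest_fragment` first.
    """


class MissingCoordinatesError(ChemIOError):
    """A 3D operation was requested on a 2D-only (SMILES-derived) molecule."""


@dataclass(frozen=True)
class Molecule:
    """A molecule as an ordered atom list plus a bond graph.

    ``coords`` is ``None`` for 2D-only structures (e.g. parsed from
    SMILES); such molecules support composition descriptors but refuse
    geometry-dependent ones.
    """

    symbols: tuple[str, ...]
    masses: np.ndarray  # (n,) amu
    coords: np.ndarray | None  # (n, 3) Å, or None for 2D-only
    bonds: tuple[tuple[int, int, int], ...]  # (i, j, order), i < j
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.symbols)
        if n < 1:
            raise ChemIOError("molecule must have at least one atom")
        masses = np.asarray(self.masses, dtype=float)
        if masses.shape != (n,) or not np.all(masses > 0):
            raise ChemIOError("atomic masses must be positive, one per atom")
        object.__setattr__(self, "masses", masses)
        if self.coords is not None:
            coords = np.asarray(self.coords, dtype=float)
            if coords.shape != (n, 3) or not np.all(np.isfinite(coords)):
                raise ChemIOError("coordinates must be a finite (n, 3) array")
            object.__setattr__(self, "coords", coords)
        seen = set()
        norm = []
        for i, j, order in self.bonds:
            if i == j:
                raise ChemIOError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ChemIOError(f"bond ({i}, {j}) references a missing atom")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ChemIOError(f"duplicate bond {key}")
            seen.add(key)
            norm.append((key[0], key[1], int(order)))
        object.__setattr__(self, "bonds", tuple(norm))

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def has_3d(self) -> bool:
        return self.coords is not None

    @property
    def atoms(self) -> list[tuple[str, float, tuple[float, float, float] | None]]:
        """Ordered (symbol, mass, xyz) view of the atom list."""
        return [
            (s, float(m), None if self.coords is None else tuple(self.coords[i]))
            for i, (s, m) in enumerate(zip(self.symbols, self.masses))
        ]

    def adjacency(self) -> csr_matrix:
        n = self.n_atoms
        rows, cols = [], []
        for i, j, _ in self.bonds:
            rows += [i, j]
            cols += [j, i]
        data = np.ones(len(rows))
        return csr_matrix((data, (rows, cols)), shape=(n, n))


@dataclass(frozen=True)
class LabeledCompound:
    id: str
    name: str
    structure: Molecule | str  # a Molecule or raw SMILES text
    label: str

    def __post_init__(self) -> None:
        if self.label not in (SUBSTRATE, NON_SUBSTRATE):
            raise ChemIOError(f"label must be {SUBSTRATE!r} or {NON_SUBSTRATE!r}")


@dataclass
class CompoundSet:
    compounds: list[LabeledCompound]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [c.id for c in self.compounds]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ChemIOError(f"duplicate compound ids: {dupes}")

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self):
        return iter(self.compounds)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.compounds]

    @property
    def labels(self) -> pd.Series:
        return pd.Series({c.id: c.label for c in self.compounds}).loc[self.ids]

    def class_counts(self) -> dict[str, int]:
        counts = {SUBSTRATE: 0, NON_SUBSTRATE: 0}
        for c in self.compounds:
            counts[c.label] += 1
        return counts


# ---------------------------------------------------------------------------
# conversion to/from RDKit


def _from_rdkit(mol: Chem.Mol, name: str = "") -> Molecule:
    symbols = tuple(a.GetSymbol() for a in mol.GetAtoms())
    masses = np.array([atomic_mass(s) for s in symbols])
    coords = None
    if mol.GetNumConformers() > 0:
        conf = mol.GetConformer()
        coords = np.array(
            [[p.x, p.y, p.z] for p in (conf.GetAtomPosition(i) for i in range(mol.GetNumAtoms()))]
        )
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_ORDER.get(b.GetBondType(), 1))
        for b in mol.GetBonds()
    )
    if not name and mol.HasProp("_Name"):
        name = mol.GetProp("_Name")
    return Molecule(symbols, masses, coords, bonds, name=name)


def _to_rdkit(m: Molecule) -> Chem.Mol:
    rw = Chem.RWMol()
    for s in m.symbols:
        atom = Chem.Atom(s)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                 3: Chem.BondType.TRIPLE, 4: Chem.BondType.AROMATIC}
    for i, j, order in m.bonds:
        rw.AddBond(i, j, order_map.get(order, Chem.BondType.SINGLE))
    mol = rw.GetMol()
    if m.coords is not None:
        conf = Chem.Conformer(m.n_atoms)
        for i, xyz in enumerate(m.coords):
            conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
        mol.AddConformer(conf)
    mol.SetProp("_Name", m.name)
    return mol


# ---------------------------------------------------------------------------
# readers / writers


def read_sdf(path: str | Path) -> list[Molecule]:
    """Read a V2000 SDF file into a list of :class:`Molecule`.

    Atom order and record order are preserved; element symbols are mapped to
    the pinned standard atomic-mass table. A malformed record raises
    :class:`SdfRecordError` carrying the zero-based record index. An empty
    file returns an empty list with a warning.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        warnings.warn(f"SDF file {path} is empty", stacklevel=2)
        return []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    out: list[Molecule] = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise SdfRecordError(idx)
        try:
            out.append(_from_rdkit(mol))
        except Exception as exc:  # bad element / bad geometry
            raise SdfRecordError(idx, str(exc)) from exc
    return out


def write_sdf(molecules: Iterable[Molecule], path: str | Path) -> None:
    """Write molecules as V2000 molblocks (round-trips with :func:`read_sdf`)."""
    with open(path, "w") as fh:
        for m in molecules:
            fh.write(Chem.MolToMolBlock(_to_rdkit(m), kekulize=False))
            fh.write("$$$$\n")


def molecule_from_smiles(smiles: str, name: str = "") -> Molecule:
    """Parse SMILES into a 2D-only Molecule with explicit hydrogens.

    Raises :class:`ChemIOError` on unparseable input. The result has
    ``coords=None``; geometry descriptors refuse it.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemIOError(f"unparseable SMILES: {smiles!r}")
    mol = Chem.AddHs(mol)
    return _from_rdkit(mol, name=name)


def _read_table(path: str | Path) -> pd.DataFrame:
    # header required; comma or tab sniffed
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def read_smiles_table(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a delimited table with id/name/smiles columns.

    SMILES strings are not parsed here; validation is deferred to
    :func:`molecule_from_smiles` when structures are materialized.
    """
    df = _read_table(path)
    for col in ("id", "name", "smiles"):
        if col not in df.columns:
            raise ChemIOError(f"smiles table is missing required column {col!r}")
    return [
        (str(r["id"]).strip(), str(r["name"]).strip(), str(r["smiles"]).strip())
        for _, r in df.iterrows()
    ]


def read_label_table(path: str | Path) -> dict[str, str]:
    """Read compound class labels; returns id → {substrate, non-substrate}."""
    df = _read_table(path)
    if "id" not in df.columns:
        raise ChemIOError("label table is missing required column 'id'")
    label_col = next((c for c in ("label", "class") if c in df.columns), None)
    if label_col is None:
        raise ChemIOError("label table is missing a 'label' (or 'class') column")
    out: dict[str, str] = {}
    for row_no, (_, r) in enumerate(df.iterrows(), start=2):  # 1 = header line
        cid = str(r["id"]).strip()
        token = str(r[label_col]).strip().lower()
        if token not in LABEL_ALIASES:
            raise ChemIOError(f"unknown class token {token!r} on row {row_no}")
        if cid in out:
            raise ChemIOError(f"duplicate compound id {cid!r} on row {row_no}")
        out[cid] = LABEL_ALIASES[token]
    return out


# ---------------------------------------------------------------------------
# graph / geometry primitives


def fragment_count(m: Molecule) -> int:
    n, _ = connected_components(m.adjacency(), directed=False)
    return int(n)


def largest_fragment(m: Molecule) -> Molecule:
    """Keep the largest covalent fragment (explicit salt-stripping opt-in)."""
    n_comp, labels = connected_components(m.adjacency(), directed=False)
    if n_comp == 1:
        return m
    sizes = np.bincount(labels)
    keep = int(np.argmax(sizes))
    idx = np.flatnonzero(labels == keep)
    remap = {int(old): new for new, old in enumerate(idx)}
    return Molecule(
        symbols=tuple(m.symbols[i] for i in idx),
        masses=m.masses[idx],
        coords=None if m.coords is None else m.coords[idx],
        bonds=tuple(
            (remap[i], remap[j], o) for i, j, o in m.bonds if i in remap and j in remap
        ),
        name=m.name,
    )


def topological_distances(m: Molecule) -> np.ndarray:
    """All-pairs bond-count distances (symmetric, zero diagonal).

    Raises :class:`DisconnectedMoleculeError` for multi-fragment structures;
    pass through :func:`largest_fragment` first to opt in to salt stripping.
    """
    d = shortest_path(m.adjacency(), method="BF", directed=False, unweighted=True)
    if np.isinf(d).any():
        raise DisconnectedMoleculeError(
            "bond graph is disconnected; use largest_fragment() to keep the "
            "largest covalent fragment"
        )
    return d.astype(int)


def interatomic_distances(m: Molecule) -> np.ndarray:
    """Euclidean distance matrix in Å."""
    if m.coords is None:
        raise MissingCoordinatesError(f"molecule {m.name!r} is 2D-only")
    return cdist(m.coords, m.coords)
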