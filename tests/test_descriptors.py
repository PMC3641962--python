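"""Descriptor engine vs independent brute-force oracles.

The oracle functions below evaluate each descriptor definition directly —
explicit Python loops, a hand-built breadth-first search, and a hand-built
influence matrix — sharing no code with the implementation.
"""

import math
from collections import Counter, deque

import numpy as np
import pandas as pd
import pytest

from bcrpsvm.chem_io import CompoundSet, LabeledCompound, molecule_from_smiles
from bcrpsvm.descriptors import (
    MASS,
    UNIT,
    DegenerateGeometryError,
    DescriptorError,
    DescriptorMatrix,
    aac,
    compute_descriptor_matrix,
    getaway_r_autocorrelation,
    leverages,
    load_descriptor_table,
    morse_signal,
    spherosity,
)
from bcrpsvm.masses import CARBON_MASS
from bcrpsvm.synthetic import toy_molecules
from conftest import random_rigid_transform, transformed
from test_chem_io import simple_mol


# ---------------------------------------------------------------------------
# independent oracles


def oracle_aac(mol):
    counts = Counter(mol.symbols)
    n = len(mol.symbols)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def oracle_spherosity(mol):
    centred = mol.coords - mol.coords.mean(axis=0)
    cov = np.zeros((3, 3))
    for row in centred:
        cov += np.outer(row, row)
    cov /= len(centred)
    lam = sorted(np.linalg.eigvalsh(cov), reverse=True)
    return 3.0 * lam[2] / sum(lam)


def oracle_weights(mol, kind):
    if kind == "unit":
        return [1.0] * mol.n_atoms
    return [m / CARBON_MASS for m in mol.masses]


def oracle_morse(mol, s, kind):
    w = oracle_weights(mol, kind)
    total = 0.0
    for i in range(mol.n_atoms):
        for j in range(i + 1, mol.n_atoms):
            r = math.dist(mol.coords[i], mol.coords[j])
            x = s * r
            total += w[i] * w[j] * (1.0 if x == 0 else math.sin(x) / x)
    return total


def oracle_bfs_distances(mol):
    adj = {i: [] for i in range(mol.n_atoms)}
    for i, j, _ in mol.bonds:
        adj[i].append(j)
        adj[j].append(i)
    dist = {}
    for start in range(mol.n_atoms):
        seen = {start: 0}
        q = deque([start])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if v not in seen:
                    seen[v] = seen[u] + 1
                    q.append(v)
        dist[start] = seen
    return dist


def oracle_getaway(mol, lag, kind):
    centred = mol.coords - mol.coords.mean(axis=0)
    h_full = centred @ np.linalg.pinv(centred.T @ centred) @ centred.T
    h = np.diag(h_full)
    w = oracle_weights(mol, kind)
    topo = oracle_bfs_distances(mol)
    total = 0.0
    for i in range(mol.n_atoms):
        for j in range(i + 1, mol.n_atoms):
            if topo[i].get(j) == lag:
                r = math.dist(mol.coords[i], mol.coords[j])
                total += math.sqrt(h[i] * h[j]) / r * w[i] * w[j]
    return total


# ---------------------------------------------------------------------------


class TestAac:
    def test_single_element_molecule_is_zero(self):
        o2 = simple_mol("OO", [[0, 0, 0], [0, 0, 1.21]], [(0, 1, 2)])
        assert aac(o2) == 0.0

    def test_methane_and_water_entropies(self, toys):
        assert aac(toys["methane"]) == pytest.approx(0.7219, abs=5e-5)
        assert aac(toys["water"]) == pytest.approx(0.9183, abs=5e-5)

    def test_invariant_under_atom_reordering(self, toys):
        m = toys["acetone"]
        perm = np.random.default_rng(0).permutation(m.n_atoms)
        reordered = simple_mol(
            [m.symbols[i] for i in perm], m.coords[perm], []
        )
        assert aac(reordered) == pytest.approx(aac(m), rel=1e-12)


class TestSpherosity:
    def test_planar_molecule_is_zero(self, toys):
        assert spherosity(toys["benzene"]) == pytest.approx(0.0, abs=1e-12)

    def test_collinear_molecule_is_zero(self, toys):
        assert spherosity(toys["carbon-dioxide"]) == pytest.approx(0.0, abs=1e-12)

    def test_regular_tetrahedron_is_one(self):
        verts = [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]
        mol = simple_mol("CCCC", verts, [])
        assert spherosity(mol) == pytest.approx(1.0, rel=1e-12)

    def test_coincident_atoms_degenerate(self):
        mol = simple_mol("CC", [[0, 0, 0], [0, 0, 0]], [(0, 1, 1)])
        with pytest.raises(DegenerateGeometryError):
            spherosity(mol)


class TestMorse:
    def test_zero_scattering_gives_weight_pair_sum(self, toys):
        m = toys["water"]
        w = MASS.weights(m)
        expected = sum(
            w[i] * w[j] for i in range(3) for j in range(i + 1, 3)
        )
        assert morse_signal(m, 0.0, MASS) == pytest.approx(expected, rel=1e-12)

    def test_two_atom_summand(self):
        mol = simple_mol("CC", [[0, 0, 0], [0, 0, 1.5]], [(0, 1, 1)])
        assert morse_signal(mol, 16.0, UNIT) == pytest.approx(
            math.sin(24.0) / 24.0, rel=1e-12
        )

    def test_single_atom_is_zero(self):
        mol = simple_mol("C", [[0, 0, 0]], [])
        assert morse_signal(mol, 16.0, UNIT) == 0.0

    def test_unit_weight_bound(self, toys):
        for m in toys.values():
            n = m.n_atoms
            assert abs(morse_signal(m, 7.0, UNIT)) <= n * (n - 1) / 2 + 1e-12


class TestGetaway:
    def test_no_pair_at_lag_gives_zero(self, toys):
        # ethane's longest path is H-C-C-H = 3 bonds
        assert getaway_r_autocorrelation(toys["ethane"], 4, UNIT) == 0.0

    def test_water_hand_computed_lag2(self, toys):
        m = toys["water"]
        h = leverages(m)
        r_hh = math.dist(m.coords[1], m.coords[2])
        expected = math.sqrt(h[1] * h[2]) / r_hh
        assert getaway_r_autocorrelation(m, 2, UNIT) == pytest.approx(expected, rel=1e-12)

    def test_nonnegative_for_positive_weights(self, toys):
        for m in toys.values():
            for lag in (1, 2, 3):
                if m.n_atoms > lag:
                    assert getaway_r_autocorrelation(m, lag, MASS) >= 0


@pytest.mark.parametrize(
    "name,impl,oracle",
    [
        ("AAC", aac, oracle_aac),
        ("SPH", spherosity, oracle_spherosity),
        ("Mor17m", lambda m: morse_signal(m, 16.0, MASS), lambda m: oracle_morse(m, 16.0, "mass")),
        ("Mor25m", lambda m: morse_signal(m, 24.0, MASS), lambda m: oracle_morse(m, 24.0, "mass")),
        ("R2m", lambda m: getaway_r_autocorrelation(m, 2, MASS), lambda m: oracle_getaway(m, 2, "mass")),
    ],
)
def test_descriptors_match_bruteforce_oracles(name, impl, oracle, toys):
    """Every native descriptor equals a direct formula evaluation on all
    toy fixtures (> 5 molecules)."""
    for mol in toys.values():
        expected = oracle(mol)
        got = impl(mol)
        assert got == pytest.approx(expected, rel=1e-9, abs=1e-12), (name, mol.name)


def test_descriptors_rigid_motion_invariance(toys):
    """All five descriptors are unchanged by random rotations + translations."""
    rng = np.random.default_rng(7)
    mol = toys["acetone"]
    base = {
        "AAC": aac(mol),
        "SPH": spherosity(mol),
        "Mor17m": morse_signal(mol, 16.0, MASS),
        "Mor25m": morse_signal(mol, 24.0, MASS),
        "R2m": getaway_r_autocorrelation(mol, 2, MASS),
    }
    for _ in range(5):
        q, t = random_rigid_transform(rng)
        moved = transformed(mol, q, t)
        assert aac(moved) == pytest.approx(base["AAC"], abs=1e-9)
        assert spherosity(moved) == pytest.approx(base["SPH"], abs=1e-9)
        assert morse_signal(moved, 16.0, MASS) == pytest.approx(base["Mor17m"], abs=1e-9)
        assert morse_signal(moved, 24.0, MASS) == pytest.approx(base["Mor25m"], abs=1e-9)
        assert getaway_r_autocorrelation(moved, 2, MASS) == pytest.approx(base["R2m"], abs=1e-9)


def test_pairwise_descriptors_invariant_under_atom_reordering(toys):
    m = toys["isobutylene"]
    rng = np.random.default_rng(3)
    perm = rng.permutation(m.n_atoms)
    inv = np.argsort(perm)
    from bcrpsvm.chem_io import Molecule

    reordered = Molecule(
        symbols=tuple(m.symbols[i] for i in perm),
        masses=m.masses[perm],
        coords=m.coords[perm],
        bonds=tuple((int(inv[i]), int(inv[j]), o) for i, j, o in m.bonds),
        name=m.name,
    )
    assert morse_signal(reordered, 16.0, MASS) == pytest.approx(
        morse_signal(m, 16.0, MASS), rel=1e-9
    )
    assert getaway_r_autocorrelation(reordered, 2, MASS) == pytest.approx(
        getaway_r_autocorrelation(m, 2, MASS), rel=1e-9
    )


class TestDescriptorMatrix:
    def test_compute_matrix_columns_named_as_final_model(self):
        dm = compute_descriptor_matrix(toy_molecules())
        assert dm.descriptor_names == ["AAC", "SPH", "Mor17m", "Mor25m", "R2m"]
        assert dm.shape == (7, 5)
        assert np.all(np.isfinite(dm.values))

    def test_2d_only_molecule_aborts_with_compound_id(self):
        flat = molecule_from_smiles("CC", name="flat")
        cs = CompoundSet([LabeledCompound("flat", "flat", flat, "substrate")])
        with pytest.raises(DescriptorError, match="flat"):
            compute_descriptor_matrix(cs, ("Mor17m",))

    def test_2d_only_drop_policy(self, toys):
        flat = molecule_from_smiles("CC", name="flat")
        cs = CompoundSet(
            [
                LabeledCompound("ok", "water", toys["water"], "substrate"),
                LabeledCompound("flat", "flat", flat, "non-substrate"),
            ]
        )
        dm = compute_descriptor_matrix(cs, ("Mor17m",), on_error="drop")
        assert dm.ids == ["ok"]
        assert "flat" in dm.provenance["__dropped__"]

    def test_load_table(self, tmp_path):
        p = tmp_path / "table.csv"
        p.write_text("id,d1,d2\na,1.0,2.0\nb,3.5,4.5\n")
        dm = load_descriptor_table(p)
        assert dm.shape == (2, 2)
        assert all(v == "ingested" for k, v in dm.provenance.items() if k in dm.descriptor_names)

    def test_load_table_na_policies(self, tmp_path):
        p = tmp_path / "table.csv"
        p.write_text("id,d1,d2\na,1.0,NA\nb,3.5,4.5\n")
        with pytest.raises(DescriptorError, match="d2"):
            load_descriptor_table(p)
        dm = load_descriptor_table(p, missing="drop-column")
        assert dm.descriptor_names == ["d1"]
        dm2 = load_descriptor_table(p, missing="drop-row")
        assert dm2.ids == ["b"]

    def test_duplicate_column_header_rejected(self, tmp_path):
        p = tmp_path / "table.csv"
        p.write_text("id,d1,d1\na,1.0,2.0\n")
        with pytest.raises(DescriptorError, match="duplicate"):
            load_descriptor_table(p)

    def test_serialization_with_provenance_sidecar(self, tmp_path):
        frame = pd.DataFrame({"d1": [1.0, 2.0]}, index=["a", "b"])
        dm = DescriptorMatrix(frame)
        out = tmp_path / "dm.csv"
        dm.to_csv(out)
        assert "d1: computed" in (tmp_path / "dm.csv.provenance.txt").read_text()
        back = load_descriptor_table(out)
        assert np.allclose(back.values, dm.values)
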