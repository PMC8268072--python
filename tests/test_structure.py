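"""PDB ingestion and solvent-exposure computation."""

import numpy as np
import pytest

from abdev.errors import DataError, PdbParseError
from abdev.structure import (
    Atom,
    StructureModel,
    compute_exposure,
    neighbor_exposure,
    read_pdb,
    relative_exposure,
    residue_sasa,
    sasa,
    write_pdb,
)

PROBE = 1.4
R_C = 1.70  # carbon vdW


def carbon(i, x, y=0.0, z=0.0, res=1, chain="A", name="CA"):
    return Atom(chain, res, "ALA", name, "C", x, y, z)


class TestReadPdb:
    def test_single_atom(self, tmp_path):
        p = tmp_path / "a.pdb"
        p.write_text(
            "ATOM      1  CA  ALA A   1      11.104   6.134  -6.504  1.00  0.00           C\n"
        )
        model = read_pdb(p)
        assert len(model.atoms) == 1
        assert model.atoms[0].element == "C"
        assert model.atoms[0].x == pytest.approx(11.104)

    def test_waters_excluded(self, tmp_path):
        p = tmp_path / "w.pdb"
        p.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2  O   HOH A   2       5.000   0.000   0.000  1.00  0.00           O\n"
        )
        assert len(read_pdb(p).atoms) == 1

    def test_element_inferred_from_atom_name(self, tmp_path):
        p = tmp_path / "e.pdb"
        p.write_text(
            "ATOM      1  NZ  LYS A   1       0.000   0.000   0.000  1.00  0.00\n"
        )
        assert read_pdb(p).atoms[0].element == "N"

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  GLY A   2      badxyz   0.000   0.000  1.00  0.00           C\n"
        )
        with pytest.raises(PdbParseError, match=":2"):
            read_pdb(p)

    def test_altloc_b_dropped(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA BALA A   1       0.500   0.000   0.000  1.00  0.00           C\n"
        )
        assert len(read_pdb(p).atoms) == 1

    def test_write_read_roundtrip(self, tmp_path):
        model = StructureModel(atoms=(carbon(0, 0.0), carbon(1, 3.8, res=2)))
        p = tmp_path / "rt.pdb"
        write_pdb(model, p)
        back = read_pdb(p)
        assert len(back.atoms) == 2
        assert back.atoms[1].x == pytest.approx(3.8)


class TestSasa:
    def test_isolated_sphere_matches_analytic_area(self):
        model = StructureModel(atoms=(carbon(0, 0.0),))
        area = sasa(model, probe_radius=PROBE, n_points=960)[0]
        exact = 4.0 * np.pi * (R_C + PROBE) ** 2
        assert abs(area - exact) / exact < 0.01

    def test_coincident_atoms_fully_occlude(self):
        """Two spheres at zero distance: every surface point of each lies
        strictly inside the other's expanded sphere."""
        model = StructureModel(atoms=(carbon(0, 0.0), carbon(0, 0.0)))
        areas = sasa(model)
        assert areas[0] == 0.0 and areas[1] == 0.0

    def test_distant_atoms_equal_isolated_value(self):
        iso = sasa(StructureModel(atoms=(carbon(0, 0.0),)))[0]
        model = StructureModel(atoms=(carbon(0, 0.0), carbon(1, 50.0)))
        areas = sasa(model)
        assert areas[0] == pytest.approx(iso) and areas[1] == pytest.approx(iso)

    def test_monotone_nonincreasing_as_atoms_added(self):
        rng = np.random.default_rng(2)
        base = [carbon(i, *xyz) for i, xyz in enumerate(rng.uniform(0, 8, size=(6, 3)))]
        prev = sasa(StructureModel(atoms=tuple(base)))
        for k in range(3):
            base.append(carbon(10 + k, *rng.uniform(0, 8, size=3)))
            cur = sasa(StructureModel(atoms=tuple(base)))
            assert np.all(cur[: len(prev)] <= prev + 1e-9)
            prev = cur

    def test_convergence_with_point_count(self):
        model = StructureModel(atoms=(carbon(0, 0.0),))
        a1 = sasa(model, n_points=960)[0]
        a2 = sasa(model, n_points=1920)[0]
        assert abs(a2 - a1) / a1 < 0.005

    def test_empty_structure_rejected(self):
        with pytest.raises(DataError):
            sasa(StructureModel(atoms=()))


class TestRelativeExposure:
    def test_normalisation_and_clamping(self):
        model = StructureModel(atoms=(Atom("A", 1, "GLY", "CA", "C", 0, 0, 0),))
        ref = {"G": 104.0}
        for value, expected in [(104.0, 1.0), (0.0, 0.0), (150.0, 1.0)]:
            prof = relative_exposure(model, {("A", 1): value}, reference=ref)["A"]
            assert prof.relative[0] == pytest.approx(expected)

    def test_missing_reference_entry_rejected(self):
        model = StructureModel(atoms=(Atom("A", 1, "ALA", "CA", "C", 0, 0, 0),))
        with pytest.raises(DataError):
            relative_exposure(model, {("A", 1): 10.0}, reference={"G": 104.0})


class TestNeighborExposure:
    def _grid_model(self, n=27, spacing=4.0):
        atoms = []
        idx = 1
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    atoms.append(
                        Atom("A", idx, "ALA", "CB", "C", i * spacing, j * spacing, k * spacing)
                    )
                    idx += 1
        return StructureModel(atoms=tuple(atoms))

    def test_isolated_residue_fully_exposed(self):
        model = StructureModel(atoms=(Atom("A", 1, "ALA", "CB", "C", 0, 0, 0),))
        assert neighbor_exposure(model)["A"].relative[0] == 1.0

    def test_saturated_neighborhood_reads_buried(self):
        model = self._grid_model()
        prof = neighbor_exposure(model, radius=10.0, n_max=20)["A"]
        center = 13  # middle of the 3x3x3 grid, 26 neighbors within 10 A
        assert prof.relative[center] == 0.0

    def test_counts_match_brute_force_pairwise_scan(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(0, 15, size=(20, 3))
        atoms = tuple(
            Atom("A", i + 1, "ALA", "CB", "C", *xyz) for i, xyz in enumerate(coords)
        )
        prof = neighbor_exposure(StructureModel(atoms=atoms), radius=6.0, n_max=20)["A"]
        for i in range(20):
            n = sum(
                1
                for j in range(20)
                if j != i and np.linalg.norm(coords[i] - coords[j]) <= 6.0
            )
            assert prof.relative[i] == pytest.approx(max(0.0, 1.0 - n / 20))

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(12)
        coords = rng.uniform(0, 12, size=(15, 3))
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        moved = coords @ rot.T + np.array([5.0, -3.0, 2.0])
        prof_a = neighbor_exposure(
            StructureModel(atoms=tuple(Atom("A", i + 1, "ALA", "CB", "C", *c)
                                       for i, c in enumerate(coords)))
        )["A"]
        prof_b = neighbor_exposure(
            StructureModel(atoms=tuple(Atom("A", i + 1, "ALA", "CB", "C", *c)
                                       for i, c in enumerate(moved)))
        )["A"]
        assert prof_a.relative == pytest.approx(prof_b.relative)


def test_compute_exposure_end_to_end(tmp_path):
    """SASA -> relative exposure pipeline on a two-residue dipeptide."""
    atoms = (
        Atom("A", 1, "GLY", "CA", "C", 0.0, 0.0, 0.0),
        Atom("A", 2, "GLY", "CA", "C", 3.8, 0.0, 0.0),
    )
    profiles = compute_exposure(StructureModel(atoms=atoms))
    prof = profiles["A"]
    assert len(prof.relative) == 2
    assert all(0.0 <= r <= 1.0 for r in prof.relative)
    assert prof.method == "shrake_rupley"
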