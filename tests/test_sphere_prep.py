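"""Spherical-boundary system preparation."""

import numpy as np
import pytest

from dualfep.ligand_io import Atom, LigandTopology
from dualfep.sphere_prep import (
    AtomRecord,
    Residue,
    SimulationSphere,
    Structure,
    classify_atoms,
    neutralize_outside,
    read_structure_pdb,
    remove_overlapping_waters,
    solvate_sphere,
    sphere_center,
    write_structure_pdb,
)
from dualfep.synthetic_data import gen_toy_system


def _point_ligand(name, *coords):
    atoms = [Atom(f"C{i+1}", "C", "c3", 0.0, tuple(map(float, c)))
             for i, c in enumerate(coords)]
    return LigandTopology(name, atoms, charge_groups=[list(range(len(atoms)))])


def _water(resid, oxygen):
    ox, oy, oz = oxygen
    return Residue("HOH", resid, [AtomRecord("O", "O", (ox, oy, oz)),
                                  AtomRecord("H1", "H", (ox + 0.95, oy, oz)),
                                  AtomRecord("H2", "H", (ox, oy + 0.95, oz))])


class TestSphereCenter:
    def test_midpoint_of_two_single_atom_ligands(self):
        a = _point_ligand("LA", (0, 0, 0))
        b = _point_ligand("LB", (2, 0, 0))
        assert sphere_center("cog_two_ligands", ligands=(a, b)) == (1.0, 0.0, 0.0)

    def test_identical_ligand_twice_gives_own_centroid(self):
        a = _point_ligand("LA", (1, 2, 3), (3, 2, 1))
        assert sphere_center("cog_two_ligands", ligands=(a, a)) == \
            pytest.approx((2.0, 2.0, 2.0))

    def test_matches_coordinate_mean_oracle(self):
        rng = np.random.default_rng(7)
        xa, xb = rng.normal(size=(4, 3)), rng.normal(size=(2, 3))
        a = _point_ligand("LA", *xa)
        b = _point_ligand("LB", *xb)
        expected = np.vstack([xa, xb]).mean(axis=0)
        assert sphere_center("cog_two_ligands", ligands=(a, b)) == \
            pytest.approx(tuple(expected))

    def test_empty_selection_errors(self):
        empty = LigandTopology("EMP")
        with pytest.raises(ValueError, match="empty"):
            sphere_center("cog_two_ligands", ligands=(empty, empty))

    def test_other_modes(self):
        s = Structure([Residue("ALA", 7, [AtomRecord("CA", "C", (1, 1, 1)),
                                          AtomRecord("CB", "C", (3, 3, 3))])])
        assert sphere_center("cartesian", xyz=(1, 2, 3)) == (1.0, 2.0, 3.0)
        assert sphere_center("residue", structure=s, resid=7) == pytest.approx((2, 2, 2))
        lig = _point_ligand("LA", (5, 5, 5))
        assert sphere_center("ligand_atom", ligand=lig, atom_name="C1") == (5, 5, 5)


class TestClassify:
    def test_atom_on_boundary_counts_inside(self):
        s = Structure([Residue("ALA", 1, [AtomRecord("CA", "C", (25.0, 0, 0))])])
        out = classify_atoms(s, SimulationSphere((0, 0, 0), 25.0), shell_width=0.0)
        assert out.residues[0].atoms[0].region == "inside"

    def test_shell_assignment(self):
        s = Structure([Residue("ALA", 1, [AtomRecord("CA", "C", (23.0, 0, 0))])])
        out = classify_atoms(s, SimulationSphere((0, 0, 0), 25.0), shell_width=3.0)
        assert out.residues[0].atoms[0].region == "shell"

    def test_counts_match_brute_force_scan(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(-30, 30, size=(100, 3))
        s = Structure([Residue("ALA", i, [AtomRecord("CA", "C", tuple(p))])
                       for i, p in enumerate(pts)])
        sph = SimulationSphere((0, 0, 0), 25.0)
        out = classify_atoms(s, sph, shell_width=3.0)
        d = np.linalg.norm(pts, axis=1)
        expected = {"inside": int(np.sum(d <= 22.0)),
                    "shell": int(np.sum((d > 22.0) & (d <= 25.0))),
                    "outside": int(np.sum(d > 25.0))}
        assert out.region_counts() == expected
        assert sum(expected.values()) == 100  # partition property

    def test_invariant_under_rigid_translation(self):
        rng = np.random.default_rng(12)
        pts = rng.uniform(-30, 30, size=(50, 3))
        shift = np.array([5.0, -7.0, 2.0])
        s1 = Structure([Residue("ALA", i, [AtomRecord("CA", "C", tuple(p))])
                        for i, p in enumerate(pts)])
        s2 = Structure([Residue("ALA", i, [AtomRecord("CA", "C", tuple(p + shift))])
                        for i, p in enumerate(pts)])
        c1 = classify_atoms(s1, SimulationSphere((0, 0, 0), 25.0)).region_counts()
        c2 = classify_atoms(s2, SimulationSphere(tuple(shift), 25.0)).region_counts()
        assert c1 == c2


class TestRemoveWaters:
    def test_no_clash_is_identity(self):
        lig = _point_ligand("LA", (0, 0, 0))
        waters = Structure([_water(1, (10, 0, 0)), _water(2, (0, 10, 0))])
        out = remove_overlapping_waters(waters, lig, lig, cutoff=2.4)
        assert out.n_atoms() == waters.n_atoms()

    def test_single_clash_removes_whole_residue(self):
        lig = _point_ligand("LA", (0, 0, 0))
        waters = Structure([_water(1, (1.0, 0, 0)), _water(2, (10, 0, 0))])
        out = remove_overlapping_waters(waters, lig, lig, cutoff=2.4)
        assert [r.resid for r in out.residues] == [2]

    def test_matches_exhaustive_pairwise_filter(self):
        rng = np.random.default_rng(13)
        lig_a = _point_ligand("LA", *rng.uniform(-3, 3, size=(4, 3)))
        lig_b = _point_ligand("LB", *rng.uniform(-3, 3, size=(3, 3)))
        waters = Structure([_water(i, tuple(p)) for i, p in
                            enumerate(rng.uniform(-8, 8, size=(50, 3)))])
        cutoff = 2.4
        out = remove_overlapping_waters(waters, lig_a, lig_b, cutoff)
        heavy = np.array([a.xyz for lig in (lig_a, lig_b) for a in lig.atoms])
        survivors = []
        for res in waters.residues:
            wxyz = np.array([a.xyz for a in res.atoms])
            dmin = np.linalg.norm(wxyz[:, None] - heavy[None], axis=2).min()
            if dmin > cutoff:
                survivors.append(res.resid)
        assert [r.resid for r in out.residues] == survivors

    def test_subset_and_monotone_in_cutoff(self):
        rng = np.random.default_rng(14)
        lig = _point_ligand("LA", *rng.uniform(-2, 2, size=(3, 3)))
        waters = Structure([_water(i, tuple(p)) for i, p in
                            enumerate(rng.uniform(-6, 6, size=(40, 3)))])
        ids = {r.resid for r in waters.residues}
        prev = ids
        for cutoff in (1.0, 2.0, 3.0, 4.0):
            kept = {r.resid for r in
                    remove_overlapping_waters(waters, lig, lig, cutoff).residues}
            assert kept <= prev  # larger cutoff never retains more
            prev = kept


class TestNeutralize:
    def test_inside_residue_unchanged(self):
        s = Structure([Residue("ASP", 1, [AtomRecord(n, n[0], (float(i), 0, 0))
                                          for i, n in enumerate(["CG", "OD1", "OD2"])])])
        out, log = neutralize_outside(s, SimulationSphere((0, 0, 0), 25.0))
        assert out.residues[0].name == "ASP"
        assert log == []

    def test_outside_lys_renamed_and_logged(self):
        s = Structure([Residue("LYS", 9, [AtomRecord("NZ", "N", (30.0, 0, 0))])])
        out, log = neutralize_outside(s, SimulationSphere((0, 0, 0), 25.0))
        assert out.residues[0].name == "LYN"
        assert len(log) == 1 and log[0].resid == 9 and log[0].old_name == "LYS"

    def test_matches_brute_force_centroid_rule(self):
        system = gen_toy_system(10, 0, seed=3)
        sph = SimulationSphere((0, 0, 0), 6.0)
        out, log = neutralize_outside(system, sph, shell_width=1.5)
        from dualfep.sphere_prep import CHARGED_GROUP_ATOMS, NEUTRAL_VARIANT
        expected = []
        for res in system.residues:
            if res.name in NEUTRAL_VARIANT:
                c = res.centroid(CHARGED_GROUP_ATOMS[res.name])
                if np.linalg.norm(c) > 4.5:
                    expected.append(res.resid)
        assert [rec.resid for rec in log] == expected
        assert expected  # the toy system must actually exercise the rule

    def test_only_names_change(self):
        system = gen_toy_system(8, 0, seed=4)
        out, _ = neutralize_outside(system, SimulationSphere((0, 0, 0), 5.0))
        assert out.n_atoms() == system.n_atoms()
        assert np.allclose(out.coordinates(), system.coordinates())

    def test_unknown_residue_warns(self):
        s = Structure([Residue("XXX", 1, [AtomRecord("C1", "C", (0, 0, 0))])])
        with pytest.warns(UserWarning, match="XXX"):
            _, log = neutralize_outside(s, SimulationSphere((0, 0, 0), 25.0))
        assert log == []


class TestSolvate:
    def test_count_matches_grid_enumeration(self):
        sph = SimulationSphere((0, 0, 0), 6.0)
        out = solvate_sphere(sph, Structure(), grid_spacing=3.1)
        # independent enumeration of cubic-grid nodes inside the sphere
        count = 0
        m = 3
        for i in range(-m, m + 1):
            for j in range(-m, m + 1):
                for k in range(-m, m + 1):
                    if np.linalg.norm(np.array([i, j, k]) * 3.1) <= 6.0:
                        count += 1
        waters = [r for r in out.residues if r.name == "HOH"]
        assert len(waters) == count
        assert all(len(r.atoms) == 3 for r in waters)

    def test_offset_grid_with_tiny_sphere_places_nothing(self):
        sph = SimulationSphere((0, 0, 0), 1.0)
        out = solvate_sphere(sph, Structure(), grid_spacing=3.1,
                             grid_origin=(1.55, 1.55, 1.55))
        assert out.n_atoms() == 0

    def test_idempotent(self):
        sph = SimulationSphere((0, 0, 0), 6.0)
        once = solvate_sphere(sph, Structure(), grid_spacing=3.1)
        twice = solvate_sphere(sph, once, grid_spacing=3.1)
        assert twice.n_atoms() == once.n_atoms()

    def test_deterministic(self):
        sph = SimulationSphere((1, 2, 3), 5.0)
        a = solvate_sphere(sph, Structure(), grid_spacing=3.1)
        b = solvate_sphere(sph, Structure(), grid_spacing=3.1)
        assert a.coordinates() == pytest.approx(b.coordinates())


class TestStructurePdb:
    def test_roundtrip(self, tmp_path):
        system = gen_toy_system(3, 5, seed=5)
        p = tmp_path / "sys.pdb"
        write_structure_pdb(system, p)
        back = read_structure_pdb(p)
        assert back.n_atoms() == system.n_atoms()
        assert [r.name for r in back.residues] == [r.name for r in system.residues]
        assert np.allclose(back.coordinates(), system.coordinates(), atol=1e-3)
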