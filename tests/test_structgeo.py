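"""Structure geometry: distances, χ1 rotation, superposition, SASA."""

import math

import numpy as np
import pytest
import biotite.structure as bst

from sqgsuite import structgeo as sg
from sqgsuite.syndata import make_toy_structure
from oracles import monte_carlo_sasa, quaternion_rmsd


def atoms_from(rows):
    arr = bst.AtomArray(len(rows))
    for i, (chain, res_id, name, element, xyz) in enumerate(rows):
        arr.chain_id[i] = chain
        arr.res_id[i] = res_id
        arr.res_name[i] = "LIG"
        arr.atom_name[i] = name
        arr.element[i] = element
        arr.coord[i] = xyz
    arr.hetero[:] = False
    return sg.Structure(arr)


def random_rotation(seed):
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def transformed(s: sg.Structure, R: np.ndarray, t: np.ndarray) -> sg.Structure:
    arr = s.atoms.copy()
    arr.coord = (R @ arr.coord.astype(float).T).T + t
    return sg.Structure(arr, name=s.name)


class TestDistance:
    def test_constructed_separation(self):
        s = make_toy_structure("sphere-pair", separation=3.4)
        d = sg.distance(s, dict(res_id=1, atom_name="C1"),
                        dict(res_id=2, atom_name="C1"))
        assert d == pytest.approx(3.4, abs=1e-5)

    def test_symmetry(self):
        s = make_toy_structure("sphere-pair", separation=5.0)
        a = dict(res_id=1, atom_name="C1")
        b = dict(res_id=2, atom_name="C1")
        assert sg.distance(s, a, b) == sg.distance(s, b, a)

    def test_ambiguous_selection_rejected(self):
        s = make_toy_structure("sphere-pair")
        with pytest.raises(ValueError, match="ambiguous"):
            sg.distance(s, dict(atom_name="C1"), dict(res_id=2))

    def test_rigid_motion_invariance(self):
        s = make_toy_structure("sphere-pair", separation=3.4)
        moved = transformed(s, random_rotation(1), np.array([5.0, -2.0, 9.0]))
        a = dict(res_id=1, atom_name="C1")
        b = dict(res_id=2, atom_name="C1")
        assert sg.distance(moved, a, b) == pytest.approx(3.4, abs=1e-5)


class TestChi1:
    def test_identical_structures_rotate_zero(self):
        ref, _ = make_toy_structure("rotated-copy", angle=72.0)
        assert sg.sidechain_rotation(ref, ref, "A", 1) == pytest.approx(0.0)

    @pytest.mark.parametrize("angle", [10.0, 72.0, 179.0, 250.0])
    def test_constructed_rotation_recovered_on_circle(self, angle):
        ref, rot = make_toy_structure("rotated-copy", angle=angle)
        expected = min(angle % 360, 360 - angle % 360)
        assert sg.sidechain_rotation(ref, rot, "A", 1) == pytest.approx(
            expected, abs=1e-4
        )

    def test_rigid_motion_invariance(self):
        ref, rot = make_toy_structure("rotated-copy", angle=72.0)
        moved = transformed(rot, random_rotation(3), np.array([1.0, 2.0, 3.0]))
        assert sg.sidechain_rotation(ref, moved, "A", 1) == pytest.approx(
            72.0, abs=1e-3
        )

    def test_missing_atoms_rejected(self):
        s = make_toy_structure("sphere-pair")
        with pytest.raises(ValueError):
            sg.chi1(s, "A", 1)


class TestSuperposition:
    def test_self_rmsd_zero(self):
        ref, _ = make_toy_structure("rotated-copy")
        helix = make_toy_structure("helix-dimer", n_res=10)
        R, t, rmsd = sg.kabsch(helix.atoms.coord, helix.atoms.coord)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_rmsd_zero(self):
        helix = make_toy_structure("helix-dimer", n_res=10)
        P = helix.atoms.coord.astype(float)
        Q = (random_rotation(5) @ P.T).T + np.array([3.0, -1.0, 7.0])
        _, _, rmsd = sg.kabsch(P, Q)
        assert rmsd == pytest.approx(0.0, abs=1e-7)

    @pytest.mark.parametrize("seed", range(10))
    def test_kabsch_equals_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        P = rng.normal(size=(n, 3))
        Q = rng.normal(size=(n, 3))
        _, _, rmsd = sg.kabsch(P, Q)
        assert rmsd == pytest.approx(quaternion_rmsd(P, Q), abs=1e-8)

    def test_no_reflection(self):
        rng = np.random.default_rng(11)
        P = rng.normal(size=(6, 3))
        Q = P.copy()
        Q[:, 0] *= -1  # mirrored: a proper rotation cannot undo this
        R, _, _ = sg.kabsch(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_superpose_rmsd_on_residue_structures(self):
        helix = make_toy_structure("helix-dimer", n_res=12)
        a = helix.select(chain="A")
        moved = transformed(a, random_rotation(7), np.array([4.0, 4.0, 4.0]))
        rmsd, n_res = sg.superpose_rmsd(a, moved, backbone=("CA",))
        assert rmsd == pytest.approx(0.0, abs=1e-5)
        assert n_res == 12

    def test_too_few_common_residues_rejected(self):
        helix = make_toy_structure("helix-dimer", n_res=12)
        a = helix.select(chain="A")
        b = helix.select(chain="B")
        sub = sg.Structure(b.atoms[b.atoms.res_id <= 2])
        with pytest.raises(ValueError, match="common residues"):
            sg.superpose_rmsd(a, sub, backbone=("CA",))


class TestSASA:
    def test_isolated_atom_matches_closed_form(self):
        s = atoms_from([("A", 1, "C1", "C", (0, 0, 0))])
        _, total = sg.sasa(s)
        exact = 4 * math.pi * (1.70 + 1.4) ** 2
        assert total == pytest.approx(exact, rel=0.005)

    def test_far_apart_atoms_are_additive(self):
        one = atoms_from([("A", 1, "C1", "C", (0, 0, 0))])
        two = atoms_from([("A", 1, "C1", "C", (0, 0, 0)),
                          ("A", 2, "C1", "C", (50, 0, 0))])
        _, t1 = sg.sasa(one)
        _, t2 = sg.sasa(two)
        assert t2 == pytest.approx(2 * t1, rel=1e-9)

    def test_fully_caged_atom_has_zero_sasa(self):
        # enclose a central atom in a tight spherical shell of neighbours
        pts = sg.sphere_lattice(64) * 2.8
        rows = [("A", 1, "C0", "C", (0.0, 0.0, 0.0))]
        rows += [("A", i + 2, "C1", "C", tuple(p)) for i, p in enumerate(pts)]
        s = atoms_from(rows)
        areas, _ = sg.sasa(s)
        assert areas[0] == 0.0

    def test_lattice_convergence(self):
        s = make_toy_structure("helix-dimer", n_res=8)
        _, coarse = sg.sasa(s, n_points=960)
        _, fine = sg.sasa(s, n_points=10000)
        assert coarse == pytest.approx(fine, rel=0.01)

    def test_rotation_invariance_within_lattice_tolerance(self):
        s = make_toy_structure("helix-dimer", n_res=8)
        moved = transformed(s, random_rotation(13), np.zeros(3))
        _, a = sg.sasa(s)
        _, b = sg.sasa(moved)
        assert b == pytest.approx(a, rel=0.01)

    def test_unknown_element_rejected(self):
        s = atoms_from([("A", 1, "FE", "FE", (0, 0, 0))])
        with pytest.raises(ValueError, match="radius"):
            sg.sasa(s)


class TestInterface:
    def test_non_touching_chains_bury_nothing(self):
        helix = make_toy_structure("helix-dimer", n_res=10, offset=100.0)
        rep = sg.interface_report(helix, "A", "B")
        assert rep.buried_total == pytest.approx(0.0, abs=1e-6)

    def test_buried_area_matches_monte_carlo_oracle(self):
        """Total buried area on the overlapping helix dimer agrees with an
        independent random-direction sampler to 2%."""
        helix = make_toy_structure("helix-dimer", n_res=15, offset=5.0)
        rep = sg.interface_report(helix, "A", "B", n_points=2000)

        core = helix.without_solvent()
        a = core.select(chain="A").atoms.coord.astype(float)
        b = core.select(chain="B").atoms.coord.astype(float)
        radii_a = np.full(len(a), 1.70)
        radii_b = np.full(len(b), 1.70)
        mc = (monte_carlo_sasa(a, radii_a, 1.4, 20000, seed=0)
              + monte_carlo_sasa(b, radii_b, 1.4, 20000, seed=1)
              - monte_carlo_sasa(np.vstack([a, b]),
                                 np.full(len(a) + len(b), 1.70),
                                 1.4, 20000, seed=2))
        assert rep.buried_total == pytest.approx(mc, rel=0.02)

    def test_fraction_bookkeeping(self):
        helix = make_toy_structure("helix-dimer", n_res=12, offset=5.0)
        rep = sg.interface_report(helix, "A", "B")
        assert rep.buried_total == pytest.approx(
            rep.sasa_monomer_a + rep.sasa_monomer_b - rep.sasa_dimer, abs=1e-9
        )
        assert rep.buried_per_side == pytest.approx(rep.buried_total / 2)
        assert 0 <= rep.buried_fraction_of_monomer <= 100

    def test_missing_chain_rejected(self):
        helix = make_toy_structure("helix-dimer", n_res=5)
        with pytest.raises(ValueError, match="chain"):
            sg.interface_report(helix, "A", "Z")


class TestIO:
    def test_pdb_round_trip_counts_and_coords(self, tmp_path):
        s = make_toy_structure("helix-dimer", n_res=9)
        path = tmp_path / "toy.pdb"
        sg.write_structure(s, path)
        back = sg.read_structure(path)
        assert len(back) == len(s)
        assert np.allclose(back.atoms.coord, s.atoms.coord, atol=1e-3)

    def test_pdb_and_mmcif_agree(self, tmp_path):
        s = make_toy_structure("helix-dimer", n_res=9)
        sg.write_structure(s, tmp_path / "toy.pdb")
        sg.write_structure(s, tmp_path / "toy.cif")
        p = sg.read_structure(tmp_path / "toy.pdb")
        c = sg.read_structure(tmp_path / "toy.cif")
        assert len(p) == len(c)
        assert np.allclose(p.atoms.coord, c.atoms.coord, atol=1e-3)
        assert list(p.atoms.chain_id) == list(c.atoms.chain_id)

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        pdb_text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60 10.00           C\n"
            "ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.40 10.00           C\n"
            "END\n"
        )
        path = tmp_path / "alt.pdb"
        path.write_text(pdb_text)
        s = sg.read_structure(path)
        assert len(s) == 1
        assert s.atoms.coord[0][0] == pytest.approx(0.0)

    def test_unrecognised_format_rejected(self, tmp_path):
        p = tmp_path / "x.xyz"
        p.write_text("")
        with pytest.raises(ValueError, match="format"):
            sg.read_structure(p)

    def test_waters_stripped_by_default(self, tmp_path):
        pdb_text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C\n"
            "HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00 10.00           O\n"
            "END\n"
        )
        path = tmp_path / "wat.pdb"
        path.write_text(pdb_text)
        assert len(sg.read_structure(path)) == 1
        assert len(sg.read_structure(path, keep_waters=True)) == 2
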