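"""PDB I/O, Kabsch superposition, regional RMSD and clash scanning."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import hptkit as h
from hptkit.structure import select_atoms, vdw_radius

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  C   ALA A   1      12.685   7.143  -4.896  1.00 10.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.60 10.00           C
ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.40 10.00           C
END
"""

MULTIMODEL_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       9.000   9.000   9.000  1.00 10.00           C
ENDMDL
END
"""


def rigid(coords, seed=0, angle_deg=None):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng) if angle_deg is None else Rotation.from_euler(
        "xyz", [angle_deg, 0, 0], degrees=True
    )
    return coords @ rot.as_matrix().T + rng.uniform(-15, 15, 3)


def carbon(serial, resseq, xyz, chain="A", name="CA"):
    return h.Atom(serial=serial, name=name, altloc="", resname="ALA",
                  chain=chain, resseq=resseq, icode="", xyz=np.asarray(xyz),
                  element="C")


class TestReadPdb:
    def test_minimal_file(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        model = h.read_pdb(p)
        assert model.n_atoms == 3
        ca = model.get("A", 1, "CA")
        assert ca is not None
        assert ca.xyz == pytest.approx([11.639, 6.071, -5.147])
        assert ca.element == "C" and not ca.is_hetero

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        model = h.read_pdb(p)
        assert model.n_atoms == 1
        assert model.get("A", 1, "CA").xyz[0] == pytest.approx(1.0)

    def test_first_model_only(self, tmp_path):
        p = tmp_path / "nmr.pdb"
        p.write_text(MULTIMODEL_PDB)
        model = h.read_pdb(p)
        assert model.n_atoms == 1
        assert model.get("A", 1, "CA").xyz[0] == pytest.approx(0.0)

    def test_round_trip_write_read(self, tmp_path):
        base, _, _ = h.generate_structure_pair(h.StructureDesign(seed=1))
        p = tmp_path / "rt.pdb"
        h.write_pdb(base, p)
        back = h.read_pdb(p)
        assert back.n_atoms == base.n_atoms
        for a, b in zip(base.atoms, back.atoms):
            assert a.key == b.key
            assert a.xyz == pytest.approx(b.xyz, abs=1e-3)  # PDB precision


class TestMatchAtoms:
    def test_identical_structures_pair_every_residue(self):
        base, _, _ = h.generate_structure_pair(h.StructureDesign(seed=0))
        P, Q, keys = h.match_atoms(base, base, "CA")
        assert len(keys) == base.n_atoms
        assert np.allclose(P, Q)

    def test_intersection_of_residue_ranges(self):
        a = h.StructureModel([carbon(i, i, [i, 0, 0]) for i in range(1, 11)])
        b = h.StructureModel([carbon(i, i, [i, 0, 0]) for i in range(3, 15)])
        _, _, keys = h.match_atoms(a, b, "CA")
        assert [k[1] for k in keys] == list(range(3, 11))

    def test_chain_map_equivalence(self):
        a = h.StructureModel([carbon(i, i, [i, 1, 0], chain="X") for i in range(1, 6)])
        b = h.StructureModel([carbon(i, i, [i, 1, 0], chain="B") for i in range(1, 6)])
        P, Q, keys = h.match_atoms(a, b, "CA", chain_map={"X": "B"})
        assert len(keys) == 5
        with pytest.raises(ValueError, match="no common atoms"):
            h.match_atoms(a, b, "CA")


class TestKabsch:
    def test_self_superposition_is_identity(self):
        P = np.random.default_rng(0).normal(size=(10, 3))
        sup = h.kabsch_superpose(P, P)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert sup.rotation == pytest.approx(np.eye(3), abs=1e-12)

    def test_recovers_random_rigid_transform(self):
        P = np.random.default_rng(1).normal(size=(10, 3)) * 5
        Q = rigid(P, seed=42)
        sup = h.kabsch_superpose(P, Q)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)
        assert sup.apply(P) == pytest.approx(Q)

    def test_beats_rotation_grid_oracle(self):
        """Kabsch optimum must not exceed any grid-searched rotation."""
        P = np.array([[0, 0, 0], [3, 0, 0], [0, 2, 0], [1, 1, 2]], dtype=float)
        Q = rigid(P, seed=7) + np.random.default_rng(7).normal(0, 0.3, P.shape)
        sup = h.kabsch_superpose(P, Q)
        Pc, Qc = P - P.mean(0), Q - Q.mean(0)
        step = 15
        best = np.inf
        for ex, ey, ez in itertools.product(
            range(0, 360, step), range(0, 180, step), range(0, 360, step)
        ):
            R = Rotation.from_euler("zyz", [ex, ey, ez], degrees=True).as_matrix()
            r = np.sqrt(((Pc @ R.T - Qc) ** 2).sum() / len(P))
            best = min(best, r)
        assert sup.rmsd <= best + 1e-12

    def test_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(5)
        P = rng.normal(size=(20, 3)) * 4
        Q = rigid(P, seed=9) + rng.normal(0, 0.5, P.shape)
        sup = h.kabsch_superpose(P, Q)
        rot, rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        assert sup.rmsd == pytest.approx(rssd / np.sqrt(len(P)), rel=1e-6)
        assert sup.rotation == pytest.approx(rot.as_matrix(), abs=1e-6)

    def test_rigid_invariance_of_rmsd(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(15, 3)) * 3
        Q = P + rng.normal(0, 0.4, P.shape)
        r0 = h.kabsch_superpose(P, Q).rmsd
        r1 = h.kabsch_superpose(rigid(P, seed=11), rigid(Q, seed=12)).rmsd
        assert r1 == pytest.approx(r0, abs=1e-8)

    def test_collinear_configuration_rejected(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="degenerate"):
            h.kabsch_superpose(P, rigid(P, seed=1))

    def test_mirror_not_used(self):
        """A reflected point set must not superpose to zero RMSD."""
        P = np.random.default_rng(2).normal(size=(10, 3)) * 3
        Q = P * np.array([-1.0, 1.0, 1.0])  # mirror image
        sup = h.kabsch_superpose(P, Q)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)
        assert sup.rmsd > 0.1


class TestRegionRmsd:
    def test_identical_structures_zero_in_both_modes(self):
        base, _, _ = h.generate_structure_pair(h.StructureDesign(seed=2))
        region = h.RegionSpec("A", [(11, 21)])
        for mode in ("global_frame", "local_fit"):
            assert h.region_rmsd(base, base, region, mode) == pytest.approx(0.0, abs=1e-12)

    def test_displaced_region_local_zero_global_equals_offset(self):
        d = h.StructureDesign(
            n_residues=800,
            displacements={"shifted": ((101, 106), 1.7)},
            noise_sd=0.0, seed=4,
        )
        base, partner, truth = h.generate_structure_pair(d)
        region = h.RegionSpec("A", [(101, 106)])
        assert h.region_rmsd(partner, base, region, "local_fit") == pytest.approx(0.0, abs=1e-9)
        got = h.region_rmsd(partner, base, region, "global_frame")
        assert got == pytest.approx(1.7, rel=0.05)

    def test_full_region_matches_overall_superposition(self):
        base, partner, _ = h.generate_structure_pair(h.StructureDesign(seed=6))
        n = base.n_atoms
        region = h.RegionSpec("A", [(1, n)])
        P, Q, _ = h.match_atoms(partner, base, "CA")
        overall = h.kabsch_superpose(P, Q).rmsd
        assert h.region_rmsd(partner, base, region, "global_frame") == pytest.approx(overall)

    def test_local_fit_never_exceeds_global_frame(self):
        base, partner, _ = h.generate_structure_pair(
            h.StructureDesign(seed=8, displacements={"a": ((31, 45), 1.2)})
        )
        for span in [(31, 45), (5, 25), (60, 100)]:
            region = h.RegionSpec("A", [span])
            local = h.region_rmsd(partner, base, region, "local_fit")
            glob = h.region_rmsd(partner, base, region, "global_frame")
            assert local <= glob + 1e-9


class TestClashScan:
    def _model(self, atoms):
        return h.StructureModel(atoms)

    def test_distant_atoms_no_clash(self):
        a = self._model([carbon(1, 1, [0, 0, 0])])
        b = self._model([carbon(1, 1, [10, 0, 0], chain="B")])
        pairs = h.clash_scan(a, h.RegionSpec("A", [(1, 1)], "heavy"),
                             b, h.RegionSpec("B", [(1, 1)], "heavy"))
        assert pairs == []

    def test_two_carbons_at_two_angstroms(self):
        """Overlap = 1.70 + 1.70 - 2.0 = 1.4 Å."""
        a = self._model([carbon(1, 1, [0, 0, 0])])
        b = self._model([carbon(1, 1, [2.0, 0, 0], chain="B")])
        pairs = h.clash_scan(a, h.RegionSpec("A", [(1, 1)], "heavy"),
                             b, h.RegionSpec("B", [(1, 1)], "heavy"),
                             overlap_threshold=0.4)
        assert len(pairs) == 1
        assert pairs[0].overlap == pytest.approx(1.4)
        assert pairs[0].distance == pytest.approx(2.0)

    def test_matches_brute_force_oracle_on_random_selections(self, rng):
        elements = ["C", "N", "O", "S"]
        def random_model(chain, n=50):
            atoms = []
            for i in range(n):
                el = elements[int(rng.integers(4))]
                atoms.append(h.Atom(
                    serial=i + 1, name=f"{el}{i}", altloc="", resname="UNK",
                    chain=chain, resseq=i + 1, icode="",
                    xyz=rng.uniform(0, 12, 3), element=el,
                ))
            return self._model(atoms)

        a, b = random_model("A"), random_model("B")
        sel_a = h.RegionSpec("A", [(1, 50)], "heavy")
        sel_b = h.RegionSpec("B", [(1, 50)], "heavy")
        pairs = h.clash_scan(a, sel_a, b, sel_b, overlap_threshold=0.4)
        expected = set()
        for x in a.atoms:
            for y in b.atoms:
                d = float(np.linalg.norm(x.xyz - y.xyz))
                if vdw_radius(x.element) + vdw_radius(y.element) - d > 0.4:
                    expected.add((x.ident, y.ident))
        assert {(p.atom_a, p.atom_b) for p in pairs} == expected
        overlaps = [p.overlap for p in pairs]
        assert overlaps == sorted(overlaps, reverse=True)

    def test_symmetry_in_selections(self, rng):
        atoms_a = [carbon(i, i, rng.uniform(0, 6, 3)) for i in range(1, 15)]
        atoms_b = [carbon(i, i, rng.uniform(0, 6, 3), chain="B") for i in range(1, 15)]
        a, b = self._model(atoms_a), self._model(atoms_b)
        sa = h.RegionSpec("A", [(1, 14)], "heavy")
        sb = h.RegionSpec("B", [(1, 14)], "heavy")
        fwd = {(p.atom_a, p.atom_b) for p in h.clash_scan(a, sa, b, sb)}
        rev = {(p.atom_b, p.atom_a) for p in h.clash_scan(b, sb, a, sa)}
        assert fwd == rev

    def test_hydrogens_excluded_by_default(self):
        ha = h.Atom(serial=1, name="H1", altloc="", resname="UNK", chain="A",
                    resseq=1, icode="", xyz=np.zeros(3), element="H")
        cb = carbon(1, 1, [1.0, 0, 0], chain="B")
        a, b = self._model([ha, carbon(2, 2, [50, 0, 0])]), self._model([cb])
        pairs = h.clash_scan(a, h.RegionSpec("A", [(1, 2)], "heavy"),
                             b, h.RegionSpec("B", [(1, 1)], "heavy"))
        assert pairs == []

    def test_empty_selection_rejected(self):
        a = self._model([carbon(1, 1, [0, 0, 0])])
        with pytest.raises(ValueError, match="empty"):
            h.clash_scan(a, h.RegionSpec("A", [(5, 6)], "heavy"),
                         a, h.RegionSpec("A", [(1, 1)], "heavy"))


def test_selection_filters():
    atoms = [
        carbon(1, 1, [0, 0, 0], name="CA"),
        carbon(2, 1, [1, 0, 0], name="CB"),
        h.Atom(serial=3, name="N", altloc="", resname="ALA", chain="A",
               resseq=1, icode="", xyz=np.array([2.0, 0, 0]), element="N"),
        h.Atom(serial=4, name="O", altloc="", resname="HOH", chain="A",
               resseq=99, icode="", xyz=np.array([3.0, 0, 0]), element="O",
               is_hetero=True),
    ]
    m = h.StructureModel(atoms)
    assert [a.name for a in select_atoms(m, "CA")] == ["CA"]
    assert [a.name for a in select_atoms(m, "backbone")] == ["CA", "N"]
    assert len(select_atoms(m, "heavy")) == 3  # water/het excluded
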