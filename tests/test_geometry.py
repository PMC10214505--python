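"""Structure parsing, contacts, interfaces, SASA/BSA and superposition."""

import math

import numpy as np
import pytest

from dualbind import geometry as geo

THREE_ATOM_PDB = """\
ATOM      1  CA  ALA R   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  N   ALA R   1       1.500   0.000   0.000  1.00  0.00           N
ATOM      3  O   GLY L   2       4.900   0.000   0.000  1.00  0.00           O
END
"""


def atom(x, y, z, element="C", chain="R", resnum=1, serial=1, name=None):
    return geo.AtomRecord(
        serial=serial, name=name or element, element=element, chain=chain,
        resnum=resnum, icode="", resname="ALA", coords=(x, y, z),
        side_tag=chain if chain in "RLS" else "other",
        radius=geo.assign_radius(element),
    )


class TestRadii:
    @pytest.mark.parametrize("element,expected", [
        ("H", 1.2), ("C", 1.7), ("N", 1.55), ("O", 1.52),
        ("F", 1.47), ("B", 1.92), ("P", 1.8), ("S", 1.8),
    ])
    def test_tabulated_values(self, element, expected):
        assert geo.assign_radius(element) == expected

    def test_chlorine_default_is_physical(self):
        assert geo.assign_radius("Cl") == 1.75
        assert geo.assign_radius("Cl", literal_chlorine=True) == 0.2

    def test_unknown_element_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="X"):
            assert geo.assign_radius("X", default=1.7) == 1.7
        with pytest.raises(KeyError):
            geo.assign_radius("X", strict=True)


class TestReadStructure:
    def test_three_atom_fixture(self, tmp_path):
        p = tmp_path / "tiny.pdb"
        p.write_text(THREE_ATOM_PDB)
        atoms = geo.read_structure(p, {"R": "R", "L": "L"})
        assert [a.element for a in atoms] == ["C", "N", "O"]
        assert [a.side_tag for a in atoms] == ["R", "R", "L"]
        assert atoms[0].radius == 1.7

    def test_element_inferred_from_atom_name_when_column_blank(self, tmp_path):
        p = tmp_path / "noelem.pdb"
        p.write_text("ATOM      1  CA  ALA R   1       0.000   0.000   0.000"
                     "  1.00  0.00\nEND\n")
        atoms = geo.read_structure(p, {"R": "R"})
        assert atoms[0].element == "C"

    def test_unmapped_chain_is_an_error(self, tmp_path):
        p = tmp_path / "tiny.pdb"
        p.write_text(THREE_ATOM_PDB)
        with pytest.raises(KeyError, match="L"):
            geo.read_structure(p, {"R": "R"})

    def test_missing_file_is_an_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            geo.read_structure(tmp_path / "nope.pdb", {})

    def test_fixture_side_tags_match_generator_plan(self, toy_complex):
        tags = {a.side_tag for a in toy_complex["atoms"]}
        assert tags == {"R", "L", "S"}


class TestContacts:
    def test_coincident_centers_touch(self):
        a = atom(0, 0, 0, "H")
        p = geo.ProbeRecord((0, 0, 0), 3.0, "polar", 1)
        assert geo.in_contact(a, p)

    def test_just_outside_radius_sum(self):
        a = atom(0, 0, 0, "H")  # 1.2 A
        p = geo.ProbeRecord((4.3, 0, 0), 3.0, "polar", 1)
        assert not geo.in_contact(a, p)  # 4.3 > 4.2

    def test_agrees_with_direct_distance_on_random_pairs(self):
        rng = np.random.default_rng(6)
        elements = ["H", "C", "N", "O", "S"]
        for _ in range(1000):
            a = atom(*rng.uniform(-3, 3, 3), element=elements[rng.integers(5)])
            p = geo.ProbeRecord(tuple(rng.uniform(-3, 3, 3)),
                                float(rng.uniform(0.2, 3.0)), "apolar", 1)
            expected = math.dist(a.coords, p.center) < a.radius + p.radius
            assert geo.in_contact(a, p) == expected

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(7)
        rot = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(rot) < 0:
            rot[:, 0] *= -1
        shift = rng.normal(size=3)
        for _ in range(50):
            ax, px = rng.uniform(-3, 3, 3), rng.uniform(-3, 3, 3)
            a1 = atom(*ax)
            p1 = geo.ProbeRecord(tuple(px), 1.0, "polar", 1)
            a2 = atom(*(rot @ ax + shift))
            p2 = geo.ProbeRecord(tuple(rot @ px + shift), 1.0, "polar", 1)
            assert geo.in_contact(a1, p1) == geo.in_contact(a2, p2)


class TestInterfaceResidues:
    def test_pair_within_cutoff(self):
        r = [atom(0, 0, 0, chain="R", resnum=1)]
        l = [atom(4.9, 0, 0, chain="L", resnum=9)]
        rs, ls = geo.interface_residues(r, l)
        assert rs == {("R", 1, "")} and ls == {("L", 9, "")}

    def test_pair_beyond_cutoff(self):
        r = [atom(0, 0, 0, chain="R")]
        l = [atom(5.1, 0, 0, chain="L")]
        rs, ls = geo.interface_residues(r, l)
        assert rs == set() and ls == set()

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            geo.interface_residues([], [atom(0, 0, 0)])

    def test_matches_all_pairs_double_loop(self):
        rng = np.random.default_rng(8)
        r = [atom(*rng.uniform(0, 30, 3), chain="R", resnum=i // 3, serial=i)
             for i in range(100)]
        l = [atom(*rng.uniform(0, 30, 3), chain="L", resnum=i // 3, serial=i)
             for i in range(100)]
        rs, ls = geo.interface_residues(r, l, cutoff=5.0)
        brute_r, brute_l = set(), set()
        for a in r:
            for b in l:
                if math.dist(a.coords, b.coords) <= 5.0:
                    brute_r.add(a.residue_id)
                    brute_l.add(b.residue_id)
        assert rs == brute_r and ls == brute_l

    def test_toy_complex_recovers_planted_interface(self, toy_complex):
        atoms = toy_complex["atoms"]
        r = [a for a in atoms if a.side_tag == "R"]
        l = [a for a in atoms if a.side_tag == "L"]
        rs, ls = geo.interface_residues(r, l)
        planted_r = set(toy_complex["manifest"]["interface_residues_r"])
        planted_l = set(toy_complex["manifest"]["interface_residues_l"])
        assert {rid[1] for rid in rs} == planted_r
        assert {rid[1] for rid in ls} == planted_l


class TestSasa:
    def test_isolated_sphere_matches_analytic_area(self):
        total, _ = geo.sasa([atom(0, 0, 0, "C")], probe_radius=1.4, n_points=960)
        assert total == pytest.approx(4 * math.pi * (1.7 + 1.4) ** 2, rel=0.02)

    def test_distant_atoms_are_additive(self):
        a, b = atom(0, 0, 0, "C"), atom(100, 0, 0, "O", serial=2)
        total, per_atom = geo.sasa([a, b])
        lone = geo.sasa([a])[0] + geo.sasa([b])[0]
        assert total == pytest.approx(lone, rel=1e-9)
        assert per_atom.sum() == pytest.approx(total)

    def test_overlapping_pair_matches_high_density_oracle(self):
        pair = [atom(0, 0, 0, "C"), atom(2.0, 0, 0, "C", serial=2)]
        coarse = geo.sasa(pair, n_points=960)[0]
        fine = geo.sasa(pair, n_points=10_000)[0]
        assert coarse == pytest.approx(fine, rel=0.01)

    def test_burial_is_monotone_in_added_atoms(self):
        rng = np.random.default_rng(9)
        base = [atom(*rng.uniform(0, 8, 3), serial=i) for i in range(10)]
        extra = [atom(*rng.uniform(0, 8, 3), serial=100 + i) for i in range(5)]
        base_total, per_base = geo.sasa(base)
        _, per_all = geo.sasa(base + extra)
        assert (per_all[:10] <= per_base + 1e-9).all()

    def test_hydrogens_excluded_by_default(self):
        heavy = atom(0, 0, 0, "C")
        h = atom(1.0, 0, 0, "H", serial=2)
        with_h = geo.sasa([heavy, h])[0]
        assert with_h == pytest.approx(geo.sasa([heavy])[0])
        assert geo.sasa([heavy, h], include_hydrogens=True)[0] != pytest.approx(with_h)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            geo.sasa([atom(0, 0, 0)], n_points=8)


class TestBuriedSurface:
    def make_sides(self, s_shift=(0.0, 0.0, 0.0)):
        r = [atom(0, 0, 0, "C", chain="R"), atom(3, 0, 0, "C", chain="R", serial=2)]
        l = [atom(10, 0, 0, "C", chain="L"), atom(13, 0, 0, "C", chain="L", serial=2)]
        s = [atom(6.5 + s_shift[0], s_shift[1], s_shift[2], "C", chain="S")]
        return r, l, s

    def test_distant_stabilizer_buries_nothing(self):
        r, l, _ = self.make_sides()
        s = [atom(500, 0, 0, "C", chain="S")]
        rep = geo.buried_surface(r, l, s)
        assert rep.bsa_rs == pytest.approx(0.0, abs=1e-6)
        assert rep.bsa_ls == pytest.approx(0.0, abs=1e-6)

    def test_receptor_only_contact_gives_zero_ratio(self):
        r = [atom(0, 0, 0, "C", chain="R")]
        l = [atom(50, 0, 0, "C", chain="L")]
        s = [atom(2.5, 0, 0, "C", chain="S")]
        rep = geo.buried_surface(r, l, s)
        assert rep.bsa_rs > 1.0
        assert rep.ratio == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_geometry_gives_unit_ratio(self):
        r = [atom(-3, 0, 0, "C", chain="R")]
        l = [atom(3, 0, 0, "C", chain="L")]
        s = [atom(0, 0, 0, "C", chain="S")]
        rep = geo.buried_surface(r, l, s)
        assert rep.ratio == pytest.approx(1.0, rel=0.02)

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(10)
        rot = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(rot) < 0:
            rot[:, 0] *= -1
        shift = np.array([5.0, -3.0, 11.0])
        r, l, s = self.make_sides()
        rep1 = geo.buried_surface(r, l, s)

        def move(atoms):
            out = []
            for a in atoms:
                x = rot @ np.array(a.coords) + shift
                out.append(atom(*x, element=a.element, chain=a.chain,
                                resnum=a.resnum, serial=a.serial))
            return out

        rep2 = geo.buried_surface(move(r), move(l), move(s))
        assert rep2.bsa_rs == pytest.approx(rep1.bsa_rs, abs=0.5)
        assert rep2.bsa_ls == pytest.approx(rep1.bsa_ls, abs=0.5)

    def test_empty_stabilizer_rejected(self):
        r, l, _ = self.make_sides()
        with pytest.raises(ValueError):
            geo.buried_surface(r, l, [])


class TestSuperposition:
    def test_identical_sets(self):
        xyz = np.random.default_rng(11).normal(size=(10, 3))
        res = geo.superpose(xyz, xyz)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_pure_translation_has_zero_rmsd(self):
        xyz = np.random.default_rng(12).normal(size=(8, 3))
        res = geo.superpose(xyz + np.array([3.0, -1.0, 7.0]), xyz)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(13)
        mob = rng.normal(size=(20, 3))
        ref = rng.normal(size=(20, 3))
        res = geo.superpose(mob, ref)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_planted_noise_rmsd_matches_direct_formula(self):
        rng = np.random.default_rng(14)
        ref = rng.normal(size=(50, 3)) * 10
        noise = rng.normal(scale=0.3, size=(50, 3))
        rot = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(rot) < 0:
            rot[:, 0] *= -1
        mob = (ref + noise) @ rot.T + np.array([4.0, 5.0, 6.0])
        res = geo.superpose(mob, ref)
        direct = math.sqrt((noise ** 2).sum() / 50)
        # superposition can only reduce the apparent deviation
        assert res.rmsd <= direct + 1e-9
        assert res.rmsd == pytest.approx(direct, rel=0.05)

    def test_superposed_rmsd_never_exceeds_raw(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            mob = rng.normal(size=(12, 3))
            ref = rng.normal(size=(12, 3))
            raw = math.sqrt(((mob - ref) ** 2).sum() / 12)
            assert geo.superpose(mob, ref).rmsd <= raw + 1e-12

    def test_degenerate_inputs_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            geo.superpose(line, line)
        with pytest.raises(ValueError):
            geo.superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestIrmsdSeries:
    def frames_from(self, reference, transforms):
        out = []
        for rot, shift in transforms:
            frame = []
            for a in reference:
                x = rot @ np.array(a.coords) + shift
                frame.append(atom(*x, element=a.element, chain=a.chain,
                                  resnum=a.resnum, serial=a.serial))
            out.append(frame)
        return out

    def reference(self):
        rng = np.random.default_rng(16)
        return [atom(*rng.uniform(0, 10, 3), element="C", chain="R",
                     resnum=i // 2 + 1, serial=i) for i in range(12)]

    def test_identical_frames_give_zeros(self):
        ref = self.reference()
        iface = {a.residue_id for a in ref}
        frames = [ref, ref]
        series = geo.irmsd_series(frames, ref, iface)
        np.testing.assert_allclose(series, 0.0, atol=1e-10)

    def test_rigid_rotation_gives_zeros(self):
        ref = self.reference()
        iface = {a.residue_id for a in ref}
        rng = np.random.default_rng(17)
        rot = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(rot) < 0:
            rot[:, 0] *= -1
        frames = self.frames_from(ref, [(rot, np.array([1.0, 2.0, 3.0]))])
        series = geo.irmsd_series(frames, ref, iface)
        np.testing.assert_allclose(series, 0.0, atol=1e-9)

    def test_planted_linear_drift_is_monotone(self):
        ref = self.reference()
        iface = {a.residue_id for a in ref}
        rng = np.random.default_rng(18)
        direction = rng.normal(size=(12, 3))
        direction -= direction.mean(axis=0)  # not a pure translation
        frames = []
        for k in range(1, 6):
            frame = [atom(*(np.array(a.coords) + 0.1 * k * direction[i]),
                          element=a.element, chain=a.chain, resnum=a.resnum,
                          serial=a.serial)
                     for i, a in enumerate(ref)]
            frames.append(frame)
        series = geo.irmsd_series(frames, ref, iface)
        assert (np.diff(series) > 0).all()

    def test_atom_mismatch_names_the_frame(self):
        ref = self.reference()
        iface = {a.residue_id for a in ref}
        with pytest.raises(ValueError, match="frame 0"):
            geo.irmsd_series([ref[:-1]], ref, iface)
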