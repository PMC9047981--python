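"""Toy generators, quadrature oracles and closed-form references."""

import numpy as np
import pytest

from smdcycle.constants import kbt
from smdcycle.errors import EstimationError, GeometryError
from smdcycle.synthetic import (OracleResult, ToyDimerSpec,
                                exact_free_energy_1d,
                                free_energy_difference_1d,
                                harmonic_release_reference,
                                make_structure_fixture, make_toy_dimer,
                                toy_cycle_oracle, toy_interface_potential)

T = 298.0


class TestToyDimer:
    def test_deterministic_for_seed(self):
        a_sys, a_rs = make_toy_dimer(ToyDimerSpec(seed=4))
        b_sys, b_rs = make_toy_dimer(ToyDimerSpec(seed=4))
        np.testing.assert_array_equal(a_sys.positions, b_sys.positions)
        assert a_rs == b_rs

    def test_single_bead_monomers_accepted(self):
        system, rs = make_toy_dimer(ToyDimerSpec(n_beads=1))
        assert system.n_beads == 2
        assert rs.census() == 11  # point restraints collapse onto bead 0

    def test_default_restraint_census_is_eleven(self):
        _, rs = make_toy_dimer(ToyDimerSpec())
        assert rs.census() == 11
        assert len(rs.shape) == 2 and len(rs.planar) == 2 and len(rs.point) == 6

    def test_monomer_coms_start_on_axis(self):
        system, _ = make_toy_dimer(ToyDimerSpec())
        for g in (system.group(0), system.group(1)):
            com = system.positions[g].mean(axis=0)
            assert abs(com[1]) < 1e-9 and abs(com[2]) < 1e-9

    def test_invalid_spec_rejected(self):
        with pytest.raises(EstimationError):
            ToyDimerSpec(eps=-1.0)


class TestExactFreeEnergy1D:
    def test_flat_potential_equal_windows(self):
        x = np.linspace(0.0, 10.0, 2001)
        res = exact_free_energy_1d((x, np.zeros_like(x)), T, (1.0, 3.0),
                                   (6.0, 8.0))
        assert res.dF == pytest.approx(0.0, abs=1e-10)
        assert res.method == "quadrature"

    def test_square_well_closed_form(self):
        # U = -eps inside the bound window, 0 outside:
        # dF = -eps - kT ln(L_b / L_u) exactly
        eps = 20.0
        x = np.linspace(0.0, 10.0, 40001)
        U = np.where((x >= 1.0) & (x <= 3.0), -eps, 0.0)
        res = exact_free_energy_1d((x, U), T, (1.0, 3.0), (6.0, 10.0))
        expected = -eps - kbt(T) * np.log(2.0 / 4.0)
        assert res.dF == pytest.approx(expected, abs=2e-3)

    def test_harmonic_vs_flat_window_closed_form(self):
        k = 10.0
        sig = np.sqrt(kbt(T) / k)
        # grid chosen so the flat unbound window edges (15, 29) are on-grid
        x = np.linspace(-3.0, 30.0, 330001)
        U = np.where(x < 11 * sig, 0.5 * k * x ** 2, 0.0)
        L = 29.0 - 15.0
        res = exact_free_energy_1d((x, U), T, (-10 * sig, 10 * sig),
                                   (15.0, 29.0))
        expected = -kbt(T) * np.log(np.sqrt(2 * np.pi) * sig / L)
        assert res.dF == pytest.approx(expected, abs=1e-8)

    def test_standard_state_term(self):
        x = np.linspace(0.0, 10.0, 2001)
        res = exact_free_energy_1d((x, np.zeros_like(x)), T, (1.0, 3.0),
                                   (6.0, 8.0), standard_volume=2.0 * np.e)
        assert res.dF == pytest.approx(kbt(T), rel=1e-6)

    def test_coarse_grid_rejected(self):
        from smdcycle.errors import ResolutionError
        x = np.linspace(0, 10, 12)
        U = 40.0 * np.sin(x * 8) ** 2
        with pytest.raises(ResolutionError):
            exact_free_energy_1d((x, U), T, (0.0, 4.0), (6.0, 10.0))


class TestHarmonicRelease:
    def test_identity_release(self):
        assert harmonic_release_reference(50.0, 50.0, 1, T) == 0.0

    def test_release_to_half_kcal(self):
        val = harmonic_release_reference(50.0, 0.5, 1, T)
        assert val == pytest.approx(0.5 * kbt(T) * np.log(0.01), rel=1e-12)
        assert val == pytest.approx(-1.364, abs=2e-3)

    def test_dof_additivity(self):
        one = harmonic_release_reference(50.0, 0.5, 1, T)
        assert harmonic_release_reference(50.0, 0.5, 2, T) == pytest.approx(
            2 * one)

    def test_nonpositive_k_rejected(self):
        with pytest.raises(EstimationError):
            harmonic_release_reference(50.0, 0.0, 1, T)


class TestCycleOracle:
    def test_consistency_with_generic_difference(self):
        spec = ToyDimerSpec()
        res = toy_cycle_oracle(spec, 3.4, 0.5)
        x = np.linspace(2.25, 20.0, 40001)
        U = toy_interface_potential(spec, x)
        alt = free_energy_difference_1d(
            x, U + 0.25 * (x - 3.4) ** 2, U + 0.25 * (x - 9.0) ** 2, T)
        assert res.dF == pytest.approx(alt.dF, abs=5e-3)

    def test_deeper_well_binds_stronger(self):
        shallow = toy_cycle_oracle(ToyDimerSpec(eps=2.0), 3.4, 0.5)
        deep = toy_cycle_oracle(ToyDimerSpec(eps=4.0), 3.4, 0.5)
        assert deep.dF < shallow.dF

    def test_full_release_rejected(self):
        with pytest.raises(EstimationError):
            toy_cycle_oracle(ToyDimerSpec(), 3.4, 0.0)

    def test_negative_oracle_error_rejected(self):
        with pytest.raises(EstimationError):
            OracleResult(dF=0.0, error=-1.0)


class TestStructureFixtures:
    def test_pipi_geometry_planted_exactly(self):
        from smdcycle.interface import RING_DEFINITIONS, _ring_geometry

        s = make_structure_fixture("pi-pi", distance=4.0, angle_deg=20.0)
        model = next(s.get_models())
        coms = []
        for res in model.get_residues():
            com, _ = _ring_geometry(res, RING_DEFINITIONS["PHE"])
            coms.append(com)
        assert np.linalg.norm(coms[0] - coms[1]) == pytest.approx(4.0,
                                                                  abs=1e-3)

    def test_roundtrip_through_pdb_text(self):
        from smdcycle.io import read_pdb, write_pdb

        s = make_structure_fixture("pi-pi", distance=4.0, angle_deg=0.0)
        text = write_pdb(s)
        s2 = read_pdb(text)
        a = np.array([at.get_coord() for at in s.get_atoms()])
        b = np.array([at.get_coord() for at in s2.get_atoms()])
        np.testing.assert_allclose(a, b, atol=1e-3)

    def test_multi_frame_counts(self):
        s = make_structure_fixture("multi-frame", n_frames=10, occupancy=0.7)
        assert len(list(s.get_models())) == 10

    def test_impossible_geometry_rejected(self):
        with pytest.raises(GeometryError):
            make_structure_fixture("pi-pi", distance=-1.0)
        with pytest.raises(GeometryError):
            make_structure_fixture("warp-core")
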