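"""Langevin integrator and steered-run driver."""

import numpy as np
import pytest

from smdcycle.constants import kbt
from smdcycle.dynamics import SimState, run_equilibrium, run_smd, step_langevin
from smdcycle.errors import ConfigurationError, NumericalBlowupError
from smdcycle.jarzynski import jarzynski_estimate
from smdcycle.restraints import PointRestraint, RestraintSet, Schedule
from smdcycle.system import ToySystem, physical_energy_forces
from smdcycle.restraints import restraint_energy_forces


def pinned_bead(k=50.0):
    """One bead pinned in z (plus a far-away partner to satisfy the
    two-monomer invariant; it carries no force)."""
    system = ToySystem(positions=np.array([[0.0, 0, 0], [50.0, 0, 0]]),
                       masses=np.array([12.0, 12.0]),
                       monomer=np.array([0, 1]))
    rs = RestraintSet(point=[PointRestraint(bead=0, k=k, fix_y=False,
                                            fix_z=True, z0=0.0)])
    return system, rs


def test_zero_temperature_descent():
    """With T = 0 the thermostat only damps: restraint energy cannot grow."""
    system, rs = pinned_bead()
    x0 = system.positions.copy()
    x0[0, 2] = 0.5  # displaced in the pinned coordinate
    state = SimState(positions=x0, velocities=np.zeros_like(x0),
                     rng=np.random.default_rng(0))
    energies = []
    for _ in range(2000):
        e, _ = restraint_energy_forces(system, rs, state.positions)
        ke = 0.5 * np.sum(system.masses[:, None] * state.velocities ** 2) / 418.4
        energies.append(float(e) + float(ke))
        state = step_langevin(state, system, rs, dt=0.002, friction=5.0,
                              temperature=0.0)
    assert energies[-1] < 1e-3 * energies[0]
    # the dissipative descent never climbs (beyond integrator rounding)
    assert max(np.diff(energies)) <= 1e-3 * energies[0]


def test_equipartition_variance():
    """Position variance in a k = 50 harmonic well at 298 K approaches
    k_B T / k (equipartition), within 5%."""
    system, rs = pinned_bead(k=50.0)
    res = run_equilibrium(system, rs, dt=0.002, n_steps=100000, friction=2.0,
                          temperature=298.0, n_traj=16, seed=3,
                          frame_stride=20)
    var = res.frames[:, :, 0, 2].var()
    assert var == pytest.approx(kbt(298.0) / 50.0, rel=0.05)


def test_identical_seeds_identical_trajectories():
    system, rs = pinned_bead()
    sch = Schedule("force-constant", 50.0, -0.4, 100.0)
    a = run_smd(system, rs, sch, dt=0.002, friction=1.0, temperature=298.0,
                n_traj=3, seed=11, n_equil_steps=200)
    b = run_smd(system, rs, sch, dt=0.002, friction=1.0, temperature=298.0,
                n_traj=3, seed=11, n_equil_steps=200)
    np.testing.assert_array_equal(a.final_positions, b.final_positions)
    for ta, tb in zip(a.traces, b.traces):
        np.testing.assert_array_equal(ta.work, tb.work)


def test_trajectory_stream_independent_of_ensemble_size():
    """Trajectory i is bit-identical whether run alone or inside a larger
    ensemble (counter-based per-trajectory streams)."""
    system, rs = pinned_bead()
    sch = Schedule("force-constant", 50.0, -0.4, 50.0)
    big = run_smd(system, rs, sch, dt=0.002, friction=1.0, temperature=298.0,
                  n_traj=4, seed=7, n_equil_steps=100)
    solo = run_smd(system, rs, sch, dt=0.002, friction=1.0, temperature=298.0,
                   n_traj=1, seed=7, n_equil_steps=100)
    np.testing.assert_array_equal(big.traces[0].work, solo.traces[0].work)


def test_energy_conservation_without_thermostat(toy):
    """friction = 0, T = 0 reduces to velocity Verlet; total energy of the
    unscheduled toy is conserved to O(dt^2)."""
    system, restraints = toy
    rng = np.random.default_rng(2)
    v0 = rng.normal(0.0, 0.1, system.positions.shape)

    def total_energy(x, v):
        ep, _ = physical_energy_forces(system, x)
        er, _ = restraint_energy_forces(system, restraints, x)
        ke = 0.5 * np.sum(system.masses[:, None] * v * v) / 418.4
        return float(ep + er + ke)

    state = SimState(positions=system.positions.copy(), velocities=v0.copy(),
                     rng=rng)
    e0 = total_energy(state.positions, state.velocities)
    for _ in range(2000):
        state = step_langevin(state, system, restraints, dt=0.002,
                              friction=0.0, temperature=0.0)
    e1 = total_energy(state.positions, state.velocities)
    assert abs(e1 - e0) < 5e-4 * max(1.0, abs(e0))


def test_static_schedule_accumulates_no_work():
    system, rs = pinned_bead()
    from smdcycle.restraints import CVSpring
    sch = Schedule("center", 50.0, 0.0, 10.0)
    rs = RestraintSet(cv=CVSpring(k=50.0, center=50.0), point=rs.point)
    out = run_smd(system, rs, sch, dt=0.002, friction=1.0, temperature=298.0,
                  n_traj=2, seed=1)
    for t in out.traces:
        np.testing.assert_allclose(t.work, 0.0, atol=1e-12)


def test_instantaneous_force_constant_jump_matches_fep():
    """Equilibrate at k_old, jump the force constant instantaneously: the
    Jarzynski average of W = 0.5*(k_new - k_old)*z^2 must reproduce the
    free-energy perturbation closed form (1/2) k_B T ln(k_new/k_old)."""
    system, rs = pinned_bead(k=50.0)
    res = run_equilibrium(system, rs, dt=0.002, n_steps=60000, friction=2.0,
                          temperature=298.0, n_traj=8, seed=9, frame_stride=30)
    z = res.frames[:, :, 0, 2].ravel()
    k_old, k_new = 50.0, 100.0
    works = 0.5 * (k_new - k_old) * z ** 2
    est = jarzynski_estimate(works, 298.0)
    ref = 0.5 * kbt(298.0) * np.log(k_new / k_old)
    assert est == pytest.approx(ref, abs=0.03)


def test_schedule_step_mismatch_rejected():
    system, rs = pinned_bead()
    sch = Schedule("force-constant", 50.0, -0.4, 100.0)
    with pytest.raises(ConfigurationError):
        run_smd(system, rs, sch, dt=0.002, n_steps=1234)


def test_non_finite_forces_blow_up_loudly():
    system, rs = pinned_bead()
    bad = system.positions.copy()
    bad[0, 2] = np.nan  # the pinned coordinate feels the restraint force
    sch = Schedule("force-constant", 50.0, -0.4, 1.0)
    with pytest.raises(NumericalBlowupError):
        run_smd(system, rs, sch, dt=0.002, init_positions=bad, n_traj=1)


def test_work_additive_over_contiguous_segments():
    """Cumulative work at intermediate grid points equals the partial sums
    of the increments (additivity over contiguous time segments)."""
    system, rs = pinned_bead()
    sch = Schedule("force-constant", 50.0, -0.45, 100.0)
    out = run_smd(system, rs, sch, dt=0.002, friction=1.0, temperature=298.0,
                  n_traj=2, seed=4, n_equil_steps=500)
    for t in out.traces:
        inc = np.diff(t.work)
        np.testing.assert_allclose(t.work[1:], np.cumsum(inc), rtol=1e-12)
        assert t.work[0] == 0.0
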