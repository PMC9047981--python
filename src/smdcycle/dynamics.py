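"""Stochastic dynamics for toy dimers: a BAOAB Langevin integrator and the
steered-run driver that accumulates nonequilibrium work.

The integrator is the BAOAB splitting of Langevin dynamics (half kick, half
drift, Ornstein–Uhlenbeck velocity refresh, half drift, half kick).  With
zero friction and zero temperature it reduces to velocity Verlet.

Steering follows a discrete protocol: at each step the scheduled parameter
jumps from lambda_t to lambda_{t+dt} at frozen coordinates — accumulating
external work dW = V(r; lambda_{t+dt}) - V(r; lambda_t) — and the system is
then propagated one step at the new parameter value.  This discrete work is
exactly the quantity entering the Jarzynski average for the simulated Markov
chain; its dt->0 limit is the familiar integral of dV/dlambda * lambda_dot.

Randomness: each trajectory draws from its own generator seeded by
``(master_seed, trajectory_index)``, so any single trajectory is bit-for-bit
reproducible regardless of how many trajectories run alongside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import KB, KCAL_PER_MOL_IN_AMU_A2_PS2 as ACC
from .errors import ConfigurationError, NumericalBlowupError
from .jarzynski import WorkTrace
from .restraints import RestraintSet, Schedule, restraint_energy_forces
from .system import ToySystem, cv_com_distance_x, physical_energy_forces

__all__ = ["SimState", "step_langevin", "run_smd", "run_equilibrium", "SMDResult"]

_NOISE_CHUNK = 512


@dataclass
class SimState:
    """Instantaneous state of one trajectory (or a stacked ensemble)."""

    positions: np.ndarray
    velocities: np.ndarray
    time: float = 0.0
    work: float = 0.0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)


def _total_forces(system, restraints, positions, t, lam=None):
    e_p, f_p = physical_energy_forces(system, positions)
    if restraints is not None:
        e_r, f_r = restraint_energy_forces(system, restraints, positions, t, lam)
        e_p = e_p + e_r
        f_p = f_p + f_r
    if not np.all(np.isfinite(f_p)):
        bad = np.argwhere(~np.isfinite(f_p))
        bead = int(bad[0][-2]) if bad.size else -1
        raise NumericalBlowupError(f"non-finite force on bead {bead}")
    return e_p, f_p


def _baoab(positions, velocities, forces, masses, dt, friction, temperature,
           noise):
    """One BAOAB update at fixed restraint parameters; returns new (x, v) and
    expects ``forces`` at the input positions.  ``noise`` is standard normal
    with the shape of ``velocities``."""
    m = masses[:, None]
    v = velocities + 0.5 * dt * ACC * forces / m
    x = positions + 0.5 * dt * v
    if friction > 0:
        c1 = np.exp(-friction * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * ACC * KB * temperature / m)
        v = c1 * v + c2 * noise
    x = x + 0.5 * dt * v
    return x, v


def step_langevin(state: SimState, system: ToySystem,
                  restraints: RestraintSet | None, dt: float,
                  friction: float, temperature: float) -> SimState:
    """Advance one trajectory by a single BAOAB step (restraint parameters
    evaluated at the state's current time)."""
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    if friction < 0 or temperature < 0:
        raise ConfigurationError("friction and temperature must be >= 0")
    _, f = _total_forces(system, restraints, state.positions, state.time)
    noise = state.rng.standard_normal(state.velocities.shape) \
        if friction > 0 else np.zeros_like(state.velocities)
    x, v = _baoab(state.positions, state.velocities, f, system.masses,
                  dt, friction, temperature, noise)
    _, f2 = _total_forces(system, restraints, x, state.time + dt)
    v = v + 0.5 * dt * ACC * f2 / system.masses[:, None]
    return SimState(positions=x, velocities=v, time=state.time + dt,
                    work=state.work, rng=state.rng)


@dataclass
class SMDResult:
    """Output of a steered (or equilibrium) ensemble run."""

    traces: list                    # list[WorkTrace], one per trajectory
    lam_grid: np.ndarray            # recorded driven-coordinate grid
    final_positions: np.ndarray     # (n_traj, n_beads, 3)
    final_velocities: np.ndarray
    com_disp: np.ndarray | None = None   # (n_rec, n_traj, 3) COM(I)-COM(II)
    frames: np.ndarray | None = None     # (n_rec, n_traj, n_beads, 3)


def _work_jump(system, restraints, sch, positions, lam_old, lam_new,
               restr_energy_at_old):
    """Analytic V(r; lam_new) - V(r; lam_old) for the two steering modes."""
    if sch.driven == "center":
        k = restraints.cv.k
        xi = cv_com_distance_x(system, positions)
        return 0.5 * k * ((xi - lam_new) ** 2 - (xi - lam_old) ** 2)
    # force-constant ramp: V scales linearly in lambda
    return restr_energy_at_old * (lam_new - lam_old) / lam_old


def run_smd(system: ToySystem, restraints: RestraintSet,
            schedule: Schedule | None = None, *, dt: float,
            n_steps: int | None = None, friction: float = 1.0,
            temperature: float = 298.0, n_traj: int = 1, seed: int = 0,
            n_equil_steps: int = 0, record_stride: int | None = None,
            lambda_bin: float | None = None, frame_stride: int = 0,
            init_positions: np.ndarray | None = None) -> SMDResult:
    """Run an ensemble of steered trajectories and return their work traces.

    Each trajectory starts from the system coordinates (or
    ``init_positions``), draws Maxwell–Boltzmann velocities, equilibrates for
    ``n_equil_steps`` with the schedule frozen at lambda0, then steers for
    ``n_steps`` (defaulting to schedule.duration/dt, and required to match it
    otherwise).  Work is recorded on a uniform grid of the driven quantity:
    every ``record_stride`` steps, or at spacing ``lambda_bin`` in the driven
    coordinate (default 0.1 A for center schedules, 0.5 kcal mol^-1 A^-2 for
    force-constant ramps).
    """
    if schedule is None:
        schedule = restraints.schedule
    if schedule is None:
        raise ConfigurationError("run_smd needs a schedule (use run_equilibrium "
                                 "for unscheduled dynamics)")
    restraints = replace(restraints, schedule=schedule)
    steps_needed = int(round(schedule.duration / dt))
    if n_steps is None:
        n_steps = steps_needed
    elif abs(n_steps * dt - schedule.duration) > 1e-9 * max(1.0, schedule.duration):
        raise ConfigurationError(
            f"n_steps*dt = {n_steps * dt} does not match schedule duration "
            f"{schedule.duration}")
    if record_stride is None:
        if schedule.velocity == 0.0:
            record_stride = max(1, n_steps // 100)
        else:
            if lambda_bin is None:
                lambda_bin = 0.1 if schedule.driven == "center" else 0.5
            record_stride = max(1, round(lambda_bin / (abs(schedule.velocity) * dt)))
    record_stride = min(record_stride, n_steps)
    while n_steps % record_stride:
        record_stride -= 1

    x0 = system.positions if init_positions is None else np.asarray(init_positions)
    if x0.ndim == 2:
        x = np.broadcast_to(x0, (n_traj,) + x0.shape).copy()
    else:
        x = x0.copy()
    m = system.masses[:, None]
    rngs = [np.random.default_rng([int(seed), i]) for i in range(n_traj)]
    vscale = np.sqrt(ACC * KB * temperature / m)
    v = np.stack([vscale * r.standard_normal(x.shape[1:]) for r in rngs])

    def draw_noise(count):
        # (count, n_traj, n_beads, 3); per-trajectory streams
        return np.stack([r.standard_normal((count,) + x.shape[1:])
                         for r in rngs], axis=1)

    def loop(x, v, n, scheduled, work, records):
        t_sched = 0.0
        e_r, f_r = restraint_energy_forces(
            system, restraints, x, 0.0, lam=schedule.lambda0)
        _, f_p = physical_energy_forces(system, x)
        f = f_p + f_r
        done = 0
        rec_i = 0
        while done < n:
            chunk = min(_NOISE_CHUNK, n - done)
            noise = draw_noise(chunk) if friction > 0 else None
            for j in range(chunk):
                k_step = done + j
                lam_old = schedule.value(t_sched) if scheduled else schedule.lambda0
                if scheduled and k_step % record_stride == 0:
                    records["lam"][rec_i] = lam_old
                    records["work"][rec_i] = work
                    records["time"][rec_i] = t_sched
                    rec_i += 1
                if scheduled:
                    lam_new = schedule.value(t_sched + dt)
                    work = work + _work_jump(system, restraints, schedule,
                                             x, lam_old, lam_new, e_r)
                else:
                    lam_new = schedule.lambda0
                nj = noise[j] if noise is not None else np.zeros_like(v)
                xn, vh = _baoab(x, v, f, system.masses, dt, friction,
                                temperature, nj)
                e_r, f_r = restraint_energy_forces(system, restraints, xn,
                                                   0.0, lam=lam_new)
                _, f_p = physical_energy_forces(system, xn)
                f = f_p + f_r
                if not np.all(np.isfinite(f)):
                    bad = np.argwhere(~np.isfinite(f))
                    raise NumericalBlowupError(
                        f"non-finite force on bead {int(bad[0][-2])}")
                v = vh + 0.5 * dt * ACC * f / m
                x = xn
                if scheduled:
                    t_sched += dt
                if frame_stride and scheduled and (k_step + 1) % frame_stride == 0:
                    records["frames"].append(x.copy())
            done += chunk
        if scheduled:
            records["lam"][rec_i] = schedule.value(t_sched)
            records["work"][rec_i] = work
            records["time"][rec_i] = t_sched
        return x, v, work

    # equilibration at frozen lambda0
    if n_equil_steps:
        x, v, _ = loop(x, v, n_equil_steps, False, 0.0, None)

    n_rec = n_steps // record_stride + 1
    records = {
        "lam": np.zeros(n_rec),
        "work": np.zeros((n_rec, n_traj)),
        "time": np.zeros(n_rec),
        "frames": [],
    }
    work0 = np.zeros(n_traj)
    x, v, _ = loop(x, v, n_steps, True, work0, records)

    traces = [WorkTrace(traj_id=i, time=records["time"],
                        lam=records["lam"], work=records["work"][:, i])
              for i in range(n_traj)]
    frames = np.stack(records["frames"]) if records["frames"] else None
    com = None
    if frames is not None:
        g0, g1 = system.group(0), system.group(1)
        w0 = system.masses[g0] / system.masses[g0].sum()
        w1 = system.masses[g1] / system.masses[g1].sum()
        com = (np.einsum("fnij,i->fnj", frames[:, :, g0, :], w0)
               - np.einsum("fnij,i->fnj", frames[:, :, g1, :], w1))
    return SMDResult(traces=traces, lam_grid=records["lam"],
                     final_positions=x, final_velocities=v,
                     com_disp=com, frames=frames)


def run_equilibrium(system: ToySystem, restraints: RestraintSet | None, *,
                    dt: float, n_steps: int, friction: float = 1.0,
                    temperature: float = 298.0, n_traj: int = 1, seed: int = 0,
                    frame_stride: int = 10,
                    init_positions: np.ndarray | None = None) -> SMDResult:
    """Unscheduled ensemble dynamics; records frames and COM displacement
    vectors every ``frame_stride`` steps.  Work is identically zero."""
    x0 = system.positions if init_positions is None else np.asarray(init_positions)
    if x0.ndim == 2:
        x = np.broadcast_to(x0, (n_traj,) + x0.shape).copy()
    else:
        x = x0.copy()
    m = system.masses[:, None]
    rngs = [np.random.default_rng([int(seed), i]) for i in range(n_traj)]
    vscale = np.sqrt(ACC * KB * temperature / m)
    v = np.stack([vscale * r.standard_normal(x.shape[1:]) for r in rngs])

    frames = []
    _, f_p = physical_energy_forces(system, x)
    if restraints is not None:
        _, f_r = restraint_energy_forces(system, restraints, x, 0.0)
        f = f_p + f_r
    else:
        f = f_p
    done = 0
    while done < n_steps:
        chunk = min(_NOISE_CHUNK, n_steps - done)
        if friction > 0:
            noise = np.stack([r.standard_normal((chunk,) + x.shape[1:])
                              for r in rngs], axis=1)
        else:
            noise = None
        for j in range(chunk):
            nj = noise[j] if noise is not None else np.zeros_like(v)
            xn, vh = _baoab(x, v, f, system.masses, dt, friction, temperature, nj)
            _, f_p = physical_energy_forces(system, xn)
            if restraints is not None:
                _, f_r = restraint_energy_forces(system, restraints, xn, 0.0)
                f = f_p + f_r
            else:
                f = f_p
            if not np.all(np.isfinite(f)):
                bad = np.argwhere(~np.isfinite(f))
                raise NumericalBlowupError(
                    f"non-finite force on bead {int(bad[0][-2])}")
            v = vh + 0.5 * dt * ACC * f / m
            x = xn
            if (done + j + 1) % frame_stride == 0:
                frames.append(x.copy())
        done += chunk

    frames = np.stack(frames) if frames else None
    com = None
    if frames is not None:
        g0, g1 = system.group(0), system.group(1)
        w0 = system.masses[g0] / system.masses[g0].sum()
        w1 = system.masses[g1] / system.masses[g1].sum()
        com = (np.einsum("fnij,i->fnj", frames[:, :, g0, :], w0)
               - np.einsum("fnij,i->fnj", frames[:, :, g1, :], w1))
    return SMDResult(traces=[], lam_grid=np.zeros(0), final_positions=x,
                     final_velocities=v, com_disp=com, frames=frames)
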