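"""End-to-end toy thermodynamic cycle.

Runs the three steered processes on a toy dimer —

* A: release every restraint force constant (50 -> k_end) in the unbound
  state;
* B: pull the CV-spring center from the unbound distance to just past the
  interface minimum with all restraints stiff, and read the bound free
  energy off the profile minimum;
* C: release the restraints in the bound state, centered at the profile
  minimum —

estimates each stage free energy with the Jarzynski equality, measures the
standard-state and rotational-restriction correction inputs from weakly
restrained equilibrium runs of the two released end states, and assembles
the cycle.  The exact quadrature oracle for the same pair of end states
(:func:`smdcycle.synthetic.toy_cycle_oracle`) provides the closure check.

The ``tier`` argument scales every steering speed: tier=1 is the converged
(slow) tier; tier=10 and tier=100 drive the same protocols 10x and 100x
faster for convergence studies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cycle import (CorrectionInputs, CycleComponents, CycleResult,
                    assemble_cycle, measure_correction_inputs,
                    rotational_correction, standard_state_correction)
from .dynamics import SMDResult, run_equilibrium, run_smd
from .jarzynski import (FreeEnergyProfile, bootstrap_error, build_profile,
                        jarzynski_estimate, profile_minimum)
from .restraints import CVSpring, RestraintSet, Schedule
from .synthetic import OracleResult, ToyDimerSpec, make_toy_dimer, toy_cycle_oracle

__all__ = ["ToyCycleOutcome", "run_toy_cycle", "scale_restraints",
           "shift_to_distance"]


def scale_restraints(restraints: RestraintSet, factor: float) -> RestraintSet:
    """A new restraint set with every force constant multiplied by ``factor``."""
    new = RestraintSet(
        cv=None if restraints.cv is None else
        replace(restraints.cv, k=restraints.cv.k * factor),
        shape=[replace(r, k=r.k * factor) for r in restraints.shape],
        planar=[replace(r, k=r.k * factor) for r in restraints.planar],
        point=[replace(r, k=r.k * factor) for r in restraints.point],
        flat_bottom=None if restraints.flat_bottom is None else
        replace(restraints.flat_bottom, k=restraints.flat_bottom.k * factor),
        schedule=None)
    return new


def shift_to_distance(system, distance: float) -> np.ndarray:
    """Coordinates with monomer II translated along x so the COM x-distance
    equals ``distance`` (monomer I fixed)."""
    from .system import cv_com_distance_x

    pos = system.positions.copy()
    cur = float(cv_com_distance_x(system))
    g1 = system.group(1)
    sign = np.sign(pos[g1][:, 0].mean() - pos[system.group(0)][:, 0].mean())
    pos[g1, 0] += sign * (distance - cur)
    return pos


@dataclass
class ToyCycleOutcome:
    """Everything the toy cycle produces."""

    components: CycleComponents
    assembled: CycleResult          # -A+B+C+V+R with propagated sigma
    raw_sum: float                  # -dF_A + dF_B + dF_C (no corrections)
    sigma: float                    # quadrature of the three stage errors
    oracle: OracleResult            # exact dF between the released end states
    closure_gap: float              # |raw_sum - oracle.dF|
    profile_B: FreeEnergyProfile
    lambda_star: float
    correction_inputs: CorrectionInputs | None


def run_toy_cycle(spec: ToyDimerSpec = ToyDimerSpec(), *, seed: int = 1,
                  tier: float = 1.0, k_end: float = 0.5,
                  v_pull: float = 0.05, pull_to: float = 3.2,
                  release_duration: float = 250.0, dt: float = 0.002,
                  friction: float = 1.0, n_traj: int = 40,
                  n_equil_steps: int = 2500, n_boot: int = 1000,
                  measure_corrections: bool = True,
                  correction_steps: int = 30000) -> ToyCycleOutcome:
    """Run processes A, B and C on the toy dimer and assemble the cycle.

    ``v_pull`` (A/ps) and ``release_duration`` (ps) define the converged
    tier; ``tier`` multiplies the speed of all three protocols.  Returns the
    assembled cycle together with the exact oracle and the closure gap.
    """
    T = spec.temperature
    system, restraints = make_toy_dimer(spec)
    d_u = spec.d_unbound
    k0 = spec.k

    # --- process B: center pull d_u -> pull_to, everything stiff ------------
    v = -abs(v_pull) * tier
    duration_b = (pull_to - d_u) / v
    sched_b = Schedule("center", d_u, v, duration_b)
    res_b = run_smd(system, restraints, sched_b, dt=dt, friction=friction,
                    temperature=T, n_traj=n_traj, seed=seed * 1000 + 1,
                    n_equil_steps=n_equil_steps, lambda_bin=0.1)
    profile = build_profile(res_b.traces, T, n_boot=n_boot, seed=seed)
    lambda_star, dF_B = profile_minimum(profile)
    i_star = int(np.flatnonzero(profile.lam == lambda_star)[0])
    s_B = float(profile.err[i_star])

    # --- process A: k-ramp release in the unbound state ---------------------
    dur_rel = release_duration / tier
    sched_k = Schedule("force-constant", k0, (k_end - k0) / dur_rel, dur_rel)
    res_a = run_smd(system, restraints, sched_k, dt=dt, friction=friction,
                    temperature=T, n_traj=n_traj, seed=seed * 1000 + 2,
                    n_equil_steps=n_equil_steps, lambda_bin=0.5)
    W_a = np.array([t.work[-1] for t in res_a.traces])
    dF_A = jarzynski_estimate(W_a, T)
    s_A = bootstrap_error(W_a, T, n_boot=n_boot, seed=seed + 1)

    # --- process C: k-ramp release in the bound state (center lambda*) ------
    bound_pos = shift_to_distance(system, lambda_star)
    bound_restraints = replace(
        restraints, cv=CVSpring(k=k0, center=lambda_star), schedule=None)
    res_c = run_smd(system, bound_restraints, sched_k, dt=dt,
                    friction=friction, temperature=T, n_traj=n_traj,
                    seed=seed * 1000 + 3, n_equil_steps=n_equil_steps,
                    lambda_bin=0.5, init_positions=bound_pos)
    W_c = np.array([t.work[-1] for t in res_c.traces])
    dF_C = jarzynski_estimate(W_c, T)
    s_C = bootstrap_error(W_c, T, n_boot=n_boot, seed=seed + 2)

    # --- exact oracle between the two released end states -------------------
    oracle = toy_cycle_oracle(spec, lambda_star, k_end)

    # --- corrections from the released end states ---------------------------
    inputs = None
    dF_V = dF_R = 0.0
    if measure_corrections:
        released_u = scale_restraints(restraints, k_end / k0)
        released_b = scale_restraints(bound_restraints, k_end / k0)
        eq_u = run_equilibrium(system, released_u, dt=dt, n_steps=correction_steps,
                               friction=friction, temperature=T, n_traj=4,
                               seed=seed * 1000 + 4, frame_stride=20)
        eq_b = run_equilibrium(system, released_b, dt=dt,
                               n_steps=correction_steps, friction=friction,
                               temperature=T, n_traj=4,
                               seed=seed * 1000 + 5,
                               frame_stride=20, init_positions=bound_pos)
        inputs = measure_correction_inputs(eq_b.com_disp, eq_u.com_disp,
                                           temperature=T)
        dF_V = float(standard_state_correction(inputs))
        dF_R = float(rotational_correction(inputs))

    components = CycleComponents(dF_A=float(dF_A), dF_B=float(dF_B),
                                 dF_C=float(dF_C), dF_V=dF_V, dF_R=dF_R,
                                 s_A=float(s_A), s_B=s_B, s_C=float(s_C),
                                 temperature=T)
    assembled = assemble_cycle(components)
    raw_sum = -components.dF_A + components.dF_B + components.dF_C
    sigma = float(np.sqrt(s_A ** 2 + s_B ** 2 + s_C ** 2))
    return ToyCycleOutcome(components=components, assembled=assembled,
                           raw_sum=float(raw_sum), sigma=sigma, oracle=oracle,
                           closure_gap=float(abs(raw_sum - oracle.dF)),
                           profile_B=profile, lambda_star=float(lambda_star),
                           correction_inputs=inputs)
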