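"""Assembly of the absolute binding free energy from the restrained
thermodynamic cycle.

The cycle replaces the intractable direct binding process D by three steered
processes: A releases the restraints in the unbound state, B binds the two
restrained monomers along the x axis, C releases the restraints in the bound
state.  Closing the cycle,

    dF_D = -dF_A + dF_B + dF_C,

and after converting the restrained unbound volume to the standard state and
accounting for the rotational freedom suppressed by the bound-state
restraints,

    dF = -dF_A + dF_B + dF_C + dF_V + dF_R.

The standard-state correction moves one molecule from the volume it can
explore in the restrained unbound state, V_u = dr_x,u * dr_y,u * dr_z,u, to
the standard-state volume V_0 = 1661 A^3:

    dF_V = k_B T ln(V_0 / V_u)            (positive when V_u < V_0)

The rotational-restriction correction compares the transverse patch the
restrained bound monomer may occupy, approximated as an ellipse with
semi-axes dr_y,b and dr_z,b at radius r_b, with the full orientational
sphere of area 4*pi*r_b^2:

    dF_R = -k_B T ln(4 r_b^2 / (dr_y,b * dr_z,b))   (negative for tight
                                                     transverse restraints)

Because steering runs along a fixed axis (a Cartesian coordinate, not a
radial one), no Jacobian correction enters the profile.

Uncertainty is propagated as independent Gaussian quadrature over the three
simulated stages only; the corrections are treated as exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import V0_STANDARD, kbt
from .errors import EstimationError

__all__ = [
    "CycleComponents", "CorrectionInputs", "CycleResult",
    "standard_state_correction", "rotational_correction", "assemble_cycle",
    "measure_correction_inputs",
]


@dataclass(frozen=True)
class CycleComponents:
    """The five free-energy components of the cycle (kcal mol^-1) with the
    stage errors of the three simulated processes."""

    dF_A: float
    dF_B: float
    dF_C: float
    dF_V: float = 0.0
    dF_R: float = 0.0
    s_A: float = 0.0
    s_B: float = 0.0
    s_C: float = 0.0
    temperature: float = 298.0

    def __post_init__(self):
        if min(self.s_A, self.s_B, self.s_C) < 0:
            raise EstimationError("stage errors must be >= 0")


@dataclass(frozen=True)
class CorrectionInputs:
    """Geometric inputs of the two corrections (all in A).

    dr_x_u, dr_y_u, dr_z_u: min-to-max spans of the monomer–monomer distance
    components in the restrained unbound state.  dr_y_b, dr_z_b: maximum
    transverse deviations in the restrained bound state.  r_b: average radial
    monomer–monomer distance in the (un)restrained bound state.
    """

    dr_x_u: float
    dr_y_u: float
    dr_z_u: float
    dr_y_b: float
    dr_z_b: float
    r_b: float
    V0: float = V0_STANDARD
    temperature: float = 298.0

    def __post_init__(self):
        if min(self.dr_x_u, self.dr_y_u, self.dr_z_u,
               self.dr_y_b, self.dr_z_b) <= 0:
            raise EstimationError("all spans/deviations must be positive")
        if self.r_b <= 0 or self.V0 <= 0:
            raise EstimationError("r_b and V0 must be positive")


def standard_state_correction(inputs: CorrectionInputs) -> float:
    """dF_V = k_B T ln(V_0 / (dr_x,u * dr_y,u * dr_z,u)), kcal mol^-1."""
    v_u = inputs.dr_x_u * inputs.dr_y_u * inputs.dr_z_u
    return kbt(inputs.temperature) * np.log(inputs.V0 / v_u)


def rotational_correction(inputs: CorrectionInputs) -> float:
    """dF_R = -k_B T ln(4 r_b^2 / (dr_y,b * dr_z,b)), kcal mol^-1."""
    arg = 4.0 * inputs.r_b ** 2 / (inputs.dr_y_b * inputs.dr_z_b)
    return -kbt(inputs.temperature) * np.log(arg)


@dataclass(frozen=True)
class CycleResult:
    dF: float
    sigma: float
    components: CycleComponents

    def as_dict(self) -> dict:
        c = self.components
        return {
            "dF_A": c.dF_A, "s_A": c.s_A,
            "dF_B": c.dF_B, "s_B": c.s_B,
            "dF_C": c.dF_C, "s_C": c.s_C,
            "dF_V": c.dF_V, "dF_R": c.dF_R,
            "dF": self.dF, "sigma": self.sigma,
            "temperature": c.temperature,
        }


def assemble_cycle(components: CycleComponents) -> CycleResult:
    """dF = -dF_A + dF_B + dF_C + dF_V + dF_R; sigma = sqrt(sA^2+sB^2+sC^2)."""
    vals = [components.dF_A, components.dF_B, components.dF_C,
            components.dF_V, components.dF_R]
    if not np.all(np.isfinite(vals)):
        raise EstimationError("cycle components must be finite")
    dF = (-components.dF_A + components.dF_B + components.dF_C
          + components.dF_V + components.dF_R)
    sigma = float(np.sqrt(components.s_A ** 2 + components.s_B ** 2
                          + components.s_C ** 2))
    return CycleResult(dF=float(dF), sigma=sigma, components=components)


def measure_correction_inputs(bound_frames, unbound_frames,
                              unrestrained_bound_frames=None,
                              V0: float = V0_STANDARD,
                              temperature: float = 298.0) -> CorrectionInputs:
    """Measure the correction inputs from trajectory frames.

    ``bound_frames`` / ``unbound_frames`` are arrays of per-frame
    monomer–monomer COM displacement vectors, shape (n_frames, 3) or
    (n_frames, n_traj, 3), from the *restrained* bound and unbound runs.
    Spans are max - min per component (unbound); transverse deviations are
    max |y|, max |z| (bound).  r_b is the mean radial distance, taken from
    ``unrestrained_bound_frames`` when given (the proper, restraint-free
    bound ensemble) and from the bound frames otherwise.
    """
    b = np.asarray(bound_frames, dtype=float).reshape(-1, 3)
    u = np.asarray(unbound_frames, dtype=float).reshape(-1, 3)
    if len(b) < 2 or len(u) < 2:
        raise EstimationError("need at least two frames per state to span")
    spans = u.max(axis=0) - u.min(axis=0)
    if np.any(spans <= 0):
        raise EstimationError("degenerate (zero) span in the unbound frames")
    dev_y = float(np.max(np.abs(b[:, 1])))
    dev_z = float(np.max(np.abs(b[:, 2])))
    rb_src = b if unrestrained_bound_frames is None else \
        np.asarray(unrestrained_bound_frames, dtype=float).reshape(-1, 3)
    r_b = float(np.mean(np.linalg.norm(rb_src, axis=1)))
    return CorrectionInputs(dr_x_u=float(spans[0]), dr_y_u=float(spans[1]),
                            dr_z_u=float(spans[2]), dr_y_b=dev_y,
                            dr_z_b=dev_z, r_b=r_b, V0=V0,
                            temperature=temperature)
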