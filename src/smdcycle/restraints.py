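"""Restraint potentials and steering schedules.

The restraint vocabulary mirrors the scheme used for restrained binding
simulations of protein dimers:

* one collective-variable (CV) spring, 0.5*k*(xi - lambda)^2, on the
  monomer–monomer COM x-distance — the steered coordinate;
* one shape restraint per monomer — harmonic in the centroid-free deviation
  from the reference coordinates (no rotational superposition; rotation is
  pinned by the point restraints);
* one planar restraint per monomer, 0.5*k*(dy^2 + dz^2) on the monomer COM,
  keeping the binding axis on x;
* six single-bead point restraints (y and z fixed / z only / y only),
  suppressing rigid rotation of each monomer;
* optionally a flat-bottom umbrella on the radial COM distance with knots
  r1 <= r2 <= r3 <= r4: zero on [r2, r3], parabolic on [r1, r2] and [r3, r4],
  linear beyond r1 and r4 with slope matched at the knots.

A :class:`Schedule` drives either the CV-spring center ("center", the pulling
processes) or a global scale on every restraint force constant
("force-constant", the restraint-release processes), linearly in time:
lambda(t) = lambda0 + v*t.

All energies are kcal mol^-1, all force constants kcal mol^-1 A^-2; forces
are exact negative gradients (verified against central differences in the
test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .system import ToySystem, _com

__all__ = [
    "Schedule", "CVSpring", "ShapeRestraint", "PlanarRestraint",
    "PointRestraint", "FlatBottom", "RestraintSet", "restraint_energy_forces",
]


@dataclass(frozen=True)
class Schedule:
    """Linear steering protocol lambda(t) = lambda0 + v*t.

    ``driven`` is "center" (lambda is the CV-spring center, A) or
    "force-constant" (lambda is the common restraint force constant,
    kcal mol^-1 A^-2; every restraint's k is scaled by lambda(t)/lambda0).
    ``velocity`` is in units of the driven quantity per ps.
    """

    driven: str
    lambda0: float
    velocity: float
    duration: float

    def __post_init__(self):
        if self.driven not in ("center", "force-constant"):
            raise ConfigurationError(f"unknown driven quantity {self.driven!r}")
        if self.duration <= 0:
            raise ConfigurationError("schedule duration must be positive")
        if self.driven == "force-constant":
            if self.lambda0 <= 0:
                raise ConfigurationError("force-constant schedule needs lambda0 > 0")
            if self.lambda0 + self.velocity * self.duration <= 0:
                raise ConfigurationError(
                    "force-constant schedule must stay positive; release to "
                    "exactly zero has no normalizable end state")

    def value(self, t):
        return self.lambda0 + self.velocity * np.asarray(t, dtype=float)

    @property
    def lambda_end(self) -> float:
        return self.lambda0 + self.velocity * self.duration


@dataclass(frozen=True)
class CVSpring:
    k: float = 50.0
    center: float = 0.0


@dataclass(frozen=True)
class ShapeRestraint:
    """0.5*k*sum_i |(r_i - c) - (ref_i - c_ref)|^2 over one monomer's beads,
    with c the unweighted centroid (translation removed, no rotational fit)."""
    monomer: int = 0
    k: float = 50.0


@dataclass(frozen=True)
class PlanarRestraint:
    """0.5*k*((Ycom - y0)^2 + (Zcom - z0)^2) on the mass-weighted monomer COM."""
    monomer: int = 0
    k: float = 50.0
    y0: float = 0.0
    z0: float = 0.0


@dataclass(frozen=True)
class PointRestraint:
    """Harmonic pin of selected transverse coordinates of a single bead.

    ``fix_y``/``fix_z`` select which coordinates are pinned: both (line fix),
    z only, or y only.  x is never pinned so the monomer can translate along
    the binding axis.
    """
    bead: int = 0
    k: float = 50.0
    fix_y: bool = True
    fix_z: bool = True
    y0: float = 0.0
    z0: float = 0.0


@dataclass(frozen=True)
class FlatBottom:
    """Flat-bottom umbrella on the radial monomer–monomer COM distance."""
    k: float = 50.0
    r1: float = 0.0
    r2: float = 0.0
    r3: float = 0.0
    r4: float = 0.0

    def __post_init__(self):
        if not (self.r1 <= self.r2 <= self.r3 <= self.r4):
            raise ConfigurationError("flat-bottom knots must satisfy r1<=r2<=r3<=r4")

    def energy_deriv(self, r):
        """U(r) and dU/dr, vectorized."""
        r = np.asarray(r, dtype=float)
        u = np.zeros_like(r)
        du = np.zeros_like(r)
        k = self.k
        lo = r < self.r2
        hi = r > self.r3
        # parabolic shoulders
        upar_lo = 0.5 * k * (r - self.r2) ** 2
        upar_hi = 0.5 * k * (r - self.r3) ** 2
        u = np.where(lo, upar_lo, u)
        du = np.where(lo, k * (r - self.r2), du)
        u = np.where(hi, upar_hi, u)
        du = np.where(hi, k * (r - self.r3), du)
        # linear continuation beyond r1 / r4 with matched slope and value
        below = r < self.r1
        s1 = k * (self.r1 - self.r2)
        u1 = 0.5 * k * (self.r1 - self.r2) ** 2
        u = np.where(below, u1 + s1 * (r - self.r1), u)
        du = np.where(below, s1, du)
        above = r > self.r4
        s4 = k * (self.r4 - self.r3)
        u4 = 0.5 * k * (self.r4 - self.r3) ** 2
        u = np.where(above, u4 + s4 * (r - self.r4), u)
        du = np.where(above, s4, du)
        return u, du


@dataclass
class RestraintSet:
    """The full restraint set applied to a toy dimer, plus one optional schedule.

    At most one schedule may be active per run; it is carried by the set, not
    by an individual restraint, because a force-constant release ramps every
    restraint simultaneously.
    """

    cv: CVSpring | None = None
    shape: list = field(default_factory=list)
    planar: list = field(default_factory=list)
    point: list = field(default_factory=list)
    flat_bottom: FlatBottom | None = None
    schedule: Schedule | None = None

    def __post_init__(self):
        for r in self.restraints():
            if r.k < 0:
                raise ConfigurationError("restraint force constants must be >= 0")
        if self.schedule is not None and self.schedule.driven == "center" \
                and self.cv is None:
            raise ConfigurationError("center schedule requires a CV spring")

    def restraints(self) -> list:
        out = []
        if self.cv is not None:
            out.append(self.cv)
        out.extend(self.shape)
        out.extend(self.planar)
        out.extend(self.point)
        if self.flat_bottom is not None:
            out.append(self.flat_bottom)
        return out

    def census(self) -> int:
        """Number of individual restraints in the set."""
        return len(self.restraints())

    def scheduled_value(self, t):
        if self.schedule is None:
            raise ConfigurationError("restraint set has no schedule")
        return self.schedule.value(t)


def restraint_energy_forces(system: ToySystem, restraints: RestraintSet,
                            positions: np.ndarray, t: float = 0.0,
                            lam: float | None = None):
    """Total restraint energy and forces at time ``t``.

    ``lam`` overrides the scheduled value (used for the work jump
    V(r; lambda') - V(r; lambda)).  With a "center" schedule, lambda replaces
    the CV-spring center; with "force-constant", every restraint's k is
    scaled by lambda/lambda0.  Broadcasts over leading ensemble axes.

    Returns ``(energy, forces)``.
    """
    positions = np.asarray(positions, dtype=float)
    lead = positions.shape[:-2]
    energy = np.zeros(lead)
    forces = np.zeros_like(positions)
    masses = system.masses

    center = restraints.cv.center if restraints.cv is not None else None
    kscale = 1.0
    sch = restraints.schedule
    if sch is not None:
        if lam is None:
            lam = float(sch.value(t))
        if sch.driven == "center":
            center = lam
        else:
            kscale = lam / sch.lambda0
    elif lam is not None:
        raise ConfigurationError("lam supplied but restraint set has no schedule")
    if kscale < 0:
        raise ConfigurationError("scheduled force constant became negative")

    g0, g1 = system.group(0), system.group(1)
    w0 = masses[g0] / masses[g0].sum()
    w1 = masses[g1] / masses[g1].sum()

    if restraints.cv is not None:
        k = restraints.cv.k * kscale
        x0 = _com(positions, masses, g0)[..., 0]
        x1 = _com(positions, masses, g1)[..., 0]
        xi = np.abs(x0 - x1)
        dev = xi - center
        energy += 0.5 * k * dev * dev
        sgn = np.sign(x0 - x1)
        grad = k * dev * sgn  # dU/dx0com
        forces[..., g0, 0] += -grad[..., None] * w0
        forces[..., g1, 0] += +grad[..., None] * w1

    for s in restraints.shape:
        k = s.k * kscale
        idx = system.group(s.monomer)
        sub = positions[..., idx, :]
        ref = system.reference[idx]
        d = (sub - sub.mean(axis=-2, keepdims=True)) - (ref - ref.mean(axis=0))
        energy += 0.5 * k * np.sum(d * d, axis=(-1, -2))
        # d is centroid-free, so the projected gradient is simply k*d
        forces[..., idx, :] += -k * d

    for p in restraints.planar:
        k = p.k * kscale
        idx = system.group(p.monomer)
        com = _com(positions, masses, idx)
        dy = com[..., 1] - p.y0
        dz = com[..., 2] - p.z0
        energy += 0.5 * k * (dy * dy + dz * dz)
        w = masses[idx] / masses[idx].sum()
        forces[..., idx, 1] += -k * dy[..., None] * w
        forces[..., idx, 2] += -k * dz[..., None] * w

    for p in restraints.point:
        k = p.k * kscale
        if p.fix_y:
            dy = positions[..., p.bead, 1] - p.y0
            energy += 0.5 * k * dy * dy
            forces[..., p.bead, 1] += -k * dy
        if p.fix_z:
            dz = positions[..., p.bead, 2] - p.z0
            energy += 0.5 * k * dz * dz
            forces[..., p.bead, 2] += -k * dz

    if restraints.flat_bottom is not None:
        fb = restraints.flat_bottom
        if kscale != 1.0:
            fb = FlatBottom(fb.k * kscale, fb.r1, fb.r2, fb.r3, fb.r4)
        c0 = _com(positions, masses, g0)
        c1 = _com(positions, masses, g1)
        d = c0 - c1
        r = np.linalg.norm(d, axis=-1)
        u, du = fb.energy_deriv(r)
        energy += u
        grad = (du / r)[..., None] * d  # dU/d(com0)
        forces[..., g0, :] += -grad[..., None, :] * w0[:, None]
        forces[..., g1, :] += +grad[..., None, :] * w1[:, None]

    return energy, forces
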