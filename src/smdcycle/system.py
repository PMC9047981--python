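"""Toy dimer systems.

A :class:`ToySystem` is a small bead model of two "monomers" tagged I and II,
standing in for a protein dimer.  Monomers are held together internally by
harmonic bonds; the attractive interface between them is either

* ``axial`` — an LJ-form well acting on the monomer–monomer center-of-mass
  distance along the x axis (the steering collective variable).  This makes
  the binding coordinate exactly one-dimensional, so the binding free energy
  has an exact quadrature oracle; or
* ``pair`` — a conventional 12-6 Lennard-Jones potential between every
  inter-monomer bead pair.

All force routines broadcast over arbitrary leading (ensemble) axes: positions
may be shaped ``(n_beads, 3)`` or ``(n_traj, n_beads, 3)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSystemError

__all__ = ["ToySystem", "cv_com_distance_x", "physical_energy_forces"]


@dataclass
class ToySystem:
    """Bead positions, masses, topology and interface parameters of a toy dimer.

    Parameters
    ----------
    positions : (n, 3) array, A
    masses : (n,) array, amu
    monomer : (n,) int array of 0 (monomer I) or 1 (monomer II)
    bonds : list of (i, j, k_bond, r0) harmonic bonds, intra-monomer only
    interface : None | ("axial", eps, sigma) | ("pair", eps, sigma)
        eps in kcal mol^-1, sigma in A.
    reference : (n, 3) array, A — restraint target coordinates
    charges : optional (n,) array (unused by the default toys)
    """

    positions: np.ndarray
    masses: np.ndarray
    monomer: np.ndarray
    bonds: list = field(default_factory=list)
    interface: tuple | None = None
    reference: np.ndarray | None = None
    charges: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.monomer = np.asarray(self.monomer, dtype=int)
        n = len(self.masses)
        if self.positions.shape != (n, 3):
            raise InvalidSystemError("positions must be (n, 3) matching masses")
        if np.any(self.masses <= 0):
            raise InvalidSystemError("all masses must be positive")
        if set(np.unique(self.monomer)) - {0, 1}:
            raise InvalidSystemError("monomer labels must be 0 or 1")
        if not np.any(self.monomer == 0) or not np.any(self.monomer == 1):
            raise InvalidSystemError("both monomer groups must be non-empty")
        for (i, j, kb, r0) in self.bonds:
            if self.monomer[i] != self.monomer[j]:
                raise InvalidSystemError(f"bond {i}-{j} crosses the interface")
            if kb < 0 or r0 <= 0:
                raise InvalidSystemError(f"bond {i}-{j} has invalid parameters")
        if self.reference is None:
            self.reference = self.positions.copy()
        else:
            self.reference = np.asarray(self.reference, dtype=float)
            if self.reference.shape != self.positions.shape:
                raise InvalidSystemError("reference must match positions in shape")
        if self.interface is not None:
            kind, eps, sigma = self.interface
            if kind not in ("axial", "pair"):
                raise InvalidSystemError(f"unknown interface kind {kind!r}")
            if eps <= 0 or sigma <= 0:
                raise InvalidSystemError("interface eps and sigma must be positive")

    @property
    def n_beads(self) -> int:
        return len(self.masses)

    def group(self, which: int) -> np.ndarray:
        """Bead indices of monomer ``which`` (0 or 1)."""
        return np.flatnonzero(self.monomer == which)


def _com(positions: np.ndarray, masses: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Mass-weighted center of mass of the selected beads; broadcasts over
    leading axes.  Returns shape ``positions.shape[:-2] + (3,)``."""
    w = masses[idx] / masses[idx].sum()
    return np.einsum("...ij,i->...j", positions[..., idx, :], w)


def cv_com_distance_x(system: ToySystem, positions: np.ndarray | None = None):
    """|X_com(I) - X_com(II)|, the steering collective variable (A).

    The collective variable is the absolute monomer–monomer center-of-mass
    distance projected on the x axis, with mass-weighted centers.
    """
    if positions is None:
        positions = system.positions
    g0, g1 = system.group(0), system.group(1)
    x0 = _com(positions, system.masses, g0)[..., 0]
    x1 = _com(positions, system.masses, g1)[..., 0]
    return np.abs(x0 - x1)


def _lj(r, eps, sigma):
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def _lj_deriv(r, eps, sigma):
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r


def physical_energy_forces(system: ToySystem, positions: np.ndarray):
    """Energy (kcal mol^-1) and forces of the unrestrained toy Hamiltonian.

    Includes harmonic bonds and the interface term.  Broadcasts over leading
    ensemble axes; returns ``(energy, forces)`` with ``energy`` shaped like
    the leading axes and ``forces`` like ``positions``.
    """
    positions = np.asarray(positions, dtype=float)
    lead = positions.shape[:-2]
    energy = np.zeros(lead)
    forces = np.zeros_like(positions)

    for (i, j, kb, r0) in system.bonds:
        d = positions[..., i, :] - positions[..., j, :]
        r = np.linalg.norm(d, axis=-1)
        dr = r - r0
        energy += 0.5 * kb * dr * dr
        f = (-kb * dr / r)[..., None] * d
        forces[..., i, :] += f
        forces[..., j, :] -= f

    if system.interface is not None:
        kind, eps, sigma = system.interface
        if kind == "axial":
            g0, g1 = system.group(0), system.group(1)
            x0 = _com(positions, system.masses, g0)[..., 0]
            x1 = _com(positions, system.masses, g1)[..., 0]
            xi = np.abs(x0 - x1)
            energy += _lj(xi, eps, sigma)
            dU = _lj_deriv(xi, eps, sigma)  # dU/dxi
            sgn = np.sign(x0 - x1)
            w0 = system.masses[g0] / system.masses[g0].sum()
            w1 = system.masses[g1] / system.masses[g1].sum()
            # dxi/dx_i = +- w_i * sgn
            forces[..., g0, 0] += -(dU * sgn)[..., None] * w0
            forces[..., g1, 0] += +(dU * sgn)[..., None] * w1
        else:  # pair LJ between all inter-monomer bead pairs
            g0, g1 = system.group(0), system.group(1)
            d = positions[..., g0, None, :] - positions[..., None, g1, :]
            r = np.linalg.norm(d, axis=-1)
            energy += _lj(r, eps, sigma).sum(axis=(-1, -2))
            f = (-_lj_deriv(r, eps, sigma) / r)[..., None] * d
            # scatter-add back
            forces[..., g0, :] += f.sum(axis=-2)
            forces[..., g1, :] -= f.sum(axis=-3)

    return energy, forces
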