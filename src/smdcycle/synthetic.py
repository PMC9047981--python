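"""Synthetic substrates with known answers.

Three families of ground truth stand in for the unreachable protein-scale
reference data:

* toy dimers (:func:`make_toy_dimer`) whose binding coordinate is exactly
  one-dimensional, so their free energies have quadrature oracles
  (:func:`exact_free_energy_1d`, :func:`toy_cycle_oracle`);
* closed-form references for harmonic restraint release
  (:func:`harmonic_release_reference`);
* minimal PDB structure fixtures with planted aromatic-ring pairs,
  donor–H–acceptor triplets, buried residues and multi-frame occupancy
  patterns (:func:`make_structure_fixture`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson

from Bio.PDB.StructureBuilder import StructureBuilder

from .constants import beta, kbt
from .errors import EstimationError, GeometryError, ResolutionError
from .restraints import (CVSpring, PlanarRestraint, PointRestraint,
                         RestraintSet, ShapeRestraint)
from .system import ToySystem

__all__ = [
    "ToyDimerSpec", "OracleResult", "make_toy_dimer", "toy_interface_potential",
    "exact_free_energy_1d", "free_energy_difference_1d", "toy_cycle_oracle",
    "harmonic_release_reference", "make_structure_fixture",
]


@dataclass(frozen=True)
class ToyDimerSpec:
    """Parameters of the default toy dimer.

    Three beads per monomer are enough for the COM, planar and point
    restraints to act on distinct degrees of freedom.  The interface is an
    LJ-form well of depth ``eps`` and size ``sigma`` acting on the
    monomer–monomer COM x-distance (see the methods note), placing the bound
    minimum at 2^(1/6)*sigma.
    """

    n_beads: int = 3
    eps: float = 3.0
    sigma: float = 3.0
    bond_k: float = 50.0
    k: float = 50.0
    d_unbound: float = 9.0
    temperature: float = 298.0
    seed: int = 0
    interface_kind: str = "axial"

    def __post_init__(self):
        if self.eps <= 0 or self.sigma <= 0:
            raise EstimationError("eps and sigma must be positive")
        if self.n_beads < 1:
            raise EstimationError("need at least one bead per monomer")


@dataclass(frozen=True)
class OracleResult:
    """A reference free energy with its estimated numerical error."""

    dF: float
    method: str = "quadrature"
    error: float = 0.0

    def __post_init__(self):
        if self.error < 0:
            raise EstimationError("oracle error must be >= 0")


def make_toy_dimer(spec: ToyDimerSpec):
    """Build the toy dimer and its full eleven-restraint set.

    Returns ``(system, restraints)``.  The system starts in the restrained
    unbound configuration (COM distance ``spec.d_unbound`` along x) and its
    reference coordinates equal the starting coordinates.  The restraint set
    is the protein-scheme analog: 1 CV spring + 2 shape restraints + 2
    planar restraints + 6 single-bead point restraints (census 11).
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    base = np.array([[0.0, 0.0, 0.0], [0.0, 0.9, 0.0], [0.0, 0.0, 0.9]])
    offsets = base[:spec.n_beads].copy()
    if spec.n_beads > 3:
        extra = rng.uniform(-0.6, 0.6, size=(spec.n_beads - 3, 3))
        extra[:, 0] = 0.0
        offsets = np.vstack([offsets, extra])
    offsets += rng.normal(0.0, 0.02, size=offsets.shape)  # break exact symmetry

    n = spec.n_beads
    pos = np.zeros((2 * n, 3))
    pos[:n] = offsets
    pos[n:] = offsets + np.array([spec.d_unbound, 0.0, 0.0])
    # shift so each monomer COM sits on the x axis (y = z = 0)
    for g in (slice(0, n), slice(n, 2 * n)):
        pos[g, 1:] -= pos[g, 1:].mean(axis=0)
    masses = np.full(2 * n, 12.0)
    monomer = np.array([0] * n + [1] * n)

    bonds = []
    if n >= 2:
        for m0 in (0, n):
            for i in range(n):
                for j in range(i + 1, n):
                    r0 = float(np.linalg.norm(pos[m0 + i] - pos[m0 + j]))
                    bonds.append((m0 + i, m0 + j, spec.bond_k, r0))

    system = ToySystem(positions=pos, masses=masses, monomer=monomer,
                       bonds=bonds, interface=(spec.interface_kind, spec.eps,
                                               spec.sigma),
                       reference=pos.copy())

    k = spec.k
    planar = [PlanarRestraint(monomer=m, k=k, y0=0.0, z0=0.0) for m in (0, 1)]
    shape = [ShapeRestraint(monomer=m, k=k) for m in (0, 1)]
    point = []
    fixes = [(True, True), (False, True), (True, False)]  # line / z-only / y-only
    for m0 in (0, n):
        for which, (fy, fz) in enumerate(fixes):
            b = m0 + (which % n)
            point.append(PointRestraint(bead=b, k=k, fix_y=fy, fix_z=fz,
                                        y0=float(pos[b, 1]),
                                        z0=float(pos[b, 2])))
    restraints = RestraintSet(cv=CVSpring(k=k, center=spec.d_unbound),
                              shape=shape, planar=planar, point=point)
    return system, restraints


def toy_interface_potential(spec: ToyDimerSpec, x):
    """The toy interface well U_int(xi) on a grid of COM x-distances."""
    sr6 = (spec.sigma / np.asarray(x, dtype=float)) ** 6
    return 4.0 * spec.eps * (sr6 * sr6 - sr6)


def _log_integral(xs, us, b):
    shift = us.min()
    val = simpson(np.exp(-b * (us - shift)), x=xs)
    if val <= 0:
        raise ResolutionError("non-positive quadrature integral")
    return np.log(val) - b * shift


def exact_free_energy_1d(potential_on_grid, temperature: float,
                         bound_window, unbound_window,
                         standard_volume: float | None = None) -> OracleResult:
    """Binding free energy of a 1-D potential by direct quadrature.

    dF = -k_B T ln( int_bound e^(-beta U) dx / int_unbound e^(-beta U) dx )
    plus, when ``standard_volume`` is given, the 1-D standard-state term
    k_B T ln(L_std / L_u) converting the unbound window length L_u to the
    standard length L_std (the 1-D analog of the V_u -> V_0 transfer).

    ``potential_on_grid`` is ``(x, U)``.  The numerical error is estimated by
    re-evaluating on every second grid point (Richardson-style); a
    discrepancy beyond 0.05 k_B T raises a resolution error.
    """
    x, U = (np.asarray(a, dtype=float) for a in potential_on_grid)
    if x.ndim != 1 or x.shape != U.shape or x.size < 9:
        raise ResolutionError("potential grid must be 1-D with >= 9 points")
    b = beta(temperature)

    def estimate(step):
        xs, us = x[::step], U[::step]
        mb = (xs >= bound_window[0]) & (xs <= bound_window[1])
        mu = (xs >= unbound_window[0]) & (xs <= unbound_window[1])
        if mb.sum() < 5 or mu.sum() < 5:
            raise ResolutionError("window resolves fewer than 5 grid points")
        lb = _log_integral(xs[mb], us[mb], b)
        lu = _log_integral(xs[mu], us[mu], b)
        return -(lb - lu) / b

    dF = estimate(1)
    dF2 = estimate(2)
    err = abs(dF - dF2) / 15.0
    if abs(dF - dF2) > 0.05 * kbt(temperature):
        raise ResolutionError(
            f"quadrature not converged: halving the grid moves dF by {dF - dF2:.3g}")
    if standard_volume is not None:
        L_u = unbound_window[1] - unbound_window[0]
        dF += kbt(temperature) * np.log(standard_volume / L_u)
    return OracleResult(dF=float(dF), method="quadrature", error=float(err))


def free_energy_difference_1d(x, U_target, U_ref, temperature: float) -> OracleResult:
    """F[U_target] - F[U_ref] for two 1-D potentials on one grid, by
    quadrature over the whole grid (integrands must decay within it)."""
    x = np.asarray(x, dtype=float)
    Ut = np.asarray(U_target, dtype=float)
    Ur = np.asarray(U_ref, dtype=float)
    b = beta(temperature)

    def estimate(step):
        return -(_log_integral(x[::step], Ut[::step], b)
                 - _log_integral(x[::step], Ur[::step], b)) / b

    dF = estimate(1)
    err = abs(dF - estimate(2)) / 15.0
    if abs(dF - estimate(2)) > 0.05 * kbt(temperature):
        raise ResolutionError("quadrature not converged")
    return OracleResult(dF=float(dF), method="quadrature", error=float(err))


def toy_cycle_oracle(spec: ToyDimerSpec, lambda_bound: float,
                     k_end: float, d_unbound: float | None = None,
                     n_grid: int = 40001) -> OracleResult:
    """Exact free-energy difference between the released bound and released
    unbound states of the toy cycle.

    Both end states carry the weak residual CV spring (force constant
    ``k_end``) left by the restraint-release ramp, centered at
    ``lambda_bound`` and at the unbound distance respectively.  Because the
    toy interface acts on the COM x-distance alone, every transverse and
    internal degree of freedom contributes identically to both states and
    cancels exactly; the difference reduces to 1-D quadrature over the
    effective axial potential.
    """
    if k_end <= 0:
        raise EstimationError("k_end must be positive (no normalizable end "
                              "state exists for a fully released dimer)")
    du = spec.d_unbound if d_unbound is None else d_unbound
    sigma_spring = np.sqrt(kbt(spec.temperature) / k_end)
    x_lo = 0.75 * spec.sigma
    x_hi = du + 10.0 * sigma_spring
    x = np.linspace(x_lo, x_hi, n_grid)
    U_int = toy_interface_potential(spec, x)
    U_b = U_int + 0.5 * k_end * (x - lambda_bound) ** 2
    U_u = U_int + 0.5 * k_end * (x - du) ** 2
    res = free_energy_difference_1d(x, U_b, U_u, spec.temperature)
    return OracleResult(dF=res.dF, method="quadrature", error=res.error)


def harmonic_release_reference(k_from: float, k_to: float, n_dof: int,
                               temperature: float) -> float:
    """dF = (n_dof/2) k_B T ln(k_to / k_from) for changing the force constant
    of a harmonic restraint on n_dof independent coordinates.

    Release to exactly zero has no finite reference without a confining box,
    hence both force constants must be positive.
    """
    if k_from <= 0 or k_to <= 0:
        raise EstimationError("force constants must be positive")
    return 0.5 * n_dof * kbt(temperature) * float(np.log(k_to / k_from))


# ---------------------------------------------------------------------------
# structure fixtures
# ---------------------------------------------------------------------------

_RING_RADIUS = 1.39  # A, aromatic C-C ring circumradius


def _hexagon(center, normal):
    """Six ring-carbon coordinates of a regular hexagon."""
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    a = np.array([1.0, 0.0, 0.0])
    if abs(normal @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    ang = np.arange(6) * np.pi / 3.0
    return (np.asarray(center)
            + _RING_RADIUS * (np.cos(ang)[:, None] * e1
                              + np.sin(ang)[:, None] * e2))


class _Builder:
    """Tiny convenience wrapper around Bio.PDB's StructureBuilder."""

    def __init__(self, sid="SYNT"):
        self.sb = StructureBuilder()
        self.sb.init_structure(sid)
        self.serial = 1

    def model(self, i):
        self.sb.init_model(i)

    def chain(self, cid):
        self.sb.init_chain(cid)
        self.sb.init_seg("    ")

    def residue(self, resname, resseq):
        self.sb.init_residue(resname, " ", resseq, " ")

    def atom(self, name, coord, element=None):
        element = element or name[0]
        fullname = f"{name:>4s}" if len(name) < 4 else name
        self.sb.init_atom(name, np.asarray(coord, dtype=float), 0.0, 1.0,
                          " ", fullname, self.serial, element)
        self.serial += 1

    def done(self):
        return self.sb.get_structure()


_PHE_RING = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]


def _add_phe(b, resseq, ring_center, normal, anchor_offset):
    """A minimal PHE: backbone stubs + a planted aromatic ring."""
    b.residue("PHE", resseq)
    ring = _hexagon(ring_center, normal)
    anchor = np.asarray(ring_center) + np.asarray(anchor_offset)
    b.atom("N", anchor + [0.0, 0.0, 0.0])
    b.atom("CA", anchor + [1.2, 0.6, 0.0])
    b.atom("C", anchor + [2.4, 0.0, 0.2])
    b.atom("O", anchor + [2.6, -1.1, 0.6])
    b.atom("CB", anchor + [1.3, 1.6, 1.0])
    # hexagon order CG, CD1, CE1, CZ, CE2, CD2 walks around the ring
    for name, xyz in zip(_PHE_RING, ring):
        b.atom(name, xyz)


def make_structure_fixture(kind: str, seed: int = 0, **params):
    """Construct a minimal PDB structure with a planted interaction.

    kinds
    -----
    ``pi-pi``       params: distance (ring-COM separation, A, default 4.0),
                    angle_deg (normal-normal acute angle, default 0.0)
    ``hbond``       params: distance (O-N, default 2.8), angle_deg
                    (donor-H-acceptor, default 160.0)
    ``burial``      params: separation (chain-chain gap, default 4.0);
                    chain B caps residue 2 of chain A, burying it
    ``multi-frame`` params: n_frames (default 10), occupancy (fraction,
                    default 0.7), plus the hbond geometry parameters;
                    the planted pair is present in round(occupancy*n_frames)
                    models and displaced elsewhere

    Planted geometry is exact to better than 1e-3 A.  Returns a Bio.PDB
    Structure (write it with :func:`smdcycle.io.write_pdb`).
    """
    rng = np.random.default_rng(seed)
    b = _Builder()

    if kind == "pi-pi":
        d = float(params.get("distance", 4.0))
        ang = float(params.get("angle_deg", 0.0))
        if d <= 0:
            raise GeometryError("ring separation must be positive")
        b.model(0)
        b.chain("A")
        _add_phe(b, 1, np.zeros(3), [0.0, 0.0, 1.0], [4.0, 0.0, 0.0])
        b.chain("B")
        n2 = [0.0, np.sin(np.deg2rad(ang)), np.cos(np.deg2rad(ang))]
        _add_phe(b, 1, [0.0, 0.0, d], n2, [-4.0, 0.0, 0.0])
        return b.done()

    if kind == "hbond":
        d = float(params.get("distance", 2.8))
        ang = float(params.get("angle_deg", 160.0))
        if d <= 0:
            raise GeometryError("O-N distance must be positive")
        return _build_hbond_structure(d, ang)

    if kind == "burial":
        sep = float(params.get("separation", 4.0))
        if sep <= 0:
            raise GeometryError("separation must be positive")
        return _build_burial_structure(sep)

    if kind == "multi-frame":
        n_frames = int(params.get("n_frames", 10))
        occ = float(params.get("occupancy", 0.7))
        if not 0.0 <= occ <= 1.0:
            raise GeometryError("occupancy must be in [0, 1]")
        d = float(params.get("distance", 2.8))
        ang = float(params.get("angle_deg", 160.0))
        n_present = int(round(occ * n_frames))
        order = np.arange(n_frames)
        rng.shuffle(order)
        present_frames = set(order[:n_present].tolist())
        sb = _Builder()
        for f in range(n_frames):
            sb.model(f)
            _fill_hbond_model(sb, d, ang, present=(f in present_frames))
        return sb.done()

    raise GeometryError(f"unknown fixture kind {kind!r}")


def _fill_hbond_model(b, d_on, angle_deg, present=True):
    alpha = np.deg2rad(angle_deg)
    N = np.zeros(3)
    H = np.array([1.01, 0.0, 0.0])
    u = np.array([-np.cos(alpha), np.sin(alpha), 0.0])
    hp = H - N
    bq = 2.0 * hp @ u
    cq = hp @ hp - d_on ** 2
    disc = bq * bq - 4.0 * cq
    if disc < 0:
        raise GeometryError("requested O-N distance and angle are incompatible")
    rho = (-bq + np.sqrt(disc)) / 2.0
    if rho <= 0:
        raise GeometryError("requested O-N distance and angle are incompatible")
    O = H + rho * u
    if not present:
        O = O + np.array([5.0, 0.0, 0.0])

    b.chain("A")
    b.residue("ALA", 1)
    b.atom("N", N)
    b.atom("H", H)
    b.atom("CA", N + np.array([-0.8, -1.1, 0.0]))
    b.atom("C", N + np.array([-2.2, -0.9, 0.3]))
    b.atom("O", N + np.array([-2.9, -1.9, 0.4]))
    b.atom("CB", N + np.array([-0.7, -1.9, 1.3]))
    b.chain("B")
    b.residue("GLY", 1)
    b.atom("N", O + np.array([2.6, 1.2, 0.0]))
    b.atom("CA", O + np.array([2.2, 0.2, 0.9]))
    b.atom("C", O + np.array([0.9, -0.4, 0.4]))
    b.atom("O", O)


def _build_hbond_structure(d_on, angle_deg):
    b = _Builder()
    b.model(0)
    _fill_hbond_model(b, d_on, angle_deg, present=True)
    return b.done()


def _build_burial_structure(sep):
    """Chain A: three small residues in a row; residue 2's sidechain blob
    faces +x.  Chain B: a cap of carbons at distance ``sep`` burying residue
    2 in the bound structure."""
    b = _Builder()
    b.model(0)
    b.chain("A")
    for i, y in enumerate((-5.0, 0.0, 5.0), start=1):
        b.residue("ALA" if i != 2 else "LEU", i)
        base = np.array([0.0, y, 0.0])
        b.atom("N", base + [0.0, -0.6, 0.0])
        b.atom("CA", base)
        b.atom("C", base + [0.0, 0.6, 0.6])
        b.atom("O", base + [0.0, 0.6, 1.8])
        b.atom("CB", base + [1.5, 0.0, 0.0])
        if i == 2:  # bulky sidechain toward +x
            b.atom("CG", base + [2.9, 0.0, 0.0])
            b.atom("CD1", base + [3.6, 1.2, 0.0])
            b.atom("CD2", base + [3.6, -1.2, 0.0])
    b.chain("B")
    b.residue("UNK", 1)
    # cap of carbons over residue 2's sidechain
    k = 0
    for dy in (-1.5, 0.0, 1.5):
        for dz in (-1.5, 0.0, 1.5):
            k += 1
            b.atom(f"C{k}", np.array([3.6 + sep, dy, dz]), element="C")
    return b.done()
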