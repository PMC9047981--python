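"""Protein–protein interface analysis.

Operates on Bio.PDB structures (read with :func:`smdcycle.io.read_pdb`).
Provided analyzers:

* solvent-accessible surface area (Shrake–Rupley sphere sampling with Bondi
  van-der-Waals radii, 1.4 A probe) and per-residue delta-SASA ranking
  between an unbound and a bound structure;
* pi–pi contact detection between aromatic six-membered rings: ring-COM
  distance < 7.2 A and normal–normal acute angle < 30 deg (parallel) or
  > 50 deg (T-shaped); the 30–50 deg band is rejected.  Thresholds are
  strict inequalities; boundary values do not fire;
* hydrogen-bond detection: O–N distance < 3.0 A and donor–H–acceptor angle
  > 135 deg, donors being nitrogens with an attached (or ideally placed)
  hydrogen and acceptors being oxygens;
* per-frame occupancy of a residue pair over a multi-model trajectory;
* alanine-truncation mutant construction (keep backbone + C-beta, rename);
* the nonpolar solvation term G_np = 0.0072 * SASA.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np

from Bio.PDB.SASA import ShrakeRupley

from .constants import BONDI_RADII
from .errors import AlignmentError, GeometryError, SmdCycleError

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord", "SasaResult", "sasa", "delta_sasa", "detect_pipi",
    "detect_hbonds", "occupancy", "mutate_to_ala", "nonpolar_solvation",
    "RING_DEFINITIONS",
]

#: Six-membered aromatic ring atom names per residue type.
RING_DEFINITIONS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
}

_BACKBONE_KEEP = {"N", "CA", "C", "O", "OXT", "CB",
                  "H", "H1", "H2", "H3", "HA", "HA2", "HA3"}


@dataclass(frozen=True)
class InteractionRecord:
    """One detected interface contact."""

    kind: str                   # "pi-pi-parallel" | "pi-pi-T-shaped" | "hbond"
    res_a: tuple                # (chain id, residue number, residue name)
    res_b: tuple
    distance: float             # A (ring-COM or O-N)
    angle: float                # deg (normal-normal acute or donor-H-acceptor)
    frame: int = 0

    def pair(self):
        return frozenset((self.res_a[:2], self.res_b[:2]))


@dataclass
class SasaResult:
    per_atom: dict              # (chain, resseq, atom name) -> A^2
    per_residue: dict           # (chain, resseq, resname) -> A^2
    total: float
    probe: float
    n_points: int


def _first_model(structure):
    if structure.level == "S":
        return next(structure.get_models())
    return structure


def _models(structure):
    if structure.level == "S":
        return list(structure.get_models())
    return [structure]


def _res_key(res):
    return (res.get_parent().id, res.id[1], res.get_resname())


def _split_groups(model, groups=None):
    """Partition chain ids into the two monomers.  By default the sorted
    chain list is split in half (e.g. insulin's A,B vs C,D)."""
    ids = sorted(ch.id for ch in model)
    if groups is None:
        if len(ids) < 2:
            raise GeometryError("need at least two chains to define monomers")
        half = len(ids) // 2
        groups = (tuple(ids[:half]), tuple(ids[half:]))
    g0, g1 = (set(g) for g in groups)
    if g0 & g1:
        raise GeometryError("monomer chain groups overlap")
    return g0, g1


def sasa(structure, probe: float = 1.4, n_points: int = 960) -> SasaResult:
    """Solvent-accessible surface area by Shrake–Rupley sphere sampling.

    Each atom's accessible area is the exposed fraction of the sphere of
    radius r_vdw + probe times that sphere's total area, with r_vdw from the
    Bondi table.  An element missing from the table is an explicit error.
    """
    model = _first_model(structure)
    for atom in model.get_atoms():
        el = (atom.element or "").strip().upper()
        if el not in BONDI_RADII:
            res = atom.get_parent()
            raise SmdCycleError(
                f"no van-der-Waals radius for element {el!r} "
                f"(atom {atom.get_name()} in {_res_key(res)})")
    sr = ShrakeRupley(probe_radius=probe, n_points=n_points,
                      radii_dict=dict(BONDI_RADII))
    sr.compute(model, level="A")
    per_atom, per_res = {}, {}
    for res in model.get_residues():
        rk = _res_key(res)
        for atom in res:
            a = float(atom.sasa)
            per_atom[(rk[0], rk[1], atom.get_name())] = a
            per_res[rk] = per_res.get(rk, 0.0) + a
    total = float(sum(per_res.values()))
    return SasaResult(per_atom=per_atom, per_residue=per_res, total=total,
                      probe=probe, n_points=n_points)


def delta_sasa(bound: SasaResult, unbound: SasaResult):
    """Per-residue SASA loss on binding (unbound - bound), ranked.

    Returns a pandas DataFrame with columns chain, resseq, resname,
    delta_sasa sorted by descending area loss; exact ties are ordered by
    residue number.  The two results must cover the same residues.
    """
    import pandas as pd

    if set(bound.per_residue) != set(unbound.per_residue):
        missing = set(bound.per_residue) ^ set(unbound.per_residue)
        raise AlignmentError(f"residue sets differ: {sorted(missing)[:5]} ...")
    rows = [
        {"chain": k[0], "resseq": k[1], "resname": k[2],
         "delta_sasa": unbound.per_residue[k] - bound.per_residue[k]}
        for k in bound.per_residue
    ]
    df = pd.DataFrame(rows)
    return (df.sort_values(["delta_sasa", "resseq"],
                           ascending=[False, True], kind="mergesort")
              .reset_index(drop=True))


def _ring_geometry(res, ring_atoms):
    coords = []
    for name in ring_atoms:
        if name in res:
            coords.append(res[name].get_coord())
    if len(coords) < 3:
        raise GeometryError(f"ring in {_res_key(res)} has fewer than 3 atoms")
    coords = np.asarray(coords, dtype=float)
    com = coords.mean(axis=0)
    # normal = singular vector of the centered coordinates with the smallest
    # singular value (robust to slight non-planarity)
    _, _, vt = np.linalg.svd(coords - com)
    return com, vt[-1]


def detect_pipi(structure, ring_definitions=None, groups=None,
                distance_cutoff: float = 7.2, parallel_max: float = 30.0,
                tshaped_min: float = 50.0, frame: int = 0):
    """Detect inter-monomer pi–pi contacts in one model.

    A ring pair is recorded when its COM distance is strictly below
    ``distance_cutoff`` and the acute angle between the ring normals is
    strictly below ``parallel_max`` (parallel) or strictly above
    ``tshaped_min`` (T-shaped); the band in between is rejected.
    """
    rings = ring_definitions or RING_DEFINITIONS
    model = _models(structure)[frame] if structure.level == "S" else structure
    g0, g1 = _split_groups(model, groups)
    per_group = ([], [])
    for res in model.get_residues():
        names = rings.get(res.get_resname())
        if not names:
            continue
        cid = res.get_parent().id
        which = 0 if cid in g0 else 1 if cid in g1 else None
        if which is None:
            continue
        com, normal = _ring_geometry(res, names)
        per_group[which].append((_res_key(res), com, normal))

    out = []
    for ka, ca, na in per_group[0]:
        for kb, cb, nb in per_group[1]:
            d = float(np.linalg.norm(ca - cb))
            if not d < distance_cutoff:
                continue
            cosang = abs(float(na @ nb)) / (np.linalg.norm(na) * np.linalg.norm(nb))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if ang < parallel_max:
                kind = "pi-pi-parallel"
            elif ang > tshaped_min:
                kind = "pi-pi-T-shaped"
            else:
                continue
            out.append(InteractionRecord(kind=kind, res_a=ka, res_b=kb,
                                         distance=d, angle=ang, frame=frame))
    return out


def _ideal_hydrogen(n_atom, res):
    """Place an ideal amide hydrogen opposite the bisector of N's heavy
    neighbors (used when the file carries no hydrogens)."""
    npos = n_atom.get_coord()
    dirs = []
    for atom in res:
        if atom is n_atom or atom.element == "H":
            continue
        d = atom.get_coord() - npos
        r = np.linalg.norm(d)
        if 0.1 < r < 1.7:
            dirs.append(d / r)
    if not dirs:
        return None
    v = -np.sum(dirs, axis=0)
    nv = np.linalg.norm(v)
    if nv < 1e-6:
        return None
    return npos + 1.01 * v / nv


def detect_hbonds(structure, groups=None, distance_cutoff: float = 3.0,
                  angle_min: float = 135.0, frame: int = 0):
    """Detect inter-monomer hydrogen bonds in one model.

    Donors are nitrogens carrying a hydrogen within 1.25 A (an ideal H is
    placed from the heavy-atom geometry when the structure has none — each
    placement is logged); acceptors are oxygens.  A bond is recorded when
    O–N < ``distance_cutoff`` strictly and the donor–H–acceptor angle
    exceeds ``angle_min`` strictly.
    """
    model = _models(structure)[frame] if structure.level == "S" else structure
    g0, g1 = _split_groups(model, groups)

    donors = ([], [])   # (N pos, H pos, res key)
    acceptors = ([], [])
    n_skipped = 0
    for res in model.get_residues():
        cid = res.get_parent().id
        which = 0 if cid in g0 else 1 if cid in g1 else None
        if which is None:
            continue
        for atom in res:
            el = (atom.element or atom.get_name()[0]).strip().upper()
            if el == "N":
                npos = atom.get_coord()
                hpos = None
                for other in res:
                    oel = (other.element or other.get_name()[0]).strip().upper()
                    if oel == "H" and np.linalg.norm(
                            other.get_coord() - npos) < 1.25:
                        hpos = other.get_coord()
                        break
                if hpos is None:
                    hpos = _ideal_hydrogen(atom, res)
                    if hpos is None:
                        n_skipped += 1
                        continue
                    logger.info("placed ideal H on %s %s",
                                _res_key(res), atom.get_name())
                donors[which].append((npos, hpos, _res_key(res)))
            elif el == "O":
                acceptors[which].append((atom.get_coord(), _res_key(res)))
    if n_skipped:
        logger.warning("skipped %d donors lacking hydrogen", n_skipped)

    out = []
    for side in (0, 1):
        for npos, hpos, kd in donors[side]:
            for opos, ka in acceptors[1 - side]:
                d = float(np.linalg.norm(opos - npos))
                if not d < distance_cutoff:
                    continue
                v1 = npos - hpos
                v2 = opos - hpos
                cosang = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if ang > angle_min:
                    out.append(InteractionRecord(
                        kind="hbond", res_a=kd, res_b=ka, distance=d,
                        angle=ang, frame=frame))
    return out


def occupancy(structure, detector, pair, **detector_kwargs) -> float:
    """Percent of frames in which ``detector`` fires for the residue pair.

    ``pair`` is an unordered pair of (chain id, residue number) tuples;
    ``detector`` is :func:`detect_pipi`, :func:`detect_hbonds` or any
    callable with the same (structure, ..., frame=i) signature.
    """
    models = _models(structure)
    if not models:
        raise GeometryError("structure has no models")
    want = frozenset(tuple(p) for p in pair)
    hits = 0
    for i in range(len(models)):
        records = detector(structure, frame=i, **detector_kwargs)
        if any(r.pair() == want for r in records):
            hits += 1
    return 100.0 * hits / len(models)


def mutate_to_ala(structure, chain_id: str, resseq: int):
    """Alanine-truncation mutant: keep backbone + C-beta, rename to ALA.

    Removes every sidechain atom beyond C-beta of the selected residue and
    renames it ALA; every other residue is untouched.  An existing alanine
    is a rename-only no-op (idempotent); glycine has no C-beta and is an
    explicit error.  Returns a deep copy.
    """
    new = copy.deepcopy(structure)
    found = False
    for model in _models(new):
        if chain_id not in [c.id for c in model]:
            continue
        chain = model[chain_id]
        target = None
        for res in chain:
            if res.id[1] == resseq:
                target = res
                break
        if target is None:
            continue
        found = True
        if target.get_resname() == "GLY":
            raise GeometryError(
                f"residue {chain_id}{resseq} is glycine: no C-beta to keep")
        if target.get_resname() != "ALA":
            if "CB" not in target:
                raise GeometryError(
                    f"residue {chain_id}{resseq} has no C-beta atom")
            for atom in [a for a in target]:
                if atom.get_name() not in _BACKBONE_KEEP:
                    target.detach_child(atom.get_id())
        target.resname = "ALA"
    if not found:
        raise GeometryError(f"residue {chain_id}{resseq} not found")
    return new


def nonpolar_solvation(total_sasa: float) -> float:
    """Nonpolar solvation free energy G_np = 0.0072 * SASA (kcal mol^-1)."""
    if total_sasa < 0:
        raise GeometryError("SASA must be non-negative")
    return 0.0072 * total_sasa
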