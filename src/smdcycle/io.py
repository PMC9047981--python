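"""File formats: PDB structures, TSV work traces and profiles, YAML run
configuration, and run manifests.

PDB reading/writing is delegated to Bio.PDB behind a thin validating layer;
work traces travel as 3-column TSV (time_ps, lambda, work_kcal_mol) and
profiles as (lambda, dF, err), both lossless to 1e-9 relative.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from .errors import ConfigurationError, ParseError
from .jarzynski import FreeEnergyProfile, WorkTrace

__all__ = [
    "read_pdb", "write_pdb", "read_work_tsv", "write_work_tsv",
    "read_profile_tsv", "write_profile_tsv", "RunConfig", "write_manifest",
]

WORK_COLUMNS = ["time_ps", "lambda", "work_kcal_mol"]
PROFILE_COLUMNS = ["lambda", "dF_kcal_mol", "err_kcal_mol"]


def read_pdb(source, structure_id: str = "struct"):
    """Parse a PDB file (path, text, or file-like) into a Bio.PDB structure.

    ATOM/HETATM/MODEL records in the fixed-column dialect; insertion codes
    are preserved by the underlying parser.  Malformed records raise
    :class:`ParseError`.
    """
    if hasattr(source, "read"):
        handle = source
    elif isinstance(source, str) and "\n" in source:
        handle = _io.StringIO(source)
    elif isinstance(source, (str, os.PathLike)):
        handle = open(source)
    else:
        raise ParseError(f"cannot read PDB from {type(source).__name__}")
    try:
        parser = PDBParser(QUIET=True, PERMISSIVE=False)
        return parser.get_structure(structure_id, handle)
    except (PDBConstructionException, ValueError) as exc:
        raise ParseError(f"malformed PDB record: {exc}") from exc
    finally:
        if handle is not source and not isinstance(source, _io.StringIO):
            handle.close()


def write_pdb(structure, path=None) -> str:
    """Serialize a Bio.PDB structure; returns the PDB text and optionally
    writes it to ``path``."""
    pio = PDBIO()
    pio.set_structure(structure)
    buf = _io.StringIO()
    pio.save(buf)
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def write_work_tsv(trace: WorkTrace, path) -> None:
    df = pd.DataFrame({WORK_COLUMNS[0]: trace.time,
                       WORK_COLUMNS[1]: trace.lam,
                       WORK_COLUMNS[2]: trace.work})
    df.to_csv(path, sep="\t", index=False, float_format="%.15g")


def read_work_tsv(path, traj_id: int = 0) -> WorkTrace:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != WORK_COLUMNS:
        raise ParseError(f"expected columns {WORK_COLUMNS}, got {list(df.columns)}")
    if df.isna().any().any():
        raise ParseError(f"{path}: work trace contains NaN")
    return WorkTrace(traj_id=traj_id, time=df[WORK_COLUMNS[0]].to_numpy(),
                     lam=df[WORK_COLUMNS[1]].to_numpy(),
                     work=df[WORK_COLUMNS[2]].to_numpy())


def write_profile_tsv(profile: FreeEnergyProfile, path) -> None:
    df = pd.DataFrame({PROFILE_COLUMNS[0]: profile.lam,
                       PROFILE_COLUMNS[1]: profile.dF,
                       PROFILE_COLUMNS[2]: profile.err})
    df.to_csv(path, sep="\t", index=False, float_format="%.15g")


def read_profile_tsv(path) -> FreeEnergyProfile:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != PROFILE_COLUMNS:
        raise ParseError(f"expected columns {PROFILE_COLUMNS}, "
                         f"got {list(df.columns)}")
    if df.isna().any().any():
        raise ParseError(f"{path}: profile contains NaN")
    return FreeEnergyProfile(lam=df[PROFILE_COLUMNS[0]].to_numpy(),
                             dF=df[PROFILE_COLUMNS[1]].to_numpy(),
                             err=df[PROFILE_COLUMNS[2]].to_numpy(),
                             n_traj=0)


@dataclass
class RunConfig:
    """Configuration of one steered or equilibrium ensemble run.

    Physical parameters use the package units (A, ps, K, kcal mol^-1);
    defaults mirror the protein run plan (40 independent trajectories per
    process) at toy scale.
    """

    schedule_type: str = "center"      # center | force-constant | none
    lambda0: float = 9.0
    velocity: float = -0.05
    duration: float = 116.0
    dt: float = 0.002
    friction: float = 1.0
    temperature: float = 298.0
    n_trajectories: int = 40
    seed: int = 1
    n_equil_steps: int = 5000
    output_dir: str = "runs"
    toy: dict = field(default_factory=dict)  # ToyDimerSpec overrides

    def __post_init__(self):
        if self.n_trajectories < 1:
            raise ConfigurationError("n_trajectories must be >= 1")
        for name in ("duration", "dt", "temperature"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.friction < 0:
            raise ConfigurationError("friction must be >= 0")

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
            with open(source) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(source)
        if not isinstance(data, dict):
            raise ConfigurationError("run config must be a YAML mapping")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigurationError(f"bad run config: {exc}") from exc

    def to_yaml(self) -> str:
        header = ("# smdcycle run configuration\n"
                  "# units: lengths A, times ps, temperature K,\n"
                  "#        force constants kcal mol^-1 A^-2\n")
        return header + yaml.safe_dump(asdict(self), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def write_manifest(path, config: RunConfig | None = None, seed=None,
                   extra: dict | None = None) -> dict:
    """Write the reproducibility manifest of a run (config hash, seed,
    package version) as JSON; returns the manifest dict."""
    from . import __version__

    manifest = {"package": "smdcycle", "version": __version__}
    if config is not None:
        manifest["config_sha256"] = config.digest()
        manifest["config"] = asdict(config)
    if seed is not None:
        manifest["seed"] = int(seed)
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
        fh.write("\n")
    return manifest
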