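"""Readers and writers for standard frame formats, topology tables,
declarative configs and run manifests.

Internal units are nm throughout; Angstrom appears only at the
PDB/XYZ boundary (handled by MDAnalysis, whose native length unit is
Angstrom). GRO files are nm on disk, again converted by MDAnalysis.
Human-facing tables use 1-based monomer/bead indices and say so in
their headers; everything internal is 0-based.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import warnings

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # MDAnalysis deprecation chatter
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

from . import __version__
from .simulate import SimConfig, Trajectory
from .topology import (
    ChainTopology,
    IonContent,
    ParticleSystem,
    build_chain,
)

_FORMATS = {".pdb": "PDB", ".gro": "GRO", ".xyz": "XYZ"}

#: element stand-ins for the bead roles (PDB/XYZ need atom names)
_ROLE_TO_NAME = {"BB": "C", "SC": "C", "CX": "O", "CA": "CA", "CL": "CL",
                 "K": "K"}


def _detect_format(path, fmt=None) -> str:
    if fmt:
        return fmt.upper()
    suffix = Path(path).suffix.lower()
    if suffix not in _FORMATS:
        raise ValueError(
            f"cannot detect format from extension {suffix!r}; pass "
            "format explicitly"
        )
    return _FORMATS[suffix]


def write_frames(trajectory: Trajectory, path, fmt: str | None = None):
    """Write a trajectory as PDB/XYZ (multi-frame) or GRO (last frame).

    Coordinates are converted from nm to the format's native unit.
    """
    fmt = _detect_format(path, fmt)
    coords_ang = np.asarray(trajectory.coordinates, dtype=float) * 10.0
    if not np.all(np.isfinite(coords_ang)):
        raise ValueError("non-finite coordinate; refusing to write")
    if fmt == "PDB" and np.any(np.abs(coords_ang) >= 10000):
        raise ValueError(
            "coordinate out of range for fixed-width PDB fields"
        )
    n_atoms = coords_ang.shape[1]
    u = mda.Universe.empty(n_atoms, trajectory=True)
    if trajectory.system is not None:
        names = [_ROLE_TO_NAME[r] for r in trajectory.system.roles]
    else:
        names = ["C"] * n_atoms
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resids", [1])
    u.add_TopologyAttr("resnames", ["CGP"])
    dim = np.array([trajectory.box * 10.0] * 3 + [90.0, 90.0, 90.0])
    u.load_new(coords_ang, format=MemoryReader, dimensions=dim)
    path = str(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # cosmetic PDB field warnings
        if fmt == "GRO":
            u.trajectory[-1]
            u.atoms.write(path)
        else:
            with mda.Writer(path, n_atoms, multiframe=True) as w:
                for _ in u.trajectory:
                    w.write(u.atoms)


def read_frames(path, fmt: str | None = None, box: float | None = None,
                system: ParticleSystem | None = None,
                xyz_unit: str = "angstrom") -> Trajectory:
    """Read a PDB/GRO/XYZ frame sequence into a Trajectory (nm).

    ``box`` (nm) overrides or supplies the box when the file lacks one
    (XYZ). ``xyz_unit`` declares the XYZ length unit ("angstrom" or
    "nm"). A truncated or inconsistent frame raises with its index.
    """
    path = str(path)
    if not Path(path).exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, fmt)
    if fmt == "XYZ":
        _check_xyz_complete(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(path, format=fmt)
        except (EOFError, ValueError) as err:
            raise ValueError(f"malformed {fmt} file {path}: {err}") from err
    scale = 0.1  # Angstrom -> nm (MDAnalysis positions are Angstrom)
    if fmt == "XYZ" and xyz_unit == "nm":
        scale = 1.0
    frames = []
    times = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i, ts in enumerate(u.trajectory):
                frames.append(ts.positions.copy() * scale)
                times.append(float(ts.time) if np.isfinite(ts.time)
                             else i)
    except (EOFError, ValueError) as err:
        raise ValueError(
            f"truncated or malformed frame {len(frames)} in {path}: {err}"
        ) from err
    coords = np.array(frames)
    if box is None:
        dims = u.dimensions
        if dims is None or dims[0] <= 0:
            raise ValueError(
                f"{path} carries no box information; pass box= explicitly"
            )
        box = float(dims[0]) * 0.1
    return Trajectory(
        coordinates=coords, box=box, times=np.asarray(times, dtype=float),
        system=system, metadata={"source": path, "format": fmt},
    )


def _check_xyz_complete(path) -> None:
    """XYZ frames are (n_atoms + 2)-line blocks; a short final block
    means a truncated frame (some readers drop it silently)."""
    lines = Path(path).read_text().splitlines()
    while lines and not lines[-1].strip():
        lines.pop()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        n_atoms = int(lines[0].split()[0])
    except (ValueError, IndexError) as err:
        raise ValueError(f"{path}: malformed XYZ header line 1") from err
    block = n_atoms + 2
    n_full, rem = divmod(len(lines), block)
    if rem:
        raise ValueError(
            f"{path}: truncated frame {n_full} "
            f"({rem} stray lines after {n_full} complete frames)"
        )


# ---------------------------------------------------------------------------
# topology table


def write_topology_table(system: ParticleSystem, path) -> None:
    """Flat text table: bead index, monomer, role, charge (1-based)."""
    top = system.topology
    lines = [
        "# particle table; indices are 1-based (internal storage is "
        "0-based)",
        "index\tmonomer\trole\tcharge",
    ]
    monomer = list(top.monomer_of_bead) + [-1] * system.ions.n_ions
    for i, (role, q) in enumerate(zip(system.roles, system.charges)):
        m = monomer[i] + 1 if monomer[i] >= 0 else 0
        lines.append(f"{i + 1}\t{m}\t{role}\t{q:g}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# declarative config


DEFAULT_CONFIG = {
    "n_monomers": 32,
    "side_len": 1,
    "molality": 0.07,
    "box": 7.0,
    "temperature": 300.0,
    "timestep": 0.005,
    "friction": 1.0,
    "seed": 0,
    "n_steps": 1000,
    "save_every": 100,
}


def load_config(path) -> dict:
    """Key-value config (YAML subset) for chain + ions + run settings."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = dict(DEFAULT_CONFIG)
    unknown = set(raw) - set(cfg)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(raw)
    return cfg


def system_from_config(cfg: dict) -> ParticleSystem:
    from .topology import ions_for_molality, solvent_mass_for_box

    top = build_chain(int(cfg["n_monomers"]), int(cfg["side_len"]))
    ions = ions_for_molality(
        float(cfg["molality"]), solvent_mass_for_box(float(cfg["box"])),
        top.total_charge,
    )
    return ParticleSystem(topology=top, ions=ions)


def simconfig_from_config(cfg: dict) -> SimConfig:
    return SimConfig(
        temperature=float(cfg["temperature"]),
        timestep=float(cfg["timestep"]),
        friction=float(cfg["friction"]), seed=int(cfg["seed"]),
        n_steps=int(cfg["n_steps"]), save_every=int(cfg["save_every"]),
        box=float(cfg["box"]),
    )


# ---------------------------------------------------------------------------
# run manifest


@dataclass
class RunManifest:
    """Provenance record emitted once per CLI run."""

    command: str
    config: dict
    seeds: dict
    version: str = __version__
    started: str = ""
    finished: str = ""
    outputs: dict = field(default_factory=dict)  # path -> sha256

    def add_output(self, path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[str(path)] = digest

    def write(self, path) -> None:
        self.finished = datetime.datetime.now().isoformat(
            timespec="seconds"
        )
        Path(path).write_text(json.dumps(asdict(self), indent=2,
                                         default=str) + "\n")


def new_manifest(command: str, config: dict, seeds: dict) -> RunManifest:
    return RunManifest(
        command=command, config=config, seeds=seeds,
        started=datetime.datetime.now().isoformat(timespec="seconds"),
    )
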