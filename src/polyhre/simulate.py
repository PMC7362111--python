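"""Implicit-solvent Langevin dynamics of the coarse-grained system.

The integrator is BAOAB [Leimkuhler & Matthews]: velocity half-kick,
position half-drift, Ornstein-Uhlenbeck friction/noise step, half-drift,
half-kick. With zero friction the O-step is the identity and the scheme
reduces exactly to velocity Verlet, which conserves energy; this limit
is used by the energy-drift regression tests.

Constant-volume (NVT) Langevin stands in for pressure-coupled dynamics:
with implicit solvent there is no meaningful pressure to couple to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .constants import KB
from .forcefield import EnergyModel, ForceField
from .topology import ParticleSystem, ROLE_CARBOXYL

MAX_FORCE = 1e7  # kJ/mol/nm; larger signals a blow-up


@dataclass(frozen=True)
class SimConfig:
    """Run parameters of one Langevin simulation."""

    temperature: float = 300.0  # K
    timestep: float = 0.005  # ps
    friction: float = 1.0  # 1/ps
    seed: int = 0
    n_steps: int = 1000
    save_every: int = 100
    box: float = 7.0  # nm, cubic edge

    def __post_init__(self):
        for name in ("temperature", "timestep", "box"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")


@dataclass
class Frame:
    """One snapshot: coordinates (nm), cubic box edge (nm), time (ps)."""

    coordinates: np.ndarray
    box: float
    time: float = 0.0
    velocities: np.ndarray | None = None


@dataclass
class Trajectory:
    """Ordered frames plus the provenance needed to re-analyse them."""

    coordinates: np.ndarray  # (n_frames, n_particles, 3) nm
    box: float
    times: np.ndarray  # (n_frames,) ps
    system: ParticleSystem | None  # None for bare geometric fixtures
    config: SimConfig | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> Frame:
        return Frame(self.coordinates[i], self.box, float(self.times[i]))

    def __iter__(self):
        return (self.frame(i) for i in range(self.n_frames))


def kinetic_temperature(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Instantaneous temperature from the kinetic energy (equipartition)."""
    ke = 0.5 * float(np.sum(masses[:, None] * velocities**2))
    ndof = 3 * len(masses)
    return 2.0 * ke / (ndof * KB)


def maxwell_velocities(masses: np.ndarray, temperature: float,
                       rng: np.random.Generator) -> np.ndarray:
    sigma = np.sqrt(KB * temperature / masses)
    return rng.standard_normal((len(masses), 3)) * sigma[:, None]


def build_initial_frame(system: ParticleSystem, box: float,
                        rng: np.random.Generator,
                        bond_r0: float = 0.35,
                        minimize_steps: int = 200) -> Frame:
    """Deterministic (seeded) clash-free starting configuration.

    The backbone is grown as a persistent random walk confined to the
    box, side chains are attached radially, ions are placed uniformly
    with a minimum separation, and a short steepest-descent relaxation
    removes residual overlaps.
    """
    top = system.topology
    n = system.n_particles
    pos = np.zeros((n, 3))
    margin = 0.5
    lo, hi = margin, box - margin

    # backbone: persistent random walk, reflected at the walls
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    pos[0] = box / 2.0
    for i in range(1, top.n_monomers):
        for _ in range(200):
            trial_dir = direction + 0.55 * rng.standard_normal(3)
            trial_dir /= np.linalg.norm(trial_dir)
            trial = pos[i - 1] + bond_r0 * trial_dir
            if np.all(trial > lo) and np.all(trial < hi):
                far = True
                if i >= 3:
                    d = np.linalg.norm(pos[: i - 2] - trial, axis=1)
                    far = bool(np.all(d > 0.30))
                if far:
                    break
        pos[i] = trial
        direction = trial_dir

    # side chains: radial placement away from the local backbone axis
    bead = top.n_monomers
    for m in range(top.n_monomers):
        lo_i, hi_i = max(m - 1, 0), min(m + 1, top.n_monomers - 1)
        axis = pos[hi_i] - pos[lo_i]
        axis /= max(np.linalg.norm(axis), 1e-9)
        radial = rng.standard_normal(3)
        radial -= axis * (radial @ axis)
        radial /= max(np.linalg.norm(radial), 1e-9)
        anchor = pos[m]
        for s in range(top.side_len):
            anchor = anchor + bond_r0 * 0.9 * radial
            pos[bead] = np.clip(anchor, 0.1, box - 0.1)
            bead += 1

    # ions: uniform, rejecting close contacts
    for i in range(top.n_beads, n):
        for _ in range(2000):
            trial = rng.uniform(0.0, box, 3)
            d = pos[:i] - trial
            d -= box * np.round(d / box)
            if np.all(np.einsum("ij,ij->i", d, d) > 0.30**2):
                break
        pos[i] = trial

    if minimize_steps:
        model = EnergyModel(system, ForceField(bond_r0=bond_r0))
        pos = _steepest_descent(model, pos, box, minimize_steps)
    return Frame(coordinates=pos, box=box, time=0.0)


def _steepest_descent(model: EnergyModel, pos: np.ndarray, box: float,
                      n_steps: int, max_disp: float = 0.01) -> np.ndarray:
    pos = pos.copy()
    for _ in range(n_steps):
        _, forces = model.energy_forces(pos, box)
        fmax = float(np.abs(forces).max())
        if fmax < 100.0:
            break
        pos += forces * (max_disp / fmax)
    return pos


def run_langevin(initial: Frame, config: SimConfig, system: ParticleSystem,
                 ff: ForceField | None = None, alpha: float = 0.0,
                 bias=None, rng: np.random.Generator | None = None,
                 model: EnergyModel | None = None) -> Trajectory:
    """Integrate Langevin dynamics and return the saved trajectory.

    The first saved frame is the initial one; ``n_steps == 0`` returns a
    single-frame trajectory. Identical inputs and seed give bit-identical
    output.
    """
    if model is None:
        model = EnergyModel(system, ff or ForceField(), alpha=alpha,
                            bias=bias)
    if rng is None:
        rng = np.random.default_rng(config.seed)

    masses = system.masses
    dt = config.timestep
    gamma = config.friction
    kt = KB * config.temperature
    pos = np.array(initial.coordinates, dtype=float)
    box = initial.box
    if initial.velocities is not None:
        vel = np.array(initial.velocities, dtype=float)
    elif gamma > 0:
        vel = maxwell_velocities(masses, config.temperature, rng)
    else:
        vel = np.zeros_like(pos)

    # OU step constants
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(max(1.0 - c1 * c1, 0.0))
    noise_sigma = np.sqrt(kt / masses)[:, None]
    inv_m = (1.0 / masses)[:, None]

    n_saved = config.n_steps // config.save_every + 1
    coords_out = np.empty((n_saved, len(masses), 3))
    times_out = np.empty(n_saved)
    coords_out[0] = pos
    times_out[0] = initial.time
    saved = 1

    _, forces = model.energy_forces(pos, box)
    for step in range(1, config.n_steps + 1):
        vel += 0.5 * dt * forces * inv_m
        pos += 0.5 * dt * vel
        if gamma > 0:
            vel = c1 * vel + c2 * noise_sigma * rng.standard_normal(
                pos.shape
            )
        pos += 0.5 * dt * vel
        _, forces = model.energy_forces(pos, box)
        fmax = float(np.abs(forces).max())
        if not np.isfinite(fmax) or fmax > MAX_FORCE:
            worst = int(np.abs(forces).max(axis=1).argmax())
            raise FloatingPointError(
                f"force overflow at step {step} on particle {worst} "
                f"(role {system.roles[worst]}): |F|={fmax:.3g} kJ/mol/nm"
            )
        vel += 0.5 * dt * forces * inv_m
        if step % config.save_every == 0:
            coords_out[saved] = pos
            times_out[saved] = initial.time + step * dt
            saved += 1

    meta = {"config": asdict(config), "final_velocities": vel,
            "alpha": alpha}
    return Trajectory(
        coordinates=coords_out[:saved], box=box, times=times_out[:saved],
        system=system, config=config, metadata=meta,
    )
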