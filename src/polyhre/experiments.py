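"""Desk-scale numerical experiments built from the simulator.

These are the package's coarse-grained analogues of the reference
study's observations: the non-monotonic chain size versus CaCl2
content (collapse at low molality, partial recovery at high molality)
and the faster destruction of planted calcium bridges when the
ion-carboxyl Lennard-Jones sigma is raised to the top-replica value.
Both are directional, seed-averaged checks, not quantitative
reproductions of the atomistic results.

Problem sizes (steps, seeds) default to values that keep a full
experiment in the minutes range on one core; they are parameters, and
the defaults are echoed in the returned metadata.
"""

from __future__ import annotations

import numpy as np

from .analysis.bridges import bridge_count_series
from .analysis.shape import radius_of_gyration
from .constants import SIGMA_CA_CARBOXYL
from .forcefield import EnergyModel, ForceField
from .simulate import (
    Frame,
    SimConfig,
    Trajectory,
    _steepest_descent,
    build_initial_frame,
    run_langevin,
)
from .topology import (
    ParticleSystem,
    build_chain,
    ions_for_molality,
    solvent_mass_for_box,
)

BOX = 7.0  # nm, the reference simulation box edge
N_MONOMERS = 32


def make_system(molality: float, side_len: int = 1,
                box: float = BOX) -> ParticleSystem:
    """Chain + ions for a CaCl2 molality in the reference box."""
    top = build_chain(N_MONOMERS, side_len)
    ions = ions_for_molality(molality, solvent_mass_for_box(box),
                             top.total_charge)
    return ParticleSystem(topology=top, ions=ions)


def collapse_rg(molality: float, seed: int, n_steps: int = 20000,
                side_len: int = 1, friction: float = 0.5,
                window: int = 10) -> float:
    """Late-window mean chain Rg (nm) of one seeded annealing run.

    The chain starts from a seeded extended coil and anneals for
    ``n_steps`` Langevin steps; the returned value is the mean Rg over
    the last ``window`` saved frames.
    """
    system = make_system(molality, side_len)
    rng = np.random.default_rng([seed, int(round(molality * 1000))])
    initial = build_initial_frame(system, BOX, rng)
    cfg = SimConfig(temperature=300.0, timestep=0.005, friction=friction,
                    n_steps=n_steps, save_every=max(n_steps // 40, 1),
                    seed=seed, box=BOX)
    traj = run_langevin(initial, cfg, system, rng=rng)
    sel = np.arange(system.topology.n_beads)
    rgs = [radius_of_gyration(traj.coordinates[i], sel)
           for i in range(traj.n_frames)]
    return float(np.mean(rgs[-window:]))


def make_bridged_frame(system: ParticleSystem, box: float,
                       rng: np.random.Generator,
                       contact: float = 0.30) -> Frame:
    """Start configuration with every Ca2+ planted as a bridge.

    The chain lies in a serpentine with all carboxyls on one side;
    Ca ion j sits at ``contact`` nm from the carboxyls of monomers
    (2j, 2j+1), i.e. bridging them. Remaining ions are placed randomly
    away from the chain; a short relaxation removes soft clashes.
    """
    top = system.topology
    n = system.n_particles
    pos = np.zeros((n, 3))
    per_row = 10
    spacing = 0.35
    for m in range(top.n_monomers):
        row, col = divmod(m, per_row)
        x = 1.0 + spacing * (col if row % 2 == 0 else per_row - 1 - col)
        # small zig-zag keeps backbone triples off exact collinearity
        pos[m] = [x, 1.2 + 1.3 * row + 0.02 * (m % 2), box / 2.0]
    bead = top.n_monomers
    for m in range(top.n_monomers):
        for s in range(top.side_len):
            pos[bead] = pos[m] + [0.0, 0.0, 0.35 * (s + 1) * 0.9]
            bead += 1
    carboxyls = top.charged_bead_indices
    ca_idx = system.ion_indices_of("CA")
    h = np.sqrt(max(contact**2 - (spacing / 2.0) ** 2, 1e-4))
    for j, ca in enumerate(ca_idx):
        m_a, m_b = 2 * j, 2 * j + 1
        if m_b >= top.n_monomers:
            # more ions than monomer pairs: park the rest in solution
            pos[ca] = rng.uniform(0.5, box - 0.5, 3)
            continue
        mid = 0.5 * (pos[carboxyls[m_a]] + pos[carboxyls[m_b]])
        pos[ca] = mid + [0.0, 0.0, h]
    other = np.setdiff1d(system.ion_indices, ca_idx)
    for i in other:
        for _ in range(2000):
            trial = rng.uniform(0.0, box, 3)
            d = pos[:i] - trial
            d -= box * np.round(d / box)
            if np.all(np.einsum("ij,ij->i", d, d) > 0.30**2):
                break
        pos[i] = trial
    model = EnergyModel(system, ForceField())
    pos = _steepest_descent(model, pos, box, 100, max_disp=0.005)
    return Frame(coordinates=pos, box=box, time=0.0)


def bridge_survival(sigma: float, seed: int, molality: float = 0.07,
                    epsilon: float = 0.50208, n_steps: int = 6000,
                    cutoff: float = 0.35, window: int = 5) -> float:
    """Mean number of live bridges at the end of a seeded run.

    Starts from a fully bridged configuration (one bridge per Ca2+
    where geometry allows) and integrates with the ion-carboxyl LJ pair
    set to (sigma, epsilon); returns the mean bridge count over the
    last ``window`` saved frames. Raising sigma toward the top-replica
    value weakens the Ca-carboxyl contact and dissolves bridges faster.
    """
    system = make_system(molality)
    rng = np.random.default_rng([seed, int(round(sigma * 1e4))])
    initial = make_bridged_frame(system, BOX, rng)
    ff = ForceField().with_ion_carboxyl(sigma, epsilon)
    cfg = SimConfig(temperature=300.0, timestep=0.005, friction=1.0,
                    n_steps=n_steps, save_every=max(n_steps // 20, 1),
                    seed=seed, box=BOX)
    traj = run_langevin(initial, cfg, system, ff=ff, rng=rng)
    counts = bridge_count_series(traj, cutoff)
    return float(np.mean(counts[-window:]))


def toy_exchange_acceptance(delta_over_kt: float, n_attempts: int,
                            rng: np.random.Generator,
                            temperature: float = 300.0) -> float:
    """Empirical acceptance of repeated Metropolis swap draws.

    A two-replica toy with analytic energies arranged so the exchange
    exponent equals ``delta_over_kt``; returns the accepted fraction
    over ``n_attempts`` draws.
    """
    from .constants import KB
    from .hre import exchange_probability

    du = delta_over_kt * KB * temperature
    p = exchange_probability(0.0, du, 0.0, 0.0, temperature, temperature)
    draws = rng.random(n_attempts)
    return float(np.mean(draws < p))
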