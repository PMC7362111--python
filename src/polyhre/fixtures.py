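"""Deterministic synthetic inputs with known ground truth.

Every generator here plants a property (bridges with scheduled
lifetimes, exact gyration-tensor principal radii, prescribed dihedral
states, ion lattices with chosen pair spacings, uniform ion gases) and
emits the ground truth alongside the data, so each analysis operation
can be checked against an independently constructed answer. The ground
truth is derived combinatorially from the construction schedule, never
by running the analysis being tested.

Fixtures reuse the simulator's Trajectory container so the analysis
code has a single ingestion path; their geometry is synthetic and makes
no attempt at force-field realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis.bridges import BridgeRecord
from .analysis.dihedrals import RegionMap, UNDEFINED
from .simulate import Frame, Trajectory
from .topology import IonContent, ParticleSystem, build_chain

DEFAULT_CUTOFF = 0.35  # nm; matches the analysis default


# ---------------------------------------------------------------------------
# planted calcium bridges


@dataclass(frozen=True)
class PlantedBridge:
    """One scheduled (ion, monomer pair) bridge span, frames inclusive."""

    ca_ion: int  # index among Ca2+ ions (0-based)
    monomer_a: int
    monomer_b: int
    birth: int
    death: int

    def __post_init__(self):
        if self.monomer_a == self.monomer_b:
            raise ValueError("bridge monomers must differ")
        if self.death < self.birth:
            raise ValueError("death < birth")

    @property
    def pair(self):
        return tuple(sorted((self.monomer_a, self.monomer_b)))


def _ground_truth_records(schedule, n_frames: int, ca_offset: int):
    """Bridge records implied by a schedule, by pure set algebra.

    Per frame each ion's bound-monomer set is the union of its active
    scheduled pairs; every pair within that set is a live identity.
    Contiguous runs of the same identity become records.
    """
    live = {}  # identity -> set of frames
    for f in range(n_frames):
        for ion in {s.ca_ion for s in schedule}:
            monomers = set()
            for s in schedule:
                if s.ca_ion == ion and s.birth <= f <= s.death:
                    monomers.update(s.pair)
            ms = sorted(monomers)
            for i in range(len(ms)):
                for j in range(i + 1, len(ms)):
                    live.setdefault((ion, (ms[i], ms[j])), set()).add(f)
    records = []
    for (ion, pair), frames in live.items():
        frames = sorted(frames)
        start = prev = frames[0]
        for f in frames[1:] + [None]:
            if f is not None and f == prev + 1:
                prev = f
                continue
            records.append(BridgeRecord(ca_index=ca_offset + ion,
                                        monomers=pair, birth_frame=start,
                                        death_frame=prev))
            if f is not None:
                start = prev = f
    records.sort(key=lambda r: (r.birth_frame, r.ca_index, r.monomers))
    return records


def make_planted_bridge_trajectory(
    schedule, n_frames: int, n_monomers: int = 32, side_len: int = 1,
    n_ca: int | None = None, box: float = 24.0,
    cutoff: float = DEFAULT_CUTOFF, seed: int = 0,
):
    """Trajectory whose bridge content follows ``schedule`` exactly.

    Chain beads park on a wide grid (everything farther apart than the
    cutoff); during a bridge's life the scheduled carboxyl beads gather
    around their ion at 0.25 nm. Returns ``(trajectory, records)`` with
    the ground-truth :class:`BridgeRecord` list.
    """
    schedule = list(schedule)
    top = build_chain(n_monomers, side_len)
    if n_ca is None:
        n_ca = max((s.ca_ion for s in schedule), default=-1) + 1
        n_ca = max(n_ca, 1)
    for s in schedule:
        if s.ca_ion >= n_ca:
            raise ValueError(f"schedule uses Ca ion {s.ca_ion} >= {n_ca}")
        if not (0 <= s.monomer_a < n_monomers
                and 0 <= s.monomer_b < n_monomers):
            raise ValueError("schedule monomer index out of range")
        if s.death >= n_frames:
            raise ValueError(
                f"schedule span {s.birth}-{s.death} exceeds n_frames="
                f"{n_frames}: infeasible"
            )
    ions = IonContent(n_ca=n_ca, n_cl=2 * n_ca, n_k=n_monomers)
    system = ParticleSystem(topology=top, ions=ions)
    ca_offset = top.n_beads

    spacing = max(3.0 * cutoff, 1.2)
    per_row = max(int(box // spacing) - 1, 2)

    def grid_site(k, z):
        return np.array([
            1.0 + spacing * (k % per_row),
            1.0 + spacing * (k // per_row),
            z,
        ])

    # static parking positions
    base = np.zeros((system.n_particles, 3))
    for b in range(top.n_beads):
        base[b] = grid_site(b, 1.0)
    for i, p in enumerate(range(ca_offset, system.n_particles)):
        base[p] = grid_site(i, box - 2.0)
    cluster_dirs = np.array([
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1],
        [0, 0, -1],
    ], dtype=float)

    coords = np.empty((n_frames, system.n_particles, 3))
    carboxyl_of_monomer = {
        int(top.monomer_of_bead[b]): int(b)
        for b in top.charged_bead_indices
    }
    for f in range(n_frames):
        pos = base.copy()
        owner = {}
        ions_active = {s.ca_ion for s in schedule
                       if s.birth <= f <= s.death}
        for ion in sorted(ions_active):
            monomers = set()
            for s in schedule:
                if s.ca_ion == ion and s.birth <= f <= s.death:
                    monomers.update(s.pair)
            for m in monomers:
                if owner.setdefault(m, ion) != ion:
                    raise ValueError(
                        f"infeasible schedule: monomer {m} bound to two "
                        f"ions in frame {f}"
                    )
            if len(monomers) > len(cluster_dirs):
                raise ValueError(
                    "infeasible schedule: an ion cannot coordinate more "
                    f"than {len(cluster_dirs)} monomers"
                )
            site = grid_site(ion, box / 2.0)
            pos[ca_offset + ion] = site
            for d, m in zip(cluster_dirs, sorted(monomers)):
                pos[carboxyl_of_monomer[m]] = site + 0.25 * d
        coords[f] = pos
    traj = Trajectory(
        coordinates=coords, box=box,
        times=np.arange(n_frames, dtype=float), system=system,
        metadata={"fixture": "planted_bridges", "cutoff": cutoff,
                  "seed": seed},
    )
    return traj, _ground_truth_records(schedule, n_frames, ca_offset)


# ---------------------------------------------------------------------------
# rigid shapes with exact principal radii


def make_rigid_shape_trajectory(principal_radii, n_beads: int = 500,
                                n_frames: int = 5, seed: int = 0,
                                box: float = 50.0) -> Trajectory:
    """Rigid point cloud whose gyration tensor is exactly as requested.

    A seeded Gaussian cloud is affinely corrected so its principal
    radii equal ``principal_radii`` (sorted descending, zeros allowed)
    to machine precision; each frame is a rigid rotation of the same
    cloud, so all shape metrics are frame-invariant.
    """
    radii = np.asarray(principal_radii, dtype=float)
    if radii.size != 3 or np.any(radii < 0):
        raise ValueError("principal_radii must be 3 non-negative values")
    if not (radii[0] >= radii[1] >= radii[2]):
        raise ValueError("principal_radii must be sorted descending")
    if n_beads < 4:
        raise ValueError("n_beads must be >= 4")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_beads, 3))
    x -= x.mean(axis=0)
    cov = x.T @ x / n_beads
    eigval, eigvec = np.linalg.eigh(cov)
    y = (x @ eigvec) / np.sqrt(eigval)  # whitened, identity tensor
    y = y[:, ::-1] * radii  # largest radius on the first axis
    y -= y.mean(axis=0)
    coords = np.empty((n_frames, n_beads, 3))
    center = np.full(3, box / 2.0)
    for f in range(n_frames):
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        coords[f] = y @ q.T + center
    return Trajectory(
        coordinates=coords, box=box,
        times=np.arange(n_frames, dtype=float), system=None,
        metadata={"fixture": "rigid_shape", "seed": seed,
                  "principal_radii": radii.tolist()},
    )


# ---------------------------------------------------------------------------
# dihedral state series


def make_state_series(label_matrix, region_map: RegionMap | None = None):
    """(phi, psi) arrays realizing a per-monomer/per-frame label matrix.

    Angles are placed at region centroids (and a fixed off-region point
    for "other"), so classification recovers the matrix exactly.
    Returns ``(phi, psi, labels)`` with shapes (n_frames, n_monomers).
    """
    if region_map is None:
        region_map = RegionMap.load()
    labels = np.asarray(label_matrix, dtype=object)
    if labels.ndim != 2:
        raise ValueError("label_matrix must be 2-D (frames x monomers)")
    other_point = (150.0, -150.0)
    if region_map.classify_point(*other_point) != region_map.other_label:
        raise ValueError("internal off-region anchor fell inside a region")
    phi = np.full(labels.shape, np.nan)
    psi = np.full(labels.shape, np.nan)
    for idx in np.ndindex(labels.shape):
        lab = labels[idx]
        if lab == UNDEFINED:
            continue
        if lab == region_map.other_label:
            phi[idx], psi[idx] = other_point
        elif lab in region_map.labels:
            phi[idx], psi[idx] = region_map.centroid(lab)
        else:
            raise ValueError(f"unknown label {lab!r}")
    return phi, psi, labels


def chain_from_torsions(torsions_deg, bond_length: float = 0.35,
                        bond_angle_deg: float = 110.0) -> np.ndarray:
    """Backbone coordinates realizing the given torsion sequence.

    Internal-coordinate (NeRF-style) chain building: fixed bond length
    and planar angle, torsion ``i`` set between beads (i, i+1, i+2,
    i+3) with the IUPAC sign convention. Returns (n_torsions + 3, 3).
    """
    tors = np.radians(np.asarray(torsions_deg, dtype=float))
    theta = np.radians(bond_angle_deg)
    n = tors.size + 3
    pos = np.zeros((n, 3))
    pos[1] = [bond_length, 0.0, 0.0]
    pos[2] = pos[1] + bond_length * np.array(
        [-np.cos(theta), np.sin(theta), 0.0]
    )
    for i in range(3, n):
        phi = tors[i - 3]
        b1 = pos[i - 2] - pos[i - 3]
        b2 = pos[i - 1] - pos[i - 2]
        b2h = b2 / np.linalg.norm(b2)
        nvec = np.cross(b1, b2)
        nh = nvec / np.linalg.norm(nvec)
        mh = np.cross(nh, b2h)
        d = (
            -bond_length * np.cos(theta) * b2h
            + bond_length * np.sin(theta)
            * (np.cos(phi) * mh + np.sin(phi) * nh)
        )
        pos[i] = pos[i - 1] + d
    return pos


def make_torsion_trajectory(torsion_matrix_deg, side_len: int = 1,
                            box: float = 50.0) -> Trajectory:
    """Trajectory whose backbone torsions equal ``torsion_matrix_deg``.

    Rows are frames, columns the n_monomers - 3 backbone torsions. Side
    chains are attached trivially; ions are absent.
    """
    tors = np.atleast_2d(np.asarray(torsion_matrix_deg, dtype=float))
    n_frames, n_tors = tors.shape
    n_monomers = n_tors + 3
    top = build_chain(n_monomers, side_len)
    system = ParticleSystem(
        topology=top, ions=IonContent(n_ca=0, n_cl=0, n_k=n_monomers)
    )
    coords = np.zeros((n_frames, system.n_particles, 3))
    center = np.full(3, box / 2.0)
    for f in range(n_frames):
        backbone = chain_from_torsions(tors[f, : n_monomers - 3])
        backbone = backbone - backbone.mean(axis=0) + center
        coords[f, :n_monomers] = backbone
        bead = n_monomers
        for m in range(n_monomers):
            for s in range(top.side_len):
                coords[f, bead] = backbone[m] + [0.0, 0.0,
                                                 0.25 * (s + 1)]
                bead += 1
        # K+ counterions parked far from everything
        for i, p in enumerate(range(top.n_beads, system.n_particles)):
            coords[f, p] = [1.0 + 0.8 * i, 1.0, 1.0]
    return Trajectory(
        coordinates=coords, box=box,
        times=np.arange(n_frames, dtype=float), system=system,
        metadata={"fixture": "torsion_chain"},
    )


# ---------------------------------------------------------------------------
# ion lattices and uniform gases


def make_ion_lattice(spacings, box: float = 24.0,
                     cutoff: float = DEFAULT_CUTOFF):
    """Frame whose adsorbed-Ca pair distances realize ``spacings`` (nm).

    Each spacing becomes an isolated Ca2+ pair (pairs 4 nm apart, so
    cross-pair distances stay beyond a 2 nm analysis window), with a
    carboxyl bead 0.1 nm from each ion so the pair counts as adsorbed.
    Returns ``(trajectory, ground_truth_peaks)``.
    """
    spacings = [float(s) for s in spacings]
    if not spacings or min(spacings) <= 0:
        raise ValueError("spacings must be positive")
    if max(spacings) > 3.5:
        raise ValueError("spacing beyond the 4 nm pair separation is "
                         "geometrically unrealizable here")
    n_pairs = len(spacings)
    n_monomers = max(2 * n_pairs, 4)
    top = build_chain(n_monomers, 1)
    ions = IonContent(n_ca=2 * n_pairs, n_cl=4 * n_pairs, n_k=n_monomers)
    system = ParticleSystem(topology=top, ions=ions)
    pos = np.zeros((system.n_particles, 3))
    # park everything on a far grid first
    for p in range(system.n_particles):
        pos[p] = [1.0 + 1.2 * (p % 16), 1.0 + 1.2 * (p // 16), box - 2.0]
    carboxyls = top.charged_bead_indices
    ca_idx = system.ion_indices_of("CA")
    z = box / 2.0
    for j, s in enumerate(spacings):
        c = np.array([2.0 + 4.0 * j, 2.0, z])
        a = c - [s / 2.0, 0, 0]
        b = c + [s / 2.0, 0, 0]
        pos[ca_idx[2 * j]] = a
        pos[ca_idx[2 * j + 1]] = b
        pos[carboxyls[2 * j]] = a + [0, 0.1, 0]
        pos[carboxyls[2 * j + 1]] = b + [0, 0.1, 0]
    traj = Trajectory(
        coordinates=pos[None, :, :], box=box, times=np.zeros(1),
        system=system,
        metadata={"fixture": "ion_lattice", "spacings": spacings},
    )
    return traj, tuple(sorted(spacings))


def make_uniform_gas(n_ions: int = 200, n_frames: int = 20,
                     box: float = 8.0, seed: int = 0) -> Trajectory:
    """Uniform Ca2+ gas, fully adsorbed by construction.

    Eight carboxyl beads sit at the quarter positions of the box, so
    every point lies within sqrt(3)/4 * box of a charged bead; with an
    adsorption cutoff just under box/2 all ions count as adsorbed and
    the adsorbed-pair g(r) must converge to 1.
    """
    rng = np.random.default_rng(seed)
    top = build_chain(8, 1)
    ions = IonContent(n_ca=n_ions, n_cl=2 * n_ions, n_k=8)
    system = ParticleSystem(topology=top, ions=ions)
    coords = np.empty((n_frames, system.n_particles, 3))
    quarters = np.array([
        [i, j, k] for i in (0.25, 0.75) for j in (0.25, 0.75)
        for k in (0.25, 0.75)
    ]) * box
    carboxyls = top.charged_bead_indices
    ca_idx = system.ion_indices_of("CA")
    other_ions = np.setdiff1d(system.ion_indices, ca_idx)
    for f in range(n_frames):
        pos = np.zeros((system.n_particles, 3))
        pos[carboxyls] = quarters
        pos[: top.n_beads][~np.isin(np.arange(top.n_beads), carboxyls)] = (
            quarters[: top.n_beads - len(carboxyls)] + 0.05
        )
        pos[ca_idx] = rng.uniform(0.0, box, (n_ions, 3))
        pos[other_ions] = rng.uniform(0.0, box, (other_ions.size, 3))
        coords[f] = pos
    return Trajectory(
        coordinates=coords, box=box,
        times=np.arange(n_frames, dtype=float), system=system,
        metadata={"fixture": "uniform_gas", "seed": seed},
    )
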