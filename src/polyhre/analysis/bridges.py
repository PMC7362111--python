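"""Adsorbed ions, effective complex charge, calcium bridges and loops.

An ion counts as *adsorbed* when its minimum-image distance to any
charged chain bead is within the adsorption cutoff (closed boundary: a
distance exactly equal to the cutoff is adsorbed). A Ca2+ ion forms a
*bridge* in a frame when it is simultaneously within the cutoff of
charged beads belonging to two or more distinct monomers; each
(ion, monomer pair) combination is one bridge identity, so an ion
coordinating three monomers carries three concurrent pair-bridges.

The cutoff is a model parameter, not a published value; the default of
0.35 nm is the first-minimum scale of Ca-O(carboxylate) contact
distances and is echoed into every output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..topology import ROLE_CA, ROLE_CL, ROLE_K, ParticleSystem

DEFAULT_CUTOFF = 0.35  # nm


def _min_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


def _check_cutoff(cutoff: float, box: float):
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if cutoff > box / 2:
        raise ValueError(
            f"cutoff {cutoff} nm exceeds half the box ({box / 2} nm); "
            "minimum-image distances are ambiguous"
        )


def adsorbed_ions(coordinates: np.ndarray, box: float,
                  system: ParticleSystem,
                  cutoff: float = DEFAULT_CUTOFF) -> dict:
    """Sets of adsorbed ion indices per species for one frame.

    Returns ``{"CA": set, "CL": set, "K": set}`` of global particle
    indices whose minimum-image distance to the nearest charged chain
    bead is <= cutoff.
    """
    _check_cutoff(cutoff, box)
    charged = system.topology.charged_bead_indices
    out = {ROLE_CA: set(), ROLE_CL: set(), ROLE_K: set()}
    chain_pos = coordinates[charged]
    for role in out:
        idx = system.ion_indices_of(role)
        if idx.size == 0 or charged.size == 0:
            continue
        d = coordinates[idx][:, None, :] - chain_pos[None, :, :]
        d = _min_image(d, box)
        dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        near = dist.min(axis=1) <= cutoff
        out[role] = set(int(i) for i in idx[near])
    return out


def effective_charge(coordinates: np.ndarray, box: float,
                     system: ParticleSystem,
                     cutoff: float = DEFAULT_CUTOFF,
                     include_k: bool = False) -> float:
    """Charge (e) of the chain plus its adsorbed ions.

    Zero marks exact charge neutralization; positive values indicate
    overcharging. K+ counterions are excluded by default (the complex is
    defined by the chain with its adsorbed Ca2+ and Cl-); pass
    ``include_k=True`` to count them as well.
    """
    ads = adsorbed_ions(coordinates, box, system, cutoff)
    charge = system.topology.total_charge
    charge += 2.0 * len(ads[ROLE_CA]) - 1.0 * len(ads[ROLE_CL])
    if include_k:
        charge += 1.0 * len(ads[ROLE_K])
    return float(charge)


@dataclass(frozen=True)
class BridgeRecord:
    """One contiguous lifetime of a (Ca ion, monomer pair) bridge."""

    ca_index: int
    monomers: tuple  # (m_i, m_j), m_i < m_j
    birth_frame: int
    death_frame: int  # inclusive

    def __post_init__(self):
        if self.death_frame < self.birth_frame:
            raise ValueError("death_frame must be >= birth_frame")
        if len(set(self.monomers)) < 2:
            raise ValueError("a bridge joins >= 2 distinct monomers")

    @property
    def lifetime_frames(self) -> int:
        return self.death_frame - self.birth_frame + 1

    @property
    def chain_distance(self) -> int:
        return abs(self.monomers[1] - self.monomers[0])


def bridging_pairs_in_frame(coordinates: np.ndarray, box: float,
                            system: ParticleSystem,
                            cutoff: float = DEFAULT_CUTOFF) -> set:
    """All (ca_index, (m_i, m_j)) bridge identities present in a frame."""
    _check_cutoff(cutoff, box)
    top = system.topology
    charged = top.charged_bead_indices
    ca_idx = system.ion_indices_of(ROLE_CA)
    pairs = set()
    if ca_idx.size == 0 or charged.size == 0:
        return pairs
    d = coordinates[ca_idx][:, None, :] - coordinates[charged][None, :, :]
    d = _min_image(d, box)
    dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    within = dist <= cutoff
    monomer_of_charged = top.monomer_of_bead[charged]
    for row, ca in enumerate(ca_idx):
        monomers = sorted(set(monomer_of_charged[within[row]].tolist()))
        for ai in range(len(monomers)):
            for bi in range(ai + 1, len(monomers)):
                pairs.add((int(ca), (int(monomers[ai]),
                                     int(monomers[bi]))))
    return pairs


def detect_bridges(trajectory, cutoff: float = DEFAULT_CUTOFF,
                   gap_tolerance: int = 0) -> list:
    """Bridge records with lifetimes over a trajectory.

    A bridge's identity is its (Ca ion, monomer pair); a contiguous
    span of bridging frames is one record, and spans separated by at
    most ``gap_tolerance`` non-bridging frames are merged. Records are
    sorted by birth frame (then ion, then monomers).
    """
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be >= 0")
    system = trajectory.system
    open_spans = {}  # identity -> [birth, last_seen]
    closed = []
    for f in range(trajectory.n_frames):
        present = bridging_pairs_in_frame(
            trajectory.coordinates[f], trajectory.box, system, cutoff
        )
        for ident in present:
            if ident in open_spans:
                open_spans[ident][1] = f
            else:
                open_spans[ident] = [f, f]
        stale = [
            ident for ident, (_, last) in open_spans.items()
            if ident not in present and f - last > gap_tolerance
        ]
        for ident in stale:
            birth, last = open_spans.pop(ident)
            closed.append(BridgeRecord(ident[0], ident[1], birth, last))
    for ident, (birth, last) in open_spans.items():
        closed.append(BridgeRecord(ident[0], ident[1], birth, last))
    closed.sort(key=lambda r: (r.birth_frame, r.ca_index, r.monomers))
    return closed


def bridge_count_series(trajectory, cutoff: float = DEFAULT_CUTOFF):
    """Number of distinct bridge identities in each frame."""
    return np.array([
        len(bridging_pairs_in_frame(trajectory.coordinates[f],
                                    trajectory.box, trajectory.system,
                                    cutoff))
        for f in range(trajectory.n_frames)
    ])


def loop_distribution(bridges, trajectory=None,
                      cutoff: float = DEFAULT_CUTOFF,
                      per_frame: bool = True) -> dict:
    """Histogram of along-chain distances between bridged monomers.

    With ``per_frame=True`` (default) each bridge contributes once per
    frame it lives, weighting persistent loops by their lifetime; with
    ``per_frame=False`` each record contributes once. Returns
    ``{chain_distance: count}``.
    """
    counts = {}
    for rec in bridges:
        weight = rec.lifetime_frames if per_frame else 1
        d = rec.chain_distance
        counts[d] = counts.get(d, 0) + weight
    return dict(sorted(counts.items()))
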