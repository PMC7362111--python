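"""Bead-spring chain architecture and ion bookkeeping.

The coarse-grained chain has one backbone bead per monomer and a short
side chain of ``side_len`` beads; the terminal side-chain bead carries
the deprotonated carboxyl charge of -1 e. ``side_len=1`` emulates a
poly(aspartic acid)-like architecture, ``side_len=2`` a poly(glutamic
acid)-like one (one extra methylene-equivalent bead).

Bead ordering is deterministic: backbone beads 0..n-1 first, then side
chains monomer by monomer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import AVOGADRO

# particle role labels
ROLE_BACKBONE = "BB"
ROLE_SIDE = "SC"
ROLE_CARBOXYL = "CX"
ROLE_CA = "CA"
ROLE_CL = "CL"
ROLE_K = "K"

CHAIN_ROLES = (ROLE_BACKBONE, ROLE_SIDE, ROLE_CARBOXYL)
ION_ROLES = (ROLE_CA, ROLE_CL, ROLE_K)


@dataclass(frozen=True)
class ChainTopology:
    """Connectivity and charge layout of one coarse-grained chain."""

    n_monomers: int
    side_len: int
    bead_charges: np.ndarray  # (n_beads,) elementary charges
    bead_roles: tuple  # (n_beads,) role labels
    bond_list: np.ndarray  # (n_bonds, 2) bead indices
    angle_list: np.ndarray  # (n_angles, 3) backbone triples
    dihedral_list: np.ndarray  # (n_monomers-3, 4) backbone quadruples
    monomer_of_bead: np.ndarray  # (n_beads,) 0-based monomer index

    @property
    def n_beads(self) -> int:
        return self.bead_charges.size

    @property
    def total_charge(self) -> float:
        return float(self.bead_charges.sum())

    @property
    def backbone_indices(self) -> np.ndarray:
        return np.arange(self.n_monomers)

    @property
    def charged_bead_indices(self) -> np.ndarray:
        """Indices of the carboxyl(ate) beads (one per monomer)."""
        return np.nonzero(self.bead_charges != 0)[0]


def build_chain(n_monomers: int, side_len: int) -> ChainTopology:
    """Construct the chain topology for ``n_monomers`` monomers.

    Parameters
    ----------
    n_monomers:
        Degree of polymerization; must be >= 4 so that at least one
        backbone torsion exists.
    side_len:
        Number of side-chain beads per monomer; the terminal one is the
        charged carboxyl bead. Values outside {1, 2} are permitted but
        flagged with a warning (they leave the reference architectures).
    """
    if n_monomers < 4:
        raise ValueError(
            f"n_monomers={n_monomers}: at least 4 monomers are required "
            "to define a backbone dihedral"
        )
    if side_len < 1:
        raise ValueError("side_len must be >= 1 (the charged terminus)")
    if side_len not in (1, 2):
        warnings.warn(
            f"side_len={side_len} is outside the reference architectures "
            "(1 = PASA-like, 2 = PGA-like)",
            stacklevel=2,
        )

    n_beads = n_monomers * (1 + side_len)
    charges = np.zeros(n_beads)
    roles = [ROLE_BACKBONE] * n_monomers
    monomer_of_bead = np.empty(n_beads, dtype=np.intp)
    monomer_of_bead[:n_monomers] = np.arange(n_monomers)

    bonds = [(i, i + 1) for i in range(n_monomers - 1)]
    # side chains, monomer by monomer
    next_bead = n_monomers
    for m in range(n_monomers):
        prev = m  # attach to the backbone bead
        for s in range(side_len):
            bonds.append((prev, next_bead))
            monomer_of_bead[next_bead] = m
            terminal = s == side_len - 1
            roles.append(ROLE_CARBOXYL if terminal else ROLE_SIDE)
            if terminal:
                charges[next_bead] = -1.0
            prev = next_bead
            next_bead += 1

    angles = np.array(
        [(i, i + 1, i + 2) for i in range(n_monomers - 2)], dtype=np.intp
    )
    dihedrals = np.array(
        [(i, i + 1, i + 2, i + 3) for i in range(n_monomers - 3)],
        dtype=np.intp,
    )
    return ChainTopology(
        n_monomers=n_monomers,
        side_len=side_len,
        bead_charges=charges,
        bead_roles=tuple(roles),
        bond_list=np.array(bonds, dtype=np.intp),
        angle_list=angles,
        dihedral_list=dihedrals,
        monomer_of_bead=monomer_of_bead,
    )


@dataclass(frozen=True)
class IonContent:
    """Explicit ion counts of one simulated system.

    Electroneutrality with the chain and CaCl2 stoichiometry are
    enforced at construction.
    """

    n_ca: int
    n_cl: int
    n_k: int
    molality: float = 0.0

    def __post_init__(self):
        if min(self.n_ca, self.n_cl, self.n_k) < 0:
            raise ValueError("ion counts must be non-negative")
        if self.n_cl != 2 * self.n_ca:
            raise ValueError(
                f"CaCl2 stoichiometry violated: n_cl={self.n_cl} != "
                f"2*n_ca={2 * self.n_ca}"
            )

    @property
    def n_ions(self) -> int:
        return self.n_ca + self.n_cl + self.n_k

    def net_charge(self, chain_charge: float) -> float:
        return chain_charge + 2 * self.n_ca - self.n_cl + self.n_k

    def is_electroneutral(self, chain_charge: float) -> bool:
        return self.net_charge(chain_charge) == 0


def ions_for_molality(
    molality: float, solvent_mass: float, chain_charge: float
) -> IonContent:
    """Ion counts for a CaCl2 molality in a given solvent mass.

    Parameters
    ----------
    molality:
        CaCl2 concentration in mol per kg of solvent (>= 0).
    solvent_mass:
        Solvent mass in kg (e.g. density * box volume).
    chain_charge:
        Total chain charge in e (negative); neutralized by K+ ions,
        one per charged monomer.
    """
    if molality < 0:
        raise ValueError("molality must be >= 0")
    if solvent_mass <= 0:
        raise ValueError("solvent_mass must be > 0")
    n_ca = int(round(molality * solvent_mass * AVOGADRO))
    return IonContent(
        n_ca=n_ca,
        n_cl=2 * n_ca,
        n_k=int(round(abs(chain_charge))),
        molality=molality,
    )


def solvent_mass_for_box(box: float, density: float = 997.0) -> float:
    """Mass (kg) of solvent filling a cubic box of edge ``box`` nm."""
    return density * (box * 1e-9) ** 3


@dataclass(frozen=True)
class ParticleSystem:
    """A chain plus its explicit ions: the complete particle set.

    Particle ordering: chain beads (as in :class:`ChainTopology`), then
    Ca2+, Cl-, K+ ions.
    """

    topology: ChainTopology
    ions: IonContent
    masses: np.ndarray = field(default=None)

    def __post_init__(self):
        if not self.ions.is_electroneutral(self.topology.total_charge):
            raise ValueError(
                "system is not electroneutral: net charge "
                f"{self.ions.net_charge(self.topology.total_charge)}"
            )
        if self.masses is None:
            object.__setattr__(self, "masses", self._default_masses())

    def _default_masses(self) -> np.ndarray:
        per_role = {
            ROLE_BACKBONE: 56.0,  # backbone unit (CH-CO-NH equivalent)
            ROLE_SIDE: 14.0,  # methylene-equivalent linker
            ROLE_CARBOXYL: 44.0,  # CO2- group
            ROLE_CA: 40.08,
            ROLE_CL: 35.45,
            ROLE_K: 39.10,
        }
        return np.array([per_role[r] for r in self.roles])

    @property
    def n_particles(self) -> int:
        return self.topology.n_beads + self.ions.n_ions

    @property
    def roles(self) -> tuple:
        ions = self.ions
        return (
            self.topology.bead_roles
            + (ROLE_CA,) * ions.n_ca
            + (ROLE_CL,) * ions.n_cl
            + (ROLE_K,) * ions.n_k
        )

    @property
    def charges(self) -> np.ndarray:
        ions = self.ions
        ion_charges = np.concatenate(
            [
                np.full(ions.n_ca, 2.0),
                np.full(ions.n_cl, -1.0),
                np.full(ions.n_k, 1.0),
            ]
        )
        return np.concatenate([self.topology.bead_charges, ion_charges])

    @property
    def ion_indices(self) -> np.ndarray:
        return np.arange(self.topology.n_beads, self.n_particles)

    def ion_indices_of(self, role: str) -> np.ndarray:
        roles = np.asarray(self.roles)
        return np.nonzero(roles == role)[0]
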