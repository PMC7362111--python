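"""Coarse-grained force field: bonded terms, Lennard-Jones, implicit-
solvent Coulomb, and the alpha-scaled dihedral bias.

The nonbonded pair energy is the 12-6 Lennard-Jones form

    U(r) = 4 eps [ (sigma/r)^12 - (sigma/r)^6 ]

truncated and shifted at the cutoff, with ``sigma`` and ``eps`` set per
particle-role pair (Lorentz-Berthelot mixing with explicit overrides,
notably the ion-carboxyl pair whose sigma/eps the replica ladder
varies). Electrostatics are Bjerrum-scaled Coulomb in implicit solvent,

    U(r) = kB T_ref l_B q_i q_j / r,

truncated and shifted at a cutoff of several Bjerrum lengths — an
accuracy/speed trade-off relative to lattice-sum methods, with the
cutoff exposed in the configuration.

Inner loops are JIT-compiled with numba when available and fall back to
the pure-Python implementations otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import BJERRUM_WATER, COULOMB_T_REF, KB, SIGMA_CA_CARBOXYL
from .topology import (
    ROLE_BACKBONE,
    ROLE_CA,
    ROLE_CARBOXYL,
    ROLE_CL,
    ROLE_K,
    ROLE_SIDE,
    ParticleSystem,
)

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


OVERLAP_TOL = 1e-6  # nm; pairs closer than this signal a corrupt frame


@dataclass(frozen=True)
class PairPotential:
    """Lennard-Jones parameters of one pair class."""

    sigma: float  # nm, distance of zero pair energy
    epsilon: float  # kJ/mol, well depth

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")

    def energy(self, r):
        sr6 = (self.sigma / np.asarray(r)) ** 6
        return 4 * self.epsilon * (sr6 * sr6 - sr6)


#: Default per-role LJ parameters (self pairs); cross pairs by
#: Lorentz-Berthelot mixing unless overridden.
DEFAULT_ROLE_LJ = {
    ROLE_BACKBONE: PairPotential(0.40, 0.50),
    ROLE_SIDE: PairPotential(0.35, 0.50),
    ROLE_CARBOXYL: PairPotential(0.35, 0.50),
    ROLE_CA: PairPotential(0.24, 0.50),
    ROLE_CL: PairPotential(0.40, 0.50),
    ROLE_K: PairPotential(0.30, 0.50),
}


def default_pair_overrides() -> dict:
    return {
        frozenset((ROLE_CA, ROLE_CARBOXYL)): PairPotential(
            SIGMA_CA_CARBOXYL, 0.50208
        )
    }


@dataclass(frozen=True)
class ForceField:
    """Parameter set of the coarse-grained model.

    The bonded stiffnesses are free parameters of the model (no
    transferable reference exists for them); defaults give a flexible,
    numerically well-behaved chain and are echoed into every run's
    metadata.
    """

    bond_k: float = 2000.0  # kJ/mol/nm^2
    bond_r0: float = 0.35  # nm
    angle_k: float = 25.0  # kJ/mol/rad^2
    angle_theta0: float = math.radians(130.0)
    dihedral_k: float = 1.5  # kJ/mol, 3-fold torsional barrier
    dihedral_mult: int = 3
    dihedral_phase: float = 0.0
    role_lj: dict = field(default_factory=lambda: dict(DEFAULT_ROLE_LJ))
    pair_overrides: dict = field(default_factory=default_pair_overrides)
    lj_cutoff: float = 1.2  # nm
    coulomb_cutoff: float = 2.1  # nm, >= 3 Bjerrum lengths
    bjerrum_length: float = BJERRUM_WATER

    def with_ion_carboxyl(self, sigma: float, epsilon: float) -> "ForceField":
        """Copy with the Ca2+-carboxyl LJ pair replaced (replica ladder)."""
        overrides = dict(self.pair_overrides)
        overrides[frozenset((ROLE_CA, ROLE_CARBOXYL))] = PairPotential(
            sigma, epsilon
        )
        return replace(self, pair_overrides=overrides)

    def pair_potential(self, role_i: str, role_j: str) -> PairPotential:
        key = frozenset((role_i, role_j))
        if key in self.pair_overrides:
            return self.pair_overrides[key]
        a, b = self.role_lj[role_i], self.role_lj[role_j]
        return PairPotential(
            0.5 * (a.sigma + b.sigma), math.sqrt(a.epsilon * b.epsilon)
        )

    @property
    def coulomb_prefactor(self) -> float:
        """kB T_ref l_B, kJ/mol nm per unit charge product."""
        return KB * COULOMB_T_REF * self.bjerrum_length


# ---------------------------------------------------------------------------
# kernels


@njit(cache=True)
def _min_image(d, box):
    return d - box * np.round(d / box)


@njit(cache=True)
def _nonbonded_kernel(pos, box, sig, eps, qq, excl, lj_cut, coul_cut, forces):
    n = pos.shape[0]
    energy = 0.0
    lj_cut2 = lj_cut * lj_cut
    coul_cut2 = coul_cut * coul_cut
    for i in range(n):
        for j in range(i + 1, n):
            if excl[i, j]:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box * round(dx / box)
            dy -= box * round(dy / box)
            dz -= box * round(dz / box)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < OVERLAP_TOL * OVERLAP_TOL:
                return np.nan  # overlapping pair; caller raises
            fscal = 0.0
            if r2 < lj_cut2:
                s2 = sig[i, j] * sig[i, j] / r2
                s6 = s2 * s2 * s2
                s12 = s6 * s6
                # shift so U(lj_cut) = 0
                sc2 = sig[i, j] * sig[i, j] / lj_cut2
                sc6 = sc2 * sc2 * sc2
                energy += 4.0 * eps[i, j] * (s12 - s6 - sc6 * sc6 + sc6)
                fscal += 4.0 * eps[i, j] * (12.0 * s12 - 6.0 * s6) / r2
            if qq[i, j] != 0.0 and r2 < coul_cut2:
                r = math.sqrt(r2)
                energy += qq[i, j] * (1.0 / r - 1.0 / coul_cut)
                fscal += qq[i, j] / (r2 * r)
            if fscal != 0.0:
                forces[i, 0] += fscal * dx
                forces[i, 1] += fscal * dy
                forces[i, 2] += fscal * dz
                forces[j, 0] -= fscal * dx
                forces[j, 1] -= fscal * dy
                forces[j, 2] -= fscal * dz
    return energy


@njit(cache=True)
def _bond_kernel(pos, box, bonds, k, r0, forces):
    energy = 0.0
    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box * round(dx / box)
        dy -= box * round(dy / box)
        dz -= box * round(dz / box)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0
        energy += 0.5 * k * dr * dr
        fscal = -k * dr / r
        forces[i, 0] += fscal * dx
        forces[i, 1] += fscal * dy
        forces[i, 2] += fscal * dz
        forces[j, 0] -= fscal * dx
        forces[j, 1] -= fscal * dy
        forces[j, 2] -= fscal * dz
    return energy


@njit(cache=True)
def _angle_kernel(pos, box, angles, k, theta0, forces):
    energy = 0.0
    for t in range(angles.shape[0]):
        i, j, l = angles[t, 0], angles[t, 1], angles[t, 2]
        ax = pos[i, 0] - pos[j, 0]
        ay = pos[i, 1] - pos[j, 1]
        az = pos[i, 2] - pos[j, 2]
        bx = pos[l, 0] - pos[j, 0]
        by = pos[l, 1] - pos[j, 1]
        bz = pos[l, 2] - pos[j, 2]
        ax -= box * round(ax / box)
        ay -= box * round(ay / box)
        az -= box * round(az / box)
        bx -= box * round(bx / box)
        by -= box * round(by / box)
        bz -= box * round(bz / box)
        la = math.sqrt(ax * ax + ay * ay + az * az)
        lb = math.sqrt(bx * bx + by * by + bz * bz)
        cos_t = (ax * bx + ay * by + az * bz) / (la * lb)
        if cos_t > 1.0:
            cos_t = 1.0
        elif cos_t < -1.0:
            cos_t = -1.0
        theta = math.acos(cos_t)
        dtheta = theta - theta0
        energy += 0.5 * k * dtheta * dtheta
        sin_t = math.sqrt(1.0 - cos_t * cos_t)
        if sin_t < 1e-8:
            sin_t = 1e-8
        coeff = k * dtheta / sin_t
        # dtheta/dr_i and dtheta/dr_l
        f_ix = coeff * (bx / (la * lb) - cos_t * ax / (la * la))
        f_iy = coeff * (by / (la * lb) - cos_t * ay / (la * la))
        f_iz = coeff * (bz / (la * lb) - cos_t * az / (la * la))
        f_lx = coeff * (ax / (la * lb) - cos_t * bx / (lb * lb))
        f_ly = coeff * (ay / (la * lb) - cos_t * by / (lb * lb))
        f_lz = coeff * (az / (la * lb) - cos_t * bz / (lb * lb))
        forces[i, 0] += f_ix
        forces[i, 1] += f_iy
        forces[i, 2] += f_iz
        forces[l, 0] += f_lx
        forces[l, 1] += f_ly
        forces[l, 2] += f_lz
        forces[j, 0] -= f_ix + f_lx
        forces[j, 1] -= f_iy + f_ly
        forces[j, 2] -= f_iz + f_lz
    return energy


@njit(cache=True)
def _dihedral_kernel(
    pos, box, quads, kd, mult, phase, alpha, bias_k, bias_a, forces
):
    energy = 0.0
    for q in range(quads.shape[0]):
        i1, i2, i3, i4 = quads[q, 0], quads[q, 1], quads[q, 2], quads[q, 3]
        b1 = np.empty(3)
        b2 = np.empty(3)
        b3 = np.empty(3)
        for d in range(3):
            b1[d] = pos[i2, d] - pos[i1, d]
            b2[d] = pos[i3, d] - pos[i2, d]
            b3[d] = pos[i4, d] - pos[i3, d]
            b1[d] -= box * round(b1[d] / box)
            b2[d] -= box * round(b2[d] / box)
            b3[d] -= box * round(b3[d] / box)
        n1 = np.empty(3)
        n2 = np.empty(3)
        n1[0] = b1[1] * b2[2] - b1[2] * b2[1]
        n1[1] = b1[2] * b2[0] - b1[0] * b2[2]
        n1[2] = b1[0] * b2[1] - b1[1] * b2[0]
        n2[0] = b2[1] * b3[2] - b2[2] * b3[1]
        n2[1] = b2[2] * b3[0] - b2[0] * b3[2]
        n2[2] = b2[0] * b3[1] - b2[1] * b3[0]
        lb2 = math.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
        ln1 = n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2
        ln2 = n2[0] ** 2 + n2[1] ** 2 + n2[2] ** 2
        if ln1 < 1e-12 or ln2 < 1e-12:
            continue  # collinear triple: torsion undefined, zero force
        m1x = n1[1] * n2[2] - n1[2] * n2[1]
        m1y = n1[2] * n2[0] - n1[0] * n2[2]
        m1z = n1[0] * n2[1] - n1[1] * n2[0]
        y = (m1x * b2[0] + m1y * b2[1] + m1z * b2[2]) / lb2
        x = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
        phi = math.atan2(y, x)
        # energy and -dU/dphi
        energy += kd * (1.0 + math.cos(mult * phi - phase))
        du = -kd * mult * math.sin(mult * phi - phase)
        if alpha != 0.0:
            for n in range(bias_k.shape[0]):
                nn = n + 1
                energy += alpha * bias_k[n] * (
                    1.0 + math.cos(nn * phi - bias_a[n])
                )
                du += -alpha * bias_k[n] * nn * math.sin(nn * phi - bias_a[n])
        c1 = du * lb2 / ln1
        c4 = -du * lb2 / ln2
        f1 = np.empty(3)
        f4 = np.empty(3)
        for d in range(3):
            f1[d] = c1 * n1[d]
            f4[d] = c4 * n2[d]
        tb = (b1[0] * b2[0] + b1[1] * b2[1] + b1[2] * b2[2]) / (lb2 * lb2)
        sb = (b3[0] * b2[0] + b3[1] * b2[1] + b3[2] * b2[2]) / (lb2 * lb2)
        for d in range(3):
            forces[i1, d] += f1[d]
            forces[i2, d] += -(1.0 + tb) * f1[d] + sb * f4[d]
            forces[i3, d] += tb * f1[d] - (1.0 + sb) * f4[d]
            forces[i4, d] += f4[d]
    return energy


# ---------------------------------------------------------------------------


class EnergyModel:
    """Force field bound to a concrete particle system.

    Precomputes per-pair LJ/Coulomb parameter tables and the bonded
    exclusion mask (1-2 and 1-3 neighbours) so that energies and forces
    are evaluated by flat array kernels.
    """

    def __init__(self, system: ParticleSystem, ff: ForceField,
                 alpha: float = 0.0, bias=None):
        self.system = system
        self.ff = ff
        self.alpha = float(alpha)
        if bias is None:
            self.bias_k = np.zeros(1)
            self.bias_a = np.zeros(1)
        else:
            self.bias_k = np.asarray(bias.k, dtype=float)
            self.bias_a = np.asarray(bias.a, dtype=float)

        roles = system.roles
        n = system.n_particles
        unique_roles = sorted(set(roles))
        sig = np.empty((n, n))
        eps = np.empty((n, n))
        pair = {}
        for a in unique_roles:
            for b in unique_roles:
                pair[(a, b)] = ff.pair_potential(a, b)
        role_idx = np.array(roles)
        for i in range(n):
            for j in range(n):
                p = pair[(role_idx[i], role_idx[j])]
                sig[i, j] = p.sigma
                eps[i, j] = p.epsilon
        q = system.charges
        self.sig = sig
        self.eps = eps
        self.qq = np.outer(q, q) * ff.coulomb_prefactor

        excl = np.zeros((n, n), dtype=np.bool_)
        top = system.topology
        adj = [[] for _ in range(top.n_beads)]
        for i, j in top.bond_list:
            excl[i, j] = excl[j, i] = True
            adj[i].append(j)
            adj[j].append(i)
        for i in range(top.n_beads):  # 1-3 exclusions
            for j in adj[i]:
                for l in adj[j]:
                    if l != i:
                        excl[i, l] = excl[l, i] = True
        self.excl = excl

        self.bonds = np.ascontiguousarray(top.bond_list)
        self.angles = np.ascontiguousarray(top.angle_list)
        self.dihedrals = np.ascontiguousarray(top.dihedral_list)

    def energy_forces(self, positions: np.ndarray, box: float):
        """Total potential energy (kJ/mol) and forces (kJ/mol/nm)."""
        pos = np.ascontiguousarray(positions, dtype=float)
        forces = np.zeros_like(pos)
        ff = self.ff
        e_nb = _nonbonded_kernel(
            pos, box, self.sig, self.eps, self.qq, self.excl,
            ff.lj_cutoff, ff.coulomb_cutoff, forces,
        )
        if math.isnan(e_nb):
            raise ValueError(
                "overlapping particles (pair distance < "
                f"{OVERLAP_TOL} nm): corrupt frame"
            )
        e = e_nb
        e += _bond_kernel(pos, box, self.bonds, ff.bond_k, ff.bond_r0, forces)
        if len(self.angles):
            e += _angle_kernel(
                pos, box, self.angles, ff.angle_k, ff.angle_theta0, forces
            )
        if len(self.dihedrals):
            e += _dihedral_kernel(
                pos, box, self.dihedrals, ff.dihedral_k,
                float(ff.dihedral_mult), ff.dihedral_phase,
                self.alpha, self.bias_k, self.bias_a, forces,
            )
        return e, forces

    def energy(self, positions: np.ndarray, box: float) -> float:
        return self.energy_forces(positions, box)[0]


def total_energy(frame, system: ParticleSystem, ff: ForceField,
                 alpha: float = 0.0, bias=None) -> float:
    """Total potential energy of one frame under the given Hamiltonian."""
    model = EnergyModel(system, ff, alpha=alpha, bias=bias)
    return model.energy(frame.coordinates, frame.box)
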