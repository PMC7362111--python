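"""Physical constants and reference values shared across the package.

Internal units follow the GROMACS convention: length in nm, energy in
kJ/mol, time in ps, mass in g/mol (amu), temperature in K, charge in
elementary units.
"""

#: Boltzmann constant, kJ mol^-1 K^-1.
KB = 8.31446261815324e-3

#: Avogadro constant, mol^-1.
AVOGADRO = 6.02214076e23

#: Density of liquid water at ~300 K, kg m^-3 (used to convert a cubic
#: solvent box into a solvent mass for molality -> ion-count conversion).
WATER_DENSITY = 997.0

#: Ion-carboxyl Lennard-Jones sigma (nm): the corrected value of Church
#: et al. adopted as the default contact parameter for Ca2+ with a
#: carboxyl(ate) bead, and the uncorrected value it replaced.
SIGMA_CA_CARBOXYL = 0.281
SIGMA_CA_CARBOXYL_UNCORRECTED = 0.2732

#: Replica-ladder endpoints for the 21-replica Hamiltonian replica
#: exchange scheme: temperature (K), dihedral-bias scale alpha
#: (dimensionless), ion-carboxyl LJ sigma (nm) and epsilon (kJ/mol).
LADDER_T_RANGE = (300.0, 315.0)
LADDER_ALPHA_RANGE = (0.0, -1.0)
LADDER_SIGMA_RANGE = (0.273239, 0.31)
LADDER_EPSILON_RANGE = (0.50208, 0.472106)
LADDER_N_REPLICAS = 21

#: Ca-Ca nearest-neighbour peak positions (nm) in calcium oxalate
#: tri-hydrate (COT) and di-hydrate (COD) crystals, used as reference
#: peak lists when matching adsorbed-ion pair distributions.
COT_PEAKS = (0.47, 0.53, 0.63, 0.88)
COD_PEAKS = (0.43, 0.63, 0.99, 1.38)

#: CaCl2 concentration (mol per kg of water) -> number of Ca2+ ions for
#: the simulated 7 nm box systems, as used in the reference study.
ION_COUNTS_BY_MOLALITY = {
    0.0: 0,
    0.03: 6,
    0.07: 14,
    0.29: 58,
    0.75: 145,
    1.0: 190,
}

#: Bjerrum length of water at ~300 K, nm. Sets the Coulomb strength of
#: the implicit-solvent model.
BJERRUM_WATER = 0.7

#: Reference temperature (K) entering the Coulomb prefactor
#: kB * T_ref * l_B; kept fixed so that the Hamiltonian does not change
#: with the thermostat target.
COULOMB_T_REF = 300.0
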