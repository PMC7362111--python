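# Methods

## The model

`polyhre` studies the Ca²⁺-induced conformational collapse of short
anionic poly(amino acid) chains with a coarse-grained, implicit-solvent
model. The chain has one backbone bead per monomer and a side chain of
`side_len` beads whose terminal bead carries the −1 e charge of a
deprotonated carboxyl group; `side_len = 1` emulates a
poly(aspartate)-like architecture and `side_len = 2` a
poly(glutamate)-like one (one extra methylene-equivalent bead — the
only structural difference between the two). The reference system is a
32-mer (total charge −32 e) in a cubic 7 nm box with explicit K⁺
counterions (one per monomer) and CaCl₂ at a prescribed molality; the
molality → ion-count conversion uses the solvent mass of the box at
997 kg/m³, giving e.g. 14 Ca²⁺ / 28 Cl⁻ at 0.07 mol/kg. At the two
highest reference salt contents this rounding gives slightly more ions
(60, 154, 206 Ca²⁺) than the reference counts (58, 145, 190), because
the real solvent mass of a packed box is reduced by the ions' own
volume; the reference counts are shipped as constants and used by the
stoichiometry checks.

Interactions:

* **Bonds / angles / torsions.** Harmonic bonds (k = 2000 kJ mol⁻¹ nm⁻²,
  r₀ = 0.35 nm), harmonic backbone angles (k = 25 kJ mol⁻¹ rad⁻²,
  θ₀ = 130°), and a mild three-fold backbone torsion
  k_d (1 + cos 3x) with k_d = 1.5 kJ/mol. No transferable reference
  exists for these stiffnesses at this resolution; they are free model
  parameters chosen for a flexible, numerically well-behaved chain and
  echoed into every run's metadata.
* **Lennard-Jones.** U(r) = 4ε[(σ/r)¹² − (σ/r)⁶], truncated-shifted at
  1.2 nm, with per-role σ/ε tables and Lorentz–Berthelot mixing. The
  ion–carboxyl pair is an explicit override: its default σ = 0.281 nm
  follows the corrected Ca²⁺–carboxylate contact parameter of Church
  et al. (raised from the uncorrected 0.2732 nm), ε = 0.50208 kJ/mol.
  This is the pair the replica ladder manipulates.
* **Electrostatics.** Bjerrum-scaled Coulomb in implicit water,
  U(r) = k_B T_ref l_B q_i q_j / r with l_B = 0.7 nm and T_ref = 300 K
  (fixed so the Hamiltonian does not change with the thermostat),
  truncated-shifted at 2.1 nm = 3 l_B. A truncated-shifted potential
  instead of a lattice sum is an accuracy/speed trade-off appropriate
  for a desk-scale model; the cutoff is a config parameter.

Dynamics are NVT Langevin (BAOAB splitting, default dt = 0.005 ps,
friction 0.5–2 ps⁻¹). There is no pressure coupling: with implicit
solvent there is no meaningful pressure. With friction = 0 the scheme
reduces exactly to velocity Verlet; the tests verify < 10⁻⁴ relative
energy drift over 10⁴ steps in that limit, equipartition of a harmonic
bond to 5%, and free-particle diffusion D = k_BT/(mγ) to 10%.

## Dihedral bias and its fit

Replica ladders flatten the backbone torsion landscape with

    U_bias(x) = α Σₙ₌₁¹⁵ kₙ (1 + cos(n x − aₙ)),   −1 ≤ α ≤ 0.

The coefficients come from the torsional potential of mean force,
estimated as the inverse-Boltzmann transform −k_BT ln p̂(x) of the
binned torsion distribution (72 uniform bins over (−π, π]; empty bins
are capped at the maximum finite PMF + k_BT and flagged). Because a PMF
carries no absolute offset, the cosine series is fitted modulo an
additive constant; on the uniform grid this reduces the fit to a
closed-form linear least-squares problem in the {cos nx, sin nx} basis
(the DFT in disguise), which is deterministic, exact for exactly
representable series, and recovers planted amplitudes within a few
percent from 10⁶ Boltzmann samples. One shared bias is fitted for all
backbone torsions; per-type fitting is available by fitting separate
angle subsets. φ and ψ are treated independently.

## Replica ladder and exchange

The 21-replica ladder interpolates all four parameters linearly between
endpoints: T 300 → 315 K, α 0 → −1, ion–carboxyl σ 0.273239 → 0.31 nm
and ε 0.50208 → 0.472106 kJ/mol. The published ε values are exactly
linear between their endpoints, so linear interpolation also realises
the "minimal neighbouring energy difference" construction that produced
them. Replica 0 is the neutral replica whose ensemble is the analysis
target.

Exchanges are Metropolis state swaps between neighbouring slots with

    P = min[1, exp(−((U_i(x_j) − U_i(x_i))/k_BT_i
                    − (U_j(x_j) − U_j(x_i))/k_BT_j))].

Design choices where the published description is silent:
configurations (not parameters) swap between fixed-parameter slots —
observationally equivalent, and it keeps per-slot ensembles contiguous;
attempts alternate between even (0-1, 2-3, …) and odd neighbour pairs
on successive epochs (standard, ergodic); velocities are not rescaled
on swap because the Langevin thermostat re-equilibrates momenta within
a few friction times. Walker identities are tracked for round-trip
(slot 0 → top → 0) diagnostics. Seeding: one master seed; per-replica
streams at fixed offsets plus a dedicated swap stream, so runs are
bit-reproducible.

## Trajectory analysis

* **Shape.** The gyration tensor's eigenvalues give principal radii
  R_x ≥ R_y ≥ R_z; asphericity b = (R_x − (R_y+R_z)/2)/R_x, shape
  anisotropy k² = 1 − 3(R_xR_y + R_yR_z + R_xR_z)/(R_x+R_y+R_z)², and
  prolateness P = (2R_x−R_y−R_z)(2R_y−R_x−R_z)(2R_z−R_y−R_x) /
  [2(R_x²+R_y²+R_z²−R_xR_y−R_yR_z−R_xR_z)^{3/2}] are evaluated on the
  radii exactly in this form; a flag switches to the
  squared-eigenvalue variant common elsewhere in the literature.
  Isotropic configurations (vanishing denominator) return P = 0 by
  convention, flagged. Metrics are computed per frame and then
  averaged; note that for strongly fluctuating shapes the mean of P
  over frames can differ visibly from P evaluated at the mean radii
  (the reported reference prolateness of the PGA 0.07 mol/kg system
  deviates ~0.04 from the closed-form value of its own mean radii for
  exactly this reason).
* **Adsorption, charge, bridges.** An ion is adsorbed when its
  minimum-image distance to the nearest charged chain bead is ≤ the
  adsorption cutoff; the boundary is closed (distance = cutoff counts).
  The cutoff is not a published value; the default 0.35 nm is the
  first-minimum scale of Ca–O(carboxylate) contacts, exposed in config
  and echoed in outputs. The effective complex charge is the chain
  charge plus adsorbed Ca²⁺ and Cl⁻ (K⁺ excluded by default, included
  behind a flag). A Ca²⁺ bridges when it is within cutoff of charged
  beads of ≥ 2 distinct monomers; a bridge's identity is the
  (ion, monomer pair), so an ion coordinating three monomers carries
  three concurrent pair-bridges (this inflates loop counts relative to
  a per-ion definition, and is documented). Lifetimes are contiguous
  bridging spans; spans separated by ≤ `gap_tolerance` frames merge.
  Loop sizes are along-chain monomer separations, weighted per frame by
  default (per-record behind a flag).
* **Dihedral states.** On a one-bead-per-monomer backbone, consecutive
  torsions serve as (φ, ψ): monomer m gets φ = torsion(m−2…m+1) and
  ψ = torsion(m−1…m+2); ψ of one monomer is therefore the same torsion
  as φ of the next, and the two monomers at each chain end are
  `undefined` and excluded from statistics. Region polygons on the
  (φ, ψ) torus (PPII, 2.5₁, 3₁₀, right/left α) ship as an editable JSON
  file of documented rectangles — defaults in the spirit of standard
  Ramachandran partitions, not an authoritative reproduction of any
  specific one. Points on shared borders resolve to the lowest region
  id; the point-in-polygon test is wrap-aware ray casting with on-edge
  inclusion. Barrier transitions are those crossing the partition
  {3₁₀, αR, αL} (compact helical) vs {2.5₁, PPII} (extended); crossings
  involving `other` count toward total transitions only.
* **Pair distributions.** g(r) over per-frame adsorbed-Ca²⁺ pairs,
  normalized by ideal-gas shell volume at the adsorbed-ion density so a
  uniform gas gives g = 1. Peaks (plateau-aware local maxima of the
  lightly smoothed profile) are matched greedily, closest pairs first,
  to the reference Ca–Ca spacings of calcium oxalate tri-hydrate
  (0.47, 0.53, 0.63, 0.88 nm) and di-hydrate (0.43, 0.63, 0.99,
  1.38 nm), which ship as constants.

## Synthetic fixtures

Every analysis operation is validated against generators that plant the
property being measured and emit the ground truth alongside the data:
scheduled bridges (ground truth derived combinatorially from the
schedule, never from distances), rigid clouds with exact principal
radii (affine-corrected Gaussian clouds, rigidly rotated per frame),
per-monomer state labels realized as region-centroid angles (and, where
the shared-torsion constraint allows, as 3-D chains built from internal
coordinates), ion lattices realizing prescribed pair spacings, and
uniform ion gases. Fixtures reuse the simulator's trajectory container,
are byte-deterministic given (spec, seed), and make no attempt at
force-field realism — passing the oracle-equivalence tests certifies
the analysis algebra, not the physics of real trajectories.

What the fixtures deliberately do not emulate: thermal noise in bridge
geometry, correlated ion motion, realistic Ramachandran densities, or
atomistic length scales. Conclusions about real (atomistic or
experimental) systems require the CG simulations plus the directional
checks below, and carry the usual caveats of a two-orders-coarser
model.

## Desk-scale experiment defaults

The qualitative reference behaviours are reproduced as seed-averaged
directional experiments at the reference system size (32-mer, 7 nm box,
reference molalities): annealing a seeded extended coil for 2×10⁴ steps
(dt 0.005 ps, friction 0.5 ps⁻¹) and averaging chain R_g over the last
quarter gives the collapse (R_g drops from ≈1.8 nm salt-free to
≈1.4 nm at 0.07 mol/kg) and partial recovery (≈1.5 nm at 0.29 mol/kg);
starting from a serpentine chain with every Ca²⁺ planted as a bridge
and integrating 6×10³ steps shows faster bridge dissolution at the
top-replica σ = 0.31 nm than at 0.281 nm. These run sizes are chosen so
a full five-seed experiment completes in minutes on one core; they are
parameters of `polyhre.experiments`, not hard-coded.

## Numerical notes and limitations

* Pairwise kernels are O(N²) (no cell lists) — appropriate for ≤ 10³
  particles; numba-JIT-compiled with a pure-Python fallback.
* Collinear backbone triples make a torsion undefined; the kernel
  skips them with zero force rather than dividing by zero.
* Overlapping particles (r < 10⁻⁶ nm) raise immediately as corrupt
  input; forces above 10⁷ kJ mol⁻¹ nm⁻¹ abort the run naming the
  particle and step.
* The molality → count conversion rounds to the nearest integer ion;
  electroneutrality is enforced exactly through the K⁺ count.
* GRO output is single-frame (last frame); PDB/XYZ are multi-frame.
  PDB/XYZ I/O runs through MDAnalysis and is Ångström on disk,
  nm in memory.
* The CG model makes no attempt to reproduce absolute atomistic R_g
  values in nm; only directions and orderings of changes are
  meaningful, which is how the tests treat them.
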