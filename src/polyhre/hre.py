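"""Hamiltonian replica exchange over a (T, alpha, sigma, epsilon) ladder.

Each replica slot holds a fixed Hamiltonian: thermostat temperature T,
dihedral-bias scale alpha, and the ion-carboxyl Lennard-Jones sigma and
epsilon. All four parameters are linearly interpolated between the
ladder endpoints; with 21 replicas and the reference endpoints this
reproduces the published parameter table row for row. Slot 0 is the
neutral replica (unbiased Hamiltonian), whose ensemble is the analysis
target.

Exchange attempts are Metropolis moves between neighbouring slots with
acceptance

    P = min[1, exp(-( (U_i(x_j) - U_i(x_i)) / kB T_i
                    - (U_j(x_j) - U_j(x_i)) / kB T_j ))],

where U_i is the Hamiltonian of slot i evaluated on a configuration x.
On acceptance the *configurations* swap between slots (state exchange);
walker identities are tracked for round-trip diagnostics. Attempts
alternate between even (0-1, 2-3, ...) and odd (1-2, 3-4, ...) neighbour
pairs on successive attempt epochs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .constants import (
    KB,
    LADDER_ALPHA_RANGE,
    LADDER_EPSILON_RANGE,
    LADDER_N_REPLICAS,
    LADDER_SIGMA_RANGE,
    LADDER_T_RANGE,
)
from .forcefield import EnergyModel, ForceField
from .simulate import Frame, SimConfig, Trajectory, run_langevin
from .topology import ParticleSystem


@dataclass(frozen=True)
class ReplicaParams:
    """Hamiltonian of one replica slot."""

    index: int
    temperature: float  # K
    alpha: float  # dihedral-bias scale, <= 0
    sigma: float  # ion-carboxyl LJ sigma, nm
    epsilon: float  # ion-carboxyl LJ epsilon, kJ/mol

    def __post_init__(self):
        if self.temperature <= 0 or self.sigma <= 0 or self.epsilon <= 0:
            raise ValueError("temperature, sigma and epsilon must be > 0")


@dataclass(frozen=True)
class ReplicaLadder:
    """Ordered replica slots; index 0 is the neutral replica."""

    replicas: tuple

    def __post_init__(self):
        for name in ("temperature", "alpha", "sigma", "epsilon"):
            vals = [getattr(r, name) for r in self.replicas]
            diffs = np.diff(vals)
            if len(diffs) and not (
                np.all(diffs > 0) or np.all(diffs < 0) or np.all(diffs == 0)
            ):
                raise ValueError(f"ladder not monotone in {name}")

    def __len__(self):
        return len(self.replicas)

    def __getitem__(self, i):
        return self.replicas[i]

    def __iter__(self):
        return iter(self.replicas)

    def as_table(self) -> str:
        """Tab-separated echo in the published format."""
        lines = ["Replica\tT, K\talpha\tsigma, nm\teps, kJ/mol"]
        for r in self.replicas:
            lines.append(
                f"{r.index}\t{r.temperature:g}\t{r.alpha:g}"
                f"\t{r.sigma:g}\t{r.epsilon:g}"
            )
        return "\n".join(lines)


def build_ladder(
    n_replicas: int = LADDER_N_REPLICAS,
    T_range=LADDER_T_RANGE,
    alpha_range=LADDER_ALPHA_RANGE,
    sigma_range=LADDER_SIGMA_RANGE,
    epsilon_range=LADDER_EPSILON_RANGE,
) -> ReplicaLadder:
    """Linear ladder: every parameter interpolated endpoint-to-endpoint.

    The published epsilon values are exactly linear between their
    endpoints, so linear interpolation reproduces the full reference
    table (including the minimum-energy-difference epsilon choice).
    """
    if n_replicas < 2:
        ranges = (T_range, alpha_range, sigma_range, epsilon_range)
        if n_replicas == 1 and all(r[0] == r[1] for r in ranges):
            pass
        else:
            raise ValueError(
                "n_replicas must be >= 2 (or 1 with equal endpoints)"
            )
    grids = [
        np.linspace(lo, hi, n_replicas)
        for lo, hi in (T_range, alpha_range, sigma_range, epsilon_range)
    ]
    replicas = tuple(
        ReplicaParams(index=i, temperature=float(grids[0][i]),
                      alpha=float(grids[1][i]), sigma=float(grids[2][i]),
                      epsilon=float(grids[3][i]))
        for i in range(n_replicas)
    )
    return ReplicaLadder(replicas=replicas)


def exchange_probability(U_i_xi: float, U_i_xj: float, U_j_xj: float,
                         U_j_xi: float, T_i: float, T_j: float) -> float:
    """Metropolis acceptance probability of a neighbour-state swap.

    ``U_i_xj`` is the energy of configuration x_j under Hamiltonian i,
    etc. Overflowing exponents clamp to 0 or 1.
    """
    if T_i <= 0 or T_j <= 0:
        raise ValueError("temperatures must be > 0")
    arg = (U_i_xj - U_i_xi) / (KB * T_i) - (U_j_xj - U_j_xi) / (KB * T_j)
    if arg <= 0.0:
        return 1.0
    if arg > 700.0:  # exp underflow guard; exact exponent preserved below
        return 0.0
    return math.exp(-arg)


@dataclass
class ExchangeAttempt:
    time: float
    pair: tuple
    U_i_xi: float
    U_i_xj: float
    U_j_xj: float
    U_j_xi: float
    probability: float
    accepted: bool


@dataclass
class ExchangeLog:
    """All exchange attempts plus per-pair aggregate frequencies."""

    attempts: list = field(default_factory=list)
    n_replicas: int = 0
    replica_of_walker: list = field(default_factory=list)
    # walker_slot_series[t][w] = slot occupied by walker w after epoch t
    walker_slot_series: list = field(default_factory=list)

    def record(self, attempt: ExchangeAttempt):
        self.attempts.append(attempt)

    def pair_counts(self):
        attempted = {}
        accepted = {}
        for at in self.attempts:
            attempted[at.pair] = attempted.get(at.pair, 0) + 1
            if at.accepted:
                accepted[at.pair] = accepted.get(at.pair, 0) + 1
        return attempted, accepted

    def to_table(self) -> str:
        lines = [
            "time\ti\tj\tU_i_xi\tU_i_xj\tU_j_xj\tU_j_xi\tprob\taccepted"
        ]
        for at in self.attempts:
            lines.append(
                f"{at.time:g}\t{at.pair[0]}\t{at.pair[1]}"
                f"\t{at.U_i_xi:.6g}\t{at.U_i_xj:.6g}\t{at.U_j_xj:.6g}"
                f"\t{at.U_j_xi:.6g}\t{at.probability:.6g}"
                f"\t{int(at.accepted)}"
            )
        return "\n".join(lines)


def exchange_frequency_profile(log: ExchangeLog) -> dict:
    """Accepted/attempted per neighbour pair plus round-trip counts.

    A round trip is one walker's excursion slot 0 -> top slot -> slot 0.
    Pairs never attempted are reported with frequency ``None``.
    """
    attempted, accepted = log.pair_counts()
    freqs = {}
    for pair in sorted(attempted):
        freqs[pair] = accepted.get(pair, 0) / attempted[pair]
    n = log.n_replicas
    for i in range(max(n - 1, 0)):
        freqs.setdefault((i, i + 1), None)
    round_trips = 0
    if n > 1 and log.walker_slot_series:
        n_walkers = len(log.walker_slot_series[0])
        for w in range(n_walkers):
            phase = None  # None -> seen bottom; 'top' -> seen top after
            for slots in log.walker_slot_series:
                s = slots[w]
                if s == 0 and phase == "top":
                    round_trips += 1
                    phase = "bottom"
                elif s == 0:
                    phase = "bottom"
                elif s == n - 1 and phase == "bottom":
                    phase = "top"
    return {"pair_frequencies": freqs, "round_trips": round_trips}


def run_hre(
    ladder: ReplicaLadder,
    system: ParticleSystem,
    config: SimConfig,
    initial: Frame,
    bias,
    n_steps: int,
    exchange_interval: int,
    equilibration_steps: int = 0,
    base_ff: ForceField | None = None,
    master_seed: int | None = None,
):
    """Synchronized replica run with Metropolis state exchange.

    Every replica starts from ``initial``, is equilibrated without
    exchanges, then runs production in segments of
    ``exchange_interval`` steps separated by exchange epochs. Returns
    ``(per-slot Trajectory list, ExchangeLog)``. The same master seed
    reproduces the run exactly.
    """
    if master_seed is None:
        master_seed = config.seed
    base_ff = base_ff or ForceField()
    n_rep = len(ladder)
    models = []
    for rep in ladder:
        ff = base_ff.with_ion_carboxyl(rep.sigma, rep.epsilon)
        models.append(EnergyModel(system, ff, alpha=rep.alpha, bias=bias))
    # fixed-offset per-replica streams + one swap stream
    rngs = [np.random.default_rng(master_seed + 1000 * (i + 1))
            for i in range(n_rep)]
    swap_rng = np.random.default_rng(master_seed + 999)

    frames = [Frame(np.array(initial.coordinates), initial.box, 0.0)
              for _ in range(n_rep)]
    walker_of_slot = list(range(n_rep))
    log = ExchangeLog(n_replicas=n_rep)
    slot_coords = [[] for _ in range(n_rep)]
    slot_times = [[] for _ in range(n_rep)]

    def advance(slot, steps, t0):
        rep = ladder[slot]
        cfg = dc_replace(config, temperature=rep.temperature,
                         n_steps=steps, save_every=max(steps, 1))
        traj = run_langevin(frames[slot], cfg, system,
                            rng=rngs[slot], model=models[slot])
        frames[slot] = Frame(traj.coordinates[-1], traj.box,
                             t0 + steps * config.timestep,
                             velocities=traj.metadata["final_velocities"])
        return frames[slot]

    t = 0.0
    if equilibration_steps:
        for s in range(n_rep):
            advance(s, equilibration_steps, t)
        t += equilibration_steps * config.timestep

    n_epochs = n_steps // exchange_interval if exchange_interval > 0 else 0
    for s in range(n_rep):
        slot_coords[s].append(np.array(frames[s].coordinates))
        slot_times[s].append(t)
    for epoch in range(n_epochs):
        for s in range(n_rep):
            advance(s, exchange_interval, t)
        t += exchange_interval * config.timestep
        start = 0 if epoch % 2 == 0 else 1
        for i in range(start, n_rep - 1, 2):
            j = i + 1
            xi, xj = frames[i].coordinates, frames[j].coordinates
            U_i_xi = models[i].energy(xi, frames[i].box)
            U_i_xj = models[i].energy(xj, frames[j].box)
            U_j_xj = models[j].energy(xj, frames[j].box)
            U_j_xi = models[j].energy(xi, frames[i].box)
            prob = exchange_probability(
                U_i_xi, U_i_xj, U_j_xj, U_j_xi,
                ladder[i].temperature, ladder[j].temperature,
            )
            accepted = bool(swap_rng.random() < prob)
            log.record(ExchangeAttempt(
                time=t, pair=(i, j), U_i_xi=U_i_xi, U_i_xj=U_i_xj,
                U_j_xj=U_j_xj, U_j_xi=U_j_xi, probability=prob,
                accepted=accepted,
            ))
            if accepted:
                frames[i], frames[j] = (
                    Frame(frames[j].coordinates, frames[j].box,
                          frames[i].time,
                          velocities=frames[j].velocities),
                    Frame(frames[i].coordinates, frames[i].box,
                          frames[j].time,
                          velocities=frames[i].velocities),
                )
                walker_of_slot[i], walker_of_slot[j] = (
                    walker_of_slot[j], walker_of_slot[i],
                )
        slot_of_walker = [0] * n_rep
        for slot, walker in enumerate(walker_of_slot):
            slot_of_walker[walker] = slot
        log.walker_slot_series.append(list(slot_of_walker))
        for s in range(n_rep):
            slot_coords[s].append(np.array(frames[s].coordinates))
            slot_times[s].append(t)
    log.replica_of_walker = list(walker_of_slot)

    trajectories = []
    for s in range(n_rep):
        trajectories.append(Trajectory(
            coordinates=np.array(slot_coords[s]), box=initial.box,
            times=np.array(slot_times[s]), system=system, config=config,
            metadata={"replica": ladder[s].__dict__,
                      "master_seed": master_seed},
        ))
    return trajectories, log
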