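"""Backbone dihedral states: Ramachandran-style classification,
transition counting, and regular-segment statistics.

On a one-bead-per-monomer backbone, consecutive torsions play the roles
of (phi, psi): monomer ``m`` is assigned phi = torsion(m-2..m+1) and
psi = torsion(m-1..m+2), so psi of one monomer is shared with phi of
the next, and chain-end monomers without both torsions are labelled
``undefined`` and excluded from statistics.

Regions are polygons on the (phi, psi) torus loaded from an editable
JSON data file; every point maps to exactly one label ("other" catches
the remainder) and points on shared borders resolve deterministically
to the lowest region id. The high-energy-barrier partition groups the
compact helical regions (3_10, right/left alpha) against the extended
ones (2.5_1, PPII): a transition between the two groups crosses the
high barrier of the Ramachandran landscape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from MDAnalysis.lib.distances import calc_dihedrals

UNDEFINED = "undefined"


def _default_region_file():
    return resources.files("polyhre.data") / "ramachandran_regions.json"


@dataclass(frozen=True)
class RegionMap:
    """Labelled polygons on the (phi, psi) torus, degrees."""

    labels: tuple  # region labels, ordered by id
    polygons: tuple  # matching vertex arrays, shape (k, 2)
    other_label: str = "other"
    barrier_partition: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path=None) -> "RegionMap":
        src = path if path is not None else _default_region_file()
        with open(src) if isinstance(src, str) else src.open() as fh:
            raw = json.load(fh)
        regions = sorted(raw["regions"], key=lambda r: r["id"])
        return cls(
            labels=tuple(r["label"] for r in regions),
            polygons=tuple(
                np.asarray(r["polygon"], dtype=float) for r in regions
            ),
            other_label=raw.get("other_label", "other"),
            barrier_partition=raw.get("barrier_partition", {}),
        )

    @property
    def all_labels(self) -> tuple:
        return self.labels + (self.other_label,)

    def centroid(self, label: str) -> tuple:
        poly = self.polygons[self.labels.index(label)]
        return tuple(poly.mean(axis=0))

    def classify_point(self, phi: float, psi: float) -> str:
        """Label of one (phi, psi) point in degrees (wrap-aware)."""
        p = _wrap_deg(np.array([phi, psi]))
        for label, poly in zip(self.labels, self.polygons):
            # test the wrapped point and its torus images
            for dphi in (0.0, -360.0, 360.0):
                for dpsi in (0.0, -360.0, 360.0):
                    if _point_in_polygon(p[0] + dphi, p[1] + dpsi, poly):
                        return label
        return self.other_label


def _wrap_deg(x):
    """Wrap degrees to [-180, 180)."""
    return (np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0


def _point_in_polygon(x: float, y: float, poly: np.ndarray) -> bool:
    """Ray-casting test; points on an edge count as inside."""
    n = len(poly)
    inside = False
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        # on-edge check (collinear and within bounding segment)
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-9:
            if (min(x1, x2) - 1e-9 <= x <= max(x1, x2) + 1e-9
                    and min(y1, y2) - 1e-9 <= y <= max(y1, y2) + 1e-9):
                return True
        if (y1 > y) != (y2 > y):
            x_int = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_int:
                inside = not inside
    return inside


@dataclass
class DihedralStateSeries:
    """Per-monomer, per-frame conformational state labels."""

    labels: np.ndarray  # (n_frames, n_monomers) of strings ('U' undefined)
    region_map: RegionMap
    dt: float = 1.0  # time between frames (ps or frames)

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def n_monomers(self) -> int:
        return self.labels.shape[1]

    def defined_mask(self) -> np.ndarray:
        return self.labels[0] != UNDEFINED

    def population_fractions(self) -> dict:
        """Occupancy fraction of each label over all defined entries."""
        defined = self.labels[:, self.defined_mask()]
        total = defined.size
        return {
            lab: float(np.count_nonzero(defined == lab)) / total
            for lab in self.region_map.all_labels
        }


def backbone_torsions(coordinates: np.ndarray, box: float,
                      n_monomers: int) -> np.ndarray:
    """All backbone torsions (deg) of one frame; index i = beads i..i+3.

    Uses the standard IUPAC sign convention (via MDAnalysis).
    """
    quads = np.arange(n_monomers - 3)
    dims = np.array([box, box, box, 90.0, 90.0, 90.0])
    rad = calc_dihedrals(
        coordinates[quads], coordinates[quads + 1],
        coordinates[quads + 2], coordinates[quads + 3], box=dims,
    )
    return np.degrees(rad)


def phi_psi_series(trajectory) -> tuple:
    """(phi, psi) in degrees per monomer per frame.

    Returns arrays of shape (n_frames, n_monomers) with NaN where a
    monomer lacks one of its torsions (the two monomers at each end).
    """
    n_mon = trajectory.system.topology.n_monomers
    n_frames = trajectory.n_frames
    phi = np.full((n_frames, n_mon), np.nan)
    psi = np.full((n_frames, n_mon), np.nan)
    for f in range(n_frames):
        tors = backbone_torsions(trajectory.coordinates[f],
                                 trajectory.box, n_mon)
        # monomer m: phi = torsion(m-2), psi = torsion(m-1)
        for m in range(2, n_mon - 2):
            phi[f, m] = tors[m - 2]
            psi[f, m] = tors[m - 1]
    return phi, psi


def classify_angles(phi: np.ndarray, psi: np.ndarray,
                    region_map: RegionMap | None = None,
                    dt: float = 1.0) -> DihedralStateSeries:
    """Classify (phi, psi) arrays (degrees) into region labels.

    NaN entries (missing torsions) become ``undefined``.
    """
    if region_map is None:
        region_map = RegionMap.load()
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    if phi.shape != psi.shape:
        raise ValueError("phi and psi must have the same shape")
    labels = np.empty(phi.shape, dtype=object)
    cache = {}
    for idx in np.ndindex(phi.shape):
        if np.isnan(phi[idx]) or np.isnan(psi[idx]):
            labels[idx] = UNDEFINED
            continue
        key = (round(phi[idx], 6), round(psi[idx], 6))
        if key not in cache:
            cache[key] = region_map.classify_point(phi[idx], psi[idx])
        labels[idx] = cache[key]
    return DihedralStateSeries(labels=labels, region_map=region_map, dt=dt)


def classify_dihedral_states(trajectory,
                             region_map: RegionMap | None = None
                             ) -> DihedralStateSeries:
    """Per-monomer conformational states of a trajectory."""
    phi, psi = phi_psi_series(trajectory)
    dt = float(trajectory.times[1] - trajectory.times[0]) \
        if trajectory.n_frames > 1 else 1.0
    return classify_angles(phi, psi, region_map, dt=dt)


def transition_frequencies(states: DihedralStateSeries,
                           barrier_partition: dict | None = None) -> dict:
    """Per-monomer transition counts and rates.

    A transition is any label change between consecutive frames; a
    barrier transition crosses the A/B partition (compact helical vs
    extended states). Rates are per unit of the series' time step.
    Returns a dict with per-monomer arrays ``all_transitions``,
    ``barrier_transitions`` (counts) and the matching ``*_rate`` arrays.
    """
    if states.n_frames < 2:
        raise ValueError("need at least 2 frames to count transitions")
    part = barrier_partition or states.region_map.barrier_partition
    group_a = set(part.get("A", ()))
    group_b = set(part.get("B", ()))
    lab = states.labels
    n_mon = states.n_monomers
    all_t = np.zeros(n_mon, dtype=int)
    barrier_t = np.zeros(n_mon, dtype=int)
    for m in range(n_mon):
        col = lab[:, m]
        if col[0] == UNDEFINED:
            continue
        changed = col[1:] != col[:-1]
        all_t[m] = int(np.count_nonzero(changed))
        for f in np.nonzero(changed)[0]:
            before, after = col[f], col[f + 1]
            if ((before in group_a and after in group_b)
                    or (before in group_b and after in group_a)):
                barrier_t[m] += 1
    span = (states.n_frames - 1) * states.dt
    return {
        "all_transitions": all_t,
        "barrier_transitions": barrier_t,
        "all_rate": all_t / span,
        "barrier_rate": barrier_t / span,
    }


def regular_segment_lengths(frame_labels: np.ndarray) -> dict:
    """Histogram of maximal runs of identical labels along the chain.

    ``frame_labels`` is one frame's per-monomer label vector; undefined
    monomers break runs and are excluded. Returns {run_length: count}.
    """
    runs = {}
    current_label, length = None, 0
    for lab in list(frame_labels) + [None]:
        if lab == current_label and lab is not None and lab != UNDEFINED:
            length += 1
        else:
            if current_label not in (None, UNDEFINED) and length:
                runs[length] = runs.get(length, 0) + 1
            current_label = lab
            length = 1 if lab not in (None, UNDEFINED) else 0
    return dict(sorted(runs.items()))
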