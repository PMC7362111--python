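"""Gyration-tensor shape descriptors.

For a set of equal-mass particles the gyration tensor is

    S_ab = (1/N) sum_i (r_i,a - r_cm,a)(r_i,b - r_cm,b);

its eigenvalues sorted descending give the squared principal radii
Rx^2 >= Ry^2 >= Rz^2 and Rg^2 = Rx^2 + Ry^2 + Rz^2. The scalar
descriptors are computed on the principal *radii* (square roots):

    asphericity      b  = (Rx - (Ry + Rz)/2) / Rx
    shape anisotropy k2 = 1 - 3 (RxRy + RyRz + RxRz) / (Rx+Ry+Rz)^2
    prolateness      P  = (2Rx-Ry-Rz)(2Ry-Rx-Rz)(2Rz-Ry-Rx)
                          / [2 (Rx^2+Ry^2+Rz^2-RxRy-RyRz-RxRz)^{3/2}]

b = 0 and k2 = 0 correspond to a sphere, k2 = 1 to an ideal rod; P > 0
is prolate, P < 0 oblate. A squared-component variant (descriptors on
the eigenvalues instead of their square roots, common elsewhere in the
literature) is available via ``squared=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ISOTROPIC_TOL = 1e-12
CLAMP_TOL = 1e-9


@dataclass(frozen=True)
class ShapeMetrics:
    """Principal radii (nm, sorted Rx >= Ry >= Rz) and derived scalars."""

    R_x: float
    R_y: float
    R_z: float
    R_g: float
    b: float
    k2: float
    P: float
    clamped: bool = False  # derived value nudged back into range
    isotropic: bool = False  # P undefined (0/0), set to 0 by convention


def shape_from_principal_radii(R_x: float, R_y: float, R_z: float,
                               squared: bool = False) -> ShapeMetrics:
    """Descriptors from given principal radii (Rx >= Ry >= Rz >= 0)."""
    if not (R_x >= R_y >= R_z >= 0):
        raise ValueError("principal radii must satisfy Rx >= Ry >= Rz >= 0")
    if squared:
        rx, ry, rz = R_x**2, R_y**2, R_z**2
    else:
        rx, ry, rz = R_x, R_y, R_z
    rg = float(np.sqrt(R_x**2 + R_y**2 + R_z**2))
    if rx <= 0:
        return ShapeMetrics(R_x, R_y, R_z, rg, 0.0, 0.0, 0.0,
                            isotropic=True)
    b = (rx - 0.5 * (ry + rz)) / rx
    s = rx + ry + rz
    k2 = 1.0 - 3.0 * (rx * ry + ry * rz + rx * rz) / (s * s)
    denom_core = rx**2 + ry**2 + rz**2 - rx * ry - ry * rz - rx * rz
    isotropic = denom_core <= ISOTROPIC_TOL * max(rx * rx, 1e-300)
    if isotropic:
        p = 0.0
    else:
        p = ((2 * rx - ry - rz) * (2 * ry - rx - rz) * (2 * rz - ry - rx)
             / (2.0 * denom_core**1.5))
    clamped = False
    for name, val, lo, hi in (("b", b, 0.0, 1.0), ("k2", k2, 0.0, 1.0),
                              ("P", p, -1.0, 1.0)):
        if val < lo - CLAMP_TOL or val > hi + CLAMP_TOL:
            raise FloatingPointError(
                f"shape descriptor {name}={val} outside its range by "
                "more than the numerical tolerance"
            )
    if not 0.0 <= b <= 1.0:
        b, clamped = float(np.clip(b, 0, 1)), True
    if not 0.0 <= k2 <= 1.0:
        k2, clamped = float(np.clip(k2, 0, 1)), True
    if not -1.0 <= p <= 1.0:
        p, clamped = float(np.clip(p, -1, 1)), True
    return ShapeMetrics(R_x, R_y, R_z, rg, float(b), float(k2), float(p),
                        clamped=clamped, isotropic=isotropic)


def gyration_tensor(coordinates: np.ndarray, selection=None,
                    squared: bool = False) -> ShapeMetrics:
    """Shape metrics of one frame (equal masses assumed).

    ``selection`` is an optional index array restricting the particle
    set (typically the chain beads). Coordinates must be whole-molecule
    (unwrapped) — the gyration tensor is not minimum-image aware.
    """
    coords = np.asarray(coordinates, dtype=float)
    if selection is not None:
        coords = coords[np.asarray(selection)]
    if coords.shape[0] < 2:
        raise ValueError("gyration tensor requires at least 2 particles")
    centered = coords - coords.mean(axis=0)
    tensor = centered.T @ centered / coords.shape[0]
    eigvals = np.linalg.eigvalsh(tensor)[::-1]  # descending
    eigvals = np.clip(eigvals, 0.0, None)
    r = np.sqrt(eigvals)
    return shape_from_principal_radii(r[0], r[1], r[2], squared=squared)


def radius_of_gyration(coordinates: np.ndarray, selection=None) -> float:
    coords = np.asarray(coordinates, dtype=float)
    if selection is not None:
        coords = coords[np.asarray(selection)]
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def rg_distribution(trajectory, selection=None, bin_width: float = 0.02):
    """Per-frame Rg series and its normalized histogram.

    Returns ``(rg_series, bin_edges, density)``; the histogram uses
    uniform bins of ``bin_width`` nm spanning the observed range.
    """
    if trajectory.n_frames < 1:
        raise ValueError("trajectory has no frames")
    rgs = np.array([
        radius_of_gyration(trajectory.coordinates[i], selection)
        for i in range(trajectory.n_frames)
    ])
    lo = np.floor(rgs.min() / bin_width) * bin_width
    hi = np.ceil(rgs.max() / bin_width) * bin_width
    n_bins = max(int(round((hi - lo) / bin_width)), 1)
    edges = lo + np.arange(n_bins + 1) * bin_width
    density, _ = np.histogram(rgs, bins=edges, density=True)
    return rgs, edges, density
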