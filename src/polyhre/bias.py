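"""Dihedral potential of mean force and its cosine-series bias fit.

The replica ladder softens the backbone torsion landscape by adding, in
replica ``i``, the scaled potential

    U_bias(x) = alpha_i * sum_{n=1}^{15} k_n (1 + cos(n x - a_n)),

with alpha running from 0 (neutral replica) to -1 (fully flattened).
The coefficients (k_n, a_n) come from a least-squares fit of this series
to the torsional potential of mean force, itself the inverse-Boltzmann
transform of the torsion-angle distribution sampled in salt-free
conditions:

    F(x) = -kB T ln p(x),   min-shifted to zero.

A PMF is only defined up to an additive constant, so the fit is carried
out modulo a constant shift. On the uniform PMF grid this makes the fit
a closed-form linear least-squares problem in the harmonic basis
{cos nx, sin nx} (the discrete Fourier transform in disguise), which is
deterministic and exact for exactly representable series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import KB

N_TERMS = 15


@dataclass(frozen=True)
class BiasPotential:
    """Amplitudes ``k`` (kJ/mol) and phases ``a`` (rad) of the series."""

    k: np.ndarray
    a: np.ndarray
    fit_residual_rms: float = 0.0

    def __post_init__(self):
        k = np.atleast_1d(np.asarray(self.k, dtype=float))
        a = np.atleast_1d(np.asarray(self.a, dtype=float))
        if k.shape != a.shape:
            raise ValueError("k and a must have the same length")
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "a", a)

    @property
    def n_terms(self) -> int:
        return self.k.size

    def __call__(self, x, alpha: float = 1.0):
        return evaluate_bias(self, alpha, x)

    def derivative(self, x, alpha: float = 1.0):
        """Analytic dU/dx at scale ``alpha``."""
        x = np.asarray(x, dtype=float)
        n = np.arange(1, self.n_terms + 1)
        return alpha * np.sum(
            -self.k * n * np.sin(np.multiply.outer(x, n) - self.a), axis=-1
        )


@dataclass(frozen=True)
class PMFEstimate:
    """Binned potential of mean force over (-pi, pi], min-shifted to 0."""

    bin_centers: np.ndarray
    pmf_values: np.ndarray  # kJ/mol
    counts: np.ndarray
    temperature: float
    empty_bins_capped: int = 0

    @property
    def n_bins(self) -> int:
        return self.bin_centers.size


def wrap_angles(x):
    """Wrap angles (rad) to (-pi, pi]."""
    x = np.asarray(x, dtype=float)
    wrapped = -((-x + np.pi) % (2 * np.pi) - np.pi)
    return wrapped


def estimate_pmf(angles, n_bins: int = 72,
                 temperature: float = 300.0) -> PMFEstimate:
    """Inverse-Boltzmann PMF of a torsion-angle sample.

    Empty bins cannot be assigned -kB T ln 0; they are capped at the
    maximum finite PMF plus one kB T and flagged via
    ``empty_bins_capped``.
    """
    angles = wrap_angles(angles)
    if angles.size < 10 * n_bins:
        raise ValueError(
            f"need at least {10 * n_bins} samples for {n_bins} bins, "
            f"got {angles.size}"
        )
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(angles, bins=edges)
    if np.count_nonzero(counts) <= 1:
        raise ValueError("degenerate distribution: all samples in one bin")
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = counts / counts.sum()
    kt = KB * temperature
    with np.errstate(divide="ignore"):
        pmf = np.where(counts > 0, -kt * np.log(np.maximum(p, 1e-300)),
                       np.inf)
    finite = np.isfinite(pmf)
    pmf = pmf - pmf[finite].min()
    n_empty = int(np.count_nonzero(~finite))
    if n_empty:
        cap = pmf[finite].max() + kt
        pmf = np.where(finite, pmf, cap)
        warnings.warn(
            f"{n_empty} empty PMF bins capped at max finite + kB T",
            stacklevel=2,
        )
    return PMFEstimate(
        bin_centers=centers, pmf_values=pmf, counts=counts,
        temperature=temperature, empty_bins_capped=n_empty,
    )


def fit_cosine_series(pmf: PMFEstimate, n_terms: int = N_TERMS,
                      weight_by_counts: bool = False) -> BiasPotential:
    """Least-squares fit of ``sum k_n (1 + cos(n x - a_n))`` to the PMF.

    The harmonic amplitudes/phases are obtained by linear least squares
    in the {cos nx, sin nx} basis with the additive constant profiled
    out (a PMF carries no absolute offset). Deterministic; the residual
    RMS (after optimal shift) is stored on the result.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    x = pmf.bin_centers
    y = pmf.pmf_values
    n = np.arange(1, n_terms + 1)
    design = np.concatenate(
        [
            np.ones((x.size, 1)),
            np.cos(np.multiply.outer(x, n)),
            np.sin(np.multiply.outer(x, n)),
        ],
        axis=1,
    )
    w = np.sqrt(pmf.counts) if weight_by_counts else None
    if w is not None:
        coef, *_ = np.linalg.lstsq(design * w[:, None], y * w, rcond=None)
    else:
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    p, q = coef[1 : 1 + n_terms], coef[1 + n_terms :]
    k = np.hypot(p, q)
    a = np.arctan2(q, p)
    a = np.where(k > 1e-12, a, 0.0)
    model = design @ coef
    resid = model - y
    rms = float(np.sqrt(np.mean(resid**2)))
    return BiasPotential(k=k, a=a, fit_residual_rms=rms)


def _series(bias: BiasPotential, x: np.ndarray) -> np.ndarray:
    n = np.arange(1, bias.n_terms + 1)
    return np.sum(
        bias.k * (1.0 + np.cos(np.multiply.outer(x, n) - bias.a)), axis=-1
    )


def evaluate_bias(bias: BiasPotential, alpha: float, x):
    """Scaled bias energy ``alpha * sum k_n (1 + cos(n x - a_n))``.

    ``alpha = 0`` returns exactly zero. The physical range is
    -1 <= alpha <= 0 (a flattening potential); values outside are
    allowed but warned about.
    """
    if alpha > 0 or alpha < -1:
        warnings.warn(
            f"alpha={alpha} outside the ladder range [-1, 0]", stacklevel=2
        )
    x = np.asarray(x, dtype=float)
    if alpha == 0.0:
        return np.zeros_like(x) if x.ndim else 0.0
    out = alpha * _series(bias, x)
    return out if x.ndim else float(out)


def export_tabulated(bias: BiasPotential, alpha: float, n_points: int,
                     path, degrees: bool = False) -> None:
    """Write a three-column table (angle, U, -dU/dx) on a uniform grid.

    The grid covers (-pi, pi] with ``n_points`` points; the derivative
    column is analytic. ``degrees=True`` writes the angle column in
    degrees (for MD-engine tabulated-potential formats); the energy
    derivative stays per radian.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    x = -np.pi + np.arange(1, n_points + 1) * (2 * np.pi / n_points)
    u = evaluate_bias(bias, alpha, x)
    minus_du = -bias.derivative(x, alpha=alpha)
    angle_col = np.degrees(x) if degrees else x
    header = (
        "tabulated dihedral bias\n"
        f"alpha = {alpha!r}; n_terms = {bias.n_terms}; "
        f"angle unit = {'deg' if degrees else 'rad'}\n"
        "angle\tenergy_kJ_per_mol\tminus_dU_dx"
    )
    np.savetxt(path, np.column_stack([angle_col, u, minus_du]),
               header=header, fmt="%.12e", delimiter="\t")


def read_tabulated(path):
    """Read a table written by :func:`export_tabulated`."""
    data = np.loadtxt(path)
    return data[:, 0], data[:, 1], data[:, 2]


def serialize_coefficients(bias: BiasPotential, path) -> None:
    """Write coefficients as a flat key-value text file."""
    with open(path, "w") as fh:
        fh.write(f"n_terms = {bias.n_terms}\n")
        fh.write(f"fit_residual_rms = {float(bias.fit_residual_rms)!r}\n")
        for i, (k, a) in enumerate(zip(bias.k, bias.a), start=1):
            fh.write(f"k_{i} = {float(k)!r}\n")
            fh.write(f"a_{i} = {float(a)!r}\n")


def load_coefficients(path) -> BiasPotential:
    kv = {}
    with open(path) as fh:
        for line in fh:
            if "=" in line:
                key, val = line.split("=", 1)
                kv[key.strip()] = float(val)
    n = int(kv["n_terms"])
    k = np.array([kv[f"k_{i}"] for i in range(1, n + 1)])
    a = np.array([kv[f"a_{i}"] for i in range(1, n + 1)])
    return BiasPotential(k=k, a=a,
                         fit_residual_rms=kv.get("fit_residual_rms", 0.0))


def sample_boltzmann_angles(bias: BiasPotential, n_samples: int,
                            temperature: float = 300.0,
                            rng: np.random.Generator | None = None,
                            grid: int = 4096) -> np.ndarray:
    """Draw torsion angles from p(x) ~ exp(-U_bias(x; alpha=1)/kB T).

    Inverse-CDF sampling on a fine grid; deterministic given the rng
    state. Used by the parameter-recovery tests and the synthetic
    fixture generators.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    x = np.linspace(-np.pi, np.pi, grid + 1)
    u = _series(bias, x)
    w = np.exp(-(u - u.min()) / (KB * temperature))
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]))])
    cdf /= cdf[-1]
    return np.interp(rng.random(n_samples), cdf, x)
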