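"""PMF estimation and cosine-series bias fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyhre.bias import (
    BiasPotential,
    PMFEstimate,
    estimate_pmf,
    evaluate_bias,
    export_tabulated,
    fit_cosine_series,
    read_tabulated,
    sample_boltzmann_angles,
    serialize_coefficients,
    load_coefficients,
    wrap_angles,
)
from polyhre.constants import KB


def uniform_grid_pmf(values, temperature=300.0):
    n = len(values)
    edges = np.linspace(-np.pi, np.pi, n + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PMFEstimate(bin_centers=centers,
                       pmf_values=np.asarray(values, dtype=float),
                       counts=np.ones(n), temperature=temperature)


# ---------------------------------------------------------------- PMF


def test_uniform_samples_give_flat_pmf():
    rng = np.random.default_rng(0)
    angles = rng.uniform(-np.pi, np.pi, 200000)
    pmf = estimate_pmf(angles, n_bins=36)
    # Poisson noise on ~5600 counts/bin -> ~1.3% in density, so the
    # PMF spread stays within a few times kB T * sigma_rel
    n_per_bin = len(angles) / 36
    noise = KB * 300.0 / np.sqrt(n_per_bin)
    assert pmf.pmf_values.max() - pmf.pmf_values.min() < 6 * noise


def test_inverse_boltzmann_recovers_cosine_pmf():
    """Samples from p ~ exp(-cos x) give PMF = kB T cos x + const."""
    rng = np.random.default_rng(1)
    T = 300.0
    x_grid = np.linspace(-np.pi, np.pi, 4097)
    w = np.exp(-np.cos(x_grid))
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]))])
    cdf /= cdf[-1]
    angles = np.interp(rng.random(10**6), cdf, x_grid)
    pmf = estimate_pmf(angles, n_bins=72, temperature=T)
    expected = KB * T * np.cos(pmf.bin_centers)
    expected -= expected.min()
    rmsd = np.sqrt(np.mean((pmf.pmf_values - expected) ** 2))
    assert rmsd < 0.05 * (KB * T * 2)  # < 5% of peak-to-peak amplitude


def test_pmf_linear_in_temperature():
    rng = np.random.default_rng(2)
    angles = np.concatenate([rng.normal(0, 0.5, 50000),
                             rng.uniform(-np.pi, np.pi, 20000)])
    p1 = estimate_pmf(angles, 36, temperature=300.0)
    p2 = estimate_pmf(angles, 36, temperature=600.0)
    np.testing.assert_allclose(p2.pmf_values, 2.0 * p1.pmf_values,
                               rtol=1e-10)


def test_pmf_requires_enough_samples():
    with pytest.raises(ValueError, match="samples"):
        estimate_pmf(np.zeros(100), n_bins=36)


def test_degenerate_distribution_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        estimate_pmf(np.full(1000, 0.1), n_bins=10)


def test_empty_bins_capped_and_flagged():
    rng = np.random.default_rng(3)
    angles = rng.uniform(-1.0, 1.0, 5000)  # leaves outer bins empty
    with pytest.warns(UserWarning, match="empty"):
        pmf = estimate_pmf(angles, n_bins=36)
    assert pmf.empty_bins_capped > 0
    assert np.all(np.isfinite(pmf.pmf_values))


def test_wrap_angles_range():
    x = np.array([-np.pi, np.pi, 3 * np.pi, -3 * np.pi + 0.1])
    w = wrap_angles(x)
    assert np.all(w > -np.pi - 1e-12) and np.all(w <= np.pi + 1e-12)


# ---------------------------------------------------------------- fit


def test_fit_exact_single_term():
    x = uniform_grid_pmf(np.zeros(72)).bin_centers
    pmf = uniform_grid_pmf(2.0 * (1 + np.cos(x - 0.3)))
    fit = fit_cosine_series(pmf)
    assert fit.k[0] == pytest.approx(2.0, abs=1e-9)
    assert fit.a[0] == pytest.approx(0.3, abs=1e-9)
    assert np.all(fit.k[1:] < 1e-6)


def test_fit_exact_third_harmonic():
    x = uniform_grid_pmf(np.zeros(72)).bin_centers
    pmf = uniform_grid_pmf(1.0 + np.cos(3 * x))
    fit = fit_cosine_series(pmf)
    assert fit.k[2] == pytest.approx(1.0, abs=1e-9)
    assert fit.a[2] == pytest.approx(0.0, abs=1e-9)


def test_fit_reconstruction_from_sampled_pmf():
    rng = np.random.default_rng(4)
    x_grid = np.linspace(-np.pi, np.pi, 4097)
    w = np.exp(-np.cos(x_grid))
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]))])
    cdf /= cdf[-1]
    angles = np.interp(rng.random(10**6), cdf, x_grid)
    pmf = estimate_pmf(angles, 72)
    fit = fit_cosine_series(pmf)
    x = pmf.bin_centers
    model = -evaluate_bias(fit, -1.0, x)
    # compare up to the additive constant a PMF does not carry
    resid = (model - model.mean()) - (pmf.pmf_values
                                      - pmf.pmf_values.mean())
    assert np.sqrt(np.mean(resid**2)) < 0.05


def test_fit_residual_monotone_in_n_terms():
    rng = np.random.default_rng(5)
    x = uniform_grid_pmf(np.zeros(90)).bin_centers
    y = np.abs(np.sin(2 * x)) + 0.3 * np.cos(5 * x)  # not exactly a series
    pmf = uniform_grid_pmf(y - y.min())
    residuals = [fit_cosine_series(pmf, n).fit_residual_rms
                 for n in range(1, 16)]
    assert all(r2 <= r1 + 1e-12
               for r1, r2 in zip(residuals, residuals[1:]))


def test_parameter_recovery_from_boltzmann_sampling():
    """Planted k_n recovered within 10% at 1e6 samples."""
    rng = np.random.default_rng(6)
    k = np.zeros(15)
    a = np.zeros(15)
    k[[0, 2, 5]] = [2.0, 1.2, 0.8]
    a[[0, 2, 5]] = [0.3, -0.7, 1.1]
    planted = BiasPotential(k=k, a=a)
    angles = sample_boltzmann_angles(planted, 10**6, 300.0, rng)
    fit = fit_cosine_series(estimate_pmf(angles, 72, 300.0))
    for n in (1, 3, 6):
        assert fit.k[n - 1] == pytest.approx(k[n - 1], rel=0.10)
        assert fit.a[n - 1] == pytest.approx(a[n - 1], abs=0.1)


# ----------------------------------------------------------- evaluate


def test_evaluate_alpha_zero_is_exactly_zero():
    bias = BiasPotential(k=np.ones(15), a=np.zeros(15))
    assert evaluate_bias(bias, 0.0, 1.234) == 0.0


@pytest.mark.parametrize("alpha, x, expected", [
    (-0.5, 0.0, -1.0),   # -0.5 * 1 * (1 + cos 0)
    (-1.0, np.pi, 0.0),  # 1 + cos(pi) = 0
])
def test_evaluate_single_term_values(alpha, x, expected):
    bias = BiasPotential(k=np.array([1.0]), a=np.array([0.0]))
    assert evaluate_bias(bias, alpha, x) == pytest.approx(expected,
                                                          abs=1e-12)


def test_evaluate_warns_outside_range():
    bias = BiasPotential(k=np.array([1.0]), a=np.array([0.0]))
    with pytest.warns(UserWarning, match="alpha"):
        evaluate_bias(bias, 0.5, 0.0)


@given(x=st.floats(-10, 10), alpha=st.floats(-1, 0))
@settings(max_examples=100, deadline=None)
def test_bias_periodicity(x, alpha):
    bias = BiasPotential(k=np.arange(1, 16) * 0.1,
                         a=np.linspace(-1, 1, 15))
    u1 = evaluate_bias(bias, alpha, x)
    u2 = evaluate_bias(bias, alpha, x + 2 * np.pi)
    assert abs(u1 - u2) < 1e-10


# ------------------------------------------------------------- export


def test_export_alpha_zero_all_zero_energy(tmp_path):
    bias = BiasPotential(k=np.array([2.0]), a=np.array([0.1]))
    path = tmp_path / "tab.txt"
    export_tabulated(bias, 0.0, 100, path)
    _, u, du = read_tabulated(path)
    assert np.all(u == 0.0)


def test_export_roundtrip_and_closed_form(tmp_path):
    bias = BiasPotential(k=np.array([1.5]), a=np.array([0.4]))
    path = tmp_path / "tab.txt"
    export_tabulated(bias, -0.8, 4, path)
    x, u, _ = read_tabulated(path)
    expected = -0.8 * 1.5 * (1 + np.cos(x - 0.4))
    np.testing.assert_allclose(u, expected, atol=1e-10)


def test_export_derivative_matches_finite_difference(tmp_path):
    bias = BiasPotential(k=np.array([1.0, 0.0, 0.5]),
                         a=np.array([0.2, 0.0, -0.6]))
    path = tmp_path / "tab.txt"
    n = 10**4
    export_tabulated(bias, -1.0, n, path)
    x, u, minus_du = read_tabulated(path)
    fd = -np.gradient(u, x)
    inner = slice(2, -2)
    scale = np.abs(minus_du[inner]).max()
    assert np.allclose(minus_du[inner], fd[inner],
                       atol=1e-4 * scale)


def test_coefficients_roundtrip(tmp_path):
    bias = BiasPotential(k=np.linspace(0.1, 1.5, 15),
                         a=np.linspace(-3, 3, 15),
                         fit_residual_rms=0.0123)
    path = tmp_path / "coeffs.txt"
    serialize_coefficients(bias, path)
    back = load_coefficients(path)
    np.testing.assert_allclose(back.k, bias.k, rtol=1e-15)
    np.testing.assert_allclose(back.a, bias.a, rtol=1e-15)
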