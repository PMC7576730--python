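"""Pointwise modulus spectra, averaging and working-range selection."""

import numpy as np
import pytest
from scipy.signal import savgol_filter

from espectra import (
    ElasticitySpectrum,
    MeanSpectrum,
    SimulationConfig,
    average_spectra,
    bilayer_indentation_curve,
    bilayer_profile,
    generate_homogeneous,
    hertz_indentation_curve,
    pointwise_modulus,
    select_working_range,
    to_force_indentation,
)
from espectra.errors import ValidationError


def test_hertz_curve_yields_flat_spectrum():
    curve = hertz_indentation_curve(5e3, 8e-6, delta_max=800e-9, step=2e-9)
    spec = pointwise_modulus(curve)
    assert spec.delta_grid[0] >= 25e-9 * (1 - 1e-9)
    np.testing.assert_allclose(spec.E, 5e3, rtol=0.01)


def test_bilayer_curve_reproduces_generating_profile():
    E0, Eb, d0, R, lam = 9.8e3, 8.4e3, 300e-9, 3.5e-6, 1.74
    curve = bilayer_indentation_curve(E0, Eb, d0, R, lam, delta_max=800e-9, step=2e-9)
    spec = pointwise_modulus(curve)
    truth = bilayer_profile(spec.delta_grid, E0, Eb, d0, R, lam)
    np.testing.assert_allclose(spec.E, truth, rtol=0.01)


def test_local_stiffness_identity_between_modulus_and_derivative():
    """E(delta) * 2 sqrt(R delta) / (1 - nu^2) must equal the smoothed
    dF/ddelta at every grid point (the relation is algebraic)."""
    R, nu = 8e-6, 0.5
    curve = hertz_indentation_curve(5e3, R, nu=nu, delta_max=600e-9, step=2e-9)
    spec = pointwise_modulus(curve)
    # recompute the derivative exactly as the spectrum does
    grid_step = spec.grid_step
    full_grid = np.arange(grid_step, curve.delta[-1] + 0.5 * grid_step, grid_step)
    full_grid = full_grid[full_grid <= curve.delta[-1]]
    F_grid = np.interp(full_grid, curve.delta, curve.F)
    window = int(round(25e-9 / grid_step))
    window += 1 - window % 2
    dFdd = savgol_filter(F_grid, max(window, 5), 3, deriv=1, delta=grid_step, mode="interp")
    keep = full_grid >= 25e-9 * (1 - 1e-9)
    lhs = spec.E * 2 * np.sqrt(R * spec.delta_grid) / (1 - nu**2)
    np.testing.assert_allclose(lhs, dFdd[keep], rtol=1e-9)


def test_spectrum_noise_decreases_with_depth():
    """The 1/sqrt(delta) prefactor amplifies force noise most at shallow
    depth: across-curve variance of E(delta) must drop as delta grows."""
    cfg = SimulationConfig(
        model="homogeneous", E=5e3, R=8e-6, k=0.049,
        noise_sigma_F=20e-12, n_curves=40, seed=55,
    )
    batch = generate_homogeneous(cfg)
    specs = []
    for curve, rec in zip(batch.curves, batch.manifest):
        fic = to_force_indentation(curve, rec["z0_m"])
        specs.append(pointwise_modulus(fic))
    mean = average_spectra(specs)
    g = mean.delta_grid
    full = mean.n_curves_per_point == mean.n_curves_per_point.max()
    shallow = full & (g >= 30e-9) & (g < 150e-9)
    deep = full & (g >= 450e-9) & (g < 600e-9)
    assert np.mean(mean.E_std[shallow] ** 2) > 2 * np.mean(mean.E_std[deep] ** 2)


def test_too_shallow_curve_is_rejected():
    curve = hertz_indentation_curve(5e3, 8e-6, delta_max=100e-9, step=2e-9)
    with pytest.raises(ValidationError):
        pointwise_modulus(curve)


# ---------------------------------------------------------------------------
# averaging

def _spec(grid, E):
    return ElasticitySpectrum(delta_grid=grid, E=np.asarray(E, float))


def test_average_of_identical_spectra_is_the_spectrum():
    grid = np.arange(25e-9, 400e-9, 5e-9)
    s = _spec(grid, np.linspace(9e3, 8e3, len(grid)))
    mean = average_spectra([s] * 4)
    np.testing.assert_allclose(mean.E_mean, s.E)
    np.testing.assert_allclose(mean.E_std, 0.0)
    assert np.all(mean.n_curves_per_point == 4)


def test_average_of_two_spectra_is_pointwise_mean():
    grid = np.arange(25e-9, 200e-9, 5e-9)
    a = _spec(grid, np.full(len(grid), 4e3))
    b = _spec(grid, np.full(len(grid), 6e3))
    mean = average_spectra([a, b])
    np.testing.assert_allclose(mean.E_mean, 5e3)


def test_average_with_unequal_lengths_hand_computed():
    """Three curves of different depth: past the shortest, statistics run
    over the remaining curves only (expected values computed by hand)."""
    step = 5e-9
    g1 = 25e-9 + step * np.arange(4)   # ends first
    g2 = 25e-9 + step * np.arange(6)
    g3 = 25e-9 + step * np.arange(6)
    s1 = _spec(g1, [1000, 1000, 1000, 1000])
    s2 = _spec(g2, [2000, 2000, 2000, 2000, 2000, 2000])
    s3 = _spec(g3, [3000, 3000, 3000, 3000, 4000, 6000])
    mean = average_spectra([s1, s2, s3])
    np.testing.assert_array_equal(mean.n_curves_per_point, [3, 3, 3, 3, 2, 2])
    np.testing.assert_allclose(mean.E_mean, [2000, 2000, 2000, 2000, 3000, 4000])
    # SD at the 5th point: sample SD of {2000, 4000} = sqrt(2) * 1000
    assert mean.E_std[4] == pytest.approx(np.sqrt(2) * 1000)


def test_average_empty_list_is_error():
    with pytest.raises(ValidationError):
        average_spectra([])


# ---------------------------------------------------------------------------
# working range

def _mean(grid, E):
    return MeanSpectrum(
        delta_grid=grid, E_mean=np.asarray(E, float),
        E_std=np.zeros(len(grid)), n_curves_per_point=np.ones(len(grid), int),
    )


def test_flat_spectrum_keeps_full_range():
    grid = np.arange(25e-9, 1e-6, 5e-9)
    lo, hi = select_working_range(_mean(grid, np.full(len(grid), 5e3)))
    assert lo == pytest.approx(25e-9)
    assert hi == pytest.approx(800e-9)


def test_decaying_bilayer_spectrum_keeps_full_range():
    grid = np.arange(25e-9, 1e-6, 5e-9)
    E = bilayer_profile(grid, 9.8e3, 8.4e3, 300e-9, 3.5e-6)
    lo, hi = select_working_range(_mean(grid, E))
    assert hi == pytest.approx(800e-9)


def test_substrate_rise_onset_detected_within_100nm():
    grid = np.arange(25e-9, 1.2e-6, 5e-9)
    E = bilayer_profile(grid, 9.8e3, 8.4e3, 300e-9, 3.5e-6)
    rise = np.where(grid > 600e-9, 5e3 * ((grid - 600e-9) / 200e-9) ** 2, 0.0)
    lo, hi = select_working_range(_mean(grid, E + rise), hard_cap=2e-6)
    assert abs(hi - 600e-9) <= 100e-9


def test_noisy_flat_spectrum_not_truncated(rng):
    grid = np.arange(25e-9, 1e-6, 5e-9)
    E = 5e3 * (1 + 0.01 * rng.standard_normal(len(grid)))
    lo, hi = select_working_range(_mean(grid, E), hard_cap=900e-9)
    assert hi == pytest.approx(900e-9)
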