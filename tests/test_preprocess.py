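"""Smoothing, ratio-of-variances contact detection, conversion and QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from espectra import (
    ForceDistanceCurve,
    PreprocessConfig,
    SimulationConfig,
    find_contact_point,
    generate_homogeneous,
    qc_batch,
    qc_filter,
    smooth_curve,
    to_force_indentation,
)
from espectra.errors import ConfigError, ContactPointNotFoundError
from espectra.preprocess import _rov_trace


def _curve(z, F, R=8e-6, k=0.049):
    from espectra import AcquisitionMetadata

    md = AcquisitionMetadata(probe_radius=R, spring_constant=k)
    return ForceDistanceCurve(z=np.asarray(z, float), F=np.asarray(F, float), metadata=md)


# ---------------------------------------------------------------------------
# smoothing

def test_smoothing_reproduces_cubic_polynomial_exactly():
    z = np.linspace(0, 2e-6, 400)
    F = 1e-3 * z + 5e2 * z**2 + 1e9 * z**3
    out = smooth_curve(_curve(z, F), PreprocessConfig(sg_polyorder=3))
    np.testing.assert_allclose(out.F, F, rtol=1e-10, atol=1e-20)


def test_smoothing_keeps_constant_constant():
    z = np.linspace(0, 2e-6, 200)
    out = smooth_curve(_curve(z, np.full_like(z, 3e-10)), PreprocessConfig())
    np.testing.assert_allclose(out.F, 3e-10, rtol=1e-12)


def test_smoothing_matches_brute_force_sliding_fit_and_reduces_noise(rng):
    """Interior samples must equal a brute-force local polynomial LS fit,
    and white noise on a line must shrink by the filter's analytic factor."""
    z = np.linspace(0, 2e-6, 600)
    sigma = 5e-12
    noise = rng.normal(0, sigma, z.size)
    F = 1e-4 * z + noise
    cfg = PreprocessConfig(sg_window=50e-9, sg_polyorder=2)
    out = smooth_curve(_curve(z, F), cfg)

    # brute-force sliding polynomial fit oracle
    dz = z[1] - z[0]
    w = int(round(cfg.sg_window / dz))
    if w % 2 == 0:
        w += 1
    half = w // 2
    brute = np.empty_like(F)
    for i in range(half, len(z) - half):
        sl = slice(i - half, i + half + 1)
        coeffs = np.polyfit(z[sl] - z[i], F[sl], cfg.sg_polyorder)
        brute[i] = coeffs[-1]
    np.testing.assert_allclose(out.F[half:-half], brute[half:-half], rtol=0, atol=1e-18)

    # analytic variance-reduction factor: ||h||^2 from the filter response
    from scipy.signal import savgol_coeffs

    h = savgol_coeffs(w, cfg.sg_polyorder)
    resid_out = out.F - 1e-4 * z
    expected_std = sigma * np.sqrt(np.sum(h**2))
    assert np.std(resid_out[half:-half]) == pytest.approx(expected_std, rel=0.15)


def test_smoothing_window_exceeding_curve_is_config_error():
    z = np.linspace(0, 30e-9, 20)
    with pytest.raises(ConfigError):
        smooth_curve(_curve(z, np.zeros_like(z)), PreprocessConfig(sg_window=1e-6))


# ---------------------------------------------------------------------------
# contact point

def test_rov_trace_matches_brute_force():
    rng = np.random.default_rng(5)
    F = rng.normal(0, 1, 80)
    w = 10
    rov, offset, _ = _rov_trace(F, w)
    assert offset == w
    for i in range(w, len(F) - w):
        fwd = np.var(F[i + 1 : i + w + 1], ddof=1)
        back = np.var(F[i - w : i], ddof=1)
        assert rov[i - w] == pytest.approx(fwd / back, rel=1e-12)


def test_contact_point_recovered_on_noisy_hertz_curves():
    """Monte-Carlo: median |error| below the sample spacing equivalent,
    every curve within a few samples of the generator's ground truth."""
    cfg = SimulationConfig(
        model="homogeneous", E=5e3, R=8e-6, k=0.049,
        noise_sigma_F=20e-12, n_curves=40, seed=101,
    )
    batch = generate_homogeneous(cfg)
    pp = PreprocessConfig()
    step = cfg.sampling_step
    errs = []
    for curve, rec in zip(batch.curves, batch.manifest):
        sm = smooth_curve(curve, pp)
        cp = find_contact_point(sm, pp)
        errs.append((cp.z0 - rec["z0_m"]) / step)
    errs = np.array(errs)
    assert np.median(np.abs(errs)) <= 2.0
    assert np.mean(np.abs(errs) <= 3.0) >= 0.9


def test_pure_noise_has_no_contact_point(rng):
    z = 2e-9 * np.arange(1200)
    curve = _curve(z, rng.normal(0, 20e-12, z.size))
    with pytest.raises(ContactPointNotFoundError):
        find_contact_point(curve, PreprocessConfig())


def test_noiseless_kink_with_noise_floor_is_global_and_last_peak():
    """With a pre-contact noise floor, RoV peaks exactly once at the kink."""
    rng = np.random.default_rng(3)
    cfg = SimulationConfig(
        model="homogeneous", E=5e3, R=8e-6, k=0.049,
        noise_sigma_F=0.0, contact_offset_z0=1.2e-6, n_curves=1,
    )
    curve = generate_homogeneous(cfg).curves[0]
    F = curve.F + np.where(curve.z < 1.2e-6, rng.normal(0, 5e-12, len(curve)), 0.0)
    noisy = _curve(curve.z, F)
    pp = PreprocessConfig(refine_contact=False)
    cp = find_contact_point(noisy, pp)
    # last prominent peak coincides with the global RoV maximum
    assert cp.index == int(np.argmax(cp.rov)) + cp.rov_index_offset
    assert abs(cp.z0 - 1.2e-6) <= 5 * cfg.sampling_step


@settings(max_examples=20, deadline=None, derandomize=True)
@given(shift=st.floats(min_value=-1e-6, max_value=1e-6, allow_nan=False))
def test_contact_point_translation_equivariance(shift):
    cfg = SimulationConfig(
        model="homogeneous", E=5e3, R=8e-6, k=0.049,
        noise_sigma_F=20e-12, contact_offset_z0=1.0e-6, n_curves=1, seed=77,
    )
    curve = generate_homogeneous(cfg).curves[0]
    pp = PreprocessConfig()
    cp = find_contact_point(curve, pp)
    shifted = _curve(curve.z + shift, curve.F)
    cp2 = find_contact_point(shifted, pp)
    assert cp2.index == cp.index
    assert cp2.z0 == curve.z[cp.index] + shift


# ---------------------------------------------------------------------------
# conversion to force-indentation

def test_rigid_cantilever_limit_gives_delta_equals_z_minus_z0():
    z = np.linspace(0, 2e-6, 100)
    F = np.maximum(z - 1e-6, 0) ** 1.5 * 1e4
    curve = _curve(z, F, k=1e12)
    fic = to_force_indentation(curve, 1e-6)
    np.testing.assert_allclose(fic.delta, z[z >= 1e-6] - 1e-6, atol=1e-18)


def test_infinitely_stiff_sample_gives_zero_indentation():
    # F = k (z - z0): every nanometre of travel bends the cantilever
    k = 0.049
    z = np.linspace(0, 2e-6, 100)
    F = np.maximum(z - 1e-6, 0) * k
    fic = to_force_indentation(_curve(z, F, k=k), 1e-6)
    np.testing.assert_allclose(fic.delta, 0.0, atol=1e-20)


def test_conversion_preserves_forces_and_recovers_generator_truth():
    from espectra import hertz_force

    cfg = SimulationConfig(
        model="homogeneous", E=5e3, R=8e-6, k=0.049,
        noise_sigma_F=0.0, contact_offset_z0=1e-6, n_curves=1,
    )
    curve = generate_homogeneous(cfg).curves[0]
    fic = to_force_indentation(curve, 1e-6)
    # forces re-indexed, not altered
    assert np.all(np.isin(fic.F, curve.F))
    # F(delta) matches the exact Hertz forward model within interp tolerance
    truth = hertz_force(fic.delta, 5e3, 8e-6)
    mask = fic.delta > 20e-9
    np.testing.assert_allclose(fic.F[mask], truth[mask], rtol=2e-3)


# ---------------------------------------------------------------------------
# QC

def test_strong_baseline_tilt_rejected_as_no_flat_region():
    cfg = SimulationConfig(
        model="homogeneous", E=5e3, R=8e-6, k=0.049,
        noise_sigma_F=20e-12, baseline_tilt=5e-4, n_curves=1, seed=9,
    )
    batch = generate_homogeneous(cfg)
    z0 = batch.manifest[0]["z0_m"]
    rep = qc_filter(batch.curves[0], z0, PreprocessConfig())
    assert not rep.accepted and "no_flat_region" in rep.reasons
    # oracle: least-squares slope of the pre-contact segment is the tilt
    z, F = batch.curves[0].z, batch.curves[0].F
    pre = z < z0 - 100e-9
    slope = np.polyfit(z[pre], F[pre], 1)[0]
    assert slope == pytest.approx(5e-4, rel=0.05)


def test_clean_curve_accepted_and_flag_mirrors_reasons():
    cfg = SimulationConfig(
        model="homogeneous", E=5e3, R=8e-6, k=0.049,
        noise_sigma_F=20e-12, n_curves=1, seed=9,
    )
    batch = generate_homogeneous(cfg)
    rep = qc_filter(batch.curves[0], batch.manifest[0]["z0_m"], PreprocessConfig())
    assert rep.accepted and rep.reasons == ()


def test_batch_qc_rejects_high_noise_outlier():
    cfg = SimulationConfig(
        model="homogeneous", E=5e3, R=8e-6, k=0.049,
        noise_sigma_F=20e-12, n_curves=8, seed=13,
    )
    batch = generate_homogeneous(cfg)
    loud_cfg = SimulationConfig(
        model="homogeneous", E=5e3, R=8e-6, k=0.049,
        noise_sigma_F=50 * 20e-12, n_curves=1, seed=14,
    )
    loud = generate_homogeneous(loud_cfg)
    curves = batch.curves + loud.curves
    z0s = [m["z0_m"] for m in batch.manifest] + [loud.manifest[0]["z0_m"]]
    reports = qc_batch(curves, z0s, PreprocessConfig())
    assert all(r.accepted for r in reports[:-1])
    assert "high_noise" in reports[-1].reasons
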