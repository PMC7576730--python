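"""Synthetic force-curve generation with exact ground truth.

Two forward models are provided:

``homogeneous``
    Hertzian indentation of an elastic half-space (modulus E).

``bilayer_exponential``
    Self-consistent bilayer: the depth profile E(delta) of the exponential
    bilayer model is pushed through the pointwise Oliver–Pharr relation,

        F(delta) = int_0^delta 2 sqrt(R t) E(t) / (1 - nu^2) dt,

    which has a closed form (an incomplete-gamma expression) for the
    exponential profile.  By construction the elasticity-spectrum pipeline
    is exactly invertible on these curves, which isolates numerical error
    from model error in recovery studies.

``bilayer_fea_surrogate``
    Placeholder for a layered-contact polynomial surrogate of finite-element
    simulations.  The coefficient table is not bundled with this package, so
    requesting this model raises :class:`SurrogateUnavailableError`; the
    self-consistent generator above is the available numerical reference.

Force curves are mapped to the displacement axis via z = z0 + delta + F/k
(cantilever compliance included), a flat pre-contact baseline (optionally
tilted) is prepended, and Gaussian force noise is added throughout.  Every
stochastic choice draws from a single seeded generator whose stream also
encodes the model name, so identical seeds give bit-identical batches and
different models give different ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import gammainc

from .bilayer import LAMBDA_DEFAULT
from .curve_io import (
    AcquisitionMetadata,
    ForceDistanceCurve,
    ForceIndentationCurve,
    write_curve,
)
from .errors import ConfigError, SurrogateUnavailableError, ValidationError
from .hertz import hertz_force

__all__ = [
    "SimulationConfig",
    "SyntheticBatch",
    "bilayer_force",
    "hertz_indentation_curve",
    "bilayer_indentation_curve",
    "generate_homogeneous",
    "generate_bilayer",
    "generate_fea_surrogate",
    "write_batch",
]

_MODEL_CODES = {"homogeneous": 0, "bilayer_exponential": 1, "bilayer_fea_surrogate": 2}


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative description of a synthetic indentation experiment.

    All quantities SI.  ``contact_offset_z0=None`` randomizes the contact
    point per curve, uniform over [0.25, 0.5] of the displacement range, so
    contact-point detection is genuinely exercised.  A seed is mandatory
    whenever any output is stochastic (noise or randomized contact).
    """

    model: str
    E: float = 5.2e3
    E0: float = 9.8e3
    Eb: float = 8.4e3
    d0: float = 300e-9
    lam: float = LAMBDA_DEFAULT
    R: float = 3.5e-6
    k: float = 0.3
    nu: float = 0.5
    z_range: float = 3e-6
    sampling_step: float = 2e-9
    contact_offset_z0: float | None = None
    noise_sigma_F: float = 20e-12
    baseline_tilt: float = 0.0
    n_curves: int = 1
    seed: int | None = None

    def __post_init__(self):
        if self.model not in _MODEL_CODES:
            raise ConfigError(f"unknown model {self.model!r}; expected one of {sorted(_MODEL_CODES)}")
        for name in ("E", "E0", "Eb", "d0", "lam", "R", "k", "z_range", "sampling_step"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not (0 <= self.nu <= 0.5):
            raise ConfigError("nu must lie in [0, 0.5]")
        if self.noise_sigma_F < 0:
            raise ConfigError("noise_sigma_F cannot be negative")
        if self.n_curves < 1:
            raise ConfigError("n_curves must be >= 1")
        if self.contact_offset_z0 is not None and not (
            0 < self.contact_offset_z0 < self.z_range
        ):
            raise ConfigError("contact_offset_z0 must fall inside the displacement range")
        stochastic = self.noise_sigma_F > 0 or self.contact_offset_z0 is None
        if stochastic and self.seed is None:
            raise ConfigError("a seed is mandatory for any stochastic output")


@dataclass(frozen=True)
class SyntheticBatch:
    """Generated curves plus the ground-truth manifest (one record per curve)."""

    curves: list[ForceDistanceCurve]
    manifest: list[dict]
    config: SimulationConfig


def bilayer_force(delta, E0: float, Eb: float, d0: float, R: float,
                  lam: float = LAMBDA_DEFAULT, nu: float = 0.5):
    """Indentation force of the self-consistent exponential bilayer (SI).

    Integrates the pointwise relation dF/ddelta = 2 sqrt(R delta) E(delta)
    / (1 - nu^2) over the exponential profile; in the contact radius
    u = sqrt(R t) the integral is (4 / (R (1-nu^2))) * int_0^a u^2 E(u) du
    with a = sqrt(R delta), evaluated in closed form through the lower
    incomplete gamma function.  Reduces exactly to the Hertz force when
    E0 == Eb.
    """
    if min(E0, Eb, d0, R, lam) <= 0:
        raise ValidationError("all bilayer parameters must be positive")
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValidationError("indentation depth must be non-negative")
    a = np.sqrt(R * delta)
    c = lam / d0
    pref = 4.0 / (R * (1.0 - nu**2))
    bulk = Eb * a**3 / 3.0
    # int_0^a u^2 exp(-c u) du = gamma(3, c a) / c^3 = 2 * gammainc(3, c a) / c^3
    layer = (E0 - Eb) * 2.0 * gammainc(3.0, c * a) / c**3
    out = pref * (bulk + layer)
    return out if out.ndim else float(out)


def _indentation_grid(delta_max: float, step: float) -> np.ndarray:
    n = int(round(delta_max / step))
    return step * np.arange(0, n + 1)


def hertz_indentation_curve(
    E: float, R: float, *, k: float = 0.3, nu: float = 0.5,
    delta_max: float = 800e-9, step: float = 2e-9, label: str = "hertz-exact",
) -> ForceIndentationCurve:
    """Exact noiseless Hertzian F(delta) curve (no contact uncertainty)."""
    d = _indentation_grid(delta_max, step)
    F = hertz_force(d, E, R, nu)
    md = AcquisitionMetadata(probe_radius=R, spring_constant=k, poisson_ratio=nu, label=label)
    return ForceIndentationCurve(delta=d, F=F, contact_point_z=0.0, metadata=md)


def bilayer_indentation_curve(
    E0: float, Eb: float, d0: float, R: float, lam: float = LAMBDA_DEFAULT,
    *, k: float = 0.3, nu: float = 0.5, delta_max: float = 800e-9,
    step: float = 2e-9, label: str = "bilayer-exact",
) -> ForceIndentationCurve:
    """Exact noiseless self-consistent bilayer F(delta) curve."""
    d = _indentation_grid(delta_max, step)
    F = bilayer_force(d, E0, Eb, d0, R, lam, nu)
    md = AcquisitionMetadata(probe_radius=R, spring_constant=k, poisson_ratio=nu, label=label)
    return ForceIndentationCurve(delta=d, F=F, contact_point_z=0.0, metadata=md)


def _synthesize_curve(
    force_of_delta, cfg: SimulationConfig, z0: float, rng: np.random.Generator,
    label: str,
) -> ForceDistanceCurve:
    z = cfg.sampling_step * np.arange(int(round(cfg.z_range / cfg.sampling_step)) + 1)
    if z0 >= z[-1]:
        raise ConfigError("displacement range shorter than the contact offset")

    # invert z(delta) = z0 + delta + F(delta)/k on a dense grid
    d_max = z[-1] - z0  # F/k >= 0, so delta never exceeds the remaining travel
    n_dense = max(1000, 4 * int(np.ceil(d_max / cfg.sampling_step)))
    d_dense = np.linspace(0.0, d_max, n_dense)
    F_dense = force_of_delta(d_dense)
    z_of_d = z0 + d_dense + F_dense / cfg.k

    F = np.zeros_like(z)
    post = z >= z0
    F[post] = np.interp(z[post], z_of_d, F_dense)
    if cfg.baseline_tilt != 0.0:
        F = F + cfg.baseline_tilt * (z - z[0])
    if cfg.noise_sigma_F > 0:
        F = F + rng.normal(0.0, cfg.noise_sigma_F, size=len(z))

    md = AcquisitionMetadata(
        probe_radius=cfg.R, spring_constant=cfg.k, poisson_ratio=cfg.nu, label=label
    )
    return ForceDistanceCurve(z=z, F=F, metadata=md)


def _batch(cfg: SimulationConfig, force_of_delta, params: dict) -> SyntheticBatch:
    rng = np.random.default_rng(
        None if cfg.seed is None else [cfg.seed, _MODEL_CODES[cfg.model]]
    )
    if cfg.contact_offset_z0 is None:
        z0s = cfg.z_range * rng.uniform(0.25, 0.5, size=cfg.n_curves)
    else:
        z0s = np.full(cfg.n_curves, cfg.contact_offset_z0)

    curves, manifest = [], []
    for i, z0 in enumerate(z0s):
        label = f"{cfg.model}-{i:04d}"
        curves.append(_synthesize_curve(force_of_delta, cfg, float(z0), rng, label))
        manifest.append(
            {
                "label": label,
                "model": cfg.model,
                "z0_m": float(z0),
                "noise_sigma_F_N": cfg.noise_sigma_F,
                "baseline_tilt_N_per_m": cfg.baseline_tilt,
                **params,
            }
        )
    return SyntheticBatch(curves=curves, manifest=manifest, config=cfg)


def generate_homogeneous(cfg: SimulationConfig) -> SyntheticBatch:
    """Batch of Hertzian curves with noise and per-curve contact offsets."""
    if cfg.model != "homogeneous":
        raise ConfigError(f"config model is {cfg.model!r}, not 'homogeneous'")
    params = {"E_Pa": cfg.E, "R_m": cfg.R, "k_N_per_m": cfg.k, "nu": cfg.nu}
    return _batch(cfg, lambda d: hertz_force(d, cfg.E, cfg.R, cfg.nu), params)


def generate_bilayer(cfg: SimulationConfig) -> SyntheticBatch:
    """Batch of self-consistent exponential-bilayer curves."""
    if cfg.model != "bilayer_exponential":
        raise ConfigError(f"config model is {cfg.model!r}, not 'bilayer_exponential'")
    params = {
        "E0_Pa": cfg.E0, "Eb_Pa": cfg.Eb, "d0_m": cfg.d0, "lambda": cfg.lam,
        "R_m": cfg.R, "k_N_per_m": cfg.k, "nu": cfg.nu,
    }
    return _batch(
        cfg, lambda d: bilayer_force(d, cfg.E0, cfg.Eb, cfg.d0, cfg.R, cfg.lam, cfg.nu), params
    )


def generate_fea_surrogate(cfg: SimulationConfig) -> ForceIndentationCurve:
    """Layered-contact polynomial surrogate (coefficients not bundled).

    Always raises :class:`SurrogateUnavailableError`: the published
    polynomial coefficient table for the stiff-film-on-compliant-half-space
    finite-element model is not distributed with this package.  Use
    :func:`bilayer_indentation_curve` (the self-consistent generator) as the
    numerical reference for calibration and recovery studies.
    """
    if cfg.model != "bilayer_fea_surrogate":
        raise ConfigError(f"config model is {cfg.model!r}, not 'bilayer_fea_surrogate'")
    raise SurrogateUnavailableError(
        "the layered-contact FEA polynomial coefficients are not bundled; "
        "use the self-consistent bilayer generator "
        "(espectra.synthdata.bilayer_indentation_curve / generate_bilayer) instead"
    )


def write_batch(batch: SyntheticBatch, outdir: str | Path, dialect: str = "csv2col") -> list[Path]:
    """Write each curve in the canonical dialect plus a ground-truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, curve in enumerate(batch.curves):
        ext = "csv" if dialect == "csv2col" else "tsv"
        p = outdir / f"curve_{i:04d}.{ext}"
        write_curve(curve, p, dialect=dialect)
        paths.append(p)
    (outdir / "manifest.json").write_text(json.dumps(batch.manifest, indent=2) + "\n")
    return paths
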