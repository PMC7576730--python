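"""Exponential bilayer model of the elasticity spectrum.

A cell is idealized as a stiff surface layer (the actin cortex, modulus E0,
thickness d0) on an indefinitely thick softer bulk (modulus Eb).  The depth
dependence of the apparent modulus is captured phenomenologically by an
exponential decay in the contact radius a = sqrt(R * delta):

    E(delta) = Eb + (E0 - Eb) * exp(-Lambda * sqrt(R * delta) / d0)

Lambda is a dimensionless decay factor calibrated once against a numerical
layered-contact indentation curve (default 1.74).  Because the profile
depends on Lambda and d0 only through Lambda/d0, rescaling Lambda rescales
the fitted thickness by the same factor and leaves E0, Eb untouched:
absolute thicknesses inherit the calibration, relative changes do not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .curve_io import ForceIndentationCurve
from .errors import CalibrationError, FitError, ValidationError
from .spectra import MeanSpectrum, pointwise_modulus

__all__ = [
    "LAMBDA_DEFAULT",
    "BilayerFit",
    "SessionAggregate",
    "bilayer_profile",
    "fit_bilayer",
    "calibrate_lambda",
    "aggregate_sessions",
]

#: calibrated exponential decay factor (dimensionless)
LAMBDA_DEFAULT = 1.74


@dataclass(frozen=True)
class BilayerFit:
    """Fitted bilayer parameters with standard errors (SI units)."""

    E0: float
    Eb: float
    d0: float
    lambda_used: float
    param_se: tuple[float, float, float]  # (E0, Eb, d0)
    fit_rms: float
    n_points: int
    fit_range: tuple[float, float]
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if not (self.E0 > 0 and self.Eb > 0 and self.d0 > 0):
            raise ValidationError("E0, Eb and d0 must all be positive")
        if not (self.fit_range[0] < self.fit_range[1]):
            raise ValidationError("fit range must be a non-empty interval")


@dataclass(frozen=True)
class SessionAggregate:
    """Size-weighted summary of repeated measurement sessions."""

    weighted_mean: dict[str, float]
    weighted_variance: dict[str, float]
    n_sessions: int
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValidationError("weights must be non-negative and sum to 1")
        object.__setattr__(self, "weights", w)


def bilayer_profile(delta, E0: float, Eb: float, d0: float, R: float,
                    lam: float = LAMBDA_DEFAULT):
    """Model spectrum E(delta) of a stiff layer on a soft bulk (all SI).

    Equals E0 at zero depth and decays to Eb over a contact-radius scale
    d0 / Lambda, i.e. a depth scale d0^2 / (Lambda^2 R).
    """
    if min(E0, Eb, d0, R, lam) <= 0:
        raise ValidationError("all bilayer parameters must be positive")
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValidationError("indentation depth must be non-negative")
    out = Eb + (E0 - Eb) * np.exp(-lam * np.sqrt(R * delta) / d0)
    return out if out.ndim else float(out)


def _init_guess(grid: np.ndarray, E: np.ndarray, R: float) -> tuple[float, float, float]:
    n = len(grid)
    n_head = max(1, n // 10)
    n_tail = max(1, n // 5)
    e0 = float(np.mean(E[:n_head]))
    eb = float(np.mean(E[-n_tail:]))
    d0 = R / 10.0
    floor = max(1e-3, 1e-6 * abs(eb) + 1e-3)
    return max(e0, floor), max(eb, floor), d0


def fit_bilayer(
    mean: MeanSpectrum,
    R: float,
    lam: float = LAMBDA_DEFAULT,
    fit_range: tuple[float, float] | None = None,
    *,
    weighted: bool = False,
    n_restarts: int = 5,
    seed: int = 0,
) -> BilayerFit:
    """Nonlinear least squares of the bilayer profile to a mean spectrum.

    Free parameters are (E0, Eb, d0), fitted in log space to enforce
    positivity; Lambda is held at its calibrated value.  Initialization:
    E0 from the first 10% of the spectrum, Eb from the last 20%, d0 = R/10;
    up to ``n_restarts`` log-normally jittered restarts (deterministic for
    a given ``seed``) guard against a bad starting point.  Standard errors
    come from the fit covariance via the delta method.  With
    ``weighted=True`` points are weighted by 1/SE^2 of the mean (SD/sqrt(n));
    the default is the unweighted fit of the average spectrum.

    An inverted contrast (E0 < Eb, a soft layer on a stiff bulk) is allowed
    and flagged ``inverted_contrast``; a vanishing contrast leaves d0
    unidentifiable and is flagged ``degenerate_thickness``.
    """
    grid = np.asarray(mean.delta_grid, dtype=float)
    E = np.asarray(mean.E_mean, dtype=float)
    if fit_range is not None:
        lo, hi = fit_range
        m = (grid >= lo) & (grid <= hi)
        grid, E = grid[m], E[m]
        sd = np.asarray(mean.E_std)[m]
        nn = np.asarray(mean.n_curves_per_point)[m]
    else:
        sd = np.asarray(mean.E_std)
        nn = np.asarray(mean.n_curves_per_point)
    if len(grid) < 10:
        raise FitError(f"need >= 10 grid points in the fit range, have {len(grid)}")
    if lam <= 0 or R <= 0:
        raise ValidationError("R and Lambda must be positive")

    sigma = None
    if weighted:
        se = sd / np.sqrt(np.maximum(nn, 1))
        se = np.where(se > 0, se, np.nanmax(se) if np.nanmax(se) > 0 else 1.0)
        sigma = se

    def model(d, log_e0, log_eb, log_d0):
        # inline profile with clipped exponents: the optimizer may probe
        # extreme log values that would underflow the validated entry point
        e0 = np.exp(np.clip(log_e0, -200.0, 200.0))
        eb = np.exp(np.clip(log_eb, -200.0, 200.0))
        d0_ = np.exp(np.clip(log_d0, -200.0, 200.0))
        return eb + (e0 - eb) * np.exp(-lam * np.sqrt(R * d) / d0_)

    e0g, ebg, d0g = _init_guess(grid, E, R)
    rng = np.random.default_rng(seed)
    best = None
    last_err: Exception | None = None
    for trial in range(n_restarts):
        if trial == 0:
            p0 = [np.log(e0g), np.log(ebg), np.log(d0g)]
        else:
            p0 = [
                np.log(e0g) + rng.normal(0, 0.3),
                np.log(ebg) + rng.normal(0, 0.3),
                np.log(d0g) + rng.normal(0, 0.7),
            ]
        try:
            with warnings.catch_warnings():
                # restarts from bad basins may yield singular covariances;
                # they lose the residual comparison below anyway
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, pcov = curve_fit(
                    model, grid, E, p0=p0, sigma=sigma, absolute_sigma=False, maxfev=20_000
                )
        except (RuntimeError, ValueError) as exc:
            last_err = exc
            continue
        resid = E - model(grid, *popt)
        rms = float(np.sqrt(np.mean(resid**2)))
        if best is None or rms < best[2]:
            best = (popt, pcov, rms)
    if best is None:
        raise FitError(f"bilayer fit failed to converge after {n_restarts} restarts: {last_err}")

    popt, pcov, rms = best
    e0, eb, d0 = np.exp(popt)
    se_log = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    se = (float(e0 * se_log[0]), float(eb * se_log[1]), float(d0 * se_log[2]))

    flags: list[str] = []
    if e0 < eb:
        flags.append("inverted_contrast")
    contrast = abs(e0 - eb)
    if contrast <= 1e-3 * max(e0, eb) or (np.isfinite(se[2]) and se[2] > 10 * d0):
        flags.append("degenerate_thickness")

    return BilayerFit(
        E0=float(e0),
        Eb=float(eb),
        d0=float(d0),
        lambda_used=float(lam),
        param_se=se,
        fit_rms=rms,
        n_points=len(grid),
        fit_range=(float(grid[0]), float(grid[-1])),
        flags=tuple(flags),
    )


def calibrate_lambda(
    numeric_curve: ForceIndentationCurve,
    truth: tuple[float, float, float],
    R: float,
    *,
    derivative_step: float | None = None,
    fit_range: tuple[float, float] | None = None,
) -> float:
    """Calibrate the decay factor against a numerical bilayer curve.

    The elasticity spectrum of ``numeric_curve`` (a layered-contact
    indentation curve with known ground truth) is fitted with (E0, Eb, d0)
    held fixed at ``truth`` and Lambda as the single free parameter.
    """
    E0, Eb, d0 = truth
    if not (E0 > 0 and Eb > 0 and d0 > 0):
        raise ValidationError("ground-truth parameters must be positive")
    if abs(E0 - Eb) <= 1e-6 * max(E0, Eb):
        raise CalibrationError("zero modulus contrast: the decay factor is unconstrained")

    kwargs = {} if derivative_step is None else {"derivative_step": derivative_step}
    spec = pointwise_modulus(numeric_curve, **kwargs)
    grid, E = spec.delta_grid, spec.E
    if fit_range is not None:
        m = (grid >= fit_range[0]) & (grid <= fit_range[1])
        grid, E = grid[m], E[m]

    def model(d, log_lam):
        lam = np.exp(np.clip(log_lam, -50.0, 50.0))
        return Eb + (E0 - Eb) * np.exp(-lam * np.sqrt(R * d) / d0)

    try:
        popt, _ = curve_fit(model, grid, E, p0=[np.log(1.5)], maxfev=20_000)
    except (RuntimeError, ValueError) as exc:
        raise CalibrationError(f"Lambda calibration fit failed: {exc}") from exc
    return float(np.exp(popt[0]))


def aggregate_sessions(fits: list[BilayerFit], n_cells: list[int]) -> SessionAggregate:
    """Combine repeated sessions with weights proportional to session size.

    For each parameter p in (E0, Eb, d0) the report is the weighted mean
    sum(w_i p_i) and the weighted variance of the repeats about that mean,
    sum(w_i (p_i - mean)^2), with w_i = n_i / sum(n).
    """
    if len(fits) != len(n_cells):
        raise ValidationError("fits and n_cells must have equal length")
    if len(fits) < 2:
        raise ValidationError("session aggregation needs at least 2 sessions")
    n = np.asarray(n_cells, dtype=float)
    if np.any(n <= 0):
        raise ValidationError("session sizes must be positive")
    w = n / n.sum()

    means: dict[str, float] = {}
    variances: dict[str, float] = {}
    for name in ("E0", "Eb", "d0"):
        vals = np.array([getattr(f, name) for f in fits], dtype=float)
        mu = float(w @ vals)
        means[name] = mu
        variances[name] = float(w @ (vals - mu) ** 2)
    return SessionAggregate(
        weighted_mean=means,
        weighted_variance=variances,
        n_sessions=len(fits),
        weights=w,
    )
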