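"""Classical single-modulus (Hertzian) analysis.

For a rigid sphere of radius R indenting an elastic half-space of Young's
modulus E and Poisson's ratio nu to depth delta:

    F = (4/3) * E / (1 - nu^2) * sqrt(R) * delta^(3/2)

The per-curve fit treats E as the single free parameter; a population of
per-curve moduli is summarized by the peak of a Gaussian fitted to its
histogram (robust against the skewed tails typical of cell data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .curve_io import ForceIndentationCurve
from .errors import FitError, ValidationError

__all__ = [
    "HertzFit",
    "HertzPopulation",
    "hertz_force",
    "fit_hertz",
    "population_peak",
    "default_fit_depth",
]


@dataclass(frozen=True)
class HertzFit:
    """Single-curve Hertz fit result (SI units)."""

    E: float
    fit_range: tuple[float, float]
    residual_rms: float
    n_points: int

    def __post_init__(self):
        if not (self.E > 0):
            raise ValidationError("fitted modulus must be positive")
        if not (self.fit_range[0] < self.fit_range[1]):
            raise ValidationError("fit range must be a non-empty interval")


@dataclass(frozen=True)
class HertzPopulation:
    """Population summary: histogram-peak position +/- its standard error."""

    E_values: np.ndarray
    peak: float
    peak_sem: float
    n_curves: int

    def __post_init__(self):
        if self.n_curves != len(self.E_values) or self.n_curves < 1:
            raise ValidationError("n_curves must equal len(E_values) >= 1")


def hertz_force(delta, E: float, R: float, nu: float = 0.5):
    """Force on a sphere of radius R at indentation delta (all SI).

    Accepts scalar or array ``delta``; negative depths raise.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation depth must be non-negative")
    if E <= 0 or R <= 0:
        raise ValueError("E and R must be positive")
    out = (4.0 / 3.0) * (E / (1.0 - nu**2)) * np.sqrt(R) * delta**1.5
    return out if out.ndim else float(out)


def default_fit_depth(R: float, hard_cap: float = 800e-9) -> float:
    """Default maximum fit depth: min(800 nm, 10% of the probe radius).

    Shallow enough to stay within small-strain contact mechanics and clear
    of the rigid-dish substrate contribution.
    """
    return min(hard_cap, 0.1 * R)


def fit_hertz(curve: ForceIndentationCurve, delta_max: float | None = None) -> HertzFit:
    """Least-squares fit of the Hertz relation over [0, delta_max].

    The model is linear in E, so the plain least-squares optimum has the
    closed form E = <F, g> / <g, g> with g(delta) the unit-modulus Hertz
    force; a non-positive optimum raises :class:`FitError`.
    """
    md = curve.metadata
    if delta_max is None:
        delta_max = default_fit_depth(md.probe_radius)
    mask = curve.delta <= delta_max
    d, F = curve.delta[mask], curve.F[mask]
    if len(d) < 10:
        raise FitError(f"need >= 10 points below delta_max={delta_max!r}, have {len(d)}")
    g = (4.0 / 3.0) * np.sqrt(md.probe_radius) * d**1.5 / (1.0 - md.poisson_ratio**2)
    denom = float(g @ g)
    if denom == 0.0:
        raise FitError("degenerate fit: all depths are zero")
    E = float(F @ g) / denom
    if E <= 0:
        raise FitError(f"non-physical (non-positive) modulus from fit: {E!r} Pa")
    resid = F - E * g
    return HertzFit(
        E=E,
        fit_range=(float(d.min()), float(d.max())),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=len(d),
    )


def _gauss(x, A, mu, sigma):
    return A * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def population_peak(E_values) -> HertzPopulation:
    """Peak position (+/- SEM) of a Gaussian fitted to the modulus histogram.

    Binning follows the Freedman–Diaconis rule.  Degenerate inputs (all
    values equal) return that value with SEM 0 and a warning.
    """
    E = np.asarray(E_values, dtype=float)
    if E.ndim != 1 or len(E) < 1 or not np.all(np.isfinite(E)):
        raise ValidationError("E_values must be a finite 1-D array")
    if np.ptp(E) == 0.0:
        warnings.warn("all modulus values identical; population peak is degenerate")
        return HertzPopulation(E_values=E, peak=float(E[0]), peak_sem=0.0, n_curves=len(E))
    if len(E) < 10:
        raise ValidationError("need >= 10 values for a histogram-peak summary")

    counts, edges = np.histogram(E, bins="fd")
    if np.count_nonzero(counts) < 4:  # FD can over-merge heavy-tailed data
        counts, edges = np.histogram(E, bins="sturges")
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = [float(counts.max()), float(np.median(E)), float(np.std(E))]
    try:
        popt, pcov = curve_fit(_gauss, centers, counts, p0=p0, maxfev=10_000)
        peak, sem = float(popt[1]), float(np.sqrt(pcov[1, 1]))
    except (RuntimeError, ValueError) as exc:
        raise FitError("Gaussian histogram fit failed") from exc
    return HertzPopulation(E_values=E, peak=peak, peak_sem=sem, n_curves=len(E))
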