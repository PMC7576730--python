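"""Elasticity spectra: depth-resolved apparent Young's modulus E(delta).

The pointwise (Oliver–Pharr) relation links the local slope of the
force–indentation curve to the modulus through the contact radius
a = sqrt(R * delta) of a spherical probe:

    dF/ddelta = 2 a E / (1 - nu^2)
    E(delta)  = (1 - nu^2) / (2 sqrt(R delta)) * dF/ddelta

For a Hertzian half-space this yields a constant spectrum equal to the
generating modulus, which is the internal consistency check between the
integral (Hertz fit) and differential (spectrum) views of the same curve.
Derivatives are taken with a Savitzky–Golay filter over a window expressed
as a physical length, so results are sampling-rate invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .curve_io import ForceIndentationCurve
from .errors import MetadataError, ValidationError
from .hertz import HertzPopulation, population_peak

__all__ = [
    "ElasticitySpectrum",
    "MeanSpectrum",
    "pointwise_modulus",
    "average_spectra",
    "select_working_range",
    "spectrum_peak",
    "DERIVATIVE_STEP",
    "GRID_STEP",
]

#: default physical width of the derivative window (m)
DERIVATIVE_STEP = 25e-9
#: uniform resampling spacing of the depth grid (m)
GRID_STEP = 5e-9


@dataclass(frozen=True)
class ElasticitySpectrum:
    """Apparent modulus on a uniform depth grid, for one curve."""

    delta_grid: np.ndarray
    E: np.ndarray
    source_curve_id: str = ""

    def __post_init__(self):
        d = np.asarray(self.delta_grid, dtype=float)
        E = np.asarray(self.E, dtype=float)
        if len(d) != len(E):
            raise ValidationError("grid and E lengths differ")
        if len(d) < 2:
            raise ValidationError("a spectrum needs at least 2 grid points")
        steps = np.diff(d)
        if not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValidationError("delta grid must be uniformly spaced")
        if not np.all(np.isfinite(E)):
            raise ValidationError("E must be finite on the reported range")
        object.__setattr__(self, "delta_grid", d)
        object.__setattr__(self, "E", E)

    @property
    def grid_step(self) -> float:
        return float(self.delta_grid[1] - self.delta_grid[0])


@dataclass(frozen=True)
class MeanSpectrum:
    """Pointwise mean +/- SD over a batch of spectra, with per-point counts."""

    delta_grid: np.ndarray
    E_mean: np.ndarray
    E_std: np.ndarray
    n_curves_per_point: np.ndarray

    def __post_init__(self):
        n = np.asarray(self.n_curves_per_point, dtype=int)
        if np.any(np.asarray(self.E_std) < 0):
            raise ValidationError("standard deviation cannot be negative")
        if np.any(np.diff(n) > 0):
            raise ValidationError("per-point curve counts cannot increase with depth")
        object.__setattr__(self, "n_curves_per_point", n)


def pointwise_modulus(
    curve: ForceIndentationCurve,
    derivative_step: float = DERIVATIVE_STEP,
    grid_step: float = GRID_STEP,
    source_curve_id: str = "",
) -> ElasticitySpectrum:
    """Compute E(delta) for one curve via the pointwise Oliver–Pharr relation.

    The curve is linearly resampled onto a uniform depth grid (spacing
    ``grid_step``, at most ``derivative_step``/3), dF/ddelta is estimated by
    a Savitzky–Golay first-derivative filter whose window spans
    ``derivative_step``, and E is reported for delta >= ``derivative_step``
    (the modulus is numerically undefined at zero depth).
    """
    R = curve.metadata.probe_radius
    nu = curve.metadata.poisson_ratio
    if not (R > 0):
        raise MetadataError("probe radius required for the contact radius")
    if grid_step > derivative_step / 3:
        grid_step = derivative_step / 3

    delta_max = float(curve.delta[-1])
    if delta_max <= 5 * derivative_step:
        raise ValidationError(
            f"curve too shallow for a spectrum: depth {delta_max!r} m "
            f"<= 5 x derivative step {derivative_step!r} m"
        )
    grid = np.arange(grid_step, delta_max + 0.5 * grid_step, grid_step)
    grid = grid[grid <= delta_max]
    F_grid = np.interp(grid, curve.delta, curve.F)

    window = int(round(derivative_step / grid_step))
    if window % 2 == 0:
        window += 1
    window = max(window, 5)
    dFdd = savgol_filter(
        F_grid, window_length=window, polyorder=3, deriv=1, delta=grid_step, mode="interp"
    )

    E = (1.0 - nu**2) / (2.0 * np.sqrt(R * grid)) * dFdd
    keep = grid >= derivative_step * (1 - 1e-9)
    return ElasticitySpectrum(
        delta_grid=grid[keep], E=E[keep], source_curve_id=source_curve_id
    )


def average_spectra(spectra: list[ElasticitySpectrum]) -> MeanSpectrum:
    """Pointwise mean and SD across curves on a common grid.

    Spectra must share the grid spacing (they do when produced by
    :func:`pointwise_modulus` with common settings).  Beyond the depth of
    the shorter curves the per-point count drops and statistics run over
    the remaining curves only; no extrapolation is performed.
    """
    if not spectra:
        raise ValidationError("cannot average an empty list of spectra")
    step = spectra[0].grid_step
    for s in spectra:
        if not np.isclose(s.grid_step, step, rtol=1e-6):
            raise ValidationError("spectra must share the grid spacing before averaging")

    start = min(s.delta_grid[0] for s in spectra)
    stop = max(s.delta_grid[-1] for s in spectra)
    n_pts = int(round((stop - start) / step)) + 1
    grid = start + step * np.arange(n_pts)

    mat = np.full((len(spectra), n_pts), np.nan)
    for row, s in enumerate(spectra):
        i0 = int(round((s.delta_grid[0] - start) / step))
        mat[row, i0 : i0 + len(s.E)] = s.E

    counts = np.sum(np.isfinite(mat), axis=0)
    valid = counts >= 1
    grid, mat, counts = grid[valid], mat[:, valid], counts[valid]
    mean = np.nanmean(mat, axis=0)
    sd = np.zeros_like(mean)
    multi = counts > 1
    if np.any(multi):
        sd[multi] = np.nanstd(mat[:, multi], axis=0, ddof=1)
    return MeanSpectrum(
        delta_grid=grid, E_mean=mean, E_std=sd, n_curves_per_point=counts
    )


def select_working_range(
    mean: MeanSpectrum,
    hard_cap: float = 800e-9,
    slope_window: float = 100e-9,
    t_threshold: float = 2.0,
    persistence_length: float | None = None,
) -> tuple[float, float]:
    """Trustworthy depth interval of a mean spectrum.

    The upper limit is the smaller of ``hard_cap`` and the substrate-rise
    onset: the first depth at which a running linear fit of <E(delta)> over
    a ``slope_window`` turns persistently positive after having been
    non-positive.  "Persistently" means significantly positive — slope
    exceeding ``t_threshold`` times its own standard error — for every
    window starting within a ``persistence_length`` span (default: one
    slope window), which keeps sampling noise in a flat or decaying
    spectrum from triggering a false onset.  When no rise is detected the
    full (grid start, hard_cap) range is returned.
    """
    grid, E = np.asarray(mean.delta_grid), np.asarray(mean.E_mean)
    if len(grid) < 10:
        raise ValidationError("mean spectrum must cover at least 10 grid points")
    step = grid[1] - grid[0]
    w = max(4, int(round(slope_window / step)))
    if w >= len(grid):
        return float(grid[0]), hard_cap
    if persistence_length is None:
        persistence_length = slope_window
    run_needed = max(1, int(round(persistence_length / step)))

    # LS slope over each window of w points, vectorized via convolution
    x = (np.arange(w) - (w - 1) / 2) * step
    denom = float(x @ x)
    kernel = x[::-1] / denom
    slopes = np.convolve(E, kernel, mode="valid")          # slopes[j] over E[j:j+w]
    box = np.ones(w)
    s_y = np.convolve(E, box, mode="valid")
    s_y2 = np.convolve(E**2, box, mode="valid")
    sse = np.maximum(s_y2 - s_y**2 / w - slopes**2 * denom, 0.0)
    sigma2 = sse / max(w - 2, 1)
    se = np.sqrt(sigma2 / denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slopes / se, np.sign(slopes) * np.inf)

    rising = t > t_threshold
    seen_nonpos = False
    run = 0
    for j in range(len(slopes)):
        if slopes[j] <= 0:
            seen_nonpos = True
            run = 0
        elif rising[j] and seen_nonpos:
            run += 1
            if run >= run_needed:
                onset = grid[j - run + 1]  # start of the first rising window
                return float(grid[0]), float(min(hard_cap, onset))
        else:
            run = 0
    return float(grid[0]), hard_cap


def spectrum_peak(mean: MeanSpectrum) -> HertzPopulation:
    """Histogram-peak summary of the mean-spectrum values.

    Mirrors the population summary used for per-curve Hertz moduli, applied
    to <E(delta)> sampled over the depth grid; for a near-flat spectrum the
    peak estimates the plateau modulus.
    """
    return population_peak(np.asarray(mean.E_mean))
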