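"""Raw-curve conditioning: smoothing, contact-point detection, conversion, QC.

The contact point z0 is located by the ratio-of-variances (RoV) statistic:
at each interior sample i the variance of the force over a forward window is
divided by the variance over a backward window.  Before contact both windows
see only instrument noise (RoV ~ 1); as the forward window slides onto the
rising contact region the ratio grows sharply, and it collapses again once
the backward window also contains contact data.  The *last* prominent peak
of RoV(i) along z marks the contact point.  The method needs no assumption
about the polynomial shape of the post-contact force.

The raw RoV peak carries a noise-dependent late bias of a few samples: just
past contact the force is still below the noise floor, so the backward
window stays "quiet" for a few more samples and the ratio keeps growing.
By default the peak is therefore used as a coarse candidate and z0 is
refined by a local piecewise fit (flat baseline + 3/2-power contact rise)
over the surrounding samples; the refinement is switchable for a literal
last-peak read-out.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import find_peaks, savgol_filter

from .curve_io import ForceDistanceCurve, ForceIndentationCurve
from .errors import (
    ConfigError,
    ContactPointNotFoundError,
    EmptyCurveError,
    MetadataError,
    ValidationError,
)

__all__ = [
    "PreprocessConfig",
    "QCReport",
    "ContactPoint",
    "smooth_curve",
    "find_contact_point",
    "to_force_indentation",
    "qc_filter",
    "qc_batch",
]

#: hard ceiling on the RoV half-window, in samples
_ROV_MAX_SAMPLES = 150
#: minimum samples a RoV window must cover
_ROV_MIN_SAMPLES = 8


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable parameters of the conditioning stage (lengths in metres).

    ``rov_window`` is converted to samples and capped at 150 samples, so the
    window straddles the noise-regime change without spanning the whole
    contact region.  ``rov_min_prominence`` is a fraction of max(RoV).
    QC thresholds left as ``None`` are derived per curve / per batch (see
    :func:`qc_filter` and :func:`qc_batch`).
    """

    sg_window: float = 30e-9
    sg_polyorder: int = 3
    rov_window: float = 300e-9
    rov_min_prominence: float = 0.10
    rov_min_peak: float = 3.0
    refine_contact: bool = True
    qc_baseline_slope_max: float | None = None
    qc_noise_rms_max: float | None = None
    subtract_deflection: bool = True

    def __post_init__(self):
        if self.sg_window <= 0 or self.rov_window <= 0:
            raise ConfigError("window lengths must be positive")
        if self.sg_polyorder < 1:
            raise ConfigError("sg_polyorder must be >= 1")
        if not (0 < self.rov_min_prominence <= 1):
            raise ConfigError("rov_min_prominence is a fraction of max(RoV) in (0, 1]")


@dataclass(frozen=True)
class ContactPoint:
    """Located contact point plus the full RoV trace for diagnostics."""

    index: int
    z0: float
    rov: np.ndarray
    rov_index_offset: int  # rov[j] corresponds to curve sample j + offset
    variance_floored: bool = False


@dataclass(frozen=True)
class QCReport:
    accepted: bool
    reasons: tuple[str, ...]
    baseline_slope: float
    baseline_noise_rms: float

    def __post_init__(self):
        if self.accepted != (len(self.reasons) == 0):
            raise ValidationError("accepted flag must mirror an empty reason list")


def _window_samples(length_m: float, dz: float, minimum: int = 3) -> int:
    w = max(minimum, int(round(length_m / dz)))
    return w


def smooth_curve(curve: ForceDistanceCurve, cfg: PreprocessConfig) -> ForceDistanceCurve:
    """Savitzky–Golay smooth the force channel; z is untouched.

    The window is expressed as a physical length and converted using the
    median sample spacing.  Endpoints use a polynomial fit over the edge
    window evaluated in place (no padding artifacts).
    """
    dz = float(np.median(np.diff(curve.z)))
    w = _window_samples(cfg.sg_window, dz, minimum=cfg.sg_polyorder + 2)
    if w % 2 == 0:
        w += 1
    if w > len(curve):
        raise ConfigError(
            f"smoothing window of {w} samples exceeds the {len(curve)}-sample curve"
        )
    F_s = savgol_filter(curve.F, window_length=w, polyorder=cfg.sg_polyorder, mode="interp")
    return ForceDistanceCurve(z=curve.z, F=F_s, metadata=curve.metadata)


def _rov_trace(F: np.ndarray, w: int) -> tuple[np.ndarray, int, bool]:
    """RoV(i) = Var(F[i+1 .. i+w]) / Var(F[i-w .. i-1]) for i in [w, n-w-1]."""
    n = len(F)
    windows = sliding_window_view(F, w)           # windows[j] = F[j .. j+w-1]
    var = windows.var(axis=-1, ddof=1)            # var[j] over F[j .. j+w-1]
    fwd = var[w + 1:]                             # i = w .. n-w-1 -> var over F[i+1 ..]
    back = var[: n - 2 * w]                       # var over F[i-w .. i-1]
    floored = bool(np.any(back <= 0))
    eps = np.finfo(float).tiny * 1e16
    return fwd / np.maximum(back, eps), w, floored


def _refine_contact_index(z: np.ndarray, F: np.ndarray, idx: int, half: int) -> int:
    """Refine a coarse contact index by a local piecewise least-squares fit.

    Within ``idx +/- half`` samples, every sample is tried as contact
    candidate zc for the model F = c + B * max(z - zc, 0)^(3/2) (flat
    baseline, Hertzian-type rise; B >= 0), linear in (c, B) for fixed zc.
    The candidate minimizing the residual sum of squares wins.  Candidate
    positions are sample indices, so the refinement is exactly
    translation-equivariant in z.
    """
    lo, hi = max(0, idx - half), min(len(z), idx + half + 1)
    zs, Fs = z[lo:hi], F[lo:hi]
    n = len(zs)
    ones = np.ones(n)
    best_j, best_sse = idx - lo, np.inf
    for j in range(n):
        g = np.maximum(zs - zs[j], 0.0) ** 1.5
        X = np.column_stack([ones, g])
        coef, *_ = np.linalg.lstsq(X, Fs, rcond=None)
        if coef[1] < 0:  # unphysical pull-in; score as baseline-only
            r = Fs - Fs.mean()
        else:
            r = Fs - X @ coef
        sse = float(r @ r)
        if sse < best_sse:
            best_sse, best_j = sse, j
    return lo + best_j


def find_contact_point(curve: ForceDistanceCurve, cfg: PreprocessConfig) -> ContactPoint:
    """Locate z0 from the last prominent peak of the ratio of variances.

    Peaks are local maxima of RoV with prominence at least
    ``rov_min_prominence * max(RoV)``; among them the one at largest z wins.
    With ``cfg.refine_contact`` (the default) the winning peak seeds a local
    piecewise baseline-plus-contact fit that removes the late bias of the
    raw peak position.  Raises :class:`ContactPointNotFoundError` when no
    peak qualifies.
    """
    dz = float(np.median(np.diff(curve.z)))
    w = min(_ROV_MAX_SAMPLES, _window_samples(cfg.rov_window, dz, minimum=_ROV_MIN_SAMPLES))
    if len(curve) < 2 * w + 2:
        raise ConfigError(
            f"curve of {len(curve)} samples too short for RoV windows of {w} samples"
        )
    rov, offset, floored = _rov_trace(curve.F, w)
    if float(rov.max()) < cfg.rov_min_peak:
        # no variance-regime change anywhere: noise-only curve
        raise ContactPointNotFoundError(
            f"maximum ratio of variances {rov.max():.2f} below the floor "
            f"{cfg.rov_min_peak}; no contact detected"
        )
    prominence = cfg.rov_min_prominence * float(rov.max())
    peaks, _ = find_peaks(rov, prominence=prominence)
    if peaks.size == 0:
        raise ContactPointNotFoundError(
            "no ratio-of-variances peak above the prominence threshold"
        )
    idx = int(peaks[-1]) + offset
    if cfg.refine_contact:
        idx = _refine_contact_index(curve.z, curve.F, idx, half=min(w, 50))
    return ContactPoint(
        index=idx, z0=float(curve.z[idx]), rov=rov, rov_index_offset=offset,
        variance_floored=floored,
    )


def to_force_indentation(
    curve: ForceDistanceCurve,
    z0: float,
    *,
    subtract_deflection: bool = True,
) -> ForceIndentationCurve:
    """Convert F(z) to F(delta) given the contact point.

    delta_i = (z_i - z0) - F_i / k: the piezo travel past contact minus the
    cantilever deflection x = F/k.  With ``subtract_deflection=False`` only
    the axis shift is applied (delta = z - z0).  Pre-contact samples are
    dropped, delta is clipped at 0 and back-steps are removed so the result
    is monotone.
    """
    z, F = curve.z, curve.F
    if not (z[0] <= z0 <= z[-1]):
        raise ValidationError(f"z0={z0!r} outside the curve range [{z[0]!r}, {z[-1]!r}]")
    k = curve.metadata.spring_constant
    if not (k > 0):
        raise MetadataError("spring constant required for indentation conversion")

    mask = z >= z0
    if not np.any(mask):
        raise EmptyCurveError("all samples lie before the contact point")
    zc, Fc = z[mask], F[mask]
    delta = zc - z0
    if subtract_deflection:
        delta = delta - Fc / k
    delta = np.maximum(delta, 0.0)

    # drop back-steps so delta is non-decreasing (forces are preserved)
    keep = np.ones(len(delta), dtype=bool)
    running_max = np.maximum.accumulate(delta)
    keep[1:] = delta[1:] >= running_max[:-1]
    delta, Fc = delta[keep], Fc[keep]
    if len(delta) == 0:
        raise EmptyCurveError("no indentation samples remain after monotonicity filtering")

    return ForceIndentationCurve(
        delta=delta, F=Fc, contact_point_z=float(z0), metadata=curve.metadata
    )


# ---------------------------------------------------------------------------
# quality control

def _baseline_stats(
    curve: ForceDistanceCurve, z0: float | None, guard: float = 0.0
) -> tuple[float, float, float]:
    """Least-squares slope, residual RMS and length of the pre-contact segment.

    ``guard`` (m) is excluded just before z0 so smoothing leakage from the
    contact region does not contaminate the baseline statistics.
    """
    z, F = curve.z, curve.F
    if z0 is None:
        cut = len(z)
    else:
        cut = int(np.searchsorted(z, z0 - guard))
    if cut < 8:
        return np.nan, np.nan, 0.0
    zb, Fb = z[:cut], F[:cut]
    slope, intercept = np.polyfit(zb, Fb, 1)
    resid = Fb - (slope * zb + intercept)
    return float(slope), float(np.sqrt(np.mean(resid**2))), float(zb[-1] - zb[0])


def qc_filter(
    curve: ForceDistanceCurve,
    z0: float | None,
    cfg: PreprocessConfig,
) -> QCReport:
    """Accept/reject a curve based on its pre-contact baseline.

    Rules (each contributes a reason identifier when violated):

    - ``no_contact_point``: z0 is ``None`` (detection failed);
    - ``no_flat_region``: |baseline slope| exceeds ``qc_baseline_slope_max``
      (default: 3 x baseline noise RMS / baseline length);
    - ``high_noise``: baseline residual RMS exceeds ``qc_noise_rms_max``
      (no default at the single-curve level; see :func:`qc_batch` for the
      batch-median rule).
    """
    reasons: list[str] = []
    slope, rms, blen = _baseline_stats(curve, z0, guard=2 * cfg.sg_window)
    if z0 is None:
        reasons.append("no_contact_point")
    if np.isfinite(slope):
        slope_max = cfg.qc_baseline_slope_max
        if slope_max is None and blen > 0:
            # epsilon keeps an exactly flat noiseless baseline acceptable
            slope_max = 3.0 * rms / blen + 1e-15
        if slope_max is not None and abs(slope) > slope_max:
            reasons.append("no_flat_region")
        if cfg.qc_noise_rms_max is not None and rms > cfg.qc_noise_rms_max:
            reasons.append("high_noise")
    return QCReport(
        accepted=not reasons,
        reasons=tuple(reasons),
        baseline_slope=slope,
        baseline_noise_rms=rms,
    )


def qc_batch(
    curves: Sequence[ForceDistanceCurve],
    z0s: Sequence[float | None],
    cfg: PreprocessConfig,
) -> list[QCReport]:
    """Batch QC with the noise threshold tied to the batch median.

    When ``qc_noise_rms_max`` is unset, it becomes 5x the median baseline
    noise RMS of the batch, so "high random variations" is judged relative
    to the session's own noise floor.
    """
    if len(curves) != len(z0s):
        raise ValidationError("curves and z0s must have equal length")
    noise = [
        _baseline_stats(c, z0, guard=2 * cfg.sg_window)[1] for c, z0 in zip(curves, z0s)
    ]
    finite = [x for x in noise if np.isfinite(x)]
    cfg_eff = cfg
    if cfg.qc_noise_rms_max is None and finite:
        cfg_eff = replace(cfg, qc_noise_rms_max=5.0 * float(np.median(finite)))
    return [qc_filter(c, z0, cfg_eff) for c, z0 in zip(curves, z0s)]
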