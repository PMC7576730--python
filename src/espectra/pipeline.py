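"""End-to-end batch analysis: raw curves in, fitted parameters out.

This is the library-level orchestration behind the ``espectra analyze``
command: smooth -> contact point -> QC -> convert -> per-curve Hertz fits
and elasticity spectra -> mean spectrum -> working range -> bilayer fit.
Per-curve failures are recorded and the run continues; curves in always
equals accepted plus rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bilayer import LAMBDA_DEFAULT, BilayerFit, fit_bilayer
from .curve_io import ForceDistanceCurve, ForceIndentationCurve
from .errors import EspectraError
from .hertz import HertzFit, HertzPopulation, fit_hertz, population_peak
from .preprocess import (
    PreprocessConfig,
    QCReport,
    find_contact_point,
    qc_batch,
    smooth_curve,
)
from .preprocess import to_force_indentation
from .spectra import (
    DERIVATIVE_STEP,
    ElasticitySpectrum,
    MeanSpectrum,
    average_spectra,
    pointwise_modulus,
    select_working_range,
    spectrum_peak,
)

__all__ = ["AnalysisOptions", "AnalysisResult", "analyze_curves"]


@dataclass(frozen=True)
class AnalysisOptions:
    """Toggles and parameters for a batch analysis run."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    run_hertz: bool = True
    run_spectra: bool = True
    run_bilayer: bool = True
    lam: float = LAMBDA_DEFAULT
    delta_max: float | None = None       # Hertz fit depth; None -> min(800 nm, R/10)
    derivative_step: float = DERIVATIVE_STEP
    working_range_cap: float = 800e-9
    seed: int = 0


@dataclass
class AnalysisResult:
    """Everything a batch run produced, per curve and aggregated."""

    n_curves: int
    n_accepted: int
    qc_reports: list[QCReport]
    contact_points: list[float | None]
    indentation_curves: list[ForceIndentationCurve | None]
    hertz_fits: list[HertzFit | None]
    hertz_population: HertzPopulation | None
    spectra: list[ElasticitySpectrum | None]
    mean_spectrum: MeanSpectrum | None
    spectrum_population: HertzPopulation | None
    working_range: tuple[float, float] | None
    bilayer: BilayerFit | None
    errors: dict[int, str]

    @property
    def n_rejected(self) -> int:
        return self.n_curves - self.n_accepted


def analyze_curves(
    curves: list[ForceDistanceCurve],
    options: AnalysisOptions | None = None,
) -> AnalysisResult:
    """Run the full analysis over a batch of raw force–distance curves."""
    opts = options or AnalysisOptions()
    n = len(curves)
    errors: dict[int, str] = {}

    smoothed: list[ForceDistanceCurve] = []
    z0s: list[float | None] = []
    for i, curve in enumerate(curves):
        try:
            sm = smooth_curve(curve, opts.preprocess)
        except EspectraError as exc:
            errors[i] = f"smoothing: {exc}"
            sm = curve
        smoothed.append(sm)
        try:
            z0s.append(find_contact_point(sm, opts.preprocess).z0)
        except EspectraError as exc:
            errors[i] = f"contact point: {exc}"
            z0s.append(None)

    reports = qc_batch(smoothed, z0s, opts.preprocess)

    indented: list[ForceIndentationCurve | None] = []
    for i, (sm, z0, rep) in enumerate(zip(smoothed, z0s, reports)):
        if not rep.accepted or z0 is None:
            indented.append(None)
            continue
        try:
            indented.append(
                to_force_indentation(
                    sm, z0, subtract_deflection=opts.preprocess.subtract_deflection
                )
            )
        except EspectraError as exc:
            errors[i] = f"conversion: {exc}"
            indented.append(None)

    hertz_fits: list[HertzFit | None] = [None] * n
    hertz_pop = None
    if opts.run_hertz:
        for i, fic in enumerate(indented):
            if fic is None:
                continue
            try:
                hertz_fits[i] = fit_hertz(fic, opts.delta_max)
            except EspectraError as exc:
                errors[i] = f"hertz: {exc}"
        E_vals = [f.E for f in hertz_fits if f is not None]
        if len(E_vals) >= 10:
            hertz_pop = population_peak(np.array(E_vals))

    spectra: list[ElasticitySpectrum | None] = [None] * n
    mean_spec = None
    spec_pop = None
    working = None
    bilayer_fit = None
    if opts.run_spectra:
        for i, fic in enumerate(indented):
            if fic is None:
                continue
            try:
                spectra[i] = pointwise_modulus(
                    fic, derivative_step=opts.derivative_step,
                    source_curve_id=fic.metadata.label or str(i),
                )
            except EspectraError as exc:
                errors[i] = f"spectrum: {exc}"
        good = [s for s in spectra if s is not None]
        if good:
            mean_spec = average_spectra(good)
            try:
                spec_pop = spectrum_peak(mean_spec)
            except EspectraError:
                spec_pop = None
            try:
                working = select_working_range(mean_spec, hard_cap=opts.working_range_cap)
            except EspectraError:
                working = None
            if opts.run_bilayer and working is not None:
                R = curves[0].metadata.probe_radius
                try:
                    bilayer_fit = fit_bilayer(
                        mean_spec, R, lam=opts.lam, fit_range=working, seed=opts.seed
                    )
                except EspectraError as exc:
                    errors[-1] = f"bilayer: {exc}"

    n_accepted = sum(1 for fic in indented if fic is not None)
    return AnalysisResult(
        n_curves=n,
        n_accepted=n_accepted,
        qc_reports=reports,
        contact_points=z0s,
        indentation_curves=indented,
        hertz_fits=hertz_fits,
        hertz_population=hertz_pop,
        spectra=spectra,
        mean_spectrum=mean_spec,
        spectrum_population=spec_pop,
        working_range=working,
        bilayer=bilayer_fit,
        errors=errors,
    )
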