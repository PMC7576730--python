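# Methods

## Contact-mechanics background

A rigid sphere of radius `R` indenting an elastic half-space of Young's
modulus `E` and Poisson's ratio `ν` to depth `δ` follows the Hertz relation
`F = (4/3)·E/(1−ν²)·√R·δ^{3/2}`. The pointwise generalization links the
local stiffness of the curve to the modulus through the contact radius:
`dF/dδ = 2a·E/(1−ν²)` with `a = √(Rδ)` for a sphere. Inverting it gives the
depth-resolved apparent modulus

    E(δ) = (1−ν²)/(2√(Rδ)) · dF/dδ,

the *elasticity spectrum*. Substituting the Hertz force shows that the
spectrum of a homogeneous sample is exactly the constant `E`; this identity
(tested to <1% on noiseless synthetic curves across 0.3–50 kPa and probe
radii 3.5–8 µm) is the core internal-consistency check of the
implementation. Note that the δ-dependence of the prefactor is `δ^{−1/2}`:
it is the only form consistent with the contact-radius substitution,
dimensional analysis, and the flat-spectrum identity. Cells are treated as
incompressible (`ν = 0.5` by default, overridable per curve).

## Pipeline

1. **Smoothing.** The force channel is smoothed with a Savitzky–Golay
   filter whose window is specified as a physical length (default 30 nm)
   and converted with the median sample spacing; endpoints are handled by
   the filter's edge-window polynomial fit, so there are no padding
   artifacts. Smoothing assumes approximately uniform z-sampling.

2. **Contact point.** The ratio of variances
   `RoV(i) = Var(F[i+1…i+w]) / Var(F[i−w…i−1])` is ~1 in the pre-contact
   noise, grows sharply as the forward window slides onto the contact rise,
   and collapses once the backward window does too. Local maxima with
   prominence ≥ 10% of max(RoV) are candidate contacts and the last one
   (largest z) wins; a curve whose maximum RoV stays below an absolute
   floor (default 3) contains no variance-regime change and is reported as
   contact-free. The window is min(150 samples, 300 nm): wide enough to
   straddle the noise-regime change, narrow enough not to span the whole
   contact region. Because the force stays below the noise floor for a few
   samples past true contact, the raw RoV peak is systematically late by
   3–6 samples at realistic noise (20 pN). The peak therefore seeds a local
   piecewise least-squares refinement — flat baseline plus a
   `(z−z₀)^{3/2}` rise, each sample in ±min(w, 50) samples tried as the
   break point — which removes the bias; in Monte-Carlo over 500 noisy
   curves ≥95% land within 3 samples (6 nm) of ground truth. The
   refinement is index-based, hence exactly translation-equivariant, and
   can be disabled (`refine_contact=False`) for a literal last-peak
   read-out.

3. **Conversion.** `δ = (z − z₀) − F/k`: piezo travel past contact minus
   cantilever deflection. Deflection subtraction is on by default and
   switchable (`subtract_deflection=False` keeps `δ = z − z₀`) for
   instruments whose export already reports tip position. Pre-contact
   samples are dropped, δ is clipped at zero and back-steps removed;
   forces are never altered, only re-indexed.

4. **Quality control.** A curve is rejected when (a) no contact point was
   found, (b) the pre-contact baseline slope exceeds its threshold
   (default: 3× baseline noise RMS divided by baseline length — "no flat
   region"), or (c) the baseline residual RMS exceeds 5× the batch median
   ("high random variations"). A guard band of twice the smoothing window
   before z₀ keeps smoothing leakage out of the baseline statistics.
   Reports list every violated rule; rejected curves are excluded, not
   repaired.

5. **Spectra.** Each curve is linearly resampled onto a uniform 5 nm depth
   grid and differentiated with a Savitzky–Golay first-derivative filter
   spanning 25 nm (polynomial order 3). The 25 nm derivative step sets the
   depth resolution; E(δ) is reported from one derivative step onward
   (the modulus is numerically undefined at zero depth). Spectra are
   averaged pointwise on the common grid with no extrapolation: beyond the
   depth of shorter curves the per-point count drops and statistics run
   over the remaining curves.

6. **Working range.** The trusted upper depth is min(800 nm, substrate-rise
   onset). The onset is the first depth where the running 100 nm linear
   fit of ⟨E(δ)⟩ turns *significantly* positive (slope > 2× its standard
   error) for a sustained 100 nm span after having been non-positive; the
   significance requirement keeps sampling noise in flat or decaying
   spectra from triggering a false rise. The 800 nm cap and the ~10%-of-R
   Hertz-fit depth default keep the analysis in the small-strain,
   substrate-free regime.

7. **Bilayer fit.** `E(δ) = E_b + (E₀−E_b)·exp(−Λ√(Rδ)/d₀)` is fitted to
   the mean spectrum by nonlinear least squares in log-parameters
   (positivity by construction), unweighted by default (the average
   spectrum is the fitted object; 1/SE² weighting is available).
   Initialization: E₀ from the first 10% of the spectrum, E_b from the
   last 20%, d₀ = R/10; up to five log-normally jittered restarts with a
   fixed seed guard against bad basins. Standard errors come from the fit
   covariance via the delta method. An inverted contrast (E₀ < E_b) is
   allowed and flagged; a vanishing contrast leaves d₀ unidentifiable and
   is flagged degenerate.

8. **Sessions.** Repeated sessions are combined per parameter by a mean
   weighted with session size (cell count); the reported error bar is the
   weighted variance of the repeats about that mean.

## The decay factor Λ

The exponential bilayer profile depends on Λ and d₀ only through Λ/d₀, so
Λ must be fixed a priori to give d₀ an absolute scale; rescaling Λ → cΛ
rescales the fitted thickness by exactly c and leaves both moduli
untouched (verified numerically to <0.5%). The package ships Λ = 1.74 as
the calibrated default. `calibrate_lambda` implements the calibration:
compute the elasticity spectrum of a numerical layered-contact indentation
curve with known ground truth, freeze (E₀, E_b, d₀) at the truth, and fit
Λ as the single free parameter.

The intended external reference for that calibration is a polynomial
surrogate of finite-element simulations of a stiff film on a compliant
half-space. Its coefficient table is not distributed with this package:
requesting the `bilayer_fea_surrogate` model raises a clear error, and the
self-consistent exponential generator (below) serves as the numerical
reference instead. On self-consistent curves the calibration is a round
trip — it returns the generating Λ essentially exactly, and the
physiological-range sweep (modulus contrast 1.2–10×, thickness
100–500 nm) spreads by well under 1%. This measures the numerical
fidelity of the spectrum-plus-fit chain, not the adequacy of the
exponential form as an approximation to layered contact; users with access
to an independent layered-contact solver can pass its curve to
`calibrate_lambda` directly.

## Synthetic data

The generator is the package's ground-truth instrument. `homogeneous`
curves follow the Hertz force; `bilayer_exponential` curves integrate the
pointwise relation over the exponential profile,
`F(δ) = ∫₀^δ 2√(Rt)·E(t)/(1−ν²) dt`, which evaluates in closed form
through the lower incomplete gamma function (cross-checked against
adaptive quadrature to 1e-8). Self-consistency makes the spectrum pipeline
exactly invertible on these curves, isolating numerical error from model
error. Forces are mapped to the displacement axis with cantilever
compliance, `z = z₀ + δ + F/k`, by inverting z(δ) on a dense grid (4×
oversampled); a flat (optionally tilted) baseline precedes contact and
Gaussian force noise is added throughout. Contact offsets are randomized
per curve by default so detection is genuinely exercised. All randomness
flows from one seeded generator whose stream encodes the model name:
identical seeds give bit-identical batches, different models different
ones. A ground-truth manifest (per-curve z₀ and parameters) accompanies
every batch.

Default conditions: sampling step 2 nm, displacement range 3 µm, force
noise 20 pN RMS, gel scenario E = 5.2 kPa with R = 8 µm / k = 0.049 N/m,
cell-bilayer scenario 9.8/8.4 kPa, d₀ = 300 nm with R = 3.5 µm /
k = 0.3 N/m. What the generator does *not* emulate: viscoelastic rate
dependence, adhesion, thermal drift, multiple contacts, or instrument
discretization — passing tests demonstrate correctness of the analysis
chain under ideal elastic assumptions, not robustness to those artifacts.

## Validation studies and problem sizes

The test suite runs, among others: flat-spectrum identity over a 3×2
modulus/radius grid; a 97-curve noisy gel batch through the full pipeline
(Hertz peak and spectrum peak within 10% of truth); contact-point recovery
on 500 noisy curves; noiseless bilayer recovery of 9.8 kPa / 300 nm /
8.4 kPa to <0.5%; Λ calibration to <5% with a 12-cell parameter sweep; and
20 replicates of 100 spectra with 5% multiplicative noise for cell-like
parameters (cortex 4 kPa ≈ 9× bulk, 450 Pa bulk, 300 nm), each parameter
recovered within 10%. These sizes keep the whole suite under a minute on
one core while giving the Monte-Carlo assertions comfortable margins.

## Known limitations

- **Low-contrast identifiability.** When the layer/bulk contrast is small
  (e.g. 9.8 vs 8.4 kPa) and the probe is bead-sized, most of the
  exponential decay occurs shallower than the first reported spectrum
  point (25 nm), and E₀/d₀ become noise-sensitive extrapolations; the
  bulk modulus remains robust. Sharp probes move the decay into the
  resolved window. The fit covariance (reported standard errors and the
  degeneracy flag) is the per-run diagnostic.
- **Shallow-depth bias.** The 25 nm derivative window averages across the
  steepest part of a fast-decaying profile, so cortex stiffness from
  bead-scale probes reads as a conservative lower bound.
- **Absolute thickness.** d₀ inherits the Λ calibration; relative changes
  between conditions do not.
- The elastic, adhesion-free, time-independent contact assumptions of the
  underlying models apply throughout; approach curves only.
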