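# espectra

Elasticity-spectra analysis of nanoindentation force curves: depth-resolved
apparent Young's modulus and exponential-bilayer (actin cortex) fitting for
single-cell and soft-gel force spectroscopy.

## What problem this solves

Cantilever-based nanoindentation (AFM, FluidFM, ferrule-top indenters)
measures a force–distance curve `F(z)` as a spherical probe of radius `R`
presses into a soft sample. The standard analysis fits the whole curve with
the Hertz model,

    F = (4/3) · E/(1−ν²) · √R · δ^{3/2},

collapsing the sample into a single Young's modulus `E`. Living cells are
not homogeneous: a thin, stiffer actomyosin shell — the actin cortex — sits
on a softer interior, and a single-modulus fit averages the two away.

This package implements the *elasticity spectrum* (ES) view. Instead of one
integral fit, the local slope of the force–indentation curve is converted,
point by point, into an apparent modulus using the pointwise (Oliver–Pharr)
relation with contact radius `a = √(Rδ)`:

    E(δ) = (1−ν²) / (2√(Rδ)) · dF/dδ.

For a homogeneous sample `E(δ)` is flat and equals the Hertzian modulus.
For a cortex-on-bulk cell it decays with depth, and fitting the exponential
bilayer model

    E(δ) = E_b + (E₀ − E_b) · exp(−Λ·√(Rδ)/d₀)

yields the cortex stiffness `E₀`, cortex thickness `d₀` and bulk elasticity
`E_b`. `Λ` is a dimensionless decay factor calibrated once against a
numerical layered-contact indentation curve (default 1.74); it enters the
results purely as a thickness scale factor, so relative changes in `d₀`
(e.g. under cytoskeletal drugs) do not depend on it.

The pipeline covers the full path from raw curves to parameters: Savitzky–
Golay smoothing, contact-point detection by the ratio-of-variances method,
deflection-corrected conversion `F(z) → F(δ)`, baseline quality control,
per-curve Hertz fits and spectra, batch averaging, working-range selection
(stopping before the rigid-substrate rise), bilayer fitting, and
size-weighted aggregation of repeated sessions. A synthetic-data module
generates Hertzian and bilayer curves with exact ground truth so every
stage is testable offline.

## Worked example

`examples/02_bilayer_recovery.py` builds the noiseless indentation curve of
a 9.8 kPa / 300 nm layer on an 8.4 kPa bulk (3.5 µm sphere), computes its
elasticity spectrum, and fits the bilayer model:

```
truth : E0 = 9.80 kPa, d0 = 300 nm, Eb = 8.40 kPa
fit   : E0 = 9.80 kPa, d0 = 300 nm, Eb = 8.40 kPa  (Lambda fixed at 1.74)
calibrated decay factor Lambda = 1.741
```

The three material parameters come back to well under 1%, and refitting
with `(E₀, E_b, d₀)` frozen recovers the decay factor — the calibration
round trip that anchors the thickness scale.

`examples/01_hertz_vs_spectrum.py` runs 97 noisy synthetic gel curves
(5.2 kPa, 20 pN force noise) through the full pipeline:

```
curves accepted        : 97/97
Hertz population peak  : 5.16 +/- 0.00 kPa
mean-spectrum peak     : 5.19 +/- 0.00 kPa
generating modulus     : 5.20 kPa
```

Both estimates sit within 1% of the generating modulus: on a homogeneous
material the integral (Hertz) and differential (spectrum) analyses agree.

`examples/03_cell_sessions.py` simulates two cell measurement sessions and
aggregates the per-session bilayer fits with cell-count weights.

## Command line

```bash
espectra simulate --model bilayer_exponential --n 30 --seed 7 --out curves/
espectra analyze --input curves/ --out results/
espectra calibrate-lambda
espectra qc-report --input curves/ --out qc/
```

`analyze` writes `results.json` (parameter blocks), `results_spectrum.csv`
(mean spectrum), `per_curve.csv`, `qc.csv` and `run.log`; reruns with the
same inputs and seed are byte-identical (timestamps live only in the log).

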