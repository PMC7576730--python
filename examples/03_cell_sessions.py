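"""Cell-like sessions: batch pipeline plus size-weighted aggregation.

Simulates two measurement sessions of cortex-on-bulk cells (cortex 4 kPa /
300 nm over a 450 Pa cytoplasm, 3.5 um bead), runs the full pipeline on
each — smoothing, ratio-of-variances contact detection, QC, spectra,
bilayer fit — and combines the per-session fits with weights proportional
to the number of cells, as one would combine biological repeats.
"""

import espectra as es

fits, sizes = [], []
for session, (n_cells, seed) in enumerate([(25, 301), (35, 302)], start=1):
    cfg = es.SimulationConfig(
        model="bilayer_exponential", E0=4.0e3, Eb=450.0, d0=300e-9,
        R=3.5e-6, k=0.3, noise_sigma_F=20e-12, n_curves=n_cells, seed=seed,
    )
    batch = es.generate_bilayer(cfg)
    result = es.analyze_curves(batch.curves)
    fit = result.bilayer
    fits.append(fit)
    sizes.append(n_cells)
    print(f"session {session}: {result.n_accepted}/{result.n_curves} curves, "
          f"E0 = {fit.E0/1e3:.2f} kPa, Eb = {fit.Eb:.0f} Pa, "
          f"d0 = {fit.d0/1e-9:.0f} nm")

agg = es.aggregate_sessions(fits, sizes)
m, v = agg.weighted_mean, agg.weighted_variance
print()
print(f"weighted over {agg.n_sessions} sessions ({sum(sizes)} cells):")
print(f"  cortex stiffness E0 = {m['E0']/1e3:.2f} kPa (var {v['E0']/1e6:.3f} kPa^2)")
print(f"  bulk elasticity  Eb = {m['Eb']:.0f} Pa   (var {v['Eb']:.0f} Pa^2)")
print(f"  cortex thickness d0 = {m['d0']/1e-9:.0f} nm  (var {v['d0']/1e-18:.0f} nm^2)")
print()
print("Generating truth: 4 kPa / 450 Pa / 300 nm.  The bulk elasticity is")
print("recovered tightly; cortex stiffness and thickness scatter more from")
print("session to session because with a micrometre-scale bead the cortex")
print("signal is confined to the shallowest (noisiest) depths — the reason")
print("repeats are aggregated, and cortex stiffness reads as a conservative")
print("lower bound at this probe size.")
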