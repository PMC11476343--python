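# memquant

Quantification toolkit for **hybrid photosynthetic membranes** — supported
lipid bilayers assembled from natural thylakoid material and synthetic DOPC
lipids inside polymerized-lipid template corrals — and for the natural
thylakoid membranes they are compared against.

It is aimed at biophysicists characterizing such membranes with
fluorescence-lifetime imaging microscopy (FLIM) and atomic force microscopy
(AFM), and implements the complete measurement chain as a tested library
plus a `memquant` command-line tool:

- **`memquant.flim`** — TCSPC decay analysis. Photon histograms are fit with
  an IRF-convolved multi-exponential model by Poisson maximum likelihood,
  reporting the amplitude-weighted mean lifetime
  ⟨τ⟩ = Σᵢaᵢτᵢ / Σᵢaᵢ (the discriminator between densely packed, quenched
  chlorophyll-protein membranes, ⟨τ⟩ ≈ 0.4 ns, and dilute protein in a fluid
  bilayer, ⟨τ⟩ ≈ 4 ns). Per-pixel "FastFLIM" first-moment estimates,
  25 ps-binned lifetime frequency distributions, and one/two-component
  Gaussian deconvolution of those distributions into coexisting
  photophysical populations.
- **`memquant.kinetics`** — membrane-assembly kinetics from time-lapse FLIM:
  per-frame two-Gaussian amplitude tracking and Langmuir adsorption fits
  A(t) = A_max(1 − e^(−Rt)), with the saturation time defined as
  t_sat = −ln(0.02)/R (time to 98% of A_max), plus linear fits for the
  adsorbing-thylakoid channel and rate-ratio comparison.
- **`memquant.frap`** — fluorescence recovery after photobleaching:
  reference-corral correction that exactly cancels acquisition
  photobleaching, single-exponential recovery fits, mobile fractions
  (I_∞ − I₀₊)/(I_pre − I₀₊) and relative diffusion rates.
- **`memquant.afm`** — height-map quantification: polynomial leveling, robust
  plateau step heights, pore segmentation with per-pore depth, and particle
  detection with the protein-candidate gates (5–10 nm height, 10–20 nm
  diameter at half height) and per-area densities.
- **`memquant.density`** — the three-stage "LHCII equivalents" chain that
  converts corral photon counts into protein counts, areal densities and
  membrane area fractions via a proteoliposome calibration standard, with a
  lifetime-ratio quenching correction and first-order uncertainty
  propagation.
- **`memquant.synthetic`** — generators for every input above with known
  ground truth (IRF-convolved Poisson photon statistics, patterned
  two-population FLIM images, Langmuir/linear assembly series, FRAP traces,
  AFM topographs with mesas, pores, particles, roughness and tilt), all
  deterministic under explicit seeds.
- **`memquant.pipeline`** — end-to-end simulate → analyze → report runs and
  the photochemical-assay (DMBQ / hydroxylamine) condition analysis.

## Worked example

```python
import numpy as np
from memquant import synthetic, flim, frap, kinetics

# fit a simulated hybrid-membrane decay (10^6 photons, 90 ps IRF, 25 ps bins)
hist = synthetic.simulate_decay(synthetic.hybrid_model(), 10**6, rng_seed=42)
fit = flim.fit_decay(hist, n_components="auto")
print(f"<tau> = {fit.mean_lifetime_ns:.2f} ns "
      f"({fit.n_components} components, chi2_r = {fit.chi_squared_reduced:.2f})")

# protein-channel FRAP with global photobleaching and 2% noise
series, _ = synthetic.simulate_frap_series(
    mobile_fraction=0.77, recovery_halftime_s=20.0,
    reference_bleach_rate=0.0025, n_frames=50, frame_interval_s=4.0,
    noise_sd=0.02, rng_seed=42)
result = frap.fit_recovery(series)
print(f"mobile fraction = {result.mobile_fraction:.2f}, "
      f"halftime = {result.recovery_halftime_s:.1f} s")

# Langmuir fit of a lipid-channel deposition curve
t = np.arange(0.0, 1000.0 + 1e-9, 20.0)
track = kinetics.AmplitudeTrack("lipid_dye", t, 1 - np.exp(-0.039 * t))
lf = kinetics.fit_langmuir(track)
print(f"R = {lf.rate_per_s:.3f} s^-1, t_sat = {lf.t_sat_s:.0f} s")
```

prints

```
<tau> = 4.07 ns (2 components, chi2_r = 1.02)
mobile fraction = 0.78, halftime = 20.5 s
R = 0.039 s^-1, t_sat = 100 s
```

The fitted ⟨τ⟩ recovers the generative amplitude-weighted lifetime
(4.06 ns) within its statistical error; the FRAP estimator recovers the
77% mobile fraction after the reference correction removes the 1%-per-frame
acquisition bleaching; the Langmuir fit returns the deposition rate exactly
on noiseless data, and the 98% saturation definition places t_sat at 100 s
for R = 0.039 s⁻¹.

The same operations are available from the shell, e.g.:

```sh
memquant simulate decay --tau 4.7 --tau 1.5 --amp 0.8 --amp 0.2 \
    --photons 1000000 --seed 1 --out decay.csv
memquant flim fit --decay decay.csv
memquant run --seed 1 --out-dir results_demo
```

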