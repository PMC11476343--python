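# Methods

This note records the models implemented in `memquant`, their assumptions,
the default parameters and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical choices that matter.

## Decay model and lifetime estimation

A TCSPC histogram is modeled as a sum of exponential decays convolved with
a Gaussian instrument response function (IRF) plus a constant uncorrelated
background:

    y(t) = Σ_k c_k · EMG(t; τ_k, σ, t₀) · Δt + b,

where `EMG` is the exponentially modified Gaussian (the analytic
convolution of a one-sided exponential with a Gaussian of width σ), `c_k`
the photon count of component k, `t₀` the pulse position and Δt the bin
width. One wrap of the previous excitation period is added so long-lived
tails that fold around the repetition window are modeled. The EMG is
evaluated in a numerically stable piecewise form (`erfcx` on one branch,
the identity `erfcx(b) = 2e^{b²} − erfcx(−b)` on the other) so it neither
overflows at late times nor underflows near the pulse.

**Fitting is Poisson maximum likelihood**, implemented as least squares on
deviance residuals. Neyman weighting (1/√observed) was measured during
development to bias the recovered amplitude-weighted lifetime low by ≈2%
at 10⁵ photons for the slow-decay model; the deviance formulation removes
that bias (≤0.4% at the same photon budget, per the test suite's
50-replicate recovery check). The fit domain starts where the rising edge
first exceeds 1% of the peak; pre-pulse bins inform only the background
estimate (mean of bins more than 5σ before the pulse, falling back to a
fitted constant). The background parameter is initialized off its zero
bound because the bound transform has zero gradient exactly at the
boundary and can stall the optimizer.

Component count: `"auto"` increases n from 1 to 3 until the reduced
chi-squared passes the < 1.1 acceptance gate; components are reported in
ascending τ and the headline value is the amplitude-weighted mean
⟨τ⟩ = Σaτ/Σa with a_k = c_k/τ_k (the pre-exponential factor). Fits with
fewer than 1000 photons are refused for multi-component models.

**FastFLIM** (per-pixel) is the background-subtracted first moment of the
arrival-time histogram minus the IRF centroid, clamped at ≥ 0, undefined
(NaN) below 20 photons. Note the physics: the first moment estimates the
*intensity-weighted* lifetime Σcτ²/Σcτ, which for a multi-exponential pixel
exceeds the amplitude-weighted ⟨τ⟩ — e.g. the hybrid-membrane decay model
with ⟨τ⟩ = 4.06 ns has per-pixel FastFLIM values near 4.5 ns. This is
expected and is why per-pixel lifetime distributions center above the
ensemble-fit ⟨τ⟩.

Lifetime distributions use 25 ps bins by default, exclude starved pixels
(< 20 photons, counted in a QC field) and are optionally peak-normalized.
Gaussian deconvolution (1 or 2 components) is plain least squares on the
binned distribution, seeded greedily (tallest peak first, second component
at the maximum of the residual); with center hints the centers are
constrained to ±0.5 ns, which stabilizes per-frame fits in time-lapse
series. A two-component solution whose centers are closer than the larger
FWHM with both amplitudes above 10% of the peak is flagged degenerate — a
unimodal distribution therefore either raises or returns one negligible
component, never two spurious populations.

## Assembly kinetics

The corral-filling species follows Langmuir adsorption — uptake rate
proportional to remaining free area — giving A(t) = A_max(1 − e^(−Rt));
the loosely adsorbing thylakoid signal grows linearly over the observation
window. Tracking deconvolutes each frame into two Gaussians with centers
softly constrained around steady-state estimates taken from the final
(best-populated) frame; frames with degenerate fits are flagged and
linearly interpolated, and more than 30% degenerate frames aborts the
analysis. The Langmuir fit initializes R from the half-maximum time
(ln 2/t_half) and A_max from the final frame, and warns when a straight
line fits as well (variance-ratio F-test) or when the track spans less
than one e-folding.

**Saturation time** is defined as the time to reach 98% of A_max,
t_sat = −ln(0.02)/R. The definition is a package choice (no standard one
exists); it maps R = 0.039 s⁻¹ to ≈100 s and R = 0.007 s⁻¹ to ≈560 s,
consistent with the printed rate/saturation pairs for the lipid and
protein channels. Uncertainty on R is available either first-order (from
the fit covariance) or by residual bootstrap (`bootstrap_rate_ci`).

## FRAP

The corrected trace is bleach(t)/reference(t), normalized so the
pre-bleach mean is 1 — any multiplicative decay shared by both ROIs
(acquisition photobleaching) cancels exactly, which the tests check to
machine precision. Recovery is a single exponential
I(t) = I₀₊ + (I_∞ − I₀₊)(1 − e^(−kt)) with I₀₊ the first post-bleach frame
and I_∞ the fit asymptote; mobile fraction = (I_∞ − I₀₊)/(1 − I₀₊),
halftime = ln 2/k. The single-exponential model is a deliberate
simplification: no bleach-spot geometry is assumed, so absolute diffusion
coefficients (µm²/s) are out of scope and mobilities are compared through
the rate-constant ratio k_a/k_b. A camera offset must be declared
(`background` field) — the ratio correction is only exact after additive
offsets are removed, and the tests cover that failure mode.

## AFM topography

Leveling subtracts a polynomial background surface (order 0–2) fit on
background pixels only (an exclusion mask keeps mesas/pores/particles out
of the fit) and zeroes the background median; it is idempotent and
commutes with constant offsets. Step heights are differences of plateau
medians with pooled-variance uncertainty; the profile-line mode splits the
profile by iterated two-means and refuses plateaus separated by less than
3 pooled standard deviations.

Pores are connected components deeper than half the minimum depth below
the plateau median, kept if their equivalent diameter exceeds 30 nm and
their floor depth exceeds 2 nm (defaults); per-pore depth is plateau
median minus the median of the rim-eroded pore core. Particles are local
maxima on a lightly smoothed map (σ = 1 px), separated by watershed;
**height is read from the raw leveled map at the peak** because smoothing
biases a curved cap's apex low by ≈2hσ²/a²; the diameter is the
equivalent diameter of the area above half maximum, chosen because
half-height widths are robust to tip-broadening tails. Protein-candidate
gates are 5–10 nm height and 10–20 nm diameter; sub-classes P1–P3 are the
tertiles of the height gate (no numeric boundaries exist in the
literature for the three observed profile types, so tertiles are the
documented default). Densities count gated particles per analyzed area,
which excludes template mesas and a 2-pixel border. Attribution against a
protein-free control is plain arithmetic: fraction = (ρ_test −
ρ_control)/ρ_test, protein density = ρ_test − ρ_control. Note 77.0 and
9.7 µm⁻² give 87% and 67.3 µm⁻² exactly; the commonly quoted ≈80% / ≈60
µm⁻² are rounded versions of the same arithmetic, and this package
reports the exact values.

## Density chain

Stage 1/2: counts per LHCII trimer = counts per proteoliposome ÷ LHCII per
proteoliposome. Stage 3: equivalents = (corral counts ÷ counts per LHCII)
× (τ_standard/τ_hybrid). The lifetime ratio is a quantum-yield proxy for
the different quenching state of the calibration standard — a quenched
standard under-emits per protein, so its counts-per-protein must be scaled
up before being applied to unquenched membranes. The correction form is a
package choice (the exact published calibration is not distributed) and
is fully configurable. Acquisition metadata, when supplied on both sides,
must match exactly or the chain refuses to run — intensity calibration is
meaningless across different excitation/collection settings.

Defaults: corral area 400 µm² (20 × 20 µm); 54 chlorophylls per LHCII
equivalent (inferred from the published 3 080 000 Chl / 57 100
equivalents); footprint 50.3 nm² per trimer (back-computed from the
published 143 µm⁻² ↔ 0.72% pair). The shipped calibration config values
are synthetic placeholders, back-calibrated so the default chain
reproduces the published best-estimate outputs end to end; measured
values can be dropped in verbatim. Uncertainties propagate first-order
(root-sum-square of relative uncertainties through the product/quotient
chain) and are validated against a 10⁵-draw Monte Carlo oracle in the
tests. AFM reconciliation divides the static (AFM-visible) density by
(1 − mobile fraction), since mobile proteins are invisible to the slow
raster scan.

## Synthetic data: what it emulates, and what it does not

Generators draw photons from the exponential mixture (photon share of
component k ∝ a_kτ_k), add Gaussian IRF jitter, wrap into the repetition
window and histogram; background is uniform Poisson. Defaults are the
study conditions: Gaussian IRF of 90 ps FWHM (the excitation pulse width,
with detector jitter folded into the same Gaussian — the detector's own
response is not separately published), 25 ps bins, 50 ns repetition
window. The reference decay models are two-component mixtures whose
amplitude-weighted means equal the measured sample values — thylakoid
(0.7 @ 0.25 ns, 0.3 @ 0.75 ns → 0.40 ns) and hybrid (0.2 @ 1.5 ns,
0.8 @ 4.7 ns → 4.06 ns); the per-pixel lifetime populations are Gaussians
at 0.57 ns (FWHM 0.15 ns) and 4.58 ns (FWHM 2.31 ns). Per-pixel photon
budgets default to a few hundred (Poisson), chosen so per-pixel FastFLIM
scatter is comparable to the widths the distributions are meant to show;
the real instrument's per-pixel budget is not published.

Topographs are: plane + linear tilt + template mesa + membrane plateau +
flat-bottomed pores with 1-pixel linear rims + paraboloid-cap particles
(base diameter √2 × the half-height diameter) + white Gaussian roughness
(default 0.15 nm RMS, typical supported-bilayer imaging). Feature
placement is rejection-sampled without overlap and errors out when the
requested packing cannot be placed. FRAP traces multiply an exponential
recovery by a global bleaching decay shared with the reference ROI, with
optional multiplicative Gaussian noise. Assembly series are noiseless
two-Gaussian distributions scaled by the Langmuir/linear amplitude laws,
with optional Poisson noise at a stated counts scale.

Not emulated: singlet–singlet annihilation, detector afterpulsing and
pile-up, correlated (1/f) AFM noise and scan-line artifacts, AFM
tip-convolution beyond the cap geometry itself, spatial heterogeneity of
protein density inside a corral, and vendor file formats. Passing
recovery tests on this synthetic data therefore demonstrates estimator
correctness at realistic noise levels — not robustness to every
instrument artifact found in real recordings.

## Problem sizes and determinism

Default problem sizes are desk-scale: 10⁶ photons for ensemble decay
fits, 10⁴ pixels for distribution deconvolution, 50-frame kinetics and
FRAP series, and 2 × 2 µm topographs at 2 nm pixels (1000² grid) for pore
scenes, 1 × 1 µm at 2 nm for particle scenes. Every generator takes an
explicit seed and is byte-deterministic; the pipeline derives one
independent child seed stream per stage from the run seed, so adding or
removing stages does not perturb the others. All lifetimes are reported
in ns (2 decimals at the reporting surface), internal time arithmetic is
in ps; heights and depths in nm; rates in s⁻¹.

## Known limitations

- Individual exponential components of a multi-exponential fit are only
  weakly identifiable at 10⁵ photons; the amplitude-weighted mean is the
  robust quantity and the only one the package headlines.
- The FastFLIM first moment is bias-free only for negligible background
  after subtraction and a fully contained decay; lifetimes approaching
  the repetition window are truncated.
- The F-test used to warn of non-saturating tracks compares equal
  parameter counts and is a heuristic, not a calibrated model-selection
  criterion.
- Pore depth assumes a flat floor wider than the rim-erosion margin;
  narrow V-shaped defects would be reported shallow.
- The density chain's absolute scale is entirely set by the calibration
  standard; with the shipped synthetic placeholders only ratios and the
  documented published-output consistency are meaningful.
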