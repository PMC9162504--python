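# Methods

## Model

`slabmc` solves time-dependent radiative transport in a plane-parallel slab
by Monte Carlo. A photon packet of unit statistical weight is launched at
the entrance plane z = 0, refracts into the slab through a stochastic
unpolarized-Fresnel interaction, and then alternates exponential free
flights (mean `ls = 1/μs`) with Henyey–Greenstein deflections
(`⟨cosθ⟩ = g`). Weight decays continuously as `exp(−μa·path)`; the clock
advances by `path·n/c` with the energy velocity `v = c/n_slab`,
`c = 299.792458 μm/ps`. At a face the packet is specularly reflected with
the local Fresnel probability (certainly, beyond the critical angle) or
Snell-refracted out and recorded with its exit position, time, weight and
scattering order. Assumptions: scalar (unpolarized) transport, a single
homogeneous layer, smooth planar interfaces, unbounded transverse extent,
independent scattering, no interference or speckle.

Low-weight packets (below 10⁻⁴) undergo Russian roulette with survival
probability 0.1. The roulette boost is booked *against* the absorbed tally,
so for every photon `transmitted + reflected + absorbed + truncated = 1`
holds to machine precision; `energy_balance` enforces 10⁻¹⁰ and raising on
violation turns any future bookkeeping bug into a hard failure rather than
a silent bias. Packets exceeding the time cap (default 50 ps) are tallied
as `truncated` and always reported.

A photon's full state after an internal reflection is memoryless, so a
fresh step is sampled rather than carrying the residual step — statistically
identical for the exponential law and simpler in the kernel.

## Sources

**Temporal.** sech² emission times use the logistic quantile
`Q(ξ) = s·ln(ξ/(1−ξ))`, `s = Δτp/(4·ln(1+√2))`; Gaussian pulses use the
normal quantile scaled so the intensity FWHM is Δτp; `delta` emits at t = 0.
The sech²↔autocorrelation FWHM ratio is the family constant ≈1.5427,
obtained by root-finding on the closed-form autoconvolution
`∝ (x·cosh x − sinh x)/sinh³x` (certified in the tests against a brute-force
numerical autoconvolution). The sech² spectrum is the squared Fourier
transform of the *field envelope* `sech(γp t)`, i.e. sech²-shaped with
argument scale `π/(2γp)`; this normalization reproduces the sech²
time–bandwidth product Δν·Δτp ≈ 0.315.

**Spatial.** The Gaussian ray bundle draws `(xs, ys)` in a launch plane a
distance d before the focus (waist ws) and `(xf, yf)` in the focal plane
(waist w0), each coordinate `(w/2)·Φ⁻¹(ξ)` — identical to the inverse-error-
function form, with 1/e²-radius semantics `σ = w/2`. Defaults `d = 100·zR`
and `ws = w0·√(1+(d/zR)²)` place the launch plane deep in the far field so
the bundle envelope follows `w(z) = w0·√(1+(z/zR)²)` at all z (a tested
invariant, 3%). The photon clock is the sampled pulse offset at the focal
plane — an aplanatic focusing system is isochronous at focus, so no
marginal-ray delay is added — plus the external free flight if the focus is
offset from the entrance (default: focus exactly at the entrance). Rays can
also be pushed through thin lenses, free space and flat interfaces with
standard ABCD ray-transfer matrices; a quasi-collimated bundle of width W
focuses to the diffraction-limited radius λf/(πW), which is how the ABCD
path is tested.

**Entry.** The front-interface Fresnel reflection is applied per ray with
its actual (generally non-normal) incidence, and the refracted direction is
used inside the slab.

## Step sampling

The production samplers have unbounded support:

* `inverse_cdf_64` — uniform doubles (53-bit resolution, the resolution a
  64-bit integer draw retains after float conversion) mapped through
  `−ls·log1p(−ξ)`; when ξ falls within 2⁻³² of 1 the sampler banks an offset
  of `32·ln 2·ls ≈ 22.18·ls` and redraws, which by memorylessness yields an
  exactly exponential, unbounded variate;
* `ziggurat` — NumPy's rejection-based exponential generator.

`truncation_bound(bits) = bits·ln 2` quantifies the naive-sampler artifact
(22.18·ls at 32 bits), a deliberately truncated 32-bit reference sampler
demonstrates it, and `tail_audit` measures empirical tail probabilities
with Clopper–Pearson intervals. The numba kernel inlines the same
memorylessness recursion.

## Detectors and statistics

Default grids: 25-fs time bins over [0, 10] ps; 5-μm annuli to 1.5 mm;
image frames at 13.5 μm/px. The mean square width is evaluated from exact
per-photon moment accumulators (Σw, Σw·ρ² per time bin), not from the
binned radial histogram, eliminating radial quadrature bias; standard
errors come from the squared-weight accumulators by the delta method. Empty
bins are NaN, never zero. The radial histogram and frames exist for
profile-style comparisons and are annulus-area- and peak-normalized only at
presentation time.

## Fitting and retrieval

* **Decay time**: weighted least squares of ln(weight) vs t with
  Poisson-motivated weights (∝ bin weight). The default window is
  **[3, 9] ps** for the thin-membrane geometry: the log-slope is still
  curving before ~3 ps because light trapped beyond the critical angle
  releases over the first few picoseconds, and a window that starts too
  early overestimates τ by ~5%. The same window-stability analysis is
  applied to the thick reference slab, where the fitted rate must match the
  known diffusion eigenvalue `τ1 = (L+2ze)²/(π²D)` — it does once the
  window starts well after the peak ([30, 60] ps there).
* **MSW growth rate**: weighted linear fit of ⟨ρ²⟩(t) over **[1.0, 3.5] ps**
  (the frame-delay range of the imaging experiment). The thin-slab growth
  is quasi-ballistic (super-diffusive), so the slope is mildly
  window-dependent: it relaxes from ≈1.29×10⁴ μm²/ps on [1.0, 3.5] ps to
  ≈1.20×10⁴ μm²/ps on late windows for the 164-μm membrane, versus the
  diffusive rate 4D ≈ 1.08×10⁴ μm²/ps.
* **Two-step retrieval**: ⟨ρ²⟩ is a ratio of weighted moments, so a global
  reweighting `exp(−μa·v·t)` cancels exactly (a tested invariant); the MSW
  slope therefore pins ls′ independently of absorption. Step 1 bisects
  ls′ ∈ [10, 100] μm (tolerance 0.25 μm) so the μa = 0 forward MC matches
  the measured slope, using common random numbers across evaluations and
  asserting monotonicity of the objective; step 2 sets
  `μa = (1/τ_meas − 1/τ_MC)/v`. μa is a small difference of two similar
  rates, so its relative uncertainty is intrinsically much larger than
  ls′'s. A negative estimate is flagged, never clipped.

### Magnitude convention for the measured MSW growth rate

The published growth-rate figure for this membrane carries an exponent of
10⁵ μm²/ps. That magnitude is not attainable in slab transport with these
parameters: the kinematic bound ⟨ρ²⟩(t) ≤ (vt)² − L² caps the achievable
slope well below it except exactly at the ballistic horizon, the diffusive
rate is 1.08×10⁴ μm²/ps, and this simulator — validated to 1.3% against the
diffusion value of d⟨ρ²⟩/dt in the thick-slab limit — computes
1.20–1.29×10⁴ μm²/ps at ls′ = 41.2 μm with either the Henyey–Greenstein or
the exact Mie phase function, for every window between 0.85 and 10 ps and
every ls′ ∈ [10, 300] μm. Since the companion quantities (decay time
≈4 ps, retrieved ls′ = 41.2 μm, absorption length ~22 mm) are all
quantitatively consistent with a growth rate of 1.19×10⁴ μm²/ps, the
package treats the printed exponent as a typo: retrieval examples and the
reproduction script feed the measured mantissa at 10⁴ μm²/ps. The
simulated growth rate itself is always reported as computed.

## Synthetic-data scope

The canned configurations (`generate_fixtures`) define the study
conditions: `membrane` (L = 164 μm, n = 1.526, ls′ = 41.2 μm, g = 0.165,
μa = 4.5×10⁻⁵ μm⁻¹, 94-fs sech², ray bundle w0 = 5 μm focused at the
entrance), `clear_slab` (scattering-free, n = 1.509 — ballistic transit
0.825 ps and internally reflected replica at +1.651 ps), `thick_slab`
(L = 20·ls, index-matched, isotropic — the diffusion oracle), and
`gpb_vs_grb` (source-model comparison, μa = 0). The simulator emulates an
idealized experiment: no detector numerical aperture or field-of-view
limits, no camera noise or background, no gate-pulse width (frames are
ideal time slices; an instrument response can be applied afterwards with
`convolve_irf`), monodisperse spherical particles, and no polarization.
Passing tests therefore certify the transport model and estimators, not
those instrument effects; in real frames a noise floor inflates ⟨ρ²⟩ at
late delays, which is why the experimental uncertainty on μa is large.

## Numerical choices

Monte Carlo runs are deterministic given (config, N, seed): fixed-size
sequential batches, per-batch source (PCG64) and kernel (Mersenne-Twister)
substreams derived via `SeedSequence`. Roulette threshold 10⁻⁴/survival 0.1
(absorption is weak here, μa·ls ~ 10⁻³, so continuous attenuation is the
low-variance choice). Mie series truncation follows the Wiscombe criterion;
the asymmetry parameter uses the host-index size parameter and assumes
non-absorbing spheres. Direction rotations renormalize to unit length each
event; near-axial directions (|μz| > 0.99999) use the degenerate rotation.
Problem sizes: the headline slab runs use 5×10⁶ photons (decay time to
~0.5%, MSW slope to ~0.4% statistical); retrieval evaluations use 10⁶
photons per bisection step, which propagates to roughly ±1 μm on ls′.

## Known limitations

Single layer only (no glass-backed stacks); unpolarized scalar transport;
Henyey–Greenstein phase function (a tabulated-Mie experiment changed the
thin-slab observables by <3%, consistent with similarity scaling, but
strongly structured phase functions may deviate more); no dependent
scattering or polydispersity corrections in the Mie estimates; the
retrieval assumes the slab geometry and g are known and only (ls′, μa) are
free.
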