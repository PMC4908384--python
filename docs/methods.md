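# Methods

## Physical model

The package models the optoacoustic (photoacoustic) generation of pressure
waves by pulsed laser light delivered through an optical fiber into a
water-like absorbing fluid, as occurs in intra-cochlear optical
stimulation. The model is linear acoustics in an inviscid, homogeneous,
unbounded medium:

```
∇²p − (1/c²) ∂²p/∂t² = −(β/C_p) ∂H/∂t ,      H(x,t) = A_e(x) · P(t)
```

whose retarded-potential solution is evaluated at the field point,

```
p(x,t) = Γ/(4πc²) ∫ dV' A_e(x') P'(t − R/c) / R ,    R = |x − x'| .
```

Assumptions and their observable consequences:

- **Separable heating.** The spatial deposition `A_e` (Beer–Lambert decay
  of a top-hat beam) is fixed during the pulse; thermal diffusion during
  the pulse is neglected. This is valid in the thermally confined regime,
  i.e. for pulses shorter than `τ_th = δ²/4κ` (4.9 ms for a 105 µm fiber
  in water, δ = 52.5 µm, κ = 1.4·10⁻⁷ m²/s).
- **Derivative drive.** Pressure is proportional to `P'(t)`: flat-top
  pulses yield one positive (onset) and one negative (offset) transient
  separated by exactly the pulse duration, and the constant plateau is
  silent. Both facts are asserted by tests (interval to within one sample,
  plateau residual < 1% of peak).
- **Linearity.** Doubling pulse energy doubles every pressure sample; peak
  pressure is linear in max dP/dt across constant-energy sweeps (R² > 0.99).
- **No cavitation, no nonlinearity, no reflections.** Pulse energies are
  microjoules; the water volume is treated as unbounded (the experimental
  tank is ~10⁶ times the cochlear fluid volume, so no cochlear resonances
  are modelled either).
- **No beam divergence.** NA 0.22 over the ≤ 5 mm simulated depth adds
  little radius growth compared with the penetration-depth scales involved;
  the beam is a straight cylinder.

Confinement classification uses `δ = min(1/μ_a, r)`: stress-confined for
pulses shorter than `τ_p = δ/c` (~35 ns), thermally confined up to
`τ_th`, unconfined beyond; boundaries are inclusive toward the tighter
regime. For every absorption coefficient reachable in the experiments
(≤ 124 cm⁻¹) the fiber radius is the smaller dimension — the penetration
depth would only take over above ~190 cm⁻¹. The heated-zone shape is
classified by the dimensionless product `μ_a·r` (cylinder < 0.1 <
transition < 10 < disk). Note `μ_a·δ` could never exceed 1 by
construction, so the product deliberately uses the fiber radius.

## Numerical scheme

- **Source voxelization.** Axisymmetric ring voxels; at least 10 cells
  across `min(1/μ_a, r)` radially and axially (hard floor of 5, below
  which a resolution error is raised). Axial extent `min(5/μ_a, 5 mm)`.
  The per-cell deposition uses the exact cell-averaged exponential, so the
  absorbed-fraction invariant `Σ A_e dV = 1 − exp(−μ_a L)` holds to
  rounding error.
- **Retarded-time evaluation.** Each voxel's weight `A_e dV / R` is
  deposited into a delay histogram at `τ = R/c` with linear splitting
  between adjacent time bins (equivalent to linear interpolation of `P'`
  at the retarded time); the histogram is convolved with the sampled
  `P'(t)` (overlap-add FFT). The pulse grid is refined so that `c·dt` is
  below half the voxel size, and the pulse must resolve its own 10–90%
  rise with at least 10 samples.
- **Near field.** A field point inside the source volume is legal but
  flagged; the `1/R` weight of the enclosing voxel is clamped at half a
  voxel. The default observation point (on-axis, 0.1 mm beyond the tip) is
  inside the illuminated cylinder for most absorption values, so the flag
  is routinely set in the study configurations. Off-axis points break the
  ring symmetry and are handled by 24-fold azimuthal subdivision.
- **Validation oracle.** The solver is checked against the closed-form
  N-wave of a uniformly heated sphere (partial-volume antialiased
  voxelization, radius/50 cells): 2.5% L∞ agreement, tested at 3%.
- **Measurement chain.** 4th-order Butterworth low-pass at 100 kHz applied
  zero-phase (timing-preserving), then sampling at 102 kHz. The input is
  zero-padded (pressure is identically zero outside the solved window) and
  decimated in stages, because a 100 kHz corner applied directly at GHz
  rates is numerically fragile.

## Default parameters

| parameter | default | why |
|---|---|---|
| fiber radius | 52.5 µm | 105 µm core fiber used in the experiments |
| pulse energy / plateau power | 6 µJ / 150 mW | the two study conditions |
| flat-top rise/fall | 1 µs | the flat-top laser's edge time is not published; 1 µs resolves the 10 µs shortest flat-top while staying far slower than the detector limit. Exposed in the config. |
| nanosecond pulse | 4 ns FWHM Gaussian | the Q-switched/OPO laser |
| c, κ | 1484 m/s, 1.4·10⁻⁷ m²/s | water |
| Γ | 0.11 | βc²/C_p for water near 20 °C (β = 2.07·10⁻⁴ K⁻¹, C_p = 4181 J/(kg·K)); consistency within 5% is asserted |
| field point | on-axis, 0.1 mm beyond tip | hydrophone-fiber distance; axial vs lateral placement is ambiguous in the experimental description, both are configurable |
| chain | 100 kHz low-pass, 102 kHz sampling | amplifier bandwidth and DAQ rate |
| water μ_a table | 12 nodes, 845–2100 nm | standard water-absorption literature values; 1.34 cm⁻¹ @ 1300 nm and 0.039 cm⁻¹ @ 845 nm anchors are pinned in tests. Interpolation is linear in log μ_a (the spectrum spans three decades). |
| ink calibration | slope 15.13 cm⁻¹/%, intercept 1.34 cm⁻¹ | line through pure water at 0% reaching ~77 cm⁻¹ at 5% ink |
| cuvette pathlength | 1 cm | typical spectrometer cell; configurable |

## Synthetic data

The generators emulate the statistical structure of the raw measurements,
not their idiosyncrasies:

- **Photodiode traces**: ideal pulse → first-order 25 ns detector
  rise-time filter → additive Gaussian noise (default 0.5% of peak).
- **Hydrophone recordings**: mean of `n` independent noisy shots (default
  10⁴, matching the experimental averaging). Single-shot σ defaults to
  3 Pa — about 10% of the ~30 Pa single-shot amplitudes of the strongest
  (nanosecond) pulses — an assumption, since measured noise floors are not
  published. The √n reduction is verified over seeds. The detectability
  flag in the sweeps marks points whose post-chain amplitude falls below
  3× the residual noise after averaging.
- **Ink series**: transmission with multiplicative noise; dilutions with
  transmission below 10⁻⁴ are flagged as outside the measurement range and
  recovered by linear extrapolation of the calibration fit, as in the
  experimental protocol.

All generators are pure functions of (parameters, integer seed); replicate
draws come sequentially from one seeded stream.

What passing tests on synthetic data do **not** show: agreement with
absolute in vivo CAP amplitudes (no cochlear mechanics or guinea-pig
audiogram is modelled), the measured reversal of the amplitude–absorption
correlation (see limitations), or real spectrometer noise statistics.

## CAP surrogate calibration

The surrogate — 6th-order Butterworth band-pass 5 Hz–5 kHz, full-wave
rectification, unit-area alpha kernel `t/τ² e^{−t/τ}` — has two free
constants: the integration time τ = 0.35 ms and the peak-detection
prominence fraction 0.3 (a local maximum only counts as a *separate*
response if the adjacent valley dips by ≥ 30% of the response maximum,
with a minimum peak separation of one integration time). Both are **tuned,
not fitted**: they were chosen so that the simulated onset/offset merge
threshold lands near the experimentally observed ~1 ms (the default
configuration gives 0.92 ms), and they carry no physiological
interpretation beyond "the neural read-out integrates for a fraction of a
millisecond". Amplitudes are arbitrary units; only relative comparisons
across sweep points are meaningful. The surrogate output is unipolar
(rectified), so the biphasic N1–P1 read-out maps to baseline-to-peak.

## Problem sizes

The default study configurations use ~10⁴ ring voxels per source
(10 cells across the 52.5 µm scale, ≤ 5 mm axial extent) and time steps of
~1.8 ns in the solver; a full `run-all` (three sweeps, 10–10⁴ µs pulse
durations, ink calibration, merge-threshold bisection) completes in about
40 s on one CPU core. Tests use reduced sweep grids with the same physical
defaults.

## Known limitations

- **The high-absorption amplitude reversal is reported, not reproduced.**
  Experimentally the pressure amplitude at fixed distance peaks near
  57.5 cm⁻¹ (water) / 8.89 cm⁻¹ (ink) and falls beyond. The linear
  far-field model here produces only a mild interior maximum (near
  100 cm⁻¹ on the default grid) driven by the shrinking overlap between
  deposition volume and the fixed observation distance; the wave-geometry
  physics behind the measured reversal (line-source → point-source
  transition and its different range attenuation) is not modelled. The
  sweep therefore *reports* the argmax and its `μ_a·r` product as
  diagnostics rather than asserting the measured values.
- **Post-chain SPL of microsecond flat-top pulses.** The instantaneous
  onset transient of a 30 µs / 6 µJ pulse at 0.1 mm is ~3.9 Pa (~132 dB re
  1 µPa), but the transient is only ~2 µs wide, so the 100 kHz recording
  chain attenuates it to ~0.8 Pa (~118 dB). Reported underwater SPLs in
  the 130–160 dB range correspond to the nanosecond-pulse configurations,
  which the model reproduces; a microsecond flat-top cannot reach them
  after the measurement chain under this linear model.
- **Offset amplitude second-order effects.** Measurements show the offset
  transient does not depend exclusively on the maximum negative slope; the
  linear model makes onset and offset exactly antisymmetric for symmetric
  edges and cannot capture that asymmetry.
- **No inter-pulse thermal buildup**: repetition rate is irrelevant under
  single-pulse linear modelling.
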