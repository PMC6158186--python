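# Methods

`simplesyn` models transmitter release at a *simple synapse* — a single
presynaptic active zone (AZ) of a cerebellar parallel-fibre bouton
contacting a molecular-layer interneuron — as a chain of four stages:

1. a 3D buffered reaction–diffusion model of presynaptic Ca²⁺,
2. an allosteric five-site Ca²⁺ sensor producing the fusion hazard of a
   docked vesicle,
3. a stochastic two-step vesicle pool model
   (recycling pool ⇄ replacement site ⇄ docking site → fusion), and
4. statistics of the resulting release latencies (asynchronous-envelope
   separation, shared-τ biexponential decomposition, BIC model choice,
   crossover index, count covariance, variance–mean), plus a synthetic
   quantal-EPSC generator and deconvolution detector that close the loop
   from release times back to detected events.

## Ca²⁺ reaction–diffusion model (`geometry`, `calcium3d`, `wellmixed`)

The bouton is a 0.9 × 0.5 × 0.5 μm box on a cubic grid (10 nm voxels by
default; 20 nm supported). Twenty-seven voltage-gated Ca²⁺ channels sit on
the z = 0 face in three 3×3 clusters (20 nm channel spacing; cluster
centres on an equilateral triangle of 126 nm side, centred on the face).
Each channel passes a Gaussian Ca²⁺ current (peak 0.2 pA, FWHM 0.34 ms)
per action potential; 0.2 pA corresponds to 6.24×10⁵ ions s⁻¹ and ≈226
ions per AP.

Species: free Ca²⁺ (D = 220 μm² s⁻¹), an immobile endogenous buffer
(2 mM, K_D 50 μM, k_on 2×10⁸ M⁻¹s⁻¹), mobile ATP (200 μM, K_D,Ca 200 μM,
k_on 5×10⁸ M⁻¹s⁻¹, D 220 μm² s⁻¹) and calretinin, modelled as 100 μM of
cooperative two-site pairs with a slow low-affinity first step
(k_on 3.6×10⁶ M⁻¹s⁻¹, K_D 14.7 μM) and a fast high-affinity second step
(k_on 3.1×10⁸ M⁻¹s⁻¹, K_D 64.5 nM), D = 20 μm² s⁻¹ — published calretinin
kinetics; all rates are config-exposed. The endogenous buffer is treated
as immobile, the conventional assumption for a high-capacity low-affinity
buffer. An optional "imaging-comparison" buffer set adds the indicator
dye OGB-6F (500 μM, K_D 5.1 μM); the default release simulations exclude
the dye because the reference global amplitude is a dye-corrected
estimate.

Integration is explicit Euler with a 7-point Laplacian, reflecting
boundaries on all six faces, and first-order binding kinetics; the time
step must satisfy D·dt/dx² ≤ 1/6 (violations raise with the bound named).
The default step is the conventional 0.03 μs; production runs use 0.06 μs
(still well below the 0.0758 μs bound at 10 nm), and halving dt changes
the contour peak by <2 % (asserted in the tests). A fused-loop numba
kernel accelerates the stepper; a pure-numpy reference path produces
bitwise-comparable results and the two are cross-checked in the suite.

Extrusion is a linear surface pump toward resting Ca²⁺ on all faces with
permeability p (μm ms⁻¹). The published description of extrusion does not
fix its units, so p is a calibrated surrogate: p = 0.15 μm ms⁻¹
simultaneously reproduces the published maxima of the Ca²⁺-dependent
recruitment rates during an 8-AP 200-Hz train (R_f max ≈ 0.55 ms⁻¹,
S_f max ≈ 0.042 ms⁻¹), the ≈0.9 μM single-AP global peak, and a global
decay consistent with facilitation vanishing by the 80 ms paired-pulse
interval.

Outputs are two averages of the free-Ca²⁺ field: **local** — over the
first voxel layer at 40 ± 5 nm in-plane distance from the convex-hull
edge of the nearest channel cluster (where docked vesicles sit) — and
**global** — over voxels >100 nm from every cluster. With the defaults a
single AP yields a local peak near 46–50 μM and a global peak near
0.95 μM.

Trains can be integrated in full 3D or, routinely, in
*template-superposition* mode: the local microdomain template (single-AP
local minus its own global component) is superposed per AP — with the
tail beyond the template window continued exponentially, since the
saturated-buffer halo relaxes over a few ms — on top of a well-mixed
(single-compartment, LSODA-integrated) mass-balance solution of the same
buffers and pump. For one AP the two modes agree within 2 %; template
mode does not capture intra-train saturation of the microdomain (see
Limitations).

## Allosteric fusion sensor (`sensor`)

Five sequential Ca²⁺ binding steps V₀…V₅: binding (5−n)·k_on·[Ca],
unbinding n·k_off·bⁿ⁻¹, fusion from Vₙ at l₊·fⁿ with l₊ = γ/f⁵
(k_on 5×10⁸ M⁻¹s⁻¹, k_off 5000 s⁻¹, b = 0.75, f = 31.3, γ = 2100 s⁻¹).
The cooperativity factor b is applied to unbinding (the standard form of
this sensor model; applying it to binding instead is a known alternative
convention). The hazard h(t) is the fusion flux of the not-yet-fused
population. The master equation is integrated by forward-Euler substeps
capped at 0.05 transition probability per substep; a matrix-exponential
propagator serves as an independent oracle in the tests (<0.5 % in
cumulative release probability).

Activity-dependent fatigue ("slow release"): immediately after a docking
site releases, its sensor runs with k_on/10 and k_off/2.5, recovering
linearly to the normal values over 40 ms (1 s under latrunculin B). The
first two release events of an AZ, and sites that have never released,
use the normal parameters. Fully fatigued parameters reduce the
single-AP fusion probability from 0.64 to 0.05. For Monte Carlo use the
hazard is precomputed on a grid of recovery fractions φ (21 levels,
linear interpolation) — a quasi-static treatment justified because
fatigue recovery (≥40 ms) is slow against sensor equilibration (<1 ms).

## Two-step pool model (`twostep`)

Four independent docking sites per AZ; each has an associated replacement
site. Rates: S_f (pool→RS) and R_f (RS→DS) are Michaelis–Menten in the
*global* Ca²⁺ (V_max 60 s⁻¹ / 800 s⁻¹, both K_d 2 μM); fusion is driven by
the *local* Ca²⁺ through the sensor; S_b (RS→pool) and R_b (DS→RS, only
into an empty RS) are calibrated so that resting occupancies are
δ₀ = 0.3 (0.15 at 1.5 mM external Ca²⁺) and ρ₀ = 0.9 at 50 nM Ca²⁺.
Because the resting per-site chain 00–10–01–11 is a birth–death path,
the calibration is closed-form: with a = S_f/S_b and r = R_f/R_b,
ρ = a/(1+a) and δ = ar/(1+ar), giving R_b ≈ 409.8 s⁻¹ and
S_b ≈ 0.163 s⁻¹ at the defaults (checked against a generator eigen-solve).
Dual occupancy (RS and DS filled) is allowed; the recycling pool is
infinite. Undocked vesicles return to their own replacement site; loss to
the cytosol is not modelled.

Deterministic (mean-field) integration uses the per-site 4-state ODE;
with replenishment off it reduces to the two-parameter single-AP model
(dδ/dt = −h·δ). Monte Carlo uses 0.01 ms steps, independent Bernoulli
draws per transition (p = 1−exp(−rate·dt), guarded to stay <0.1), applied
in the order S_b, R_f, R_b, S_f, fusion — docking before fusion, so a
vesicle can dock and fuse within one step (two-step release). Initial
states are drawn from the resting stationary law (or the product of
target marginals when scripted rates make the chain degenerate). One seed
drives the whole run; 5000 trials is the study condition.

Origin labels are maintained online: at every AP, vesicles on a DS are
relabelled "docked" and on an RS "replacement"; pool-supplied vesicles
carry "recycling" until the next AP; fusion records the docked vesicle's
current label — i.e., the compartment the vesicle occupied immediately
before the most recent AP preceding its release.

## Latency statistics (`latency`)

Timing convention: scenario AP times are *stimulus* times; Ca²⁺ influx
peaks 0.4 ms later (conduction plus waveform lag), so latencies carry the
physiological ~0.4 ms base delay and the late part of each inter-AP
interval is free of the next stimulus' release onset.

Asynchronous release is separated by deleting events in the first 4.6 ms
(200 Hz) or 5 ms (100 Hz) after each AP (other frequencies: period minus
0.4 ms), smoothing the surviving late-interval rate with a masked 1-ms
moving average (deleted synchronous peaks cannot bleed into the
envelope), bridging gaps with straight lines, and smoothing again (2 ms).
Synchronous = total − envelope, without flooring, so counts are conserved
(verified to 2 %).

Per-stimulus cumulative synchronous curves are built at event resolution
(0.05 ms) with the integrated envelope subtracted, and fitted jointly:
A_f,i(1−e^−(t−t₀)/τ_fast) + A_s,i(1−e^−(t−t₀)/τ_slow) with τ_fast, τ_slow
and the onset delay t₀ shared across stimuli and amplitudes free.
Identification constraints: τ_fast ∈ [0.1, 1.0] ms,
τ_slow ≥ τ_fast + 0.5 ms, t₀ ∈ [0, 1.2] ms (the alignment allowance);
several starting points are tried and the best least-squares solution
kept. When raw latencies are available the τ confidence intervals come
from a basic (reflected) nonparametric bootstrap over events — the
sampling noise of empirical distributions dominates and is not captured
by least-squares standard errors on cumulative curves; for curve-only
fits an autocorrelation-inflated standard error is reported instead.

BIC comparison (mono- vs biexponential) scores both models on the
*increments* of the cumulative curve, weighted by 1/√mass estimated from
the smoothed empirical increments: increments are quasi-independent and
the weighting makes the Gaussian-RSS convention
BIC = n·ln(RSS/n) + k·ln(n) behave correctly for counting noise. When
the biexponential collapses onto the mono fit, mono wins by exactly
2·ln n.

The crossover index is the first stimulus whose slow amplitude fraction
reaches the fast one (ties resolve to that stimulus; `None` if never).
Count windows: 5 ms after each AP (3 ms windows for the 3 ms paired
interval) and 0–5 / 5–35 / 35–65 ms after the last AP; covariance is the
sample covariance of per-trial counts.

## Synthetic EPSCs (`epsc`)

The miniature-EPSC kernel is the five-parameter triple-exponential
(rise time, amplitude, fast decay, slow decay, slow fraction), normalized
so the peak equals the amplitude. Rendering draws per-event amplitudes
from a lognormal with CV 0.307 (lognormal keeps amplitudes positive at
this CV; the empirical histograms are near-Gaussian with CV < 0.5),
applies pairwise occlusion against the immediately preceding event
(factor 1−(1−ω)e^−Δt/τ, ω = 0.648, τ = 1.50 ms; multi-event saturation is
a documented simplification) and adds Gaussian noise. Sampling is 0.02 ms.

Detection divides the trace by the kernel in the Fourier domain with a
Wiener-style floor (10⁻³ of the peak power, config-exposed), picks local
maxima above a robust (MAD-based) threshold, refines times by parabolic
interpolation, merges candidates within the 0.2 ms detection limit, and
fits amplitudes by linear least squares of kernel copies. Round-trip
recall and precision are ≥95 % with ≤0.05 ms timing error at event rates
≤1 ms⁻¹, CV ≤0.3 and SNR ≥10. Events above 1.7× a reference mean
amplitude (strict inequality) are split into two simultaneous
half-amplitude events, compensating merged pairs.

## Scenarios (`scenarios`, `cli`)

Named presets reproduce the studied conditions: `single_ap`,
`paired_pulse`, `ctrl_3ca_200hz`, `ctrl_3ca_100hz`, `lowca_1p5_200hz`
(δ₀ = 0.15, influx ×0.5), `tea_3ca_100hz` (influx FWHM ×2 — a surrogate
for K⁺-channel block broadening the AP) and `latb_3ca_200hz` (R_f ×0.5,
fatigue recovery 1 s). The 1.5 mM and TEA influx factors are surrogates
for unpublished calibrations and are config-exposed. `run_scenario`
executes the full chain with a content-addressed cache for the single-AP
3D solution and emits a machine-readable report (counts, τs, amplitude
fractions, crossover, asynchronous windows, covariances, config hash);
equal seeds give byte-identical outputs. The `simplesyn` CLI wraps the
library (`simulate-ca`, `run`, `compare`, `synth-epsc`, `detect`).

## Problem sizes used

Production single-AP 3D runs use the full 90×50×50 grid at dt 0.06 μs
over 3 ms (≈50k steps, a few minutes). The test suite runs the same
configuration once per session at dt 0.07 μs, plus coarse 20 nm grids for
stepper-level properties; Monte Carlo checks in the tests use 2000 trials
per seed (five seeds for crossover statistics), while the acceptance
script uses the full 5000.

## What the synthetic data do and do not show

The synthetic-EPSC generator emulates quantal amplitude variability,
receptor-occlusion of near-simultaneous events, baseline noise and the
0.2 ms separation limit of deconvolution. It does not model receptor
saturation/desensitization kinetics beyond the empirical occlusion
factor, stimulus artifacts, or recording-hardware filtering; passing
round-trip tests therefore demonstrates correctness of the detection
pipeline, not robustness to every feature of real recordings.

## Known limitations

- Channel gating is deterministic (identical Gaussian flux per channel);
  stochastic channel openings would add latency jitter at low open
  probability.
- Template-superposition trains superpose a fixed microdomain template,
  underestimating intra-train saturation of the local buffers. The
  full-3D train mode (practical at 20 nm) shows a modest additional
  inter-AP local elevation (~2 μM late in the train).
- The intra-train accumulation of local Ca²⁺, together with the fatigue
  trajectories, controls how much of late-train release is slow. Under
  this package's surrogate choices the slow synchronous component grows
  monotonically through the train but saturates near a 0.2–0.35 amplitude
  fraction in the 3 mM/200 Hz control, so the fast→slow crossover falls
  later than in the reference simulations, and the cumulated
  replacement/docked origin ratio reaches ~0.35 rather than ~2/3. The
  latrunculin-B scenario, by contrast, reproduces the reference crossover
  (median stimulus 6), and all single-AP and recruitment-rate checkpoints
  are met. See the acceptance suite for the exact assertions.
- The extrusion pump, calretinin kinetics, and the 1.5 mM/TEA/LatB influx
  factors are calibrated or literature surrogates; all are config-exposed
  and their calibration anchors are stated above.
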