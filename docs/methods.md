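# Methods

## Model and reduction

Two limit-cycle oscillators with period normalized to 2π (spike at phase
0) are driven by weak, partially correlated colored noise:

    θ₁' = 1 + ε Δ₁(θ₁) x(t)
    θ₂' = 1 + ε Δ₂(θ₂) y(t) + ε² ω
    x'  = −x/τ + ξ_x/√τ,   y' = −y/τ + ξ_y/√τ

with unit white noises of cross-intensity c (`⟨ξ_x(t) ξ_y(t')⟩ =
c δ(t−t')`).  The OU processes are **amplitude-fixed**: stationary
variance 1/2 for every τ, autocovariance `(1/2) e^{−|s|/τ}` (mass τ).
Shrinking τ therefore whitens the input at constant power — the
experimentally natural dial — and the convention is invariant under time
rescaling, which is what lets Morris-Lecar quantities (τ in ms) map onto
phase units by the single substitution `τ → 2πτ/T`.  The frequency
detuning enters at order ε², the same order as the noise variance; larger
detuning admits no synchronization at all.

Second-order averaging over the fast phase and the noise gives a
stationary flux balance for the phase-difference density R(φ),
φ = θ₂ − θ₁ wrapped to [−π, π):

    d/dφ { [c·g(φ) − C₁] R } + (2ω/τ − C₂) R = K,
    R, g 2π-periodic,  ∫R dφ = 1,  K = (2ω/τ − C₂)/(2π)

with, writing `h_nm(φ) = (1/2π)∫ Δ_n(θ) Δ_m(θ+φ) dθ` and `ρ_τ` the
*unit-mass* exponential kernel (harmonic multiplier `1/(1+k²τ²)`):

* `g_nm = ρ_τ ∗ h_nm`, `g = 2 g₁₂` (the correlated transport term),
* `C₁ = g₁₁(0) + g₂₂(0)` (total effective diffusion),
* `C₂ = 2(ν₁ − ν₂)`, `νⱼ = −τ Σ_{k≥1} k² ĥ_k^{(jj)}/(1+k²τ²)`, the
  asymmetry of the noise-induced mean frequency slowings (zero for
  identical PRCs),
* K is *forced* by integrating the equation over one period and is kept
  as a consistency assertion, never a free constant.

Division of the raw balance by the kernel mass τ puts every PRC
coefficient in unit-mass form and moves the mass into the detuning
coefficient `2ω/τ`.  Two consequences shape the results: the detuning-
to-transport ratio carries the factor `(1+τ²)/τ`, minimized at τ = 1 —
the origin of the noise-time-constant **resonance** for detuned pairs —
and ε appears nowhere, so the density is noise-amplitude independent to
leading order (verified by Monte Carlo at ε up to 1).

Sign and scale conventions of C₂ and the detuning term are pinned by two
independent oracles in the test suite: the measured mean frequency shift
`(⟨θ'⟩−1)/ε²` of a single simulated oscillator, and bin-wise agreement of
BVP and Monte Carlo densities for detuned heterogeneous pairs.

Special cases used throughout: for identical PRCs and ω = 0 the BVP
integrates to the closed form `R = N/(C₁ − c g(φ))`, symmetric and peaked
at 0; at small c, `R = 1/2π + c R₁` gives the linear OP slope
`2π|R̂₁,₁|`, which for single-harmonic PRCs
`Δⱼ = sin aⱼ − sin(θ+aⱼ)` evaluates to
`(1/2)/(1 + (τ²+1)(sin²aⱼ + sin²aₖ))` — whence the ordering
OP₁₁ > OP₁₂ > OP₂₂ for a₁ < a₂ in [0, π/2]: pairing a good synchronizer
with a bad one beats the bad homogeneous pair at low correlation.

## Numerical choices

**BVP solver.** Fourier collocation: the first-order periodic operator is
dense in harmonic space (Toeplitz convolution with the harmonics of
`c·g − C₁` plus the constant drift); the zero mode, which the operator
annihilates up to the forced identity, is replaced by the normalization
row `2π R̂₀ = 1`.  Default 128 modes.  The residual of the ODE — with the
product `(c g − C₁)R` formed pointwise on a 4× fine grid so truncation is
measured honestly — must stay below 1e−8 (relative to the solution
scale); solutions dipping below −1e−6 are rejected rather than clipped.
The homogeneous c = 1 problem is a delta limit and is refused as
degenerate (positivity of `C₁ − c·max g` is checked on construction);
heterogeneous pairs remain strictly non-degenerate at c = 1 by
Cauchy-Schwarz.

**Simulation.** Euler-Maruyama on a shared grid for phases and noise (no
sub-stepping), numba-compiled; PRCs enter through a 4096-point periodic
linear lookup.  Defaults mirror the headline runs: dt = 0.05, burn-in
t = 1000, total t = 201000, 100 bins on [−π, π) with the seam tie at π
mapped to −π.  Plain Itô stepping is used; at the standard ε and dt the
Itô-Stratonovich discrepancy is below sampling error (the
ε-independence test is the guard), but at ε ≥ 0.5 the step must be
refined (dt ≈ 0.01) to keep the discretization bias below the Monte Carlo
error.  One master seed spawns three independent streams (common,
private-x, private-y); with c = 1 the two noise paths are identical by
construction.  OU initial conditions are drawn from the stationary
Gaussian, so no noise transient exists.

**PRC families.** Double-sinusoidal
`sin a − sin(θ+a) + b sin 2θ` (DC component `sin a`) and exponential-sine
`scale·(sin a − sin(x+a))·e^{C(x−2π)}` on x ∈ [0, 2π), periodized by
wrapping (the jump at 0 is accepted; the family serves as a fitting
model, not for derivative-sensitive terms).  Tabulated PRCs (≥ 16
strictly increasing samples in [0, 2π)) are interpolated with periodic
cubic splines — smoothness the filtered-correlation terms need.  The
exponential-sine fit is Levenberg-Marquardt least squares initialized
from the phase of the first Fourier harmonic (a) and the early/late
log-magnitude ratio (C), which avoids the family's local minima; the
susceptibility optimum of this family sits at `a = −arctan C`, the
zero-DC tuning, and the susceptibility itself is computed as
`(1 − a₀²/g(0))/2π` with the DC component a₀ in closed form.

**Morris-Lecar layer.** The two-variable conductance model uses the base
set V_K = −84, V_L = −60, V_Ca = 120 mV, g_K = 8, g_L = 2, g_Ca = 4
mS/cm², C_m = 20 µF/cm², V_a = −1.2, V_b = 18, V_c = 2, V_d = 30 mV;
current I and recovery rate φ_w select the operating point.  The
same-frequency comparison pair (I = 120, φ_w = 0.04) and (I = 110,
φ_w = 0.04616) spikes at 73.1 ms with distinctly different PRCs.  The
Hopf-regime instance uses the canonical Hopf geometry (g_Ca = 4.4,
φ_w = 0.04, I = 95), period 91.2 ms; the SNIC-regime partner is a
reconstruction from the canonical SNIC geometry (V_c = 12, V_d = 17.4 mV,
φ_w = 1/15) with its current tuned at run time (Brent's method) to
period-match the Hopf cell, as the same-frequency comparison requires.
Deterministic integration is LSODA at rtol 1e−10 with event-based
upward-crossing detection at 0 mV after a 2000 ms transient discard;
period drift between consecutive cycles above 0.1% raises an error, and
fewer than three crossings reports "no oscillation".

The infinitesimal PRC is the voltage component of the periodic solution
of the adjoint system `Z' = −J(X₀(t))ᵀ Z`, integrated backward over
repeated periods on a periodic cubic interpolant of the cycle until the
period map converges (1e−6), then normalized so `Z·F ≡ 1` and expressed
as radians of phase shift per unit injected charge density,
`Δ(θ) = (2π/T) Z_V(θ)/C_m`.  An independent oracle applies brief square
current pulses (0.5 ms) at 32 phases and measures the asymptotic
spike-time shift; reporting each probe at the pulse *center* cancels the
first-order smearing of the finite width, and the two PRCs agree within
2% of the peak.  Stochastic pair runs use Euler-Maruyama at
dt = 0.01–0.02 ms, cell 1 driven by σx and cell 2 by σy (the model
display repeats "σx" for both cells, which would make c irrelevant; the
cross-cell reading is implemented).  Phase is reconstructed from voltage
by the Hilbert transform of the mean-subtracted trace, remapped through a
monotone lookup (Hilbert angle → elapsed-time fraction × 2π) built on the
noise-free cycle, so the noise-free trajectory has exactly uniform phase
velocity.

## Synthetic data

Two generators emulate data this package would otherwise take from
experiments.  `synthetic_prc_table` produces tabulated PRCs —
exponential-sine truth plus i.i.d. Gaussian noise scaled to a fraction of
the PRC peak (default 5%, 64 samples) — to exercise the fitting path; it
reproduces measurement noise but not the correlated errors or
phase-estimation artifacts of spike-triggered-average PRC estimation, so
fit-recovery results certify the optimizer, not the experimental
pipeline.  The population study samples double-sinusoidal PRCs with
uniform parameters (defaults a ∈ [0, π/2), b = 0.3, rate-matched ω = 0),
classifies each cell by the area under its homogeneous OP-vs-c curve, and
asks when the heterogeneous pair beats the bad homogeneous pair for
c ∈ (0, 0.3].  Passing tests show the mechanism — DC-component-governed
correlation transfer — not the statistics of any real cell population
(those require recorded PRCs).

## Parameter defaults

| parameter | default | meaning |
|-----------|---------|---------|
| τ | 1 (phase units) / 5 ms (ML) | OU correlation time |
| c | 0.8 | input correlation in [0, 1] |
| ε | 0.1–0.5 | noise magnitude (drops out of the theory) |
| ω | 0 | detuning; rate difference is ε²ω |
| dt | 0.05 (phase) / 0.01–0.02 ms (ML) | Euler-Maruyama step |
| T, burn-in | 201000, 1000 | run length for headline densities |
| grid | 256 | periodic-function grid (power of two) |
| n_modes | 128 | BVP collocation harmonics |
| n_bins | 100 | density bins on [−π, π) |

Peak position is defined as the angle of the resultant vector
`atan2(S, C)` — robust to binning noise — rather than the argmax bin.

## Limitations

* The theory is leading-order in ε: at ε ≈ 1 Monte Carlo densities show
  a small peak distortion (a few percent), largest for heterogeneous,
  detuned pairs.
* Exact OP symmetry in ±ω holds only when C₂ = 0 (identical PRCs);
  heterogeneous pairs are symmetric about the tiny offset `ω = C₂τ/2`
  (∼10⁻³ for the standard pair).
* Only the marginal density R(φ) is computed, never the joint density in
  (x, y, θ, φ); populations beyond two oscillators are out of scope, as
  is PRC estimation from recorded voltage traces.
* The difference process mixes slowly at weak noise (relaxation
  ∝ 1/ε²), so empirical densities need runs of thousands of cycles;
  block-resampled standard errors are used wherever simulation is
  compared to theory.
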