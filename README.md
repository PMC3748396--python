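# ousync

Correlated colored-noise-induced synchronization of heterogeneous neural
oscillators: phase-reduced Langevin simulation, an analytical solver for
the stationary phase-difference density, synchrony metrics, and a
Morris-Lecar biophysical validation layer.

## The problem

Regularly firing neurons that share part of their synaptic input can
synchronize without any direct coupling.  How well they do so depends on
the input correlation `c`, the correlation time `τ` of the (colored,
Ornstein-Uhlenbeck) input fluctuations, and — centrally here — on how
*different* the two cells are, both in their phase-response curves (PRCs)
and in their firing rates.

A spiking cell near its limit cycle reduces to a phase
`θ ∈ [0, 2π)` obeying

```
θ₁' = 1 + ε Δ₁(θ₁) x(t)
θ₂' = 1 + ε Δ₂(θ₂) y(t) + ε² ω
```

where `Δⱼ` are the PRCs, `(x, y)` is a correlated OU pair
(`⟨ξₓ ξᵧ⟩ = c δ`, variance 1/2, autocorrelation `(1/2) e^{−|s|/τ}`),
`ε` the noise magnitude and `ω` a frequency detuning entering at the same
`ε²` order as the noise variance.  To leading order the stationary density
`R(φ)` of the phase difference `φ = θ₂ − θ₁` solves a first-order periodic
boundary value problem

```
d/dφ { [c g(φ) − C₁] R } + (2ω/τ − C₂) R = K,   ∫ R dφ = 1
```

whose coefficients are elementary filtered correlations of the PRCs:
`g = 2 ρ_τ ∗ h₁₂`, `C₁ = g₁₁(0) + g₂₂(0)` with
`h_nm(φ) = (1/2π)∫ Δ_n(θ) Δ_m(θ+φ) dθ`, and `C₂` the asymmetry of the
noise-induced frequency shifts (zero for identical PRCs).  `ε` drops out:
the density is noise-amplitude independent.  Synchrony is summarized by
the order parameter `OP = |∫ e^{iφ} R(φ) dφ|` (0 flat, 1 delta).

The package computes `R(φ)` three independent ways — Euler-Maruyama
Monte Carlo of the Langevin pair, spectral solution of the BVP, and a
closed form `R = N/(C₁ − c g)` for matched pairs — and validates the
whole reduction on the two-variable Morris-Lecar conductance model
(adjoint-computed PRCs, Hilbert-transform phase reconstruction).

## Worked example

The heterogeneous pair studied throughout uses double-sinusoidal PRCs
`Δⱼ(θ) = sin aⱼ − sin(θ + aⱼ) + bⱼ sin 2θ` with
`(a₁, b₁) = (0.1, 0.32)` and `(a₂, b₂) = (0.6, 0.30)`:

```python
from ousync import (make_double_sine, build_problem, solve_density,
                    order_parameter, susceptibility)

p1, p2 = make_double_sine(0.1, 0.32), make_double_sine(0.6, 0.30)
prob = build_problem(p1, p2, tau=1.0, c=0.8, omega=0.0)
print(f"C1 = {prob.C1:.4f}, C2 = {prob.C2:.5f}")
d = solve_density(prob, n_modes=128, n_bins=100)
s = order_parameter(d)
print(f"OP = {s.op:.3f}, peak = {s.peak_angle:.3f} rad")
print(f"susceptibility(PRC1) = {susceptibility(p1, 1.0):.4f}")
print(f"susceptibility(PRC2) = {susceptibility(p2, 1.0):.4f}")
```

prints

```
C1 = 0.8480, C2 = -0.00496
OP = 0.289, peak = -0.474 rad
susceptibility(PRC1) = 0.1533
susceptibility(PRC2) = 0.0713
```

Read: at 80% input correlation the mismatched pair reaches only a modest
OP of 0.29, and the density peak sits at −0.47 rad — PRC heterogeneity
alone offsets the preferred phase difference even with no frequency
detuning.  PRC 1, with the smaller DC component, transfers correlation
about twice as efficiently as PRC 2 (susceptibilities 0.153 vs 0.071 of
the theoretical maximum 1/2π ≈ 0.159) — it is the "good synchronizer" of
the pair.  Counterintuitively, at low `c` the mixed pair synchronizes
*better* than two bad synchronizers (`ousync sweep-c` reproduces the
orderings).

The same studies run from the shell:

```
ousync density --a1 0.1 --b1 0.32 --a2 0.6 --b2 0.30 --tau 1 --c 0.8 --out density.csv
ousync sweep-c   --out sweep_c.csv        # OP vs input correlation
ousync sweep-tau --omega 0.5 --out sweep_tau.csv   # resonance when detuned
ousync ml-density --sigma 6 --tau 5 --c 0.8 --out ml.csv  # Morris-Lecar pair
```

## Layout

| module                | contents |
|-----------------------|----------|
| `ousync.prc`          | PRC families, tabulated PRCs + CSV I/O, exponential-sine fitting, phase correlations `h_nm` |
| `ousync.noise`        | correlated OU pair generator and stationary moments |
| `ousync.langevin`     | Euler-Maruyama phase-pair simulator, empirical densities |
| `ousync.theory`       | BVP assembly (`g`, `C₁`, `C₂`), Fourier-collocation solver, closed form, small-`c` expansion |
| `ousync.metrics`      | order parameter, spike-time cross-correlation, susceptibility |
| `ousync.mlneuron`     | Morris-Lecar model, limit cycle + period, adjoint PRC, pulse-PRC oracle, Hilbert phase, noisy pair simulation |
| `ousync.experiments`  | sweeps over `c`, `τ`, `ω`, PRC shape; synthetic-population study |
| `ousync.cli`          | `ousync` command-line entry point |

See `docs/methods.md` for the model derivation conventions, parameter
defaults, numerical choices, and known limitations.
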