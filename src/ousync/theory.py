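"""Stationary phase-difference density of a correlated-noise-driven pair.

In the weak-noise limit the wrapped phase difference
:math:`\\phi = \\theta_2 - \\theta_1` of two oscillators driven by
partially correlated OU noise has a stationary density R(phi) obeying a
first-order periodic boundary value problem

.. math::
    \\frac{d}{d\\phi}\\Big\\{[c\\,g(\\phi) - C_1]\\,R\\Big\\}
    + \\Big(\\frac{2\\omega}{\\tau} - C_2\\Big)\\,R = K,
    \\qquad K = \\frac{2\\omega/\\tau - C_2}{2\\pi},
    \\qquad \\int_{-\\pi}^{\\pi} R\\,d\\phi = 1,

with periodic R and g.  All coefficients are elementary integrals of the
PRCs filtered by the unit-mass exponential kernel
``rho_tau(s) = (1/(2 tau)) exp(-|s|/tau)``:

* ``g_nm = rho_tau * h_nm`` (harmonic k of h multiplied by
  ``1/(1 + k^2 tau^2)``); the correlated transport term is
  ``g = 2 g_12`` and the constant is ``C_1 = g_11(0) + g_22(0)``;
* ``C_2 = 2 (nu_1 - nu_2)`` is twice the asymmetry of the noise-induced
  mean frequency shifts
  ``nu_j = int_0^inf rho_tau(s) h_jj'(s) ds
         = -tau sum_k k^2 hhat_k^{(jj)} / (1 + k^2 tau^2)``,
  which vanishes for identical PRCs.

The simulated OU noise is amplitude-fixed (autocovariance
``(1/2) exp(-|s|/tau)``, mass tau, variance 1/2).  Dividing the raw
averaged balance by that mass leaves every filtered-PRC coefficient in
unit-mass form and moves the kernel mass into the detuning coefficient
``2 omega / tau``; this is the origin of the ``(1 + tau^2)/tau`` detuning
factor behind the noise-time-constant resonance of detuned pairs.

Note the noise amplitude :math:`\\epsilon` appears nowhere: to leading
order the phase-difference density is independent of the noise magnitude.
Integrating the BVP over one period forces
``K = (2 omega/tau - C_2)/(2 pi)``, which is kept as a consistency
relation, never a free constant.  The phase correlations are normalized
as ``h_nm = (1/2pi) int Delta_n Delta_m``; multiplying the whole equation
by ``2 pi`` (i.e. dropping the 1/(2pi) from h) gives the equivalent
``4 pi omega`` form of the detuning term.

The BVP is solved by Fourier collocation: the operator is dense in
harmonic space, the zero-mode row is replaced by the normalization
constraint, and the solution is evaluated spectrally on any bin grid.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .langevin import PhaseDifferenceDensity
from .prc import (DEFAULT_GRID, TWO_PI, PeriodicFunction, PRCSpec,
                  cross_correlation_h, fourier_coefficients)


class DegenerateProblemError(ValueError):
    """Transport coefficient C1 - c max g loses positivity (c -> 1 delta limit)."""


@dataclass
class StationaryProblem:
    """Coefficients of the stationary-density BVP.

    ``g`` is the correlated cross-term entering ``c * g(phi)`` (equal to
    twice the filtered cross-correlation of the two PRCs); ``C1`` is the
    sum of the two filtered autocorrelations at zero lag; ``C2`` is the
    filtered-noise-induced frequency-shift asymmetry (zero for identical
    PRCs).
    """

    g: PeriodicFunction
    C1: float
    C2: float
    omega: float
    c: float
    tau: float

    @property
    def K(self) -> float:
        # forced by integrating the BVP over one period
        return self.drift / TWO_PI

    @property
    def drift(self) -> float:
        """Constant detuning coefficient 2 omega / tau - C2."""
        return 2.0 * self.omega / self.tau - self.C2

    @property
    def degenerate(self) -> bool:
        return self.C1 - self.c * float(np.max(self.g.values)) <= 0.0


def ou_filter(h: PeriodicFunction, tau: float) -> PeriodicFunction:
    """Convolve a periodic function with the OU autocorrelation kernel.

    Harmonic k is multiplied by ``1/(1 + k^2 tau^2)``; the DC component is
    unchanged and ``tau -> 0`` returns the input.
    """
    if tau <= 0:
        raise ValueError(f"time constant tau must be positive, got {tau}")
    ks = h.wavenumbers
    return PeriodicFunction.from_coefficients(
        h.coefficients / (1.0 + (ks * tau) ** 2))


def filtered_correlation(prc_n: PRCSpec, prc_m: PRCSpec, tau: float,
                         n: int = DEFAULT_GRID) -> PeriodicFunction:
    """Filtered phase correlation ``g_nm = rho_tau * h_nm``."""
    return ou_filter(cross_correlation_h(prc_n, prc_m, n), tau)


def noise_frequency_shift(prc: PRCSpec, tau: float,
                          n: int = DEFAULT_GRID) -> float:
    """Mean frequency shift of a single noise-driven oscillator, per eps^2.

    For ``theta' = 1 + eps Delta(theta) x`` with OU drive, averaging gives
    ``<theta'> = 1 + eps^2 nu`` with
    ``nu = int_0^inf rho_tau(s) h'(s) ds``.  In harmonics of
    ``h = h_nn``: ``nu = -tau sum_{k>=1} k^2 hhat_k / (1 + k^2 tau^2)``
    (always a slowing for tau > 0).
    """
    if tau <= 0:
        raise ValueError(f"time constant tau must be positive, got {tau}")
    a = fourier_coefficients(prc, n)
    ks = np.fft.fftfreq(n, d=1.0 / n).astype(int)
    h_k = np.abs(a) ** 2
    pos = ks > 0
    return float(-tau * np.sum(ks[pos] ** 2 * h_k[pos]
                               / (1.0 + (ks[pos] * tau) ** 2)))


def build_problem(prc1: PRCSpec, prc2: PRCSpec, tau: float, c: float,
                  omega: float = 0.0, n: int = DEFAULT_GRID) -> StationaryProblem:
    """Assemble the stationary-density BVP for a PRC pair."""
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"correlation c must lie in [0, 1], got {c}")
    if tau <= 0:
        raise ValueError(f"time constant tau must be positive, got {tau}")
    g11 = filtered_correlation(prc1, prc1, tau, n)
    g22 = filtered_correlation(prc2, prc2, tau, n)
    g12 = filtered_correlation(prc1, prc2, tau, n)
    g = PeriodicFunction(2.0 * g12.values)
    C1 = float(g11.values[0] + g22.values[0])
    C2 = 2.0 * (noise_frequency_shift(prc1, tau, n)
                - noise_frequency_shift(prc2, tau, n))
    return StationaryProblem(g=g, C1=C1, C2=C2, omega=float(omega),
                             c=float(c), tau=float(tau))


def _density_from_harmonics(r_hat: np.ndarray, modes: np.ndarray,
                            n_bins: int, provenance: str) -> PhaseDifferenceDensity:
    centers = PhaseDifferenceDensity.bin_centers_for(n_bins)
    values = np.real(np.exp(1j * np.outer(centers, modes)) @ r_hat)
    return PhaseDifferenceDensity(centers, values, provenance)


def solve_density(problem: StationaryProblem, n_modes: int = 128,
                  n_bins: int = 256) -> PhaseDifferenceDensity:
    """Solve the stationary BVP by Fourier collocation.

    The first-order periodic ODE becomes a dense linear system on the
    harmonics of R; the zero-mode row (a multiple of the integrated
    identity ``drift = 2 pi K``) is replaced by the normalization
    constraint.  The returned density is spectrally evaluated at the
    ``n_bins`` bin centers; the max-norm residual of the ODE on the
    collocation grid must not exceed 1e-8, and solutions dipping below
    -1e-6 are rejected rather than clipped.
    """
    if problem.degenerate:
        raise DegenerateProblemError(
            "transport coefficient C1 - c*max(g) is not positive; "
            "the density approaches a delta function (c -> 1 limit)")
    M = max(n_modes // 2, 8)
    modes = np.arange(-M, M + 1)
    nm = modes.size

    # B(phi) = c g(phi) - C1 in harmonic space
    b_hat = np.zeros(nm, dtype=complex)
    g_hat = problem.g.coefficients
    ng = g_hat.size
    for idx, k in enumerate(modes):
        if -ng // 2 <= k < ng // 2:
            b_hat[idx] = problem.c * g_hat[k % ng]
    b_hat[M] -= problem.C1

    # row k: i k sum_m B_{k-m} R_m + drift * R_k = K delta_{k0}
    A = np.zeros((nm, nm), dtype=complex)
    rhs = np.zeros(nm, dtype=complex)
    for row, k in enumerate(modes):
        for col, m in enumerate(modes):
            d = k - m
            if -M <= d <= M:
                A[row, col] = 1j * k * b_hat[d + M]
        A[row, row] += problem.drift
        rhs[row] = problem.K if k == 0 else 0.0
    # normalization row replaces the (dependent) zero mode
    A[M, :] = 0.0
    A[M, M] = TWO_PI
    rhs[M] = 1.0

    try:
        r_hat = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(
            "singular BVP system; try more Fourier modes") from exc

    # residual of the ODE on a fine grid, with the product B*R formed
    # pointwise so that spectral truncation error is measured honestly
    nfine = 4 * nm
    grid = np.arange(nfine) * (TWO_PI / nfine)
    E = np.exp(1j * np.outer(grid, modes))
    b_vals = np.real(E @ b_hat)
    r_vals = np.real(E @ r_hat)
    prod_hat = np.fft.fft(b_vals * r_vals) / nfine
    k_fine = np.fft.fftfreq(nfine, d=1.0 / nfine)
    dbr = np.real(np.fft.ifft(1j * k_fine * prod_hat) * nfine)
    residual = np.max(np.abs(dbr + problem.drift * r_vals - problem.K))
    scale = max(1.0, float(np.max(np.abs(r_vals))), abs(problem.C1))
    if residual > 1e-8 * scale:
        raise RuntimeError(
            f"BVP residual {residual:.2e} exceeds tolerance; "
            "try more Fourier modes")
    density = _density_from_harmonics(r_hat, modes, n_bins, "bvp")
    if float(np.min(density.values)) < -1e-6:
        raise RuntimeError(
            "negative density in BVP solution (insufficient resolution "
            "or invalid problem)")
    return density


def closed_form_density(prc: PRCSpec, tau: float, c: float,
                        n_bins: int = 256,
                        allow_degenerate: bool = False) -> PhaseDifferenceDensity:
    """Closed-form stationary density of a homogeneous pair at omega = 0.

    For identical PRCs ``C2 = 0`` and ``g`` is even, so the BVP integrates
    immediately to ``R(phi) = N / (C1 - c g(phi))``; the density is
    symmetric and peaks at phi = 0.  At ``c = 1`` the density degenerates
    to a delta function; a (non-normalizable) limiting indicator is
    returned only when ``allow_degenerate`` is set.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"correlation c must lie in [0, 1], got {c}")
    g11 = filtered_correlation(prc, prc, tau)
    g = PeriodicFunction(2.0 * g11.values)
    C1 = 2.0 * float(g11.values[0])
    centers = PhaseDifferenceDensity.bin_centers_for(n_bins)
    denom = C1 - c * np.real(
        np.exp(1j * np.outer(centers, g.wavenumbers)) @ g.coefficients)
    if np.min(denom) <= 0.0:
        if not allow_degenerate or c < 1.0:
            raise DegenerateProblemError(
                "closed-form density degenerates (delta limit at c = 1)")
        values = np.zeros(n_bins)
        values[np.argmin(np.abs(centers))] = 1.0 / (TWO_PI / n_bins)
        return PhaseDifferenceDensity(centers, values, "closed_form")
    values = 1.0 / denom
    density = PhaseDifferenceDensity(centers, values, "closed_form")
    return density.normalized()


@dataclass
class SmallCExpansion:
    """First-order expansion R = 1/(2pi) + c R1(phi) + O(c^2)."""

    R0: float
    R1: PeriodicFunction
    op_slope: float  # OP ~ op_slope * c as c -> 0


def small_c_expansion(problem: StationaryProblem) -> SmallCExpansion:
    """Expand the BVP solution to first order in the input correlation.

    The zeroth order is uniform; the first-order balance in harmonics is
    ``R1_k = i k g_k / (2 pi (i k C1 - drift))`` and the linear OP slope
    is ``2 pi |R1_1|``, which for single-harmonic PRCs reproduces
    ``OP_jk = c/ (1 + (tau^2+1)(sin^2 a_j + sin^2 a_k))``.
    """
    g_hat = problem.g.coefficients
    ks = problem.g.wavenumbers
    mu = problem.drift
    r1_hat = np.zeros_like(g_hat)
    nonzero = ks != 0
    r1_hat[nonzero] = (1j * ks[nonzero] * g_hat[nonzero]
                       / (TWO_PI * (1j * ks[nonzero] * problem.C1 - mu)))
    R1 = PeriodicFunction.from_coefficients(r1_hat)
    op_slope = float(TWO_PI * np.abs(r1_hat[1]))
    return SmallCExpansion(R0=1.0 / TWO_PI, R1=R1, op_slope=op_slope)


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def export_problem_csv(problem: StationaryProblem, grid_path, sidecar_path) -> None:
    """Write the g grid as CSV plus a scalar sidecar (C1, C2, K, tau, c, omega)."""
    import csv

    with open(grid_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["phi_rad", "g_value"])
        writer.writerows(zip(problem.g.grid, problem.g.values))
    with open(sidecar_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["C1", "C2", "K", "tau", "c", "omega"])
        writer.writerow([problem.C1, problem.C2, problem.K,
                         problem.tau, problem.c, problem.omega])


def export_density_csv(density: PhaseDifferenceDensity, path) -> None:
    """Write a density as CSV ``phi_rad,density``."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["phi_rad", "density"])
        writer.writerows(zip(density.bin_centers, density.values))
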