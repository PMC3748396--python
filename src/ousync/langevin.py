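"""Langevin simulation of a phase-reduced oscillator pair.

The pair obeys

.. math::
    \\theta_1' = 1 + \\epsilon \\Delta_1(\\theta_1) x(t), \\qquad
    \\theta_2' = 1 + \\epsilon \\Delta_2(\\theta_2) y(t) + \\epsilon^2 \\omega,

with (x, y) a correlated Ornstein-Uhlenbeck pair (correlation ``c``, time
constant ``tau``).  The frequency detuning enters at order
:math:`\\epsilon^2` — the same order as the noise variance — which is the
regime in which noise correlations can compete with detuning at all.
Trajectories are integrated by Euler-Maruyama on a single shared time
grid, and the empirical stationary density of the wrapped phase
difference :math:`\\phi = \\theta_2 - \\theta_1` is estimated by
histogramming after a burn-in.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .prc import PRCSpec

TWO_PI = 2.0 * np.pi


def wrap_phase(phi):
    """Wrap angles to the half-open interval [-pi, pi); pi maps to -pi."""
    return np.mod(np.asarray(phi, dtype=float) + np.pi, TWO_PI) - np.pi


@dataclass
class PhasePairTrace:
    """Unwrapped phase trajectories of a noise-driven oscillator pair."""

    theta1: np.ndarray
    theta2: np.ndarray
    dt: float
    eps: float
    omega: float
    tau: float
    c: float
    burn_in: float
    seed: int

    @property
    def n(self) -> int:
        return self.theta1.size

    @property
    def burn_in_index(self) -> int:
        return min(int(round(self.burn_in / self.dt)), self.n)

    def phase_difference(self, include_burn_in: bool = False) -> np.ndarray:
        """Wrapped phase difference theta2 - theta1 in [-pi, pi)."""
        i0 = 0 if include_burn_in else self.burn_in_index
        return wrap_phase(self.theta2[i0:] - self.theta1[i0:])


@dataclass
class PhaseDifferenceDensity:
    """Normalized density R(phi) on a uniform grid over [-pi, pi)."""

    bin_centers: np.ndarray
    values: np.ndarray
    provenance: str  # {simulation | bvp | closed_form}

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_centers.shape != self.values.shape:
            raise ValueError("bin centers and values must align")

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def bin_width(self) -> float:
        return TWO_PI / self.n_bins

    @property
    def is_normalized(self) -> bool:
        return abs(float(np.sum(self.values)) * self.bin_width - 1.0) <= 1e-6

    def normalized(self) -> "PhaseDifferenceDensity":
        total = float(np.sum(self.values)) * self.bin_width
        return PhaseDifferenceDensity(self.bin_centers, self.values / total,
                                      self.provenance)

    @staticmethod
    def bin_centers_for(n_bins: int) -> np.ndarray:
        width = TWO_PI / n_bins
        return -np.pi + (np.arange(n_bins) + 0.5) * width


@njit(cache=False)
def _phase_pair_kernel(prc1_tab, prc2_tab, eps, omega, tau, dt, n_steps,
                       xi1, xi2, x0, y0, theta1, theta2):
    m = prc1_tab.shape[0] - 1  # tables carry a wrapped endpoint
    inv_bin = m / TWO_PI
    drift = 1.0 - dt / tau
    amp = np.sqrt(dt / tau)
    det = eps * eps * omega
    x = x0
    y = y0
    t1 = 0.0
    t2 = 0.0
    for i in range(n_steps):
        theta1[i] = t1
        theta2[i] = t2
        # linear table lookup of the PRCs at the wrapped phases
        p1 = (t1 % TWO_PI) * inv_bin
        j1 = int(p1)
        f1 = p1 - j1
        d1 = prc1_tab[j1] + (prc1_tab[j1 + 1] - prc1_tab[j1]) * f1
        p2 = (t2 % TWO_PI) * inv_bin
        j2 = int(p2)
        f2 = p2 - j2
        d2 = prc2_tab[j2] + (prc2_tab[j2 + 1] - prc2_tab[j2]) * f2
        t1 = t1 + dt * (1.0 + eps * d1 * x)
        t2 = t2 + dt * (1.0 + eps * d2 * y + det)
        x = drift * x + amp * xi1[i]
        y = drift * y + amp * xi2[i]
        if not (np.isfinite(t1) and np.isfinite(t2)
                and np.isfinite(x) and np.isfinite(y)):
            return i
    return -1


def _prc_table(prc: PRCSpec, n: int) -> np.ndarray:
    values = prc.sample(n)
    return np.concatenate([values, values[:1]])


def simulate_phase_pair(prc1: PRCSpec, prc2: PRCSpec, eps: float,
                        omega: float, tau: float, c: float,
                        dt: float = 0.05, T: float = 201000.0,
                        burn_in: float = 1000.0, seed: int = 0,
                        prc_grid: int = 4096) -> PhasePairTrace:
    """Euler-Maruyama integration of the phase pair under correlated OU drive.

    The OU pair is generated internally on the same time grid as the
    phases (no sub-stepping); PRCs are evaluated through a dense linear
    lookup table of size ``prc_grid``.
    """
    if eps < 0:
        raise ValueError("noise magnitude eps must be >= 0")
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"correlation c must lie in [0, 1], got {c}")
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be positive")

    n_steps = int(round(T / dt))
    ss = np.random.SeedSequence(seed)
    rng_common, rng_x, rng_y = (np.random.default_rng(s) for s in ss.spawn(3))
    sqc, sqp = np.sqrt(c), np.sqrt(1.0 - c)
    common = rng_common.standard_normal(n_steps + 1)
    xi1 = sqc * common + sqp * rng_x.standard_normal(n_steps + 1)
    xi2 = sqc * common + sqp * rng_y.standard_normal(n_steps + 1)
    sigma_st = np.sqrt(0.5)
    x0, y0 = sigma_st * xi1[0], sigma_st * xi2[0]

    theta1 = np.empty(n_steps)
    theta2 = np.empty(n_steps)
    bad = _phase_pair_kernel(_prc_table(prc1, prc_grid),
                             _prc_table(prc2, prc_grid),
                             float(eps), float(omega), float(tau), float(dt),
                             n_steps, xi1[1:], xi2[1:], x0, y0,
                             theta1, theta2)
    if bad >= 0:
        raise RuntimeError(f"phase integration blew up at step {bad}")
    return PhasePairTrace(theta1=theta1, theta2=theta2, dt=dt, eps=eps,
                          omega=omega, tau=tau, c=c, burn_in=burn_in,
                          seed=seed)


def empirical_density(trace: PhasePairTrace,
                      n_bins: int = 100) -> PhaseDifferenceDensity:
    """Normalized histogram of the wrapped phase difference after burn-in."""
    phi = trace.phase_difference()
    if phi.size == 0:
        raise ValueError("no samples remain after burn-in")
    return density_from_samples(phi, n_bins)


def density_from_samples(phi: np.ndarray,
                         n_bins: int = 100) -> PhaseDifferenceDensity:
    """Histogram wrapped phase-difference samples into a normalized density."""
    phi = wrap_phase(phi)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(phi, bins=edges)
    width = TWO_PI / n_bins
    values = counts / (phi.size * width)
    return PhaseDifferenceDensity(PhaseDifferenceDensity.bin_centers_for(n_bins),
                                  values, "simulation")
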