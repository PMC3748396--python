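"""Pairs of partially correlated Ornstein-Uhlenbeck (OU) processes.

Each marginal follows ``x' = -x/tau + xi_x/sqrt(tau)`` where ``xi_x`` is
unit white noise; the white-noise drives of the two processes have
cross-intensity ``c`` (``<xi_x(t) xi_y(t')> = c delta(t-t')``).  The
stationary statistics are Gaussian with the amplitude-fixed normalization
used throughout: variance ``1/2`` for every tau, autocorrelation
``(1/2) exp(-|s|/tau)`` (mass tau).  Shrinking tau whitens the noise while
keeping its amplitude fixed, which is the experimentally natural dial for
"faster" input fluctuations.

Correlation is induced by shared/private white-noise increments,
``xi_x = sqrt(c) xi_common + sqrt(1-c) xi_private``, the minimal symmetric
construction with the stated cross-intensity.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class NoisePairTrace:
    """Sampled paths of two correlated OU processes."""

    x: np.ndarray
    y: np.ndarray
    dt: float
    tau: float
    c: float
    seed: int

    def __post_init__(self):
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite values in OU trace")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) * self.dt


def _validate(tau: float, c: float, dt: float) -> None:
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"correlation c must lie in [0, 1], got {c}")
    if tau <= 0:
        raise ValueError(f"time constant tau must be positive, got {tau}")
    if dt <= 0:
        raise ValueError(f"time step dt must be positive, got {dt}")
    if dt > tau / 5:
        warnings.warn(f"dt={dt} is coarse relative to tau={tau} "
                      "(recommend dt <= tau/5)", stacklevel=3)


def correlated_increments(rng_common, rng_x, rng_y, c: float, n: int):
    """Unit-intensity white-noise increments with cross-intensity c."""
    common = rng_common.standard_normal(n)
    sqc, sqp = np.sqrt(c), np.sqrt(1.0 - c)
    xi_x = sqc * common + sqp * rng_x.standard_normal(n)
    xi_y = sqc * common + sqp * rng_y.standard_normal(n)
    return xi_x, xi_y


def simulate_ou_pair(tau: float, c: float, dt: float, T: float,
                     seed: int = 0, exact: bool = False) -> NoisePairTrace:
    """Euler-Maruyama paths of a correlated OU pair.

    Initial conditions are drawn from the stationary Gaussian so no
    transient discard is needed.  With ``exact=True`` the exact
    exponential (Gillespie) update replaces Euler-Maruyama as a
    cross-check mode.  With ``c=1`` and identical seed the two paths are
    identical.
    """
    _validate(tau, c, dt)
    n = int(round(T / dt))
    ss = np.random.SeedSequence(seed)
    rng_common, rng_x, rng_y = (np.random.default_rng(s) for s in ss.spawn(3))

    xi_x, xi_y = correlated_increments(rng_common, rng_x, rng_y, c, n + 1)
    sigma_st = np.sqrt(0.5)
    x = np.empty(n)
    y = np.empty(n)
    # stationary start built from the same shared/private decomposition
    x[0] = sigma_st * xi_x[0]
    y[0] = sigma_st * xi_y[0]

    if exact:
        decay = np.exp(-dt / tau)
        amp = sigma_st * np.sqrt(1.0 - decay * decay)
        for i in range(1, n):
            x[i] = decay * x[i - 1] + amp * xi_x[i]
            y[i] = decay * y[i - 1] + amp * xi_y[i]
    else:
        drift = 1.0 - dt / tau
        amp = np.sqrt(dt / tau)
        for i in range(1, n):
            x[i] = drift * x[i - 1] + amp * xi_x[i]
            y[i] = drift * y[i - 1] + amp * xi_y[i]
    return NoisePairTrace(x=x, y=y, dt=dt, tau=tau, c=c, seed=seed)


def ou_stationary_moments(tau: float):
    """Stationary variance and autocorrelation function of the OU process.

    Returns ``(variance, acf)`` with ``variance = 1/2`` and
    ``acf(s) = (1/2) exp(-|s|/tau)``; the kernel mass is tau.  The theory
    module consumes the unit-mass (normalized) version of this kernel and
    carries the mass tau in its detuning coefficient.
    """
    if tau <= 0:
        raise ValueError(f"time constant tau must be positive, got {tau}")
    variance = 0.5

    def acf(s):
        return variance * np.exp(-np.abs(np.asarray(s, dtype=float)) / tau)

    return variance, acf
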