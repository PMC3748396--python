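"""Morris-Lecar biophysical layer.

A two-variable conductance model (voltage V, recovery w)

.. math::
    C_m \\dot V = I - g_L (V - V_L) - g_K w (V - V_K)
                  - g_{Ca} m_\\infty(V) (V - V_{Ca}) + \\sigma x(t)

.. math::
    \\dot w = \\phi_w\\,[w_\\infty(V) - w]\\,/\\,\\tau_w(V)

with ``m_inf(V) = 0.5 (1 + tanh((V-V_a)/V_b))``,
``w_inf(V) = 0.5 (1 + tanh((V-V_c)/V_d))`` and
``tau_w(V) = 1/cosh((V-V_c)/(2 V_d))``.  Depending on parameters the
onset of repetitive firing is through a Hopf bifurcation (PRC with a
substantial negative lobe) or a SNIC bifurcation (predominantly
non-negative PRC).

This module finds the noise-free limit cycle and its period, computes the
infinitesimal PRC as the voltage component of the periodic solution of
the adjoint (transposed-Jacobian) system, simulates pairs of cells under
partially correlated OU current noise, and reconstructs phases from
voltage traces via the Hilbert transform remapped through the noise-free
cycle so that phase advances uniformly in time.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq
from scipy.signal import hilbert

from .langevin import PhaseDifferenceDensity, density_from_samples, wrap_phase
from .prc import PRCSpec, make_tabulated

TWO_PI = 2.0 * np.pi


class NoOscillationError(RuntimeError):
    """The deterministic model does not spike repetitively."""


class NotConvergedError(RuntimeError):
    """Period or adjoint iteration failed to settle."""


@dataclass(frozen=True)
class MLParameters:
    """Morris-Lecar parameters (mV, mS/cm^2, uF/cm^2, uA/cm^2, 1/ms)."""

    i_app: float
    phi_w: float
    v_k: float = -84.0
    v_l: float = -60.0
    v_ca: float = 120.0
    g_k: float = 8.0
    g_l: float = 2.0
    g_ca: float = 4.0
    c_m: float = 20.0
    v_a: float = -1.2
    v_b: float = 18.0
    v_c: float = 2.0
    v_d: float = 30.0

    def __post_init__(self):
        if min(self.g_k, self.g_l, self.g_ca) < 0:
            raise ValueError("conductances must be non-negative")
        if self.c_m <= 0:
            raise ValueError("membrane capacitance must be positive")


#: same-frequency pair with different PRCs (both spike with a 73.1 ms
#: period although currents and recovery rates differ)
SAME_FREQ_A = MLParameters(i_app=120.0, phi_w=0.04)
SAME_FREQ_B = MLParameters(i_app=110.0, phi_w=0.04616)

#: Hopf-regime cell: canonical Hopf geometry (g_Ca = 4.4); its noise-free
#: period computes to 91.2 ms
HOPF_REGIME = MLParameters(i_app=95.0, phi_w=0.04, g_ca=4.4)


def snic_parameters(period_ms: Optional[float] = None) -> MLParameters:
    """SNIC-regime parameter set tuned to a target period.

    Synthetic reconstruction: the recovery-gate geometry uses the
    canonical SNIC values (V_c = 12 mV, V_d = 17.4 mV, phi_w = 1/15) and
    the applied current is tuned so the noise-free period matches
    ``period_ms`` (default: the Hopf-regime cell's period, giving the
    same-frequency Hopf/SNIC comparison pair).
    """
    if period_ms is None:
        period_ms = find_limit_cycle(HOPF_REGIME, rtol=1e-8, atol=1e-8).period
    base = MLParameters(i_app=46.0, phi_w=1.0 / 15.0, v_c=12.0, v_d=17.4)
    return tune_current_for_period(base, period_ms, bracket=(41.5, 70.0))


def phase_time_constant(tau_ms: float, period_ms: float) -> float:
    """Rescale a noise time constant from ms to 2pi-period phase units.

    The amplitude-fixed OU process keeps its stationary variance under
    time rescaling, so only tau needs conversion when passing ML-derived
    quantities to the phase-reduced theory.
    """
    return TWO_PI * tau_ms / period_ms


def m_inf(V, p: MLParameters):
    return 0.5 * (1.0 + np.tanh((V - p.v_a) / p.v_b))


def w_inf(V, p: MLParameters):
    return 0.5 * (1.0 + np.tanh((V - p.v_c) / p.v_d))


def tau_w(V, p: MLParameters):
    return 1.0 / np.cosh((V - p.v_c) / (2.0 * p.v_d))


def ml_rhs(t, state, p: MLParameters):
    V, w = state
    dv = (p.i_app - p.g_l * (V - p.v_l) - p.g_k * w * (V - p.v_k)
          - p.g_ca * m_inf(V, p) * (V - p.v_ca)) / p.c_m
    dw = p.phi_w * (w_inf(V, p) - w) / tau_w(V, p)
    return [dv, dw]


def ml_jacobian(V, w, p: MLParameters):
    sech2_m = 1.0 / np.cosh((V - p.v_a) / p.v_b) ** 2
    dm = 0.5 * sech2_m / p.v_b
    a11 = (-p.g_l - p.g_k * w - p.g_ca * (dm * (V - p.v_ca) + m_inf(V, p))) / p.c_m
    a12 = -p.g_k * (V - p.v_k) / p.c_m
    arg = (V - p.v_c) / (2.0 * p.v_d)
    sech2_w = 1.0 / np.cosh((V - p.v_c) / p.v_d) ** 2
    dwinf = 0.5 * sech2_w / p.v_d
    a21 = p.phi_w * (dwinf * np.cosh(arg)
                     + (w_inf(V, p) - w) * np.sinh(arg) / (2.0 * p.v_d))
    a22 = -p.phi_w * np.cosh(arg)
    return np.array([[a11, a12], [a21, a22]])


@dataclass
class MLCycle:
    """Noise-free limit cycle sampled on a uniform time grid over one period."""

    period: float
    t: np.ndarray       # uniform grid on [0, period)
    V: np.ndarray
    w: np.ndarray
    params: MLParameters
    adjoint_v: Optional[np.ndarray] = None  # filled by adjoint_prc

    @property
    def n(self) -> int:
        return self.t.size

    def interpolant(self):
        """Periodic cubic interpolant of (V, w) over one period."""
        t = np.concatenate([self.t, [self.period]])
        V = np.concatenate([self.V, [self.V[0]]])
        w = np.concatenate([self.w, [self.w[0]]])
        return (CubicSpline(t, V, bc_type="periodic"),
                CubicSpline(t, w, bc_type="periodic"))


_SPIKE_THRESHOLD = 0.0  # mV, upward crossing defines phase 0


def find_limit_cycle(params: MLParameters, dt: float = 0.05,
                     transient: float = 2000.0, n_points: int = 1024,
                     rtol: float = 1e-10, atol: float = 1e-10) -> MLCycle:
    """Locate the stable limit cycle and its period.

    Integrates past the transient, measures the period from successive
    upward crossings of the 0 mV voltage threshold, and resamples one
    cycle onto a uniform grid of ``n_points``.  Raises
    ``NoOscillationError`` for fewer than 3 crossings and
    ``NotConvergedError`` if consecutive periods differ by more than
    0.1%.
    """
    y0 = [params.v_l, float(w_inf(params.v_l, params))]
    settle = solve_ivp(ml_rhs, (0.0, transient), y0, args=(params,),
                       rtol=rtol, atol=atol, dense_output=False,
                       method="LSODA")
    if not settle.success:
        raise RuntimeError(f"transient integration failed: {settle.message}")

    def upward(t, y, p):
        return y[0] - _SPIKE_THRESHOLD
    upward.terminal = False
    upward.direction = 1.0

    horizon = 4000.0
    sol = solve_ivp(ml_rhs, (0.0, horizon), settle.y[:, -1], args=(params,),
                    rtol=rtol, atol=atol, events=upward, method="LSODA",
                    dense_output=True)
    crossings = sol.t_events[0]
    if crossings.size < 3:
        raise NoOscillationError(
            f"no sustained oscillation (found {crossings.size} spikes "
            f"in {horizon} ms)")
    periods = np.diff(crossings)
    drift = np.abs(np.diff(periods)) / periods[:-1]
    if np.max(drift[-5:] if drift.size > 5 else drift) > 1e-3:
        raise NotConvergedError("period drift between consecutive cycles "
                                "exceeds 0.1%")
    period = float(np.mean(periods[-min(10, periods.size):]))

    # resample one cycle starting at a threshold crossing
    t0 = crossings[-2]
    ts = t0 + np.arange(n_points) * (period / n_points)
    states = sol.sol(ts)
    closure = sol.sol([t0, t0 + period])
    amp = np.ptp(states[0])
    if np.linalg.norm(closure[:, 1] - closure[:, 0]) > 1e-6 * amp:
        raise NotConvergedError("cycle does not close to tolerance")
    return MLCycle(period=period, t=ts - t0, V=states[0], w=states[1],
                   params=params)


def tune_current_for_period(params: MLParameters, target_ms: float,
                            bracket=(80.0, 160.0)) -> MLParameters:
    """Adjust the applied current so the noise-free period hits a target."""

    def gap(i_app):
        return find_limit_cycle(replace(params, i_app=i_app),
                                rtol=1e-8, atol=1e-8).period - target_ms

    i_star = brentq(gap, *bracket, xtol=1e-6)
    return replace(params, i_app=float(i_star))


def adjoint_prc(cycle: MLCycle, params: Optional[MLParameters] = None,
                max_periods: int = 50, tol: float = 1e-6,
                n_phases: int = 256) -> PRCSpec:
    """Infinitesimal PRC from the adjoint of the linearized flow.

    The adjoint system ``Z' = -J(X0(t))^T Z`` is integrated backward in
    time over repeated periods until periodic (successive-period relative
    change below ``tol``), then normalized so ``Z . F(X0) = 1`` at every
    point (phase measured in time units).  The returned tabulated PRC is
    the voltage component expressed in radians of phase shift per unit
    injected charge density: ``Delta(theta) = (2 pi / T) Z_V(theta)/C_m``,
    on phases [0, 2pi) with the spike at 0.
    """
    p = params or cycle.params
    T = cycle.period
    v_spl, w_spl = cycle.interpolant()

    def backward_rhs(s, z):
        t = (-s) % T
        J = ml_jacobian(float(v_spl(t)), float(w_spl(t)), p)
        return J.T @ z

    z = np.array([1.0, 0.0])
    prev = None
    for _ in range(max_periods):
        sol = solve_ivp(backward_rhs, (0.0, T), z, rtol=1e-11, atol=1e-12,
                        method="LSODA")
        z = sol.y[:, -1]
        scale = np.linalg.norm(z)
        if scale == 0 or not np.all(np.isfinite(z)):
            raise NotConvergedError("adjoint iteration collapsed")
        z = z / scale
        if prev is not None and np.max(np.abs(z - prev)) < tol:
            break
        prev = z.copy()
    else:
        raise NotConvergedError(
            f"adjoint not periodic after {max_periods} periods")

    # one converged backward pass sampled on the cycle grid
    s_grid = np.linspace(0.0, T, n_phases, endpoint=False)
    sol = solve_ivp(backward_rhs, (0.0, T), z, rtol=1e-11, atol=1e-12,
                    t_eval=s_grid, method="LSODA")
    zs = sol.y[:, ::-1]          # backward samples at t = T - s
    ts = (T - s_grid)[::-1] % T  # = T/n, 2T/n, ..., 0 -> reorder to [0, T)
    order = np.argsort(ts)
    ts = ts[order]
    zs = zs[:, order]

    # normalize so Z . F = 1 along the whole cycle
    F = np.array([ml_rhs(0.0, (v, w), p)
                  for v, w in zip(v_spl(ts), w_spl(ts))]).T
    zdotf = np.einsum("ij,ij->j", zs, F)
    mean_zf = float(np.mean(zdotf))
    if abs(mean_zf) < 1e-14:
        raise NotConvergedError("degenerate adjoint normalization")
    zs = zs / mean_zf
    if np.max(np.abs(zdotf / mean_zf - 1.0)) > 1e-5:
        raise NotConvergedError("Z . F not constant along the cycle")

    phases = ts * (TWO_PI / T)
    delta_v = (TWO_PI / T) * zs[0] / p.c_m
    prc = make_tabulated(phases, delta_v)
    cycle.adjoint_v = delta_v
    return prc


def direct_pulse_prc(params: MLParameters, cycle: MLCycle,
                     n_phases: int = 32, amplitude: float = 2.0,
                     duration: float = 0.5, n_periods: int = 12) -> PRCSpec:
    """Finite-perturbation PRC oracle from brief current pulses.

    A square pulse of ``amplitude`` uA/cm^2 for ``duration`` ms is applied
    at each probe phase; the asymptotic spike-time shift is converted to
    radians and normalized by the injected charge density
    ``amplitude * duration`` to match the adjoint convention.  The table
    phase is reported at the pulse center (onset plus half the duration),
    which cancels the first-order smearing of the finite pulse width.
    """
    T = cycle.period
    v_spl, w_spl = cycle.interpolant()
    horizon = n_periods * T

    def upward(t, y, p):
        return y[0] - _SPIKE_THRESHOLD
    upward.terminal = False
    upward.direction = 1.0

    def late_spikes(y0, pars, t0=0.0):
        sol = solve_ivp(ml_rhs, (t0, horizon), y0, args=(pars,),
                        rtol=1e-10, atol=1e-10, events=upward,
                        method="LSODA")
        return sol.t_events[0]

    ref_spikes = late_spikes([cycle.V[0], cycle.w[0]], params)
    phases = np.arange(n_phases) * (TWO_PI / n_phases)
    shifts = np.empty(n_phases)
    pulsed = replace(params, i_app=params.i_app + amplitude)
    for i, ph in enumerate(phases):
        t_on = ph * T / TWO_PI
        start = [float(v_spl(t_on)), float(w_spl(t_on))]
        during = solve_ivp(ml_rhs, (t_on, t_on + duration), start,
                           args=(pulsed,), rtol=1e-10, atol=1e-10,
                           method="LSODA")
        spikes = late_spikes(during.y[:, -1], params, t0=t_on + duration)
        # asymptotic spike advance relative to the unperturbed train,
        # folded to the nearest period (advance = positive shift)
        t_pert = spikes[-1]
        t_ref = ref_spikes[np.argmin(np.abs(ref_spikes - t_pert))]
        delta_t = t_ref - t_pert
        delta_t -= T * np.round(delta_t / T)
        shifts[i] = TWO_PI * delta_t / T
    # radians per unit injected charge density (matches the adjoint scale)
    center_phases = phases + np.pi * duration / T
    return make_tabulated(center_phases, shifts / (amplitude * duration))


# ---------------------------------------------------------------------------
# stochastic pair simulation
# ---------------------------------------------------------------------------

@dataclass
class MLPairTrace:
    """Euler-Maruyama voltage/recovery traces of two noise-driven cells."""

    V1: np.ndarray
    w1: np.ndarray
    V2: np.ndarray
    w2: np.ndarray
    dt: float
    sigma: float
    tau: float
    c: float
    seed: int

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.V1.size) * self.dt


@njit(cache=False)
def _ml_pair_kernel(n_steps, dt, sigma, tau, xi1, xi2, y0, out,
                    i1, i2, phi1, phi2,
                    v_k, v_l, v_ca, g_k, g_l, g_ca, c_m, v_a, v_b, v_c, v_d):
    V1, w1, V2, w2 = y0
    x = 0.0
    y = 0.0
    drift = 1.0 - dt / tau
    amp = np.sqrt(dt / tau)
    for i in range(n_steps):
        out[0, i] = V1
        out[1, i] = w1
        out[2, i] = V2
        out[3, i] = w2
        minf1 = 0.5 * (1.0 + np.tanh((V1 - v_a) / v_b))
        winf1 = 0.5 * (1.0 + np.tanh((V1 - v_c) / v_d))
        cosh1 = np.cosh((V1 - v_c) / (2.0 * v_d))
        minf2 = 0.5 * (1.0 + np.tanh((V2 - v_a) / v_b))
        winf2 = 0.5 * (1.0 + np.tanh((V2 - v_c) / v_d))
        cosh2 = np.cosh((V2 - v_c) / (2.0 * v_d))
        dv1 = (i1 - g_l * (V1 - v_l) - g_k * w1 * (V1 - v_k)
               - g_ca * minf1 * (V1 - v_ca) + sigma * x) / c_m
        dv2 = (i2 - g_l * (V2 - v_l) - g_k * w2 * (V2 - v_k)
               - g_ca * minf2 * (V2 - v_ca) + sigma * y) / c_m
        V1 += dt * dv1
        w1 += dt * phi1 * (winf1 - w1) * cosh1
        V2 += dt * dv2
        w2 += dt * phi2 * (winf2 - w2) * cosh2
        x = drift * x + amp * xi1[i]
        y = drift * y + amp * xi2[i]
        if not (np.isfinite(V1) and np.isfinite(V2)):
            return i
    return -1


def simulate_ml_pair(params1: MLParameters, params2: MLParameters,
                     sigma: float, tau: float, c: float,
                     dt: float = 0.01, T: float = 20000.0,
                     seed: int = 0) -> MLPairTrace:
    """Simulate two Morris-Lecar cells driven by a correlated OU pair.

    Cell 1 receives ``sigma * x`` and cell 2 ``sigma * y`` where (x, y)
    are OU processes with correlation ``c`` and time constant ``tau`` (ms).
    Both cells must share the passive/channel parameters of ``params1``
    except current and recovery rate, which may differ.
    """
    if dt > 0.05:
        raise ValueError("dt must be <= 0.05 ms for the stochastic ML pair")
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"correlation c must lie in [0, 1], got {c}")
    n_steps = int(round(T / dt))
    ss = np.random.SeedSequence(seed)
    rng_common, rng_x, rng_y = (np.random.default_rng(s) for s in ss.spawn(3))
    sqc, sqp = np.sqrt(c), np.sqrt(1.0 - c)
    common = rng_common.standard_normal(n_steps)
    xi1 = sqc * common + sqp * rng_x.standard_normal(n_steps)
    xi2 = sqc * common + sqp * rng_y.standard_normal(n_steps)

    p = params1
    y0 = np.array([p.v_l + 20.0, 0.2, p.v_l + 20.0, 0.2])
    out = np.empty((4, n_steps))
    bad = _ml_pair_kernel(n_steps, dt, float(sigma), float(tau), xi1, xi2,
                          y0, out,
                          params1.i_app, params2.i_app,
                          params1.phi_w, params2.phi_w,
                          p.v_k, p.v_l, p.v_ca, p.g_k, p.g_l, p.g_ca,
                          p.c_m, p.v_a, p.v_b, p.v_c, p.v_d)
    if bad >= 0:
        raise RuntimeError(f"Morris-Lecar integration blew up at step {bad}")
    return MLPairTrace(V1=out[0], w1=out[1], V2=out[2], w2=out[3],
                       dt=dt, sigma=sigma, tau=tau, c=c, seed=seed)


# ---------------------------------------------------------------------------
# Hilbert-phase reconstruction
# ---------------------------------------------------------------------------

def _reference_phase_map(cycle: MLCycle):
    """Monotone lookup from Hilbert-transform angle to temporal phase.

    Built on the noise-free cycle: the analytic-signal angle of a few
    tiled periods is unwrapped, the middle period is kept, and the map
    (HT angle -> elapsed-time fraction x 2pi) is returned as interpolation
    nodes.
    """
    reps = 8
    v = np.tile(cycle.V - np.mean(cycle.V), reps)
    psi = np.unwrap(np.angle(hilbert(v)))
    n = cycle.n
    mid = psi[(reps // 2) * n:(reps // 2 + 1) * n]
    if np.any(np.diff(mid) <= 0):
        raise ValueError("non-monotone Hilbert phase on the reference cycle")
    if not np.isclose(mid[-1] - mid[0], TWO_PI, rtol=0.05):
        raise ValueError("reference Hilbert phase does not advance 2pi "
                         "per period")
    # lookup nodes: HT angle relative to the spike (0 .. 2pi, closed) ->
    # temporal phase (0 .. 2pi, closed)
    psi_spike = float(np.angle(np.exp(1j * mid[0])))
    rel_nodes = np.append(mid - mid[0], TWO_PI)
    temporal_nodes = np.append(np.arange(n) * (TWO_PI / n), TWO_PI)
    return psi_spike, rel_nodes, temporal_nodes


def hilbert_phase(voltage: np.ndarray, cycle: MLCycle) -> np.ndarray:
    """Temporal phase in [0, 2pi) reconstructed from a voltage trace.

    The analytic-signal angle of the mean-subtracted trace is remapped
    through the monotone lookup built on the noise-free limit cycle, so
    the noise-free cycle itself has uniformly advancing phase.
    """
    psi_spike, rel_nodes, temporal_nodes = _reference_phase_map(cycle)
    psi = np.angle(hilbert(np.asarray(voltage) - np.mean(voltage)))
    rel = np.mod(psi - psi_spike, TWO_PI)
    return np.mod(np.interp(rel, rel_nodes, temporal_nodes), TWO_PI)


def ml_phase_difference_density(trace: MLPairTrace, cycle1: MLCycle,
                                cycle2: MLCycle, n_bins: int = 100,
                                burn_in: float = 2000.0) -> PhaseDifferenceDensity:
    """Phase-difference density of an ML pair via Hilbert phases."""
    i0 = min(int(round(burn_in / trace.dt)), trace.V1.size)
    th1 = hilbert_phase(trace.V1[i0:], cycle1)
    th2 = hilbert_phase(trace.V2[i0:], cycle2)
    return density_from_samples(wrap_phase(th2 - th1), n_bins)
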