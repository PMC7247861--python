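"""Batch growth simulation and process metrics.

A batch (discontinuous) cultivation follows the single ODE

    dc_X/dt = mu(q_ph(c_X), T(t)) * c_X,

where q_ph is recomputed from the instantaneous biomass concentration at
every step.  Two integrators are provided: a fixed-step explicit Euler
scheme (matching the estimation replays) and an adaptive, stiff-capable
scheme (LSODA) used for optimization and verification runs.

Also here: volumetric biomass productivity Pr = (c_end - c_start)/duration
and the (M)APE accuracy metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import GrowthParameters, ctmi_phi, specific_growth_rate
from .reactor import ReactorGeometry, photon_supply_density

__all__ = [
    "TemperatureProfile",
    "SimulationResult",
    "simulate_batch",
    "euler_at_times",
    "batch_productivity_many",
    "productivity",
    "mape",
]


@dataclass(frozen=True)
class TemperatureProfile:
    """Piecewise-linear temperature signal T(t), or a constant.

    ``times`` [d] must be strictly increasing; evaluation outside the
    record holds the boundary values (no extrapolation beyond them).
    """

    times: np.ndarray | None
    values: np.ndarray | float

    def __post_init__(self) -> None:
        if self.times is not None:
            t = np.asarray(self.times, dtype=float)
            v = np.asarray(self.values, dtype=float)
            if t.ndim != 1 or t.size != v.size:
                raise ValueError("times and values must be 1-D and equally long")
            if np.any(np.diff(t) <= 0):
                raise ValueError("profile times must be strictly increasing")
            if not np.all(np.isfinite(v)):
                raise ValueError("profile values must be finite")
            object.__setattr__(self, "times", t)
            object.__setattr__(self, "values", v)

    @classmethod
    def constant(cls, T: float) -> "TemperatureProfile":
        return cls(times=None, values=float(T))

    @classmethod
    def from_samples(cls, times, values) -> "TemperatureProfile":
        return cls(times=np.asarray(times, float), values=np.asarray(values, float))

    def __call__(self, t):
        if self.times is None:
            return self.values if np.isscalar(t) else np.full(np.shape(t), self.values)
        return np.interp(t, self.times, self.values)


@dataclass
class SimulationResult:
    """Trajectory of a batch simulation."""

    times: np.ndarray  # d
    c_x: np.ndarray  # g/L
    q_ph: np.ndarray  # mol_ph g^-1 d^-1
    mu: np.ndarray  # 1/d
    temperature: np.ndarray  # deg C

    def __post_init__(self) -> None:
        n = len(self.times)
        if not all(len(a) == n for a in (self.c_x, self.q_ph, self.mu, self.temperature)):
            raise ValueError("trajectory arrays must have equal length")
        if np.any(self.c_x <= 0):
            raise ValueError("biomass concentration must stay positive")

    @property
    def productivity(self) -> float:
        """Pr over the simulated span [g L^-1 d^-1]."""
        return productivity(self.c_x[0], self.c_x[-1], self.times[-1] - self.times[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_d": self.times,
                "c_X_gpl": self.c_x,
                "q_ph": self.q_ph,
                "mu": self.mu,
                "T_C": self.temperature,
            }
        )


def _as_profile(temperature) -> TemperatureProfile:
    if isinstance(temperature, TemperatureProfile):
        return temperature
    if np.isscalar(temperature):
        return TemperatureProfile.constant(float(temperature))
    raise TypeError("temperature must be a TemperatureProfile or a scalar")


def simulate_batch(
    c_X0: float,
    t_end: float,
    temperature_profile,
    params: GrowthParameters,
    geometry: ReactorGeometry,
    method: str = "adaptive",
    step: float = 0.01,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_out: int = 201,
) -> SimulationResult:
    """Integrate the batch growth ODE from ``c_X0`` over ``t_end`` days.

    ``method='euler'`` uses a fixed step (``step`` [d], reporting every
    step); ``method='adaptive'`` uses LSODA with the given tolerances,
    reporting on an ``n_out``-point grid.
    """
    if not c_X0 > 0:
        raise ValueError("c_X0 must be positive")
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    profile = _as_profile(temperature_profile)
    S = photon_supply_density(geometry)

    if method == "euler":
        if not step > 0:
            raise ValueError("euler step must be positive")
        n = max(1, int(np.ceil(t_end / step)))
        times = np.linspace(0.0, t_end, n + 1)
        temps = np.asarray(profile(times), dtype=float)
        c = np.empty(n + 1)
        c[0] = c_X0
        phi = ctmi_phi(temps, params)
        mu_max, K, m = params.mu_max, params.K_S_ph, params.m_ph
        for i in range(n):
            q = S / c[i]
            mu_i = mu_max * (q - m) / (q - m + K) * phi[i]
            c[i + 1] = c[i] * (1.0 + (times[i + 1] - times[i]) * mu_i)
    elif method == "adaptive":
        def rhs(t, y):
            q = S / y[0]
            return [specific_growth_rate(q, float(profile(t)), params) * y[0]]

        times = np.linspace(0.0, t_end, n_out)
        sol = solve_ivp(
            rhs, (0.0, t_end), [c_X0], method="LSODA", t_eval=times,
            rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        c = sol.y[0]
        temps = np.asarray(profile(times), dtype=float)
    else:
        raise ValueError(f"unknown method {method!r}")

    q_traj = S / c
    mu_traj = specific_growth_rate(q_traj, temps, params)
    return SimulationResult(times=times, c_x=c, q_ph=q_traj, mu=mu_traj, temperature=temps)


def _euler_core(c0, dt, phi, S, mu_max, K, m):
    n = dt.size
    c = np.empty(n + 1)
    c[0] = c0
    ci = c0
    for i in range(n):
        net = S / ci - m
        ci = ci * (1.0 + dt[i] * mu_max * net / (net + K) * phi[i])
        if ci <= 0.0:  # crossed zero: abandoned, caller penalizes
            c[i + 1 :] = np.nan
            return c
        c[i + 1] = ci
    return c


try:  # compiled kernel: the estimation objective calls this ~10^4 times
    from numba import njit

    _euler_core = njit(cache=False, fastmath=False)(_euler_core)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    pass


class EulerReplay:
    """Precomputed fixed-step Euler replay of one experiment.

    Refines each sampling interval into equal substeps no larger than
    ``max_step`` and interpolates temperature linearly onto the refined
    grid once; each call then only evaluates the CTMI factor for the
    trial parameters and runs the scalar Euler recursion.
    """

    def __init__(self, sample_times, sample_temps, S, max_step=0.01):
        t = np.asarray(sample_times, dtype=float)
        grids = [np.array([t[0]])]
        for a, b in zip(t[:-1], t[1:]):
            k = max(1, int(np.ceil((b - a) / max_step)))
            grids.append(np.linspace(a, b, k + 1)[1:])
        self.grid = np.concatenate(grids)
        self.temps = np.interp(self.grid, t, np.asarray(sample_temps, dtype=float))
        self.dt = np.diff(self.grid)
        self.idx = np.searchsorted(self.grid, t)
        self.S = float(S)

    def __call__(self, c_X0, params_vector) -> np.ndarray:
        mu_max, K, m, t_min, t_opt, t_max = (float(v) for v in params_vector[:6])
        T = self.temps
        num = (T - t_max) * (T - t_min) ** 2
        den = (t_opt - t_min) * (
            (t_opt - t_min) * (T - t_opt) - (t_opt - t_max) * (t_opt + t_min - 2.0 * T)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where((T > t_min) & (T < t_max), num / den, 0.0)
        c = _euler_core(float(c_X0), self.dt, phi, self.S, mu_max, K, m)
        return c[self.idx]


def euler_at_times(
    c_X0: float,
    sample_times: np.ndarray,
    sample_temps: np.ndarray,
    params_vector: np.ndarray,
    S: float,
    max_step: float = 0.01,
) -> np.ndarray:
    """Euler-integrate the growth ODE and return c_X at ``sample_times``.

    ``params_vector`` is (mu_max, K_S_ph, m_ph, T_min, T_opt, T_max) as
    raw floats (no validity checks here — the estimation objective
    penalizes invalid triples), ``S`` the volumetric photon supply
    [mol_ph L^-1 d^-1].  One-shot wrapper around :class:`EulerReplay`.
    """
    return EulerReplay(sample_times, sample_temps, S, max_step)(c_X0, params_vector)


def batch_productivity_many(
    theta: np.ndarray,
    c_X0,
    t_cyc: float,
    T,
    geometry: ReactorGeometry,
    step: float = 0.01,
) -> np.ndarray:
    """Vectorized batch productivity at constant temperature.

    Integrates the growth ODE with fixed-step Euler simultaneously for
    many parameter vectors / initial concentrations (broadcast against
    each other).  ``theta`` has shape (n, 6) in the canonical parameter
    order; ``c_X0`` and ``T`` scalars or length-n arrays.  Returns Pr
    [g L^-1 d^-1] per sample.  Used by the Sobol sensitivity scan and the
    productivity surfaces, where hundreds of thousands of simulations are
    needed.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    mu_max, K, m = theta[:, 0], theta[:, 1], theta[:, 2]
    t_min, t_opt, t_max = theta[:, 3], theta[:, 4], theta[:, 5]
    T = np.asarray(T, dtype=float)
    num = (T - t_max) * (T - t_min) ** 2
    den = (t_opt - t_min) * (
        (t_opt - t_min) * (T - t_opt) - (t_opt - t_max) * (t_opt + t_min - 2.0 * T)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where((T > t_min) & (T < t_max), num / den, 0.0)
    S = photon_supply_density(geometry)
    n = max(1, int(np.ceil(t_cyc / step)))
    dt = t_cyc / n
    c0_arr = np.asarray(c_X0, dtype=float)
    shape = np.broadcast_shapes(mu_max.shape, c0_arr.shape, phi.shape)
    start = np.broadcast_to(c0_arr, shape)
    rate = np.broadcast_to(mu_max * phi, shape)
    m_b = np.broadcast_to(m, shape)
    K_b = np.broadcast_to(K, shape)
    c = start.astype(float).copy()
    for _ in range(n):
        net = S / c - m_b
        c *= 1.0 + dt * rate * net / (net + K_b)
    return (c - start) / t_cyc


def productivity(c_X_start: float, c_X_end: float, duration: float) -> float:
    """Volumetric biomass productivity (c_end - c_start)/duration [g L^-1 d^-1]."""
    if not duration > 0:
        raise ValueError("duration must be positive")
    return (c_X_end - c_X_start) / duration


def mape(measured, modeled) -> float:
    """Mean absolute percent error between measured and modeled values [%].

    For a single pair this is the absolute percent error (APE).  Measured
    entries must be non-zero.
    """
    meas = np.asarray(measured, dtype=float)
    mod = np.asarray(modeled, dtype=float)
    if meas.shape != mod.shape or meas.ndim != 1 or meas.size == 0:
        raise ValueError("measured and modeled must be equal-length 1-D arrays")
    if np.any(meas == 0):
        raise ValueError("measured values must be non-zero")
    return float(100.0 / meas.size * np.sum(np.abs(meas - mod) / np.abs(meas)))
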