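"""Two-stage growth-parameter estimation with multistart simplex.

Stage 1 (temperature) fits, over the reorganized cluster datasets, the
s + 3 parameters (mu_opt_1..s, T_min, T_opt, T_max) by least squares of
mu_bar against mu_opt_k * phi(T), started from every 5-degree grid
combination of cardinal temperatures that satisfies the CTMI validity
constraints.  Stage 2 (light) fits (mu_max, K_S_ph, m_ph) to the cluster
optima against their q_ph labels from a 10x10x10 grid of starts.  The
final stage fits the m + 6 parameters (per-experiment inoculation
concentrations plus the six shared model parameters) by least squares of
measured against ODE-simulated biomass trajectories, seeded by the
initial candidates.  All minimizations use the Nelder-Mead downhill
simplex (200 iterations per start by default).

Uncertainty of the final estimate comes from a delete-2 jackknife over
experiments.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy.optimize import minimize

from .dataprep import ClusterDataset, ExperimentTimeSeries
from .model import GrowthParameters, ctmi_phi, validate_cardinal_temperatures
from .reactor import ReactorGeometry, photon_supply_density
from .simulate import EulerReplay

__all__ = [
    "SearchRange",
    "InitialEstimate",
    "FinalEstimate",
    "build_search_range",
    "cardinal_start_grid",
    "light_start_grid",
    "estimate_temperature_stage",
    "estimate_light_stage",
    "combine_candidates",
    "final_estimate",
    "jackknife_delete2",
]

# literature caps used when constructing the search range
MU_MAX_CAP = 3.8  # 1/d
M_PH_CAP = 0.32  # mol_ph g^-1 d^-1
T_FLOOR = -5.0  # deg C
T_CEIL = 50.0  # deg C

_PENALTY = 1e8


@dataclass(frozen=True)
class SearchRange:
    """Per-parameter (lower, upper) bounds for the estimation."""

    mu_max: tuple
    K_S_ph: tuple
    m_ph: tuple
    T_min: tuple
    T_opt: tuple
    T_max: tuple

    def __post_init__(self) -> None:
        for name in GrowthParameters.PARAM_NAMES:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower bound {lo} must be < upper {hi}")

    def as_dict(self) -> dict:
        return {n: getattr(self, n) for n in GrowthParameters.PARAM_NAMES}


@dataclass
class InitialEstimate:
    """One candidate from the two-stage initial estimation."""

    mu_opts: np.ndarray  # per-cluster optimum growth rates [1/d]
    T_min: float
    T_opt: float
    T_max: float
    J_temperature: float
    mu_max: float | None = None
    K_S_ph: float | None = None
    m_ph: float | None = None
    J_light: float | None = None
    start: tuple | None = None

    def theta(self) -> np.ndarray:
        """Six-parameter vector (requires both stages)."""
        if self.mu_max is None:
            raise ValueError("light stage not attached to this candidate")
        return np.array(
            [self.mu_max, self.K_S_ph, self.m_ph, self.T_min, self.T_opt, self.T_max]
        )


@dataclass
class FinalEstimate:
    """Result of the final multi-experiment ODE fit."""

    params: GrowthParameters
    c_X0: np.ndarray  # per-experiment inoculation estimates [g/L]
    J: float
    experiment_ids: list = field(default_factory=list)
    n_starts: int = 0
    converged: bool = True


def build_search_range(
    temperatures,
    mu_bar,
    q_ph,
    t_max_lower: str = "data",
) -> SearchRange:
    """Search range from pooled observations plus literature caps.

    Rules: T_min in [-5 degC, lowest observed T]; T_opt in [-5, 50]
    subject to CTMI validity at fit time; T_max in [highest observed T,
    50] (``t_max_lower='literature'`` replaces the lower bound by 32 degC);
    mu_max in [highest observed mu_bar, 3.8]; K_S_ph in [0, highest
    observed q_ph]; m_ph in [0, 0.32].
    """
    T = np.asarray(temperatures, dtype=float)
    mu = np.asarray(mu_bar, dtype=float)
    q = np.asarray(q_ph, dtype=float)
    if T.size == 0 or mu.size == 0 or q.size == 0:
        raise ValueError("empty pooled data")
    tmax_lo = 32.0 if t_max_lower == "literature" else float(T.max())
    return SearchRange(
        mu_max=(float(mu.max()), MU_MAX_CAP),
        K_S_ph=(0.0, float(q.max())),
        m_ph=(0.0, M_PH_CAP),
        T_min=(T_FLOOR, float(T.min())),
        T_opt=(T_FLOOR, T_CEIL),
        T_max=(tmax_lo, T_CEIL),
    )


def cardinal_start_grid(search_range: SearchRange, step: float = 5.0) -> list:
    """All CTMI-valid cardinal triples on a ``step``-spaced grid.

    Each axis is scanned from its lower bound upward in increments of
    ``step``; triples violating the ordering or midpoint constraints are
    discarded.  On the reference campaign ranges this yields 70 starts.
    """
    def axis(lo, hi):
        return np.arange(lo, hi + 1e-9, step)

    tmins = axis(*search_range.T_min)
    topts = axis(*search_range.T_opt)
    tmaxs = axis(*search_range.T_max)
    return [
        (a, b, c)
        for a, b, c in itertools.product(tmins, topts, tmaxs)
        if validate_cardinal_temperatures(a, b, c)
    ]


def light_start_grid(search_range: SearchRange, n_grid: int = 10) -> list:
    """The (mu_max, K_S_ph, m_ph) start lattice: ``n_grid`` equidistant
    values per axis spanning the search range (1,000 starts by default)."""
    axes = [
        np.linspace(*search_range.mu_max, n_grid),
        np.linspace(*search_range.K_S_ph, n_grid),
        np.linspace(*search_range.m_ph, n_grid),
    ]
    return [np.asarray(x) for x in itertools.product(*axes)]


def _phi_raw(T, t_min, t_opt, t_max):
    num = (T - t_max) * (T - t_min) ** 2
    den = (t_opt - t_min) * (
        (t_opt - t_min) * (T - t_opt) - (t_opt - t_max) * (t_opt + t_min - 2.0 * T)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where((T > t_min) & (T < t_max), num / den, 0.0)


def _cardinal_penalty(t_min, t_opt, t_max) -> float:
    """Smooth penalty for invalid triples (zero when valid)."""
    v = 0.0
    if t_min >= t_opt:
        v += (t_min - t_opt + 1.0) ** 2
    if t_opt >= t_max:
        v += (t_opt - t_max + 1.0) ** 2
    mid = 0.5 * (t_min + t_max)
    if t_opt <= mid:
        v += (mid - t_opt + 1.0) ** 2
    return v


def estimate_temperature_stage(
    cluster_datasets: list,
    search_range: SearchRange,
    grid_step: float = 5.0,
    max_iter: int = 200,
) -> list:
    """Multistart simplex fit of (mu_opt_1..s, T_min, T_opt, T_max).

    Returns all runs as :class:`InitialEstimate` candidates sorted by the
    attained objective value.
    """
    if not cluster_datasets:
        raise ValueError("no cluster datasets")
    s = len(cluster_datasets)
    T_all = [d.temperatures for d in cluster_datasets]
    mu_all = [d.mu_bar for d in cluster_datasets]
    mu_init = np.array([max(float(np.max(m)), 1e-3) for m in mu_all])

    def objective(theta):
        mu_opts = theta[:s]
        t_min, t_opt, t_max = theta[s], theta[s + 1], theta[s + 2]
        pen = _cardinal_penalty(t_min, t_opt, t_max)
        if pen > 0:
            return _PENALTY * (1.0 + pen)
        J = 0.0
        for k in range(s):
            resid = mu_all[k] - mu_opts[k] * _phi_raw(T_all[k], t_min, t_opt, t_max)
            J += float(resid @ resid)
        return J

    starts = cardinal_start_grid(search_range, grid_step)
    if not starts:
        raise ValueError("no valid cardinal grid start within the search range")

    candidates = []
    for triple in starts:
        x0 = np.concatenate([mu_init, triple])
        res = minimize(
            objective, x0, method="Nelder-Mead",
            options={"maxiter": max_iter, "xatol": 1e-4, "fatol": 1e-4},
        )
        th = res.x
        if not validate_cardinal_temperatures(th[s], th[s + 1], th[s + 2]):
            continue
        candidates.append(
            InitialEstimate(
                mu_opts=th[:s].copy(), T_min=float(th[s]), T_opt=float(th[s + 1]),
                T_max=float(th[s + 2]), J_temperature=float(res.fun), start=tuple(triple),
            )
        )
    candidates.sort(key=lambda c: c.J_temperature)
    return candidates


def estimate_light_stage(
    mu_opt_per_cluster,
    q_ph_per_cluster,
    search_range: SearchRange,
    n_grid: int = 10,
    max_iter: int = 200,
) -> list:
    """Multistart simplex fit of (mu_max, K_S_ph, m_ph) to cluster optima.

    Starts on an ``n_grid``-per-axis lattice spanning the search range
    (1,000 starts at the default).  Returns (mu_max, K_S_ph, m_ph, J)
    tuples sorted by J.
    """
    mu_k = np.asarray(mu_opt_per_cluster, dtype=float)
    q_k = np.asarray(q_ph_per_cluster, dtype=float)
    if mu_k.size < 3:
        warnings.warn("fewer than 3 cluster optima: light stage is under-determined")
    starts = light_start_grid(search_range, n_grid)

    def objective(theta):
        mu_max, K, m = theta
        if mu_max <= 0 or K < 0 or m < 0:
            return _PENALTY
        den = q_k - m + K
        if np.any(den <= 0):
            return _PENALTY
        resid = mu_k - mu_max * (q_k - m) / den
        return float(resid @ resid)

    results = []
    for x0 in starts:
        res = minimize(
            objective, np.asarray(x0), method="Nelder-Mead",
            options={"maxiter": max_iter, "xatol": 1e-4, "fatol": 1e-4},
        )
        if res.fun < _PENALTY:
            results.append((*map(float, res.x), float(res.fun)))
    results.sort(key=lambda r: r[-1])
    return results


def distinct_light_candidates(results, rel_J: float = 0.10, atol: float = 0.05) -> list:
    """Keep local optima whose J is within ``rel_J`` of the best and whose
    parameters differ beyond ``atol`` from every already-kept candidate."""
    kept = []
    if not results:
        return kept
    J_best = results[0][-1]
    for r in results:
        if r[-1] > J_best * (1.0 + rel_J) + 1e-12:
            break
        if all(np.max(np.abs(np.array(r[:3]) - np.array(k[:3]))) > atol for k in kept):
            kept.append(r)
    return kept


def combine_candidates(
    temperature_candidates: list,
    search_range: SearchRange,
    n_grid: int = 10,
    max_iter: int = 200,
    q_ph_labels=None,
    n_temperature: int = 2,
    rel_J: float = 0.10,
) -> list:
    """Run the light stage for the best temperature candidates and attach
    the results, yielding full six-parameter initial candidates.

    ``q_ph_labels`` are the cluster q_ph values aligned with the
    mu_opt vectors.  Distinct local optima of either stage each produce a
    candidate (the reference analysis retains two).
    """
    if q_ph_labels is None:
        raise ValueError("q_ph_labels (per-cluster photon availabilities) required")
    q_k = np.asarray(q_ph_labels, dtype=float)

    # distinct temperature-stage optima: J within rel_J of the best,
    # cardinal triples differing beyond 0.5 degC
    distinct_T: list = []
    if temperature_candidates:
        J_best = temperature_candidates[0].J_temperature
        for c in temperature_candidates:
            if c.J_temperature > J_best * (1.0 + rel_J) + 1e-12:
                break
            trip = np.array([c.T_min, c.T_opt, c.T_max])
            if all(
                np.max(np.abs(trip - np.array([k.T_min, k.T_opt, k.T_max]))) > 0.5
                for k in distinct_T
            ):
                distinct_T.append(c)
            if len(distinct_T) >= n_temperature:
                break

    out = []
    for cand in distinct_T:
        light = estimate_light_stage(
            cand.mu_opts, q_k, search_range, n_grid=n_grid, max_iter=max_iter
        )
        for mu_max, K, m, J in distinct_light_candidates(light):
            out.append(
                InitialEstimate(
                    mu_opts=cand.mu_opts, T_min=cand.T_min, T_opt=cand.T_opt,
                    T_max=cand.T_max, J_temperature=cand.J_temperature,
                    mu_max=mu_max, K_S_ph=K, m_ph=m, J_light=J, start=cand.start,
                )
            )
    return out


def _fit_arrays(experiments: list) -> list:
    """(times, measured c_X, temperatures) per experiment."""
    out = []
    for e in experiments:
        if isinstance(e, ExperimentTimeSeries):
            out.append((e.times, e.biomass(), e.temperature))
        else:  # (times, c_x, temps) triple
            t, c, T = e
            out.append((np.asarray(t, float), np.asarray(c, float), np.asarray(T, float)))
    return out


def final_estimate(
    experiments: list,
    initial_candidates: list,
    geometry: ReactorGeometry,
    integrator: str = "euler",
    step: float = 0.01,
    max_iter: int = 200,
    restarts: int = 0,
    sample_stride: int = 1,
) -> FinalEstimate:
    """Multi-experiment ODE fit of the m + 6 parameters.

    Minimizes the pooled SSE between measured and simulated biomass
    trajectories over (c_X0_1..m, mu_max, K_S_ph, m_ph, T_min, T_opt,
    T_max), simulating every experiment with its recorded temperature
    series.  Each initial candidate seeds one Nelder-Mead run (plus
    ``restarts`` re-initializations of the simplex at the incumbent,
    which tightens convergence at negligible structural cost); the best
    run wins.  CTMI-invalid triples and failed integrations are penalized,
    not raised.

    ``experiments`` may be :class:`ExperimentTimeSeries` (with fitted OD
    correlations) or raw (times, c_X, temperature) triples.
    ``sample_stride`` thins the measurement points entering the SSE.
    """
    if not experiments:
        raise ValueError("no experiments")
    if not initial_candidates:
        raise ValueError("no initial candidates")
    data = _fit_arrays(experiments)
    if sample_stride > 1:
        data = [
            (t[::sample_stride], c[::sample_stride], T[::sample_stride])
            for t, c, T in data
        ]
    m = len(data)
    S = photon_supply_density(geometry)

    if integrator == "adaptive":
        from scipy.integrate import solve_ivp

        def simulate_one(c0, t, T, theta):
            def rhs(tt, y):
                q = S / y[0]
                Tv = np.interp(tt, t, T)
                phi = float(_phi_raw(np.asarray(Tv), theta[3], theta[4], theta[5]))
                net = q - theta[2]
                return [theta[0] * net / (net + theta[1]) * phi * y[0]]

            sol = solve_ivp(
                rhs, (t[0], t[-1]), [c0], method="LSODA",
                t_eval=t, rtol=1e-8, atol=1e-10,
            )
            return sol.y[0] if sol.success else None
    elif integrator != "euler":
        raise ValueError(f"unknown integrator {integrator!r}")

    replays = (
        [EulerReplay(t, T, S, max_step=step) for t, _, T in data]
        if integrator == "euler"
        else None
    )

    def objective(x):
        c0s, theta = x[:m], x[m:]
        pen = _cardinal_penalty(theta[3], theta[4], theta[5])
        if pen > 0 or theta[0] <= 0 or theta[1] < 0 or theta[2] < 0 or np.any(
            c0s <= 0
        ):
            return _PENALTY * (1.0 + pen + float(np.sum(c0s <= 0)))
        J = 0.0
        for j, (t, c_meas, T) in enumerate(data):
            if replays is not None:
                c_sim = replays[j](c0s[j], theta)
            else:
                c_sim = simulate_one(c0s[j], t, T, theta)
            if c_sim is None or np.any(~np.isfinite(c_sim)):
                return _PENALTY
            resid = c_meas - c_sim
            J += float(resid @ resid)
        return J

    best = None
    for cand in initial_candidates:
        theta0 = cand.theta() if isinstance(cand, InitialEstimate) else np.asarray(
            cand, dtype=float
        )
        x0 = np.concatenate([[c[1][0] for c in data], theta0])
        res = minimize(
            objective, x0, method="Nelder-Mead",
            options={"maxiter": max_iter, "xatol": 1e-4, "fatol": 1e-4},
        )
        # re-seeding the simplex at the incumbent escapes the collapsed
        # simplex and tightens convergence; stop early when J stagnates
        for _ in range(restarts):
            prev = res.fun
            res = minimize(
                objective, res.x, method="Nelder-Mead",
                options={
                    "maxiter": max(max_iter, 200 * (m + 6)),
                    "xatol": 1e-9, "fatol": 1e-14,
                },
            )
            if prev - res.fun <= 1e-14 + 1e-9 * abs(prev):
                break
        if best is None or res.fun < best.fun:
            best = res

    theta = best.x[m:]
    if not validate_cardinal_temperatures(theta[3], theta[4], theta[5]):
        raise RuntimeError("final estimate ended on an invalid cardinal triple")
    ids = [
        e.experiment_id if isinstance(e, ExperimentTimeSeries) else str(i)
        for i, e in enumerate(experiments)
    ]
    return FinalEstimate(
        params=GrowthParameters.from_vector(theta),
        c_X0=best.x[:m].copy(),
        J=float(best.fun),
        experiment_ids=ids,
        n_starts=len(initial_candidates),
        converged=bool(best.fun < _PENALTY),
    )


def jackknife_delete2(experiments: list, fit_function, d: int = 2) -> dict:
    """Delete-d jackknife (d = 2) over experiments.

    Calls ``fit_function(subset)`` for every leave-``d``-out subset
    (C(m, d) of them; 105 for m = 15) and returns, per parameter
    position, the jackknife mean, the delete-d standard error

        sigma = sqrt((m - d) / (d * C(m, d)) * sum (theta_s - mean)^2)

    and the normal-theory 95% interval mean +- 1.96 sigma.  Failing
    subset fits are recorded and excluded with a warning.
    """
    m = len(experiments)
    if m < d + 2:
        raise ValueError(f"need at least {d + 2} experiments, got {m}")
    thetas, failures = [], []
    for drop in itertools.combinations(range(m), d):
        subset = [e for i, e in enumerate(experiments) if i not in drop]
        try:
            thetas.append(np.asarray(fit_function(subset), dtype=float))
        except Exception as exc:  # noqa: BLE001 - subset failures are data
            failures.append((drop, repr(exc)))
    if failures:
        warnings.warn(f"{len(failures)} of {comb(m, d)} jackknife refits failed")
    if not thetas:
        raise RuntimeError("all jackknife refits failed")
    arr = np.vstack(thetas)
    mean = arr.mean(axis=0)
    n_sub = arr.shape[0]
    sigma = np.sqrt((m - d) / (d * n_sub) * np.sum((arr - mean) ** 2, axis=0))
    return {
        "mean": mean,
        "sigma": sigma,
        "ci95": (mean - 1.96 * sigma, mean + 1.96 * sigma),
        "n_resamples": n_sub,
        "n_failures": len(failures),
        "failures": failures,
    }
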