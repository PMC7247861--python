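"""Model-based maximization of biomass productivity.

The decision variables are the process parameters: inoculation biomass
concentration c_X0 [g/L], cultivation cycle time t_cyc [d] and
temperature T [deg C].  The objective is the simulated batch productivity
Pr = (c_X(t_cyc) - c_X0) / t_cyc, maximized with the Nelder-Mead simplex
on smooth coordinate transforms (log for the positive variables,
logistic for T within its bounds).  The free-temperature optimum sits at
the model's T_opt, and the free-cycle-time optimum is a corner point at
the lower t_cyc bound: shrinking the cycle time toward zero approaches
continuous operation, for which a closed-form optimum exists and serves
as an analytic oracle.

Continuous-limit derivation (documented, re-derived from the kinetics):
as t_cyc -> 0 the batch collapses to a steady state at concentration c,
with Pr(c) = mu(q_ph(c)) * c at T_opt and q_ph(c) = S / c, where
S = total photon flux / V_L [mol_ph L^-1 d^-1].  Writing
Pr(c) = mu_max * c * (S - m*c) / (S - m*c + K*c) and setting
dPr/dc = 0 yields m*(K - m)*c^2 + 2*m*S*c - S^2 = 0, whose positive root
simplifies (factor sqrt(m)*(sqrt(K) - sqrt(m))) to

    c* = S / (m + sqrt(m*K)),

and substituting back, S - m c* = c* sqrt(m K), so

    Pr* = mu_max * c* * sqrt(m*K) / (sqrt(m*K) + K).

For m -> 0 there is no interior optimum (Pr grows monotonically in c).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

import numpy as np
from scipy.optimize import minimize

from .model import GrowthParameters
from .reactor import ReactorGeometry, photon_supply_density
from .simulate import batch_productivity_many, simulate_batch

__all__ = [
    "OptimizationResult",
    "optimize_productivity",
    "continuous_limit_optimum",
    "productivity_surface",
    "reoptimized_campaign",
]

DEFAULT_BOUNDS = {"c_X0": (0.01, 5.0), "t_cyc": (0.01, 10.0)}


@dataclass
class OptimizationResult:
    """Optimal process parameters and the attained productivity."""

    c_X0_opt: float
    t_cyc_opt: float
    T_opt_process: float
    Pr_opt: float
    converged: bool = True
    trace: dict = field(default_factory=dict)


def _pr_adaptive(c0, t_cyc, T, params, geometry, rtol=1e-8) -> float:
    res = simulate_batch(
        c0, t_cyc, T, params, geometry, method="adaptive", rtol=rtol, n_out=2
    )
    return res.productivity


def optimize_productivity(
    params: GrowthParameters,
    geometry: ReactorGeometry,
    bounds: dict | None = None,
    fixed: dict | None = None,
    max_iter: int = 400,
    verify_rtol: float = 1e-8,
) -> OptimizationResult:
    """Simplex maximization of batch productivity.

    ``fixed`` maps a subset of {'c_X0', 't_cyc', 'T'} to fixed values;
    the remaining variables are free within ``bounds`` (defaults: c_X0 in
    [0.01, 5] g/L, t_cyc in [0.01, 10] d, T within the model's growth
    range).  Bound handling is by coordinate transform — log for c_X0 and
    t_cyc, logistic for T — so the simplex runs unconstrained.  The
    returned optimum is re-simulated with the adaptive integrator at
    ``verify_rtol`` and reported from that verification run.
    """
    fixed = dict(fixed or {})
    b = dict(DEFAULT_BOUNDS)
    eps = 0.05 * (params.T_max - params.T_min)
    b["T"] = (params.T_min + eps, params.T_max - eps)
    if bounds:
        b.update(bounds)
    if b["t_cyc"][0] <= 0:
        raise ValueError("t_cyc lower bound must be positive")

    free = [v for v in ("c_X0", "t_cyc", "T") if v not in fixed]

    def encode(name, value):
        lo, hi = b[name]
        if name == "T":
            p = np.clip((value - lo) / (hi - lo), 1e-6, 1 - 1e-6)
            return np.log(p / (1 - p))
        return np.log(np.clip(value, lo, hi))

    def decode(name, z):
        lo, hi = b[name]
        if name == "T":
            return lo + (hi - lo) / (1.0 + np.exp(-z))
        return float(np.clip(np.exp(z), lo, hi))

    defaults = {"c_X0": 0.5, "t_cyc": 1.0, "T": params.T_opt}

    def unpack(x):
        vals = dict(fixed)
        for name, z in zip(free, x):
            vals[name] = decode(name, z)
        return vals

    def objective(x):
        v = unpack(x)
        try:
            pr = _pr_adaptive(
                v["c_X0"], v["t_cyc"], v["T"], params, geometry, rtol=1e-6
            )
        except (ValueError, RuntimeError, FloatingPointError):
            return 1e6
        return -float(pr)

    if free:
        x0 = np.array([encode(n, defaults[n]) for n in free])
        res = minimize(
            objective, x0, method="Nelder-Mead",
            options={"maxiter": max_iter, "xatol": 1e-8, "fatol": 1e-10},
        )
        res = minimize(  # restart tightens the corner/interior optimum
            objective, res.x, method="Nelder-Mead",
            options={"maxiter": max_iter, "xatol": 1e-8, "fatol": 1e-12},
        )
        vals = unpack(res.x)
        converged = bool(res.success or res.fun < 0)
        trace = {"nfev": res.nfev, "message": res.message}
    else:
        vals, converged, trace = dict(fixed), True, {}

    pr_verified = _pr_adaptive(
        vals["c_X0"], vals["t_cyc"], vals["T"], params, geometry, rtol=verify_rtol
    )
    return OptimizationResult(
        c_X0_opt=float(vals["c_X0"]), t_cyc_opt=float(vals["t_cyc"]),
        T_opt_process=float(vals["T"]), Pr_opt=float(pr_verified),
        converged=converged, trace=trace,
    )


def continuous_limit_optimum(params: GrowthParameters, geometry: ReactorGeometry):
    """Closed-form continuous-operation optimum (c*, Pr*).

    See the module docstring for the derivation.  Requires m_ph > 0 and
    K_S_ph > 0; with zero maintenance the productivity has no interior
    maximum in the biomass concentration.
    """
    m, K, mu_max = params.m_ph, params.K_S_ph, params.mu_max
    if m <= 0 or K <= 0:
        raise ValueError(
            "no interior continuous-limit optimum: requires m_ph > 0 and K_S_ph > 0"
        )
    S = photon_supply_density(geometry)
    root = sqrt(m * K)
    c_star = S / (m + root)
    pr_star = mu_max * c_star * root / (root + K)
    return c_star, pr_star


def productivity_surface(
    params: GrowthParameters,
    geometry: ReactorGeometry,
    axes: dict,
    fixed: dict | None = None,
    step: float = 0.005,
) -> np.ndarray:
    """Dense Pr evaluation over a 2-D process-parameter grid.

    ``axes`` maps exactly two of {'c_X0', 't_cyc', 'T'} to 1-D value
    arrays; ``fixed`` supplies the third (temperature defaults to the
    model's T_opt).  Returns Pr with shape (len(first axis), len(second
    axis)), row-major in the order the axes are given.
    """
    if len(axes) != 2:
        raise ValueError("exactly two grid axes required")
    names = list(axes)
    grids = {n: np.asarray(axes[n], dtype=float) for n in names}
    for n, g in grids.items():
        if g.size < 2 or np.ptp(g) == 0:
            raise ValueError(f"degenerate range for axis {n!r}")
    vals = {"T": params.T_opt}
    vals.update(fixed or {})

    out = np.empty((grids[names[0]].size, grids[names[1]].size))
    theta = params.as_vector()

    def pr_vec(c0, t_cyc, T):
        return batch_productivity_many(theta, c0, t_cyc, T, geometry, step=step)

    # t_cyc must be scalar per call; vectorize over the other axes
    if "t_cyc" in names:
        i_t = names.index("t_cyc")
        other = names[1 - i_t]
        for j, tc in enumerate(grids["t_cyc"]):
            c0 = grids[other] if other == "c_X0" else vals["c_X0"]
            T = grids[other] if other == "T" else vals["T"]
            pr = pr_vec(c0, tc, T)
            if i_t == 0:
                out[j, :] = pr
            else:
                out[:, j] = pr
    else:  # c_X0 x T grid at fixed t_cyc
        mesh = dict(zip(names, np.meshgrid(*(grids[n] for n in names), indexing="ij")))
        out[:, :] = pr_vec(mesh["c_X0"], vals["t_cyc"], mesh["T"])
    return out


def reoptimized_campaign(
    t_cyc_values,
    params: GrowthParameters,
    geometry: ReactorGeometry,
) -> dict:
    """Per-cycle-time optimal productivity at T_opt for a campaign.

    For every cycle time, finds the productivity-maximizing inoculation
    concentration at the model's optimum temperature, then reports the
    per-experiment optima and their mean (and median, since the two can
    differ noticeably for campaigns mixing short and week-long cycles).
    """
    t_cycs = [float(t) for t in t_cyc_values]
    if not t_cycs:
        raise ValueError("empty cycle-time list")
    rows = []
    for tc in t_cycs:
        res = optimize_productivity(
            params, geometry, fixed={"t_cyc": tc, "T": params.T_opt}
        )
        rows.append((tc, res.c_X0_opt, res.Pr_opt))
    pr = np.array([r[2] for r in rows])
    return {
        "per_experiment": rows,
        "mean_Pr": float(pr.mean()),
        "median_Pr": float(np.median(pr)),
    }
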