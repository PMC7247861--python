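"""Variance-based (Sobol) sensitivity of predicted productivity.

The model output M = Pr(c_X0, t_cyc, T, theta) is decomposed over the
six growth parameters theta.  Samples follow the Saltelli cross-sampling
scheme over a scrambled Sobol' low-discrepancy base sequence of dimension
2k: base matrices A and B plus the k column-swapped matrices AB_i and
BA_i give N * (2k + 2) model evaluations and allow first-, second- and
total-order index estimation:

    S_i  = mean(Y_B * (Y_ABi - Y_A)) / Var(Y)
    S_Ti = mean((Y_A - Y_ABi)^2) / (2 * Var(Y))
    S_ij = mean(Y_BAi * Y_ABj - Y_A * Y_B) / Var(Y) - S_i - S_j

Indices below 0.01 are classified "non-sensitive", indices of at least
0.1 "highly sensitive", everything between "sensitive".

Scenario analysis evaluates the indices at 9 process-condition scenarios:
all combinations of low/medium/high (20/50/80% of the experimental
range) inoculation concentration and temperature, at a fixed medium
cycle time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .model import GrowthParameters
from .reactor import ReactorGeometry
from .simulate import batch_productivity_many

__all__ = [
    "SensitivityScenario",
    "SobolResult",
    "saltelli_sample",
    "sobol_indices",
    "default_scenarios",
    "scenario_sensitivity",
]

NON_SENSITIVE = 0.01
HIGHLY_SENSITIVE = 0.1


@dataclass(frozen=True)
class SensitivityScenario:
    """One process-condition scenario for the sensitivity scan."""

    c_X0: float  # g/L
    T: float  # deg C
    t_cyc: float  # d
    label: str = ""


@dataclass
class SobolResult:
    """Estimated sensitivity indices for one scenario."""

    names: list
    S1: np.ndarray  # first order
    ST: np.ndarray  # total order
    S2: np.ndarray | None = None  # second order, (k, k), upper triangle
    S1_conf: np.ndarray | None = None
    ST_conf: np.ndarray | None = None
    scenario: SensitivityScenario | None = None
    degenerate: bool = False  # zero output variance

    def classification(self, order: str = "total") -> dict:
        """Map parameter -> 'non-sensitive' / 'sensitive' / 'highly sensitive'."""
        vals = self.ST if order == "total" else self.S1
        out = {}
        for name, v in zip(self.names, vals):
            if not np.isfinite(v) or v < NON_SENSITIVE:
                out[name] = "non-sensitive"
            elif v >= HIGHLY_SENSITIVE:
                out[name] = "highly sensitive"
            else:
                out[name] = "sensitive"
        return out


def saltelli_sample(
    parameter_ranges: dict,
    N: int,
    seed: int = 0,
    second_order: bool = True,
) -> tuple:
    """Generate the Saltelli design over ``parameter_ranges``.

    ``parameter_ranges`` maps parameter name -> (lower, upper); zero-width
    ranges are held fixed at their value and excluded from the varying
    dimension count k.  Returns ``(matrix, meta)`` where ``matrix`` has
    ``N * (2k + 2)`` rows (``N * (k + 2)`` without second-order blocks)
    and one column per parameter (fixed ones constant), and ``meta``
    records the block structure for :func:`sobol_indices`.  ``N`` should
    be a power of two for the Sobol' base sequence.
    """
    if not parameter_ranges:
        raise ValueError("empty parameter ranges")
    names = list(parameter_ranges)
    varying = [n for n in names if parameter_ranges[n][1] > parameter_ranges[n][0]]
    fixed = {n: parameter_ranges[n][0] for n in names if n not in varying}
    k = len(varying)
    if k == 0:
        raise ValueError("all parameter ranges have zero width")

    sampler = qmc.Sobol(d=2 * k, scramble=True, rng=np.random.default_rng(seed))
    base = sampler.random(N)
    A_u, B_u = base[:, :k], base[:, k:]
    lo = np.array([parameter_ranges[n][0] for n in varying])
    hi = np.array([parameter_ranges[n][1] for n in varying])

    def scale(u):
        return lo + u * (hi - lo)

    blocks = [scale(A_u), scale(B_u)]
    for i in range(k):
        AB = A_u.copy()
        AB[:, i] = B_u[:, i]
        blocks.append(scale(AB))
    if second_order:
        for i in range(k):
            BA = B_u.copy()
            BA[:, i] = A_u[:, i]
            blocks.append(scale(BA))
    varying_mat = np.vstack(blocks)

    matrix = np.empty((varying_mat.shape[0], len(names)))
    for j, n in enumerate(names):
        if n in fixed:
            matrix[:, j] = fixed[n]
        else:
            matrix[:, j] = varying_mat[:, varying.index(n)]
    meta = {
        "names": names,
        "varying": varying,
        "fixed": fixed,
        "N": N,
        "k": k,
        "second_order": second_order,
    }
    return matrix, meta


def _bootstrap_conf(estimator, n_rows, rng, n_boot=100):
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, n_rows, n_rows)
        stats.append(estimator(idx))
    return 1.96 * np.std(np.asarray(stats), axis=0, ddof=1)


def sobol_indices(model_outputs, meta: dict, n_boot: int = 100, seed: int = 0) -> SobolResult:
    """Sobol index estimators for outputs aligned with a Saltelli sample."""
    Y = np.asarray(model_outputs, dtype=float)
    N, k = meta["N"], meta["k"]
    second = meta["second_order"]
    expected = N * (2 * k + 2) if second else N * (k + 2)
    if Y.size != expected:
        raise ValueError(f"expected {expected} outputs, got {Y.size}")
    Y_A = Y[:N]
    Y_B = Y[N : 2 * N]
    Y_AB = [Y[(2 + i) * N : (3 + i) * N] for i in range(k)]
    Y_BA = (
        [Y[(2 + k + i) * N : (3 + k + i) * N] for i in range(k)] if second else None
    )

    pooled = np.concatenate([Y_A, Y_B])
    V = np.var(pooled)
    names = meta["varying"]
    if V == 0:
        return SobolResult(
            names=names, S1=np.full(k, np.nan), ST=np.full(k, np.nan),
            degenerate=True,
        )

    def s1_st(idx):
        a, b = Y_A[idx], Y_B[idx]
        v = np.var(np.concatenate([a, b]))
        s1 = np.array([np.mean(b * (Y_AB[i][idx] - a)) for i in range(k)]) / v
        st = np.array([0.5 * np.mean((a - Y_AB[i][idx]) ** 2) for i in range(k)]) / v
        return np.concatenate([s1, st])

    full = s1_st(np.arange(N))
    S1, ST = full[:k], full[k:]

    S2 = None
    if second:
        S2 = np.full((k, k), np.nan)
        for i in range(k):
            for j in range(i + 1, k):
                vij = np.mean(Y_BA[i] * Y_AB[j] - Y_A * Y_B) / V
                S2[i, j] = vij - S1[i] - S1[j]

    rng = np.random.default_rng(seed)
    conf = _bootstrap_conf(s1_st, N, rng, n_boot) if n_boot else None
    return SobolResult(
        names=names, S1=S1, ST=ST, S2=S2,
        S1_conf=None if conf is None else conf[:k],
        ST_conf=None if conf is None else conf[k:],
    )


def default_scenarios(
    c_X0_range: tuple = (0.27, 1.03),
    T_range: tuple = (19.0, 31.0),
    t_cyc_range: tuple = (0.7, 7.0),
    levels: tuple = (0.2, 0.5, 0.8),
) -> list:
    """The 9 low/medium/high (c_X0, T) scenarios at a medium cycle time.

    Levels are fractions of the experimental ranges; the default ranges
    are those of the reference repeated-batch campaign.
    """
    t_cyc = t_cyc_range[0] + 0.5 * (t_cyc_range[1] - t_cyc_range[0])
    tags = dict(zip(levels, ("low", "medium", "high")))
    out = []
    for pc in levels:
        for pt in levels:
            out.append(
                SensitivityScenario(
                    c_X0=c_X0_range[0] + pc * (c_X0_range[1] - c_X0_range[0]),
                    T=T_range[0] + pt * (T_range[1] - T_range[0]),
                    t_cyc=t_cyc,
                    label=f"c_X0={tags[pc]},T={tags[pt]}",
                )
            )
    return out


def scenario_sensitivity(
    params: GrowthParameters,
    geometry: ReactorGeometry,
    scenarios: list | None = None,
    N: int = 1024,
    seed: int = 0,
    n_sigma: float = 3.0,
    step: float = 0.01,
    second_order: bool = False,
    fixed_parameters: tuple = (),
    n_boot: int = 0,
) -> list:
    """Sobol indices of batch productivity for each process scenario.

    Parameter ranges are the point estimates +- ``n_sigma`` standard
    deviations (``params.sigma`` must be set).  Parameters named in
    ``fixed_parameters`` are held at their point estimate (supporting the
    reduced k = 5 variant alongside the default k = 6).  Productivity is
    evaluated by vectorized fixed-step batch simulation at constant
    scenario temperature.
    """
    if params.sigma is None:
        raise ValueError("params.sigma required to build sampling ranges")
    ranges = {}
    for name in GrowthParameters.PARAM_NAMES:
        val = getattr(params, name)
        if name in fixed_parameters:
            ranges[name] = (val, val)
        else:
            sig = params.sigma[name]
            ranges[name] = (val - n_sigma * sig, val + n_sigma * sig)
    if scenarios is None:
        scenarios = default_scenarios()

    results = []
    for sc in scenarios:
        matrix, meta = saltelli_sample(
            ranges, N, seed=seed, second_order=second_order
        )
        Y = batch_productivity_many(
            matrix, sc.c_X0, sc.t_cyc, sc.T, geometry, step=step
        )
        res = sobol_indices(Y, meta, n_boot=n_boot, seed=seed)
        res.scenario = sc
        results.append(res)
    return results
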