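"""Synthetic repeated-batch campaigns with the measurement structure the
pipeline assumes.

The forward model is the batch growth ODE under a diurnal temperature
signal plus a two-channel measurement model: a near-infrared optical
density sensor, linear in biomass with per-experiment coefficients
(a, b) and multiplicative Gaussian noise, and daily off-line dry-weight
samples in duplicate with additive Gaussian noise.  The default
15-experiment design reproduces the reference campaign's inoculation
concentrations (0.27-1.03 g/L) and cycle times (0.7-7 d); set
temperatures are mostly 20-25 degC with one warm experiment at 31 degC.
Temperature control is emulated by a sinusoid of one-day period clipped
to the controller's hysteresis band around the set-point.

The generator is the test bed for every pipeline stage and drives the
parameter-recovery harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .dataprep import (
    ExperimentTimeSeries,
    calibrate_experiment,
    prepare_experiment,
    reorganize_datasets,
)
from .model import GrowthParameters
from .reactor import ReactorGeometry, pilot_reactor
from .simulate import TemperatureProfile, simulate_batch

__all__ = [
    "CampaignSpec",
    "RecoveryReport",
    "reference_parameters",
    "reference_campaign_design",
    "generate_temperature_profile",
    "generate_campaign",
    "parameter_recovery_trial",
]

# set temperatures: most experiments 20-25 degC, experiment 10 at 31 degC
_DEFAULT_T_SET = (
    22.0, 23.5, 21.0, 24.0, 22.5, 20.5, 24.5, 21.5, 23.0, 31.0,
    20.0, 22.0, 23.5, 21.0, 24.5,
)


def reference_parameters() -> GrowthParameters:
    """Final growth-parameter estimates for N. granulata in the pilot
    reactor, with their jackknife standard deviations."""
    return GrowthParameters(
        mu_max=1.56, K_S_ph=1.89, m_ph=0.346,
        T_min=2.3, T_opt=27.93, T_max=32.59,
        sigma={
            "mu_max": 0.17, "K_S_ph": 0.31, "m_ph": 0.010,
            "T_min": 2.9, "T_opt": 0.37, "T_max": 0.42,
        },
    )


def reference_campaign_design() -> pd.DataFrame:
    """The 15-experiment repeated-batch design (cycle times, inoculation
    concentrations, measured productivities, OD-correlation coefficients)."""
    ref = resources.files("algrow.data").joinpath("campaign_design.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, dtype={"experiment": str})


def _design_defaults():
    d = reference_campaign_design()
    return (
        tuple(d["c_x0_gpl"]),
        tuple(d["t_cyc_d"]),
        tuple(zip(d["a_gpl_per_au"], d["b_gpl"])),
    )


@dataclass
class CampaignSpec:
    """Configuration of a synthetic repeated-batch campaign."""

    n_experiments: int = 15
    c_X0: tuple = None  # g/L, per experiment
    t_cyc: tuple = None  # d
    T_set: tuple = _DEFAULT_T_SET
    params: GrowthParameters = field(default_factory=reference_parameters)
    geometry: ReactorGeometry = field(default_factory=pilot_reactor)
    diurnal_amplitude: float = 2.0  # K
    hysteresis_band: float = 1.0  # K, clipping half-width around T_set
    sampling_interval_min: float = 10.0
    od_correlation: tuple = None  # per-experiment (a, b)
    sigma_od: float = 0.01  # multiplicative OD noise
    sigma_dw: float = 0.02  # additive dry-weight noise [g/L]
    integrator: str = "adaptive"  # forward-model scheme; "euler" matches the
    # estimator's fixed-step replay exactly (noise-free identifiability tests)
    euler_step: float = 0.01  # d, substep bound for the euler forward model
    seed: int = 0

    def __post_init__(self) -> None:
        c0_ref, tc_ref, ab_ref = _design_defaults()
        if self.c_X0 is None:
            self.c_X0 = c0_ref[: self.n_experiments]
        if self.t_cyc is None:
            self.t_cyc = tc_ref[: self.n_experiments]
        if self.od_correlation is None:
            self.od_correlation = tuple(
                ab_ref[i % len(ab_ref)] for i in range(self.n_experiments)
            )
        if self.T_set is None or len(self.T_set) < self.n_experiments:
            raise ValueError("need a set temperature per experiment")
        self.T_set = tuple(self.T_set)[: self.n_experiments]
        for name, vals in (("c_X0", self.c_X0), ("t_cyc", self.t_cyc)):
            if len(vals) != self.n_experiments:
                raise ValueError(f"{name} length != n_experiments")
            if any(v <= 0 for v in vals):
                raise ValueError(f"{name} entries must be positive")
        if self.sigma_od < 0 or self.sigma_dw < 0:
            raise ValueError("noise levels must be non-negative")

    def rngs(self) -> list:
        """One independent generator per experiment, derived from the
        campaign seed."""
        return [
            np.random.default_rng(s)
            for s in np.random.SeedSequence(self.seed).spawn(self.n_experiments)
        ]


@dataclass
class RecoveryReport:
    """True-vs-estimated comparison from one recovery trial."""

    true_params: GrowthParameters
    estimate: object  # FinalEstimate
    abs_error: np.ndarray
    rel_error: np.ndarray
    ci_covers: np.ndarray | None
    seed: int
    failure: str | None = None


def generate_temperature_profile(
    spec: CampaignSpec, experiment_index: int
) -> TemperatureProfile:
    """Diurnal temperature signal of one experiment.

    T(t) = T_set + A sin(2 pi t + phase), clipped to the controller
    hysteresis band T_set +- band; sampled at the spec interval and
    deterministic for a given (seed, experiment index).
    """
    rng = spec.rngs()[experiment_index]
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t_cyc = spec.t_cyc[experiment_index]
    t_set = spec.T_set[experiment_index]
    dt = spec.sampling_interval_min / (24.0 * 60.0)
    times = np.linspace(0.0, t_cyc, max(2, int(round(t_cyc / dt)) + 1))
    raw = t_set + spec.diurnal_amplitude * np.sin(2.0 * np.pi * times + phase)
    values = np.clip(raw, t_set - spec.hysteresis_band, t_set + spec.hysteresis_band)
    return TemperatureProfile.from_samples(times, values)


def generate_campaign(spec: CampaignSpec) -> list:
    """Simulate the campaign and apply the measurement model.

    Returns one :class:`ExperimentTimeSeries` per experiment, with OD
    computed by inverting the linear sensor map on the simulated biomass
    (plus multiplicative noise) and daily duplicate off-line dry-weight
    samples (plus additive noise).  Byte-identical for equal seeds.
    """
    rngs = spec.rngs()
    out = []
    for j in range(spec.n_experiments):
        profile = generate_temperature_profile(spec, j)
        times = profile.times
        if spec.integrator == "euler":
            from .reactor import photon_supply_density
            from .simulate import euler_at_times

            c_x = euler_at_times(
                spec.c_X0[j], times, np.asarray(profile.values, float),
                spec.params.as_vector(), photon_supply_density(spec.geometry),
                max_step=spec.euler_step,
            )
        else:
            sim = simulate_batch(
                spec.c_X0[j], spec.t_cyc[j], profile, spec.params, spec.geometry,
                method="adaptive", rtol=1e-8, n_out=len(times),
            )
            c_x = np.interp(times, sim.times, sim.c_x)
        a, b = spec.od_correlation[j]
        rng = rngs[j]
        rng.uniform()  # skip the phase draw consumed by the profile
        od = (c_x - b) / a * (1.0 + rng.normal(0.0, spec.sigma_od, times.size))

        # daily sampling snapped to the on-line grid (off-line samples are
        # drawn from the same suspension the sensor sees)
        marks = np.unique(
            np.concatenate([np.arange(0.0, spec.t_cyc[j], 1.0), [spec.t_cyc[j]]])
        )
        off_idx = np.unique(
            np.clip(np.searchsorted(times, marks - 1e-12), 0, times.size - 1)
        )
        off_times = times[off_idx]
        c_off = c_x[off_idx]
        rows = []
        for rep in (1, 2):
            rows.append(
                pd.DataFrame(
                    {
                        "time_d": off_times,
                        "c_x_gpl": c_off + rng.normal(0.0, spec.sigma_dw, c_off.size),
                        "replicate": rep,
                    }
                )
            )
        offline = pd.concat(rows, ignore_index=True).sort_values(
            ["time_d", "replicate"], ignore_index=True
        )
        out.append(
            ExperimentTimeSeries(
                experiment_id=f"{j + 1:02d}",
                times=times,
                od_nir=od,
                temperature=np.asarray(profile.values, dtype=float),
                ph=np.full(times.size, 7.25),
                offline_samples=offline,
                t_cyc=spec.t_cyc[j],
                c_X0=spec.c_X0[j],
                meta={"true_a": a, "true_b": b, "T_set": spec.T_set[j]},
            )
        )
    return out


def parameter_recovery_trial(spec: CampaignSpec, estimator_config: dict | None = None) -> RecoveryReport:
    """Generate -> prepare -> two-stage estimate -> compare.

    ``estimator_config`` keys (all optional): ``n_clusters``, ``grid_step``,
    ``n_grid``, ``max_iter``, ``integrator``, ``step``, ``restarts``,
    ``sample_stride``, ``jackknife`` (bool).  Estimation failures are
    recorded on the report, not raised.
    """
    from .estimate import (
        build_search_range,
        combine_candidates,
        estimate_temperature_stage,
        final_estimate,
        jackknife_delete2,
    )

    cfg = dict(estimator_config or {})
    try:
        experiments = generate_campaign(spec)
        for e in experiments:
            calibrate_experiment(e)
        prepared = [prepare_experiment(e, spec.geometry) for e in experiments]
        pooled = pd.concat(prepared, ignore_index=True)
        srange = build_search_range(pooled["T_C"], pooled["mu_bar"], pooled["q_ph"])
        clusters = reorganize_datasets(prepared, n_clusters=cfg.get("n_clusters", 10))
        temp_cands = estimate_temperature_stage(
            clusters, srange, grid_step=cfg.get("grid_step", 5.0),
            max_iter=cfg.get("max_iter", 200),
        )
        candidates = combine_candidates(
            temp_cands, srange, n_grid=cfg.get("n_grid", 10),
            max_iter=cfg.get("max_iter", 200),
            q_ph_labels=[c.q_ph for c in clusters],
        )
        fit = final_estimate(
            experiments, candidates, spec.geometry,
            integrator=cfg.get("integrator", "euler"),
            step=cfg.get("step", 0.01),
            max_iter=cfg.get("max_iter", 200),
            restarts=cfg.get("restarts", 0),
            sample_stride=cfg.get("sample_stride", 1),
        )
    except Exception as exc:  # noqa: BLE001 - harness records failures
        return RecoveryReport(
            true_params=spec.params, estimate=None,
            abs_error=np.full(6, np.nan), rel_error=np.full(6, np.nan),
            ci_covers=None, seed=spec.seed, failure=repr(exc),
        )

    truth = spec.params.as_vector()
    est = fit.params.as_vector()
    abs_err = np.abs(est - truth)
    rel_err = abs_err / np.abs(truth)

    ci_covers = None
    if cfg.get("jackknife"):
        def refit(subset):
            sub_fit = final_estimate(
                subset, [fit.params.as_vector()], spec.geometry,
                integrator=cfg.get("integrator", "euler"),
                step=cfg.get("step", 0.01),
                max_iter=cfg.get("max_iter", 200),
                sample_stride=cfg.get("sample_stride", 1),
            )
            return sub_fit.params.as_vector()

        jk = jackknife_delete2(experiments, refit)
        lo, hi = jk["ci95"]
        ci_covers = (truth >= lo) & (truth <= hi)

    return RecoveryReport(
        true_params=spec.params, estimate=fit,
        abs_error=abs_err, rel_error=rel_err,
        ci_covers=ci_covers, seed=spec.seed,
    )
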