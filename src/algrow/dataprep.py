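"""Raw experiment time series -> estimator inputs.

Three transformations feed the two-stage estimation:

1. the per-experiment linear OD -> dry-weight correlation,
2. the central-difference approximated growth rate mu_delta and its
   +-1 h moving-average smoothing mu_bar, and
3. the pooled-data reorganization: pooling all experiments, grouping by
   (quantized) photon availability q_ph, averaging over repeated
   temperatures, clustering the q_ph range into equal-width intervals and
   keeping, per interval, the dataset with the widest temperature span.

The reorganized cluster datasets are what the temperature stage of the
initial estimation fits; the light stage then fits the cluster optima
against their q_ph labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .reactor import ReactorGeometry, photon_supply_density

__all__ = [
    "ExperimentTimeSeries",
    "GrowthRateSeries",
    "ClusterDataset",
    "fit_od_correlation",
    "od_to_biomass",
    "approximate_growth_rate",
    "prepare_experiment",
    "reorganize_datasets",
]

HOUR = 1.0 / 24.0  # in days


@dataclass
class ExperimentTimeSeries:
    """One batch experiment: on-line signals plus daily off-line samples.

    ``offline_samples`` is a DataFrame with columns ``time_d``,
    ``c_x_gpl`` and ``replicate``; duplicate dry-weight replicates at the
    same time are averaged before correlation fitting.  ``correlation``
    holds the fitted (a, b, R^2) of c_X = a * OD + b once available.
    """

    experiment_id: str
    times: np.ndarray  # d
    od_nir: np.ndarray  # AU
    temperature: np.ndarray  # deg C
    ph: np.ndarray
    offline_samples: pd.DataFrame
    t_cyc: float
    c_X0: float | None = None
    correlation: tuple | None = None  # (a, b, r2)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od_nir = np.asarray(self.od_nir, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.ph = np.asarray(self.ph, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.experiment_id}: times must be strictly increasing")
        if not np.all(np.isfinite(self.od_nir)):
            raise ValueError(f"{self.experiment_id}: OD contains non-finite values")
        span = self.times[-1] - self.times[0]
        if abs(span - self.t_cyc) > 0.2 * max(self.t_cyc, 1.0):
            warnings.warn(
                f"{self.experiment_id}: record span {span:.2f} d differs from "
                f"declared t_cyc {self.t_cyc:.2f} d"
            )

    def biomass(self) -> np.ndarray:
        """On-line biomass concentration from the fitted OD correlation [g/L]."""
        if self.correlation is None:
            raise ValueError("no OD correlation fitted yet")
        a, b = self.correlation[0], self.correlation[1]
        return od_to_biomass(self.od_nir, a, b)


@dataclass
class GrowthRateSeries:
    """Approximated growth rates at the interior sample times.

    Points whose +-1 h stencil or smoothing window would extend beyond
    the record are dropped, not padded.
    """

    times: np.ndarray
    mu_delta: np.ndarray
    mu_delta_smoothed: np.ndarray


@dataclass
class ClusterDataset:
    """One reorganized dataset: a q_ph label and (T, mu_bar) observations."""

    cluster_index: int
    q_ph: float
    temperatures: np.ndarray
    mu_bar: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.mu_bar = np.asarray(self.mu_bar, dtype=float)
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("observations must be sorted by unique temperature")

    @property
    def t_span(self) -> float:
        return float(self.temperatures[-1] - self.temperatures[0]) if len(
            self.temperatures
        ) > 1 else 0.0


def fit_od_correlation(od_at_sample_times, offline_c_X) -> tuple:
    """OLS fit of c_X versus OD: returns (slope a, intercept b, R^2)."""
    od = np.asarray(od_at_sample_times, dtype=float)
    cx = np.asarray(offline_c_X, dtype=float)
    if od.size < 2 or od.size != cx.size:
        raise ValueError("need at least 2 paired (OD, c_X) samples")
    if np.ptp(od) == 0:
        raise ValueError("OD has zero variance; correlation undefined")
    res = stats.linregress(od, cx)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def od_to_biomass(od, a: float, b: float):
    """Linear sensor map c_X = a * OD + b [g/L]."""
    return a * np.asarray(od, dtype=float) + b


def calibrate_experiment(series: ExperimentTimeSeries) -> ExperimentTimeSeries:
    """Fit the OD correlation from the experiment's own off-line samples.

    Duplicate replicates at the same sampling time are averaged; each
    off-line time is paired with the nearest on-line OD sample.
    """
    off = (
        series.offline_samples.groupby("time_d", as_index=False)["c_x_gpl"].mean()
    )
    idx = np.clip(
        np.searchsorted(series.times, off["time_d"].to_numpy()), 0, len(series.times) - 1
    )
    # nearest sample (searchsorted gives right neighbour)
    left = np.clip(idx - 1, 0, None)
    use_left = np.abs(series.times[left] - off["time_d"].to_numpy()) < np.abs(
        series.times[idx] - off["time_d"].to_numpy()
    )
    idx = np.where(use_left, left, idx)
    series.correlation = fit_od_correlation(
        series.od_nir[idx], off["c_x_gpl"].to_numpy()
    )
    return series


def _nearest_within(times: np.ndarray, target: float, tol: float) -> int | None:
    i = np.searchsorted(times, target)
    best, dist = None, tol
    for j in (i - 1, i):
        if 0 <= j < times.size and abs(times[j] - target) <= dist:
            best, dist = j, abs(times[j] - target)
    return best


def approximate_growth_rate(
    times, c_x, half_window_h: float = 1.0, lookup_tol_h: float = 0.25
) -> GrowthRateSeries:
    """Central-difference growth rate with +-1 h moving-average smoothing.

    mu_delta(t) = (c_X(t + h) - c_X(t - h)) / (2 h * c_X(t)) with
    h = ``half_window_h`` (in hours; converted to days internally).  The
    two stencil values are looked up as the nearest recorded samples
    within ``lookup_tol_h`` of the target times; points without both
    neighbours are skipped.  Smoothing averages all mu_delta points whose
    time lies within +-h of t; points whose smoothing window extends
    beyond the record are dropped.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(c_x, dtype=float)
    h = half_window_h * HOUR
    tol = lookup_tol_h * HOUR

    valid_t, mu_d = [], []
    for i in range(t.size):
        jm = _nearest_within(t, t[i] - h, tol)
        jp = _nearest_within(t, t[i] + h, tol)
        if jm is None or jp is None or jm == jp:
            continue
        mu_d.append((c[jp] - c[jm]) / (2.0 * h * c[i]))
        valid_t.append(t[i])
    valid_t = np.asarray(valid_t)
    mu_d = np.asarray(mu_d)

    keep, smooth = [], []
    for i, ti in enumerate(valid_t):
        if ti - h < t[0] or ti + h > t[-1]:
            continue
        win = np.abs(valid_t - ti) <= h + 1e-12
        keep.append(i)
        smooth.append(float(np.mean(mu_d[win])))
    keep = np.asarray(keep, dtype=int)
    return GrowthRateSeries(
        times=valid_t[keep], mu_delta=mu_d[keep], mu_delta_smoothed=np.asarray(smooth)
    )


def prepare_experiment(
    series: ExperimentTimeSeries, geometry: ReactorGeometry
) -> pd.DataFrame:
    """Per-point (time, c_X, T, q_ph, mu_bar) table for the reorganization.

    Requires a fitted OD correlation (see :func:`calibrate_experiment`).
    """
    c_x = series.biomass()
    rates = approximate_growth_rate(series.times, c_x)
    idx = np.searchsorted(series.times, rates.times)
    S = photon_supply_density(geometry)
    cx_at = c_x[idx]
    if np.any(cx_at <= 0):
        keep = cx_at > 0
        idx, cx_at = idx[keep], cx_at[keep]
        rates = GrowthRateSeries(
            rates.times[keep], rates.mu_delta[keep], rates.mu_delta_smoothed[keep]
        )
    return pd.DataFrame(
        {
            "experiment_id": series.experiment_id,
            "time_d": rates.times,
            "c_x_gpl": cx_at,
            "T_C": series.temperature[idx],
            "q_ph": S / cx_at,
            "mu_bar": rates.mu_delta_smoothed,
        }
    )


def _round_sig(x: np.ndarray, sig: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    nz = x != 0
    mag = np.floor(np.log10(np.abs(x[nz])))
    out[nz] = np.round(x[nz] / 10.0**mag, sig - 1) * 10.0 ** mag
    return out


def reorganize_datasets(
    prepared: list,
    n_clusters: int = 10,
    qph_sig_digits: int = 3,
    temp_resolution: float = 0.1,
) -> list:
    """Pool, group, cluster and select the (T, mu_bar) datasets.

    Steps: concatenate the per-experiment tables; quantize q_ph to
    ``qph_sig_digits`` significant digits and group equal values into
    datasets; within each dataset round T to ``temp_resolution`` and
    average mu_bar over identical T, sorting by T; split the pooled q_ph
    range into ``n_clusters`` equal-width intervals (half-open, the last
    closed) and assign each dataset by its q_ph label; per interval keep
    the dataset with the widest T span (ties: more observations, then
    lowest q_ph).  Returns at most ``n_clusters`` datasets ordered by
    cluster index; empty intervals yield none.
    """
    if not prepared:
        raise ValueError("no prepared experiments supplied")
    pooled = pd.concat(prepared, ignore_index=True)
    if pooled.empty:
        raise ValueError("prepared experiments contain no observations")
    pooled = pooled.assign(q_key=_round_sig(pooled["q_ph"].to_numpy(), qph_sig_digits))

    datasets = []
    for q_key, grp in pooled.groupby("q_key"):
        t_round = np.round(grp["T_C"].to_numpy() / temp_resolution) * temp_resolution
        agg = (
            pd.DataFrame({"T": t_round, "mu_bar": grp["mu_bar"].to_numpy()})
            .groupby("T", as_index=False)["mu_bar"]
            .mean()
            .sort_values("T")
        )
        datasets.append((float(q_key), agg["T"].to_numpy(), agg["mu_bar"].to_numpy()))

    q_lo = min(d[0] for d in datasets)
    q_hi = max(d[0] for d in datasets)
    width = (q_hi - q_lo) / n_clusters if q_hi > q_lo else 1.0

    by_cluster: dict[int, list] = {}
    for q, T, mu in datasets:
        k = int((q - q_lo) / width) if q < q_hi else n_clusters - 1
        k = min(k, n_clusters - 1)
        by_cluster.setdefault(k, []).append((q, T, mu))

    selected = []
    for k in sorted(by_cluster):
        cands = by_cluster[k]
        # widest T span; ties -> more observations -> lowest q_ph label
        cands.sort(key=lambda d: (-(d[1][-1] - d[1][0]), -len(d[1]), d[0]))
        q, T, mu = cands[0]
        selected.append(
            ClusterDataset(cluster_index=k + 1, q_ph=q, temperatures=T, mu_bar=mu)
        )
    if len(selected) < n_clusters:
        warnings.warn(
            f"only {len(selected)} of {n_clusters} q_ph clusters are non-empty"
        )
    return selected
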