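"""Search ranges, the two-stage estimator, the final ODE fit and the
delete-2 jackknife."""

import numpy as np
import pytest

from algrow.dataprep import ClusterDataset, calibrate_experiment
from algrow.estimate import (
    SearchRange,
    build_search_range,
    cardinal_start_grid,
    combine_candidates,
    estimate_light_stage,
    estimate_temperature_stage,
    final_estimate,
    jackknife_delete2,
    light_start_grid,
)
from algrow.model import GrowthParameters, ctmi_phi, mu_opt
from algrow.synthetic import generate_campaign


class TestSearchRange:
    def test_rules_from_pooled_data(self):
        sr = build_search_range([19.0, 25.0, 31.0], [0.4, 1.0], [0.6, 1.9])
        assert sr.T_min == (-5.0, 19.0)
        assert sr.T_max == (31.0, 50.0)
        assert sr.T_opt == (-5.0, 50.0)
        assert sr.mu_max == (1.0, 3.8)
        assert sr.K_S_ph == (0.0, 1.9)
        assert sr.m_ph == (0.0, 0.32)

    def test_literature_t_max_lower_bound(self):
        sr = build_search_range([19.0, 31.0], [1.0], [1.9], t_max_lower="literature")
        assert sr.T_max == (32.0, 50.0)

    def test_empty_data_raises(self):
        with pytest.raises(ValueError):
            build_search_range([], [], [])

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            SearchRange(
                mu_max=(2.0, 1.0), K_S_ph=(0, 1), m_ph=(0, 1),
                T_min=(-5, 19), T_opt=(-5, 50), T_max=(31, 50),
            )


class TestStartGrids:
    def test_reference_cardinal_grid_has_70_valid_triples(self):
        sr = build_search_range([19.0, 31.0], [1.0], [1.9])
        starts = cardinal_start_grid(sr, step=5.0)
        assert len(starts) == 70
        from algrow.model import validate_cardinal_temperatures

        assert all(validate_cardinal_temperatures(*t) for t in starts)

    def test_light_grid_has_1000_starts(self):
        sr = build_search_range([19.0, 31.0], [1.0], [1.9])
        assert len(light_start_grid(sr, n_grid=10)) == 1000

    def test_over_constrained_range_raises(self):
        sr = SearchRange(
            mu_max=(1.0, 3.8), K_S_ph=(0, 1.9), m_ph=(0, 0.32),
            # T_opt can never exceed the T_min/T_max midpoint on this grid
            T_min=(30.0, 31.0), T_opt=(-5.0, -4.0), T_max=(32.0, 33.0),
        )
        with pytest.raises(ValueError):
            estimate_temperature_stage(
                [ClusterDataset(1, 1.0, [20.0, 25.0], [0.2, 0.3])], sr
            )


def _synthetic_clusters(true, q_values, rng, n_temps=8):
    clusters, mu_opts = [], []
    for k, q in enumerate(q_values):
        mu_k = mu_opt(q, true)
        T = np.unique(np.round(np.sort(rng.uniform(10, 32, n_temps)), 1))
        clusters.append(
            ClusterDataset(k + 1, q, T, mu_k * ctmi_phi(T, true))
        )
        mu_opts.append(mu_k)
    return clusters, np.asarray(mu_opts)


class TestTemperatureStage:
    def test_recovers_known_cardinals(self, rng):
        true = GrowthParameters(1.5, 2.0, 0.3, 5.0, 25.0, 33.0)
        clusters, _ = _synthetic_clusters(true, np.linspace(0.6, 1.9, 6), rng)
        sr = SearchRange(
            mu_max=(0.8, 3.8), K_S_ph=(0, 2.5), m_ph=(0, 0.32),
            T_min=(-5, 10), T_opt=(-5, 50), T_max=(32, 50),
        )
        best = estimate_temperature_stage(clusters, sr, max_iter=2000)[0]
        assert best.T_min == pytest.approx(5.0, abs=0.1)
        assert best.T_opt == pytest.approx(25.0, abs=0.1)
        assert best.T_max == pytest.approx(33.0, abs=0.1)

    def test_interpolable_single_cluster_reaches_zero(self):
        true = GrowthParameters(1.5, 2.0, 0.3, 5.0, 25.0, 33.0)
        T = np.array([15.0, 24.0, 30.0])
        cluster = ClusterDataset(1, 1.0, T, mu_opt(1.0, true) * ctmi_phi(T, true))
        sr = SearchRange(
            mu_max=(0.8, 3.8), K_S_ph=(0, 2.5), m_ph=(0, 0.32),
            T_min=(-5, 10), T_opt=(-5, 50), T_max=(32, 50),
        )
        best = estimate_temperature_stage([cluster], sr, max_iter=2000)[0]
        assert best.J_temperature < 1e-10


class TestLightStage:
    def test_recovers_initial_candidate_parameters(self):
        # cluster optima placed exactly on the kinetics with the second
        # initial-estimate solution of the reference analysis
        true = GrowthParameters(1.76, 2.27, 0.29, 2.3, 27.93, 32.59)
        q = np.linspace(0.6, 1.9, 8)
        mu_k = mu_opt(q, true)
        sr = build_search_range([19.0, 31.0], [float(mu_k.max())], [1.9])
        best = estimate_light_stage(mu_k, q, sr)[0]
        assert best[0] == pytest.approx(1.76, abs=1e-4)
        assert best[1] == pytest.approx(2.27, abs=1e-4)
        assert best[2] == pytest.approx(0.29, abs=1e-4)
        assert best[3] < 1e-10

    def test_under_determined_warns(self):
        sr = build_search_range([19.0, 31.0], [1.0], [1.9])
        with pytest.warns(UserWarning, match="under-determined"):
            estimate_light_stage([0.5, 0.6], [1.0, 1.5], sr, n_grid=3, max_iter=50)

    def test_saturated_regime_collapses_K(self):
        sr = build_search_range([19.0, 31.0], [0.5], [1.9])
        best = estimate_light_stage([0.5] * 5, np.linspace(1.0, 1.9, 5), sr, n_grid=5)[0]
        assert best[1] < 0.05  # K_S_ph driven toward zero


class TestFinalFit:
    def test_noise_free_self_fit_beats_perturbed_starts(self, identifiable_spec):
        exps = generate_campaign(identifiable_spec)
        for e in exps:
            calibrate_experiment(e)
        truth = identifiable_spec.params.as_vector()
        perturbed = truth * np.array([1.05, 0.95, 1.02, 1.2, 1.005, 0.995])
        fit = final_estimate(
            exps, [perturbed], identifiable_spec.geometry,
            integrator="euler", max_iter=400, restarts=15,
        )
        est = fit.params.as_vector()
        np.testing.assert_allclose(est, truth, rtol=1e-3)
        assert fit.J < 1e-8

    def test_requires_inputs(self, geometry):
        with pytest.raises(ValueError):
            final_estimate([], [np.ones(6)], geometry)


class TestJackknife:
    def test_resample_count_for_15_experiments(self):
        jk = jackknife_delete2(list(range(15)), lambda s: [float(np.mean(s))])
        assert jk["n_resamples"] == 105
        assert jk["n_failures"] == 0

    def test_identical_observations_collapse_ci(self):
        jk = jackknife_delete2([3.7] * 8, lambda s: [float(np.mean(s))])
        assert jk["sigma"][0] == pytest.approx(0.0, abs=1e-14)
        lo, hi = jk["ci95"]
        assert lo[0] == pytest.approx(hi[0], abs=1e-12)

    def test_failures_recorded_and_excluded(self):
        def flaky(subset):
            if 0 not in subset:
                raise RuntimeError("boom")
            return [float(np.mean(subset))]

        with pytest.warns(UserWarning, match="refits failed"):
            jk = jackknife_delete2(list(range(6)), flaky)
        # element 0 is dropped in 5 of the C(6,2) = 15 delete pairs
        assert jk["n_failures"] == 5
        assert jk["n_resamples"] == 10

    def test_too_few_experiments(self):
        with pytest.raises(ValueError):
            jackknife_delete2([1, 2, 3], lambda s: [0.0])


def test_two_stage_candidates_feed_final_fit(identifiable_spec):
    """The combined initial candidates carry valid six-parameter vectors."""
    import pandas as pd

    from algrow.dataprep import prepare_experiment, reorganize_datasets

    exps = generate_campaign(identifiable_spec)
    for e in exps:
        calibrate_experiment(e)
    prepared = [prepare_experiment(e, identifiable_spec.geometry) for e in exps]
    pooled = pd.concat(prepared, ignore_index=True)
    sr = build_search_range(pooled["T_C"], pooled["mu_bar"], pooled["q_ph"])
    clusters = reorganize_datasets(prepared)
    temp_cands = estimate_temperature_stage(clusters, sr)
    cands = combine_candidates(
        temp_cands, sr, n_grid=5, q_ph_labels=[c.q_ph for c in clusters]
    )
    assert cands
    for c in cands:
        theta = c.theta()
        assert theta.shape == (6,)
        assert theta[0] > 0
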