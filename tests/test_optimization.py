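"""Productivity optimization: fixed-cycle optima, the continuous-operation
closed form, surfaces and the campaign re-optimization."""

import numpy as np
import pytest

from algrow.model import GrowthParameters
from algrow.optimize import (
    continuous_limit_optimum,
    optimize_productivity,
    productivity_surface,
    reoptimized_campaign,
)
from algrow.simulate import simulate_batch
from algrow.synthetic import reference_campaign_design


@pytest.fixture(scope="module")
def table3(params, geometry):
    """Fixed-cycle-time optima at the model's optimum temperature."""
    out = {}
    for tc in (7.0, 3.5, 1.0):
        out[tc] = optimize_productivity(
            params, geometry, fixed={"t_cyc": tc, "T": params.T_opt}
        )
    return out


class TestFixedCycleOptima:
    def test_seven_day_cycle(self, table3):
        r = table3[7.0]
        assert r.c_X0_opt == pytest.approx(0.17, abs=0.02)
        assert r.Pr_opt == pytest.approx(0.37, abs=0.01)

    def test_half_week_cycle(self, table3):
        r = table3[3.5]
        assert r.c_X0_opt == pytest.approx(0.43, abs=0.02)
        assert r.Pr_opt == pytest.approx(0.46, abs=0.01)

    def test_one_day_cycle(self, table3):
        r = table3[1.0]
        assert r.c_X0_opt == pytest.approx(0.84, abs=0.02)
        assert r.Pr_opt == pytest.approx(0.50, abs=0.01)

    def test_optimum_pr_non_increasing_in_cycle_time(self, table3):
        assert table3[1.0].Pr_opt >= table3[3.5].Pr_opt >= table3[7.0].Pr_opt

    def test_returned_optimum_reproduces_on_resimulation(self, table3, params, geometry):
        for r in table3.values():
            res = simulate_batch(
                r.c_X0_opt, r.t_cyc_opt, r.T_opt_process, params, geometry,
                method="adaptive", rtol=1e-8,
            )
            assert res.productivity == pytest.approx(r.Pr_opt, rel=1e-6)


class TestContinuousLimit:
    def test_closed_form_reference_values(self, params, geometry):
        c_star, pr_star = continuous_limit_optimum(params, geometry)
        assert c_star == pytest.approx(1.07, abs=0.01)
        assert pr_star == pytest.approx(0.50, abs=0.01)

    def test_numerical_optimizer_approaches_closed_form(self, params, geometry):
        c_star, pr_star = continuous_limit_optimum(params, geometry)
        r = optimize_productivity(
            params, geometry, fixed={"t_cyc": 0.01, "T": params.T_opt}
        )
        assert r.c_X0_opt == pytest.approx(c_star, rel=0.01)
        assert r.Pr_opt == pytest.approx(pr_star, rel=0.01)

    def test_convergence_toward_corner_as_cycle_shrinks(self, params, geometry, table3):
        c_star, _ = continuous_limit_optimum(params, geometry)
        c_opts = [table3[7.0].c_X0_opt, table3[3.5].c_X0_opt, table3[1.0].c_X0_opt]
        gaps = [abs(c - c_star) for c in c_opts]
        assert gaps[0] > gaps[1] > gaps[2]

    def test_no_interior_optimum_without_maintenance(self, geometry):
        p = GrowthParameters(1.5, 1.9, 0.0, 2.3, 27.93, 32.59)
        with pytest.raises(ValueError):
            continuous_limit_optimum(p, geometry)


class TestFreeVariables:
    def test_free_temperature_converges_to_model_optimum(self, params, geometry):
        r = optimize_productivity(params, geometry, fixed={"t_cyc": 1.0})
        assert r.T_opt_process == pytest.approx(params.T_opt, abs=0.05)
        assert r.c_X0_opt == pytest.approx(0.84, abs=0.02)

    def test_free_cycle_time_hits_lower_bound(self, params, geometry):
        r = optimize_productivity(
            params, geometry, fixed={"T": params.T_opt},
            bounds={"t_cyc": (0.05, 10.0)},
        )
        assert r.t_cyc_opt == pytest.approx(0.05, abs=0.01)

    def test_invalid_bounds(self, params, geometry):
        with pytest.raises(ValueError):
            optimize_productivity(params, geometry, bounds={"t_cyc": (0.0, 5.0)})


class TestSurface:
    def test_cycle_time_surface_argmax_at_shortest_cycle(self, params, geometry):
        t_axis = np.linspace(0.5, 7.0, 14)
        c_axis = np.linspace(0.1, 2.0, 39)
        surf = productivity_surface(params, geometry, {"t_cyc": t_axis, "c_X0": c_axis})
        i, _ = np.unravel_index(np.argmax(surf), surf.shape)
        assert i == 0

    def test_temperature_surface_has_interior_maximum_at_t_opt(self, params, geometry):
        T_axis = np.linspace(20.0, 32.0, 49)
        c_axis = np.linspace(0.2, 2.0, 19)
        surf = productivity_surface(
            params, geometry, {"T": T_axis, "c_X0": c_axis}, fixed={"t_cyc": 1.0}
        )
        i, _ = np.unravel_index(np.argmax(surf), surf.shape)
        assert T_axis[i] == pytest.approx(params.T_opt, abs=0.3)

    def test_grid_maximum_below_optimizer(self, params, geometry, table3):
        c_axis = np.linspace(0.1, 2.0, 39)
        surf = productivity_surface(
            params, geometry, {"t_cyc": np.array([1.0, 2.0]), "c_X0": c_axis}
        )
        assert surf.max() <= table3[1.0].Pr_opt + 1e-3

    def test_refinement_stability(self, params, geometry):
        c_coarse = np.linspace(0.2, 1.6, 15)
        c_fine = np.linspace(0.2, 1.6, 29)
        s1 = productivity_surface(
            params, geometry, {"T": np.array([26.0, 28.0]), "c_X0": c_coarse},
            fixed={"t_cyc": 1.0},
        )
        s2 = productivity_surface(
            params, geometry, {"T": np.array([26.0, 28.0]), "c_X0": c_fine},
            fixed={"t_cyc": 1.0},
        )
        coarse_cell = c_coarse[1] - c_coarse[0]
        assert abs(c_fine[np.argmax(s2[1])] - c_coarse[np.argmax(s1[1])]) <= coarse_cell

    def test_degenerate_axes_rejected(self, params, geometry):
        with pytest.raises(ValueError):
            productivity_surface(params, geometry, {"t_cyc": np.array([1.0])})


class TestCampaignReoptimization:
    def test_reference_campaign_mean_and_median(self, params, geometry):
        t_cycs = reference_campaign_design()["t_cyc_d"]
        out = reoptimized_campaign(t_cycs, params, geometry)
        assert len(out["per_experiment"]) == 15
        # week-long cycles cap the per-cycle optimum near 0.37, which pins
        # the campaign mean well below the short-cycle optima
        assert out["mean_Pr"] == pytest.approx(0.438, abs=0.005)
        assert out["median_Pr"] == pytest.approx(0.459, abs=0.005)

    def test_uniform_one_day_campaign(self, params, geometry):
        out = reoptimized_campaign([1.0] * 3, params, geometry)
        assert out["mean_Pr"] == pytest.approx(0.50, abs=0.01)

    def test_empty_campaign_rejected(self, params, geometry):
        with pytest.raises(ValueError):
            reoptimized_campaign([], params, geometry)
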