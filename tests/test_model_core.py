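"""Algebraic core: CTMI factor, Monod-with-maintenance kinetics, light map."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from algrow.model import (
    GrowthParameters,
    ctmi_phi,
    growth_yield,
    mu_opt,
    specific_growth_rate,
    validate_cardinal_temperatures,
)
from algrow.reactor import (
    ReactorGeometry,
    equivalent_path_length,
    specific_photon_availability,
    total_photon_flux,
)


def ctmi_direct(T, t_min, t_opt, t_max):
    """Independent term-by-term transcription of the CTMI expression,
    used as an oracle against the vectorized implementation."""
    if T <= t_min or T >= t_max:
        return 0.0
    numerator = (T - t_max) * (T - t_min) ** 2
    bracket = (t_opt - t_min) * (T - t_opt) - (t_opt - t_max) * (t_opt + t_min - 2 * T)
    return numerator / ((t_opt - t_min) * bracket)


@pytest.mark.parametrize(
    "triple,expected",
    [
        ((2.3, 27.93, 32.59), True),  # fitted reference cardinals
        ((0, 15, 40), False),  # optimum below the midpoint
        ((0, 20, 40), False),  # exactly at the midpoint: strict inequality
        ((10, 5, 40), False),  # unordered
        ((np.nan, 20, 40), False),
    ],
)
def test_cardinal_triple_validity(triple, expected):
    assert validate_cardinal_temperatures(*triple) is expected


def test_growth_parameters_reject_invalid_cardinals():
    with pytest.raises(ValueError):
        GrowthParameters(1.0, 1.0, 0.1, 0.0, 20.0, 40.0)
    with pytest.raises(ValueError):
        GrowthParameters(-1.0, 1.0, 0.1, 2.3, 27.93, 32.59)


class TestCTMI:
    def test_boundary_and_optimum_values(self, params):
        assert ctmi_phi(params.T_opt, params) == pytest.approx(1.0, abs=1e-12)
        assert ctmi_phi(params.T_min, params) == 0.0
        assert ctmi_phi(params.T_max, params) == 0.0
        assert ctmi_phi(params.T_min - 5.0, params) == 0.0
        assert ctmi_phi(params.T_max + 5.0, params) == 0.0

    def test_matches_direct_transcription(self, params):
        for T in np.linspace(params.T_min - 2, params.T_max + 2, 97):
            assert ctmi_phi(float(T), params) == pytest.approx(
                ctmi_direct(float(T), params.T_min, params.T_opt, params.T_max),
                abs=1e-12,
            )

    def test_unit_interval_and_unique_maximum(self, params):
        grid = np.linspace(params.T_min + 1e-6, params.T_max - 1e-6, 4001)
        phi = ctmi_phi(grid, params)
        assert np.all(phi >= 0.0) and np.all(phi <= 1.0 + 1e-12)
        away = np.abs(grid - params.T_opt) > 0.05
        assert np.all(phi[away] < 1.0)

    @settings(deadline=None, derandomize=True)
    @given(
        t_min=st.floats(-5, 15),
        gap1=st.floats(1.0, 25.0),
        gap2=st.floats(0.5, 10.0),
        frac=st.floats(0.001, 0.999),
    )
    def test_bounded_for_arbitrary_valid_triples(self, t_min, gap1, gap2, frac):
        t_opt = t_min + gap1
        t_max = t_opt + gap2
        if not validate_cardinal_temperatures(t_min, t_opt, t_max):
            return
        p = GrowthParameters(1.0, 1.0, 0.0, t_min, t_opt, t_max)
        T = t_min + frac * (t_max - t_min)
        assert -1e-9 <= ctmi_phi(T, p) <= 1.0 + 1e-9


class TestMuOpt:
    def test_identities(self, params):
        assert mu_opt(params.m_ph, params) == 0.0
        half = mu_opt(params.m_ph + params.K_S_ph, params)
        assert half == pytest.approx(params.mu_max / 2, rel=1e-12)
        assert mu_opt(1e9, params) == pytest.approx(params.mu_max, rel=1e-6)

    def test_monotone_and_bounded(self, params):
        q = np.linspace(0.0, 20.0, 2001)
        mu = mu_opt(q, params)
        assert np.all(np.diff(mu) >= 0)
        assert np.all(mu <= params.mu_max)

    def test_negative_below_maintenance(self, params):
        assert mu_opt(params.m_ph / 2, params) < 0.0

    def test_domain_error(self):
        p = GrowthParameters(1.0, 0.5, 2.0, 2.3, 27.93, 32.59)
        with pytest.raises(ValueError):
            mu_opt(1.0, p)  # q - m = -1 <= -K


def test_specific_growth_rate_is_exact_product(params):
    q = np.linspace(0.1, 5.0, 57)
    for T in (15.0, 24.0, params.T_opt, 30.0):
        np.testing.assert_array_equal(
            specific_growth_rate(q, T, params), mu_opt(q, params) * ctmi_phi(T, params)
        )
    assert specific_growth_rate(1.0, params.T_min - 1, params) == 0.0


class TestGrowthYield:
    def test_reference_value(self, params):
        # Y = mu_opt / (q - m) at q = 1.9 with the fitted parameters
        q = 1.9
        y = growth_yield(mu_opt(q, params), q, params)
        assert y == pytest.approx(1.56 / (1.9 - 0.346 + 1.89), rel=1e-9)
        assert y == pytest.approx(0.453, abs=0.001)

    def test_limit_toward_maintenance(self, params):
        q = params.m_ph + 1e-9
        y = growth_yield(mu_opt(q, params), q, params)
        assert y == pytest.approx(params.mu_max / params.K_S_ph, rel=1e-6)

    def test_error_at_maintenance(self, params):
        with pytest.raises(ValueError):
            growth_yield(0.0, params.m_ph, params)


class TestReactorLight:
    def test_path_length(self):
        assert equivalent_path_length(0.020) == pytest.approx(0.0314159, abs=1e-6)
        assert equivalent_path_length(2 / np.pi) == pytest.approx(1.0, rel=1e-12)
        with pytest.raises(ValueError):
            equivalent_path_length(0.0)

    def test_total_flux_pilot_reactor(self, geometry):
        # sum of the 20 intensities is 6739 umol m^-2 s^-1
        assert sum(geometry.I0) == 6739
        assert geometry.c == 20
        flux = total_photon_flux(geometry)
        assert flux == pytest.approx(6739 * (1.269 / 20) * 86400e-6, rel=1e-12)
        assert flux == pytest.approx(36.95, abs=0.01)

    def test_unit_round_trip(self):
        g = ReactorGeometry(r=0.02, V_L=0.03, A=1.0, I0=(1e6 / 86400,))
        assert total_photon_flux(g) == pytest.approx(1.0, rel=1e-12)
        g0 = ReactorGeometry(r=0.02, V_L=0.03, A=1.0, I0=(0.0, 0.0))
        assert total_photon_flux(g0) == 0.0

    def test_specific_availability(self, geometry):
        la = specific_photon_availability(1.07, geometry)
        assert la.q_ph == pytest.approx(36.94373712 / (30 * 1.07), rel=1e-9)
        assert la.q_ph == pytest.approx(1.151, abs=0.002)
        la2 = specific_photon_availability(0.648, geometry)
        assert la2.q_ph == pytest.approx(1.90, abs=0.01)
        with pytest.raises(ValueError):
            specific_photon_availability(0.0, geometry)

    def test_photon_supply_conservation(self, geometry):
        ref = specific_photon_availability(1.0, geometry).q_ph
        for c in np.geomspace(0.05, 10, 25):
            la = specific_photon_availability(c, geometry)
            assert la.q_ph * c == pytest.approx(ref, rel=1e-12)
        assert specific_photon_availability(2.0, geometry).q_ph == pytest.approx(
            specific_photon_availability(1.0, geometry).q_ph / 2, rel=1e-12
        )

    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            ReactorGeometry(r=0.02, V_L=0.03, A=1.0, I0=())
        with pytest.raises(ValueError):
            ReactorGeometry(r=0.02, V_L=0.03, A=1.0, I0=(-1.0,))
        g = ReactorGeometry(r=0.02, V_L=0.03, A=1.0, I0=(10.0,) * 4)
        assert g.A_z * g.c == pytest.approx(g.A, rel=1e-12)
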