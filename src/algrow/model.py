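"""Growth kinetics of light-limited microalgal cultures.

The specific growth rate is modeled as a product of two factors,

    mu(q_ph, T) = mu_opt(q_ph) * phi(T),

where ``mu_opt`` is a Monod-type function of the biomass-specific photon
availability rate ``q_ph`` [mol_ph g^-1 d^-1] with a photon maintenance
offset, evaluated at the optimum temperature, and ``phi`` is the Cardinal
Temperature Model with Inflexion (CTMI): a dimensionless factor in [0, 1]
defined by the three cardinal temperatures (T_min, T_opt, T_max), zero
outside the growth range and exactly 1 at T_opt.

Units follow the conventions used throughout the package: rates in 1/d,
specific photon rates in mol_ph g^-1 d^-1, temperatures in deg C.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GrowthParameters",
    "validate_cardinal_temperatures",
    "ctmi_phi",
    "mu_opt",
    "specific_growth_rate",
    "growth_yield",
]


def validate_cardinal_temperatures(t_min: float, t_opt: float, t_max: float) -> bool:
    """Check a cardinal temperature triple for CTMI validity.

    Valid iff ``t_min < t_opt < t_max`` and ``t_opt`` lies strictly above
    the midpoint ``(t_min + t_max) / 2``, i.e. closer to ``t_max`` than to
    ``t_min``.  The strict midpoint inequality is what produces the
    asymmetric, inflected shape of the temperature response; triples on
    the boundary are rejected.
    """
    if not (np.isfinite(t_min) and np.isfinite(t_opt) and np.isfinite(t_max)):
        return False
    return bool(t_min < t_opt < t_max and t_opt > 0.5 * (t_min + t_max))


@dataclass(frozen=True)
class GrowthParameters:
    """The six kinetic/thermal parameters of the growth model.

    Parameters
    ----------
    mu_max : float
        Maximum specific growth rate [1/d]; > 0.
    K_S_ph : float
        Specific photon half-saturation constant [mol_ph g^-1 d^-1]; >= 0.
    m_ph : float
        Specific photon maintenance coefficient [mol_ph g^-1 d^-1]; >= 0.
        Photon flux diverted to non-growth purposes; offsets q_ph.
    T_min, T_opt, T_max : float
        Cardinal temperatures [deg C]; must form a valid CTMI triple.
    sigma : dict, optional
        Per-parameter standard deviations (e.g. from a jackknife analysis).
    ci95 : dict, optional
        Per-parameter (lower, upper) 95% confidence bounds.
    """

    mu_max: float
    K_S_ph: float
    m_ph: float
    T_min: float
    T_opt: float
    T_max: float
    sigma: dict | None = field(default=None, compare=False)
    ci95: dict | None = field(default=None, compare=False)

    PARAM_NAMES = ("mu_max", "K_S_ph", "m_ph", "T_min", "T_opt", "T_max")

    def __post_init__(self) -> None:
        if not self.mu_max > 0:
            raise ValueError(f"mu_max must be > 0, got {self.mu_max}")
        if self.K_S_ph < 0:
            raise ValueError(f"K_S_ph must be >= 0, got {self.K_S_ph}")
        if self.m_ph < 0:
            raise ValueError(f"m_ph must be >= 0, got {self.m_ph}")
        if not validate_cardinal_temperatures(self.T_min, self.T_opt, self.T_max):
            raise ValueError(
                "invalid cardinal temperatures: require "
                "T_min < T_opt < T_max and T_opt > (T_min + T_max)/2, got "
                f"({self.T_min}, {self.T_opt}, {self.T_max})"
            )

    def as_vector(self) -> np.ndarray:
        """Parameters as an array ordered like :attr:`PARAM_NAMES`."""
        return np.array(
            [self.mu_max, self.K_S_ph, self.m_ph, self.T_min, self.T_opt, self.T_max]
        )

    @classmethod
    def from_vector(cls, theta, sigma=None, ci95=None) -> "GrowthParameters":
        theta = np.asarray(theta, dtype=float)
        return cls(*theta[:6], sigma=sigma, ci95=ci95)


def ctmi_phi(T, params: GrowthParameters):
    """CTMI temperature factor phi(T) in [0, 1].

    Zero for T <= T_min or T >= T_max; 1 exactly at T = T_opt.  Accepts
    scalars or arrays.
    """
    t_min, t_opt, t_max = params.T_min, params.T_opt, params.T_max
    T = np.asarray(T, dtype=float)
    num = (T - t_max) * (T - t_min) ** 2
    den = (t_opt - t_min) * (
        (t_opt - t_min) * (T - t_opt) - (t_opt - t_max) * (t_opt + t_min - 2.0 * T)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where((T > t_min) & (T < t_max), num / den, 0.0)
    if phi.ndim == 0:
        return float(phi)
    return phi


def mu_opt(q_ph, params: GrowthParameters):
    """Monod-with-maintenance specific growth rate at T_opt [1/d].

    mu_opt = mu_max * (q_ph - m_ph) / (q_ph - m_ph + K_S_ph).

    Negative values (q_ph < m_ph, maintenance-dominated decline) are
    returned as-is, not clamped; the productivity optimizer relies on this
    penalty at excessive biomass concentrations.

    Raises
    ------
    ValueError
        If the denominator is non-positive (q_ph - m_ph <= -K_S_ph).
    """
    q_ph = np.asarray(q_ph, dtype=float)
    net = q_ph - params.m_ph
    den = net + params.K_S_ph
    if np.any(den <= 0):
        raise ValueError(
            "mu_opt undefined: q_ph - m_ph + K_S_ph <= 0 "
            f"(min denominator {np.min(den)})"
        )
    out = params.mu_max * net / den
    if out.ndim == 0:
        return float(out)
    return out


def specific_growth_rate(q_ph, T, params: GrowthParameters):
    """Combined specific growth rate mu(q_ph, T) = mu_opt(q_ph) * phi(T) [1/d]."""
    return mu_opt(q_ph, params) * ctmi_phi(T, params)


def growth_yield(mu_opt_value, q_ph, params: GrowthParameters):
    """Growth yield on photons Y_X,ph = mu_opt / (q_ph - m_ph) [g/mol_ph].

    With the Monod-with-maintenance kinetics substituted this equals
    ``mu_max / (q_ph - m_ph + K_S_ph)``; in the limit q_ph -> m_ph the
    quotient tends to ``mu_max / K_S_ph``.

    Raises
    ------
    ValueError
        If q_ph <= m_ph (no net photon supply for growth).
    """
    q_ph = np.asarray(q_ph, dtype=float)
    net = q_ph - params.m_ph
    if np.any(net <= 0):
        raise ValueError("growth yield undefined for q_ph <= m_ph")
    out = np.asarray(mu_opt_value, dtype=float) / net
    if out.ndim == 0:
        return float(out)
    return out
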