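"""Reactor geometry and light availability for a compartmented tubular PBR.

The tubular photobioreactor is modeled as ``c`` one-sidedly illuminated
compartments of equal projection area ``A_z = A / c``.  Each compartment
carries a constant surface light intensity; the biomass-specific photon
availability rate follows from the summed photon flux,

    q_ph(c_X) = 1 / (V_L * c_X) * sum_z I_0,z * A_z,

with I_0 converted from umol_ph m^-2 s^-1 to mol_ph m^-2 d^-1 assuming
permanent (24 h) illumination.  Concentrations are handled in g/L with
the liquid volume in L, so q_ph comes out in mol_ph g^-1 d^-1.

A bundled description of the 30 L pilot-scale reactor used throughout the
analyses (20 compartments, measured light map) is available via
:func:`pilot_reactor`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from math import pi

import numpy as np
import yaml

__all__ = [
    "ReactorGeometry",
    "LightAvailability",
    "equivalent_path_length",
    "total_photon_flux",
    "specific_photon_availability",
    "load_reactor",
    "pilot_reactor",
]

#: umol m^-2 s^-1  ->  mol m^-2 d^-1 under 24 h illumination
_UMOL_S_TO_MOL_D = 86400.0e-6


@dataclass(frozen=True)
class ReactorGeometry:
    """Geometry and surface light map of a compartmented tubular reactor.

    Parameters
    ----------
    r : float
        Glass tube inner radius [m].
    V_L : float
        Total liquid volume [m^3].
    A : float
        Illuminated reactor projection surface [m^2].
    I0 : tuple of float
        Per-compartment surface light intensities [umol_ph m^-2 s^-1];
        the compartment count is ``len(I0)``.
    """

    r: float
    V_L: float
    A: float
    I0: tuple

    def __post_init__(self) -> None:
        if not (self.r > 0 and self.V_L > 0 and self.A > 0):
            raise ValueError("r, V_L and A must all be positive")
        if len(self.I0) == 0:
            raise ValueError("light map is empty")
        if any(i < 0 for i in self.I0):
            raise ValueError("light intensities must be non-negative")
        object.__setattr__(self, "I0", tuple(float(i) for i in self.I0))

    @property
    def c(self) -> int:
        """Number of modeled compartments."""
        return len(self.I0)

    @property
    def A_z(self) -> float:
        """Per-compartment projection area [m^2] (equal split A / c)."""
        return self.A / self.c

    @property
    def V_L_litres(self) -> float:
        return self.V_L * 1000.0


@dataclass(frozen=True)
class LightAvailability:
    """Photon supply at a given biomass concentration."""

    q_ph: float  # mol_ph g^-1 d^-1
    total_flux: float  # mol_ph d^-1

    def __post_init__(self) -> None:
        if self.q_ph < 0 or self.total_flux < 0:
            raise ValueError("photon quantities must be non-negative")


def equivalent_path_length(r: float) -> float:
    """Average light path length pi*r/2 [m] of the flat-panel equivalent.

    A tube of inner radius ``r`` treated as a flat panel of equal volume
    has this mean optical path.  Raises on non-positive radius.
    """
    if not r > 0:
        raise ValueError(f"radius must be positive, got {r}")
    return pi * r / 2.0


def total_photon_flux(geometry: ReactorGeometry) -> float:
    """Total photon flux sum_z I_0,z * A_z [mol_ph/d] under 24 h light."""
    return float(np.sum(geometry.I0) * geometry.A_z * _UMOL_S_TO_MOL_D)


def specific_photon_availability(c_X, geometry: ReactorGeometry) -> LightAvailability:
    """Biomass-specific photon availability rate at concentration ``c_X`` [g/L].

    Strictly decreasing in c_X; the product q_ph * c_X is a constant of
    the geometry (conservation of photon supply).
    """
    c_X = float(c_X)
    if c_X <= 0:
        raise ValueError("c_X must be positive (q_ph is unbounded at zero biomass)")
    flux = total_photon_flux(geometry)
    return LightAvailability(q_ph=flux / (geometry.V_L_litres * c_X), total_flux=flux)


def photon_supply_density(geometry: ReactorGeometry) -> float:
    """Volumetric photon supply S = total flux / V_L [mol_ph L^-1 d^-1].

    Convenience constant: q_ph(c_X) = S / c_X for c_X in g/L.
    """
    return total_photon_flux(geometry) / geometry.V_L_litres


def load_reactor(path) -> ReactorGeometry:
    """Read a reactor description file (YAML).

    Expected keys: ``r_m``, ``V_L_m3``, ``A_m2`` and ``compartments`` (list
    of surface intensities in umol_ph m^-2 s^-1, row-major in the reactor's
    height/depth order).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    missing = {"r_m", "V_L_m3", "A_m2", "compartments"} - set(raw)
    if missing:
        raise ValueError(f"reactor file {path} missing keys: {sorted(missing)}")
    return ReactorGeometry(
        r=float(raw["r_m"]),
        V_L=float(raw["V_L_m3"]),
        A=float(raw["A_m2"]),
        I0=tuple(float(v) for v in raw["compartments"]),
    )


def pilot_reactor() -> ReactorGeometry:
    """The 30 L pilot-scale tubular photobioreactor (bundled description)."""
    ref = resources.files("algrow.data").joinpath("pilot_reactor.yaml")
    with resources.as_file(ref) as path:
        return load_reactor(path)
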