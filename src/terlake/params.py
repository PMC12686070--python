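"""Parameter and state containers for the lake chemostat model.

Units follow limnological convention: concentrations in mg m^-3 (equal to
ug L^-1), biomass in mg C m^-3, rates in d^-1, depth in m, irradiance in
umol photons m^-2 s^-1.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

from .errors import InvalidParameterError

#: Atomic masses used for mass -> molar conversion of N:P ratios.
N_MOLAR_MASS = 14.007
P_MOLAR_MASS = 30.974

#: Algal biomass (mg C m^-3) below which a steady state counts as washout.
WASHOUT_BIOMASS = 1e-3


@dataclass(frozen=True)
class ModelParams:
    """Physiological, physical and light parameters of the lake model.

    Defaults place the four reference supply scenarios in the intended
    limitation regimes: the two low-concentration scenarios are nutrient
    limited throughout, the two high-concentration scenarios are capped by
    algal self-shading (see :func:`terlake.scenarios.calibrate_light`).

    Attributes
    ----------
    mu_max:
        Maximum specific algal growth rate, d^-1.
    a:
        Dilution rate (inverse water residence time), d^-1.
    z_max:
        Maximum (mixed-layer) depth, m.
    m_N, m_P:
        Half-saturation constants for N and P limitation, mg m^-3.
    c_N, c_P:
        Algal N and P quotas, mg nutrient per mg C.
    I_in:
        Incident surface irradiance, umol photons m^-2 s^-1.
    h_I:
        Half-saturation irradiance for growth, same units as ``I_in``.
    k_bg:
        Background light attenuation, m^-1.
    k_A:
        Algal specific light attenuation, m^2 per mg C.
    o2_per_c:
        O2 produced per C fixed when converting production to oxygen units,
        mg O2 per mg C (32/12 corresponds to a photosynthetic quotient of 1).
    """

    mu_max: float = 1.0
    a: float = 0.1
    z_max: float = 2.5
    m_N: float = 10.8
    m_P: float = 1.5
    c_N: float = 0.1084
    c_P: float = 0.015
    I_in: float = 300.0
    h_I: float = 120.0
    k_bg: float = 0.2
    k_A: float = 7.3e-4
    o2_per_c: float = 32.0 / 12.0

    def __post_init__(self) -> None:
        for field in dataclasses.fields(self):
            value = getattr(self, field.name)
            if not isinstance(value, (int, float)):
                raise InvalidParameterError(f"{field.name} must be numeric, got {value!r}")
            if not value > 0:
                raise InvalidParameterError(
                    f"{field.name} must be strictly positive, got {value!r}"
                )
        if self.a >= self.mu_max:
            warnings.warn(
                f"dilution rate a={self.a} >= mu_max={self.mu_max}: "
                "algae cannot persist (washout regime)",
                stacklevel=2,
            )

    @property
    def consumption_ratio_molar(self) -> float:
        """Molar N:P ratio consumed per unit biomass built, (c_N/14.007)/(c_P/30.974)."""
        return (self.c_N / N_MOLAR_MASS) / (self.c_P / P_MOLAR_MASS)

    def replace(self, **changes: float) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class Supply:
    """Nutrient input concentrations, mg m^-3."""

    N_in: float
    P_in: float

    def __post_init__(self) -> None:
        if not self.N_in > 0:
            raise InvalidParameterError(f"N_in must be strictly positive, got {self.N_in!r}")
        if not self.P_in > 0:
            raise InvalidParameterError(f"P_in must be strictly positive, got {self.P_in!r}")


@dataclass
class ModelState:
    """State vector of the lake model: algae A (mg C m^-3), dissolved N and P (mg m^-3)."""

    A: float
    N: float
    P: float

    def __post_init__(self) -> None:
        # Clip tiny negative excursions produced by the integrator.
        for name in ("A", "N", "P"):
            value = getattr(self, name)
            if value < 0:
                if value > -1e-12:
                    setattr(self, name, 0.0)
                else:
                    raise InvalidParameterError(f"{name} must be non-negative, got {value!r}")
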