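"""Saltation hop-length physics.

Wind-blown sand-sized grains travel by saltation: successive ballistic
hops along the surface.  The characteristic horizontal length of one hop,
``L_salt``, follows the scaling

    L_salt = 1091.5 * (v**2 / g)**(1/3) * (u_star - u_star_t) / sqrt(g * d)

where ``v`` is the kinematic viscosity of the atmosphere (dynamic
viscosity / density), ``g`` the surface gravity, ``d`` the grain
diameter, ``u_star`` the shear (friction) velocity of the wind and
``u_star_t`` the impact-threshold shear velocity below which saltation
is not sustained.  All quantities are SI; lengths are returned in
metres.

The module ships Mars defaults (thin CO2 atmosphere, low gravity, shear
velocity taken as the midpoint of the 1.12-1.78 m/s estimate range)
under which a 1 mm grain hops about 29 m and a 0.125 mm grain about
81 m per hop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import BelowThresholdError, InvalidParameterError

__all__ = [
    "PlanetaryEnvironment",
    "WindRegime",
    "ParticleClass",
    "MARS_ENVIRONMENT",
    "MARS_WIND",
    "HOP_COEFFICIENT",
    "kinematic_viscosity",
    "hop_length",
]

#: Dimensionless prefactor of the hop-length scaling law.
HOP_COEFFICIENT = 1091.5


@dataclass(frozen=True)
class PlanetaryEnvironment:
    """Atmosphere and gravity defining the saltation regime.

    Parameters
    ----------
    dynamic_viscosity : float
        Dynamic viscosity of the near-surface atmosphere, kg m^-1 s^-1.
    fluid_density : float
        Atmospheric density, kg m^-3.
    gravity : float
        Surface gravitational acceleration, m s^-2.
    """

    dynamic_viscosity: float
    fluid_density: float
    gravity: float

    def __post_init__(self) -> None:
        for name in ("dynamic_viscosity", "fluid_density", "gravity"):
            value = getattr(self, name)
            if not (value > 0.0 and math.isfinite(value)):
                raise InvalidParameterError(
                    f"{name} must be strictly positive and finite, got {value!r}"
                )

    @property
    def kinematic_viscosity(self) -> float:
        """Kinematic viscosity v = eta / rho, m^2 s^-1."""
        return self.dynamic_viscosity / self.fluid_density


@dataclass(frozen=True)
class WindRegime:
    """Wind forcing: shear velocity and impact threshold, both m s^-1.

    ``shear_velocity`` may equal the threshold (hop length degenerates to
    zero) but sustained saltation requires it to be at least the
    threshold; that ordering is checked by :func:`hop_length`, not here,
    so that sub-threshold regimes remain representable.
    """

    shear_velocity: float
    impact_threshold: float

    def __post_init__(self) -> None:
        for name in ("shear_velocity", "impact_threshold"):
            value = getattr(self, name)
            if not (value > 0.0 and math.isfinite(value)):
                raise InvalidParameterError(
                    f"{name} must be strictly positive and finite, got {value!r}"
                )

    @property
    def excess_shear(self) -> float:
        """u_star - u_star_t, the saltation-driving velocity excess."""
        return self.shear_velocity - self.impact_threshold


@dataclass(frozen=True)
class ParticleClass:
    """A saltating grain size class with diameter ``d`` in metres."""

    diameter: float

    def __post_init__(self) -> None:
        if not (self.diameter > 0.0 and math.isfinite(self.diameter)):
            raise InvalidParameterError(
                f"particle diameter must be strictly positive, got {self.diameter!r}"
            )


#: Mars near-surface atmosphere and gravity.
MARS_ENVIRONMENT = PlanetaryEnvironment(
    dynamic_viscosity=1.3e-5, fluid_density=0.02, gravity=3.71
)

#: Mars wind regime: shear velocity at the midpoint of the estimated
#: 1.12-1.78 m/s range, impact threshold at the bottom of it.
MARS_WIND = WindRegime(shear_velocity=1.45, impact_threshold=1.12)


def kinematic_viscosity(env: PlanetaryEnvironment) -> float:
    """Return the kinematic viscosity eta/rho of ``env`` in m^2 s^-1."""
    return env.kinematic_viscosity


def hop_length(
    env: PlanetaryEnvironment, wind: WindRegime, particle: ParticleClass
) -> float:
    """Saltation hop length L_salt in metres.

    Evaluates ``1091.5 * (v^2/g)^(1/3) * (u* - u*t) / sqrt(g d)``.  The
    result scales as ``d**-0.5`` in grain diameter and linearly in the
    shear-velocity excess; it is exactly zero when the shear velocity
    equals the impact threshold.

    Raises
    ------
    BelowThresholdError
        If the shear velocity is below the impact threshold (no
        sustained saltation, so no hop length is defined).
    """
    if wind.shear_velocity < wind.impact_threshold:
        raise BelowThresholdError(
            f"shear velocity {wind.shear_velocity} m/s is below the impact "
            f"threshold {wind.impact_threshold} m/s: no sustained saltation"
        )
    v = env.kinematic_viscosity
    g = env.gravity
    return (
        HOP_COEFFICIENT
        * (v * v / g) ** (1.0 / 3.0)
        * wind.excess_shear
        / math.sqrt(g * particle.diameter)
    )
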