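"""Physical property types and settling laws for blood-cell centrifugation.

Plasma is the continuous phase; red cells, white cells and platelets are
dispersed phases treated as rigid spheres of uniform size and density.
A single particle settles at the Stokes terminal velocity; a suspension
settles slower because of particle crowding and the return backflow of
displaced plasma, which is modelled by the Richardson-Zaki hindered
settling law with exponent ``m`` and a packing cut-off ``alpha_max`` at
which the solids flux vanishes (the packed bed is absorbing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: Standard gravitational acceleration (m/s^2).
G_STANDARD = 9.81

#: Particle Reynolds number above which the Richardson-Zaki exponent
#: m = 5 is no longer a good description of hindered settling.
REYNOLDS_VALIDITY_BOUND = 0.2


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


@dataclass(frozen=True)
class FluidPhase:
    """Continuous (liquid) phase.

    Parameters
    ----------
    density : float
        Mass density in kg/m^3.
    viscosity : float
        Dynamic viscosity in Pa*s.
    """

    density: float
    viscosity: float

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise InvalidParameterError("fluid density must be positive")
        if self.viscosity <= 0:
            raise InvalidParameterError("fluid viscosity must be positive")


@dataclass(frozen=True)
class ParticleSpecies:
    """Dispersed (solid) phase: a rigid sphere population.

    Parameters
    ----------
    name : str
        Label, e.g. ``"RBC"``, ``"WBC"``, ``"PLT"``.
    diameter : float
        Sphere diameter in metres.
    density : float
        Mass density in kg/m^3.
    """

    name: str
    diameter: float
    density: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise InvalidParameterError("particle diameter must be positive")
        if self.density <= 0:
            raise InvalidParameterError("particle density must be positive")


@dataclass(frozen=True)
class SettlingModel:
    """Hindered-settling (Richardson-Zaki) description of one species.

    Parameters
    ----------
    u_inf : float
        Terminal settling velocity of an isolated particle under 1 g, m/s.
    m_exponent : float
        Richardson-Zaki index; 5 is the low-Reynolds-number value for
        rigid spheres.
    alpha_max : float
        Maximum attainable solids volume fraction in the packed bed.
        0.8 is used for blood cells, which deform when packed.
    """

    u_inf: float
    m_exponent: float = 5.0
    alpha_max: float = 0.8

    def __post_init__(self) -> None:
        if self.m_exponent <= 0:
            raise InvalidParameterError("m_exponent must be positive")
        if not 0 < self.alpha_max <= 1:
            raise InvalidParameterError("alpha_max must lie in (0, 1]")


@dataclass(frozen=True)
class CentrifugeProtocol:
    """One centrifugation run: constant spin speed for a fixed duration.

    ``acceleration_g`` is the relative centrifugal acceleration at the
    tube bottom, a_c/g = omega^2 R_o / g.
    """

    acceleration_g: float
    spin_time: float
    gravity: float = G_STANDARD

    def __post_init__(self) -> None:
        if self.acceleration_g <= 0:
            raise InvalidParameterError("acceleration_g must be positive")
        if self.spin_time <= 0:
            raise InvalidParameterError("spin_time must be positive")


# Default constituent properties (SI units).
PLASMA = FluidPhase(density=1032.0, viscosity=1.0e-3)
RBC = ParticleSpecies("RBC", diameter=8.0e-6, density=1125.0)
WBC = ParticleSpecies("WBC", diameter=10.0e-6, density=1065.0)
PLT = ParticleSpecies("PLT", diameter=1.0e-6, density=1050.0)

#: Typical initial volume fraction of white blood cells in whole blood.
BETA_O_DEFAULT = 0.01


def stokes_settling_velocity(
    species: ParticleSpecies, fluid: FluidPhase, gravity: float = G_STANDARD
) -> float:
    """Terminal velocity of an isolated sphere, (rho_s - rho_l) d^2 g / (18 mu).

    Positive toward the tube bottom; negative for particles lighter than
    the suspending fluid (they cream instead of settling).
    """
    return (
        (species.density - fluid.density)
        * species.diameter**2
        * gravity
        / (18.0 * fluid.viscosity)
    )


def centrifugal_settling_velocity(
    species: ParticleSpecies, fluid: FluidPhase, protocol: CentrifugeProtocol
) -> float:
    """Terminal velocity under the centrifugal field at the tube bottom.

    U_o = u_inf * (a_c / g): Stokes' law with g replaced by omega^2 R_o.
    """
    u_inf = stokes_settling_velocity(species, fluid, protocol.gravity)
    return u_inf * protocol.acceleration_g


def particle_reynolds(
    species: ParticleSpecies, fluid: FluidPhase, protocol: CentrifugeProtocol
) -> float:
    """Particle Reynolds number Re_p = rho_l |U_o| d / mu_l.

    Emits a ``UserWarning`` when Re_p >= 0.2, outside the validity range
    of the m = 5 hindered-settling exponent.
    """
    u_o = centrifugal_settling_velocity(species, fluid, protocol)
    re_p = fluid.density * abs(u_o) * species.diameter / fluid.viscosity
    if re_p >= REYNOLDS_VALIDITY_BOUND:
        warnings.warn(
            f"particle Reynolds number {re_p:.3g} exceeds the validity "
            f"bound {REYNOLDS_VALIDITY_BOUND} for the m = 5 hindered-"
            "settling exponent",
            UserWarning,
            stacklevel=2,
        )
    return re_p


def settling_model_for(
    species: ParticleSpecies,
    fluid: FluidPhase,
    gravity: float = G_STANDARD,
    m_exponent: float = 5.0,
    alpha_max: float = 0.8,
) -> SettlingModel:
    """Build the hindered-settling model of a species in a fluid."""
    return SettlingModel(
        u_inf=stokes_settling_velocity(species, fluid, gravity),
        m_exponent=m_exponent,
        alpha_max=alpha_max,
    )


def batch_flux(alpha, model: SettlingModel):
    """Kynch batch flux density function (m/s), vectorised over ``alpha``.

    f_bk(alpha) = -u_inf * alpha * (1 - alpha)^m   for 0 < alpha < alpha_max
                = 0                                otherwise.

    The sign convention follows the height-above-bottom axis: a negative
    flux moves solids toward the tube bottom.  The flux is clamped to
    exactly zero at and above ``alpha_max``: the packed bed absorbs
    arriving particles and releases none.
    """
    a = np.asarray(alpha, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise InvalidParameterError("alpha must lie in [0, 1]")
    inside = (a > 0) & (a < model.alpha_max)
    out = np.where(inside, -model.u_inf * a * (1.0 - a) ** model.m_exponent, 0.0)
    if np.isscalar(alpha) or np.ndim(alpha) == 0:
        return float(out)
    return out
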