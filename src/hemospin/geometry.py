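"""Tube geometry: cross-section profiles and volume/height conversions.

The radial coordinate r runs from the rotation centre toward the tube
bottom, which sits at r = R_o (``rotor_radius``).  User-facing interface
positions are reported as heights above the tube bottom, so the upper
(plasma) layer volume reads literally as the column between the mixture
surface at height L and the supernatant front at height I_ns.

Two bottom shapes are supported: a flat bottom (constant cross-section
A = pi D^2 / 4) and a conical bottom modelled as a frustum that tapers
linearly from ``cone_top_diameter`` (the full tube diameter by default)
at the cylinder-cone junction down to ``cone_bottom_diameter`` at the
bottom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import InvalidParameterError


class CapacityError(ValueError):
    """Requested volume exceeds the tube capacity."""


@dataclass(frozen=True)
class TubeGeometry:
    rotor_radius: float  # R_o, m
    tube_diameter: float  # D, m
    straight_area: float  # A = pi D^2 / 4, m^2
    capacity: float  # V_t, m^3
    bottom_shape: str = "flat"  # "flat" | "conical"
    cone_height: float = 0.0  # h_c, m (conical only)
    cone_bottom_diameter: float = 0.0  # d_b, m (conical only; 0 = apex)
    cone_top_diameter: float = 0.0  # m (conical only; 0 = tube diameter)

    def __post_init__(self) -> None:
        if self.rotor_radius <= 0:
            raise InvalidParameterError("rotor_radius must be positive")
        if self.capacity <= 0:
            raise InvalidParameterError("capacity must be positive")
        if self.bottom_shape not in ("flat", "conical"):
            raise InvalidParameterError(
                f"unknown bottom_shape {self.bottom_shape!r}"
            )
        if self.bottom_shape == "conical":
            if not 0 < self.cone_height < self.rotor_radius:
                raise InvalidParameterError(
                    "cone_height must lie in (0, rotor_radius)"
                )
            top = self.cone_top_diameter or self.tube_diameter
            if not 0 < top <= self.tube_diameter:
                raise InvalidParameterError(
                    "cone_top_diameter must lie in (0, tube_diameter]"
                )
            if not 0 <= self.cone_bottom_diameter < top:
                raise InvalidParameterError(
                    "cone_bottom_diameter must lie in [0, cone top diameter)"
                )

    # -- constructors -------------------------------------------------

    @staticmethod
    def flat(
        rotor_radius: float = 0.150,
        area: float = 120e-6,
        capacity: float = 15e-6,
    ) -> "TubeGeometry":
        """Flat-bottom tube; defaults are a 15 mL tube with A = 120 mm^2
        at R_o = 150 mm."""
        return TubeGeometry(
            rotor_radius=rotor_radius,
            tube_diameter=math.sqrt(4.0 * area / math.pi),
            straight_area=area,
            capacity=capacity,
        )

    @staticmethod
    def conical(
        rotor_radius: float = 0.150,
        area: float = 120e-6,
        capacity: float = 15e-6,
        cone_height: float | None = None,
        cone_bottom_diameter: float | None = None,
        cone_top_diameter: float = 0.0,
    ) -> "TubeGeometry":
        """Conical-bottom (Falcon-style) tube.

        Defaults: a frustum of height 0.2 R_o tapering from the full tube
        diameter D at the cylinder-cone junction down to 0.25 D at the
        bottom, matching a clinical conical tube whose bore must meet the
        cylinder at full width.  A narrower ``cone_top_diameter`` (with a
        step at the junction) is also supported.
        """
        diameter = math.sqrt(4.0 * area / math.pi)
        if cone_height is None:
            cone_height = 0.2 * rotor_radius
        if cone_bottom_diameter is None:
            cone_bottom_diameter = 0.25 * diameter
        return TubeGeometry(
            rotor_radius=rotor_radius,
            tube_diameter=diameter,
            straight_area=area,
            capacity=capacity,
            bottom_shape="conical",
            cone_height=cone_height,
            cone_bottom_diameter=cone_bottom_diameter,
            cone_top_diameter=cone_top_diameter,
        )

    # -- profile ------------------------------------------------------

    @property
    def usable_length(self) -> float:
        """Fill height that exactly holds the rated capacity."""
        return height_from_volume(self, self.capacity)

    @property
    def cone_top(self) -> float:
        """Effective diameter at the top of the conical section."""
        return self.cone_top_diameter or self.tube_diameter

    def diameter_at(self, r):
        """Tube diameter at radial position r (vectorised).

        When ``cone_top_diameter`` is narrower than the tube, the area
        steps down at the cylinder-cone junction; the annular shelf is
        treated as wall.
        """
        r = np.asarray(r, dtype=float)
        if self.bottom_shape == "flat":
            return np.full_like(r, self.tube_diameter)
        junction = self.rotor_radius - self.cone_height
        in_cone = r >= junction - 1e-15
        frac = np.clip((r - junction) / self.cone_height, 0.0, 1.0)
        cone_d = self.cone_top + frac * (self.cone_bottom_diameter - self.cone_top)
        return np.where(in_cone, cone_d, self.tube_diameter)


def area_profile(geometry: TubeGeometry, r):
    """Cross-sectional area (m^2) at radial position(s) r.

    Constant in the cylindrical section; in the bottom cone the diameter
    tapers linearly, so the area is quadratic in r and continuous at the
    cylinder-cone junction.
    """
    r_arr = np.asarray(r, dtype=float)
    top = geometry.rotor_radius - geometry.usable_length
    if np.any(r_arr < top - 1e-12) or np.any(
        r_arr > geometry.rotor_radius + 1e-12
    ):
        raise InvalidParameterError("radial position outside the tube")
    area = math.pi / 4.0 * geometry.diameter_at(r_arr) ** 2
    if np.isscalar(r) or np.ndim(r) == 0:
        return float(area)
    return area


def _frustum_volume_from_bottom(geometry: TubeGeometry, height: float) -> float:
    """Volume between the tube bottom and ``height`` inside the cone."""
    d_b = geometry.cone_bottom_diameter
    d_top = geometry.cone_top
    h_c = geometry.cone_height
    if d_top == d_b:
        return math.pi / 4.0 * d_top**2 * height
    d_h = d_b + (d_top - d_b) * height / h_c
    # integral of pi d(h)^2 / 4 dh: frustum of height `height`
    return math.pi * height / 12.0 * (d_b**2 + d_b * d_h + d_h**2)


def volume_from_height(geometry: TubeGeometry, fill_height: float) -> float:
    """Volume (m^3) of the column between the bottom and ``fill_height``."""
    if fill_height < 0:
        raise InvalidParameterError("fill height must be non-negative")
    if geometry.bottom_shape == "flat":
        return geometry.straight_area * fill_height
    h_c = geometry.cone_height
    if fill_height <= h_c:
        return _frustum_volume_from_bottom(geometry, fill_height)
    return _frustum_volume_from_bottom(geometry, h_c) + geometry.straight_area * (
        fill_height - h_c
    )


def height_from_volume(geometry: TubeGeometry, volume: float) -> float:
    """Fill height L such that the column from the bottom holds ``volume``.

    Closed form in both sections: L = V/A for the cylinder, and a cube
    root of the frustum volume formula inside the cone.
    """
    if volume <= 0:
        raise InvalidParameterError("volume must be positive")
    if volume > geometry.capacity * (1 + 1e-12):
        raise CapacityError(
            f"volume {volume*1e6:.3f} mL exceeds tube capacity "
            f"{geometry.capacity*1e6:.3f} mL"
        )
    if geometry.bottom_shape == "flat":
        return volume / geometry.straight_area
    cone_vol = _frustum_volume_from_bottom(geometry, geometry.cone_height)
    if volume >= cone_vol:
        return geometry.cone_height + (volume - cone_vol) / geometry.straight_area
    # invert the frustum formula: d(h)^3 = d_b^3 + 12 V (d_top - d_b)/(pi h_c)
    d_b = geometry.cone_bottom_diameter
    d_top = geometry.cone_top
    h_c = geometry.cone_height
    d_cubed = d_b**3 + 12.0 * volume * (d_top - d_b) / (math.pi * h_c)
    d_at = d_cubed ** (1.0 / 3.0)
    return (d_at - d_b) * h_c / (d_top - d_b)


def volume_between(geometry: TubeGeometry, r_lo: float, r_hi: float) -> float:
    """Exact volume (m^3) between radial positions r_lo <= r_hi."""
    if r_hi < r_lo:
        raise InvalidParameterError("inverted radial bounds")
    h_hi = geometry.rotor_radius - r_lo  # upper height above bottom
    h_lo = geometry.rotor_radius - r_hi
    if h_lo < -1e-12:
        raise InvalidParameterError("radial position below the tube bottom")
    return volume_from_height(geometry, h_hi) - volume_from_height(
        geometry, max(h_lo, 0.0)
    )


@dataclass(frozen=True)
class MixtureColumn:
    """The whole-blood column occupying the bottom of the tube."""

    fill_height: float  # L, m
    whole_blood_volume: float  # V_WB, m^3
    top_radius: float  # R_o - L, m

    @staticmethod
    def from_volume(geometry: TubeGeometry, volume: float) -> "MixtureColumn":
        length = height_from_volume(geometry, volume)
        return MixtureColumn(
            fill_height=length,
            whole_blood_volume=volume,
            top_radius=geometry.rotor_radius - length,
        )


DEFAULT_FLAT_TUBE = TubeGeometry.flat()
DEFAULT_CONICAL_TUBE = TubeGeometry.conical()
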