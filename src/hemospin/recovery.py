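"""Layer interfaces and recovery rates.

After spinning, the column splits into a clear plasma layer, a retarded
settling (suspension) zone and a packed bed.  The supernatant/suspension
interface I_ns bounds the recoverable plasma volume V_UL from below;
the suspension/sediment interface I_sd is the top of the packed bed.
The white-cell layer sits between the white-cell supernatant front I_pW
(from an independent WBC solve) and the red-cell front I_ns.

Recovery rates:

    E_plas = V_UL / (V_WB (1 - H_e))
    E_WBC  = c_w * V_layer / (beta_o V_WB)

with H_e the hematocrit, beta_o the initial WBC volume fraction and c_w
an empirical capture coefficient of order 1e-3 to 1e-2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CentrifugeProtocol, InvalidParameterError
from .geometry import MixtureColumn, TubeGeometry, volume_between
from .solver import ConcentrationField

#: Default absolute concentration threshold for the clear-liquid front.
EPS_CLEAR_DEFAULT = 1e-3
#: Default margin below alpha_max for the packed-bed boundary.
EPS_PACKED_DEFAULT = 1e-3


@dataclass(frozen=True)
class InterfaceSet:
    """Layer boundaries at one instant, as heights above the tube bottom."""

    I_ns: float  # supernatant/suspension interface, m
    I_sd: float  # suspension/sediment interface, m
    time: float  # s
    all_clear: bool = False  # column fully clear at the threshold
    all_packed: bool = False  # no cell below the packed-bed threshold


@dataclass
class RecoveryResult:
    """Recovery rates and intermediates for one protocol."""

    E_plas: float
    E_PLT: float
    E_WBC: float
    V_UL: float  # m^3
    hematocrit: float
    c_w: float
    protocol: CentrifugeProtocol
    I_ns: float = float("nan")
    I_sd: float = float("nan")
    I_pW: float = float("nan")
    ratio: float = float("nan")  # E_PLT / E_plas from the correlation
    plt_clipped: bool = False
    plas_clipped: bool = False


def _crossing_height(
    heights: np.ndarray, alpha: np.ndarray, level: float, fill_height: float
):
    """Height of the topmost crossing of ``alpha`` through ``level``.

    ``heights`` decrease with index (index 0 is the column top).  Returns
    the linearly interpolated height of the first cell (from the top)
    with alpha >= level, together with degeneracy flags.
    """
    above = alpha >= level
    if not above.any():
        return 0.0, True  # nothing reaches the level
    i = int(np.argmax(above))
    if i == 0:
        return fill_height, False  # no clear zone above the first cell
    # linear interpolation between cell i-1 (below level) and i
    a0, a1 = alpha[i - 1], alpha[i]
    h0, h1 = heights[i - 1], heights[i]
    frac = (level - a0) / (a1 - a0)
    return float(h0 + frac * (h1 - h0)), False


def locate_interfaces(
    field: ConcentrationField,
    t: float,
    eps_clear: float = EPS_CLEAR_DEFAULT,
    eps_packed: float = EPS_PACKED_DEFAULT,
) -> InterfaceSet:
    """Extract I_ns and I_sd from a stored snapshot.

    ``t`` must be one of the field's stored times.  Interfaces are
    sub-cell interpolated at the levels ``eps_clear`` (clear liquid) and
    ``alpha_max - eps_packed`` (packed bed), measured as heights above
    the tube bottom.  Degenerate columns (all clear, or packed to the
    top) return flagged boundary values instead of raising.
    """
    idx = np.nonzero(np.isclose(field.times, t, rtol=1e-10, atol=1e-12))[0]
    if idx.size == 0:
        raise InvalidParameterError(f"time {t} s is not stored in the field")
    alpha = field.alpha[int(idx[0])]
    heights = field.heights
    fill = field.column.fill_height

    i_ns, all_clear = _crossing_height(heights, alpha, eps_clear, fill)
    level_packed = field.model.alpha_max - eps_packed
    i_sd, no_bed = _crossing_height(heights, alpha, level_packed, fill)
    all_packed = not no_bed and i_sd >= fill
    return InterfaceSet(
        I_ns=i_ns,
        I_sd=i_sd,
        time=float(t),
        all_clear=all_clear,
        all_packed=all_packed,
    )


def upper_layer_volume(
    interfaces: InterfaceSet, column: MixtureColumn, geometry: TubeGeometry
) -> float:
    """Volume of the clear plasma layer above I_ns (m^3).

    In a flat tube this is (L - I_ns) A; conical bottoms use the exact
    geometric integral.
    """
    r_o = geometry.rotor_radius
    return volume_between(
        geometry, r_o - column.fill_height, r_o - interfaces.I_ns
    )


def plasma_recovery(
    interfaces: InterfaceSet,
    column: MixtureColumn,
    geometry: TubeGeometry,
    hematocrit: float,
) -> float:
    """Plasma recovery E_plas = V_UL / (V_WB (1 - H_e)), clipped to [0, 1]."""
    if not 0 < hematocrit < 1:
        raise InvalidParameterError("hematocrit must lie in (0, 1)")
    v_ul = upper_layer_volume(interfaces, column, geometry)
    e_plas = v_ul / (column.whole_blood_volume * (1.0 - hematocrit))
    return float(min(max(e_plas, 0.0), 1.0))


def wbc_recovery(
    rbc_interfaces: InterfaceSet,
    wbc_interfaces: InterfaceSet,
    geometry: TubeGeometry,
    column: MixtureColumn,
    beta_o: float,
    c_w: float,
) -> float:
    """White-cell recovery from the buffy-layer thickness.

    The WBC-dominant layer spans heights [I_ns, I_pW]; its volume,
    scaled by the empirical capture coefficient c_w, is compared with
    the initial WBC volume beta_o V_WB.  Clipped below at zero (the
    white-cell front can numerically dip below the red-cell front when
    both are in the same smeared region).
    """
    if beta_o <= 0:
        raise InvalidParameterError("beta_o must be positive")
    i_pw = wbc_interfaces.I_ns  # the WBC field's own supernatant front
    thickness = i_pw - rbc_interfaces.I_ns
    if thickness <= 0:
        return 0.0
    r_o = geometry.rotor_radius
    layer_volume = volume_between(
        geometry, r_o - i_pw, r_o - rbc_interfaces.I_ns
    )
    return float(c_w * layer_volume / (beta_o * column.whole_blood_volume))


def fully_settled_plasma_bound(hematocrit: float, alpha_max: float) -> float:
    """Upper bound (1 - H_e/alpha_max) / (1 - H_e) on E_plas.

    Reached when every red cell has packed into a bed of height
    H_e L / alpha_max (flat tube mass balance).
    """
    return (1.0 - hematocrit / alpha_max) / (1.0 - hematocrit)
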