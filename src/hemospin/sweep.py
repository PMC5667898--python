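"""Protocol sweeps, critical accelerations and optimization maps.

The dimensionless sedimentation equation depends on time and spin speed
only through t* = t_c a_g u_inf / R_o, so an entire acceleration sweep
at fixed spin time (or time sweep at fixed acceleration) requires a
single solve per hematocrit, sampled at the per-protocol dimensionless
times.  The correlation ratio is evaluated analytically per protocol.

Averaging conventions: reported mean recoveries are arithmetic means
over the hematocrit set {0.37, 0.45, 0.52} and, for white cells, over
the endpoints {1e-3, 1e-2} of the empirical capture coefficient c_w.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    BETA_O_DEFAULT,
    CentrifugeProtocol,
    FluidPhase,
    G_STANDARD,
    InvalidParameterError,
    PLASMA,
    ParticleSpecies,
    RBC,
    SettlingModel,
    WBC,
    stokes_settling_velocity,
)
from .correlation import (
    CorrelationCoefficients,
    DEFAULT_COEFFICIENTS,
    pi_groups,
    platelet_plasma_ratio,
    platelet_recovery,
)
from .geometry import MixtureColumn, TubeGeometry, volume_between
from .recovery import (
    EPS_CLEAR_DEFAULT,
    EPS_PACKED_DEFAULT,
    InterfaceSet,
    RecoveryResult,
    _crossing_height,
    plasma_recovery,
    wbc_recovery,
)
from .solver import build_grid_arrays, solve_dimensionless

#: Validated parameter envelope; outside it the model extrapolates.
PAPER_REGIME = {
    "acceleration_g": (100.0, 1500.0),
    "spin_time_s": (120.0, 900.0),
    "hematocrit": (0.37, 0.52),
}


@dataclass
class SweepSpec:
    """Grids and study conditions for a protocol sweep."""

    geometry: TubeGeometry = field(default_factory=TubeGeometry.flat)
    whole_blood_volume: float = 9e-6  # m^3
    hematocrit_set: tuple = (0.37, 0.45, 0.52)
    c_w_set: tuple = (1e-3, 1e-2)
    acceleration_grid: np.ndarray = field(
        default_factory=lambda: np.arange(100.0, 1501.0, 20.0)
    )
    time_grid_min: tuple = (2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 15)
    rbc: ParticleSpecies = RBC
    wbc: ParticleSpecies = WBC
    fluid: FluidPhase = PLASMA
    beta_o: float = BETA_O_DEFAULT
    m_exponent: float = 5.0
    alpha_max: float = 0.8
    n_cells: int = 200
    cfl_number: float = 0.5
    eps_clear: float = EPS_CLEAR_DEFAULT
    eps_packed: float = EPS_PACKED_DEFAULT
    coefficients: CorrelationCoefficients = DEFAULT_COEFFICIENTS
    include_wbc: bool = True
    gravity: float = G_STANDARD

    def __post_init__(self) -> None:
        self.acceleration_grid = np.asarray(self.acceleration_grid, dtype=float)
        if self.acceleration_grid.size and np.any(
            np.diff(self.acceleration_grid) <= 0
        ):
            raise InvalidParameterError("acceleration grid must be increasing")
        lo, hi = PAPER_REGIME["acceleration_g"]
        if self.acceleration_grid.size and (
            self.acceleration_grid[0] < lo or self.acceleration_grid[-1] > hi
        ):
            warnings.warn(
                "acceleration grid extends outside the validated range "
                f"[{lo:.0f}g, {hi:.0f}g]; the model is unvalidated below "
                "about 100g where gravity is no longer negligible",
                UserWarning,
                stacklevel=2,
            )

    @property
    def column(self) -> MixtureColumn:
        return MixtureColumn.from_volume(self.geometry, self.whole_blood_volume)

    def rbc_model(self) -> SettlingModel:
        return SettlingModel(
            u_inf=stokes_settling_velocity(self.rbc, self.fluid, self.gravity),
            m_exponent=self.m_exponent,
            alpha_max=self.alpha_max,
        )

    def wbc_model(self) -> SettlingModel:
        return SettlingModel(
            u_inf=stokes_settling_velocity(self.wbc, self.fluid, self.gravity),
            m_exponent=self.m_exponent,
            alpha_max=self.alpha_max,
        )


def _front_heights(
    spec: SweepSpec, alpha_o: float, model: SettlingModel, t_stars: np.ndarray
) -> np.ndarray:
    """Supernatant-front heights (m) at the given dimensionless times.

    One dimensionless solve serves every requested time; the front is
    located by sub-cell interpolation at the clear-liquid threshold.
    """
    column = spec.column
    r_faces, r_centers, face_areas, cell_vols = build_grid_arrays(
        spec.geometry, column, spec.n_cells
    )
    order = np.argsort(t_stars, kind="stable")
    _, history = solve_dimensionless(
        np.full(spec.n_cells, alpha_o),
        r_faces,
        face_areas,
        cell_vols,
        model.m_exponent,
        model.alpha_max,
        spec.cfl_number,
        t_stars[order],
    )
    heights = spec.geometry.rotor_radius * (1.0 - r_centers)
    fronts_sorted = np.array(
        [
            _crossing_height(heights, snap, spec.eps_clear, column.fill_height)[0]
            for snap in history
        ]
    )
    fronts = np.empty_like(fronts_sorted)
    fronts[order] = fronts_sorted
    return fronts


def _eplas_from_fronts(
    spec: SweepSpec, fronts: np.ndarray, hematocrit: float
) -> np.ndarray:
    column = spec.column
    out = np.empty_like(fronts)
    for i, i_ns in enumerate(fronts):
        ifc = InterfaceSet(I_ns=float(i_ns), I_sd=0.0, time=0.0)
        out[i] = plasma_recovery(ifc, column, spec.geometry, hematocrit)
    return out


def _ratio_curve(spec: SweepSpec, t_c: float, accels: np.ndarray) -> np.ndarray:
    """Correlation ratio E_PLT/E_plas per acceleration at fixed spin time."""
    column = spec.column
    u_ref = stokes_settling_velocity(spec.rbc, spec.fluid, spec.gravity)
    c = spec.coefficients
    pi2 = spec.geometry.capacity / (
        spec.geometry.straight_area * column.fill_height
    )
    pi3 = t_c * u_ref / column.fill_height
    return np.exp(c.c2) * np.exp(
        c.c1 * pi2**c.e2 * pi3**c.e3 * np.asarray(accels, dtype=float) ** c.e4
    )


def _wbc_layer_volumes(
    spec: SweepSpec, i_pw: np.ndarray, i_ns: np.ndarray
) -> np.ndarray:
    """Buffy-layer volumes between the WBC and RBC supernatant fronts."""
    r_o = spec.geometry.rotor_radius
    vols = np.zeros_like(i_pw)
    for k in range(i_pw.size):
        if i_pw[k] > i_ns[k]:
            vols[k] = volume_between(
                spec.geometry, r_o - i_pw[k], r_o - i_ns[k]
            )
    return vols


def recovery_curve(spec: SweepSpec, t_c: float) -> pd.DataFrame:
    """Recovery rates over the acceleration grid at fixed spin time (s).

    One row per acceleration; per-hematocrit and averaged E_plas and
    E_PLT, plus c_w- and hematocrit-averaged E_WBC when requested.
    """
    accels = spec.acceleration_grid
    if accels.size == 0:
        return pd.DataFrame(
            columns=["t_c_min", "a_c_g", "E_plas_mean", "E_PLT_mean", "E_WBC_mean"]
        )
    rbc_model = spec.rbc_model()
    r_o = spec.geometry.rotor_radius
    t_stars_rbc = accels * t_c * rbc_model.u_inf / r_o

    data: dict = {
        "t_c_min": np.full(accels.size, t_c / 60.0),
        "a_c_g": accels,
    }
    ratio = _ratio_curve(spec, t_c, accels)
    data["ratio"] = ratio

    eplas_by_he = {}
    eplt_by_he = {}
    clip_any = np.zeros(accels.size, dtype=bool)
    fronts_by_he = {}
    for he in spec.hematocrit_set:
        fronts = _front_heights(spec, he, rbc_model, t_stars_rbc)
        fronts_by_he[he] = fronts
        eplas = _eplas_from_fronts(spec, fronts, he)
        eplt = np.minimum(ratio * eplas, 1.0)
        clip_any |= ratio * eplas > 1.0
        eplas_by_he[he] = eplas
        eplt_by_he[he] = eplt
        data[f"E_plas_He{he:g}"] = eplas
        data[f"E_PLT_He{he:g}"] = eplt
    data["E_plas_mean"] = np.mean(list(eplas_by_he.values()), axis=0)
    data["E_PLT_mean"] = np.mean(list(eplt_by_he.values()), axis=0)
    data["plt_clipped"] = clip_any

    if spec.include_wbc:
        # The white-cell concentration field is solved with the same
        # initial fraction as the red cells (weak-coupling surrogate:
        # white cells ride in the same crowded suspension and settle on
        # their own, slower velocity scale); the small true white-cell
        # fraction beta_o enters only the recovery normalisation.
        wbc_model = spec.wbc_model()
        t_stars_wbc = accels * t_c * wbc_model.u_inf / r_o
        c_w_mean = float(np.mean(spec.c_w_set))
        v_wb = spec.column.whole_blood_volume
        ewbc_by_he = []
        for he in spec.hematocrit_set:
            i_pw = _front_heights(spec, he, wbc_model, t_stars_wbc)
            data[f"I_pW_He{he:g}_m"] = i_pw
            vols = _wbc_layer_volumes(spec, i_pw, fronts_by_he[he])
            ewbc = c_w_mean * vols / (spec.beta_o * v_wb)
            data[f"E_WBC_He{he:g}"] = ewbc
            ewbc_by_he.append(ewbc)
        data["E_WBC_mean"] = np.mean(ewbc_by_he, axis=0)

    return pd.DataFrame(data)


@dataclass(frozen=True)
class CriticalPoint:
    """Location and value of a recovery-curve maximum."""

    acceleration_g: float
    e_max: float
    at_edge: bool = False
    tie: bool = False


def critical_acceleration(
    curve: pd.DataFrame, column: str = "E_PLT_mean"
) -> CriticalPoint:
    """Argmax of a recovery curve over acceleration.

    Interior maxima are refined by quadratic interpolation through the
    discrete peak and its neighbours (exact for parabolas).  A plateau
    (e.g. the clipped 100% region) returns its leftmost point with a tie
    flag; a maximum at a grid edge is returned with an edge flag.
    """
    if len(curve) < 3:
        raise InvalidParameterError("curve needs at least 3 points")
    x = curve["a_c_g"].to_numpy(dtype=float)
    y = curve[column].to_numpy(dtype=float)
    y_max = y.max()
    winners = np.nonzero(y >= y_max - 1e-12)[0]
    i = int(winners[0])
    if winners.size > 1:
        return CriticalPoint(
            acceleration_g=float(x[i]),
            e_max=float(y_max),
            at_edge=i == 0,
            tie=True,
        )
    if i == 0 or i == y.size - 1:
        return CriticalPoint(
            acceleration_g=float(x[i]), e_max=float(y[i]), at_edge=True
        )
    # quadratic through the three bracketing points
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:  # degenerate curvature; keep the grid point
        return CriticalPoint(acceleration_g=float(x1), e_max=float(y1))
    xv = -b / (2.0 * a)
    c0 = y1 - a * x1**2 - b * x1
    yv = a * xv**2 + b * xv + c0
    return CriticalPoint(acceleration_g=float(xv), e_max=float(yv))


def polar_curve(spec: SweepSpec, t_c_list) -> pd.DataFrame:
    """(E_plas, E_PLT) pairs over the acceleration grid for several spin
    times.  Pairs from different spin times collapse onto one curve
    because both quantities depend on time and acceleration only through
    their product."""
    quiet = replace(spec, include_wbc=False)
    frames = []
    for t_c in t_c_list:
        curve = recovery_curve(quiet, t_c)
        frames.append(
            curve[["t_c_min", "a_c_g", "E_plas_mean", "E_PLT_mean"]]
        )
    if not frames:
        return pd.DataFrame(
            columns=["t_c_min", "a_c_g", "E_plas_mean", "E_PLT_mean"]
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class SensitivityBudget:
    """Gain/loss decomposition of dE_PLT/da_c at one spin time.

    gain = ratio * dE_plas/da_c is the rate at which faster spinning
    clears more plasma; loss = |dratio/da_c| * E_plas is the rate at
    which platelets are dragged into the bed.  Their balance marks the
    critical acceleration.
    """

    table: pd.DataFrame
    balance_ac: float | None


def sensitivity_budget(
    spec: SweepSpec, t_c: float, hematocrit: float
) -> SensitivityBudget:
    """Numerical dE_plas/da_c, analytic dratio/da_c and their balance."""
    if spec.acceleration_grid.size < 5:
        raise InvalidParameterError(
            "need at least 5 acceleration points for central differences"
        )
    single = replace(spec, hematocrit_set=(hematocrit,), include_wbc=False)
    curve = recovery_curve(single, t_c)
    a = curve["a_c_g"].to_numpy()
    eplas = curve[f"E_plas_He{hematocrit:g}"].to_numpy()
    ratio = curve["ratio"].to_numpy()

    deplas = np.gradient(eplas, a)
    c = spec.coefficients
    column = spec.column
    u_ref = stokes_settling_velocity(spec.rbc, spec.fluid, spec.gravity)
    pi2 = spec.geometry.capacity / (
        spec.geometry.straight_area * column.fill_height
    )
    pi3 = t_c * u_ref / column.fill_height
    # d(ratio)/da for unit exponents: c1 Pi2 Pi3 ratio(a)
    dratio = c.c1 * pi2 * pi3 * ratio

    gain = ratio * deplas
    loss = np.abs(dratio) * eplas
    diff = gain - loss
    balance = None
    sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
    if sign_change.size:
        k = int(sign_change[0])
        # linear root refinement between grid points k and k+1
        f0, f1 = diff[k], diff[k + 1]
        balance = float(a[k] - f0 * (a[k + 1] - a[k]) / (f1 - f0))
    table = pd.DataFrame(
        {
            "a_c_g": a,
            "E_plas": eplas,
            "ratio": ratio,
            "dEplas_dac": deplas,
            "dratio_dac": dratio,
            "gain_term": gain,
            "loss_term": loss,
        }
    )
    return SensitivityBudget(table=table, balance_ac=balance)


def geometry_crossing(
    flat_curve: pd.DataFrame,
    conical_curve: pd.DataFrame,
    column: str = "E_PLT_mean",
) -> float | None:
    """Acceleration where the flat- and conical-tube curves cross beyond
    both peaks (linearly interpolated); None when they do not cross."""
    a_flat = flat_curve["a_c_g"].to_numpy()
    a_con = conical_curve["a_c_g"].to_numpy()
    if a_flat.size != a_con.size or not np.allclose(a_flat, a_con):
        raise InvalidParameterError("curves must share the acceleration grid")
    y_flat = flat_curve[column].to_numpy()
    y_con = conical_curve[column].to_numpy()
    diff = y_flat - y_con
    if np.all(diff == 0):
        return None
    # the reversal sets in once the earlier of the two maxima is passed
    start = min(int(np.argmax(y_flat)), int(np.argmax(y_con)))
    seg = diff[start:]
    sign_change = np.nonzero((seg[:-1] > 0) & (seg[1:] <= 0))[0]
    if sign_change.size == 0:
        return None
    k = start + int(sign_change[0])
    f0, f1 = diff[k], diff[k + 1]
    if f1 == f0:
        return float(a_flat[k])
    return float(a_flat[k] - f0 * (a_flat[k + 1] - a_flat[k]) / (f1 - f0))


@dataclass
class OptimizationMap:
    """Gridded recoveries over (spin time, acceleration)."""

    t_c_values: np.ndarray  # s
    accelerations: np.ndarray  # g multiples
    e_plt: np.ndarray  # shape (nt, na), hematocrit-averaged
    e_wbc: np.ndarray | None  # same shape, c_w- and He-averaged

    def query(self, t_c: float, acceleration_g: float) -> dict:
        """Bilinear interpolation of the map at one protocol."""
        from scipy.interpolate import RegularGridInterpolator

        pt = np.array([[t_c, acceleration_g]])
        out = {}
        interp = RegularGridInterpolator(
            (self.t_c_values, self.accelerations), self.e_plt
        )
        out["E_PLT"] = float(interp(pt)[0])
        if self.e_wbc is not None:
            interp_w = RegularGridInterpolator(
                (self.t_c_values, self.accelerations), self.e_wbc
            )
            out["E_WBC"] = float(interp_w(pt)[0])
        return out

    def to_frame(self) -> pd.DataFrame:
        nt, na = self.e_plt.shape
        data = {
            "t_c_min": np.repeat(self.t_c_values / 60.0, na),
            "a_c_g": np.tile(self.accelerations, nt),
            "E_PLT_mean": self.e_plt.ravel(),
        }
        if self.e_wbc is not None:
            data["E_WBC_mean"] = self.e_wbc.ravel()
        return pd.DataFrame(data)

    def operating_points(self, target_e_plt: float = 0.8) -> dict:
        """Named protocol suggestions read off the grid.

        time_efficient: shortest spin reaching the target platelet
        recovery (at its best acceleration); integrity_preserving: the
        lowest acceleration reaching it (at its best time); trade_off:
        the feasible point minimising the normalised cost
        a_c/max(a_c) + t_c/max(t_c).  Falls back to the global maximum
        when the target is out of reach.
        """
        feasible = self.e_plt >= target_e_plt
        points = {}

        def pack(it, ia):
            entry = {
                "t_c_min": float(self.t_c_values[it] / 60.0),
                "a_c_g": float(self.accelerations[ia]),
                "E_PLT": float(self.e_plt[it, ia]),
            }
            if self.e_wbc is not None:
                entry["E_WBC"] = float(self.e_wbc[it, ia])
            return entry

        if not feasible.any():
            it, ia = np.unravel_index(np.argmax(self.e_plt), self.e_plt.shape)
            best = pack(int(it), int(ia))
            return {k: best for k in ("time_efficient", "integrity_preserving", "trade_off")}

        it = int(np.nonzero(feasible.any(axis=1))[0][0])
        points["time_efficient"] = pack(it, int(np.argmax(self.e_plt[it])))
        ia = int(np.nonzero(feasible.any(axis=0))[0][0])
        points["integrity_preserving"] = pack(int(np.argmax(self.e_plt[:, ia])), ia)

        tt, aa = np.nonzero(feasible)
        cost = (
            self.t_c_values[tt] / self.t_c_values.max()
            + self.accelerations[aa] / self.accelerations.max()
        )
        k = int(np.argmin(cost))
        points["trade_off"] = pack(int(tt[k]), int(aa[k]))
        return points


def optimization_map(spec: SweepSpec) -> OptimizationMap:
    """Dense (t_c, a_c) recovery map for protocol selection."""
    t_values = np.asarray(
        [t * 60.0 for t in spec.time_grid_min], dtype=float
    )
    na = spec.acceleration_grid.size
    e_plt = np.empty((t_values.size, na))
    e_wbc = np.empty((t_values.size, na)) if spec.include_wbc else None
    for i, t_c in enumerate(t_values):
        curve = recovery_curve(spec, t_c)
        e_plt[i] = curve["E_PLT_mean"].to_numpy()
        if e_wbc is not None:
            e_wbc[i] = curve["E_WBC_mean"].to_numpy()
    return OptimizationMap(
        t_c_values=t_values,
        accelerations=spec.acceleration_grid.copy(),
        e_plt=e_plt,
        e_wbc=e_wbc,
    )


def single_recovery(
    spec: SweepSpec,
    protocol: CentrifugeProtocol,
    hematocrit: float,
    c_w: float | None = None,
) -> RecoveryResult:
    """Full recovery result (E_plas, E_PLT, E_WBC) for one protocol."""
    if c_w is None:
        c_w = float(np.mean(spec.c_w_set))
    single = replace(spec, acceleration_grid=np.array([protocol.acceleration_g]))
    rbc_model = single.rbc_model()
    r_o = spec.geometry.rotor_radius
    t_star = np.array(
        [protocol.acceleration_g * protocol.spin_time * rbc_model.u_inf / r_o]
    )
    i_ns = float(_front_heights(single, hematocrit, rbc_model, t_star)[0])
    column = spec.column
    ifc = InterfaceSet(I_ns=i_ns, I_sd=0.0, time=protocol.spin_time)
    e_plas = plasma_recovery(ifc, column, spec.geometry, hematocrit)
    groups = pi_groups(
        spec.geometry, column, protocol, species=spec.rbc, fluid=spec.fluid
    )
    ratio = platelet_plasma_ratio(groups, spec.coefficients)
    e_plt, clipped = platelet_recovery(e_plas, ratio)

    e_wbc = float("nan")
    i_pw = float("nan")
    if spec.include_wbc:
        wbc_model = single.wbc_model()
        t_star_w = np.array(
            [protocol.acceleration_g * protocol.spin_time * wbc_model.u_inf / r_o]
        )
        # same initial fraction as the red cells; see recovery_curve
        i_pw = float(_front_heights(single, hematocrit, wbc_model, t_star_w)[0])
        wbc_ifc = InterfaceSet(I_ns=i_pw, I_sd=0.0, time=protocol.spin_time)
        e_wbc = wbc_recovery(
            ifc, wbc_ifc, spec.geometry, column, spec.beta_o, c_w
        )

    from .recovery import upper_layer_volume

    return RecoveryResult(
        E_plas=e_plas,
        E_PLT=e_plt,
        E_WBC=e_wbc,
        V_UL=upper_layer_volume(ifc, column, spec.geometry),
        hematocrit=hematocrit,
        c_w=c_w,
        protocol=protocol,
        I_ns=i_ns,
        I_pW=i_pw,
        ratio=ratio,
        plt_clipped=clipped,
    )


def averaged_platelet_recovery(
    spec: SweepSpec, t_c: float, acceleration_g: float
) -> float:
    """Hematocrit-averaged E_PLT at one (spin time, acceleration)."""
    protocol = CentrifugeProtocol(
        acceleration_g=acceleration_g, spin_time=t_c, gravity=spec.gravity
    )
    quiet = replace(spec, include_wbc=False)
    values = [
        single_recovery(quiet, protocol, he).E_PLT for he in spec.hematocrit_set
    ]
    return float(np.mean(values))
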