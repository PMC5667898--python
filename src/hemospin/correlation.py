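"""Dimensional-analysis correlation between platelet and plasma recovery.

Buckingham-Pi reduction of E_PLT = f(A, L, u_inf, U_o, t_c, V_t, E_plas)
yields four dimensionless groups:

    Pi1 = ln(E_PLT / E_plas)      the recovery-rate ratio (natural log)
    Pi2 = V_t / (A L)             tube capacity over blood column volume
    Pi3 = t_c / (L / u_inf)       spin time over the column settling time
    Pi4 = U_o / u_inf = a_c / g   centrifugal over gravitational settling

and the fitted power-law correlation

    Pi1 = c1 Pi2^e2 Pi3^e3 Pi4^e4 + c2,

with default coefficients c1 = -0.0122, c2 = 0.5128 and unit exponents,
equivalently E_PLT / E_plas = 1.67 exp(-0.0122 Pi2 Pi3 Pi4).  The log is
the natural logarithm: exp(0.5128) = 1.670 reproduces the exponential
prefactor exactly, whereas base 10 would give 3.26.

The reference settling velocity u_inf is the red-cell Stokes velocity:
red cells are the dominant dispersed phase, and only their velocity
makes Pi2 Pi3 Pi4 of order 10-100 over clinical protocols, producing
the observed exponential decay of the ratio with acceleration; the
platelet velocity would render the exponent negligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import (
    CentrifugeProtocol,
    FluidPhase,
    InvalidParameterError,
    ParticleSpecies,
    PLASMA,
    RBC,
    stokes_settling_velocity,
)
from .geometry import MixtureColumn, TubeGeometry

#: Exact column schema of the correlation-record CSV interchange format.
RECORD_COLUMNS = [
    "V_t_mL",
    "A_mm2",
    "L_mm",
    "t_c_min",
    "a_c_g",
    "u_inf_m_per_s",
    "ratio",
]


@dataclass(frozen=True)
class PiGroups:
    """The predictor groups of the correlation (pi1 omitted when predicting)."""

    pi2: float
    pi3: float
    pi4: float
    pi1: float | None = None

    def __post_init__(self) -> None:
        if self.pi2 < 1:
            raise InvalidParameterError(
                "pi2 < 1: the blood column exceeds the tube capacity"
            )
        if self.pi3 <= 0 or self.pi4 <= 0:
            raise InvalidParameterError("pi3 and pi4 must be positive")

    @property
    def product(self) -> float:
        return self.pi2 * self.pi3 * self.pi4


@dataclass(frozen=True)
class CorrelationCoefficients:
    """Coefficients of Pi1 = c1 Pi2^e2 Pi3^e3 Pi4^e4 + c2."""

    c1: float = -0.0122
    c2: float = 0.5128
    e2: float = 1.0
    e3: float = 1.0
    e4: float = 1.0

    def __post_init__(self) -> None:
        for v in (self.c1, self.c2, self.e2, self.e3, self.e4):
            if not math.isfinite(v):
                raise InvalidParameterError("coefficients must be finite")


DEFAULT_COEFFICIENTS = CorrelationCoefficients()


@dataclass(frozen=True)
class CorrelationRecord:
    """One observed (condition, recovery-ratio) pair."""

    V_t: float  # m^3
    A: float  # m^2
    L: float  # m
    t_c: float  # s
    acceleration_g: float
    u_inf: float  # m/s
    observed_ratio: float  # E_PLT / E_plas

    def __post_init__(self) -> None:
        if self.observed_ratio <= 0:
            raise InvalidParameterError("observed_ratio must be positive")

    @property
    def pi_product(self) -> float:
        pi2 = self.V_t / (self.A * self.L)
        pi3 = self.t_c * self.u_inf / self.L
        return pi2 * pi3 * self.acceleration_g


def pi_groups(
    geometry: TubeGeometry,
    column: MixtureColumn,
    protocol: CentrifugeProtocol,
    u_inf_ref: float | None = None,
    species: ParticleSpecies = RBC,
    fluid: FluidPhase = PLASMA,
) -> PiGroups:
    """Predictor Pi groups for one protocol.

    ``u_inf_ref`` defaults to the red-cell Stokes velocity in plasma.
    """
    if column.fill_height <= 0:
        raise InvalidParameterError("zero mixture column height")
    if u_inf_ref is None:
        u_inf_ref = stokes_settling_velocity(species, fluid, protocol.gravity)
    return PiGroups(
        pi2=geometry.capacity / (geometry.straight_area * column.fill_height),
        pi3=protocol.spin_time * u_inf_ref / column.fill_height,
        pi4=protocol.acceleration_g,
    )


def platelet_plasma_ratio(
    groups: PiGroups,
    coeffs: CorrelationCoefficients = DEFAULT_COEFFICIENTS,
) -> float:
    """Predicted ratio E_PLT / E_plas = exp(c2) exp(c1 Pi2^e2 Pi3^e3 Pi4^e4)."""
    exponent = (
        coeffs.c1
        * groups.pi2**coeffs.e2
        * groups.pi3**coeffs.e3
        * groups.pi4**coeffs.e4
    )
    return math.exp(coeffs.c2) * math.exp(exponent)


def platelet_recovery(e_plas: float, ratio: float) -> tuple[float, bool]:
    """E_PLT = ratio * E_plas, clipped to at most 1.

    Returns ``(E_PLT, clipped)``; the clip flag records when the nominal
    prediction exceeded total recovery.
    """
    if not 0 <= e_plas <= 1:
        raise InvalidParameterError("E_plas must lie in [0, 1]")
    if ratio <= 0:
        raise InvalidParameterError("ratio must be positive")
    raw = ratio * e_plas
    if raw > 1.0:
        return 1.0, True
    return raw, False


@dataclass
class CorrelationFit:
    """Fitted coefficients with ordinary least-squares diagnostics."""

    coefficients: CorrelationCoefficients
    r_squared: float
    residuals: np.ndarray
    stderr_c1: float = float("nan")
    stderr_c2: float = float("nan")
    n_records: int = 0


class FitError(RuntimeError):
    """The regression design is degenerate."""


def _records_to_arrays(records) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Accept CorrelationRecord iterables or a schema DataFrame."""
    if isinstance(records, pd.DataFrame):
        missing = [c for c in RECORD_COLUMNS if c not in records.columns]
        if missing:
            raise InvalidParameterError(f"missing record columns: {missing}")
        v_t = records["V_t_mL"].to_numpy() * 1e-6
        area = records["A_mm2"].to_numpy() * 1e-6
        length = records["L_mm"].to_numpy() * 1e-3
        t_c = records["t_c_min"].to_numpy() * 60.0
        a_g = records["a_c_g"].to_numpy()
        u_inf = records["u_inf_m_per_s"].to_numpy()
        ratio = records["ratio"].to_numpy()
    else:
        recs = list(records)
        v_t = np.array([r.V_t for r in recs])
        area = np.array([r.A for r in recs])
        length = np.array([r.L for r in recs])
        t_c = np.array([r.t_c for r in recs])
        a_g = np.array([r.acceleration_g for r in recs])
        u_inf = np.array([r.u_inf for r in recs])
        ratio = np.array([r.observed_ratio for r in recs])
    pi2 = v_t / (area * length)
    pi3 = t_c * u_inf / length
    pi4 = a_g
    pi1 = np.log(ratio)
    return pi1, pi2, pi3, pi4


def fit_correlation(records, fix_exponents: bool = True) -> CorrelationFit:
    """Refit the correlation to observed (condition, ratio) records.

    With ``fix_exponents`` (the default) the fit is ordinary least
    squares of Pi1 = ln(ratio) on the product Pi2 Pi3 Pi4, giving the
    slope c1 and intercept c2.  With free exponents a nonlinear least
    squares fits Pi1 = c1 Pi2^e2 Pi3^e3 Pi4^e4 + c2 in log space.
    """
    pi1, pi2, pi3, pi4 = _records_to_arrays(records)
    n = pi1.size
    if fix_exponents:
        if n < 2:
            raise FitError("at least 2 records are needed with fixed exponents")
        x = pi2 * pi3 * pi4
        if np.ptp(x) == 0:
            raise FitError("rank-deficient design: all Pi products identical")
        res = stats.linregress(x, pi1)
        coeffs = CorrelationCoefficients(c1=res.slope, c2=res.intercept)
        fitted = res.slope * x + res.intercept
        residuals = pi1 - fitted
        ss_tot = float(np.sum((pi1 - pi1.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(residuals**2)) / ss_tot
        return CorrelationFit(
            coefficients=coeffs,
            r_squared=r2,
            residuals=residuals,
            stderr_c1=float(res.stderr),
            stderr_c2=float(res.intercept_stderr),
            n_records=n,
        )

    if n < 5:
        raise FitError("at least 5 records are needed with free exponents")

    def model(params):
        c1, c2, e2, e3, e4 = params
        return c1 * pi2**e2 * pi3**e3 * pi4**e4 + c2

    def resid(params):
        return model(params) - pi1

    start = np.array([-0.0122, 0.5128, 1.0, 1.0, 1.0])
    sol = optimize.least_squares(resid, start, method="lm", max_nfev=20000)
    if not sol.success:
        raise FitError(f"nonlinear fit failed: {sol.message}")
    c1, c2, e2, e3, e4 = sol.x
    residuals = -sol.fun
    ss_tot = float(np.sum((pi1 - pi1.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(sol.fun**2)) / ss_tot
    return CorrelationFit(
        coefficients=CorrelationCoefficients(c1=c1, c2=c2, e2=e2, e3=e3, e4=e4),
        r_squared=r2,
        residuals=residuals,
        n_records=n,
    )
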