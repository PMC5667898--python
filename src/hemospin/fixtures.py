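"""Synthetic correlation datasets for testing the regression layer.

The generator emulates the structure of pooled clinical observations:
whole-blood volumes between 3.5 and 9 mL, spin times between 5 and 10
minutes and accelerations between 100g and 1500g in the default 15 mL
tube, with the recovery-rate ratio following the exponential correlation
plus independent Gaussian noise on its logarithm.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import PLASMA, RBC, stokes_settling_velocity
from .correlation import (
    CorrelationCoefficients,
    DEFAULT_COEFFICIENTS,
    RECORD_COLUMNS,
)
from .geometry import TubeGeometry, height_from_volume


def generate_correlation_fixture(
    n: int,
    coeffs: CorrelationCoefficients = DEFAULT_COEFFICIENTS,
    noise_sd: float = 0.0,
    seed: int | None = None,
    geometry: TubeGeometry | None = None,
    volume_range_ml: tuple = (3.5, 9.0),
    time_range_min: tuple = (5.0, 10.0),
    acceleration_range_g: tuple = (100.0, 1500.0),
) -> pd.DataFrame:
    """Draw ``n`` synthetic (condition, recovery-ratio) records.

    Deterministic for a given ``seed``.  With ``noise_sd = 0`` the
    records lie exactly on the correlation line, so a regression must
    recover the generating coefficients to rounding error.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if geometry is None:
        geometry = TubeGeometry.flat()
    rng = np.random.default_rng(seed)
    v_wb = rng.uniform(*volume_range_ml, size=n) * 1e-6
    t_c = rng.uniform(*time_range_min, size=n) * 60.0
    a_g = rng.uniform(*acceleration_range_g, size=n)
    u_inf = stokes_settling_velocity(RBC, PLASMA)

    lengths = np.array([height_from_volume(geometry, v) for v in v_wb])
    pi2 = geometry.capacity / (geometry.straight_area * lengths)
    pi3 = t_c * u_inf / lengths
    product = pi2**coeffs.e2 * pi3**coeffs.e3 * a_g**coeffs.e4
    eps = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
    ratio = np.exp(coeffs.c2 + coeffs.c1 * product + eps)

    return pd.DataFrame(
        {
            "V_t_mL": np.full(n, geometry.capacity * 1e6),
            "A_mm2": np.full(n, geometry.straight_area * 1e6),
            "L_mm": lengths * 1e3,
            "t_c_min": t_c / 60.0,
            "a_c_g": a_g,
            "u_inf_m_per_s": np.full(n, u_inf),
            "ratio": ratio,
        },
        columns=RECORD_COLUMNS,
    )
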