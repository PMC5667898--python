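import numpy as np
import pytest

import hemospin as hs


@pytest.fixture(scope="session")
def plasma():
    return hs.PLASMA


@pytest.fixture(scope="session")
def flat_tube():
    return hs.TubeGeometry.flat()


@pytest.fixture(scope="session")
def conical_tube():
    return hs.TubeGeometry.conical()


@pytest.fixture(scope="session")
def rbc_model():
    return hs.settling_model_for(hs.RBC, hs.PLASMA)


@pytest.fixture(scope="session")
def fig3_field(flat_tube):
    """The demonstration solve: 9 mL in the flat tube, initial fraction
    0.4, packing limit 0.65, spun at 1000 g for 10 minutes."""
    column = hs.MixtureColumn.from_volume(flat_tube, 9e-6)
    model = hs.settling_model_for(hs.RBC, hs.PLASMA, alpha_max=0.65)
    protocol = hs.CentrifugeProtocol(acceleration_g=1000.0, spin_time=600.0)
    return hs.solve_sedimentation(
        0.4,
        hs.RBC,
        hs.PLASMA,
        model,
        flat_tube,
        column,
        protocol,
        output_times=[0.0, 25.0, 100.0, 300.0, 600.0],
    )


def brute_force_interface_flux(alpha_left, alpha_right, r_star, m=5.0,
                               alpha_max=0.8, u_inf=1.0, n_grid=4001):
    """Independent oracle for the monotone interface flux: brute-force
    extremisation of the clamped batch flux over the state interval,
    in the height-above-bottom sign convention (left = nearer the
    bottom, negative = settling toward the bottom)."""

    lo, hi = min(alpha_left, alpha_right), max(alpha_left, alpha_right)
    grid = np.linspace(lo, hi, n_grid)
    vals = np.where(
        grid >= alpha_max - 1e-12, 0.0, grid * (1.0 - grid) ** m
    )
    if alpha_right <= alpha_left:
        extremum = vals.min()
    else:
        extremum = vals.max()
    return -u_inf * r_star * extremum
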