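import numpy as np
import pytest

from fibrilkit import dls, synthgen


@pytest.fixture
def instrument_37c() -> dls.InstrumentConfig:
    """Typical cuvette-DLS configuration at 37 degC (viscosity from water)."""
    return dls.InstrumentConfig(temperature=310.15)


@pytest.fixture
def fig_mass_pairs() -> list[tuple[float, float]]:
    """Printed (R_H nm, M kDa) calibration pairs of the DLS instrument."""
    return [(4.1, 81.5), (4.0, 81.3), (4.1, 84.0), (4.4, 87.0),
            (17.2, 2300.0), (18.9, 2800.0), (13.0, 1200.0), (4.1, 85.7)]


@pytest.fixture
def make_isotherm():
    """Factory for synthetic Hill isotherms on 12 log-spaced concentrations
    in [0.1 K_D, 10 K_D]."""
    def _make(k_d: float, n: float, r_max: float = 100.0,
              noise_sd: float = 0.0, seed: int = 0, n_points: int = 12):
        grid = np.geomspace(0.1 * k_d, 10.0 * k_d, n_points)
        return synthgen.gen_isotherm(
            synthgen.SimSpec("isotherm", {"k_d": k_d, "n": n, "r_max": r_max},
                             grid, noise_sd, seed))
    return _make


@pytest.fixture
def fixture_dir(tmp_path):
    from fibrilkit import pipeline
    pipeline.make_fixtures(tmp_path, seed=0)
    return tmp_path
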