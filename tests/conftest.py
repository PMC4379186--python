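"""Shared fixtures: grids, reference parameters, published ranking data,
and session-scoped forward solves reused across test modules."""

import numpy as np
import pytest

from keradyn import (
    FixedParameters,
    GAConfig,
    SpatialGrid,
    TurnoverParameters,
    build_scenario,
    integrate,
)

# Published model-selection table: (scenario, K, AIC, delta, rank).
# Weights are printed only as 0 (< 1e-12) except scenarios 21 (0.99999)
# and 31 (2.7e-8).
RANKING_TABLE = [
    (1, 3, 2012.996, 510.3519, 13),
    (2, 3, 2019.144, 516.4999, 19),
    (3, 3, 2018.634, 515.9895, 18),
    (4, 3, 2512.249, 1009.604, 36),
    (5, 3, 2283.252, 780.6081, 28),
    (6, 3, 2340.069, 837.4254, 31),
    (7, 5, 2011.436, 508.7923, 11),
    (8, 5, 2011.724, 509.0804, 12),
    (9, 5, 2013.609, 510.9647, 14),
    (10, 5, 2014.842, 512.1975, 15),
    (11, 5, 2015.148, 512.5043, 16),
    (12, 5, 2017.034, 514.3897, 17),
    (13, 3, 1839.930, 337.2861, 7),
    (14, 3, 2479.026, 976.3817, 35),
    (15, 3, 1738.738, 236.0939, 5),
    (16, 3, 2114.919, 612.2750, 23),
    (17, 3, 2458.497, 955.8532, 34),
    (18, 3, 2002.972, 500.3279, 9),
    (19, 5, 1668.771, 166.1274, 3),
    (20, 5, 2387.721, 885.0770, 32),
    (21, 5, 1502.644, 0.0, 1),
    (22, 5, 2073.809, 571.1653, 21),
    (23, 5, 2338.356, 835.7119, 29),
    (24, 5, 1893.875, 391.2309, 8),
    (25, 3, 1703.773, 201.1292, 4),
    (26, 3, 2410.565, 907.9213, 33),
    (27, 3, 2006.784, 504.1403, 10),
    (28, 3, 2067.488, 564.8442, 20),
    (29, 3, 2243.066, 740.4220, 27),
    (30, 3, 2145.639, 642.9953, 26),
    (31, 5, 1537.479, 34.83477, 2),
    (32, 5, 2339.200, 836.5561, 30),
    (33, 5, 2119.447, 616.8033, 24),
    (34, 5, 2074.025, 571.3811, 22),
    (35, 5, 1834.186, 331.5420, 6),
    (36, 5, 2143.595, 640.9505, 25),
]


@pytest.fixture(scope="session")
def grid():
    return SpatialGrid()


@pytest.fixture(scope="session")
def fixed():
    return FixedParameters()


@pytest.fixture(scope="session")
def best_fit_params():
    """Published optimal turnover parameters of the winning scenario
    (constant-speed drift, Michaelis-Menten, constant assembly,
    perinuclear mollified disassembly)."""
    return TurnoverParameters(k_ass=9.3819, k_S=570.73,
                              k_dis=0.9998, k_I=976.07)


@pytest.fixture(scope="session")
def scenario21():
    return build_scenario(21)


@pytest.fixture(scope="session")
def scenario21_traj(scenario21, best_fit_params, grid, fixed):
    """Scenario 21 integrated 24 h -> 48 h at the published optimum, with
    an early snapshot to check stabilization."""
    return integrate(scenario21, best_fit_params, grid=grid, fixed=fixed,
                     output_times=[26.5 * 3600.0])


def reference_params_for(spec):
    """Physically sensible turnover parameters for any scenario kind:
    1e-3 /s levels for linear kinetics (the illustration level used for
    the rate-profile figures), the published optimum for nonlinear."""
    if spec.turnover == "linear":
        return TurnoverParameters(k_ass=1e-3, k_dis=1e-3)
    return TurnoverParameters(k_ass=9.3819, k_S=570.73,
                              k_dis=0.9998, k_I=976.07)


@pytest.fixture(scope="session")
def all_scenario_trajectories(grid, fixed):
    """One full 24 h integration per scenario at reference parameters;
    shared by the conservation/symmetry/positivity tests.

    Starts from a symmetrized 24-h profile: the printed initial-profile
    formula is slightly asymmetric in its 2 um mollification windows, and
    these tests probe properties of the scheme, not of that formula.
    """
    import numpy as np

    from keradyn import KeratinState, initial_state
    from keradyn.solver import SOLUBLE_FRACTION_T0, T0_SECONDS

    I0 = initial_state(grid).I
    I_sym = 0.5 * (I0 + I0[::-1])
    y0 = KeratinState(S=SOLUBLE_FRACTION_T0 * I_sym, I=I_sym,
                      t=T0_SECONDS)
    out = {}
    for idx in range(1, 37):
        spec = build_scenario(idx)
        out[idx] = integrate(spec, reference_params_for(spec),
                             grid=grid, fixed=fixed, y0=y0)
    return out


@pytest.fixture()
def tiny_ga():
    """Small deterministic GA budget for tests (the library default,
    population 60 x 120 generations, is a production setting)."""
    return GAConfig(population=12, generations=8, polish=True,
                    polish_maxfev=250, search_rtol=1e-4, search_atol=1e-4,
                    final_rtol=1e-4, final_atol=1e-4)
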