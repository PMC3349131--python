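"""Shared fixtures.

Heavy multi-pair treatment runs are session-scoped and shared between the
delivery-method tests and the acceptance suite; everything is generated
programmatically at collection time (no stored fixtures).
"""

import warnings

import numpy as np
import pytest

import fustherm as ft

# the 0.4 mm multi-pair grid resolves the smallest lumen with ~1 cell across
# the radius, which rasterize flags; that is the intended working resolution.
warnings.filterwarnings(
    "ignore", message="vessel radius .* resolved by fewer than 2 cells")


@pytest.fixture(scope="session")
def s6_scenario():
    return ft.make_scenario("multi_pair")


@pytest.fixture(scope="session")
def s6_grid(s6_scenario):
    return ft.Grid.for_box(s6_scenario.domain_size, 0.4e-3)


@pytest.fixture(scope="session")
def s6_fields(s6_scenario, s6_grid):
    return ft.rasterize(s6_scenario, s6_grid)


def run_s6_treatment(scenario, grid, kind, p0_w_cm3, seed=None, n_events=56,
                     variable=False):
    plan = ft.make_plan(kind, scenario, p0=p0_w_cm3 * 1e6, seed=seed,
                        n_events=n_events)
    ctrl = ft.DoseController() if variable else None
    tmpl = ft.treatment_source((0.0, 0.0, 0.0), p0_w_cm3)
    return ft.run_treatment(scenario, grid, plan, controller=ctrl,
                            source_template=tmpl)


@pytest.fixture(scope="session")
def s6_full_fixed(s6_scenario, s6_grid):
    """Full 56-event fixed-power (16.5 W/cm^3) treatments, one per kind."""
    return {
        kind: run_s6_treatment(s6_scenario, s6_grid, kind, 16.5, seed=1)
        for kind in ("random", "sequential", "spiral")
    }


@pytest.fixture(scope="session")
def s6_full_variable_random(s6_scenario, s6_grid):
    """Full 56-event dose-capped random treatment (one seed)."""
    return run_s6_treatment(s6_scenario, s6_grid, "random", 16.5, seed=1,
                            variable=True)


@pytest.fixture(scope="session")
def s6_reduced_pairs(s6_scenario, s6_grid):
    """Fixed/variable pairs on a shortened 12-event schedule.

    Random kind over five seeds plus one sequential and one spiral pair;
    used for the power-control uniformity comparison at tractable cost.
    """
    out = {}
    for kind, seeds in (("random", (0, 1, 2, 3, 4)),
                        ("sequential", (None,)), ("spiral", (None,))):
        for seed in seeds:
            fx = run_s6_treatment(s6_scenario, s6_grid, kind, 16.5, seed=seed,
                                  n_events=12)
            var = run_s6_treatment(s6_scenario, s6_grid, kind, 16.5, seed=seed,
                                   n_events=12, variable=True)
            out[(kind, seed)] = (fx, var)
    return out


@pytest.fixture(scope="session")
def pair_comparison():
    """Counterflow pair vs no-vessel 60 s runs on a shared 0.75 mm grid."""
    sc = ft.make_scenario("counterflow_pair")
    grid = ft.Grid.for_box(sc.domain_size, 0.75e-3)
    cfg = ft.SolverConfig(dt=0.1)
    src = ft.single_vessel_source((30e-3, 30e-3, 20e-3))
    with_v = ft.simulate(sc, grid, src, 60.0, cfg)
    without = ft.simulate(ft.no_vessel(sc), grid, src, 60.0, cfg)
    return sc, grid, with_v, without


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
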