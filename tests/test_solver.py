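"""Bioheat stepper: equilibrium, kernels, advection, stability, schemes."""

import numpy as np
import pytest

import fustherm as ft
from fustherm.grid import Grid
from fustherm.materials import MaterialProperties
from fustherm.scenarios import FieldMap, Scenario
from fustherm.solver import Simulation, SolverConfig, build_coefficients


def test_zero_power_equilibrium():
    """Uniform core temperature with all boundaries at 37 is a fixed point."""
    sc = ft.make_scenario("counterflow_pair", domain_size=(20e-3, 20e-3, 20e-3))
    grid = Grid.for_box(sc.domain_size, 1e-3)
    sim = Simulation(sc, grid, SolverConfig(dt=0.2))
    sim.run_for(60.0)
    assert np.abs(sim.T - 37.0).max() < 1e-9
    assert sim.dose.max() == 0.0


def test_explicit_dt_bound_enforced():
    sc = ft.make_scenario("counterflow_pair")
    grid = Grid.for_box(sc.domain_size, 0.5e-3)
    with pytest.raises(ValueError, match="monotone bound"):
        Simulation(sc, grid, SolverConfig(dt=0.5))
    with pytest.raises(ValueError, match="multiple of dt"):
        Simulation(sc, grid, SolverConfig(dt=0.05)).run_for(0.07)


def _bar_scenario(length, spacing):
    """Quasi-1-D insulated tissue bar (single row of cells, h = 0)."""
    return Scenario(domain_size=(length, spacing, spacing),
                    boundary_thickness=np.inf, label="bar")


def test_heat_kernel_1d_point_release():
    """A unit impulse relaxes to the 1-D Gaussian kernel with alpha = k/(rho c)."""
    dx = 0.2e-3
    L = 25.6e-3
    sc = _bar_scenario(L, dx)
    grid = Grid.for_box(sc.domain_size, dx)
    sim = Simulation(sc, grid, SolverConfig(dt=0.05, scheme="implicit"))
    ic = grid.shape[0] // 2
    amp = 100.0
    sim.T[ic, 0, 0] += amp
    sim.run_for(5.0)
    x = grid.axis_coords(0) - grid.axis_coords(0)[ic]
    alpha = MaterialProperties().alpha_t
    assert alpha == pytest.approx(4.5e-7)
    t = 5.0
    exact = 37.0 + amp * dx / np.sqrt(4 * np.pi * alpha * t) * np.exp(
        -x**2 / (4 * alpha * t))
    num = sim.T[:, 0, 0]
    l2 = np.linalg.norm(num - exact) / np.linalg.norm(exact - 37.0)
    assert l2 < 0.02


def test_advection_translates_pulse():
    """Uniform-flow column: a pulse moves at w with upwind smearing and the
    heat content is conserved until it reaches the outlet."""
    n = 200
    shape = (1, 1, n)
    dz = 0.5e-3
    grid = Grid(spacing=(dz, dz, dz), shape=shape)
    mats = MaterialProperties(k_eff=1e-9, k_b=1e-9)
    w0 = 0.005  # Courant w dt/dz = 0.5
    vz = np.full(shape, w0)
    fields = FieldMap(
        grid=grid, materials=mats,
        vessel_id=np.zeros(shape, dtype=np.int16),
        w=np.abs(vz), velocity=(np.zeros(shape), np.zeros(shape), vz),
        k_node=np.full(shape, 1e-9),
        inv_rc=np.full(shape, 1.0 / mats.rc_b),
        inlet_cells=np.array([0]), h_boundary=0.0)
    sc = Scenario(domain_size=tuple(s * d for s, d in zip(shape, grid.spacing)),
                  materials=mats, boundary_thickness=np.inf)
    sim = Simulation(sc, grid, SolverConfig(dt=0.05), fields=fields)
    sim.T[0, 0, 20:40] = 47.0
    excess0 = (sim.T - 37).sum()
    com0 = (np.arange(n) * (sim.T[0, 0] - 37)).sum() / excess0
    t = 2.0
    sim.run_for(t)
    excess = (sim.T - 37).sum()
    com = (np.arange(n) * (sim.T[0, 0] - 37)).sum() / excess
    assert excess == pytest.approx(excess0, rel=1e-6)   # conservation
    assert (com - com0) * dz == pytest.approx(w0 * t, rel=0.05)
    assert sim.T.max() <= 47.0 + 1e-9                   # monotone
    assert sim.T.min() >= 37.0 - 1e-9


def test_discrete_maximum_principle(rng):
    """Without a source, temperatures stay inside the initial/boundary hull."""
    sc = ft.make_scenario("counterflow_pair", domain_size=(24e-3, 24e-3, 24e-3))
    grid = Grid.for_box(sc.domain_size, 1e-3)
    sim = Simulation(sc, grid, SolverConfig(dt=0.2))
    sim.T[...] = 37.0 + 8.0 * rng.random(grid.shape)
    hi = sim.T.max()
    sim.step(100)
    assert sim.T.max() <= hi + 1e-9
    assert sim.T.min() >= 37.0 - 1e-9


def test_explicit_implicit_agreement():
    """The two diffusion schemes converge to the same field."""
    sc = ft.make_scenario("secondary_artery", transverse=30e-3)
    grid = Grid.for_cylinder(15e-3, 40e-3, 0.3e-3)
    src = ft.single_vessel_source((0, 0, 20e-3))
    dt = 0.02
    res = {}
    for scheme in ("explicit", "implicit"):
        r = ft.simulate(sc, grid, src, 10.0, SolverConfig(dt=dt, scheme=scheme))
        res[scheme] = r.state.T
    pe = res["explicit"].max() - 37
    pi = res["implicit"].max() - 37
    assert pi == pytest.approx(pe, rel=0.02)


def test_grid_refinement_convergence():
    """Peak focal rise changes <3% between spacing s and s/2 (axisym)."""
    sc = ft.make_scenario("secondary_artery", transverse=30e-3)
    src = ft.single_vessel_source((0, 0, 20e-3))
    peaks = []
    for sp, dt in ((0.3e-3, 0.02), (0.15e-3, 0.02)):
        grid = Grid.for_cylinder(15e-3, 40e-3, sp)
        r = ft.simulate(sc, grid, src, 20.0,
                        SolverConfig(dt=dt, scheme="implicit"))
        peaks.append(r.state.T.max() - 37)
    assert abs(peaks[1] - peaks[0]) / peaks[1] < 0.03


def test_vanishing_vessel_limit():
    """Shrinking the vessel radius drives the solution toward the
    no-vessel one (even a 0.12 mm lumen on the axis still sips some heat)."""
    src = ft.single_vessel_source((0, 0, 20e-3))
    grid = Grid.for_cylinder(15e-3, 40e-3, 0.1e-3)
    cfg = SolverConfig(dt=0.05, scheme="implicit")
    pn = ft.simulate(ft.no_vessel(ft.make_scenario("secondary_artery")),
                     grid, src, 20.0, cfg).state.T.max() - 37
    diffs = []
    for radius in (0.3e-3, 0.12e-3):
        sc = ft.make_scenario("secondary_artery", radius=radius,
                              transverse=30e-3)
        pv = ft.simulate(sc, grid, src, 20.0, cfg).state.T.max() - 37
        diffs.append(abs(pv - pn) / pn)
    assert diffs[1] < diffs[0]
    assert diffs[1] < 0.12


def test_energy_audit_closes():
    """All per-step energy change is attributable to source, boundary,
    advection and inlet exchange; the interior conduction residual vanishes."""
    sc = ft.make_scenario("counterflow_pair", domain_size=(24e-3, 24e-3, 24e-3))
    grid = Grid.for_box(sc.domain_size, 1e-3)
    sim = Simulation(sc, grid, SolverConfig(dt=0.2))
    sim.set_source(ft.single_vessel_source((12e-3, 12e-3, 12e-3)))
    sim.step(25)  # develop gradients first
    for _ in range(5):
        terms = sim.step_audited()
        assert abs(terms["residual"]) < 0.01 * abs(terms["source"])


def test_probe_linear_field_exact():
    grid = Grid.for_box((10e-3, 10e-3, 10e-3), 1e-3)
    X, Y, Z = grid.cell_centers()
    T = 37.0 + 100.0 * X + 50.0 * Y + 20.0 * Z
    pts = [(3.3e-3, 4.7e-3, 5.1e-3), (5e-3, 5e-3, 5e-3)]
    vals = ft.probe_temperature(T, grid, pts)
    for p, v in zip(pts, vals):
        assert v == pytest.approx(37.0 + 100 * p[0] + 50 * p[1] + 20 * p[2],
                                  rel=1e-9)


def test_determinism():
    sc = ft.make_scenario("counterflow_pair", domain_size=(20e-3, 20e-3, 20e-3))
    grid = Grid.for_box(sc.domain_size, 1e-3)
    src = ft.single_vessel_source((10e-3, 10e-3, 10e-3))
    a = ft.simulate(sc, grid, src, 5.0, SolverConfig(dt=0.1)).state
    b = ft.simulate(sc, grid, src, 5.0, SolverConfig(dt=0.1)).state
    assert np.array_equal(a.T, b.T)
    assert np.array_equal(a.dose, b.dose)


def test_single_vessel_runs_match_expected_pattern():
    """Large artery: low intravascular heating, hot side downstream.
    Secondary artery: lumen heats close to perivascular tissue."""
    src = ft.single_vessel_source((0, 0, 20e-3))
    cfg = SolverConfig(dt=0.025)  # axisym monotone bound is tighter on-axis
    grid = Grid.for_cylinder(15e-3, 40e-3, 0.25e-3)

    big = ft.make_scenario("large_artery", length=40e-3, transverse=30e-3)
    sim = Simulation(big, grid, cfg)
    sim.set_source(src)
    sim.run_for(60.0)
    f = sim.fields
    lum = f.lumen_mask
    lumen_mean = (sim.T - 37)[lum].mean()
    tissue_rise = (sim.T - 37)[~lum].max()
    assert lumen_mean < 0.25 * tissue_rise  # bulk blood stays relatively cool
    # asymmetry: downstream (+z, above focus) half of the lumen is warmer
    k_mid = grid.shape[1] // 2
    up = (sim.T - 37)[lum & (np.arange(grid.shape[1]) >= k_mid)[None, :]].mean()
    down = (sim.T - 37)[lum & (np.arange(grid.shape[1]) < k_mid)[None, :]].mean()
    assert up > 1.5 * down

    small = ft.make_scenario("secondary_artery", transverse=30e-3)
    sim2 = Simulation(small, grid, cfg)
    sim2.set_source(src)
    sim2.run_for(60.0)
    lum2 = sim2.fields.lumen_mask
    lumen_rise2 = (sim2.T - 37)[lum2].max()
    tissue_rise2 = (sim2.T - 37)[~lum2].max()
    assert lumen_rise2 > 0.6 * tissue_rise2  # significant blood heating
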