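"""Pennes bioheat stepping: equilibrium, perfusion limits, linearity."""

import numpy as np
import pytest

import mwablate as mw
from mwablate.bioheat import BioheatParams, BioheatSystem, run_transient, step_temperature
from mwablate.fixtures import (
    make_bioheat_mms_case,
    make_perfusion_ode_case,
    uniform_tissue_grid,
)


@pytest.fixture(scope="module")
def wide_grid():
    """Domain large against the ~5 mm perfusion screening length, so the
    centre behaves like unbounded tissue."""
    return uniform_tissue_grid(r_max=0.06, z_max=0.12, nr=25, nz=49)


@pytest.fixture(scope="module")
def params():
    return BioheatParams()


def cell_field(grid, value):
    return np.full((grid.shape[0] - 1, grid.shape[1] - 1), float(value))


def test_body_temperature_equilibrium(wide_grid, params):
    """With no heating, T = T_b is a fixed point to machine precision."""
    T0 = np.full(wide_grid.shape, params.T_b)
    T1 = step_temperature(wide_grid, T0, 1.0, params, cell_field(wide_grid, 0.0))
    assert np.nanmax(np.abs(T1 - params.T_b)) < 1e-9


def test_uniform_heating_perfusion_balance(wide_grid, params):
    """Steady rise equals Q / (rho_b W_b c_b) far from the boundary."""
    Q = params.perfusion_coefficient  # chosen to give exactly 1 K
    sysm = BioheatSystem(wide_grid, params)
    T = sysm.steady_state(sysm.integrate_source(cell_field(wide_grid, Q)))
    ir = np.argmin(np.abs(wide_grid.r_coords - 0.0))
    iz = np.argmin(np.abs(wide_grid.z_coords - 0.06))
    dT = T.reshape(wide_grid.shape)[ir, iz] - params.T_b
    assert dT == pytest.approx(1.0, rel=5e-3)


def test_conduction_free_ode_limit(wide_grid):
    """With k -> 0 every node follows the scalar perfusion ODE exactly."""
    p = BioheatParams(k_thermal=1e-9)
    Q = 2.0 * p.perfusion_coefficient  # 2 K steady rise
    case = make_perfusion_ode_case(p, Q)
    hist = run_transient(
        wide_grid, p, cell_field(wide_grid, Q), duration=300.0, dt=0.25
    )
    mid = hist.final_field[10, 20]
    assert mid == pytest.approx(float(case.evaluate(300.0)), abs=0.02)
    # rate constant: temperature at one time constant
    tau = 1.0 / case.params["rate_constant"]
    i = np.argmin(np.abs(hist.peak_times - tau))
    assert hist.peak_trace[i] == pytest.approx(
        float(case.evaluate(hist.peak_times[i])), abs=0.02
    )


def test_linearity_and_superposition(params):
    grid = uniform_tissue_grid(nr=13, nz=17)
    rng = np.random.default_rng(7)
    Q1 = rng.uniform(0, 5e4, (12, 16))
    Q2 = rng.uniform(0, 5e4, (12, 16))
    kw = dict(duration=50.0, dt=1.0, store_every=50.0)
    h1 = run_transient(grid, params, Q1, **kw)
    h2 = run_transient(grid, params, Q2, **kw)
    h12 = run_transient(grid, params, Q1 + Q2, **kw)
    lhs = h12.final_field - params.T_b
    rhs = (h1.final_field - params.T_b) + (h2.final_field - params.T_b)
    assert np.allclose(np.nan_to_num(lhs), np.nan_to_num(rhs), rtol=1e-8, atol=1e-10)
    # doubling the source doubles the rise
    h2x = run_transient(grid, params, 2.0 * Q1, **kw)
    assert np.allclose(
        np.nan_to_num(h2x.final_field - params.T_b),
        2.0 * np.nan_to_num(h1.final_field - params.T_b),
        rtol=1e-8,
        atol=1e-10,
    )


def test_discrete_maximum_principle(params):
    """Non-negative heating never drives tissue below body temperature."""
    grid = uniform_tissue_grid(nr=13, nz=17)
    rng = np.random.default_rng(3)
    Q = rng.uniform(0, 1e6, (12, 16))
    hist = run_transient(grid, params, Q, duration=100.0, dt=2.0, store_every=10.0)
    for f in hist.fields:
        assert np.nanmin(f) >= params.T_b - 1e-9


def test_time_step_insensitivity_of_final_peak(coarse_grid, default_domain, port_245, params):
    """Halving dt moves the 600 s peak temperature by far less than 0.1 K."""
    sample = mw.get_properties("inflated", 2.45e9)
    mat = mw.build_material_map(coarse_grid, sample)
    sol = mw.solve_field(mw.assemble_helmholtz(coarse_grid, mat, port_245))
    h1 = run_transient(coarse_grid, params, sol.Q_ext, 600.0, dt=2.0, store_every=600.0)
    h2 = run_transient(coarse_grid, params, sol.Q_ext, 600.0, dt=1.0, store_every=600.0)
    assert abs(h1.T_max_final - h2.T_max_final) < 0.1


def test_per_step_energy_audit(params):
    """Storage change balances conduction + perfusion + source each step."""
    grid = uniform_tissue_grid(nr=17, nz=21)
    rng = np.random.default_rng(11)
    Q = rng.uniform(0, 2e5, (16, 20))
    hist = run_transient(
        grid, params, Q, duration=30.0, dt=1.0, store_every=30.0, audit=True
    )
    assert hist.max_energy_residual < 5e-3


def test_zero_heating_has_zero_saturation_time(wide_grid, params):
    hist = run_transient(
        wide_grid, params, cell_field(wide_grid, 0.0), duration=20.0, dt=2.0
    )
    assert hist.saturation_time == 0.0
    assert hist.T_max_final == pytest.approx(params.T_b, abs=1e-9)


def test_peak_trace_monotone_under_constant_heating(wide_grid, params):
    hist = run_transient(
        wide_grid,
        params,
        cell_field(wide_grid, 5e4),
        duration=60.0,
        dt=2.0,
    )
    assert np.all(np.diff(hist.peak_trace) >= -1e-12)


def test_probe_trace_recorded_every_step(wide_grid, params):
    probe = (0.01, 0.06)
    hist = run_transient(
        wide_grid,
        params,
        cell_field(wide_grid, 1e5),
        duration=20.0,
        dt=1.0,
        probes=[probe],
    )
    assert len(hist.probe_traces[probe]) == len(hist.peak_times) == 21


def test_invalid_inputs_rejected(wide_grid, params):
    with pytest.raises(ValueError):
        run_transient(wide_grid, params, cell_field(wide_grid, 0.0), duration=0.5, dt=1.0)
    with pytest.raises(ValueError):
        step_temperature(wide_grid, np.full(wide_grid.shape, 310.0), -1.0, params,
                         cell_field(wide_grid, 0.0))
    T_bad = np.full(wide_grid.shape, 310.0)
    T_bad[3, 3] = np.inf
    with pytest.raises(FloatingPointError):
        step_temperature(wide_grid, T_bad, 1.0, params, cell_field(wide_grid, 0.0))
    with pytest.raises(ValueError):
        BioheatParams(rho=-1.0)


def test_manufactured_steady_state(params):
    """The discrete operator reproduces a manufactured steady solution and
    improves under refinement."""
    R, L = 0.03, 0.06
    case = make_bioheat_mms_case(params, R, L)
    errs = []
    for n in (13, 25, 49):
        grid = uniform_tissue_grid(R, L, n, 2 * n - 1)
        sysm = BioheatSystem(grid, params)
        rc, zc = np.meshgrid(grid.r_centers, grid.z_centers, indexing="ij")
        S = sysm.integrate_source(case.params["Q_mms"](rc, zc))
        T = sysm.steady_state(S).reshape(grid.shape)
        Rg, Zg = np.meshgrid(grid.r_coords, grid.z_coords, indexing="ij")
        T_ex = case.evaluate(Rg, Zg)
        errs.append(np.linalg.norm(T - T_ex) / np.linalg.norm(T_ex - params.T_b))
    assert errs[-1] < case.tolerance
    order = np.log(errs[0] / errs[-1]) / np.log(4.0)
    assert order >= 1.0
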