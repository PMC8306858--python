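"""Electromagnetic solver: analytic coax limit, power bookkeeping, SAR."""

import numpy as np
import pytest
from scipy.integrate import quad

import mwablate as mw
from mwablate.em import COAX_EPS_R, EMMaterialMap, build_material_map
from mwablate.fixtures import coax_line_grid, make_helmholtz_mms_case, uniform_tissue_grid
from mwablate.geometry import Region


@pytest.fixture(scope="module")
def coax_solution(port_245):
    grid = coax_line_grid(port_245)
    mat = EMMaterialMap(
        eps_r=np.where(
            grid.labels == Region.COAX_DIELECTRIC, port_245.coax_eps_r, 1.0
        ),
        sigma=np.zeros(grid.labels.shape),
        is_conductor=grid.labels == Region.CONDUCTOR,
    )
    sol = mw.solve_field(mw.assemble_helmholtz(grid, mat, port_245))
    return grid, sol


def test_mode_amplitude_closed_form(port_245):
    """C from the power normalization reproduces 10 W when re-integrated."""
    C, Z = port_245.mode_amplitude, port_245.wave_impedance
    P, _ = quad(
        lambda r: 0.5 * (C / r) * (C / (Z * r)) * 2 * np.pi * r,
        port_245.r_in,
        port_245.r_out,
    )
    assert P == pytest.approx(port_245.power_w, rel=1e-12)
    assert C == pytest.approx(
        np.sqrt(
            port_245.power_w * Z / (np.pi * np.log(port_245.r_out / port_245.r_in))
        ),
        rel=1e-14,
    )


def test_matched_coax_reproduces_tem_mode(coax_solution, port_245):
    """On a matched line the solver returns the travelling TEM field."""
    grid, sol = coax_solution
    assert sol.reflected_power / port_245.power_w < 0.01
    r = grid.r_coords
    mask = (r > port_245.r_in * 1.001) & (r < port_245.r_out * 0.999)
    H_exact = port_245.mode_amplitude / (port_245.wave_impedance * r[mask])
    rel = np.abs(np.abs(sol.H_phi[mask, :]) - H_exact[:, None]) / H_exact[:, None]
    assert rel.max() < 0.01
    assert sol.absorbed_power == 0.0  # lossless line


def test_lossless_tissue_absorbs_nothing(coarse_grid, port_245):
    sample = mw.DielectricSample(2.45e9, 20.5, 0.0)
    mat = build_material_map(coarse_grid, sample)
    sol = mw.solve_field(mw.assemble_helmholtz(coarse_grid, mat, port_245))
    assert sol.absorbed_power == 0.0
    prof = mw.compute_sar_profile(sol, coarse_grid, 2.5e-3)
    assert np.all(prof[:, 1] == 0.0)


def test_power_balance_and_refinement(default_domain, port_245):
    """Incident power splits into reflection + absorption + outflow; the
    residual shrinks as the grid is refined."""
    sample = mw.get_properties("inflated", 2.45e9)
    errs = []
    for h, hc in [(0.3e-3, 2.0e-3), (0.1e-3, 0.75e-3)]:
        grid = mw.generate_grid(default_domain, h, hc)
        sol = mw.solve_field(
            mw.assemble_helmholtz(grid, build_material_map(grid, sample), port_245)
        )
        errs.append(sol.power_balance_error())
    assert errs[-1] < 0.05
    assert errs[-1] < errs[0] + 0.01


def test_solution_residual_and_heating_sign(coarse_grid, port_245):
    sample = mw.get_properties("deflated", 2.45e9)
    sol = mw.solve_field(
        mw.assemble_helmholtz(coarse_grid, build_material_map(coarse_grid, sample), port_245)
    )
    assert sol.residual < 1e-10
    assert np.all(sol.Q_ext >= 0.0)
    assert sol.absorbed_power > 0.0
    # SAR is heating density over tissue density, zero outside tissue
    tissue = coarse_grid.labels == Region.TISSUE
    assert np.allclose(sol.SAR[tissue], sol.Q_ext[tissue] / sol.rho_tissue)
    assert np.all(sol.SAR[~tissue] == 0.0)


def test_sar_profile_definition_and_errors(coarse_grid, default_domain, port_245):
    sample = mw.get_properties("inflated", 2.45e9)
    sol = mw.solve_field(
        mw.assemble_helmholtz(coarse_grid, build_material_map(coarse_grid, sample), port_245)
    )
    prof = mw.compute_sar_profile(sol, coarse_grid, 2.5e-3)
    assert prof.shape == (coarse_grid.shape[1], 2)
    ic = np.searchsorted(coarse_grid.r_coords, 2.5e-3) - 1
    # grid-line samples average the two adjacent cells of the probe column
    assert prof[:, 1].max() <= sol.SAR[ic, :].max() + 1e-12
    assert prof[:, 1].max() == pytest.approx(sol.SAR[ic, :].max(), rel=5e-3)
    with pytest.raises(ValueError, match="antenna"):
        mw.compute_sar_profile(sol, coarse_grid, 0.5e-3)
    with pytest.raises(ValueError, match="grid"):
        mw.compute_sar_profile(sol, coarse_grid, 1.0)


def test_zero_measure_port_reported(port_245):
    grid = uniform_tissue_grid()  # no coax cells at the inlet
    mat = build_material_map(grid, mw.DielectricSample(2.45e9, 20.0, 0.5))
    with pytest.raises(ValueError, match="port"):
        mw.assemble_helmholtz(grid, mat, port_245)


def test_manufactured_solution_convergence(port_245):
    """Discrete Helmholtz operator converges to a manufactured field at
    order >= 1."""
    eps_hat = 20.0 - 4.0j
    k0 = port_245.omega / 299792458.0
    R, L = 0.02, 0.04
    case = make_helmholtz_mms_case(eps_hat, k0, R, L)
    errs, hs = [], []
    for n in (17, 33, 65):
        grid = uniform_tissue_grid(R, L, n, 2 * n - 1)
        mat = EMMaterialMap(
            eps_r=np.full(grid.labels.shape, eps_hat.real),
            sigma=np.full(
                grid.labels.shape, -eps_hat.imag * port_245.omega * 8.8541878128e-12
            ),
            is_conductor=np.zeros(grid.labels.shape, dtype=bool),
        )
        sysm = mw.assemble_helmholtz(
            grid,
            mat,
            port_245,
            forcing=case.params["forcing"],
            dirichlet_boundary=case.evaluate,
        )
        sol = mw.solve_field(sysm)
        Rg, Zg = np.meshgrid(grid.r_coords, grid.z_coords, indexing="ij")
        v_ex = case.evaluate(Rg, Zg)
        err = np.linalg.norm(sol.v - v_ex) / np.linalg.norm(v_ex)
        errs.append(err)
        hs.append(R / (n - 1))
    order = np.log(errs[0] / errs[-1]) / np.log(hs[0] / hs[-1])
    assert errs[-1] < case.tolerance
    assert errs[0] > errs[1] > errs[2]
    # asymptotically first order (1/r-weighted fluxes near the axis);
    # the pre-asymptotic observed rate approaches 1 from below
    assert order >= 0.8
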