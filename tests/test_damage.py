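"""Arrhenius damage integral, necrotic fraction and zone morphology."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from mwablate.bioheat import TemperatureHistory
from mwablate.damage import (
    ArrheniusParams,
    DamageField,
    damage_rate,
    integrate_arrhenius,
    necrotic_fraction_curve,
    time_to_threshold,
    zone_morphology,
)
from mwablate.fixtures import make_synthetic_history, uniform_tissue_grid

ARR = ArrheniusParams()


def constant_T_alpha(T, duration, p=ARR):
    """Closed form for a constant-temperature exposure."""
    return p.A * duration * np.exp(-p.delta_E / (p.R_gas * T))


def test_theta_from_alpha_identity():
    f = DamageField(alpha=np.array([0.0, 1.0]), theta_d=np.array([0.0, 0.0]))
    # theta = 1 - exp(-alpha) by definition
    hist = make_synthetic_history("constant", duration=10.0)
    d = integrate_arrhenius(hist)
    assert np.allclose(d.theta_d, -np.expm1(-d.alpha))
    assert -np.expm1(-1.0) == pytest.approx(0.6321, abs=1e-4)


def test_body_temperature_exposure_matches_closed_form():
    """600 s at 37 C: tiny accumulated damage, exact against the closed form."""
    hist = make_synthetic_history("constant", duration=600.0, T_base=310.15)
    d = integrate_arrhenius(hist)
    exact = constant_T_alpha(310.15, 600.0)
    assert d.alpha[0, 0] == pytest.approx(exact, rel=1e-12)
    # far below the ablation-zone threshold
    assert d.theta_d[0, 0] < 0.2


def test_boiling_exposure_matches_closed_form():
    hist = make_synthetic_history("constant", duration=60.0, T_base=373.0, dt=0.5)
    d = integrate_arrhenius(hist)
    assert d.alpha[0, 0] == pytest.approx(constant_T_alpha(373.0, 60.0), rel=1e-10)


def test_piecewise_constant_history_matches_interval_sum():
    """Trapezoid over a piecewise-constant history equals the per-segment
    closed forms when segments are sampled with duplicated breakpoints."""
    segs = [(330.0, 100.0), (360.0, 50.0), (345.0, 200.0)]
    times, temps = [0.0], [segs[0][0]]
    t = 0.0
    for T, L in segs:
        times += [t, t + L]
        temps += [T, T]
        t += L
    times, temps = np.array(times), np.array(temps)
    hist = TemperatureHistory(
        times=times,
        fields=temps[:, None, None],
        peak_times=times,
        peak_trace=temps,
        T_b=310.15,
    )
    d = integrate_arrhenius(hist)
    exact = sum(constant_T_alpha(T, L) for T, L in segs)
    assert d.alpha[0, 0] == pytest.approx(exact, rel=1e-10)


def test_trapezoid_matches_adaptive_quadrature_on_smooth_histories():
    """Dense trapezoid integration agrees with scipy adaptive quadrature."""
    rng = np.random.default_rng(20210713)
    for _ in range(100):
        T0 = rng.uniform(320.0, 350.0)
        amp = rng.uniform(0.0, 15.0)
        period = rng.uniform(40.0, 120.0)
        ramp = rng.uniform(5.0, 15.0)
        dur = 120.0

        def T_of_t(t):
            return T0 + ramp * t / dur + amp * np.sin(2 * np.pi * t / period)

        t = np.arange(0.0, dur + 1e-9, 0.02)
        temps = T_of_t(t)
        hist = TemperatureHistory(
            times=t, fields=temps[:, None, None], peak_times=t, peak_trace=temps,
            T_b=310.15,
        )
        alpha = integrate_arrhenius(hist).alpha[0, 0]
        exact, _ = quad(lambda s: damage_rate(T_of_t(s), ARR), 0, dur, limit=200)
        assert alpha == pytest.approx(exact, rel=1e-6)


def test_necrotic_fraction_curve_monotone_and_bounded():
    hist = make_synthetic_history("ramp-plateau", duration=300.0, T_plateau=373.0)
    curve = necrotic_fraction_curve(hist, probe=(0.0, 0.0))
    assert np.all(np.diff(curve[:, 1]) >= 0)
    assert curve[:, 1].min() >= 0.0 and curve[:, 1].max() <= 1.0
    t99 = time_to_threshold(curve, 0.99)
    assert 0 < t99 < 300.0
    # a cold run never crosses the threshold
    cold = necrotic_fraction_curve(
        make_synthetic_history("constant", duration=100.0), probe=(0.0, 0.0)
    )
    assert np.isnan(time_to_threshold(cold, 0.99))


def test_empty_history_rejected():
    hist = TemperatureHistory(
        times=np.array([]), fields=np.empty((0, 1, 1)),
        peak_times=np.array([]), peak_trace=np.array([]), T_b=310.15,
    )
    with pytest.raises(ValueError):
        integrate_arrhenius(hist)


@pytest.fixture(scope="module")
def ellipse_zone():
    """Synthetic damage field: theta high inside a known (r, z) ellipse."""
    grid = uniform_tissue_grid(r_max=0.02, z_max=0.04, nr=81, nz=161)
    R, Z = np.meshgrid(grid.r_coords, grid.z_coords, indexing="ij")
    a_r, a_z, z0 = 0.006, 0.012, 0.02
    rho2 = (R / a_r) ** 2 + ((Z - z0) / a_z) ** 2
    alpha = 5.0 * np.exp(-rho2)  # theta = 0.632 near rho2 ~ ln(5/1) = 1.6
    theta = -np.expm1(-alpha)
    return grid, DamageField(alpha=alpha, theta_d=theta), (a_r, a_z, z0)


def test_zone_morphology_of_known_ellipse(ellipse_zone):
    grid, field, (a_r, a_z, z0) = ellipse_zone
    area, axial, radial, aspect = zone_morphology(field, grid)
    scale = np.sqrt(np.log(5.0))  # contour alpha = 1
    assert radial == pytest.approx(a_r * scale, rel=0.02)
    assert axial == pytest.approx(2 * a_z * scale, rel=0.02)
    assert aspect == pytest.approx(2 * a_z / a_r, rel=0.03)
    # (r,z)-plane area of the half-ellipse contour
    assert area == pytest.approx(np.pi / 2 * a_r * a_z * scale**2, rel=0.03)


def test_zone_area_monotone_in_threshold(ellipse_zone):
    grid, field, _ = ellipse_zone
    areas = [zone_morphology(field, grid, thr)[0] for thr in np.linspace(0.05, 0.95, 10)]
    assert np.all(np.diff(areas) <= 0)


def test_empty_zone_returns_zeros():
    grid = uniform_tissue_grid(nr=9, nz=9)
    field = DamageField(alpha=np.zeros(grid.shape), theta_d=np.zeros(grid.shape))
    assert zone_morphology(field, grid) == (0.0, 0.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        zone_morphology(field, grid, threshold=1.5)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    T=st.floats(280.0, 400.0),
    duration=st.floats(1.0, 1000.0),
)
def test_constant_exposure_property(T, duration):
    """alpha >= 0 always; theta stays within [0, 1] even for huge alpha."""
    hist = make_synthetic_history("constant", duration=duration, T_base=T, dt=duration / 10)
    d = integrate_arrhenius(hist)
    assert d.alpha.min() >= 0.0
    assert 0.0 <= d.theta_d.min() and d.theta_d.max() <= 1.0
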